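import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracle_utils

from aluedit.pipeline import RunConfig, run_pipeline
from aluedit.simulate import GeneratorConfig, generate_dataset
from aluedit.structure import parse_dot_bracket, classify_substructures


@pytest.fixture(scope="session")
def example_structure():
    """16-mer with two helices, a 2x2 interior loop and a hairpin."""
    pt = parse_dot_bracket("GATCAGCTTAAGCAGC", "((..((....))..))")
    return pt, classify_substructures(pt)


@pytest.fixture(scope="session")
def noise_free_dataset(tmp_path_factory):
    """Small noise-free synthetic dataset (lossless round trip expected)."""
    outdir = tmp_path_factory.mktemp("noise_free")
    cfg = GeneratorConfig.noise_free(seed=11, n_alu_pairs=6)
    return generate_dataset(cfg, outdir)


def make_run_config(dataset, outdir, **params) -> RunConfig:
    return RunConfig(
        mismatch_tsv=str(dataset.mismatch_tsv),
        alu_bed=str(dataset.alu_bed),
        snp_bed=str(dataset.snp_bed),
        genome_fasta=str(dataset.genome_fasta),
        ct_dir=str(dataset.ct_dir),
        outdir=str(outdir),
        **params,
    )


@pytest.fixture(scope="session")
def noise_free_run(noise_free_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("noise_free_out")
    cfg = make_run_config(noise_free_dataset, outdir)
    qc = run_pipeline(cfg)
    return noise_free_dataset, cfg, qc
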