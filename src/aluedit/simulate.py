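"""Seeded synthetic data with a known ground-truth editing model.

The generator emulates the inputs of the real analysis end to end:

* a genome with planted ~280-nt Alu-like repeats occurring as nearby
  sense/antisense pairs (each pair diverged independently from a fixed
  consensus by substitutions and short indels), inter-pair spacing large
  enough that the nearest antisense Alu is always the within-pair partner;
* per-neighborhood fold ensembles: the primary structure is the duplex
  formed by the two Alu copies (base-level alignment of the arms; mismatched
  columns become interior loops, indels become bulges/asymmetric loops),
  plus perturbed suboptimal folds with free energies assigned so Boltzmann
  weights hit configured targets;
* known SNP positions and mismatch-record noise;
* editing events drawn per adenosine from a multiplicative model over
  substructure kind, edge distance (cePos), opposite nucleotide, flanking
  nucleotides, loop symmetry and structural entropy:

      p = baseline(kind) * f(up1) * f(dn1) * f(opNuc) * f(cePos)
          * f(symmetry) * exp(-lambda * H),   clipped to [0, 1].

Edited sites are emitted as A>G mismatch records on simulated RNAs, each
spanning ``rna_span`` consecutive same-strand neighborhoods (long pre-mRNAs
contain several Alu pairs), so that true sites form clusters of >=
``min_cluster`` identical mismatches; the rare RNA whose edit count falls
below the cluster threshold is demoted to unedited in the truth labels (the
editing process is cluster-forming by construction).  Decoy non-A>G
mismatches and SNP-overlapping records are added at configured rates.

Everything is a deterministic function of ``GeneratorConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from aluedit import io
from aluedit.neighborhoods import (
    Neighborhood,
    build_neighborhood,
    extract_sequences,
    find_partner_alu,
    merge_neighborhoods,
    neighborhoods_to_bed,
)
from aluedit.structure import (
    PairingTable,
    classify_substructures,
    contexts_to_frame,
    revcomp,
)
from aluedit.thermo import (
    BODY_TEMPERATURE,
    GAS_CONSTANT,
    BoltzmannEnsemble,
    ensemble_profiles,
)

BASES = "ACGT"

# fixed Alu-like consensus (~60% GC, as for real Alus); any fixed string works
_consensus_rng = np.random.default_rng(280)
ALU_CONSENSUS = "".join(
    _consensus_rng.choice(list(BASES), size=280, p=[0.2, 0.3, 0.3, 0.2])
)

#: per-kind baseline editing probabilities (observed detection-scale rates
#: in large human Alu surveys; these are frequencies, not biochemical rates)
DEFAULT_BASELINE = {
    "bulge": 0.031,
    "hairpin": 0.032,
    "helix": 0.044,
    "interior": 0.091,
    "junction": 0.024,
    "strand": 0.020,
}

#: upstream-neighbour multipliers (T strongly preferred, G avoided)
DEFAULT_UP1 = {"A": 1.11, "C": 1.0, "G": 0.32, "T": 2.2}
#: downstream-neighbour multipliers (G preferred)
DEFAULT_DN1 = {"A": 0.9, "C": 0.9, "G": 1.8, "T": 0.55}
#: opposite-nucleotide multipliers (C, i.e. an A.C mismatch, strongly preferred)
DEFAULT_OPNUC = {"A": 1.0, "C": 3.5, "G": 0.75, "T": 1.0}

#: inter-Alu gap bins (nt) and their weights
DEFAULT_GAP_BINS = ((100, 1000), (1000, 2000), (2000, 3000), (3000, 6800))
DEFAULT_GAP_WEIGHTS = (0.61, 0.22, 0.09, 0.08)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic world; ``seed`` fixes every output byte."""

    seed: int = 0
    n_alu_pairs: int = 40
    alu_length: int = 280
    gap_bins: tuple = DEFAULT_GAP_BINS
    gap_weights: tuple = DEFAULT_GAP_WEIGHTS
    inter_pair_spacer: int = 8000  # > max gap, so partners stay within a pair
    divergence: float = 0.15  # substitutions per site between pair copies
    indel_rate: float = 0.02
    max_indel: int = 3
    # fold ensemble: rich enough that most duplex sites fluctuate, emulating
    # the many suboptimal folds relevant at body temperature
    n_folds: int = 8
    energy_gap_scale: float = 0.5  # kcal/mol, exponential gaps between folds
    fold_weights: tuple | None = None  # explicit Boltzmann weight targets
    temperature: float = BODY_TEMPERATURE
    n_perturb_windows: int = 5
    perturb_window: tuple = (8, 25)
    # editing model
    baseline: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE))
    up1_effect: dict = field(default_factory=lambda: dict(DEFAULT_UP1))
    dn1_effect: dict = field(default_factory=lambda: dict(DEFAULT_DN1))
    opnuc_effect: dict = field(default_factory=lambda: dict(DEFAULT_OPNUC))
    helix_cepos_slope: float = 0.03  # linear gain per bp into the helix
    helix_cepos_cap: int = 10
    interior_cepos_factor: float = 0.2  # interior sites off the loop edge
    symmetric_loop_boost: float = 2.0  # interior loops with asymmetry 0
    entropy_lambda: float = 1.0  # editing suppressed as exp(-lambda * H)
    # noise and detection
    snp_rate: float = 0.001  # SNPs per genome bp
    snp_mismatch_fraction: float = 0.5  # SNPs that also emit a mismatch record
    decoy_rate: float = 2.0  # mean decoy mismatches per RNA
    sensitivity: float = 1.0  # detection probability per edited site
    min_cluster: int = 3
    rna_span: int = 10  # consecutive same-strand neighborhoods per simulated RNA
    brain_fraction: float = 0.5  # tissue_tag mix of the simulated RNAs

    @classmethod
    def noise_free(cls, seed: int = 0, **overrides) -> "GeneratorConfig":
        """Defaults with all record-level noise off (lossless round trip)."""
        return cls(
            seed=seed,
            snp_mismatch_fraction=0.0,
            decoy_rate=0.0,
            sensitivity=1.0,
            **overrides,
        )

    @classmethod
    def isolated_effects(
        cls,
        seed: int = 0,
        up1_t: float = 2.2,
        opnuc_c: float = 3.5,
        entropy_lambda: float = 1.0,
        **overrides,
    ) -> "GeneratorConfig":
        """Conditions for parameter-recovery studies: only the upstream-T,
        opposite-C and entropy effects act, everything else is flat."""
        return cls(
            seed=seed,
            up1_effect={"A": 1.0, "C": 1.0, "G": 1.0, "T": up1_t},
            dn1_effect={b: 1.0 for b in BASES},
            opnuc_effect={"A": 1.0, "C": opnuc_c, "G": 1.0, "T": 1.0},
            helix_cepos_slope=0.0,
            interior_cepos_factor=1.0,
            symmetric_loop_boost=1.0,
            entropy_lambda=entropy_lambda,
            snp_mismatch_fraction=0.0,
            decoy_rate=0.0,
            sensitivity=1.0,
            **overrides,
        )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _mutate(seq: str, rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    """Diverged copy of ``seq``: substitutions plus short indels."""
    out: list[str] = []
    i = 0
    while i < len(seq):
        r = rng.random()
        if r < cfg.indel_rate / 2:  # deletion
            i += int(rng.integers(1, cfg.max_indel + 1))
            continue
        if r < cfg.indel_rate:  # insertion
            out.extend(rng.choice(list(BASES), size=int(rng.integers(1, cfg.max_indel + 1))))
        b = seq[i]
        if rng.random() < cfg.divergence:
            b = BASES[(BASES.index(b) + int(rng.integers(1, 4))) % 4]
        out.append(b)
        i += 1
    return "".join(out)


def _draw_gap(rng: np.random.Generator, cfg: GeneratorConfig) -> int:
    k = rng.choice(len(cfg.gap_bins), p=np.asarray(cfg.gap_weights) / sum(cfg.gap_weights))
    lo, hi = cfg.gap_bins[k]
    return int(rng.integers(lo, hi))


def generate_genome(config: GeneratorConfig, rng: np.random.Generator | None = None):
    """Random genome with planted sense/antisense Alu-like pairs and SNPs.

    Returns ``(genome, alu_bed, snp_bed)`` where ``genome`` is a
    ``{chrom: sequence}`` dict.  Each pair consists of one plus- and one
    minus-strand copy of the consensus, independently diverged; the gap
    between them follows the configured bin distribution.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chrom = "chr1"
    parts: list[str] = []
    alus = []
    cursor = 0

    def emit(seq: str):
        nonlocal cursor
        parts.append(seq)
        cursor += len(seq)

    emit(_random_seq(rng, 300))
    for k in range(config.n_alu_pairs):
        copy1 = _mutate(ALU_CONSENSUS, rng, config)
        copy2 = _mutate(ALU_CONSENSUS, rng, config)
        first_plus = bool(rng.random() < 0.5)
        gap = _draw_gap(rng, config)
        for idx, (copy, plus) in enumerate(
            [(copy1, first_plus), (copy2, not first_plus)]
        ):
            start = cursor
            emit(copy if plus else revcomp(copy))
            alus.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": cursor,
                    "name": f"alu_{k}_{'a' if idx == 0 else 'b'}",
                    "score": 0,
                    "strand": "+" if plus else "-",
                }
            )
            if idx == 0:
                emit(_random_seq(rng, gap))
        emit(_random_seq(rng, config.inter_pair_spacer))
    genome = {chrom: "".join(parts)}
    alu_bed = pd.DataFrame(alus)
    n = len(genome[chrom])
    n_snps = rng.binomial(n, config.snp_rate)
    snp_pos = np.sort(rng.choice(n, size=n_snps, replace=False))
    snp_bed = pd.DataFrame(
        {
            "chrom": chrom,
            "start": snp_pos,
            "end": snp_pos + 1,
            "name": [f"snp_{i}" for i in range(n_snps)],
            "score": 0,
            "strand": "+",
        }
    )
    if config.n_alu_pairs == 0:
        alu_bed = pd.DataFrame(columns=io.BED_COLUMNS)
    return genome, alu_bed, snp_bed


_PAIRABLE = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


def _duplex_pairs(seq: str, arm1: tuple[int, int], arm2: tuple[int, int]) -> dict[int, int]:
    """Base-pair map of the duplex between two arms of one folded sequence.

    ``arm1``/``arm2`` are 0-based half-open spans in ``seq`` with
    ``arm1`` entirely 5' of ``arm2``.  The arms are aligned base-by-base
    (arm1 vs the reverse complement of arm2, global alignment) and aligned
    columns whose bases can pair (Watson-Crick or G.T wobble) become base
    pairs; everything else is left unpaired.  The result is non-crossing by
    construction (alignments are monotone).
    """
    s1 = seq[arm1[0] : arm1[1]]
    s2 = seq[arm2[0] : arm2[1]]
    rc2 = revcomp(s2)
    res = edlib.align(s1, rc2, mode="NW", task="path")
    pairs: dict[int, int] = {}
    i = k = 0  # indices into s1 and rc2
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        count = int(num)
        num = ""
        if ch in "=XM":
            for _ in range(count):
                p1 = arm1[0] + i + 1  # 1-based fold position
                p2 = arm2[0] + (len(s2) - 1 - k) + 1
                if (seq[p1 - 1], seq[p2 - 1]) in _PAIRABLE:
                    pairs[p1] = p2
                    pairs[p2] = p1
                i += 1
                k += 1
        elif ch == "I":  # extra bases in s1
            i += count
        elif ch == "D":  # extra bases in rc2
            k += count
    return pairs


def _perturb(pairs: dict[int, int], rng: np.random.Generator, cfg: GeneratorConfig) -> dict[int, int]:
    """Alternative fold: unpair a few random windows of the duplex."""
    out = dict(pairs)
    paired = sorted(p for p in out if p < out[p])
    if not paired:
        return out
    for _ in range(cfg.n_perturb_windows):
        anchor = paired[int(rng.integers(len(paired)))]
        width = int(rng.integers(cfg.perturb_window[0], cfg.perturb_window[1] + 1))
        for p in range(anchor, anchor + width):
            q = out.pop(p, None)
            if q is not None:
                out.pop(q, None)
    return out


def _fold_energies(
    n_folds: int, n_ground_pairs: int, rng: np.random.Generator, cfg: GeneratorConfig
) -> list[float]:
    if cfg.fold_weights is not None:
        w = np.asarray(cfg.fold_weights, dtype=float)
        if len(w) != n_folds or np.any(w <= 0):
            raise ValueError("fold_weights must be positive and match n_folds")
        w = w / w.sum()
        g0 = -0.5 * max(n_ground_pairs, 1)
        rt = GAS_CONSTANT * cfg.temperature
        return [g0 + rt * float(np.log(w[0] / wk)) for wk in w]
    g = -0.5 * max(n_ground_pairs, 1)
    energies = [g]
    for _ in range(n_folds - 1):
        g += float(rng.exponential(cfg.energy_gap_scale)) + 0.05
        energies.append(g)
    return energies


def generate_fold_ensembles(
    neighborhoods: list[Neighborhood],
    sequences: dict[str, str],
    alu_bed: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> dict[str, BoltzmannEnsemble]:
    """One fold ensemble per neighborhood (keyed by neighborhood name).

    The ground state is the Alu/antisense-Alu duplex; the remaining
    ``n_folds - 1`` structures are perturbations with higher free energies.
    """
    alu_by_name = {a.name: a for a in alu_bed.itertuples()}
    ensembles: dict[str, BoltzmannEnsemble] = {}
    for nb in neighborhoods:
        seq = sequences[nb.header()] if nb.header() in sequences else sequences[nb.name]
        arms = []
        for aid in nb.alu_ids:
            alu = alu_by_name[aid]
            lo = nb.genomic_to_fold(alu.start)
            hi = nb.genomic_to_fold(alu.end - 1)
            lo, hi = min(lo, hi), max(lo, hi)
            arms.append((lo - 1, hi))  # 0-based half-open in fold frame
        if len(arms) != 2:
            raise ValueError(f"neighborhood {nb.name} must contain exactly one Alu pair")
        arms.sort()
        if arms[0][1] + 3 > arms[1][0]:
            raise ValueError(f"neighborhood {nb.name}: arms too close to fold")
        ground = _duplex_pairs(seq, arms[0], arms[1])
        fold_maps = [ground] + [
            _perturb(ground, rng, config) for _ in range(config.n_folds - 1)
        ]
        n_pairs = sum(1 for p in ground if p < ground[p])
        energies = _fold_energies(config.n_folds, n_pairs, rng, config)
        structures = [
            PairingTable(seq, pm, free_energy=e, structure_id=f"{nb.name} fold {k + 1}")
            for k, (pm, e) in enumerate(zip(fold_maps, energies))
        ]
        ensembles[nb.name] = BoltzmannEnsemble(structures, temperature=config.temperature)
    return ensembles


def write_ct(ensemble: BoltzmannEnsemble, path) -> None:
    """Write an ensemble as a multi-record 6-column CT file."""
    with open(path, "w") as fh:
        for pt in ensemble.structures:
            n = len(pt)
            fh.write(f"{n}\tdG = {pt.free_energy:.2f}\t{pt.structure_id}\n")
            for i in range(1, n + 1):
                j = pt.pairs.get(i, 0)
                fh.write(f"{i}\t{pt.sequence[i-1]}\t{i-1}\t{(i+1) % (n+1)}\t{j}\t{i}\n")


def editing_probability(row, cfg: GeneratorConfig) -> float:
    """The multiplicative ground-truth editing model for one site context."""
    p = cfg.baseline[row["kind"]]
    p *= cfg.up1_effect.get(row["up1"], 1.0)
    p *= cfg.dn1_effect.get(row["dn1"], 1.0)
    if row["op_nuc"] in BASES:
        p *= cfg.opnuc_effect.get(row["op_nuc"], 1.0)
    if row["kind"] == "helix":
        p *= 1.0 + cfg.helix_cepos_slope * min(row["ce_pos"], cfg.helix_cepos_cap)
    elif row["kind"] == "interior":
        if row["ce_pos"] > 0:
            p *= cfg.interior_cepos_factor
        if row["asymmetry"] == 0:
            p *= cfg.symmetric_loop_boost
    p *= float(np.exp(-cfg.entropy_lambda * row["entropy"]))
    return float(min(1.0, max(0.0, p)))


def build_all_neighborhoods(alu_bed: pd.DataFrame) -> list[Neighborhood]:
    """Merged neighborhoods for every Alu (one per Alu strand and pair)."""
    nbs = []
    for alu in alu_bed.itertuples():
        partner = find_partner_alu(alu, alu_bed)
        if partner is not None:
            nbs.append(build_neighborhood(alu, partner))
    return merge_neighborhoods(nbs)


def site_truth_table(
    neighborhoods: list[Neighborhood],
    sequences: dict[str, str],
    ensembles: dict[str, BoltzmannEnsemble],
    alu_bed: pd.DataFrame,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Ground-truth context table: one row per Alu-strand adenosine.

    Contexts (kind, cePos, opNuc, neighbours) come from the minimum-energy
    fold; entropy and ground-state kind from the full ensemble.  Each site is
    attributed to the neighborhood matching its Alu's strand.
    """
    alu_by_name = {a.name: a for a in alu_bed.itertuples()}
    frames = []
    for nb in neighborhoods:
        ens = ensembles[nb.name]
        ground = ens.ground_state
        classified = classify_substructures(ground)
        own_alus = [alu_by_name[a] for a in nb.alu_ids if alu_by_name[a].strand == nb.strand]
        positions, gpos = [], []
        seq = ground.sequence
        for alu in own_alus:
            for p in range(alu.start, alu.end):
                fp = nb.genomic_to_fold(p)
                if seq[fp - 1] == "A":
                    positions.append(fp)
                    gpos.append((alu.name, p))
        if not positions:
            continue
        ctx = contexts_to_frame(ground, classified, positions)
        prof = ensemble_profiles(ens, positions)
        ctx = ctx.merge(prof, on="position")
        ctx.insert(0, "neighborhood", nb.name)
        ctx.insert(1, "chrom", nb.chrom)
        ctx.insert(2, "gpos", [g[1] for g in gpos])
        ctx.insert(3, "strand", nb.strand)
        ctx.insert(4, "alu_id", [g[0] for g in gpos])
        frames.append(ctx)
    return pd.concat(frames, ignore_index=True)


def simulate_editing(
    truth: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw editing events and emit mismatch records.

    Returns ``(truth, mismatches)``: ``truth`` gains ``p_edit`` and
    ``edited`` columns; ``mismatches`` is a record table with one simulated
    RNA per neighborhood carrying the detected A>G mismatches in transcript
    order, plus decoy mismatches.  Neighborhood RNAs whose edited-site count
    falls below ``min_cluster`` are demoted to unedited (truth and records).
    """
    if truth.empty:
        raise ValueError("empty site context table")
    truth = truth.copy()
    truth["p_edit"] = [editing_probability(row, config) for _, row in truth.iterrows()]
    truth["edited"] = rng.random(len(truth)) < truth["p_edit"]
    # one simulated RNA covers `rna_span` consecutive same-strand
    # neighborhoods (long pre-mRNAs contain several Alu pairs), so editing
    # clusters form at the transcript level
    nb_order = (
        truth.groupby(["strand", "neighborhood"], sort=False)["gpos"]
        .min()
        .reset_index()
        .sort_values(["strand", "gpos"])
    )
    rna_of_nb = {}
    for strand, g in nb_order.groupby("strand"):
        for i, nb_name in enumerate(g["neighborhood"]):
            rna_of_nb[nb_name] = f"rna_{strand}_{i // config.rna_span}"
    truth["rna_id"] = truth["neighborhood"].map(rna_of_nb)
    # demote RNAs whose edit count cannot form a mismatch cluster
    for _, idx in truth.groupby("rna_id").groups.items():
        n_edit = int(truth.loc[idx, "edited"].sum())
        if 0 < n_edit < config.min_cluster:
            truth.loc[idx, "edited"] = False
    records = []
    for rna_id, g in truth.groupby("rna_id"):
        edited = g[g["edited"]]
        if edited.empty:
            continue
        detected = edited[rng.random(len(edited)) < config.sensitivity]
        strand = g["strand"].iloc[0]
        tissue = "brain" if rng.random() < config.brain_fraction else "non_brain"
        for _, site in detected.iterrows():
            ref, alt = ("A", "G") if strand == "+" else ("T", "C")
            records.append(
                {
                    "rna_id": rna_id,
                    "chrom": site["chrom"],
                    "pos": int(site["gpos"]),
                    "strand": strand,
                    "ref": ref,
                    "alt": alt,
                    "tissue_tag": tissue,
                    # transcript order: 5'->3' on the RNA's strand
                    "_order": site["gpos"] if strand == "+" else -site["gpos"],
                }
            )
        for _ in range(rng.poisson(config.decoy_rate)):
            # decoy mismatch near a random covered site; never the A>G type
            # (in either strand frame), so decoys split but never join runs
            anchor = int(g["gpos"].iloc[int(rng.integers(len(g)))])
            pos = anchor + int(rng.integers(-100, 101))
            ref = BASES[int(rng.integers(4))]
            alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            if (ref, alt) in (("A", "G"), ("T", "C")):
                alt = "C" if ref == "A" else "G"
            records.append(
                {
                    "rna_id": rna_id,
                    "chrom": g["chrom"].iloc[0],
                    "pos": pos,
                    "strand": strand,
                    "ref": ref,
                    "alt": alt,
                    "tissue_tag": tissue,
                    "_order": float(pos) if strand == "+" else -float(pos),
                }
            )
    mismatches = pd.DataFrame(records)
    if not mismatches.empty:
        mismatches = (
            mismatches.sort_values(["rna_id", "_order"], kind="stable")
            .drop(columns="_order")
            .reset_index(drop=True)
        )
    truth = truth.drop(columns="rna_id")
    return truth, mismatches


def emit_snp_mismatches(
    snp_bed: pd.DataFrame,
    genome: dict[str, str],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Mismatch records sitting on known SNPs (to be removed by the filter)."""
    rows = []
    for snp in snp_bed.itertuples():
        if rng.random() >= config.snp_mismatch_fraction:
            continue
        ref = genome[snp.chrom][snp.start]
        if ref not in BASES:
            continue
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        rows.append(
            {
                "rna_id": f"rna_snp_{snp.name}",
                "chrom": snp.chrom,
                "pos": snp.start,
                "strand": "+",
                "ref": ref,
                "alt": alt,
                "tissue_tag": "",
            }
        )
    return pd.DataFrame(rows, columns=io.MISMATCH_COLUMNS)


@dataclass
class SyntheticDataset:
    """Paths and in-memory handles of one generated dataset."""

    outdir: Path
    genome_fasta: Path
    alu_bed: Path
    snp_bed: Path
    mismatch_tsv: Path
    ct_dir: Path
    truth_tsv: Path
    neighborhood_bed: Path
    manifest: Path
    truth: pd.DataFrame


def generate_dataset(config: GeneratorConfig, outdir) -> SyntheticDataset:
    """Generate every pipeline input under ``outdir`` (seed-deterministic)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome, alu_bed, snp_bed = generate_genome(config, rng)

    genome_fasta = outdir / "genome.fa"
    io.write_fasta(genome.items(), genome_fasta)
    io.write_bed(alu_bed, outdir / "alus.bed")
    io.write_bed(snp_bed, outdir / "snps.bed")

    ct_dir = outdir / "folds"
    ct_dir.mkdir(exist_ok=True)
    truth = pd.DataFrame()
    mismatches = pd.DataFrame(columns=io.MISMATCH_COLUMNS)
    nb_bed = pd.DataFrame(columns=io.BED_COLUMNS)
    if len(alu_bed):
        neighborhoods = build_all_neighborhoods(alu_bed)
        seqs = dict(
            (h, s) for h, s in extract_sequences(neighborhoods, str(genome_fasta))
        )
        # key sequences by plain name as well
        sequences = {h.split("|")[0]: s for h, s in seqs.items()} | seqs
        ensembles = generate_fold_ensembles(neighborhoods, sequences, alu_bed, config, rng)
        for nb in neighborhoods:
            write_ct(ensembles[nb.name], ct_dir / f"{nb.name}.ct")
        nb_bed = neighborhoods_to_bed(neighborhoods)
        truth = site_truth_table(neighborhoods, sequences, ensembles, alu_bed, config)
        truth, mismatches = simulate_editing(truth, config, rng)
        snp_noise = emit_snp_mismatches(snp_bed, genome, config, rng)
        if not snp_noise.empty:
            mismatches = pd.concat([mismatches, snp_noise], ignore_index=True)
    io.write_mismatches(mismatches, outdir / "mismatches.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    nb_bed.to_csv(outdir / "neighborhoods.bed", sep="\t", header=False, index=False)
    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps(dataclasses.asdict(config), indent=2, default=list))
    return SyntheticDataset(
        outdir=outdir,
        genome_fasta=genome_fasta,
        alu_bed=outdir / "alus.bed",
        snp_bed=outdir / "snps.bed",
        mismatch_tsv=outdir / "mismatches.tsv",
        ct_dir=ct_dir,
        truth_tsv=outdir / "truth.tsv",
        neighborhood_bed=outdir / "neighborhoods.bed",
        manifest=manifest,
        truth=truth,
    )
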