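"""End-to-end orchestration: site calling -> neighborhoods -> structure
annotation -> context statistics -> ensemble thermodynamics.

``run_pipeline`` consumes a :class:`RunConfig` pointing at a mismatch table,
Alu and SNP BED files, a genome FASTA and a directory of per-neighborhood CT
fold ensembles (named ``<chrom>:<start>-<end>(<strand>).ct``), and writes a
report bundle of TSV tables plus QC metrics.  Given identical inputs the
bundle is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from aluedit import io, sites as sites_mod, stats as stats_mod
from aluedit.neighborhoods import (
    DEFAULT_FLANK,
    DEFAULT_MERGE_OVERLAP,
    Neighborhood,
    build_neighborhood,
    find_partner_alu,
    merge_neighborhoods,
    neighborhoods_to_bed,
)
from aluedit.structure import classify_substructures, contexts_to_frame, parse_ct
from aluedit.thermo import (
    BODY_TEMPERATURE,
    BoltzmannEnsemble,
    ensemble_profiles,
    entropy_profile,
)

logger = logging.getLogger(__name__)

SELECTED_NEIGHBOR_OFFSETS = (-18, -9, -1, 7, 9, 10, 13, 15)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    mismatch_tsv: str
    alu_bed: str
    snp_bed: str
    genome_fasta: str
    ct_dir: str
    outdir: str
    min_cluster: int = 3
    flank: int = DEFAULT_FLANK
    merge_overlap: int = DEFAULT_MERGE_OVERLAP
    temperature: float = BODY_TEMPERATURE
    k_max: int = 30
    min_support: int = 50
    n_entropy_bins: int = 10
    helix_len_cap: int = 30
    loop_len_cap: int = 10
    cepos_cap: int = 15

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _call_sites(cfg: RunConfig):
    records = io.read_mismatches(cfg.mismatch_tsv)
    snps = io.read_bed(cfg.snp_bed)
    alus = io.read_bed(cfg.alu_bed)
    filtered = sites_mod.filter_snps(records, snps)
    in_alu = sites_mod.intersect_alus(filtered, alus)
    if in_alu.empty:
        raise PipelineError("site_calling", "no mismatches inside Alus after SNP filtering")
    e1 = sites_mod.call_editing_clusters(in_alu, min_cluster=cfg.min_cluster)
    if e1.empty:
        raise PipelineError("site_calling", "no mismatch clusters found")
    ag_fraction = float((
        (e1["alu_ref"] == "A") & (e1["alu_alt"] == "G")
    ).mean()) if "alu_ref" in e1.columns else float("nan")
    return e1, alus, ag_fraction


def _build_neighborhoods(e1: pd.DataFrame, alus: pd.DataFrame, cfg: RunConfig):
    edited_ids = set(e1["alu_id"])
    member_ids = set(edited_ids)
    alu_by_name = {a.name: a for a in alus.itertuples()}
    partners = {}
    for aid in sorted(edited_ids):
        partner = find_partner_alu(alu_by_name[aid], alus)
        if partner is not None:
            member_ids.add(partner.name)
            partners[aid] = partner.name
    nbs = []
    for aid in sorted(member_ids):
        partner = find_partner_alu(alu_by_name[aid], alus)
        if partner is None:
            logger.warning("Alu %s has no antisense partner; skipped", aid)
            member_ids.discard(aid)
            continue
        nbs.append(build_neighborhood(alu_by_name[aid], partner, flank=cfg.flank))
    merged = merge_neighborhoods(nbs, min_overlap=cfg.merge_overlap)
    member_bed = alus[alus["name"].isin(member_ids)].reset_index(drop=True)
    return merged, member_bed


def _annotate(
    site_table: pd.DataFrame,
    neighborhoods: list[Neighborhood],
    member_bed: pd.DataFrame,
    cfg: RunConfig,
) -> pd.DataFrame:
    """Attach SiteContext and ensemble-profile columns to every site row."""
    alu_strand = dict(zip(member_bed["name"], member_bed["strand"]))
    frames = []
    for nb in neighborhoods:
        own_ids = [a for a in nb.alu_ids if alu_strand.get(a) == nb.strand]
        if not own_ids:
            continue
        sub = site_table[site_table["alu_id"].isin(own_ids)]
        if sub.empty:
            continue
        ct_path = Path(cfg.ct_dir) / f"{nb.name}.ct"
        if not ct_path.exists():
            raise PipelineError("annotate", f"missing fold ensemble {ct_path}")
        try:
            structures = parse_ct(ct_path)
        except Exception as exc:  # noqa: BLE001 - stage failure must name the record
            raise PipelineError("annotate", f"{ct_path}: {exc}") from exc
        ensemble = BoltzmannEnsemble(structures, temperature=cfg.temperature)
        ground = ensemble.ground_state
        if len(ground) != nb.end - nb.start:
            raise PipelineError(
                "annotate",
                f"{ct_path}: structure length {len(ground)} != neighborhood span "
                f"{nb.end - nb.start}",
            )
        fold_pos = [nb.genomic_to_fold(p) for p in sub["pos"]]
        classified = classify_substructures(ground)
        ctx = contexts_to_frame(ground, classified, fold_pos, k_max=cfg.k_max)
        prof = ensemble_profiles(ensemble, fold_pos)
        ctx = ctx.merge(prof, on="position")
        ctx = ctx.rename(columns={"position": "fold_pos"})
        merged = sub.reset_index(drop=True).join(ctx.reset_index(drop=True))
        merged["neighborhood"] = nb.name
        frames.append(merged)
    if not frames:
        raise PipelineError("annotate", "no site could be annotated")
    out = pd.concat(frames, ignore_index=True)
    out["is_edited"] = out["label"] == "E1"
    return out


def _pooled(series: pd.Series, cap: int) -> pd.Series:
    return series.clip(upper=cap).astype(int)


def _write_stats(annotated: pd.DataFrame, cfg: RunConfig, outdir: Path) -> dict:
    st = annotated
    tables: dict[str, pd.DataFrame] = {}
    tables["substructure_editing_freq"] = stats_mod.frequency_by(st, "kind")
    helix = st[st["kind"] == "helix"].copy()
    interior = st[st["kind"] == "interior"].copy()
    helix["length"] = _pooled(helix["strand_len"], cfg.helix_len_cap)
    interior["length"] = _pooled(interior["strand_len"], cfg.loop_len_cap)
    tables["freq_vs_helix_length"] = stats_mod.frequency_by(helix, "length")
    tables["freq_vs_loop_strand_length"] = stats_mod.frequency_by(interior, "length")
    tables["asymmetry_profile"] = stats_mod.asymmetry_profile(st)
    helix["ce"] = _pooled(helix["ce_pos"], cfg.cepos_cap)
    interior["ce"] = _pooled(interior["ce_pos"], cfg.cepos_cap)
    tables["freq_vs_cepos_helix"] = stats_mod.frequency_by(helix, "ce")
    tables["freq_vs_cepos_interior"] = stats_mod.frequency_by(interior, "ce")
    edge = interior[interior["ce_pos"] == 0]
    if not edge.empty:
        tables["helix_flank_freq"] = stats_mod.frequency_by(edge, "helix_flank")
    for stratum in ("helix", "interior"):
        for feature in ("up1", "dn1", "joint_up_dn"):
            tables[f"enrichment_{feature}_{stratum}"] = stats_mod.enrichment_factors(
                st, feature, stratum=stratum, min_support=cfg.min_support
            )
    tables["joint_context_enrichment_interior"] = stats_mod.enrichment_factors(
        st, "joint_up_dn_op", stratum="interior", min_support=cfg.min_support
    )
    tables["opnuc_freq"] = stats_mod.frequency_by(
        st[st["op_nuc"].isin(list("ACGT"))], "op_nuc"
    )
    tables["neighbor_chi2_helix"] = stats_mod.neighbor_chi2(st, stratum="helix")
    tables["neighbor_chi2_interior"] = stats_mod.neighbor_chi2(st, stratum="interior")
    t5 = []
    for stratum in ("helix", "interior"):
        for off in SELECTED_NEIGHBOR_OFFSETS:
            rows = stats_mod.neighbor_enrichment(st, off, stratum=stratum)
            t5.append(rows)
    tables["selected_neighbor_enrichment"] = pd.concat(t5, ignore_index=True)
    tables["entropy_profile_by_ground_state"] = entropy_profile(st, n_bins=cfg.n_entropy_bins)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    # brain vs non-brain comparison of the downstream-G preference (helix E1)
    report: dict = {}
    e1h = st[(st["kind"] == "helix") & st["is_edited"]]
    brain = e1h[e1h["tissue_tag"] == "brain"]
    nonbrain = e1h[e1h["tissue_tag"] == "non_brain"]
    if len(brain) and len(nonbrain):
        k1, n1 = int((brain["dn1"] == "G").sum()), len(brain)
        k2, n2 = int((nonbrain["dn1"] == "G").sum()), len(nonbrain)
        p = stats_mod.two_proportion_test(k1, n1, k2, n2)
        report["brain_vs_nonbrain_dn1G"] = {
            "brain": [k1, n1],
            "non_brain": [k2, n2],
            "p_value": p,
            "p_bonferroni_4contexts": stats_mod.bonferroni([p], m=4)[0],
        }
    return report


def validate_inputs(cfg: RunConfig) -> list[dict]:
    """Format/consistency diagnostics for the configured inputs (no raising)."""
    issues: list[dict] = []
    for label in ("mismatch_tsv", "alu_bed", "snp_bed", "genome_fasta", "ct_dir"):
        path = Path(getattr(cfg, label))
        if not path.exists():
            issues.append({"kind": "missing_path", "path": str(path), "input": label})
    if issues:
        return issues
    for label in ("alu_bed", "snp_bed"):
        try:
            bed = io.read_bed(getattr(cfg, label))
        except ValueError as exc:
            issues.append({"kind": "coordinate", "input": label, "detail": str(exc)})
            continue
        if (bed["end"] < bed["start"]).any():
            issues.append({"kind": "coordinate", "input": label, "detail": "end < start"})
        if not bed.groupby("chrom")["start"].apply(lambda s: s.is_monotonic_increasing).all():
            issues.append({"kind": "unsorted", "input": label})
    genome = Fasta(str(cfg.genome_fasta))
    try:
        alus = io.read_bed(cfg.alu_bed)
        for alu in alus.itertuples():
            if alu.chrom not in genome or alu.end > len(genome[alu.chrom]):
                issues.append(
                    {"kind": "out_of_bounds", "input": "alu_bed", "detail": alu.name}
                )
    except ValueError:
        pass
    for ct in sorted(Path(cfg.ct_dir).glob("*.ct")):
        try:
            parse_ct(ct)
        except Exception as exc:  # noqa: BLE001 - diagnostics, not control flow
            kind = "pseudoknot" if "crossing" in str(exc) else "ct_parse"
            issues.append({"kind": kind, "input": str(ct), "detail": str(exc)})
    try:
        io.read_mismatches(cfg.mismatch_tsv)
    except ValueError as exc:
        issues.append({"kind": "mismatch_format", "detail": str(exc)})
    return issues


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write the report bundle; returns QC metrics."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    e1, alus, ag_fraction = _call_sites(cfg)
    neighborhoods, member_bed = _build_neighborhoods(e1, alus, cfg)
    neighborhoods_to_bed(neighborhoods).to_csv(
        outdir / "neighborhoods.bed", sep="\t", header=False, index=False
    )
    site_table = sites_mod.assemble_site_sets(e1, member_bed, cfg.genome_fasta)
    if site_table.empty:
        raise PipelineError("assemble", "no adenosines found in member Alus")
    annotated = _annotate(site_table, neighborhoods, member_bed, cfg)
    annotated.to_csv(outdir / "annotated_sites.tsv", sep="\t", index=False)
    report = _write_stats(annotated, cfg, outdir)
    qc = {
        "config_hash": cfg.config_hash(),
        "n_e1": int((annotated["label"] == "E1").sum()),
        "n_e0": int((annotated["label"] == "E0").sum()),
        "overall_editing_fraction": float((annotated["label"] == "E1").mean()),
        "called_ag_fraction": ag_fraction,
        "n_neighborhoods": len(neighborhoods),
        "n_member_alus": len(member_bed),
        **report,
    }
    (outdir / "qc_report.json").write_text(json.dumps(qc, indent=2, sort_keys=True))
    return qc
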