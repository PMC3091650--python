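"""Editing-site calling from RNA-to-genome alignment mismatches.

The calling chain is: remove mismatches overlapping known SNPs, keep only
mismatches inside annotated Alu repeats (re-expressed on the Alu's strand,
so an A-to-G edit seen as T>C on the reference inside a minus-strand Alu
becomes A>G), and call clusters — within one RNA alignment, maximal runs of
identical mismatches with no intervening mismatch of a different type; all
members of runs of at least ``min_cluster`` (default 3) mismatches become
putative editing sites (E1).  The control set E0 consists of all remaining
Alu-strand adenosines inside the analysed Alus.

"Consecutive" is read RNA-locally: adjacency in the ordered mismatch list of
one RNA alignment, with no genomic-distance cap.
"""

from __future__ import annotations

import logging

import pandas as pd
from intervaltree import IntervalTree
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _interval_trees(bed: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, g in bed.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), i) for i, (s, e) in enumerate(zip(g["start"], g["end"])) if e > s
        )
    return trees


def filter_snps(records: pd.DataFrame, snp_bed: pd.DataFrame) -> pd.DataFrame:
    """Drop mismatch records overlapping any known-SNP interval (order kept)."""
    if snp_bed.empty:
        return records.copy()
    if not snp_bed.groupby("chrom")["start"].apply(lambda s: s.is_monotonic_increasing).all():
        logger.warning("SNP BED is not coordinate-sorted; sorting internally")
    trees = _interval_trees(snp_bed)
    keep = [
        not (row.chrom in trees and trees[row.chrom].overlaps_point(row.pos))
        for row in records.itertuples()
    ]
    return records[keep].reset_index(drop=True)


def intersect_alus(records: pd.DataFrame, alu_bed: pd.DataFrame) -> pd.DataFrame:
    """Keep mismatches inside Alus; annotate Alu id/strand; re-express on Alu strand.

    A record covered by two overlapping Alus is assigned to the Alu with the
    smaller start (logged).  The re-expressed mismatch (``alu_ref`` >
    ``alu_alt``) is the complement of the reference-frame mismatch for
    minus-strand Alus.
    """
    alu_rows = alu_bed.reset_index(drop=True)
    trees: dict[str, IntervalTree] = {}
    for i, alu in enumerate(alu_rows.itertuples()):
        if alu.end > alu.start:
            trees.setdefault(alu.chrom, IntervalTree()).addi(alu.start, alu.end, i)
    names = alu_rows["name"].tolist()
    strands = alu_rows["strand"].tolist()
    kept = []
    for row in records.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        hits = sorted(tree[row.pos], key=lambda iv: iv.begin)
        if not hits:
            continue
        if len(hits) > 1:
            logger.info(
                "mismatch %s:%d inside %d overlapping Alus; assigned to smallest start",
                row.chrom, row.pos, len(hits),
            )
        i = hits[0].data
        flip = strands[i] == "-"
        kept.append(
            {
                **row._asdict(),
                "alu_id": names[i],
                "alu_strand": strands[i],
                "alu_ref": _COMPLEMENT[row.ref] if flip else row.ref,
                "alu_alt": _COMPLEMENT[row.alt] if flip else row.alt,
            }
        )
    out = pd.DataFrame(kept)
    if not out.empty:
        out = out.drop(columns=["Index"], errors="ignore")
    return out


def call_editing_clusters(records: pd.DataFrame, min_cluster: int = 3) -> pd.DataFrame:
    """Call putative editing (E1) positions from mismatch clusters.

    Within each RNA alignment (rows grouped by ``rna_id`` in transcript
    order), maximal runs of mismatches of one type — with no intervening
    mismatch of a different type — are clusters; every member of a cluster of
    size >= ``min_cluster`` becomes an E1 position.  Positions from different
    RNAs are unioned by genomic coordinate.
    """
    if records.empty:
        return pd.DataFrame(columns=["chrom", "pos"])
    called = []
    for _, rna in records.groupby("rna_id", sort=False):
        rows = list(rna.itertuples())
        run: list = []
        run_type = None
        for row in rows + [None]:
            mtype = (row.ref, row.alt) if row is not None else None
            if mtype != run_type:
                if run_type is not None and len(run) >= min_cluster:
                    called.extend(run)
                run, run_type = [], mtype
            if row is not None:
                run.append(row)
    if not called:
        return pd.DataFrame(columns=["chrom", "pos"])
    df = pd.DataFrame([r._asdict() for r in called]).drop(columns=["Index"], errors="ignore")
    # union by genomic coordinate; keep the first supporting record's annotation
    df = df.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)
    return df


def assemble_site_sets(
    e1_positions: pd.DataFrame, alu_bed: pd.DataFrame, genome_fasta
) -> pd.DataFrame:
    """Emit every Alu-strand adenosine of the given Alus, labelled E1 or E0.

    ``genome_fasta`` is a path or a :class:`pyfaidx.Fasta`.  An E1 call whose
    reference base is not A on its Alu's strand (a likely alignment artifact)
    is excluded with a warning.  Adenosines outside the given Alus do not
    enter the table.
    """
    genome = genome_fasta if isinstance(genome_fasta, Fasta) else Fasta(str(genome_fasta))
    e1_keys = set(zip(e1_positions["chrom"], e1_positions["pos"])) if len(e1_positions) else set()
    tags = {}
    if "tissue_tag" in e1_positions.columns:
        tags = {
            (c, p): t
            for c, p, t in zip(
                e1_positions["chrom"], e1_positions["pos"], e1_positions["tissue_tag"]
            )
        }
    rows = []
    seen_e1 = set()
    for alu in alu_bed.itertuples():
        seq = str(genome[alu.chrom][alu.start : alu.end]).upper()
        target = "A" if alu.strand == "+" else "T"  # genome base that is A on the Alu strand
        for off, base in enumerate(seq):
            if base != target:
                continue
            pos = alu.start + off
            key = (alu.chrom, pos)
            is_e1 = key in e1_keys
            if is_e1:
                seen_e1.add(key)
            rows.append(
                {
                    "chrom": alu.chrom,
                    "pos": pos,
                    "strand": alu.strand,
                    "alu_id": alu.name,
                    "label": "E1" if is_e1 else "E0",
                    "tissue_tag": tags.get(key, "") if is_e1 else "",
                }
            )
    dropped = e1_keys - seen_e1
    for chrom, pos in sorted(dropped):
        logger.warning(
            "E1 call at %s:%d is not an Alu-strand adenosine in the given Alus; dropped",
            chrom, pos,
        )
    return pd.DataFrame(rows)
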