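"""Construction of the dsRNA-forming genomic neighborhoods.

For each Alu carrying editing sites, the nearest oppositely-oriented Alu on
the same chromosome is located (edge-to-edge gap, ties broken toward the
downstream candidate), and the neighborhood spans both Alus plus 200 nt of
flank on each side.  Neighborhoods overlapping by more than 400 bp on the
same strand are merged transitively.  The neighborhood strand is the edited
Alu's strand, and all structure coordinates downstream are expressed on that
strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from pyfaidx import Fasta

from aluedit.structure import revcomp

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 200
DEFAULT_MERGE_OVERLAP = 400


@dataclass
class Neighborhood:
    """A genomic window to be folded: Alu pair span plus flanks.

    Coordinates 0-based half-open; ``strand`` is the edited Alu's strand.
    """

    chrom: str
    start: int
    end: int
    strand: str
    alu_ids: list[str] = field(default_factory=list)

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"

    def header(self) -> str:
        return f"{self.name}|{','.join(self.alu_ids)}"

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def genomic_to_fold(self, pos: int) -> int:
        """Map a genomic position to a 1-based position in the folded strand."""
        if not (self.start <= pos < self.end):
            raise IndexError(f"{pos} outside {self.name}")
        return pos - self.start + 1 if self.strand == "+" else self.end - pos

    def fold_to_genomic(self, fold_pos: int) -> int:
        if not (1 <= fold_pos <= self.end - self.start):
            raise IndexError(f"fold position {fold_pos} outside {self.name}")
        return self.start + fold_pos - 1 if self.strand == "+" else self.end - fold_pos


def parse_neighborhood_header(header: str) -> Neighborhood:
    loc, _, ids = header.partition("|")
    chrom, _, rest = loc.rpartition(":")
    span, strand = rest[:-1].split("("), rest[-2]
    start, end = span[0].split("-")
    return Neighborhood(chrom, int(start), int(end), strand,
                        ids.split(",") if ids else [])


def find_partner_alu(alu, alu_bed: pd.DataFrame):
    """Nearest opposite-strand Alu on the same chromosome (edge-to-edge gap).

    Ties are broken toward the downstream candidate.  Returns the partner row
    (named tuple) or ``None`` (logged) when the chromosome has no antisense
    Alu.
    """
    want = "-" if alu.strand == "+" else "+"
    cands = alu_bed[(alu_bed["chrom"] == alu.chrom) & (alu_bed["strand"] == want)]
    if cands.empty:
        logger.warning("no antisense Alu for %s on %s; neighborhood skipped", alu.name, alu.chrom)
        return None
    best = None
    best_key = None
    for cand in cands.itertuples():
        gap = max(cand.start - alu.end, alu.start - cand.end, 0)
        downstream = cand.start >= alu.start
        key = (gap, 0 if downstream else 1, cand.start)
        if best_key is None or key < best_key:
            best, best_key = cand, key
    return best


def build_neighborhood(
    alu, partner, flank: int = DEFAULT_FLANK, chrom_length: int | None = None
) -> Neighborhood:
    """Interval [min(starts) - flank, max(ends) + flank), clipped to the contig."""
    start = min(alu.start, partner.start) - flank
    end = max(alu.end, partner.end) + flank
    if start < 0:
        logger.info("neighborhood of %s clipped at contig start", alu.name)
        start = 0
    if chrom_length is not None and end > chrom_length:
        logger.info("neighborhood of %s clipped at contig end", alu.name)
        end = chrom_length
    return Neighborhood(alu.chrom, start, end, alu.strand, [alu.name, partner.name])


def merge_neighborhoods(
    neighborhoods: list[Neighborhood], min_overlap: int = DEFAULT_MERGE_OVERLAP
) -> list[Neighborhood]:
    """Merge neighborhoods overlapping by more than ``min_overlap`` bp on the
    same strand (transitive closure; strict inequality), replacing each class
    with its spanning interval and unioning the Alu member lists.  The result
    is independent of input order."""
    merged: list[Neighborhood] = []
    by_key: dict[tuple[str, str], list[Neighborhood]] = {}
    for nb in neighborhoods:
        by_key.setdefault((nb.chrom, nb.strand), []).append(nb)
    for (chrom, strand), group in sorted(by_key.items()):
        group = sorted(group, key=lambda nb: (nb.start, nb.end))
        current: Neighborhood | None = None
        for nb in group:
            if current is not None and min(current.end, nb.end) - nb.start > min_overlap:
                current.end = max(current.end, nb.end)
                current.alu_ids = sorted(set(current.alu_ids) | set(nb.alu_ids))
            else:
                current = Neighborhood(chrom, nb.start, nb.end, strand, sorted(set(nb.alu_ids)))
                merged.append(current)
    return merged


def extract_sequences(neighborhoods: list[Neighborhood], genome_fasta) -> list[tuple[str, str]]:
    """(header, sequence) per neighborhood, on the edited Alu's strand.

    Headers carry the genomic coordinate map: ``chrom:start-end(strand)|alu_ids``.
    """
    genome = genome_fasta if isinstance(genome_fasta, Fasta) else Fasta(str(genome_fasta))
    out = []
    for nb in neighborhoods:
        chrom_len = len(genome[nb.chrom])
        if nb.end > chrom_len:
            raise ValueError(f"neighborhood {nb.name} extends beyond contig end ({chrom_len})")
        seq = str(genome[nb.chrom][nb.start : nb.end]).upper()
        if nb.strand == "-":
            seq = revcomp(seq)
        out.append((nb.header(), seq))
    return out


def neighborhoods_to_bed(neighborhoods: list[Neighborhood]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": nb.chrom,
                "start": nb.start,
                "end": nb.end,
                "name": ",".join(nb.alu_ids),
                "score": 0,
                "strand": nb.strand,
            }
            for nb in neighborhoods
        ]
    )
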