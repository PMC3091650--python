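"""RNA secondary-structure parsing and per-nucleotide micro-classification.

A predicted secondary structure is held as a :class:`PairingTable` — the
sequence plus a partial, symmetric, non-crossing base-pair map.  Every
nucleotide is assigned to exactly one of six substructure kinds:

====================  =========================================================
``helix``             maximal stack of base pairs (i,j),(i+1,j-1),...
``interior``          loop closed by two helices with unpaired nucleotides on
                      both strands
``bulge``             loop closed by two helices, unpaired on one strand only
``hairpin``           loop closed by a single helix
``junction``          multibranch loop (three or more closing helices)
``strand``            exterior single strand (enclosed by no pair), including
                      dangling ends
====================  =========================================================

Loop elements contain *only* the unpaired nucleotides forming their
constituent strands; the closing base pairs belong to their helices.  The
partition property (each position in exactly one element) is the backbone of
all downstream site statistics.

Coordinates are 1-based within a structure record, matching the CT
convention.  Sequences are normalised to the DNA alphabet on ingest
(U -> T); G.T (G.U) wobble pairs are accepted as helix pairs.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

KINDS = ("helix", "interior", "bulge", "hairpin", "junction", "strand")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class StructureError(ValueError):
    """Base class for structure ingestion/validation failures."""


class CTParseError(StructureError):
    """Malformed CT (connectivity table) input."""


class IntegrityError(StructureError):
    """Base-pair map is not a symmetric partial involution."""


class PseudoknotError(StructureError):
    """Crossing base pairs (pseudoknot); not representable here."""


def _normalize_sequence(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _validate_pairs(sequence: str, pairs: dict[int, int]) -> None:
    n = len(sequence)
    for i, j in pairs.items():
        if not (1 <= i <= n and 1 <= j <= n):
            raise IntegrityError(f"pair position out of range: {i}<->{j} (n={n})")
        if i == j:
            raise IntegrityError(f"position {i} pairs with itself")
        if pairs.get(j) != i:
            raise IntegrityError(f"asymmetric pairing: {i}->{j} but {j}->{pairs.get(j)}")
    # non-crossing check: scan left to right with a stack of expected closers
    stack: list[int] = []
    for i in range(1, n + 1):
        j = pairs.get(i)
        if j is None:
            continue
        if j > i:
            stack.append(j)
        else:
            if not stack or stack[-1] != i:
                raise PseudoknotError(f"crossing pairs at position {i}")
            stack.pop()
    if stack:  # unreachable with a symmetric map, kept as a guard
        raise IntegrityError("unclosed pairs after scan")


@dataclass
class PairingTable:
    """One secondary structure: sequence, base-pair map and free energy.

    ``pairs`` maps 1-based position -> 1-based partner and is required to be
    symmetric, self-pair-free and non-crossing (validated on construction).
    ``free_energy`` is the fold's Gibbs free energy in kcal/mol; ``None`` for
    single-structure inputs without an energy annotation.
    """

    sequence: str
    pairs: dict[int, int] = field(default_factory=dict)
    free_energy: float | None = None
    structure_id: str = "structure_1"

    def __post_init__(self) -> None:
        self.sequence = _normalize_sequence(self.sequence)
        _validate_pairs(self.sequence, self.pairs)

    def __len__(self) -> int:
        return len(self.sequence)

    def partner(self, position: int) -> int | None:
        return self.pairs.get(position)


@dataclass(frozen=True)
class StructuralElement:
    """One substructure element of the six-way partition.

    For ``helix`` elements ``strands`` holds the ordered stacked pairs
    ``((i1,j1),(i2,j2),...)`` with i ascending; ``size`` is the number of
    stacked base pairs.  For loop kinds ``strands`` holds the maximal
    contiguous unpaired runs as ``(start, end)`` inclusive spans, and
    ``size`` counts the member nucleotides.
    """

    kind: str
    element_id: int
    members: tuple[int, ...]
    strands: tuple[tuple[int, int], ...]
    size: int

    @property
    def strand_lengths(self) -> tuple[int, ...]:
        if self.kind == "helix":
            return (self.size,)
        return tuple(e - s + 1 for s, e in self.strands)


class ClassifiedStructure(Sequence):
    """Element partition of a structure plus a per-position index.

    Behaves as a sequence of :class:`StructuralElement`; ``element_of(pos)``
    returns the element containing a 1-based position, and ``kind_of`` gives
    the per-position kind vector used for ensemble averaging.
    """

    def __init__(self, pt: PairingTable, elements: list[StructuralElement]):
        self.pairing_table = pt
        self.elements = elements
        n = len(pt)
        self._elem_of: list[int | None] = [None] * (n + 1)
        # helix: position -> stacked-pair index; loop: position -> strand index
        self._within: list[int] = [0] * (n + 1)
        for e in elements:
            if e.kind == "helix":
                for m, (i, j) in enumerate(e.strands):
                    self._elem_of[i] = e.element_id
                    self._elem_of[j] = e.element_id
                    self._within[i] = m
                    self._within[j] = m
            else:
                for si, (s, t) in enumerate(e.strands):
                    for p in range(s, t + 1):
                        self._elem_of[p] = e.element_id
                        self._within[p] = si

    def __getitem__(self, i):
        return self.elements[i]

    def __len__(self) -> int:
        return len(self.elements)

    def element_of(self, position: int) -> StructuralElement:
        eid = self._elem_of[position]
        if eid is None:
            raise IndexError(f"position {position} out of range 1..{len(self.pairing_table)}")
        return self.elements[eid]

    def stack_index_of(self, position: int) -> int:
        return self._within[position]

    def strand_index_of(self, position: int) -> int:
        return self._within[position]

    @property
    def kind_of(self) -> list[str | None]:
        """1-based position -> kind (index 0 unused)."""
        out: list[str | None] = [None] * (len(self.pairing_table) + 1)
        for p in range(1, len(self.pairing_table) + 1):
            eid = self._elem_of[p]
            out[p] = self.elements[eid].kind if eid is not None else None
        return out


# ---------------------------------------------------------------------------
# parsing


_ENERGY_RE = re.compile(r"(?:dG|DG|ENERGY|Energy)\s*=\s*(-?\d+(?:\.\d+)?)")


def parse_ct(source) -> list[PairingTable]:
    """Parse one or more records from a 6-column CT (connectivity table) file.

    ``source`` may be a path, a text stream, or the file content itself.
    Each record starts with a header line ``<length> ... dG = <x> ...``;
    the energy annotation is optional.  Raises :class:`CTParseError` on
    malformed lines, :class:`IntegrityError` on asymmetric pairing and
    :class:`PseudoknotError` on crossing pairs.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    lines = text.splitlines()
    records: list[PairingTable] = []
    ln = 0
    rec_no = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        header = lines[ln]
        try:
            n = int(header.split()[0])
        except (ValueError, IndexError):
            raise CTParseError(f"line {ln + 1}: expected record header with length, got {header!r}")
        m = _ENERGY_RE.search(header)
        energy = float(m.group(1)) if m else None
        name_part = header[m.end():].strip() if m else " ".join(header.split()[1:])
        rec_no += 1
        structure_id = name_part or f"structure_{rec_no}"
        bases: list[str] = []
        pairs: dict[int, int] = {}
        for k in range(1, n + 1):
            ln_k = ln + k
            if ln_k >= len(lines):
                raise CTParseError(f"line {ln_k + 1}: truncated record (expected {n} lines)")
            cols = lines[ln_k].split()
            if len(cols) < 6:
                raise CTParseError(
                    f"line {ln_k + 1}: expected >= 6 columns, got {len(cols)}"
                )
            try:
                idx = int(cols[0])
                pair = int(cols[4])
            except ValueError:
                raise CTParseError(f"line {ln_k + 1}: non-integer index or pair column")
            if idx != k:
                raise CTParseError(f"line {ln_k + 1}: index {idx} out of order (expected {k})")
            bases.append(cols[1])
            if pair != 0:
                pairs[idx] = pair
        for i, j in pairs.items():
            if pairs.get(j) != i:
                raise IntegrityError(
                    f"record {structure_id}: position {i} pairs with {j} "
                    f"but {j} pairs with {pairs.get(j, 0)}"
                )
        records.append(
            PairingTable("".join(bases), pairs, free_energy=energy, structure_id=structure_id)
        )
        ln += n + 1
    if not records:
        raise CTParseError("no CT records found")
    return records


def parse_dot_bracket(
    sequence: str, db_string: str, energy: float | None = None, structure_id: str = "structure_1"
) -> PairingTable:
    """Build a :class:`PairingTable` from Vienna-style dot-bracket notation."""
    if len(sequence) != len(db_string):
        raise StructureError(
            f"length mismatch: sequence {len(sequence)} vs structure {len(db_string)}"
        )
    pairs: dict[int, int] = {}
    stack: list[int] = []
    for pos, ch in enumerate(db_string, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            i = stack.pop()
            pairs[i] = pos
            pairs[pos] = i
        elif ch != ".":
            raise StructureError(f"unexpected character {ch!r} at position {pos}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return PairingTable(sequence, pairs, free_energy=energy, structure_id=structure_id)


def to_dot_bracket(pt: PairingTable) -> str:
    out = ["."] * len(pt)
    for i, j in pt.pairs.items():
        out[i - 1] = "(" if i < j else ")"
    return "".join(out)


# ---------------------------------------------------------------------------
# classification


def classify_substructures(pt: PairingTable) -> ClassifiedStructure:
    """Partition every nucleotide of ``pt`` into the six substructure kinds.

    Helices are maximal stacks of pairs.  Each closing pair's accessible face
    is examined: one closing pair -> hairpin; two closing pairs -> interior
    loop (unpaired on both strands) or bulge (one strand); three or more ->
    junction.  Unpaired nucleotides enclosed by no pair form exterior
    ``strand`` elements (one per maximal run).
    """
    n = len(pt)
    pairs = pt.pairs
    elements: list[StructuralElement] = []

    def add(kind: str, members: tuple[int, ...], strands: tuple[tuple[int, int], ...], size: int):
        elements.append(StructuralElement(kind, len(elements), members, strands, size))

    # helices: walk maximal stacks
    for i in range(1, n + 1):
        j = pairs.get(i)
        if j is None or j < i:
            continue
        if pairs.get(i - 1) == j + 1:  # continuation of a stack
            continue
        stack: list[tuple[int, int]] = []
        a, b = i, j
        while a < b and pairs.get(a) == b:
            stack.append((a, b))
            a, b = a + 1, b - 1
        members = tuple(p for ij in stack for p in ij)
        add("helix", members, tuple(stack), len(stack))

    def face(lo: int, hi: int) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """Children pairs and unpaired runs directly accessible in (lo, hi)."""
        children: list[tuple[int, int]] = []
        runs: list[tuple[int, int]] = []
        k = lo + 1
        run_start = None
        while k < hi:
            j = pairs.get(k)
            if j is not None:
                if run_start is not None:
                    runs.append((run_start, k - 1))
                    run_start = None
                children.append((k, j))
                k = j + 1
            else:
                if run_start is None:
                    run_start = k
                k += 1
        if run_start is not None:
            runs.append((run_start, hi - 1))
        return children, runs

    # loops: the face of every closing pair that is not pure stacking
    for i in range(1, n + 1):
        j = pairs.get(i)
        if j is None or j < i:
            continue
        children, runs = face(i, j)
        if not runs and len(children) == 1:
            continue  # helix stacking, no loop
        n_close = 1 + len(children)
        members = tuple(p for s, e in runs for p in range(s, e + 1))
        if n_close == 1:
            add("hairpin", members, tuple(runs), len(members))
        elif n_close == 2:
            kind = "interior" if len(runs) == 2 else "bulge"
            add(kind, members, tuple(runs), len(members))
        else:
            if members:  # a junction with no unpaired nucleotides owns nothing
                add("junction", members, tuple(runs), len(members))

    # exterior strands: top-level unpaired runs
    _, ext_runs = face(0, n + 1)
    for s, e in ext_runs:
        members = tuple(range(s, e + 1))
        add("strand", members, ((s, e),), len(members))

    return ClassifiedStructure(pt, elements)


# ---------------------------------------------------------------------------
# per-site context


UNDEFINED = "undefined"
NOT_APPLICABLE = "n/a"


@dataclass(frozen=True)
class SiteContext:
    """Structural and sequence context of one position in one structure."""

    position: int
    base: str
    kind: str
    strand_len: int
    opp_strand_len: int
    asymmetry: int | None
    ce_pos: int
    op_nuc: str
    helix_flank: str
    up: tuple[str | None, ...]  # up[k-1] = nucleotide k positions 5'
    dn: tuple[str | None, ...]  # dn[k-1] = nucleotide k positions 3'

    def up_nbr(self, k: int) -> str | None:
        return self.up[k - 1]

    def dn_nbr(self, k: int) -> str | None:
        return self.dn[k - 1]


def _as_classified(pt: PairingTable, elements) -> ClassifiedStructure:
    if isinstance(elements, ClassifiedStructure):
        return elements
    return ClassifiedStructure(pt, list(elements))


def opposite_nucleotide(pt: PairingTable, elements, position: int) -> str:
    """The structurally opposite nucleotide of ``position``.

    Helix sites: the pairing partner's base.  Interior-loop sites at a strand
    edge (ce_pos = 0): the most 5' nucleotide of one strand faces the most 3'
    nucleotide of the other, except that a length-1 strand facing an opposite
    strand longer than one nucleotide has no defined opposite
    (``"undefined"``).  All other sites return ``"n/a"``.
    """
    cs = _as_classified(pt, elements)
    elem = cs.element_of(position)
    seq = pt.sequence
    if elem.kind == "helix":
        return seq[pt.pairs[position] - 1]
    if elem.kind != "interior":
        return NOT_APPLICABLE
    own = elem.strands[cs.strand_index_of(position)]
    other = elem.strands[1 - cs.strand_index_of(position)]
    own_len = own[1] - own[0] + 1
    other_len = other[1] - other[0] + 1
    if position != own[0] and position != own[1]:
        return NOT_APPLICABLE  # ce_pos > 0
    if own_len == 1 and other_len > 1:
        return UNDEFINED
    if position == own[0]:  # most 5' of own strand -> most 3' of the other
        return seq[other[1] - 1]
    return seq[other[0] - 1]  # most 3' -> most 5'


def site_context(pt: PairingTable, elements, position: int, k_max: int = 30) -> SiteContext:
    """Full :class:`SiteContext` for a 1-based position.

    ce_pos counts base-pair steps from the nearest helix terminus for helix
    sites, and nucleotides from the nearest end of the site's own strand for
    loop sites.  Neighbours are taken from the primary sequence regardless of
    element boundaries; positions beyond the record yield ``None``.
    """
    n = len(pt)
    if not (1 <= position <= n):
        raise IndexError(f"position {position} out of range 1..{n}")
    cs = _as_classified(pt, elements)
    elem = cs.element_of(position)
    seq = pt.sequence
    asymmetry: int | None = None
    opp_len = 0
    if elem.kind == "helix":
        m = cs.stack_index_of(position)
        ce_pos = min(m, elem.size - 1 - m)
        strand_len = elem.size
        helix_flank = NOT_APPLICABLE
    else:
        own = elem.strands[cs.strand_index_of(position)]
        strand_len = own[1] - own[0] + 1
        ce_pos = min(position - own[0], own[1] - position)
        if elem.kind == "interior":
            other = elem.strands[1 - cs.strand_index_of(position)]
            opp_len = other[1] - other[0] + 1
            asymmetry = opp_len - strand_len
        up_paired = position > 1 and (position - 1) in pt.pairs
        dn_paired = position < n and (position + 1) in pt.pairs
        helix_flank = {
            (True, True): "both",
            (True, False): "upstream-only",
            (False, True): "downstream-only",
            (False, False): "neither",
        }[(up_paired, dn_paired)]
    op_nuc = opposite_nucleotide(pt, cs, position)
    up = tuple(seq[position - 1 - k] if position - k >= 1 else None for k in range(1, k_max + 1))
    dn = tuple(seq[position - 1 + k] if position + k <= n else None for k in range(1, k_max + 1))
    return SiteContext(
        position=position,
        base=seq[position - 1],
        kind=elem.kind,
        strand_len=strand_len,
        opp_strand_len=opp_len,
        asymmetry=asymmetry,
        ce_pos=ce_pos,
        op_nuc=op_nuc,
        helix_flank=helix_flank,
        up=up,
        dn=dn,
    )


def contexts_to_frame(
    pt: PairingTable, elements=None, positions: Iterable[int] | None = None, k_max: int = 30
) -> pd.DataFrame:
    """Tabulate :class:`SiteContext` rows, one per (structure_id, position)."""
    cs = _as_classified(pt, classify_substructures(pt) if elements is None else elements)
    if positions is None:
        positions = range(1, len(pt) + 1)
    rows = []
    for pos in positions:
        c = site_context(pt, cs, pos, k_max=k_max)
        row = {
            "structure_id": pt.structure_id,
            "position": c.position,
            "base": c.base,
            "kind": c.kind,
            "strand_len": c.strand_len,
            "opp_strand_len": c.opp_strand_len,
            "asymmetry": c.asymmetry,
            "ce_pos": c.ce_pos,
            "op_nuc": c.op_nuc,
            "helix_flank": c.helix_flank,
        }
        for k in range(1, k_max + 1):
            row[f"up{k}"] = c.up[k - 1]
            row[f"dn{k}"] = c.dn[k - 1]
        rows.append(row)
    return pd.DataFrame(rows)
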