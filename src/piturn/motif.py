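"""RxxxE-motif scanning, class-marker audits, and residue-numbering maps.

Works on multiple sequence alignments of nuclear-receptor ligand-binding
domains.  Three coordinate systems coexist and are mapped explicitly:

* generic alignment numbering (1-based columns of the reference MSA),
* native author numbering of each receptor (e.g. R348 in human RXRa),
* Brelivet marker numbering for the class I / class II dimerization
  markers (e.g. W40, R105).

The packaged anchor table records, per receptor, which native residue sits
at each anchored alignment position; positions between anchors of the same
secondary-structure block follow by contiguity.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO

GAP_CHARS = {"-", "."}

#: motif variants: (basic residue, acidic offset in ungapped coordinates)
VARIANT_SPECS: dict[str, tuple[str, int]] = {
    "RxxxE": ("R", 4),
    "KxxxE": ("K", 4),
    "QxxxE": ("Q", 4),
    "RxxxxxxE": ("R", 7),
}
#: canonical motif first; variants are degradation states
VARIANT_PRECEDENCE = ("RxxxE", "KxxxE", "QxxxE", "RxxxxxxE")


# ---------------------------------------------------------------------------
# alignments


@dataclasses.dataclass
class Alignment:
    """Ordered gapped rows over the amino-acid alphabet; columns 1-based."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            offenders = sorted(t for t, s in self.rows.items()
                               if len(s) != max(lengths))
            raise ValueError(f"ragged alignment; offending taxa: {offenders}")
        self.rows = {t: s.upper().replace(".", "-") for t, s in self.rows.items()}

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, taxon: str) -> str:
        return self.rows[taxon]


def read_alignment(path: str | Path, format: str = "auto") -> Alignment:
    """Read an aligned FASTA or Clustal file; '.' and '-' unify as gap."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        head = path.read_text().lstrip()[:30].upper()
        fmt = "clustal" if head.startswith("CLUSTAL") else "fasta"
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    rows: dict[str, str] = {}
    for rec in msa:
        if rec.id in rows:
            raise ValueError(f"duplicate taxon label {rec.id!r}")
        rows[rec.id] = str(rec.seq)
    return Alignment(rows)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in aln.rows.items():
            fh.write(f">{taxon}\n{seq}\n")


# ---------------------------------------------------------------------------
# motif scanning


@dataclasses.dataclass(frozen=True)
class MotifHit:
    taxon: str
    basic_column: int      # 1-based alignment column of R/K/Q
    acidic_column: int     # 1-based alignment column of E
    variant: str
    window: tuple[int, int]

    def __post_init__(self) -> None:
        if self.acidic_column <= self.basic_column:
            raise ValueError("acidic column must follow the basic column")


def scan_motif(aln: Alignment, window: tuple[int, int] | None = None,
               variants: Iterable[str] = VARIANT_PRECEDENCE) -> list[MotifHit]:
    """Gap-aware scan for RxxxE-family motifs.

    Pattern spacing is counted over non-gap residues, so a motif split by
    gap columns is still found.  The basic residue's alignment column must
    fall inside the window.  At a shared anchor the canonical RxxxE beats
    its variants; hits are non-overlapping (ungapped extents) per row.
    """
    if window is None:
        window = (1, aln.n_cols)
    lo, hi = window
    if lo > hi or lo < 1 or hi > aln.n_cols:
        raise ValueError(f"window {window} empty or outside 1..{aln.n_cols}")
    ordered = [v for v in VARIANT_PRECEDENCE if v in set(variants)]
    unknown = set(variants) - set(VARIANT_SPECS)
    if unknown:
        raise ValueError(f"unknown variants: {sorted(unknown)}")

    hits: list[MotifHit] = []
    for taxon, seq in aln.rows.items():
        residues = [(i + 1, c) for i, c in enumerate(seq) if c not in GAP_CHARS]
        taken: set[int] = set()   # ungapped indices already inside a hit
        for pos in range(len(residues)):
            col, aa = residues[pos]
            if not (lo <= col <= hi):
                continue
            for variant in ordered:
                basic, offset = VARIANT_SPECS[variant]
                if aa != basic or pos + offset >= len(residues):
                    continue
                acidic_col, acidic_aa = residues[pos + offset]
                if acidic_aa != "E":
                    continue
                span = set(range(pos, pos + offset + 1))
                if span & taken:
                    continue
                taken |= span
                hits.append(MotifHit(taxon, col, acidic_col, variant, window))
                break
    return sorted(hits, key=lambda h: (h.taxon, h.basic_column))


# ---------------------------------------------------------------------------
# class I / class II dimerization markers


@dataclasses.dataclass(frozen=True)
class Marker:
    position: int              # Brelivet numbering
    allowed: frozenset[str]
    marker_class: str          # "I", "II", or "universal"


#: differentially conserved dimerization markers, Brelivet numbering:
#: class I (monomer/homodimer receptors) E5, W40, K/R55, R/K93, R105;
#: class II (RXR heterodimer partners) E/D42, R62, H/R/K90;
#: E50 and R105 universally conserved.  R105 is listed both as a class I
#: marker and as universal; it is treated as universal but still counted
#: in class I audits.
DEFAULT_MARKERS: tuple[Marker, ...] = (
    Marker(5, frozenset("E"), "I"),
    Marker(40, frozenset("W"), "I"),
    Marker(55, frozenset("KR"), "I"),
    Marker(93, frozenset("RK"), "I"),
    Marker(105, frozenset("R"), "universal"),
    Marker(42, frozenset("ED"), "II"),
    Marker(62, frozenset("R"), "II"),
    Marker(90, frozenset("HRK"), "II"),
    Marker(50, frozenset("E"), "universal"),
)

#: markers that also count toward a class audit despite universal status
_UNIVERSAL_ALSO_CLASS_I = frozenset({105})


@dataclasses.dataclass
class MarkerReport:
    taxon: str
    present: dict[int, bool]               # Brelivet position -> found
    skipped: list[int]                     # positions without a column mapping
    class_i_missing: list[int]
    class_ii_missing: list[int]
    verdict: str                           # class I | class II | outlier | undetermined
    notes: list[str]


def audit_class_markers(row: str, taxon: str,
                        position_map: dict[int, int],
                        markers: Sequence[Marker] = DEFAULT_MARKERS,
                        strict: bool = False) -> MarkerReport:
    """Check which dimerization markers a gapped alignment row carries.

    ``position_map`` maps Brelivet positions to 1-based alignment columns.
    Unmapped positions are skipped with a note (or raise when ``strict``).
    Verdict: 'class I' / 'class II' when exactly that class is complete,
    'outlier' when the closest class misses at most 2 markers,
    'undetermined' otherwise (including the degenerate both-complete case).
    """
    present: dict[int, bool] = {}
    skipped: list[int] = []
    notes: list[str] = []
    for m in markers:
        col = position_map.get(m.position)
        if col is None:
            if strict:
                raise KeyError(f"marker position {m.position} has no column mapping")
            skipped.append(m.position)
            continue
        if not (1 <= col <= len(row)):
            raise ValueError(f"mapped column {col} outside the row")
        present[m.position] = row[col - 1].upper() in m.allowed
    if skipped:
        notes.append(f"unmapped marker positions skipped: {skipped}")

    def missing(cls: str) -> list[int]:
        out = []
        for m in markers:
            counts = (m.marker_class == cls or
                      (cls == "I" and m.position in _UNIVERSAL_ALSO_CLASS_I))
            if counts and m.position in present and not present[m.position]:
                out.append(m.position)
        return sorted(set(out))

    miss_i, miss_ii = missing("I"), missing("II")
    if 105 in miss_i:
        notes.append("R105 is both universally conserved and a class I marker; "
                     "its absence is counted against class I")
    if not miss_i and miss_ii:
        verdict = "class I"
    elif not miss_ii and miss_i:
        verdict = "class II"
    elif not miss_i and not miss_ii:
        verdict = "undetermined"
        notes.append("both marker classes complete; classes cannot be discriminated")
    elif min(len(miss_i), len(miss_ii)) <= 2:
        verdict = "outlier"
    else:
        verdict = "undetermined"
    return MarkerReport(taxon, present, skipped, miss_i, miss_ii, verdict, notes)


# ---------------------------------------------------------------------------
# alignment <-> native numbering


@dataclasses.dataclass(frozen=True)
class AnchorCell:
    taxon: str
    alignment_position: int
    native_number: int
    expected_aa: str
    element: str                # secondary-structure block label, e.g. "H7"


@dataclasses.dataclass
class AnchorBlock:
    """A contiguity block: inside it, native number differences equal
    alignment position differences."""

    taxon: str
    element: str
    aln_start: int
    aln_end: int
    offset: int                 # native = alignment position + offset

    def contains(self, position: int) -> bool:
        return self.aln_start <= position <= self.aln_end


class AnchorTable:
    """Per-taxon anchors tying alignment positions to native residue numbers."""

    def __init__(self, cells: Iterable[AnchorCell],
                 block_pad: int = 0) -> None:
        self.cells = sorted(cells, key=lambda c: (c.taxon, c.alignment_position))
        self.blocks: dict[str, list[AnchorBlock]] = {}
        by_taxon_elem: dict[tuple[str, str], list[AnchorCell]] = {}
        for c in self.cells:
            by_taxon_elem.setdefault((c.taxon, c.element), []).append(c)
        for (taxon, elem), cells_ in by_taxon_elem.items():
            offsets = {c.native_number - c.alignment_position for c in cells_}
            if len(offsets) != 1:
                raise ValueError(
                    f"{taxon}/{elem}: anchors are not mutually contiguous "
                    f"(offsets {sorted(offsets)})")
            start = min(c.alignment_position for c in cells_) - block_pad
            end = max(c.alignment_position for c in cells_) + block_pad
            self.blocks.setdefault(taxon, []).append(
                AnchorBlock(taxon, elem, start, end, offsets.pop()))

    def taxa(self) -> list[str]:
        return sorted(self.blocks)

    def map_to_native(self, taxon: str, alignment_position: int) -> tuple[int, str | None]:
        """Native residue number (and the anchored amino acid, if this exact
        position is an anchor cell) for an alignment position."""
        for block in self.blocks.get(taxon, ()):
            if block.contains(alignment_position):
                native = alignment_position + block.offset
                aa = next((c.expected_aa for c in self.cells
                           if c.taxon == taxon and
                           c.alignment_position == alignment_position), None)
                return native, aa
        raise KeyError(f"unanchored position {alignment_position} for {taxon}")

    def map_to_alignment(self, taxon: str, native_number: int) -> int:
        for block in self.blocks.get(taxon, ()):
            pos = native_number - block.offset
            if block.contains(pos):
                return pos
        raise KeyError(f"native residue {native_number} of {taxon} "
                       "falls outside all anchored blocks")

    def restrict(self, taxon: str, element: str) -> "AnchorTable":
        """Table limited to one taxon's anchors in one block (the block span
        is preserved so contiguity mapping still covers the element)."""
        cells = [c for c in self.cells if c.taxon == taxon and c.element == element]
        if not cells:
            raise KeyError(f"no anchors for {taxon}/{element}")
        return AnchorTable(cells)

    def single_anchor(self, taxon: str, alignment_position: int,
                      span: tuple[int, int]) -> "AnchorTable":
        """Table rebuilt from one anchor cell plus an assumed contiguous span."""
        cells = [c for c in self.cells if c.taxon == taxon and
                 c.alignment_position == alignment_position]
        if not cells:
            raise KeyError(f"{taxon} has no anchor at position {alignment_position}")
        cell = cells[0]
        table = AnchorTable([cell])
        block = table.blocks[taxon][0]
        block.aln_start, block.aln_end = span
        return table


def map_alignment_to_native(anchors: AnchorTable, taxon: str,
                            alignment_position: int) -> tuple[int, str | None]:
    """Functional alias of :meth:`AnchorTable.map_to_native`."""
    return anchors.map_to_native(taxon, alignment_position)


def map_native_to_alignment(anchors: AnchorTable, taxon: str,
                            native_number: int) -> int:
    return anchors.map_to_alignment(taxon, native_number)


# ---------------------------------------------------------------------------
# packaged fixtures


def _data_path(name: str) -> Path:
    return Path(str(resources.files("piturn").joinpath("data", name)))


def load_anchor_table(path: str | Path | None = None) -> AnchorTable:
    """The packaged residue-mapping table (six receptors, fifteen anchored
    alignment positions spanning helices H4-H5 through H11)."""
    path = _data_path("table1_anchors.tsv") if path is None else Path(path)
    cells = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            taxon, pos, native, aa, element = line.split("\t")
            cells.append(AnchorCell(taxon, int(pos), int(native), aa, element))
    return AnchorTable(cells)


def load_brelivet_map(path: str | Path | None = None) -> dict[int, int]:
    """Brelivet marker position -> generic alignment position."""
    path = _data_path("brelivet_map.tsv") if path is None else Path(path)
    mapping: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            aln, brelivet = line.split("\t")
            mapping[int(brelivet)] = int(aln)
    return mapping
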