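"""Accessors for the packaged nuclear-receptor desk-scale dataset.

The tree and character table are transcriptions of published qualitative
statements about motif occurrence across the NR superfamily (50 tips,
relative branch lengths reflecting the reported fast/slow lineages), not
the original inference files; they load through the same readers as any
user-supplied data.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .evolution import CharacterMatrix, PhyloTree, read_tree
from .motif import AnchorTable, load_anchor_table, load_brelivet_map

STATE_LABELS = ("absent", "present")


def data_dir() -> Path:
    return Path(str(resources.files("piturn").joinpath("data")))


def load_nr_tree() -> PhyloTree:
    """Curated NR phylogeny (rooted between the HNF4 side and the rest)."""
    return read_tree((data_dir() / "nr_tree.nwk").read_text())


def load_nr_piturn_states() -> CharacterMatrix:
    """Reconciled pi-turn presence/absence per lineage (0=absent, 1=present)."""
    return CharacterMatrix.from_tsv(data_dir() / "nr_piturn_states.tsv",
                                    labels=STATE_LABELS)


def load_anchors() -> AnchorTable:
    return load_anchor_table()


def load_brelivet_positions() -> dict[int, int]:
    return load_brelivet_map()


def marker_column_map() -> dict[int, int]:
    """Brelivet marker position -> alignment column, from the packaged map."""
    return load_brelivet_map()


def build_reference_row(taxon: str, n_cols: int = 340,
                        background: str = "A") -> str:
    """Synthetic gapless alignment row carrying a receptor's anchored
    residues at their alignment columns (background filled with alanine).

    Useful for marker audits driven by the packaged anchor table alone.
    """
    anchors = load_anchor_table()
    row = [background] * n_cols
    for cell in anchors.cells:
        if cell.taxon == taxon:
            row[cell.alignment_position - 1] = cell.expected_aa
    return "".join(row)


def build_spnr2_like_row(n_cols: int = 340, background: str = "A") -> str:
    """Synthetic row emulating the sponge receptor SpNR2: all class I
    markers intact except W40 replaced by valine and R105 by lysine."""
    columns = load_brelivet_map()
    residue_at = {40: "V", 42: "E", 50: "E", 61: "D", 62: "T",
                  93: "R", 100: "R", 105: "K", 106: "S"}
    row = [background] * n_cols
    for brelivet, aln_col in columns.items():
        row[aln_col - 1] = residue_at[brelivet]
    return "".join(row)
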