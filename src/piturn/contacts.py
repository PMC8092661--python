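"""Dimer-interface contact networks and buried surface area.

Enumerates inter-subunit contacts between two chains of a dimer, types
them (hydrogen bond, salt bridge, van der Waals, water-mediated), bins
them by secondary-structure element pairs (helices H7-H11 and the loop
H8-H9 of each subunit), scores the interface asymmetry that
distinguishes RXR heterodimers, and computes solvent-accessible /
buried surface areas by Shrake-Rupley sphere sampling with a fixed
deterministic point set.

Contact criteria are distance-only by default: crystal structures lack
hydrogens and bonds are reported at the residue level, so donor/acceptor
geometry is approximated by heavy-atom (N/O) proximity.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

from .helix import ACIDIC_ATOMS, BASIC_ATOMS
from .structure import Structure

#: default distance cutoffs, Angstrom
DEFAULT_CUTOFFS = {
    "hbond": 3.5,
    "salt_bridge": 4.0,
    "vdw": 4.5,
    "water": 3.5,
}

#: van der Waals radii (Angstrom) for SASA; unknown elements fall back to C
VDW_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}
DEFAULT_RADIUS = 1.7
PROBE_RADIUS = 1.4

POLAR_ELEMENTS = {"N", "O"}


@dataclasses.dataclass(frozen=True)
class ContactRecord:
    chain_a: str
    residue_a: int
    resname_a: str
    atom_a: str
    chain_b: str
    residue_b: int
    resname_b: str
    atom_b: str
    contact_type: str          # hbond | salt_bridge | vdw | water_mediated
    distance: float
    water: tuple[str, int] | None = None   # (chain, residue number) of bridge


def _side_chain_charge_atoms(resname: str) -> tuple[str, ...]:
    return BASIC_ATOMS.get(resname, ()) + ACIDIC_ATOMS.get(resname, ())


def enumerate_interface_contacts(structure: Structure, chain_a: str, chain_b: str,
                                 cutoffs: Mapping[str, float] | None = None,
                                 ) -> list[ContactRecord]:
    """All typed contacts between two chains, one record per residue pair.

    Typing precedence per residue pair: salt bridge > hydrogen bond > VdW
    (a salt-bridging pair also satisfies H-bond geometry; it is reported
    once, as the salt bridge).  Water-mediated contacts additionally list
    residue pairs bridged by a single water whose oxygen lies within the
    water cutoff of a polar atom in each chain.
    """
    cut = dict(DEFAULT_CUTOFFS)
    if cutoffs:
        cut.update(cutoffs)
    for cid in (chain_a, chain_b):
        if cid not in structure:
            raise KeyError(f"chain {cid!r} not in structure")

    def atoms_of(cid: str):
        out = []
        for res in structure[cid]:
            if res.is_water:
                continue
            for atom in res.atoms.values():
                if atom.element != "H":
                    out.append((res, atom))
        return out

    atoms_a, atoms_b = atoms_of(chain_a), atoms_of(chain_b)
    best: dict[tuple, ContactRecord] = {}
    rank = {"salt_bridge": 0, "hbond": 1, "vdw": 2}

    for res_a, at_a in atoms_a:
        for res_b, at_b in atoms_b:
            d = float(np.linalg.norm(at_a.xyz - at_b.xyz))
            if d > cut["vdw"]:
                continue
            salt_atoms = (
                (at_a.name in BASIC_ATOMS.get(res_a.name, ()) and
                 at_b.name in ACIDIC_ATOMS.get(res_b.name, ())) or
                (at_a.name in ACIDIC_ATOMS.get(res_a.name, ()) and
                 at_b.name in BASIC_ATOMS.get(res_b.name, ())))
            polar = at_a.element in POLAR_ELEMENTS and at_b.element in POLAR_ELEMENTS
            if salt_atoms and d <= cut["salt_bridge"]:
                ctype = "salt_bridge"
            elif polar and d <= cut["hbond"]:
                ctype = "hbond"
            else:
                ctype = "vdw"
            key = (res_a.id, res_b.id)
            rec = ContactRecord(chain_a, res_a.number, res_a.name, at_a.name,
                                chain_b, res_b.number, res_b.name, at_b.name,
                                ctype, d)
            cur = best.get(key)
            if cur is None or (rank[ctype], d) < (rank[cur.contact_type], cur.distance):
                best[key] = rec

    records = list(best.values())

    # water bridges: one water O touching a polar atom of each chain
    for wchain in structure.chains.values():
        for wres in wchain:
            if not wres.is_water or "O" not in wres.atoms:
                continue
            w = wres.coord("O")
            near: dict[str, list] = {chain_a: [], chain_b: []}
            for cid, pool in ((chain_a, atoms_a), (chain_b, atoms_b)):
                for res, atom in pool:
                    if atom.element in POLAR_ELEMENTS and \
                       np.linalg.norm(atom.xyz - w) <= cut["water"]:
                        near[cid].append((res, atom))
            for res_a, at_a in near[chain_a]:
                for res_b, at_b in near[chain_b]:
                    d = float(np.linalg.norm(at_a.xyz - w) +
                              np.linalg.norm(at_b.xyz - w))
                    records.append(ContactRecord(
                        chain_a, res_a.number, res_a.name, at_a.name,
                        chain_b, res_b.number, res_b.name, at_b.name,
                        "water_mediated", d, water=(wchain.id, wres.number)))
    return sorted(records, key=lambda r: (r.residue_a, r.residue_b, r.contact_type))


# ---------------------------------------------------------------------------
# element binning


@dataclasses.dataclass
class ElementMap:
    """Named secondary-structure elements per chain as residue ranges."""

    elements: dict[str, dict[str, tuple[int, int]]]   # chain -> name -> (lo, hi)

    def __post_init__(self) -> None:
        for cid, elems in self.elements.items():
            spans = sorted(elems.values())
            for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
                if lo2 <= hi1:
                    raise ValueError(f"chain {cid}: overlapping element ranges")

    def element_of(self, chain: str, residue: int) -> str:
        for name, (lo, hi) in self.elements.get(chain, {}).items():
            if lo <= residue <= hi:
                return name
        return "other"


@dataclasses.dataclass
class ElementContactMatrix:
    """Counts per ordered (element_A, element_B) pair, split by type."""

    counts: dict[tuple[str, str, str], int]        # (elem_a, elem_b, type) -> n
    pi_turn_contacts: int                           # A-side residue in the pi-turn set
    total: int

    def count(self, elem_a: str, elem_b: str, contact_type: str | None = None) -> int:
        if contact_type is not None:
            return self.counts.get((elem_a, elem_b, contact_type), 0)
        return sum(n for (a, b, _), n in self.counts.items()
                   if a == elem_a and b == elem_b)


def bin_contacts_by_element(contacts: Sequence[ContactRecord], em: ElementMap,
                            pi_turn_residues: Iterable[int] = ()) -> ElementContactMatrix:
    """Bin interface contacts by element pair.

    ``pi_turn_residues`` optionally lists A-side author residue numbers of
    the pi-turn motif (e.g. mapped from generic positions 202, 205, 206,
    210) whose contacts are tallied separately.
    """
    pi_set = set(pi_turn_residues)
    counts: dict[tuple[str, str, str], int] = {}
    pi_count = 0
    for rec in contacts:
        ea = em.element_of(rec.chain_a, rec.residue_a)
        eb = em.element_of(rec.chain_b, rec.residue_b)
        key = (ea, eb, rec.contact_type)
        counts[key] = counts.get(key, 0) + 1
        if rec.residue_a in pi_set:
            pi_count += 1
    return ElementContactMatrix(counts, pi_count, total=len(contacts))


def asymmetry_score(matrix_ab: ElementContactMatrix,
                    matrix_ba: ElementContactMatrix) -> int:
    """count(H7_A <-> loopH8-H9_B) - count(H7_B <-> loopH8-H9_A).

    Positive means chain A behaves like RXR in a heterodimer: its helix H7
    (carrying the pi-turn) packs against the partner's loop H8-H9 more than
    the reverse.  Zero for a symmetric homodimer interface.
    """
    return (matrix_ab.count("H7", "loopH8-H9") -
            matrix_ba.count("H7", "loopH8-H9"))


# ---------------------------------------------------------------------------
# solvent-accessible and buried surface area


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack((np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)))


def compute_sasa(structure: Structure, probe_radius: float = PROBE_RADIUS,
                 n_points: int = 960, include_water: bool = False,
                 ) -> dict[tuple[str, tuple[int, str], str], float]:
    """Shrake-Rupley per-atom solvent-accessible surface area (A^2).

    Each atom's accessible sphere (VdW radius + probe) is sampled with the
    same fixed golden-spiral point set; a point survives if it is outside
    every neighbouring atom's accessible sphere.
    """
    all_keys, all_coords = structure.atom_array(include_water=include_water)
    keys, coords, radii = [], [], []
    for key, xyz in zip(all_keys, all_coords):
        cid, rid, aname = key
        atom = structure[cid].residue_by_number(rid[0], rid[1]).atoms[aname]
        if atom.element == "H":
            continue
        keys.append(key)
        coords.append(xyz)
        radii.append(VDW_RADII.get(atom.element, DEFAULT_RADIUS) + probe_radius)
    coords = np.asarray(coords)
    radii = np.asarray(radii)
    heavy = range(len(keys))
    unit = _sphere_points(n_points)

    areas: dict[tuple[str, tuple[int, str], str], float] = {}
    for i in heavy:
        r_i = radii[i]
        pts = coords[i] + r_i * unit
        accessible = np.ones(n_points, dtype=bool)
        d2 = np.sum((coords - coords[i]) ** 2, axis=1)
        neighbours = np.flatnonzero((d2 < (radii + r_i) ** 2) &
                                    (np.arange(len(keys)) != i))
        for j in neighbours:
            accessible &= np.sum((pts - coords[j]) ** 2, axis=1) > radii[j] ** 2
            if not accessible.any():
                break
        areas[keys[i]] = 4.0 * np.pi * r_i ** 2 * accessible.sum() / n_points
    return areas


def total_sasa(structure: Structure, **kw) -> float:
    return float(sum(compute_sasa(structure, **kw).values()))


def buried_surface_area(structure: Structure, chain_a: str, chain_b: str,
                        **kw) -> float:
    """BSA = SASA(A alone) + SASA(B alone) - SASA(AB complex), in A^2.

    Symmetric in chain order and invariant under rigid-body motion of the
    whole complex (up to the fixed sampling resolution).
    """
    for cid in (chain_a, chain_b):
        if cid not in structure:
            raise KeyError(f"chain {cid!r} not in structure")
    pair = Structure([structure[chain_a], structure[chain_b]])
    alone_a = Structure([structure[chain_a]])
    alone_b = Structure([structure[chain_b]])
    return total_sasa(alone_a, **kw) + total_sasa(alone_b, **kw) - total_sasa(pair, **kw)
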