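"""Lightweight protein-structure container and PDB/mmCIF input/output.

The container keeps only what hydrogen-bond and contact analysis need:
chains of ordered residues with named atoms and Cartesian coordinates in
Angstroms.  Parsing is delegated to :mod:`gemmi`; the first model is used,
alternate locations are resolved to the highest-occupancy conformer
(alphabetical altloc identifier breaking ties), and waters are retained but
flagged so interface code can treat them separately.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

WATER_NAMES = {"HOH", "WAT", "DOD"}

#: default element inferred from a backbone/pseudo atom name prefix
_ELEMENT_FROM_NAME = {"N": "N", "C": "C", "O": "O", "S": "S", "H": "H"}


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite numbers")


@dataclasses.dataclass
class Residue:
    number: int                 # author sequence number
    name: str                   # 3-letter code
    atoms: dict[str, Atom] = dataclasses.field(default_factory=dict)
    insertion_code: str = ""
    is_water: bool = False

    @property
    def id(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)

    def coord(self, atom_name: str) -> np.ndarray:
        return self.atoms[atom_name].xyz

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C", "O"))

    def add_atom(self, name: str, xyz, element: str | None = None) -> Atom:
        if element is None:
            element = _ELEMENT_FROM_NAME.get(name[:1], "C")
        atom = Atom(name, element, np.asarray(xyz, dtype=float))
        self.atoms[name] = atom
        return atom


class Chain:
    """Ordered residues of one chain; ordering strictly increasing by
    (author number, insertion code)."""

    def __init__(self, chain_id: str, residues: Iterable[Residue] = ()) -> None:
        self.id = chain_id
        self.residues: list[Residue] = list(residues)
        self._check_order()

    def _check_order(self) -> None:
        ids = [r.id for r in self.residues]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError(f"chain {self.id}: residue ordering not strictly increasing")

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> Residue:
        return self.residues[i]

    def residue_by_number(self, number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.number == number and r.insertion_code == icode:
                return r
        raise KeyError(f"chain {self.id}: no residue {number}{icode}")

    def append(self, residue: Residue) -> None:
        self.residues.append(residue)
        self._check_order()


class Structure:
    """Chains of residues; the substrate of every geometric operation."""

    def __init__(self, chains: Iterable[Chain] = (), name: str = "") -> None:
        self.name = name
        self.chains: dict[str, Chain] = {}
        for c in chains:
            if c.id in self.chains:
                raise ValueError(f"duplicate chain id {c.id!r}")
            self.chains[c.id] = c

    def __getitem__(self, chain_id: str) -> Chain:
        return self.chains[chain_id]

    def __contains__(self, chain_id: str) -> bool:
        return chain_id in self.chains

    def add_chain(self, chain: Chain) -> None:
        if chain.id in self.chains:
            raise ValueError(f"duplicate chain id {chain.id!r}")
        self.chains[chain.id] = chain

    def iter_residues(self, include_water: bool = True):
        for chain in self.chains.values():
            for res in chain:
                if include_water or not res.is_water:
                    yield chain.id, res

    def atom_array(self, include_water: bool = True):
        """All heavy-atom coordinates with (chain, residue index, atom name) keys."""
        keys, coords = [], []
        for cid, res in self.iter_residues(include_water):
            for aname, atom in res.atoms.items():
                keys.append((cid, res.id, aname))
                coords.append(atom.xyz)
        return keys, (np.array(coords) if coords else np.empty((0, 3)))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid-body copy: x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_chains = []
        for chain in self.chains.values():
            residues = []
            for res in chain:
                new = Residue(res.number, res.name, {}, res.insertion_code, res.is_water)
                for aname, atom in res.atoms.items():
                    new.atoms[aname] = Atom(atom.name, atom.element,
                                            rotation @ atom.xyz + translation)
                residues.append(new)
            new_chains.append(Chain(chain.id, residues))
        return Structure(new_chains, name=self.name)


# ---------------------------------------------------------------------------
# reading


def _resolve_altlocs(res: gemmi.Residue) -> dict[str, gemmi.Atom]:
    """One atom per name: highest occupancy, then alphabetical altloc."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        cur = best.get(atom.name)
        if cur is None:
            best[atom.name] = atom
        else:
            key_new = (atom.occ, -ord(atom.altloc or "~"))
            key_cur = (cur.occ, -ord(cur.altloc or "~"))
            if key_new > key_cur:
                best[atom.name] = atom
    return best


def read_structure(path: str | Path, format: str = "auto",
                   altloc: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Only the first model is kept.  ``altloc`` selects a specific alternate
    conformer identifier instead of the default highest-occupancy rule
    (useful for structures deposited with two backbone conformations).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no model in file")
    st.setup_entities()
    model = st[0]

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        seen: set[tuple[int, str]] = set()
        for gres in gchain:
            num = gres.seqid.num
            icode = (gres.seqid.icode or "").strip()
            if (num, icode) in seen:
                continue
            seen.add((num, icode))
            if altloc is not None:
                atoms = {a.name: a for a in gres
                         if a.altloc in ("", altloc)}
            else:
                atoms = _resolve_altlocs(gres)
            res = Residue(num, gres.name, {}, icode,
                          is_water=gres.name in WATER_NAMES)
            for aname, gatom in atoms.items():
                el = gatom.element.name if gatom.element else ""
                res.atoms[aname] = Atom(aname, el or _ELEMENT_FROM_NAME.get(aname[:1], "C"),
                                        np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]))
            residues.append(res)
        residues.sort(key=lambda r: r.id)
        if residues:
            chains.append(Chain(gchain.name, residues))
    if not chains:
        raise ValueError(f"{path}: empty model")
    return Structure(chains, name=st.name or path.stem)


# ---------------------------------------------------------------------------
# writing


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a minimal single-model PDB file (ATOM records only)."""
    lines = []
    serial = 1
    for chain in structure.chains.values():
        for res in chain:
            for atom in res.atoms.values():
                name = atom.name
                # PDB atom-name column convention: element right-aligned in 13-14
                field = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d} {field}{'':1s}{res.name:>3s} "
                    f"{chain.id:1s}{res.number:4d}{res.insertion_code:1s}   "
                    f"{atom.xyz[0]:8.3f}{atom.xyz[1]:8.3f}{atom.xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
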