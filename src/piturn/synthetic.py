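"""Synthetic inputs for every pipeline stage, generated at desk scale.

Fixtures produced here emulate the study conditions of the analysis:
ideal helical backbones with planted pi-bulge segments, two-chain toy
dimers with designed cross-chain salt bridges, alignments with planted
RxxxE-family motifs, and birth-process trees carrying discrete characters
evolved under a symmetric-rate continuous-time Markov model.  Every
generator is deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .structure import Atom, Chain, Residue, Structure
from .evolution import PhyloTree, RateModel, TreeNode

HELIX_CLASSES = ("alpha", "three_ten", "pi")

#: default backbone dihedrals (phi, psi) in degrees per helix class
DEFAULT_DIHEDRALS: dict[str, tuple[float, float]] = {
    "alpha": (-57.0, -47.0),
    "three_ten": (-49.0, -26.0),
    "pi": (-57.0, -70.0),
}

# standard backbone geometry (lengths in Angstrom, angles in degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0


@dataclasses.dataclass
class HelixSpec:
    """Ordered helical segments making up one synthetic chain."""

    segments: Sequence[tuple[str, int]]
    residue_name: str = "ALA"
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("HelixSpec needs at least one segment")
        for cls, length in self.segments:
            if cls not in HELIX_CLASSES:
                raise ValueError(f"unknown helix_class {cls!r}; expected one of {HELIX_CLASSES}")
            if length < 1:
                raise ValueError(f"segment length must be >= 1, got {length}")
        if self.total_length < 6:
            raise ValueError("total length must be >= 6 (minimum for one N+5 bond)")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.segments)

    def per_residue_classes(self) -> list[str]:
        out: list[str] = []
        for cls, length in self.segments:
            out.extend([cls] * length)
        return out


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement of atom D given chain A-B-C, |CD|, angle BCD, dihedral ABCD."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(dihedral),
        np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_ideal_helix(spec: HelixSpec,
                     phi_psi_table: dict[str, tuple[float, float]] | None = None,
                     ) -> Structure:
    """Build a poly-residue backbone (N, CA, C, O) by chain extension.

    Each residue takes the (phi, psi) dihedrals of its segment's helix
    class; omega is fixed trans.  Residues are numbered 1..n without gaps.
    """
    table = dict(DEFAULT_DIHEDRALS)
    if phi_psi_table:
        for cls, (phi, psi) in phi_psi_table.items():
            if not (-180.0 < phi <= 180.0 and -180.0 < psi <= 180.0):
                raise ValueError(f"{cls}: phi/psi must lie in (-180, 180]")
            table[cls] = (phi, psi)
    classes = spec.per_residue_classes()
    n = len(classes)

    # seed atoms of residue 1 in an arbitrary frame
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = np.deg2rad(ANGLE_N_CA_C)
    C = [CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]

    for i in range(1, n):
        psi_prev = table[classes[i - 1]][1]
        phi_i = table[classes[i]][0]
        N.append(_place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi_prev))
        CA.append(_place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, OMEGA))
        C.append(_place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi_i))

    # carbonyl oxygens: anti to the next amide nitrogen; the final residue
    # uses a virtual next N continued with its own psi
    O: list[np.ndarray] = []
    for i in range(n):
        if i < n - 1:
            next_n = N[i + 1]
        else:
            psi_last = table[classes[-1]][1]
            next_n = _place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi_last)
        O.append(_place_atom(next_n, CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, 180.0))

    residues = []
    for i in range(n):
        res = Residue(i + 1, spec.residue_name)
        res.atoms["N"] = Atom("N", "N", N[i])
        res.atoms["CA"] = Atom("CA", "C", CA[i])
        res.atoms["C"] = Atom("C", "C", C[i])
        res.atoms["O"] = Atom("O", "O", O[i])
        residues.append(res)
    return Structure([Chain(spec.chain_id, residues)], name="ideal_helix")


# ---------------------------------------------------------------------------
# toy dimers


def make_toy_dimer(n_res_per_chain: int = 20, separation: float = 20.0,
                   bridge_pairs: Sequence[tuple[int, int, float]] = (),
                   vdw_cutoff: float = 4.5) -> Structure:
    """Two parallel ideal alpha-helices (chains A, B) with designed bridges.

    Each listed pair (resA, resB, target distance) receives one pseudo
    side-chain atom per residue -- an arginine-like nitrogen (``NH1``) on
    chain A and a glutamate-like oxygen (``OE1``) on chain B -- placed on
    the line joining the two CA atoms so the pseudo-atom distance equals
    the target exactly.  All non-listed inter-chain atom pairs stay farther
    than ``vdw_cutoff + 1`` Angstrom.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    for ra, rb, d in bridge_pairs:
        if d < 2.5:
            raise ValueError(f"target distance {d} below 2.5 A is physically infeasible")
    if len({ra for ra, _, _ in bridge_pairs}) < len(bridge_pairs) or \
       len({rb for _, rb, _ in bridge_pairs}) < len(bridge_pairs):
        raise ValueError("contradictory bridge constraints: residue listed twice")

    spec = HelixSpec([("alpha", n_res_per_chain)], chain_id="A")
    helix = make_ideal_helix(spec)

    # align the helix axis with x so the inter-chain offset (along z) is
    # perpendicular to both helices everywhere
    ca = np.array([r.coord("CA") for r in helix["A"]])
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid)
    axis = vt[0]
    ref = np.array([0.0, 0.0, 1.0])
    y_dir = np.cross(ref, axis)
    if np.linalg.norm(y_dir) < 1e-6:
        ref = np.array([0.0, 1.0, 0.0])
        y_dir = np.cross(ref, axis)
    y_dir /= np.linalg.norm(y_dir)
    z_dir = np.cross(axis, y_dir)
    rot = np.vstack([axis, y_dir, z_dir])   # rows: new basis
    helix = helix.transformed(rot, -rot @ centroid)
    chain_a = helix["A"]

    offset = np.array([0.0, 0.0, separation])
    residues_b = []
    for res in chain_a:
        new = Residue(res.number, res.name)
        for aname, atom in res.atoms.items():
            new.atoms[aname] = Atom(atom.name, atom.element, atom.xyz + offset)
        residues_b.append(new)
    chain_b = Chain("B", residues_b)
    dimer = Structure([chain_a, chain_b], name="toy_dimer")

    for ra, rb, target in bridge_pairs:
        res_a = chain_a.residue_by_number(ra)
        res_b = chain_b.residue_by_number(rb)
        ca_a, ca_b = res_a.coord("CA"), res_b.coord("CA")
        u = ca_b - ca_a
        dist = np.linalg.norm(u)
        if dist < target:
            raise ValueError(f"bridge ({ra},{rb}): CA atoms closer ({dist:.1f} A) "
                             f"than the target distance {target} A")
        u /= dist
        mid = (ca_a + ca_b) / 2.0
        res_a.name = "ARG"
        res_b.name = "GLU"
        res_a.add_atom("NH1", mid - (target / 2.0) * u, element="N")
        res_b.add_atom("OE1", mid + (target / 2.0) * u, element="O")

    # verify everything except the designed pseudo-atom pairs stays clear
    designed = {(ra, "NH1", rb, "OE1") for ra, rb, _ in bridge_pairs}
    for res_a in chain_a:
        for res_b in chain_b:
            for aa in res_a.atoms.values():
                for ab in res_b.atoms.values():
                    if (res_a.number, aa.name, res_b.number, ab.name) in designed:
                        continue
                    if np.linalg.norm(aa.xyz - ab.xyz) <= vdw_cutoff + 1.0:
                        raise ValueError(
                            "infeasible geometry: non-designed inter-chain atoms "
                            f"A/{res_a.number}/{aa.name} and B/{res_b.number}/"
                            f"{ab.name} fall inside the VdW cutoff margin; "
                            "spread the bridges or increase the separation")
    return dimer


# ---------------------------------------------------------------------------
# alignments with planted motifs

#: columns spanned and (anchor, offset-to-acidic, letters) per motif variant
MOTIF_VARIANTS: dict[str, tuple[str, int, str]] = {
    "RxxxE": ("R", 4, "E"),
    "KxxxE": ("K", 4, "E"),
    "QxxxE": ("Q", 4, "E"),
    "RxxxxxxE": ("R", 7, "E"),
}

_BACKGROUND_AA = sorted(set("ACDFGHILMNPSTVWY"))  # 20 aa minus {R, K, Q, E}


def make_planted_alignment(n_rows: int, n_cols: int,
                           plants: Sequence[tuple[int, int, str]] = (),
                           seed: int = 0) -> dict[str, str]:
    """Random alignment rows with motif variants planted at given columns.

    ``plants`` lists (row index, 1-based column of the basic residue,
    variant label).  Background columns are drawn uniformly from residues
    outside {R, K, Q, E} so no spurious motif can arise.  Returns an
    ordered mapping label -> sequence.
    """
    rng = np.random.default_rng(seed)
    rows = [list(rng.choice(_BACKGROUND_AA, size=n_cols)) for _ in range(n_rows)]

    occupied: set[tuple[int, int]] = set()
    for row, col, variant in plants:
        if variant not in MOTIF_VARIANTS:
            raise ValueError(f"unknown motif variant {variant!r}")
        basic, span, acidic = MOTIF_VARIANTS[variant]
        if not (0 <= row < n_rows):
            raise ValueError(f"row {row} out of range")
        if not (1 <= col and col + span <= n_cols):
            raise ValueError(f"plant {variant} at column {col} does not fit in {n_cols} columns")
        cells = {(row, c) for c in range(col, col + span + 1)}
        if cells & occupied:
            raise ValueError(f"plant at row {row}, column {col} overlaps a previous plant")
        occupied |= cells
        rows[row][col - 1] = basic
        rows[row][col - 1 + span] = acidic
    return {f"row{idx:03d}": "".join(r) for idx, r in enumerate(rows)}


# ---------------------------------------------------------------------------
# trees and simulated characters


def make_random_tree(n_tips: int, seed: int = 0) -> PhyloTree:
    """Pure-birth (Yule) tree scaled to unit root-to-tip depth.

    Ultrametric by construction: lineages split at exponential waiting
    times with unit rate; pendant branches extend to the final epoch.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)

    # active lineages carry their birth time; split times accumulate
    t = 0.0
    root = TreeNode(label=None, length=0.0)
    active: list[tuple[TreeNode, float]] = [(root, 0.0)]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, birth = active.pop(i)
        node.length = (node.length or 0.0) + (t - birth) if node is not root else 0.0
        left, right = TreeNode(length=0.0), TreeNode(length=0.0)
        node.children = [left, right]
        active.append((left, t))
        active.append((right, t))
    t_end = t + rng.exponential(1.0 / len(active))
    tips = []
    for node, birth in active:
        node.length = t_end - birth
        tips.append(node)
    for k, node in enumerate(tips):
        node.label = f"t{k + 1}"
    tree = PhyloTree(root)
    depth = max(tree.tip_depths().values())
    tree.scale(1.0 / depth)
    return tree


@dataclasses.dataclass
class SimulatedCharacterSet:
    """Ground truth of one forward simulation: node states, per-branch
    transition events, resulting tip table, model, and seed."""

    tree: PhyloTree
    node_states: dict[int, int]                   # node id -> state index
    events: dict[int, list[tuple[float, int, int]]]  # node id -> (time, from, to)
    tip_states: dict[str, int]
    model: RateModel
    seed: int


def simulate_character_evolution(tree: PhyloTree, model: RateModel,
                                 root_state: int | str = "draw from prior",
                                 seed: int = 0) -> SimulatedCharacterSet:
    """Gillespie simulation of a discrete character down the tree.

    Waiting times in state s are exponential with rate -Q[s, s]; jumps go
    to state j with probability Q[s, j] / -Q[s, s].  Deterministic given
    the seed.
    """
    rng = np.random.default_rng(seed)
    Q = model.Q
    k = model.k
    if isinstance(root_state, str):
        if root_state != "draw from prior":
            raise ValueError(f"unknown root_state {root_state!r}")
        state0 = int(rng.choice(k, p=model.prior))
    else:
        state0 = int(root_state)
        if not 0 <= state0 < k:
            raise ValueError(f"root state {state0} out of range for {k} states")

    node_states: dict[int, int] = {}
    events: dict[int, list[tuple[float, int, int]]] = {}
    tip_states: dict[str, int] = {}

    def walk(node: TreeNode, state: int) -> None:
        if node is not tree.root:
            if node.length < 0:
                raise ValueError("negative branch length")
            t, branch_events = 0.0, []
            while True:
                rate = -Q[state, state]
                if rate <= 0:
                    break
                t += rng.exponential(1.0 / rate)
                if t >= node.length:
                    break
                probs = np.maximum(Q[state], 0.0)
                probs[state] = 0.0
                new_state = int(rng.choice(k, p=probs / probs.sum()))
                branch_events.append((t, state, new_state))
                state = new_state
            events[id(node)] = branch_events
        node_states[id(node)] = state
        if node.is_leaf():
            tip_states[node.label] = state
        for child in node.children:
            walk(child, state)

    walk(tree.root, state0)
    return SimulatedCharacterSet(tree, node_states, events, tip_states, model, seed)
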