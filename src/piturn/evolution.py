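"""Discrete-character evolution on rooted trees.

Implements the machinery needed to trace a binary or multi-state trait
over a phylogeny: symmetric-rate continuous-time Markov models (ER/SYM),
Felsenstein pruning likelihood, maximum-likelihood rate estimation,
marginal ancestral-state reconstruction, stochastic character mapping
(sampled complete histories conditional on tip data), and parsimony
counts (Fitch/Hartigan minimum changes and single-origin Dollo losses).

Missing tip data is handled conservatively: an unknown tip contributes an
all-ones partial likelihood and is pruned before parsimony counting,
never silently recoded.  Multifurcations are supported natively
throughout (products over all children in the pruning pass, Hartigan
voting in parsimony).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar

# ---------------------------------------------------------------------------
# trees


class TreeNode:
    __slots__ = ("label", "length", "children", "index")

    def __init__(self, label: str | None = None, length: float = 0.0,
                 children: list["TreeNode"] | None = None) -> None:
        self.label = label
        self.length = length
        self.children: list[TreeNode] = children or []
        self.index: int = -1

    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted tree with branch lengths; multifurcations allowed."""

    def __init__(self, root: TreeNode) -> None:
        self.root = root
        self._reindex()
        labels = [t.label for t in self.tips()]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise ValueError("every tip must carry a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for node in self.postorder():
            if node is not self.root:
                if not np.isfinite(node.length) or node.length < 0:
                    raise ValueError(f"branch length must be finite and >= 0, got {node.length}")

    def _reindex(self) -> None:
        self._postorder: list[TreeNode] = []
        self._parent: dict[int, TreeNode | None] = {}

        def walk(node: TreeNode, parent: TreeNode | None) -> None:
            self._parent[id(node)] = parent
            for child in node.children:
                walk(child, node)
            node.index = len(self._postorder)
            self._postorder.append(node)

        walk(self.root, None)

    def postorder(self) -> list[TreeNode]:
        return self._postorder

    def parent(self, node: TreeNode) -> TreeNode | None:
        return self._parent[id(node)]

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf()]

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    def n_tips(self) -> int:
        return len(self.tips())

    def tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}

        def walk(node: TreeNode, depth: float) -> None:
            if node.is_leaf():
                depths[node.label] = depth
            for child in node.children:
                walk(child, depth + child.length)

        walk(self.root, 0.0)
        return depths

    def scale(self, factor: float) -> None:
        for node in self.postorder():
            if node is not self.root:
                node.length *= factor

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf():
                return f"{node.label}:{node.length:.10g}"
            inner = ",".join(render(c) for c in node.children)
            lbl = node.label or ""
            if node is self.root:
                return f"({inner}){lbl}"
            return f"({inner}){lbl}:{node.length:.10g}"

        return render(self.root) + ";"


def read_tree(newick: str) -> PhyloTree:
    """Parse a Newick string (or text of one tree) into a :class:`PhyloTree`."""
    try:
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parser error types
        raise ValueError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = TreeNode(label=label, length=dnode.edge.length or 0.0)
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return PhyloTree(convert(dtree.seed_node))


# ---------------------------------------------------------------------------
# characters


@dataclasses.dataclass
class CharacterMatrix:
    """Tip states for one character: taxon -> state index, None = unknown."""

    states: dict[str, int | None]
    labels: Sequence[str] = ()

    def __post_init__(self) -> None:
        if self.labels:
            k = len(self.labels)
            for taxon, s in self.states.items():
                if s is not None and not (0 <= s < k):
                    raise ValueError(f"{taxon}: state index {s} out of range for {k} states")

    @property
    def k(self) -> int:
        if self.labels:
            return len(self.labels)
        observed = [s for s in self.states.values() if s is not None]
        return (max(observed) + 1) if observed else 0

    def observed_states(self) -> set[int]:
        return {s for s in self.states.values() if s is not None}

    @classmethod
    def from_tsv(cls, path, labels: Sequence[str] = ("absent", "present"),
                 missing_tokens: frozenset[str] = frozenset({"?", "NA", "unknown", "-"})):
        """Two-column TSV (taxon, state label); '#' lines are comments."""
        states: dict[str, int | None] = {}
        lookup = {lbl: i for i, lbl in enumerate(labels)}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                taxon, value = line.split("\t")[:2]
                if value in missing_tokens:
                    states[taxon] = None
                elif value in lookup:
                    states[taxon] = lookup[value]
                else:
                    states[taxon] = int(value)
        return cls(states, labels)


# ---------------------------------------------------------------------------
# rate models


class RateModel:
    """Symmetric-rate CTMC: Q with q_ij = q_ji >= 0, zero row sums, root prior."""

    def __init__(self, Q: np.ndarray, prior: np.ndarray | None = None,
                 labels: Sequence[str] = ()) -> None:
        Q = np.asarray(Q, dtype=float)
        k = Q.shape[0]
        if Q.shape != (k, k):
            raise ValueError("Q must be square")
        off = Q - np.diag(np.diag(Q))
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal rates must be non-negative")
        if not np.allclose(off, off.T):
            raise ValueError("SYM model requires q_ij == q_ji")
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("rows of Q must sum to zero")
        self.Q = Q
        self.k = k
        self.labels = tuple(labels) if labels else tuple(str(i) for i in range(k))
        if prior is None:
            prior = np.full(k, 1.0 / k)
        prior = np.asarray(prior, dtype=float)
        if prior.shape != (k,) or not np.isclose(prior.sum(), 1.0) or np.any(prior < 0):
            raise ValueError("root prior must be a probability vector of length k")
        self.prior = prior

    @classmethod
    def equal_rates(cls, k: int, q: float, **kw) -> "RateModel":
        """ER model: every transition at rate q."""
        Q = np.full((k, k), q, dtype=float)
        np.fill_diagonal(Q, -(k - 1) * q)
        return cls(Q, **kw)

    @classmethod
    def sym(cls, k: int, rates: Sequence[float], **kw) -> "RateModel":
        """SYM model from the upper-triangle rates, row-major order."""
        rates = np.asarray(rates, dtype=float)
        m = k * (k - 1) // 2
        if rates.shape != (m,):
            raise ValueError(f"SYM with {k} states needs {m} rates, got {rates.shape}")
        Q = np.zeros((k, k))
        iu = np.triu_indices(k, 1)
        Q[iu] = rates
        Q = Q + Q.T
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return cls(Q, **kw)

    def upper_rates(self) -> np.ndarray:
        return self.Q[np.triu_indices(self.k, 1)]


def transition_matrix(model: RateModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, P(0) = I."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if t == 0:
        return np.eye(model.k)
    P = expm(model.Q * t)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# pruning likelihood


def _tip_partial(k: int, state: int | None) -> np.ndarray:
    if state is None:
        return np.ones(k)
    if not 0 <= state < k:
        raise ValueError(f"state index {state} out of range for {k} states")
    partial = np.zeros(k)
    partial[state] = 1.0
    return partial


def _upward_pass(tree: PhyloTree, chars: CharacterMatrix, model: RateModel):
    """Partial likelihoods and per-branch P matrices; log-scaled.

    Returns (partials, log_scale, P) indexed by node.index; P[i] is the
    transition matrix along the branch above node i.
    """
    k = model.k
    n = len(tree.postorder())
    partials = np.empty((n, k))
    log_scale = np.zeros(n)
    P: list[np.ndarray | None] = [None] * n
    for node in tree.postorder():
        i = node.index
        if node is not tree.root:
            P[i] = transition_matrix(model, node.length)
        if node.is_leaf():
            if node.label not in chars.states:
                raise KeyError(f"tip {node.label!r} has no character entry")
            partials[i] = _tip_partial(k, chars.states[node.label])
        else:
            part = np.ones(k)
            for child in node.children:
                j = child.index
                part = part * (P[j] @ partials[j])
                log_scale[i] += log_scale[j]
            m = part.max()
            if m <= 0:
                # impossible data under this model (e.g. zero rates, conflicting tips)
                partials[i] = part
                continue
            partials[i] = part / m
            log_scale[i] += np.log(m)
    return partials, log_scale, P


def pruning_loglik(tree: PhyloTree, chars: CharacterMatrix, model: RateModel) -> float:
    """Felsenstein pruning log-likelihood; missing tips as all-ones partials."""
    partials, log_scale, _ = _upward_pass(tree, chars, model)
    r = tree.root.index
    lik = float(model.prior @ partials[r])
    if lik <= 0:
        return -np.inf
    return np.log(lik) + log_scale[r]


# ---------------------------------------------------------------------------
# ML rate fitting


@dataclasses.dataclass
class FitResult:
    model: RateModel
    loglik: float
    converged: bool
    n_evals: int


def fit_rates_ml(tree: PhyloTree,
                 chars: CharacterMatrix | Sequence[CharacterMatrix],
                 model_spec: str = "ER", k: int | None = None,
                 max_rate: float = 1e3, tol: float = 1e-8,
                 prior: np.ndarray | None = None) -> FitResult:
    """Maximize the pruning likelihood over non-negative transition rates.

    ``model_spec`` selects ER (one shared rate) or SYM (one rate per
    unordered state pair).  ``chars`` may be one character or several
    independent characters sharing the state space; their log-likelihoods
    add.  Invariant data returns the rate-zero boundary with a warning
    rather than failing.
    """
    spec = model_spec.upper()
    if spec not in {"ER", "SYM"}:
        raise ValueError(f"model_spec must be 'ER' or 'SYM', got {model_spec!r}")
    char_list = [chars] if isinstance(chars, CharacterMatrix) else list(chars)
    if k is None:
        k = max(c.k for c in char_list)
    if k < 2:
        raise ValueError("need at least 2 states")

    def total_loglik(model: RateModel) -> float:
        return sum(pruning_loglik(tree, c, model) for c in char_list)

    if all(len(c.observed_states()) < 2 for c in char_list):
        warnings.warn("all observed tips share one state; returning rate-0 boundary model")
        model = RateModel.equal_rates(k, 0.0, prior=prior)
        return FitResult(model, total_loglik(model), True, 1)

    evals = [0]

    if spec == "ER":
        def nll(q: float) -> float:
            evals[0] += 1
            return -total_loglik(RateModel.equal_rates(k, q, prior=prior))

        # the surface can have a saturation plateau at high rates; scan a
        # log-spaced grid first, then refine around the best bracket
        grid = np.geomspace(1e-4, max_rate, 40)
        values = [nll(q) for q in grid]
        i = int(np.argmin(values))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                              options={"xatol": tol})
        model = RateModel.equal_rates(k, float(res.x), prior=prior)
        return FitResult(model, -float(res.fun), bool(res.success), evals[0])

    m = k * (k - 1) // 2

    def nll_vec(rates: np.ndarray) -> float:
        evals[0] += 1
        return -total_loglik(RateModel.sym(k, rates, prior=prior))

    # start from the best shared rate on a coarse log grid (avoids the
    # high-rate saturation plateau), then optimize per-pair rates
    grid = np.geomspace(1e-4, max_rate, 25)
    q0 = grid[int(np.argmin([nll_vec(np.full(m, q)) for q in grid]))]
    x0 = np.full(m, q0)
    res = minimize(nll_vec, x0, method="L-BFGS-B",
                   bounds=[(0.0, max_rate)] * m, options={"ftol": tol, "gtol": 1e-8})
    model = RateModel.sym(k, res.x, prior=prior)
    return FitResult(model, -float(res.fun), bool(res.success), evals[0])


# ---------------------------------------------------------------------------
# marginal ancestral reconstruction


def marginal_asr(tree: PhyloTree, chars: CharacterMatrix,
                 model: RateModel) -> dict[int, np.ndarray]:
    """Marginal posterior state probabilities for every node.

    Up/down message passing: the downward message into a node combines the
    root prior with the upward partials of everything outside that node's
    subtree.  Keys are node indices (``node.index``); each vector sums to 1.
    """
    partials, _, P = _upward_pass(tree, chars, model)
    k = model.k
    down: dict[int, np.ndarray] = {tree.root.index: model.prior.copy()}
    posteriors: dict[int, np.ndarray] = {}

    for node in reversed(tree.postorder()):  # preorder
        i = node.index
        post = down[i] * partials[i]
        total = post.sum()
        if total <= 0:
            raise ValueError("data impossible under the supplied model")
        posteriors[i] = post / total
        if node.is_leaf():
            continue
        child_msgs = {c.index: P[c.index] @ partials[c.index] for c in node.children}
        for child in node.children:
            msg = down[i].copy()
            for other in node.children:
                if other is not child:
                    msg = msg * child_msgs[other.index]
            down[child.index] = P[child.index].T @ msg
    return posteriors


# ---------------------------------------------------------------------------
# stochastic character mapping


@dataclasses.dataclass
class SimmapSample:
    """One sampled character history: states at nodes plus, for every
    non-root node, the ordered (state, duration) segments of the branch
    above it, durations summing to the branch length."""

    node_states: dict[int, int]
    branch_segments: dict[int, list[tuple[int, float]]]

    def transition_count(self) -> int:
        return sum(len(seg) - 1 for seg in self.branch_segments.values())

    def transition_counts_by_type(self, k: int) -> np.ndarray:
        counts = np.zeros((k, k), dtype=int)
        for segments in self.branch_segments.values():
            for (a, _), (b, _) in zip(segments, segments[1:]):
                counts[a, b] += 1
        return counts


def _sample_path_rejection(rng, model: RateModel, a: int, b: int, t: float,
                           max_tries: int) -> list[tuple[int, float]] | None:
    Q = model.Q
    k = model.k
    for _ in range(max_tries):
        state, elapsed = a, 0.0
        segments: list[tuple[int, float]] = []
        while True:
            rate = -Q[state, state]
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if elapsed + wait >= t:
                segments.append((state, t - elapsed))
                break
            segments.append((state, wait))
            elapsed += wait
            probs = np.maximum(Q[state], 0.0)
            probs[state] = 0.0
            state = int(rng.choice(k, p=probs / probs.sum()))
        if state == b:
            return segments
    return None


def _sample_path_uniformization(rng, model: RateModel, a: int, b: int,
                                t: float) -> list[tuple[int, float]]:
    """Exact endpoint-conditioned path via uniformization (virtual jumps)."""
    Q = model.Q
    k = model.k
    R = float(np.max(-np.diag(Q)))
    if R <= 0:
        if a != b:
            raise RuntimeError("zero-rate model cannot connect differing endpoints")
        return [(a, t)]
    U = np.eye(k) + Q / R

    # sample the number of virtual jumps: p(n) prop. to Pois(Rt)(n) [U^n]_ab
    powers = [np.eye(k)]
    log_pois = -R * t
    target = rng.random() * expm(Q * t)[a, b]
    cum, n = 0.0, -1
    while True:
        n += 1
        if n > 0:
            powers.append(powers[-1] @ U)
            log_pois += np.log(R * t) - np.log(n)
        cum += np.exp(log_pois) * powers[n][a, b]
        if cum >= target or n > 10000:
            break

    times = np.sort(rng.random(n) * t)
    states = [a]
    for i in range(1, n):
        # bridge: p(s_i = c) prop. to U[s_{i-1}, c] * [U^{n-i}]_{c, b}
        w = U[states[-1]] * powers[n - i][:, b]
        states.append(int(rng.choice(k, p=w / w.sum())))
    if n > 0:
        states.append(b)

    segments: list[tuple[int, float]] = []
    cur, start = a, 0.0
    for i in range(1, n + 1):
        if states[i] != cur:
            segments.append((cur, times[i - 1] - start))
            start = times[i - 1]
            cur = states[i]
    segments.append((cur, t - start))
    return segments


def sample_conditioned_path(model: RateModel, a: int, b: int, t: float,
                            rng: np.random.Generator | int = 0,
                            rejection_tries: int = 1000) -> list[tuple[int, float]]:
    """One (state, duration) path along a branch conditional on endpoints.

    Rejection sampling first; exact uniformization after ``rejection_tries``
    failed attempts.  Durations sum to ``t``; the path starts in ``a`` and
    ends in ``b``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if t == 0:
        if a != b:
            raise ValueError("zero-length branch cannot connect differing states")
        return [(a, 0.0)]
    path = _sample_path_rejection(rng, model, a, b, t, rejection_tries)
    if path is None:
        path = _sample_path_uniformization(rng, model, a, b, t)
    return path


def sample_stochastic_maps(tree: PhyloTree, chars: CharacterMatrix,
                           model: RateModel, n: int, seed: int = 0,
                           rejection_tries: int = 1000) -> list[SimmapSample]:
    """Sample complete character histories conditional on tip data.

    Node states come from their joint conditional distribution (root-to-tip
    sampling over the upward partials); branch paths are drawn conditional
    on their endpoints, by rejection first and exact uniformization after
    ``rejection_tries`` failures.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    partials, _, P = _upward_pass(tree, chars, model)
    k = model.k
    samples: list[SimmapSample] = []
    preorder = list(reversed(tree.postorder()))

    for _ in range(n):
        node_states: dict[int, int] = {}
        segments: dict[int, list[tuple[int, float]]] = {}
        for node in preorder:
            i = node.index
            if node is tree.root:
                w = model.prior * partials[i]
                node_states[i] = int(rng.choice(k, p=w / w.sum()))
                continue
            parent_state = node_states[tree.parent(node).index]
            w = P[i][parent_state] * partials[i]
            state = int(rng.choice(k, p=w / w.sum()))
            node_states[i] = state
            if node.length == 0:
                if state != parent_state:
                    raise AssertionError("zero-length branch with differing endpoint states")
                segments[i] = [(state, 0.0)]
                continue
            path = _sample_path_rejection(rng, model, parent_state, state,
                                          node.length, rejection_tries)
            if path is None:
                path = _sample_path_uniformization(rng, model, parent_state,
                                                   state, node.length)
            segments[i] = path
        samples.append(SimmapSample(node_states, segments))
    return samples


@dataclasses.dataclass
class TransitionSummary:
    node_frequencies: dict[int, np.ndarray]   # node index -> state frequencies
    mean_counts: np.ndarray                   # (k, k) mean count per ordered type
    count_quantiles: dict[str, float]         # quantiles of the total count
    n_samples: int


def summarize_maps(samples: Sequence[SimmapSample], k: int,
                   quantiles: Sequence[float] = (0.025, 0.5, 0.975)) -> TransitionSummary:
    """Node state frequencies and transition-count statistics over samples."""
    if not samples:
        raise ValueError("need at least one sample")
    node_ids = set(samples[0].node_states)
    counts = {i: np.zeros(k) for i in node_ids}
    type_counts = np.zeros((k, k))
    totals = []
    for s in samples:
        if set(s.node_states) != node_ids:
            raise ValueError("samples come from different trees")
        for i, state in s.node_states.items():
            counts[i][state] += 1
        type_counts += s.transition_counts_by_type(k)
        totals.append(s.transition_count())
    n = len(samples)
    freqs = {i: c / n for i, c in counts.items()}
    qs = {f"q{q:g}": float(np.quantile(totals, q)) for q in quantiles}
    return TransitionSummary(freqs, type_counts / n, qs, n)


# ---------------------------------------------------------------------------
# parsimony


def fitch_parsimony(tree: PhyloTree, chars: CharacterMatrix) -> int:
    """Minimum number of state changes (Hartigan voting; handles
    multifurcations exactly).  Tips with missing data are pruned."""
    cost = 0

    def walk(node: TreeNode) -> set[int] | None:
        nonlocal cost
        if node.is_leaf():
            s = chars.states.get(node.label)
            return None if s is None else {s}
        child_sets = [cs for cs in (walk(c) for c in node.children) if cs is not None]
        if not child_sets:
            return None
        votes: dict[int, int] = {}
        for cs in child_sets:
            for s in cs:
                votes[s] = votes.get(s, 0) + 1
        kmax = max(votes.values())
        cost += len(child_sets) - kmax
        return {s for s, v in votes.items() if v == kmax}

    walk(tree.root)
    return cost


def dollo_loss_count(tree: PhyloTree, chars: CharacterMatrix,
                     root_state: int = 1) -> int:
    """Losses under single-origin, irreversible-loss (Dollo) parsimony.

    The character is binary (0 = absent, 1 = present) and declared present
    at the root; each loss is placed on the highest node whose non-missing
    tip descendants are all absent.  Tips with missing data do not anchor
    or veto a loss.
    """
    observed = chars.observed_states()
    if not observed <= {0, 1}:
        raise ValueError("Dollo counting requires a binary (0/1) character")
    if root_state != 1:
        if 1 in observed:
            raise ValueError("root declared absent but present tips exist; "
                             "violates the single-origin premise")
        return 0

    losses = 0

    def walk(node: TreeNode) -> str:
        """Returns 'absent', 'present', or 'nodata' for the subtree."""
        nonlocal losses
        if node.is_leaf():
            s = chars.states.get(node.label)
            if s is None:
                return "nodata"
            return "present" if s == 1 else "absent"
        child_status = [walk(c) for c in node.children]
        informative = [st for st in child_status if st != "nodata"]
        if not informative:
            return "nodata"
        if all(st == "absent" for st in informative):
            return "absent"
        # mixed subtree: each maximal all-absent child clade takes one loss
        for st in child_status:
            if st == "absent":
                losses += 1
        return "present"

    if walk(tree.root) == "absent":
        losses += 1  # everything observed is absent: one loss below the root
    return losses


# ---------------------------------------------------------------------------
# plain-text output helpers


def write_posterior_tsv(tree: PhyloTree, posteriors: dict[int, np.ndarray],
                        labels: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("# marginal ancestral state posteriors; node = postorder index\n")
        fh.write("node\tis_tip\tlabel\t" + "\t".join(f"p_{l}" for l in labels) + "\n")
        for node in tree.postorder():
            p = posteriors[node.index]
            fh.write(f"{node.index}\t{int(node.is_leaf())}\t{node.label or '.'}\t"
                     + "\t".join(f"{x:.6f}" for x in p) + "\n")


def write_simmap_samples(tree: PhyloTree, samples: Sequence[SimmapSample],
                         labels: Sequence[str], path) -> None:
    """Documented plain-text format: one line per branch per sample,
    ``sample<TAB>node<TAB>state:duration,state:duration,...``"""
    with open(path, "w") as fh:
        fh.write("# stochastic map samples; node = postorder index of the branch's"
                 " child node; segments run parent-to-child\n")
        for si, s in enumerate(samples):
            for i, segments in sorted(s.branch_segments.items()):
                seg = ",".join(f"{labels[st]}:{d:.6g}" for st, d in segments)
                fh.write(f"{si}\t{i}\t{seg}\n")
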