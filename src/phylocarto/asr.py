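"""Maximum-likelihood ancestral reconstruction of a discrete character.

The character evolves on the fixed, time-calibrated tree under an F81-like
continuous-time Markov model: substitutions land on state j with stationary
probability pi_j regardless of the current state, giving the closed-form
transition probability

    P(j | i, t) = pi_j + (delta_ij - pi_j) * exp(-beta * scale * t)

where beta = 1 / (1 - sum pi_k^2) normalizes the process to one expected
substitution per unit of scaled branch length, and ``scale`` is a constant
branch-length multiplier fitted by maximum likelihood to match the rate of
evolution of the character to the time scale of the tree.

The module provides the total likelihood by Felsenstein's pruning
algorithm (with per-node rescaling against underflow), the per-node
marginal posterior state probabilities by the up-down algorithm, the joint
ML reconstruction by Pupko-style dynamic programming, and the display rule
that retains, at each node, every modality whose posterior probability
reaches the majority modality minus a user percentage of its value.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DataError, OptimizationError, ParameterError
from .tree import AnnotatedTree

DEFAULT_SCALE_BRACKET = (1e-4, 1e3)


@dataclass
class F81Model:
    """States, stationary frequencies and the fitted branch-scaling factor."""

    states: list[str]
    pi: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        self.pi = np.asarray(self.pi, float)
        if len(self.states) < 2:
            raise ParameterError("an F81 model needs at least two states")
        if len(self.pi) != len(self.states):
            raise ParameterError("pi length must match the number of states")
        if abs(self.pi.sum() - 1.0) > 1e-12 or (self.pi <= 0).any():
            raise ParameterError("pi must be strictly positive and sum to 1")
        if self.scale <= 0:
            raise ParameterError("scale must be positive")

    @property
    def m(self) -> int:
        return len(self.states)

    @property
    def beta(self) -> float:
        return 1.0 / (1.0 - float(self.pi @ self.pi))

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise DataError(f"unknown state label {state!r}") from None

    def rate_matrix(self) -> np.ndarray:
        """The normalized F81 rate matrix Q (rows sum to zero)."""
        q = self.beta * np.tile(self.pi, (self.m, 1))
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


def f81_matrix(model: F81Model, t: float, scale: float | None = None) -> np.ndarray:
    """Transition probability matrix P(t) in closed form."""
    if t < 0:
        raise ParameterError("branch length must be non-negative")
    s = model.scale if scale is None else scale
    decay = math.exp(-model.beta * s * t)
    p = (1.0 - decay) * np.tile(model.pi, (model.m, 1))
    p[np.diag_indices(model.m)] += decay
    return p


def f81_transition_prob(model: F81Model, i: str | int, j: str | int, t: float) -> float:
    """P(state j at the child | state i at the parent, branch length t)."""
    ii = i if isinstance(i, int) else model.index(i)
    jj = j if isinstance(j, int) else model.index(j)
    return float(f81_matrix(model, t)[ii, jj])


# ---------------------------------------------------------------------------
# tip data


def empirical_frequencies(
    tip_states: dict[str, object], states: list[str], pseudocount: float = 1.0
) -> np.ndarray:
    """Tip-state frequencies with a pseudocount per state (never zero)."""
    counts = np.full(len(states), pseudocount, float)
    idx = {s: i for i, s in enumerate(states)}
    for value in tip_states.values():
        if value is None:
            continue
        if isinstance(value, str):
            counts[idx[value]] += 1.0
    return counts / counts.sum()


def observed_states(tip_states: dict[str, object]) -> list[str]:
    found = set()
    for value in tip_states.values():
        if isinstance(value, str):
            found.add(value)
        elif value is not None:
            found.update(value)
    return sorted(found)


def _tip_vector(value, model: F81Model) -> np.ndarray:
    """Conditional likelihood vector at a tip: a point mass for an observed
    state, a 0/1 mask for an ambiguity set, all ones for missing data."""
    if value is None:
        return np.ones(model.m)
    vec = np.zeros(model.m)
    if isinstance(value, str):
        vec[model.index(value)] = 1.0
    else:
        for s in value:
            vec[model.index(s)] = 1.0
        if not vec.any():
            raise DataError("empty ambiguity set")
    return vec


def _tip_vectors(tree: AnnotatedTree, tip_states: dict[str, object], model: F81Model):
    vectors = {}
    for tip in tree.tips():
        label = tip.taxon_label
        if label not in tip_states:
            raise DataError(f"tip {label!r} has no state in the trait data")
        vectors[tip.id] = _tip_vector(tip_states[label], model)
    return vectors


# ---------------------------------------------------------------------------
# pruning


def _partials(tree: AnnotatedTree, tip_states, model: F81Model, scale: float):
    """Post-order conditional likelihoods with per-node rescaling.

    Returns (partials, log_rescale_total, transition matrices per node).
    """
    tips = _tip_vectors(tree, tip_states, model)
    partials: dict[int, np.ndarray] = {}
    pmats: dict[int, np.ndarray] = {}
    log_rescale = 0.0
    for nid in tree.postorder():
        node = tree.nodes[nid]
        if node.parent is not None:
            pmats[nid] = f81_matrix(model, node.branch_length or 0.0, scale)
        if node.is_leaf:
            partials[nid] = tips[nid].astype(float)
            continue
        vec = np.ones(model.m)
        for c in node.children:
            vec = vec * (pmats[c] @ partials[c])
        top = vec.max()
        if top <= 0:
            raise OptimizationError("zero likelihood: data impossible under the model")
        partials[nid] = vec / top
        log_rescale += math.log(top)
    return partials, log_rescale, pmats


def pruning_log_likelihood(
    tree: AnnotatedTree,
    tip_states: dict[str, object],
    model: F81Model,
    scale: float | None = None,
) -> float:
    """Total log-likelihood of the tip data by Felsenstein's pruning."""
    s = model.scale if scale is None else scale
    partials, log_rescale, _ = _partials(tree, tip_states, model, s)
    site = float(model.pi @ partials[tree.root_id])
    if site <= 0:
        raise OptimizationError("zero likelihood at the root")
    return math.log(site) + log_rescale


def fit_scale(
    tree: AnnotatedTree,
    tip_states: dict[str, object],
    pi: np.ndarray,
    states: list[str] | None = None,
    bracket: tuple[float, float] = DEFAULT_SCALE_BRACKET,
) -> tuple[float, float]:
    """ML estimate of the branch-scaling factor.

    One-dimensional Brent maximization of the pruning log-likelihood over
    log(scale) inside ``bracket``; returns (scale, log-likelihood).  The
    result never scores below either bracket end.
    """
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ParameterError("bracket must satisfy 0 < lo < hi")
    if states is None:
        states = observed_states(tip_states)
    model = F81Model(states=states, pi=np.asarray(pi, float))

    def negll(log_s: float) -> float:
        value = -pruning_log_likelihood(tree, tip_states, model, scale=math.exp(log_s))
        if not math.isfinite(value):
            raise OptimizationError("non-finite likelihood during scale fitting")
        return value

    res = minimize_scalar(
        negll, bounds=(math.log(lo), math.log(hi)), method="bounded",
        options={"xatol": 1e-7},
    )
    candidates = [(negll(math.log(lo)), lo), (negll(math.log(hi)), hi),
                  (res.fun, math.exp(res.x))]
    best_negll, best_scale = min(candidates, key=lambda t: t[0])
    return best_scale, -best_negll


# ---------------------------------------------------------------------------
# marginal posteriors (up-down) and joint ML (max-product DP)


def marginal_posteriors(
    tree: AnnotatedTree, tip_states: dict[str, object], model: F81Model
) -> dict[int, np.ndarray]:
    """Posterior P(state | all tip data) for every node; vectors sum to 1."""
    partials, _, pmats = _partials(tree, tip_states, model, model.scale)
    outside: dict[int, np.ndarray] = {tree.root_id: model.pi.copy()}
    posteriors: dict[int, np.ndarray] = {}
    for nid in tree.preorder():
        node = tree.nodes[nid]
        post = outside[nid] * partials[nid]
        total = post.sum()
        if total <= 0:
            raise OptimizationError("zero posterior mass (data impossible)")
        posteriors[nid] = post / total
        if node.is_leaf:
            continue
        down = [pmats[c] @ partials[c] for c in node.children]
        for k, c in enumerate(node.children):
            sib = outside[nid].copy()
            for k2, vec in enumerate(down):
                if k2 != k:
                    sib = sib * vec
            out = sib @ pmats[c]
            top = out.max()
            outside[c] = out / top if top > 0 else out
    return posteriors


def joint_ml(
    tree: AnnotatedTree, tip_states: dict[str, object], model: F81Model
) -> tuple[dict[int, str], float]:
    """Single best assignment of states to all nodes (Pupko dynamic
    programming); returns (node -> state label, joint log-likelihood).
    Ties break toward the lowest state index."""
    tips = _tip_vectors(tree, tip_states, model)
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi)
    # cost[v][s] = max over states of the clade of v of the log-likelihood,
    # given that v's parent is in state s; choice[v][s] = the argmax state of v
    cost: dict[int, np.ndarray] = {}
    choice: dict[int, np.ndarray] = {}
    for nid in tree.postorder():
        node = tree.nodes[nid]
        if node.is_leaf:
            with np.errstate(divide="ignore"):
                own = np.log(tips[nid])
        else:
            own = np.zeros(model.m)
            for c in node.children:
                own = own + cost[c]
        if node.parent is None:
            scores = log_pi + own
            root_state = int(np.argmax(scores))
            best = float(scores[root_state])
            assignment_root = root_state
            continue
        with np.errstate(divide="ignore"):
            log_p = np.log(f81_matrix(model, node.branch_length or 0.0, model.scale))
        table = log_p + own[None, :]  # [parent state, own state]
        choice[nid] = np.argmax(table, axis=1)
        cost[nid] = table[np.arange(model.m), choice[nid]]

    assignment: dict[int, str] = {}
    state_of: dict[int, int] = {tree.root_id: assignment_root}
    for nid in tree.preorder():
        node = tree.nodes[nid]
        if node.parent is not None:
            state_of[nid] = int(choice[nid][state_of[node.parent]])
        assignment[nid] = model.states[state_of[nid]]
    return assignment, best


# ---------------------------------------------------------------------------
# display rules


def retain_modalities(posterior: np.ndarray, percent: float, states: list[str]) -> list[str]:
    """States retained for display: all whose probability reaches the
    majority modality minus ``percent`` per cent of its value."""
    if not (0 <= percent <= 100):
        raise ParameterError("percent must be in [0, 100]")
    posterior = np.asarray(posterior, float)
    threshold = posterior.max() * (1.0 - percent / 100.0)
    return [s for s, p in zip(states, posterior) if p >= threshold - 1e-12]


def cluster_pie_counts(
    retained: dict[int, list[str]],
    grouping: dict[int, int],
    tips_only: bool = False,
    tree: AnnotatedTree | None = None,
) -> dict[int, dict[str, int]]:
    """Per-group counts of retained categories, for pie-chart rendering.

    ``grouping`` maps node id to group index (a spatial clustering
    assignment or a transition-tree membership).  A node retaining several
    modalities increments each of them.
    """
    if tips_only and tree is None:
        raise ParameterError("tips_only counting needs the tree")
    missing = [nid for nid in retained if nid not in grouping]
    if missing:
        from .errors import CoverageError

        raise CoverageError(f"grouping lacks nodes {missing[:10]}", missing)
    counts: dict[int, dict[str, int]] = {}
    for nid, states_kept in retained.items():
        if tips_only and not tree.nodes[nid].is_leaf:
            continue
        group = counts.setdefault(grouping[nid], {})
        for s in states_kept:
            group[s] = group.get(s, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# high-level driver + I/O


@dataclass
class ASRResult:
    model: F81Model
    log_likelihood: float
    marginals: dict[int, np.ndarray]
    joint: dict[int, str]
    joint_log_likelihood: float
    retained: dict[int, list[str]] = field(default_factory=dict)


def reconstruct(
    tree: AnnotatedTree,
    tip_states: dict[str, object],
    states: list[str] | None = None,
    pi: np.ndarray | str = "empirical",
    fit: bool = True,
    scale: float = 1.0,
    threshold_percent: float = 20.0,
    bracket: tuple[float, float] = DEFAULT_SCALE_BRACKET,
) -> ASRResult:
    """Fit the model (optionally), then reconstruct marginals, the joint
    assignment and the retained modality sets in one call.

    ``pi`` may be "empirical" (tip frequencies with +1 pseudocount, the
    default), "equal", or an explicit frequency vector.
    """
    if states is None:
        states = observed_states(tip_states)
    if isinstance(pi, str):
        if pi == "empirical":
            freqs = empirical_frequencies(tip_states, states)
        elif pi == "equal":
            freqs = np.full(len(states), 1.0 / len(states))
        else:
            raise ParameterError(f"unknown pi mode {pi!r}")
    else:
        freqs = np.asarray(pi, float)
    if fit:
        scale, loglik = fit_scale(tree, tip_states, freqs, states, bracket)
    model = F81Model(states=states, pi=freqs, scale=scale)
    if not fit:
        loglik = pruning_log_likelihood(tree, tip_states, model)
    marginals = marginal_posteriors(tree, tip_states, model)
    joint, joint_ll = joint_ml(tree, tip_states, model)
    retained = {
        nid: retain_modalities(vec, threshold_percent, states)
        for nid, vec in marginals.items()
    }
    return ASRResult(model, loglik, marginals, joint, joint_ll, retained)


def read_tip_states_csv(path) -> dict[str, str]:
    """Two-column CSV ``taxon,state`` (header row optional)."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if rows and rows[0][:2] == ["taxon", "state"]:
        rows = rows[1:]
    for row in rows:
        if len(row) >= 2 and row[0].strip():
            out[row[0].strip()] = row[1].strip()
    return out


def tip_states_from_tree(tree: AnnotatedTree) -> dict[str, str | None]:
    """Tip states read off the tree's discrete-trait annotations."""
    return {tip.taxon_label: tip.discrete_trait for tip in tree.tips()}


def result_to_csv(result: ASRResult, out_path) -> None:
    with open(out_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["node_id"] + [f"p_{s}" for s in result.model.states]
            + ["joint_state", "retained"]
        )
        for nid in sorted(result.marginals):
            writer.writerow(
                [nid]
                + [repr(float(p)) for p in result.marginals[nid]]
                + [result.joint[nid], "|".join(result.retained.get(nid, []))]
            )


def annotate_tree(tree: AnnotatedTree, result: ASRResult) -> AnnotatedTree:
    """Write joint states and posteriors back onto the tree's annotations
    so they survive NEXUS round-trips."""
    for nid, node in tree.nodes.items():
        node.discrete_trait = result.joint[nid]
        probs = ",".join(repr(float(p)) for p in result.marginals[nid])
        node.extra["state_probs"] = "{" + probs + "}"
    return tree
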