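"""Amino-acid phylogenetic likelihood on condition-labelled trees.

Implements Felsenstein pruning with branch-heterogeneous equilibrium
frequencies (one frequency vector per condition), exact marginal ancestral
reconstruction by inside-outside message passing, and the "one change"
constraint that forces at least one substitution on phenotype-transition
branches. All computations are vectorised over alignment columns; gaps are
marginalised; partial likelihoods are rescaled per node to avoid underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .phylo_core import ANCESTRAL, CONVERGENT, ConditionedTree, GAP

FREQ_FLOOR = 1e-6


def _floor_freqs(freqs: np.ndarray) -> np.ndarray:
    """Floor zero frequencies at 1e-6 and renormalise.

    Profiles produced by count-thresholding rules can assign frequency 0 to
    states that are nonetheless observed in the column; without the floor
    such states would force a -inf log-likelihood.
    """
    f = np.maximum(np.asarray(freqs, dtype=float), FREQ_FLOOR)
    return f / f.sum()


@dataclass
class AAModel:
    """20-state substitution model with per-condition frequencies.

    ``exchangeabilities`` is a symmetric 20x20 matrix of relative exchange
    rates; None selects uniform exchange, for which transition matrices have
    the closed form P(t) = e^{-t/beta} I + (1 - e^{-t/beta}) 1 pi^T. Each
    condition's rate matrix Q_ij = r_ij pi_j is rescaled to expected rate 1
    under that condition's frequencies. The root is weighted with the
    ancestral-condition frequencies unless ``root_freqs`` overrides it.
    """

    freqs: dict[str, np.ndarray]
    exchangeabilities: np.ndarray | None = None
    root_freqs: np.ndarray | None = None

    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.freqs = {k: _floor_freqs(v) for k, v in self.freqs.items()}
        if ANCESTRAL not in self.freqs:
            raise ValueError("model needs frequencies for the ancestral "
                             "condition")
        if self.exchangeabilities is not None:
            R = np.asarray(self.exchangeabilities, dtype=float)
            if R.shape != (20, 20) or not np.allclose(R, R.T):
                raise ValueError("exchangeabilities must be symmetric 20x20")
            if np.any(R < 0):
                raise ValueError("exchangeabilities must be non-negative")
            self.exchangeabilities = R
        if self.root_freqs is None:
            self.root_freqs = self.freqs[ANCESTRAL]
        else:
            self.root_freqs = _floor_freqs(self.root_freqs)

    @classmethod
    def homogeneous(cls, freqs, exchangeabilities=None) -> "AAModel":
        f = np.asarray(freqs, dtype=float)
        return cls(freqs={ANCESTRAL: f, CONVERGENT: f},
                   exchangeabilities=exchangeabilities)

    def condition_freqs(self, condition: str) -> np.ndarray:
        if condition not in self.freqs:
            raise KeyError(f"no frequencies for condition {condition!r}")
        return self.freqs[condition]

    def rate_matrix(self, condition: str) -> np.ndarray:
        pi = self.condition_freqs(condition)
        if self.exchangeabilities is None:
            Q = np.tile(pi, (20, 1))
        else:
            Q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -(pi * np.diag(Q)).sum()
        return Q / rate

    def transition_matrix(self, condition: str, t: float) -> np.ndarray:
        """P(t) for a branch of length ``t`` under ``condition``."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        key = (condition, round(float(t), 12))
        if key in self._cache:
            return self._cache[key]
        pi = self.condition_freqs(condition)
        if self.exchangeabilities is None:
            beta = 1.0 - (pi ** 2).sum()
            e = np.exp(-t / beta)
            P = e * np.eye(20) + (1.0 - e) * np.tile(pi, (20, 1))
        else:
            P = expm(self.rate_matrix(condition) * t)
        self._cache[key] = P
        return P


def one_change_transition(P: np.ndarray) -> np.ndarray:
    """Condition a row-stochastic matrix on at least one change.

    The diagonal is zeroed and each row renormalised by 1 - P[i,i]. A row
    with P[i,i] = 1 admits no change: it is returned as all zeros, which
    propagates a -inf log-likelihood contribution downstream.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if np.any(P < -1e-12) or np.any(np.abs(P.sum(axis=1) - 1) > 1e-8):
        raise ValueError("P must be row-stochastic")
    out = P.copy()
    np.fill_diagonal(out, 0.0)
    rowsum = out.sum(axis=1)
    stuck = rowsum <= 0
    rowsum[stuck] = 1.0
    out = out / rowsum[:, None]
    out[stuck] = 0.0
    return out


class PruningEngine:
    """Per-tree pruning machinery with precomputed branch matrices.

    Built once per (tree, model) pair, then reused across all alignment
    columns: ``loglik`` and ``ancestral`` accept a full (n_leaves, n_sites)
    state matrix and are vectorised over sites.
    """

    def __init__(self, ctree: ConditionedTree, model: AAModel | None = None,
                 oc_on_transitions: bool = False, *,
                 P: dict[int, np.ndarray] | None = None,
                 root_freqs: np.ndarray | None = None) -> None:
        self.ctree = ctree
        self.model = model
        t = ctree.tree
        self.postorder = t.postorder()
        if P is not None:
            self.P = P
            if root_freqs is None:
                if model is None:
                    raise ValueError("root_freqs required with explicit P")
                root_freqs = model.root_freqs
            self.root_freqs = np.asarray(root_freqs, dtype=float)
            return
        if model is None:
            raise ValueError("either a model or explicit branch matrices "
                             "are required")
        self.root_freqs = model.root_freqs
        self.P = {}
        for v in range(t.n_nodes):
            if v == t.root:
                continue
            Pv = model.transition_matrix(ctree.branch_condition(v),
                                         t.lengths[v])
            if oc_on_transitions and ctree.is_transition[v]:
                Pv = one_change_transition(Pv)
            self.P[v] = Pv

    def _check_leaves(self, leaf_states: np.ndarray) -> np.ndarray:
        t = self.ctree.tree
        leaf_states = np.atleast_2d(np.asarray(leaf_states, dtype=int))
        if leaf_states.shape[0] != len(t.leaves()):
            raise ValueError("state matrix rows do not match tree leaves")
        if leaf_states.max(initial=GAP) > 19 or leaf_states.min(initial=0) < GAP:
            raise ValueError("unknown amino-acid state index")
        return leaf_states

    def _partials(self, leaf_states: np.ndarray):
        """Post-order conditional likelihoods, rescaled per node.

        Returns (partials keyed by node, shape (n_sites, 20); per-site log
        scale accumulators).
        """
        t = self.ctree.tree
        leaves = t.leaves()
        leaf_row = {v: k for k, v in enumerate(leaves)}
        n_sites = leaf_states.shape[1]
        L: dict[int, np.ndarray] = {}
        logscale = np.zeros(n_sites)
        for v in self.postorder:
            if t.is_leaf(v):
                s = leaf_states[leaf_row[v]]
                arr = np.zeros((n_sites, 20))
                gap = s == GAP
                arr[gap] = 1.0
                arr[np.arange(n_sites)[~gap], s[~gap]] = 1.0
            else:
                arr = np.ones((n_sites, 20))
                for c in t.children[v]:
                    arr = arr * (L[c] @ self.P[c].T)
                mx = arr.max(axis=1)
                ok = mx > 0
                with np.errstate(divide="ignore"):
                    logscale += np.where(ok, np.log(np.where(ok, mx, 1.0)),
                                         -np.inf)
                arr = np.where(ok[:, None], arr / np.where(ok, mx, 1.0)[:, None],
                               0.0)
            L[v] = arr
        return L, logscale

    def loglik(self, leaf_states) -> np.ndarray:
        """Per-site log-likelihood; -inf when no state assignment has
        positive probability (e.g. under a violated one-change constraint)."""
        leaf_states = self._check_leaves(leaf_states)
        L, logscale = self._partials(leaf_states)
        root = L[self.ctree.tree.root] @ self.root_freqs
        with np.errstate(divide="ignore"):
            return np.log(root) + logscale

    def ancestral(self, leaf_states):
        """Marginal posteriors over states at every internal node.

        Returns (posteriors: dict node -> (n_sites, 20), MAP states:
        dict node -> (n_sites,) int). Exact inside-outside message passing.
        """
        t = self.ctree.tree
        leaf_states = self._check_leaves(leaf_states)
        n_sites = leaf_states.shape[1]
        L, _ = self._partials(leaf_states)
        up: dict[int, np.ndarray] = {
            t.root: np.tile(self.root_freqs, (n_sites, 1))
        }
        # messages from child subtrees to their parent's state space
        msg = {c: L[c] @ self.P[c].T for c in self.P}
        for v in t.preorder():
            for c in t.children[v]:
                out = up[v].copy()
                for s in t.children[v]:
                    if s != c:
                        out = out * msg[s]
                out = out @ self.P[c]
                norm = out.sum(axis=1, keepdims=True)
                norm[norm == 0] = 1.0
                up[c] = out / norm
        posteriors, map_states = {}, {}
        for v in range(t.n_nodes):
            if t.is_leaf(v):
                continue
            post = up[v] * L[v]
            norm = post.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            post = post / norm
            posteriors[v] = post
            map_states[v] = post.argmax(axis=1)
        return posteriors, map_states


def prune_loglik(ctree: ConditionedTree, column, model: AAModel,
                 oc_on_transitions: bool = False) -> float:
    """Log-likelihood of one amino-acid column (states in tree-leaf order,
    GAP = -1 marginalised)."""
    engine = PruningEngine(ctree, model, oc_on_transitions=oc_on_transitions)
    col = np.asarray(column, dtype=int).reshape(-1, 1)
    return float(engine.loglik(col)[0])


def marginal_ancestral(ctree: ConditionedTree, column, model: AAModel):
    """Marginal posterior and MAP state per internal node for one column."""
    engine = PruningEngine(ctree, model)
    col = np.asarray(column, dtype=int).reshape(-1, 1)
    posteriors, maps = engine.ancestral(col)
    return ({v: p[0] for v, p in posteriors.items()},
            {v: int(m[0]) for v, m in maps.items()})
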