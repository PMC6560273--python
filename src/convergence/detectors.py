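"""Per-site detectors of convergent amino-acid substitutions.

Five methods, each mapping (alignment, condition-labelled tree) to one
score per site, oriented so that higher means more evidence of convergence:

* ``identical`` - ancestral reconstruction at the ends of every
  phenotype-transition branch; scores the fraction of transitions that
  substituted to the same derived amino acid.
* ``topological`` - log-likelihood of a rearranged tree grouping the
  convergent clades minus that of the species tree.
* ``multinomial`` - Pearson chi-squared homogeneity test between the
  amino-acid count vectors of ancestral- and convergent-phenotype taxa
  (no tree; a deliberate phylogeny-blind baseline).
* ``tdg09`` - likelihood-ratio test of one count-derived profile for the
  whole tree against separate ancestral/convergent profiles.
* ``pcoc`` - profile change with one change: best homogeneous profile from
  a library against the best ordered profile pair with the convergent
  profile on convergent branches and at least one substitution forced on
  each transition branch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .likelihood import AAModel, PruningEngine, one_change_transition
from .mutsel import ProfileLibrary
from .phylo_core import (Alignment, ANCESTRAL, CONVERGENT, ConditionedTree,
                         GAP, PhyloTree, parse_newick, translate)

METHOD_NAMES = ("identical", "topological", "multinomial", "tdg09", "pcoc")

P_FLOOR = 1e-300


@dataclass
class SiteScores:
    """Per-site output of one detector.

    ``raw`` is the method's native statistic, ``score`` the standardized
    ranking score (higher = more convergent), ``pvalue`` present only for
    the test-based methods. NaN marks sites where the statistic is
    undefined (e.g. one phenotype group entirely gapped); such sites are
    excluded from ranking and never called.
    """

    method: str
    raw: np.ndarray
    score: np.ndarray | None = None
    pvalue: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.raw)


def standardize(scores: SiteScores) -> SiteScores:
    """Fill the standardized score: -log10(p) for test-based methods
    (p floored at 1e-300), the raw statistic for likelihood-difference and
    fraction-based methods. NaN sentinels propagate."""
    if scores.pvalue is not None:
        with np.errstate(invalid="ignore"):
            score = -np.log10(np.clip(scores.pvalue, P_FLOOR, 1.0))
    else:
        score = np.asarray(scores.raw, dtype=float).copy()
    return replace(scores, score=score)


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _aa_states(alignment: Alignment, ctree: ConditionedTree) -> np.ndarray:
    """Alignment as an (n_leaves, n_sites) amino-acid matrix in tree leaf
    order; codon alignments are translated on the fly."""
    if alignment.kind == "codon":
        alignment = translate(alignment)
    names = ctree.tree.leaf_names()
    if set(names) != set(alignment.taxa):
        raise ValueError("alignment taxa do not match tree leaves")
    row = {t: i for i, t in enumerate(alignment.taxa)}
    return alignment.states[[row[n] for n in names]]


def empirical_aa_model(alignment: Alignment,
                       exchangeabilities: np.ndarray | None = None) -> AAModel:
    """Homogeneous model with alignment-wide empirical amino-acid
    frequencies (floored and renormalised)."""
    states = alignment.states
    if alignment.kind == "codon":
        states = translate(alignment).states
    counts = np.bincount(states[states != GAP].ravel(), minlength=20).astype(float)
    freqs = counts / counts.sum() if counts.sum() else np.full(20, 0.05)
    return AAModel.homogeneous(freqs, exchangeabilities=exchangeabilities)


def _leaf_condition_mask(ctree: ConditionedTree) -> np.ndarray:
    """Boolean per tree leaf (in leaf order): True = convergent phenotype."""
    t = ctree.tree
    return np.array([ctree.is_convergent[v] for v in t.leaves()])


# ---------------------------------------------------------------------------
# identical
# ---------------------------------------------------------------------------

def detect_identical(alignment: Alignment, ctree: ConditionedTree,
                     model: AAModel | None = None) -> SiteScores:
    """Independent substitutions to the same amino acid on every transition.

    Marginal MAP states are reconstructed at both ends of each transition
    branch (observed states are used when the clade root is a leaf). With x
    the modal derived amino acid over transition branches, the raw score is
    the fraction of transition branches whose parent-end state differs from
    x while the child-end state equals x; a site is called convergent only
    at score 1.
    """
    if not ctree.clade_roots:
        raise ValueError("tree has no transition branches")
    states = _aa_states(alignment, ctree)
    model = model or empirical_aa_model(alignment)
    engine = PruningEngine(ctree, model)
    _, maps = engine.ancestral(states)
    t = ctree.tree
    leaf_row = {v: k for k, v in enumerate(t.leaves())}
    n_sites = states.shape[1]
    child_states = np.empty((len(ctree.clade_roots), n_sites), dtype=int)
    parent_states = np.empty_like(child_states)
    for k, r in enumerate(ctree.clade_roots):
        child_states[k] = states[leaf_row[r]] if t.is_leaf(r) else maps[r]
        parent_states[k] = maps[t.parent[r]]
    modal = np.full(n_sites, -2)
    for s in range(n_sites):
        vals = child_states[:, s]
        vals = vals[vals >= 0]
        if len(vals):
            modal[s] = np.bincount(vals, minlength=20).argmax()
    hits = (child_states == modal) & (parent_states != modal) & (modal >= 0)
    raw = hits.sum(axis=0) / len(ctree.clade_roots)
    return standardize(SiteScores(method="identical", raw=raw))


# ---------------------------------------------------------------------------
# topological
# ---------------------------------------------------------------------------

def _subtree_newick(t: PhyloTree, v: int) -> str:
    """Newick fragment for the subtree at ``v`` including its entering
    branch length."""
    label = t.names[v] or ""
    if t.is_leaf(v):
        return f"{label}:{t.lengths[v]:.10g}"
    inner = ",".join(_subtree_newick(t, c) for c in t.children[v])
    return f"({inner}){label}:{t.lengths[v]:.10g}"


def build_convergent_topology(ctree: ConditionedTree) -> PhyloTree:
    """Rearranged tree with all convergent clades grouped into one clade.

    Clades are pruned and re-joined in their original left-to-right order
    by a caterpillar of new internal nodes, then attached as sister to the
    remaining species tree at its root. Pendant and within-clade branch
    lengths are preserved; every newly created internal branch gets the
    median branch length of the species tree.
    """
    t = ctree.tree
    if len(ctree.clade_roots) < 2:
        return t
    m = float(np.median(np.delete(t.lengths, t.root)))
    order = {v: i for i, v in enumerate(t.preorder())}
    roots = sorted(ctree.clade_roots, key=order.get)
    parts = [_subtree_newick(t, r) for r in roots]
    cat = f"({parts[0]},{parts[1]}):{m:.10g}"
    for p in parts[2:]:
        cat = f"({cat},{p}):{m:.10g}"
    remaining = t.newick(exclude=set(roots))
    remaining = remaining.rstrip(";")
    return parse_newick(f"({remaining}:{m:.10g},{cat});")


def _homogeneous_ctree(tree: PhyloTree) -> ConditionedTree:
    n = tree.n_nodes
    return ConditionedTree(tree=tree, is_convergent=np.zeros(n, bool),
                           is_transition=np.zeros(n, bool), clade_roots=[])


def detect_topological(alignment: Alignment, ctree: ConditionedTree,
                       model: AAModel | None = None) -> SiteScores:
    """Site support for the convergent topology over the species topology.

    Raw score = loglik(convergent topology) - loglik(species topology),
    same homogeneous model on both trees; positive scores favour grouping
    the convergent taxa.
    """
    model = model or empirical_aa_model(alignment)
    species = _homogeneous_ctree(ctree.tree)
    conv = _homogeneous_ctree(build_convergent_topology(ctree))
    ll_species = PruningEngine(species, model).loglik(
        _aa_states(alignment, species))
    ll_conv = PruningEngine(conv, model).loglik(_aa_states(alignment, conv))
    return standardize(SiteScores(method="topological",
                                  raw=ll_conv - ll_species))


# ---------------------------------------------------------------------------
# multinomial
# ---------------------------------------------------------------------------

def detect_multinomial(alignment: Alignment,
                       taxon_conditions) -> SiteScores:
    """Chi-squared homogeneity test between phenotype groups, site by site.

    ``taxon_conditions`` is a ConditionedTree or a dict taxon ->
    "ancestral"/"convergent". Gaps are dropped; a monomorphic column scores
    0 with p = 1; a site where one group is entirely gapped is undefined
    (NaN).
    """
    if isinstance(taxon_conditions, ConditionedTree):
        taxon_conditions = taxon_conditions.leaf_conditions()
    if alignment.kind == "codon":
        alignment = translate(alignment)
    conv_mask = np.array(
        [taxon_conditions[t] == CONVERGENT for t in alignment.taxa])
    if conv_mask.all() or not conv_mask.any():
        raise ValueError("both phenotype groups must be non-empty")
    A = alignment.states[~conv_mask]
    C = alignment.states[conv_mask]
    n_sites = alignment.n_sites
    raw = np.empty(n_sites)
    pvals = np.empty(n_sites)
    for s in range(n_sites):
        ca = np.bincount(A[:, s][A[:, s] != GAP], minlength=20)
        cc = np.bincount(C[:, s][C[:, s] != GAP], minlength=20)
        if ca.sum() == 0 or cc.sum() == 0:
            raw[s] = np.nan
            pvals[s] = np.nan
            continue
        observed = (ca + cc) > 0
        if observed.sum() == 1:
            raw[s] = 0.0
            pvals[s] = 1.0
            continue
        table = np.vstack([ca[observed], cc[observed]])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        raw[s] = chi2
        pvals[s] = p
    return standardize(SiteScores(method="multinomial", raw=raw,
                                  pvalue=pvals))


# ---------------------------------------------------------------------------
# tdg09
# ---------------------------------------------------------------------------

def tdg09_profiles(column: np.ndarray, conv_mask: np.ndarray):
    """Count-derived profiles (global, ancestral, convergent) for a column.

    Within each group, amino acids with count <= 1 are considered absent
    and get frequency 0; remaining counts are renormalised. If every count
    is <= 1 the rule degenerates and the profile falls back to equal
    frequencies over the observed states.
    """
    column = np.asarray(column)
    conv_mask = np.asarray(conv_mask, dtype=bool)

    def profile(vals: np.ndarray) -> np.ndarray:
        counts = np.bincount(vals[vals != GAP], minlength=20).astype(float)
        kept = np.where(counts > 1, counts, 0.0)
        if kept.sum() == 0:
            observed = counts > 0
            if not observed.any():
                return np.full(20, 1.0 / 20)
            return observed / observed.sum()
        return kept / kept.sum()

    return (profile(column), profile(column[~conv_mask]),
            profile(column[conv_mask]))


def detect_tdg09(alignment: Alignment, ctree: ConditionedTree,
                 exchangeabilities: np.ndarray | None = None) -> SiteScores:
    """Likelihood-ratio test for distinct ancestral/convergent profiles.

    Null: one global count-derived profile on every branch. Alternative:
    the ancestral profile on ancestral branches (and the root), the
    convergent profile on convergent branches. Raw score 2(l1 - l0) clamped
    at 0; p-value from chi-squared with df = (nzA - 1) + (nzC - 1) -
    (nzG - 1), floored at 1, where nz counts the profile's non-zero states.
    """
    states = _aa_states(alignment, ctree)
    conv_mask = _leaf_condition_mask(ctree)
    n_sites = states.shape[1]
    raw = np.empty(n_sites)
    pvals = np.empty(n_sites)
    for s in range(n_sites):
        col = states[:, s].reshape(-1, 1)
        pg, pa, pc = tdg09_profiles(states[:, s], conv_mask)
        m0 = AAModel.homogeneous(pg, exchangeabilities=exchangeabilities)
        m1 = AAModel(freqs={ANCESTRAL: pa, CONVERGENT: pc},
                     exchangeabilities=exchangeabilities)
        l0 = PruningEngine(ctree, m0).loglik(col)[0]
        l1 = PruningEngine(ctree, m1).loglik(col)[0]
        stat = max(0.0, 2.0 * (l1 - l0))
        df = max(1, (np.count_nonzero(pa) - 1) + (np.count_nonzero(pc) - 1)
                 - (np.count_nonzero(pg) - 1))
        raw[s] = stat
        pvals[s] = stats.chi2.sf(stat, df)
    return standardize(SiteScores(method="tdg09", raw=raw, pvalue=pvals))


# ---------------------------------------------------------------------------
# pcoc
# ---------------------------------------------------------------------------

def detect_pcoc(alignment: Alignment, ctree: ConditionedTree,
                library: ProfileLibrary,
                exchangeabilities: np.ndarray | None = None) -> SiteScores:
    """Profile change + one change, maximised over a finite profile library.

    M0: best homogeneous profile. M1: best ordered pair (ancestral profile,
    convergent profile), the convergent profile governing convergent
    branches and the transition-branch matrices conditioned on at least one
    substitution. Raw score = loglik(M1) - loglik(M0).
    """
    if len(library) < 2:
        raise ValueError("pcoc needs a library with at least two profiles")
    states = _aa_states(alignment, ctree)
    t = ctree.tree
    branches = [v for v in range(t.n_nodes) if v != t.root]
    conv_branches = [v for v in branches if ctree.is_convergent[v]]
    anc_branches = [v for v in branches if not ctree.is_convergent[v]]
    trans = set(np.flatnonzero(ctree.is_transition))

    # per-profile transition matrices, plain and one-change-conditioned
    plain: list[dict[int, np.ndarray]] = []
    occed: list[dict[int, np.ndarray]] = []
    models: list[AAModel] = []
    for p in library:
        m = AAModel.homogeneous(p.frequencies,
                                exchangeabilities=exchangeabilities)
        models.append(m)
        Pd = {v: m.transition_matrix(ANCESTRAL, t.lengths[v])
              for v in branches}
        plain.append(Pd)
        occed.append({v: one_change_transition(Pd[v]) for v in trans})

    ll_hom = np.stack([
        PruningEngine(ctree, P=plain[k], root_freqs=models[k].root_freqs)
        .loglik(states)
        for k in range(len(library))
    ])
    m0 = ll_hom.max(axis=0)
    hom_best = ll_hom.argmax(axis=0)

    m1 = np.full(states.shape[1], -np.inf)
    for ka in range(len(library)):
        for kc in range(len(library)):
            if ka == kc:
                continue
            P = {}
            for v in anc_branches:
                P[v] = plain[ka][v]
            for v in conv_branches:
                P[v] = occed[kc][v] if v in trans else plain[kc][v]
            ll = PruningEngine(ctree, P=P,
                               root_freqs=models[ka].root_freqs).loglik(states)
            np.maximum(m1, ll, out=m1)
    raw = m1 - m0
    scores = standardize(SiteScores(method="pcoc", raw=raw))
    scores.best_homogeneous = hom_best  # noqa: attr-defined (diagnostic)
    return scores


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def run_method(name: str, alignment: Alignment, ctree: ConditionedTree,
               library: ProfileLibrary | None = None,
               model: AAModel | None = None,
               exchangeabilities: np.ndarray | None = None) -> SiteScores:
    """Run one detector by name (see METHOD_NAMES)."""
    if name == "identical":
        return detect_identical(alignment, ctree, model=model)
    if name == "topological":
        return detect_topological(alignment, ctree, model=model)
    if name == "multinomial":
        return detect_multinomial(alignment, ctree)
    if name == "tdg09":
        return detect_tdg09(alignment, ctree,
                            exchangeabilities=exchangeabilities)
    if name == "pcoc":
        if library is None:
            raise ValueError("pcoc requires a profile library")
        return detect_pcoc(alignment, ctree, library,
                           exchangeabilities=exchangeabilities)
    raise ValueError(f"unknown method {name!r}; valid methods: "
                     f"{', '.join(METHOD_NAMES)}")
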