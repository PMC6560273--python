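"""Stochastic simulation of codon columns along condition-labelled trees.

Each site evolves by an exact event-driven (Gillespie) continuous-time
Markov chain under a mutation-selection generator, with the ancestral model
on ancestral branches and the convergent model inside convergent clades
(including, by default, the transition branch itself). Every jump is
recorded, so substitutions can be classified as type 1 (on the branch where
the phenotype changes), type 2 (non-synonymous, on later convergent
branches) or background.

The benchmark generator reproduces three study designs over a site set with
a fixed fraction of truly convergent (Ha) sites:

* ``profile_change`` - Ha sites swap to a second fitness profile in
  convergent clades, selection efficacy constant;
* ``nes_scaling`` - the profile is shared but NeS changes in convergent
  clades at Ha sites;
* ``combined`` - every site undergoes a genome-wide NeS change in
  convergent clades and Ha sites additionally swap profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mutsel import (MutationModel, MutSelMatrix, ProfileLibrary,
                     build_mutsel_matrix)
from .phylo_core import (Alignment, ConditionedTree, GeneticCode, PhyloTree,
                         STANDARD_CODE, annotate_conditions)

TYPE1 = "type1"
TYPE2 = "type2"
BACKGROUND = "background"

CASES = ("profile_change", "nes_scaling", "combined")


@dataclass
class SubstitutionRecord:
    """One recorded jump of the codon chain."""

    branch: int          # child-node id of the branch (-1 if free-standing)
    site: int
    time: float          # offset from the start of the branch
    from_codon: int
    to_codon: int
    synonymous: bool
    convergence_class: str = BACKGROUND


def evolve_branch(start_codon: int, Q: MutSelMatrix, t: float,
                  rng: np.random.Generator):
    """Evolve one codon for time ``t`` and record every jump.

    Exact simulation of the continuous-time chain: exponential holding
    times at rate -Q[s, s], embedded jumps proportional to off-diagonal
    rates.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    exit_rates, jump_cdf = Q.jump_tables()
    aa = Q.code.aa_of_codon
    records: list[SubstitutionRecord] = []
    s = int(start_codon)
    now = 0.0
    while True:
        rate = exit_rates[s]
        if rate <= 0:
            break
        now += rng.exponential(1.0 / rate)
        if now > t:
            break
        j = int(np.searchsorted(jump_cdf[s], rng.random(), side="right"))
        j = min(j, len(exit_rates) - 1)
        records.append(SubstitutionRecord(
            branch=-1, site=-1, time=now, from_codon=s, to_codon=j,
            synonymous=bool(aa[s] == aa[j])))
        s = j
    return s, records


def simulate_site(ctree: ConditionedTree, model_A: MutSelMatrix,
                  model_C: MutSelMatrix, rng: np.random.Generator,
                  site: int = 0, transition_under_ancestral: bool = False):
    """Simulate one codon column down the tree.

    The root state is drawn from the ancestral model's stationary
    distribution; each branch evolves under the model of its condition. By
    default the transition branch runs under the convergent model (its
    evolution is already governed by the new environment); set
    ``transition_under_ancestral`` to delay the switch to the clade proper.
    Records are classified type1/type2/background.
    """
    if model_A.code is not model_C.code:
        raise ValueError("models must share a genetic code")
    if model_A.mutation != model_C.mutation:
        raise ValueError("models must share a mutation model")
    tree = ctree.tree
    states = np.empty(tree.n_nodes, dtype=int)
    states[tree.root] = rng.choice(len(model_A.pi), p=model_A.pi)
    all_records: list[SubstitutionRecord] = []
    for v in tree.preorder():
        if v == tree.root:
            continue
        conv = ctree.is_convergent[v]
        if conv and transition_under_ancestral and ctree.is_transition[v]:
            Q = model_A
        else:
            Q = model_C if conv else model_A
        end, recs = evolve_branch(states[tree.parent[v]], Q, tree.lengths[v],
                                  rng)
        states[v] = end
        for r in recs:
            r.branch = v
            r.site = site
            if ctree.is_transition[v]:
                r.convergence_class = TYPE1
            elif conv and not r.synonymous:
                r.convergence_class = TYPE2
            else:
                r.convergence_class = BACKGROUND
        all_records.extend(recs)
    column = states[tree.leaves()]
    return column, all_records


@dataclass
class SimulationScenario:
    """Parameters of one benchmark simulation run.

    NeS values are dimensionless selection efficacies; the reference value
    used for rate normalisation is the ancestral (cases 1-2) or genome-wide
    (case 3) efficacy, so branch lengths always mean expected substitutions
    per site under the baseline environment.
    """

    case: str
    library: ProfileLibrary
    n_sites: int
    nes_ancestral: float = 4.0
    nes_convergent: float = 4.0
    nes_genome: float | None = None
    fraction_convergent: float = 0.02
    seed: int = 0
    transition_under_ancestral: bool = False

    def __post_init__(self) -> None:
        if self.case not in CASES:
            raise ValueError(f"unknown case {self.case!r}; expected one of "
                             f"{CASES}")
        if not 0.0 <= self.fraction_convergent <= 1.0:
            raise ValueError("fraction_convergent must be in [0, 1]")
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        for v in (self.nes_ancestral, self.nes_convergent):
            if v < 0:
                raise ValueError("NeS values must be non-negative")
        if self.case == "combined":
            if self.nes_genome is None or self.nes_genome < 0:
                raise ValueError("case 'combined' needs a non-negative "
                                 "genome-wide NeS")


@dataclass
class TruthLabels:
    """Per-site ground truth of a benchmark simulation."""

    labels: np.ndarray               # bool, True = Ha (convergent site)
    profile_ancestral: list[str]
    profile_convergent: list[str]
    nes_ancestral: np.ndarray
    nes_convergent: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "site": np.arange(self.n_sites),
            "convergent": self.labels.astype(int),
            "profile_ancestral": self.profile_ancestral,
            "profile_convergent": self.profile_convergent,
            "nes_ancestral": self.nes_ancestral,
            "nes_convergent": self.nes_convergent,
        })


def _site_models(scenario: SimulationScenario, is_ha: bool,
                 rng: np.random.Generator, mut: MutationModel,
                 code: GeneticCode):
    """Pick profiles and NeS values for one site and build its matrices."""
    lib = scenario.library
    needs_pair = is_ha and scenario.case in ("profile_change", "combined")
    if needs_pair and len(lib) < 2:
        raise ValueError("library too small to draw two distinct profiles")
    i = int(rng.integers(len(lib)))
    if needs_pair:
        j = int(rng.integers(len(lib) - 1))
        j = j + 1 if j >= i else j
        p_anc, p_conv = lib[i], lib[j]
    else:
        p_anc = p_conv = lib[i]
    if scenario.case == "profile_change":
        nes_anc = nes_conv = scenario.nes_ancestral
    elif scenario.case == "nes_scaling":
        nes_anc = scenario.nes_ancestral
        nes_conv = scenario.nes_convergent if is_ha else scenario.nes_ancestral
    else:  # combined: genome-wide scaling for every site
        nes_anc = scenario.nes_genome
        nes_conv = scenario.nes_convergent
    model_A = build_mutsel_matrix(mut, p_anc, nes_anc, code=code)
    model_C = build_mutsel_matrix(mut, p_conv, nes_conv, code=code,
                                  scale=model_A.scale)
    return model_A, model_C, (p_anc.id, p_conv.id, nes_anc, nes_conv)


def simulate_benchmark(ctree: ConditionedTree, scenario: SimulationScenario,
                       mut: MutationModel | None = None,
                       code: GeneticCode = STANDARD_CODE,
                       return_records: bool = False):
    """Simulate a full benchmark alignment with known per-site truth.

    Ha sites are an exact-count uniform draw without replacement
    (round(fraction * n_sites) sites). Each site uses its own RNG stream
    seeded from (master seed, site index), so results are reproducible
    site-by-site.
    """
    mut = mut or MutationModel()
    n = scenario.n_sites
    rng_assign = np.random.default_rng(
        np.random.SeedSequence([scenario.seed, 1]))
    n_pos = int(round(scenario.fraction_convergent * n))
    labels = np.zeros(n, dtype=bool)
    if n_pos:
        labels[rng_assign.choice(n, size=n_pos, replace=False)] = True
    columns = np.empty((len(ctree.tree.leaves()), n), dtype=int)
    meta_pa, meta_pc = [], []
    meta_na = np.empty(n)
    meta_nc = np.empty(n)
    records: list[SubstitutionRecord] = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([scenario.seed,
                                                            2, i]))
        model_A, model_C, (pa, pc, na, nc) = _site_models(
            scenario, bool(labels[i]), rng, mut, code)
        col, recs = simulate_site(
            ctree, model_A, model_C, rng, site=i,
            transition_under_ancestral=scenario.transition_under_ancestral)
        columns[:, i] = col
        meta_pa.append(pa)
        meta_pc.append(pc)
        meta_na[i] = na
        meta_nc[i] = nc
        if return_records:
            records.extend(recs)
    taxa = ctree.tree.leaf_names()
    alignment = Alignment(taxa=taxa, states=columns, kind="codon")
    truth = TruthLabels(labels=labels, profile_ancestral=meta_pa,
                        profile_convergent=meta_pc, nes_ancestral=meta_na,
                        nes_convergent=meta_nc)
    if return_records:
        return alignment, truth, records
    return alignment, truth


def records_to_frame(records: list[SubstitutionRecord],
                     code: GeneticCode = STANDARD_CODE) -> pd.DataFrame:
    return pd.DataFrame({
        "site": [r.site for r in records],
        "branch": [r.branch for r in records],
        "time": [r.time for r in records],
        "from_codon": [code.codons[r.from_codon] for r in records],
        "to_codon": [code.codons[r.to_codon] for r in records],
        "synonymous": [int(r.synonymous) for r in records],
        "class": [r.convergence_class for r in records],
    })


# ---------------------------------------------------------------------------
# Tree fixture generator
# ---------------------------------------------------------------------------

def generate_benchmark_tree(n_taxa: int, n_transitions: int,
                            seed: int | None = None,
                            height: float = 1.0) -> ConditionedTree:
    """Pure-birth (Yule) tree with non-nested convergent clades.

    The ultrametric tree is rescaled to the requested root-to-tip height
    (expected substitutions per site under the reference model) and
    ``n_transitions`` clade roots are drawn uniformly among eligible nodes,
    rejecting nesting and configurations that leave no ancestral leaf.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if n_transitions < 1:
        raise ValueError("need at least one convergent transition")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    parent = [-1, 0, 0]
    lengths = [0.0, 0.0, 0.0]
    active = [1, 2]
    while len(active) < n_taxa:
        dt = rng.exponential(1.0 / len(active))
        for v in active:
            lengths[v] += dt
        k = int(rng.integers(len(active)))
        v = active.pop(k)
        for _ in range(2):
            parent.append(v)
            lengths.append(0.0)
            active.append(len(parent) - 1)
    dt = rng.exponential(1.0 / len(active))
    for v in active:
        lengths[v] += dt

    n_nodes = len(parent)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for v in range(1, n_nodes):
        children[parent[v]].append(v)
    names: list[str | None] = [None] * n_nodes
    leaf_counter = 0
    for v in range(n_nodes):
        if not children[v]:
            leaf_counter += 1
            names[v] = f"T{leaf_counter:03d}"
    tree = PhyloTree(parent=np.array(parent), lengths=np.array(lengths),
                     names=names, children=children)
    h = tree.height()
    tree.lengths *= height / h

    leaves = set(tree.leaves())
    candidates = [v for v in range(tree.n_nodes) if v != tree.root]
    rng.shuffle(candidates)
    chosen: list[int] = []
    covered: set[int] = set()
    for v in candidates:
        if len(chosen) == n_transitions:
            break
        if any(tree.is_ancestor(v, c) or tree.is_ancestor(c, v)
               for c in chosen):
            continue
        sub_leaves = {u for u in tree.subtree(v) if tree.is_leaf(u)}
        if covered | sub_leaves >= leaves:
            continue
        chosen.append(v)
        covered |= sub_leaves
    if len(chosen) < n_transitions:
        raise ValueError(
            f"could not place {n_transitions} non-nested convergent clades "
            f"on a {n_taxa}-taxon tree")
    return annotate_conditions(tree, chosen)
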