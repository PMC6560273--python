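"""Amino-acid fitness profiles and mutation-selection codon models.

The generator over the 61 sense codons combines an HKY-style nucleotide
mutation process with amino-acid fitness differences through the standard
population-genetic fixation factor

    h(S) = S / (1 - exp(-S)),   h(0) = 1,

where S = NeS * (f_destination - f_origin) is the scaled selection
coefficient of a non-synonymous change. NeS (selection efficacy, the product
of effective population size and selective pressure) enters only through
this factor: raising it makes the equilibrium amino-acid usage more peaked
around the fittest residues while preserving their relative order, lowering
it flattens the usage, with NeS = 0 recovering the neutral mutation process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .phylo_core import AA_ORDER, GeneticCode, STANDARD_CODE

NUCLEOTIDES = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


# ---------------------------------------------------------------------------
# Fitness profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitnessProfile:
    """Site-specific fitnesses of the 20 amino acids.

    Stored as log-fitnesses (identifiable up to an additive constant); the
    ``frequencies`` view is the softmax, i.e. the propensity vector the
    profile would induce in an amino-acid level model with symmetric
    exchange.
    """

    log_fitness: np.ndarray
    id: str = "profile"

    def __post_init__(self) -> None:
        f = np.asarray(self.log_fitness, dtype=float)
        if f.shape != (20,):
            raise ValueError("a fitness profile has exactly 20 entries")
        object.__setattr__(self, "log_fitness", f)

    @classmethod
    def from_frequencies(cls, freqs, id: str = "profile") -> "FitnessProfile":
        freqs = np.asarray(freqs, dtype=float)
        if np.any(freqs <= 0) or abs(freqs.sum() - 1) > 1e-8:
            raise ValueError("frequencies must be positive and sum to 1")
        return cls(log_fitness=np.log(freqs), id=id)

    @property
    def frequencies(self) -> np.ndarray:
        w = np.exp(self.log_fitness - self.log_fitness.max())
        return w / w.sum()

    def at_efficacy(self, nes: float) -> np.ndarray:
        """Propensity vector with log-fitnesses scaled by ``nes``.

        This is the amino-acid level view of selection-efficacy scaling:
        the ranking of amino acids is exactly preserved for any nes > 0 and
        the vector sharpens (entropy decreases) as nes grows.
        """
        if nes < 0:
            raise ValueError("nes must be non-negative")
        w = np.exp(nes * (self.log_fitness - self.log_fitness.max()))
        return w / w.sum()


@dataclass
class ProfileLibrary:
    """Ordered collection of distinct fitness profiles."""

    profiles: list[FitnessProfile]
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("profile library must be non-empty")
        keys = {tuple(np.round(p.frequencies, 12)) for p in self.profiles}
        if len(keys) != len(self.profiles):
            raise ValueError("profiles must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.profiles)

    def __getitem__(self, i: int) -> FitnessProfile:
        return self.profiles[i]

    def __iter__(self):
        return iter(self.profiles)

    def to_tsv(self, path: str) -> None:
        rows = [[p.id, *p.frequencies] for p in self.profiles]
        df = pd.DataFrame(rows, columns=["id", *AA_ORDER])
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str) -> "ProfileLibrary":
        df = pd.read_csv(path, sep="\t")
        missing = [a for a in AA_ORDER if a not in df.columns]
        if missing:
            raise ValueError(f"profile TSV lacks amino-acid columns {missing}")
        profiles = [
            FitnessProfile.from_frequencies(row[list(AA_ORDER)].to_numpy(float),
                                            id=str(row["id"]))
            for _, row in df.iterrows()
        ]
        return cls(profiles=profiles)


def generate_profile_library(n: int, concentration: float = 0.3,
                             seed: int | None = None) -> ProfileLibrary:
    """Draw ``n`` profiles from a symmetric Dirichlet over the 20-simplex.

    Small concentrations give peaked, site-like profiles (a few favoured
    amino acids); large concentrations approach the uniform profile.
    """
    if n < 1:
        raise ValueError("library size must be at least 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = rng.dirichlet(np.full(20, concentration), size=n)
    draws = np.maximum(draws, 1e-8)
    draws /= draws.sum(axis=1, keepdims=True)
    profiles = [FitnessProfile.from_frequencies(d, id=f"p{i:04d}")
                for i, d in enumerate(draws)]
    return ProfileLibrary(profiles=profiles, seed=seed)


# ---------------------------------------------------------------------------
# Mutation model (HKY-style)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationModel:
    """Nucleotide mutation process: transition/transversion ratio kappa and
    target base frequencies (HKY parameterisation, reversible)."""

    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        bf = np.asarray(self.base_freqs, dtype=float)
        if bf.shape != (4,) or np.any(bf <= 0) or abs(bf.sum() - 1) > 1e-8:
            raise ValueError("base frequencies must be a positive 4-simplex")
        object.__setattr__(self, "base_freqs", tuple(float(x) for x in bf))

    def rate(self, from_nt: str, to_nt: str) -> float:
        """Mutation rate from one nucleotide to another (unnormalised)."""
        if from_nt == to_nt:
            raise ValueError("no self-rate")
        mult = self.kappa if (from_nt, to_nt) in _TRANSITIONS else 1.0
        return mult * self.base_freqs[NUCLEOTIDES.index(to_nt)]


# ---------------------------------------------------------------------------
# Codon-pair structure (cached per genetic code)
# ---------------------------------------------------------------------------

class _CodonPairs:
    """Directed single-nucleotide-step codon pairs and their metadata."""

    def __init__(self, code: GeneticCode) -> None:
        I, J, frm, to = [], [], [], []
        for i, ci in enumerate(code.codons):
            for j, cj in enumerate(code.codons):
                if i == j:
                    continue
                diff = [k for k in range(3) if ci[k] != cj[k]]
                if len(diff) == 1:
                    I.append(i)
                    J.append(j)
                    frm.append(ci[diff[0]])
                    to.append(cj[diff[0]])
        self.i = np.array(I)
        self.j = np.array(J)
        self.from_nt = frm
        self.to_nt = to
        self.synonymous = code.aa_of_codon[self.i] == code.aa_of_codon[self.j]
        self.aa_i = code.aa_of_codon[self.i]
        self.aa_j = code.aa_of_codon[self.j]
        # nucleotide-level base-frequency product per codon (Halpern-Bruno phi)
        self.nt_index = np.array(
            [[NUCLEOTIDES.index(c[k]) for k in range(3)] for c in code.codons]
        )


_PAIR_CACHE: dict[int, _CodonPairs] = {}


def _pairs(code: GeneticCode) -> _CodonPairs:
    key = id(code)
    if key not in _PAIR_CACHE:
        _PAIR_CACHE[key] = _CodonPairs(code)
    return _PAIR_CACHE[key]


# ---------------------------------------------------------------------------
# Fixation factor
# ---------------------------------------------------------------------------

def fixation_factor(S) -> np.ndarray:
    """h(S) = S / (1 - e^{-S}), evaluated stably.

    A Taylor series (1 + S/2 + S^2/12) guards the removable singularity for
    |S| < 1e-4; very negative S underflows to 0, very positive S approaches
    S itself.
    """
    S = np.asarray(S, dtype=float)
    out = np.empty_like(S)
    small = np.abs(S) < 1e-4
    out[small] = 1.0 + S[small] / 2.0 + S[small] ** 2 / 12.0
    big_neg = S <= -700
    out[big_neg] = 0.0
    rest = ~small & ~big_neg
    out[rest] = S[rest] / (-np.expm1(-S[rest]))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Mutation-selection matrices
# ---------------------------------------------------------------------------

@dataclass
class MutSelMatrix:
    """61x61 mutation-selection generator.

    ``scale`` is the raw stationary substitution rate the generator was
    divided by, so that the reference model has expected rate 1 per unit
    branch length; heterogeneous companions built with the same scale are
    deliberately *not* renormalised.
    """

    Q: np.ndarray
    nes: float
    profile: FitnessProfile
    mutation: MutationModel
    pi: np.ndarray
    scale: float
    code: GeneticCode = field(default=STANDARD_CODE, repr=False)

    _exit_rates: np.ndarray | None = field(default=None, repr=False)
    _jump_cdf: np.ndarray | None = field(default=None, repr=False)
    _jump_targets: np.ndarray | None = field(default=None, repr=False)

    @property
    def stationary_rate(self) -> float:
        """Expected substitutions per unit time at stationarity."""
        return float(-(self.pi * np.diag(self.Q)).sum())

    def jump_tables(self):
        """Exit rates and per-state embedded-jump CDFs for event-driven
        simulation (built lazily, cached)."""
        if self._exit_rates is None:
            n = self.Q.shape[0]
            off = self.Q.copy()
            np.fill_diagonal(off, 0.0)
            exit_rates = off.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                probs = off / exit_rates[:, None]
            probs[exit_rates == 0] = 0.0
            self._exit_rates = exit_rates
            self._jump_cdf = np.cumsum(probs, axis=1)
            self._jump_targets = np.arange(n)
        return self._exit_rates, self._jump_cdf


def build_mutsel_matrix(mut: MutationModel, profile: FitnessProfile,
                        nes: float, code: GeneticCode = STANDARD_CODE,
                        scale: float | None = None) -> MutSelMatrix:
    """Assemble the mutation-selection generator for one site.

    Rates exist only between codons differing at a single nucleotide
    position; synonymous steps move at the mutation rate, non-synonymous
    steps are multiplied by the fixation factor of
    S = nes * (f_destination - f_origin).

    When ``scale`` is None the generator is normalised to expected rate 1 at
    its own stationary distribution (reference-model convention); passing
    the reference model's raw rate instead keeps a shared time scale across
    heterogeneous conditions.
    """
    if nes < 0:
        raise ValueError("nes must be non-negative")
    pairs = _pairs(code)
    n = code.n_codons
    mu = np.array([mut.rate(f, t) for f, t in zip(pairs.from_nt, pairs.to_nt)])
    f = profile.log_fitness
    S = nes * (f[pairs.aa_j] - f[pairs.aa_i])
    h = np.where(pairs.synonymous, 1.0, fixation_factor(S))
    Q = np.zeros((n, n))
    Q[pairs.i, pairs.j] = mu * h
    np.fill_diagonal(Q, -Q.sum(axis=1))
    pi = stationary_distribution(Q)
    raw_rate = float(-(pi * np.diag(Q)).sum())
    if scale is None:
        scale = raw_rate
    Q = Q / scale
    return MutSelMatrix(Q=Q, nes=nes, profile=profile, mutation=mut, pi=pi,
                        scale=scale, code=code)


def stationary_distribution(Q) -> np.ndarray:
    """Left null vector of a generator, normalised to a probability vector.

    Works for any irreducible generator (no reversibility assumed); raises
    if the solve is numerically singular beyond tolerance or yields
    non-positive mass.
    """
    Qm = Q.Q if isinstance(Q, MutSelMatrix) else np.asarray(Q, dtype=float)
    n = Qm.shape[0]
    # Grassmann-Taksar-Heyman elimination: subtraction-free, so the result
    # is componentwise accurate even for stiff generators (peaked profiles
    # at high NeS span many orders of magnitude in rate).
    A = Qm.copy()
    np.fill_diagonal(A, 0.0)
    for k in range(n - 1, 0, -1):
        s = A[k, :k].sum()
        if s <= 0:
            raise ValueError("generator is reducible; no unique stationary "
                             "distribution")
        A[:k, k] /= s
        A[:k, :k] += np.outer(A[:k, k], A[k, :k])
    pi = np.empty(n)
    pi[0] = 1.0
    for k in range(1, n):
        pi[k] = pi[:k] @ A[:k, k]
    pi = np.maximum(pi, 1e-300)
    pi = pi / pi.sum()
    resid = np.abs(pi @ Qm).max()
    if resid > 1e-8 * max(1.0, np.abs(Qm).max()):
        raise ValueError(f"stationary solve residual too large ({resid:g})")
    return pi


def halpern_bruno_stationary(mut: MutationModel, profile: FitnessProfile,
                             nes: float,
                             code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """Closed-form stationary distribution for a reversible mutation model:
    pi_c proportional to phi(c) * exp(nes * f_aa(c)), with phi(c) the product
    of the base frequencies of c's nucleotides."""
    pairs = _pairs(code)
    bf = np.asarray(mut.base_freqs)
    log_phi = np.log(bf)[pairs.nt_index].sum(axis=1)
    logw = log_phi + nes * profile.log_fitness[code.aa_of_codon]
    w = np.exp(logw - logw.max())
    return w / w.sum()


def equilibrium_aa_distribution(mut: MutationModel, profile: FitnessProfile,
                                nes: float,
                                code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """Amino-acid marginal of the codon stationary distribution."""
    m = build_mutsel_matrix(mut, profile, nes, code=code)
    out = np.zeros(20)
    np.add.at(out, code.aa_of_codon, m.pi)
    return out


def matrix_exponential_rows(Q, t: float) -> np.ndarray:
    """Rows of e^{Qt}; long-time rows converge to the stationary vector."""
    Qm = Q.Q if isinstance(Q, MutSelMatrix) else np.asarray(Q, dtype=float)
    return expm(Qm * t)
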