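# Methods

## Mutation–selection codon model

Sites evolve independently over the 61 sense codons of the standard
genetic code. The generator combines an HKY mutation process — rate
μ(x→y) = π_y·κ for transitions, π_y for transversions, defaults κ = 2 and
equal base frequencies — with amino-acid selection through the standard
diffusion fixation factor h(S) = S/(1 − e^{−S}), S = NeS·Δf, applied to
non-synonymous single-nucleotide steps only. Multi-nucleotide codon
changes have rate zero. NeS ≥ 0 is dimensionless; Δf is the log-fitness
difference of the destination and origin amino acids.

NeS enters *only* through the fixation factor. The "profile flattening"
seen when efficacy changes is then an emergent property of the
equilibrium: the stationary codon distribution is π_c ∝ φ(c)·e^{NeS·f},
whose amino-acid marginal sharpens (entropy strictly decreases over
NeS ∈ {0, 1, 4, 8} for every profile in the default library) as NeS grows.
One subtlety worth stating: amino-acid *ranking* under the codon-marginal
equilibrium is not exactly invariant to NeS, because codon degeneracy
(weight φ) can reorder low-frequency residues; rank preservation is exact
at the profile level, i.e. for the efficacy-scaled propensity vector
softmax(NeS·f) (`FitnessProfile.at_efficacy`). Tests assert entropy
monotonicity on the codon marginal and rank invariance on the profile
view.

Rate normalisation: the ancestral-condition generator at the scenario's
reference NeS is rescaled to one expected substitution per unit branch
length at stationarity, and the convergent-condition generator is divided
by the *same* constant, not renormalised. Branch lengths therefore mean
the same thing on every branch, and NeS changes alter realised
substitution counts, as they should.

Stationary distributions are computed with the Grassmann–Taksar–Heyman
elimination rather than a linear solve: at NeS = 8 with peaked profiles
the generator spans many orders of magnitude in rate (condition numbers
near 1e18) and an LU solve returns negative entries, while GTH is
subtraction-free and componentwise accurate (agrees with the
Halpern–Bruno closed form to ~1e-15 across the default library).

## Fitness profiles

Site profiles are symmetric-Dirichlet draws on the 20-simplex converted to
log-fitnesses. The default concentration 0.3 gives peaked, site-like
profiles with a handful of favoured residues, qualitatively similar to
profile sets estimated from large alignment collections; the default
library size is 263. Profiles are stored/read as TSV (id + 20
frequencies).

## Simulation

Simulation is event-driven (Gillespie): exponential holding times at rate
−Q[s,s], embedded jumps proportional to off-diagonal rates. This costs
more than endpoint sampling by matrix exponentials but yields the full
substitution record, which the benchmark needs to classify events as
type 1 (on the phenotype-transition branch), type 2 (non-synonymous, on a
later convergent branch) or background.

The root state is drawn from the ancestral model's stationary
distribution (the ancestral condition is the baseline environment). The
transition branch itself evolves under the convergent model by default —
the phenotype change is placed at the start of that branch, which is also
what the one-change detector assumes — with a switch
(`transition_under_ancestral`) to delay the change to the clade proper.

Truly convergent (Ha) sites are an exact-count uniform draw:
round(fraction × n_sites) site indices without replacement, default
fraction 0.02. Scenario definitions: case `profile_change` swaps in a
second library profile on convergent branches at constant NeS; case
`nes_scaling` keeps the profile and changes NeS on convergent branches of
Ha sites; case `combined` applies a genome-wide NeS change (NeS_G →
NeS_C) on every site and adds the profile change on Ha sites. Each site
has its own RNG stream seeded by (master seed, site index), so per-site
results are reproducible independently of execution order; truth labels,
the tree and each profile library use separate named substreams of the
master seed.

Benchmark trees are pure-birth (Yule) trees rescaled to a root-to-tip
height of 1.0 expected substitutions per site, with convergent clade
roots drawn uniformly among nodes subject to: no nesting, and at least
one leaf left ancestral. The default benchmark uses 36 taxa, 5
transitions and 1000 sites — large enough for stable AUC differences,
small enough that the full suite runs on a laptop. The generator emulates
the shape of empirical phylogenies only coarsely: clade sizes follow the
Yule draw (often small), branch lengths are ultrametric, and none of
biased gene conversion, CpG hypermutability, epistasis, rate variation,
indels or incomplete lineage sorting is simulated. Passing benchmarks
therefore demonstrate correct behaviour under the model's own
assumptions, not robustness to those confounders on real data.

## Amino-acid likelihood

Detectors that need a tree likelihood work at the amino-acid level with
Felsenstein pruning, vectorised over alignment columns, with per-node
rescaling against underflow. Default exchangeabilities are uniform, for
which P(t) has the closed form e^{−t/β}I + (1 − e^{−t/β})1πᵀ with
β = 1 − Σπ² (an empirical 20×20 exchangeability matrix can be supplied as
TSV and is exponentiated numerically). Branch-heterogeneous models carry
one frequency vector per condition; the root uses the
ancestral-condition frequencies. Branch lengths are taken as given —
none of the detectors re-optimises them, and the convergent-topology
method does not re-optimise lengths on the rearranged tree.

Count-derived profiles may contain zeros for states that are nonetheless
observed (the count ≤ 1 rule); frequencies are floored at 1e-6 and
renormalised before rate matrices are built, so such states cannot force
a −∞ likelihood. Gaps are treated as missing data: marginalised in
likelihoods, excluded from all count vectors.

The one-change constraint zeroes the diagonal of a branch's transition
matrix and renormalises rows; a row with no off-diagonal mass (identity
matrix, e.g. a zero-length transition branch) becomes all-zero and
propagates a −∞ log-likelihood, signalling that the constraint cannot be
met.

## Detectors

* **identical** — marginal ancestral reconstruction (exact
  inside–outside message passing) gives MAP states at both ends of every
  transition branch; with x the modal derived amino acid, the raw score
  is the fraction of transition branches with parent ≠ x and child = x.
  The graded fraction (not just the all-or-nothing call at 1.0) is kept
  so the method can be ranked on PR curves; ties in the modal state break
  toward the lowest amino-acid index.
* **topological** — the convergent topology is built by pruning the
  convergent clades, suppressing resulting unifurcations (lengths
  summed), joining the clades in their original left-to-right order by a
  caterpillar of new nodes, and attaching that group as sister to the
  remaining tree at its root. New internal branches get the median branch
  length of the species tree; pendant and within-clade lengths are
  preserved. This construction is one of several defensible choices; the
  score is loglik(convergent) − loglik(species) under one homogeneous
  model.
* **multinomial** — Pearson χ² homogeneity on the 2×K table of amino-acid
  counts (K = states observed in the pooled column), df = K − 1.
  Monomorphic columns score 0 with p = 1; a site with one group entirely
  gapped is undefined (NaN) and excluded from ranking. Note the test is
  asymptotic: at typical phylogenetic group sizes (tens of taxa) it is
  conservative (empirically 1–4% rejection at nominal 5%); calibration is
  verified in the asymptotic regime (400 sequences per group).
* **tdg09** — per-group count profiles with the count ≤ 1 zeroing rule
  (equal frequencies over observed states if everything is a singleton);
  LRT of one global profile vs ancestral + convergent profiles, statistic
  2Δℓ clamped at 0, df = (nzA − 1) + (nzC − 1) − (nzG − 1) floored at 1.
* **pcoc** — maximum likelihood over a finite profile library: best
  homogeneous profile (M0) vs best ordered profile pair with the
  convergent profile on convergent branches and the one-change constraint
  on transition branches (M1); score = ℓ(M1) − ℓ(M0). No rate-category
  mixtures and no posterior probabilities — a deliberate desk-scale
  simplification that keeps the profile-change + one-change mechanism.
  The detection library is generated separately from the simulation
  library (default 40 profiles from the same Dirichlet family, own seed
  substream): detectors in practice scan a fixed pre-estimated profile
  collection, not the profiles that generated the data, and the pair scan
  is quadratic in library size.

Standardisation for cross-method comparison: test-based methods score
−log10(p) (p floored at 1e-300); likelihood-difference methods use the
raw difference; identical uses its fraction. NaN sentinels propagate and
rank last.

## Evaluation

PR curves place one threshold at each distinct defined score; the curve
always contains a recall-0 endpoint and the all-positive call (precision
= prevalence, recall 1). AUC is the trapezoid over recall with ties in
recall resolved to the maximum precision; the estimator is recorded in
the result metadata so a step-wise variant can be compared. Sensitivity
at precision is the maximum recall among points with precision ≥ the
threshold (default 0.90), 0 if unreachable. Ranking is max-tie ("tied
elements get the highest rank"); undefined scores rank last, which is
conservative for the method being scored.

## Numerical details

* h(S) uses the Taylor series 1 + S/2 + S²/12 for |S| < 1e-4 (removable
  singularity) and underflows to 0 below S = −700.
* Equilibrium checks against long-time matrix exponentials use e^{Qt}
  at t = 500; note that peaked high-NeS profiles are metastable (spectral
  relaxation times of 1e4+), so fixed-start simulations are compared to
  stationarity only for flat profiles at low NeS, while benchmark roots
  are drawn from the stationary law directly.
* Transition-matrix caches key on (condition, branch length rounded to
  1e-12).

## Limitations

Single-site models only (no epistasis); no indels; no rate variation
beyond the profile/NeS mechanism; one genetic code; detectors assume the
convergent clades are known without error; gene-level aggregation of site
scores is out of scope. AUC values at the default benchmark size carry
Monte-Carlo noise of roughly ±0.05–0.1 (20 positive sites), which should
be kept in mind when comparing methods whose AUCs are close.
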