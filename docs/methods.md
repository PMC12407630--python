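# Methods

`mekfit` calibrates an ODE model of MEK-isoform-dependent ERK activation
against a mixture of quantitative relative time series and qualitative
up/down comparisons, and quantifies uncertainty by profile likelihood and
adaptive MCMC. This note records the model, the statistical machinery, the
numerical choices, and what the synthetic-data experiments do and do not
demonstrate.

## The reaction network

The model is an explicitly enumerated mass-action network (23 species, 33
uni-/bimolecular reactions) for the EGFR → SOS1 → RAS → RAF → MEK1/MEK2 →
ERK cascade. Time is in seconds; abundances in molecules/cell; first-order
rate constants in 1/s and second-order in 1/(molecule·s).

Signal flow: ligand-driven receptor dimerization (`c1L·c2`, a product of
the two named constants on one bimolecular step) and fast in-dimer
transphosphorylation (`t1`) produce active phospho-receptor dimers, which
are degraded at rate `d3` (free or SOS1-bound — so total EGFR and SOS1 are
conserved only when `d3 = 0`). pEGFR recruits SOS1 (`b1`/`n1`); the complex
drives RAS GDP→GTP exchange (`a1` vs hydrolysis `i1`); RAS-GTP activates
RAF (`a2`/`i2`); active RAF phosphorylates both MEK isoforms on their
activation sites (`p1`/`u1`). Activated MEK monomers form homo- and
heterodimers (`b2`/`n2`, `b3`/`n3`, `b4`/`n4`), and dimer-bound active MEK
phosphorylates ERK (`p2a` for MEK1, `p2b` for MEK2; heterodimers carry one
reaction at each rate; `u2` reverses). The MEK2/MEK1 activity ratio X = 5
is already folded into `p2b = X·p2a` and is kept as metadata only. Two
ERK-mediated negative feedbacks close the loop: phosphorylation of SOS1
(`p3`, reversed by `u3`), which blocks receptor binding, and Thr292
phosphorylation of MEK1 (`p4`/`u4`), which makes MEK1
activation-incompetent and recruits the PHP phosphatase (`b5`/`n5`) that
strips the activation sites (`u5`).

The kinetic role of MEK dimerization — which configurations phosphorylate
ERK — is not fully constrained by the published material; this package's
choice (any dimer-bound activated MEK is catalytically active, monomers are
not) is a documented design decision, as is the reduction itself: the
original study used a combinatorially expanded rule-based model, and this
network preserves every adjustable parameter's role and the feedback
topology rather than the exact species list.

One reference value deserves note: the published table prints
p3 = 2.0e-2, which is dimensionally implausible for a bimolecular rate
(with ~1e6 active ERK it implies instantaneous SOS1 shutdown) and is
inconsistent with the published optimization bounds [9e-11, 4e-8], whose
geometric center — like every other parameter's — sits at the reference
value. The package uses p3 = 2.0e-9.

Initial abundances are fixed (EGFR 5e5, SOS1 2e5, RAS 5e5, RAF 5e5,
MEK1 1.34e5, MEK2 6.6e4, ERK 3e6, PHP 3e6); the receptor/adaptor pools
start at their peak copy numbers rather than being produced by a
pre-stimulation synthesis/degradation simulation.

### Cell-line variants

Five variants are structural transformations of the same base network:

- **WT** — the base network.
- **KO** — MEK1 knockout: the MEK1 pool starts at 0.
- **N78G** — dimerization-dead MEK1: the `b2` and `b4` association
  reactions are removed (their reverse steps are retained; the dimers can
  never form).
- **T292A** — feedback-site mutant: both `p4` reactions are removed. With
  `p4 = 0` the WT and T292A networks are identical, a nesting property the
  tests assert exactly.
- **T292D** — phosphomimetic: the entire MEK1 pool starts
  Thr292-phosphorylated and `u4` is removed, leaving MEK1 constitutively
  inhibited.

### Observables and integration

Observables are linear species combinations: `MEK_pRDS` (all
activation-site-phosphorylated MEK, dimers counted twice), `ERK_pp`
(doubly-phosphorylated ERK), `pEGFR` (phospho-receptor subunits, two per
dimer), `pSOS1`. Negative excursions from the integrator are clamped to
zero in observables only, never in the raw state.

Integration uses LSODA (stiff-capable, via `scipy.integrate.odeint`) with
an analytic Jacobian assembled from the stoichiometry; the right-hand side
and Jacobian are numba-compiled. Defaults are rtol 1e-8 / atol 1e-2
molecules. The inference hot path uses rtol 1e-6 / atol 0.1, which changes
observables by ~6e-7 relative (measured against a rtol 1e-10 reference) —
four orders of magnitude below the 2% measurement noise — at 1.5× speed.
Moiety totals (RAS, RAF, ERK, MEK, PHP) are conserved to better than 1e-6
relative in all tests.

## Data models and likelihoods

**Quantitative data** are relative intensities y ∈ (0, 1] on a time grid,
with "nan" marking missing cells (EXP dialect: tab-delimited, first column
time, headers naming observables). Each cell is modeled as
y = Scale_obs · f(t, θ) + ε, ε ~ N(0, σ²) homoscedastic, giving the
negative log-likelihood (n/2)·ln(2πσ²) + F_quant/(2σ²) with
F_quant = Σ (y − Scale·f)². Scale factors attach only to the WT
quantitative comparison (the only condition with time-series data).

**Qualitative data** are pairwise orderings, one per line (PROP dialect):

    WT.MEK_pRDS at time = 300 < N78G.MEK_pRDS at time = 300

with z = 1 encoding "left ≥ right". The model difference
δ = g(A, θ) − g(B, θ) is computed from *unscaled* outputs (both sides share
units, so scale factors cancel). The Bernoulli noise model
P(z = 1) = 1/(1 + e^(−δ/s)) gives the exact per-statement negative
log-likelihood ln(1 + e^(−δ/s)) + (1 − z)·δ/s; in the small-s limit,
s × (that likelihood) converges to the hinge penalty
w·[max(0, −δ) + (1 − z)·δ] with w = 1/s, which is w·|δ| when the sign of δ
contradicts z and 0 otherwise. δ = 0 satisfies either outcome (zero
penalty), and the Heaviside prediction uses H(0) = 1, consistent with
z = 1 ⇔ A ≥ B. Default weights are w = 1 (s = 1), overridable per
statement or globally.

**Two scoring modes.** Optimization (MLE) minimizes
F(θ) = F_quant + F_qual with the hinge penalty — the raw sum of squares
needs no σ. Bayesian sampling uses the exact Gaussian likelihood with σ as
an adjustable hyperparameter plus the exact logistic likelihood, under a
proper uniform prior on the box Θ; outside the box the log-posterior is
−∞. Rate constants, scale factors, and σ are sampled and optimized on the
log10 scale.

Simulation failures inside an optimization are penalized with a
large-but-finite objective (1e12, configurable to raise instead); inside
the posterior they yield −∞ with a logged warning.

## Optimization and profile likelihood

The global fit uses DE/rand/1/bin differential evolution with mutation
F = 0.8, crossover CR = 0.9, population 15 × dimension (minimum 20),
reflection at the box boundary, and an optional early stop when the
population's objective spread collapses. Every candidate respects the box;
the per-generation best is non-increasing; runs are bit-reproducible given
a seed.

Profiles re-optimize all remaining parameters while one parameter sweeps a
log-spaced grid, warm-starting each re-fit from the neighboring optimum and
sweeping outward from the MLE. Classification against the pointwise
chi-square cut Δ = 1.92 (= χ²₁(95%)/2): crossing `mle + Δ` on both sides of
the minimum → *identifiable*; one side → *practically-unidentifiable-low/
-high*; neither → *unidentifiable*.

The cut is defined on the likelihood (chi-square) scale, so the pipeline
profiles the likelihood-form objective: the concentrated Gaussian term
(n/2)·ln(F_quant/n) — σ profiled out analytically — plus the hinge penalty,
whose molecule-scale weights make any ordering violation decisive. Applying
the same cut to the raw sum of squares would make it noise-level-dependent
(with σ = 0.02, a rise of 1.92 in raw SSE corresponds to a chi-square
change of ~4800), which is why the likelihood units are the defensible
choice here. `profile_parameter` itself is generic and profiles any
objective callable.

## Adaptive MCMC and diagnostics

The sampler is random-walk Metropolis with three phases (burn-in,
adaptation, production; only production retained, no thinning). A global
step-size multiplier is tuned toward 23.4% acceptance by stochastic
approximation through burn-in and adaptation; during adaptation the
proposal covariance is additionally re-estimated every 100 iterations from
the accumulated post-burn-in draws (scaled 2.38²/d, regularized with
1e-8·I), with re-estimation stopping shortly before production so the step
size can re-equilibrate to the final covariance. Everything is frozen for
production. Out-of-box proposals are rejected through the prior. Chains are
bit-reproducible given a seed.

Diagnostics are implemented natively following the rank-normalization
approach of Vehtari and colleagues: split-R̂ on rank-normal scores (Blom
offset), by default taking the maximum of the location statistic and the
median-folded scale statistic (the unfolded statistic is available and is
exactly invariant under monotone transforms); bulk ESS as the ESS of
rank-normalized split chains with Geyer's initial positive/monotone
sequence truncation of the FFT autocovariance; tail ESS as the minimum ESS
of the 5% and 95% quantile-indicator sequences. The implementation agrees
with ArviZ to well under 1% on fixture chains (exactly, in practice) and is
cross-checked against it in the test suite; constant chains report NaN
("undefined") rather than crashing.

Posterior predictive bands simulate a seeded subsample of production draws
through a variant model and report the per-time median and nested central
credible intervals (10–95% by default); failed draws are dropped with a
logged count. Constraint satisfaction fractions score, for each statement,
the fraction of simulated draws whose Heaviside prediction matches z; the
implementation equals a brute-force recount exactly.

## Synthetic data: what it emulates, and study conditions

The generator draws data with exactly the statistical structure the
likelihoods assume, from the reference ground truth (all reference rate
values; in particular d3 = u3 = 1.0e-3):

- **Quantitative**: WT is simulated on the default six measurement times
  (300, 600, 900, 1800, 2700, 3600 s) for pEGFR, pSOS1, ERK_pp; true scale
  factors are chosen to put each noiseless peak at 0.95 (emulating
  relative intensities normalized to their maximum, with headroom for
  noise); i.i.d. Gaussian noise σ = 0.02 is added; values are clipped into
  (0, 1] with a logged count (clipping, not rejection, preserves n); 5% of
  cells are blanked to "nan".
- **Qualitative**: the default 15 statements compare MEK_pRDS between each
  of KO/N78G/T292D and WT at 300/1800/3600 s (9), plus WT cross-time
  orderings of MEK_pRDS and ERK_pp (6). Outcomes are drawn
  z ~ Bernoulli(1/(1 + e^(−δ/s))) at the truth; the default s = 1 molecule
  is negligible against molecule-scale differences, so orderings are
  effectively noiseless — as for scored blot comparisons; s = 0 forces the
  Heaviside limit exactly.

Two standard problems package these conditions:

- **Recovery problem** (MLE/profile stage): adjustable {d3, u3, three scale
  factors} with the optimization box [8e-5, 3e-2] for the rates
  (geometric center at the truth) and ±0.5 decades around each true scale
  factor; penalty-form objective; all five variants simulated.
- **Bayesian problem**: adjustable {d3, u3, scales, σ} with the wider UQ
  box [1e-5, 1e-1] for the rates and σ ∈ [2e-3, 2e-1] (geometrically
  centered on the generating 0.02); exact-likelihood posterior. To keep
  desk-scale sampling affordable the statement set is restricted to the
  two-variant WT/KO design (9 statements — KO-vs-WT at the three
  comparison times plus the six WT cross-time orderings), so each posterior
  evaluation integrates two variants; the full five-variant design remains
  the default everywhere else, and satisfaction fractions for all variants
  can still be evaluated post hoc from posterior draws.

Problem sizes used by the tests and the acceptance script (chosen for a
single-CPU desk run): the recovery fit uses DE with population 20 for up to
50 generations (early stop at spread < 1e-3), replicated over five data
seeds; profiles use an 8-point grid per rate with population-14 × 20
re-fits; sampling uses five chains with phases (2000, 5000, 10000), a
schedule verified to keep worst-case R̂ − 1 below 0.02 across independent
seed sets, plus two further two-chain replicates at (2000, 5000, 6000) for
coverage counting. The full-scale schedule (25k/25k/250k) is available
through configuration.

**What passing tests show — and what they do not.** The synthetic
experiments validate the machinery end to end: when data really follow the
assumed noise models, the pipeline recovers the generating parameters
(within 0.3 log10 units), classifies d3 and u3 as practically identifiable,
and produces converged posteriors whose 95% intervals cover the truth.
They do not validate the noise models themselves against real blots:
densitometric saturation, replicate correlation, heteroscedasticity, and
mis-specified statement weights are all outside the generator, and real
relative data would also confront the reduced network with structural
error that the synthetic data cannot exhibit by construction.

## Numerical conventions and degenerate inputs

- H(0) = 1; δ = 0 incurs zero penalty for either z.
- `sigmoid_prob` is overflow-safe for |δ/s| up to 1e4 and beyond (logistic
  via `expit`; the log-likelihood via `logaddexp`).
- Empty quantitative tables contribute 0 to every score (empty-sum
  convention); parsing accepts out-of-range values but a separate
  validation pass flags them.
- Profile curves keep NaN gaps where a re-fit fails and classify from the
  finite points; a fully-NaN curve is an error.
- DE reflects out-of-box proposals at the boundary; the sampler instead
  rejects them through the prior (reflection would bias the kernel without
  a matching proposal correction).
- Ties in rank normalization use average ranks with the Blom (3/8) offset.
- The `fit_de` early-stop tolerance is off (0.0) unless requested.

## Known limitations

- The reduced network is a surrogate: structural fidelity to the original
  rule-based species list is a non-goal, so absolute trajectories are not
  comparable to the original study's — only the parameter roles, variant
  contrasts, and feedback topology are.
- The penalty weights of the original 90-statement dataset are not public;
  defaults are w = 1 and results with real data would depend on that
  heuristic.
- Single-σ homoscedastic noise across observables and times is an explicit
  simplification (per-observable σ is a configuration extension, off by
  default).
- The sampler is a single-site random-walk Metropolis; strongly correlated
  or multimodal posteriors beyond the desk-scale problem may need the
  full-scale schedule or a different kernel.
- SBML import is an interface stub by design; the built-in network is the
  tested path.
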