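# Methods

## Model

The package analyses a metabolic network at steady state under mass-action
kinetics. Let S be the stoichiometric matrix over *internal* metabolites
(boundary species, suffixed `_ext`, are implicit sources/sinks and
contribute no balance row) and let x be a metabolome snapshot. Each
reaction step i carries a rate

    v_i = k_i · M_i(x),      M_i(x) = ∏_{j : S_ji < 0} x_j^{|S_ji|},

i.e. M_i is the product of the step's substrate concentrations raised to
their stoichiometric multiplicities; a step whose substrates are all
boundary species has M_i = 1 and acts as a constant influx. At steady
state S·v = 0, so the set of rate-constant vectors consistent with the
observed snapshot is the polyhedral cone

    C(x) = { k ≥ 0 : S · diag(M(x)) · k = 0 },

the **k-cone**. It is the flux cone { v ≥ 0 : S v = 0 } rescaled
elementwise by 1/M(x).

A literal signed-exponent variant of M (products entering with inverse
powers) is available via `convention="literal"` for sensitivity analysis;
the substrate convention is the default because it is the mass-action rate
law itself.

### Differential activity

If the two conditions share a flux distribution v (constant influxes, same
steady-state throughput), then v = M_A·k_A = M_B·k_B componentwise, hence

    k_B / k_A = M_A / M_B    per step.

`differential_activity` evaluates log2(M_A(x_a)/M_B(x_b)) for replicate
pairs (a, b), tests the per-step sample of log-ratios against 0 with a
one-sample t-test, corrects across steps by Benjamini–Hochberg (Holm
optional), and reports direction (up = more active in condition B, the
orientation recorded in every output header). Steps with M ≡ 1
(boundary-only substrates) are structurally uninformative and reported
unchanged with fold change 0.

**Pairing and degrees of freedom.** The default policy forms all
n_A × n_B cross pairs but sets the t-test degrees of freedom to
min(n_A, n_B) − 1. Cross pairs reuse each replicate n times; treating the
n_A·n_B ratios as independent would inflate significance roughly
√(n)-fold. The min−1 correction makes the standard error of the mean
ratio match its true sampling variance in expectation while discarding no
data; the null-calibration suite verifies the resulting type-I rate stays
below nominal. An `index` policy (i-th vs i-th replicate) is available
for genuinely paired designs.

When the flux is *not* invariant (e.g. an influx was perturbed), the
estimator is biased by the flux ratio; the synthetic generator flags such
scenarios (`non_flux_invariant`) so they can be studied deliberately.

### Cone enumeration

Extreme rays of C(x) are computed by the double description method run in
exact rational arithmetic (`fractions.Fraction`): starting from the
nonnegative orthant, each balance equality cuts the ray set, adjacent
positive/negative ray pairs being combined; adjacency uses the
combinatorial zero-set test. Consequences:

- residuals max|S·diag(M)·k| of returned rays are *exactly* zero;
- rays are canonically normalized (max entry 1) and deterministically
  ordered (support pattern, then entries), so equal cones compare equal.

Float concentrations are converted through their decimal representation,
so exactness is preserved for any finite-precision input. Exact
enumeration is intended for networks up to a few hundred steps; the
package targets curated medium-size reconstructions, not genome scale.

An independent oracle, `enumerate_rays_bruteforce`, enumerates candidate
supports exhaustively and keeps supports whose restricted system has a
one-dimensional, strictly-positive null space (sympy rationals). It is
exponential in the step count and used only to cross-check the double
description on small networks (the two share no code path).

### Metabolome statistics

Differential metabolites: two-sided Welch t-test on log concentrations
(robust default for n≈3 metabolomics replicates; the pooled-variance
choice is immaterial at equal n), fold changes reported in log2. A
metabolite is significant when p < alpha (default 0.05) AND
|log2 FC| > lfc_min (default 1). Degenerate inputs: fewer than two
replicates → p undefined (NaN), never significant; zero variance with
equal means → p = 1 (no evidence of change) rather than NaN.

Over-representation: upper-tail hypergeometric probability P(X ≥ k) of
the overlap between the significant set and each pathway, with the
*measured* metabolites as the background universe (the standard ORA
choice; an external compound database would deflate p-values with
compounds that could never have been selected). Holm and
Benjamini–Hochberg run across all tested sets; a pathway is enriched only
if both the Holm value and the FDR fall below their thresholds (default
0.05 each). Median normalization and mean-centering, sometimes applied
before quantitative enrichment, are no-ops for membership-based ORA and
are omitted.

Cross-cell-line intersection reports both the pathways/metabolites shared
by all lines and the exact Venn region counts.

## Synthetic data generator

`synth` produces inputs with precisely the statistical structure the
analysis assumes:

- **Kinetics.** dx/dt = S·v(x) with v_i = k_i·M_i(x); boundary influxes
  are zero-order (constant rate). This makes the flux-invariant scenario
  constructible: perturbing an interior k changes pools, not throughput,
  so the activity estimator's answer is exact at zero noise — the
  strongest possible correctness probe. Influx perturbations are allowed
  and flagged as breaking that assumption.
- **Steady state.** LSODA integration from x = 1 in doubling time
  windows until max|dx/dt| < 1e-10, with an overflow guard; the returned
  state is checked strictly positive. Structurally unbalanced models
  (influx with no efflux) fail loudly rather than returning a pseudo
  steady state.
- **Noise.** Replicates are lognormal with median x and
  log-sd = sqrt(log(1+cv²)) — multiplicative, positivity-preserving, the
  standard metabolomics error model. Additive Gaussian noise is
  deliberately not offered. Default cv = 0.1 (a typical relative spread
  for targeted metabolomics); default n = 3 replicates per condition.
- **Toy models.** `chain` (2 internal metabolites, closed-form steady
  state x = influx/k), `branch` (2-dimensional flux space), and
  `gsh_motif` (6 internal metabolites: glutathione synthesis via GCL/GSS,
  a GPX/GSR redox cycle, GGT/ANPEP degradation, amino-acid uptake). All
  are small enough for exact cone enumeration inside tests.
- **Three-cell-line scenario.** Fourteen independent
  uptake → metabolite → secretion chains; all three lines quadruple the
  secretion constants of chains 1–6 (the shared core, |log2 FC| = 2 per
  affected metabolite), each line additionally perturbs two private
  chains, two chains stay null. The designed shared signature is
  therefore exactly 6 metabolites, recovered by the p < 0.05 &
  |log2 FC| > 1 filter plus intersection under the default noise.

What the generator does *not* emulate: correlated measurement error
across metabolites, batch effects, missing values, ionization/annotation
artifacts, or kinetics beyond mass action (no saturation, no allosteric
regulation). Passing tests therefore demonstrate correctness of the
inference given the model's assumptions, not robustness to real-data
violations of them.

## Bundled reconstruction

`data/reconstruction_synthetic_74x112.txt` is a hand-curated SYNTHETIC
STAND-IN network — 74 internal metabolites and 112 reactions spanning
glycolysis, the pentose phosphate pathway, the TCA cycle, amino-acid,
one-carbon, glutathione, fatty-acid and polyamine metabolism — providing
a structurally realistic medium-size instance for parsing, validation and
scale tests. It is not a transcription of any published reconstruction.

## Numerical and design choices

- Stoichiometric coefficients are exact rationals end to end; matrix
  layout is fixed by declaration order, so identical input files give
  bit-identical matrices.
- Reversible reactions are split into `_fwd`/`_rev` steps before any cone
  computation (k ≥ 0 is only meaningful per direction); the split is
  idempotent.
- Reactions mentioning a metabolite twice have the coefficients summed;
  reaction ids are restricted to `[A-Za-z0-9_]+`.
- Unmeasured internal metabolites default to concentration 1 in both
  conditions (neutral in every ratio) and the affected steps are flagged
  `uses_unmeasured`; a strict mode raises instead.
- Expression overlay: a reaction mapped to several significant genes with
  conflicting directions is labelled `ambiguous`, never coerced.
- Pipeline determinism: a fixed config (including seed) produces
  byte-identical TSVs; the manifest records thresholds, policies, the
  ratio orientation and a config digest.

## Problem sizes

Tests and the acceptance script use 20 random networks (≤6 internal
metabolites, ≤8 steps) for oracle comparisons, 50 random concentration
pairs for the cone-correspondence check, 200 simulated null experiments
for calibration, and the 74×112 bundled network for structural checks —
sizes at which the exhaustive oracles are exact and the whole suite runs
in seconds.

## Known limitations

- Exact double description scales poorly past a few hundred steps; no
  float fallback path is wired into `kcone_basis` beyond the residual
  reporting, because every intended use fits the exact path.
- The activity estimator identifies k ratios only up to the shared-flux
  assumption; condition pairs with changed uptake rates violate it and
  are only detected when the generator flags them.
- ORA treats pathways as flat member sets; no topology or quantitative
  weighting.
- Metabolite identifiers are taken verbatim; no mapping to HMDB/KEGG.
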