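# Methods

## Scope and data model

`protlen` analyses the distribution of protein lengths (z, in amino-acid
residues) across species. The unit of analysis is a **proteome**: the
non-redundant (nr) set of protein sequences of one species, obtained from a
raw protein FASTA by removing exact duplicate sequences and sequences that
occur as contiguous substrings of longer ones, and optionally removing
records whose annotation line matches keywords such as *transposon* or
*retrovirus*. Within a duplicate group the longest sequence is kept; among
equal sequences the first occurrence in file order retains its id and
description (the choice of surviving metadata is a convention — it does not
affect any downstream statistic, which all operate on sequences and
lengths). Substring matching is case-insensitive in effect because all
sequences are uppercased on input. Ambiguous residues (X, B, Z, U, O) are
retained and count toward length; they are excluded only from composition
percentages. Records containing internal stop symbols are treated as
malformed and skipped with a warning; a single trailing `*` is stripped
silently, as it is a common FASTA convention for the translated stop.

## Candidate length laws

Four laws compete for the bulk of the distribution, all supported on
(0, ∞):

| model          | density f(z)                                            | k |
|----------------|---------------------------------------------------------|---|
| `gamma_free`   | α^θ z^(θ−1) e^(−αz) / Γ(θ)                              | 2 |
| `gamma_fixed2` | α² z e^(−αz)                                            | 1 |
| `lognormal`    | exp(−(log z − μ)² / 2σ²) / (z σ √(2π))                  | 2 |
| `sexp`         | αβ/(β−α) (e^(−αz) − e^(−βz)), α < β (hypoexponential)   | 2 |

The gamma's α multiplies z in the exponent, i.e. it is a **rate** (per aa),
and is labelled as such everywhere, even though shape/scale vocabulary is
common for this family. The hypoexponential (sum of two independent
exponentials) degenerates to `gamma_fixed2` as β → α; numerically the
density is evaluated through `expm1` and switches to the analytic limit
α² z e^(−αz) below a relative rate gap of 1e−10, which keeps the two
parametrisations within 1e−8 of each other at a relative gap of 1e−6.
Because (α, β) and (β, α) give identical likelihoods, estimates are
canonicalised to α ≤ β.

A Pareto power law f(z) = a·zm^a / z^(a+1) on z > zm describes the extreme
right tail only, fitted to lengths strictly above a threshold (default
1,500 aa). Its printed distribution function in some sources is
inconsistent with this density; the implementation uses the CDF implied by
the density, P(Z ≤ z) = 1 − (zm/z)^a.

## Fitting

Fitting subsets the sample to an **open** length range, by default
0 < z < 1,500 aa, and maximises the *untruncated* likelihood on the subset
— no renormalisation of the density over the window. This is deliberately
crude ("untruncated likelihood on truncated data"): the window exists to
blunt the influence of the heavy tail on the bulk fit, not to model the
tail, which has its own Pareto treatment. All four models are fitted on the
identical filtered sample so their AICs (2k − 2 log L) are comparable; the
model with the smallest AIC wins, with exact ties broken
fewest-parameters-first in the fixed order (`gamma_fixed2`, `sexp`,
`gamma_free`, `lognormal`). A non-converged fit is excluded from winner
selection with a warning.

The log-normal MLE is closed-form (meanlog = mean of log z; sdlog = RMS
deviation of log z with divisor n). The gammas and the hypoexponential are
maximised numerically in log-parameter space (L-BFGS-B with analytic
gradient for the gammas, Nelder-Mead for the hypoexponential, whose
likelihood ridge along the α = β boundary is kinder to a simplex) starting
from moment estimators: gamma via mean/variance matching; hypoexponential
by solving 1/α + 1/β = m, 1/α² + 1/β² = v, falling back to
(0.5, 1.5)·(2/m) when that system has no real positive solution. The
returned log-likelihood is never below the starting value's; for
`gamma_fixed2` the moment start (rate = 2/mean) *is* the exact MLE, so the
optimiser legitimately returns it unchanged. Samples with all lengths equal
raise a non-identifiability error rather than returning a degenerate fit.

For the Pareto tail, zm is the tail minimum and the shape is the standard
closed form n / Σ log(z_i/zm) (verified in tests against a brute-force
likelihood grid). Goodness of fit uses equal-probability bins under the
fitted model — bins = min(10, n/5), never fewer than 3, so every expected
count is ≥ 5 — with statistic Σ(O−E)²/E on df = bins − 2 (one estimated
shape; zm is treated as a support boundary, not an estimated parameter in
the χ² accounting).

AIC values are computed on the range-filtered n for all models uniformly;
reporting a per-model n would make the criteria incomparable.

## Inference on the gamma shape

The shape MLE's standard error comes from the information matrix. In the
(shape θ, rate α) parametrisation the per-observation information is

    I(θ, α) = [[ψ′(θ), −1/α], [−1/α, θ/α²]],

giving asymptotic shape variance [I⁻¹]_θθ / n = θ / (θψ′(θ) − 1) / n
(≈ 6.8997/n at θ = 2, since ψ′(2) = π²/6 − 1). For this family the
negative Hessian of the log-likelihood contains no data terms, so observed
and expected information coincide identically at the estimate — the
observed-information prescription and the analytic formula are the same
number, and a bootstrap cross-check in the tests agrees to within 20%.

Per-species estimates θ̂_j with standard errors σ_j are pooled as the
*unweighted* mean θ̄ with variance Σσ_j²/J², assuming independence across
species, and H0: θ = θ0 (default 2) is tested two-sided against the
standard normal. Species enter unweighted even though proteome sizes differ
by orders of magnitude — the pooled quantity is "the typical species'
shape", not a residue-weighted average; an inverse-variance-weighted
variant is available but not default. Phylogenetic correlation between
species is ignored by construction; the p-value is anti-conservative to
the extent that related species share shape.

## Composition bias

Per protein, the percentage of each of the 20 standard amino acids is
computed over standard residues only; a protein with no standard residue
has undefined composition and is dropped from correlations (not
zero-filled). Per species, Pearson r between each residue's percentage and
raw (untransformed) protein length is the bias profile; a residue with
constant percentage across the proteome gets a missing r. Profiles are
averaged within taxon groups with SE = sd/√(species count), missing for
singleton groups. Correlations are computed on the deduplicated set, since
duplicate records would double-count their composition.

## Annotation diagnostics

Two qualitative observations about annotation quality are formalised:

* **classification** — a proteome is `interior_mode` iff lengths
  151–250 aa outnumber lengths 51–150 aa (inclusive windows), else
  `monotone_suspect`; a monotonically decreasing histogram in this range is
  the signature of raw six-frame ORF calling rather than curated gene
  models. `sharp_cutoff` flags a smallest observed length inside a
  configurable window (default 20–60 aa), the footprint of a hard minimum
  ORF length in the calling pipeline.
* **peak calls** — against the AIC-best fitted model (so the diagnostic is
  self-consistent per species), the expected count of each 1-aa bin
  [k, k+1) is n·(F(k+1) − F(k)). A bin is called iff it is a strict local
  maximum over a ±2 aa window and its Poisson z-score
  (O − E)/√E exceeds a threshold (default 5). The scan is restricted to
  the fit's length range, since the bulk model says nothing meaningful
  about the Pareto tail. The window pair, the ±2 aa neighbourhood and the
  threshold are this package's formalisation of behaviour that is usually
  described only qualitatively; the false-positive control (≤ 1 spurious
  call per pure-model proteome on average) and the power floor (injections
  of ≥ 10√E are never missed) are verified by simulation in the test
  suite.

Peak detection requires n ≥ 1,000 (configurable); below that, single-length
excesses are indistinguishable from noise at any sensible threshold.

## Random-ORF theory

With i.i.d. bases at frequencies A = T = (1−g)/2, G = C = g/2 for GC
fraction g, the per-codon stop probability is p(g) = a³ + 2a²(g/2) with
a = (1−g)/2 — equal to 3/64 at g = 1/2. The number of codons scanned up to
and *including* the first stop is geometric with mean 1/p; that convention
(rather than 1/p − 1) is the one consistent with the standard quoted
values of ~21 aa (64 nt) at uniform composition, 14 aa at 35% GC and
31 aa at 60% GC, and is what `expected_orf_length` and the geometric
simulator implement. Codon positions are i.i.d.; there is no start-codon
conditioning — this is deliberately the back-of-envelope null model whose
failure to describe real proteomes motivates the selection-based reading
of the observed distributions.

## Synthetic proteomes

The generator emulates the statistical structure the analysis assumes, so
every stage can be tested against known truth without downloading genomes:

* integer lengths from any candidate law, rounded to the nearest integer
  (rounding, not truncation, so fitted continuous models stay centred on
  the discrete data) and redrawn below a minimum length (annotation-cutoff
  emulation). Default background: gamma with shape 2.3 and rate 0.005
  (mean 460 aa) — a shape at the centre of the empirically observed 1.5–3
  range and a mean in the eukaryotic regime;
* residues drawn per position from a baseline frequency vector (database
  average frequencies) tilted linearly in length,
  f_aa(L) = base_aa + slope_aa·(L − mean L), renormalised per protein —
  the simplest mechanism producing composition-vs-length Pearson
  structure; infeasible tilts (negative frequency at an emitted length)
  raise an error rather than being clipped;
* injected artifacts with exact bookkeeping: extra records at one exact
  length (gene-family peaks), exact-duplicate copies, excised internal
  substrings of ≥ 15 aa (long enough that chance recurrence of a random
  15-mer in a desk-scale proteome is negligible, keeping the dedup ledger
  exact), and records tagged with a transposon keyword.

One seeded generator drives each proteome; identical specs produce
byte-identical FASTA. What the generator does **not** emulate: real
homology (duplicates are literal copies, not diverged paralogs), secondary
structure or codon-level signal in sequences, phylogenetic correlation
between species, and mixture-shaped empirical distributions. Tests passing
on synthetic data therefore establish that the estimators and diagnostics
recover the structure they target when the model holds — not that any
particular real proteome follows these laws.

## Problem sizes and calibration checks

Simulation-based guarantees in the test suite use sizes at which the
asymptotics are informative but the suite stays fast: 2×10⁵ draws for
reference-parameter recovery (shape SE ≈ 0.006 at that n), 2×10⁴-protein
proteomes for peak power/false-positive checks over 50 replicates, and a
10⁴-protein proteome for the end-to-end pipeline run. The type-I-error
check of the pooled shape test draws per-species estimates directly from
their asymptotic sampling law (θ̂_j ~ N(2, σ_j²) with σ_j from the
information formula at realistic per-species n) over 500 replicates of 84
species: this isolates the calibration of the pooling and test machinery
itself, which is the property being claimed, at a cost that permits many
replicates; the validity of the asymptotic law for the underlying MLE is
covered separately by the bootstrap and recovery tests.

## Known limitations

* The likelihood ignores integer rounding of lengths (continuous laws on
  discrete data); at protein scales the effect is far below sampling error.
* Range filtering without renormalisation biases bulk-model parameters
  slightly when tail mass above the window is non-negligible.
* The pooled shape test treats species as independent.
* The hypoexponential boundary α = β is the closure of the family; data
  truly generated at the boundary make its second parameter weakly
  identified, and AIC selection between `sexp` and `gamma_fixed2` near the
  boundary is decided by a sub-unit likelihood difference.
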