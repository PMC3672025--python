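# Methods

## Generative model

One binding event in a candidate region is described by three region-specific
parameters — the site center μ (bp), the binding intensity ν (expected tags
per strand per event), the local background ρ (tags/bp/strand) — and two
genome-wide shape parameters: σ, the standard deviation of the cross-link
location around μ, and β, the mean of the exponential cross-link-to-fragment-end
distance. A reverse-strand tag's leftmost coordinate is x = ξ + E with
ξ ~ N(μ, σ²) and E ~ Exp(β); marginally x follows the exponentially modified
Gaussian

f_R(x) = Φ((x−μ)/σ − σ/β) · (1/β) · exp(−(x−μ)/β + σ²/(2β²)),

and forward-strand tags follow the mirror image f_L(μ−z) = f_R(μ+z). The two
strands share ν and ρ. Counts Y_j per position per strand are independent
Poisson with mean λ_j = ν f(j) + ρ; the continuous density is evaluated at
integer positions without discrete renormalization (the sum over positions is
approximated by the unit integral, so Σ_j (λ_j − ρ) ≈ ν).

**Censoring.** Positions whose tag sequence is not unique in the genome
cannot receive uniquely mapped tags. They are excluded from the likelihood
(each mappable position–strand pair contributes one Poisson log-pmf term;
censored pairs contribute nothing). The estimated ν therefore exceeds the
observed tag count in proportion to the censored density mass — the intended
compensation behavior, verified by simulation (40 % censoring, ν recovered
within a few percent).

Coordinates are 1-based inclusive throughout the library; BED input/output
converts at the boundary (0-based half-open).

## Estimation

Per region, (μ, ν, ρ) are estimated by bounded quasi-Newton (L-BFGS-B with
analytic gradient) with (σ, β) fixed, under ν ≥ 0, ρ > 0 and μ confined to
the region. The μ constraint matters: outside the region the density barely
overlaps the data and an arbitrarily large ν times a vanishing tail can mimic
a background tilt, destroying the interpretability of ν̂.

Initialization is deterministic and scale-free: μ₀ is the midpoint between
the modes of 20-bp-smoothed strand profiles, ρ₀ the 25th percentile of
per-position counts (robust to the peak), ν₀ the excess of the tag total over
w·2ρ₀, split per strand. A coarse μ scan (≈64 grid points) supplies a second
start so the returned fit is the global, not merely a local, maximizer; the
closed-form ν = 0 boundary profile (ρ̂̂ = total tags / mappable
position–strand pairs) is always evaluated too, so the fit never falls below
the null. Convergence failures are flagged on the fit, never raised.
Objective tolerance 1e-12 (relative, L-BFGS-B `ftol`); gradient tolerance
1e-8.

**Standard errors.** The covariance of (μ̂, ν̂, ρ̂) is the inverse observed
information — the negative Hessian of the log-likelihood at the optimum,
computed by central finite differences with steps (0.01 bp, 0.1 tag,
1e-4 tag/bp). The expectation form of the information is analytically messy;
the observed information is the standard surrogate. When the Hessian is
singular or indefinite, or ν̂ sits too close to the boundary for a symmetric
stencil, SEs are reported as missing (NaN) rather than fabricated. SE
calibration is checked by simulation (empirical SD of μ̂ tracks the mean
reported SE within ~20 %).

**Global shape.** (σ, β) are trained by maximizing the summed region
log-likelihood over regions whose μ is anchored at a known motif-site center,
with each region's (ν, ρ) profiled out at an inner concave 2-parameter
optimum; the outer search is Nelder–Mead in (log σ, log β). Anchoring μ at
the motif site (rather than profiling it) is a deliberate choice: it removes
the location/shape trade-off and is what the motif information is for.
Without training data the defaults σ = 30, β = 50 apply. As a by-product,
the mean fragment length is 2β̂ + d − 1 for tag length d (both fragment ends
average β from the cross-link; the right tag's location is its leftmost
base, hence the −1).

## Tests

**Binding LR test.** λ = −2 log[L(μ̂̂, 0, ρ̂̂)/L(θ̂)], referred to χ²₁,
clipped at 0. Two opposing effects act on its null calibration:

* the ν ≥ 0 boundary makes χ²₁ conservative (with μ *fixed*, simulated
  type-I error at nominal 0.05 is ≈ 0.02, consistent with the
  ½χ²₀ + ½χ²₁ mixture);
* μ is unidentified under ν = 0, so maximizing over a free μ makes λ a
  location-scan (Davies-type) statistic. A region of width w supports
  roughly w/(σ+β) quasi-independent peak locations; at w = 400,
  σ+β = 100 this predicts ~4× the one-location rate, and simulation gives
  ≈ 0.12–0.16 at nominal 0.05.

The second effect dominates, so the reported χ²₁ p-value is
**anticonservative for weak signals**; it remains an excellent ranking and
screening statistic, and deep-tail calls (p < 10⁻³) on pure background
datasets are rare end to end (the region pre-selection step removes most
noise regions first). Users should treat LR p-values near the nominal
threshold with caution.

**Goodness of fit.** The saturated alternative gives each mappable
position–strand pair its own intensity (MLE λ̂ = y, 0·log 0 ≡ 0), so the
statistic is the Poisson deviance 2Σ[y log(y/λ̂₀) − (y − λ̂₀)] with
df = (mappable position–strand pairs) − 3; σ and β are treated as known, and
the saturated model is per-position-per-strand (both are implementation
definitions; the df convention is recorded here because reasonable
alternatives exist). df ≤ 0 yields an undefined test (NaN p, peak kept).
Small p-values flag counts the single-event model cannot explain: PCR spikes
in short regions, multiple binding in long ones. Under the true model ≤ 1 %
of simulated regions fall below p = 0.01 (the χ² approximation is adequate
at moderate counts).

**Screening.** A peak is masked iff its region is shorter than the length
cutoff AND its GOF p-value is below the p cutoff — short ill-fitting regions
are spike suspects; long ill-fitting regions are multiple-binding candidates
and are kept. Screening changes flags and ranks only, never fit values.
When motif sites are available, the recommended (length, p) pair maximizes
the area under the precision-vs-rank curve (truncated at rank 10 000) over
the grid {200, 300, 400, 500} × {10⁻², 10⁻⁴, 10⁻⁶, 10⁻⁸}, ties resolved to
the least aggressive pair.

## Region selection

The genome is tiled with non-overlapping windows (default 150 bp); a window
with at least the minimum pooled tag count (default 15) qualifies, and runs
of neighboring qualifying windows merge into one region. Region lengths are
therefore multiples of the window length, from one window upward, and an
isolated tag pileup yields exactly one minimum-length region. A 1-bp sliding
window was considered and rejected: under union-merge semantics every window
containing a pileup qualifies, so the minimum achievable region length would
be nearly twice the window, and "minimum length = window length" is the
documented contract. Both strands are pooled (binding evidence spans both);
duplicate tags are kept (the Poisson model accommodates them, and PCR
pathology is the GOF screen's job); the merge threshold is ≥ min_count.
Tags located inside the unmappable set contradict the mappability input and
are dropped with a warning at ingest.

## Motif p-values

PSSM scores are integer log-odds: round(100 · log₂(((count + 0.25)/(colsum +
1)) / 0.25)) — a 0.25 pseudocount against the equal-base background, scaled
by 100 so the lattice is exact. The null distribution of a segment score
(bases i.i.d. uniform) is computed exactly by convolving the L per-column
4-point distributions on the integer lattice; a site's p-value is the
upper-tail mass at its score. The scale factor 100 is an implementation
parameter: coarser lattices trade accuracy (a warning is available via
`max_rounding_error`) for speed, and integer input matrices with step 1
incur no rounding at all. Scanning covers both strands (reverse strand via
the reverse-complemented matrix, whose null distribution is identical);
windows containing non-ACGT bases are skipped; the default p cutoff is
5×10⁻⁶. A site's coordinate is the center of its window, start + ⌊L/2⌋ —
exactly mirror-symmetric between strands for odd L, off by one for even L as
for any single-base center convention.

## Simulator

`simulate_region` generates one region either as direct Poisson counts at
the model intensity ("count" mode) or mechanistically — Poisson(ν) tags per
strand at round(ξ ± E), plus uniform background positions — and the two
modes agree distributionally (χ² two-sample test on binned counts). Tag
coordinates round half-up. Censoring zeroes counts at masked positions and
nothing else (the i.i.d. mask path consumes the same RNG stream regardless
of the fraction, so masked and unmasked runs at one seed are otherwise
identical). `simulate_dataset` plants multiple peaks on multiple chromosomes
and writes the exact dialects the readers consume.

Default simulation conditions used throughout the test suite: σ = 40,
β = 60, ν = 200 (300 for shape training), ρ = 0.1–0.2 per bp per strand
within regions and 0.01–0.02 genome-wide, region widths 400–500 bp,
1 Mb chromosomes with 20 planted peaks for end-to-end runs, and fixed seeds
everywhere. Replicate counts (200 for parameter recovery, 1000 for LR
calibration, 500 for GOF calibration) are the package's chosen precision
targets for the quantities being estimated.

What the simulator does **not** emulate — and what passing tests therefore
do not establish about real data: sequence-dependent fragmentation and
amplification bias, PCR duplicate bursts (the GOF screen is tested against
directly constructed count anomalies instead), fragment-length variation
between molecules beyond the exponential model, chromatin-state-dependent
background (the model's background is locally uniform), read errors and
mapping artifacts, and multiple nearby binding events within one region.

## Known limitations

* One binding event per region: multi-modal regions fail the GOF screen
  rather than being decomposed.
* The LR p-value's null calibration is anticonservative for free-location
  fits (see above).
* The background is locally uniform; slowly varying genome-wide background
  is handled by per-region ρ, but sharp accessibility gradients within a
  region are not.
* SAM input is text-parsed via pysam and requires a header; BED and Bowtie
  inputs may be gzipped, SAM not.
* The observed tag density of some factors shows features (e.g. central
  dips) the model deliberately does not represent.
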