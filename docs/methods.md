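# Methods

This note documents the models and procedures implemented in `platysense`,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical choices made where the design was
genuinely open.

## Cluster-level expression quantification

De novo assemblies split one gene across partially redundant transcripts.
The quantification unit is therefore a *cluster*: transcripts connected by
chains of pairwise exact shared substrings of at least `min_overlap` bp
(default 50, matching a 50-bp read length so any read maps within one
cluster). Sharing a substring of length ≥ k is equivalent to sharing a
k-mer, so clustering indexes canonical 50-mers (k-mers containing `N` are
excluded; reverse-complement overlaps count by default, controllable via
`strand_agnostic`) and takes the union-find closure. The partition is
invariant to input order; cluster ids derive from the lexicographically
smallest member.

**Nominal length.** Each cluster's length is that of its non-redundant
sequence: the longest member seeds a growing concatenate, and every other
member — processed in decreasing length, ties broken by id (the procedure
is order-dependent in principle, so the order is fixed deterministically) —
contributes only the parts not covered by an exact match of ≥ `min_overlap`
bp against any existing segment. Uncovered pieces are appended as separate
segments rather than string-concatenated, so no artificial junction k-mers
arise. Residual overlap pieces shorter than `min_overlap` are *not*
detected and count as novel sequence; this is inherent to the overlap
definition, and the test oracles only use layouts where every intersection
piece is 0 or ≥ the threshold.

**Expression.** `E[g,s] = C[g,s] / (L_g/10³) / (N_s/10⁶)` with `N_s` the
column sum of the count table — the total *counted* (mapped) reads, the
only total a count table defines. The expressed-gene rule (≥ 12 units in
≥ 1 replicate) and the DE pre-filter (CPM strictly > 1 in ≥ 3 samples) are
implemented with the stated strictness: the expression threshold is
inclusive, the CPM comparison strict, the FDR threshold inclusive (≤ 0.05).

## Enrichment and signature partition

Enrichment in a sorted population requires FDR ≤ 0.05 *and* a sorted-group
mean exceeding both unsorted backgrounds; means are arithmetic means of
per-replicate normalized expression (the natural reading when the DE engine
works on normalized abundances). The signature partition is plain set
algebra — common = EP ∩ TRE, specific = set differences — and satisfies
`|specific| + |common| = |enriched|` by construction. The DE statistic
itself (dispersion estimation, exact NB test) is deliberately an *input*:
any engine that emits per-gene FDRs and group means can feed this module.

## Cross-species overlap permutation test

Queries map to targets by best hit (lowest E-value at E ≤ 10⁻²⁰; ties go to
the higher bit score, then the lexicographically smaller target — BLAST
output does not define an order among exact ties). Overlap is counted in
*distinct target genes* by default, since several query genes routinely
collapse onto one target homolog; a `count="query"` mode exists.

The null draws `10⁴` query sets of the observed size uniformly **without
replacement** from the full query universe, maps each through the same
best-hit map, and computes the same statistic. `p = #{null ≥ observed} /
n_perm`; when no null draw reaches the observed value the result is the
bound `1/n_perm` with `p_is_bound` set — a frequency of zero is an
artifact of finite resampling, not evidence of p = 0. The engine is
vectorized (random-key argpartition for without-replacement sampling,
sorted-run counting for distinct targets) and processes permutations in
batches of 2000 to bound memory.

**Calibration.** On an injective fully-mapped universe the null is exactly
hypergeometric, which the tests exploit as a closed-form oracle. The plain
empirical p is discrete (overlap counts occupy ~a dozen atoms at the test's
scale), so a Kolmogorov–Smirnov uniformity check on it would reject for any
correct implementation. Calibration checks therefore use the standard
randomized p-value `p* = (n_gt + U·(n_eq + 1)) / (n_perm + 1)`, which is
exactly U(0,1) when the observed set is exchangeable with the null draws;
`OverlapResult` stores `n_gt` and `n_eq` for this purpose.

## Action spectrum and λ_max

Per wavelength, a baseline-subtracted peak response is extracted per trace
and the dose–response points (replicates pooled; an `average-first` mode
would carry identical least-squares information) are fitted with
`R(x) = B + (T−B)/(1 + 10^{h(logEC50 − x)})` on log₁₀ irradiance, `B` fixed
to the measured assay baseline. Starts are deterministic (T = max response,
h = 1, logEC50 = median dose). Non-convergence or a non-positive fitted
slope flags the wavelength; flagged wavelengths are excluded from the
spectrum with a warning rather than silently fitted.

Relative sensitivity is reciprocal EC50 normalized to the most sensitive
wavelength (`s = EC50_min/EC50`, maximum exactly 1). The Govardovskii
A1-pigment template (α-band with λ_max-dependent shape parameter plus the
0.26-amplitude Gaussian β-band; the β-band can be disabled) is evaluated
over a 400–550 nm grid at 1-nm steps and the sum of squared deviations from
the spectrum is minimized by exhaustive scan — deterministic, and the full
SS profile is returned for plotting. The raw template tops out ~0.1 % above
1 a fraction of a nanometre off λ_max; it is renormalized to its λ_max value
(and clipped at 1) so the peak is exactly 1 at λ_max and the returned values
stay in (0, 1]. Only the A1 (retinal) chromophore template is implemented;
marine invertebrate rhabdomeric pigments use A1.

**Recovery behavior.** Noise-free synthetic spectra generated from the
template recover λ_max exactly on the 1-nm grid at 440, 471 and 500 nm even
though the nine assay wavelengths (420–600 nm) do not contain the peak: the
residual rescaling from normalizing at the nearest assay wavelength is
second-order. With Gaussian noise of σ = 0.05 on the sensitivities the scan
stays within ±3 nm of truth in ~99 % of runs. With 5 %-of-top Gaussian
noise on the *raw responses*, propagated through the full
peak → EC50 → sensitivity → scan pipeline, the recovery-within-±3-nm rate
is ~80 % (λ_max error sd ≈ 2.8 nm): the per-wavelength logEC50 standard
error of ~0.05–0.1 decades is at the least-squares information limit for
3 replicates × 8 doses at that signal-to-noise ratio, and the error of the
reference (minimum-EC50) wavelength rescales every sensitivity coherently,
which the unweighted SS scan cannot distinguish from a λ_max shift. Both
rates are recomputed and reported by `scripts/acceptance.py`.

## Undulation behavior

Tracks carry seven named points; classification uses the five trunk points
(`body1`–`body5`). QC excludes an animal if *any* point is annotated in
less than 90 % of frames. Interior gaps are filled by per-coordinate linear
interpolation; leading/trailing gaps take the nearest observed value
(linear interpolation is undefined there).

Each non-overlapping 10-s window is scored per point and axis with a
mean-removed, untapered periodogram (`scipy.signal.periodogram`); the
dominant frequency comes from the axis with the larger peak power, with the
DC bin excluded from the search. *Total movement* is the larger
peak-to-peak coordinate range of the two axes — "total movement" is
ambiguous between range and path length, so range is the default and a
`movement_mode="pathlength"` alternative is provided. A window is
undulation when any trunk point satisfies both inclusive bands
(0.5–10 px, 0.5–1.5 Hz). The label is translation-invariant and symmetric
in the five points by construction.

Undulation ratios are fractions of undulating windows per 180-s bin,
aligned to recording start. Per-animal AUC integrates the piecewise-linear
ratio curve (values at bin midpoints, flat extension at the edges) over a
zeitgeber-hour interval by the trapezoidal rule, in ratio·hours — a
constant ratio of 1 over 8 h gives exactly 8. Group statistics follow the
standard recipe: Shapiro–Wilk per group, paired Wilcoxon signed-rank within
genotype across conditions, Mann–Whitney/Wilcoxon rank-sum between
genotypes, α = 0.05. All-zero paired differences are reported as p = 1
with a `degenerate` flag rather than an exception.

## Synthetic data: what it does and does not emulate

All generators are deterministic given a seed (identical bytes for
identical arguments) and return the generating truth.

- **Transcript clusters** are chains of members sharing planted exact
  overlaps, rejection-sampled so no 50-mer is shared across clusters —
  truth partitions are exact. Real assemblies add sequencing errors,
  repeats and chimeras; inexact overlaps are out of scope, so passing tests
  show correctness of the clustering *rule*, not robustness to
  polymorphism.
- **Count experiments** draw negative-binomial counts (dispersion 0.1, the
  usual bulk-RNA scale) for three groups × 3 replicates with planted
  enriched genes at a given fold change; per-gene base means are lognormal
  with a floor of 20 counts so planted mean comparisons are unambiguous at
  fold 20. FDRs are *synthetic* truth-consistent values (planted < 0.05)
  with a configurable flip rate — the DE test itself is intentionally not
  re-implemented, so these data exercise the set logic, not inference.
- **Homology universes** have configurable mapped fraction, injectivity and
  planted signature enrichment; mapped pairs get E-values below 10⁻²⁰ and
  decoy hits above the threshold exercise the gate. The injective
  fully-mapped case is the hypergeometric oracle; non-injective maps shift
  the distinct-target null downward, which is tested.
- **Dose–response tables** set `EC50(λ) = EC50_peak / template(λ, λ_max)`
  so sensitivity follows the template exactly, with 8 log-spaced doses
  *centered per wavelength on its own EC50* (±2 decades) and 3 replicates.
  Real assays use one absolute irradiance ladder for all wavelengths, which
  leaves red-shifted curves poorly anchored; per-wavelength centering
  isolates estimator behavior from dose-placement artifacts. Defaults:
  top 500, baseline 100, Hill 1, logEC50 at peak 13 (log₁₀ photons
  cm⁻² s⁻¹) — typical scales for luminescence-reporter opsin assays.
- **Tracks** oscillate the trunk points sinusoidally during scheduled bouts
  (amplitude is the sine amplitude, so peak-to-peak is twice that), with
  slow drift (0.02 px/s), sub-threshold jitter (0.05 px), and per-point
  missing rates; 5 fps and 30-min recordings keep test runtimes in seconds
  while leaving 0.1-Hz frequency resolution, ample for a 0.5–1.5 Hz band.
  Real worm kinematics (waveform propagation, tube interactions) are not
  modeled, so passing tests validate the window classifier, not pose
  estimation.

## Problem sizes

The verification runs use deliberately moderate sizes chosen to exercise
every code path at tight tolerances: 50-transcript clustering instances
against the all-pairs oracle, a 1000-gene homology universe with 10⁴
permutations (and 200 × 2000 permutations for null calibration), 100 seeded
spectral-recovery runs, and 2 × 16 tracked animals over 30 simulated
minutes for the group comparison.

## Known limitations

- Overlap detection is exact-match only; a single mismatch inside an
  overlap splits it.
- The λ_max scan assumes the action spectrum is template-shaped; screening
  pigments or multiple co-expressed opsins would bias it.
- The permutation test treats the homology map as fixed truth; uncertainty
  in the BLAST assignments is not propagated.
- The behavior classifier's frequency resolution is 1/window (0.1 Hz at
  10-s windows), so bout frequencies near the band edges can flip bins.
- Repository shape: the stages are exposed as module-level functions with
  results dataclasses (`DoseResponseFit`, `TemplateFit`, `OverlapResult`)
  rather than a single Model/Results object pair, because the pipeline is
  five heterogeneous stages of which only one is a fitted model.
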