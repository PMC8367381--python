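# platysense

Analysis toolkit for studies of rhabdomeric-opsin-expressing sensory cells —
cephalic eye photoreceptors (EP) and the segmentally repeated trunk
*r-opsin1*-expressing (TRE) cells of the marine annelid *Platynereis
dumerilii* — and for any dataset with the same shape: a de novo
transcriptome quantified per sorted cell population, cross-species gene-set
comparisons, a heterologous opsin bioassay, and long-term keypoint tracking
of locomotor behavior.

The package covers five analysis stages, each usable on its own:

- **`platysense.expression`** — transcripts shorter than 250 bp are dropped;
  transcripts sharing an exact sequence overlap of ≥ 50 bp (either strand)
  are grouped into clusters ("genes") by transitive closure; each cluster
  gets a nominal length `L_g` (longest member plus the non-overlapping parts
  of the rest), and expression is computed as
  `E[g,s] = C[g,s] / (L_g/10³) / (N_s/10⁶)` — counts per kilobase of nominal
  length per million counted reads. A gene counts as *expressed* at
  ≥ 12 of these units in at least one replicate.
- **`platysense.enrichment`** — genes with CPM > 1 in ≥ 3 samples enter
  differential testing (done by any external DE engine); genes with
  FDR ≤ 0.05 whose sorted-population mean exceeds both unsorted backgrounds
  are *enriched*; the two enriched sets are partitioned into
  population-specific and common signatures.
- **`platysense.homology`** — each query-species gene is assigned the target
  gene of its best BLAST hit at E ≤ 10⁻²⁰; whether a query gene set
  over-represents a target signature is tested against 10⁴ size-matched
  random query sets, reporting the empirical tail frequency
  `p = #{null overlap ≥ observed} / 10⁴` (a bound `p < 1/10⁴` when no null
  draw reaches the observed overlap).
- **`platysense.spectral`** — per-wavelength luminescence dose–response
  curves are fitted with a variable-slope four-parameter logistic (bottom
  fixed at the assay baseline) to obtain EC50 values; relative sensitivity
  `s(λ) = EC50_min / EC50(λ)` forms the action spectrum, and the
  Govardovskii A1 visual-pigment template is scanned over candidate λ_max
  (400–550 nm, 1-nm grid) for the least-squares optimum.
- **`platysense.behavior`** — keypoint tracks of seven body points are
  QC'd (every point ≥ 90 % annotated), gap-filled linearly, and scored in
  10-s windows: a window is *undulation* when any trunk point moves
  0.5–10 px peak-to-peak with a dominant periodogram frequency of
  0.5–1.5 Hz. Window labels become 3-min undulation ratios, per-animal
  trapezoidal AUC over a zeitgeber interval, and Shapiro–Wilk plus Wilcoxon
  signed-rank / rank-sum group comparisons.

`platysense.simulate` generates seed-deterministic synthetic inputs with
known ground truth for every stage (planted transcript clusters,
negative-binomial count experiments, homology universes, template-derived
dose–response tables, scheduled undulation bouts).

## Worked example

Recover an opsin's spectral peak from noisy synthetic dose–response data,
then test a gene set for signature enrichment:

```python
import numpy as np
from platysense import simulate, spectral, homology

doses, truth = simulate.gen_action_spectrum_data(471.0, noise_sd=10.0, seed=8)
fits, spectrum, template = spectral.analyze_action_spectrum(
    doses, baselines=truth["baseline"]
)
print("lambda_max:", template.lambda_max, "nm")
for wl, s in zip(spectrum.wavelengths, spectrum.relative_sensitivity):
    print(f"  {wl:.0f} nm  sensitivity {s:.3f}  logEC50 {fits[wl].log_ec50:.2f}")

scenario = simulate.gen_homology_universe(
    n_query=1000, signature_size=100, query_set_size=50,
    planted_enrichment=3.0, seed=4,
)
result = homology.permutation_overlap_test(
    scenario.universe, scenario.query_set, scenario.mapping,
    scenario.signature, n_perm=10_000, seed=5,
)
print("observed overlap:", result.observed)
print("null mean ± sd: %.2f ± %.2f" % (result.null_mean, result.null_sd))
print("empirical p:", result.p_value)
```

Output:

```
lambda_max: 471.0 nm
  420 nm  sensitivity 0.478  logEC50 13.29
  442 nm  sensitivity 0.790  logEC50 13.07
  458 nm  sensitivity 0.839  logEC50 13.05
  480 nm  sensitivity 1.000  logEC50 12.97
  500 nm  sensitivity 0.689  logEC50 13.13
  520 nm  sensitivity 0.367  logEC50 13.41
  540 nm  sensitivity 0.135  logEC50 13.84
  568 nm  sensitivity 0.016  logEC50 14.77
  600 nm  sensitivity 0.001  logEC50 16.01
observed overlap: 15
null mean ± sd: 5.00 ± 2.06
empirical p: 0.0001
```

The fitted λ_max of 471 nm is the template peak the data were generated
from: the action spectrum peaks at 480 nm (the assay wavelength closest to
471 nm) and falls off to 0.1 % sensitivity at 600 nm, a three-decade EC50
shift. The overlap test finds 15 of the 50 query genes' homologs in the
100-gene signature, versus 5.0 ± 2.1 expected for random size-matched sets;
no null draw reached 15, so the tail frequency is reported as the bound
p < 10⁻⁴.

A `platysense` console command exposes the same stages
(`quantify`, `enrich`, `overlap`, `spectrum`, `undulate`, `simulate`);
see `platysense --help`.

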