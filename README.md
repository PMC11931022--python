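# wmfcs — white-matter functional connectivity strength

`wmfcs` is a tested, reusable pipeline for studying the *function* of brain
white matter (WM) with resting-state fMRI, built around the two region-wise
statistics used to characterise radiation-induced WM dysfunction in
nasopharyngeal-carcinoma patients observed before and after radiation
therapy: connectivity strength within white matter and between gray matter
(GM) and white matter.

It is aimed at neuroimaging researchers who have regional BOLD time series
(or 4D volumes plus a combined GM/WM parcellation) and want the full chain —
motion quality control, frame-level cleaning, connectivity strength, group
inference with FDR control, and dose–response partial correlations — with
every step unit-tested against independent oracles.  Because no patient data
are distributable, the package ships a first-class synthetic-cohort
generator that reproduces the study conditions (two groups of 47 and 64
subjects, 164 regions, 240 frames at TR 2.4 s, effects and dose correlations
matched to the published group summaries), so the whole pipeline is testable
end to end.

## The statistics

From cleaned region time series, the pipeline computes the Fisher-z
transformed Pearson correlation between every pair of regions,
`z_ij = atanh(corr(x_i, x_j))`, giving a 164 × 164 symmetric matrix over
114 GM regions (100 cortical + 14 subcortical) and 50 WM regions.  Two
degree-like summaries follow:

* **WW-FCS** — for WM region *i*: `mean_{j ∈ WM, j ≠ i} z_ij`, its average
  connectivity with the other 49 WM regions;
* **GW-FCS** — for GM region *g*: `mean_{j ∈ WM} z_gj`, its average
  connectivity with all 50 WM regions.

Group differences are assessed per region by ordinary least squares of FCS
on `[intercept, group, age, sex, mean FD]` with Benjamini–Hochberg FDR
control applied per family (m = 50 for WW, m = 114 for GW), and
dose–response is assessed by partial correlation between FCS and the maximum
radiation dose to the brainstem / left temporal lobe given the same
covariates (df = n − 2 − g).

Upstream of the statistics the pipeline implements the standard cleaning
chain: drop the first 5 volumes; Power's framewise displacement
`FD(t) = Σ|Δtrans| + 50 mm · Σ|Δrot|`; censor frames with FD > 0.5 mm by
linear interpolation; regress the Friston 24-parameter motion model, linear
and quadratic trends, and the sub-0.01 Hz discrete-cosine set in one joint
projection; and subject-level exclusion by Euler-number modified Z-score
(< −3.5), mean FD (> 0.5 mm) or motion-outlier ratio (> 0.3).

## Worked example

Summary-level statistics from published group summaries (mean (SD) WW-FCS of
the left superior cerebellar peduncle, 0.25 (0.11) in 47 pre-RT vs
0.19 (0.10) in 64 post-RT subjects):

```python
>>> from wmfcs.inference import pooled_t_from_summary, posthoc_power_two_sample, fdr_bh
>>> res = pooled_t_from_summary(0.25, 0.11, 47, 0.19, 0.10, 64)
>>> print(f"t = {res.t:.2f}, df = {res.df}, p = {res.p:.4f}")
t = -2.99, df = 109, p = 0.0034
>>> pw = posthoc_power_two_sample(0.25, 0.11, 47, 0.19, 0.10, 64)
>>> print(f"d = {pw.effect_size:.3f}, power = {pw.power:.3f}")
d = 0.575, power = 0.843
>>> fdr_bh([0.0035, 0.0018, 0.00039, 0.0012, 0.0033], m=50).round(4)
array([0.035 , 0.03  , 0.0195, 0.03  , 0.035 ])
```

The group difference is t = −2.99 (p = 0.0034), a pooled-SD effect size of
0.575 with 84% post hoc power at α = 0.05; the smallest raw p in the
WW family adjusts to q = 0.0195 under BH with family size 50.

A full synthetic run — simulate, QC, clean, FCS, statistics, report:

```bash
wmfcs run --out demo_run --seed 7
```

completes in a few seconds and writes `participants.tsv`, `qc_report.tsv`,
`fcs.tsv`, `table2.tsv`, `demographics.tsv`, `dose_assoc.tsv`, `power.tsv`,
a markdown `report.md` and a `manifest.json` with SHA-256 hashes of every
output (reruns with the same seed are bit-identical).  With seed 7 the
report's WW table begins:

```
| region                          | pre mean (SD) | post mean (SD) | t     | p       | p-FDR   |
| lh_Superior_cerebellar_peduncle | 0.40 (0.11)   | 0.30 (0.12)    | -4.38 | 2.8e-05 | 0.00046 |
```

i.e. the configured 0.06–0.08 Fisher-z reductions in the five WM and six GM
target regions are detected after FDR correction (this seed's cohort drew a
larger-than-average group difference; across replicate cohorts the detection
rate matches the noncentral-t power).  Subcommands `simulate`, `qc`,
`preprocess`, `extract`, `fcs`, `stats` and `report` expose each stage over
TSV/NIfTI files; see `wmfcs --help`.

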