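# nvcoupling

Neurovascular coupling (NVC) analysis for resting-state fMRI + arterial
spin labelling cohorts, with a fully synthetic cohort generator so that the
whole pipeline is testable end to end without any patient data.

**Who this is for.** Neuroimaging researchers studying the interplay between
cerebral perfusion and neural activity — e.g. in amyotrophic lateral
sclerosis (ALS), where reduced coupling in the default mode network (DMN) has
been proposed as a marker of disease progression — and methodologists who
want a reproducible, oracle-tested reference implementation of the NVC
statistic and its surrounding cohort statistics.

## The statistic

For a subject with a z-scored CBF map and a z-scored neural-activity
surrogate map (ALFF, ReHo or DC), the NVC of a brain region or network *U*
is the spatial Pearson correlation across its voxels,

```
R_U = corr( CBF(v), F(v) ;  v ∈ U ),        z_U = atanh(R_U)
```

with networks pooling all of their regions' voxels (never averaging
per-region R values). Subjects × units matrices of Fisher-z values feed the
statistical layer:

- **group-effect scan** — per column, OLS `NVC ~ group + age + sex` with a
  partial F test for group and Benjamini–Hochberg FDR within the matrix;
- **progression stratification** — 1-D k-means (k = 3) on the 12-month
  ALSFRS-R change, labelling very fast / fast / slow progressors (VFP/FP/SP);
- **cognition correlations** — Pearson r of an NVC column against ECAS
  subscores, FDR across the score family;
- **ROC discrimination** — Mann–Whitney AUC with stratified-bootstrap (or
  DeLong) confidence intervals;
- **summary-table utilities** — pooled means and one-way ANOVA F statistics
  reconstructed exactly from printed (n, mean, SD) cells.

Upstream, the package computes the maps themselves: band-pass filtering
(0.01–0.1 Hz), Gaussian smoothing, Friston-24 + WM/CSF nuisance regression,
ALFF / ReHo (Kendall's W) / degree centrality, and single-PLD PCASL CBF
quantification via the standard single-compartment calibration formula.

## Worked example

Summary-statistics utilities on printed subgroup cells (respiratory
ALSFRS-R at 12 months; 27 slow, 13 fast, 8 very fast progressors):

```python
>>> from nvcoupling import SummaryGroup, anova_from_summary, pooled_mean
>>> cells = [SummaryGroup(27, 11.00, 1.44), SummaryGroup(13, 9.31, 2.84),
...          SummaryGroup(8, 0.00, 0.00)]
>>> round(pooled_mean(cells), 2)
8.71
>>> f, df1, df2, p = anova_from_summary(cells)
>>> print(f"F({df1},{df2}) = {f:.2f}, p = {p:.2e}")
F(2,45) = 112.45, p = 3.13e-18
```

Progression stratification on well-separated ΔALSFRS-R values:

```python
>>> import numpy as np
>>> from nvcoupling import cluster_progression
>>> delta = np.array([-41, -40, -42, -14, -13, -15, -4, -5, -3], float)
>>> cluster_progression(delta, seed=0).as_frame()
cluster  centroid  n  monthly_rate
    VFP     -41.0  3     -3.416667
     FP     -14.0  3     -1.166667
     SP      -4.0  3     -0.333333
```

A full synthetic-cohort run from the shell (48 patients + 32 controls,
100-region atlas; smoothing disabled because the planted coupling pattern
lives at voxel resolution):

```bash
nvcoupling all --seed 7 --fwhm-mm 0 --cohort-root cohort --output-root derivatives
cat derivatives/stats/report.md
```

which on this seed prints (about a minute on one CPU):

```
## Progression stratification (k-means on ΔALSFRS-R)
- VFP: centroid -40.25, n=8, -3.35 points/month
- FP: centroid -14.00, n=13, -1.17 points/month
- SP: centroid -3.89, n=27, -0.32 points/month
## Group-effect scans (FDR within each matrix)
- ALFF_network: significant units: none
...
```

The generator plants a one-SD DMN coupling reduction in patients; at this
seed the scan saw it (DMN F = 6.03, p = 0.016 in `stats.json`) but the
network-family FDR correction left it short of the 5% threshold — a useful
reminder that a ~90%-power effect is missed in roughly one run in ten.
Per-stage outputs (feature z-maps, CBF maps, NVC matrices as TSV, the
resolved configuration and a caching manifest) land under `derivatives/`.

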