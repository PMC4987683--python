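# ebclock

Developmental-clock analysis of embryoid-body (EB) differentiation from
live Brachyury-GFP reporter imaging and single-EB qPCR profiling.

Embryoid bodies — aggregates of ~500 mouse embryonic stem cells —
spontaneously form mesendoderm, marked by a transient pulse of the
Brachyury (Bry-GFP) reporter. Onset timing varies by many hours between
co-seeded EBs, but once expression begins its progression is stereotyped.
That makes the onset time itself a per-EB clock: snapshot expression
measurements taken at harvest can be re-ordered by *developmental age*
(DevA = harvest time − Bry-GFP onset) instead of wall-clock time,
revealing temporal trends that harvest time alone scrambles.

`ebclock` implements the full analysis as a tested Python library, plus a
synthetic-data generator that emulates the study conditions (onset
83.3 ± 3.7 h after seeding, onset-to-peak 12.8 ± 2.2 h, EB radii
113 ± 19 µm, CHIR/Bmp4 perturbation presets) so every stage can be
validated by latent-truth recovery.

## The model

Each EB's filtered GFP point count over time is fitted with a
five-parameter impulse curve, the product of a rising and a falling
logistic

```
N(t) = A · L(β₁(t − t₁)) · L(−β₂(t − t₂)),    L(x) = 1 / (1 + e⁻ˣ)
```

where `A` is the peak point count, `β₁`/`β₂` the normalized progression
and recession rates (h⁻¹), and `t₁`/`t₂` approximately the half-peak times
of onset and decline. Onset is the rising-flank crossing of a 300-point
threshold on the fitted curve; timing statistics are robust to thresholds
in 300–600. qPCR CT matrices are normalized with the two most stable
housekeeping genes (geNorm and NormFinder must agree on the pair) into
−ΔΔCT, and genes correlated with Wnt3 are classified into dependency
modes by how CHIR — which activates canonical Wnt signaling while
down-regulating Wnt3 itself — moves them relative to the control
gene-vs-Wnt3 trend.

## Modules

| module | what it does |
|---|---|
| `ebclock.synthgen` | synthetic cohorts: impulse count curves, spherical-shell GFP point clouds with clutter, CT panels, perturbation presets, truth records |
| `ebclock.pointcloud` | close-neighbor and bounding-box filters, point counting, minimal-enclosing-circle radius, volume occupancy |
| `ebclock.kinetics` | impulse model evaluation and least-squares fitting, onset/peak detection, DevA, cohort timing statistics |
| `ebclock.qpcrnorm` | geNorm/NormFinder stability, −ΔΔCT normalization, nearest-neighbor imputation, correlation clustering, fold ranges |
| `ebclock.clocktrends` | DevA sorting, percent variance explained (DevA vs harvest), local linear kernel smoothing, threshold robustness |
| `ebclock.perturbmodes` | group expression shifts, PCA of perturbation groups, Wnt3-dependency mode classification |
| `ebclock.io`, `ebclock.pipeline` | CSV/JSON/YAML interchange; clouds → counts → clocks plumbing |

## Worked example

```python
from ebclock.kinetics import cohort_timing_stats
from ebclock.pipeline import clocks_from_series
from ebclock.synthgen import CohortConfig, gen_cohort

cohort = gen_cohort(CohortConfig(n_ebs=25, seed=7))
clocks = clocks_from_series(cohort.series, threshold=300.0)
stats = cohort_timing_stats(clocks)
print(f"onset {stats['onset_mean']:.1f} ± {stats['onset_sd']:.1f} h, "
      f"onset-to-peak {stats['onset_to_peak_mean']:.1f} h")
```

prints

```
onset 82.5 ± 3.7 h, onset-to-peak 12.6 h
```

— the pipeline recovers the simulated cohort's latent onset distribution
(83.3 ± 3.7 h) and onset-to-peak interval (12.8 h) from noisy count
curves; the median per-EB onset error is ~0.05 h at these noise levels.
The `examples/` directory holds one short script per capability
(simulation, filtering, fitting, normalization, clock trends, dependency
modes), each printing the numbers it computes and what they mean.

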