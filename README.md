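# sgbold

Savitzky-Golay filtering for single-subject fMRI test-retest reliability and
detectable connectivity.

## The problem

Group-level fMRI reproducibility can look respectable (ICC ≈ 0.7) while the
time course of a single subject barely correlates with its own retest
(r ≈ 0.25). That ceiling matters clinically: by attenuation theory the
correlation observable between two measured node time courses can never exceed

    r_AB ≤ √(ρ_A · ρ_B)

where ρ_A and ρ_B are the test-retest reliabilities of the node time courses.
With ρ = 0.25 at both ends, no path can show more than r = 0.25 of
*detectable* connectivity, whatever the true coupling is.

`sgbold` implements a post-processing framework that attacks this ceiling with
data-driven Savitzky-Golay (SG) filters around a standard GLM denoising core:

1. **Denoise** — regress out 12 nuisance principal components (5 white-matter,
   5 ventricle, 2 head-motion) per run.
2. **Detrend** — add a slow-trend regressor to the same GLM: the SG smooth of
   the series itself (e.g. SG window 311 / degree 40, or 69/6), or a classical
   128-s discrete-cosine basis for comparison.
3. **Clean** — low-pass the residual with a second SG filter (e.g. 15/8), or
   with the classical Gaussian/HRF kernels for comparison.

SG parameters are chosen by brute force: for every (window, degree) cell the
filtered *observed* series from one run is correlated against an empirical
*predictor* built from the other run (the event-related average tiled once per
event), in both directions, so the choice is never self-referential. Cleaning
candidates are additionally masked by how far they push the lag 1–4
autocorrelations away from the predictor's (RMSE < 0.1), because a low-pass
filter can fake reliability by simply making everything autocorrelated.

The metric suite quantifies the payoff per subject and per node/path:
Pearson test-retest reliability, connectivity, the attenuation upper bound,
detectable connectivity (observed correlation capped at the bound, zeroed on
"corrupt" paths whose node reliability is non-positive), group ICC(2,1), FFT
band-power audits of what each cleaning filter removed, and a Pareto-style
clinical feasibility screen (e.g. ≥ 7 of 34 nodes above a reliability cutoff).

Because no public dataset accompanies the method, the package ships a
first-class synthetic generator (`sgbold.synth`) that reproduces the study
conditions — 34 nodes × 487 TRs at TR = 1.24 s, 24 task events near 0.04 Hz
with within-trial structure in 0.04–0.25 Hz, subject-specific HRF shapes,
sub-0.04 Hz drifts, AR(1) noise and nuisance leakage — with exact stored
ground truth.

## Worked example

```python
from sgbold import SimConfig, simulate_dataset, summary_table
from sgbold.glm import PRESETS

ds = simulate_dataset(SimConfig(n_subjects=10, n_nodes=10, seed=11))
for name in ("denoise", "detrend_sg69_6", "clean_sg15_8"):
    s = summary_table(ds, PRESETS[name]).summary()
    print(f"{name:15s} reliability {s['grand_mean_reliability']:.2f}  "
          f"connectivity {s['grand_mean_connectivity']:.2f}  "
          f"detectable {s['grand_mean_detectable']:.2f}  "
          f"corrupt {s['pct_corrupt_paths']:.0f}%")
```

prints

```
denoise         reliability 0.24  connectivity 0.25  detectable 0.22  corrupt 0%
detrend_sg69_6  reliability 0.35  connectivity 0.35  detectable 0.32  corrupt 2%
clean_sg15_8    reliability 0.43  connectivity 0.43  detectable 0.40  corrupt 2%
```

Reading: denoising alone leaves grand-mean single-subject reliability at 0.24;
adding SG(69/6) detrending inside the GLM lifts it to 0.35 by removing drift
below 0.04 Hz that the nuisance regressors miss; SG(15/8) cleaning of the
residual reaches 0.43. Detectable connectivity — the part of the observed
connectivity that the reliability ceiling can support — rises accordingly,
from 0.22 to 0.40.

The same workflow is available from the shell:

```bash
sgbold simulate --seed 11 --out data/
sgbold find-filter --data data/ --phase detrend --out detrend_grid.tsv
sgbold find-filter --data data/ --phase clean --detrend-window 69 --detrend-degree 6 --out clean_grid.tsv
sgbold test-filter --data data/ --pipeline clean_sg15_8 --out report
sgbold montecarlo --out mc.tsv
sgbold spectra --data data/ --pipeline clean_sg15_8 --out spectra.tsv
```

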