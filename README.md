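# megconn

Multi-frequency MEG effective-connectivity analysis: band-limited
virtual-sensor reconstruction, correlation connectivity with t-value
thresholding, Granger-causal edge direction, graph-theoretic network
summaries, and a group/clinical statistics layer — plus a synthetic-data
generator that plants known directed couplings and group differences so
every stage can be validated against exact ground truth.

## Who this is for

Researchers analyzing task-MEG (or EEG) recordings of two subject groups —
the motivating design is migraine patients vs healthy controls viewing
emotional facial expressions — who want a directed, signed, thresholded
source-space connectivity graph per subject and frequency band, and a
reproducible group-comparison layer on top of it.  Because subject-level
MEG data for such studies are rarely shareable, the package treats its
cohort simulator as a first-class module: every estimator in the pipeline
is exercised against planted ground truth.

## The analysis in brief

Per subject and band (delta 1–4, theta 4–8, alpha 8–12, beta 13–30, gamma
30–90 Hz):

1. remove DC, 50 Hz notch, zero-phase band-pass; epoch around the stimulus
   trigger and average the 90–180 ms window;
2. project to source space with a unit-gain LCMV beamformer (baseline-
   covariance and null-constrained variants for connectivity work); merge
   voxels closer than 10 mm;
3. correlate every source pair on the averaged evoked window,
   `R = C(X_a,X_b)/(S_a S_b)`, and threshold by the t value
   `Tp = R·sqrt((K−2)/(1−R²))` at p < 0.01;
4. assign direction to retained edges by conditional (multivariate) Granger
   causality on single-trial data (F-test at 0.05; one significant
   direction → directed, both → bidirectional); sign edges by the
   correlation (excitatory/inhibitory) and label nodes driver/driven;
5. summarize the graph by degree D, strength S, path length L, clustering C.

At the group level: Fisher's exact test on the prevalence of the directed
PFC→TL pattern, pooled-variance t-tests on the metrics with Bonferroni
(0.05/5 = 0.01 and 0.05/20 = 0.0025) and Benjamini–Hochberg FDR reported
side by side, and Spearman correlations of clinical covariates (headache
history, attack frequency, duration, VAS, HAM-A, HAM-D) with the metrics
within the patient group.

See `docs/methods.md` for the estimation choices (why GC runs on
evoked-subtracted single trials without zero-phase band-passing, why the
correlation window is decimated to the band's effective sample count, and
why the beamformer uses baseline covariance with null constraints).

## Worked example

Simulate one full cohort under the study conditions (24 patients with the
directed prefrontal→temporal coupling planted at prevalence 19/24 vs 24
controls at 8/24, clinical HAM-D copula-linked to network strength at
Spearman −0.5) and run the whole pipeline:

```python
from megconn.study import run_replicate

result, rho = run_replicate(seed=123)
print(f"prevalence table {result.prevalence_table.tolist()}")
print(f"Fisher p = {result.fisher_p:.4f}")
print(f"recovered HAM-D ~ strength Spearman rho = {rho:.3f}")
```

prints

```
prevalence table [[17, 7], [3, 21]]
Fisher p = 0.0001
recovered HAM-D ~ strength Spearman rho = -0.261
```

Reading: 17 of 24 patients and 3 of 24 controls show at least one directed
PFC→TL edge in the gamma band (this seed happened to draw only 3
pattern-positive controls — all 3 were found); the prevalence difference is
significant by Fisher's exact test; and the planted negative clinical
correlation comes back with the correct sign.  Per-subject edge lists and
metric tables are available through the staged runner:

```bash
megconn run-all --seed 7 --out out/
# -> out/recordings/  out/analysis/{metrics,edges}.csv  out/stats/report.json
```

The same stages are exposed individually (`megconn simulate`,
`megconn connect`, `megconn stats`) and everything is deterministic given
the seed — re-running with an unchanged config reuses cached stages,
fresh runs are byte-identical.

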