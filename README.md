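# ecgrt — resting-ECG ischemia scoring with EMD and the RT intensity index

`ecgrt` implements an energy-decomposition analysis of short resting ECG
recordings aimed at the early detection of myocardial ischemia.  A stable
10-second single-lead window is decomposed by **empirical mode
decomposition (EMD)** into intrinsic mode functions C1–C8, ordered from the
fastest oscillation to the slowest: C1–C2 carry the high-frequency QRS
content, the middle components the P/T-wave superpositions, and the slowest
ones the beat rhythm.  Each window is then scored with the **RT intensity
index**

```
RT = (α·E₁ + β·E₂ + γ·E₃) / Σᵢ₌₁⁸ Eᵢ ,      Eᵢ = Σₜ Cᵢ(t)²
```

with weights constrained by α ≥ β ≥ γ > 0 and α + β + γ < 1 (defaults
0.5, 0.3, 0.15), so 0 ≤ RT ≤ α.  The index is the weighted fraction of
total component energy carried by the three fastest components; it rises
when high-frequency QRS energy is elevated, as reported in patients with
coronary stenoses, and is invariant to overall amplitude scaling.

The package is for signal-processing and biostatistics researchers who
want a tested, reproducible version of this pipeline: a from-scratch EMD
(cubic-spline envelopes, mirror boundaries, Cauchy + IMF-count sifting
criterion), the scoring layer, and the cohort statistics (group summary
rows, pairwise-vs-reference Welch *t*-tests with Bonferroni correction
under three grouping models, negative threshold, ROC/AUC).  Because the
original patient recordings are not public, a first-class synthetic cohort
generator produces labeled single-lead records (PQRST morphology at
250 Hz, baseline wander, powerline and EMG noise) with a tunable
`ischemia_factor` that injects band-limited high-frequency energy into the
QRS support.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort with the published arm sizes 47 / 4 / 14 / 8:

```
python analysis/01_simulate_cohort.py   # 73 labeled records, manifest
python analysis/02_score_cohort.py      # preprocess -> EMD -> RT per subject
python analysis/03_cohort_stats.py      # models 1-3, threshold, ROC
python analysis/04_table_checks.py      # published-table arithmetic checks
```

Step 02 prints the per-group index (seed 1):

```
  negative  n=47  RT  6.45% +/- 1.89%
  normal    n= 4  RT 11.93% +/- 2.99%
  lt50      n=14  RT 13.85% +/- 2.48%
  ge50      n= 8  RT 16.55% +/- 3.24%
```

— the index increases monotonically with the simulated stenosis severity.
Step 03 then reports, among others:

```
Model 1: positive (14.38%) vs negative (6.45%):  t=11.77, p_adj=9.2e-14
Model 3: normal vs negative   p_adj=0.098 (ns)
         lt50   vs negative   p_adj=2e-08
         ge50   vs negative   p_adj=9.1e-05
negative threshold 7.01%  (flags 26/26 positives);  AUC 0.979
```

Model 3 reproduces the clinical pattern that the small normal-imaging arm
does not separate from the negative reference while both stenosis arms do.
Step 04 re-derives the published cohort tables' internal arithmetic from
their printed (n, mean, SD) inputs — e.g. SE 4.34/√47 = 0.63, the 95% CI
upper bound 23.57, the count-weighted positive mean 27.96 — and tabulates
recomputed vs printed values (all agree within ±0.01).

The same pipeline is available as a CLI:

```
ecgrt run --config configs/demo.yaml --out demo_run
ecgrt synth --out cohort_dir --seed 1      # records + manifest only
```

## Layout

```
src/ecgrt/        library: synthetic, preprocess, emd, hht, rt, stats,
                  io, pipeline, cli
analysis/         numbered narrative drivers (see worked example)
tests/            pytest suite incl. end-to-end acceptance checks
scripts/          acceptance.py
docs/methods.md   model, parameter and design notes
```
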