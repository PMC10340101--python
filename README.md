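# stripsurvey

Density estimation and survey-efficiency analysis for strip-based
surveys of benthic organisms — built around the three protocols used in
underwater visual surveys of zebra mussels (*Dreissena polymorpha*):

* **quadrat surveys** — counts in small fixed-area frames, detection
  assumed perfect;
* **double-observer removal surveys** — a trailing observer re-searches
  a narrow strip for clusters missed by the lead observer, identifying
  a constant per-observer detection probability *p*;
* **distance-removal surveys** — a wider strip with perpendicular
  distances recorded; per-observer detection follows a half-normal
  curve `g(y) = p0 · exp(−y²/2σ²)` that may be imperfect on the line
  (`p0 ≤ 1`), with the two-observer removal configuration identifying
  `p0`.

It is aimed at invasive-species monitoring programs choosing between
designs: it answers "what density, with what uncertainty, and how many
transects would I need for a target precision?"

## The estimator

For strip designs, with `n` detected clusters (druses) over `T`
transects of total length `L` and half-width `w`, mean cluster size
`Ê(s)`, and average detection probability `P̂`,

    D̂ = n · Ê(s) / (2w · P̂ · L)        [individuals / m²]

with the first-order (delta-method) variance decomposition

    Var(D̂) ≈ D̂² ( Var(n)/n² + Var(Ê(s))/Ê(s)² + Var(P̂)/P̂² )

where `Var(n)` is the design-based, length-weighted encounter-rate
variance over transects,

    Var(n) = L/(T−1) · Σᵢ lᵢ (nᵢ/lᵢ − n/L)².

Quadrat surveys use the explicit sampled area with `P̂ = 1`.  Detection
models are fitted by maximum likelihood conditional on detection by at
least one observer (full independence), with `P̂` and its standard
error from the observed information; a binned chi-squared test checks
the fit of the half-normal curve.  The effort module solves
`cv_target = CV(D̂) · T_completed / T_estimated` (with a conventional
`1/√T` variant for comparison).

A first-class synthetic-data generator (`stripsurvey.simulator`)
realises clustered druse populations — a Thomas process whose parents
represent patches of hard substrate, with zero-truncated Poisson or
negative-binomial cluster sizes — and executes all three protocols on
the same virtual lake, enabling bias, coverage and design-efficiency
experiments without field data.  Three presets (`florida_like`,
`burgan_like`, `little_birch_like`) span low-density pioneer to
high-density, strongly clustered populations.

## Worked example

Simulate a medium-density lake and estimate density under each design:

```sh
cat > scenario.yaml <<EOF
preset: burgan_like
seed: 7
EOF
stripsurvey simulate --config scenario.yaml --out data --seed 7
stripsurvey estimate --design distance --transects data/transects.csv \
    --detections data/detections.csv --out out_dist
```

which prints (true density of this scenario: 0.291 /m²):

```
simulated 1349 druses (1621 individuals); wrote data/
[read] 15 distance transects
[read] 80 detection events
[fit] distance_removal_hn: P_hat=0.5457 (se 0.0408)
[estimate] D_hat=0.302372 /m^2, cv=0.2158; wrote out_dist/results.csv
```

i.e. the half-normal removal fit estimates that a cluster in the 2-m
strip is found by at least one observer with probability 0.55, and the
corrected density 0.302 /m² (CV 21.6%) brackets the truth.  After
running `estimate` for the other two designs, compare efficiencies:

```
$ stripsurvey compare --results out_quad --results out_rem --results out_dist
   source   design    D_hat       cv  T_completed  prop_var_count  prop_var_cluster_size  prop_var_detection  T_linear_rule  T_sqrt_rule
 out_quad  quadrat 0.360000 0.437781           15        1.000000               0.000000            0.000000            66          287
  out_rem  removal 0.268085 0.223981           15        0.950568               0.048828            0.000605            34           75
 out_dist distance 0.302372 0.215767           15        0.839051               0.041030            0.119919            32           70
```

All three designs recover the truth within uncertainty; at this
density the quadrat survey is the least precise per transect
(`T_linear_rule` = transects needed for CV 0.1 under the linear rule),
and most of the variance comes from between-transect counts rather
than detection.  `stripsurvey recover --config scenario.yaml --reps 300
--seed 1 --out rec/` runs the full replicated bias/coverage experiment.

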