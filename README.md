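# regtex

Tools for studying **texture-regularity perception**: how the spacing,
size and positional jitter of texture elements jointly determine how
regular a pattern looks, and which image-computable statistic the visual
system could be reading out.

The package is aimed at visual psychophysicists and computational
neuroscientists. It covers the full arc of a conjoint-measurement study of
regularity:

1. **Stimuli** — lattices of zero-balanced difference-of-Gaussians (DoG)
   micropatterns on 9×9 / 7×7 / 6×6 notional grids (element spacing levels),
   with three element sizes and five uniform positional-jitter ranges,
   rendered inside a 2.91° circular aperture. Overlapping elements are
   redrawn within the same jitter range until the layout is overlap-free.
2. **Conjoint data** — the exhaustive paired-comparison design
   (45 conditions → (44·45)/2 + 45 = 1035 pairs), a reader/writer for the
   7-column per-trial response CSV format, and conjoint-proportions
   matrices.
3. **Three-factor MLCM** — maximum-likelihood conjoint measurement with a
   probit decision rule. The choice between two textures follows
   Δ = R_ijk − R_pqr + ε, ε ~ N(0, 1), P(choose first) = Φ(Δ). Twelve
   nested specifications of R_ijk (baseline; one-factor; two-additive-
   factor; two-interactive-factor; all-two-way; full three-way) are fitted
   by IRLS and compared with likelihood-ratio tests, splitting the
   explained deviance into main effects, two-way and three-way
   interactions.
4. **Wavelet encoding models** — log-Gabor filter-bank energies (50
   log-spaced SFs × 12 orientations), mean-normalized to equate totals
   across orientations or SFs, summarised by distribution statistics
   (kurtosis, skew, FWHM, peakedness, SD) of the SF or orientation
   marginals and by their spread across channels. The headline statistic is
   the SD across orientations of the per-orientation SF-distribution skew
   (`sf_x_ori_skew_std`).
5. **Evaluation** — Pearson correlations of each statistic with the
   measured regularity scale and forward stepwise regression (partial-F
   entry at α = 0.05), plus an end-to-end pipeline driver.

A simulated-observer generator (normal internal value per condition, the
larger draw wins) lets every stage run, and be tested, without any
experimental data.

## Worked example

`examples/mlcm_battery.py` simulates one observer (4 repetitions of all
1035 pairs) and runs the model battery:

```
                            deviance  df  p_adjusted  significant
effect
main_spacing                 239.535   2       0.000         True
main_size                     92.850   2       0.000         True
main_jitter                 2127.028   4       0.000         True
interaction_spacing_jitter   129.998   8       0.000         True
interaction_size_jitter       39.328   8       0.000         True
interaction_spacing_size       3.641   4       1.000        False
threeway                      21.898  16       0.147        False
```

Each deviance is the likelihood-ratio improvement of the richer model in
one of the seven battery tests; jitter dominates, both jitter interactions
are present, and spacing × size and the three-way interaction are absent —
the structure built into the simulated observer. The one-factor estimates,
normalized so that the jitter level-5 drop equals −1, put the spacing and
size effects at a few percent of the jitter range (`sp3 ≈ +0.21`,
`sz2 ≈ −0.09` for this observer), and the spacing × jitter profile shows
the jitter effect to be ~1.8× stronger at the smallest spacing.

`examples/full_pipeline.py` closes the loop: observers whose internal
scale follows the stimuli's actual skew spread are traced back to that
statistic —

```
per-model mean correlation with the group regularity scale:
ori         0.397
ori_x_sf   -0.380
sf          0.090
sf_x_ori    0.958

stepwise selection from the 10 SF / SF x orientation parameters: ['sf_x_ori_skew_std']
R^2 = 0.985 (adjusted 0.985)
```

The other examples (`generate_stimuli.py`, `conjoint_proportions.py`,
`wavelet_models.py`) demonstrate layout statistics, the proportions heat
map and the filter-bank analysis one piece at a time.

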