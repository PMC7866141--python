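# thermoplace

Analysis toolkit for the **two-plate thermal place preference assay** in
mice — the behavioral test in which a freely moving animal chooses between
two adjacent plates held at different temperatures, and the share of time
spent on each plate indexes its thermal sensitivity. The assay is used to
detect cold hypersensitivity in chemotherapy-induced peripheral neuropathy
(a single oxaliplatin dose induces the model) and to screen analgesics:
after a drug, the **loss** of a previously significant plate preference, or
its **reversal** toward the physiologically less comfortable plate, is read
as an analgesic effect.

The package is aimed at behavioral-pharmacology labs running (or
simulating) this assay. It provides:

- **`thermoplace.track`** — a frame-differencing video tracker. For each
  pair of consecutive frames it resizes, grayscales and median-filters the
  images, takes the absolute difference, binarizes it at a fixed threshold,
  median-filters the mask, and counts white pixels left and right of the
  arena midline; the richer side is where the mouse moved. Iterations
  without sufficient motion (a stationary animal is invisible to frame
  differencing) are resolved by carrying the last determined side forward.
- **`thermoplace.protocol`** — the experimental vocabulary: plate pairs,
  the standard nine-session schedule walking 0–45 °C in contiguous 5 °C
  pairs (5 min per session, animal placed on the colder plate), and the
  three timepoints *before-oxaliplatin* / *pre-drug* / *post-drug*.
- **`thermoplace.simulate`** — a stochastic thermotaxis agent (Poisson
  side-crossing attempts, sigmoidal side choice on the comfort difference,
  within-plate jitter, immobility episodes), a grayscale video renderer
  with sensor noise and illumination drift, and a cohort generator with
  per-subject parameter jitter. It supplies ground truth for every
  downstream stage.
- **`thermoplace.stats`** — per-session repeated-measures ANOVA across
  timepoints, paired plate-vs-plate contrasts and Tukey-adjusted
  cross-timepoint contrasts on `pct_colder`, significance stars, and the
  maintained / lost / reversed analgesia classification.
- a CLI: `thermoplace simulate | track | analyze | report`.

## The model in brief

Let $p_c \in [0,100]$ be the percentage of session time a mouse spends on
the colder plate; the warmer plate's share is $100 - p_c$. Within a
timepoint, the plate-vs-plate comparison is the paired contrast
$p_c - (100 - p_c)$, i.e. a one-sample test of $p_c$ against 50 %.
Across the three timepoints, $p_c$ is analyzed with a one-way
repeated-measures ANOVA and pairwise Tukey contrasts on the studentized
range ($q = t\sqrt{2}$, $k$ family means, $n-1$ df). A session's drug
effect is classified from the pre-drug and post-drug preference directions
(each *warmer*, *colder* or *none* at adjusted $p < 0.05$):

| pre-drug | post-drug | category |
|---|---|---|
| significant | none | **lost** |
| significant | opposite side | **reversed** |
| significant | same side | **maintained** |
| none | — | no baseline |

The synthetic agent crosses plates at Poisson rate $\lambda$ and settles
on the left plate with probability
$\sigma\!\left(\beta\,[c(T_\text{left}) - c(T_\text{right})]\right)$, where
$c(T)$ is a concave comfort score peaking at the murine thermal
preferendum (~26 °C) with an extra penalty above the heat-stress onset
(34 °C), and $\beta \ge 0$ is the preference gain. Treatments rescale or
invert $\beta$ and shift the comfort optimum (cold hypersensitivity is a
warm-shifted optimum with a sharpened gain).

## Worked example

Simulate a ten-mouse cohort under the broad-band (pregabalin-like)
analgesic profile, then analyze it:

```bash
thermoplace simulate --out demo --seed 42 --profile pregabalin
thermoplace analyze --cohort demo/cohort.csv --out demo/analysis
```

which prints:

```
session  range(degC)   pre          post         category
      1     0-5     warmer****   none  ns     lost
      2     5-10    warmer****   colder****   reversed
      3    10-15    warmer****   colder****   reversed
      4    15-20    warmer****   colder****   reversed
      5    20-25    warmer****   colder****   reversed
      6    25-30    warmer**     colder****   reversed
      7    30-35    colder***    colder***    maintained
      8    35-40    colder****   colder****   maintained
      9    40-45    colder****   colder****   maintained
analgesia: lost at sessions [1], reversed at [2, 3, 4, 5, 6], maintained at [7, 8, 9]
```

Reading: before the drug the neuropathic (post-oxaliplatin) mice prefer
the warmer plate at every pair up to 25–30 °C (stars: plate-vs-plate
adjusted $p$); after the drug the preference is abolished at 0–5 °C and
flipped toward the colder plate across 5–30 °C — the loss/reversal pattern
that indexes analgesia — while above 30 °C the cold-side preference
(heat-stress avoidance) is untouched. `demo/analysis/calls.csv` holds the
underlying p-values, and `thermoplace report --calls demo/analysis/calls.csv
--out fig.png` draws the bar figure.

To track a recording instead of simulating one:

```bash
thermoplace track --video frames_dir/ --pair 0,5 --out tracked/
```

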