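# Methods

This note documents the models, parameters and design choices behind
the package, and what its synthetic-region tests do and do not show.

## Scope and data model

Everything lives on one rectangular grid (`GridSpec`): row-major from
the northwest corner, a cell value covering the whole cell, nodata
sentinel −9999 by default, CRS recorded as a label only. Two rasters
are aligned iff every spec field except nodata matches, and every
stage rejects unaligned inputs. The class coding is 0 Urban, 1 Pasture,
2 Crops, 3 Forest, 5 Non-forest nature (4 unused); water is removed
from the active map before analysis (`freeze_classes`) because it
barely changes on the modelled horizon, and frozen cells take no part
in demand totals or allocation.

The real national inputs (a 1990–2018 land-cover series, gridded
environmental and accessibility drivers) are not redistributable at
desk scale and are out of scope. Published scalar tables — the 2018
class areas, the 1990–2018 change counts with their elasticities, and
the 2018 validation confusion counts — ship in `deltaclue.datasets`
and are treated as inputs.

## Land-cover preparation

Fine category maps are reclassified by a total lookup table and
aggregated by blocks of `factor²` cells to the analysis grid; each
coarse cell takes the modal class of its block with nodata cells
excluded from both the mode and the prevalence denominator. Majority
ties break to the lowest class code — a deterministic, documented rule
chosen for test stability. Non-divisible grids can be padded south/east
with nodata.

## Historic transitions and elasticities

Transitions are counted over every consecutive snapshot pair;
`per_class_changes` is the off-diagonal row sum. Conversion
elasticities scale these counts into [0, 1]. The exact scaling behind
the published Dutch table is not recoverable from the counts, so the
canonical path (`method="table"`) takes the published vector verbatim
(Urban 0.90, Pasture 0.04, Crops 0.01, Forest 0.88, Non-forest nature
0.91, Water 0.99) and `method="minmax"` —
`1 − (changes − min)/(max − min)`, two decimals — is provided as a
documented approximation that tracks the published values to about
0.01. The allow matrix defaults to all-permitted among active classes
(historically, almost every conversion was observed); frozen classes
get identity rows and columns, and no minimum/maximum residence time is
imposed by default (the age raster exists as a mechanism but is
disabled).

## Scenario demand

The demand builder applies, in order: urban from its share of the
total; pasture and crops either from a rural-share split (a
`pasture_fraction` of the rural reduction comes out of pasture) or as
direct per-class values where the source rules were adjusted by hand;
forest as the 2018 stock plus the scenario gain; non-forest nature as
the exact remainder, making conservation structural. All areas are
rounded to the nearest 100 ha, half away from zero — the rounding that
reproduces the published tables.

Succession accounting: land abandoned at a linear rate over an
`horizon` of 32 years becomes forest iff abandoned at least `lag`
years (default 30) before the end, so a fraction
`max(0, horizon − lag)/horizon` of the eligible abandoned pool closes;
existing open nature contributes an `advanced_fraction` already far
enough along. That fraction is the one unpublished degree of freedom in
the source arithmetic and is exposed as a parameter (default 0); the
built-in scenarios carry their published forest gains directly.

Annual trajectories interpolate linearly between the current stocks
and the 2050 table (the sources give only endpoint demands), each row
re-rounded to the 100 ha unit and re-balanced on the largest class so
every row sums exactly to the total.

## Suitability models

Per class, a one-vs-rest binary logistic regression (statsmodels
`Logit`), matching the per-class structure of the legacy coefficient
files rather than a single multinomial fit. Predictors pass a greedy
correlation screen first: while any retained pair has |r| > 0.7, the
member of the worst pair with the larger mean absolute correlation to
the others is dropped (ties: the alphabetically later name); constant
predictors are dropped with a warning. Selection is bidirectional
stepwise on AIC starting from the full candidate model (the
conservative reading of "bidirectional"; `start="empty"` is available),
applying the best single add-or-drop move until none decreases AIC.
An intercept-only final model is allowed. Fits that fail outright fall
back to L-BFGS; near-separation is flagged and coefficients are capped
at |50|. Note the statistical floor: AIC retains a pure-noise predictor
whenever its likelihood-ratio statistic exceeds 2, i.e. with
probability ≈ 0.157 each — the stepwise cannot and should not drive
this to zero. AUC uses the Mann–Whitney rank form with ties counted ½.

## Dynamic drivers

- Flood composite: `0.1·d10 + 0.01·d100 + 0.001·d1000 + 0.00001·d100000`
  over the four event-depth rasters (weights are the annual exceedance
  probabilities).
- Year interpolation is cellwise linear between two dated maps, exact
  at both endpoints and affine in the year; `fractional_endpoint`
  returns the map at a fractional position (e.g. a milder scenario
  taking the three-quarter point of a severe trajectory as its own
  endpoint).
- Distance rasters are Euclidean in the projected CRS from cell
  centers to the nearest feature open in the query year
  (`open ≤ year < close`); polylines are densified at half the
  cellsize, bounding the point-set approximation error well under a
  cell. An empty open set yields a finite far-distance sentinel (1e30)
  with a warning rather than infinities.
- Climate uses a trailing moving average (window 20 years by default);
  when the series is shorter than the window the available prefix is
  averaged with a warning.
- Land price is an OLS on the covariate stack; predictions are
  rescaled so their maximum equals the training maximum — only
  relative spatial differences carry information, and the training
  maximum is the documented anchor.
- Future flood probability-band conversion is an input, not a
  computation: the composite formula is in scope, the band choices are
  data.

## Allocation engine

The engine reproduces the qualitative behaviour of the CLUE family's
iterative competition variable with an explicit, simple rule set:

- Probability is additive:
  `P = suitability + w_k·locspec + competition_k + elas_k·[incumbent]`.
- Assignment is the allowed-class argmax per cell; ties keep the
  incumbent, then take the lowest class code (stability +
  determinism).
- Competition updates by
  `gain · (demand − allocated)/demand` per class and iteration;
  convergence is a per-class relative deviation ≤ `tolerance`.
  Defaults (tolerance 0.0035, gain 0.05, max 2000 iterations) are
  config-exposed because the source values were set by trial and error
  and are not printed.
- Demand is converted internally from hectares to whole cells by
  largest-remainder rounding, making conservation of the active cell
  count exact.
- Elasticity 1.0 makes a class's cells immovable (the "changes are
  impossible" endpoint); the upfront feasibility check considers only
  the allow matrix and restriction mask, so demand that requires an
  immovable class to shrink surfaces as a non-convergence diagnostic
  (with per-class deviations attached) rather than an upfront
  infeasibility error.
- The neighbourhood-enrichment term of the wider framework is a
  deliberate no-op: nothing in the implemented workflow uses it.

On 50×50 regions the loop typically converges in 30–250 iterations per
year; each year warm-starts from the previous competition vector.

## Validation

Confusion matrices are oriented rows = predicted, columns = reference,
so user's accuracy is the row formula and producer's the column
formula. Percentages report to one decimal, half away from zero. The
published 2018 counts reproduce the published overall accuracy (87.6 %)
and most per-class cells exactly; the urban and forest cells disagree
with the published table in the last decimal when recomputed from the
printed counts (e.g. urban user's recomputes to 74.7 against a printed
74.8) — consistent with independent rounding in the source tables —
and are therefore not asserted. Multi-resolution accuracy
majority-aggregates both maps with the landcover rule before scoring,
discounting near-misses; the null model scores the unchanged old map
against the new one.

## Synthetic study regions

`deltaclue.synth` generates what the tests need and nothing more:
standardised moving-average-smoothed Gaussian driver fields; a class
map sampled from the softmax of per-class linear predictors (one class
per cell, yet consistent with one-vs-rest logistic fitting); a history
evolved by a known per-cell Markov matrix; and random restriction
masks with exact cell counts. Defaults: 50×50 cells of 1 km, 3 drivers
with smoothing radius 2, five active classes each driven by one
dominant coefficient of magnitude 1.5 with alternating sign, diagonal
stay-probabilities spreading away-rates over 0.02–0.10 so the
propensity ordering is strict. These sizes keep a full pipeline run
under a second while leaving parameter-recovery tests comfortable
statistical margins.

What passing these tests shows: the machinery is self-consistent —
fitted models recover planted coefficients' identity and sign, derived
elasticities recover planted propensity orderings, allocation meets
demand under restrictions and allow constraints, every dialect
round-trips. What it does not show: performance on real landscapes,
where drivers are collinear and non-Gaussian, change is spatially
structured, and class geometry is autocorrelated far beyond these
fields. The synthetic drift used in the hindcast analysis is spatially
random by construction, so the no-change null retains an edge on
overall accuracy there — the model's advantage shows where it should,
in producer's accuracy for classes with net change.

## Known limitations

- The engine is not bit-compatible with the original CLUE-family
  executable; the competition update rule is this package's own, tuned
  to reproduce the documented qualitative behaviour.
- The published Dutch 2050 maps cannot be reproduced without the real
  national rasters; no attempt is made.
- One published demand cell (SSP5 crops) lands one 100-ha rounding
  unit away from its published value when derived strictly from the
  stated 60/40 split; the remainder class absorbs the difference.
- Stepwise selection inherits AIC's fixed false-inclusion rate
  (≈ 0.157 per noise candidate); downstream allocation is insensitive
  to such small spurious coefficients.
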