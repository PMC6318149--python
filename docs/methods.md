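# Methods

## The demand model

Each of the 11 training tasks is described by a small discrete parameter
space (`cogtaskgen.params.DEFAULT_SPACES`). For every task × axis pair
(axes: memory, executive functions, attention, language, difficulty) the
demand model is linear in numeric encodings of the parameters,

    demand = intercept + Σ cᵢ · xᵢ ,

clamped to the 1–10 rating scale and reported to two decimals
(round-half-away-from-zero, matching the precision of the published rating
summaries). Count parameters encode as their value; binary and categorical
parameters use indicator or ordinal codings with the *easier* level at 0
(numeric problems = 0 / textual = 1; no clue = 0 / picture clue = 1; goal
given = 0 / hidden = 1; stimulus numbers = 0 / letters = 1 / symbols = 2;
story length short = 0 / medium = 1 / long = 2; blanks at the start of a
sequence = 1, elsewhere = 0). The indicator convention is forced by
consistency between the published coefficient tables and the published
min–max rating ranges: the problem-resolution language range 4.65–5.75 only
arises from a 0/1 coding of the problem type.

Axes that no parameter significantly moves are constant at the mean expert
rating for that task (*fallback mean*); such axes have a degenerate
(min = max) adaptation range.

### Shipped coefficients

Five models ship with published fixed-effect coefficients, used verbatim:
problem resolution (language: 4.65 + 1.10·type; difficulty:
4.870 + 0.542·operations + 0.365·tens) and comprehension of contexts
(executive functions: 0.25 + 1.20·descriptions; language:
1.45 + 1.00·descriptions; difficulty: 1.05 + 0.75·descriptions).

The remaining models are **endpoint calibrated**: for each task × axis with
a published (min, max) rating range and a set of significant parameters
named by the expert customization guidelines, we construct the linear model
whose prediction at the all-easiest grid corner equals the published
minimum, whose prediction at the all-hardest corner equals the published
maximum, and whose min-to-max span is apportioned equally across the named
parameters. All coefficients come out positive because the encodings are
oriented along the guideline directions. This construction reproduces every
published mean/min/max and every stated monotonicity (asserted by grid
enumeration in the test suite) without claiming to recover the original
per-parameter estimates — those require the undeposited raw ratings.
Calibrated replacements can be dropped in through the coefficient
configuration file (`cogtaskgen dump-models` emits the same format).

One deliberate grid choice: comprehension of contexts offers 2 or 3
descriptions. The published range endpoints for its three modeled axes
coincide exactly with the model evaluated at 2 and 3 descriptions, so the
default grid stops at 3; larger description counts would extrapolate beyond
the rated material.

The printed problem-resolution difficulty model predicts 5.41–7.40 over the
default grid while the rated variants spanned 5.35–7.20; the published
coefficients are kept verbatim and the (slightly wider) enumerated range is
reported as such.

## Parameter grids

The published task list names the tunable parameters but not their ranges.
The defaults (word search 4–10 words, clue none/word/picture; problem
resolution 1–4 operations, ones/tens; sequences step 1–5, 1–3 missing,
position start/middle/end, ascending/descending; action sequencing 3–8
steps, goal given/hidden; association and image pairs 3–10 pairs;
cancellation numbers/letters/symbols, 1–3 target and 2–8 distractor types,
pool 50–200 in steps of 25, random/grid; categorization 2–5 categories × 3–8
items; mazes 5–15 odd; stories textual/pictorial × short/medium/long × 2–6
questions) are chosen to be clinically plausible, consistent with the scale
of the original 67-variant rating study, and small enough that every grid
(at most 882 points) enumerates in milliseconds — which is what makes both
the exhaustive range computation and the exact inverse matching trivial.

## Inverse matching

`match_task` minimizes the weighted Euclidean distance between a target
profile and the predicted profile over the full grid (default weights 1 on
all five axes). Enumeration order is lexicographic — declared parameter
order, lowest levels first — and only a strictly smaller distance replaces
the incumbent, so ties resolve deterministically to the lexicographically
first optimum. `generate_program` matches all 11 tasks; with the close-match
filter on, tasks whose distance exceeds the threshold (default 1.5 rating
units — no metric or threshold is published, so both are exposed as
configuration) are excluded. MoCA subscores map linearly onto the profile:
value = 1 + 9·score/max per axis (attention /6, delayed recall +
orientation /11, visuospatial-executive + abstraction /7, naming +
language /6, total /30). The default direction sends higher subscores to
higher demand targets — train at the level the patient can sustain; an
`--invert` flag flips the convention, which is genuinely ambiguous in the
source material.

## Procedural generation

All randomness flows from one explicit integer seed through Python's
deterministic Mersenne generator; per-task sub-seeds are derived from the
program seed by SHA-256 over `"{seed}/{task_id}"`, so one program seed
reproduces every document. Serialization is canonical JSON, making
determinism testable byte-for-byte.

Generator specifics worth knowing:

* **Word search** places words by randomized depth-first backtracking over
  four directions (forward, down, up, main diagonal), overlap allowed where
  letters agree; grid side = max(longest word, word count + 4), grown once
  by 2 before generation fails. Unfilled cells get uniform random letters.
* **Cancellation** draws each target type's occurrence count uniformly from
  [0.1, 0.3] × pool size. The "numbers" alphabet is the numerals 1–20 (ten
  digits alone cannot supply 3 target + 8 distractor distinct types).
* **Numeric sequences** prints six sequences per sheet. Starting values are
  drawn from [0, 20] and descending sequences start at their highest term so
  no term is negative. A single sequence per sheet would be both a thin
  worksheet and (with only 21 possible starts) unable to satisfy the
  never-the-same-twice property; the sheet of six restores both.
* **Mazes** are perfect mazes: a depth-first spanning tree over the
  size × size cell lattice (size² − 1 carved passages), entrance top-left,
  exit bottom-right, key = the unique tree path.
* **Arithmetic problems** use + and − with operands in [1, 9] (ones) or
  [10, 99] (tens), redrawn until every left-to-right partial result is a
  non-negative integer. Textual problems instantiate daily-living templates
  whose operator pattern fixes the operand arity.
* **Stories and scenes are templates**, not verbatim texts: stories carry
  randomized slots (names, places, counts — answers derive from the slot
  values, sums included), and scene descriptions are fact templates whose
  false variants substitute foil fillers. This is what gives the
  bank-driven tasks enough entropy that repeated generation at fixed
  parameters does not repeat content.
* Image-based content (picture clues, image pairs, pictorial story panels,
  scene drawings) is represented by stable `img:...` asset identifiers with
  alt text; rendering embeds placeholders and no artwork ships. The
  image-pairs 30-minute delayed recall is a printed instruction, not a
  timed software behavior.

Every generator has an independent verification oracle
(`verify_document`): a line scanner for word search, a recount for
cancellation, arithmetic-progression reconstruction for sequences, BFS on
the passage graph for mazes, left-to-right re-evaluation for arithmetic,
and bank re-derivation for the content tasks. The oracle re-derives keys
from payloads by a different route than the generator built them, so
corrupting either side fails verification.

## Calibration machinery

The estimator behind `fit_demand_model` is fixed-effects ordinary least
squares (statsmodels) of ratings on encoded parameters with an intercept.
The original analysis used a multilevel fit with random slopes and
autoregressive errors; without the raw ratings there is nothing to estimate
those variance components from, and the package's defaults come from
published coefficients, so calibration only needs a sound, fully testable
estimator. Presentation order is retained in the record model so an order
covariate can be included as a predictor if desired.

* Significance screening drops predictors with two-sided p ≥ 0.05 (the
  level is conventional; only the screening itself is documented) and
  refits; with no survivors the model degenerates to the grand-mean
  fallback.
* AIC = 2k − 2·loglik and BIC = k·ln(n) − 2·loglik under a Gaussian
  likelihood with the maximum-likelihood variance estimate, k counting the
  intercept, the slopes, and the residual variance.
* Cronbach's alpha uses the standard item-variance form with sample
  (n − 1) variances over a raters × items matrix; rows with missing cells
  are dropped listwise.
* `simulate_ratings` provides the synthetic expert panel used for testing:
  rating = model prediction + per-rater normal intercept + normal noise,
  clamped to [1, 10], each rater seeing the design in an own shuffled
  presentation order. It emulates panel consistency and additive noise; it
  does **not** emulate rater-specific slopes, order drift, serial
  correlation, or the discreteness of true Likert responses (rounding is
  optional and off by default), so passing recovery tests show the
  estimator is correct under its own assumptions, not that real expert
  panels satisfy them.

Test scale: the recovery check fits 200 simulated 20-rater panels (noise
sd 1) and requires the generating coefficients within ±3 standard errors in
≥ 99% of fits; the consistency check uses a 67-variant stratified design —
the scale of the original study — at noise sd 0.3 and rater sd 0.2.

## Difficulty adaptation

Mean session performance ≥ 70% raises the difficulty axis by 0.5, ≤ 50%
lowers it by 0.5, and the open band (50, 70) leaves the profile unchanged —
the source bands are "70% to 100%" and "0% to 50%", so both boundary values
are treated as belonging to the change branches, and the in-between band is
an explicit no-change choice. Difficulty is clamped to [1, 10]; the four
cognitive axes are only ever changed by a new assessment (`reassess`).

## Known limitations

* Endpoint calibration fixes two points per axis; the relative weighting of
  parameters within an axis (equal apportionment) is an assumption, not an
  estimate.
* The English content banks are compact fixtures; clinical deployment would
  want larger, clinician-reviewed banks (the formats are plain JSON).
* No PDF output; sheets render as plain text and HTML for printing.
* Scores are entered by the clinician; the package does not grade completed
  sheets.
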