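# cogtaskgen

Personalized paper-and-pencil cognitive rehabilitation tasks, generated from
expert-calibrated demand models.

## The problem

Cognitive impairments after stroke — in memory, attention, executive
functions, and language — are routinely trained with paper-and-pencil
worksheets, but clinicians usually assemble and grade those worksheets by
hand, and the difficulty of a given sheet for a given patient is judged
subjectively. `cogtaskgen` turns that tacit judgment into an explicit,
quantitative pipeline for clinicians and rehabilitation researchers:

1. **Demand models.** Eleven standard training tasks (word search, problem
   resolution, numeric sequences, action sequencing, association,
   cancellation, categorization, comprehension of contexts, image pairs,
   mazes, memory of stories) are parameterized (word count, number of
   operations, maze size, ...), and each task × axis pair carries a linear
   model of the expert-rated demand on a 1–10 scale:

   *demand* = *intercept* + Σᵢ *cᵢ* · *xᵢ*

   where the *xᵢ* are numeric encodings of the task parameters. Axes that
   no parameter significantly moves use the mean expert rating as a
   constant (the *fallback mean*). Predictions are clamped to [1, 10] and
   the five axes — memory, executive functions, attention, language,
   difficulty — form a task's *demand profile*.
2. **Inverse matching.** Given a target profile for a patient (entered
   directly or mapped linearly from Montreal Cognitive Assessment
   subscores), the package enumerates each task's full parameter grid and
   picks the configuration whose predicted profile minimizes the weighted
   Euclidean distance to the target. A full program is the best match of
   all 11 tasks, optionally filtered to close matches only.
3. **Procedural generation.** Each matched configuration is turned into a
   printable worksheet plus answer key (letter grids, mazes, arithmetic
   problems, stories with questions, ...) from seeded randomness and
   shipped content banks — two generated sheets are never the same, and the
   same seed always reproduces the same sheet. Every document can be
   re-checked by an independent verification oracle.
4. **Adaptation.** Between sessions, mean task performance (0–100%) drives
   a staircase on the difficulty axis only: ≥ 70% raises difficulty by 0.5,
   ≤ 50% lowers it by 0.5, and the four cognitive axes change only through
   reassessment.
5. **Calibration.** Given a fresh table of expert ratings, the package
   refits the demand models (ordinary least squares with significance
   screening and AIC/BIC comparison), reports Cronbach's alpha per rating
   matrix, and emits a coefficient configuration that overrides the shipped
   defaults.

## Worked example

Generate one comprehension-of-contexts sheet with 3 descriptions:

```sh
$ cogtaskgen generate-task comprehension_of_contexts -p descriptions=3 --seed 7 --out demo
predicted demand profile: memory=2.63  executive_functions=3.85  attention=3.40  language=4.45  difficulty=3.30
wrote demo/comprehension_of_contexts-seed7.json
wrote demo/comprehension_of_contexts-seed7.sheet.txt
wrote demo/comprehension_of_contexts-seed7.key.txt
```

The profile line is the model prediction for this configuration: with 3
descriptions the executive-functions demand is 0.25 + 1.20·3 = 3.85 and the
overall difficulty 1.05 + 0.75·3 = 3.30, on the 1–10 expert rating scale;
memory (2.63) and attention (3.40) are parameter-independent fallback
means. The sheet itself reads:

```
Comprehension of contexts
=========================

An afternoon in the park  [image: img:scene-park]

Mark the descriptions that match the scene:
  [ ] 1. Two children are playing with a hammer.
  [ ] 2. A woman is reading a newspaper under a tree.
  [ ] 3. A vendor is selling furniture near the gate.
```

and the key names description 2 as the only correct one.

A full program for a patient profile (all axes at 5) comes from

```sh
$ cogtaskgen generate-program --profile profile.json --seed 3 --out program
program: 11 of 11 tasks included
  word_search: distance 1.877 (included)
  ...
  memory_of_stories: distance 0.890 (included)
```

which writes eleven sheets, keys, and a manifest recording each task's
chosen parameters, predicted profile, and match distance. The same library
calls are available from Python (`cogtaskgen.generate_program`,
`cogtaskgen.match_task`, ...). MoCA input, session adaptation
(`cogtaskgen adapt`), model dumps and re-calibration
(`cogtaskgen calibrate`) are covered in `cogtaskgen --help`.

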