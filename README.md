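# handdx

Hand-function assessment from 21-landmark motion capture, paired with a
hand-disease knowledge-graph question-answering engine.

`handdx` is aimed at rehabilitation researchers and engineers building
camera-based hand assessment tools. Monocular hand-pose estimators output 21
three-dimensional joint landmarks per video frame (one wrist node plus four
nodes per finger including the fingertip); this package turns such landmark
streams into clinically interpretable measurements and scores, and answers
patients' disease questions against a structured knowledge graph — the two
halves of an intelligent hand-assisted diagnosis workflow.

## What it computes

**Kinematics.** For each of the 14 clinically measured joints (MCP/PIP/DIP of
the four fingers, plus the thumb MCP and interphalangeal joint), the flexion
angle at vertex Y between proximal X and distal Z is

```
∠XYZ = arccos( XY·YZ / (|XY||YZ|) )
```

reported in degrees (0° = fully extended). Over a motion sequence, range of
motion (ROM) is the range between the maximum and minimum angle. Thumb
opposition is the minimum thumb-tip to little-finger-MCP distance, successful
when it drops below the 3 cm contact margin. The hand-joint surface-normal
consistency metric L_n treats every joint triplet as a triangular joint
surface and sums |unit predicted edge · ground-truth unit face normal| over
the three edges of each face — zero exactly when predicted edges lie in their
true face planes.

**Scoring.** ROMs map to 0–10 point scores through the hand-joint functional
activity standard: e.g. MCP 70°–90° → 7.5–10 points (linearly interpolated),
50°–69° → 5–7.5, and so on per joint class; opposition scores 10/5/0 for
can/hard/can't; thumb active ROM (summed thumb MCP + IP ROM) scores 10 when
above 90°. Normal reference ranges are MCP 70–90°, PIP 80–100°, DIP 30–45°.

**Synthetic motion.** A forward-kinematic generator renders programmed joint
trajectories (e.g. repetitions of open-palm-to-clenched-fist) into landmark
sequences with optional seeded Gaussian landmark noise, so the whole pipeline
is testable with exactly known ground truth.

**Knowledge-graph QA.** Line-delimited disease records load into a typed
property graph (Disease, Food, Drug, Department, Producer entities; relations
such as `acompany_with`, `do_eat`, `no_eat`, `recommand_drug`). Questions are
linked to entities with an Aho–Corasick dictionary automaton, classified into
14 intents by trigger keywords, expanded by fixed query templates into
attribute lookups or 1-hop retrievals, and rendered as sentences.

## Worked example

Generate a noise-free fist-cycle recording and assess it:

```
$ handdx simulate --out demo.json --seed 1
$ handdx assess demo.json
joint        class     min     max     ROM  score  flag
thumb_MCP    MCP      0.00   90.00   90.00  10.00  normal
thumb_DIP    DIP      0.00   50.00   50.00  10.00  normal+
index_MCP    MCP      0.00   90.00   90.00  10.00  normal
index_PIP    PIP      0.00  100.00  100.00  10.00  normal
index_DIP    DIP      0.00   45.00   45.00  10.00  normal
...
opposition: achieved (min 16.2 mm, threshold 30 mm) score 10.0
thumb AROM: 140.00 deg score 10.0
total score: 160.00
```

Each row is one joint: its observed angle extremes, ROM, rubric score and
whether the ROM reaches the normal reference range (`+` marks motion above
the reference maximum, e.g. the thumb IP sweeping 50° against a 45° DIP
reference). The preset sweeps every joint to the top of its scoring band and
closes the thumb within the 30 mm opposition margin, so all 16 components
score 10 for a maximum total of 160.

Ask the knowledge graph a question (`kg.jsonl` as written by
`handdx.fixtures.write_example_records`):

```
$ handdx ask --graph kg.jsonl "What should tenosynovitis patients eat and what drugs help?"
Recommended foods for tenosynovitis: stewed lamb with persimmons
Recommended drugs for tenosynovitis: dexamethasone sodium phosphate injection
```

The question matched one disease entity and two intents (food and drug
recommendation); each intent ran its query template and rendered the
retrieved neighbours.

Other subcommands: `kg-load` (validate + stats), `batch-qa` (JSON lines),
`export-cypher` (write-only graph export), `simulate --spec` (custom
trajectories).

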