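# Methods

This note records the measurement model, the scoring conventions, the
synthetic-data design and the numerical choices behind `handdx`, including
the places where the underlying clinical conventions leave the design open.

## Landmark model and joint angles

The hand is represented by 21 named landmarks in millimetres: the wrist
(standing in for the carpal block, whose internal mobility is negligible for
whole-hand assessment) and four nodes per finger — MCP, PIP, DIP, tip for the
fingers; CMC, MCP, IP, tip for the thumb. The ordering follows the layout
that monocular pose estimators emit, so estimator output can be fed in
directly. Wrist posture is assumed neutral; only finger flexion/extension is
measured (abduction, circumduction and wrist angles are out of scope).

Fourteen joints are measured: three per finger and two for the thumb (the
thumb lacks a middle phalanx, so it has a single interphalangeal joint,
reported as `thumb_DIP` to align with per-finger reporting; `thumb_IP` is an
accepted alias). Each joint needs a proximal and a distal reference landmark
around its vertex. For PIP and DIP joints these are the flanking landmarks on
the finger chain. For a finger's MCP joint the proximal anchor is the wrist —
the metacarpal shaft is not separately observable in a 21-point model — and
for the thumb MCP it is the thumb CMC node. This anchoring is a convention of
this package, not a clinical standard: the goniometric definition references
the metacarpal axis, which coincides with the wrist→MCP direction only
approximately in a real hand and exactly in our synthetic model.

The flexion angle is the angle between the two bone vectors, 0° when the
chain is straight. Although it is defined as `arccos` of the normalized dot
product, it is computed as `atan2(|XY × YZ|, XY·YZ)`: the two forms are
mathematically identical, but `arccos` loses about half the available
precision near 0° and 180°, where the argument's derivative diverges, while
`atan2` is uniformly well conditioned. This is what lets noise-free
round-trip tests demand recovery of programmed angles — including exactly 0°
— to 1e-9 degrees. The dot-product argument is clamped to [−1, 1] wherever
`arccos` appears in oracle code. Bone vectors shorter than 1e-9 mm raise
`DegenerateSegment` rather than returning an arbitrary direction.

## ROM, opposition, thumb AROM

ROM is the global max − min of the per-frame angle trajectory, computed over
the full sequence rather than per repetition — with multiple fist cycles the
global range equals the per-cycle range for any cycle that reaches the
extremes, and the global definition is robust to incomplete cycles. It
requires at least two frames (`TooFewFrames` otherwise).

Thumb opposition is the Euclidean thumb-tip to little-finger-MCP distance;
the test succeeds when the minimum over frames is strictly below the 30 mm
contact margin (3 cm). The boundary is read strictly ("below" the margin); a
minimum of exactly 30 mm fails, which matters only on a set of measure zero
but is pinned down in tests. Thumb active ROM is the sum of the thumb MCP and
IP ROMs, compared against the 90° threshold.

## Surface-normal consistency

Every joint triplet (three connected joints) is treated as a triangular joint
surface; the face set is exactly the 14 joint triplets. The metric between a
predicted and a ground-truth frame is

    L_n = Σ_f Σ_{(i,j) ⊂ f} | unit(pred_i − pred_j) · n̂_f(gt) |

summed over the three edges of each face, where n̂_f(gt) is the unit normal
of the ground-truth face. Each edge is normalized once; the ground-truth
normal is a unit vector, so the metric is invariant to translation and
uniform scaling of the prediction and vanishes iff every predicted edge lies
in its own true face plane. Ground-truth faces whose vertices are collinear
(cross-product norm below 1e-9 times the product of edge norms — a fully
extended finger) have no defined normal; they are skipped and excluded from
`n_faces_evaluated`, and a frame with no evaluable face raises
`NoEvaluableFaces`. A zero-length predicted edge is an error, not a zero
contribution. Here the metric is an evaluation quantity for comparing
predicted against reference landmarks, not a training objective.

## Scoring rubric

The activity standard prints four ROM bands per joint class with score
ranges:

| class | bands (deg → points) |
|-------|----------------------|
| MCP   | <30 → 0–2.5, 30–49 → 2.5–5, 50–69 → 5–7.5, 70–90 → 7.5–10 |
| PIP   | <30 → 0–2.5, 30–59 → 2.5–5, 60–79 → 5–7.5, 80–100 → 7.5–10 |
| DIP   | <15 → 0–2.5, 15–19 → 2.5–5, 20–29 → 5–7.5, 30–45 → 7.5–10 |

Two conventions are needed to make this a total function on nonnegative
reals. First, the printed integer-gapped bands (…–49, 50–…) become contiguous
half-open intervals ([30, 50), [50, 70), [70, ∞) for MCP, analogously for
PIP/DIP), so every real ROM falls in exactly one band. Second, the printed
score ranges come with no mapping rule; linear interpolation across each band
is adopted because it is continuous, monotone and agrees with the printed
endpoints — the score at 80° MCP is 8.75, the midpoint of [7.5, 10]. ROM
above the top band's printed maximum clamps at 10: hypermobility grading is
outside the rubric's scope, so excess motion is not penalized or rewarded,
only flagged `above_reference` in the report (with a 1e-9° guard so measured
ROMs a few ulps above an exact endpoint are not flagged).

Opposition scores are categorical (can 10 / hard 5 / can't 0). The
kinematic test yields only achieved/not_achieved; the intermediate "hard"
grade has no quantitative definition in the standard, so it is off by
default and assignable through an optional second distance threshold
(suggested 60 mm) for users who want a three-way grading. Thumb AROM scores
10 above 90°, 5 for measurable motion up to 90°, 0 for no motion
(stiffness). The report's total is the plain sum of the 14 joint scores plus
opposition and thumb AROM — maximum 160.

A ROM at or above its class's lower reference bound (MCP 70°, PIP 80°,
DIP 30°) is classified `normal`, below it `reduced`.

## Synthetic hand generator

The generator exists so that every kinematic operation has exact ground
truth. The wrist sits at the origin with the palm in the z = 0 plane; each
finger is a planar chain of hinge joints — consistent with interphalangeal
joints being hinge joints — whose bone vectors rotate by cumulative flexion
within the finger's plane, curling toward the palm. The thumb's flexion
plane is spanned by its column direction and the direction from its CMC to
the little-finger MCP, so thumb flexion sweeps the tip across the palm
toward the opposition target; this is a deliberate simplification of the
thumb's saddle-joint kinematics sufficient to reproduce an opposition
movement. Abduction is not simulated.

Default bone lengths are rounded adult-hand magnitudes (fixtures, not
measured values): e.g. index chain 40/25/20 mm phalanges with the MCP at
(25, 85, 0) mm, thumb column 45/32/25 mm. All lengths are configurable.

Trajectories are piecewise-linear per-joint breakpoint profiles. The
fist-cycle preset runs each joint through a triangle wave from 0° to its
scoring-band top target (MCP 90°, PIP 100°, DIP 45°, thumb MCP 90°, thumb IP
50°) and back, 3–4 repetitions of 40 frames (at a nominal 30 Hz this is
~1.3 s per open-close cycle, a natural pace), with the thumb CMC sweeping to
35° so the thumb tip passes ~16 mm from the little-finger MCP at mid-cycle —
within the 30 mm opposition margin. Measurement noise is isotropic Gaussian
per landmark per frame, seeded; the default preset is noise-free.

What the generator does **not** emulate: estimator-specific error structure
(occlusion-induced drift, depth ambiguity, temporally correlated jitter),
soft-tissue deformation, joint coupling, abduction, or inter-subject
anatomical variation. Tests passing on synthetic data therefore validate the
measurement and scoring pipeline given landmarks, not the quality of any
upstream pose estimator — estimator error on flexed thumbs in particular is
known to be much larger than isotropic noise.

Noise-robustness tests compare recovered ROM against a Monte-Carlo oracle
that models the noisy triplet directly (true triplet geometry + isotropic
jitter, angle recomputed from pairwise distances via the law of cosines),
asserting agreement within 3 standard deviations of the oracle distribution;
under landmark noise the max−min estimator is biased upward by extreme-value
effects, so comparing against the oracle's distribution rather than the
noise-free value is the statistically honest check. Problem sizes throughout
the suite (500-frame sequences, 300 Monte-Carlo replicates, 1000 random
poses, 200 automaton trials) keep the whole suite in a few seconds while
leaving estimator standard errors far below the asserted tolerances.

## Knowledge graph

Records are line-delimited JSON, one disease per line, validated by a
pydantic model. Loading produces one Disease entity per record, deduplicated
Food/Drug/Department/Producer entities, one relation per list element, and
the eight per-disease text attributes. Complications become Disease entities
(stub nodes when no record of their own exists) linked by `acompany_with`.
Symptoms are stored as a disease attribute (a list of phrases), not as
entities, mirroring the schema's entity inventory. `drugs_of` is oriented
Producer → Drug. Entity names are NFKC-normalized and trimmed; matching is
exact thereafter. Loading is order-invariant and idempotent, and referential
integrity (no dangling endpoints, domain/range typing) holds after every
load — both are asserted property-style in tests.

The store is an in-memory `networkx.MultiDiGraph` behind the module's own
API; no graph database is required. A write-only Cypher-text export is
provided for users who do run one; it is never parsed back.

## QA engine

The pipeline is retrieval-by-template at a single hop: dictionary automaton →
entity matches → intent classification → query template → graph retrieval →
sentence rendering. The general framing of such systems allows multi-step
reasoning over a question-specific subgraph; the deployed design here fixes
the step count at one, which the module boundary keeps explicit (a
`QueryPlan` could hold multi-hop primitives, but none are shipped). Ranking
is degenerate: every retrieved entity is kept (all scores equal, threshold
zero), so the answer set equals the retrieved set — asserted in tests.

The Aho–Corasick automaton is implemented in-package (trie + BFS failure
links + output links) and checked for exact match-set equality against naive
substring search on randomized dictionaries. Overlapping matches resolve to
the longest, ties to the leftmost. Matching is over lower-cased text
(byte-preserving for ASCII; full casefolding can change string lengths and
is deliberately avoided so spans always index the original question).

The intent taxonomy is the closed 14-element set induced by the eight
disease attributes and the graph relations (minus producer-to-drug as a
disease question, plus symptom): desc, cause, prevention, cure_way,
cure_lasttime, cured_probe, easy_get, symptom, complication, department,
food_recommend, food_avoid, drug_recommend, drug_producer. Trigger keywords
ship in English as a pluggable table (the deployed ancestor of this design
was Chinese; the published trigger lists are not available, so the shipped
table is a reconstruction). Trigger hits inside a matched entity's span are
ignored — "sheath" contains "eat" — and longer triggers beat shorter
overlapping ones ("cure rate" over "cure"). Entities matched with no
trigger default to the description intent; a question with no entity match
returns a clarification message rather than an empty answer. Questions with
several matched diseases answer each intent per disease; food/drug entities
in the question are used for reverse lookups only (e.g. drug → producer).

Unknown entities at execution time produce an empty result with a warning
instead of an exception: a user-facing QA loop should degrade, not crash.
End-to-end answering is deterministic — identical question and graph yield a
byte-identical rendered answer.

## Known limitations

- MCP angles are anchored at the wrist, not the metacarpal shaft; absolute
  MCP angles on real hands will differ slightly from dorsal goniometry.
- The rubric's linear band interpolation and the strict opposition boundary
  are conventions chosen here; other implementations of the same printed
  standard could differ within a band or exactly at 30 mm.
- The fixture knowledge graph is a miniature synthetic stand-in (a few
  diseases); entity/relation counts of a production corpus are not
  reproduced, only the schema and query behaviour.
- Substring-based entity linking requires exact names; misspellings and
  synonyms are not resolved.
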