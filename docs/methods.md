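# Methods

## Scoring model

Every detected nucleus is classified twice by independent mechanisms
("double reading"): once by appearance and once from its signal counts.
Both reads use the same five-class vocabulary — `normal`, `low`, `high`
(the ordinal "classified" subset), `uncertain`, `artifact`.

### Per-nucleus ratio rule (signal-count read)

Given counts `(n_HER2, n_CEN17, n_cluster)` the rules apply in a fixed
order:

1. `n_CEN17 = 0` → **artifact** (no reference signal; this precedes the
   cluster rule, so a cluster without any CEN17 is still an artifact);
2. `n_CEN17 = 1` → **uncertain** (a one-signal reference makes the ratio
   untrustworthy); an analogous single-HER2 rule exists behind
   `ScoringThresholds.one_her2_uncertain` but is off by default;
3. `n_cluster ≥ 1` → ratio fixed at 10 (an unresolvable HER2 accumulation
   is treated as strong amplification);
4. `n_HER2 = 0` → ratio fixed at 1;
5. otherwise ratio `= n_HER2 / n_CEN17`, capped at 10.

The ratio is graded `≤ 1.5` → normal, `(1.5, 6]` → low, `> 6` → high.
Both boundary values belong to the lower class.

The ratio is written HER2/CEN17 throughout: a normal diploid nucleus
(2 HER2, 2 CEN17) must score 1 and an amplified nucleus must score high
values (9–10), which fixes HER2 as the numerator.

### Image-level calls

* **Nucleus-detector (ND) call** — over nuclei whose *appearance* class is
  normal/low/high (uncertain and artifact nuclei are excluded from the
  denominator): ratio-1 = fraction graded low, ratio-2 = fraction graded
  high. `ratio-2 > 0.4` → HIGH; else `ratio-1 ≥ 0.2` → LOW; else NORMAL.
  HIGH takes precedence when both rules trigger. The boundary conventions
  differ deliberately: the low rule is inclusive ("at least 0.2"), the
  high rule exclusive ("greater than 0.4"); no row of the packaged
  validation table sits on either boundary, so the table cannot
  discriminate — both are configurable.
* **Signal-detector (SD) call** — the arithmetic mean of the defined
  per-nucleus ratios (nuclei read as artifact/uncertain contribute
  nothing; nuclei with zero HER2 contribute their forced ratio of 1).
  Mean `> 6` → HIGH; `> 1` → LOW; else NORMAL. The low bound is 1.0, not
  1.5: validation rows with means 1.17–1.40 are printed LOW, which is
  only consistent with 1.0 (a mean of exactly 1.00 is NORMAL).
* **Final call** — the consensus of the two reads; disagreement yields
  `DISCORDANT` rather than an arbitration, because the two reads are the
  method's error-surfacing mechanism.

Degenerate inputs: an image with no classified nuclei reports
ratio-1 = ratio-2 = 0 and an undefined mean, is called NORMAL, and carries
explicit warnings.

Ratios are carried at full precision internally and rounded to two
decimals only in reports, matching the precision of the validation table.

## Reference detectors

The detector layer is a contract; the shipped backends are deterministic
classical algorithms chosen for reproducibility at desk scale.

* **Nucleus localization** — Gaussian smoothing (σ = 2 px) of the blue
  (DAPI) channel, Otsu threshold with a floor of 60 (8-bit) so blank
  images yield no mask, hole filling, connected components, area filter
  1,500–60,000 px² at the nominal 40× scale, tight boxes.
* **Hue unmixing** — HER2 channel `= max(R − 0.5 G, 0)`, CEN17 channel
  `= max(G − 0.5 R, 0)`. Pixels with near-saturated red (≥ 245) are
  blanked in the CEN17 channel: inside a dense HER2 accumulation the red
  channel clips and green would otherwise bleed through the unmixing as
  phantom CEN17 signal.
* **Appearance read** — background-subtracted channel masses inside the
  nucleus box (background = channel median; only pixels ≥ 25 above it
  count) are divided by the mass of one reference spot to give
  spot-equivalents. The reference masses are measured by
  `calibrated_spot_masses`, which stamps a single spot of the reference
  color on a nucleus-colored patch and measures it with the identical
  extraction, making the estimate unbiased by the mass floor. CEN17
  spot-equivalents `< 0.5` → artifact, `< 1.5` → uncertain; otherwise the
  spot-equivalent ratio is graded with the 1.5/6.0 boundaries. A single
  contiguous HER2-positive region ≥ 100 px² is the visual signature of a
  cluster and forces a high read. Confidence is the distance to the
  nearest decision boundary, clipped into [0.05, 1].
* **Signal read** — per channel, multiscale Laplacian-of-Gaussian blob
  detection (σ ∈ [1.3, 3], response threshold 0.08 on channels scaled to
  [0, 1]) with greedy non-maximum suppression at IoU 0.5; detected boxes
  are ±3σ squares using the nominal spot scale σ = 2 px. Contiguous
  HER2-positive regions ≥ 100 px² are emitted as one `HER2_cluster` box
  and suppress any single-HER2 blob whose center they contain.
* **Assignment** — a signal belongs to the nucleus box containing its
  center; among overlapping boxes the nearest box center wins, exact ties
  go to the lower nucleus index. Signals detected twice from overlapping
  crops are deduplicated by per-class NMS before assignment.
* **Matching** (evaluation only) — greedy one-to-one matching by
  descending IoU on half-open boxes, default threshold 0.5, deterministic
  tie-breaks by index.

## Synthetic data

The simulator emulates single-filter FISH acquisition: 1600 × 1200 px RGB
scenes, dark background (5, 5, 20), nuclei as anti-aliased filled ellipses
(20, 20, 140), HER2 spots as Gaussian peaks of (230, 120, 30), CEN17 of
(40, 220, 40), σ = 2 px, additive Gaussian noise (σ = 2 on 8 bits when
clean). Default class mixture: 0.35 normal / 0.25 low / 0.20 high /
0.10 uncertain / 0.10 artifact; 8–14 nuclei per image.

Planted counts are drawn strictly inside each class's ratio interval with
margin (normal < 1.4, low in [2, 5], high singles in [7, 9] or one
cluster), and the generator *asserts* that the scoring rules recover the
intended class from the planted counts. Uncertain nuclei carry exactly one
CEN17 signal; artifacts carry none. Ellipse size scales with the planted
signal load so an 11 px minimum spot separation is always feasible.
Cluster members (4–6) are placed 3–7 px apart within 70 % of the 12 px
cluster radius — dense enough to be unresolvable into singles, spread
enough to form one contiguous accumulation.

Low quality adds Gaussian blur (σ = 2.5 px), heavier noise (σ = 12),
40 % signal attenuation and a 0.3 nucleus-overlap probability, emulating
blurred, weak and overlapping FFPE material.

What the simulator does **not** emulate: tissue autofluorescence and
texture, uneven illumination, chromatic aberration, partial/truncated
nuclei at image borders, z-stack defocus. Clean-data regression results
therefore bound the algorithmic pipeline, not performance on clinical
images; the appearance read is calibrated against the simulator's own
spot model and would need recalibration (`DetectorParams.calib_*`) for a
different acquisition setup.

Determinism: a `(config, seed)` pair fixes every byte of output. Dataset
seeds are spawned from the master seed via `numpy` seed sequences; render
noise is seeded from the scene seed.

## Agreement statistics

Evaluation pools uncertain and artifact into `unidentifiable`, giving the
four-class scale (unidentifiable, normal, low, high). Weighted Cohen's
kappa uses `κ = 1 − Σ w·O / Σ w·E`. Default weights are linear in ordinal
distance among (normal, low, high), normalized to [0, 1], with
`unidentifiable` at maximal disagreement (1) against every other class —
declaring a nucleus unscorable is qualitatively different from
mis-grading it. Because κ depends on this choice, linear, quadratic and
custom weight matrices are all first-class arguments. Light's kappa is
the mean over unordered rater pairs; a detector is compared to a team by
averaging its pairwise kappas with each member. Degenerate strata (empty,
or with undefined kappa) are reported as undefined rather than raising.

## Validation-table evaluation

The packaged fixture transcribes the 57-image validation table (ratio-1,
ratio-2, mean HER2/CEN17, both printed detector calls, three pathologist
grades). `evaluate_table3` re-derives both calls from the printed ratios,
verifies them against the printed calls (57/57 with the defaults above),
forms the consensus, and compares it with the pathologist majority:
55/57 (96.5 %) concordant-and-correct, 2 images discordant — one where
the mean ratio of exactly 1.00 makes the SD read NORMAL against an ND
read of LOW, and one where a mean of 7.00 makes the SD read HIGH against
LOW.

## Problem sizes in the test suite

Most tests run on 800 × 600 scenes with 4–7 nuclei; the end-to-end
regression uses 20 full-size (1600 × 1200) clean images, where the
classical backends achieve nucleus precision/recall ≥ 0.95 at IoU 0.5,
per-nucleus count-based class accuracy ≥ 0.95, and ≥ 19/20 image calls
equal to the planted grade. These are package regression thresholds on
synthetic data, not claims about clinical imagery.

## Known limitations

* Overlapping or touching nuclei merge into one component in the
  classical segmentation; low-quality recall degrades accordingly (no
  watershed splitting is attempted).
* The appearance read's intensity-ratio estimate loses accuracy under
  heavy attenuation (low quality), biasing it toward uncertain/artifact.
* Cluster detection keys on contiguous channel area and will read a very
  tight multi-spot group (< ~3 px spacing) as fewer singles or, above the
  area threshold, as a cluster; this mirrors the ambiguity the class was
  introduced for.
* The clinical equivocal band (HER2/CEN17 ≈ 1.8–2.2) and ASCO/CAP
  category logic are out of scope; grades here are the pipeline's
  low/normal/high vocabulary.
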