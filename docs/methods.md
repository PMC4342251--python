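# Methods

## The assay and its sampling protocol

A trial places one female and two males in a shallow rectangular tank
(water depth a few cm, so movement is effectively planar) and records
their body positions for 100 s at one sample per 5 s, endpoints
inclusive — 21 grid frames per trial. Body position is the midpoint of
head and tail when files supply head/tail pairs; files may also supply
centers directly. The grid rule is `floor(window/step) + 1` points;
both window and step are configurable (`--window`, `--step`).

Raw frames are snapped to the nearest grid point within an alignment
tolerance (0.5 s default). A grid point with no raw frame in tolerance
is flagged missing; frames where *any* of the three fish is missing are
excluded from every denominator for that trial and never interpolated.
A trial retaining fewer than 80% complete frames is rejected by default
(configurable down to 0).

## The normalized frame and the guarding circle

Each frame is transformed so that the female sits at (0, 0) and the
reference male at (1, 0). With f the vector from female to reference,
n the vector from female to focal male, and D² = ‖f‖²,

    X = (f · n) / D²,    Y = (f_x n_y − f_y n_x) / D².

This is the unique orientation-preserving similarity transform with
those two anchors; it preserves angles and distance ratios, so every
downstream quantity is invariant under global translation, rotation,
uniform scaling, and (because membership depends on Y only through Y²)
reflection of the raw coordinates. Coordinate calibration therefore
never needs to be metric, though cm are recommended.

The guarding circle is the disc of center (1/2, 0), radius 1/2;
membership simplifies to X² + Y² ≤ X. By Thales' theorem this holds
exactly when the angle at the focal male subtended by the female and
the rival is ≥ 90°. The package treats this equivalence as normative
and tests it by brute force against the raw-coordinate dot-product
sign over 10⁵ random configurations.

A formula sometimes quoted for this transform carries an extra factor
‖n‖ and a 3/2-power of D² in the denominator; that variant breaks both
the (1, 0) anchor and the obtuse-angle equivalence, so this package
implements the plain similarity transform above, which satisfies both.

Numerical choices: the circle boundary (right angle) counts as inside —
a measure-zero convention fixed for determinism; frames with the female
and reference male coincident are invalid and drop from the
denominator; exactly on the boundary the two membership routes can
round to opposite sides by one ulp, so the equivalence property is
asserted off-boundary only.

## Indices and tests

**Near/far assignment.** Within a trial, the male with the smaller mean
Euclidean distance to the female over retained frames is "near". An
exact tie breaks toward the lexicographically smaller fish id and is
flagged.

**Guarding index** = (frames with focal male in circle) / (retained
frames); with full trials it is a multiple of 1/21. In the guarding
test the focal fish is the near male and the far male is the reference;
in the dominance test each male is scored as focal with the other as
reference (no pre-selection), and per frame at most one of the two
indicators can be 1 (a triangle has at most one non-acute angle).

**Merged controls.** Three fish recorded (or simulated) in separate
tanks are superimposed into a virtual triad and analyzed identically.
Independence makes the near-male index a pure geometry/movement-
statistics quantity — the no-interaction null.

**Guarding test.** Two-sided two-sample Student (equal-variance) t-test
of index lists, df = n₁ + n₂ − 2; Welch offered as a flag. SEM is
sample SD (n − 1 denominator) / √n. Indices print to one decimal as
percentages.

**Dominance test.** Exact two-sided Mann–Whitney U by full enumeration
of all C(n₁+n₂, n₁) assignments of the pooled observed values (ties
contribute 1/2 to U, so tied data are exact); the p-value is the
doubled smaller tail, capped at 1 — at 6 sessions per male, complete
separation gives p = 2/924. Enumeration is the default up to 8 per
side; beyond that a tie-corrected normal approximation is used. The
verdict is "equal" when p > α (0.05 default), otherwise the
higher-mean male is dominant. Variants of the exact two-sided p exist
(mid-p, point-mass handling); this package fixes the doubled-tail rule
and documents it, since published dominance calls do not always state
their variant.

**Proximity bias.** Per pooled complete frame, whichever male is closer
to the female scores the frame; counts are tested against 50:50 with a
1-df chi-square goodness of fit. Exact-tie frames are excluded from the
test and reported separately. Counts are always computed from the data,
never assumed from the nominal frames-per-trial arithmetic.

**Paternity summary.** Per-dominance-class brood percentages of
marker-positive progeny, one-way ANOVA, and hand-computed Scheffé
pairwise contrasts: F_pair = (m_i − m_j)² / (MSW (1/n_i + 1/n_j))
referred to (k−1) F_{k−1, N−k}. No multiple-testing correction is
applied across classes.

## The simulator

No movement model is implied by the assay itself, so the generator is
the package's own: the simplest model whose single guarding-drive dial
spans the observed index range (~0.19–0.63 in published strain
comparisons, higher under strong asymmetry).

Each fish carries a persistent heading (correlated random walk). Per
internal step (dt = 0.5 s, dividing the 5-s grid), the new heading is
the normalized sum of

    persistence · previous heading        (2.0)
  + attract_weight · unit(female − male)  (1.0, males, interacting mode)
  + guard_drive · unit(target − male)     (3.0 default per male)
  + Gaussian noise                        (sd 1.0)

where the interposition target lies on the female→rival segment at
fraction 0.25 — between the pair, nearer the female, where a guarding
male holds station. Positions advance at constant speed (3 cm/s, a
realistic cruising speed for a ~3 cm fish in a small arena) and reflect
off the walls of a 19 × 13 cm arena, the standard tank footprint. In
independent mode all coupling weights are zeroed and each fish is
simulated in its own virtual arena from its own random substream —
statistically exactly the separate-tank recording that merged controls
superimpose. Identical config + seed reproduces output bit-for-bit;
per-trial seeds derive as base + trial index.

With these defaults the model reproduces the study's qualitative
structure: merged-control near-male indices average ~0.29 (the
independence geometry puts them in a 0.20–0.45 band), symmetric
competing guards reach ~0.51, and an asymmetric pair (drives 4.0 vs
1.0 — one committed guard, one indifferent rival, as when dominance has
been settled) averages ~0.71 for the near male. Symmetric drives
plateau near 0.51 however strong: two equally driven males keep
displacing each other, which is why the strong-guarding regime in the
validation suite is the asymmetric one.

What the simulator does *not* emulate: wall-following, burst-glide
kinematics, courtship displays, spawning, or any learned asymmetry
between sessions. Passing the validation suite therefore shows the
pipeline recovers interaction structure a minimal steering model
plants — not that real fish move like the model.

## Problem sizes in the validation suite

The property suites use 10⁵ random configurations for the membership
equivalence, 10³ triads × 10² transforms for similarity invariance,
30 seeds per condition for the index-band and monotonicity checks, and
50 replicates of 6 sessions for dominance recovery — sizes at which the
Monte-Carlo error of every checked mean is well inside the asserted
bands.

## Known limitations

- Strictly planar geometry; depth is ignored.
- The exact Mann–Whitney enumeration is O(C(n₁+n₂, n₁)) and intended
  for the small session counts of dominance protocols.
- The asymptotic rank-sum fallback (n > 8 per side) is tie-corrected
  but not exact.
- Merged controls built from *recorded* solo sessions inherit whatever
  non-stationarity those recordings contain; the permutation-style
  shuffling of fish across trials is deliberately not a default
  anywhere.
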