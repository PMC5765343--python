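# Methods

## The measurement problem

Hyperactivation of *Drosophila* sperm — the increase in flagellar beating
vigour after transfer to the female reproductive tract — is quantified
from high-speed monochrome video of sperm in Ringer's solution. The
acquisition geometry this package defaults to is a 228 × 320 px 8-bit
frame at 300 frames/s for 1000 frames, with 28 pixels spanning 10 µm
(m = 72,960 analyzed pixels per frame). Three parameters summarise a
recording: a per-point flagellar beat frequency, a per-point lateral
beat speed, and a whole-field intensity index capturing the motion of
all sperm in view at once.

## Synthetic recordings and their ground truth

No raw recordings accompany the original observations, so estimator
validation rests on a synthetic generator whose kinematics are exact.
The flagellum midline is a traveling sinusoid on a straight axis,

y(s, t) = A(s) · sin(2π f t − 2π s/λ + φ),

where s is the axial position (fraction of the length L), A(s) an
optionally linearly tapered amplitude, f the beat frequency, and λ the
spatial wavelength. This is the minimal model with a known beat
frequency; every estimator's target value is analytic (frequency f,
period-averaged lateral speed 4·A·f at fixed s). Rendering deposits a
Gaussian point-spread profile (σ = 1.5 px by default) around the
midline polyline sampled at 0.25 px steps, draws the head as a filled
disc with the same roll-off, adds i.i.d. Gaussian noise per pixel per
frame, clips to [0, 255] and quantises by rounding half up. Frame k
represents t = k/fps exactly (no exposure integration), frames are
row-major with the origin at the top-left pixel and row increasing
downward, and a (model, seed, frame index) triple renders
bit-identically. Construction rejects beat frequencies at or above the
Nyquist limit fps/2.

Default model values are chosen as a plausible single visible flagellum
at this magnification: L = 40 µm of visible flagellum, A = 5 µm,
λ = 25 µm, f = 15 Hz (the magnitude observed for sperm after transfer
to females), peak brightness 200 on a background of 30.

What the generator does **not** emulate: multiple interacting sperm,
curvature of the sperm axis, hydrodynamics, exposure blur, non-Gaussian
camera noise, or background debris. Passing recovery tests therefore
demonstrates correctness of the estimators' numerics on a known signal,
not robustness to the full variability of real recordings.

## Beat frequency (zero crossings)

The intensity trace at a measurement point — the mean of a (2r+1)²
window, one real value per frame — is smoothed with a centred moving
average (default 3 frames, to suppress 8-bit quantisation chatter),
centred by subtracting its mean (median optional), and sign changes of
consecutive samples are counted; zero-valued samples inherit the
previous sign so plateaus are not double-counted. The estimate is
crossings / (2 · duration), using the duration of the smoothed trace
(a 3-frame window trims one sample per side). A trace that is constant
after centring yields 0 Hz rather than an error. The estimate is
quantised to half a crossing count: 1/(2T) ≈ 0.15 Hz at T ≈ 3.33 s.

Default measurement points sit at five axial fractions (0.1 … 0.9) with
windows spanning laterally from the centreline to just above the local
beat crest. The flagellum then occupies the window during exactly the
upper half of each cycle, producing a near-50 %-duty intensity wave
whose mean crossings are evenly spaced; this bounds the worst-case
estimate error by one count quantum at every point. (A point placed at
the crest instead sees a short once-per-cycle pulse whose asymmetric
crossing gaps can lose one count at the window edges.)

## Beat speed (kymograph tracking)

A probe segment is fixed perpendicular to the flagellum axis; its
bilinearly interpolated intensity profile per frame forms a kymograph.
The per-frame flagellum position is the subpixel peak (parabola through
the argmax and neighbours). Frames whose peak does not exceed the
kymograph median plus three robust SDs (1.4826 · MAD) are dropped as
untracked; more than 50 % dropped raises an untrackable-input error.
Speed is the mean absolute displacement per frame interval × fps ×
(10 / px_per_10µm) µm/s. On sinusoidal input this estimates 4·A·f with
a discretisation factor sin(πf/fps)/(πf/fps) (0.4 % at 15 Hz, 300 fps);
recovery tests show < 0.5 % error across A ∈ {2, 5, 8} µm and
f ∈ {5, 15} Hz.

## Intensity index

The whole-field index is the literal formula

index = 1/(m(n−d)) Σ_{i=d+1..n} Σ_{j=1..m} |p_ji − p_j,i−d| / g × 100,

vectorised as the mean absolute lag-d frame difference (computed in
int16 to avoid uint8 wrap-around). The lag d is a free parameter of the
statistic; the default is d = 1, the finest temporal resolution at
300 frames/s, exposed as a flag because any other default would be
equally arbitrary and d = 1 maximises sensitivity. Bounds:
0 ≤ index ≤ 100·(g−1)/g, attained at identical frames and at full-frame
0/255 flicker respectively.

## Rank statistics

* **Exact Wilcoxon–Mann–Whitney.** The reported W is the first group's
  U (rank sum minus n₁(n₁+1)/2, midranks under ties) — the convention
  consistent with the published (W, n, p) triples. The tie-free null
  pmf of U is built by exact integer polynomial arithmetic (the
  generating function of U is a Gaussian binomial coefficient), capped
  at n₁·n₂ ≤ 400 before falling back to the normal approximation. The
  two-sided p doubles the smaller tail and caps at 1; this, not the
  sum-of-less-likely-outcomes rule, reproduces the published values.
  Under ties the p-value comes from complete enumeration of the
  C(N, n₁) assignments of the observed pooled values when that count is
  ≤ 2·10⁶, else seeded Monte-Carlo with 10⁵ permutations flagged
  `exact=False`. Note that a tie-affected p is data-dependent: it
  cannot be recovered from (W, n₁, n₂) alone.
* **Kruskal–Wallis** uses midranks with the tie-correction divisor
  1 − Σ(t³−t)/(N³−N); all-identical data return H = 0, p = 1.
* **Dunn's post hoc** compares mean ranks with the tie-corrected
  pooled variance; by default raw p-values are tested at α (the
  adjustment, if any, behind the published multiple comparisons is not
  documented, so none is silently applied — Bonferroni and Holm are
  explicit options).
* **Compact letter display** uses insert-and-absorb: start from one set
  containing all groups, split on each significant pair, drop absorbed
  subsets, and letter the remaining sets a, b, c … by their earliest
  group. Groups share a letter iff no comparison between them is
  significant.
* **Holm** is the sequential Bonferroni: step-down (m−k)·p with
  monotonicity enforcement. **Chi-square** is Pearson's test without
  continuity correction (delegated to scipy), df = (r−1)(c−1).

## Fertility arithmetic

Decrease between timepoints is 100·(1 − late/early); retention is its
complement. Display rounding is half-up at a caller-chosen number of
decimals with trailing-zero trimming, because published percentages mix
one-decimal and integer display; full precision is always returned.
Proportions carry Wilson score intervals by default (Clopper–Pearson
optional) — a deliberate addition, as small-n proportions without
intervals are uninterpretable. Count comparisons delegate to the exact
rank test and tier significance as ** (adjusted p < 0.01),
* (< 0.05), NS otherwise, with a Bonferroni family size supplied by the
caller.

## Problem sizes and numerical choices

Validation suites run at the default acquisition geometry (1000 frames,
228 × 320) for frequency recovery and 600 frames for speed recovery;
unit tests use a 64 × 96 px, 150-frame scaled-down geometry, which
preserves every property being checked (the estimators are local in
both space and time). Null calibration of the exact test uses 2000
replicates at n = 5 + 5; power checks use 200 replicates. Subpixel peak
interpolation falls back to the integer argmax at profile edges or on
degenerate (zero-curvature) neighbourhoods. Measurement windows and
probes must lie fully inside the frame; violations raise errors naming
the offending geometry rather than clamping silently.

## Known limitations

The zero-crossing estimator's accuracy is bounded by the count quantum
1/(2T); it assumes a single dominant oscillation at the point. The
kymograph tracker follows the brightest crossing only — multi-sperm
fields need one probe per sperm. The intensity index depends on the
unrecorded lag d, so published index values are comparable only within
one d. The synthetic sinusoid cannot validate behaviour on irregular or
aperiodic beating.
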