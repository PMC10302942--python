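# Methods

`biofoulmon` implements the computational side of an early-warning monitoring
scheme for biofouling in reverse-osmosis (RO) membrane modules. Four data
streams are analysed: time-lapse photographs of the membrane/feed-spacer
surface, light transmission through polymer optical fibers (POF) laid in the
feed channel, an organic-carbon mass balance across the module, and hydraulic
process records (permeability, feed-channel pressure drop). This note
documents the models, the defaults and their rationale, the numerical
choices, and what the bundled synthetic world does and does not establish.

## Image registration

The camera and module wobble between exposures (motor vibration, thermal
expansion), so frames must be aligned before they can be compared
pixel-by-pixel. The motion model is a **pure integer translation**: a feature
region (`TemplateROI`, chosen manually, at least 8×8 px) is cropped from the
grayscale reference frame and matched against each sensed grayscale frame by
normalized cross-correlation (NCC). The NCC score at placement (u, v) is the
Pearson correlation between the template and the same-sized image window —
computed over *valid* placements only (template fully inside the image), so
no border padding artifacts arise. Windows with zero variance have no
defined score; they are flagged NaN and excluded from the peak search. The
map is evaluated with an FFT-based matcher and agrees with the brute-force
per-window Pearson definition to better than 1e-8 (enforced by test).

The peak (ties broken row-major: smallest row, then smallest column, a
deterministic convention) gives the frame's offset. The color frame is then
cropped to `(H - Mr) × (W - Mc)` with the window anchored at
`floor(margin/2)` and shifted by the offset, so the feature region occupies
identical coordinates in every registered frame. Default margins (127, 175)
turn a 2064×3088 camera frame into a 1937×2913 registered frame. Grayscale
conversion uses the exact BT.601 luma weights 0.299/0.587/0.114 (sum 1, so
white maps to exactly 1.0).

**Bounded peak search.** `register_series` restricts the NCC peak search to
the movement room `floor(margin/2)` around the ROI. Two reasons: (i) an
offset beyond the movement room cannot be compensated by the crop anyway;
(ii) the spacer mesh is periodic (period ≈ frame_height/12), and once the
feature region itself becomes overgrown late in an experiment, a wider
search can lock onto a still-clean mesh alias one period away — we observed
exactly this failure mode on synthetic runs. Callers who want to *observe*
excessive motion (and use the abort/drop failure policy) can pass a wider
`search_room` explicitly.

## Image similarity indicator

Each registered frame is split into its R, G, B layers and each layer is
compared against the corresponding layer of the reference frame (the first
registered frame, i.e. the clean surface photographed before fouling) with
the 2-D Pearson coefficient

    r = Σ (A − Ā)(B − B̄) / sqrt(Σ (A − Ā)² · Σ (B − B̄)²).

This equals the Pearson correlation of the flattened pixel vectors; it is
invariant to affine intensity changes, so uniform illumination drift does
not move the indicator (until pixels saturate the 8-bit range — saturation
is a genuine nonlinearity and does lower r slightly). Computation is done in
double precision directly on the [0, 255] layers; the result is clamped to
[−1, 1]. A zero-variance layer yields a *missing* value with a recorded
reason rather than a numeric sentinel — a constant frame is an instrument
fault, not similarity evidence.

Biofilm shifts the near-white surface toward brown, which attenuates blue
strongest and red least; r_blue therefore falls earliest and deepest, and
the final-frame ordering r_blue ≤ r_green ≤ r_red is a standing property of
any fouling scenario.

## Process metrics

* Carbon rate (mg/h): `C˙ = TOC_Ret·V˙_Ret − TOC_Feed·V˙_Feed`. Negative
  while carbon accumulates in the module (microbial attachment), positive
  once biofilm sloughs into the retentate (detachment).
* Permeability (L m⁻² h⁻¹ bar⁻¹): `Pw = V˙_p / (A · TMP_net)`. The membrane
  area of a flat lab module is not a published constant and is a required
  input (column or argument); net TMP is taken as an input column, not
  reconstructed from osmotic pressure. Non-positive area or TMP raise; in
  the vectorized series wrapper, missing or invalid inputs propagate as NaN,
  never silent zeros.

## Onset, plateau and CIP detection

Detection is a baseline-threshold rule — the simplest defensible automation
of what a process engineer does by eye. For each signal: estimate μ and σ
from the first `baseline_window` samples (default 24, i.e. one day at the
1 h sampling rate; the pipeline wrapper converts 24 h into samples for
coarser series), after discarding everything before the conditioning cutoff
(default 96 h — fiber transmission is not trustworthy until its conditioning
decay has leveled off). An onset is the first time the signal stays beyond
μ ∓ k·σ in the stated direction for `persistence` consecutive samples
(defaults k = 3, persistence = 5). On gradually growing disturbances the
detected onset necessarily lags the physical one: the deviation must first
grow past k·σ. An optional diurnal filter (off by default) replaces the
signal by its centered 24 h rolling median, which cancels the daily
temperature cycle while preserving persistent level shifts.

Plateau detection fits a rolling least-squares slope over `window` samples
and reports the end of the first window whose |slope| ≤ `slope_tol` after a
given time (typically a detected onset): constancy is only confirmed after
observing a full quiet window.

Cleaning-in-place (CIP) evaluation scores each event as
`recovery = (post − pre) / (baseline − pre)` with medians over short
flanking windows (default 5 samples) and the series' initial level as
baseline, clamped to [0, 1]. A weaker cleaning of a more mature biofilm
recovers a smaller fraction of the accumulated loss.

## Synthetic world

No experimental dataset accompanies the method, so the package ships a
generator whose output has the statistical structure the detectors assume.
All randomness derives from one seed through named `SeedSequence` child
streams (texture, patches, jitter, image noise, POF noise, process noise):
a fixed `ScenarioConfig` reproduces output byte-for-byte, and the image and
fiber simulators share one patch history.

* **Clean scene**: low-frequency smoothed Gaussian noise (near-white
  membrane, mean ≈ 209/255) overlaid with a darker periodic diamond spacer
  mesh (period frame_height/12) — feature-rich so NCC can lock. The scene is
  larger than the frame by `jitter_max` on each side; each frame is a crop
  at a planted integer offset drawn uniformly in [−jitter_max, jitter_max]²
  (frame 0 is the clean reference at offset (0, 0)).
* **Biofilm**: circular patches nucleate at Poisson times (default 0.5/h)
  after `onset_h` (default 120 h), radii grow linearly (default 2 px/h at
  full frame size), and the per-pixel deposit density saturates as coverage
  `c = 1 − exp(−density)` — a logistic-like plateau without a hand-tuned
  cap. A CIP event multiplies accumulated density by (1 − efficacy), so
  coverage is monotone between events and drops at each event.
* **Color shift**: per-channel intensity is
  `clean · (1 − c · a_ch) · illumination(t) + noise`, with attenuations
  (R, G, B) = (0.15, 0.45, 0.75): white → brown. Illumination drifts 2% per
  100 h (multiplicative); pixel noise is 2 intensity units; both values are
  stated-world choices, no magnitudes being published.
* **POF transmission**: `(1 − A) + A·e^(−t/τ)` conditioning envelope
  (A = 0.2, τ = 24 h → limiting value reached by ≈ 96 h), a ±1% 24 h
  sinusoid (daily temperature cycle; magnitude unpublished, 1% chosen as
  "small"), and fouling attenuation `exp(−k·min(c, cap))` with k = 2 and
  cap 0.6 (an overgrown fiber stops responding). The reference fiber omits
  the fouling factor. Traces are normalized to 1 at t = 0; relative
  measurement noise 0.2%.
* **Process records** (feed 11.5 L/h, retentate 10 L/h, permeate 1.5 L/h,
  baseline TOC 1 mg/L, TMP 10 bar, area 0.01 m²): the carbon rate follows a
  two-phase template (ramp to −1.5 mg/h at onset, single sign change to
  +1.5 mg/h when detachment starts at onset + 50 h); permeability rises ~5%
  after the feed switch (pH-driven surface-charge effect) and declines 30%
  from onset + 80 h; FCP is flat (50 ± 0.5 mbar) and rises last, from
  onset + 100 h. The default phase spacing (blue/POF first, permeability
  ~80 h later, FCP ~100 h later) reproduces the canonical early-warning
  ordering with margins wide enough that detection lag cannot reorder the
  calls.

**What a green test does not establish.** The generator's biofilm is an
idealized disk process with a single color axis; real biofilms are
spatially structured, specular, and co-occur with scaling and air bubbles.
Jitter is pure translation — no rotation, scale, defocus or rolling-shutter
effects. Illumination drift is spatially uniform, so Pearson invariance
makes the similarity indicator *exactly* blind to it, which flatters the
null false-positive rate relative to a camera with spatially varying gain.
POF physics is an empirical attenuation law, not evanescent-field optics.
Passing tests establish that the algorithms are implemented correctly and
behave as designed on data with the assumed structure — not that the
defaults are calibrated to any particular plant.

## Numerical choices

* NCC undefined-window mask: integral-image window variance with a relative
  threshold of 1e-9 of the window mean square (cumsum cancellation error is
  orders of magnitude below this for genuinely textured windows).
* Pearson r and NCC scores clamped to [−1, 1]; peak ties row-major.
* Detector baseline σ uses ddof = 1; an exactly constant series has σ = 0
  and never fires (deviation must be strict).
* Degenerate inputs raise typed errors (`ConfigurationError`, `InputError`,
  `FormatError`, `FeaturelessTemplateError`, `ExcessiveMotionError`,
  `UndefinedSimilarityError`) rather than returning sentinels.
* TIFF I/O is uncompressed 8-bit RGB only; anything else is rejected, not
  converted.

## Known limitations

* Integer-pixel registration only; sub-pixel motion blurs the similarity
  indicator slightly rather than being compensated.
* The onset detector assumes an approximately stationary baseline after the
  conditioning cutoff; strong baseline trends inflate σ and delay calls.
* CIP recovery uses short flanking medians; regrowth within the flank
  window biases recovery slightly downward.
* The carbon-rate template is a stated two-phase world, not a mechanistic
  growth/detachment model; only its sign structure and timing are meant to
  be realistic.
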