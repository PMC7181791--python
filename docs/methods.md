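# Methods

`ringforce` analyses contractile force in ring-shaped engineered cardiac
microtissues that form around pairs of soft elastomeric microcantilevers
("posts") in a multiwell plate. This note records the models, numerical
choices and assumptions behind each module, and what the synthetic-data
generators do and do not emulate.

## Force transduction (beam mechanics)

Each post is modelled as a prismatic Euler–Bernoulli cantilever of length
L (mm), rectangular section w × t (mm, bending along t, so
I = w·t³/12 mm⁴) and Young's modulus E (MPa). The tissue ring applies a
point load F at height a above the base; the camera observes the top edge
of the post at height x (default: the tip, x = L). The small-deflection
solution is

    δ(x) = F · a²(3x − a) / (6 E I),   x ≥ a,

which reduces to F·a³/(3EI) when observed at the load point. With
geometry in mm, E in MPa, F in µN and δ in µm, the unit bookkeeping
collapses to a single factor of 10⁻³ (documented and tested in isolation
in `ringforce.units`).

Defaults: the ring sits just below the angled anchor tip, so
a = L − anchor_length with anchor_length = 0.5 mm and a 45° anchor angle.
The default post geometry (L = 3 mm, w = t = 0.6 mm, E = 1.5 MPa) is a
**synthetic placeholder** for a soft PDMS post — plate manufacturers do
not publish these dimensions, so quantitative force numbers should come
from a user-supplied geometry or, preferably, an empirical calibration.

The closed form deliberately ignores the tapered anchor tip and any
viscoelasticity; those effects are absorbed by the empirical
force–displacement calibration measured with a micro-force transducer.
`fit_calibration` fits either a line through the origin (single stiffness
k in µN/µm; the small-deflection regime) or a full cubic, requires
strictly increasing displacements, and rejects fits that are not monotone
non-decreasing over the sampled range. `force_from_deflection` evaluates
the fitted map; queries beyond twice the calibrated range emit an
`ExtrapolationWarning` rather than failing, because screening wells
occasionally exceed the calibrated span and the user should decide.

Verification: the closed form is checked against an independent two-pass
trapezoidal integration of the curvature equation v'' = M/(EI) over a
36-point grid of lengths, moduli and load heights (max relative error
observed ≈ 4·10⁻⁸).

## Imaging pipeline

Coordinates are 0-based, origin top-left, row = y, col = x, bounding
boxes half-open; this convention is stated once and used everywhere.

* **Post detection** — posts are darker than the bright-field background
  (a flag inverts polarity). Global Otsu threshold → connected
  components → filters: area ≥ 20 px, area ≤ 25% of the frame, and
  height/width ≥ 1.5 (posts are vertically elongated). Candidates sort
  by centroid x; with two expected posts the outermost pair is labelled
  left/right. Failure raises an error carrying the candidates found.
* **Autofocus** — a pure scoring function (variance of the discrete
  Laplacian); the argmax over a provided focal stack picks the sharpest
  slice. No hardware control is modelled.
* **Kymograph** — row t of the kymograph is one fixed pixel row of frame
  t; the default scanline is the centre row of the ROI. Videos are
  multi-page TIFFs with an `fps` / `pixel_size_um` JSON sidecar.

## Edge tracking and contraction metrics

Per kymograph row the tracker finds the first crossing of the half-range
intensity threshold scanning from the post side and interpolates linearly
between the two straddling pixels (sub-pixel output). Continuity is
enforced by restricting the search to ±15 px (configurable) around the
previous row's edge. Rows without a crossing inherit the previous
position; if more than 5% of rows lack one, tracking fails loudly with
the affected rows listed.

**Baseline.** The diastolic reference is the centred rolling
10th-percentile of the position trace over a 2 s window. Displacement is
computed against this *time-varying* floor (so slow drift of the resting
position — thermal stage drift, tissue remodelling — does not bias
per-beat amplitudes), while the median across windows is reported as the
scalar `baseline_px`. A trace must be at least 2 s long. The 10th
percentile assumes the tissue spends ≥ 10% of each beat period at or near
diastole, which holds up to ~120 bpm with the default waveform timings.

**Beats and metrics.** Peaks are scipy local maxima with prominence
≥ 1 µm and spacing ≥ 0.25 s (both configurable); onset/end are the
nearest samples at 10% of the peak amplitude flanking each peak. Per
tissue:

* beats per minute = 60 / median inter-peak interval (robust to partial
  beats at the video boundaries; < 2 beats reports 0),
* contraction amplitude = median per-beat peak displacement above
  baseline (median guards against a single aberrant beat),
* contraction / relaxation velocity = median across beats of the maximal
  central-difference slope on the rise / fall phase,
* force = the calibration map applied to the amplitude, when a
  calibration is supplied.

Sign convention: motion toward the well centre (contraction) is
positive. All steps are deterministic: identical inputs give
bit-identical metrics.

`compare_automated_manual` reports Pearson r, the least-squares line and
residuals between automated and user-supplied manual amplitude readings;
it is an interface for external manual measurements, not a second
tracker.

## Experiment design (face-centred CCD + RSM)

`generate_ccd` builds three-level face-centred central composite designs:
2^k factorial corners × r_f, 2k axial points at ±1 × r_a, centre × r_c,
in a deterministic order (factorial, axial, centre; lexicographic within
block). The standard three-factor tissue-formulation design uses
cardiomyocyte fraction 50/70/90%, collagen 1.8/2.0/2.2 mg/mL and
40k/70k/100k total cells; with r_f = r_a = 4, r_c = 8 it has 64 runs, and
unreplicated it has the 15 distinct conditions.

`fit_quadratic` fits the full quadratic model in coded units by OLS
(statsmodels). The per-term ANOVA uses partial (Type III) single-df sums
of squares, F = t² against the residual mean square — for this balanced,
sign-symmetric design partial and sequential SS coincide for the
standard ordering. Conventions: constant responses give R² = 0 (zero
total SS); zero residual variance yields NaN F/p (no valid test); rank
deficiency raises an error naming the aliased terms.

`predict_optimum` maximises (or minimises) the fitted quadratic over the
coded box [−1, 1]^k: the interior stationary point is used when it lies
in the box with the right curvature, and a 3^k lattice of multistart
points polished by bound-constrained L-BFGS-B handles boundary optima.
Against a 51³ brute-force grid on 100 random surfaces the shortfall is
at machine precision. Reported settings are clipped to the box and
decoded to natural units; rounding for bench practicality is left to the
user.

## Drug-screen statistics

Effects are the relative change in contraction amplitude versus vehicle:
each dose group's centre within an experiment is normalised to that
experiment's vehicle centre, and per-experiment relative changes are then
aggregated across experiments. The aggregation order (normalise first,
aggregate second) is an assumption — source tables rarely state it — and
matches the "independent experiments, each with replicates" structure.
The centre statistic is a config enum: mean ± SD (default) or
median ± MAD (unscaled). Pairwise tests are two-sided Mann–Whitney U
(dose wells vs pooled vehicle wells): exact enumeration when both
samples are ≤ 8 and tie-free, otherwise the normal approximation with
tie and continuity corrections. p-values are unadjusted by default, with
an optional clearly-labelled Holm column.

`seeding_plan` emits the robotic dispense schedule: wells in plate
row-major order, batches of 16 by default (96 wells → 6 batches), four
2.5 µL droplets per well cycling north/east/south/west. Plans always
partition the well set.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (spec, seed) and return
machine-readable ground truth.

* **Waveforms** — periodic pulses with a fast linear (or cosine) rise
  over 0.15 s and slower fall over 0.3 s, optional Gaussian noise, linear
  drift and the analytic per-beat slopes in the truth record. Defaults
  (60 bpm, 10 µm amplitude) sit in the range typical of these tissues.
* **Scenes** — two dark vertical posts (intensity 600) in a bright well
  (3000, 16-bit scale), the tracked post's inner edge displaced per frame
  with area-weighted sub-pixel anti-aliasing, plus a Gaussian optical
  blur (σ = 0.8 px) because real bright-field optics band-limit the edge
  — a strictly one-pixel step would make mid-level interpolation
  systematically biased by up to ~0.09 px. Videos default to 20 s at 100
  frames/s, 0.2 µm/px. A fast path renders the centre-row kymograph
  directly; it equals the video route because the scene is vertically
  uniform across the posts.
* **CCD responses** — y = Xβ + N(0, σ²) on any generated design. The
  preset β has a dominant positive cardiomyocyte-fraction effect and a
  concave collagen effect, and its generating surface peaks at 90% CM,
  2.03 mg/mL collagen and 75,400 cells — the published optimal
  formulation — at a maximal deflection of ~8 µm.
* **Dose–response tables** — Hill scaling of a 10 µm vehicle amplitude
  over the standard five-dose panel (1 nM…10 µM), with presets for a
  myosin-inhibitor-like and calcium-blocker-like negative inotrope and a
  beta-agonist-like positive inotrope that saturates near 1 µM.

Not emulated: optical point-spread beyond a 1-D Gaussian, illumination
gradients, tissue out-of-plane motion, beat-to-beat amplitude
variability, inter-well biological variance, and any tissue mechanics —
so passing recovery tests demonstrates the correctness of the image
analysis and statistics, not robustness to every real-world artefact.

## Problem sizes used in validation

The validation suite uses 20 s / 100 fps videos (2000 frames, 220×60 px)
over a 12-point grid of rates (30–120 bpm) and amplitudes (2–10 µm) at
zero and 5%-of-range pixel noise; 500 seeded replicates for
coefficient-recovery coverage (observed ≈ 99.7% within 3 SE); 100 random
surfaces against a 51³ grid for the optimiser; and exhaustive
enumeration of all tie-free Mann–Whitney cases with n₁, n₂ ≤ 6. These
sizes give stable statistics while keeping the whole suite fast enough
to run routinely.

## Known limitations

* Small-deflection, prismatic beam theory only; large deflections and
  anchor compliance must go through the empirical calibration.
* The tracker assumes one monotone intensity edge per scanline within
  the search window; gross occlusions (debris crossing the ROI) surface
  as tracking errors rather than being inpainted.
* The per-term ANOVA covers single-df terms of the quadratic model only;
  lack-of-fit decomposition against pure error is not implemented.
* Relative-change summaries pool vehicle wells across experiments for
  the U test while normalising centres per experiment; with strong
  between-experiment shifts the test is conservative.
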