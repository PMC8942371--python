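# Methods

This note documents the models, numerical choices, and limitations behind
`edgeforce`. Units are µm, s, Pa throughout; frames are 0-based, sectors and
depth windows 1-based.

## Synthetic data model

The generator (`edgeforce.synthdata`) emulates a single migrating cell on a
soft substrate, observed per edge sector. It is the package's ground-truth
source: every downstream stage is validated by parameter recovery against
it.

**Edge kinematics.** Each sector executes an alternating schedule of
protrusion and retraction events separated by quiescent gaps. An event is a
half-cosine displacement ramp of amplitude A (uniform 1.5–4 µm, signed by
type) and duration D (uniform 90–240 s): d(t) = A/2·(1 − cos π(t−t₀)/D).
The velocity of this ramp is maximal exactly at the event midpoint, so the
Vmax anchor has a closed form (t₀ + D/2), which the detector tests exploit.
Scheduled onsets are snapped to the frame grid and durations to an even
number of frames so that onset and Vmax both fall on sampled frames; the
scheduled anchors are then exactly observable and recovery errors measure
the analysis, not the sampling. Gaps are uniform 20–60 s — short enough
that a 40-min movie carries ~10 events per sector, long enough that
neighbouring events' signal bumps do not merge.

**Signals.** Rac1 is a baseline plus Gaussian bumps (σ = 15 s): a positive
bump 40 s before each protrusion onset, a negative bump at protrusion Vmax,
and a positive bump at retraction Vmax. RhoA mirrors Rac1 advanced by 25 s
(the midpoint of the 20–30 s range under study) with the Vmax bumps
sign-inverted. Traction is a baseline (100 Pa) plus a coupling
(30 Pa per Rac1 unit) applied to the Rac1 signal delayed by 40 s, with a
quiescent-baseline pre-history so the shift is exact in the sampled series.
An optional RhoA→force coupling exists but is off by default: the analysis
should discover the RhoA–force anticorrelation through the Rac1 chain, not
have it injected twice. Signals attenuate with window depth as
exp(−(d−1)/3), so the depth-2 analysis windows carry near-full amplitude.
Default noise SDs are 1.0 (equal to the bump amplitude) for Rac1/RhoA and
10 Pa for traction — per-window SNR of 1, recovered by averaging ~500
events. Two seeds separate the event schedule ("biology") from measurement
noise.

**Bead images.** Beads are 2D Gaussian spots (σ = 1.5 px, amplitude jitter
±30%) at 0.8 beads/µm² — a dense TFM prep at 0.2 µm/px. The deformed image
moves each bead by the displacement field interpolated at its position; the
field comes from the same Fourier-space elastic forward model the inverse
uses, making forward→inverse a genuine round-trip contract. No
photobleaching or optics beyond the Gaussian spot.

**Cell movies.** A star-convex cell: radius per angular sector follows the
scheduled displacement, rendered into mTFP1 (constant interior intensity)
and FRET (interior intensity × Rac1) channels so the channel ratio encodes
the true signal. Useful for validating segmentation → windowing → detection
end-to-end; not a realistic optical model.

**Perturbation scenarios.** Each sector carries one event; activation times
target t_act = onset + t̄_Vmax + offset, where t̄_Vmax is the mean
time-to-Vmax of the generated control population (as an experimenter would
calibrate it) and offsets are −10/−15/−20/−25 s. The injected effect is an
additive edge-velocity change that ramps linearly over 20 s to its plateau
(default +0.02 µm/s): photoactivation acts with finite kinetics. The ramp
matters — an instantaneous step changes only the height of the mean
velocity curve, while a finite rise also shifts its extremum, which is the
behaviour the offset-group predictions (later/higher protrusion Vmax,
earlier/shallower retraction Vmax) describe. An optional traction step
supports the traction-change analyses.

## Traction force microscopy

**PIV.** 32-px interrogation windows on an 8-px node grid. Per node the
mean-subtracted windows are cross-correlated by zero-padded FFT with
overlap-area normalization — circular correlation of aperiodic windows is
biased toward zero lag by a triangular envelope (a ~20% shift
underestimation at these correlation-peak widths), and dividing by the
overlap removes it. The integer peak (search radius window/4) is refined by
Gaussian log-parabolic interpolation (exact for Gaussian peaks, parabolic
fallback). A second predictor–corrector pass un-warps the deformed image by
the first-pass field and re-correlates, suppressing displacement-gradient
bias inside windows. Flat windows are flagged invalid; the normalized-median
outlier test replaces outliers with the local median and flags them; gaps
are filled by linear interpolation with nearest-neighbour fallback. On
rendered bead pairs the estimator reaches ~0.05 px RMS for rigid shifts and
stays below 0.1 px for smooth fields with peak displacements ≲1.5 px.

**FTTC.** Boussinesq half-space kernel with ν = 0.5 (incompressible
polyacrylamide convention; exposed as a parameter). The inverse solves the
2×2 Tikhonov normal equations per wavevector; the DC mode is zeroed (no net
force). Because the inverse operator grows like |k|, PIV noise at the node
Nyquist dominates unregularized reconstructions; the pipeline therefore
band-limits the node field with a Gaussian of σ = 1.2 nodes before
inversion and uses λ = 1×10⁻⁴ µm/Pa by default, chosen on the synthetic
dipole fixture where the error curve is flat over λ ∈ [0, 2×10⁻⁴]
(an L-curve-corner choice). The FFT assumes periodicity, so the outer ring
of nodes (about one interrogation window) is unreliable; round-trip
accuracy statements exclude that margin. On the σ = 8 µm, 400 Pa dipole at
E = 6.9 kPa the full pipeline recovers traction with ~8% relative RMS
error.

## Windowing

Segmentation is a per-frame Otsu threshold on the biosensor channel,
largest connected component, hole filling, and closing (disk radius 2).
Contours come from marching squares, smoothed along their length with a
periodic Gaussian (σ = 2 px of arc) — the raw staircase overestimates
perimeter by ~5% — and resampled at uniform 0.5-px arc spacing. The sector
count S = round(perimeter/width) is fixed on the first frame; each later
frame re-anchors the equal-arc partition at the contour point nearest the
previous frame's first-sector centre, so sectors follow the same edge
region for smoothly moving contours (no merges or splits; strongly concave
shapes where normals cross are handled best-effort by the nearest-contour
assignment). Depth windows are 1-µm bands of the inward Euclidean distance.

Edge velocity per sector is the mean signed distance from the previous
frame's contour points to the current contour polygon (positive = old edge
point now interior = protrusion), divided by the frame interval;
displacement is the cumulative sum, so velocity integrates back to
displacement exactly. Binary-mask quantization limits the per-step edge
position to a few hundredths of a pixel; on disk phantoms growing
0.5 px/frame the recovered mean velocity is accurate to ~3–5%. Window means
ignore undefined pixels and report a window missing when fewer than 25% of
its pixels are defined. Migration speed is the mean step length of the
smoothing-spline-smoothed centroid path, in µm/hour.

## Event analysis

Temporal smoothing is a cubic smoothing spline with the csaps-style
parameter p ∈ (0, 1]: internally the penalty weight is (1−p)/p on the
sample-time mesh, so p = 1 interpolates and p → 0 tends to the
least-squares line; straight-line signals are reproduced exactly for any p.
The default p = 0.5 at 10-s sampling is reported in run metadata; it is a
mesh-dependent quantity.

Phases are maximal strictly monotone runs of the (smoothed) displacement —
flat stretches separate phases and belong to none; series boundaries
delimit phases so single-event series are detectable. Rising runs are
protrusions, falling runs retractions; Vmax is the frame of maximal speed
within the phase, with numerical ties broken toward the earliest frame.
Filters use ≥ semantics: distance ≥ 1 µm and duration ≥ 60 s are retained.
z-normalization is per window over its full series; zero-spread windows are
excluded from ensembles. Alignment extracts a (depth × relative time) slab
per event around the chosen anchor (default −120…+120 s), with NaN beyond
the movie boundary rather than dropping truncated events; analyses default
to depth 2 (1–2 µm from the edge). Bootstrap CIs resample events, not time
points (percentile method, 1000 resamples, 95%). With n = 100 Gaussian
events the percentile interval's true coverage is ≈94%, the expected
small-sample behaviour of the method.

The depth-5 temporal-alignment QC compares each frame's traction profile
along the edge with the previous frame's: frames that duplicate the
previous profile exactly, or whose correlation falls below 0.5 while both
profiles have spread above half the stack's median (quiescent stretches
carry no ordering information), are flagged. It is report-only; no frames
are dropped, since the appropriate corrective action is data-dependent.

## Cross-correlation

Correlations are Pearson, computed per event over the overlapping segment
at each lag (pairwise deletion of missing samples, minimum overlap 4
points), then averaged across events — preserving n per lag for inference —
rather than correlating grand-mean curves; both conventions are exposed via
the event-set construction. Convention: corr(lag) pairs x(t) with
y(t + lag), so a positive peak lag means y follows x. Peak lags break ties
toward the smallest |lag|. Absolute correlation amplitudes depend on the
noise level and are not interpreted; lag locations and signs are.

## Perturbation statistics

Controls are unperturbed events aligned at onset; the mean time from onset
to Vmax calibrates the offset grouping. An event joins offset group Δ when
t_act − (onset + t̄_Vmax) is within 2.5 s of Δ (half the 5-s perturbation
frame interval); ungrouped events are dropped. DID curves are the
onset-aligned group mean minus the control mean, for velocity or for
distance (the running integral of velocity from onset).

Cell-wise traction change is the per-cell ratio of mean traction in the
activation region 3–4 min after activation to 0–1 min before, with a paired
t test. Window-wise change compares the traction change over a 2-min
horizon in depth-2 windows of sectors whose event began within 20 s before
activation against phase-matched windows of events that completed before
activation, with a two-sample t test.

The resampling FDR handles the large control/perturbed imbalance: per
iteration the control pool is subsampled without replacement to the
perturbed size; per time point a two-sample Welch t test compares the
within-group absolute deviations (each series about its own group mean)
against the pooled absolute deviations (all series about the grand mean) —
a spread-versus-pooled-spread statistic that responds to mean shifts
between the groups. A label-shuffled regrouping of the same data yields a
matched null P value. A Levene-type alternative (group deviations about the
pooled mean, tested against each other) is available behind a strategy
switch but has no power against pure symmetric mean shifts, which is why it
is not the default. Storey q-values (smoother π₀) are computed over all
grouped and all randomized P values; the significance threshold is the
0.1th percentile of the randomized q-values (a fixed cutoff is available as
an option), and a group is significant when its mean q-value falls below
it. On Gaussian nulls the procedure's false-significance rate is ~0 over
100 seeded replicates, and a 3-SD mean shift is detected in all of them.

## Problem sizes and determinism

Recovery analyses use ~500 detected protrusion events (90 sectors × 250
frames at 10 s), perturbation scenarios 200 control + 4×60 perturbed events
at 5 s, FDR calibration 100 replicates at 1000 iterations, and bootstrap
calibration 1000 replicates of 100 series — sizes at which the Monte Carlo
error is well inside each check's tolerance. All randomness flows through
explicit seeds (numpy Generator); identical configuration and seed
reproduce outputs bit-for-bit, and run directories archive the resolved
configuration, seeds, and input hashes.

## Limitations

Synthetic movies are star-convex with idealized noise; passing tests
demonstrate correctness of the analysis chain, not robustness to real
imaging artifacts (uneven illumination, biosensor bleaching, segmentation
failure modes on textured cytoplasm). The TFM stack assumes an infinite
elastic half space (no finite-thickness correction) and 2D in-plane
displacements. Sector correspondence assumes smooth contour motion between
frames; topological events (fusion, fragmentation) are out of scope. The
survivor bias that event filters impose on perturbed retraction populations
(weak events pushed under the distance/duration thresholds by the
perturbation itself) is inherent to the filter-then-compare design and is
why group extremum heights are read from the difference curves, not from
filtered group means alone.
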