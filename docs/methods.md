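# Methods

This note documents the models, algorithms and numerical choices behind
`tubulekit`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the design was genuinely open.

## 1. Dynamic-instability model

A microtubule end is modelled as a three-state continuous-time Markov
chain over {growth, shrink, pause} with five transition rates
(per minute):

| rate | transition | meaning |
|------|------------|---------|
| `f_cat` | growth → shrink | catastrophe |
| `f_res` | shrink → growth | rescue |
| `f_gp`  | growth → pause  | pause entry |
| `f_pg`  | pause → growth  | pause exit into growth |
| `f_ps`  | pause → shrink  | pause exit into shrinkage |

Within a phase the end moves at a constant velocity: `+v_g` (growth),
`-v_s` (shrink), `0` (pause), all in um/min.  Phase durations are
exponential, which is the minimal generative model consistent with
event-frequency analyses of TIRF kymographs; real catastrophe timing is
known to show age-dependence (gamma-like waiting times) that this chain
does not capture.  There is no direct shrink → pause transition: a
"pause interrupted by small catastrophes" behaviour is reproduced by
cycling pause → shrink → (zero-speed growth), keeping the five rates
identifiable.

The seed is an absorbing floor at `x = 0`: a shrinking end that reaches
the seed instantly resumes growth, reflecting regrowth from the stable
GMPCPP template.  In the junction experiment the floor sits at the
junction position instead, and a shrink phase reaching it converts to
growth with probability `p_rescue_at_junction`, otherwise the trajectory
terminates.

Simulation is event-driven (exact, Gillespie-style): waiting times are
drawn from the state's total exit rate, the branch from the relative
rates, and the piecewise-linear trajectory plus the exact phase segments
are recorded as ground truth.  Truth segments are labelled by realised
slope sign, so a zero-speed "growth" state is recorded as a pause.  All
randomness flows through one seeded `numpy` generator per call; the same
seed reproduces a trace bit for bit.

The stationary phase occupancy used in the occupancy tests is computed
independently by solving `pi Q = 0` for the generator matrix.

## 2. Kymograph rendering and end extraction

Rendering follows the TIRF geometry: rows are frames (2 s default),
columns are space (0.107 um/px default, typical for a 100x/sCMOS setup).
Pixels covered by the lattice — between the minus and plus end positions,
plus a 1.5-um seed span — receive expected value `signal`, the rest
`background`, with coverage-weighted partial pixels at the ends so the
above-background mass per row equals the lattice extent exactly.  Rows
are convolved with a Gaussian PSF (sigma 1.2 px default) and each pixel
receives an independent Poisson draw.  The default photon levels
(signal 170, background 40 counts) give `SNR = (S - B)/sqrt(S) ≈ 10`.

Extraction runs per frame: the plateau is estimated from the central
seed columns (always lit, away from the blurred seed edges) and the
background from a global 5% quantile — per-row background quantiles fail
on frames where the lattice fills most of the row.  The end is the
outermost crossing of `background + 0.5 * (plateau - background)`,
interpolated linearly between pixel centres.  Because the blurred edge
profile is symmetric about the true edge, the half-maximum crossing is
unbiased; measured round-trip accuracy is ~0.015 px RMS without noise
and ~0.25 px RMS at SNR 10.  Frames with no crossing yield NaN; gaps of
at most 3 frames are bridged by linear interpolation, longer gaps split
the trace.

## 3. Trace segmentation

The segmenter partitions a sampled trace into linear phases and
classifies each by the strict pause criterion: a segment is a pause when
its |velocity| is **strictly less than** 0.24 um/min at the plus end
(0.12 at the minus end); ties go to growth or shrinkage by sign.

Two breakpoint searches are provided:

- **Penalized exact search (default).**  Minimise
  `sum(RSS of per-segment line fits) + beta * (#segments)` over all
  shared-endpoint segmentations by an O(n^2) dynamic program.  The
  penalty defaults to `2 * sigma^2 * ln(n)` with `sigma` estimated
  robustly from second differences (MAD), with a tiny floor so that
  noise-free piecewise-linear traces return the minimal segmentation.
  The factor 2 was calibrated on simulated traces so that pauses of
  >= 15 s are detected essentially completely at SNR-10 extraction noise
  while pure-noise breakpoints remain rare; detection below that
  duration is handled statistically (section 4).
- **Recursive splitting.**  Top-down splitting at the interior point of
  maximum deviation until every segment's residual is below
  `residual_tol` (default two pixels).  Kept as a simple alternative; it
  misses short events near its tolerance and is not used by the
  recovery benchmarks.

Both searches share the post-processing: least-squares slopes per
segment (interior-trimmed for segments of >= 4 samples, because the
shared boundary samples straddle transitions and bias slopes toward
zero), greedy merging of same-class neighbours, and absorption of
unsupported segments (pauses shorter than `min_segment_frames`; growth
or shrink excursions smaller than `min_event_length = 0.2` um, which is
what suppresses noise-induced events).  Each boundary is then refined to
the intersection of the adjacent fitted lines, which recovers transition
times to well under one frame and makes event durations and amplitudes
nearly unbiased.  Finally each segment is re-classified using only the
samples strictly inside its refined boundaries (pure-phase samples) and
the merge/absorb pass is repeated to a fixed point.

## 4. Dynamics estimation

Per microtubule: `v_g`/`v_s` are unweighted means of per-event fitted
slopes (events shorter than `min_speed_event_duration`, default 6 s in
the pipeline, are excluded from the speed means only — their slopes mix
adjacent phases); `f_cat` = transitions into shrinkage / total growth
time; `f_res` = transitions out of shrinkage (into growth *or* pause) /
total shrinkage time; `f_pause` = pause count / total (growth + pause)
time.  The pause denominator is a package decision — pauses interrupt
growth, so shrink time is excluded — recorded in output metadata.
Undefined ratios (events over zero exposure) are flagged rather than
silently zeroed.

Two optional, default-off refinements make the pooled estimators
unbiased under realistic sampling:

- **Seed exclusion** (`seed_exclusion_um`).  In seeded assays, regrowth
  at the seed is templated nucleation, not a lattice rescue.  Rescues at
  positions below the cutoff are discarded *and* the matching shrink
  exposure time below the cutoff is removed from the denominator, which
  is the standard censored-exposure construction and keeps `f_res`
  unbiased.
- **Detection-limit (left-truncation) corrections** in the pooled
  estimator.  Three classes of events escape a 2-s / 0.107-um sampling:
  pauses shorter than ~15 s, shrink excursions smaller than ~0.4 um,
  and shrink–growth–shrink triples whose middle growth is shorter than
  ~4 s (which merge two catastrophes into one).  Each class is corrected
  with the exponential left-truncation MLE: observed sizes above the
  floor estimate the scale `tau = mean(v - v_min)`, the undetected
  fraction is `1 - exp(-v_min/tau)`, and the expected time hidden in the
  wrong phase (e.g. undetected pause time inside growth segments) is
  moved between denominators.  The floors are detectability limits
  measured on simulations, not free parameters; they are only valid
  while event sizes are exponential, which holds for the Markov model
  and approximately for real dynamics.

Pooled values are totals-over-totals across microtubules; standard
errors come from a bootstrap over microtubules (200 resamples).

With these settings the full pipeline (simulate → render at SNR 10 →
extract → segment → estimate; 500 30-min movies) recovers all five
generating parameters within ~2% and within 3 Monte-Carlo SE; the
remaining percent-level deficits are residual event-detection losses,
not systematic definition mismatches.

## 5. Dilution and junction classification

Post-dilution traces are classified with explicit numeric stand-ins for
the qualitative population descriptions: **persistent pause** (no shrink
segment and total loss < 0.5 um in the window), **slow
depolymerisation** (shrinkage occupies >= 90% of the window), otherwise
**pause with catastrophes**, with precedence in that order.  The window
defaults to the full 30-min post-dilution movie.  These thresholds are
package choices; the three simulator regimes are classified with 100%
accuracy at 200 traces each, so the result is insensitive to moderate
threshold changes.

Rescue positions in the junction assay are compared against the known
junction position with tolerance `delta = 0.2 um` (about two pixels);
rescues within the tolerance count "at the junction", farther ones
"beyond".

## 6. B-tubule curvature

Traces are registered by the rigid transform (rotation + translation,
no reflection — tomographic slices keep handedness) that maps the outer
junction X to the origin and the A-tubule centre O onto the negative
x-axis, so all B-tubules extend into x > 0 from a common anchor.  The
transform is closed-form from the O–X direction; registration is
idempotent and distance-preserving to 1e-9.

Curvature per trace: circumradii of consecutive point triplets
(collinear triplets flagged non-finite and excluded).  The reported
`triplet_mean` radius is the **inverse of the mean curvature** (harmonic
mean of finite circumradii).  This matters: with ~10 points and 0.3 nm
jitter on a 13.5 nm arc, near-collinear triplets make raw circumradii
heavy-tailed and their arithmetic mean inconsistent (tens of nm),
whereas curvatures average stably — the harmonic mean recovers the
generating radius to ~0.3% and agrees exactly with the circumradius on
perfect circles.  A direct algebraic (Kasa) circle fit is provided as
the alternative estimator; the two agree on clean data and bracket each
other under jitter.  No smoothing or resampling is applied before
curvature.

The in-vivo comparison radius uses the two-circle method on a transverse
ring slice: circles are fitted to the external and internal wall
surfaces (half-maximum crossings along radial rays from the intensity
centroid) and averaged.  Blur shifts both surface estimates
symmetrically, so the mid-wall average is robust to the slice's point
spread.

Group comparison reports mean ± SD of per-trace mean radii, group sizes
and the percent change; raw values are exported so significance testing
can be done with standard statistics tooling, which is deliberately out
of scope here.

## 7. Ciliary profiles

Profiles are extracted along a traced polyline at one-pixel arclength
spacing, averaging bilinear samples across a perpendicular width of
0.17 um.  Normalisation maps arclength to a 0–100% scale (101 bins by
default) and each channel to percent of its own maximum — no minimum
subtraction, since the quantity of interest is percent of maximum
fluorescence and background is assumed pre-subtracted (a
`subtract-min` style correction can be applied upstream).  Ensembles are
summarised per bin as mean ± SEM with the sample SD (n−1).  The
proximal end is by convention the first polyline point; identification
is the caller's responsibility.  The enrichment index is the proximal /
distal mean intensity ratio split at 50% length; it is invariant to the
max normalisation, which makes it robust to the normalisation bias that
per-profile maxima introduce under multiplicative noise.

## 8. Synthetic data: what it does and does not emulate

The generators cover every input the analysis consumes: stochastic end
traces (plus dilution and junction modes), Poisson/PSF kymographs,
jittered circular-arc tubule traces with known radius and posed O/X
landmarks (O placed on the concave side at the 13.5 nm A-tubule radius;
arcs default to 270°, roughly the span of a 10-protofilament incomplete
tubule), annular density slices of known mid-wall radius, and
two-channel proximally-enriched profiles (hard step by default, logistic
optional, per-sample multiplicative noise).

They do **not** emulate: age-dependent catastrophe statistics, uneven
illumination or camera fixed-pattern noise, kymograph curvature from
drifting microtubules, 3-D tilt of tomographic slices (foreshortening),
out-of-focus cilia or cross-channel bleed-through.  Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated noise models, not robustness to every experimental artefact.

## 9. Problem sizes and numerical notes

The benchmark sizes (500 rendered movies for parameter recovery, 200
traces per dilution regime, 200 arcs per jitter study, 100 profiles per
ensemble) were chosen so Monte-Carlo standard errors are small enough to
resolve percent-level biases while a full run of the suite plus the
reproduction script stays in the minutes range on a single core.
Line-fit statistics use globally centred coordinates to avoid
cancellation; the DP enforces segments of at least two samples;
registration refuses |O − X| below 1e-9 nm; circle fits reject collinear
input rather than returning unstable radii.
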