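# Methods

## Posture model

A swimming fish is reduced, per frame, to four points A, B, C, D placed at
arc-length fractions 0, 1/3, 2/3 and 1 of the dorsal midline (A = head,
D = end of the caudal peduncle). The three chords AB, BC, CD approximate
head, trunk and tail, and body curvature is summarized by three signed
turning angles: β between AB and BC (head-trunk), γ between BC and CD
(trunk-tail), and α between AB and CD (head-tail). The sign convention is
counterclockwise-positive in image coordinates with y pointing down; only
magnitudes enter the summary statistics, so the convention matters only for
reading raw traces. The tail-beat amplitude is the perpendicular distance
from D to the infinite line through A and B; note that because the head
segment itself yaws during a beat, the peak of this quantity is larger than
the lateral excursion of the tail relative to the swimming axis.

## Segmentation

Frames are contrast-stretched so the 1st/99th intensity percentiles map to
0/255 (a monotone mapping that saturates faint structures such as fins
toward the background; a constant frame maps to all zeros), then smoothed
with a Gaussian of σ = 1.5 px. Smoothing suppresses sensor noise at the
cost of exact silhouette boundaries; with σ = 0 and full-range stretch the
Otsu partition of a noiseless synthetic frame reproduces the rendered fish
pixel set exactly, which is how the segmentation is validated.

A static background (median of the first 25 frames) provides motion-based
clipping: the bounding box of pixels differing from the background by more
than 10 intensity levels, dilated by 10 px, restricts all further work; if
less than 10⁻⁴ of the region changed, the full region of interest is used.
All of these values are configuration-exposed; they are conservative
defaults, not measured constants.

Binarization uses Otsu's criterion over the 256-bin histogram, implemented
directly so the tie-break is pinned (smallest maximizing threshold) and
testable against an exhaustive scan. The fish is assumed darker than the
background (silhouette imaging); polarity is configurable. The fish blob is
chosen among 8-connected components by area fraction of the ROI
([0.002, 0.25]), elongation (≥ 2.5) and solidity ([0.3, 0.95]); an adult
fish silhouette is elongated, and while bending it is non-convex, which the
solidity ceiling exploits to reject convex clutter. Ties go to the larger
area, then greater elongation, then smaller bounding-box x.

## Midline

The blob is thinned with the Zhang-Suen two-subiteration parallel
algorithm (8-connectivity), iterated to convergence; the output is always a
subset of the blob, which doubles as a per-frame validity check. The
skeleton pixels form a graph with step weights 1 and √2; the dorsal line is
the longest geodesic between degree-1 endpoints, which prunes fin spurs
deterministically. A skeleton with no endpoint (a closed loop) invalidates
the frame; a disconnected skeleton falls back to its largest component.

Head/tail assignment uses body thickness: the endpoint whose first 10% of
arc length has the larger mean distance-transform value is the head (fish
heads are thicker than caudal peduncles). An exact tie falls back to a
configured swimming direction (fish hold station facing upstream in a
tunnel, so the heading is known).

Two refinements are applied before measuring: the staircase pixel path is
smoothed with a 9-point moving average (digital 8-connected paths overstate
arc length by up to ~8%, which would shift the equidistributed points), and
each end is extended along its local tangent by the blob's
distance-transform value there, because thinning stops roughly one local
half-width short of the true body ends. Without the extension the missing
~6 px at the head tilts segment AB and biases the recovered tail-beat
amplitude upward by about +10%; with it the bias is below 2%. A, B, C, D
are then interpolated at subpixel positions along the refined polyline —
pixel-snapped points would add avoidable quantization noise to angles built
on only three segments. Body length for BL-normalization is the median
refined path arc length over valid frames (a user-supplied standard length
can override it).

## Cycle statistics

Each signed angle trace is mean-subtracted and low-pass filtered
(4th-order zero-phase Butterworth, cutoff 25 Hz by default — far above the
~10 Hz tail beat of a zebrafish at moderate speed, low enough to kill pixel
jitter; Gustafsson edge handling keeps the filter exactly time-reversal
symmetric so summaries do not depend on play direction). Half cycles of
bending are the intervals between consecutive zero crossings
(subframe-interpolated, rounded to frames; intervals under 3 frames merge
into a neighbor). The mean tail-beat frequency divides the half-cycle count
by the time between the first and last crossing, using every detected
crossing; a Fourier-peak estimate serves as an independent cross-check in
tests only. The half-cycle curvature is the time average of |angle| within
each half cycle, averaged over half cycles ((2/π)·peak for a sinusoid);
the signed-trace peak is a property of the trace, not reported separately.
The amplitude summary is the mean over half cycles (of the γ trace) of the
per-half-cycle maximum amplitude; the amplitude trace is low-pass filtered
first because the maximum of a noisy signal is biased upward by roughly the
noise amplitude (~+7% at the default operating point), and its real content
lives at twice the tail-beat frequency, well inside the passband.

Invalid frames are bridged by linear interpolation when a gap is at most 20
frames (20 ms at 1000 fps); longer gaps split the trace into segments whose
cycles are pooled (total cycles over total spanned time). Short dropouts
therefore neither fabricate nor destroy cycles, and a single long dropout
does not corrupt crossing detection across it.

## Validity rules

Per frame: no qualifying blob, more than one qualifying candidate (when a
single fish is expected), skeleton not contained in the blob, a constant
(degenerate) histogram at thresholding, a cyclic skeleton, or coincident
body points each invalidate the frame with a distinct reason code. A fully
blank frame surfaces as a degenerate histogram — there is nothing to
threshold — while near-blank noisy frames surface as `no_blob`; both mean
"no fish found". A video is accepted for evaluation only when the invalid
fraction is strictly below 10% (exactly 10% is rejected).

## Synthetic fish

The generator emulates silhouette video of steady carangiform swimming:
the midline's lateral displacement is a single sinusoidal traveling wave
y(s,t) = A(s)·sin(2πft − 2πs/λ) with arc position s ∈ [0,1], a linear
amplitude envelope A (1 px at the head to 15 px at the tail by default),
frequency f = 10 Hz and wavelength λ = 1 body length — canonical values
for steady swimming at moderate speed. The axial coordinate is compressed
each frame so the curve's arc length equals the body length exactly
(bending must not stretch the body, and the lateral amplitudes are left
untouched so they remain the recoverable ground truth). Defaults film
1 s at 1000 fps, a 200 px body centered in a 400×160 px frame — a
scaled-down geometry chosen to keep full-length runs fast while leaving
>10 px of clearance around the fish.

The body is rendered as all pixels within a head-heavy, tail-tapering
half-width profile of the midline (exact point-to-segment distances;
half-width floored at 1.2 px so the tail stays connected), dark fish
(intensity 40) on a light background (200), with optional i.i.d. Gaussian
pixel noise. Rendering is a pure function of (config, frame index), so
frames are bit-reproducible. Ground-truth angles and amplitudes are
computed from the analytic midline by the *same* geometry functions the
pipeline uses — there is no second implementation to drift.

Corruption modes exercise the validity rules: `blank` (frame replaced by
background), `split_blob` (a background band cuts the fish in two) and
`speckle` (small dark clutter). What the generator does **not** emulate:
fins and texture, shadows and reflections, water-surface glare, defocus,
body roll/pitch, swimming-speed drift, or multiple fish. Passing the
recovery tests therefore shows the chain is correct for a clean silhouette
of known geometry, not that segmentation is robust to every artifact of a
real tunnel recording; the selection-criteria and validity machinery exist
precisely because real frames fail in ways synthetic ones do not.

## Numerical choices and degenerate inputs

Otsu ties break to the smallest threshold; blob-selection ties are totally
ordered; a constant preprocessed frame maps to zeros and then fails
thresholding with a distinct reason. Frequency is undefined (None) below
two full cycles, and curvature/amplitude summaries are None with no
detected half cycles — except that a trace with finite amplitudes but no
oscillation degrades the amplitude summary to the plain per-frame mean
(a straight swimmer reports amplitude 0, not "undefined"). The arc-length
compression factor is solved by bisection to 10⁻¹² px. All angle outputs
lie in (−180°, 180°].

## Operating sizes

Full-scale validation runs use the 1000-frame default video (about 10 s to
generate and 15 s to analyze on one CPU); unit tests use a 150-frame clip
at 500 fps (3 tail-beat cycles), enough for every estimator to converge.

## Known limitations

Single fish, 2-D silhouette only; the midline is a polyline, not a spline,
so angle traces carry ~1° of pixel-level jitter; the thickness-based head
call can fail on a fish whose tail is occluded or folded; the amplitude
definition is relative to the instantaneous head segment, not the swimming
axis; and the acceptance rule counts frames over the whole analyzed
window regardless of where motion clipping fell back to the full region
of interest.
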