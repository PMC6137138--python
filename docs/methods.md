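# Methods

## Overview

`mazetrack` scores single-animal behavioral videos recorded from above
(zenithal view) in four standard rodent tests: the open field (OF), the
elevated plus maze (EPM), the Y-maze (YM) and the Morris water maze
(MWM).  The pipeline is classical background-subtraction tracking:

1. optional Gaussian smoothing of every frame;
2. a static background model (per-pixel mean over all frames by default,
   median as a robust alternative);
3. a difference stack, `|frame − background|`, so dark-on-light and
   light-on-dark animals are handled by one code path;
4. automatic binarization by the bimodal-histogram "Minimum" method;
5. 8-connected components, a minimum-area filter, one expansion/erosion
   (3×3 closing) cycle, and selection of the animal blob;
6. centroid trajectory with displacement, speed, movement-threshold
   suppression and freezing detection;
7. region occupancy from the blob perimeter (or centroid), hysteresis
   entry/exit events, and per-test metrics.

All geometry lives in pixel coordinates (x = column, y = row, origin
top-left) with a single cm-per-pixel calibration factor attached.

## Detection model and assumptions

The method assumes a single animal that contrasts with a static
background under roughly constant illumination.  The **Minimum
threshold** smooths the 256-bin intensity histogram of the pooled
difference stack with a 3-bin moving mean (edge bins replicate their
single neighbor) until exactly two local maxima remain, then takes the
lowest bin of the valley between them.  A histogram that never becomes
bimodal raises a convergence error; the caller may fall back to a manual
threshold override, which is also recorded in the parameters file.  The
threshold is computed once per video (stack-level) because the pooled
histogram is far more stable than single frames; a per-frame mode exists
behind a configuration flag.

Components below `min_area_px2` (default 50 px²; this must be set per
setup from the animal's apparent size) are discarded.  The chosen blob is
the one nearest the previous centroid, or the largest in the first frame.
Frames with no surviving component carry the last centroid forward, are
flagged undetected, and contribute zero displacement — dropouts never add
phantom distance.

A known failure mode is an animal that rests in one place for a large
fraction of the video: it becomes part of the mean background and locally
cancels out of the difference stack.  The median background resists this
up to ~50% occupancy per pixel.  Uneven illumination and shadows are out
of scope.

## Kinematics

Displacement between consecutive frames is the Euclidean distance between
centroids; speed is displacement over the frame interval `1/fps`.
Displacements below `movement_threshold_px` (default 1.0 px) are treated
as "did not move": they are excluded from distance and from the speed
numerator, while elapsed time always counts.  This absorbs segmentation
jitter, which otherwise inflates path length.  Average speed is total
(suppressed) distance divided by total elapsed time `(T−1)/fps`; the
alternative — the mean of per-interval speeds — is deliberately not the
default because suppressed intervals would need an arbitrary convention.

**Freezing** is a maximal run of consecutive sub-threshold intervals
lasting at least `freeze_min_duration_s` (default 0.5 s, configurable
down to 0).  A bare per-interval definition over-counts jitter; half a
second is at the short end of common practice.  Each freezing episode is
attributed to the region occupied at its first frame.

## Regions and events

Maze regions are shapely geometries built by parametric constructors (or
loaded from user polygons): OF — a 38 cm square split 5×5 with a central
3×3 block (7.6 cm cells, 22.8 cm center); EPM — 25×7 cm arms around an
8×8 cm center with thin edge zones flanking the open arms; YM — three
35×7 cm arms at 120° around a central triangle; MWM — a 125 cm pool with
four quadrants, a 10 cm platform disc and a 10 cm wall band.  Region
boundaries default to half-integer pixel coordinates (between pixel
centers); with boundaries on integer coordinates, boundary-inclusive
membership systematically annexes a full row of perimeter pixels and
biases event timing by about half a frame per crossing.

Occupancy of a region is the fraction of blob **perimeter points** inside
it (boundary-inclusive; over a partition, each point is assigned to the
lowest-index region that covers it, so fractions sum to exactly 1).  An
area-fraction mode exists for sensitivity checks.  The water maze instead
uses the blob center of mass.

Entries and exits are a hysteresis state machine: the animal enters a
region when occupancy reaches the entry fraction (OF 0.70, EPM 0.80, YM
0.90) and leaves when occupancy falls to `1 − exit_fraction`.  The
Y-maze's exit rule is explicit ("90% of the body out", occupancy ≤ 0.1);
the OF/EPM exit threshold defaults to the symmetric complement of the
entry fraction, which prevents chatter when the animal sits on a
boundary.  Time in a region counts the frames between its entry and exit
events; between an exit and the next entry the animal is assigned to the
transition region (OF: outer; EPM/YM: center), so region times always
partition the tracked duration exactly.  The Y-maze's central triangle is
only this transition zone: it is smaller than the animal, so a
body-fraction "visit" to it would be noise, and no reported metric needs
it.

**Head dips** (EPM edge exploration) are maximal runs of frames in which
the animal is inside an open arm and its mask overlaps an edge zone by at
least `min_overlap_px2` (default 20 px²); runs separated by fewer than
`min_gap_frames` (default 5) merge.  The event rule is this package's
construction — the behavior is conventionally named but has no standard
algorithmic definition.

**Spontaneous alternation** is the percentage of sliding windows of three
consecutive arm entries that visit three different arms, out of `n − 2`
windows; undefined (reported "n/a") below three entries.  A well-formed
hysteresis event stream never has two identical consecutive entries and
the strict function rejects them, but a real animal can legally re-enter
the arm it just left, so the scorer counts repeat-containing windows as
simply non-alternating.

**MWM latency** is the time of the first frame whose centroid lies on the
platform disc (an optional minimum dwell is available, default 0); a
video that never satisfies it reports the literal sentinel "Did not find
platform".

## Synthetic validation data

The generator renders an anti-aliased ellipse (default 3×1.5 cm semi-axes;
4×2.5 cm for the swimming animal) moving along scripted waypoints with
linear interpolation, over a static background (intensity 100 with a
fixed noise texture of sd 3) plus per-frame Gaussian noise (sd 6), at a
foreground contrast of ±80 and 25 fps — conditions representative of an
indoor behavioral rig, with both bright and dark animals exercised.
Rendering is fully deterministic given the script seed.

Ground truth is computed from the script, never from rendered pixels:
true centroids and path length come from the waypoints; occupancy comes
from the perimeter of the *exact, noise-free ellipse raster* (the
analytic shape discretized to the pixel grid, extracted with the same
perimeter rule as the detector).  This definition makes ground truth
"what a perfect detector would measure": continuous-boundary sampling has
measurably different point-density statistics than a pixel perimeter
(8-connected diagonal runs are undersampled by √2), which shows up as a
spurious half-frame disagreement per boundary crossing that says nothing
about detection quality.  Ground-truth events and metrics are produced by
running the same rule set on these analytic inputs, so rule logic and
detection error are separately testable.

The standard validation suite generates ten videos per maze with varied
entry counts (the OF suite makes exactly `i` center entries in video
`i`), speeds (14–24 cm/s), dwell and freezing episodes, wall hugging, a
never-found platform trial, and confined-to-one-arm trials.  Confined
scenarios pace the full arm rather than sitting still — a parked animal
is invisible to background subtraction (see above), which is a detection
limitation, not a scoring one; fully static edge cases are exercised at
the scoring layer directly.  Scripted dwells are kept clear of the 0.5 s
freezing cutoff (short pauses ≤ 0.3 s, true freezes ≥ 0.8 s) so the
freeze classification is never decided by a rounding frame.

On these conditions the pipeline recovers centroids within 1 px in ≥ 99%
of frames, path length within 2%, every entry/visit/head-dip count
exactly, region and freezing times within two frame durations, and
platform latency within one frame; recovered-vs-truth Pearson
correlations per metric family exceed 0.99.  What passing does *not*
show: robustness to illumination drift, shadows, occlusion, animals
resting against similar-intensity backgrounds, or non-elliptical posture
(rearing/grooming are not detectable by design).

## Numerical choices

* Gaussian blur radius is the distance at which the kernel decays to
  e^(−1/2), i.e. σ; reflect padding avoids dark borders.
* Color is collapsed by unweighted channel averaging — detection only
  needs contrast, not luma fidelity.
* Closing uses a 3×3 structuring element with the erosion treating pixels
  beyond the border as foreground, so the cycle is extensive everywhere.
* Ties: boundary points count as inside; a centroid on a shared boundary
  goes to the lower-index region; equal-area candidate blobs resolve by
  scan order.
* Histogram smoothing is capped at 10 000 iterations.
* The frame-by-frame table writes interval quantities on the row of the
  interval's end frame (row 0 carries zeros).
* Suite problem sizes — ten videos of roughly 5–45 s per maze at 0.2–0.3
  cm/px — were chosen so the full four-maze validation runs in a few
  minutes on one core while every scenario still contains multi-visit
  structure.

## Known limitations

* Single animal only; no identity tracking, posture, or keypoints.
* No illumination-field correction; shadows merge into the blob.
* The entry-fraction rules are the automated operationalization of
  "entered with all four legs"; they are deterministic but not identical
  to human judgment, and freezing is over-counted relative to an observer
  who discounts head movement.
* The waypoint generator is not a behavioral model of rodent locomotion;
  it validates measurement, not biology.
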