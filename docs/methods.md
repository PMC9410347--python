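# Methods

This note records the models and procedures implemented in `ortrack`, the
parameter conventions, what the synthetic scenes do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Ground-plane localization

A person's image location is the arithmetic midpoint of the left and
right ankle keypoints (COCO indices 15 and 16). The midpoint is mapped
to world floor coordinates by the camera's image-to-ground homography;
the homogeneous scale is eliminated by dividing through the third
coordinate, and |w| ≤ 1e−12 is treated as a point at infinity (error).
Homographies are stored normalized to a unit bottom-right entry so that
equality is well defined, and must be invertible (|det| > 1e−12 after
normalization). Ground units are centimeters throughout, matching the
scale on which the distance gates are expressed.

Homography estimation — needed because real deployments measure their
own floor correspondences — is the normalized DLT: Hartley normalization
of both point sets (centroid at the origin, mean distance √2), the null
vector of the 2n × 9 design matrix via SVD, and de-normalization. With
more than four correspondences this is the algebraic least-squares fit;
the RMS reprojection residual is returned alongside. Rank deficiency
(e.g. collinear points) is detected from the second-smallest singular
value and rejected.

## Confidence filtering

A detection is kept iff its whole-pose score is at least `T11` **and**
at least one ankle score is at least `T12`. The rule deletes on strict
"less than", so scores exactly at a threshold survive; this boundary is
tested explicitly. Pose scores are not clamped to [0, 1]: top-down pose
estimators report whole-pose scores that exceed 1, and the default
`T11 = 2` only makes sense on that scale. Defaults: `T11 = 2`,
`T12 = 0.6`.

## Monocular linking

Linking is intentionally minimal — no motion model, no appearance — so
that tracklets are rarely wrong even if often incomplete; completeness
is restored later by the cross-camera clustering. Per frame:

1. Tracks unobserved for more than `T14` frames (default 60 = 1 s at
   60 FPS) are closed. A dropout of exactly `T14` frames is still
   bridged; `T14 + 1` splits the track.
2. (track, detection) pairs with ground distance ≤ `T13` (default 40 cm,
   one adult step per second of memory) form a bipartite graph. A
   maximum-cardinality, minimum-total-distance one-to-one assignment is
   computed with the Hungarian algorithm; forbidden pairs carry a cost
   larger than any feasible full assignment, which makes the solver
   prefer more matches first and smaller total distance second.
3. Assigned detections extend their tracks; unassigned detections open
   new tracks with local ids in creation order.

A track's reference position while unobserved is its last observed
point. The gate is not scaled with the gap length by default (a
`scale_gate_with_gap` option exists for experimentation). Equal-cost
assignment ties are broken toward lower (track, detection) index by an
infinitesimal lexicographic perturbation of the cost matrix (relative
size 1e−9/(n·m)); for continuous positions exact ties have measure zero,
and the perturbation is far below any physically meaningful distance
difference.

## Cross-camera clustering (ReID)

Tracklets from all cameras are clustered DBSCAN-style on the ground
plane:

- **Core objects**: observed length strictly greater than `T21`. The
  default sets `T21` to half the sequence length (7,200 frames for a
  4-minute 60 FPS recording). Observed length (number of frames with a
  point) is used rather than the first-to-last span, which is robust to
  long internal gaps; a "span" mode is available.
- **Neighborhood**: q is a neighbor of p when the mean ground distance
  over their common frames is defined and < `T22` (default 120 cm —
  looser than the tracking gate to absorb cross-camera homography error)
  and the appearance similarity is > `T23` (default 0.6).
- **Distance definedness**: the mean distance requires at least `O_min`
  common observed frames (default 30, half a second); temporally
  disjoint tracklets have *undefined* distance rather than 0 or ∞, so
  they can never be direct neighbors but can still be related through a
  cluster.
- **Similarity**: Pearson correlation between the two tracklets' mean
  appearance histograms (per-detection histograms averaged over the
  tracklet and re-normalized). Comparing tracklet-level means keeps the
  similarity defined for temporally disjoint fragments — required for
  reattaching broken tracklets. A zero-variance histogram has similarity
  0 by convention, so blank appearances never pass the gate.
- **Expansion**: cores are processed in descending observed length (ties
  by camera then local id); each unassigned core seeds a cluster that
  grows breadth-first through core members only. Border (non-core)
  tracklets join the first cluster that reaches them but do not expand
  it — standard DBSCAN semantics.
- **Same-camera overlap rule**: a person appears at most once per camera
  frame, so two same-camera tracklets in one cluster may share at most
  `overlap_tolerance` frames (default 0). An insertion violating the
  rule is rejected; the incumbent member (reached earlier, i.e. at
  higher affinity) wins, since no remedy is canonical.

**Noise reassignment.** Unassigned tracklets are processed in descending
observed length. For noise n and cluster C, `sim(n,C)` is the mean
similarity to all members and `dist(n,C)` the mean of the defined
pairwise mean distances. C is a candidate iff `sim > T23`, `dist < T22`
*or* no member has enough temporal overlap for a defined distance, and
the overlap rule holds after insertion. Among candidates, n joins the
one minimizing `(dist/T22 if defined else 1) − sim` (weights
configurable); the undefined-distance fallback of 1 means "as bad as the
gate allows", so overlapping evidence is always preferred when it
exists. With no candidate, n becomes a fresh singleton identity. Later
noise tracklets see earlier reassignments, which is what lets two
same-camera fragments of one person both attach to the same
cross-camera cluster (the bridge).

## Appearance histograms

Per-channel intensity histograms of the bounding-box crop, concatenated
and L1-normalized; default 3 channels × 16 bins. The color space and
binning are deliberately simple — uniforms are near-uniform color
patches, and the similarity is only an auxiliary gate. Histograms may be
precomputed and embedded in the detection JSON, so the pipeline never
needs pixel data.

## Evaluation

Ground truth and predictions are compared on the ground plane with a
100 cm matching threshold (configurable; the value is an evaluation
convention, not a method parameter). Per-frame correspondences follow
the CLEAR convention: matches persist from the previous evaluated frame
while within threshold, remaining objects are matched by
minimum-total-distance assignment. MOTA counts misses, false positives,
and identity switches relative to total ground-truth instances (it can
be negative; it is at most 1). IDF1 computes the globally optimal
one-to-one identity mapping by maximizing matched-frame overlap via the
Hungarian algorithm. NMI is computed from empirical joint frequencies in
nats (the normalized ratio is base-invariant) on the aligned identity
vectors of matched detections only; unmatched ground truth is excluded
and reported as a coverage ratio instead, so NMI measures identity
consistency, not detection recall. Degenerate conventions: NMI is 1 when
both labelings are constant, 0 when exactly one is. Sparse ground truth
(e.g. one annotated frame per second) is supported by evaluating only
annotated frames.

## Scene simulator

The generator reproduces the statistical structure the method is
designed for, not its pixels:

- **Room and cameras**: 600 × 900 cm room; four oblique pinhole cameras
  placed outside the four sides, 220–300 cm high, aimed at the room
  center, with the focal length chosen so the whole floor fits the
  1920 × 1080 frame. The plane-induced homography `K [r1 r2 t]` is exact
  by construction, so camera geometry introduces no model error.
- **Motion**: waypoint-and-dwell walks — straight legs at per-leg speed
  ~N(40, 10) cm/s toward uniformly drawn station points (50 cm wall
  margin), then dwells of ~N(6, 3) s. People occupy space: pairs closer
  than 40 cm (shoulder distance) are pushed apart symmetrically each
  frame, so two bodies never coincide and detection-level identity stays
  well defined.
- **Detections**: visible identities emit a schematic 17-keypoint pose
  whose ankle midpoint equals the projected foot position up to Gaussian
  pixel noise (sd 2 px by default); confidence scores are drawn from
  kept-detection distributions (pose ~N(3, 0.3), ankles ~N(0.85, 0.08));
  appearance histograms are a uniform-class prototype plus jitter.
  Detector misses (2%) and low-score false positives (pose ~N(1.2, 0.4),
  rate 0.005/frame/camera — mostly removed by the `T11 = 2` filter)
  model the detection front end.
- **Occlusion**: per-camera ground rectangles with a drop probability
  (default 0.95). The same draw defines both ground-truth invisibility
  and missing detections — an occluded person is genuinely not visible
  in that camera. This produces the central phenomenon: tracklets broken
  for some cameras, intact for others, with gaps both shorter and longer
  than the memory window.
- **Determinism**: one seed sequence spawns independent child generators
  for cameras, motion, appearance, and per-camera noise, so outputs are
  bit-reproducible for a given seed.

Presets: `clean` (no noise of any kind, including pinned confidence
scores — the pipeline must be exact on it), `broken_tracklets` (cameras
1–3 share a central 400 × 400 cm occlusion zone, camera 0 covers
everything), `confusable_uniforms` (all identities share one histogram
class), `crowded` (stations confined within 50 cm of the room center).
Each preset has a full-length variant (14,400 frames — a 4-minute
recording) and a `_fast` variant (1,800 frames). Tests and the
acceptance script run the fast variants; results on them are the
package's reference problem sizes.

What the simulator does **not** model: articulated body motion (only the
ankles are geometrically meaningful), photometric variation, detector
confusion between adjacent people, camera desynchronization, and
ray-cast 3-D occlusion. Passing tests on these scenes therefore
demonstrates the correctness of the geometry, linking, clustering and
metric machinery under the stated noise model — not detector robustness
on real video.

## Numerical choices and limitations

- Assignment infeasibility is encoded as a cost exceeding any feasible
  total, which provably yields maximum-cardinality minimum-cost
  solutions without a separate feasibility pass.
- The homography estimate rejects configurations whose design matrix has
  a near-zero second-smallest singular value (relative 1e−9).
- NMI is clipped to [0, 1] against floating-point overshoot.
- The T22/T23 parameter sweep reuses the monocular stage across cells
  (the gates only affect clustering), making cells independent and the
  grid cheap.
- Known limitations: the tracker has no motion model, so two people
  crossing within the gate during a mutual dropout can swap; fragments
  shorter than `O_min` frames can only be reattached by appearance,
  which is weak by design in this domain; and the clustering is offline
  (the whole recording is needed before ReID).
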