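# Methods

This note records the models, algorithms, parameter choices and known
limitations of `patchtrace` at the level of detail a user needs to judge
what a passing test suite does and does not establish.

## The analysis model

The pipeline assumes a monolayer colony of rod-shaped cells imaged in
three fluorescence channels at low temporal resolution (tens of minutes
per frame), too dense and noisy for per-cell segmentation. It replaces
cells with two abstractions:

**Particles.** Each binarized frame is sampled with a Crocker–Grier-style
blob detector at an expected diameter `d`: band-pass (Gaussian at scale
`d/4` minus a boxcar of width `d`), local maxima kept at pairwise
separation ≥ `d` (brighter first, ties broken in scan order), a mass floor
of a quarter of the blob footprint in foreground pixels, and sub-pixel
refinement by iterated intensity-weighted centroids. Running on the binary
mask — not the raw fluorescence — makes detection insensitive to
brightness differences between cells. Choosing `d` below the smallest
cell dimension guarantees every cell holds at least one particle; the
bundled rule derives `d` from the average cell length `l` and width `w`
as the largest odd integer not exceeding `min(l, w, (l − w)/2)` (or
`min(w, w/2)` for round cells), clamped at 3. For the simulated rods
(`l ≈ 30`, `w = 11`) this gives `d = 9`.

**Trajectories.** Frame-to-frame linking joins particles within
`σ_max` px; within each connected candidate subnetwork the assignment
minimizing total squared displacement is chosen (an unfilled link costs
`σ_max²`; subnetworks beyond 24 nodes fall back to greedy nearest-first
and log a warning). A track losing its particle stays open for `W_max`
frames. There is no motion model: displacements come from colony growth.
Defaults follow the movie scale: `σ_max = d − 2`,
`W_max = ⌊0.15·frames⌋`, and tracks spanning fewer than
`W_min = ⌊0.10·frames⌋` frames are dropped as spurious.

**Colors.** Each trajectory point samples the RGB channels at its
position; channels are rescaled linearly by the global per-channel
minimum and maximum over the whole movie, and points normalizing to
exactly (0, 0, 0) — the global-background signature — are dropped. Two
optional refinements exist because single-pixel sampling is fragile in
crowded images (see "Numerical choices").

**Patches and the lineage.** The decision function
`Φ(v, v′) = [dist < t_d]·[|Δr| < t_r]·[|Δg| < t_g]·[|Δb| < t_b]` (strict
inequalities) induces a similarity graph per frame; patches are its
connected components (single linkage, so chains of pairwise-similar
particles form one patch). The lineage is built in three passes:

1. *Upstream propagation.* Patches are found once, at the final frame,
   where the colony is largest; every trajectory alive there carries its
   final-frame patch ID (1..C, components ordered by their top-left
   member) back to all its points. Trajectories absent from the final
   frame get the smallest unused IDs starting from 0, walking backward.
2. *Split pass* (final frame → first). Within each patch at each frame,
   members are re-clustered with Φ, and members whose own color jumps by
   at least one color threshold between this frame and their next
   observation are additionally separated — a fluorescence state change.
   The group containing the member nearest the patch's downstream
   centroid keeps the ID; jumping groups never anchor (their history
   diverges from the patch's downstream identity). Every other group
   gets a fresh ID at this and all earlier frames. A singleton patch is
   also cut at a fluorescence jump of its lone trajectory.
3. *Merge pass* (first frame → last). Coexisting patches merge when
   their oriented bounding rectangles come within `t_d` of each other
   and some cross-pair of members satisfies Φ; the patch whose lifespan
   ends later survives, ties break toward the smaller ID, and the
   absorbed patch is relabeled at this and all later frames. A patch
   starting at frame `t` also absorbs (wholly) a patch whose lifespan
   ended at most `δ_t` frames earlier when their boundary-frame
   rectangles are in range and their mean colors agree — the merge
   window for tracks that flicker out. `δ_t` defaults to `W_max`.

**The graph.** Nodes are the surviving patch IDs with lifespans, sizes
and mean colors. Edges are derived from the final assignment: whenever a
trajectory's patch ID changes between consecutive observations, its old
patch flows into the new one. Flows past the source patch's end
("terminal") always become edges — the source drained into the target —
and provably cannot form cycles, because the source's end time strictly
increases along any path. Flows between coexisting patches become edges
only when at least two trajectories moved together (single-particle
exchanges are churn); where both directions carry flow only the dominant
one is kept, and any remaining directed cycle is broken by removing its
weakest exchange flow (recorded in the graph attributes), so the output
is always a DAG. An edge is labeled a *split* when at least half of its
transitioning trajectories jumped in color across the transition (a
state change, as in the worked example's switching track) and a *merge*
otherwise (a spatial union). Merge events that erase a patch entirely —
a dying track folded into its neighbor at its birth frame — leave no
node and are kept in `graph.graph["absorbed_events"]`.

## The simulator

Cells are ellipses with center, length, width and orientation. Lengths
multiply by `1 + growth_rate` per frame; a cell reaching
`division_length` splits into two daughters laid end to end along the
parent axis with a small orientation jitter (σ = 0.15 rad) and a
slightly asymmetric length split (fraction ~ N(0.5, 0.05), clipped to
[0.35, 0.65]) that desynchronizes the cell cycle; daughter lengths sum
exactly to the parent's. Overlaps are removed by damped pairwise
repulsion sweeps — overlapping pairs (intersection area above 2% of the
smaller cell) are pushed apart along their center axis until every pair
overlaps by at most 5%, emulating the membrane that keeps chamber
colonies in a monolayer. Rendering gives each pixel the contribution
`rgb / (1 + exp(k(ρ − 1)))` per cell, where ρ is the normalized
elliptical distance (1 on the boundary) and `k = 10` the sigmoid
steepness; contributions combine by per-channel maximum, then Gaussian
noise (σ = 6) is added and the image clipped to [0, 255]. Discrete
fluorescence states map to RGB triples (default red (210, 40, 40) and
green (40, 210, 40)); states switch stochastically with a per-frame
probability (default 0) or deterministically through programmed switches
that hit a cell and its descendants at a given frame. All randomness
flows through one `numpy` generator seeded from the config.

Default study conditions: 25 frames (one per 30 min), one doubling per
five frames (division time ~2.5 h), two founders, images of 300–440 px,
colonies reaching ~40–60 cells. What the simulator does *not* emulate:
phase-contrast texture, illumination gradients, chamber wall artifacts,
cell death or photobleaching, and sub-cellular fluorescence structure.
Tests passing on these movies show the pipeline's logic is correct under
realistic geometry and noise; they do not certify performance on real
chamber recordings, whose preprocessing (background subtraction radius,
alignment) and thresholds must be chosen per data set.

## Numerical choices

* **Binarization** is median denoise (radius 1) → optional white-tophat
  background removal (off by default; the simulator's background is
  flat) → per-pixel maximum over the RGB channels → global Otsu → binary
  opening and closing (radius 1). A constant frame yields an empty mask.
  Alignment is integer-pixel phase correlation of each frame against its
  predecessor, clamped to ±20 px.
* **Ties.** Local maxima of equal brightness break in (y, x) scan
  order; patch labels order components by their top-left member; the
  split anchor breaks ties toward the top-left member; merges keep the
  later-ending, then smaller, ID. Everything is deterministic.
* **Color sampling.** Default is the nearest pixel. In crowded movies
  single-pixel sampling is noisy in a structured way: particles at cell
  rims and junctions sample the sigmoid falloff between cells and come
  out dim, and pixels at the interface of differently colored cells
  blend both emissions into intermediate colors that can chain two
  distinct subpopulations into one patch under single linkage. Two
  options address this: `sample_radius` aggregates each channel over a
  disc (statistic `"mean"` or `"max"`; the per-channel maximum reads the
  emission peak within the blob and matches how the frames compose), and
  `contrast` applies a logistic curve after the linear rescale,
  decreasing low and intensifying high fluorescence so sharp expression
  differences stay sharp at the particle level.
* **Scenario parameters.** The bundled ground-truthed scenarios
  (`patchtrace.scenarios`) use `d = 9` from the cell geometry;
  `σ_max = 12` for the two-color scenarios (colony expansion moves rim
  particles by up to ~12 px per frame; the `d − 2` default fragments
  their tracks) and the default `σ_max = 7` for the contact-timing
  scenario; `t_d = 60` (about a third of the final colony diameter,
  matching the colony-relative scale used on real chamber data) except
  `t_d = 30` for contact timing, where a tight radius makes the joining
  frame sharp; tight thresholds (30) on the informative red and green
  channels with blue ignored (threshold 255 — the channel-ignoring
  trick), disc-max color sampling and contrast 15 for the two-color
  scenarios; and no color tests at all for the same-color contact
  scenario.
* **Contact-frame ground truth.** Two colonies count as "in patch-joining
  range" at the first frame their cell outlines come within
  `t_d − 2·3.1` px, where 3.1 px is the median distance from a detected
  particle center to the cell outline, calibrated once on a single
  isolated noise-free rendered cell. Across seeds the measured joining
  frame lands within one frame of this ground truth, occasionally two
  when the closing speed dips.

## Known limitations

* Single-linkage patches chain: one mis-colored particle can bridge two
  patches. The contrast and disc-max options mitigate but cannot
  eliminate this; tight per-channel thresholds on informative channels
  are the main defense, as on real data.
* Two colonies that remain in contact through the movie end are one
  patch at the final frame, so their union is discovered by the backward
  split pass rather than a forward merge event; the
  `family_union_time` observable dates the union either way.
* Trajectory fragmentation under fast growth is expected (the particle
  count far exceeds the track count, which exceeds the patch count);
  fragments appear as short-lived upstream patches that flow into the
  colony patches via merge edges.
* The split/merge passes mutate assignments eagerly in deterministic
  sweep order; a different processing order could produce different
  (equally defensible) intermediate IDs, though the surviving partition
  is stable in all tested conditions.
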