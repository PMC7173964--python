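# Methods

`hemimorph` implements the quantitative core of single-neuron hemilineage
analysis in the *Drosophila* central brain: given registered neuron
skeletons (SWC, micrometres), neuron-type names in the hemilineage
nomenclature, and clone-induction records, it derives backbone lengths,
pairwise morphological similarity and similarity groups, topology classes,
birth-order heatmaps, and A-vs-B hemilineage statistics.  This note
describes each model/procedure, its parameters and assumptions, the design
decisions made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Skeletons and serial pruning

A neuron is a rooted tree of 3-D nodes.  When per-node intensity is
available, the soma is located at the maximum-intensity node and the tree is
re-rooted there (ties break to the lowest node id; skeletons without
intensity require an explicit root).  The tree is decomposed into
unbranched *segments* between critical points (root, branch points with two
or more children, leaves); segment lengths are sums of Euclidean edge
lengths, so the decomposition conserves total cable length exactly.

The **main trajectory** is obtained by serially pruning terminal branches
shorter than 10, then 25, then 50 um (configurable, strictly increasing).
Pruning semantics, where several choices were open:

* each threshold is iterated to a **fixpoint**: removing short terminals
  exposes new degree-2 pass-through points which are absorbed into their
  containing segment before re-testing, so no short terminal survives;
  a `fixpoint=False` flag gives the single-sweep variant;
* within one iteration all currently-short terminal segments are removed
  **simultaneously** (the sweep is frozen at iteration start), which makes
  the result independent of processing order.  Note that interleaving
  removal and re-decomposition branch-by-branch is *not* order-independent
  in general — when two short arms share a branch point, removing one can
  merge the other into a surviving longer terminal — which is why the
  frozen-sweep definition was chosen; the test-suite oracle performs
  single-branch removals from the same frozen sweep;
* a skeleton with no branch point is never pruned, so a neuron cannot be
  deleted wholesale;
* serial pruning at [10, 25, 50] um equals direct pruning at 50 um unless a
  merge assembles a branch ≥ 50 um from shorter parts; where they differ the
  serial result is the defined behaviour.

The coefficient of variation of main-trajectory lengths uses the sample
(n−1) standard deviation over the mean.

Midline crossing is decided from node positions: a skeleton crosses when it
has nodes beyond the ±tolerance band on both sides of the midline plane
(connectivity then guarantees a crossing path).  A per-edge test — one edge
with endpoints beyond both bands — would be resolution-dependent: finely
resampled skeletons have no single edge long enough to span both bands.

## Similarity scoring

Neurons are compared as **dotprops**: each unbranched segment is resampled
at 1 um spacing (endpoints kept) and every point receives a unit tangent,
the dominant principal direction of its k = 5 nearest neighbours (community
defaults; both exposed).  Tangent sign is arbitrary; scoring uses the
absolute dot product, so the representation and all scores are invariant
under rigid motion of both clouds.

The raw score of a query against a target accumulates, over query points,
`f(d, |dot|)` where `d` is the nearest-target-point distance.  The default
scoring function is the analytic surrogate `f(d, a) = exp(−d/σ)·a` with
σ = 3 um.  It preserves the defining monotonicity of published NBLAST score
tables — non-increasing in distance, non-decreasing in tangent alignment,
positive at (0, 1) — without depending on any external score table; a
tabulated distance × |dot| score matrix can be supplied instead
(out-of-range arguments clip to the nearest bin).  The reported score is the
normalized mean, `(raw(a,b)/raw(a,a) + raw(b,a)/raw(b,b))/2`, which is
symmetric and exactly 1 for identical clouds.

Pair/group extraction from an all-to-all matrix: unordered pairs with score
**strictly greater** than the cutoff (default 0.3; a secondary exploratory
cutoff of 0.2 is conventional), intra-hemilineage pairs removed by parsing
type names into hemilineage keys (lineage + A/B suffix for dual lineages,
bare lineage for lone ones), and the surviving pair graph consolidated into
connected components.  Groups are ordered by size descending, then by
lexicographically smallest member — a reporting convention only.  Matrices
read from CSV/TSV are auto-inspected (diagonal ≈ 1 → normalized; equality
with the transpose → symmetric) and asymmetric matrices are symmetrized by
averaging before thresholding, with a log message.

## Topology classification

The classifier is a geometric surrogate for what an anatomist does by eye.
**Arbor domains** are single-linkage clusters of leaf and branch-point
positions at a 20 um cut distance; clusters with fewer than 5 points are
discarded as pass-through debris.  A domain's side is taken from the signed
distances of its members to the sagittal midline plane (x = x_mid, tolerance
5 um): *straddling* when members fall on both sides or any lies within the
tolerance band, else left/right.

Classes are assigned in a fixed decision order that resolves rule overlaps
deterministically:

1. **D** (External) — any leaf outside the brain bounding box (descending
   and other brain input/output neurons);
2. **C** (Central) — exactly one domain, straddling the midline;
3. **M** (Midline) — straddling plus lateral domains coexist (so a crossing
   neuron that also covers the midline is M, not T);
4. **H** / **T** — midline-crossing neurons, split by bilateral symmetry:
   H when every lateral domain on either side has a partner whose mirrored
   centroid lies within 30 um, with at least one matched pair, else T;
5. **S** / **P** — no crossing: one domain → S, several (necessarily one
   hemisphere) → P.

All parameters (link radius, minimum cluster size, match radius, midline
tolerance) are exposed in `TopologyParams` / `BrainModel`.  The separation
of "midline targeting" (M) from mere crossing (T/H) via a straddling domain
is one operational reading of a verbal criterion; it is a package
convention, not an anatomical ground truth.  Classification is total and
single-valued, and mirror-imaging the brain leaves every assignment
unchanged.

Type names follow `<lineage><A|B?>_<class letter><serial>(<annotation>)`
with a two-digit zero-padded serial; parsing and rendering are mutually
inverse.  Lineage names end in a digit, which is what makes the optional
A/B suffix unambiguous.

## Birth-order analysis

The induction schedule has two phases in 2-hr steps: larval 18–92 hr after
larval hatching (ALH) and the pupal transition from 22 hr before to 16 hr
after pupa formation (BPF/APF).  The phases are concatenated on one ordered
axis with the pupal points after 92 hr ALH — per-animal wall-clock
alignment between the phases is unknowable, so only ordering is asserted.

* **Type-level heatmaps** show raw single-cell counts per (type, induction
  point), capped at 10 for display; window statistics always use uncapped
  counts.  Only single-cell and paired-two-cell clones date a birth;
  NB clones are excluded.
* **Production windows** are maximal runs of consecutive non-zero counts
  ("uninterrupted interval" = consecutive schedule points with count > 0;
  "well-separated" = separated by at least one zero point — no numeric gap
  being defined, one zero is the minimal reading).  A window is *detectable*
  when it yields ≥ 6 samples over ≥ 2 time points.  Whether "samples"
  counts clone records or brains is ambiguous in the field's usage; records
  are counted here and the unit is a parameter.
* **Group-level heatmaps** pool counts over a group's member types and
  normalize to sum 1 within every candidate window, so early and late
  production windows are equally visible; groups are ordered by the
  count-weighted mean time of their first window (ties: earlier start, then
  name; empty groups last, logged).
* **Birth-order inference** sorts types by the composite key (first point
  with ≥ 2 samples — first non-zero point if none reaches 2 — then peak
  time, then last non-zero point, then name), operationalizing "beginning,
  peak, or ending of recovery".  The result is deterministic and invariant
  to record order.

## Hemilineage statistics

For the dual-hemilineage lineages, three B-vs-A readouts:

* per-lineage mean main-trajectory length: one-tailed two-sample test
  (alternative B > A), Welch's unequal-variance form by default at
  α = 0.01.  The test form is a package choice — only the paired tests
  below are canonical — so pooled-variance and Mann-Whitney variants are
  selectable;
* length CV per hemilineage, compared across lineages with a paired
  one-tailed t-test (B > A), n = number of dual lineages;
* topology-class counts per hemilineage, same paired test.

Degenerate inputs are handled exactly: all paired differences zero → t = 0,
p = 0.5; zero variance with non-zero mean → p ∈ {0, 1} by sign (logged).
No multiple-testing correction is applied.

## Synthetic data

The generator plants known truth for every pipeline stage.  A brain is a
box (~600 × 400 × 250 um) with a centred sagittal midline.  Each
hemilineage owns a *lane* — a backbone running along x at a (y, z) position
on a grid with ≥ 40 um separation — emulating hemilineage-shared primary
trajectories; each type hangs compact terminal arbors (random binary trees,
log-normal branch lengths of median 5 um, root-to-tip path capped at 14 um
inside a 14-um-radius ball) at class-determined positions.  The arbor
path cap keeps connector + arbor below the final 50-um prune threshold, so
serial pruning removes terminal arbors cleanly and the planted
main-trajectory length is realised by the backbone alone.  Per-type target
lengths are realised by extending the backbone with an in-box tail (always
≥ 55 um so it survives pruning); arbor tree shapes are grown once per type
at template-building time, so duplicated types are identical up to the
per-skeleton 1-um jitter.

The study scenario mirrors the mapped-lineage census: 18 lineages, 25
hemilineages, 7 dual and 11 lone, with per-hemilineage type counts scaled
down to 5–6 (143 types in total) to keep simulation fast.  Planted
structure: the CREa1A/CREa2A pair shares one template (lineage
duplication); B hemilineages carry 3–5 topology classes against 1–2 on the
A side and a ±150 um length spread against ±15 um; CREa1 and SMPp&v1
additionally carry a B-side mean-length excess (700 vs 450 um), so the
per-lineage length test should fire for exactly those two.  Birth windows
span 4 schedule points, staggered 7 points apart within a hemilineage.
Clone sampling draws one induction time per simulated brain and recovers
each in-window type with probability 0.3 × survival (programmed cell death
is a per-type survival probability; a lone hemilineage is the limit where
one side's survival is 0).  Everything is deterministic given a seed.

What the generator does **not** emulate: registration error and
segmentation noise, true arbor-scale terminal elaboration (arbors are
deliberately compact), intensity profiles beyond soma-maximal, within-type
biological variability beyond isotropic jitter, NB-clone records, and any
asymmetry between hemispheres.  Passing tests therefore demonstrate that
the pipeline's logic recovers planted structure under clean conditions, not
that the geometric surrogates (domain clustering, the analytic scoring
function) match expert judgement on real, noisy material.

## Problem sizes and numerical choices

The acceptance script and test suite run the study scenario at 143 neurons,
2 000 simulated brains, an all-to-all matrix of 143² scores (≈ 30 s on one
CPU), and property sweeps of 500 random trees (pruning vs. brute force),
200 graphs (components vs. union-find), 1 000 count vectors (windows vs.
exhaustive scan), 100 dotprops pairs (self-score / symmetry) and 50 paired
t-tests checked against numerical quadrature to 1e-9.  Unit-vector checks
use a 1e-6 tolerance; group-heatmap window sums are asserted to 1e-9; all
other float comparisons use relative tolerances around 1e-9.  Ties anywhere
(intensity root, group ordering, birth order, group membership) break
deterministically as documented above, so repeated runs are byte-identical.

## Known limitations

* The similarity scorer is a monotone surrogate, not a reproduction of any
  published score table; absolute score values are not comparable across
  scoring functions, only the ≥-cutoff structure is.
* Domain detection inherits single-linkage chaining: elongated arborization
  can bridge visually distinct domains at the default 20-um link radius.
* The M-vs-T/H boundary depends on the midline tolerance and on cluster
  membership near the midline.
* Lengths are polyline cable lengths; no radius-aware (frustum) correction.
* The per-lineage length test form (Welch) is a convention; switching to
  Mann-Whitney can change borderline significance calls.
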