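# Methods

This note records the models, defaults, numerical choices and limitations
behind each stage, in the order the pipeline runs them.

## Phantom generator

The phantom emulates the structure of multi-channel confocal montages of
cortex around an implanted recording device. Four channels are rendered
(nuclei, microglia, astrocyte, neuron), in a 14-bit intensity range stored
in 16-bit containers, at an isotropic default spacing of 0.5 µm/voxel.

*Nuclei* are axis-aligned ellipsoids with per-axis radii drawn from the
configured range (default 1.8–2.6 µm) and a smooth `(1 − q)^0.7` radial
profile, placed by rejection sampling with a minimum center separation of
2.1 mean radii; exhausting the retry budget raises a placement error naming
the violated constraint rather than silently under-filling.

*Microglia arbors* grow by recursive bifurcation from each microglia soma:
segments of 5–10 µm advance in ~1.5-voxel steps with per-step direction
jitter (a Gaussian cone of ~12°), branch with probability 1 below the
minimum branch order and 0.5 up to the maximum (default orders 2–3), with
branch pairs rotated ±25–45° off the parent direction. Tubes are rendered by
distance-to-polyline thresholding: centerline samples every 0.25 voxel, one
Euclidean distance transform with nearest-point indices, per-point radii
decaying 15% per branch order, and a 1-voxel linear soft edge as
anti-aliasing.

*Device and density gradient.* An axis-aligned box is zeroed in all
channels and emitted as a mask; when present, cell placement accepts a
candidate at distance `d` from the device with probability
`0.15 + 0.85·exp(−d / s)` (gradient scale `s` = 50 µm default), producing
the elevated peri-device cell density the device response shows.

*Noise model*, applied in this order: signal → multiplicative smooth bias
field (default amplitude 15%) → Poisson photon noise at `photon_scale`
counts per intensity unit (default 0.05, ≈ SNR 25 at full signal) → additive
Gaussian read noise (default SD 40 of 16383) → rounding to uint16. Rounding
last makes fixed seeds byte-identical. The generator does **not** model a
real PSF (only the soft tube/blob edges), spectral bleed-through, or
anisotropic optics, so passing tests demonstrate algorithmic correctness on
idealized geometry, not performance on real tissue. The defaults are
plausible for the imaging regime but deliberately tunable: real cell
densities and arbor statistics were not available to calibrate against.

Tiling reserves a border margin equal to the largest configured shift so
every shifted crop stays inside the volume; nominal "stage" offsets follow
the regular grid and the true shifts are recorded as ground truth.

## Mosaic

The transform model is pure integer translation — correct for step-and-repeat
stages, and deliberately excluding rotation/scale. Pairwise estimation runs
phase correlation on the nominal overlap of the axial maximum-intensity
projections, then refines to the NCC-maximizing integer shift in a ±3-voxel
window; 3-D refinement searches ±5 in z and ±1 laterally, always including
the starting point so NCC is monotone non-decreasing. A pair whose optimum
leaves < 8 overlap voxels or NCC < 0.2 falls back to the nominal offset with
a low-confidence flag. The joint solve minimizes score-weighted squared
residuals of `t_j − t_i − s_ij` per axis (weights = NCC clipped to
[0.1, 1] to avoid degenerate zeros), anchor fixed at zero, then rounds to
integers. Composition allocates only the requested ROI and blends overlaps
with a separable linear feather (8 voxels default); feathering was chosen
over max-blending to avoid seams, and identical data blends to itself, so a
noiseless overlap is reproduced exactly. An ROI composition equals the same
crop of the full montage bit-exactly because the per-voxel arithmetic is
identical.

## Enhancement

Median filtering uses the full (2r+1)³ neighborhood with mirror borders.
Rolling-ball illumination correction is implemented as slice-wise grayscale
opening with a flat disk of the configured physical radius; on a linear ramp
the opening reproduces the ramp exactly, so ramps vanish while objects
smaller than the ball survive.

The curvelet transform is a 2-D slice-wise FFT frequency-wedge frame built
from raised-cosine windows: dyadic radial boundaries `b_j = 2^{j−(J−1)}`
with Meyer-style crossfades, and periodic angular bumps on θ mod π whose
count doubles every other scale (8 at the coarsest detail scale by default).
Windows are symmetrized in power under ω → −ω — the aliased Nyquist row/col
of even grids otherwise breaks the symmetry that keeps band images real —
and normalized so `Σ|U|² = 1` everywhere, making the frame numerically
tight: round trips are machine-precision and band energies satisfy Parseval
exactly. Coefficient grids are full-size per band (a redundant frame).

Enhancement hard-thresholds detail bands at `κ·σ̂` with `σ̂` the band's
median-absolute-deviation noise scale (κ = 3 default; κ ≈ 6 with 5 scales is
the documented aggressive setting that also closes ~2-voxel gaps in tubes at
half-maximum). The coarse band is never thresholded, preserving mean
intensity. Orientation at a pixel is the center angle of the band with
maximal |C| rotated 90° (the wedge center is a frequency-domain normal), so
orientation is quantized to half the wedge spacing (~11° at 8 wedges);
anisotropy is `1 − mean|C| / max|C|` over oriented bands. Volumes are
processed in overlapping 2-D tiles with feathered reassembly; orientation is
taken from the tile with the dominant feather weight since angles cannot be
averaged.

## Segmentation

The binarization energy is `Σ_v D_v(l_v) + λ Σ_{(u,v)} [l_u ≠ l_v]` on the
6-neighborhood, with data terms the negative log-likelihoods of a
two-component Gaussian mixture fit by EM on the intensity histogram
(sub-sampled above 500k voxels). The cut is solved exactly by max-flow on
integer capacities: per-voxel reduced costs (subtracting the per-voxel
minimum keeps capacities small without changing the minimizer), a ×64
fixed-point scale, and a residual-graph BFS to read off the source side.
λ = 0 therefore reproduces per-voxel likelihood-ratio thresholding exactly.
Volumes above a budget are cut per-dice with core stitching. Intensities are
used at native bit depth (8/14/16); nothing is rescaled.

Seeding computes scale-normalized `−σ²∇²G_σ` responses on a log-spaced
8-step σ ladder spanning the expected nucleus radius range; at each voxel
the allowed σ is capped by the Euclidean distance-map value, which prevents
large-scale responses from bridging touching nuclei. Seeds are local maxima
of the masked response over space × allowed scale; for a sphere of radius r
the optimum sits at σ = r/√3. The hill-climbing field is the max-over-
allowed-scale response smoothed with a σ_min/2 Gaussian (the climbed field
is otherwise under-specified); every foreground voxel follows its
steepest-ascent 26-neighbor pointer (ties to the lowest linear index, so
runs are reproducible) to a peak, resolved by pointer jumping; peaks not
claimed by any seed fall back to nearest-seed assignment and are counted.
Labels below 27 voxels (noise specks) are dropped by default. Optional
boundary refinement is a seeded watershed on the inverted distance map —
a deliberate simplification with the same interface as a full MRF shape
refinement — which cannot change the cell count.

Dicing partitions the montage into half-open cores via rounded even splits,
padded by the maximum expected object size and clipped at borders. The merge
rule retains a cell iff its centroid lies in its dice's core; half-open
boxes mean every centroid belongs to exactly one core, so retention is
exactly-once by construction. Rare voxel collisions between retained cells
go to the nearer centroid and are logged. Merging always happens in
canonical dice order, so processing order and worker count cannot affect the
output.

Features per cell: voxel count and physical volume, mean/SD intensity,
bounding box, eccentricity from the inertia-tensor eigenvalues, surface
voxel count, and per-secondary-channel association = mean intensity in the
morphological shell within the association radius (2 µm default) of the
cell surface. The microglia-channel association is what separates microglia
nuclei in classification.

## Classification

`fit_logistic` minimizes `Σ log(1 + e^{−y f(x)}) + (λ/2)‖w‖²` with an
unpenalized intercept (solved by lbfgs at tol 1e-10, so the convex fit is
deterministic and row-order independent). Features are z-scored with pool
statistics frozen when the loop starts, so standardization does not drift as
labels accumulate. The query rule is maximum uncertainty — the pool cell
with predicted probability closest to 0.5, ties to the lowest id, batch size
1 — and initialization labels one random example per class from the seeded
generator. The budget is a configuration parameter (40 by default, matching
the annotation effort the approach is designed around); no stopping rule
beyond the budget is imposed. Multi-class extension is one-vs-rest; the
pipeline's built-in task (microglia vs other) is binary.

## Tracing

Patches (7×7×3 voxels by default, vectorized in z, y, x order, mirror-padded
at borders) are standardized to zero mean and unit norm; constant patches
are flagged degenerate. OMP selects the atom with maximal |correlation| to
the residual and re-solves least squares on the support, stopping at T atoms
(default 5) or negligible residual.

Dictionary learning stacks reconstruction and classification into one
matrix, `[Y; √β H]` coded in `[D; √β L]` with unit-norm stacked columns, so
the single residual **is** the joint objective. Each iteration: (i) OMP
recoding with a per-signal acceptance guard (a new code is taken only if it
lowers that signal's residual), plus a subspace-pursuit-style support
refinement for signals the greedy pass could not improve; (ii) K-SVD rank-1
SVD updates of every atom over its users; (iii) dictionary maintenance —
collapsing near-duplicate atoms (coherence > 0.95) via exact least-squares
code transfer, and re-seeding unused or rarely-used atoms from the worst-
represented signals — with every maintenance move committed only if the
objective does not increase. The recorded objective is therefore monotone
non-increasing by construction, and on well-conditioned planted sparse
models (atoms near-orthogonal, coefficients bounded away from zero) the
objective typically collapses to zero within 10 iterations. Initialization
is class-stratified from training patches, preferring low-coherence picks.
At convergence D is renormalized to unit columns with L scaled accordingly;
classification codes a candidate in D and declares a seed iff `l1 > l2`
(ties are background). Candidate generation — local maxima of the enhanced
microglia channel above a percentile floor (80th default) — is this
package's choice; training labels for the phantom workflow come from
centerline distance (≤ 1.5 voxels positive, > 3 negative, the ambiguous
ring excluded).

The geodesic metric lives on the 26-connected voxel graph: edge weight =
physical step length × mean endpoint penalty `w(I) = 1/(1 + (I/I_ref)²)`,
`I_ref` = median nonzero intensity, so bright structure is cheap to
traverse. Distances are exact (scipy Dijkstra, multi-source with
predecessors). Tree growth is a Prim adaptation over *seed/root nodes*: the
forest repeatedly attaches the unconnected seed with minimal geodesic
distance to any tree's connected seed or root (ties broken by tree id then
seed index), and the connecting geodesic path becomes the branch geometry.
Measuring attachment distance to seed nodes — rather than to every path
voxel — is what makes each tree's summed link cost exactly the minimum
spanning tree cost of the seed pairwise geodesic-distance matrix. Growth
stops at a configurable maximum link cost (preventing background bridging);
unreachable seeds are reported, and the number of trees always equals the
number of roots. Node radii for SWC are distance-map values at the node.

Dice-and-trace crops a box per microglia sized by the maximum expected
arbor length plus a neighbor-context margin; centroids inside the box join
as competing roots so arbors stop where a neighbour's territory begins, and
only the center cell's tree is kept. A seed claimed by two kept trees keeps
its lower-cost attachment; the losing tree's subtree at that seed is pruned
(ties to the lower cell id), keeping trees valid and the merge independent
of processing order.

## Morphometry and progression

Cable length sums inter-node Euclidean steps; branch points have ≥ 2
children; tips are non-root leaves; tortuosity per root-to-tip path is path
length over straight-line distance; hull volume is the convex hull of node
positions (zero for degenerate geometry). Single-node trees are flagged
degenerate with zero lengths. Grouping of morphological states is z-scored
k-means with 10 seeded restarts, and the progression summary orders clusters
by mean device distance, reporting per-feature Spearman rank correlations
against per-cell distance; both are documented simple stand-ins with stable
interfaces so richer co-clustering/progression methods can be plugged in.
All-equidistant cells flag the ordering unstable. Device distance is the
Euclidean distance transform of the mask complement, scaled by spacing and
sampled at centroids; representing the device as a voxel mask (rather than
an outline) is this package's generalization.

## Pipeline

Stage handoff is disk-mediated so any stage can be re-run alone; the run
record (CSV + text log) is append-only, one entry per executed stage with a
parameter snapshot, and duplicate stage ids or non-monotone timestamps are
rejected. Record timestamps are logical stage indices by default so that a
fixed config + seed reproduces every output byte for byte; wall-clock
timing, when wanted, belongs in external profiling, not in the artifact.
Per-stage seeds derive from the single configured seed by fixed offsets.
ROI overrides re-process a region with different parameters and blend with
a feather ramp that lives entirely inside the ROI, so voxels outside the
region are bit-identical to the base run; overlapping overrides with
conflicting parameters are rejected up front. The parallel dice map runs
dices on worker threads, retries a crashed dice once, and always merges in
canonical dice order — worker count is observably irrelevant. Dice size is
a configuration value: choose the largest dice whose padded volume (times
the number of workers) fits comfortably in memory.

## Problem sizes used in the tests

The test suite and examples run phantoms of 20–32 × 72–96 × 72–96 voxels
with 10–30 cells and 1–3 arbors, 2×2 tile grids, 400-signal planted
dictionary models, and 20-seed repetitions for the stochastic claims; these
sizes exercise every contract (dicing, merging, competition between roots)
while keeping a full suite run in the minutes range on one CPU. The same
code paths scale to larger volumes by raising the dice budget and worker
count.
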