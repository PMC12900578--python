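# Methods

`palatemark` localizes the twelve palatal gingival-margin landmarks (FDI
16..26 — the most apical point on the palatal gingival margin of each
maxillary tooth from first molar to first molar) on 3D dental-cast surface
meshes, using a two-stage coarse-to-fine scheme over point clouds. This
note records the model, its assumptions, the parameters that matter, and
the design choices made where the design was genuinely open.

## Pipeline

1. **Mesh → cloud.** One point per mesh vertex; normals are area-weighted
   averages of incident face normals (accumulated face cross products,
   unit-normalized). Isolated vertices are dropped. STL triangle soup is
   merged by exact bit-wise coordinate equality — scanner exports repeat
   shared vertices exactly, and tolerance welding could collapse fine
   gingival detail.
2. **Canonical orientation.** Principal axes of the positions map to
   x (widest = transverse), y (antero-posterior), z (flattest =
   occluso-palatal), with deterministic sign rules: z so the mean normal
   points occlusally (+z), y so the |y|-extreme point (the anterior
   incisor region) lies at negative y, x = y × z right-handed. This makes
   preprocessing annotation-free and bit-reproducible; casts oriented
   manually in other ways are handled identically after this step.
3. **Normalization.** Translate to the bounding-box centre and scale
   isotropically by 2 / (longest-axis extent) so the longest axis spans
   [-1, 1]; aspect ratios are preserved. The composed similarity
   transform is stored so every reported error is computed in cast-frame
   millimetres after inverse transformation.
4. **Farthest-point sampling** to a fixed budget (24,000 points at full
   scale). Greedy max-min selection with a deterministic start (the point
   farthest from the centroid) and lowest-index tie-breaks; a seed option
   allows randomized starts but is off by default so preprocessing is
   reproducible bit for bit.
5. **Coarse stage.** A hierarchical point-cloud encoder (three
   set-abstraction levels with query radii 0.025 / 0.1 / 0.2 in
   normalized units; ball-query grouping over farthest-point-sampled
   centres; shared per-point perceptrons; max-pooling) with three
   feature-propagation levels back to full resolution, then two parallel
   per-point heads: a softplus-positive distance-to-nearest-landmark head
   and a 3-vector offset head. The points with the smallest predicted
   distances, displaced by their predicted offsets, give 256 candidates
   (64 in the scaled profile).
6. **Clustering and labeling.** Candidates are grouped by DBSCAN
   (physical eps in mm, converted per cast via the stored scale) and
   resolved to exactly 12 groups: the 12 largest are kept when there are
   more, the largest are split by deterministic 2-means when there are
   fewer, and noise points are recruited by nearest centroid only when
   needed. Centroids acquire FDI identities from their position along the
   arch. Two policies exist: pure angular rank order (sweep from
   posterior-right to posterior-left about the centroid mean), and — the
   default inside the experiment pipeline — optimal one-to-one matching
   against an *arch template* of per-label mean positions computed from
   the training split's ground-truth annotations. Rank order is exact
   when the centroids contain one point per tooth, but a single
   duplicated or missed tooth rotates every label between the duplicate
   and the gap; template matching keeps such damage local. When a label's
   matched centroid lies farther than ``template_fallback_mm`` (default
   4 mm) from its template position — i.e. the coarse stage missed that
   tooth — the refinement patch is centred on the template position, so
   the scorer still searches the anatomically expected region of the
   actual cast.
7. **Refinement.** A 6 mm geodesic ball (shortest paths on a symmetrized
   k-NN graph, k = 8, bridged if disconnected) is extracted around each
   centroid, standardized to a fixed point count (farthest-point
   downsampling or cyclic padding with duplicate merging), re-centred,
   and scored by a small encoder-decoder of the same family; the final
   landmark is the patch point with the highest softmax probability,
   snapped to the cloud — never interpolated — and mapped back to mm.

## Training

Both stages use Adam. The coarse stage minimizes a composite loss:
Huber (delta = 1) distance supervision against the nearest-landmark
distance field, a Huber offset term (folded into the distance supervision;
a separate weight exposes it), a symmetric squared chamfer loss between
candidates and true landmarks, and a hinge separation loss
mean over pairs of max(0, margin − d)² with margin 0.05 normalized units.
Per-point targets use the *nearest* landmark — candidates are unlabeled
until clustering, which is only coherent under that formulation.

The refinement stage is supervised with a Gaussian heatmap
exp(−d² / 2σ²), σ = 1 mm, normalized over the patch, under softmax
cross-entropy, with global gradient-norm clipping at 0.5. Training
patches are centred on ground-truth landmarks (oracle-patch mode) by
default, which stabilizes early training; centring on coarse predictions
is a config option. Oracle centres receive seeded random offsets within
a 2 mm ball: with exact ground-truth centring the scorer can collapse to
"pick the point nearest the patch centre", which transfers nothing to
inference patches centred on coarse centroids. Best-validation
checkpoints are retained for both stages. Defaults: 50 epochs per stage,
learning rates 0.001 (coarse) and 0.002 (refine), batch size 2 casts;
the scaled-down profile raises the coarse learning rate to 0.005 and
enables a global max-pooled context feature before the heads, both
chosen on validation data — at its much smaller step budget the
full-scale settings underfit the offset field, leaving teeth without
nearby candidates.

The networks are implemented in a small NumPy reverse-mode autograd
engine (`_nn.py`) with deliberately coarse-grained primitives (fused
dense layers, gather/scatter, pooled reductions), so a training step is a
short chain of BLAS calls; grouping structures depend only on point
positions and are precomputed once per cast. Parameters are float32 by
default (float64 available via config, used by the finite-difference
gradient tests). No batch normalization is used; He initialization and
Adam suffice at these widths.

## Synthetic casts

No annotated cast collection is publicly deposited, so the package ships
a parametric generator used for training, testing and the worked
examples. A parabolic arch (arch_width = 36 mm midline-to-ridge
half-width, arch_depth = 42 mm) carries a gum ridge with six tooth bumps
per side; the palatal dome descends 14 mm inside the arch; each tooth has
a small gingival concavity on its palatal flank whose centre — the
analogue of the most apical palatal gingival-margin point — is known in
closed form from the arch parameterization, so ground truth never
involves an annotation step. The surface is an analytic height field over
a jittered grid (vertex count within 10% of the target; 12,000 default,
80,000 to emulate study-scale casts), with 0.05 mm Gaussian surface
roughness, random rigid pose (±20° per axis, ±10 mm), and per-cast shape
jitter (each length parameter × Uniform(0.9, 1.1)). Molar bumps are 1.6×
wider mesiodistally, reproducing the real difficulty gradient at molars.
Repeat-annotation noise (`perturb_landmarks`, default sd 0.15 mm per
axis) is calibrated so two-session mean pairwise distance
√2 · sd · 2√(2/π) ≈ 0.34 mm matches expert intraexaminer error.

What the generator does *not* emulate: rugae, crowding, missing or
ectopic teeth, gingival inflammation, scanner noise structure, or
mixed/primary dentitions. Passing tests therefore demonstrate the
pipeline's mechanics and trainability under controlled geometry, not
clinical-grade accuracy on real casts.

## Scaled-down profile

The default test/demo profile shrinks every budget so the full two-stage
pipeline trains on one CPU in minutes: 2,048-point clouds, 64 candidates,
256-point patches, halved channel widths, set-abstraction centre counts
(512, 128, 32), 16 neighbours per ball, DBSCAN min_samples 2 (about five
candidates land on each tooth, so two mutual neighbours already mark a
stable group), coarse learning rate 0.005, global context on. The full
profile keeps the study-scale constants (24,000 / 256 / 1,024,
min_samples 4, learning rate 0.001, no global context).

## Numerical choices and degenerate inputs

- Ties: FPS and candidate selection break ties to the lowest index;
  probability-map argmax merges padded duplicates by parent index first
  and then takes the lowest parent index.
- DBSCAN eps defaults to 3 mm physical; radii stated in mm are always
  converted through the per-cast scale.
- Rank-deficient covariance (collinear clouds), zero bbox extent, < 4
  mesh vertices, < 12 candidates, and zero-variance ICC inputs raise
  typed errors rather than producing silent results.
- Landmarks farther than numerically representable from a training patch
  raise a supervision-gap error and the patch is skipped with a count.

## Known limitations

- Geodesics are graph shortest paths on the sampled cloud, not exact
  polyhedral geodesics on the mesh; with k = 8 they overestimate true
  surface distance slightly, so geodesic balls are marginally
  conservative.
- The arch-template labeling and fallback assume the test casts share
  the training population's canonical-frame arch geometry; a cast with a
  radically different arch form (severe crowding, missing teeth) would
  defeat both the template matching and the fallback positions.
- The pure rank-order FDI assignment (used when no template is
  available, e.g. `predict` on a single mesh with ad-hoc checkpoints)
  assumes one resolved centroid per tooth and degrades globally when the
  coarse stage misses a tooth.
- Real-cast performance is untested by construction (no deposited data);
  the evaluation module is ready for manifest-driven runs on real
  STL + PickPoints pairs.
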