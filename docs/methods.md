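# Methods

This note documents the model implemented by `swmclust`, the parameters that
matter, the synthetic data the tests run on, and the numerical choices made
where the design was genuinely open.

## Fiber representation and distances

A fiber is an ordered polyline of 3-D world coordinates in millimetres,
resampled to a fixed count of points (default 51) equidistant along
cumulative chord length. Resampling preserves the endpoints exactly; all
thresholds in the method (5, 7, 10, 30 mm …) are metric, so voxel indices
never appear outside the parcellation container.

The working distance is the symmetrized maximum distance between
corresponding points,
`d_ME(A,B) = min(max_i ||a_i − b_i||, max_i ||a_i − b_(Np−1−i)||)`, i.e. the
largest pointwise gap in the better of the two fiber orientations. The
reversed orientation pairs index `i` with `Np−1−i` (0-based); this is the
reading under which a fiber and its reversal are at distance zero. d_ME is
symmetric, reversal-invariant in either argument, and invariant under a
common rigid motion; it is deliberately harsher than mean-of-closest-points
style distances because neighbouring short bundles differ only slightly
along their whole course.

For segmentation the distance is augmented with a dimensionless length
penalty, `dnf = (|l_A − l_B|/max(l_A, l_B) + 1)² − 1`, added when positive.
The penalty is bounded above by 3 and is zero for equal lengths. It is added
directly to a millimetre distance; the formula is implemented exactly as
stated by the method it reproduces, mixed units included.

## Clustering

Pairs with `d_ME ≤ d_clmax` (default 30 mm; useful values for fiber data lie
roughly between 15 and 45 mm) form a sparse graph with affinities
`a_ij = exp(−d_ij/σ²)`, σ² = 60 mm. The exponent is `d/σ²` as the method
defines it, not `d²/σ²`. Agglomeration repeatedly pops the globally best
affinity from a lazy max-heap, merges the two clusters, and updates
affinities to shared neighbours by the size-weighted mean of the children's
affinities, **restricted to edges that exist**: a child with no edge to the
neighbour contributes neither value nor weight, rather than an implicit
zero, so results do not depend pathologically on the cutoff. On a complete
graph this reduces exactly to textbook UPGMA, which is what the brute-force
oracle in the test suite checks. Ties on affinity break to the
lexicographically lowest cluster-id pair, making the merge sequence
deterministic. Clusters in different graph components can never merge, so a
graph with N elements and C connected components (isolated elements
included) yields exactly N − C merges and C dendrogram roots.

The dendrogram is cut adaptively, breadth-first from each root: a node whose
descendant fibers have maximum pairwise d_ME within `d_clmax` is emitted
whole, otherwise its children are examined; leaves fall out as singletons so
the partition is total. Per-node maxima are computed bottom-up with
memoization — each leaf pair is evaluated once, at its lowest common
ancestor, so the whole partition costs one all-pairs pass per component.

A cluster is *reproducible* when it contains fibers from at least
`ceil(min_frac × n_subjects)` distinct subjects (min_frac = 0.75; for a
37-subject group the cutoff is 28). The ceiling is computed on a value
rounded at 1e-9 to keep exact multiples (e.g. 0.75 × 36 = 27) from drifting
across the integer boundary.

## Selection, matching, bagging, labeling

Selection keeps centroids with native (pre-resampling) polyline length in
the inclusive window [35, 85] mm, then removes any centroid whose minimum
d_ME to a sampled deep-white-matter reference is strictly below 10 mm. The
reference sample is 20% per bundle, drawn without replacement from a fixed
seed; with a fraction of 1.0 the result is seed-independent.

Two group atlases are compared bundle-by-bundle: a fiber "intersects" the
other bundle when its nearest counterpart is strictly closer than 5 mm, and
a pair matches when both bundles' intersection fractions exceed 50%.
Multi-way overlaps resolve greedily by descending mean fraction, giving a
deterministic one-to-one matching; matched pairs are fused by fiber union.
An alternative bundle-distance mode (mean d_ME over all cross pairs, or
between reversal-aligned centroid fibers) is available for atlas-to-atlas
comparisons.

Bagging repeats the two-group construction on random subject subsets
(10 repetitions of 2 × 27 subjects at full scale; per-repetition RNG streams
derive from one master seed), computes one representative centroid per
bundle (pointwise mean after orienting every fiber to the first, choosing
the orientation with the smaller max gap), clusters the centroids with the
same machinery at the same `d_clmax`, and keeps clusters spanning at least
`min_votes` (8) distinct repetitions.

For labeling, each fiber is oversampled ×10 and each extremity probed up to
3 oversampled points inward for the first non-zero parcellation label
(Desikan–Killiany gyral ROIs; the corpus callosum label is legal but
flagged, since callosal lookalikes are removed upstream). The bundle's label
is the unordered ROI pair claimed by the largest fraction of its fibers,
provided that fraction reaches 50%; fibers whose pair cannot be determined
are excluded from the denominator by default (a strict mode counts them
against every pair). Names follow `<ABB1>_<ABB2>_<n><x>` with abbreviations
sorted within the pair, `n` assigned per pair in descending bundle size
(deterministic, where the original scheme assigned it arbitrarily), and
`x ∈ {i, l, r}`. Interhemispheric correspondence mirrors right bundles
across x = 0 (the plane is configurable) and reuses the intersection
criterion; symmetrized right bundles are exact reflections of the fused left
bundles.

## Segmentation and laterality

A subject fiber joins the atlas bundle minimizing `d_MEn` iff that minimum
is within the bundle's threshold. Thresholds scale linearly with mean bundle
length, [35, 85] mm → [6, 8] mm, clamped outside the window; they may be
overridden per bundle. Assignment is unique (arg-min), keeping volumes
well-defined. Bundles with fewer than 10 assigned fibers count as absent.

Bundle volume is measured on a 2 mm isotropic grid anchored at the origin
with half-open cells: a voxel belongs to the mask when at least 2 *distinct*
fibers have a point in it (several points of one fiber count once; per-point
counting is available as an option). `LI = (R − L)/(R + L)` is undefined
when both volumes are zero and reported as missing. The volume t-test is the
classical pooled-variance unpaired two-tailed test (Welch optional, off by
default); identical constant samples return t = 0, p = 1 instead of an
undefined statistic. No multiple-comparison correction is applied by
default.

## Synthetic populations

The generator emulates only the geometry the pipeline is sensitive to:
U-shaped arcs (a straight chord plus a `sin^p` bump of given apex depth)
whose endpoints sit inside small box ROIs of a synthetic parcellation. When
a target length is requested, the bump exponent is solved numerically so the
arc length lands within 2%. Each subject carries a jittered copy of each
template — one rigid offset `N(0, σ)` per fiber plus smoothed per-point noise
of σ/4, keeping `d_ME(fiber, template)` within a few σ — with a per-template
presence probability, plus subject-unique random distractor arcs kept at
least 30 mm (the clustering cutoff) from every template so they can never
join a template cluster. All randomness flows from one master seed through
per-(subject, template) substreams.

What passing tests show, and what they do not: the synthetic fibers are
smooth, well-separated, and jittered isotropically, so the tests demonstrate
the correctness of the algorithmic chain (selection, clustering, matching,
voting, labeling, segmentation), not robustness to registration error,
partial-volume truncation, crossing-fiber artifacts, or parcellation noise
of real data.

The default study conditions for the end-to-end checks are two groups of
8 subjects, 10 templates at presence 0.9, jitter σ = 1 mm, 20 fibers per
bundle and 50 distractors per subject. Note that with 8 subjects the 75%
rule requires 6; at presence 0.9 a template lands in at least 6 subjects
with probability ≈ 0.96 per group, so some seed draws genuinely leave a
template below the reproducibility cutoff. Dropping it is then the *correct*
output, and the acceptance script therefore also reports recovery restricted
to templates the sampled population makes eligible.

## Problem sizes and determinism

The acceptance computations run at desk scale: 20 random clustering
instances of up to 50 elements against the dense oracle, 100 random
partitions for soundness/maximality, 1000 random fiber pairs for the metric
identities, the 8-subject two-group pipeline above, and 1000 null
simulations for t-test calibration. A full two-group build at this scale
(~1,800 pooled centroids per group) takes well under a minute per group on
one CPU; runtime is dominated by the exact all-pairs sparse distance pass,
which is block-vectorized and computes one square root per pair. All stages
are deterministic given a seed: RNG substreams are derived, ties break
lexicographically, and outputs (manifests, atlases) are byte-stable.

## Known limitations

- The average-link variant on *sparse* graphs is one of several defensible
  readings of "average-linkage restricted to existing edges"; the weighting
  is configurable in spirit (the complete-graph case is oracle-anchored, the
  sparse case is documented above).
- `bundle_mean_distance` between bundle *sets* has two modes (all-pairs
  mean, centroid-to-centroid) because the operational definition is
  ambiguous in the literature this follows; all-pairs is the default.
- Registration is consumed, never estimated: affine matrices and
  displacement fields are applied to coordinates (trilinear interpolation,
  nearest-edge displacement outside the field, with a logged warning).
- The segmentation threshold's length dependence ("6–8 mm according to
  bundle length") is made concrete as a linear map; other maps are easily
  substituted per bundle.
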