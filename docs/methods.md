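# Methods

## Scope and model

`cdrmap` analyses one CDR type at one IMGT loop length at a time. The
working assumption is the canonical-form model: CDR loops (other than
CDRH3) of a given length cluster into a small number of backbone
conformations, each associated with a sequence motif. The pipeline treats
conformational space as the set of loop backbones expressed in a common
reference frame, clusters it by density, and interprets clusters through
the annotations of their experimentally determined members.

Coordinates are consumed as-is: residue numbers in input structures are
trusted to be IMGT positions, and no renumbering is attempted. Numbering
consistency is the responsibility of upstream tooling; the package only
checks chain plausibility (length ≥ 70, start < 8, end > 120).

## Distances

**Common-frame RMSD.** After all chains are superposed onto one template by
an anchor-Cα Kabsch fit, loops are compared without per-pair refitting.
This makes the distance a true metric on the template frame (the triangle
inequality holds), which density-based clustering implicitly relies on.
The 1.5 Å framework-fit filter is strict: a fit of exactly 1.5 Å passes.

**Normalized DTW.** For mismatched lengths, dynamic time warping runs over
the two backbone atom sequences (N, CA, C per residue, in that order) with
squared Euclidean step cost, the classic step set {(1,0),(0,1),(1,1)} and
no window or slope constraint. The raw score (square root of the optimal
path cost) is rescaled by `sqrt(1/n_max)` with `n_max` the larger atom
count, putting it on the RMSD scale. For matched lengths the diagonal path
is always admissible, so normalized DTW ≤ common-frame RMSD, with equality
whenever the diagonal is the optimal path — the two metrics are close but
not identical on matched lengths, and only the inequality is guaranteed.
The DP kernel is numba-compiled when numba is importable; a pure-Python
fallback computes identical values.

## DBS cluster selection

DBSCAN needs min-points and epsilon; both are derived from the data.

* **min-points** = round(√(N/2)) by default (round(√N) as the alternate
  rule), floored at 2, with round-half-even rounding. The √(N/2) rule is
  the default; the √N alternate is stricter and can split subtle clusters
  that √(N/2) merges.
* **epsilon** comes from the sorted K-th-nearest-neighbour distance curve
  for K in 2..5. The elbow is the point of maximum perpendicular distance
  to the chord joining the curve's endpoints, taken on the convex
  (below-chord) side — the knee where the ascending k-distance plot turns
  upward. The unsigned variant can land on a concave bulge near the start
  of the curve, selecting an epsilon below the intra-cluster distance scale
  and shattering genuine clusters; the signed rule avoids this while
  agreeing with the unsigned one on cleanly two-segment curves. A purely
  concave curve falls back to the above-chord bend; a constant curve has no
  elbow and returns its value with a warning.
* **run selection**: of the four (K, epsilon) runs, the one whose DBSCAN
  cluster count equals its K wins; several matches resolve to the largest
  K, no match to the closest count at the highest K.

DBSCAN itself is implemented in-package on the precomputed matrix so that
border-point assignment is deterministic: a point counts itself among its
neighbours, core points connect at distance ≤ epsilon, and a border point
joins the first core point that reaches it in lexicographic ID order.
Labels are renumbered 1..k by descending cluster size; noise is −1.

## Cluster profiles

The cluster *centroid* is implemented as the medoid — the member minimizing
the summed distance to all other members (ties to the smallest ID). A
medoid is a real loop, so centroid–centroid distances are matrix lookups
and remain well-defined across metrics.

Logos are bitwise: per position, residue frequencies over the 20 standard
amino acids and information content `log2(20) − H` in bits, with no
small-sample correction. The consensus motif cases each position by the
top-residue frequency: uppercase ≥ 0.75, lowercase ≥ 0.35, `x` otherwise.
The thresholds are configurable; the defaults map fully conserved positions
to uppercase and flat columns to `x`, matching the conventional cased-motif
style. Note that deduplicating predicted loops to non-redundant sequences
flattens the frequency spectrum (the dominant sequence collapses to one
copy), so consensus motifs computed over non-redundant members are
systematically less emphatic than over raw draws.

Novelty calls work on the canonical-form tallies of experimental members
only (predicted loops have no annotations): a cluster with no experimental
members, or mostly unassigned ones (≥ 0.6), is a NOVEL_CANDIDATE; two or
more clusters sharing a majority label are SUBDIVISIONs of that form; a
cluster holding its majority label alone is KNOWN. Clusters whose
experimental members are assigned but mixed below the 0.6 purity threshold
are conservatively reported KNOWN. LENGTH_INDEPENDENT_CANDIDATE is set only
by the cross-length pass and takes precedence over NOVEL_CANDIDATE.

## Cross-length analysis

Length independence is tested medoid-to-medoid: a novel cluster at length
L+1 is flagged when its normalized-DTW distance to the nearest length-L
cluster medoid is smaller than to every cluster of its own length, and that
nearest cluster becomes its origin. Only length L (exactly one residue
shorter) is searched, matching the single-insertion mechanism being tested.
Because each length is analysed in its own template's frame, the shorter
analysis' medoids are first mapped into the current frame by a Kabsch fit
of the two templates' anchor Cα sets (the anchors are the same IMGT
positions for all lengths of a CDR).

The sequence-level signature of an insertion is a logo column with
top-residue frequency < 0.3 between neighbours ≥ 0.5; deleting that column
from the novel consensus and scoring positional identity against the origin
consensus gives the motif-match fraction. Without such a column the best
single-deletion alignment is reported and flagged.

## MDS

Classical (Torgerson) scaling: double-centre the squared distances, take
the top two eigenpairs, clamp negative eigenvalues to zero. It is
deterministic and exact (stress 0) for any configuration realizable in two
Euclidean dimensions. Above 500 points (configurable) a landmark variant
embeds the first 500 ID-sorted points exactly and places the rest by
distance-based triangulation against the landmarks. Embeddings are defined
only up to rotation, reflection and translation; all comparisons go through
pairwise distances, never raw coordinates.

## Synthetic data

The generator emulates the statistical regime the analysis assumes:

* several conformational clusters per CDR/length, built as cubic Bézier
  curves between the framework anchor flanks with randomized control
  points; each non-reference cluster's base is rescaled until its
  common-frame RMSD from the first cluster's base is within 10% of its
  target separation (targets within the 0.4–4.3 Å span seen in real loop
  data; `target_separation` is defined relative to the first cluster);
* member loops = base + isotropic Gaussian coordinate noise (default
  0.1 Å), kept well below inter-cluster separations (a 4× floor is
  enforced at spec construction);
* cluster sequences sampled around a motif: each position emits the motif
  residue with probability `conservation` (default 0.9), otherwise uniform
  over the other 19; `x` positions are uniform over all 20;
* a minority annotated "experimental" subset (including unassigned "*"
  loops) and a much larger "predicted" subset (the packaged example uses
  20× — the real data regime is 10–100×), with per-loop resolutions and one
  best-resolution representative per labelled cluster so template selection
  works;
* optional insertion variants: a length-(L+1) cluster whose coordinates
  re-interpolate the source cluster's mean backbone by arc length with one
  extra residue (preserving the shape, hence a small DTW to the source) and
  whose sequences carry a uniformly random residue at the insertion site
  (producing the flat logo column);
* emitted datasets graft each loop onto an idealized full-domain framework
  chain (IMGT 1–128), add per-chain framework noise (default 0.05 Å) and a
  random rigid motion, and write plain PDB files plus the annotation table
  (experimental loops only) and a ground-truth table. All randomness flows
  from the single spec seed.

Loop geometry is smooth-curve interpolation, **not** valid stereochemistry:
the pipeline consumes only backbone coordinates, so bond-geometry realism
is unnecessary. Real data additionally contains framework conformational
variation correlated with loop shape, non-Gaussian coordinate error,
density-dependent annotation coverage and genuinely ambiguous boundary
loops — none of which the generator reproduces. Passing tests therefore
demonstrate the correctness of the machinery under the canonical-form
model's assumptions, not performance on real structures.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale: tens of loops per
planted cluster (hundreds per analysis), which is ample to resolve clusters
separated by ≥ 5× the coordinate noise. The batched distance-matrix path
is exercised at small batch sizes; the 42 000 default mirrors the intended
production batch. Degenerate inputs are handled explicitly: collinear point
sets are rejected by the superposition (the rotation is underdetermined),
constant k-distance curves warn, an all-noise clustering is a valid result
with zero clusters, and reflections are never accepted as rotations.
Rounding in reported percentages is decimal half-up (not float half-even),
matching how such tables are conventionally printed.

## Known limitations

* Epsilon selection inherits the brittleness of any automatic elbow rule on
  nearly featureless k-distance curves; the selection trace (per-K epsilon
  and cluster count) is always emitted so a run can be audited.
* Cross-batch distances are never computed; clusters split across batches
  are reported per batch, as in the batched production analyses.
* The AHo length lookup is a literal 17-row table; it deliberately refuses
  to extrapolate, and one published row (H2, IMGT 10) is internally
  inconsistent with its form name — the printed value is stored and a
  warning raised on access.
* CDRH3 is accepted only behind an explicit opt-in: its space lacks
  high-density clusters and central motifs, so DBS calls there are
  unreliable.
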