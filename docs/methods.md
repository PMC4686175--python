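# Methods

## Model

A tracking result over an `N`-frame series is the quadruple `(Θ, P, I, T)`:
tracks `θ_i` (maximal gap-free temporal series of markers sharing a positive
label), the parent function `P` mapping each descendant track to the track it
descends from (or none), and the initial/terminal frame functions `I`, `T`.
A marker is the full pixel/voxel support of one label in one frame; it need
not be connected, and both full segmentation masks and single-pixel expert
dots are plain markers — the model makes no distinction. Frames are 0-based;
coordinates are integer grid points (no sub-pixel support).

The corresponding acyclic oriented graph has one vertex per marker and an
edge `(M_i^t1, M_j^t2)` iff either `i = j, t2 = t1 + 1` (TRACK semantics) or
`i ≠ j, t1 < t2, T(θ_i) = t1, I(θ_j) = t2, P(θ_j) = i` (PARENT semantics).
Parent links cover both division and re-appearance after a temporal gap; a
track may have more than two children (abnormal division). Validation rejects
a parent whose terminal frame is not strictly before the child's initial
frame, temporal gaps inside a span, stray markers, and within-frame pixel
overlap; arbitrarily long parent-child gaps are accepted (any `t1 < t2`).
Since every edge points forward in time, acyclicity is structural; the test
suite re-checks it with an independent topological-sort oracle.

## Matching and error counting

The detection test `|R ∩ C| > 0.5·|R|` is strict: covering exactly half
fails. This matters for rasterized fixtures that can hit the boundary
exactly, and it is what guarantees uniqueness — at most one computed marker
within a frame can hold a strict majority of a reference marker, because
computed markers are disjoint. The implementation still asserts uniqueness at
run time; a violation indicates overlapping computed markers that escaped
validation. A reference dot lying entirely inside a large computed region is
covered 100 % and matches, consistent with dot-style ground truth.

Two edges match iff both endpoint detection tests pass *and* the frame
indices agree at both ends; a reference edge spanning `(t1, t2)` can only
match a computed edge spanning `(t1, t2)`. Edge errors are counted on the
induced subgraph over uniquely matched computed vertices only. A matched edge
pair with differing semantics counts once as EC and never additionally as
missing. The missing-edge tally EA counts the reference-side set of
unmatched reference edges.

`NS = TP − |{computed vertices with ≥ 1 reference assigned}|`, i.e. the
total fiber excess `Σ (m − 1)` over non-split vertices. `m*` is the largest
fiber over non-split vertices and is defined as 1 when there is none, which
makes the minimality condition `w_NS·(m*−1) ≤ w_FP + w_FN·m*` vacuously
satisfiable. The condition is also reported in its input-independent weakened
form `w_NS ≤ w_FN`. Edge operations are taken as mutually irreplaceable, so
no edge-level minimality check is attempted.

## Aggregation and numerics

Weights must be non-negative with at least one positive. Aggregation is done
in exact rational arithmetic (integer counts, decimal weights) and surfaced
as a float, so the 1.5 edge-adding weight can never introduce rounding noise
into equality assertions. FULL = DETECTION + ASSOCIATION holds exactly by
linearity. Normalized rates divide NS/FN/FP by the reference vertex count and
ED/EA/EC by the reference edge count; zero denominators yield NaN with an
explicit `*_defined` flag rather than an exception.

Temporal evolution recomputes the comparison per frame prefix rather than
incrementally — `O(N)` full comparisons, but each entry is unambiguously the
measure of the truncated pair, and the series is provably non-decreasing
(extending a prefix never unmatches a vertex or edge).

## Ranking and weight sensitivity

Rankings are ascending in the measure value; exact ties share a rank and are
reported explicitly, never broken silently — borderline configurations in
weight space are precisely the sector boundaries. Transpositions are Kendall
discordant pairs. Sector maps sample rankings on a uniform grid (default
201×201) over a 2-D rectangle of weight space with the remaining weights
fixed; grid sampling replaces exact linear-inequality polygon arithmetic
because the sectors are polygonal (the measure is linear in the weights), so
refinement error is bounded by the perimeter cells — a property the tests
check. Cells landing exactly on a tie line go to a "tie" pseudo-sector. The
reference ranking is taken at the domain centre by default.

## Synthetic lineages and error injection

The generator emulates the events a time-lapse field of view produces:
random-walk migration, division into two daughters, disappearance (death or
exit), appearance (entry). Markers are axis-aligned squares of side
`2·radius + 1`, kept at Chebyshev separation `≥ 2·radius + 1 + min_gap`, so
within-frame disjointness holds by construction and overlap arithmetic in
tests is exact. Defaults (12 frames, 96×96 field, 6 initial cells, radius 2,
division 0.04 / disappearance 0.02 per cell-frame, appearance 0.1 per frame,
step ≤ 3 px) give small, readable lineages with a realistic event mix —
mostly migration with occasional divisions — while staying far from
placement deadlock; a boxed-in cell falls back to a long jump rather than
failing. One integer seed, one generator stream, no global state.
Re-appearance after a gap is not generated (it is still modelled and tested
via explicit fixtures).

The error injector applies six edit types, each realizing exactly one error
type, and predicts the resulting counts *combinatorially* from the local
lineage topology — by enumerating which reference edges lose their
counterpart — never by running the matching machinery, so recovery tests are
a genuine dual route. Edits claim their lineage neighbourhood (track, parent,
children); scripts with overlapping claims are rejected, which makes the
per-edit deltas additive:

| edit | computed-side change | predicted delta |
|------|----------------------|-----------------|
| DeleteVertex (interior) | track split, tail orphaned, children re-anchored to the tail | FN+1, EA+2 |
| AddSpurious | single-marker track in free space | FP+1 |
| Merge (span-identical pair) | one track of union markers over f frames | NS+f, EA+2(f−1)+incident parent/child links |
| CutEdge | tail after the cut becomes an orphan | EA+1 |
| AddFalseEdge | orphan track gains a fabricated parent | ED+1 |
| FlipSemantics | one daughter continues the mother's label; siblings orphaned | EC+1, EA+#siblings |

Child re-anchoring after DeleteVertex/CutEdge keeps the computed parent edge
on the true terminal marker, so no spurious ED appears; orphaning siblings in
FlipSemantics is forced by well-formedness (the extended mother no longer
terminates before them).

What the generator does **not** emulate: realistic cell shapes and
intensities, contact and crowding, segmentation noise at marker boundaries,
partial (sub-majority) overlaps, and temporal gaps. Passing recovery tests
therefore certifies the graph machinery and counting rules, not robustness to
boundary-accurate segmentation errors — which the measure by design does not
score.

## Worked-example fixture

The repository's worked example (`aogm/examples.py`, committed as JSON under
`tests/data/`) is a synthetic 5-frame pair assembled from seven spatially
disjoint canonical failures, constructed so that the comparison yields
NS=5, FN=5, FP=3, ED=1, EA=16, EC=2 with 20 true positives and 15 matched
computed vertices (25 reference vertices, 18 reference edges, m*=2). Each
sub-scenario's contribution was derived by hand from the counting rules; the
pipeline, the CLI and the acceptance script all reproduce the tallies
exactly, and at the default weights the pair prices at 105.0 (78 detection +
27 association).

## Problem sizes and tolerances

All tallies and recoveries are integer-exact; no tolerances apply to counts.
Float comparisons (aggregation, sector areas) are exact where rational
arithmetic guarantees it and use small relative bounds only for grid-area
stability. The standard test/verification sizes — 9–10-frame, 6-cell
lineages for recovery (500 pairs), ≤ 12-marker instances for the brute-force
matcher oracle (200 trials), 100 identity checks — keep the full suite around
ten seconds while exercising every code path; the counts are chosen as the
package's own verification budget.

## I/O

The directory dialect follows the de-facto challenge convention:
`mask%03d.tif` / `res_track.txt` for results, `man_track%03d.tif` /
`man_track.txt` for references, lineage lines `label begin end parent` with
parent 0 meaning none. Masks are written as 16-bit unsigned (labels above
65535 are rejected); 3-D markers become multi-page TIFFs with explicit
`minisblack` photometry. Reads always cross-check mask support against
lineage spans and re-validate the result. The JSON fixture dialect exists so
tests and the acceptance script never depend on the inferred image-directory
convention; both dialects round-trip losslessly and byte-stably.
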