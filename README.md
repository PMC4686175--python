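# aogm — cell tracking accuracy by acyclic oriented graph matching

Automated cell tracking turns a time-lapse microscopy series into a lineage
forest: which segmented object in frame *t* is which object in frame *t+1*,
where cells divide, die, or enter and leave the field of view. Comparing
tracking algorithms needs a single accuracy number that penalizes *every* kind
of tracking mistake — missed and spurious detections, undetected divisions,
and wrong temporal links — not just track-completion ratios. `aogm` provides
that number for developers and analysts benchmarking or tuning cell-tracking
pipelines against a ground-truth reference.

## The measure

A tracking result over `N` frames is a quadruple `(Θ, P, I, T)`: tracks
(gap-free series of labelled markers, each marker a pixel/voxel set), a parent
function, and per-track initial/terminal frames. It maps onto an acyclic
oriented graph whose vertices are markers and whose edges are *track links*
(consecutive markers of one track) or *parent links* (track terminal to
descendant initial — division, or re-appearance after a gap).

A reference marker `R` is assigned to a computed marker `C` in the same frame
iff `|R ∩ C| > 0.5·|R|` (strict majority). Disjointness of computed markers
makes the assignment unique without any optimization. From it the six error
counts follow:

| count | meaning | correction operation |
|-------|---------|---------------------|
| `NS`  | reference markers clustered inside shared computed markers (TP minus computed vertices with ≥ 1 assignment) | split vertex |
| `FN`  | reference markers detected by nothing | add vertex |
| `FP`  | computed markers detecting nothing | delete vertex |
| `ED`  | redundant computed edges | delete edge |
| `EA`  | reference edges with no counterpart | add edge |
| `EC`  | matched edges with wrong track/parent semantics | alter semantics |

Edge errors are evaluated on the *induced subgraph* of uniquely matched
computed vertices: edges touching false-positive or non-split vertices vanish
for free when those vertices are deleted or split. The measure is

```
AOGM = w_NS·NS + w_FN·FN + w_FP·FP + w_ED·ED + w_EA·EA + w_EC·EC
```

with non-negative weights (default `5, 10, 1, 1, 1.5, 1`, the reference
configuration of the first Cell Tracking Challenge). Zeroing the edge weights
gives the detection-only variant AOGM-D; zeroing the vertex weights gives the
association-only variant AOGM-A; FULL = D + A. When
`w_NS·(m*−1) ≤ w_FP + w_FN·m*` (largest fiber `m*`), the value is the
*minimum* cost of transforming the computed graph into the reference one.

The package also ranks multiple algorithms' counts under a weight
configuration, counts ranking transpositions (Kendall distance), maps ranking
sectors over 2-D rectangles of weight space, computes per-frame prefix
evolution of the measure, and ships a seeded synthetic lineage generator with
a six-edit error injector whose expected counts are derived independently of
the matching machinery — the package's self-contained test surface.

## Worked example

The repository ships a 5-frame fixture pair exhibiting all six error types
(`tests/data/worked_example_*.json`, also constructible via
`aogm.worked_example()`):

```python
from aogm import worked_example, compare, aggregate, CHALLENGE_WEIGHTS

ref, comp = worked_example()
report = compare(ref, comp)
print(report.counts.as_tuple())          # (5, 5, 3, 1, 16, 2)
print(report.classification.tp)          # 20
print(report.classification.matched_comp)  # 15
print(aggregate(report.counts, CHALLENGE_WEIGHTS))  # 105.0
```

The counts read: 5 splits are needed (two merged-daughter scenarios), 5
reference markers were missed, 3 computed markers are spurious, 1 computed
link is redundant, 16 reference links lack a counterpart, and 2 links have
the wrong semantics (a division reported as plain continuation and vice
versa). At the challenge weights the transformation cost is
`5·5 + 10·5 + 1·3 + 1·1 + 1.5·16 + 1·2 = 105`.

The same comparison from the shell:

```
aogm evaluate --ref tests/data/worked_example_reference.json \
              --res tests/data/worked_example_computed.json --json report.json
```

Other subcommands: `aogm simulate` (synthetic reference + corrupted copy +
expected counts), `aogm sweep` (weight-space sector map from evaluation
reports).

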