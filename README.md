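# braingraph

Graph-theoretic analysis of grayscale brain images for dementia staging:
pixel-similarity graphs, distance-based topological indices, Watts–Strogatz
(WS) small-world normalization, and multi-stage classification.

## The problem and the approach

Structural change in dementia shows up as disruption of brain-network
organization. This package implements a fully interpretable pipeline that
represents each grayscale image (e.g. a T1-weighted MRI slice) as a graph
and stages disease from six numbers describing that graph:

1. **Pixel graph.** For an image with `mn` pixels, the Brightness Distance
   Matrix `L(p,q) = |Lum(p) − Lum(q)|` is min-max normalized to
   `L_n ∈ [0,1]`; pixels `p ≠ q` are joined iff `1 − L_n(p,q) ≥ τ`
   (default τ = 0.95). The graph's largest connected component is kept.
2. **Topological indices.** With `α_r, α_s` the numbers of vertices
   strictly closer to each endpoint of edge `rs`:
   `Sz = Σ α_r α_s`, `ABC = Σ √((α_r+α_s−2)/(α_r α_s))`,
   `PI = Σ (α_r+α_s)`, `MO = Σ |α_r−α_s|`, `NGG = Σ 1/√(α_r α_s)`,
   and the Wiener index `W = Σ_{pairs} ρ(r,s)`. A graph with `MO = 0` is
   distance-balanced — the unrewired WS ring lattice is an example, and
   the package ships both a closed-form expression for the lattice's
   `α` counts and a BFS audit of it.
3. **WS normalization.** Each index vector is divided by the mean index
   vector of a matched WS ensemble (same vertex count, δ ≈ mean degree,
   rewiring probability 0.25), the small-world analogue of C/C_rand
   scaling.
4. **Classification.** SMOTE-balanced, stratified 5-fold cross-validation
   of decision-tree, logistic, RBF-SVM (σ = 1) and multilayer-perceptron
   models on the six normalized features, with accuracy, weighted
   precision/recall/F1, one-vs-rest AUC and confusion matrices per fold.

A built-in synthetic generator produces 4-class image sets whose
intensity-histogram structure induces separable graph-index distributions,
so the whole pipeline is testable without any external data. See
`docs/methods.md` for models, defaults, and design decisions.

## Worked example

```bash
braingraph simulate-data --n-per-class 2 --out-dir data --seed 1
braingraph build-graph --input data/img00000_c0.png --tau 0.95 \
    --resize 16x16 --out g0.edgelist
# -> tau=0.95 vertices=244 edges=12812
braingraph indices --graph g0.edgelist --out idx.csv
cat idx.csv
# graph_id,Sz,ABC,PI,MO,NGG,W,v,edges,C_cc,L_apl
# g0,22357929.0,4366.332581,1148604.0,583564.0,954.26801,59417.0,244,12812,0.804114,2.004216
```

The stage-0 image's 16×16 pixel graph keeps 244 of 256 pixels in its main
component with 12,812 edges; its Mostar index 583,564 (far from 0) says
the graph is strongly distance-unbalanced, and the clustering coefficient
0.80 with average path length 2.0 is the high-clustering/short-path
signature of a small-world-like, histogram-dense image.

A full run — synthetic images → features → cross-validated staging:

```bash
braingraph simulate-data --n-per-class 8 --out-dir data8 --seed 1
braingraph run --input-dir data8 --ws-reps 2 --model tree --seed 1 --out-dir out8
# -> mean accuracy 0.6190 -> out8/report.json
```

With only 8 images per class and a plain decision tree this already beats
the 0.25 chance rate; the report JSON carries per-fold metrics, confusion
matrices, the exact configuration and its hash.

The ring-lattice closed form can be audited against BFS ground truth:

```bash
braingraph theorem1 --v-range 8:20 --out thm.csv
# -> 77 cases, 36 disagreements        (all on the gamma < u branch)
```

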