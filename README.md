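# domainmatch

Training-set selection for robust egg-crack detection under domain shift.

Machine-vision crack detectors trained on one acquisition setup (one egg
origin, one camera rig, one cleaning status) degrade badly on images from a
new production site. When several annotated *domains* are available but the
deployment domain is unknown, the question is which domains to train on.
`domainmatch` implements a distance-based answer: quantify the pairwise
distribution shift between candidate training domains with a
quadratic-kernel maximum mean discrepancy (NSFE-MMD), then train on the
**maximally distant, semantically consistent pair** — the pair that spans
the widest swath of appearance space and therefore pushes a detector toward
domain-invariant features.

## Method

Given per-image feature vectors φ(x) for two domains with samples
{x₁…x_n} and {y₁…y_m}, the squared MMD is estimated by kernel sums

    MMD²(X, Y) = 1/(n(n−1)) Σ_{i≠j} k(x_i, x_j)
               + 1/(m(m−1)) Σ_{i≠j} k(y_i, y_j)
               − 2/(nm)     Σ_{i,j} k(x_i, y_j)

with the bandwidth-free quadratic kernel

    k(x, y) = (x · y)²,

which compares the *second-moment structure* of the feature vectors: the
biased (V-statistic) version equals ‖(1/n)Σxᵢxᵢᵀ − (1/m)Σy_jy_jᵀ‖²_F
exactly, an identity the test suite uses as an independent oracle. Pairwise
distances over a candidate domain set are normalized by the maximum
off-diagonal entry (NSFE normalization), so the most dissimilar pair scores
exactly 1.0 and values are comparable across feature spaces. Selection
returns the arg-max pair, subject to all domains sharing an identical
ordered label space.

The package also contains everything needed to validate the strategy
without any real data: a YOLO-format dataset reader/writer, a seeded
synthetic generator for multi-domain egg imagery (static single-egg
light-box frames vs. dynamic multi-egg conveyor frames, washed vs. dirty
shells, controllable blur / background / shell-color shift), standard
detection metrics (greedy IoU-0.5 matching, all-point-interpolated AP,
mAP@0.5), and a deterministic proxy detector (Otsu segmentation + boosted
trees on patch histograms) for comparing single-domain (SDT), multi-domain
pair (MDT), and all-domain (ADT) training on a withheld unknown domain.

## Worked example

```python
from domainmatch import (PRESETS, FeatureConfig, generate_domain,
                         domain_feature_matrices, pairwise_nsfe_mmd,
                         select_training_pair, run_benchmark)

# three known domains: static/washed single-egg, dynamic/unwashed,
# dynamic/washed — plus an unknown-origin test domain
known = [generate_domain(PRESETS[k], 30, seed=1000) for k in ("d1", "d2", "d3")]
mats = domain_feature_matrices(known, FeatureConfig())
dist = pairwise_nsfe_mmd(mats, estimator="unbiased")
print(dist.to_text_table())
sel = select_training_pair(dist, known)
print(f"selected pair: {sel.pair}  distance: {sel.distance}")

unknown = generate_domain(PRESETS["d4"], 20, seed=5000)
res = run_benchmark(known, unknown, modes=("SDT", "MDT_selected", "ADT"))
print(res.to_text_table())
```

prints

```
Domain Pair	NSFE-MMD
d1-d2	0.11
d1-d3	1
d2-d3	0.47
selected pair: ('d1', 'd3')  distance: 1.0
Method        d1  d2  d3  Precision  Recall  mAP.5
SDT           x           0.627      0.627   0.335
SDT               x       0.912      0.912   0.823
SDT                   x   0.676      0.676   0.552
MDT_selected  x       x   1.000      1.000   1.000
ADT           x   x   x   0.985      0.985   0.980
```

The static light-box domain (d1) and the heavily blurred bright conveyor
domain (d3) are the most dissimilar pair (normalized distance 1.0), so they
are selected as training data. On the unknown domain — a new site whose
frames alternate between a dark/sharp and a bright/blurred regime — the
detector trained on that pair (mAP 1.000) beats every single-domain model
(best 0.823) and slightly exceeds training on all three domains (0.980),
which dilutes the extremes with redundant middle-ground data.

The same pipeline is scriptable from the shell:

```
domainmatch make-synthetic --preset d1 --n 100 --seed 7 --out data/d1 --manifest study.yaml
domainmatch distances --manifest study.yaml --out dist.csv
domainmatch select --distances dist.csv --manifest study.yaml --mode mdt --out train/
domainmatch benchmark --manifest study.yaml --unknown d4 --out results/
```

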