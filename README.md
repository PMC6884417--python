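# blastoquant

Quantitative tools for a classic question in early mouse development: are
the first two blastomeres of the 2-cell embryo equally totipotent? When a
2-cell embryo is bisected and the halves are grown separately as
monozygotic twins, the twin blastocysts often differ sharply in their
epiblast (EPI, NANOG⁺) cell counts even though trophectoderm (CDX2⁺)
counts stay balanced — and the imbalance traces back to unevenly
distributed maternal mRNA in the oocyte, visible by single-molecule FISH.

`blastoquant` implements the three quantitative pillars of that analysis,
plus a synthetic-data generator with known ground truth so the whole
pipeline is testable without any microscope or download:

* **FISH signal eccentricity** — for an ROI on a 10-slice equatorial
  maximum-intensity projection, the distance between the unweighted pixel
  centroid and the intensity-weighted centre of mass:
  `E = sqrt(Δx² + Δy²)`. `E = 0` for uniform signal; inhomogeneous mRNA
  distributions push the centre of mass away from the centroid. Batches
  share one contrast window; groups are compared with a two-sided
  (exact, for small n) Wilcoxon/Mann–Whitney rank-sum test.
* **Twin-pair lineage statistics** — per-pair, per-germ-layer
  `C_high/C_low` ratios (balance ≈ 1, imbalance ≫ 1), the ≥ 4 EPI-cell
  sufficiency proportion with an optional ≥ 50-cell filter,
  complete-pair/singleton accounting of developmental endpoints, and the
  Fisher exact allocation test.
* **Twin-pair recovery by clustering** — hierarchical clustering of
  germ-layer count vectors or blastomere transcriptomes; a pair counts as
  recovered iff its members are dendrogram siblings. Includes the
  per-gene interblastomere ratio / coefficient-of-variation ranking and a
  simulated chance-level null.

See `docs/methods.md` for the models, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from blastoquant import (
    ImageSimParams, generate_embryo_stack,
    equatorial_projection, derive_rois,
    batch_eccentricity, compare_groups,
)

def batch(distribution, g, n, seed0):
    items = []
    for i in range(n):
        p = ImageSimParams(image_shape=(96, 96), n_slices=11,
                           geometry="oocyte", blastomere_radii_px=(30.0,),
                           n_spots=300, distribution=distribution,
                           gradient_strength=g, seed=seed0 + i)
        stack, truth = generate_embryo_stack(p)
        proj = equatorial_projection(stack, "FISH", 10)
        rois = derive_rois(proj, mode="ground_truth", geometry="oocyte",
                           ground_truth_masks=truth.roi_masks(proj.source_slices))
        items.append((stack, rois))
    return [r.e_px for r in batch_eccentricity(items, level="oocyte")]

grad = batch("gradient", 0.8, 12, 1)   # inhomogeneous, 'patterned' transcript
unif = batch("uniform", 0.0, 5, 501)   # uniform, housekeeping-like
res = compare_groups(grad, unif, labels=("gradient", "uniform"))
print(f"median E: {np.median(grad):.2f} vs {np.median(unif):.2f} px, "
      f"p = {res.p_value:.4g}")
```

prints

```
median E: 4.87 vs 0.72 px, p = 0.0003232
```

— the patterned batch sits ~5 px off-centre (the generator's analytic
offset for `g = 0.8` at r = 30 px is `g·r/4 = 6` px, shrunk slightly by
background and projection), the uniform batch shows only sampling noise,
and the exact rank-sum test flags the difference. The analogous count-table
example:

```python
from blastoquant import CountSimParams, generate_twin_counts, pair_ratios
from blastoquant.lineage import ratio_medians

table = generate_twin_counts(CountSimParams(n_pairs=1000, seed=7))
print(ratio_medians(pair_ratios(table))["median_ratio"])
```

```
layer
cdx2     1.121951
sox17    2.250000
nanog    2.000000
```

— trophectoderm near 1, EPI (and its FGF4-dependent follower, primitive
endoderm) around 2: the calibrated imbalance structure.

A thin CLI mirrors the library (`blastoquant simulate-stack`,
`blastoquant project`, `blastoquant eccentricity`, `blastoquant lineage`,
`blastoquant match`, `blastoquant ratios`, ...); run
`blastoquant --help`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch on freshly generated synthetic
data — the eccentricity experiment at the published group sizes (12 vs 5),
the twin count statistics, the clustering pair recovery, the CV ranking
and the worked-example arithmetic — printing each stage's numbers and
writing the result manifest to `--out`.
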