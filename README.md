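# landgen

Landscape-genomics analysis of SNP data: who is genetically isolated from
whom, and is that isolation driven by geography or by the environment?

`landgen` is for population geneticists working with range-wide SNP datasets
(typically RAD-seq style VCFs for tens of populations of a few individuals
each) who want the full inferential chain from genotypes to climate-change
vulnerability:

1. **Genetic structure** — per-population diversity (H<sub>O</sub>,
   H<sub>E</sub>, π at SNP sites, F<sub>IS</sub>) and pairwise
   Weir–Cockerham F<sub>ST</sub> from a filtered VCF.
2. **Landscape distances** — straight-line distance, least-cost distance
   (LCD) and circuit-theory distance (CD) over a habitat-suitability-derived
   resistance surface, plus per-variable environmental distances
   |x<sub>i</sub> − x<sub>j</sub>|.
3. **Isolation by distance vs isolation by environment** — permutation
   Mantel and partial Mantel tests, and reciprocal causal modeling (RCM):
   for every pair of candidate drivers {A, B}, the difference
   R<sub>PM</sub>(G, A | B) − R<sub>PM</sub>(G, B | A) says which one
   survives controlling for the other.
4. **Generalized dissimilarity modeling (GDM)** — monotone nonlinear matrix
   regression of F<sub>ST</sub> on environmental and geographic predictors,
   μ = 1 − exp(−η) with η = β₀ + Σ<sub>k</sub> |f<sub>k</sub>(x₁) −
   f<sub>k</sub>(x₂)| and each f<sub>k</sub> a non-negative I-spline
   combination; percent deviance explained and spline-height predictor
   importance.
5. **MLPE ranking** — pairwise mixed models y = β₀ + β₁x + Zu + e with a
   random effect per population entering each pair, ML-fitted and ranked by
   AIC.
6. **Genomic offset** — the fitted GDM projected onto current vs future
   climate rasters: offset = 1 − exp(−Σ<sub>k</sub> |f<sub>k</sub>(x<sub>k</sub><sup>fut</sup>)
   − f<sub>k</sub>(x<sub>k</sub><sup>cur</sup>)|), the expected mismatch
   between today's genotype–environment relationship and tomorrow's climate.

A seeded synthetic-landscape generator (logit-scale Gaussian-process allele
frequencies whose covariance decays with both geographic and environmental
distance) makes every stage testable end-to-end without field data, with
independently tunable IBD and IBE strength.

## Worked example

Run the whole pipeline on a synthetic landscape (12 populations × 5
individuals × 1000 SNPs on a 48×48 grid of 500 m cells):

```python
from landgen.pipeline import run_pipeline

config = {
    "seed": 7,
    "synthetic": {"n_pops": 12, "n_ind_per_pop": 5, "n_loci": 1000,
                  "grid_shape": [48, 48]},
    "tests": {"n_perm": 999},
}
out = run_pipeline(config, "demo-run")
```

which writes the VCF, distance matrices, test tables, GDM fit and offset
rasters under `demo-run/` (with SHA-256 checksums in `manifest.json`), and
prints, when summarized:

```
pairwise FST: mean 0.262, range 0.120-0.324
 variable        r     p
Euclidean 0.786703 0.001
      LCD 0.775389 0.001
       CD 0.632564 0.001
     Bio2 0.572946 0.001
GDM deviance explained: 94.6%
 predictor   height   percent
Geographic 0.144953 35.618364
      NDVI 0.078973 19.405650
      Bio6 0.045566 11.196649
predictor         AIC     dAIC
      LCD -279.351014 0.000000
Euclidean -279.021904 0.329109
       CD -270.341997 9.009017
population genomic offset: mean 0.0452, max 0.0731
```

Reading this: the populations are moderately differentiated (mean pairwise
F<sub>ST</sub> 0.26); genetic distance correlates most strongly with
straight-line and least-cost distance (Mantel r ≈ 0.78–0.79, p = 0.001 at
999 permutations — isolation by distance), with environmental correlations
behind; the GDM explains 94.6% of the deviance with geographic distance the
most important predictor (35.6% of total spline height); MLPE agrees,
ranking LCD and Euclidean distance far ahead of circuit distance
(ΔAIC = 9); and the projected genomic offset under the generator's future
climate is small (≤ 0.073 dissimilarity units at any population).

The same stages are exposed as a CLI (`landgen run --config cfg.yaml`, plus
`filter`, `diversity`, `fst`, `distances`, `mantel`, `rcm`, `gdm`, `mlpe`
subcommands for individual steps on your own VCF/TSV/raster inputs) and as
plain library functions (`landgen.genotype`, `landgen.distances`,
`landgen.association`, `landgen.gdm`, `landgen.mlpe`, `landgen.offset`).

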