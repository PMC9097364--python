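# avidiet

Quantitative four-proxy inference of diet and pedal ecology for fossil birds,
as a reusable, tested Python pipeline:

1. **Body mass** — skeletal-measurement regression for fossil mass, Youden-index
   cut-point optimisation between diet guilds on log10 mass, and mass-based
   diet exclusion rules (`avidiet.diet`).
2. **Claw morphometrics** — outer-arc curvature and arc-length ratios from
   three-point landmarks per digit (`avidiet.morphometrics`).
3. **Jaw functional indices** — the six mechanical-advantage / cranial-shape
   indices (AMA, PMA, OMA, AO, MCH, ACH) from 2D skull geometry
   (`avidiet.morphometrics`).
4. **Jaw strength** — a 2D plane-strain constant-strain-triangle finite-element
   solver with two materials (bone / rhamphotheca), articular pin + vertical
   bite constraint, and square-root-of-area load scaling that makes strain
   fields size-independent (`avidiet.fem`), post-processed into mesh-weighted
   mean strain and compositional strain-interval profiles with zero imputation
   and clr/ilr transforms (`avidiet.intervals`).

Supporting machinery: time-tree I/O, fossil grafting and linear time-scaling,
Brownian covariance, univariate/multivariate phylogenetic signal (K), and a
permutation-based pairwise group comparison under phylogenetic covariance
(`avidiet.phylo`); correlation-matrix PCA with independent fossil projection,
LDA/DAPC with posterior prediction, and agreement kappa
(`avidiet.ordination`); seeded synthetic-data generators for every input
(`avidiet.synth`); and a rule-based consensus engine combining the proxies
(`avidiet.pipeline`).

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the five acceptance criteria (phylogenetic
machinery, FEM correctness, compositional intervals, classification, and
end-to-end parameter recovery on synthetic cohorts).

## CLI

```bash
avidiet --seed 1 --out-dir out simulate          # synthetic cohort (tree, claws, diets, jaw mesh)
avidiet --out-dir out claws out/claw_landmarks.csv
avidiet --out-dir out mass measures.csv          # log10 skeletal measures -> mass + exclusions
avidiet --out-dir out fem out/example_jaw.mesh --load-node 5 --pin-node 0 --bite-node 1
avidiet --out-dir out intervals out/fem_result.csv --n-intervals 75
avidiet --out-dir out ordinate features.csv      # correlation PCA, fossils projected
avidiet --out-dir out classify features.csv --method dapc
avidiet --out-dir out signal out/tree.nwk out/traits.csv
avidiet --out-dir out hsd out/tree.nwk out/traits.csv
avidiet --out-dir out synthesize mass_estimates.csv fea_posteriors.csv
avidiet --seed 2 --out-dir out run-all           # end-to-end synthetic demo
```

Every invocation writes a run manifest (seed, config hash, library versions).
Rows of feature CSVs without a `group` label are treated as fossils and
projected/predicted as supplementary points, never influencing the fit.

## File formats

Newick trees (branch lengths in Ma), CSV trait/landmark tables keyed by
`taxon`, a documented ASCII mesh format (`# nodes: id,x,y` /
`# elements: id,n1,n2,n3,material`) plus a Gmsh ASCII v2 triangle importer,
JSON results, and optional SVG/PNG contour and phylomorphospace plots.
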