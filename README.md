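# shrubscan

Mapping and monitoring shrub encroachment in seminatural grasslands from
UAS (drone) LiDAR point clouds.

Woody species such as scotch broom (*Cytisus scoparius*) progressively
invade open grassland, homogenizing the vegetation and depressing plant
diversity unless managers intervene. Deciding where and when to intervene
needs structural information — biomass and its change — at the scale of
individual shrubs across whole management units. `shrubscan` implements a
processing chain that extracts exactly that from ultrahigh-density
(hundreds to thousands of returns per m²) dual-return LiDAR surveys:

1. **Height normalization** — a digital terrain model (DTM) from per-cell
   minimum return height on a 1 m grid; every return gets a normalized
   height NormZ = z − DTM(x, y).
2. **Layering** — thresholds split the cloud into ground
   (NormZ < 0.15 m), low vegetation (< 0.3 m), the *shrub layer*
   (0.3–3.5 m) and high vegetation (> 3.5 m).
3. **Structural features** — seven per-point attributes of the shrub
   layer, computed in metric search neighbourhoods: *pseudowaveform*
   (height variance about a normal-fitted plane, radius 0.5 m), *point
   count* (0.5 m), *ground point count* (vertical cylinder, 0.1 m),
   *rank* (relative height position, 0–100), *negative openness* (mean
   nadir angle to neighbours), *point distance*, and *mean echo count*
   (all 0.1 m). Together they encode growth form, density, surface
   roughness and light penetration — the structural signature that
   separates shrub taxa. A selection procedure (Spearman |ρ| > 0.75
   filter plus leave-one-out importance) prunes redundant variables.
4. **Fuzzy classification** — points within a size-specific radius of
   each field-surveyed reference object (RTK-GNSS position + taxon,
   including shrub-absence points) are labelled, and a CART is grown on
   the features and pruned with complexity parameter cp = 0.001. Leaves
   carry class-proportion vectors, so every point receives fuzzy class
   memberships P(class) rather than only a hard label. Accuracy is
   reported as overall accuracy, Cohen's κ and per-class
   precision/recall/F1 over 100 stratified 90/10 (or 70/30) splits.
5. **Biomass** — target-class points above a probability threshold (60%
   or 80%) are rasterized at 5 cm: pixel volume = statistic(NormZ) ×
   25 cm². Harvested, oven-dried shrubs delimited by 25-point GNSS
   delineation hulls calibrate a linear allometry mass = a + b·volume,
   judged by adjusted R² and Spearman ρ; the published reference fits
   (e.g. max metric: Y = 77.12 + 4,696.16·X, R²adj = .77) ship with the
   package.
6. **Change detection** — two co-registered epochs are differenced per
   pixel, masked to cells densely sampled in both surveys (mean
   nearest-neighbour spacing below 3 cm at field density), and summed
   into 2.5 m reporting cells; negative values are biomass decline.

A synthetic scene generator (terrain + grass + parametric shrub
archetypes with known volume and biomass, dual-return scan simulation)
makes the entire chain testable without field data.

## Worked example

```python
import shrubscan as ss
from shrubscan.synthetic import (SceneSpec, default_archetypes,
                                 generate_scene, make_reference_table,
                                 scatter_placements)

arch = list(default_archetypes().values())
placements = scatter_placements(arch, 8, (20.0, 20.0), seed=3)
scene = generate_scene(SceneSpec(placements=placements, seed=3))

dtm = ss.build_dtm(scene.cloud, cell_size=1.0)
cloud = ss.assign_layers(ss.normalize_heights(scene.cloud, dtm))
features = ss.compute_features(cloud)

refs, schema = make_reference_table(scene)
labelled = ss.drop_singleton_classes(
    ss.assemble_reference(cloud, features, refs, schema))
summary = ss.repeated_validation(labelled, train_frac=0.9, n_iter=20,
                                 base_seed=100, cp=0.001)
fit = ss.fit_biomass_model(scene.shrubs["volume_m3"],
                           scene.shrubs["biomass_g"])
```

Output for this 20 × 20 m scene (24 shrubs of three archetypes, ~100k
returns, ~32k in the shrub layer):

```
overall accuracy 92.7% (SD 0.4), kappa 89.1%
broom F1 84.0%
allometry: mass = 105.7 + 4690.9 * volume (r2_adj 1.000, Spearman rho 1.00)
```

The accuracy numbers say the three growth forms are separable from
structure alone at better than 92% of validation points; the fitted
allometry recovers the generator's true coefficients (80 + 4700·V) well
within sampling error of the 50 g biomass noise.

The same stages are available from the shell:

```bash
shrubscan synth --seed 42 --out scene/
shrubscan normalize scene/cloud.xyz --out norm.xyz --dtm-out dtm.asc
shrubscan classify norm.xyz scene/reference.csv --iters 100 --seed 42
shrubscan run --config run.cfg          # full pipeline from a config file
```

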