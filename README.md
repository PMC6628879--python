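# biospat

Spatial biodiversity mapping from point occurrences, phylogenies and
environmental rasters: diversity and endemism indices on equal-area hexagon
grids, ordination-based bioregionalization, kernel-based areas of endemism,
spatial and model-based interpolation, and SDM pre/post-processing with
validation statistics.

## What it does

- **Sample units** — flat-topped equal-area hexagon grids over a polygon
  mask; occurrence tables (`sp,x,y` CSV) or per-species binary maps become a
  site × species community matrix (`biospat.tiling`).
- **Diversity** — species richness, rarefied richness, weighted endemism,
  Faith PD, phylogenetic endemism, and Sørensen-family beta diversity with
  the turnover (Simpson) / nestedness partition, taxonomic and PhyloSor
  variants (`biospat.diversity`).
- **Composition interpolation (SCI/PCI)** — NMDS of a beta-diversity matrix
  (Kruskal stress-1, best-of-restarts), a Moran's I premise test of the axis
  scores, interpolation of axes to rasters, RGB composites, and k-means /
  CLARA-style k-medoids bioregion classification (`biospat.sci`).
- **Areas of endemism (GIE)** — weighted quartic-kernel surfaces per scale
  radius from restricted-range species, consensus across scales, and
  threshold-component extraction of AoEs with per-AoE species tables
  (`biospat.gie`).
- **Interpolation** — nearest neighbour, thin-plate spline, empirical
  variograms with WLS model fitting and ordinary kriging, GLM prediction
  surfaces (gaussian/poisson/binomial), and quartic-kernel sampling effort
  (`biospat.interp`).
- **SDM tooling** — Bioclim percentile envelopes, random and
  sampling-evidence pseudo-absences, confusion-matrix statistics
  (accuracy, precision, sensitivity, specificity, Kappa, TSS), Mann–Whitney
  AUC, Schoener's D / Hellinger I niche overlap, convex hulls, regular
  sample points, raster utilities (`biospat.sdm`).
- **Raster statistics** — band correlation, variable clustering, PCA cubes
  with scenario projection and the equal-share axis-significance rule
  (threshold 100/p %), global Moran's I, raster variograms
  (`biospat.rasterstats`).
- **Synthetic landscapes** — a seeded generator that plants known biotas,
  clades and environmental gradients so every analysis can be tested for
  recovery of ground truth (`biospat.io.synthetic`).

Formats: CSV tables, GeoJSON and ESRI shapefile masks, newick trees, and
single-/multi-band GeoTIFF rasters (read/written via `tifffile` with
standard georeferencing tags).  Coordinates are treated as planar;
geographic-degree inputs are flagged with a warning.

## CLI

One entry point, one subcommand per analysis; every run writes a config
echo, a plain-text report and a manifest with SHA-256 checksums into
`--out`:

```bash
biospat grid      --mask area.geojson --side 1.0 --out out/
biospat richness  --occ occ.csv --mask area.geojson --side 1.0 --interp nn --res 0.1 --out out/
biospat sci       --occ occ.csv --mask area.geojson --side 1.0 --axes 3 \
                  --interp nn --classify kmeans --k 4 --seed 42 --res 0.1 --out out/
biospat gie       --occ occ.csv --mask area.geojson --radii 1,2,4 --threshold 0.5 --res 0.1 --out out/
biospat interp    --samples dep.csv --method kriging --mask area.geojson --res 0.1 --out out/
biospat predict-surface --samples dep.csv --predictors rasters/ --family gaussian --out out/
biospat pca       --stack rasters/ --project scenario/ --out out/
```

Other subcommands: `rarefied-richness`, `we`, `pd`, `pe`, `beta`, `pci`,
`effort`, `bioclim`, `pseudo-absences`, `validate`, `auc`, `overlap`,
`mch`, `sample-points`, `correlate`, `cluster-vars`, `moran`, `variogram`.
Run `biospat <cmd> --help` for options.

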