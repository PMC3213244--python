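# enmkit

Elastic network model (ENM) construction and analysis for biomolecular
structures: build Gaussian (GNM) and anisotropic (ANM) network models from
atomic, coarse-grained, mixed-resolution, or density-map-derived point
models; solve for normal modes; derive fluctuation and correlation
quantities; and compare modes against principal components of structural
ensembles.

## Features

- **Structure I/O** — fixed-column PDB reader/writer (ATOM/HETATM/ANISOU,
  multi-MODEL) and MRC/CCP4 density maps.
- **Model generation** — atom selection, united-atom (centroid) models,
  greedy spherical coarse-graining, density-contour point picking, and
  mixed-resolution models (atomic region of interest + coarse remainder).
- **ENM flavors** — distance cutoff (defaults: 7.3 Å GNM, 13 Å ANM),
  inverse-power distance-weighted springs, nearest-neighbor contacts from an
  atomic model, and mixed-resolution cutoffs with the geometric-mean rule
  for cross-region pairs.
- **Mode analysis** — dense or sparse lowest-k eigensolution, spectral
  pseudo-inverse, mean-square fluctuations, internal distance fluctuations,
  cross-correlations, anisotropic displacement (ADP) tensors, collectivity,
  subset directional correlations, B-factor comparison, and multi-MODEL PDB
  mode animations.
- **Ensemble PCA** — Kabsch superposition (iterative-to-mean), covariance +
  SVD principal components, overlap / cumulative overlap / RMSIP metrics,
  and mode-set vs mode-set comparison. Report tables flag only significant
  cumulative overlaps (CO > 0.5).
- **Fixtures** — deterministic synthetic lattices, helices, mode-deformed
  ensembles, and Gaussian-blob density maps for testing without downloads.

## CLI

The console script `enmkit` exposes the pipeline:

```sh
# generate a synthetic fixture
enmkit synth --kind helix --n 20 --out helix.pdb

# prepare a node table (CA selection, optional coarse-graining)
enmkit prepare --input helix.pdb --select CA --out points.tsv

# build + solve in one step; manifest.json records all effective parameters
enmkit build --input points.tsv --kind gnm --out run/

# analyses (CSV outputs + report)
enmkit analyze --modes run/ --analyses msf,correlations,collectivity --out analysis/

# PCA of a multi-MODEL ensemble and comparison against the modes
enmkit pca --input ensemble.pdb --out pca_out/
enmkit compare --modes run/ --pca pca_out/ --n-pcs 3 --n-modes 10 --out cmp/

# mode animation (multi-MODEL PDB) + PyMOL loader script
enmkit animate --modes run/ --amplitude 2 --frames 20 \
    --out anim.pdb --viewer-script anim.pml
```

A plain-text `key=value` config file can be passed to `build` via
`--config`; explicit CLI flags override file values.

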