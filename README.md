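# nmfseg

Multimodal brain-MRI tumor compartment segmentation by rank-two
nonnegative matrix factorization of gray-level co-occurrence (GLCM)
texture features.

Each axial slice is described by a nonnegative feature-by-voxel matrix
`M`: column *j* is the 16-element Haralick texture signature of voxel
*j* (per contributing modality), computed from a sliding-window,
direction-averaged co-occurrence matrix. Under a linear mixture model,
`M ≈ W H` with two nonnegative endmembers; comparing the two abundances
per voxel splits the region in two. Four hierarchical stages apply this
split:

1. **edema** — T2 + FLAIR features inside the brain mask (bright on FLAIR)
2. **necrosis** — T1c features inside the edema mask (dark on T1c)
3. **enhancing tumor** — T1c inside `edema − necrosis` (bright on T1c)
4. **nonenhancing tumor** — T1c inside `edema − necrosis − enhanced`

The final label map uses the standard convention: 1 necrosis, 2 edema,
3 nonenhancing tumor, 4 enhancing tumor, 0 elsewhere. Evaluation
reports Dice and sensitivity over the three standard regions (complete
tumor = {1,2,3,4}, tumor core = {1,3,4}, enhancing = {4}).

A synthetic phantom generator produces co-registered T2/FLAIR/T1c
volumes with nested, texture-distinct tumor compartments and matching
ground truth, so the full pipeline is testable without clinical data.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite (GLCM brute-force
equivalence, feature formula oracles, NMF correctness, cluster-rule
fidelity, metric identities, end-to-end phantom recovery and
determinism). The full suite takes a few minutes; most of that is two
end-to-end pipeline runs.

## CLI

```sh
# generate a synthetic case
nmfseg phantom --out case/ --seed 1 --shape 64,64,8

# segment it
nmfseg run --t2 case/t2.nii.gz --flair case/flair.nii.gz \
           --t1c case/t1c.nii.gz --out pred.nii.gz [--config cfg.yaml] \
           [--save-stages stages/]

# score against ground truth
nmfseg eval --pred pred.nii.gz --gt case/truth.nii.gz --report report.txt
```

Volumes are read/written as NIfTI (`.nii`, `.nii.gz`) or uncompressed
MetaImage (`.mha`); label maps are stored as uint8.

### Configuration

YAML, all keys optional (defaults shown):

```yaml
glcm:
  levels: 32      # gray levels for windowed GLCMs (256 supported)
  window: 11      # odd sliding-window size
  distance: 1     # co-occurrence offset
nmf:
  tol: 1.0e-5
  max_iter: 500
  init: spa       # spa | maxnorm | random
include_intensity_rows: false  # append raw-intensity rows to M
```

Per-stage modality lists, guide modality, bright/dark polarity and the
per-slice voxel floor (`min_region_voxels`, default 64) can be
overridden under `stages:`.

## Conventions and notes

- Input volumes are assumed co-registered and skull-stripped; negative
  stored intensities are clipped to zero on read; the brain mask is
  simply `intensity > 0` on the stage's driving modality.
- GLCMs are symmetric (both orderings of each pair), averaged over the
  0/45/90/135-degree directions, then normalized. Windows are cropped
  at slice/mask borders; no padding is fabricated.
- Feature rows of `M` are min-max rescaled to [0,1] per row, which
  enforces the nonnegativity the factorization requires and equalizes
  feature magnitudes.
- The factorization uses deterministic successive-projection
  initialization and exact two-variable nonnegative least-squares block
  updates, so runs are bit-for-bit reproducible.
- A handful of the classical texture formulas are implemented in their
  standard (non-degenerate) forms where printed variants would be
  constant under a symmetric GLCM; see the docstring of
  `nmfseg.glcm` for the exact definitions used.
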