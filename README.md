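# lamglm — laminar signal extraction with a spatial GLM

High-resolution fMRI can resolve signals from different depths of the
cerebral cortex, but voxels almost always straddle several cortical
layers, so every voxel reports a partial-volume mixture.  `lamglm`
unmixes these signals: instead of interpolating through the cortex and
averaging, it models each voxel value in a region of interest as a
linear mixture of per-layer signals weighted by the fraction of the
voxel occupied by each layer, and solves the resulting *spatial* general
linear model

    Y = X B + eps,        B_OLS = (X'X)^-1 X'Y,
                          B_GLS = (X' O^-1 X)^-1 X' O^-1 Y,

where **Y** (n voxels x m volumes) is the data, **X** (n x k) the layer
volume distribution, **B** (k x m) the laminar signals, and **O** an
optional Gaussian spatial noise correlation with FWHM L_c.  The design
matrix is built from an equivolume level-set layering of the cortical
ribbon between the white-matter and pial surfaces (Laplace potential,
spectral gradients under a Tukey window, voxelwise mean curvature) and
exact plane–cube intersection geometry for each voxel's orientation.
The two classical extraction approaches — interpolation (column-
normalised weighted average) and winner-takes-all classification — are
provided in the same framework, and a simulated six-layer cortex with
known ground truth quantifies the laminar point spread function (PSF) of
all three.

Intended users: laminar (f)MRI researchers extracting depth profiles or
layer time courses from sub-millimetre data, and method developers who
need a controlled benchmark for laminar leakage.

## Worked example

Run the simulated-cortex PSF benchmark (builds the equivolume mesh,
rasterises it at 0.5 mm, derives the layering from the WM/pial surfaces
alone, and unmixes six single-layer indicator volumes with each method
at 0.5 mm and 1.0 mm):

```sh
$ lamglm psf --out report
peak glm_0.5mm: 96.8%
peak classification_0.5mm: 75.8%
peak interpolation_0.5mm: 68.2%
peak glm_1mm: 93.2%
peak classification_1mm: 57.2%
peak interpolation_1mm: 49.0%
kernel comparison max |dPSF|: 0.53 pp
```

Each number is the peak of the aligned-average PSF: the percentage of
signal injected into one layer that is recovered in the *correct* layer
(100% would be perfect unmixing; the rest leaks to neighbours).  The GLM
recovers ~97% at 0.5 mm and barely degrades at 1.0 mm, while
classification and interpolation lose a quarter to a half of the signal
and get markedly worse at coarser resolution — the partial-volume
leakage the spatial GLM is designed to remove.  The final line shows
that building the design from the voxel-orientation-specific cube cuts
versus the orientation-averaged kernel changes the PSFs by half a
percentage point at most.  `report/` contains the PSF matrices, aligned
profiles and a JSON summary.

The same stages are scriptable in Python:

```python
from lamglm import benchmark

gt = benchmark.simulate_ground_truth()          # ground-truth cortex
result = benchmark.run_psf_experiment(gt=gt)    # layer, design, extract
print(result.profiles[("glm", 0.5)].peak_percent)   # 96.8
```

For real data the CLI chains `layer` (WM/pial masks → equivolume
boundaries), `design` (boundaries + ROI → layer volume distribution) and
`extract` (3D/4D NIfTI + design → per-layer profiles or time courses,
`--method {glm,interp,class}`, arbitrary `--layers`, GLS via `--fwhm`).

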