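# sparsesurf

Reconstruction of full 3D structure segmentations from a handful of sparse
planar contours, by bi-Laplacian surface fairing — together with the
agreement statistics used to validate such segmentations in multi-rater
studies.

## Who this is for

Manual delineation of deep grey matter structures (caudate nucleus,
putamen, thalamus) on ~1 mm isotropic MRI is slow: a full tracing covers
every slice of a structure that spans 25–40 axial slices.  A
surface-fairing reconstruction needs only ~10 contours outlined at regular
slice intervals and fills in the rest, making large reference datasets
tractable.  `sparsesurf` implements that reconstruction, a synthetic
phantom suite to exercise it end-to-end without MRI data, and the full
agreement toolkit (Jaccard, Dice, generalized conformity index,
absolute-agreement ICC, Bland–Altman) used to report segmentation quality.

## The method

Given closed contours C₁…Cₖ on planes z₁ < … < zₖ, each resampled to p
points with consistent orientation and aligned start points, a closed tube
mesh is built: the known contours become *constrained* rings, one free
intermediate ring is placed in each gap, and a free apex vertex caps each
end.  With L = I − D⁻¹A the uniform (umbrella) graph Laplacian of the
tube's connectivity graph, the free vertex coordinates solve

&nbsp;&nbsp;&nbsp;&nbsp; Σₘ (L²)ₙₘ xₘ = Σₘ (L²)ₙₘ yₘ = Σₘ (L²)ₙₘ zₘ = 0

over all free vertices n — a smooth minimum-curvature surface passing
exactly through the delineated points.  The faired surface is rasterized
back to a voxel mask (voxel-center-inside rule, per-slice exact
cross-section scan-conversion) for comparison with voxel references.

Agreement metrics, for masks A, B (or raters A₁…A_r and a subjects×raters
volume matrix):

- Jaccard JI = |A∩B| / |A∪B|; Dice DSC = 2TP/(2TP+FP+FN) = 2·JI/(1+JI)
- generalized conformity index CIgen = Σ_{i<j} |Aᵢ∩Aⱼ| / Σ_{i<j} |Aᵢ∪Aⱼ|
- ICC (two-way, absolute agreement, single measure)
  = (MSR − MSE) / (MSR + (k−1)·MSE + k/n·(MSC − MSE))
- Bland–Altman: mean paired difference, SD, SE, 95% limits of agreement,
  two-sided paired t-test

## Worked example

```bash
python examples/01_sparse_reconstruction.py
```

```
reference phantom: 5.006 mL on a (31, 34, 31) grid
extracted 10 contours at planes [-9.1, -7.0, -4.8, -2.7, -0.6, 1.5, 3.6, 5.7, 7.8, 9.9] mm
faired surface volume:  4.929 mL
reconstructed mask:     4.985 mL
Jaccard vs reference:   0.9887
Dice vs reference:      0.9943
```

A ~5 mL ellipsoid phantom is reconstructed from 10 of its contours; the
Jaccard index of 0.989 against the reference mask means the surface-fairing
reconstruction recovers the full segmentation almost exactly from roughly a
third of the slices a complete tracing would need.  The other examples show
multi-rater agreement reporting (`02_multirater_agreement.py`) and the
volume-bias analysis of contour placement (`03_volume_bias.py`).

A thin CLI mirrors the library:

```bash
sparsesurf phantom --n 24 --seed 42 --out-dir cohort/
sparsesurf extract-contours --mask cohort/p000.nii.gz --n-contours 10 --out c.json
sparsesurf reconstruct --contours c.json --out m.ply
sparsesurf voxelize --mesh m.ply --like cohort/p000.nii.gz --out recon.nii.gz
sparsesurf evaluate --ref cohort/p000.nii.gz --test recon.nii.gz
```

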