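# fibrefab

Full-volume fiber-anisotropy analysis for segmented 3D voxel volumes:
mean intercept length (MIL) fabric tensors evaluated in sliding windows,
reduced to eigenvector fields, axial directional statistics and trabecular
morphometry.

`fibrefab` is aimed at researchers quantifying collagen fiber architecture
or trabecular microarchitecture in binary masks segmented from micro-CT
(e.g. synchrotron phase-contrast scans of fibrocartilage such as the
temporomandibular joint disc, or subchondral bone).  It answers the
questions these studies report: which anatomical direction dominates the
fiber network, how strongly and how exclusively fibers align there, how
the degree of anisotropy varies regionally (e.g. peripheral rim vs.
center), and what the tissue's volume, extents, trabecular thickness and
spacing are.

## Method

For a binary structure and a unit direction **n**, the MIL is the average
length of uninterrupted material runs met by a family of parallel test
lines traced along **n**.  Sampling many directions and fitting the
ellipsoid form

    1 / MIL(n)² = nᵀ M n

by least squares gives the fabric tensor **M**.  Its eigenvectors are the
principal material directions; on the length scale λᵢ = 1/√mᵢ
(λ₁ ≥ λ₂ ≥ λ₃, in µm) the primary eigenvector **e₁** is the dominant
fiber direction, the magnitude is λ₁, and the degree of anisotropy is

    DA = 1 − λ₃ / λ₁  ∈ [0, 1]

(0 = isotropic, → 1 = perfectly aligned).  Applying this in overlapping
cubic windows produces an eigenvector field; the field is reduced to
dominant-axis fractions over the anatomical axes (X lateral–medial,
Y ventral–dorsal, Z cranial–caudal), rose histograms of in-plane angles in
the sagittal (YZ), frontal (XZ) and transverse (XY) planes — weighted by
fiber frequency or by summed magnitude — anisotropy summaries, and
between-region contrasts.  Morphometry (volume, extents,
largest-inscribed-sphere thickness and separation, global fabric) follows
standard trabecular-bone conventions.

Because real scans of this kind are rarely public, the package ships a
first-class synthetic phantom module (parallel fibers, block-crossed
fiber families, isotropic sphere packings, trabecular random fields, and
a biconcave disc with a circumferential rim) whose ground truth validates
the whole analysis chain.

## Worked example

```python
import numpy as np
from fibrefab import (PhantomSpec, generate_phantom, sample_directions,
                      map_orientation_field, WindowSpec)
from fibrefab.directional_stats import dominant_axis_fractions, summarize_anisotropy

vol = generate_phantom(PhantomSpec(kind="parallel_fibers", shape=(64, 64, 64),
                                   fiber_radius_vox=3, target_volume_fraction=0.3,
                                   primary_axis="X", seed=7))
field = map_orientation_field(vol.mask, spacing_um=6.48,
                              window=WindowSpec(32, 16, 0.05),
                              directions=sample_directions(128))
s = dominant_axis_fractions(field)
a = summarize_anisotropy(field)
print(f"vectors: {field.vector_count}")
print(f"dominant-axis fractions X/Y/Z: {tuple(round(f, 3) for f in s.fractions)}")
print(f"anisotropy mean {a.mean:.3f} median {a.median:.3f} sd {a.sd:.3f}")
print(f"first window e1: {np.round(field.samples[0].e1, 3)}")
```

prints

```
vectors: 27
dominant-axis fractions X/Y/Z: (1.0, 0.0, 0.0)
anisotropy mean 0.621 median 0.617 sd 0.027
first window e1: [ 1.    -0.004 -0.01 ]
```

All 27 analysis windows recover the phantom's lateral–medial (X) fiber
axis as dominant: the primary eigenvector of the first window is within
0.6° of X, and the anisotropy index (mean 0.62) reports strong but not
perfect alignment, as expected for a 30% dense bundle of 3-voxel-radius
fibers.

A full run (field CSV export, rose histograms, anisotropy and morphometry
JSON, checksummed manifest) is driven by a config file:

```
fibrefab run --config run.yaml
```

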