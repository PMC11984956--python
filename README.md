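# dapquant

Quantification toolkit for centriolar **distal-appendage** imaging studies.

Distal appendages are ninefold-symmetric blade structures at the distal end
of the mother centriole that dock the preciliary vesicle and license
assembly of the primary cilium. Studies of this system quantify the same
few things over and over: per-centrosome fluorescence intensity of a
protein of interest (POI), peak-to-peak diameters of the appendage rings,
positions and sizes of vesicle-associated protein clusters from two-color
3D single-molecule localization microscopy (SMLM), categorical assay
scores (ciliation, vesicle recruitment, CP110 removal), and hierarchical
statistics that respect the replicate/cell structure of the data.

`dapquant` packages those computations as tested, scriptable pipelines,
together with synthetic-data generators that produce every input with
known ground truth, so each estimator can be validated end to end without
any microscope data.

## What is in the box

| module | contents |
| --- | --- |
| `dapquant.synthetic` | generators: centrosomal puncta fields, ninefold rings, two-channel 3D SMLM scenes (drift, channel affine, residual shifts, fiducials, outliers), filament fields, nested datasets |
| `dapquant.intensity` | rolling-ball background subtraction (Sternberg opening), threshold masks, mask merge (dilate/erode), particle analysis with size/circularity gates, centrosomal and ciliary intensity pipelines with ROUT outlier flagging |
| `dapquant.ringgeom` | max projection, four-angle peak-to-peak ring diameters with sub-pixel peak refinement, molecular-ruler extension model |
| `dapquant.smlm` | fiducial drift tracking + cubic smoothing-spline correction, CRLB/nearest-neighbour quality filters, bead-based affine registration, iterative 3D cross-correlation fine registration, cluster 1/e² sizing, COM offsets and 3D distances |
| `dapquant.scoring` | cilium length (skeleton geodesic), ciliation fraction (> 1 µm rule), vesicle positivity, CP110 dot counting |
| `dapquant.stats` | Welch's t, Fisher's exact (probability-mass two-sided), nested t, nested one-way ANOVA with Monte-Carlo Dunnett adjustment, ROUT outlier flags |

Key quantitative conventions:

- PSF ≈ isotropic 2D Gaussian, FWHM = 2√(2 ln 2)·σ.
- 1/e² full width of a Gaussian profile = 4σ.
- Molecular ruler: extension = n<sub>helical</sub>·0.15 nm + n<sub>disordered</sub>·0.4 nm + n<sub>IgG</sub>·8 nm.
- Nested tests operate on replicate means (no pseudo-replication).
- Outliers are flagged, never silently removed.

## Worked example

Render a noise-free ninefold ring whose true peak-to-peak diameter is
513.4 nm (the outer CEP83-scale ring) at 40 nm pixels with a 120 nm FWHM
PSF, and measure it back:

```python
import dapquant as dq

field, truth = dq.gen_ring_image(dq.RingConfig(diameter_nm=513.4))
m = dq.peak_to_peak_diameter(field.channel(0), field.pixel_size_nm)
print(f"measured mean diameter: {m.mean_diameter_nm:.1f} nm "
      f"(truth {truth['diameter_nm']} nm)")
for a, d in m.per_angle_diameters_nm.items():
    print(f"  {a:5.0f} deg: {d:.1f} nm")
print(f"ruler: {dq.molecular_ruler(400, 40, 0):.1f} nm")
```

prints

```
measured mean diameter: 499.7 nm (truth 513.4 nm)
      0 deg: 496.9 nm
     45 deg: 500.6 nm
     90 deg: 500.8 nm
    135 deg: 500.6 nm
ruler: 76.0 nm
```

The four per-angle diameters agree to a few nm (the ring is circular); the
mean sits ~14 nm below the generating truth, within half a 40 nm pixel —
the expected inward bias of a peak-to-peak readout on a PSF-blurred ring
(see `docs/methods.md`). The ruler value is the maximal axial extension of
a 400-residue coiled coil plus a 40-residue disordered stretch: the
epitope of an antibody can sit 76 nm away from the protein's anchor point,
which is how one protein can appear as two rings of different diameter.

The same style of round trip works for the SMLM pipeline:

```python
from dapquant.recipes import com_separation_target, width_target
sep, n = com_separation_target(seed=7)   # true separation 89 nm
w, _ = width_target(seed=7)              # true first-axis 1/e2 width 230 nm
print(f"separation: {sep:.1f} nm (n={n}); width_x: {w:.1f} nm")
# -> separation: 93.7 nm (n=2500); width_x: 227.4 nm
```

A thin CLI mirrors the library (`dapquant simulate|quantify|score|ring|smlm|stats`),
e.g.

```bash
dapquant simulate ring --seed 1 --out ring_demo
dapquant ring measure --image ring_demo/ring.tif
dapquant stats fisher --table 1 17 16 25
```

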