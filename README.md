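# camquant

Quantification of engineered cell–cell adhesion phenotypes from
fluorescence microscopy.

Synthetic cell-adhesion molecules (synCAMs) — chimeric receptors pairing an
orthogonal extracellular binder with a native adhesion intracellular
domain — reprogram how cells stick to each other: how large and how
enriched a cell–cell interface becomes, how a cell spreads on an adhesive
surface, how mixed cell populations sort inside a spheroid, and which cell
types end up in contact in a patterned assembly.  `camquant` implements the
image-derived metrics that characterize these phenotypes, together with a
synthetic-image generator that provides exact ground truth for every
metric, so the whole pipeline is testable without any experimental data.

## Metrics

**Doublet contact angle.**  For a segmented two-cell pair, a circle is
fitted to each cell's free (non-interface) boundary.  With *s<sub>i</sub>*
the signed distance from fitted centre *i* to the interface chord
(positive when the centre lies on cell *i*'s own side) and
*r̂<sub>i</sub>* the fitted radius, the per-cell angle is
*α<sub>i</sub>* = arccos(*s<sub>i</sub>* / *r̂<sub>i</sub>*), and the
reported pair angle *θ* = *α*₁ + *α*₂ is the full two-sided opening angle
(0–180° for physical doublets).  For two overlapping circles this equals
the closed-form lens value, e.g. *θ* = 2·arccos(*d*/2*r*) for equal radii
*r* at separation *d*.  Contact angle is the standard proxy for apparent
cell–cell interfacial tension.

**Interface enrichment.**  The fraction *f* of a membrane-localized
receptor signal lying within the cell–cell interface region of the
membrane band, *f* = Σ interface / Σ membrane band, after background
subtraction.

**Spreading kinetics.**  Footprint masks give area *A* (µm²), perimeter
*p* (µm, sub-pixel contour length), circularity *c* = *p*²/4π*A* and
roundness 1/*c*.  Area-versus-time series are fitted with the power law
*A* = *b·t*^1/4 (through-origin closed form for fixed exponent, log–log
least squares for a free exponent), *b* being the spreading-rate
coefficient.

**3D sorting score.**  For a two-channel spheroid stack, each channel is
binarized per slice, the cluster centre of mass is taken over the union of
foreground voxels (honouring anisotropic voxels, e.g. 10 µm z-steps over
0.6 µm pixels), and the per-channel radial occupancy *g*(*r*) is computed
in radial bins.  The sorting score *S* is the difference of the channels'
mean radii ("COM of the *g*(*r*) distribution"): *S* > 0 means the second
channel sits closer to the cluster centre.  A core–shell phantom (core
20 µm, shell 40 µm) scores *S* ≈ 20 µm; a well-mixed assembly scores
*S* ≈ 0.

**Contact graphs.**  Segmented-cell centroids with type labels yield an
undirected contact graph (distance threshold, fixed or radius-scaled), and
the interaction-probability table P(*s*,*t*) = contacts between types
*s*,*t* / all contacts — the "probability box" heat map of a patterned
assembly.  The exclusion-distance statistic compares two groups' mean
distance from the assembly centre.

## Worked example

```python
from camquant.synthetic import PairParams, make_cell_pair
from camquant.imaging import segment_two_cells
from camquant.pair_interface import contact_angle, enrichment_fraction

params = PairParams(r1=50, r2=50, d=50, enrichment_f=0.8, noise_sd=0.05, seed=0)
stack, truth = make_cell_pair(params)          # 2D doublet, 3 channels
labels = segment_two_cells(stack, ("cyto1", "cyto2"))
angle = contact_angle(labels)
enrich = enrichment_fraction(labels, stack, "membrane", cell=1)

print(f"pair contact angle : {angle.theta_pair_deg:6.2f} deg  (truth {truth.theta_deg:.2f})")
print(f"per-cell angles    : {angle.alpha_deg[0]:6.2f}, {angle.alpha_deg[1]:.2f} deg")
print(f"interface chord    : {angle.chord_length:6.2f} um   (truth {truth.chord_um:.2f})")
print(f"enrichment fraction: {enrich.f:6.3f}      (truth {truth.f_true:.3f})")
```

prints

```
pair contact angle : 120.00 deg  (truth 120.00)
per-cell angles    :  59.74, 60.26 deg
interface chord    :  86.51 um   (truth 86.60)
enrichment fraction:  0.783      (truth 0.800)
```

Two 50 µm cells whose centres sit 50 µm apart meet at the closed-form lens
angle 2·arccos(½) = 120°; the estimator recovers it to 0.01° from the
rendered image, the 86.6 µm interface chord to 0.1%, and the requested 80%
interface enrichment to 0.017 despite 5% Gaussian noise.

A command-line interface mirrors the library
(`camquant simulate pair|spread|assembly|pattern`, `camquant pair`,
`spread`, `sort`, `contacts`, `exclusion`, `intercalate`); every command
writes CSV/JSON plus OME-TIFF fixtures with ground-truth sidecars.

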