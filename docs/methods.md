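# Methods

## Data model and geometric conventions

All volumes (PET activity, SUV, dose) and structure masks live on regular
3-D voxel grids with anisotropic spacing in mm. A voxel's value represents
its centre; indices are 0-based; every distance is computed between voxel
centres in physical mm. Two objects are *co-registered* iff shape, spacing
and origin match exactly — mixed geometries are rejected rather than
resampled, because registration/resampling policy is outside this package's
scope (inputs are assumed to have been rigidly co-registered upstream).
Units are explicit tags (kBq/mL, SUV, Gy); operations declare the unit they
need and refuse anything else, which prevents silently thresholding raw
activity as if it were SUV.

NIfTI is the exchange format (diagonal, axis-aligned affines only); the
unit tag, structure role and acquisition metadata travel in JSON sidecars.
Mask roles can also be inferred from a `<case>_<ROLE>.nii.gz` filename
convention.

## SUV and decay arithmetic

Body-weight SUV: `SUV(v) = c(v) / (A_acq / (m·1000))` with `c` in kBq/mL,
`m` the patient weight in kg, and tissue density taken as 1 g/mL. The
injected activity is decay-corrected from injection to acquisition time
before the division (the standard SUV-bw convention; the clinical
description leaves this implicit). Decay correction is
`factor(Δt) = 2^(Δt/T½)`; correcting a later signal back to a reference
time multiplies by this factor. Default T½ = 109.77 min (¹⁸F). The factor
algebra (`factor(a+b) = factor(a)·factor(b)`, exact round trips) is tested
to 1e−12.

Reference regions are 10 mm-diameter sphere ROIs (tumour site and
contralateral centrum-semiovale white matter). A voxel belongs to the
sphere iff its centre lies within the radius, boundary inclusive — a
deterministic rule the brute-force test oracles share. The normal-tissue
statistic defaults to the ROI **mean** (the guideline norm); max is
available via a flag because the threshold literature is phrased in terms
of SUVmax ratios without stating the normal-side statistic.

## BTV segmentation

`BTV = {v ∈ brain : SUV(v) ≥ ratio × SUV_normal} ∖ ∪exclusions`, with the
comparison inclusive (≥) for deterministic tie handling. Thresholds 1.7
and 2.0 are the amino-acid-PET delineation ratios for high-grade glioma.
Exclusion masks (basal ganglia, which physiologically accumulate FDOPA)
are caller-supplied; the phantom provides its ground-truth blobs, real use
would supply an atlas or manual mask. Nesting (BTV2.0 ⊆ BTV1.7) and scale
invariance (image and reference multiplied by the same constant) are tested
properties. Connected-component filtering (26-connectivity; keep all /
largest / component touching a seed) is provided but defaults to *all*:
whether small disconnected supra-threshold islands should be removed is a
clinical choice the method itself does not make.

## Margins

CTV = GTV expanded 20 mm, PTV = CTV + 3 mm (lower end of the 3–5 mm setup
band; overridable). Expansion uses the Euclidean distance transform with
the grid spacing as sampling, so it is exact on anisotropic grids, unlike
structuring-element dilation. Barriers are clipping masks: barrier voxels
are removed from every target (CTV and PTV), but regions behind a barrier
are not shadowed — geodesic reachability is deliberately not modelled, as
clinical systems implement the "reduced to anatomical barriers" rule as a
clip. Both targets are also clipped to the bound (external/brain contour).
Consequently GTV∩bound∖barriers ⊆ CTV ⊆ PTV always.

Voxel-centre semantics bias expanded boundaries slightly inward (the
outermost mask voxel centre sits up to ~half a voxel inside the ideal
surface): at 1 mm voxels a 10 mm sphere expanded 20 + 3 mm recovers the
analytic 33 mm ball volume to about −3 %.

## Concordance and coverage metrics

* **Surfaces** are mask voxels with ≥ 1 face (6-connected) neighbour
  outside the mask; grid-edge voxels count as surface.
* **HD95** is the 95th percentile (linear interpolation between order
  statistics) of nearest-point distances from every *source* surface voxel
  to the *target* surface — directed, not symmetrised, because the
  clinical question is how far the GTV contour sits from the BTV contour.
* **SVC distances**: over all voxels of BTV∖GTV (not just its surface),
  the max and mean distance to the GTV surface; measuring from the full
  supplementary volume makes the mean reflect how far the PET-defined
  extent reaches beyond the GTV.
* **Volume decomposition**: within = BTV∩GTV, outside = BTV∖GTV. The
  outside volume is reported as `total − within` so the conservation
  identity holds exactly in float arithmetic (independent products differ
  in the last ulp).
* **Dose coverage**: fraction of structure voxels with
  dose ≥ iso_fraction × prescription, inclusive comparison, default 95 %
  of 60 Gy = 57 Gy.
* **Recurrence**: fraction of recurrence voxels outside each reference
  structure.

Nearest-surface distances are computed with a k-d tree over target surface
points; on masks ≤ 20³ voxels they equal a brute-force all-pairs oracle to
1e−9 mm (tested on 100 random pairs).

## Harmonization

Structure signal divided by the contralateral-ROI mean is invariant to any
global multiplicative factor on the image — scanner calibration and
radioactive decay alike, since numerator and denominator share it. This is
asserted explicitly rather than assumed. Decay arithmetic is therefore
kept for reporting absolute signal deviation against the acquisition gap,
not for the ratio. Agreement between two acquisitions' brain-normalised
signals is Pearson's r (Spearman optional) over paired samples pooled
across cases and structures (PTV, BTV1.7, BTV2.0); the mean-vs-median
choice is made when the signals are extracted, so the correlation routine
takes already-scalar pairs. Fisher-z intervals quantify uncertainty; a
1000-seed simulation at the study's n = 17 with true ρ = 0.8 confirms
~95 % interval coverage.

## The digital phantom

The generator emulates one co-registered patient: an ellipsoidal brain
(default semi-axes 75/90/70 mm) of uniform background SUV 1.0, two 11 mm
basal-ganglia spheres at T/N 2.2, and a tumour with a radially symmetric
T/N profile — step, linear, or truncated Gaussian — equal to the peak at
the centre and background at the infiltration radius. Because the profile
is analytic, the radius of any T/N iso-surface is closed form (for the
linear profile `r(t) = R·(peak−t)/(peak−1)`), hence true BTV masks and
volumes are known exactly; that is the entire basis of parameter-recovery
testing. The scanner is modelled as a Gaussian PSF (default 4 mm FWHM)
followed by multiplicative Gaussian noise (default σ = 5 %), seeded;
changing the seed changes only the noise, never the masks. The dose model
is geometric — prescription inside the PTV, linear falloff over 5 mm —
because the coverage metric needs only a plausible field, not a physics
simulation.

Defaults place the infiltration radius (35 mm) well beyond the enhancement
radius (22 mm) with peak T/N 3.8, so both threshold iso-surfaces
(26.3 / 22.5 mm) extend beyond the GTV — the phenomenon the analysis
exists to measure. Recurrence lesions are assembled voxel-by-voxel around
the reference surface point nearest the requested centre so their designed
outside-fraction is achieved within half a voxel.

What the phantom does **not** emulate: anatomical realism (gyri, ventricles,
true striatal shapes), displaced or irregular tumours (GTV and BTV are
concentric, so disagreement comes only from radius differences, whereas
clinical disagreement also comes from shape and displacement), PET
reconstruction physics (sinograms, scatter, attenuation), and MR-specific
bias fields. Passing tests therefore demonstrate correctness of the
measurement chain under known geometry, not clinical accuracy of threshold
segmentation on real images.

## Problem sizes

Unit and acceptance tests use 64³ grids at 2 mm (with 96³ at 1 mm only for
targeted accuracy checks of volume recovery and margin geometry); the
cohort script uses the default 128³ at 2 mm with 17 cases, matching the
study's cohort size. The full test suite runs in well under a minute; the
cohort script in about one minute on one CPU.

## Known limitations

* No resampling: inputs on different grids are rejected, not harmonised.
* Barrier clipping is non-geodesic (see above); a geodesic variant would
  change CTVs near thin barriers.
* HD95 is surface-voxel-centre based; sub-voxel surface models (meshes)
  would differ by fractions of a voxel.
* The harmonization correlation on phantom pairs is near 1 by construction
  (same geometry, independent noise); real cross-modality variability
  (reconstruction, positioning, uptake kinetics) is not modelled.
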