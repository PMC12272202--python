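# Methods

## The measurement problem

Seed-based resting-state functional connectivity (rs-fcMRI) assumes the BOLD
correlations it measures are neural in origin. Large cerebral vessels
violate that assumption: they carry systemic low-frequency oscillations
(sLFOs) — vasogenic BOLD fluctuations in the 0.01–0.1 Hz band that travel
with the blood — producing strong, spatially structured correlations inside
and around the macrovasculature. `vasconn` quantifies that contribution by
computing connectivity metrics with vessel masks as seed/target sets and
relating them to whole-gray-matter references.

## Connectivity metrics

For a seed set S and target set T, each seed voxel's Pearson correlations
with every target voxel (self-pairs excluded) are summarized as:

* degree `D` — number of targets with correlation above a threshold
  (default 0.15). Default counting uses `|r|`, because arterial–venous
  anti-correlations are part of the signal of interest; a strictly positive
  mode (`r > 0.15`) is available since the convention differs between
  degree-centrality implementations.
* strength `S` — spatial mean of correlations, computed over the positive
  class, the negative class, and overall.
* variance `σ²` — spatial variance of the same classes. Population
  (divide-by-N) variance is used: the correlations enumerate the full
  target set rather than sampling from it. Sample variance is a flag away.

Categories: venous–venous (VV), arterial–arterial (AA), arterial–venous
(AV), venous–arterial (VA), plus vein→GM, artery→GM and GM→GM references.
Macrovascular-to-GM contribution is expressed as voxelwise ratios
(e.g. `D_V,V : D_V,GM`) computed on GM-restricted vessel masks so numerator
and denominator share one seed set. Ratios are undefined (NaN, never zero)
where the denominator vanishes; spatial means exclude undefined voxels and
report the defined count.

Correlations are streamed in seed blocks (`block_size × n_targets` working
set), never materializing the full seed×target matrix; zero-variance voxels
are dropped from targets (shrinking `n_targets_valid`) and yield undefined
seed rows. No Fisher z-transform is applied before averaging (raw-r
averaging matches the convention of the degree/strength literature); lag-0
Pearson correlation only, no cross-correlation search.

## Perivascular shells

Shells at voxel distance 1..K (default K=3) from each vessel class are built
by iterated binary dilation and subtraction. The default structuring element
is the 26-connected cube — "one voxel away in 3D" naturally includes
diagonal neighbors, making shell distance Chebyshev distance; 6- and
18-connectivity are available for sensitivity analysis. Shells are clipped
to the brain mask and always exclude all vessel voxels of either class, so
an arterial shell never contains vein voxels. Arterial and venous shells are
dilated independently and may overlap; the overlap fraction is reported in
the run manifest. Shell profiles report the ratio metrics by distance, with
d = 0 denoting the vessel voxels themselves.

## Preprocessing

Three linear stages in fixed order, applied to already-realigned data:

1. **Nuisance regression** — least-squares removal of the WM and CSF mean
   time series (plus intercept) from every voxel; collinear regressors are
   dropped with a warning. Regressors are used raw (not band-limited first).
2. **Bandpass 0.01–0.1 Hz** — linear detrend, then an ideal (DFT
   bin-selection) filter: exactly bounded passband, zero phase distortion.
   After masking, the in-band component of the trend direction is also
   removed, which makes the whole operation an orthogonal projection and
   hence exactly idempotent.
3. **Smoothing** — per-volume Gaussian, `σ = FWHM/√(8 ln 2)` (6 mm default),
   per-axis σ in voxel units for anisotropic grids, kernel truncated at 4σ,
   zero-padded borders (plain-Gaussian tool behavior); a masked-renormalized
   variant is available. FWHM below half the smallest voxel edge is treated
   as the identity.

## The phantom

The generator emulates the data structure the analysis assumes, on a coarse
fMRI grid (default 24×24×16 at 4 mm, TR 2.2 s, 200 volumes; an `msc-like`
preset gives 64×64×36 with 818 volumes ≈ 30 min). Every voxel time series is

    x(t) = g_type · s(t − lag_type) · c(d) + background(t) + ε(t)

* `s` — the sLFO: white Gaussian noise hard band-limited to 0.01–0.1 Hz in
  the frequency domain, standardized to zero mean / unit variance. Its
  spectral support matches the analysis band exactly.
* `g_type` — venous gain +1.0, arterial gain −0.5: arteries and veins carry
  the same traveling signal with opposite BOLD sign, and arterial contrast
  is diminutive relative to venous. The arterial value is a stand-in (no
  published amplitude ratio exists) and is configurable.
* `c(d)` — extravascular coupling, `c(0)=1` in vessel voxels,
  `c₀·exp(−d/λ)` at Chebyshev distance d (matching the 26-connected shell
  metric), truncated beyond `4λ`. Defaults `c₀ = 0.5`, `λ = 2` voxels: the
  vessel's influence persists measurably at 3 voxels — the distance range
  over which perivascular contributions have been reported — while decaying
  by ~4× across the profile. Voxels equidistant from both classes couple to
  the vein (deterministic tie-break; veins dominate macrovascular BOLD).
* background — GM voxels carry `0.3·s(t − 3 s)` plus independent per-voxel
  band-limited noise (sd 2.0); WM and CSF carry half the global gain at lags
  of 4 s and 6 s with their own noise. The lags implement the sLFO as a
  traveling signal with compartment transit delays of a few seconds. They
  matter doubly: they keep the WM/CSF mean regressors only *partially*
  correlated with the vascular signal (otherwise nuisance regression would
  remove the shared sLFO from the entire phantom and erase the very effect
  under study), and they prevent the GM background from coherently
  cancelling the anti-phase arterial signal under spatial smoothing.
* `ε` — white measurement noise, sd 2.0 relative to the unit-variance sLFO,
  so the sLFO explains ~20% of raw vessel-voxel variance (~40% in-band), in
  line with reported sLFO variance shares in large vessels. Tissue
  (band-limited) noise has its own amplitude so that "noiseless" phantoms
  (ε = 0) retain living tissue fluctuations.

Geometry is deliberately minimal: nested boxes by depth-from-edge define
background / CSF / GM band / WM core, and two parallel 1-voxel-thick
axis-aligned tubes (one artery, one vein) run through the GM band on
opposite sides of the volume. All randomness derives from one seed through
fixed per-compartment sub-streams; identical specs give bit-identical
phantoms.

**What the phantom does not model:** realistic vascular trees, multi-voxel
vessel calibers, hemodynamic response functions, susceptibility/dipole
field anisotropy around vessels, motion, or spatially correlated scanner
noise. Passing the recovery experiments therefore shows the *pipeline*
faithfully extracts planted vascular correlation structure — not that real
data contain exactly this structure.

## Validation experiments

Each experiment fixes phantom conditions that isolate the probed effect:

* **Sign structure** (20 seeds, default phantom, full preprocessing
  including smoothing): mean venous–venous strength positive and mean
  arterial–venous strength negative.
* **Perivascular decay** (10 seeds): noiseless decaying-coupling phantoms —
  ε = 0 and global background off, so shells couple to vessels only through
  `c(d)` — on a 48×48×16 grid with 512 volumes, no smoothing. The mean
  degree-ratio profile must be non-increasing over d = 0..3 for both vessel
  types. Two structural effects shape this design: longer runs lower the
  null floor and sharpen the shell ordering, but let the vessel seeds'
  perivascular-halo GM degree dominate the d=0 denominator (which can
  invert the d=0→1 step); the enlarged grid tightens the Monte-Carlo means
  (longer tubes, more shell seeds). Smoothing is omitted because a 6 mm
  kernel on a 4 mm grid deterministically mixes vessel signal into shell 1
  (partial-volume leakage, a real effect but not decay). At these
  conditions the monotonicity rate is 90–100% per 10-seed batch.
* **Venous > arterial asymmetry** (same runs): venous shell profiles exceed
  arterial ones at d = 1..3. The comparison is restricted to shells because
  at d = 0 it is impossible in principle on a noiseless phantom: Pearson
  correlation is scale-invariant, so vessel-voxel maps are identical for
  any gain magnitudes.
* **Null** (coupling off, background off, 818 volumes): mean shell degree
  ratio collapses to ~0.004, an order of magnitude below the 0.05 bound
  implied by the suprathreshold rate of independent correlations at this
  series length.
* **Oracle equivalence**: the blocked streaming engine is checked against a
  one-shot dense correlation-matrix recomputation on random toy volumes to
  1e-10 (observed: float epsilon).

## Numerical conventions

* Grids compared by shape plus affine within 1e-4; 0-based voxel indexing.
* Undefined sentinel is NaN everywhere (empty sign class, zero-variance
  seed, zero denominator); means over maps are NaN-excluding with counts.
* Quartiles use linear interpolation between order statistics; box-plot
  whiskers span the full first/fourth quartile extent (min/max).
* Downsampling requires integer-factor nested grids; default binarization
  policy is "any overlap", which preserves 1-voxel vessels (a majority rule
  would erase them); an occupancy-fraction threshold is available.
* TSV outputs use fixed `%.12g` formatting so identical runs are
  byte-identical.
* The RSN-occupancy percentile is computed over the nonzero support of the
  frequency map, with ties at the percentile value included.

## Limitations

The desk-scale phantom has tens of vessel voxels and thousands of GM voxels,
so ratio magnitudes are not comparable to real-data values (which depend on
vessel-mask size and GM volume); only their structure (signs, ordering,
decay) is meaningful. Real-data use assumes inputs are already motion
corrected, slice-timing corrected, and coregistered; vessel segmentation
itself (e.g. from TOF angiography) is out of scope — binary segmentations
and an artery/vein label map are inputs.
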