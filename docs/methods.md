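# Methods

This note records the models implemented in `hilomfm`, the assumptions they
make, the parameters that matter, and the design choices taken where more
than one reasonable option existed.

## Coherent optics model

The mask-design path works with sampled 2-D complex fields carrying a
physical pixel pitch (um) and wavelength (um). Two transforms are used:

* **Lens Fourier transform.** A lens of focal length `f` maps the field one
  focal length in front of it to its back focal plane,
  `U(u,v) = (1/(i λ f)) ∬ E(x,y) exp(-i2π(ux+vy)/(λf)) dx dy`, implemented
  as a centred FFT with the output pitch rescaled to `λf/(N·pitch)`. The
  transform is unitary in energy (`Σ|U|²·pitch_out² = Σ|E|²·pitch_in²`) and
  its inverse reproduces the input grid exactly.
* **Fresnel propagation.** Free-space propagation over a signed distance
  `ΔL` uses the angular-spectrum transfer function with the Fresnel
  (paraxial) approximation, `H = exp(ikΔL)·exp(-iπλΔL(fx²+fy²))`. The
  transfer-function route keeps the sampling pitch constant, which is what
  the multi-plane Gerchberg–Saxton loop needs when it propagates back and
  forth between planes on one fixed grid. `|H| = 1`, so propagation
  conserves the array energy to rounding error. Distances beyond
  `N·pitch²/λ` alias the transfer function; the code emits a warning (not
  an error) because the plane loop intentionally uses modest `|ΔL|`.

Sign conventions (verified numerically and fixed package-wide): a positive
quadratic SLM phase `+π r² ΔL/(λ f²)` moves the focus a distance `+ΔL`
beyond the lens focal plane, and a positive linear phase
`+2π x Δx/(λ f)` displaces it by `+Δx` laterally.

The object-side focal offset `Δl` maps to the image side through the
longitudinal magnification, `ΔL = M² Δl` (M = 60 for the reference train,
so one 0.4 um section step corresponds to 1.44 mm in image space).

Non-goals: the model is scalar and paraxial — no Rayleigh–Sommerfeld
propagation, polarization, or partial coherence.

## Computational SLM grid

The reference instrument relays an 11.43 mm objective back aperture onto
the SLM through a 150 mm / 100 mm telescope, giving a ~3.8 mm aperture
radius on an 8.64 mm-wide, 8 um-pitch chip. The package models the SLM on
a square computational grid (default 512²) at the *physical* 8 um pitch:
the pitch fixes the Fourier-plane extent `λf/pitch` (13.75 mm at 550 nm),
which must accommodate the full 3×3 tile layout (9.77 mm) — coarsening the
pitch to cover the full chip width would clip the outer tiles off the grid.
The modelled aperture radius is therefore scaled to the grid (90% of its
half-width, 1.84 mm at 512²). Consequences: the modelled image-side
numerical aperture, spot sizes and depth of field differ from the bench by
the aperture ratio; tile routing, energy bookkeeping, uniformity and ghost
behaviour — the quantities the designer is judged on — are unaffected.

## Multiplex plans and the phase mask

A plan lists N focal planes: object offset `Δl` (cumulative sums of the
requested spacings, shifted so an anchor plane sits at 0; the symmetric
nine-plane layout is `-4Δz … +4Δz`), image distance `ΔL = M²Δl`, a camera
tile `(row, col)`, and a weight `w(i) ≥ 0`. One plane may carry weight
zero with `ΔL = 0`: it models the unmodulated zero-order reflection from
the SLM cover glass, which is deliberately used as the central, unshifted
focal plane. It contributes nothing to the optimization target and is
reported separately as the zero-order fraction.

**Initialization** superposes one off-axis Fresnel lens per weighted
plane: `φ₀ = Arg(Σ w(i)·exp(i[πr²ΔL_i/(λf²) + 2π(xΔx_i+yΔy_i)/(λf)]))`
inside the aperture, zero outside. Tile offsets whose tilt exceeds π phase
per SLM pixel are rejected (Nyquist limit of the modulator).

**Refinement** is the weighted global Gerchberg–Saxton iteration, executed
literally as the printed plane loop: per pass, `E_A = E₀·exp(iφ)`,
`E_B = F(E_A)`; for each weighted plane `E_C = T(E_B, ΔL_i)`, amplitude
replacement `E_D = w(i)·E_tar(i)·exp(i·Arg(E_C))`, `E_E = T(E_D, -ΔL_i)`,
`E_F = F⁻¹(E_E)`; then `φ ← Arg(Σ_i E_F(i))`. The loop bound follows the
printed `while n < max`, so `max_iter` passes execute `max_iter - 1`
updates (default 30, fixed — no adaptive stopping). Open choices resolved
here:

* **Target amplitude `E_tar`.** Not specified by the method as printed.
  Chosen: the focused image of the input aperture disk (an Airy-like spot)
  translated to the plane's tile centre and windowed to the tile,
  normalized to unit energy. This is the natural diffraction-limited spot
  for a point emitter at the anchor depth.
* **Weight placement.** The weights multiply the replaced amplitude inside
  the loop, exactly as printed. The adaptive refinement from the weighted-GS
  literature (`w(i) ← w(i)·⟨achieved⟩/achieved_i` per pass) is available
  behind `adaptive_weights=True`; the default keeps weights static.
* **Aperture.** Applied on the SLM plane (the relayed back-aperture
  circle), not inside the Fourier transform.
* **Initialization randomness.** The default start is the deterministic
  superposition; the seed only governs optional perturbed starts used in
  tests.

`quantize_phase` snaps the mask to an SLM's discrete levels (idempotent);
at 256 levels the simulated per-plane energies shift by well under 2%.

### Mask quality metrics and the crosstalk definition

`mask_report` propagates an on-axis probe through the mask and tabulates
`E[i,j]` = fraction of probe energy found at plane i's focal distance
inside plane j's tile window. Per-plane efficiency is the diagonal;
uniformity is min/max and relative std of the diagonal.

Crosstalk needs care: with all planes lying within the modelled image-side
depth of field, the energy found in tile j at plane i's distance is
dominated by plane j's *own designed beam* in transit — for any mask,
perfect or not, the raw wrong-tile fraction is ≈ (N-1)/N. The package
therefore reports **excess crosstalk**: the wrong-tile energy in excess of
each plane's reference energy measured in its own tile at its own
distance, `Σ_{i≠j} max(0, E[i,j] - E[j,j])` normalized by the within-tile
total. This isolates ghost/intermodulation energy created by the
phase-only encoding (the `Arg` of a sum is not the sum of lens terms) and
is discriminative: ~0 for a converged design, large for a corrupted one.
The gross wrong-tile fraction is reported alongside for transparency. The
published hardware efficiencies (67% SLM reflectivity, ~80% diffraction
efficiency) are instrument properties and are not modelled.

## HiLo reconstruction

The two-term image model is `I_u = I_in + I_out` (uniform illumination)
and `I_s = I_in·S + I_out` (speckle illumination, `S` unit-mean), so
`I_D = I_s - I_u = (S-1)·I_in` cancels the out-of-focus term exactly. The
sectioned image is `I_HiLo = η·LP[I_D] + HP[I_u]` with `HP = 1 - LP` and
LP a Gaussian in frequency. Choices:

* **η norm.** The scale factor is written as a ratio of filtered spectra
  without a stated norm. Chosen: L2 over all frequencies excluding DC
  (`HP(0) = 0` makes the numerator DC-free; excluding the denominator's DC
  keeps the ratio a pure passband match). When `I_D` carries no energy the
  spectral η is undefined; `eta_scale` raises with guidance and
  `hilo_reconstruct` falls back to `eta_fixed` with a logged warning — with
  `I_D = 0` the output is then just the high-pass of the uniform image.
* **Signed difference.** `(S-1)` is signed, so `LP[I_D]` can go negative;
  the default uses the signed difference as written and clips the final
  image at zero (clipped fraction logged). `rectify_difference=True` takes
  `|I_D|` before the low-pass — the variance-flavoured variant that also
  demodulates periodic illumination patterns.
* **`lp_sigma`.** No value is published. Default 0.125 cycles/pixel (the
  crossover at 1/8 of the sampling frequency); it must be tuned against
  the speckle grain in real data and is exposed everywhere.
* **Boundaries.** Filters are applied under symmetric (mirror) padding of
  one filter support to suppress FFT wrap-around.
* **Scope of η.** Whether η is global or per plane is unstated; the
  pipeline computes it per tile (per plane), since tile spectra differ.

## Synthetic data generator

The simulator defines the conditions the package is tested under:

* **Phantom.** Beads (solid spheres, default 0.5 um radius, intensity 100)
  placed uniformly at random in a voxel grid over a uniform slab
  background (default level 2), never touching the lateral boundary;
  options enforce a minimum lateral bead separation, an axial margin, and
  a reserved bead-free corner used for background measurements. The
  reference test volume is 16×16×16 um (64×64 voxels at 0.25 um laterally,
  40 slices at 0.4 um).
* **Speckle.** Fully developed speckle from a random-phase circular pupil
  of radius `N/(2·grain)`, intensity-normalized to unit mean (default
  grain ≈ 3–4 px ≈ 2× the blurred spot; the instrument's true grain and
  contrast at the sample are not published, so these are configuration
  values, not claims). The intensity histogram is exponential (contrast
  ≈ 1), as fully developed speckle statistics require.
* **Imaging model.** Fluorescence is incoherent, so per-plane rendering
  convolves intensities: the in-focus voxel slice is blurred with the
  in-focus PSF, every other slice with a Gaussian defocus kernel whose
  width grows linearly, `σ(z) = σ₀ + k·|z - z_f|` (defaults σ₀ = 1 px,
  k = 1.5 px/um). This is a deliberate simplification — not a diffraction
  PSF — sufficient for testing background rejection. The coherent path is
  used only for mask design and verification, mirroring the SLM's role.
* **Speckle application.** By default the modulation multiplies the
  rendered in-focus image only, so simulated pairs satisfy
  `I_s - I_u = (S-1)·I_in` to machine precision — the exact structure the
  two-term model assumes, asserted on every rendered pair. The
  `washed_speckle` flag enables the more physical variant where every
  slice is modulated but the speckle contrast is washed out by the same
  defocus blur; this breaks the exact identity and is what gives the HiLo
  axial response its smooth decay (used in the axial-response and
  monotonicity tests: a wider low-pass band keeps higher speckle
  frequencies, which decay faster with defocus, so the sectioning FWHM
  shrinks as the cutoff rises).
* **Noise.** Optional Poisson shot noise on expected photons plus Gaussian
  read noise; both off by default so exact-identity tests stay exact.

What passing tests on this generator do **not** show: performance on real
tissue (scattering, non-uniform staining, speckle decorrelation through
aberrated paths), chromatic effects, or detection noise at real photon
budgets. The published tissue images are qualitative and are not
reproduction targets; the property tests substitute for them.

## Volume assembly

Tiles are pure crops (no resampling). Section order is
`z = position·n_planes + rank` with ranks ordered by `Δl` ascending; which
camera tile holds which depth is configuration (`TileGrid.plane_order`),
because the physical assignment is not dictated by the algorithm. Sections
imaging beyond the requested depth are discarded from the *end* of the
stack. Per-section integral normalization (each section scaled to the mean
section integral) is off by default and available behind a flag. Images
are row-major, origin top-left, 0-based; physical coordinates refer to
pixel centres, and slice k of a phantom is centred at `(k + 1/2)·dz`.

## Problem sizes used in tests

Unit and property tests run the designer at 256² (the acceptance check at
the full 512² grid, 30 GS passes) and the end-to-end pipeline on 64 px
tiles with the 40-slice reference phantom — small enough for the whole
suite to run in well under a minute apart from the full-scale design, while
preserving every geometric ratio of the reference acquisition (9 planes,
0.4 um spacing, 16 um depth, 5 scan positions, 10 raw frames).

## Known limitations

* The Gaussian-defocus simulator cannot validate resolution claims, only
  contrast/sectioning behaviour.
* Excess crosstalk (above) is a model-specific definition; on hardware,
  tile-to-tile contamination additionally includes scattered and
  higher-order light the scalar model does not carry.
* The computational aperture rescaling (above) changes absolute image-side
  depth of field; axial selectivity claims should be read at object-side
  scale where `Δz = ΔL/M²`.
* Chromatic aberration, aberration-correction phases, hardware control and
  deblurring post-processing are out of scope.
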