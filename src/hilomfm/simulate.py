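"""Synthetic-data generator and optical forward model.

Provides everything needed to exercise the package without an instrument:

* seeded 3-D phantoms (fluorescent beads over a uniform slab background),
* fully developed speckle fields synthesized from a random-phase pupil,
* an incoherent imaging model that renders per-plane uniform/speckle image
  pairs satisfying the two-term decomposition ``I_u = I_in + I_out``,
  ``I_s = I_in S + I_out`` exactly (fluorescence adds in intensity, so the
  per-plane render convolves intensities; the coherent path in
  :mod:`hilomfm.optics` is used only for mask design and verification),
* multiplexed camera-frame rendering (each plane pasted into its tile,
  optional Poisson + read noise) and whole-scan synthesis, and
* ``simulate_mask_response``: the coherent probe propagation used to verify
  a designed phase mask plane by plane.

Defocus is modelled as a Gaussian PSF whose width grows linearly with
distance from focus, ``sigma(z) = sigma0 + slope * |z - z_focus|`` — a
deliberate simplification sufficient for testing background rejection, not
a diffraction PSF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage

from .hilo import FramePair
from .optics import ComplexField, fourier_lens_transform, fresnel_propagate
from .phase_design import MultiplexPlan, PhaseMask, PlanError, _input_field, _tile_window
from .pipeline import PipelineError, TileGrid

logger = logging.getLogger("hilomfm")


class SimulationError(ValueError):
    """Invalid simulation input."""


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

@dataclass
class Phantom:
    """3-D fluorophore density on a regular voxel grid.

    ``density`` is (nz, ny, nx), non-negative; ``voxel_size`` is
    (dz, dy, dx) in um; ``objects`` is the ground-truth record of generated
    structures (bead positions in voxels and um, intensities).
    """

    density: np.ndarray
    voxel_size: tuple[float, float, float]
    seed: int = 0
    spec: dict = dfield(default_factory=dict)
    objects: list[dict] = dfield(default_factory=list)

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.ndim != 3:
            raise SimulationError("density must be 3-D (nz, ny, nx)")
        if np.any(self.density < 0) or not np.all(np.isfinite(self.density)):
            raise SimulationError("density must be non-negative and finite")
        if any(v <= 0 for v in self.voxel_size):
            raise SimulationError("voxel sizes must be > 0")

    @property
    def z_extent(self) -> float:
        return self.density.shape[0] * self.voxel_size[0]

    def slice_z(self, k: int) -> float:
        """Physical z of slice k (slice centres, starting at dz/2)."""
        return (k + 0.5) * self.voxel_size[0]


def make_phantom(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    n_beads: int = 0,
    bead_radius: float = 0.5,
    bead_intensity: float = 100.0,
    slab_level: float = 0.0,
    seed: int = 0,
    lateral_margin: int | None = None,
    keep_clear: tuple[slice, slice] | None = None,
    min_separation: float = 0.0,
    z_margin: float = 0.0,
) -> Phantom:
    """Seeded bead-plus-slab phantom.

    Beads are solid spheres of radius ``bead_radius`` (um) placed uniformly
    at random, never touching the lateral boundary (``lateral_margin``
    voxels, default = bead radius + 2) and at least ``z_margin`` um away
    from the axial faces. ``min_separation`` (um) rejects bead centres
    whose *lateral* (y, x) distance to an existing bead is smaller, keeping
    every bead's axial profile free of other beads in its column. ``keep_clear`` reserves a lateral (y, x) region free of
    beads — useful as a known-empty patch for background measurements.
    ``slab_level`` adds a uniform background density to every voxel.
    Deterministic for a fixed seed.
    """
    nz, ny, nx = shape
    dz, dy, dx = voxel_size
    r_vox = bead_radius / dx
    if 2 * r_vox >= min(ny, nx) or bead_radius * 2 >= nz * dz:
        raise SimulationError(
            f"bead radius {bead_radius} um does not fit the volume {shape} at {voxel_size}"
        )
    if lateral_margin is None:
        lateral_margin = int(np.ceil(r_vox)) + 2
    rng = np.random.default_rng(seed)
    density = np.full(shape, float(slab_level))
    objects: list[dict] = []
    zz = (np.arange(nz) + 0.5) * dz
    yy = (np.arange(ny) + 0.5) * dy
    xx = (np.arange(nx) + 0.5) * dx
    placed = 0
    attempts = 0
    while placed < n_beads:
        attempts += 1
        if attempts > 100 * max(n_beads, 1):
            raise SimulationError("could not place all beads (volume too crowded)")
        cy = rng.uniform(yy[lateral_margin], yy[ny - 1 - lateral_margin])
        cx = rng.uniform(xx[lateral_margin], xx[nx - 1 - lateral_margin])
        z_lo = bead_radius + z_margin
        z_hi = nz * dz - bead_radius - z_margin
        if z_hi <= z_lo:
            raise SimulationError("z_margin leaves no room for bead centres")
        cz = rng.uniform(z_lo, z_hi)
        if min_separation > 0 and any(
            (ob["y_um"] - cy) ** 2 + (ob["x_um"] - cx) ** 2 < min_separation**2
            for ob in objects
        ):
            continue
        if keep_clear is not None:
            ys, xs = keep_clear
            pad = bead_radius
            if (
                yy[ys].min() - pad <= cy <= yy[ys].max() + pad
                and xx[xs].min() - pad <= cx <= xx[xs].max() + pad
            ):
                continue
        zi, yi, xi = np.meshgrid(zz - cz, yy - cy, xx - cx, indexing="ij", sparse=True)
        density[zi**2 + yi**2 + xi**2 <= bead_radius**2] += bead_intensity
        objects.append(
            {"z_um": float(cz), "y_um": float(cy), "x_um": float(cx),
             "intensity": float(bead_intensity), "radius_um": float(bead_radius)}
        )
        placed += 1
    return Phantom(
        density,
        voxel_size,
        seed=seed,
        spec={
            "n_beads": n_beads, "bead_radius": bead_radius,
            "bead_intensity": bead_intensity, "slab_level": slab_level,
        },
        objects=objects,
    )


# ---------------------------------------------------------------------------
# Speckle
# ---------------------------------------------------------------------------

@dataclass
class SpeckleField:
    """Non-negative speckle modulation with unit spatial mean."""

    S: np.ndarray
    grain_size: float    # correlation length (pixels)
    contrast: float      # std / mean
    seed: int = 0

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if np.any(self.S < 0):
            raise SimulationError("speckle modulation must be non-negative")
        if abs(self.S.mean() - 1.0) > 1e-6:
            raise SimulationError(f"speckle mean must be 1, got {self.S.mean()}")


def generate_speckle(shape: tuple[int, int], grain_size: float, seed: int = 0) -> SpeckleField:
    """Fully developed speckle from a random-phase circular pupil.

    A pupil of radius ``N / (2 * grain_size)`` filled with unit-amplitude
    random phases is Fourier-transformed; the intensity is normalized to
    mean 1. The grain size sets the speckle correlation length in pixels.
    In the fully developed limit the intensity is exponentially distributed
    with contrast (std/mean) near 1.
    """
    if grain_size < 1:
        raise SimulationError(f"grain_size must be >= 1 pixel, got {grain_size}")
    ny, nx = shape
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    # pupil radius in normalized frequency: 1 / (2 * grain)
    pupil = (fy**2 + fx**2) <= (0.5 / grain_size) ** 2
    phases = np.exp(1j * rng.uniform(0.0, 2.0 * np.pi, size=shape))
    amp = np.fft.ifft2(pupil * phases)
    intensity = np.abs(amp) ** 2
    mean = intensity.mean()
    if mean == 0:
        intensity = np.ones(shape)
        mean = 1.0
    s = intensity / mean
    return SpeckleField(
        S=s, grain_size=float(grain_size), contrast=float(s.std() / s.mean()), seed=seed
    )


# ---------------------------------------------------------------------------
# Incoherent per-plane rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DefocusPSF:
    """Gaussian defocus model: sigma(z) = sigma0 + slope * |z - z_focus|.

    ``sigma0`` is the in-focus blur (pixels), ``slope`` the widening rate
    (pixels per um of defocus).
    """

    sigma0: float = 1.0
    slope: float = 1.5

    def sigma(self, dz_um: float) -> float:
        return self.sigma0 + self.slope * abs(dz_um)


def render_plane_images(
    phantom: Phantom,
    focal_plane_z: float,
    illumination: SpeckleField | None = None,
    psf: DefocusPSF | None = None,
    washed_speckle: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one focal plane of the phantom: (I_in, I_out, I_total).

    ``I_in`` is the in-focus slab (the single voxel slice nearest
    ``focal_plane_z``) blurred with the in-focus PSF; ``I_out`` sums the
    defocus-blurred contributions of all other slices. With a speckle
    illumination the modulation multiplies the in-focus image only, so the
    rendered pair satisfies ``I_s - I_u = (S - 1) I_in`` exactly — the
    structure the two-term HiLo model assumes.

    ``washed_speckle=True`` switches to the more physical variant where
    every slice is speckle-modulated but the modulation is blurred by the
    same defocus kernel as the emission, so speckle contrast washes out
    away from focus (used for axial-response studies; the exact difference
    identity no longer holds).
    """
    psf = psf or DefocusPSF()
    nz = phantom.density.shape[0]
    shape = phantom.density.shape[1:]
    if illumination is not None and illumination.S.shape != shape:
        raise SimulationError(
            f"speckle shape {illumination.S.shape} != lateral phantom shape {shape}"
        )
    if not np.any(phantom.density):
        logger.warning("render_plane_images: phantom is empty, returning zeros")
        z = np.zeros(shape)
        return z, z.copy(), z.copy()
    dz = phantom.voxel_size[0]
    k_focus = int(round(focal_plane_z / dz - 0.5))
    i_in = np.zeros(shape)
    i_out = np.zeros(shape)
    i_total_s = np.zeros(shape)  # only used for the washed variant
    s = illumination.S if illumination is not None else None
    for k in range(nz):
        sl = phantom.density[k]
        if not np.any(sl):
            continue
        sigma = psf.sigma(phantom.slice_z(k) - focal_plane_z)
        blurred = ndimage.gaussian_filter(sl, sigma, mode="constant")
        if k == k_focus:
            i_in += blurred
        else:
            i_out += blurred
        if washed_speckle and s is not None:
            s_washed = 1.0 + ndimage.gaussian_filter(s - 1.0, sigma, mode="nearest")
            i_total_s += blurred * s_washed
    if s is None:
        i_total = i_in + i_out
    elif washed_speckle:
        i_total = i_total_s
    else:
        i_total = i_in * s + i_out
    return i_in, i_out, i_total


# ---------------------------------------------------------------------------
# Multiplexed frames and scans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise plus Gaussian read noise.

    ``photons_per_unit`` converts rendered intensity to expected photons
    (0 disables shot noise); ``read_sigma`` is the additive read-noise std
    in intensity units.
    """

    photons_per_unit: float = 0.0
    read_sigma: float = 0.0

    def apply(self, frame: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = frame
        if self.photons_per_unit > 0:
            out = rng.poisson(out * self.photons_per_unit) / self.photons_per_unit
        if self.read_sigma > 0:
            out = out + rng.normal(0.0, self.read_sigma, size=out.shape)
        return np.clip(out, 0.0, None)


def render_multiplexed_frame(
    phantom: Phantom,
    plan: MultiplexPlan,
    grid: TileGrid,
    z_center: float,
    illumination: SpeckleField | None = None,
    psf: DefocusPSF | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    washed_speckle: bool = False,
) -> np.ndarray:
    """Render one camera frame with every focal plane in its tile.

    Plane with z-rank r (dl ascending) images specimen depth
    ``z_center + dl_r`` and is pasted into the tile ``grid`` assigns to
    rank r. The phantom's lateral shape must equal the tile size. With
    ``noise=None`` the tiles equal the per-plane renders exactly.
    """
    if plan.n_planes != grid.n_planes:
        raise PipelineError(
            f"plan has {plan.n_planes} planes but tile grid expects {grid.n_planes}"
        )
    if phantom.density.shape[1:] != (grid.tile_px, grid.tile_px):
        raise PipelineError(
            f"phantom lateral shape {phantom.density.shape[1:]} != tile "
            f"({grid.tile_px}, {grid.tile_px})"
        )
    ranks = plan.z_order()
    rank_tiles = grid.rank_to_tile()
    fy = grid.origin[0] + grid.footprint[0]
    fx = grid.origin[1] + grid.footprint[1]
    frame = np.zeros((fy, fx))
    for rank, plane_idx in enumerate(ranks):
        plane = plan.planes[plane_idx]
        focal_z = z_center + plane.delta_l
        if not (0.0 <= focal_z <= phantom.z_extent):
            logger.warning(
                "plane rank %d images z=%.2f um outside the phantom (0..%.2f um)",
                rank, focal_z, phantom.z_extent,
            )
        _, _, i_total = render_plane_images(
            phantom, focal_z, illumination, psf, washed_speckle=washed_speckle
        )
        sy, sx = grid.tile_slices(rank_tiles[rank])
        frame[sy, sx] = i_total
    if noise is not None:
        frame = noise.apply(frame, np.random.default_rng(seed))
    return frame


def simulate_scan(
    phantom: Phantom,
    plan: MultiplexPlan,
    grid: TileGrid,
    scan_steps: int,
    speckle_grain: float = 4.0,
    z_first_section: float | None = None,
    psf: DefocusPSF | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    washed_speckle: bool = False,
) -> tuple[list[FramePair], SpeckleField]:
    """Synthesize a full axial scan: one uniform/speckle frame pair per step.

    The stage steps by ``n_planes * dz`` so consecutive exposures tile the
    axial axis; global section g = step * n_planes + rank images specimen
    depth ``z_first_section + g * dz``. One speckle realization is used for
    the whole scan (a static diffuser pattern). Deterministic for a fixed
    seed.
    """
    dls = sorted(p.delta_l for p in plan.planes)
    dz = dls[1] - dls[0] if len(dls) > 1 else phantom.voxel_size[0]
    if z_first_section is None:
        z_first_section = phantom.slice_z(0)
    speckle = generate_speckle((grid.tile_px, grid.tile_px), speckle_grain, seed=seed)
    pairs: list[FramePair] = []
    for step in range(scan_steps):
        z_center = z_first_section - dls[0] + step * plan.n_planes * dz
        u = render_multiplexed_frame(
            phantom, plan, grid, z_center, illumination=None, psf=psf,
            noise=noise, seed=seed + 1000 + 2 * step, washed_speckle=washed_speckle,
        )
        s = render_multiplexed_frame(
            phantom, plan, grid, z_center, illumination=speckle, psf=psf,
            noise=noise, seed=seed + 1001 + 2 * step, washed_speckle=washed_speckle,
        )
        pairs.append(FramePair(u, s, plane_meta={"step": step, "z_center": z_center}))
    return pairs, speckle


# ---------------------------------------------------------------------------
# Coherent mask verification
# ---------------------------------------------------------------------------

def simulate_mask_response(
    mask: PhaseMask,
    plan: MultiplexPlan,
    probe: ComplexField | None = None,
) -> dict:
    """Propagate a probe through a phase mask to every plane of a plan.

    The probe (default: the on-axis unit-energy aperture disk, i.e. a point
    emitter at the objective focal plane) is multiplied by the aperture and
    ``exp(i phase)``, Fourier-transformed by the lens, and Fresnel-propagated
    to each plane's dL. Returns the per-plane intensity images, the energy
    table ``table[i, j]`` = fraction of probe energy found at plane i inside
    plane j's tile window, and the mean fraction outside all tiles.
    """
    tr = mask.train
    if plan.train != tr:
        raise PlanError("mask and plan must share an optical train")
    lam = mask.wavelength
    if probe is None:
        probe = _input_field(plan, lam)
    if probe.shape != tuple(tr.slm_shape):
        raise PlanError(f"probe shape {probe.shape} != SLM grid {tr.slm_shape}")
    field = ComplexField(
        probe.field * tr.aperture_mask() * np.exp(1j * mask.phase),
        tr.slm_pitch,
        lam,
        "SLM output",
    )
    u = fourier_lens_transform(field, tr.f_fourier)
    # unitless array total at the Fourier plane; Fresnel propagation is
    # unitary on the fixed grid so every plane carries the same total
    total = float(np.sum(np.abs(u.field) ** 2))
    nf = u.shape[0]
    windows = [
        _tile_window(nf, u.pitch, plan.tile_center(p.tile_rc), plan.tile_extent / 2.0)
        for p in plan.planes
    ]
    n = plan.n_planes
    table = np.zeros((n, n))
    intensities: list[np.ndarray] = []
    outside = np.zeros(n)
    for i, p in enumerate(plan.planes):
        ez = fresnel_propagate(u, p.delta_L)
        inten = np.abs(ez.field) ** 2
        intensities.append(inten)
        plane_total = float(inten.sum())
        for j in range(n):
            table[i, j] = float(np.sum(inten * windows[j])) / total
        covered = float(np.sum(inten * np.logical_or.reduce(windows)))
        outside[i] = (plane_total - covered) / total
    return {
        "intensities": intensities,
        "energy_table": table,
        "outside_fraction": float(outside.mean()),
        "pitch_fourier": u.pitch,
        "probe_energy": total,
    }


def locate_bead_section(
    sections: np.ndarray,
    bead: dict,
    dz: float,
    pixel_size: float,
    halfwin_px: int = 3,
    halfwin_z: int = 4,
) -> float:
    """Recover a bead's axial position (fractional section index) from a stack.

    Takes the per-section peak intensity in a small lateral window around
    the bead's ground-truth (y, x), subtracts the local baseline and returns
    the intensity-weighted centroid of the axial profile around its peak.
    """
    nz, ny, nx = sections.shape
    yi = int(round(bead["y_um"] / pixel_size - 0.5))
    xi = int(round(bead["x_um"] / pixel_size - 0.5))
    ys = slice(max(yi - halfwin_px, 0), min(yi + halfwin_px + 1, ny))
    xs = slice(max(xi - halfwin_px, 0), min(xi + halfwin_px + 1, nx))
    profile = sections[:, ys, xs].max(axis=(1, 2))
    k0 = int(np.argmax(profile))
    lo, hi = max(k0 - halfwin_z, 0), min(k0 + halfwin_z + 1, nz)
    win = profile[lo:hi] - profile[lo:hi].min()
    if win.sum() == 0:
        return float(k0)
    ks = np.arange(lo, hi)
    return float(np.sum(ks * win) / np.sum(win))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def save_scan(
    pairs: list[FramePair], phantom: Phantom, basepath: str, speckle: SpeckleField | None = None
) -> dict[str, str]:
    """Write raw frames as multi-page TIFFs plus a JSON ground-truth sidecar."""
    import json

    import tifffile

    u = np.stack([p.uniform for p in pairs]).astype(np.float32)
    s = np.stack([p.speckle for p in pairs]).astype(np.float32)
    paths = {
        "uniform": f"{basepath}_uniform.tif",
        "speckle": f"{basepath}_speckle.tif",
        "sidecar": f"{basepath}_truth.json",
    }
    tifffile.imwrite(paths["uniform"], u, metadata={"axes": "TYX"})
    tifffile.imwrite(paths["speckle"], s, metadata={"axes": "TYX"})
    sidecar = {
        "phantom_seed": phantom.seed,
        "phantom_spec": phantom.spec,
        "voxel_size_um": list(phantom.voxel_size),
        "objects": phantom.objects,
        "speckle_seed": None if speckle is None else speckle.seed,
        "speckle_contrast": None if speckle is None else speckle.contrast,
    }
    with open(paths["sidecar"], "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return paths
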