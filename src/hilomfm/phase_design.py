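"""SLM phase-mask design for multi-focus imaging.

Given N requested focal planes (object-side offsets ``dl``, mapped to
image-side propagation distances ``dL = M^2 dl``) and a tile layout on the
camera, this module computes the phase mask that images every plane onto its
own camera tile:

1. ``plan_from_spacings`` turns the requested spacings into a
   :class:`MultiplexPlan` (cumulative offsets, tile assignment, weights);
2. ``init_superposition`` builds the starting phase as the argument of a
   superposition of off-axis Fresnel lenses, one per weighted plane;
3. ``wggs_optimize`` refines it with the weighted *global*
   Gerchberg–Saxton iteration: each pass forms the SLM field
   ``E_A = E_0 exp(i phi)``, Fourier-transforms it to the camera-side focal
   plane, and for every plane propagates to its ``dL(i)``, replaces the
   amplitude with ``w(i) E_tar(i)`` while keeping the phase, propagates back
   and inverse-transforms; the next phase is the argument of the coherent
   sum of the back-propagated fields.

The plane whose weight is zero models the unmodulated zero-order reflection
from the SLM cover glass: it is deliberately used as the central, unshifted
focal plane and excluded from the optimization target sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield
from typing import Sequence

import numpy as np

from .optics import (
    ComplexField,
    OpticalTrain,
    OpticsError,
    fourier_lens_transform,
    fresnel_transfer_function,
    object_to_image_distance,
)

logger = logging.getLogger("hilomfm")

TWO_PI = 2.0 * np.pi


class PlanError(ValueError):
    """Invalid multiplex plan."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FocalPlaneSpec:
    """One focal plane of a multiplex plan.

    ``delta_l`` is the object-side offset from the objective focal plane
    (um), ``delta_L = M^2 delta_l`` the image-side propagation distance from
    the Fourier-lens focal plane, ``tile_rc`` the (row, col) of the camera
    tile this plane images to, and ``weight`` the GS weighting factor w(i)
    (zero marks the unmodulated zero-order plane).
    """

    index: int
    delta_l: float
    delta_L: float
    tile_rc: tuple[int, int]
    weight: float = 1.0
    target_amplitude: str = "spot"


@dataclass
class MultiplexPlan:
    """Ordered focal planes plus the optical train and tile geometry."""

    planes: list[FocalPlaneSpec]
    spacings: list[float]
    train: OpticalTrain
    tile_shape: tuple[int, int] = (3, 3)
    tile_px: int = 501

    def __post_init__(self) -> None:
        tiles = [p.tile_rc for p in self.planes]
        if len(set(tiles)) != len(tiles):
            raise PlanError("tile assignments must be unique")
        zero_w = [p for p in self.planes if p.weight == 0.0]
        if len(zero_w) > 1:
            raise PlanError("at most one plane (the zero order) may have weight 0")
        for p in zero_w:
            if p.delta_L != 0.0:
                raise PlanError(
                    f"zero-weight plane {p.index} must sit at dL=0 (the unmodulated "
                    f"zero order), got dL={p.delta_L}"
                )
        for p in self.planes:
            if p.weight < 0:
                raise PlanError(f"plane {p.index}: weight must be >= 0")
            expected = object_to_image_distance(p.delta_l, self.train.magnification)
            if not np.isclose(p.delta_L, expected, rtol=1e-9, atol=1e-9):
                raise PlanError(
                    f"plane {p.index}: delta_L={p.delta_L} inconsistent with "
                    f"M^2*delta_l={expected}"
                )

    @property
    def n_planes(self) -> int:
        return len(self.planes)

    @property
    def tile_extent(self) -> float:
        """Physical side of one camera tile (um)."""
        return self.tile_px * self.train.camera_pitch

    def weighted_planes(self) -> list[FocalPlaneSpec]:
        return [p for p in self.planes if p.weight > 0]

    def zero_order_plane(self) -> FocalPlaneSpec | None:
        for p in self.planes:
            if p.weight == 0.0:
                return p
        return None

    def tile_center(self, tile_rc: tuple[int, int]) -> tuple[float, float]:
        """Physical (y, x) offset of a tile centre from the optical axis (um)."""
        rows, cols = self.tile_shape
        r, c = tile_rc
        dy = (r - (rows - 1) / 2.0) * self.tile_extent
        dx = (c - (cols - 1) / 2.0) * self.tile_extent
        return dy, dx

    def z_order(self) -> list[int]:
        """Plane indices sorted by delta_l ascending (the stack z order)."""
        return [p.index for p in sorted(self.planes, key=lambda p: p.delta_l)]


@dataclass
class PhaseMask:
    """A real-valued SLM phase array wrapped to [0, 2 pi).

    Phase outside the aperture circle is 0 (pass-through); ``provenance``
    records how the mask was produced (plan summary, iteration count, final
    metrics).
    """

    phase: np.ndarray
    train: OpticalTrain
    wavelength: float
    aperture: np.ndarray | None = None
    provenance: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.shape != tuple(self.train.slm_shape):
            raise PlanError(
                f"phase shape {self.phase.shape} != SLM shape {self.train.slm_shape}"
            )
        if self.aperture is None:
            self.aperture = self.train.aperture_mask()
        self.phase = np.where(self.aperture, np.mod(self.phase, TWO_PI), 0.0)


@dataclass
class GSConfig:
    """Gerchberg–Saxton run configuration.

    ``max_iter`` follows the printed loop bound ``while n < max``: the number
    of update iterations executed is ``max_iter - 1`` (``max_iter = 1`` is a
    no-op that returns the initial phase). ``wavelength`` defaults to the
    0.55 um emission band selected by the detection bandpass filter.
    """

    max_iter: int = 30
    wavelength: float = 0.55
    seed: int = 0
    adaptive_weights: bool = False
    quantization_levels: int | None = None

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise PlanError(f"max_iter must be >= 1, got {self.max_iter}")
        if not (self.wavelength > 0):
            raise PlanError(f"wavelength must be > 0, got {self.wavelength}")


# ---------------------------------------------------------------------------
# Plan construction
# ---------------------------------------------------------------------------

def plan_from_spacings(
    spacings: Sequence[float],
    train: OpticalTrain,
    anchor: int | str = "center",
    tile_shape: tuple[int, int] = (3, 3),
    tile_px: int = 501,
    weights: Sequence[float] | None = None,
    tile_order: Sequence[tuple[int, int]] | None = None,
) -> MultiplexPlan:
    """Build a multiplex plan from requested focal-plane spacings.

    ``spacings`` are the object-side gaps d_1..d_{N-1} (um) between the N
    planes; plane offsets are their cumulative sums, shifted so the anchor
    plane sits at ``dl = 0`` (``anchor="center"`` uses the middle plane,
    giving the symmetric -k dz .. +k dz layout; an integer anchors that
    plane index). Tiles are assigned row-major over ``tile_shape`` unless an
    explicit ``tile_order`` is given; with the symmetric 9-plane layout the
    middle plane naturally lands on the central tile.
    """
    spacings = [float(s) for s in spacings]
    if any(s <= 0 for s in spacings):
        raise PlanError(f"spacings must be > 0, got {spacings}")
    n = len(spacings) + 1
    cum = np.concatenate([[0.0], np.cumsum(spacings)])
    if anchor == "center":
        anchor_idx = n // 2
    else:
        anchor_idx = int(anchor)
        if not 0 <= anchor_idx < n:
            raise PlanError(f"anchor index {anchor_idx} out of range for {n} planes")
    delta_l = cum - cum[anchor_idx]

    if weights is None:
        weights = [1.0] * n
    weights = [float(w) for w in weights]
    if len(weights) != n:
        raise PlanError(f"need {n} weights, got {len(weights)}")

    if tile_order is None:
        rows, cols = tile_shape
        if n > rows * cols:
            raise PlanError(f"{n} planes do not fit a {rows}x{cols} tile grid")
        tile_order = [(r, c) for r in range(rows) for c in range(cols)][:n]
    tile_order = [tuple(t) for t in tile_order]

    planes = [
        FocalPlaneSpec(
            index=i,
            delta_l=float(delta_l[i]),
            delta_L=object_to_image_distance(float(delta_l[i]), train.magnification),
            tile_rc=tile_order[i],
            weight=weights[i],
        )
        for i in range(n)
    ]
    return MultiplexPlan(planes, spacings, train, tile_shape=tile_shape, tile_px=tile_px)


# ---------------------------------------------------------------------------
# Per-plane phase terms and targets
# ---------------------------------------------------------------------------

def _plane_phase(plan: MultiplexPlan, plane: FocalPlaneSpec, wavelength: float) -> np.ndarray:
    """Off-axis Fresnel-lens phase steering one plane to its tile.

    Quadratic term ``+pi r^2 dL / (lambda f^2)`` refocuses by +dL past the
    Fourier-lens focal plane; linear term ``+2 pi (x dx + y dy) / (lambda f)``
    displaces the focus to the tile centre (dy, dx).
    """
    tr = plan.train
    y, x = tr.slm_coords()
    yy, xx = np.meshgrid(y, x, indexing="ij")
    dy, dx = plan.tile_center(plane.tile_rc)
    # SLM Nyquist limit: at most pi phase step per pixel from the tilt
    max_off = max(abs(dy), abs(dx))
    limit = wavelength * tr.f_fourier / (2.0 * tr.slm_pitch)
    if max_off > limit:
        raise PlanError(
            f"plane {plane.index} tile {plane.tile_rc}: tilt to offset {max_off:g} um "
            f"exceeds the SLM Nyquist limit {limit:g} um"
        )
    lens = np.pi * (xx**2 + yy**2) * plane.delta_L / (wavelength * tr.f_fourier**2)
    tilt = TWO_PI * (xx * dx + yy * dy) / (wavelength * tr.f_fourier)
    return lens + tilt


def _input_field(plan: MultiplexPlan, wavelength: float) -> ComplexField:
    """E_0: uniform unit-energy disk over the aperture on the SLM grid."""
    ap = plan.train.aperture_mask().astype(float)
    ap /= np.sqrt(np.sum(ap**2))
    return ComplexField(ap, plan.train.slm_pitch, wavelength, "SLM input")


def _target_amplitudes(plan: MultiplexPlan, wavelength: float) -> list[np.ndarray]:
    """Per-plane target amplitudes E_tar(i) on the Fourier-plane grid.

    Each target is the focused image of the input aperture (an Airy-like
    spot) translated to the plane's tile centre and windowed to the tile,
    normalized to unit array energy. Returned in plan order; the zero-weight
    plane gets a zero target.
    """
    e0 = _input_field(plan, wavelength)
    focus = fourier_lens_transform(e0, plan.train.f_fourier)
    amp = np.abs(focus.field)
    pitch_f = focus.pitch
    n = amp.shape[0]
    half = plan.tile_extent / 2.0
    y = (np.arange(n) - n // 2) * pitch_f
    targets: list[np.ndarray] = []
    for p in plan.planes:
        if p.weight == 0.0:
            targets.append(np.zeros_like(amp))
            continue
        dy, dx = plan.tile_center(p.tile_rc)
        sy = int(round(dy / pitch_f))
        sx = int(round(dx / pitch_f))
        if abs(dy) + half > y[-1] + pitch_f or abs(dx) + half > y[-1] + pitch_f:
            raise PlanError(
                f"plane {p.index} tile {p.tile_rc} falls outside the Fourier-plane grid; "
                f"reduce tile offsets or use a finer SLM pitch"
            )
        tar = np.roll(amp, (sy, sx), axis=(0, 1))
        win = _tile_window(n, pitch_f, (dy, dx), half)
        tar = tar * win
        norm = np.sqrt(np.sum(tar**2))
        targets.append(tar / norm if norm > 0 else tar)
    return targets


def _tile_window(n: int, pitch: float, center: tuple[float, float], half: float) -> np.ndarray:
    """Boolean box window of half-size ``half`` (um) centred at (dy, dx)."""
    coord = (np.arange(n) - n // 2) * pitch
    wy = np.abs(coord - center[0]) <= half
    wx = np.abs(coord - center[1]) <= half
    return np.outer(wy, wx)


# ---------------------------------------------------------------------------
# Initialization and optimization
# ---------------------------------------------------------------------------

def init_superposition(plan: MultiplexPlan, config: GSConfig) -> PhaseMask:
    """Initial phase: argument of the weighted superposition of lens terms.

    phi_0 = Arg( sum_i w(i) exp(i [lens(dL_i) + tilt(tile_i)]) ) inside the
    aperture, 0 outside. The zero-weight plane contributes nothing — its
    light is the unmodulated zero order.
    """
    acc = np.zeros(plan.train.slm_shape, dtype=complex)
    for p in plan.weighted_planes():
        acc += p.weight * np.exp(1j * _plane_phase(plan, p, config.wavelength))
    if not np.any(acc):
        raise PlanError("all plane weights are zero; nothing to superpose")
    phase = np.mod(np.angle(acc), TWO_PI)
    return PhaseMask(
        phase,
        plan.train,
        config.wavelength,
        provenance={"method": "superposition", "n_planes": plan.n_planes},
    )


def wggs_optimize(
    plan: MultiplexPlan, config: GSConfig, phi0: PhaseMask | None = None
) -> PhaseMask:
    """Weighted global Gerchberg–Saxton refinement of the multiplex mask.

    Runs the plane loop ``while n < max_iter``: per iteration, the SLM field
    ``E_A = E_0 exp(i phi)`` is Fourier-transformed to the camera-side focal
    plane (``E_B``); for every weighted plane i the field is Fresnel-
    propagated to its distance (``E_C``), its amplitude replaced by
    ``w(i) E_tar(i)`` keeping ``Arg(E_C)`` (``E_D``), propagated back
    (``E_E``) and inverse-transformed (``E_F``); the next phase is
    ``Arg(sum_i E_F(i))``. Returns the final mask with a per-iteration
    convergence log (per-plane in-tile energy fraction and uniformity) in
    ``provenance["log"]``.

    With ``adaptive_weights=True`` the weights are additionally updated each
    iteration as ``w(i) <- w(i) * mean(achieved) / achieved(i)``, the
    weighted-GS refinement; the default keeps them static.
    """
    if phi0 is None:
        phi0 = init_superposition(plan, config)
    if phi0.phase.shape != tuple(plan.train.slm_shape):
        raise PlanError("phi0 is not on the plan's SLM grid")
    weighted = plan.weighted_planes()
    if not weighted:
        raise PlanError("all plane weights are zero")

    tr = plan.train
    lam = config.wavelength
    e0 = _input_field(plan, lam)
    targets_all = _target_amplitudes(plan, lam)
    targets = [targets_all[p.index] for p in weighted]
    pitch_f = tr.fourier_pitch(lam)
    nf = tr.slm_shape[0]
    windows = [
        _tile_window(nf, pitch_f, plan.tile_center(p.tile_rc), plan.tile_extent / 2.0)
        for p in weighted
    ]
    h_fwd = [
        fresnel_transfer_function((nf, nf), pitch_f, lam, p.delta_L) for p in weighted
    ]
    h_bwd = [np.conj(h) for h in h_fwd]
    weights = np.array([p.weight for p in weighted], dtype=float)
    aperture = tr.aperture_mask()

    def _prop(a: np.ndarray, h: np.ndarray) -> np.ndarray:
        return np.fft.ifft2(np.fft.fft2(a) * h)

    phase = phi0.phase.copy()
    log: list[dict] = []
    e_f = None
    for _n in range(1, config.max_iter):
        e_a = e0.field * np.exp(1j * phase)
        e_b = fourier_lens_transform(ComplexField(e_a, tr.slm_pitch, lam), tr.f_fourier)
        total = float(np.sum(np.abs(e_b.field) ** 2))
        e_g = np.zeros_like(e_a)
        achieved = np.empty(len(weighted))
        mse = np.empty(len(weighted))
        for i, p in enumerate(weighted):
            e_c = _prop(e_b.field, h_fwd[i])
            achieved[i] = float(np.sum(np.abs(e_c) ** 2 * windows[i])) / total
            amp_c = np.abs(e_c)
            norm_c = np.sqrt(np.sum(amp_c**2))
            mse[i] = float(np.mean((amp_c / norm_c - targets[i]) ** 2))
            e_d = weights[i] * targets[i] * np.exp(1j * np.angle(e_c))
            e_e = _prop(e_d, h_bwd[i])
            e_f = fourier_lens_transform(
                ComplexField(e_e, pitch_f, lam), tr.f_fourier, inverse=True
            )
            e_g += e_f.field
        phase = np.where(aperture, np.mod(np.angle(e_g), TWO_PI), 0.0)
        rel_std = float(np.std(achieved) / np.mean(achieved)) if np.mean(achieved) else np.inf
        log.append(
            {
                "iteration": _n,
                "plane_energy": achieved.tolist(),
                "amplitude_mse": mse.tolist(),
                "uniformity_rsd": rel_std,
                "min_over_max": float(achieved.min() / achieved.max()),
            }
        )
        if config.adaptive_weights:
            weights = weights * achieved.mean() / np.maximum(achieved, 1e-12)
            weights /= weights.sum()

    mask = PhaseMask(
        phase,
        tr,
        lam,
        provenance={
            "method": "wggs",
            "iterations": config.max_iter - 1,
            "adaptive_weights": config.adaptive_weights,
            "log": log,
            "final_weights": weights.tolist(),
        },
    )
    if config.quantization_levels is not None:
        mask = quantize_phase(mask, config.quantization_levels)
    return mask


def quantize_phase(mask: PhaseMask, levels: int) -> PhaseMask:
    """Snap each phase value to the nearest of ``levels`` uniform levels.

    Models the discrete addressing of a real SLM (e.g. 256 grey levels over
    one wave). Idempotent: re-quantizing at the same level count is a no-op.
    """
    if levels < 2:
        raise PlanError(f"levels must be >= 2, got {levels}")
    step = TWO_PI / levels
    q = np.mod(np.round(mask.phase / step), levels) * step
    prov = dict(mask.provenance)
    prov["quantization_levels"] = levels
    return PhaseMask(q, mask.train, mask.wavelength, mask.aperture, prov)


def mask_report(mask: PhaseMask, plan: MultiplexPlan) -> dict:
    """Simulated quality metrics of a mask under its plan.

    Propagates an on-axis probe through the mask (see
    :func:`hilomfm.simulate.simulate_mask_response`) and summarizes:
    per-plane energy fraction in the plane's own tile, uniformity (min/max
    and relative std of those fractions), excess crosstalk into wrong tiles,
    and the zero-order tile fraction.
    """
    from .simulate import simulate_mask_response  # deferred: avoids circular import

    if mask.train != plan.train:
        raise PlanError("mask and plan must share an optical train")
    resp = simulate_mask_response(mask, plan)
    table = resp["energy_table"]
    weighted = plan.weighted_planes()
    idx = {p.index: k for k, p in enumerate(plan.planes)}
    wsel = [idx[p.index] for p in weighted]
    own = np.array([table[k, k] for k in wsel])
    # Wrong-tile energy at plane i is dominated by the other planes' own
    # designed beams (all planes sit within the image-side depth of field);
    # crosstalk is therefore measured as the EXCESS over each plane's
    # reference energy in its own tile at its own distance.
    excess = 0.0
    gross = 0.0
    for a in wsel:
        for b in wsel:
            if a == b:
                continue
            gross += table[a, b]
            excess += max(0.0, table[a, b] - table[b, b])
    within = float(np.sum(table[np.ix_(wsel, wsel)]))
    report = {
        "plane_energy": own.tolist(),
        "uniformity_min_over_max": float(own.min() / own.max()) if own.max() > 0 else 0.0,
        "uniformity_rsd": float(np.std(own) / np.mean(own)) if own.mean() > 0 else np.inf,
        "crosstalk_excess_fraction": float(excess / within) if within > 0 else 0.0,
        "wrong_tile_gross_fraction": float(gross / within) if within > 0 else 0.0,
        "outside_tiles_fraction": resp["outside_fraction"],
    }
    zp = plan.zero_order_plane()
    if zp is not None:
        k = idx[zp.index]
        report["zero_order_fraction"] = float(table[k, k])
    return report


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_mask(mask: PhaseMask, basepath: str) -> dict[str, str]:
    """Write a mask as an 8-bit grayscale PNG plus a lossless float TIFF.

    Phase is mapped [0, 2 pi) -> [0, 255] in the PNG (the format SLM driver
    software usually ingests); the float32 TIFF keeps full precision. The
    convergence log, when present, goes to ``<basepath>_log.csv``.
    """
    import tifffile
    from PIL import Image

    paths = {}
    png = f"{basepath}.png"
    Image.fromarray(
        np.round(mask.phase / TWO_PI * 255.0).astype(np.uint8), mode="L"
    ).save(png)
    paths["png"] = png
    tif = f"{basepath}.tif"
    tifffile.imwrite(tif, mask.phase.astype(np.float32))
    paths["tiff"] = tif
    log = mask.provenance.get("log")
    if log:
        csv = f"{basepath}_log.csv"
        with open(csv, "w") as fh:
            n_pl = len(log[0]["plane_energy"])
            cols = ",".join(f"plane_{k}" for k in range(n_pl))
            fh.write(f"iteration,{cols},uniformity_rsd,min_over_max\n")
            for row in log:
                pe = ",".join(f"{v:.6e}" for v in row["plane_energy"])
                fh.write(
                    f"{row['iteration']},{pe},{row['uniformity_rsd']:.6e},"
                    f"{row['min_over_max']:.6e}\n"
                )
        paths["log"] = csv
    return paths
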