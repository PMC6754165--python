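"""Reference instrument geometry and plan builders.

``default_train`` models the published bench: 200 mm Fourier lens, overall
magnification 60, 6.5 um camera pixels, 550 nm detection band, and the SLM
represented on a square computational grid at the physical 8 um pixel pitch
(which fixes the Fourier-plane extent so the 3x3 tile layout fits). The
modelled back-aperture radius is scaled to the grid; see docs/methods.md.

``nine_plane_plan`` is the standard nine-plane configuration: 0.4 um
spacing, offsets -4 dz .. +4 dz, 3x3 tiles of 501 camera pixels, the middle
(unmodulated zero-order) plane carrying weight zero on the central tile.
"""

from __future__ import annotations

from .optics import OpticalTrain
from .phase_design import GSConfig, MultiplexPlan, plan_from_spacings
from .pipeline import TileGrid

#: central emission wavelength selected by the detection bandpass (um)
EMISSION_WAVELENGTH = 0.55


def default_train(grid_size: int = 512) -> OpticalTrain:
    """Reference optical train on a ``grid_size``-square SLM grid."""
    return OpticalTrain(
        f_fourier=200_000.0,
        magnification=60.0,
        slm_pitch=8.0,
        slm_shape=(grid_size, grid_size),
        aperture_radius=0.9 * grid_size * 8.0 / 2.0,
        camera_pitch=6.5,
        camera_shape=(2048, 2048),
    )


def nine_plane_plan(
    train: OpticalTrain | None = None,
    dz: float = 0.4,
    tile_px: int = 501,
) -> MultiplexPlan:
    """Nine focal planes at ``dz`` spacing, centred, zero-order in the middle."""
    train = train or default_train()
    weights = [1.0] * 9
    weights[4] = 0.0  # middle plane = unmodulated zero order
    return plan_from_spacings(
        [dz] * 8,
        train,
        anchor="center",
        tile_shape=(3, 3),
        tile_px=tile_px,
        weights=weights,
    )


def system_magnification(
    f_objective: float, f_tube: float, f_relay: float, f_fourier: float
) -> float:
    """Overall magnification of the two-stage imaging path.

    Objective + tube lens magnify by ``f_tube / f_objective``; the 4-f relay
    into the SLM Fourier plane and the condenser onto the camera add
    ``f_fourier / f_relay``. Any consistent length unit works.
    """
    for name, v in (("f_objective", f_objective), ("f_tube", f_tube),
                    ("f_relay", f_relay), ("f_fourier", f_fourier)):
        if not (v > 0):
            raise ValueError(f"{name} must be > 0, got {v}")
    return (f_tube / f_objective) * (f_fourier / f_relay)


def tile_field_of_view(train: OpticalTrain, tile_px: int) -> float:
    """Object-space side length (um) of one camera tile."""
    return tile_px * train.camera_pitch / train.magnification


def default_gs_config(**overrides) -> GSConfig:
    """GS configuration with the reference emission wavelength."""
    kwargs = {"max_iter": 30, "wavelength": EMISSION_WAVELENGTH, "seed": 0}
    kwargs.update(overrides)
    return GSConfig(**kwargs)


def tile_grid_from_plan(
    plan: MultiplexPlan, tile_px: int | None = None, origin: tuple[int, int] = (0, 0)
) -> TileGrid:
    """Camera tile grid matching a multiplex plan's tile/z-rank assignment.

    ``tile_px`` defaults to the plan's tile size; pass a smaller value for
    scaled-down simulations (the mapping tile -> z-rank is preserved).
    """
    order = {p.tile_rc: rank for rank, idx in enumerate(plan.z_order())
             for p in [plan.planes[idx]]}
    rows, cols = plan.tile_shape
    return TileGrid(
        rows=rows,
        cols=cols,
        tile_px=tile_px if tile_px is not None else plan.tile_px,
        origin=origin,
        plane_order=order,
    )
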