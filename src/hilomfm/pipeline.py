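"""End-to-end volume reconstruction for multi-focus acquisitions.

One camera exposure holds N focal planes as tiles of a single frame; two
exposures (uniform + speckle illumination) per stage position give every
plane its HiLo pair. Scanning the stage in steps of N * dz interleaves the
per-exposure planes into a uniformly spaced z-stack:

    section z-index = position * n_planes + plane_rank,

with plane_rank ordered by object-side offset dl ascending. Trailing
sections that image outside the specimen are discarded from the end of the
stack. The module also carries the acquisition arithmetic: raw-frame
counts, the speed-up over one-exposure-per-section widefield
(n_planes / frames_per_position), and the volume rate at a given camera
frame rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dfield
from typing import Sequence

import numpy as np

from .hilo import FramePair, HiLoParams, hilo_reconstruct

logger = logging.getLogger("hilomfm")


class PipelineError(ValueError):
    """Invalid pipeline input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TileGrid:
    """Layout of the camera tiles and their mapping to z-ranks.

    ``plane_order`` maps tile (row, col) -> plane rank, where rank is the
    within-exposure z position (0 = most negative dl). Which physical tile
    holds which depth is instrument configuration, not something the optics
    dictate; the default is row-major.
    """

    rows: int = 3
    cols: int = 3
    tile_px: int = 501
    origin: tuple[int, int] = (0, 0)
    plane_order: dict[tuple[int, int], int] | None = None

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.tile_px < 1:
            raise PipelineError("rows, cols and tile_px must be >= 1")
        if self.plane_order is None:
            self.plane_order = {
                (r, c): r * self.cols + c for r in range(self.rows) for c in range(self.cols)
            }
        ranks = sorted(self.plane_order.values())
        if ranks != list(range(len(self.plane_order))):
            raise PipelineError("plane_order ranks must be a permutation of 0..n-1")

    @property
    def n_planes(self) -> int:
        return len(self.plane_order)

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.rows * self.tile_px, self.cols * self.tile_px)

    def tile_slices(self, tile_rc: tuple[int, int]) -> tuple[slice, slice]:
        r, c = tile_rc
        y0 = self.origin[0] + r * self.tile_px
        x0 = self.origin[1] + c * self.tile_px
        return slice(y0, y0 + self.tile_px), slice(x0, x0 + self.tile_px)

    def rank_to_tile(self) -> list[tuple[int, int]]:
        inv = {v: k for k, v in self.plane_order.items()}
        return [inv[i] for i in range(self.n_planes)]


@dataclass
class AcquisitionPlan:
    """Axial-scan bookkeeping for one volume."""

    n_planes: int
    dz: float                      # section spacing (um)
    scan_steps: int
    step_size: float               # stage step per move (um) = n_planes * dz
    frames_per_position: int = 2   # illumination states (uniform + speckle)
    sections_discarded: int = 0

    def __post_init__(self) -> None:
        for name in ("n_planes", "scan_steps", "frames_per_position"):
            if getattr(self, name) < 1:
                raise PipelineError(f"{name} must be >= 1")
        if not (self.dz > 0):
            raise PipelineError(f"dz must be > 0, got {self.dz}")
        if not math.isclose(self.step_size, self.n_planes * self.dz, rel_tol=1e-9):
            raise PipelineError(
                f"step_size {self.step_size} != n_planes*dz = {self.n_planes * self.dz}"
            )
        if self.sections_discarded < 0:
            raise PipelineError("sections_discarded must be >= 0")

    @property
    def sections_generated(self) -> int:
        return self.scan_steps * self.n_planes

    @property
    def sections_kept(self) -> int:
        return self.sections_generated - self.sections_discarded

    @property
    def raw_frames(self) -> int:
        return self.scan_steps * self.frames_per_position


@dataclass
class VolumeStack:
    """Z-ordered optically sectioned images with uniform spacing."""

    sections: np.ndarray           # (nz, ny, nx)
    dz: float                      # axial spacing (um)
    pixel_size: float              # lateral pixel size (um)
    provenance: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.sections = np.asarray(self.sections, dtype=float)
        if self.sections.ndim != 3:
            raise PipelineError("sections must be a (nz, ny, nx) array")
        if not (self.dz > 0 and self.pixel_size > 0):
            raise PipelineError("dz and pixel_size must be > 0")

    @property
    def n_sections(self) -> int:
        return self.sections.shape[0]

    def z_coords(self) -> np.ndarray:
        return np.arange(self.n_sections) * self.dz


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def crop_tiles(frame: np.ndarray, grid: TileGrid) -> list[np.ndarray]:
    """Cut a multiplexed camera frame into per-plane sub-images.

    Pure cropping (no resampling); returned in plane-rank order (rank 0 =
    most negative dl).
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise PipelineError("frame must be 2-D")
    fy, fx = frame.shape
    for tile in grid.plane_order:
        sy, sx = grid.tile_slices(tile)
        if sy.stop > fy or sx.stop > fx or sy.start < 0 or sx.start < 0:
            raise PipelineError(
                f"tile {tile} (rows {sy.start}:{sy.stop}, cols {sx.start}:{sx.stop}) "
                f"exceeds frame bounds {frame.shape}"
            )
    out: list[np.ndarray] = [None] * grid.n_planes  # type: ignore[list-item]
    for tile, rank in grid.plane_order.items():
        sy, sx = grid.tile_slices(tile)
        out[rank] = frame[sy, sx].copy()
    return out


def plan_acquisition(
    depth: float,
    dz: float,
    n_planes: int,
    frames_per_position: int = 2,
    camera_rate: float | None = None,
) -> tuple[AcquisitionPlan, dict]:
    """Acquisition arithmetic for imaging an axial extent ``depth``.

    One stage position yields ``n_planes`` sections spanning
    ``n_planes * dz``; ``scan_steps = ceil(depth / (n_planes * dz))``
    positions cover the depth, the trailing sections beyond it are
    discarded. The counts record also reports the speed-up factor over
    widefield z-stacking (one exposure per section), ``n_planes /
    frames_per_position``, and — when a camera frame rate is supplied — the
    volume rate ``camera_rate / frames_per_position``.
    """
    if not (depth > 0):
        raise PipelineError(f"depth must be > 0, got {depth}")
    if not (dz > 0):
        raise PipelineError(f"dz must be > 0, got {dz}")
    if n_planes < 1 or frames_per_position < 1:
        raise PipelineError("n_planes and frames_per_position must be >= 1")
    per_position = n_planes * dz
    scan_steps = int(math.ceil(depth / per_position - 1e-12))
    sections_generated = scan_steps * n_planes
    sections_kept = min(int(round(depth / dz)), sections_generated)
    plan = AcquisitionPlan(
        n_planes=n_planes,
        dz=dz,
        scan_steps=scan_steps,
        step_size=per_position,
        frames_per_position=frames_per_position,
        sections_discarded=sections_generated - sections_kept,
    )
    record = {
        "scan_steps": scan_steps,
        "raw_frames": plan.raw_frames,
        "sections_generated": sections_generated,
        "sections_kept": sections_kept,
        "sections_discarded": plan.sections_discarded,
        "speedup_factor": n_planes / frames_per_position,
        "axial_extent_per_position_um": per_position,
        "volume_rate_hz": (camera_rate / frames_per_position) if camera_rate else None,
    }
    return plan, record


def _check_frames(frames: Sequence, plan: AcquisitionPlan) -> list[FramePair]:
    if len(frames) != plan.scan_steps:
        raise PipelineError(
            f"expected {plan.scan_steps} scan positions, got {len(frames)} frame pairs"
        )
    out = []
    for k, fr in enumerate(frames):
        if isinstance(fr, FramePair):
            out.append(fr)
            continue
        try:
            u, s = fr
        except Exception as exc:
            raise PipelineError(f"position {k}: cannot unpack frame pair") from exc
        if u is None or s is None:
            missing = "uniform" if u is None else "speckle"
            raise PipelineError(f"position {k}: missing {missing} illumination frame")
        out.append(FramePair(u, s))
    return out


def _normalize_sections(stack: np.ndarray) -> np.ndarray:
    """Scale each section to the mean per-section integral (flatness fix)."""
    totals = stack.sum(axis=(1, 2))
    target = totals[totals > 0].mean() if np.any(totals > 0) else 0.0
    out = stack.copy()
    for k, t in enumerate(totals):
        if t > 0:
            out[k] *= target / t
    return out


def reconstruct_volume(
    frames: Sequence,
    grid: TileGrid,
    plan: AcquisitionPlan,
    hilo_params: HiLoParams | None = None,
    pixel_size: float = 1.0,
    normalize: bool = False,
    hilo: bool = True,
) -> VolumeStack:
    """Assemble an optically sectioned volume from an axial scan.

    ``frames`` is one uniform/speckle :class:`FramePair` of full camera
    frames per stage position. Each frame is cropped into tiles, every tile
    pair is HiLo-reconstructed (per-tile eta), and sections are interleaved
    as ``z = position * n_planes + rank``; the trailing
    ``plan.sections_discarded`` sections are dropped. ``normalize=True``
    applies per-section integral normalization; ``hilo=False`` bypasses the
    reconstruction and stacks the cropped uniform tiles (the widefield
    baseline used for comparison figures).
    """
    if grid.n_planes != plan.n_planes:
        raise PipelineError(
            f"tile grid has {grid.n_planes} planes but plan expects {plan.n_planes}"
        )
    pairs = _check_frames(frames, plan)
    params = hilo_params or HiLoParams()
    sections: list[np.ndarray] = []
    for pos, pair in enumerate(pairs):
        tiles_u = crop_tiles(pair.uniform, grid)
        tiles_s = crop_tiles(pair.speckle, grid)
        for rank in range(plan.n_planes):
            if hilo:
                tile_pair = FramePair(
                    tiles_u[rank],
                    tiles_s[rank],
                    pitch=pixel_size,
                    plane_meta={"position": pos, "rank": rank},
                )
                sections.append(hilo_reconstruct(tile_pair, params))
            else:
                sections.append(tiles_u[rank])
    stack = np.stack(sections)
    if plan.sections_discarded:
        stack = stack[: plan.sections_kept]
    if normalize:
        stack = _normalize_sections(stack)
    return VolumeStack(
        stack,
        dz=plan.dz,
        pixel_size=pixel_size,
        provenance={
            "mode": "hilo" if hilo else "widefield",
            "normalized": normalize,
            "scan_steps": plan.scan_steps,
            "n_planes": plan.n_planes,
            "sections_discarded": plan.sections_discarded,
            "hilo_params": None if not hilo else vars(params).copy(),
        },
    )


def widefield_baseline(
    frames: Sequence,
    grid: TileGrid,
    plan: AcquisitionPlan,
    pixel_size: float = 1.0,
    normalize: bool = False,
) -> VolumeStack:
    """Widefield comparison stack: cropped uniform tiles only, no HiLo."""
    return reconstruct_volume(
        frames, grid, plan, pixel_size=pixel_size, normalize=normalize, hilo=False
    )


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def save_volume(stack: VolumeStack, path: str) -> None:
    """Write a z-stack as a float32 multi-page TIFF with resolution tags."""
    import tifffile

    tifffile.imwrite(
        path,
        stack.sections.astype(np.float32),
        metadata={"spacing": stack.dz, "unit": "um", "axes": "ZYX"},
        resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
    )


def load_frame_pairs(
    uniform_path: str, speckle_path: str, pitch: float = 1.0
) -> list[FramePair]:
    """Read paired multi-page TIFFs (one page per scan position)."""
    import tifffile

    u = np.atleast_3d(tifffile.imread(uniform_path))
    s = np.atleast_3d(tifffile.imread(speckle_path))
    if u.ndim == 2:
        u = u[None]
    if s.ndim == 2:
        s = s[None]
    if u.shape != s.shape:
        raise PipelineError(
            f"uniform stack {u.shape} and speckle stack {s.shape} differ"
        )
    return [FramePair(u[k].astype(float), s[k].astype(float), pitch=pitch) for k in range(u.shape[0])]
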