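"""Sampled wave-optics primitives on physically calibrated grids.

This module provides the two coherent transforms the multi-focus phase-mask
design is built on:

* the optical Fourier transform performed by a lens of focal length ``f``
  (SLM plane -> camera-side focal plane), implemented with a centred FFT and
  the ``1/(i lambda f)`` prefactor, and
* paraxial (Fresnel) free-space propagation over a signed distance ``dL``,
  implemented with the angular-spectrum transfer function so the sampling
  pitch is preserved — the property the Gerchberg–Saxton plane loop relies on
  when it propagates back and forth on one fixed grid.

Conventions, used everywhere in the package:

* arrays are centred: the optical axis passes through sample ``N // 2`` on
  each axis, and frequency grids are handled with ``fftshift`` so DC is the
  central sample of a shifted spectrum;
* all lengths are micrometres (um) internally; configuration files may use
  mm with explicit conversion at the boundary;
* the forward Fourier kernel is ``exp(-i 2 pi (ux + vy) / (lambda f))`` and
  the Fresnel transfer function is
  ``exp(i k dL) exp(-i pi lambda dL (fx^2 + fy^2))``, which together make a
  positive quadratic SLM phase ``+pi r^2 dL / (lambda f^2)`` refocus light a
  distance ``+dL`` past the lens focal plane.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("hilomfm")

#: |dL| below this (um) is treated as zero distance: the Fresnel kernel is
#: numerically degenerate and propagation falls back to identity.
FRESNEL_MIN_DISTANCE = 1e-6


class OpticsError(ValueError):
    """Invalid optical parameter or field."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ComplexField:
    """A sampled 2-D complex optical field with physical calibration.

    Parameters
    ----------
    field : np.ndarray
        2-D complex array; both dimensions must be >= 2.
    pitch : float
        Sample spacing in um (same along both axes).
    wavelength : float
        Vacuum wavelength in um.
    plane_label : str
        Free-text description of the plane the field lives in.
    """

    field: np.ndarray
    pitch: float
    wavelength: float
    plane_label: str = ""

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=complex)
        if self.field.ndim != 2 or min(self.field.shape) < 2:
            raise OpticsError(
                f"field must be 2-D with both dims >= 2, got shape {self.field.shape}"
            )
        if not (self.pitch > 0):
            raise OpticsError(f"pitch must be > 0, got {self.pitch}")
        if not (self.wavelength > 0):
            raise OpticsError(f"wavelength must be > 0, got {self.wavelength}")
        if not np.all(np.isfinite(self.field)):
            raise OpticsError("field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.field.shape

    @property
    def energy(self) -> float:
        """Total energy  sum |E|^2 * pitch^2  (um^2-weighted)."""
        return float(np.sum(np.abs(self.field) ** 2) * self.pitch**2)

    def copy(self) -> "ComplexField":
        return ComplexField(self.field.copy(), self.pitch, self.wavelength, self.plane_label)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Centred physical coordinates (y, x) in um, 1-D each."""
        ny, nx = self.field.shape
        y = (np.arange(ny) - ny // 2) * self.pitch
        x = (np.arange(nx) - nx // 2) * self.pitch
        return y, x


@dataclass(frozen=True)
class OpticalTrain:
    """Geometry of the emission path: SLM, Fourier lens and camera.

    All lengths in um. ``aperture_radius`` is the radius of the relayed
    objective back-aperture on the SLM; the phase mask is only defined inside
    this circle (outside it the SLM is a plain mirror).
    """

    f_fourier: float = 200_000.0        # focal length of the Fourier lens (um)
    magnification: float = 60.0         # total object->camera magnification
    slm_pitch: float = 8.0              # SLM pixel pitch (um)
    slm_shape: tuple[int, int] = (512, 512)
    aperture_radius: float = 1900.0     # relayed back-aperture radius (um)
    camera_pitch: float = 6.5           # camera pixel pitch (um)
    camera_shape: tuple[int, int] = (2048, 2048)

    def __post_init__(self) -> None:
        for name in ("f_fourier", "magnification", "slm_pitch", "aperture_radius", "camera_pitch"):
            if not (getattr(self, name) > 0):
                raise OpticsError(f"{name} must be > 0, got {getattr(self, name)}")
        short = min(self.slm_shape) * self.slm_pitch
        if 2 * self.aperture_radius > short:
            raise OpticsError(
                f"aperture (diameter {2 * self.aperture_radius} um) does not fit the "
                f"SLM short dimension ({short} um)"
            )

    def slm_coords(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.slm_shape
        y = (np.arange(ny) - ny // 2) * self.slm_pitch
        x = (np.arange(nx) - nx // 2) * self.slm_pitch
        return y, x

    def aperture_mask(self) -> np.ndarray:
        """Boolean circle of the relayed back-aperture on the SLM grid."""
        y, x = self.slm_coords()
        yy, xx = np.meshgrid(y, x, indexing="ij")
        return yy**2 + xx**2 <= self.aperture_radius**2

    def fourier_pitch(self, wavelength: float) -> float:
        """Sample pitch in the lens focal plane: lambda f / (N * slm_pitch)."""
        n = self.slm_shape[0]
        if self.slm_shape[0] != self.slm_shape[1]:
            raise OpticsError("fourier_pitch requires a square SLM grid")
        return wavelength * self.f_fourier / (n * self.slm_pitch)


# ---------------------------------------------------------------------------
# Centred FFT helpers
# ---------------------------------------------------------------------------

def _ft2(a: np.ndarray) -> np.ndarray:
    """Centred 2-D DFT: origin at N//2 in, origin at N//2 out."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(a)))


def _ift2(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(a)))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def fourier_lens_transform(field: ComplexField, f: float, inverse: bool = False) -> ComplexField:
    """Optical Fourier transform of a lens with focal length ``f`` (um).

    The forward transform maps a field one focal length before the lens to
    the field in its back focal plane,

        U(u, v) = (1 / (i lambda f)) * integral E(x, y)
                  exp(-i 2 pi (u x + v y) / (lambda f)) dx dy,

    with the output pitch rescaled to ``lambda f / (N * pitch_in)``.
    ``inverse=True`` applies the exact inverse so that
    ``fourier_lens_transform(fourier_lens_transform(E, f), f, inverse=True)``
    returns ``E`` on the original grid.
    """
    if not (f > 0):
        raise OpticsError(f"focal length must be > 0, got {f}")
    ny, nx = field.shape
    if ny != nx:
        raise OpticsError("fourier_lens_transform requires a square grid")
    n = ny
    lam = field.wavelength
    pitch_out = lam * f / (n * field.pitch)
    if not inverse:
        out = _ft2(field.field) * field.pitch**2 / (1j * lam * f)
        label = f"FT({field.plane_label})" if field.plane_label else "fourier"
    else:
        # exact inverse of the forward map whose input pitch was pitch_out
        out = _ift2(field.field) * (1j * lam * f) / pitch_out**2
        label = f"IFT({field.plane_label})" if field.plane_label else "inv-fourier"
    return ComplexField(out, pitch_out, lam, label)


def fresnel_transfer_function(
    shape: tuple[int, int], pitch: float, wavelength: float, distance: float
) -> np.ndarray:
    """Fresnel angular-spectrum transfer function (unshifted FFT order).

    H(fx, fy) = exp(i k dL) * exp(-i pi lambda dL (fx^2 + fy^2)); |H| = 1,
    so propagation is unitary on the sampled grid.
    """
    fy = np.fft.fftfreq(shape[0], d=pitch)
    fx = np.fft.fftfreq(shape[1], d=pitch)
    fxx, fyy = np.meshgrid(fx, fy)
    k = 2.0 * np.pi / wavelength
    return np.exp(1j * k * distance) * np.exp(
        -1j * np.pi * wavelength * distance * (fxx**2 + fyy**2)
    )


def fresnel_propagate(
    field: ComplexField, distance: float, min_distance: float = FRESNEL_MIN_DISTANCE
) -> ComplexField:
    """Paraxial free-space propagation over a signed distance ``dL`` (um).

    Implemented as multiplication by the Fresnel transfer function in the
    frequency domain (equivalent to convolution with the Fresnel kernel
    ``exp(i pi r^2 / (lambda dL)) / (i lambda dL)``); the grid and pitch are
    unchanged. ``dL = 0`` returns the field unchanged; ``0 < |dL| <
    min_distance`` falls back to identity with a logged notice.
    """
    if distance == 0.0:
        return field.copy()
    if abs(distance) < min_distance:
        logger.info(
            "fresnel_propagate: |dL|=%g um below numerical floor %g um, "
            "returning field unchanged (kernel degenerate)",
            abs(distance), min_distance,
        )
        return field.copy()
    n = min(field.shape)
    limit = n * field.pitch**2 / field.wavelength
    if abs(distance) > limit:
        warnings.warn(
            f"Fresnel sampling criterion violated: |dL|={abs(distance):g} um exceeds "
            f"N*pitch^2/lambda={limit:g} um; transfer function is aliased",
            stacklevel=2,
        )
    h = fresnel_transfer_function(field.shape, field.pitch, field.wavelength, distance)
    out = np.fft.ifft2(np.fft.fft2(field.field) * h)
    return ComplexField(out, field.pitch, field.wavelength, field.plane_label)


def object_to_image_distance(delta_l: float, magnification: float) -> float:
    """Map an object-side focal offset dl to the image-side distance dL.

    Longitudinal magnification of an imaging system with transverse
    magnification M is M^2, so ``dL = M^2 * dl`` (sign preserved).
    """
    if not (magnification > 0):
        raise OpticsError(f"magnification must be > 0, got {magnification}")
    return magnification**2 * delta_l
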