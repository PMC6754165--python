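"""HiLo optical sectioning from a uniform/speckle image pair.

Widefield fluorescence images are the sum of in-focus and out-of-focus
emission, ``I_u = I_in + I_out``. Under speckle illumination only the
in-focus contribution carries the speckle modulation S (unit mean),
``I_s = I_in * S + I_out``, so the difference image

    I_D = I_s - I_u = (S - 1) * I_in

cancels the out-of-focus term exactly. Its low-frequency content localizes
the in-focus signal; the high-frequency content of the in-focus image
survives in ``I_u`` directly (out-of-focus blur is low-frequency). The
sectioned image fuses the two bands:

    I_HiLo = eta * LP[I_D] + HP[I_u],    HP = 1 - LP,

with LP a Gaussian low-pass in frequency and ``eta`` a scalar matching the
spectral magnitude of the two bands at the crossover,
``eta = ||F(I_u) HP|| / ||F(I_D) LP||`` (L2 over frequencies, DC excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("hilomfm")


class HiLoError(ValueError):
    """Invalid HiLo input."""


class EtaDegenerateError(HiLoError):
    """Spectral-norm eta is undefined (difference image carries no energy).

    Use ``eta_mode='fixed'`` (or rely on the reconstruction fallback, which
    substitutes ``eta_fixed`` and logs a warning).
    """


@dataclass
class FramePair:
    """Co-registered uniform- and speckle-illumination frames of one plane."""

    uniform: np.ndarray
    speckle: np.ndarray
    pitch: float = 1.0
    plane_meta: dict | None = None

    def __post_init__(self) -> None:
        self.uniform = np.asarray(self.uniform, dtype=float)
        self.speckle = np.asarray(self.speckle, dtype=float)
        if self.uniform.shape != self.speckle.shape:
            raise HiLoError(
                f"frame shapes differ: {self.uniform.shape} vs {self.speckle.shape}"
            )
        if self.uniform.ndim != 2:
            raise HiLoError("frames must be 2-D")
        for name, img in (("uniform", self.uniform), ("speckle", self.speckle)):
            if not np.all(np.isfinite(img)):
                raise HiLoError(f"{name} frame contains non-finite values")
            if np.any(img < 0):
                raise HiLoError(f"{name} frame contains negative values")


@dataclass
class HiLoParams:
    """Tunable parameters of the reconstruction.

    ``lp_sigma`` is the Gaussian low-pass sigma in normalized spatial
    frequency (cycles per pixel; the sampling frequency is 1). The default
    0.125 puts the crossover at one eighth of the sampling frequency — the
    paper-scale geometry has no stated value, so this is a starting point
    users are expected to tune against their speckle grain. ``eta_mode``
    selects the spectral-norm eta or a fixed override; ``rectify_difference``
    takes |I_D| before low-pass filtering (the variance-style variant that
    avoids signed low-pass content).
    """

    lp_sigma: float = 0.125
    eta_mode: str = "spectral_norm"
    eta_fixed: float = 1.0
    rectify_difference: bool = False

    def __post_init__(self) -> None:
        if not (self.lp_sigma > 0):
            raise HiLoError(f"lp_sigma must be > 0, got {self.lp_sigma}")
        if self.eta_mode not in ("spectral_norm", "fixed"):
            raise HiLoError(f"unknown eta_mode {self.eta_mode!r}")
        if self.eta_mode == "fixed" and not (self.eta_fixed > 0):
            raise HiLoError(f"eta_fixed must be > 0, got {self.eta_fixed}")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def difference_image(pair: FramePair) -> np.ndarray:
    """I_D = I_s - I_u; equals (S - 1) I_in when the two-term model holds."""
    return pair.speckle - pair.uniform


def gaussian_partition(
    shape: tuple[int, int], params: HiLoParams
) -> tuple[np.ndarray, np.ndarray]:
    """Complementary Gaussian low/high-pass kernels in frequency domain.

    Returned in unshifted FFT order. LP(0) = 1 and HP = 1 - LP pointwise, so
    the pair partitions every frequency exactly.
    """
    fy = np.fft.fftfreq(shape[0])
    fx = np.fft.fftfreq(shape[1])
    fxx, fyy = np.meshgrid(fx, fy)
    lp = np.exp(-(fxx**2 + fyy**2) / (2.0 * params.lp_sigma**2))
    return lp, 1.0 - lp


def _pad_width(params: HiLoParams) -> int:
    # spatial support of the Gaussian: sigma_x = 1/(2 pi sigma_f) pixels
    return int(np.ceil(4.0 / (2.0 * np.pi * params.lp_sigma))) + 1


def _filter(img: np.ndarray, params: HiLoParams, band: str) -> np.ndarray:
    """Apply LP or HP with symmetric (mirror) boundary padding."""
    pad = _pad_width(params)
    padded = np.pad(img, pad, mode="symmetric")
    lp, hp = gaussian_partition(padded.shape, params)
    kernel = lp if band == "lp" else hp
    out = np.fft.ifft2(np.fft.fft2(padded) * kernel).real
    return out[pad:-pad, pad:-pad]


def eta_scale(i_u: np.ndarray, i_d: np.ndarray, params: HiLoParams) -> float:
    """Scaling factor eta matching the low and high passbands.

    eta = ||F(I_u) HP||_2 / ||F(I_D) LP||_2 over all frequencies excluding
    DC (HP(0) = 0 makes the numerator DC-free by construction; the DC of
    I_D is excluded for symmetry). ``eta_mode='fixed'`` returns
    ``eta_fixed`` unconditionally.
    """
    if params.eta_mode == "fixed":
        return params.eta_fixed
    i_u = np.asarray(i_u, dtype=float)
    i_d = np.asarray(i_d, dtype=float)
    lp, hp = gaussian_partition(i_u.shape, params)
    fu = np.fft.fft2(i_u)
    fd = np.fft.fft2(i_d)
    num2 = np.sum(np.abs(fu * hp) ** 2) - np.abs(fu[0, 0] * hp[0, 0]) ** 2
    den2 = np.sum(np.abs(fd * lp) ** 2) - np.abs(fd[0, 0] * lp[0, 0]) ** 2
    num = float(np.sqrt(num2))
    den = float(np.sqrt(den2))
    floor = 1e-12 * max(num, 1.0)
    if den <= floor:
        raise EtaDegenerateError(
            "difference image has no low-pass energy; eta is undefined — "
            "set eta_mode='fixed' (eta_fixed) to proceed"
        )
    return num / den


def hilo_reconstruct(pair: FramePair, params: HiLoParams | None = None) -> np.ndarray:
    """Optically sectioned image  I_HiLo = eta * LP[I_D] + HP[I_u].

    ``rectify_difference`` applies |I_D| before the low-pass. When the
    spectral eta is degenerate (e.g. identical frames: no speckle contrast),
    the fixed eta is substituted with a logged warning; with I_D = 0 the
    output is then just the high-pass of the uniform image — the documented
    degenerate case. Output is clipped at 0 and the clipped fraction logged.
    """
    if params is None:
        params = HiLoParams()
    i_d = difference_image(pair)
    if params.rectify_difference:
        i_d = np.abs(i_d)
    try:
        eta = eta_scale(pair.uniform, i_d, params)
    except EtaDegenerateError:
        logger.warning(
            "hilo_reconstruct: spectral eta degenerate, falling back to fixed "
            "eta=%g", params.eta_fixed,
        )
        eta = params.eta_fixed
    i_lp = _filter(i_d, params, "lp")
    i_hp = _filter(pair.uniform, params, "hp")
    out = eta * i_lp + i_hp
    clipped = float(np.mean(out < 0))
    if clipped:
        logger.debug("hilo_reconstruct: clipped %.2f%% of pixels at 0", 100 * clipped)
    return np.clip(out, 0.0, None)
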