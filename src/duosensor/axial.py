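"""Axial intensity profiling and FWHM estimation.

The effective optical sectioning of a fiber-pinhole detection path is
measured by imaging a thin fluorescent film at a series of z positions
and taking the full width at half maximum (FWHM) of the per-slice
intensity profile.  The profile background (flat dark tails) is the mean
of the lowest-decile slices; half-max crossings are located by linear
interpolation between the bracketing samples on each side of the peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ZStack

__all__ = ["AxialProfile", "z_profile", "estimate_fwhm"]


@dataclass
class AxialProfile:
    """Background-subtracted per-slice intensity versus z position."""

    z_um: np.ndarray
    intensity: np.ndarray
    background: float = 0.0

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.z_um.size != self.intensity.size:
            raise ValueError("z_um and intensity must have the same length")
        if np.any(np.diff(self.z_um) <= 0):
            raise ValueError("z_um must be strictly increasing")


def z_profile(stack: ZStack, stat: str = "mean") -> AxialProfile:
    """Per-slice spatial statistic of a z-stack, background-subtracted.

    ``stat`` is ``"mean"`` (default; a uniform thin film fills the field)
    or ``"max"``.  The background — mean of the lowest decile of slice
    values — is subtracted from the profile and reported.
    """
    if stat == "mean":
        vals = stack.data.mean(axis=(1, 2)).astype(float)
    elif stat == "max":
        vals = stack.data.max(axis=(1, 2)).astype(float)
    else:
        raise ValueError(f"unknown statistic {stat!r}")
    n_low = max(1, stack.n_slices // 10)
    background = float(np.sort(vals)[:n_low].mean())
    z = np.arange(stack.n_slices) * stack.z_step_um
    return AxialProfile(z_um=z, intensity=vals - background, background=background)


def estimate_fwhm(profile: AxialProfile) -> float:
    """FWHM of an axial profile by half-maximum linear interpolation.

    The peak must be interior (not the first/last slice) and the profile
    must fall below half-max on both sides; otherwise an error names the
    clipped side.  Multiple equal maxima use the first and warn.
    """
    y = profile.intensity
    z = profile.z_um
    peak_val = float(y.max())
    if peak_val <= 0:
        raise ValueError("profile peak is not above background")
    maxima = np.flatnonzero(y == peak_val)
    if maxima.size > 1:
        warnings.warn(f"{maxima.size} equal maxima; using the first", stacklevel=2)
    p = int(maxima[0])
    if p == 0 or p == y.size - 1:
        raise ValueError("profile maximum lies at the stack edge")
    half = peak_val / 2.0

    def _crossing(indices: np.ndarray, side: str) -> float:
        # walk outward from the peak to the first sample below half-max
        for i in indices:
            if y[i] < half:
                j = i + 1 if side == "left" else i - 1  # bracketing sample (>= half)
                frac = (half - y[i]) / (y[j] - y[i])
                return float(z[i] + frac * (z[j] - z[i]))
        raise ValueError(f"no half-maximum crossing on the {side} side (peak clipped at stack edge)")

    left = _crossing(np.arange(p - 1, -1, -1), "left")
    right = _crossing(np.arange(p + 1, y.size), "right")
    return right - left
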