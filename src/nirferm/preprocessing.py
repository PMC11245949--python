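"""Spectral corrections applied before modeling.

Two steps, in this fixed order: conversion of reflectance to absorbance,
A(lambda) = log10(1 / R(lambda)), followed by Savitzky-Golay least-squares
polynomial smoothing (derivative order 0).  Smoothing uses mirror padding so
the output keeps the full wavelength axis, which keeps wavelength indices
stable across the whole pipeline.

Note on the default window: a 3-point window with a quadratic polynomial is
mathematically the identity map (a quadratic interpolates three points
exactly), so with the default ``SGFilterSpec`` smoothing is a no-op.  A
7-point window (``half_window=3``) is the other plausible reading of
"three-step" smoothing; both are supported and the choice is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter

from .data_model import SpectrumSet


class PreprocessingError(ValueError):
    """Raised on invalid filter parameters or mode mismatches."""


@dataclass(frozen=True)
class SGFilterSpec:
    """Savitzky-Golay smoothing parameters (derivative order fixed at 0).

    ``half_window`` m gives a window of 2m + 1 points; the polynomial order
    must be smaller than the window length.
    """

    poly_order: int = 2
    half_window: int = 1

    def __post_init__(self) -> None:
        if self.half_window < 1:
            raise PreprocessingError("half_window must be a positive integer")
        if self.poly_order < 0:
            raise PreprocessingError("poly_order must be non-negative")
        if self.window_length <= self.poly_order:
            raise PreprocessingError(
                f"window length {self.window_length} must exceed "
                f"poly_order {self.poly_order}"
            )

    @property
    def window_length(self) -> int:
        return 2 * self.half_window + 1

    def coefficients(self) -> np.ndarray:
        """Convolution coefficients; for derivative order 0 they sum to 1."""
        return savgol_coeffs(self.window_length, self.poly_order)


def reflectance_to_absorbance(spectra: SpectrumSet) -> SpectrumSet:
    """Convert reflectance spectra to absorbance, A = log10(1/R)."""
    if spectra.mode != "reflectance":
        raise PreprocessingError("spectra are already in absorbance mode")
    if np.any(spectra.values <= 0):
        raise PreprocessingError("reflectance <= 0 has no defined absorbance")
    return spectra.with_values(np.log10(1.0 / spectra.values), mode="absorbance")


def sg_smooth(spectra: SpectrumSet, spec: SGFilterSpec = SGFilterSpec()) -> SpectrumSet:
    """Smooth each spectrum with a Savitzky-Golay filter.

    Mirror padding reflects ``half_window`` points at each end so the output
    has the same length as the input.
    """
    if spectra.n_wavelengths < spec.window_length:
        raise PreprocessingError(
            f"window of {spec.window_length} points exceeds spectrum length "
            f"{spectra.n_wavelengths}"
        )
    smoothed = savgol_filter(
        spectra.values,
        window_length=spec.window_length,
        polyorder=spec.poly_order,
        deriv=0,
        axis=1,
        mode="mirror",
    )
    return spectra.with_values(smoothed)
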