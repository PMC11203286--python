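"""Spectrum referencing and baseline correction.

``calibrate`` shifts the ppm axis so the internal reference singlet
(TMS in organic solvent, TSP in water) sits exactly at 0.0 ppm;
``baseline_correct`` removes a slowly varying baseline with asymmetric
least squares (AsLS).  Phase correction is deliberately absent: spectra
produced by the synthetic generator are absorption-mode by construction,
and raw instrument data must be phased upstream — a stated limitation
for real Bruker spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .synth import Spectrum

__all__ = ["CalibrationResult", "calibrate", "baseline_correct"]


@dataclass(frozen=True)
class CalibrationResult:
    shift_applied: float
    reference_found: bool
    reference_height: float


def calibrate(
    spectrum: Spectrum, reference_ppm: float = 0.0, window: float = 0.2
) -> tuple[Spectrum, CalibrationResult]:
    """Shift the axis so the reference apex lands on ``reference_ppm``.

    The apex is the intensity maximum within +-``window`` ppm of the
    expected reference position.  If no point there rises above the
    noise floor (3x the median absolute deviation of the window's
    intensities) the spectrum is returned unshifted with
    ``reference_found`` False.  Intensities are never modified.
    """
    ppm, y = spectrum.ppm, spectrum.intensity
    lo, hi = reference_ppm - window, reference_ppm + window
    if ppm.min() > lo or ppm.max() < hi:
        raise ValueError(
            f"axis [{ppm.min():g}, {ppm.max():g}] does not cover the reference "
            f"window [{lo:g}, {hi:g}] ppm"
        )
    mask = (ppm >= lo) & (ppm <= hi)
    win = y[mask]
    mad = float(np.median(np.abs(win - np.median(win))))
    apex_local = int(np.argmax(win))
    apex_height = float(win[apex_local])
    if apex_height <= 3.0 * mad:
        return spectrum, CalibrationResult(0.0, False, apex_height)
    apex_ppm = float(ppm[mask][apex_local])
    shift = reference_ppm - apex_ppm
    shifted = Spectrum(ppm=ppm + shift, intensity=y.copy(), meta=dict(spectrum.meta))
    return shifted, CalibrationResult(shift, True, apex_height)


def baseline_correct(
    spectrum: Spectrum,
    smoothness: float = 1e7,
    asymmetry: float = 0.01,
    max_iter: int = 10,
) -> Spectrum:
    """Subtract an asymmetric-least-squares baseline estimate.

    AsLS minimises ``sum w_i (y_i - z_i)^2 + smoothness * sum (d2 z)^2``
    with weights ``asymmetry`` above the baseline and ``1 - asymmetry``
    below, re-estimated until stable; peaks (above the fit) barely pull
    the baseline while the signal-free floor anchors it.  Only the
    intensities change; the axis is untouched.
    """
    y = spectrum.intensity
    if not np.all(np.isfinite(y)):
        raise ValueError("intensity contains non-finite values")
    n = len(y)
    if n < 4:
        return Spectrum(ppm=spectrum.ppm.copy(), intensity=y - np.median(y), meta=dict(spectrum.meta))
    # second-difference operator, (n-2) x n
    diff2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = smoothness * (diff2.T @ diff2)
    w = np.ones(n)
    z = y
    for _ in range(max_iter):
        weight_mat = sparse.diags(w, 0, format="csc")
        z = spsolve((weight_mat + penalty).tocsc(), w * y)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return Spectrum(ppm=spectrum.ppm.copy(), intensity=y - z, meta=dict(spectrum.meta))
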