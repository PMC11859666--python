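"""Wet-lab quantification formulas as small, exactly testable utilities:
relative RT-qPCR expression (2^-ddCt), one-phase RNA decay half-life,
xenograft tumour volume and wound-closure percentage."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


def ddct(ct_target_case: float, ct_ref_case: float,
         ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Relative expression 2^-((Ct_t,case - Ct_ref,case) -
    (Ct_t,ctrl - Ct_ref,ctrl))."""
    delta_delta = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-delta_delta))


@dataclass
class DecayFit:
    k: float
    half_life: float  # ln(2)/k; NaN when undefined
    y0: float
    defined: bool


def one_phase_decay_fit(times, abundances, plateau: float = 0.0) -> DecayFit:
    """Least-squares fit of y = plateau + (y0 - plateau) * exp(-k t).

    Abundances are fractions of the t=0 level, so y0 is free but near 1 and
    the plateau defaults to 0.  A non-positive decay rate yields an
    undefined half-life (flagged), not an error.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(abundances, dtype=float)
    if len(t) < 3:
        raise ValueError("need >= 3 timepoints")

    def model(tt, y0, k):
        return plateau + (y0 - plateau) * np.exp(-k * tt)

    try:
        (y0, k), _ = curve_fit(model, t, y, p0=(1.0, 0.1), maxfev=10000)
    except RuntimeError:
        return DecayFit(float("nan"), float("nan"), float("nan"), False)
    if k <= 1e-8:  # no measurable decay within machine precision
        return DecayFit(float(k), float("nan"), float(y0), False)
    return DecayFit(float(k), float(np.log(2.0) / k), float(y0), True)


def tumor_volume(a: float, b: float) -> float:
    """V = 0.5 * A * B^2 with A the longitudinal and B the latitudinal
    diameter."""
    if a < 0 or b < 0:
        raise ValueError("diameters must be non-negative")
    return float(0.5 * a * b * b)


def wound_closure(width_0h: float, width_12h: float) -> float:
    """Migration percentage (w0 - w12) / w0 * 100."""
    if width_0h <= 0:
        raise ValueError("initial wound width must be positive")
    return float((width_0h - width_12h) / width_0h * 100.0)
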