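"""Oliver-Pharr nanoindentation analysis.

Units throughout: load in uN, depth in nm, time in s.  With those units the
contact relations pick up a factor of 1000 to express moduli and hardness in
GPa (1 uN/nm^2 = 1000 GPa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "IndentationCurve",
    "AreaFunction",
    "IndenterConstants",
    "UnloadingFit",
    "IndentationResult",
    "segment_curve",
    "fit_unloading",
    "modulus_hardness",
    "calibrate_area_function",
    "analyze_curve",
]

_UN_PER_NM2_TO_GPA = 1000.0
_AREA_EXPONENTS = (2.0, 1.0, 0.5, 0.25, 0.125, 0.0625)


@dataclass
class AreaFunction:
    """Projected contact area A(h_c) = sum_i C_i h_c^{e_i}.

    Exponents follow the standard six-term form (2, 1, 1/2, 1/4, 1/8, 1/16);
    C0 = 24.5 is the ideal Berkovich leading coefficient.
    """

    coefficients: Sequence[float] = (24.5, 0.0, 0.0, 0.0, 0.0, 0.0)
    valid_range: tuple[float, float] = (0.0, np.inf)  # nm

    def __call__(self, h_c: float) -> float:
        h_c = float(h_c)
        lo, hi = self.valid_range
        if not (lo <= h_c <= hi):
            warnings.warn(
                f"contact depth {h_c:.1f} nm outside calibrated range [{lo}, {hi}]"
            )
        area = sum(
            c * h_c**e for c, e in zip(self.coefficients, _AREA_EXPONENTS)
        )
        if area <= 0:
            raise ValueError("area function evaluated to a non-positive area")
        return float(area)


@dataclass
class IndenterConstants:
    epsilon: float = 0.75       # Sneddon geometry factor
    beta: float = 1.0           # tip shape correction
    E_indenter: float = 1141.0  # GPa, diamond
    nu_indenter: float = 0.07
    nu_sample: float = 0.3

    def __post_init__(self) -> None:
        if not 0.7 <= self.epsilon <= 0.8:
            raise ValueError("epsilon outside [0.7, 0.8]")
        for name in ("beta", "E_indenter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class IndentationCurve:
    time: np.ndarray
    depth: np.ndarray   # nm
    load: np.ndarray    # uN
    segments: np.ndarray  # str labels: load | hold | unload

    def segment(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        sel = self.segments == name
        return self.time[sel], self.depth[sel], self.load[sel]

    def hold_duration(self) -> float:
        t = self.time[self.segments == "hold"]
        return float(t[-1] - t[0]) if t.size > 1 else 0.0


@dataclass
class UnloadingFit:
    alpha: float
    h_f: float
    m: float
    S: float       # uN/nm at h_max
    h_c: float     # nm
    h_max: float   # nm
    P_max: float   # uN


@dataclass
class IndentationResult:
    S: float
    h_c: float
    A: float       # nm^2
    E_r: float     # GPa
    E_s: float     # GPa
    H: float       # GPa
    fit: UnloadingFit = field(repr=False, default=None)
    valid: bool = True


def segment_curve(
    time: np.ndarray,
    depth: np.ndarray,
    load: np.ndarray,
    load_rate: Optional[float] = None,
) -> IndentationCurve:
    """Label raw samples as load / hold / unload.

    The hold is the contiguous region around peak load where |dP/dt| is below
    1 % of the loading rate; the loading rate defaults to the median positive
    dP/dt.
    """
    time = np.asarray(time, dtype=float)
    depth = np.asarray(depth, dtype=float)
    load = np.asarray(load, dtype=float)
    if not (time.shape == depth.shape == load.shape):
        raise ValueError("time, depth, load must have equal length")
    dt = np.gradient(time)
    dpdt = np.gradient(load) / dt
    if load_rate is None:
        pos = dpdt[dpdt > 0]
        if pos.size == 0:
            raise ValueError("no loading segment found")
        load_rate = float(np.median(pos))

    peak = int(np.argmax(load))
    plateau = np.abs(dpdt) < 0.01 * load_rate
    # grow the hold outward from the peak
    lo = peak
    while lo > 0 and plateau[lo - 1]:
        lo -= 1
    hi = peak
    while hi < len(load) - 1 and plateau[hi + 1]:
        hi += 1
    segments = np.empty(len(load), dtype=object)
    segments[:lo] = "load"
    segments[lo : hi + 1] = "hold"
    segments[hi + 1 :] = "unload"
    if not np.any(segments == "unload"):
        raise ValueError("no unload segment found")
    if not np.any(segments == "load"):
        raise ValueError("no load segment found")
    return IndentationCurve(time, depth, load, segments.astype(str))


def _power_law(h, alpha, h_f, m):
    return alpha * np.clip(h - h_f, 0.0, None) ** m


def fit_unloading(
    curve: IndentationCurve,
    fit_range: tuple[float, float] = (0.95, 0.20),
    epsilon: float = 0.75,
) -> UnloadingFit:
    """Fit P = alpha (h - h_f)^m to the unloading segment.

    The fit spans the samples whose load lies between ``fit_range`` fractions
    of the unloading peak load (default 95 %..20 %).  Contact stiffness is the
    analytic derivative at h_max and h_c = h_max - epsilon P_max / S.
    """
    _, h_un, p_un = curve.segment("unload")
    if h_un.size < 10:
        raise ValueError("unload segment must have at least 10 samples")
    # the hold segment gives the least-noisy estimate of the peak state:
    # load averages out noise and the final hold depth includes all creep
    _, h_hold, p_hold = curve.segment("hold")
    if p_hold.size >= 3:
        p_max = float(p_hold.mean())
        h_max = float(h_hold[-1])
    else:
        p_max = float(p_un.max())
        h_max = float(h_un[np.argmax(p_un)])
    hi_f, lo_f = fit_range
    sel = (p_un <= hi_f * p_max) & (p_un >= lo_f * p_max)
    if sel.sum() < 5:
        raise ValueError("too few samples in the unloading fit range")
    h_fit, p_fit = h_un[sel], p_un[sel]

    h_min = float(h_fit.min())
    m0 = 1.5
    hf0 = h_min - 0.1 * (h_max - h_min)
    a0 = p_max / max(h_max - hf0, 1e-9) ** m0
    try:
        popt, _ = curve_fit(
            _power_law,
            h_fit,
            p_fit,
            p0=(a0, hf0, m0),
            bounds=([0.0, -np.inf, 1.0], [np.inf, h_min, 3.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ValueError(f"unloading fit failed to converge: {exc}") from exc
    alpha, h_f, m = (float(v) for v in popt)
    if not 1.0 <= m <= 3.0:
        raise ValueError(f"unloading exponent m = {m:.3f} outside [1, 3]")
    s = m * alpha * (h_max - h_f) ** (m - 1.0)
    h_c = h_max - epsilon * p_max / s
    if not 0 < h_c < h_max:
        raise ValueError("contact depth outside (0, h_max): indent flagged invalid")
    return UnloadingFit(alpha, h_f, m, float(s), float(h_c), h_max, p_max)


def modulus_hardness(
    fit: UnloadingFit,
    area_function: AreaFunction,
    constants: IndenterConstants = IndenterConstants(),
) -> IndentationResult:
    """Reduced modulus, sample modulus and hardness from an unloading fit."""
    area = area_function(fit.h_c)
    e_r = _UN_PER_NM2_TO_GPA * np.sqrt(np.pi) * fit.S / (2.0 * constants.beta * np.sqrt(area))
    hardness = _UN_PER_NM2_TO_GPA * fit.P_max / area
    inv_es = 1.0 / e_r - (1.0 - constants.nu_indenter**2) / constants.E_indenter
    e_s = (1.0 - constants.nu_sample**2) / inv_es
    return IndentationResult(
        S=fit.S, h_c=fit.h_c, A=area, E_r=float(e_r), E_s=float(e_s),
        H=float(hardness), fit=fit,
    )


def analyze_curve(
    time,
    depth,
    load,
    area_function: AreaFunction,
    constants: IndenterConstants = IndenterConstants(),
    fit_range: tuple[float, float] = (0.95, 0.20),
) -> IndentationResult:
    """segment -> unloading fit -> modulus/hardness in one call."""
    curve = segment_curve(time, depth, load)
    fit = fit_unloading(curve, fit_range=fit_range, epsilon=constants.epsilon)
    return modulus_hardness(fit, area_function, constants)


def calibrate_area_function(
    curves: Sequence[IndentationCurve],
    target_E_r: float,
    constants: IndenterConstants = IndenterConstants(),
    n_terms: int = 3,
) -> AreaFunction:
    """Fit tip-area coefficients from fused-silica indents at multiple depths.

    For each indent the required area is A = (1000 sqrt(pi) S / (2 beta
    E_r_target))^2; coefficients beyond the fixed C0 = 24.5 are fit by linear
    least squares.  Requires >= 5 curves; a depth range narrower than 3x
    restricts the fit to C1 and C2 with a warning.
    """
    if len(curves) < 5:
        raise ValueError("area calibration needs at least 5 indents")
    fits = [fit_unloading(c, epsilon=constants.epsilon) for c in curves]
    h_c = np.array([f.h_c for f in fits])
    s = np.array([f.S for f in fits])
    if h_c.max() / h_c.min() < 3.0:
        warnings.warn("depth range narrower than 3x: fitting only C1 and C2")
        n_terms = 2
    target_area = (
        _UN_PER_NM2_TO_GPA * np.sqrt(np.pi) * s / (2.0 * constants.beta * target_E_r)
    ) ** 2
    residual = target_area - 24.5 * h_c**2
    design = np.column_stack(
        [h_c**e for e in _AREA_EXPONENTS[1 : 1 + n_terms]]
    )
    coefs, *_ = np.linalg.lstsq(design, residual, rcond=None)
    full = [24.5] + list(coefs) + [0.0] * (5 - n_terms)
    return AreaFunction(
        coefficients=tuple(float(c) for c in full),
        valid_range=(float(h_c.min()) * 0.5, float(h_c.max()) * 1.5),
    )
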