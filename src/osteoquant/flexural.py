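"""Three-point-bending property extraction.

Extracted structural properties: bending stiffness (maximum sliding-window
regression slope), yield by 10 % secant-stiffness reduction, failure by a
10 % instantaneous force drop, work to fracture by trapezoidal integration,
and the beam-theory tissue modulus E = K L^3 / (48 I_min).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ForceDisplacementCurve",
    "BendingConfig",
    "FlexuralProperties",
    "preprocess",
    "stiffness",
    "yield_point",
    "failure_point",
    "extract_properties",
    "tissue_modulus",
    "mass_adjust",
]


@dataclass
class ForceDisplacementCurve:
    displacement: np.ndarray  # mm, non-decreasing
    force: np.ndarray         # N
    sampling_rate: float = 100.0  # Hz

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.shape != self.force.shape:
            raise ValueError("displacement and force must have equal length")
        if self.displacement.size < 20:
            raise ValueError("curve must have at least 20 samples")
        if np.any(np.diff(self.displacement) < 0):
            raise ValueError("displacement must be non-decreasing")


@dataclass
class BendingConfig:
    span: float = 7.0                    # mm
    preload: float = 2.0                 # N
    failure_drop_fraction: float = 0.10
    yield_secant_fraction: float = 0.10
    stiffness_window_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.span <= 0:
            raise ValueError("span must be > 0")
        if self.preload < 0:
            raise ValueError("preload must be >= 0")


@dataclass
class FlexuralProperties:
    stiffness: float
    max_force: float
    max_moment: float
    yield_displacement: float
    yield_force: float
    failure_displacement: float
    post_yield_displacement: Optional[float]
    work_to_fracture: Optional[float]
    tissue_modulus: Optional[float] = None  # MPa
    irregular: bool = False
    warnings: list = field(default_factory=list)


def preprocess(curve: ForceDisplacementCurve, config: BendingConfig) -> ForceDisplacementCurve:
    """Re-zero displacement at the first crossing of the preload force.

    Samples before the crossing are discarded and an interpolated sample at
    exactly (0, preload) is prepended.
    """
    f, d = curve.force, curve.displacement
    if config.preload <= 0 or f[0] >= config.preload:
        d0 = d[0]
        return ForceDisplacementCurve(d - d0, f.copy(), curve.sampling_rate)
    above = np.nonzero(f >= config.preload)[0]
    if above.size == 0:
        raise ValueError("invalid test: force never reaches the preload")
    i = above[0]
    # linear interpolation between i-1 and i
    frac = (config.preload - f[i - 1]) / (f[i] - f[i - 1])
    d_cross = d[i - 1] + frac * (d[i] - d[i - 1])
    new_d = np.concatenate([[0.0], d[i:] - d_cross])
    new_f = np.concatenate([[config.preload], f[i:]])
    return ForceDisplacementCurve(new_d, new_f, curve.sampling_rate)


def stiffness(curve: ForceDisplacementCurve, window_fraction: float = 0.20) -> float:
    """Maximum least-squares slope over a sliding window.

    The window covers ``window_fraction`` of the samples between the first
    sample (the preload zero) and the force peak.
    """
    f, d = curve.force, curve.displacement
    peak = int(np.argmax(f))
    n = peak + 1
    w = max(5, int(round(window_fraction * n)))
    if n < 5:
        raise ValueError("fewer than 5 samples before the force peak")
    w = min(w, n)
    # rolling OLS slope via cumulative sums
    best = -np.inf
    for start in range(0, n - w + 1):
        x = d[start : start + w]
        y = f[start : start + w]
        vx = x - x.mean()
        denom = np.dot(vx, vx)
        if denom == 0:
            continue
        slope = np.dot(vx, y - y.mean()) / denom
        if slope > best:
            best = slope
    if not np.isfinite(best):
        raise ValueError("could not estimate stiffness (degenerate displacement)")
    return float(best)


def failure_point(
    curve: ForceDisplacementCurve, config: BendingConfig
) -> tuple[float, float, bool]:
    """First sample-to-sample drop exceeding the failure fraction of max force.

    Returns (d_f, F_f, detected); when no drop is found the last sample is
    returned with ``detected=False`` and a warning.
    """
    f, d = curve.force, curve.displacement
    fmax = float(f.max())
    drops = np.nonzero(-np.diff(f) > config.failure_drop_fraction * fmax)[0]
    if drops.size:
        i = int(drops[0])
        return float(d[i]), float(f[i]), True
    warnings.warn("no fracture drop detected; using the last sample as failure")
    return float(d[-1]), float(f[-1]), False


def yield_point(
    curve: ForceDisplacementCurve,
    k: float,
    config: BendingConfig,
    failure_index: Optional[int] = None,
) -> tuple[float, float]:
    """First point where secant stiffness F/d drops below (1 - f) K."""
    f, d = curve.force, curve.displacement
    stop = failure_index + 1 if failure_index is not None else len(f)
    target = (1.0 - config.yield_secant_fraction) * k
    with np.errstate(divide="ignore", invalid="ignore"):
        secant = np.where(d[:stop] > 0, f[:stop] / d[:stop], np.inf)
    below = np.nonzero(secant < target)[0]
    if below.size == 0:
        warnings.warn("secant yield criterion never met; yield set to failure")
        i = stop - 1
        return float(d[i]), float(f[i])
    i = int(below[0])
    return float(d[i]), float(f[i])


def _is_irregular(curve: ForceDisplacementCurve, tol_fraction: float = 0.02) -> bool:
    """Non-monotone force before 50 % of the peak flags a test as irregular."""
    f = curve.force
    peak = f.max()
    half = np.nonzero(f >= 0.5 * peak)[0]
    if half.size == 0:
        return False
    upto = half[0]
    if upto < 2:
        return False
    drops = -np.diff(f[: upto + 1])
    return bool(np.any(drops > tol_fraction * peak))


def extract_properties(
    curve: ForceDisplacementCurve,
    config: BendingConfig,
    i_min: Optional[float] = None,
) -> FlexuralProperties:
    """Full property extraction on one (raw) bending curve."""
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cur = preprocess(curve, config)
        k = stiffness(cur, config.stiffness_window_fraction)
        d_f, f_f, detected = failure_point(cur, config)
        fail_idx = int(np.searchsorted(cur.displacement, d_f, side="right")) - 1
        d_y, f_y = yield_point(cur, k, config, failure_index=fail_idx)
        notes.extend(str(w.message) for w in caught)

    f, d = cur.force, cur.displacement
    upto = fail_idx + 1
    max_force = float(f[:upto].max())
    irregular = _is_irregular(cur)
    if irregular:
        pyd: Optional[float] = None
        work: Optional[float] = None
        notes.append("irregular curve: PYD and work to fracture withheld")
    else:
        pyd = max(0.0, d_f - d_y)
        work = float(np.trapezoid(f[:upto], d[:upto]))
    props = FlexuralProperties(
        stiffness=k,
        max_force=max_force,
        max_moment=max_force * config.span / 4.0,
        yield_displacement=d_y,
        yield_force=f_y,
        failure_displacement=d_f,
        post_yield_displacement=pyd,
        work_to_fracture=work,
        irregular=irregular,
        warnings=notes,
    )
    if i_min is not None:
        props.tissue_modulus = tissue_modulus(k, i_min, config.span)
    return props


def tissue_modulus(k: float, i_min: float, span: float) -> float:
    """Beam-theory tissue modulus E = K L^3 / (48 I_min), in MPa.

    Units: K in N/mm, span in mm, I_min in mm^4 give E in N/mm^2 = MPa.
    """
    if k <= 0 or span <= 0:
        raise ValueError("K and span must be > 0")
    if i_min <= 0:
        raise ValueError("I_min must be > 0")
    return k * span**3 / (48.0 * i_min)


def mass_adjust(
    values: np.ndarray,
    body_mass: np.ndarray,
    strain: np.ndarray,
    reference_mass: Optional[float] = None,
) -> np.ndarray:
    """Body-mass adjustment with strain-specific regression slopes.

    For mouse i in strain s: ``y_adj = y - b_s * (m_i - m_ref)`` where b_s is
    the ordinary-least-squares slope of y on body mass within strain s and
    m_ref defaults to the grand-mean body mass over all strains.
    """
    values = np.asarray(values, dtype=float)
    body_mass = np.asarray(body_mass, dtype=float)
    strain = np.asarray(strain)
    if reference_mass is None:
        reference_mass = float(body_mass.mean())
    adjusted = values.copy()
    for s in np.unique(strain):
        sel = strain == s
        if sel.sum() < 3:
            raise ValueError(f"strain {s!r} has fewer than 3 mice")
        m = body_mass[sel]
        y = values[sel]
        vm = m - m.mean()
        denom = np.dot(vm, vm)
        if denom == 0:
            warnings.warn(
                f"constant body mass in strain {s!r}: slope undefined, "
                "values left unadjusted"
            )
            continue
        slope = np.dot(vm, y - y.mean()) / denom
        adjusted[sel] = y - slope * (m - reference_mass)
    return adjusted
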