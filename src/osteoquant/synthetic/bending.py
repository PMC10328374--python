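"""Synthetic three-point-bending force-displacement curves.

The curve is piecewise linear: elastic ramp at stiffness K to the
proportional-limit force, linear hardening to the ultimate force, a plateau,
linear softening, then a terminal fracture drop.  The attached truth reports
the yield point *as the downstream 10 % secant-stiffness criterion defines
it* (computed in closed form on the noiseless curve), so that the requested
post-yield displacement is exactly the displacement between that yield point
and failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..flexural import ForceDisplacementCurve

__all__ = ["BendingTruth", "gen_bending_curve"]


@dataclass
class BendingTruth:
    stiffness: float                 # N/mm
    yield_force: float               # N, proportional limit of the ramp
    ultimate_force: float            # N
    post_yield_displacement: float   # mm, from secant-criterion yield to failure
    span: float = 7.0                # mm
    noise_sd: float = 0.0            # N
    yield_secant_fraction: float = 0.10
    hardening_fraction: float = 0.5  # fraction of PYD spent hardening
    softening_force_fraction: float = 0.97
    # derived, filled by gen_bending_curve
    yield_displacement: float = field(default=0.0, init=False)
    failure_displacement: float = field(default=0.0, init=False)
    work_to_fracture: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if not self.ultimate_force >= self.yield_force > 0:
            raise ValueError("need ultimate_force >= yield_force > 0")
        if self.stiffness <= 0:
            raise ValueError("stiffness must be > 0")
        if self.post_yield_displacement < 0:
            raise ValueError("post_yield_displacement must be >= 0")
        if self.noise_sd >= 0.10 * self.yield_force:
            raise ValueError(
                "noise_sd >= 10% of yield force: properties unidentifiable"
            )


def _secant_yield(truth: BendingTruth, d_knee: float, d_ult: float) -> float:
    """Displacement where secant stiffness F/d first drops to (1-f)K.

    Closed form on the noiseless piecewise curve (no preload offset).
    """
    k = truth.stiffness
    target = (1.0 - truth.yield_secant_fraction) * k
    fy, fu = truth.yield_force, truth.ultimate_force
    if d_ult > d_knee:
        k2 = (fu - fy) / (d_ult - d_knee)
        # F(d) = fy + k2 (d - d_knee); solve F/d = target
        denom = target - k2
        if denom > 0:
            d = (fy - k2 * d_knee) / denom
            if d_knee <= d <= d_ult:
                return d
    # on the plateau F = fu
    return fu / target


def gen_bending_curve(
    truth: BendingTruth, seed: int, rate: float = 0.05, sampling_rate: float = 100.0
) -> tuple[ForceDisplacementCurve, BendingTruth]:
    """Generate one bending test at the given displacement rate (mm/s).

    Returns the curve and the truth with the derived yield/failure
    displacements and analytic work to fracture filled in.
    """
    rng = np.random.default_rng(seed)
    k = truth.stiffness
    fy, fu = truth.yield_force, truth.ultimate_force
    pyd = truth.post_yield_displacement
    d_knee = fy / k

    if pyd == 0:
        # pure linear ramp to the ultimate force, then fracture
        d_fail = fu / k
        d_yield = d_fail
        knots_d = [0.0, d_fail]
        knots_f = [0.0, fu]
    else:
        d_ult = d_knee + truth.hardening_fraction * pyd
        d_yield = _secant_yield(truth, d_knee, d_ult)
        d_fail = d_yield + pyd
        if d_fail <= d_ult:
            raise ValueError(
                "requested post-yield displacement too small for the curve shape"
            )
        d_soft = d_ult + 0.8 * (d_fail - d_ult)
        knots_d = [0.0, d_knee, d_ult, d_soft, d_fail]
        knots_f = [0.0, fy, fu, fu, truth.softening_force_fraction * fu]

    dt_step = rate / sampling_rate
    n = int(np.floor(d_fail / dt_step)) + 1
    disp = np.arange(n) * dt_step
    force = np.interp(disp, knots_d, knots_f)
    # terminal fracture drop over two samples
    disp = np.append(disp, [d_fail + dt_step, d_fail + 2 * dt_step])
    force = np.append(force, [0.3 * force[-1], 0.0])
    if truth.noise_sd > 0:
        force = force + rng.normal(0.0, truth.noise_sd, size=force.shape)

    truth.yield_displacement = d_yield
    truth.failure_displacement = d_fail
    truth.work_to_fracture = float(np.trapezoid(np.interp(
        np.linspace(0, d_fail, 20001), knots_d, knots_f
    ), np.linspace(0, d_fail, 20001)))
    curve = ForceDisplacementCurve(
        displacement=disp, force=force, sampling_rate=sampling_rate
    )
    return curve, truth
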