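"""Forward model of a load-hold-unload nanoindentation test.

The loading segment follows P = C h^2 (a choice: the protocol does not
constrain the loading-curve shape); the hold creeps logarithmically in time
at constant load; the unload follows the power law P = alpha (h - h_f)^m
constructed to be exactly consistent with the requested reduced modulus and
hardness at contact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..indentation import AreaFunction, IndentationCurve, IndenterConstants

__all__ = ["IndentationTruth", "gen_indentation_curve", "silica_reduced_modulus"]

_GPA_TO_UN_PER_NM2 = 1.0 / 1000.0


def silica_reduced_modulus(
    E_sample: float = 72.0,
    nu_sample: float = 0.17,
    constants: IndenterConstants = IndenterConstants(),
) -> float:
    """Reduced modulus of a sample/indenter pair (GPa)."""
    inv = (1.0 - nu_sample**2) / E_sample + (
        1.0 - constants.nu_indenter**2
    ) / constants.E_indenter
    return 1.0 / inv


@dataclass
class IndentationTruth:
    reduced_modulus: float       # GPa
    hardness: float              # GPa
    max_load: float = 1000.0     # uN
    load_rate: float = 100.0     # uN/s
    hold_time: float = 30.0      # s
    creep_amplitude: float = 0.0  # nm added during the hold
    noise_sd: float = 0.0        # uN
    m: float = 1.5               # unloading exponent
    beta: float = 1.0
    epsilon: float = 0.75

    def __post_init__(self) -> None:
        if self.reduced_modulus <= 0 or self.hardness <= 0 or self.max_load <= 0:
            raise ValueError("reduced_modulus, hardness, max_load must be > 0")
        if not 1.2 <= self.m <= 2.2:
            raise ValueError("unloading exponent m outside [1.2, 2.2]")


def gen_indentation_curve(
    truth: IndentationTruth,
    seed: int,
    area_function: Optional[AreaFunction] = None,
    sampling_rate: float = 50.0,
    creep_tau: float = 1.0,
) -> tuple[IndentationCurve, dict]:
    """Generate one three-segment indent; returns (curve, truth record).

    The contact state at peak (h_max, S, h_c, A) is derived from the truth
    via the Oliver-Pharr relations, so a correct analysis recovers the truth
    exactly in the noise-free case.
    """
    if area_function is None:
        area_function = AreaFunction()
    rng = np.random.default_rng(seed)
    p_max = truth.max_load

    # contact area and depth from hardness: H = 1000 P / A
    area = 1000.0 * p_max / truth.hardness  # nm^2
    h_c = _invert_area(area_function, area)
    # stiffness from reduced modulus: E_r = 1000 sqrt(pi) S / (2 beta sqrt(A))
    s = truth.reduced_modulus * 2.0 * truth.beta * np.sqrt(area) / (
        1000.0 * np.sqrt(np.pi)
    )
    h_max = h_c + truth.epsilon * p_max / s
    # unload power law consistent with (S, P_max, h_max)
    h_span = truth.m * p_max / s
    h_f = h_max - h_span
    alpha = p_max / h_span**truth.m

    # loading: P = C h^2 ending at the pre-creep depth
    h_load_end = h_max - truth.creep_amplitude
    t_load = p_max / truth.load_rate
    n_load = max(int(t_load * sampling_rate), 20)
    t1 = np.linspace(0.0, t_load, n_load, endpoint=False)
    p1 = truth.load_rate * t1
    h1 = h_load_end * np.sqrt(p1 / p_max)

    # hold: constant load, logarithmic creep toward h_max
    n_hold = max(int(truth.hold_time * sampling_rate), 20)
    t2 = t_load + np.linspace(0.0, truth.hold_time, n_hold, endpoint=False)
    p2 = np.full(n_hold, p_max)
    tau = creep_tau
    if truth.creep_amplitude > 0:
        creep = truth.creep_amplitude * np.log1p((t2 - t_load) / tau) / np.log1p(
            truth.hold_time / tau
        )
    else:
        creep = np.zeros(n_hold)
    h2 = h_load_end + creep

    # unload: load ramps down, depth follows the power law inverse
    t_unload = p_max / truth.load_rate
    n_unload = max(int(t_unload * sampling_rate), 20)
    t3 = t_load + truth.hold_time + np.linspace(0.0, t_unload, n_unload)
    p3 = np.clip(p_max - truth.load_rate * (t3 - t3[0]), 0.0, None)
    h3 = h_f + (p3 / alpha) ** (1.0 / truth.m)

    time = np.concatenate([t1, t2, t3])
    depth = np.concatenate([h1, h2, h3])
    load = np.concatenate([p1, p2, p3])
    if truth.noise_sd > 0:
        load = load + rng.normal(0.0, truth.noise_sd, size=load.shape)

    segments = np.concatenate(
        [
            np.full(n_load, "load", dtype=object),
            np.full(n_hold, "hold", dtype=object),
            np.full(n_unload, "unload", dtype=object),
        ]
    ).astype(str)
    curve = IndentationCurve(time=time, depth=depth, load=load, segments=segments)
    record = {
        "E_r": truth.reduced_modulus,
        "H": truth.hardness,
        "S": float(s),
        "h_c": float(h_c),
        "h_max": float(h_max),
        "h_f": float(h_f),
        "alpha": float(alpha),
        "m": truth.m,
        "A": float(area),
    }
    return curve, record


def _invert_area(area_function: AreaFunction, target: float) -> float:
    """Solve A(h_c) = target for h_c by bisection."""
    lo, hi = 1e-3, 1.0
    while area_function(hi) < target:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError("area function cannot reach the target area")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if area_function(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
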