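"""Two-genotype cohort generator with a nested measurement hierarchy.

Mouse-level outcomes are drawn from genotype-specific normals with optional
body-mass covariation; point-level outcomes (indents / spectra) add nested
random effects for mouse, quadrant and cortex region plus a residual, with
variance components expressed as fractions of the outcome variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["OutcomeSpec", "CohortSpec", "Cohort", "gen_cohort", "DEFAULT_OUTCOMES"]

GENOTYPES = ("C57Bl/6J", "TallyHO")
QUADRANTS = ("AL", "PM")
REGIONS = ("endosteal", "intracortical", "periosteal")
MICROSTRUCTURES = ("lamellar", "non_lamellar")


@dataclass(frozen=True)
class OutcomeSpec:
    """Group mean/SD per genotype for one outcome."""

    mean_control: float
    sd_control: float
    mean_diabetic: float
    sd_diabetic: float
    level: str = "mouse"  # mouse | point

    def params(self, genotype: str) -> tuple[float, float]:
        if genotype == "TallyHO":
            return self.mean_diabetic, self.sd_diabetic
        return self.mean_control, self.sd_control


# Mouse-level defaults use published-scale group statistics for each outcome;
# point-level defaults are plausible cortical-bone values with the reported
# relative group effects.
DEFAULT_OUTCOMES: dict[str, OutcomeSpec] = {
    # morphometry
    "Tt_Ar": OutcomeSpec(2.06, 0.11, 1.48, 0.07),
    "Ma_Ar": OutcomeSpec(1.20, 0.08, 0.62, 0.06),
    "Ct_Ar": OutcomeSpec(0.86, 0.04, 0.86, 0.04),
    "Ct_Th": OutcomeSpec(0.19, 0.01, 0.25, 0.01),
    "I_min": OutcomeSpec(0.15, 0.02, 0.11, 0.01),
    "I_max": OutcomeSpec(0.34, 0.04, 0.20, 0.02),
    "c": OutcomeSpec(0.66, 0.03, 0.59, 0.02),
    "Ct_Po": OutcomeSpec(0.24, 0.30, 1.43, 1.06),
    "Ct_TMD": OutcomeSpec(1159.99, 24.29, 1227.20, 17.97),
    "BV_TV": OutcomeSpec(9.38, 1.06, 3.43, 1.10),
    "Tb_Sp": OutcomeSpec(236.50, 19.01, 354.50, 37.20),
    "Tb_Th": OutcomeSpec(36.37, 1.18, 34.93, 7.30),
    "Tb_N": OutcomeSpec(4.11, 0.27, 2.85, 0.29),
    "Conn_D": OutcomeSpec(128.10, 28.65, 50.61, 28.85),
    "Tb_TMD": OutcomeSpec(947.19, 8.22, 969.26, 9.70),
    # flexural
    "max_moment": OutcomeSpec(32.68, 2.12, 34.68, 2.96),
    "stiffness": OutcomeSpec(110.79, 11.70, 111.63, 21.61),
    "post_yield_displacement": OutcomeSpec(0.17, 0.03, 0.11, 0.02),
    "work_to_fracture": OutcomeSpec(4.01, 0.74, 3.38, 0.27),
    # glycemia
    "HbA1c": OutcomeSpec(5.00, 0.39, 9.90, 1.70),
    # tissue level (point measurements)
    "E_s": OutcomeSpec(24.0, 2.4, 29.3, 2.9, level="point"),
    "H": OutcomeSpec(0.90, 0.10, 1.10, 0.12, level="point"),
    "mineral_matrix": OutcomeSpec(0.70, 0.05, 0.77, 0.06, level="point"),
    "carbonate_phosphate": OutcomeSpec(0.18, 0.02, 0.18, 0.02, level="point"),
    "crystallinity": OutcomeSpec(0.0595, 0.0008, 0.0597, 0.0008, level="point"),
    "collagen_maturity": OutcomeSpec(1.55, 0.12, 1.58, 0.12, level="point"),
    "pen_ratio": OutcomeSpec(0.145, 0.02, 0.172, 0.03, level="point"),
}


@dataclass
class CohortSpec:
    n_per_group: dict = field(default_factory=lambda: {"C57Bl/6J": 5, "TallyHO": 8})
    outcomes: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOMES))
    mass_mean: dict = field(default_factory=lambda: {"C57Bl/6J": 33.8, "TallyHO": 38.8})
    mass_sd: dict = field(default_factory=lambda: {"C57Bl/6J": 3.3, "TallyHO": 7.4})
    # outcome -> genotype -> slope (outcome units per gram)
    mass_outcome_slopes: dict = field(default_factory=dict)
    # weekly glucose: baseline mean/sd and per-week drift (mg/dL)
    glucose_baseline: dict = field(
        default_factory=lambda: {"C57Bl/6J": 165.0, "TallyHO": 285.0}
    )
    glucose_baseline_sd: dict = field(
        default_factory=lambda: {"C57Bl/6J": 10.0, "TallyHO": 25.0}
    )
    glucose_drift: dict = field(default_factory=lambda: {"C57Bl/6J": 0.0, "TallyHO": 12.0})
    glucose_noise_sd: float = 8.0
    n_weeks: int = 16
    # variance fractions for point-level outcomes; must sum to <= 1
    hierarchy_variances: dict = field(
        default_factory=lambda: {"mouse": 0.5, "quadrant": 0.1, "region": 0.1, "residual": 0.3}
    )
    points_per_region: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"n_per_group[{g!r}] must be >= 2")
        for k, v in self.hierarchy_variances.items():
            if v < 0:
                raise ValueError(f"hierarchy variance {k!r} must be >= 0")
        for spec in self.outcomes.values():
            if spec.sd_control < 0 or spec.sd_diabetic < 0:
                raise ValueError("outcome SDs must be >= 0")


@dataclass
class Cohort:
    mice: pd.DataFrame      # one row per mouse: genotype, body_mass, outcomes
    glucose: pd.DataFrame   # long: mouse, genotype, week, glucose
    points: pd.DataFrame    # long: mouse, quadrant, region, point, outcomes
    spec: CohortSpec

    def merged(self) -> pd.DataFrame:
        """Point table joined with the per-mouse covariates."""
        return self.points.merge(self.mice, on=["mouse", "genotype"], how="left")


def gen_cohort(spec: CohortSpec, seed: Optional[int] = None) -> Cohort:
    """Draw a full cohort; pure function of (spec, seed)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    mouse_rows = []
    glucose_rows = []
    point_rows = []
    hv = spec.hierarchy_variances
    mouse_ids = []
    for genotype in GENOTYPES:
        n = spec.n_per_group.get(genotype, 0)
        for i in range(n):
            mouse_ids.append((f"{'C' if genotype.startswith('C57') else 'T'}{i+1:02d}", genotype))

    for mouse, genotype in mouse_ids:
        mass = rng.normal(spec.mass_mean[genotype], spec.mass_sd[genotype])
        row = {"mouse": mouse, "genotype": genotype, "body_mass": mass}
        for name, ospec in spec.outcomes.items():
            if ospec.level != "mouse":
                continue
            mean, sd = ospec.params(genotype)
            slope = spec.mass_outcome_slopes.get(name, {}).get(genotype, 0.0)
            row[name] = (
                mean
                + slope * (mass - spec.mass_mean[genotype])
                + rng.normal(0.0, sd)
            )
        mouse_rows.append(row)

        base = rng.normal(
            spec.glucose_baseline[genotype], spec.glucose_baseline_sd[genotype]
        )
        for week in range(1, spec.n_weeks + 1):
            glucose_rows.append(
                {
                    "mouse": mouse,
                    "genotype": genotype,
                    "week": week,
                    "glucose": base
                    + spec.glucose_drift[genotype] * (week - 1)
                    + rng.normal(0.0, spec.glucose_noise_sd),
                }
            )

        point_specs = {k: v for k, v in spec.outcomes.items() if v.level == "point"}
        b_mouse = {
            name: rng.normal(0.0, np.sqrt(hv.get("mouse", 0.0)) * ospec.params(genotype)[1])
            for name, ospec in point_specs.items()
        }
        for quadrant in QUADRANTS:
            b_quad = {
                name: rng.normal(0.0, np.sqrt(hv.get("quadrant", 0.0)) * ospec.params(genotype)[1])
                for name, ospec in point_specs.items()
            }
            for region in REGIONS:
                b_reg = {
                    name: rng.normal(0.0, np.sqrt(hv.get("region", 0.0)) * ospec.params(genotype)[1])
                    for name, ospec in point_specs.items()
                }
                for point in range(spec.points_per_region):
                    micro = MICROSTRUCTURES[int(rng.integers(2))]
                    prow = {
                        "mouse": mouse,
                        "genotype": genotype,
                        "quadrant": quadrant,
                        "region": region,
                        "point": point,
                        "microstructure": micro,
                    }
                    for name, ospec in point_specs.items():
                        mean, sd = ospec.params(genotype)
                        slope = spec.mass_outcome_slopes.get(name, {}).get(genotype, 0.0)
                        resid = rng.normal(0.0, np.sqrt(hv.get("residual", 0.0)) * sd)
                        prow[name] = (
                            mean
                            + slope * (mass - spec.mass_mean[genotype])
                            + b_mouse[name]
                            + b_quad[name]
                            + b_reg[name]
                            + resid
                        )
                    point_rows.append(prow)

    return Cohort(
        mice=pd.DataFrame(mouse_rows),
        glucose=pd.DataFrame(glucose_rows),
        points=pd.DataFrame(point_rows),
        spec=spec,
    )
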