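"""Scale math for the Centiloid method.

The Centiloid (CL) scale anchors amyloid burden at 0 (mean of young,
amyloid-free controls) and 100 (mean of mild AD patients) for PiB with the
whole cerebellum as reference. For PiB the published conversion is

    CL = 93.7 * SUVR_PiB - 94.6

Calibrating a second tracer proceeds in two levels. Level 1 checks that a
local pipeline reproduces reference CL values on the standard PiB set
(gates: R^2 > 0.98, slope in [0.98, 1.02], intercept in [-2, 2]). Level 2
regresses the tracer's SUVR on paired PiB SUVR (gate: R^2 > 0.70), inverts
the fit to obtain "calculated PiB SUVR", and composes with the standard PiB
map to yield a direct tracer-SUVR -> CL equation. For florbetaben this
package's worked example reproduces CL = 153.4 * SUVR_FBB - 154.9 within
rounding of the printed coefficients.

Compositions always use full-precision fitted coefficients; printed
equations are treated as rounded views of the underlying fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .suvr import SuvrRecord

__all__ = [
    "LinearMap",
    "RegressionFit",
    "Level1Report",
    "Level2Report",
    "CohortStats",
    "STANDARD_PIB_MAP",
    "LEVEL1_CRITERIA",
    "LEVEL2_R2_GATE",
    "fit_ols",
    "apply_map",
    "invert_map",
    "compose_maps",
    "validate_level1",
    "calibrate_level2",
    "cohort_stats",
    "variance_ratio",
    "upper_normal_limit",
]

#: Absolute guard on inclusive level-1 bound checks so fits that sit exactly
#: on a bound are not rejected by floating round-off.
_BOUND_EPS = 1e-9


@dataclass(frozen=True)
class LinearMap:
    """y = m * x + b between two named scales.

    The central object of the calibration: tracer SUVR <-> PiB SUVR and
    SUVR -> CL conversions are all instances.
    """

    m: float
    b: float
    domain_scale: str = "x"
    range_scale: str = "y"

    def __call__(self, x):
        return apply_map(self, x)

    def inverse(self) -> "LinearMap":
        return invert_map(self)

    def then(self, outer: "LinearMap") -> "LinearMap":
        return compose_maps(self, outer)

    def equation(self, ndigits: int = 1) -> str:
        """Printed-style equation string, e.g. 'CL = 153.6 x SUVR_FBB - 154.5'."""
        sign = "-" if self.b < 0 else "+"
        return (
            f"{self.range_scale} = {round(self.m, ndigits)} x {self.domain_scale} "
            f"{sign} {abs(round(self.b, ndigits))}"
        )


#: Published conversion of standard-method PiB SUVR (whole cerebellum
#: reference, 50-70 min) to Centiloid units.
STANDARD_PIB_MAP = LinearMap(m=93.7, b=-94.6, domain_scale="SUVR_PiB", range_scale="CL")

#: Level-1 pipeline-validation gates on the computed-vs-reference CL fit.
LEVEL1_CRITERIA = {
    "r2_min": 0.98,          # exclusive
    "slope_range": (0.98, 1.02),   # inclusive
    "intercept_range": (-2.0, 2.0),  # inclusive, CL units
}

#: Level-2 inter-tracer correlation gate (exclusive).
LEVEL2_R2_GATE = 0.70


@dataclass(frozen=True)
class RegressionFit:
    map: LinearMap
    r_squared: float
    n: int
    residual_sd: float        # range-scale units, n-2 denominator

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression requires n >= 3")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")


@dataclass(frozen=True)
class Level1Report:
    """Pipeline-validation outcome: computed CL regressed on reference CL."""

    fit: RegressionFit
    pass_r2: bool
    pass_slope: bool
    pass_intercept: bool

    @property
    def pass_overall(self) -> bool:
        return self.pass_r2 and self.pass_slope and self.pass_intercept

    def as_dict(self) -> dict:
        return {
            "slope": self.fit.map.m,
            "intercept": self.fit.map.b,
            "r_squared": self.fit.r_squared,
            "n": self.fit.n,
            "criteria": LEVEL1_CRITERIA,
            "pass_r2": self.pass_r2,
            "pass_slope": self.pass_slope,
            "pass_intercept": self.pass_intercept,
            "pass_overall": self.pass_overall,
        }


@dataclass(frozen=True)
class Level2Report:
    """Tracer calibration: fit, gate, inversion and the direct CL equation."""

    tracer: str
    fit: RegressionFit                 # tracer SUVR on PiB SUVR
    pass_gate: bool                    # R^2 > 0.70
    to_pib: LinearMap                  # tracer SUVR -> calculated PiB SUVR
    direct_cl: LinearMap               # tracer SUVR -> CL
    standard_map: LinearMap = field(default=STANDARD_PIB_MAP)

    def as_dict(self) -> dict:
        return {
            "tracer": self.tracer,
            "n": self.fit.n,
            "fit": {
                "slope": self.fit.map.m,
                "intercept": self.fit.map.b,
                "slope_2dp": round(self.fit.map.m, 2),
                "intercept_2dp": round(self.fit.map.b, 2),
                "r_squared": self.fit.r_squared,
                "r_squared_2dp": round(self.fit.r_squared, 2),
                "residual_sd": self.fit.residual_sd,
                "equation": self.fit.map.equation(ndigits=2),
            },
            "r2_gate": LEVEL2_R2_GATE,
            "pass_gate": self.pass_gate,
            "to_pib": {"slope": self.to_pib.m, "intercept": self.to_pib.b},
            "direct_cl": {
                "slope": self.direct_cl.m,
                "intercept": self.direct_cl.b,
                "slope_1dp": round(self.direct_cl.m, 1),
                "intercept_1dp": round(self.direct_cl.b, 1),
                "equation": self.direct_cl.equation(ndigits=1),
            },
            "standard_map": {"slope": self.standard_map.m, "intercept": self.standard_map.b},
        }


@dataclass(frozen=True)
class CohortStats:
    """Sample mean/SD of CL values in one group x tracer cell."""

    group: str
    tracer: str
    n: int
    mean_cl: float
    sd_cl: float              # sample SD, n-1 denominator

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort SD requires n >= 2")
        if self.sd_cl < 0:
            raise ValueError("sd_cl must be >= 0")


def fit_ols(x, y=None) -> RegressionFit:
    """Ordinary least squares of y on x.

    ``x``/``y`` may be given as two sequences or as one sequence of (x, y)
    pairs with ``y`` omitted. R^2 is the squared Pearson correlation and the
    residual SD uses an n-2 denominator.
    """
    if y is None:
        pairs = np.asarray(x, dtype=float)
        x, y = pairs[:, 0], pairs[:, 1]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("regression requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: x has zero variance")
    res = _stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    return RegressionFit(
        map=LinearMap(m=float(res.slope), b=float(res.intercept)),
        r_squared=float(min(res.rvalue**2, 1.0)),
        n=int(n),
        residual_sd=residual_sd,
    )


def apply_map(lin: LinearMap, x):
    """m*x + b; accepts scalars or arrays."""
    x = np.asarray(x, dtype=float)
    out = lin.m * x + lin.b
    return float(out) if out.ndim == 0 else out


def invert_map(lin: LinearMap) -> LinearMap:
    """x = (y - b)/m, i.e. slope 1/m, intercept -b/m, scales swapped."""
    if lin.m == 0:
        raise ZeroDivisionError("cannot invert a map with zero slope")
    return LinearMap(
        m=1.0 / lin.m,
        b=-lin.b / lin.m,
        domain_scale=lin.range_scale,
        range_scale=lin.domain_scale,
    )


def compose_maps(inner: LinearMap, outer: LinearMap) -> LinearMap:
    """outer(inner(x)): slope outer.m*inner.m, intercept outer.m*inner.b + outer.b."""
    if inner.range_scale != outer.domain_scale:
        raise ValueError(
            f"scale mismatch: inner maps to '{inner.range_scale}' but outer "
            f"expects '{outer.domain_scale}'"
        )
    return LinearMap(
        m=outer.m * inner.m,
        b=outer.m * inner.b + outer.b,
        domain_scale=inner.domain_scale,
        range_scale=outer.range_scale,
    )


def validate_level1(computed_cl, reference_cl) -> Level1Report:
    """Check a local pipeline against reference CL values.

    Fits computed CL on reference CL and applies the published acceptance
    gates: R^2 > 0.98 (exclusive), slope in [0.98, 1.02] and intercept in
    [-2, +2] CL (both inclusive).
    """
    computed_cl = np.asarray(computed_cl, dtype=float)
    reference_cl = np.asarray(reference_cl, dtype=float)
    if computed_cl.shape != reference_cl.shape:
        raise ValueError(
            f"length mismatch: {computed_cl.size} computed vs "
            f"{reference_cl.size} reference CL values"
        )
    fit = fit_ols(reference_cl, computed_cl)
    lo_s, hi_s = LEVEL1_CRITERIA["slope_range"]
    lo_b, hi_b = LEVEL1_CRITERIA["intercept_range"]
    return Level1Report(
        fit=fit,
        pass_r2=fit.r_squared > LEVEL1_CRITERIA["r2_min"],
        pass_slope=(lo_s - _BOUND_EPS) <= fit.map.m <= (hi_s + _BOUND_EPS),
        pass_intercept=(lo_b - _BOUND_EPS) <= fit.map.b <= (hi_b + _BOUND_EPS),
    )


def calibrate_level2(
    pairs: list[tuple[SuvrRecord, SuvrRecord]],
    standard_map: LinearMap = STANDARD_PIB_MAP,
    tracer: str | None = None,
) -> Level2Report:
    """Calibrate a tracer against paired PiB scans.

    ``pairs`` holds (PiB record, tracer record) per subject; subject ids
    must match within each pair. The tracer's SUVR is regressed on PiB SUVR
    (the printed orientation), the gate R^2 > 0.70 is evaluated, the fit is
    inverted to the calculated-PiB-SUVR map, and that inverse is composed
    with the standard PiB->CL map to yield the direct CL equation. A report
    is produced even when the gate fails, so QC remains inspectable.
    """
    if len(pairs) < 3:
        raise ValueError("insufficient pairs: level-2 calibration requires n >= 3")
    mismatched = [
        (p.subject_id, t.subject_id) for p, t in pairs if p.subject_id != t.subject_id
    ]
    if mismatched:
        raise ValueError(f"unmatched subject ids in pairs: {mismatched}")
    tracer = tracer or pairs[0][1].tracer
    x = [p.suvr for p, _ in pairs]
    y = [t.suvr for _, t in pairs]
    fit = fit_ols(x, y)
    fitted = LinearMap(
        m=fit.map.m, b=fit.map.b,
        domain_scale=standard_map.domain_scale,
        range_scale=f"SUVR_{tracer}",
    )
    fit = RegressionFit(map=fitted, r_squared=fit.r_squared, n=fit.n,
                        residual_sd=fit.residual_sd)
    to_pib = invert_map(fitted)
    direct_cl = compose_maps(to_pib, standard_map)
    return Level2Report(
        tracer=tracer,
        fit=fit,
        pass_gate=fit.r_squared > LEVEL2_R2_GATE,
        to_pib=to_pib,
        direct_cl=direct_cl,
        standard_map=standard_map,
    )


def cohort_stats(cl_values, group: str, tracer: str) -> CohortStats:
    """Sample mean and SD (n-1 denominator) of CL values for one cohort."""
    vals = np.asarray(cl_values, dtype=float)
    if vals.size < 2:
        raise ValueError("cohort statistics require n >= 2")
    return CohortStats(
        group=group,
        tracer=tracer,
        n=int(vals.size),
        mean_cl=float(vals.mean()),
        sd_cl=float(vals.std(ddof=1)),
    )


def variance_ratio(tracer_stats: CohortStats, pib_stats: CohortStats) -> float:
    """SD_tracer / SD_PiB on the CL scale: relative measurement noise."""
    if pib_stats.sd_cl <= 0:
        raise ValueError("PiB cohort SD must be > 0")
    return tracer_stats.sd_cl / pib_stats.sd_cl


def upper_normal_limit(
    stats: CohortStats,
    k: float = 2.0,
    rounding: str = "nearest",
    include_mean: bool = True,
) -> float:
    """Upper limit of the normal (amyloid-negative) range in CL units.

    ``include_mean=True`` gives mean + k*SD; ``False`` gives the k*SD-only
    variant (equivalent when the young-normal mean is ~0 by construction of
    the scale). ``rounding`` is "nearest" (integer CL, as thresholds are
    conventionally reported) or "none".
    """
    if stats.sd_cl <= 0:
        raise ValueError("cohort SD must be > 0")
    limit = (stats.mean_cl if include_mean else 0.0) + k * stats.sd_cl
    if rounding == "nearest":
        return float(round(limit))
    if rounding == "none":
        return float(limit)
    raise ValueError(f"unknown rounding mode: {rounding!r}")
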