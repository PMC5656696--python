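"""Synthetic phantoms and paired-tracer cohorts with known ground truth.

Real Centiloid calibration data (standard PiB image sets, paired-tracer
scans) are distributed through external archives; this module generates
stand-ins with known generating parameters so every pipeline stage is
testable end to end.

Two generators are provided:

* a three-region block phantom (cortex shell, cerebellar block, background)
  with prescribed mean uptakes and additive Gaussian voxel noise, plus the
  exact masks of the generating regions;
* a paired PiB/tracer SUVR cohort: per subject a true PiB SUVR is drawn
  from its clinical group's distribution, mapped through a linear
  inter-tracer relation, and both tracers' observed SUVRs receive
  independent additive Gaussian measurement noise.

Default cohort structure mirrors a 35-subject head-to-head study: 10 young
controls, 6 elderly controls, 9 MCI, 8 mild AD, 2 FTD. Group means are
placed on the CL scale (young 0, elderly 20, MCI 50, AD 100, FTD 5) and
mapped to PiB SUVR through the inverse of the standard PiB map; these are
generator conventions, not measured values. Measurement noise defaults are
solved from the published young-normal CL SDs (3.48 PiB, 6.81 tracer) so
the default CL-scale SD ratio is ~1.96.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calibration import STANDARD_PIB_MAP, LinearMap, invert_map
from .suvr import SuvrRecord
from .volume_io import VoiMask, VolumeGrid

__all__ = [
    "PhantomSpec",
    "GroupSpec",
    "CohortSpec",
    "generate_phantom",
    "simulate_paired_cohort",
    "default_cohort_spec",
    "tracer_noise_for_target_r2",
    "true_pib_suvr_variance",
]

# Young-normal biological spread on the CL scale (generator convention);
# combined with the measurement-noise defaults below it reproduces the
# published young-normal total SDs.
_YOUNG_BIO_SD_CL = 3.0
_YOUNG_TOTAL_SD_CL_PIB = 3.48
_YOUNG_TOTAL_SD_CL_FBB = 6.81


@dataclass(frozen=True)
class PhantomSpec:
    """Three-region block phantom on a regular 2 mm grid."""

    dims: tuple[int, int, int] = (24, 24, 24)
    cortex_uptake: float = 2.0
    cerebellum_uptake: float = 1.25
    background_uptake: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cerebellum_uptake <= 0:
            raise ValueError("cerebellum_uptake must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, VoiMask, VoiMask]:
    """Build the phantom volume and the exact cortex/cerebellum masks.

    Layout (along the last axis): a hollow cortical shell in the upper
    half, a solid cerebellar block in the lower quarter, background
    elsewhere; the regions never overlap. Requires every dim >= 8.
    """
    nx, ny, nz = spec.dims
    if min(spec.dims) < 8:
        raise ValueError("dims too small for the three-region layout (need >= 8)")
    rng = np.random.default_rng(spec.seed)

    affine = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm isotropic, origin at corner
    values = np.full(spec.dims, spec.background_uptake, dtype=np.float64)

    # cortical shell: outer box minus inner box, upper half in z
    z0 = nz // 2
    outer = np.zeros(spec.dims, dtype=bool)
    outer[1 : nx - 1, 1 : ny - 1, z0 : nz - 1] = True
    inner = np.zeros(spec.dims, dtype=bool)
    inner[3 : nx - 3, 3 : ny - 3, z0 + 2 : nz - 3] = True
    cortex = outer & ~inner

    # cerebellar block: solid box in the lower quarter
    cerebellum = np.zeros(spec.dims, dtype=bool)
    cerebellum[2 : nx - 2, 2 : ny - 2, 1 : max(2, nz // 4)] = True

    values[cortex] = spec.cortex_uptake
    values[cerebellum] = spec.cerebellum_uptake
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=spec.dims)

    volume = VolumeGrid(values=values, affine=affine)
    cortex_mask = VoiMask(weights=cortex.astype(float), affine=affine, name="CL_cortex")
    cereb_mask = VoiMask(
        weights=cerebellum.astype(float), affine=affine, name="whole_cerebellum"
    )
    return volume, cortex_mask, cereb_mask


@dataclass(frozen=True)
class GroupSpec:
    """One clinical group: size and true PiB-SUVR distribution."""

    label: str
    n: int
    suvr_mean: float
    suvr_sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.suvr_sd < 0:
            raise ValueError("group SD must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Generating model for a paired-tracer SUVR cohort."""

    groups: tuple[GroupSpec, ...]
    relation: LinearMap                 # PiB SUVR -> tracer true SUVR
    tracer_noise_sd: float              # SUVR units, additive on observed tracer SUVR
    pib_noise_sd: float                 # SUVR units, additive on observed PiB SUVR
    seed: int = 0
    tracer: str = "FBB"

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("groups list must not be empty")
        if self.tracer_noise_sd < 0 or self.pib_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.relation.domain_scale != "SUVR_PiB":
            raise ValueError("relation must map from scale 'SUVR_PiB'")

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


def _cl_to_suvr(cl: float) -> float:
    return invert_map(STANDARD_PIB_MAP)(cl)


def default_cohort_spec(
    seed: int = 0,
    relation: LinearMap | None = None,
    tracer: str = "FBB",
) -> CohortSpec:
    """The 35-subject default layout with noise anchored to published SDs.

    Group CL means: young 0, elderly controls 20, MCI 50, AD 100, FTD 5,
    mapped through the inverse standard PiB map. PiB measurement noise is
    solved from sqrt(3.48^2 - 3^2) CL; tracer noise from
    sqrt(6.81^2 - 3^2) CL on the tracer's direct CL scale, so the default
    young-normal CL SD ratio is ~1.96.
    """
    if relation is None:
        relation = LinearMap(0.61, 0.39, "SUVR_PiB", f"SUVR_{tracer}")
    # CL-scale group means/SDs -> PiB SUVR units (1 CL = 1/93.7 SUVR)
    layout = [  # label, n, CL mean, biological CL sd
        ("young_control", 10, 0.0, _YOUNG_BIO_SD_CL),
        ("elderly_control", 6, 20.0, 20.0),
        ("mci", 9, 50.0, 30.0),
        ("ad", 8, 100.0, 25.0),
        ("ftd", 2, 5.0, 5.0),
    ]
    groups = tuple(
        GroupSpec(label, n, _cl_to_suvr(cl_mean), cl_sd / STANDARD_PIB_MAP.m)
        for label, n, cl_mean, cl_sd in layout
    )
    pib_noise_cl = math.sqrt(_YOUNG_TOTAL_SD_CL_PIB**2 - _YOUNG_BIO_SD_CL**2)
    tracer_noise_cl = math.sqrt(_YOUNG_TOTAL_SD_CL_FBB**2 - _YOUNG_BIO_SD_CL**2)
    direct_slope = STANDARD_PIB_MAP.m / relation.m  # CL per tracer-SUVR
    return CohortSpec(
        groups=groups,
        relation=relation,
        pib_noise_sd=pib_noise_cl / STANDARD_PIB_MAP.m,
        tracer_noise_sd=tracer_noise_cl / direct_slope,
        seed=seed,
        tracer=tracer,
    )


def true_pib_suvr_variance(spec: CohortSpec) -> float:
    """Mixture variance of the true PiB SUVR implied by the group layout."""
    n_tot = sum(g.n for g in spec.groups)
    mu = sum(g.n * g.suvr_mean for g in spec.groups) / n_tot
    between = sum(g.n * (g.suvr_mean - mu) ** 2 for g in spec.groups) / n_tot
    within = sum(g.n * g.suvr_sd**2 for g in spec.groups) / n_tot
    return between + within


def tracer_noise_for_target_r2(spec: CohortSpec, target_r2: float) -> float:
    """Tracer noise SD giving an expected tracer-vs-PiB R^2 of ``target_r2``.

    Closed form from the generating model: with true-SUVR variance V,
    relation slope m, PiB noise s_x and tracer noise s_y,

        rho^2 = (m V)^2 / ((V + s_x^2)(m^2 V + s_y^2))

    solved for s_y. Raises if the target exceeds what the PiB noise alone
    allows.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must lie in (0, 1)")
    v = true_pib_suvr_variance(spec)
    m2 = spec.relation.m**2
    sy2 = (m2 * v**2) / (target_r2 * (v + spec.pib_noise_sd**2)) - m2 * v
    if sy2 <= 0:
        raise ValueError("target R^2 unattainable: PiB noise already exceeds it")
    return math.sqrt(sy2)


def simulate_paired_cohort(
    spec: CohortSpec,
) -> tuple[list[tuple[SuvrRecord, SuvrRecord]], pd.DataFrame]:
    """Draw one cohort; return observed record pairs and the hidden truth.

    Observed SUVRs below 0.05 are floored there so records stay physical
    even under extreme noise (SUVR is a ratio of positive means).

    The truth table carries per subject the group label, true PiB SUVR,
    true tracer SUVR, and both observed values.
    """
    rng = np.random.default_rng(spec.seed)
    pairs: list[tuple[SuvrRecord, SuvrRecord]] = []
    rows = []
    idx = 0
    for g in spec.groups:
        true_pib = rng.normal(g.suvr_mean, g.suvr_sd, size=g.n)
        for tp in true_pib:
            tt = spec.relation(tp)
            obs_pib = max(tp + rng.normal(0.0, spec.pib_noise_sd), 0.05)
            obs_tr = max(tt + rng.normal(0.0, spec.tracer_noise_sd), 0.05)
            sid = f"S{idx:03d}"
            idx += 1
            pairs.append(
                (
                    SuvrRecord.from_means(sid, "PiB", obs_pib, 1.0),
                    SuvrRecord.from_means(sid, spec.tracer, obs_tr, 1.0),
                )
            )
            rows.append(
                {
                    "subject_id": sid,
                    "group": g.label,
                    "true_suvr_pib": tp,
                    "true_suvr_tracer": tt,
                    "suvr_pib": obs_pib,
                    "suvr_tracer": obs_tr,
                }
            )
    truth = pd.DataFrame(rows)
    return pairs, truth


def cohort_table(pairs: list[tuple[SuvrRecord, SuvrRecord]], truth: pd.DataFrame) -> pd.DataFrame:
    """Observed paired-SUVR table in the CSV dialect of the calibration CLI."""
    return pd.DataFrame(
        {
            "subject_id": [p.subject_id for p, _ in pairs],
            "group": truth["group"].to_numpy(),
            "suvr_pib": [p.suvr for p, _ in pairs],
            "suvr_tracer": [t.suvr for _, t in pairs],
        }
    )
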