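"""Synthetic mapping exports, clinical covariates and outcomes.

No public left-ventricular mapping dataset exists, so every downstream stage
is exercised against this generator.  It emulates the *statistics* of an
export — an LV-like ellipsoidal shell of mapped points with plantable
substrate abnormalities (dense-scar caps, late-potential caps, a conduction
isthmus with a steep activation ramp, unipolar-depression caps) — not the
biophysics of electrograms.

Outcomes are drawn from a stated logistic model whose default coefficients
are the published multivariable polynomial for major arrhythmic events
(intercept −21.007; NYHA class 3.889; sPAP 0.262; LAT extent 0.034; GR 0.492;
hypertension 2.638, all in logit units), reused here as generative truth so
that refitting can be checked against known coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .io import EamExport, MapPoint
from .sphere import DEFAULT_OCTANT_TABLE

__all__ = [
    "ScarPatch",
    "LatePatch",
    "VltPatch",
    "Isthmus",
    "NoiseSd",
    "SubstrateScenario",
    "OutcomeModel",
    "default_mae_model",
    "region_center_direction",
    "generate_map",
    "generate_clinical",
    "assign_outcomes",
    "event_probability",
    "BINARY_PREVALENCE",
    "CONTINUOUS_DISTRIBUTIONS",
]


def region_center_direction(region: int) -> np.ndarray:
    """Unit direction of the centroid of a region's octant (canonical frame)."""
    for signs, r in DEFAULT_OCTANT_TABLE.items():
        if r == region:
            return np.array(signs, dtype=float) / np.sqrt(3.0)
    raise ValueError(f"region index must be in 1..8, got {region}")


@dataclass(frozen=True)
class ScarPatch:
    """Angular cap whose bipolar voltage is drawn with a depressed mean."""
    region: int
    radius_deg: float
    bip_mean_mv: float


@dataclass(frozen=True)
class LatePatch:
    """Angular cap whose activation time is shifted by a fixed offset."""
    region: int
    radius_deg: float
    offset_ms: float


@dataclass(frozen=True)
class VltPatch:
    """Angular cap with depressed unipolar but normal bipolar voltage."""
    region: int
    radius_deg: float
    uni_depression_mv: float


@dataclass(frozen=True)
class Isthmus:
    """Linear activation ramp inside a region producing a steep LAT gradient.

    Within an angular cap around the region center, activation time ramps
    from 0 to ``step_ms`` over ``width_mm`` along a tangent direction, so the
    peak gradient is about step_ms / width_mm.
    """
    region: int
    width_mm: float
    step_ms: float
    radius_deg: float = 25.0


@dataclass(frozen=True)
class NoiseSd:
    """Per-channel Gaussian noise scales (mV, mV, ms, Ω)."""
    uni_v: float = 1.0
    bip_v: float = 0.3
    lat: float = 5.0
    imp: float = 8.0

    @classmethod
    def zero(cls) -> "NoiseSd":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SubstrateScenario:
    """Everything needed to generate one synthetic export, deterministically."""

    n_points: int = 1500
    shell_radii: tuple[float, float, float] = (30.0, 30.0, 40.0)  # semi-axes mm (x,y,z)
    scar_patches: tuple[ScarPatch, ...] = ()
    late_patches: tuple[LatePatch, ...] = ()
    vlt_patches: tuple[VltPatch, ...] = ()
    isthmus: Isthmus | None = None
    noise_sd: NoiseSd = field(default_factory=NoiseSd)
    radial_jitter_sd_mm: float = 1.0
    bip_mean_mv: float = 3.0    # healthy bipolar mean (>= 1.5 mV by definition)
    uni_mean_mv: float = 10.0   # healthy unipolar mean
    lat_base_ms: float = 0.0
    imp_mean_ohm: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise ValueError("n_points must be positive")
        if any(r <= 0 for r in self.shell_radii):
            raise ValueError("shell semi-axes must be positive")
        if self.bip_mean_mv < 1.5:
            raise ValueError("healthy bipolar mean must be at least 1.5 mV")
        for patch in (*self.scar_patches, *self.late_patches, *self.vlt_patches):
            if not 1 <= patch.region <= 8:
                raise ValueError(f"region index must be in 1..8, got {patch.region}")
            if patch.radius_deg <= 0:
                raise ValueError("patch angular radius must be positive")
        if self.isthmus is not None:
            if not 1 <= self.isthmus.region <= 8:
                raise ValueError(f"region index must be in 1..8, got {self.isthmus.region}")
            if self.isthmus.width_mm <= 0 or self.isthmus.radius_deg <= 0:
                raise ValueError("isthmus width and radius must be positive")


def _sample_ellipsoid(rng: np.random.Generator, n: int, radii: Sequence[float]) -> np.ndarray:
    """Uniform sample on an ellipsoid surface (rejection on the area element)."""
    a, b, c = radii
    m_max = max(a * b, b * c, a * c)
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        k = max(2 * (n - filled), 64)
        u = rng.standard_normal((k, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        m = np.sqrt((b * c * u[:, 0]) ** 2 + (a * c * u[:, 1]) ** 2 + (a * b * u[:, 2]) ** 2)
        keep = rng.random(k) < m / m_max
        pts = u[keep] * np.array([a, b, c])
        take = min(len(pts), n - filled)
        out[filled : filled + take] = pts[:take]
        filled += take
    return out


def _cap_mask(dirs: np.ndarray, region: int, radius_deg: float) -> np.ndarray:
    center = region_center_direction(region)
    cos_thr = np.cos(np.deg2rad(radius_deg))
    return dirs @ center >= cos_thr


def generate_map(scenario: SubstrateScenario, patient_id: str = "synthetic-0") -> EamExport:
    """Generate one export from a scenario; identical seeds give identical output.

    Points are sampled uniformly on the ellipsoidal shell and jittered
    radially; channel values start at the healthy means and patch effects are
    applied by membership of the point's radial direction in the patch cap.
    Overlapping patches compose: scar caps take the most depressed bipolar
    mean, unipolar depressions and LAT offsets add.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_points
    pos = _sample_ellipsoid(rng, n, scenario.shell_radii)
    if scenario.radial_jitter_sd_mm > 0:
        radial = pos / np.linalg.norm(pos, axis=1, keepdims=True)
        pos = pos + radial * rng.normal(0.0, scenario.radial_jitter_sd_mm, n)[:, None]
    dirs = pos / np.linalg.norm(pos, axis=1, keepdims=True)

    bip = np.full(n, scenario.bip_mean_mv)
    for patch in scenario.scar_patches:
        m = _cap_mask(dirs, patch.region, patch.radius_deg)
        bip[m] = np.minimum(bip[m], patch.bip_mean_mv)

    uni = np.full(n, scenario.uni_mean_mv)
    for patch in scenario.vlt_patches:
        m = _cap_mask(dirs, patch.region, patch.radius_deg)
        uni[m] -= patch.uni_depression_mv

    lat = np.full(n, scenario.lat_base_ms)
    for patch in scenario.late_patches:
        m = _cap_mask(dirs, patch.region, patch.radius_deg)
        lat[m] += patch.offset_ms
    if scenario.isthmus is not None:
        ist = scenario.isthmus
        center = region_center_direction(ist.region)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(center @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        tangent = np.cross(ref, center)
        tangent /= np.linalg.norm(tangent)
        m = _cap_mask(dirs, ist.region, ist.radius_deg)
        s = pos[m] @ tangent
        lat[m] += ist.step_ms * np.clip(s / ist.width_mm, 0.0, 1.0)

    ns = scenario.noise_sd
    bip = np.clip(bip + rng.normal(0.0, 1.0, n) * ns.bip_v, 0.0, None)
    uni = np.clip(uni + rng.normal(0.0, 1.0, n) * ns.uni_v, 0.0, None)
    lat = lat + rng.normal(0.0, 1.0, n) * ns.lat
    imp = np.clip(scenario.imp_mean_ohm + rng.normal(0.0, 1.0, n) * ns.imp, 1.0, None)
    angles = rng.uniform(-180.0, 180.0, (n, 3))

    points = [
        MapPoint(
            x=float(pos[i, 0]), y=float(pos[i, 1]), z=float(pos[i, 2]),
            alpha=float(angles[i, 0]), beta=float(angles[i, 1]), gamma=float(angles[i, 2]),
            uni_v=float(uni[i]), bip_v=float(bip[i]), lat=float(lat[i]), imp=float(imp[i]),
        )
        for i in range(n)
    ]
    return EamExport(
        patient_id=patient_id,
        points=points,
        metadata={"generator": "eamrisk.synthetic", "seed": str(scenario.seed)},
    )


# ---------------------------------------------------------------------------
# clinical covariates

#: Bernoulli prevalences of the binary covariates (0/1 columns).
BINARY_PREVALENCE: dict[str, float] = {
    "MaleSex": 0.70,
    "Hypertension": 0.50,
    "HFrEF": 0.30,
    "HFpEF": 0.15,
    "Diabetes": 0.25,
    "COPD": 0.15,
    "AF": 0.25,
    "ArrhythmicStorm": 0.15,
    "TWaveInversion": 0.30,
    "PriorStrokeTIA": 0.08,
    "FamilyHistorySCD": 0.10,
    "ParoxysmalVT": 0.30,
    "LVAneurysm": 0.08,
    "ValvularCardiopathy": 0.15,
}

#: (mean, sd, lower, upper) of the truncated-normal continuous covariates.
CONTINUOUS_DISTRIBUTIONS: dict[str, tuple[float, float, float, float]] = {
    "sPAP": (30.0, 8.0, 10.0, np.inf),
    "TAPSE": (18.0, 4.0, 6.0, np.inf),
    "LVEF": (45.0, 12.0, 10.0, 80.0),
    "iLVEDV": (80.0, 25.0, 30.0, np.inf),
    "Creatinine": (1.0, 0.3, 0.3, np.inf),
    "BMI": (26.0, 4.0, 15.0, np.inf),
    # substrate scalars, used when features are drawn directly rather than
    # computed from a generated map
    "GR": (4.0, 2.5, 0.0, np.inf),
    "LAT": (20.0, 12.0, 0.0, np.inf),
    "VLT": (15.0, 10.0, 0.0, np.inf),
    "ScarAreas": (10.0, 8.0, 0.0, np.inf),
}


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    a = (lo - mean) / sd
    b = (hi - mean) / sd if np.isfinite(hi) else np.inf
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_clinical(
    n_patients: int,
    seed: int = 0,
    missing_rate: float = 0.0,
    include_substrate: bool = True,
) -> pd.DataFrame:
    """Generate a clinical covariate table (no outcome column).

    NYHA class is uniform on {1, 2, 3, 4}; continuous covariates follow the
    truncated normals in :data:`CONTINUOUS_DISTRIBUTIONS`; binaries are
    Bernoulli with the prevalences in :data:`BINARY_PREVALENCE`.  With
    ``include_substrate`` the four substrate scalars (GR, LAT, VLT,
    ScarAreas) are drawn directly from their stated distributions — the
    isolated-modelling shortcut; the full pipeline computes them from
    generated maps instead.  ``missing_rate`` injects missing-completely-
    at-random cells.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    data["NYHA"] = rng.integers(1, 5, n_patients).astype(float)
    for name, (mean, sd, lo, hi) in CONTINUOUS_DISTRIBUTIONS.items():
        if not include_substrate and name in ("GR", "LAT", "VLT", "ScarAreas"):
            continue
        data[name] = _truncated_normal(rng, n_patients, mean, sd, lo, hi)
    for name, prev in BINARY_PREVALENCE.items():
        data[name] = (rng.random(n_patients) < prev).astype(float)
    df = pd.DataFrame(data)
    if missing_rate > 0:
        mask = rng.random(df.shape) < missing_rate
        df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))
    return df


# ---------------------------------------------------------------------------
# outcomes

@dataclass(frozen=True)
class OutcomeModel:
    """Logistic generative model: P(MAE=1) = expit(intercept + Σ coef·value)."""

    intercept: float
    coefficients: dict[str, float]


def default_mae_model() -> OutcomeModel:
    """The published multivariable logistic polynomial for MAEs (logit units)."""
    return OutcomeModel(
        intercept=-21.007,
        coefficients={
            "NYHA": 3.889,
            "sPAP": 0.262,
            "LAT": 0.034,
            "GR": 0.492,
            "Hypertension": 2.638,
        },
    )


def event_probability(cohort: pd.DataFrame, model: OutcomeModel | None = None) -> np.ndarray:
    """Per-patient generative event probability under the outcome model."""
    model = model or default_mae_model()
    missing = [c for c in model.coefficients if c not in cohort.columns]
    if missing:
        raise ValueError(f"outcome-model coefficient(s) not found in cohort: {', '.join(missing)}")
    eta = np.full(len(cohort), model.intercept)
    for name, coef in model.coefficients.items():
        col = cohort[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(f"column {name!r} has missing values; impute before assigning outcomes")
        eta += coef * col
    return expit(eta)


def assign_outcomes(
    cohort: pd.DataFrame,
    model: OutcomeModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Return a copy of the cohort with a Bernoulli ``MAE`` outcome column."""
    p = event_probability(cohort, model)
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    out["MAE"] = (rng.random(len(cohort)) < p).astype(int)
    return out
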