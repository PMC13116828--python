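"""End-to-end orchestration from one configuration file.

A run simulates a cohort (one mapping export plus a clinical row per
patient), extracts substrate features, screens and imputes the modelling
table, assigns outcomes from the generative logistic model using the
*computed* features (closing the loop between generator and feature
extractor), runs model search per requested family, and writes every
artifact plus a manifest to the run directory.

One global seed fans out to per-stage seeds through ``numpy``'s
``SeedSequence`` spawning, so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import FeatureParams, FeatureVector, extract_features
from .io import write_export
from .modeling import FAMILIES, SplitPlan, make_split, search_models
from .screening import impute, screen_variables
from .sphere import build_sphere
from .synthetic import (
    Isthmus,
    LatePatch,
    OutcomeModel,
    ScarPatch,
    SubstrateScenario,
    VltPatch,
    assign_outcomes,
    default_mae_model,
    generate_clinical,
    generate_map,
)

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "simulate_cohort"]

_STAGES = {"clinical": 0, "maps": 1, "outcomes": 2, "split": 3, "search": 4}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(_STAGES[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Fully serializable configuration of one reproducible run."""

    seed: int = 0
    n_patients: int = 32
    n_points: int = 600
    output_dir: str = "runs/demo"
    families: tuple[str, ...] = ("logistic",)
    max_vars: int = 3
    top_k: int = 6
    pool_size: int = 8
    train_fraction: float = 0.8
    n_folds: int = 3
    n_bands: int = 120
    n_lon: int = 120
    gr_radius_mm: float = 7.0
    min_cluster: int = 3
    scar_threshold_mv: float = 0.5
    operator_dependent: tuple[str, ...] = ()
    outcome_intercept: float | None = None
    outcome_coefficients: dict[str, float] | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**raw)
        cfg.families = tuple(cfg.families)
        cfg.operator_dependent = tuple(cfg.operator_dependent)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def outcome_model(self) -> OutcomeModel:
        if self.outcome_intercept is None and self.outcome_coefficients is None:
            return default_mae_model()
        base = default_mae_model()
        return OutcomeModel(
            intercept=self.outcome_intercept if self.outcome_intercept is not None else base.intercept,
            coefficients=dict(self.outcome_coefficients or base.coefficients),
        )

    def feature_params(self) -> FeatureParams:
        return FeatureParams(
            gr_radius_mm=self.gr_radius_mm,
            min_cluster=self.min_cluster,
            scar_threshold_mv=self.scar_threshold_mv,
        )


def _patient_scenario(rng: np.random.Generator, n_points: int, seed: int) -> SubstrateScenario:
    """Randomized per-patient substrate: severity drives patch burden."""
    severity = rng.random()
    regions = rng.permutation(np.arange(1, 9))
    scar, late, vlt, isthmus = [], [], [], None
    if severity > 0.35:
        scar.append(ScarPatch(int(regions[0]), 10.0 + 20.0 * severity, 0.2))
        late.append(LatePatch(int(regions[1]), 10.0 + 15.0 * severity, 40.0 + 60.0 * severity))
    if severity > 0.55:
        vlt.append(VltPatch(int(regions[2]), 8.0 + 15.0 * severity, 6.0 + 3.0 * severity))
    if severity > 0.7:
        isthmus = Isthmus(int(regions[0]), width_mm=3.0, step_ms=40.0 + 80.0 * severity)
    return SubstrateScenario(
        n_points=n_points,
        scar_patches=tuple(scar),
        late_patches=tuple(late),
        vlt_patches=tuple(vlt),
        isthmus=isthmus,
        seed=seed,
    )


def simulate_cohort(config: RunConfig, exports_dir: Path | None = None):
    """Simulate clinical rows + per-patient maps; return the merged table.

    Substrate scalars in the modelling table are the features *computed* from
    each generated map, not draws from their marginal distributions.
    """
    sphere = build_sphere(config.n_bands, config.n_lon)
    params = config.feature_params()
    clinical = generate_clinical(
        config.n_patients, seed=stage_seed(config.seed, "clinical"), include_substrate=False
    )
    rng = np.random.default_rng(stage_seed(config.seed, "maps"))
    rows = []
    for i in range(config.n_patients):
        scenario = _patient_scenario(rng, config.n_points, int(rng.integers(0, 2**31)))
        export = generate_map(scenario, patient_id=f"SYN-{i:04d}")
        if exports_dir is not None:
            write_export(export, exports_dir / f"{export.patient_id}.tsv")
        fv = extract_features(export, sphere, params)
        rows.append(fv.as_dict())
    features = pd.DataFrame(rows, index=clinical.index)
    return pd.concat([clinical, features], axis=1)



def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure aborts with the stage name in the error message.
    """
    for fam in config.families:
        if fam not in FAMILIES:
            raise ValueError(f"unknown model family {fam!r}; expected one of {FAMILIES}")

    out = Path(config.output_dir)
    exports_dir = out / "exports"
    exports_dir.mkdir(parents=True, exist_ok=True)
    (out / "models").mkdir(exist_ok=True)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    cohort = _stage("simulate", lambda: simulate_cohort(config, exports_dir))
    cohort.to_csv(out / "features.csv", index=False, float_format="%.6f")

    cohort = _stage(
        "outcomes",
        lambda: assign_outcomes(
            cohort.fillna(cohort.median(numeric_only=True)),
            config.outcome_model(),
            seed=stage_seed(config.seed, "outcomes"),
        ),
    )
    cohort.to_csv(out / "cohort.csv", index=False, float_format="%.6f")

    screened, report = _stage(
        "screening",
        lambda: screen_variables(cohort, operator_dependent=config.operator_dependent),
    )
    with open(out / "screening.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)

    plan = SplitPlan(
        train_fraction=config.train_fraction,
        n_folds=config.n_folds,
        seed=stage_seed(config.seed, "split"),
    )
    split = _stage("split", lambda: make_split(screened, plan))
    imputed, _ = impute(screened, train_index=split.train_idx)

    search_seed = stage_seed(config.seed, "search")
    for fam in config.families:
        result = _stage(
            f"search:{fam}",
            lambda fam=fam: search_models(
                imputed, fam, split,
                max_vars=config.max_vars, top_k=config.top_k,
                pool_size=config.pool_size, seed=search_seed,
            ),
        )
        with open(out / "models" / f"{fam}.json", "w") as fh:
            json.dump([r.to_dict() for r in result.reports], fh, indent=2)
        result.frequency_table().to_csv(out / f"frequency_{fam}.csv", index=False)

    manifest = {
        "config": config.to_dict(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "n_patients": int(len(cohort)),
        "event_rate": float(cohort["MAE"].mean()),
        "versions": {
            "python": platform.python_version(),
            "eamrisk": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
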