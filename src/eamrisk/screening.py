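"""Variable screening and imputation for the modelling table.

Screening applies four rules, in order, to every predictor column (the
outcome is never screened), and each dropped column is attributed to exactly
the first rule that caught it:

1. *low_coverage* — fewer than 10 % of values observed (the rule is applied
   literally: a column is retained as long as at least 10 % of its values
   are non-missing, an intentionally permissive cut).
2. *constant* — the same observed value across all patients.
3. *low_heterogeneity* — fewer than 5 % of observed values differ from the
   modal value ("differing" is read against the mode, which the constant
   rule makes the natural reference).
4. *operator_dependent* — columns flagged in configuration as reflecting
   operator choices (mapping system, catheter choice) rather than pathology.

Residual missingness is filled by median (continuous) or mode (categorical)
imputation, fitted on training rows only when a split is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ScreeningReport", "screen_variables", "impute"]

MIN_COVERAGE = 0.10
MIN_HETEROGENEITY = 0.05


@dataclass
class ScreeningReport:
    dropped: dict[str, str]          # column -> rule that removed it
    retained: list[str]
    thresholds: dict[str, float] = field(
        default_factory=lambda: {
            "min_coverage": MIN_COVERAGE,
            "min_heterogeneity": MIN_HETEROGENEITY,
        }
    )

    def by_rule(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for col, rule in self.dropped.items():
            out.setdefault(rule, []).append(col)
        return out

    def to_dict(self) -> dict:
        return {
            "dropped": dict(self.dropped),
            "by_rule": self.by_rule(),
            "retained": list(self.retained),
            "thresholds": dict(self.thresholds),
        }


def _drop_rule(col: pd.Series, operator_dependent: frozenset[str]) -> str | None:
    observed = col.dropna()
    if len(observed) / len(col) < MIN_COVERAGE:
        return "low_coverage"
    if observed.nunique() <= 1:
        return "constant"
    frac_differing = (observed != observed.mode().iloc[0]).mean()
    if frac_differing < MIN_HETEROGENEITY:
        return "low_heterogeneity"
    if col.name in operator_dependent:
        return "operator_dependent"
    return None


def screen_variables(
    cohort: pd.DataFrame,
    outcome: str = "MAE",
    operator_dependent: Sequence[str] = (),
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Apply the screening rules; returns the reduced table and a report.

    Screening is outcome-blind (predictors only) and idempotent: re-screening
    the returned table drops nothing further.
    """
    if len(cohort) < 2:
        raise ValueError("screening requires at least 2 patients")
    op = frozenset(operator_dependent)
    dropped: dict[str, str] = {}
    for col in cohort.columns:
        if col == outcome:
            continue
        rule = _drop_rule(cohort[col], op)
        if rule is not None:
            dropped[col] = rule
    retained = [c for c in cohort.columns if c not in dropped]
    return cohort[retained].copy(), ScreeningReport(dropped=dropped, retained=retained)


def _is_categorical(col: pd.Series) -> bool:
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        return True
    observed = col.dropna()
    if not len(observed):
        return False
    # integer-coded scores and 0/1 indicators impute by mode; a handful of
    # distinct integers with little repetition is still treated as continuous
    return (
        bool((observed == observed.round()).all())
        and observed.nunique() <= 10
        and observed.nunique() * 2 < len(observed)
    )


def impute(
    cohort: pd.DataFrame,
    outcome: str = "MAE",
    train_index: Iterable[int] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Fill residual missingness; returns the completed table and fill values.

    Continuous columns take the median, categorical ones the mode.  When
    ``train_index`` (positional row indices) is given, fill values are
    computed on those rows only, so held-out rows never leak into the fit.
    """
    out = cohort.copy()
    fit_rows = out.iloc[list(train_index)] if train_index is not None else out
    fills: dict[str, float] = {}
    for col in out.columns:
        if col == outcome or not out[col].isna().any():
            continue
        observed = fit_rows[col].dropna()
        if observed.empty:
            raise ValueError(
                f"column {col!r} has no observed training values to impute from"
            )
        value = observed.mode().iloc[0] if _is_categorical(out[col]) else observed.median()
        fills[col] = float(value)
        out[col] = out[col].fillna(value)
    return out, fills
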