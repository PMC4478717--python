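"""Weighted, country-stratified Cox regression with family-robust variance.

Mutation-carrier cohorts over-sample affected individuals relative to the
population, so an unweighted Cox model on carrier data over-states absolute
risk structure.  The weighted-cohort approach re-calibrates: within each
(gene, age-class) cell, affected individuals get weight p*n/n_aff and
unaffected individuals (1-p)*n/(n-n_aff), where p is the external
age-specific probability of being affected; after weighting, the weighted
affected fraction equals p exactly in every cell.  The hazard-ratio model is
a Cox partial likelihood on the age scale with baseline hazards stratified
by country, the haplogroup contrast as covariate, Efron tie handling and a
weight-aware sandwich variance clustered on family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .errors import ConfigurationError, DataError, FitError

REQUIRED_COLUMNS = (
    "sample_id",
    "family_id",
    "country",
    "gene",
    "status",
    "age_diagnosis",
    "age_censor",
)


def survival_frame(metadata: pd.DataFrame) -> pd.DataFrame:
    """Attach the analysis time: age at diagnosis if affected, else censor age."""
    for col in REQUIRED_COLUMNS:
        if col not in metadata.columns:
            raise DataError(f"missing metadata column {col!r}")
    df = metadata.copy()
    df["status"] = df["status"].astype(int)
    time = np.where(df["status"] == 1, df["age_diagnosis"], df["age_censor"])
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise DataError("event/censor times must be positive and finite")
    affected = df["status"] == 1
    if np.any(df.loc[affected, "age_diagnosis"] > df.loc[affected, "age_censor"]):
        raise DataError("diagnosis age exceeds censor age for an affected record")
    df["time"] = time
    return df


@dataclass
class IncidenceTable:
    """Per (gene, age class) target probability of being affected.

    ``table`` columns: gene, age_low, age_high, p; classes partition the
    study age range per gene, probabilities in (0, 1).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        for col in ("gene", "age_low", "age_high", "p"):
            if col not in t.columns:
                raise DataError(f"incidence table missing column {col!r}")
        if ((t["p"] <= 0) | (t["p"] >= 1)).any():
            raise DataError("incidence probabilities must lie in (0,1)")
        for gene, sub in t.groupby("gene"):
            sub = sub.sort_values("age_low")
            if not (sub["age_low"].values[1:] == sub["age_high"].values[:-1]).all():
                raise DataError(f"age classes for {gene} do not partition the range")

    def age_class(self, gene: str, age: float) -> tuple[float, float]:
        sub = self.table[self.table["gene"] == gene]
        hit = sub[(sub["age_low"] <= age) & (age < sub["age_high"])]
        if len(hit) == 0:
            # the final class is closed on the right
            last = sub.sort_values("age_high").iloc[-1] if len(sub) else None
            if last is not None and age == last["age_high"]:
                return float(last["age_low"]), float(last["age_high"])
            raise DataError(f"age {age} outside incidence table range for {gene}")
        row = hit.iloc[0]
        return float(row["age_low"]), float(row["age_high"])

    def target(self, gene: str, age_low: float) -> float:
        sub = self.table[(self.table["gene"] == gene) & (self.table["age_low"] == age_low)]
        return float(sub["p"].iloc[0])

    @classmethod
    def from_tsv(cls, path) -> "IncidenceTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class WeightScheme:
    """Weights per (gene, age_low, status); ``per_class`` for inspection."""

    per_class: pd.DataFrame  # gene, age_low, age_high, n, n_aff, p, w_aff, w_unaff

    def weight(self, gene: str, age_low: float, status: int) -> float:
        row = self.per_class[
            (self.per_class["gene"] == gene) & (self.per_class["age_low"] == age_low)
        ].iloc[0]
        return float(row["w_aff"] if status == 1 else row["w_unaff"])


def compute_weights(
    records: pd.DataFrame, incidence: IncidenceTable
) -> tuple[WeightScheme, pd.Series]:
    """Calibration weights per (gene, age class).

    Returns the scheme plus a per-record weight series aligned with
    ``records``.  Classes with zero affected or zero unaffected members get
    unit weights with a warning (the calibration is then undefined).
    """
    if "time" not in records.columns:
        records = survival_frame(records)
    cls_low = []
    cls_high = []
    for gene, age in zip(records["gene"], records["time"]):
        lo, hi = incidence.age_class(gene, float(age))
        cls_low.append(lo)
        cls_high.append(hi)
    rec = records.assign(_age_low=cls_low, _age_high=cls_high)

    rows = []
    weights = pd.Series(np.ones(len(rec)), index=rec.index, dtype=float)
    for (gene, lo, hi), sub in rec.groupby(["gene", "_age_low", "_age_high"]):
        n = len(sub)
        n_aff = int(sub["status"].sum())
        p = incidence.target(gene, lo)
        if n_aff == 0 or n_aff == n:
            warnings.warn(
                f"class ({gene}, {lo}-{hi}) has no {'unaffected' if n_aff else 'affected'}"
                " members; unit weights used"
            )
            w_aff = w_unaff = 1.0
        else:
            w_aff = p * n / n_aff
            w_unaff = (1.0 - p) * n / (n - n_aff)
        rows.append(
            {
                "gene": gene,
                "age_low": lo,
                "age_high": hi,
                "n": n,
                "n_aff": n_aff,
                "p": p,
                "w_aff": w_aff,
                "w_unaff": w_unaff,
            }
        )
        weights[sub.index] = np.where(sub["status"] == 1, w_aff, w_unaff)
    return WeightScheme(per_class=pd.DataFrame(rows)), weights


@dataclass
class CoxResult:
    hazard_ratio: float
    log_hazard: float
    robust_se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    n_events: int
    n_strata: int
    exposure: str

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "hazard_ratio": self.hazard_ratio,
            "log_hazard": self.log_hazard,
            "robust_se": self.robust_se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_used": self.n_used,
            "n_events": self.n_events,
            "n_strata": self.n_strata,
        }


def fit_weighted_cox(
    records: pd.DataFrame,
    weights: pd.Series | None = None,
    exposure: str = "exposure",
    strata: str | None = "country",
    clusters: str | None = "family_id",
    reference: str | None = None,
) -> CoxResult:
    """Weighted stratified Cox fit with cluster-robust sandwich variance.

    ``records`` must carry a binary or categorical ``exposure`` column.
    ``reference`` names the baseline level (default: the most frequent
    level, the usual epidemiological convention).  The reported contrast is
    the first non-reference level in sorted order (further levels are
    adjusted for).
    """
    df = survival_frame(records) if "time" not in records.columns else records.copy()
    if exposure not in df.columns:
        raise DataError(f"missing exposure column {exposure!r}")
    series = df[exposure].astype(str)
    if reference is None:
        reference = series.value_counts().idxmax()
    elif reference not in set(series):
        raise DataError(f"reference level {reference!r} not present")
    levels = [reference] + sorted(set(series) - {reference})
    if len(levels) < 2:
        raise DataError("need at least two exposure groups")
    for level in levels:
        if df.loc[df[exposure].astype(str) == level, "status"].sum() == 0:
            raise FitError(f"exposure group {level!r} has no events (separation)")

    model = pd.DataFrame(
        {
            "time": df["time"].astype(float),
            "status": df["status"].astype(int),
        },
        index=df.index,
    )
    dummy_cols = []
    for level in levels[1:]:
        col = f"{exposure}[{level}]"
        model[col] = (df[exposure].astype(str) == level).astype(float)
        dummy_cols.append(col)
    if strata is not None:
        model["_stratum"] = df[strata].astype(str)
        n_strata = model["_stratum"].nunique()
        for s, sub in model.groupby("_stratum"):
            if sub["status"].sum() == 0:
                warnings.warn(f"stratum {s!r} has no events and contributes nothing")
    else:
        n_strata = 1
    if clusters is not None:
        model["_cluster"] = df[clusters]
    model["_w"] = 1.0 if weights is None else np.asarray(weights, dtype=float)

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*weights.*")
        try:
            cph.fit(
                model,
                duration_col="time",
                event_col="status",
                weights_col="_w",
                cluster_col="_cluster" if clusters is not None else None,
                strata="_stratum" if strata is not None else None,
                robust=True,
                fit_options={"precision": 1e-10, "max_steps": 500},
            )
        except ConvergenceError as e:
            raise FitError(f"Cox model failed to converge: {e}") from e

    name = dummy_cols[0]
    beta = float(cph.params_[name])
    se = float(cph.standard_errors_[name])
    return CoxResult(
        hazard_ratio=float(np.exp(beta)),
        log_hazard=beta,
        robust_se=se,
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        p_value=float(cph.summary.loc[name, "p"]),
        n_used=int(len(model)),
        n_events=int(model["status"].sum()),
        n_strata=int(n_strata),
        exposure=name,
    )
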