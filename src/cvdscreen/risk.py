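"""10-year major-cardiovascular-event risk: scoring, recalibration, categories.

The risk equation follows the pooled-cohort-style form

    risk(x) = 1 - S0 ** exp(lp(x) - mean_lp)

where ``lp`` is a linear predictor on (optionally log-transformed)
covariates, ``mean_lp`` is the cohort-mean linear predictor and ``S0`` the
10-year baseline survival evaluated at the covariate mean.  Coefficient
sets are never hardcoded: they load from a versioned JSON file and can be
re-estimated on any cohort with a Cox proportional-hazards refit
(:func:`refit_coefficients`), which is how the equation is recalibrated to
a population in which the published coefficients over- or under-estimate
absolute risk.

Predicted risk is binned into the treatment-guideline categories::

    LOW        [0,     0.025)
    INT_LOW    [0.025, 0.05)
    INT_HIGH   [0.05,  0.075)
    HIGH       [0.075, 0.15)      (>= 0.075 when the high band is not split)
    VERY_HIGH  [0.15,  1]

0.075 is the threshold at which preventive statin therapy is considered.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index

__all__ = [
    "RiskCategory",
    "RiskFactorProfile",
    "RiskCoefficients",
    "MissingInputError",
    "FittingError",
    "ten_year_risk",
    "ten_year_risk_frame",
    "categorize",
    "refit_coefficients",
    "harrells_c",
    "calibration_table",
    "load_default_coefficients",
    "CATEGORY_BOUNDS",
]


class MissingInputError(ValueError):
    """A required covariate is missing (no silent imputation)."""


class FittingError(RuntimeError):
    """The proportional-hazards refit failed (non-convergence, separation...)."""


class RiskCategory(str, Enum):
    LOW = "LOW"
    INT_LOW = "INT_LOW"
    INT_HIGH = "INT_HIGH"
    HIGH = "HIGH"
    VERY_HIGH = "VERY_HIGH"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Half-open risk bounds per category, lower-inclusive ("0 to <2.5%").
CATEGORY_BOUNDS: dict[RiskCategory, tuple[float, float]] = {
    RiskCategory.LOW: (0.0, 0.025),
    RiskCategory.INT_LOW: (0.025, 0.05),
    RiskCategory.INT_HIGH: (0.05, 0.075),
    RiskCategory.HIGH: (0.075, 0.15),
    RiskCategory.VERY_HIGH: (0.15, 1.0),
}

#: Numeric covariates eligible for log transforms; the rest are 0/1 flags.
_NUMERIC = ("age", "total_cholesterol", "hdl_cholesterol", "systolic_bp")
_BINARY = ("antihypertensive", "smoker", "diabetes")
COVARIATES = _NUMERIC + _BINARY


@dataclass(frozen=True)
class RiskFactorProfile:
    """One person-exam's risk-equation inputs.

    Units: age in years, cholesterols in mmol/L, systolic blood pressure in
    mm Hg.  ``sex`` is ``"male"`` or ``"female"``.
    """

    age: float
    sex: str
    total_cholesterol: float
    hdl_cholesterol: float
    systolic_bp: float
    antihypertensive: bool
    smoker: bool
    diabetes: bool

    def validate(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not 18.0 <= self.age <= 100.0:
            raise ValueError(f"age {self.age} outside [18, 100]")
        for name in ("total_cholesterol", "hdl_cholesterol", "systolic_bp"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise MissingInputError(f"missing covariate {name}")
            if v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.hdl_cholesterol > self.total_cholesterol:
            raise ValueError("HDL cholesterol exceeds total cholesterol")

    def as_row(self) -> dict[str, float]:
        return {
            "age": self.age,
            "sex": self.sex,
            "total_cholesterol": self.total_cholesterol,
            "hdl_cholesterol": self.hdl_cholesterol,
            "systolic_bp": self.systolic_bp,
            "antihypertensive": float(self.antihypertensive),
            "smoker": float(self.smoker),
            "diabetes": float(self.diabetes),
        }


@dataclass
class RiskCoefficients:
    """A versioned coefficient set for the 10-year risk equation.

    ``betas``, ``mean_lp`` and ``s0_10y`` are keyed by stratum: ``"male"``/
    ``"female"`` for a sex-stratified fit, or the single key ``"all"``.
    ``transforms`` maps covariate name to ``"log"`` or ``"identity"`` and is
    declarative metadata: the scoring code applies it, so the recipe in the
    file always matches the arithmetic performed.
    """

    covariates: tuple[str, ...]
    transforms: Mapping[str, str]
    betas: Mapping[str, Mapping[str, float]]
    mean_lp: Mapping[str, float]
    s0_10y: Mapping[str, float]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        for cov in self.covariates:
            if cov not in COVARIATES:
                raise ValueError(f"unknown covariate {cov!r} in recipe")
        for cov, tr in self.transforms.items():
            if tr not in ("log", "identity"):
                raise ValueError(f"unknown transform {tr!r} for {cov!r}")
        for stratum, s0 in self.s0_10y.items():
            if not 0.0 < s0 < 1.0:
                raise ValueError(f"s0_10y[{stratum!r}]={s0} outside (0, 1)")

    @property
    def stratified(self) -> bool:
        return "all" not in self.betas

    def stratum_for(self, sex: str) -> str:
        return sex if self.stratified else "all"

    # -- design matrix -------------------------------------------------
    def design(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Apply the transformation recipe to raw covariate columns."""
        missing = [c for c in self.covariates if c not in frame.columns]
        if missing:
            raise MissingInputError(f"missing covariate column(s): {missing}")
        out = {}
        for cov in self.covariates:
            col = pd.to_numeric(frame[cov], errors="coerce").astype(float)
            if col.isna().any():
                raise MissingInputError(f"missing values in covariate {cov!r}")
            if self.transforms.get(cov, "identity") == "log":
                if (col <= 0).any():
                    raise ValueError(f"log transform of non-positive {cov!r}")
                col = np.log(col)
            out[cov] = col
        return pd.DataFrame(out, index=frame.index)

    def linear_predictor(self, frame: pd.DataFrame) -> pd.Series:
        X = self.design(frame)
        sex = frame["sex"] if "sex" in frame.columns else pd.Series("all", index=frame.index)
        lp = pd.Series(0.0, index=frame.index)
        for stratum, beta in self.betas.items():
            mask = (sex == stratum) if self.stratified else slice(None)
            b = pd.Series({c: beta[c] for c in self.covariates})
            if self.stratified:
                lp.loc[mask] = X.loc[mask].mul(b).sum(axis=1)
            else:
                lp = X.mul(b).sum(axis=1)
        return lp

    # -- serialisation -------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "version": self.version,
            "covariates": list(self.covariates),
            "transforms": dict(self.transforms),
            "betas": {k: dict(v) for k, v in self.betas.items()},
            "mean_lp": dict(self.mean_lp),
            "s0_10y": dict(self.s0_10y),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path_or_obj) -> "RiskCoefficients":
        if isinstance(path_or_obj, Mapping):
            payload = path_or_obj
        else:
            with open(path_or_obj) as fh:
                payload = json.load(fh)
        return cls(
            covariates=tuple(payload["covariates"]),
            transforms=payload["transforms"],
            betas=payload["betas"],
            mean_lp=payload["mean_lp"],
            s0_10y=payload["s0_10y"],
            version=payload.get("version", "unversioned"),
        )


def load_default_coefficients() -> RiskCoefficients:
    """Bundled synthetic-fit default coefficient set.

    Calibrated on the package's own synthetic cohort (it is NOT a published
    guideline coefficient set) so that a default baseline cohort lands near
    a 54/30/9/7% LOW/INT_LOW/INT_HIGH/HIGH split.
    """
    text = resources.files("cvdscreen.data").joinpath("default_coefficients.json").read_text()
    return RiskCoefficients.from_json(json.loads(text))


# ---------------------------------------------------------------------------
# scoring


def ten_year_risk_frame(frame: pd.DataFrame, coeffs: RiskCoefficients) -> pd.Series:
    """Vectorised 10-year risk for a covariate DataFrame (one row per person-exam)."""
    lp = coeffs.linear_predictor(frame)
    sex = frame["sex"] if "sex" in frame.columns else pd.Series("all", index=frame.index)
    risk = pd.Series(np.nan, index=frame.index)
    strata = ("male", "female") if coeffs.stratified else ("all",)
    for stratum in strata:
        mask = (sex == stratum) if coeffs.stratified else np.ones(len(frame), dtype=bool)
        s0 = coeffs.s0_10y[stratum]
        mlp = coeffs.mean_lp[stratum]
        risk.loc[mask] = 1.0 - s0 ** np.exp(lp.loc[mask] - mlp)
    return risk.clip(0.0, 1.0)


def ten_year_risk(profile: RiskFactorProfile, coeffs: RiskCoefficients) -> float:
    """10-year risk ``1 - S0**exp(lp - mean_lp)`` for one profile."""
    profile.validate()
    frame = pd.DataFrame([profile.as_row()])
    return float(ten_year_risk_frame(frame, coeffs).iloc[0])


def categorize(risk: float, *, split_high: bool = False) -> RiskCategory:
    """Bin a 10-year risk (fraction in [0, 1]) into its guideline category.

    Boundary values map upward (0.075 -> HIGH).  With ``split_high`` the
    high band is split at 15% into HIGH and VERY_HIGH, as used when
    describing progression beyond the treatment threshold.
    """
    if not 0.0 <= risk <= 1.0:
        raise ValueError(f"risk {risk} outside [0, 1]")
    if risk < 0.025:
        return RiskCategory.LOW
    if risk < 0.05:
        return RiskCategory.INT_LOW
    if risk < 0.075:
        return RiskCategory.INT_HIGH
    if split_high and risk >= 0.15:
        return RiskCategory.VERY_HIGH
    return RiskCategory.HIGH


# ---------------------------------------------------------------------------
# recalibration


DEFAULT_TRANSFORMS: dict[str, str] = {
    "age": "log",
    "total_cholesterol": "log",
    "hdl_cholesterol": "log",
    "systolic_bp": "log",
    "antihypertensive": "identity",
    "smoker": "identity",
    "diabetes": "identity",
}


def _profiles_to_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles.reset_index(drop=True)
    rows = [p.as_row() for p in profiles]
    return pd.DataFrame(rows)


def _fit_stratum(X: pd.DataFrame, durations, events, label: str):
    df = X.copy()
    df["_T"] = np.asarray(durations, dtype=float)
    df["_E"] = np.asarray(events, dtype=int)
    if df["_E"].sum() < 2:
        raise FittingError(f"stratum {label!r}: fewer than 2 events; cannot refit")
    # collapse exact duplicate rows into frequency weights: keeps the fit
    # exactly invariant to dataset duplication (tie approximations are not)
    df = df.groupby(list(df.columns), as_index=False, sort=False).size().rename(
        columns={"size": "_W"}
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*weights.*")
            cph.fit(df, duration_col="_T", event_col="_E", weights_col="_W",
                    fit_options={"precision": 1e-9, "r_precision": 1e-13,
                                 "max_steps": 500})
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise FittingError(f"stratum {label!r}: Cox fit failed: {exc}") from exc
    beta = cph.params_
    mean_row = X.mean()
    mean_lp = float(beta @ mean_row)
    # baseline 10-year survival at the covariate mean, linear interpolation
    # between event times; extrapolate flat (with a warning) if follow-up < 10y
    sf = cph.predict_survival_function(mean_row.to_frame().T)
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times.max() < 10.0:
        warnings.warn(
            f"stratum {label!r}: follow-up {times.max():.2f}y < 10y; "
            "extrapolating baseline survival flat to t=10",
            stacklevel=3,
        )
        s0 = float(surv[-1])
    else:
        s0 = float(np.interp(10.0, times, surv))
    s0 = min(max(s0, 1e-12), 1 - 1e-12)
    return {c: float(beta[c]) for c in X.columns}, mean_lp, s0


def refit_coefficients(
    baseline_profiles,
    durations: Sequence[float],
    events: Sequence[int],
    *,
    transforms: Mapping[str, str] | None = None,
    stratify_by_sex: bool = True,
    version: str = "refit",
) -> RiskCoefficients:
    """Recalibrate the risk equation on a cohort via a Cox PH refit.

    Parameters
    ----------
    baseline_profiles
        List of :class:`RiskFactorProfile` or a DataFrame with the eight
        covariate columns plus ``sex``.
    durations, events
        Time to major cardiovascular event or censoring (years) and the
        event indicator, aligned with ``baseline_profiles``.
    stratify_by_sex
        Fit separate male/female models (the derivation-protocol default);
        with ``False`` a single model is fitted on everyone.
    """
    frame = _profiles_to_frame(baseline_profiles)
    transforms = dict(transforms or DEFAULT_TRANSFORMS)
    recipe = RiskCoefficients(
        covariates=COVARIATES,
        transforms=transforms,
        betas={"all": {c: 0.0 for c in COVARIATES}},
        mean_lp={"all": 0.0},
        s0_10y={"all": 0.5},
    )
    X = recipe.design(frame)
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(X) != len(durations) or len(X) != len(events):
        raise ValueError("profiles, durations and events must align")

    betas: dict[str, dict[str, float]] = {}
    mean_lp: dict[str, float] = {}
    s0: dict[str, float] = {}
    if stratify_by_sex:
        for sex in ("male", "female"):
            mask = (frame["sex"] == sex).to_numpy()
            if mask.sum() == 0:
                raise FittingError(f"no rows for stratum {sex!r}")
            b, m, s = _fit_stratum(X.loc[mask], durations[mask], events[mask], sex)
            betas[sex], mean_lp[sex], s0[sex] = b, m, s
    else:
        b, m, s = _fit_stratum(X, durations, events, "all")
        betas["all"], mean_lp["all"], s0["all"] = b, m, s
    return RiskCoefficients(
        covariates=COVARIATES,
        transforms=transforms,
        betas=betas,
        mean_lp=mean_lp,
        s0_10y=s0,
        version=version,
    )


# ---------------------------------------------------------------------------
# discrimination and calibration


def harrells_c(risks, durations, events) -> float:
    """Harrell's concordance: concordant comparable pairs, ties counted 0.5.

    Higher predicted risk should pair with earlier events.
    """
    risks = np.asarray(risks, dtype=float)
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("no events: no comparable pairs, C undefined")
    try:
        return float(concordance_index(durations, -risks, events))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs, C undefined") from exc


def calibration_table(
    predicted,
    durations,
    events,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Per-bin mean predicted vs Kaplan–Meier observed 10-year event fraction.

    Bins are predicted-risk quantiles; empty/duplicate bins are merged (a
    constant prediction collapses to a single effective bin).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    predicted = np.asarray(predicted, dtype=float)
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    try:
        bins = np.asarray(pd.qcut(predicted, q=n_bins, labels=False, duplicates="drop"))
    except ValueError:
        bins = np.zeros(len(predicted), dtype=int)
    # a constant prediction drops every internal edge: one effective bin
    bins = np.nan_to_num(bins.astype(float), nan=0.0).astype(int)
    if np.asarray(pd.unique(bins)).size < n_bins:
        warnings.warn("duplicate quantile edges: bins were merged", stacklevel=2)
    rows = []
    for b in np.sort(pd.unique(bins)):
        mask = bins == b
        km = KaplanMeierFitter()
        km.fit(durations[mask], events[mask])
        s10 = float(km.predict(10.0))
        rows.append(
            {
                "bin": int(b),
                "n": int(mask.sum()),
                "mean_predicted": float(predicted[mask].mean()),
                "observed_10y": 1.0 - s10,
            }
        )
    return pd.DataFrame(rows)
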