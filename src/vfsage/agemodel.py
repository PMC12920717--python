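"""Exponential decay–age models and physiological blood-age prediction.

The diversity-decay metric λ grows exponentially with chronological age in
healthy cohorts, so the model is linear on the log scale,

    log(λ) = a + b·age + ε,      ε ~ N(0, σ²),

and the physiological blood age implied by an observed λ is the inversion

    phyloAge* = (log(λ) − a) / b.

``a`` and ``b`` are estimated by maximum likelihood.  With homoscedastic
Gaussian errors on log(λ), the likelihood profile over σ reduces to least
squares; the optimizer is still started from the conventional initial values
(a = 1/1000, b = 0.3) and its solution is cross-checked against (and, when
they agree, replaced by) the closed-form solution, so downstream
leave-one-out loops are exactly reproducible.

Logarithms are natural throughout; the fitted (a, b) pair is internally
consistent under any fixed base.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "AgeModel",
    "EvaluationReport",
    "CalibrationResult",
    "ModelFitError",
    "BelowModelSupportError",
    "fit_age_model",
    "predict_phyloage",
    "residual_age",
    "loo_evaluate",
    "calibration_regression",
    "DEFAULT_AGE_BANDS",
]

DEFAULT_AGE_BANDS: tuple[tuple[float, float], ...] = (
    (0, 30), (31, 45), (46, 60), (61, 75), (76, 100),
)


class ModelFitError(ValueError):
    """The decay–age model could not be fitted on the given training data."""


class BelowModelSupportError(ValueError):
    """λ <= 0: no retained variants, so the log-model inversion is undefined."""


@dataclass
class AgeModel:
    """Fitted constants of the exponential decay–age model plus provenance."""

    a: float
    b: float
    threshold: float = 0.01
    depth_profile: float | str = "full"
    panel_tag: str = "full"
    n_training: int = 0
    fit_log: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AgeModel":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        payload = json.loads(text)
        return cls(**payload)


def _as_age_lambda(
    training: "pd.DataFrame | Iterable[tuple[float, float]]",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(training, pd.DataFrame):
        cols = {c.lower(): c for c in training.columns}
        age_col = cols.get("age")
        lam_col = cols.get("lambda") or cols.get("lambda_value")
        if age_col is None or lam_col is None:
            raise ValueError("training table needs 'age' and 'lambda' columns")
        ages = training[age_col].to_numpy(dtype=float)
        lams = training[lam_col].to_numpy(dtype=float)
        sid_col = cols.get("sample_id")
        ids = (training[sid_col].astype(str).tolist() if sid_col
               else [f"ind{i}" for i in range(len(ages))])
    else:
        pairs = list(training)
        ages = np.array([p[0] for p in pairs], dtype=float)
        lams = np.array([p[1] for p in pairs], dtype=float)
        ids = [f"ind{i}" for i in range(len(ages))]
    return ages, lams, ids


def fit_age_model(
    training: "pd.DataFrame | Iterable[tuple[float, float]]",
    init_a: float = 0.001,
    init_b: float = 0.3,
    threshold: float = 0.01,
    depth_profile: float | str = "full",
    panel_tag: str = "full",
    drop_nonpositive: bool = False,
) -> AgeModel:
    """Fit log(λ) = a + b·age by Gaussian maximum likelihood.

    ``training`` is a sequence of (age, λ) pairs or a DataFrame with ``age``
    and ``lambda`` columns.  λ must be positive for every individual;
    ``drop_nonpositive=True`` instead excludes them with a warning (an
    individual with no retained variants carries no decay signal).  A fitted
    slope b <= 0 is an error: the model is only invertible when the decay
    metric increases with age.
    """
    ages, lams, ids = _as_age_lambda(training)
    bad = np.flatnonzero(lams <= 0)
    if bad.size:
        if drop_nonpositive:
            warnings.warn(
                f"excluding {bad.size} individual(s) with non-positive decay "
                f"metric from training: {[ids[i] for i in bad[:5]]}",
                stacklevel=2,
            )
            keep = lams > 0
            ages, lams = ages[keep], lams[keep]
            ids = [ids[i] for i in np.flatnonzero(keep)]
        else:
            raise ModelFitError(
                f"training sample {ids[bad[0]]!r} has non-positive decay "
                f"metric {lams[bad[0]]}"
            )
    n = len(ages)
    if n < 3:
        raise ModelFitError(f"at least 3 training individuals required, got {n}")
    if np.ptp(ages) == 0:
        raise ModelFitError("all training ages are equal: slope unidentifiable")
    y = np.log(lams)

    def ssr(params: np.ndarray) -> float:
        a, b = params
        r = y - a - b * ages
        return float(r @ r)

    def grad(params: np.ndarray) -> np.ndarray:
        a, b = params
        r = y - a - b * ages
        return np.array([-2.0 * r.sum(), -2.0 * (r * ages).sum()])

    opt = optimize.minimize(ssr, x0=np.array([init_a, init_b]), jac=grad,
                            method="BFGS", options={"gtol": 1e-12})
    # Closed form: the profiled Gaussian likelihood is minimised by OLS.
    b_ols = float(np.cov(ages, y, bias=True)[0, 1] / np.var(ages))
    a_ols = float(y.mean() - b_ols * ages.mean())
    agree = bool(np.max(np.abs(opt.x - [a_ols, b_ols])) < 1e-4)
    a_hat, b_hat = (a_ols, b_ols) if agree else (float(opt.x[0]), float(opt.x[1]))
    if not agree:
        warnings.warn("optimizer and closed-form OLS disagree; keeping the "
                      "optimizer solution", stacklevel=2)
    if b_hat <= 0:
        raise ModelFitError(
            f"fitted slope b = {b_hat:.4g} <= 0: decay metric does not "
            "increase with age in this cohort"
        )
    resid = y - a_hat - b_hat * ages
    dof = n - 2
    s2 = float(resid @ resid) / dof if dof > 0 else float("nan")
    sxx = float(np.sum((ages - ages.mean()) ** 2))
    fit_log = {
        "optimizer": "BFGS",
        "init": [init_a, init_b],
        "optimizer_solution": [float(opt.x[0]), float(opt.x[1])],
        "closed_form_solution": [a_ols, b_ols],
        "agreement": agree,
        "n_iter": int(opt.nit),
        "sigma2": s2,
        "se_a": float(np.sqrt(s2 * (1.0 / n + ages.mean() ** 2 / sxx))) if dof else None,
        "se_b": float(np.sqrt(s2 / sxx)) if dof else None,
        "weighting": "unweighted (common error variance on the log scale)",
    }
    return AgeModel(a=a_hat, b=b_hat, threshold=threshold,
                    depth_profile=depth_profile, panel_tag=panel_tag,
                    n_training=n, fit_log=fit_log)


def predict_phyloage(model: AgeModel, lambda_value: float) -> float:
    """Invert the model: phyloAge* = (log(λ) − a) / b.

    Negative predictions (very small λ in a young subject) are returned
    as-is, not clipped.  λ <= 0 raises :class:`BelowModelSupportError`.
    """
    if lambda_value <= 0:
        raise BelowModelSupportError(
            "decay metric is zero or negative: no retained variants, "
            "physiological age is below model support"
        )
    if model.b <= 0:
        raise ModelFitError("model slope b must be positive for inversion")
    return float((np.log(lambda_value) - model.a) / model.b)


def residual_age(model: AgeModel, lambda_value: float, age: float) -> float:
    """Excess physiological age: prediction minus chronological age."""
    return predict_phyloage(model, lambda_value) - age


@dataclass
class CalibrationResult:
    intercept: float
    slope: float
    r_squared: float
    ci_intercept: tuple[float, float]
    ci_slope: tuple[float, float]
    ci_r_squared: tuple[float, float]
    n_bootstrap: int
    seed: int


def calibration_regression(
    ages: Sequence[float],
    predictions: Sequence[float],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> CalibrationResult:
    """OLS of predicted on chronological ages with bootstrap percentile CIs.

    A perfectly calibrated predictor gives intercept 0 and slope 1.
    Bootstrap resampling is over individuals, seeded.
    """
    ages = np.asarray(ages, dtype=float)
    preds = np.asarray(predictions, dtype=float)
    if len(ages) != len(preds):
        raise ValueError("ages and predictions must have equal length")
    n = len(ages)
    if n < 3:
        raise ValueError("calibration regression requires at least 3 individuals")
    if np.ptp(ages) == 0:
        raise ValueError("zero variance in ages: regression undefined")
    res = stats.linregress(ages, preds)
    rng = np.random.default_rng(seed)
    boots = np.full((n_bootstrap, 3), np.nan)
    for i in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        if np.ptp(ages[idx]) == 0:
            continue
        b = stats.linregress(ages[idx], preds[idx])
        boots[i] = (b.intercept, b.slope, b.rvalue**2)
    ok = ~np.isnan(boots[:, 0])
    ci = np.nanpercentile(boots[ok], [2.5, 97.5], axis=0) if ok.any() else \
        np.full((2, 3), np.nan)
    return CalibrationResult(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        ci_intercept=(float(ci[0, 0]), float(ci[1, 0])),
        ci_slope=(float(ci[0, 1]), float(ci[1, 1])),
        ci_r_squared=(float(ci[0, 2]), float(ci[1, 2])),
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


@dataclass
class EvaluationReport:
    """Leave-one-out evaluation: per-individual residuals, overall and
    age-stratified errors, and a calibration regression."""

    per_individual: pd.DataFrame
    mae_overall: float
    rmse_overall: float
    strata: pd.DataFrame
    calibration: CalibrationResult | None
    fold_failures: list[dict] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.per_individual.to_csv(path, sep="\t", index=False)
        self.strata.to_csv(path.with_suffix(".strata.tsv"), sep="\t", index=False)


def _band_label(lo: float, hi: float) -> str:
    return f"{lo:g}-{hi:g}"


def loo_evaluate(
    cohort: "pd.DataFrame | Iterable[tuple[float, float]]",
    bands: Sequence[tuple[float, float]] = DEFAULT_AGE_BANDS,
    split_age: float = 65.0,
    init_a: float = 0.001,
    init_b: float = 0.3,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> EvaluationReport:
    """Leave-one-out evaluation of the decay–age model on a cohort.

    Each individual is predicted from a model fitted on the remaining
    individuals.  Errors are aggregated overall, over the configured age
    bands, and over a two-way young/old split at ``split_age``.  A fold whose
    refit fails is recorded in ``fold_failures`` rather than aborting the
    whole evaluation.
    """
    ages, lams, ids = _as_age_lambda(cohort)
    n = len(ages)
    if n < 4:
        raise ValueError(f"leave-one-out evaluation requires >= 4 individuals, got {n}")
    rows = []
    failures: list[dict] = []
    for i in range(n):
        rest = np.ones(n, dtype=bool)
        rest[i] = False
        try:
            model = fit_age_model(
                list(zip(ages[rest], lams[rest])),
                init_a=init_a, init_b=init_b, drop_nonpositive=True,
            )
            pred = predict_phyloage(model, lams[i])
        except (ModelFitError, BelowModelSupportError) as exc:
            failures.append({"sample_id": ids[i], "error": str(exc)})
            continue
        rows.append({"sample_id": ids[i], "age": ages[i],
                     "phyloage_star": pred, "residual": pred - ages[i]})
    per = pd.DataFrame(rows, columns=["sample_id", "age", "phyloage_star",
                                      "residual"])
    if per.empty:
        raise ModelFitError("every leave-one-out fold failed")
    abs_res = per["residual"].abs().to_numpy()
    mae = float(abs_res.mean())
    rmse = float(np.sqrt((per["residual"].to_numpy() ** 2).mean()))
    strata_rows = []
    # Contiguous right-closed intervals: ages between printed bands (e.g.
    # 30.5 for bands 0-30 / 31-45) fall in the higher band.
    sorted_bands = sorted(bands)
    boundaries = [sorted_bands[0][0]] + [hi for _, hi in sorted_bands]
    edges: list[tuple[float, float, str]] = [
        (boundaries[i], boundaries[i + 1], _band_label(*sorted_bands[i]))
        for i in range(len(sorted_bands))
    ]
    edges.append((-np.inf, split_age, f"<{split_age:g}"))
    edges.append((split_age, np.inf, f">={split_age:g}"))
    for k, (lo, hi, label) in enumerate(edges):
        if label.startswith("<"):
            mask = per["age"] < split_age
        elif label.startswith(">="):
            mask = per["age"] >= split_age
        elif k == 0:
            mask = (per["age"] >= lo) & (per["age"] <= hi)
        else:
            mask = (per["age"] > lo) & (per["age"] <= hi)
        sub = per.loc[mask, "residual"]
        strata_rows.append({
            "age_band": label,
            "n": int(mask.sum()),
            "rmse": float(np.sqrt((sub**2).mean())) if len(sub) else np.nan,
            "mae": float(sub.abs().mean()) if len(sub) else np.nan,
        })
    calib = None
    if len(per) >= 3 and np.ptp(per["age"].to_numpy()) > 0:
        calib = calibration_regression(per["age"], per["phyloage_star"],
                                       n_bootstrap=n_bootstrap, seed=seed)
    return EvaluationReport(per_individual=per, mae_overall=mae,
                            rmse_overall=rmse, strata=pd.DataFrame(strata_rows),
                            calibration=calib, fold_failures=failures)
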