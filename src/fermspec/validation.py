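"""Dataset splitting, internal cross-validation for latent-variable
selection, and the prediction metrics RMSEP and R2.

RMSEP = sqrt( (1/n) * sum_i (y_i - yhat_i)^2 )  on a held-out prediction set;
R2    = 1 - sum_i (y_i - yhat_i)^2 / sum_i (y_i - ybar)^2, with ybar the mean
of the reference values over the evaluated set itself.

The splitting protocol forces the samples attaining each analyte's minimum
and maximum reference value into the prediction set, so the calibration is
always evaluated across its full concentration range. Note the convention
kept here (after the source protocol): the *prediction* set is the larger
side of the split. Cross-validation defaults to contiguous blocks because
fermentation samples form a time series; fully random folds would let
neighbouring, strongly autocorrelated samples leak across the split.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .chemometrics import LinearModel, PLSRModel, fit_mlr, fit_pcr, fit_plsr
from .datasets import CalibrationDataset, FermspecError
from .preprocess import PreprocessPipeline


class ValidationError(FermspecError, ValueError):
    pass


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

def rmsep(y_ref: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean square error of prediction, in the units of y (g/L)."""
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_ref.size == 0:
        raise ValidationError("empty input")
    if y_ref.size != y_pred.size:
        raise ValidationError(
            f"length mismatch: {y_ref.size} reference vs {y_pred.size} predicted"
        )
    return float(np.sqrt(np.mean((y_ref - y_pred) ** 2)))


def r_squared(y_ref: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination against the evaluated set's own mean."""
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_ref.size != y_pred.size:
        raise ValidationError(
            f"length mismatch: {y_ref.size} reference vs {y_pred.size} predicted"
        )
    if y_ref.size < 2:
        raise ValidationError("need at least two samples for R2")
    ss_tot = float(np.sum((y_ref - y_ref.mean()) ** 2))
    if ss_tot == 0:
        raise ValidationError("reference values are constant; R2 undefined")
    ss_res = float(np.sum((y_ref - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


# --------------------------------------------------------------------------
# Splitting
# --------------------------------------------------------------------------

@dataclass
class SplitPlan:
    calibration_ids: list[str]
    prediction_ids: list[str]
    rule: str

    def __post_init__(self) -> None:
        if set(self.calibration_ids) & set(self.prediction_ids):
            raise ValidationError("calibration and prediction ids overlap")


def split_dataset(
    dataset: CalibrationDataset,
    prediction_fraction: float,
    paper_protocol: bool = True,
    seed: int = 0,
) -> SplitPlan:
    """Random calibration/prediction split at the stated fraction.

    With ``paper_protocol`` on, the samples attaining each analyte's min and
    max reference value are placed in the prediction set before the random
    assignment of the remainder, so every calibration is evaluated at the
    extremes of its range.
    """
    n = dataset.n_samples
    if n < 4:
        raise ValidationError("need at least 4 samples to split")
    if not (0.0 < prediction_fraction < 1.0):
        raise ValidationError("prediction_fraction must be in (0, 1)")
    n_pred = int(round(prediction_fraction * n))
    if n_pred == 0 or n_pred == n:
        raise ValidationError("fraction leaves an empty calibration or "
                              "prediction side")
    ids = dataset.sample_ids
    forced: list[int] = []
    if paper_protocol:
        seen: set[int] = set()
        for j, _analyte in enumerate(dataset.concentrations.analytes):
            col = dataset.concentrations.values[:, j]
            for i in (int(np.argmin(col)), int(np.argmax(col))):
                if i not in seen:
                    seen.add(i)
                    forced.append(i)
    if len(forced) > n_pred:
        warnings.warn(
            f"{len(forced)} extreme samples exceed the requested prediction "
            f"size {n_pred}; enlarging the prediction set", stacklevel=2,
        )
        n_pred = len(forced)
    rng = np.random.default_rng(seed)
    rest = [i for i in range(n) if i not in set(forced)]
    rng.shuffle(rest)
    pred_idx = sorted(forced + rest[: n_pred - len(forced)])
    cal_idx = sorted(set(range(n)) - set(pred_idx))
    rule = ("per-analyte extremes forced into prediction set"
            if paper_protocol else "uniform random")
    return SplitPlan([ids[i] for i in cal_idx], [ids[i] for i in pred_idx], rule)


# --------------------------------------------------------------------------
# Model specs and reports
# --------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Declarative model choice usable in CV and model comparison."""

    kind: str = "plsr"                      # plsr | pcr | mlr
    params: dict[str, Any] = field(default_factory=dict)
    name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("plsr", "pcr", "mlr"):
            raise ValidationError(f"unknown model kind {self.kind!r}")
        if self.name is None:
            extra = ",".join(f"{k}={v}" for k, v in self.params.items())
            self.name = self.kind + (f"({extra})" if extra else "")

    def fit(self, X: np.ndarray, y: np.ndarray,
            n_factors: int | None = None) -> PLSRModel | LinearModel:
        if self.kind == "plsr":
            k = n_factors or self.params.get("n_factors")
            if k is None:
                raise ValidationError("PLSR spec needs n_factors")
            return fit_plsr(X, y, int(k),
                            **{k2: v for k2, v in self.params.items()
                               if k2 in ("tol", "max_iter")})
        if self.kind == "pcr":
            k = n_factors or self.params.get("n_components")
            if k is None:
                raise ValidationError("PCR spec needs n_components")
            return fit_pcr(X, y, int(k))
        return fit_mlr(X, y)


@dataclass
class ValidationReport:
    """Per-analyte prediction metrics and (optionally) the RMSECV curve."""

    rmsep: dict[str, float] | None = None
    r2: dict[str, float] | None = None
    rmsecv_curve: pd.DataFrame | None = None   # index: n_factors, cols: analytes
    chosen_factors: dict[str, int] | None = None
    scheme: str = ""
    extras: dict[str, Any] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"scheme: {self.scheme}"] if self.scheme else []
        analytes = sorted((self.rmsep or self.chosen_factors or {}).keys())
        for a in analytes:
            parts = [a]
            if self.chosen_factors and a in self.chosen_factors:
                parts.append(f"k={self.chosen_factors[a]}")
            if self.rmsep and a in self.rmsep:
                parts.append(f"RMSEP={self.rmsep[a]:.4g} g/L")
            if self.r2 and a in self.r2:
                parts.append(f"R2={self.r2[a]:.4f}")
            lines.append("  " + "  ".join(parts))
        return "\n".join(lines)


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------

def _folds(n: int, scheme: str, n_blocks: int) -> list[np.ndarray]:
    if scheme == "leave_one_out":
        return [np.array([i]) for i in range(n)]
    if scheme == "contiguous_blocks":
        k = min(n_blocks, n)
        return [f for f in np.array_split(np.arange(n), k) if f.size]
    raise ValidationError(
        f"unknown CV scheme {scheme!r}; expected 'leave_one_out' or "
        "'contiguous_blocks'"
    )


def cross_validate(
    dataset: CalibrationDataset,
    model_spec: ModelSpec | None = None,
    max_factors: int = 10,
    scheme: str = "contiguous_blocks",
    n_blocks: int = 10,
    seed: int = 0,
    pipeline: PreprocessPipeline | None = None,
    parsimony_tol: float = 0.02,
) -> ValidationReport:
    """Internal cross-validation of the factor count, one analyte at a time.

    For each candidate factor count k = 1..``max_factors`` the model is
    refitted on every training fold (the preprocessing pipeline is refitted
    per fold, so no population-level state leaks from held-out samples) and
    the held-out residuals are pooled into RMSECV(k). The chosen factor
    count is the smallest k whose RMSECV lies within ``parsimony_tol``
    (default 2%) of the global minimum.
    """
    model_spec = model_spec or ModelSpec("plsr")
    if max_factors < 1:
        raise ValidationError("max_factors must be >= 1")
    n = dataset.n_samples
    folds = _folds(n, scheme, n_blocks)
    analytes = dataset.concentrations.analytes
    sq_err = {a: np.zeros(max_factors) for a in analytes}
    counts = np.zeros(max_factors)

    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        train = dataset.take(train_idx)
        test = dataset.take(test_idx)
        if pipeline is not None:
            fold_pipe = PreprocessPipeline.from_config(pipeline.to_config())
            train = fold_pipe.fit_transform(train)
            x_test = fold_pipe.transform(test.spectra).values
        else:
            x_test = test.spectra.values
        x_train = train.spectra.values
        feasible = min(train.n_samples - 1, x_train.shape[1])
        if max_factors > feasible:
            raise ValidationError(
                f"max_factors={max_factors} infeasible for a training fold of "
                f"{train.n_samples} samples x {x_train.shape[1]} wavelengths"
            )
        for a in analytes:
            y_train = train.concentrations.column(a)
            y_test = test.concentrations.column(a)
            for k in range(1, max_factors + 1):
                model = model_spec.fit(x_train, y_train, n_factors=k)
                pred = model.predict(x_test).ravel()
                sq_err[a][k - 1] += float(np.sum((y_test - pred) ** 2))
        counts += test_idx.size

    curve = pd.DataFrame(
        {a: np.sqrt(sq_err[a] / counts) for a in analytes},
        index=pd.RangeIndex(1, max_factors + 1, name="n_factors"),
    )
    chosen = {}
    for a in analytes:
        c = curve[a].to_numpy()
        threshold = (1.0 + parsimony_tol) * c.min()
        chosen[a] = int(np.flatnonzero(c <= threshold)[0]) + 1
    scheme_desc = scheme if scheme == "leave_one_out" else \
        f"{scheme}({len(folds)})"
    return ValidationReport(
        rmsecv_curve=curve, chosen_factors=chosen, scheme=scheme_desc,
        extras={"model": model_spec.name, "parsimony_tol": parsimony_tol},
    )


# --------------------------------------------------------------------------
# Evaluation and model comparison
# --------------------------------------------------------------------------

def fit_on_calibration(
    dataset: CalibrationDataset,
    split: SplitPlan,
    model_spec: ModelSpec,
    pipeline: PreprocessPipeline | None = None,
    n_factors: dict[str, int] | int | None = None,
) -> tuple[dict[str, Any], PreprocessPipeline | None]:
    """Fit one PLS1-style model per analyte on the calibration side only.

    Returns the per-analyte models and the pipeline fitted on calibration
    spectra (reused verbatim for prediction samples).
    """
    cal = dataset.subset_ids(split.calibration_ids)
    fitted_pipe = None
    if pipeline is not None:
        fitted_pipe = PreprocessPipeline.from_config(pipeline.to_config())
        cal = fitted_pipe.fit_transform(cal)
    models: dict[str, Any] = {}
    for a in cal.concentrations.analytes:
        k = n_factors.get(a) if isinstance(n_factors, dict) else n_factors
        models[a] = model_spec.fit(
            cal.spectra.values, cal.concentrations.column(a), n_factors=k
        )
    return models, fitted_pipe


def evaluate_model(
    models: dict[str, Any],
    dataset: CalibrationDataset,
    split: SplitPlan,
    pipeline: PreprocessPipeline | None = None,
) -> ValidationReport:
    """RMSEP and R2 on the prediction side, per analyte.

    ``models`` must have been fitted on the calibration side only (see
    :func:`fit_on_calibration`); this function never refits. The report also
    carries R2 pooled over calibration + prediction samples in ``extras``.
    """
    unknown = set(split.prediction_ids) - set(dataset.sample_ids)
    if unknown:
        raise ValidationError(f"split references unknown ids: {sorted(unknown)}")
    pred_ds = dataset.subset_ids(split.prediction_ids)
    full_ds = dataset.subset_ids(
        list(split.calibration_ids) + list(split.prediction_ids))
    x_pred = (pipeline.transform(pred_ds.spectra).values
              if pipeline is not None else pred_ds.spectra.values)
    x_full = (pipeline.transform(full_ds.spectra).values
              if pipeline is not None else full_ds.spectra.values)
    out_rmsep: dict[str, float] = {}
    out_r2: dict[str, float] = {}
    pooled_r2: dict[str, float] = {}
    for a, model in models.items():
        y_ref = pred_ds.concentrations.column(a)
        y_hat = model.predict(x_pred).ravel()
        out_rmsep[a] = rmsep(y_ref, y_hat)
        out_r2[a] = r_squared(y_ref, y_hat)
        pooled_r2[a] = r_squared(full_ds.concentrations.column(a),
                                 model.predict(x_full).ravel())
    return ValidationReport(
        rmsep=out_rmsep, r2=out_r2, scheme="prediction-set holdout",
        extras={"r2_pooled": pooled_r2, "rule": split.rule,
                "n_prediction": len(split.prediction_ids),
                "n_calibration": len(split.calibration_ids)},
    )


def compare_models(
    dataset: CalibrationDataset,
    model_specs: Sequence[ModelSpec],
    split: SplitPlan,
    pipeline: PreprocessPipeline | None = None,
) -> pd.DataFrame:
    """Fit and evaluate each spec; one row per (model, analyte), sorted by
    RMSEP within analyte. A failing spec contributes NaN rows with the error
    message instead of aborting the comparison."""
    if len(model_specs) < 2:
        raise ValidationError("need at least two model specs to compare")
    rows = []
    for spec in model_specs:
        try:
            models, fitted_pipe = fit_on_calibration(
                dataset, split, spec, pipeline)
            report = evaluate_model(models, dataset, split, fitted_pipe)
            for a in models:
                rows.append({"model": spec.name, "analyte": a,
                             "rmsep": report.rmsep[a], "r2": report.r2[a],
                             "error": ""})
        except Exception as exc:  # noqa: BLE001 - keep the table going
            for a in dataset.concentrations.analytes:
                rows.append({"model": spec.name, "analyte": a,
                             "rmsep": np.nan, "r2": np.nan,
                             "error": str(exc)})
    table = pd.DataFrame(rows)
    return table.sort_values(["analyte", "rmsep"]).reset_index(drop=True)
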