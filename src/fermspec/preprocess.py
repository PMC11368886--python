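"""Spectral pretreatments: region selection, Savitzky-Golay smoothing and
derivatives, standard normal variate (SNV), polynomial detrending, and a
PCA-based abnormal-sample screen, composable as an ordered pipeline.

Derivatives are segment-aware: once a wavelength interval (e.g. the
1350-1410 nm water-vapour band) has been excluded, the local polynomial
filter is applied per contiguous segment and never reaches across the gap.
Edge points that lack a full filter window are dropped, not padded.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .datasets import CalibrationDataset, FermspecError, SpectraSet


class PreprocessError(FermspecError, ValueError):
    pass


# --------------------------------------------------------------------------
# Individual transforms
# --------------------------------------------------------------------------

def select_region(
    spectra: SpectraSet,
    keep: Sequence[tuple[float, float]],
    drop: Sequence[tuple[float, float]] = (),
) -> SpectraSet:
    """Retain wavelengths inside a keep interval and outside every drop
    interval (intervals are closed). Contiguous-segment bookkeeping is
    refreshed so later derivative passes respect the new gaps."""
    if not keep:
        raise PreprocessError("keep intervals must be nonempty")
    for lo, hi in list(keep) + list(drop):
        if hi < lo:
            raise PreprocessError(f"interval ({lo}, {hi}) is not well ordered")
    lam = spectra.wavelengths
    mask = np.zeros(lam.size, dtype=bool)
    for lo, hi in keep:
        mask |= (lam >= lo) & (lam <= hi)
    for lo, hi in drop:
        mask &= ~((lam >= lo) & (lam <= hi))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise PreprocessError("region selection retained zero wavelengths")

    # new segments: split where retained indices are non-consecutive or where
    # an input segment boundary falls between them
    boundaries = {b for _, b in spectra.segments}
    segments: list[tuple[int, int]] = []
    start = 0
    for j in range(1, idx.size):
        if idx[j] != idx[j - 1] + 1 or any(
            idx[j - 1] < b <= idx[j] for b in boundaries
        ):
            segments.append((start, j))
            start = j
    segments.append((start, idx.size))
    return SpectraSet(lam[idx], spectra.values[:, idx], spectra.sample_ids,
                      tuple(segments))


def savgol(
    spectra: SpectraSet,
    window: int = 5,
    polyorder: int = 2,
    deriv: int = 1,
) -> SpectraSet:
    """Savitzky-Golay filtering per contiguous segment.

    Each output point is the ``deriv``-order derivative (per nm) of the local
    least-squares polynomial of degree ``polyorder`` fitted over ``window``
    points. ``deriv=0`` is pure smoothing. The ``(window-1)/2`` edge points
    of every segment are dropped because they lack a full window.
    """
    if window % 2 == 0:
        raise PreprocessError("window must be odd")
    if polyorder >= window:
        raise PreprocessError("window must exceed polyorder")
    if deriv > polyorder:
        raise PreprocessError("deriv must not exceed polyorder")
    half = (window - 1) // 2
    lam = spectra.wavelengths
    out_vals, out_lam, segments = [], [], []
    pos = 0
    for a, b in spectra.segments:
        if b - a < window:
            raise PreprocessError(
                f"segment [{lam[a]:.0f}, {lam[b-1]:.0f}] nm has {b - a} points, "
                f"fewer than the {window}-point window"
            )
        spacing = np.diff(lam[a:b])
        if not np.allclose(spacing, spacing[0], rtol=1e-8):
            raise PreprocessError("non-uniform spacing within a segment")
        filtered = savgol_filter(
            spectra.values[:, a:b], window, polyorder,
            deriv=deriv, delta=spacing[0], axis=1, mode="interp",
        )
        out_vals.append(filtered[:, half:b - a - half])
        out_lam.append(lam[a + half:b - half])
        n_kept = (b - a) - 2 * half
        segments.append((pos, pos + n_kept))
        pos += n_kept
    return SpectraSet(np.concatenate(out_lam), np.hstack(out_vals),
                      spectra.sample_ids, tuple(segments))


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: each spectrum centred to mean 0 and scaled
    to unit sample standard deviation (denominator n-1)."""
    if spectra.n_wavelengths < 2:
        raise PreprocessError("SNV needs at least two wavelengths")
    x = spectra.values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        names = [spectra.sample_ids[i] for i in bad]
        raise PreprocessError(f"constant spectrum (sd = 0) for sample(s) {names}")
    return spectra.with_values((x - mean) / sd)


def detrend(spectra: SpectraSet, degree: int = 1) -> SpectraSet:
    """Subtract, per spectrum, the least-squares polynomial of the given
    degree in wavelength; the output is the residual."""
    if degree < 0:
        raise PreprocessError("degree must be nonnegative")
    p = spectra.n_wavelengths
    if p <= degree + 1:
        raise PreprocessError(
            f"detrend degree {degree} under-determined with {p} wavelengths"
        )
    lam = spectra.wavelengths
    lam_norm = 2.0 * (lam - lam[0]) / (lam[-1] - lam[0]) - 1.0
    vander = np.vander(lam_norm, N=degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(vander, spectra.values.T, rcond=None)
    return spectra.with_values(spectra.values - (vander @ coef).T)


@dataclass
class OutlierReport:
    """Hotelling-T2 / Q-residual statistics for each sample."""

    table: pd.DataFrame        # columns: t2, q, flagged
    t2_limit: float
    q_limit: float

    @property
    def flagged_ids(self) -> list[str]:
        return list(self.table.index[self.table["flagged"]])


def outlier_filter(
    dataset: CalibrationDataset,
    n_components: int = 3,
    t2_limit: float = 0.99,
    q_limit: float = 0.99,
    margin: float = 2.0,
) -> tuple[np.ndarray, OutlierReport]:
    """Abnormal-sample screen in a PCA subspace of the spectra.

    Each sample is scored against the ``n_components`` principal-component
    subspace fitted *without* it (jackknife), so a gross outlier cannot mask
    itself by dragging the subspace toward its own direction. A sample is
    flagged when its Hotelling-T2 (leverage within the subspace) or Q
    residual (squared distance to the subspace) exceeds ``margin`` times the
    stated empirical quantile of the other samples' statistics; the margin
    (default 2) keeps the screen stable on clean data, where the top order
    statistic always sits slightly above any interpolated quantile. Returns
    a keep-mask (True = keep) and a per-sample report.
    """
    if not (0 < t2_limit <= 1 and 0 < q_limit <= 1):
        raise PreprocessError("quantile limits must lie in (0, 1]")
    if margin <= 0:
        raise PreprocessError("margin must be positive")
    x = dataset.spectra.values
    n, p = x.shape
    if n_components >= min(n - 1, p):
        raise PreprocessError(
            "n_components must be < min(n_samples - 1, n_wavelengths)")
    k = n_components
    t2 = np.empty(n)
    q = np.empty(n)
    for i in range(n):
        rest = np.delete(x, i, axis=0)
        mu = rest.mean(axis=0)
        _, s, vt = np.linalg.svd(rest - mu, full_matrices=False)
        basis = vt[:k]
        variances = s[:k] ** 2 / (n - 2)
        d = x[i] - mu
        scores = basis @ d
        t2[i] = float(np.sum(scores**2 / variances))
        q[i] = float(np.sum((d - basis.T @ scores) ** 2))
    def thresholds(stat: np.ndarray, limit: float) -> np.ndarray:
        if limit >= 1.0:     # the population maximum: nothing can exceed it
            return margin * np.full(n, stat.max())
        return margin * np.array(
            [np.quantile(np.delete(stat, i), limit) for i in range(n)])

    t2_thr = thresholds(t2, t2_limit)
    q_thr = thresholds(q, q_limit)
    flagged = (t2 > t2_thr) | (q > q_thr)
    report = OutlierReport(
        pd.DataFrame(
            {"t2": t2, "q": q, "flagged": flagged},
            index=pd.Index(dataset.sample_ids, name="sample_id"),
        ),
        float(np.median(t2_thr)), float(np.median(q_thr)),
    )
    return ~flagged, report


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

STEP_KINDS = ("select_region", "savgol", "snv", "detrend", "outlier_filter")


@dataclass
class PreprocessStep:
    kind: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in STEP_KINDS:
            raise PreprocessError(
                f"unknown step kind {self.kind!r}; expected one of {STEP_KINDS}"
            )
        if self.kind == "savgol":
            w = int(self.params.get("window", 5))
            o = int(self.params.get("polyorder", 2))
            if w % 2 == 0 or w <= o:
                raise PreprocessError("savgol window must be odd and > polyorder")
        if self.kind == "detrend" and int(self.params.get("degree", 1)) < 0:
            raise PreprocessError("detrend degree must be >= 0")


@dataclass
class PreprocessPipeline:
    """Ordered pretreatment chain with per-step fitted state.

    Sample-wise transforms (region selection, derivatives, SNV, detrend) are
    stateless and applied identically to calibration and new spectra. The
    outlier screen is population-level: :meth:`fit` removes flagged
    calibration samples and freezes the report; :meth:`transform` on new
    spectra skips it (screening prediction samples would silently change row
    alignment), which keeps a fitted pipeline exactly reproducible on its
    own calibration data.
    """

    steps: list[PreprocessStep] = field(default_factory=list)
    fitted_state: dict[int, Any] = field(default_factory=dict)

    def fit_transform(self, dataset: CalibrationDataset) -> CalibrationDataset:
        self.fitted_state = {}
        current = dataset
        for i, step in enumerate(self.steps):
            try:
                if step.kind == "outlier_filter":
                    mask, report = outlier_filter(current, **step.params)
                    self.fitted_state[i] = report
                    current = current.take(np.flatnonzero(mask))
                else:
                    current = CalibrationDataset(
                        _apply_step(step, current.spectra),
                        current.concentrations,
                        current.timestamps,
                    )
            except Exception as exc:
                raise PreprocessError(f"step {i} ({step.kind}): {exc}") from exc
        return current

    def transform(self, spectra: SpectraSet) -> SpectraSet:
        current = spectra
        for i, step in enumerate(self.steps):
            if step.kind == "outlier_filter":
                continue
            try:
                current = _apply_step(step, current)
            except Exception as exc:
                raise PreprocessError(f"step {i} ({step.kind}): {exc}") from exc
        return current

    def to_config(self) -> list[dict[str, Any]]:
        return [{"kind": s.kind, **s.params} for s in self.steps]

    @classmethod
    def from_config(cls, cfg: Sequence[dict[str, Any]]) -> "PreprocessPipeline":
        steps = []
        for entry in cfg:
            entry = dict(entry)
            kind = entry.pop("kind")
            steps.append(PreprocessStep(kind, entry))
        return cls(steps)


def _apply_step(step: PreprocessStep, spectra: SpectraSet) -> SpectraSet:
    if step.kind == "select_region":
        return select_region(spectra, **step.params)
    if step.kind == "savgol":
        return savgol(spectra, **step.params)
    if step.kind == "snv":
        return snv(spectra, **step.params)
    if step.kind == "detrend":
        return detrend(spectra, **step.params)
    raise PreprocessError(f"step kind {step.kind!r} not applicable to spectra")


def default_pipeline(
    *,
    include_snv: bool = True,
    deriv: int = 1,
    detrend_degree: int = 1,
    keep: Sequence[tuple[float, float]] = ((900.0, 1650.0),),
    drop: Sequence[tuple[float, float]] = ((1350.0, 1410.0),),
) -> PreprocessPipeline:
    """Standard chain: region selection (water band excluded), five-point
    second-order Savitzky-Golay first derivative, SNV, linear detrend."""
    steps = [
        PreprocessStep("select_region", {"keep": [tuple(k) for k in keep],
                                         "drop": [tuple(d) for d in drop]}),
        PreprocessStep("savgol", {"window": 5, "polyorder": 2, "deriv": deriv}),
    ]
    if include_snv:
        steps.append(PreprocessStep("snv", {}))
    steps.append(PreprocessStep("detrend", {"degree": detrend_degree}))
    return PreprocessPipeline(steps)
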