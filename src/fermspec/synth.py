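"""Synthetic fermentation trajectories and forward-modelled NIR spectra.

Three processes are emulated, in increasing order of broth complexity:

``la_batch``
    Batch L-lactic-acid fermentation by a homofermentative lactic-acid
    bacterium: logistic growth, Luedeking-Piret product formation, glucose
    drawdown from 250 g/L with no feeding. Optically the simplest broth.
``sg_fedbatch``
    Sodium-gluconate fermentation by a filamentous fungus: Monod-type glucose
    oxidation to gluconate, growth-linked ammonium and phosphate depletion.
    Mycelial broth, larger baseline drift.
``sls_multiphase``
    Sophorolipid fermentation by an oleaginous yeast on glucose plus rapeseed
    oil: glucose is pulse-fed on a 12 h schedule back into the 30-50 g/L
    window whenever it falls below 30 g/L; oil is fed continuously so the
    running level stays below 10 g/L. Gas-liquid-solid three-phase broth,
    the largest scatter and drift.

Spectra follow a Beer-Lambert forward model: per sample ``j``,

    A_j(lambda) = m_j * sum_i c_ij * eps_i(lambda)
                  + b_j(lambda) + d * solids_j + eta_j(lambda)

with a lognormal multiplicative scatter factor ``m_j``, a random low-order
polynomial baseline ``b_j``, an additive drift proportional to the suspended
solids load, and heteroscedastic Gaussian noise ``eta`` with extra variance
on the 1350-1410 nm water-vapour band. Pure-component absorptivities
``eps_i`` are sums of Gaussian bands drawn reproducibly from a seed; they are
synthetic stand-ins, not measured absorptivities of the real analytes.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import (
    CalibrationDataset,
    ConcentrationTable,
    SpectraSet,
    WavelengthGrid,
)

PROCESSES = ("la_batch", "sg_fedbatch", "sls_multiphase")

#: Per-process analyte calibration ranges (g/L) that generated trajectories
#: must respect end to end.
CALIBRATION_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "la_batch": {
        "glucose": (2.0, 256.0),
        "l_lactic_acid": (6.3, 156.0),
    },
    "sg_fedbatch": {
        "glucose": (2.0, 312.0),
        "sodium_gluconate": (49.33, 359.8),
        "ammonium": (0.38, 1.93),
        "phosphate": (1.97, 4.33),
    },
    "sls_multiphase": {
        "glucose": (8.34, 110.96),
        "sophorolipids": (3.59, 151.97),
        "rapeseed_oil": (0.57, 29.05),
    },
}

WATER_VAPOUR_BAND = (1350.0, 1410.0)


# --------------------------------------------------------------------------
# Pure component spectra
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PureComponentSpectrum:
    """Synthetic per-analyte absorptivity eps(lambda) as a sum of Gaussians.

    ``bands`` is a sequence of (center nm, width nm, amplitude AU*L/g)
    triples; ``path_coeff`` is a dimensionless path-length multiplier.
    """

    component_name: str
    bands: tuple[tuple[float, float, float], ...]
    path_coeff: float = 1.0

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("at least one band required")
        for c, w, a in self.bands:
            if w <= 0:
                raise ValueError("band widths must be positive")
            if a < 0:
                raise ValueError("band amplitudes must be nonnegative")

    def evaluate(self, grid: WavelengthGrid | np.ndarray) -> np.ndarray:
        lam = np.asarray(grid, dtype=float)
        eps = np.zeros_like(lam)
        for center, width, amp in self.bands:
            eps += amp * np.exp(-((lam - center) ** 2) / (2.0 * width**2))
        return self.path_coeff * eps


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 1.0
    return float(a @ b / (na * nb))


def generate_pure_spectra(
    components: Sequence[str],
    grid: WavelengthGrid,
    seed: int,
    *,
    max_similarity: float = 0.95,
    amplitude_scale: float | Mapping[str, float] = 0.004,
) -> list[PureComponentSpectrum]:
    """Draw one synthetic absorptivity spectrum per component.

    Each component receives 2-5 Gaussian bands with centers inside the grid
    span. Components are re-drawn until every pairwise cosine similarity of
    the evaluated spectra falls below ``max_similarity``, so the mixture
    problem stays well conditioned. ``amplitude_scale`` (AU*L/g) sets the
    typical band height, either globally or per component; the default keeps
    absorbances of order one at the concentration scale of fermentation
    broths (hundreds of g/L), and a per-component mapping lets trace
    analytes (ions at a few g/L) carry a detectable signal the way they do
    on a real instrument.
    """
    if not components:
        raise ValueError("component list must be nonempty")
    if len(set(components)) != len(components):
        raise ValueError("component names must be unique")
    rng = np.random.default_rng(seed)
    lo, hi = grid.span
    if hi <= lo:
        raise ValueError("degenerate wavelength grid")

    out: list[PureComponentSpectrum] = []
    vectors: list[np.ndarray] = []
    for name in components:
        scale = (amplitude_scale.get(name, 0.004)
                 if isinstance(amplitude_scale, Mapping) else amplitude_scale)
        for _attempt in range(200):
            n_bands = int(rng.integers(2, 6))
            centers = rng.uniform(lo, hi, size=n_bands)
            widths = rng.uniform(0.02, 0.12, size=n_bands) * (hi - lo)
            amps = scale * rng.lognormal(0.0, 0.4, size=n_bands)
            spec = PureComponentSpectrum(
                name, tuple(zip(centers, widths, amps))
            )
            vec = spec.evaluate(grid)
            if all(abs(_cosine(vec, v)) < max_similarity for v in vectors):
                out.append(spec)
                vectors.append(vec)
                break
        else:  # pragma: no cover - 200 redraws virtually never exhausted
            raise RuntimeError(f"could not draw a dissimilar spectrum for {name}")
    return out


# --------------------------------------------------------------------------
# Fermentation kinetics
# --------------------------------------------------------------------------

@dataclass
class FeedEvent:
    time: float          # h
    analyte: str
    amount: float        # g/L-equivalent added to the broth


@dataclass
class FermentationTrajectory:
    """Simulated time courses of broth composition.

    ``concentrations`` maps analyte name -> series (g/L) on ``times`` (h);
    ``solids_proxy`` aggregates biomass plus dispersed oil, the optically
    active suspended load.
    """

    process: str
    times: np.ndarray
    concentrations: dict[str, np.ndarray]
    solids_proxy: np.ndarray
    feed_events: list[FeedEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for name, series in self.concentrations.items():
            series = np.asarray(series, dtype=float)
            if series.size != self.times.size:
                raise ValueError(f"series {name!r} length mismatch")
            if np.any(series < 0):
                raise ValueError(f"negative concentration in series {name!r}")
            self.concentrations[name] = series
        self.solids_proxy = np.asarray(self.solids_proxy, dtype=float)

    @property
    def analytes(self) -> list[str]:
        return list(self.concentrations)

    def at_interval(self, interval: float) -> "FermentationTrajectory":
        """Subsample to one point per `interval` hours (off-line sampling)."""
        if interval <= 0:
            raise ValueError("sampling interval must be positive")
        keep = [0]
        next_t = self.times[0] + interval
        for i, t in enumerate(self.times):
            if t >= next_t - 1e-9:
                keep.append(i)
                next_t += interval
        idx = np.asarray(sorted(set(keep)))
        return FermentationTrajectory(
            self.process,
            self.times[idx],
            {k: v[idx] for k, v in self.concentrations.items()},
            self.solids_proxy[idx],
            list(self.feed_events),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.times}
        data.update(self.concentrations)
        data["solids_proxy"] = self.solids_proxy
        return pd.DataFrame(data)


@dataclass
class LABatchKinetics:
    """Batch lactic-acid fermentation: logistic growth + Luedeking-Piret."""

    mu: float = 0.25            # 1/h max specific growth rate
    x0: float = 0.5             # g/L inoculum biomass
    x_max: float = 12.0         # g/L carrying capacity
    alpha: float = 2.0          # g product / g biomass (growth-associated)
    beta: float = 0.15          # g product / (g biomass * h)
    yield_x: float = 0.5        # g biomass / g glucose
    yield_p: float = 0.62       # g lactate / g glucose
    glucose_0: float = 250.0
    product_0: float = 6.5
    glucose_floor: float = 2.0

    analytes = ("glucose", "l_lactic_acid")

    def initial_state(self) -> dict[str, float]:
        return {"X": self.x0, "glucose": self.glucose_0,
                "l_lactic_acid": self.product_0}

    def rates(self, s: Mapping[str, float]) -> dict[str, float]:
        if s["glucose"] <= self.glucose_floor:
            return {"X": 0.0, "glucose": 0.0, "l_lactic_acid": 0.0}
        dX = self.mu * s["X"] * (1.0 - s["X"] / self.x_max)
        dP = self.alpha * dX + self.beta * s["X"]
        dS = -(dX / self.yield_x + dP / self.yield_p)
        return {"X": dX, "glucose": dS, "l_lactic_acid": dP}


@dataclass
class SGFedBatchKinetics:
    """Gluconate fermentation: Monod glucose oxidation, nutrient depletion."""

    mu: float = 0.20
    x0: float = 1.0
    x_max: float = 15.0
    qs: float = 0.18            # g glucose / (g biomass * h)
    ks: float = 5.0             # g/L Monod constant
    yield_sg: float = 1.15      # g gluconate / g glucose (oxidative mass gain)
    glucose_0: float = 250.0
    sg_0: float = 49.5
    ammonium_0: float = 1.90
    ammonium_per_x: float = 0.10   # g NH4+ consumed per g biomass formed
    phosphate_0: float = 4.30
    phosphate_per_x: float = 0.16
    glucose_floor: float = 2.0

    analytes = ("glucose", "sodium_gluconate", "ammonium", "phosphate")

    def initial_state(self) -> dict[str, float]:
        return {
            "X": self.x0, "glucose": self.glucose_0,
            "sodium_gluconate": self.sg_0,
            "ammonium": self.ammonium_0, "phosphate": self.phosphate_0,
        }

    def rates(self, s: Mapping[str, float]) -> dict[str, float]:
        dX = self.mu * s["X"] * (1.0 - s["X"] / self.x_max)
        if s["glucose"] <= self.glucose_floor:
            uptake = 0.0
        else:
            uptake = self.qs * s["X"] * s["glucose"] / (s["glucose"] + self.ks)
        dN = -self.ammonium_per_x * dX if s["ammonium"] > 0.40 else 0.0
        dPh = -self.phosphate_per_x * dX if s["phosphate"] > 2.00 else 0.0
        return {
            "X": dX, "glucose": -uptake,
            "sodium_gluconate": self.yield_sg * uptake,
            "ammonium": dN, "phosphate": dPh,
        }


@dataclass
class SLsMultiphaseKinetics:
    """Sophorolipid fermentation on glucose + rapeseed oil.

    Glucose is checked every 12 h and pulse-fed back to ``glucose_target``
    whenever below ``glucose_low``; oil is fed continuously at a fraction of
    its instantaneous uptake, so the running level decays slowly and stays
    below 10 g/L after the initial transient.
    """

    mu: float = 0.15
    x0: float = 1.0
    x_max: float = 20.0
    qs: float = 0.045           # glucose uptake g/(g*h)
    ks: float = 3.0
    q_oil: float = 0.020        # oil uptake g/(g*h)
    k_oil: float = 0.5
    oil_feed_frac: float = 0.9  # continuous oil feed / instantaneous uptake
    y_sl_glc: float = 0.55      # g SLs / g glucose consumed
    y_sl_oil: float = 0.80      # g SLs / g oil consumed
    glucose_0: float = 100.0
    oil_0: float = 8.0
    sl_0: float = 3.7
    glucose_check_interval: float = 12.0   # h
    glucose_low: float = 30.0
    glucose_target: float = 45.0
    oil_floor: float = 0.6
    glucose_floor: float = 8.5

    analytes = ("glucose", "sophorolipids", "rapeseed_oil")

    def initial_state(self) -> dict[str, float]:
        return {
            "X": self.x0, "glucose": self.glucose_0,
            "sophorolipids": self.sl_0, "rapeseed_oil": self.oil_0,
        }

    def rates(self, s: Mapping[str, float]) -> dict[str, float]:
        dX = self.mu * s["X"] * (1.0 - s["X"] / self.x_max)
        if s["glucose"] <= self.glucose_floor:
            up_g = 0.0
        else:
            up_g = self.qs * s["X"] * s["glucose"] / (s["glucose"] + self.ks)
        up_o = self.q_oil * s["X"] * s["rapeseed_oil"] / (
            s["rapeseed_oil"] + self.k_oil)
        net_oil = (self.oil_feed_frac - 1.0) * up_o
        if s["rapeseed_oil"] <= self.oil_floor and net_oil < 0:
            net_oil = 0.0
        return {
            "X": dX,
            "glucose": -up_g,
            "rapeseed_oil": net_oil,
            "sophorolipids": self.y_sl_glc * up_g + self.y_sl_oil * up_o,
        }


KINETICS: dict[str, type] = {
    "la_batch": LABatchKinetics,
    "sg_fedbatch": SGFedBatchKinetics,
    "sls_multiphase": SLsMultiphaseKinetics,
}

#: Kinetic parameters given a mild reproducible batch-to-batch jitter so that
#: different seeds yield different but envelope-respecting runs.
_JITTERED = {
    "la_batch": ("mu", "beta", "yield_p"),
    "sg_fedbatch": ("mu", "qs", "yield_sg"),
    "sls_multiphase": ("mu", "qs", "q_oil"),
}
_JITTER_FRAC = 0.05


def default_durations(process: str) -> float:
    return {"la_batch": 72.0, "sg_fedbatch": 96.0, "sls_multiphase": 168.0}[process]


def simulate_process(
    process: str,
    params: Mapping[str, float] | None = None,
    duration: float | None = None,
    step: float = 0.5,
    seed: int = 0,
) -> FermentationTrajectory:
    """Integrate the named kinetic model and return its trajectory.

    Explicit-Euler integration at ``step`` hours; the SLs process applies its
    built-in 12 h glucose pulse-feed rule and logs each pulse as a
    :class:`FeedEvent`. Every analyte series is checked against its
    configured calibration range before returning.
    """
    key = process.lower()
    if key not in KINETICS:
        raise ValueError(f"unknown process {process!r}; expected one of {PROCESSES}")
    if duration is None:
        duration = default_durations(key)
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    if step <= 0:
        raise ValueError("step must be positive")

    rng = np.random.default_rng(seed)
    kin = KINETICS[key](**dict(params or {}))
    for name in _JITTERED[key]:
        setattr(kin, name,
                getattr(kin, name) * (1.0 + _JITTER_FRAC * rng.uniform(-1, 1)))

    n_steps = int(round(duration / step))
    times = step * np.arange(n_steps + 1)
    state = kin.initial_state()
    series: dict[str, list[float]] = {k: [v] for k, v in state.items()}
    feed_events: list[FeedEvent] = []

    check = getattr(kin, "glucose_check_interval", None)
    next_check = check if check is not None else np.inf

    for i in range(1, n_steps + 1):
        rates = kin.rates(state)
        for k in state:
            state[k] = max(state[k] + step * rates.get(k, 0.0), 0.0)
        t = times[i]
        if t >= next_check - 1e-9:
            if state["glucose"] < kin.glucose_low:
                amount = kin.glucose_target - state["glucose"]
                state["glucose"] += amount
                feed_events.append(FeedEvent(float(t), "glucose", float(amount)))
            next_check += check
        for k, v in state.items():
            series[k].append(v)

    conc = {k: np.asarray(v) for k, v in series.items() if k != "X"}
    biomass = np.asarray(series["X"])
    solids = biomass + conc.get("rapeseed_oil", 0.0)
    traj = FermentationTrajectory(key, times, conc, solids, feed_events)
    _check_envelopes(traj)
    return traj


def _check_envelopes(traj: FermentationTrajectory) -> None:
    ranges = CALIBRATION_RANGES.get(traj.process, {})
    for analyte, (lo, hi) in ranges.items():
        series = traj.concentrations.get(analyte)
        if series is None:
            continue
        if series.min() < lo - 1e-9 or series.max() > hi + 1e-9:
            raise RuntimeError(
                f"{traj.process}: {analyte} leaves its calibration range "
                f"[{lo}, {hi}] (observed [{series.min():.3g}, {series.max():.3g}])"
            )


# --------------------------------------------------------------------------
# Spectral forward model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Instrument and broth noise for the spectral forward model.

    All standard deviations are in absorbance units (AU).

    additive_sd
        White measurement noise per wavelength.
    baseline_poly_sd
        Per-degree sds of the random polynomial baseline coefficients
        (degree 0 first), evaluated on the wavelength axis normalised to
        [-1, 1]; models broth-dependent baseline drift.
    scatter_sd
        Log-scale sd of the per-sample multiplicative scatter factor.
    solids_drift_gain
        AU of additive drift per g/L of suspended solids.
    water_band_extra_sd
        Additional white-noise sd applied inside the 1350-1410 nm
        water-vapour band.
    """

    additive_sd: float = 0.002
    baseline_poly_sd: tuple[float, ...] = (0.01, 0.005)
    scatter_sd: float = 0.01
    solids_drift_gain: float = 0.0005
    water_band_extra_sd: float = 0.004

    def __post_init__(self) -> None:
        vals = (self.additive_sd, *self.baseline_poly_sd, self.scatter_sd,
                self.solids_drift_gain, self.water_band_extra_sd)
        if any(v < 0 for v in vals):
            raise ValueError("noise standard deviations must be nonnegative")

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(0.0, (0.0,), 0.0, 0.0, 0.0)


#: Default noise per process, ordered by broth complexity: the uniform
#: lactic-acid broth drifts least, the mycelial gluconate broth more, and
#: the three-phase sophorolipid broth most.
DEFAULT_NOISE: dict[str, NoiseModel] = {
    "la_batch": NoiseModel(
        additive_sd=0.002, baseline_poly_sd=(0.010, 0.005),
        scatter_sd=0.01, solids_drift_gain=0.0005, water_band_extra_sd=0.004,
    ),
    "sg_fedbatch": NoiseModel(
        additive_sd=0.003, baseline_poly_sd=(0.030, 0.015, 0.008),
        scatter_sd=0.03, solids_drift_gain=0.0010, water_band_extra_sd=0.006,
    ),
    "sls_multiphase": NoiseModel(
        additive_sd=0.004, baseline_poly_sd=(0.060, 0.030, 0.015),
        scatter_sd=0.06, solids_drift_gain=0.0020, water_band_extra_sd=0.008,
    ),
}


def synthesize_from_concentrations(
    concentrations: ConcentrationTable,
    pure: Sequence[PureComponentSpectrum],
    noise: NoiseModel,
    grid: WavelengthGrid,
    seed: int,
    *,
    solids: np.ndarray | None = None,
    timestamps: np.ndarray | None = None,
) -> CalibrationDataset:
    """Beer-Lambert forward model for an arbitrary concentration matrix."""
    by_name = {p.component_name: p for p in pure}
    missing = [a for a in concentrations.analytes if a not in by_name]
    if missing:
        raise ValueError(f"no pure spectrum for analyte(s) {missing}")
    lam = np.asarray(grid, dtype=float)
    eps = np.vstack([by_name[a].evaluate(lam) for a in concentrations.analytes])
    n = concentrations.n_samples
    if solids is None:
        solids = np.zeros(n)
    solids = np.asarray(solids, dtype=float)
    if solids.size != n:
        raise ValueError("one solids value per sample required")

    rng = np.random.default_rng(seed)
    clean = concentrations.values @ eps                      # (n, p)
    m = np.exp(rng.normal(0.0, noise.scatter_sd, size=n)) if noise.scatter_sd \
        else np.ones(n)
    lam_norm = (2.0 * (lam - lam[0]) / (lam[-1] - lam[0])) - 1.0
    vander = np.vander(lam_norm, N=len(noise.baseline_poly_sd), increasing=True)
    coeffs = rng.normal(0.0, 1.0, size=(n, len(noise.baseline_poly_sd)))
    coeffs *= np.asarray(noise.baseline_poly_sd)
    baseline = coeffs @ vander.T
    eta = rng.normal(0.0, 1.0, size=(n, lam.size)) * noise.additive_sd
    if noise.water_band_extra_sd:
        band = (lam >= WATER_VAPOUR_BAND[0]) & (lam <= WATER_VAPOUR_BAND[1])
        eta[:, band] += (rng.normal(0.0, 1.0, size=(n, int(band.sum())))
                         * noise.water_band_extra_sd)
    values = (m[:, None] * clean + baseline
              + noise.solids_drift_gain * solids[:, None] + eta)

    ids = [f"s{i:04d}" for i in range(n)]
    if concentrations.sample_ids != ids:
        ids = concentrations.sample_ids
    spectra = SpectraSet(lam, values, ids)
    conc = ConcentrationTable(concentrations.analytes, concentrations.values, ids)
    return CalibrationDataset(spectra, conc, timestamps)


def synthesize_spectra(
    traj: FermentationTrajectory,
    pure: Sequence[PureComponentSpectrum],
    noise: NoiseModel,
    grid: WavelengthGrid,
    seed: int,
) -> CalibrationDataset:
    """One synthetic spectrum per trajectory time point.

    Rows are aligned to ``traj.times`` (stored as dataset timestamps); the
    trajectory's solids proxy drives the additive solids drift term.
    """
    n = traj.times.size
    ids = [f"s{i:04d}" for i in range(n)]
    conc = ConcentrationTable(
        traj.analytes,
        np.column_stack([traj.concentrations[a] for a in traj.analytes]),
        ids,
    )
    return synthesize_from_concentrations(
        conc, pure, noise, grid, seed,
        solids=traj.solids_proxy, timestamps=traj.times,
    )
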