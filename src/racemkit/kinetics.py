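"""Racemization kinetics: observables, rate-constant extraction, and
physiological predictions.

Two directions of travel share this module.

*Analysis* goes from measurements to a second-order rate constant: fit a
pseudo-first-order constant k_obs to a decay trace (loss of ellipticity by
CD, or H/D exchange by NMR), correct it for parallel hydrolysis, and regress
k_obs against the concentration of the basic buffer component — the slope of
that buffer-dilution plot is the general-base catalytic constant k_gb
(M^-1 s^-1).  Corrections for reaction temperature (Arrhenius) and for the
fraction of substrate in the reactive protonation state bring constants
measured under lab conditions onto a common scale.

*Prediction* goes the other way: a k_gb (from a calibration line) times the
catalytic base concentration of a physiological scenario gives k_obs, hence
a racemization half-life and the fraction racemized after a given exposure.
The default scenario models blood as a 0.15 M phosphate buffer at pH 7.2
(phosphate pKa2 = 6.80 at physiological ionic strength, so about 0.107 M
dibasic phosphate), with a 24 h exposure window.

Racemization here means loss of enantiomeric excess: ee(t) = ee(0) *
exp(-k_obs t), fraction racemized = 1 - exp(-k_obs t), and half-life =
ln 2 / k_obs is the time for the ee to halve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BufferSpec",
    "KineticTrace",
    "RateMeasurement",
    "ExposureScenario",
    "RacemizationPrediction",
    "BLOOD_EQUIVALENT_BUFFER",
    "PHYSIOLOGICAL_SCENARIO",
    "GAS_CONSTANT_KCAL",
    "base_concentration",
    "fit_first_order",
    "correct_hydrolysis",
    "extract_kgb",
    "protonation_correction",
    "temperature_correction",
    "racemized_fraction",
    "half_life",
    "classify_risk",
    "predict",
    "DEFAULT_RISK_THRESHOLDS",
]

GAS_CONSTANT_KCAL = 1.987204258640832e-3  # kcal / (mol K)


@dataclass(frozen=True)
class BufferSpec:
    """A single-ionization buffer characterized by total concentration, pH and
    the pKa of the conjugate acid of the catalytic base."""

    total_concentration: float  # M
    ph: float
    pka: float
    temperature_K: float = 310.15

    def __post_init__(self) -> None:
        if self.total_concentration <= 0:
            raise ValueError("total_concentration must be positive")
        if not 0 < self.ph < 14:
            raise ValueError("pH must lie in (0, 14)")


#: Blood-equivalent buffer: 0.15 M phosphate, pH 7.2, phosphate pKa2 6.80, 37 C.
BLOOD_EQUIVALENT_BUFFER = BufferSpec(
    total_concentration=0.15, ph=7.2, pka=6.80, temperature_K=310.15
)


@dataclass
class KineticTrace:
    """A time series of a racemization observable.

    kind="cd_decay": ellipticity (mdeg) decaying to a baseline.
    kind="hd_exchange": deuterium fraction rising to a plateau.
    """

    times_s: np.ndarray
    signal: np.ndarray
    kind: str = "cd_decay"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, float)
        self.signal = np.asarray(self.signal, float)
        if self.times_s.size < 5:
            raise ValueError("a kinetic trace needs at least 5 points")
        if self.times_s.size != self.signal.size:
            raise ValueError("times and signal must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times_s < 0):
            raise ValueError("times must be >= 0")
        if self.kind not in ("cd_decay", "hd_exchange"):
            raise ValueError(f"unknown trace kind {self.kind!r}")


@dataclass(frozen=True)
class RateMeasurement:
    """One buffer-dilution point: k_obs at a known catalytic base concentration."""

    base_concentration: float  # M
    k_obs: float  # s^-1
    k_obs_se: float = 0.0  # s^-1

    def __post_init__(self) -> None:
        if self.k_obs < 0:
            raise ValueError("k_obs must be >= 0")
        if self.k_obs_se < 0:
            raise ValueError("k_obs_se must be >= 0")


@dataclass(frozen=True)
class ExposureScenario:
    buffer: BufferSpec = BLOOD_EQUIVALENT_BUFFER
    duration_s: float = 86400.0
    # (ea_kcal_mol, t_obs_K) to move k_gb from the calibration temperature to
    # the scenario temperature; None applies the calibration as-is
    arrhenius: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.duration_s) or self.duration_s < 0:
            raise ValueError("duration must be finite and >= 0")


#: 24 h in blood-equivalent buffer — the default physiological exposure.
PHYSIOLOGICAL_SCENARIO = ExposureScenario()

DEFAULT_RISK_THRESHOLDS = {"low": 0.01, "medium": 0.10}


@dataclass(frozen=True)
class RacemizationPrediction:
    log_kgb: float
    kgb_bounds: tuple[float, float]
    k_obs: float
    half_life_s: float
    fraction_racemized: float
    risk_class: str


def base_concentration(buffer: BufferSpec) -> float:
    """Concentration of the catalytic (deprotonated) buffer species.

    Henderson-Hasselbalch with a single relevant ionization:
    [B] = C_total / (1 + 10^(pKa - pH)).
    """
    return buffer.total_concentration / (1.0 + 10.0 ** (buffer.pka - buffer.ph))


def _exp_decay(t, baseline, amplitude, k):
    return baseline + amplitude * np.exp(-k * t)


def _exp_rise(t, plateau, k):
    return plateau * (1.0 - np.exp(-k * t))


def fit_first_order(trace: KineticTrace) -> dict:
    """Nonlinear least-squares fit of a pseudo-first-order rate constant.

    cd_decay:    signal(t) = baseline + amplitude * exp(-k t)
    hd_exchange: signal(t) = plateau * (1 - exp(-k t))

    Initial guesses are seeded analytically (log-linear regression on the
    baseline-subtracted signal) so convergence is reproducible.  Returns
    k_obs, amplitude, baseline and the standard error of k_obs from the fit
    covariance.
    """
    t, y = trace.times_s, trace.signal
    if np.ptp(y) == 0:
        raise ValueError("constant signal: no kinetics to fit")

    if trace.kind == "hd_exchange":
        plateau0 = y[-1] if y[-1] != 0 else y.max()
        # log-linear seed on 1 - y/plateau
        frac = 1.0 - y / plateau0
        mask = frac > 1e-12
        k0 = 1.0 / max(t[-1], 1e-30)
        if mask.sum() >= 2:
            sl = stats.linregress(t[mask], np.log(frac[mask])).slope
            if sl < 0:
                k0 = -sl
        try:
            popt, pcov = optimize.curve_fit(
                _exp_rise, t, y, p0=[plateau0, k0],
                bounds=([-np.inf, 0.0], [np.inf, np.inf]), maxfev=20000,
            )
        except RuntimeError as exc:
            raise RuntimeError(
                f"first-order fit did not converge (initial guess plateau={plateau0:g}, "
                f"k={k0:g}): {exc}"
            ) from exc
        plateau, k = popt
        k_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else math.nan
        return {
            "k_obs": float(k),
            "amplitude": float(plateau),
            "baseline": 0.0,
            "k_obs_se": k_se,
        }

    baseline0 = y[-1]
    amplitude0 = y[0] - baseline0
    if amplitude0 == 0:
        amplitude0 = np.ptp(y)
    shifted = (y - baseline0) / amplitude0
    mask = shifted > 1e-12
    k0 = 1.0 / max(t[-1], 1e-30)
    if mask.sum() >= 2:
        sl = stats.linregress(t[mask], np.log(shifted[mask])).slope
        if sl < 0:
            k0 = -sl
    try:
        popt, pcov = optimize.curve_fit(
            _exp_decay, t, y, p0=[baseline0, amplitude0, k0],
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"first-order fit did not converge (initial guess baseline={baseline0:g}, "
            f"amplitude={amplitude0:g}, k={k0:g}): {exc}"
        ) from exc
    baseline, amplitude, k = popt
    k_se = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else math.nan
    return {
        "k_obs": float(k),
        "amplitude": float(amplitude),
        "baseline": float(baseline),
        "k_obs_se": k_se,
    }


def correct_hydrolysis(
    k_obs_total: float,
    k_hydrolysis: float,
    k_obs_se: float = 0.0,
    k_hydrolysis_se: float = 0.0,
) -> float:
    """Subtract a parallel first-order hydrolysis channel from the observed rate.

    A small negative difference within the combined uncertainty floors at 0
    with a warning; a difference more negative than the combined standard
    errors is unphysical and raises.
    """
    if k_obs_total < 0 or k_hydrolysis < 0:
        raise ValueError("rate constants must be >= 0")
    diff = k_obs_total - k_hydrolysis
    if diff >= 0:
        return diff
    tolerance = math.hypot(k_obs_se, k_hydrolysis_se)
    if -diff <= tolerance:
        warnings.warn(
            "hydrolysis rate exceeds total rate within noise; flooring corrected rate at 0"
        )
        return 0.0
    raise ValueError(
        f"hydrolysis rate {k_hydrolysis:g} exceeds total rate {k_obs_total:g} "
        f"beyond the combined uncertainty {tolerance:g}"
    )


def extract_kgb(measurements: Sequence[RateMeasurement]) -> dict:
    """Buffer-dilution plot: OLS of k_obs against [base].

    slope = k_gb (M^-1 s^-1), intercept = buffer-independent background
    (water/hydroxide pathways).  A negative slope is returned as-is with a
    ``negative_slope`` warning flag rather than clipped.
    """
    if len(measurements) < 3:
        raise ValueError(f"need >= 3 measurements, got {len(measurements)}")
    conc = np.array([m.base_concentration for m in measurements])
    kobs = np.array([m.k_obs for m in measurements])
    if np.unique(conc).size < 2:
        raise ValueError("need >= 2 distinct base concentrations")
    res = stats.linregress(conc, kobs)
    if res.slope < 0:
        warnings.warn("negative buffer-dilution slope: no detectable general-base catalysis")
    return {
        "kgb": float(res.slope),
        "intercept": float(res.intercept),
        "kgb_se": float(res.stderr),
        "intercept_se": float(res.intercept_stderr),
        "negative_slope": bool(res.slope < 0),
    }


def protonation_correction(kgb_apparent: float, reactive_fraction: float) -> float:
    """Scale an apparent k_gb to the reactive protonation state.

    If only a fraction of the substrate is in the deprotonatable form, the
    intrinsic constant is the apparent one divided by that fraction.
    """
    if not 0 < reactive_fraction <= 1:
        raise ValueError("reactive_fraction must lie in (0, 1]")
    return kgb_apparent / reactive_fraction


def temperature_correction(
    k: float, t_obs_K: float, t_ref_K: float, ea_kcal_mol: float
) -> float:
    """Arrhenius transfer of a rate constant from t_obs_K to t_ref_K:
    k_ref = k * exp((Ea/R) (1/t_obs - 1/t_ref))."""
    if t_obs_K <= 0 or t_ref_K <= 0:
        raise ValueError("temperatures must be positive (K)")
    if not math.isfinite(ea_kcal_mol):
        raise ValueError("activation energy must be finite")
    return k * math.exp(
        (ea_kcal_mol / GAS_CONSTANT_KCAL) * (1.0 / t_obs_K - 1.0 / t_ref_K)
    )


def _scenario_k_obs(kgb: float, scenario: ExposureScenario) -> float:
    if kgb < 0:
        raise ValueError("k_gb must be >= 0")
    k = kgb
    if scenario.arrhenius is not None:
        ea, t_obs = scenario.arrhenius
        k = temperature_correction(k, t_obs, scenario.buffer.temperature_K, ea)
    return k * base_concentration(scenario.buffer)


def racemized_fraction(kgb: float, scenario: ExposureScenario = PHYSIOLOGICAL_SCENARIO) -> float:
    """Fraction of the enantiomeric excess lost over the scenario's exposure:
    1 - exp(-k_gb [base] t)."""
    k_obs = _scenario_k_obs(kgb, scenario)
    return float(-math.expm1(-k_obs * scenario.duration_s))


def half_life(k_obs: float) -> float:
    """ln 2 / k_obs; infinite when k_obs is 0."""
    if k_obs < 0:
        raise ValueError("k_obs must be >= 0")
    return math.inf if k_obs == 0 else math.log(2.0) / k_obs


def classify_risk(
    fraction_racemized: float,
    thresholds: Mapping[str, float] = DEFAULT_RISK_THRESHOLDS,
) -> str:
    """Bucket a predicted fraction racemized into low / medium / high.

    Defaults: < 1% low, 1-10% medium (upper bound inclusive), > 10% high.
    """
    if not 0 <= fraction_racemized <= 1:
        raise ValueError("fraction_racemized must lie in [0, 1]")
    low = thresholds.get("low", DEFAULT_RISK_THRESHOLDS["low"])
    med = thresholds.get("medium", DEFAULT_RISK_THRESHOLDS["medium"])
    if not 0 <= low <= med <= 1:
        raise ValueError(f"malformed risk thresholds: low={low}, medium={med}")
    if fraction_racemized < low:
        return "low"
    if fraction_racemized <= med:
        return "medium"
    return "high"


def predict(
    log_kgb: float,
    rmse: float = 0.0,
    scenario: ExposureScenario = PHYSIOLOGICAL_SCENARIO,
    thresholds: Mapping[str, float] = DEFAULT_RISK_THRESHOLDS,
) -> RacemizationPrediction:
    """Full prediction chain from a log10 k_gb (with calibration RMSE) to a
    physiological racemization risk summary."""
    kgb = 10.0**log_kgb
    f = 10.0**rmse
    k_obs = _scenario_k_obs(kgb, scenario)
    frac = float(-math.expm1(-k_obs * scenario.duration_s))
    return RacemizationPrediction(
        log_kgb=log_kgb,
        kgb_bounds=(kgb / f, kgb * f),
        k_obs=k_obs,
        half_life_s=half_life(k_obs),
        fraction_racemized=frac,
        risk_class=classify_risk(frac, thresholds),
    )
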