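"""Seeded synthetic kinetic data with known ground truth.

Every fitting pathway in the package (exponential trace fits,
buffer-dilution plots, calibration-line refits) can be exercised against
data whose generating parameters are known exactly.  Generators are pure
functions of their parameters and seed — the same call always returns
byte-identical arrays — and embed the ground truth in their return value so
round-trip tests never have to re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import CalibrationDataset, CalibrationLine, CalibrationPoint
from .kinetics import KineticTrace, RateMeasurement

__all__ = ["FixtureSpec", "gen_trace", "gen_buffer_series", "gen_calibration_dataset"]


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducibility envelope for a generator: seed, noise model, size."""

    seed: int = 0
    noise_sigma: float = 0.0  # 0 disables noise
    n_points: int = 50

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_trace(
    k_obs: float,
    amplitude: float = 100.0,
    baseline: float = 0.0,
    spec: FixtureSpec = FixtureSpec(),
    kind: str = "cd_decay",
) -> tuple[KineticTrace, dict]:
    """Synthetic first-order decay (or exchange) trace.

    Times are log-spaced over [0, 5/k_obs] — five half-life-scales, dense at
    early times where the decay carries most information — with Gaussian
    observational noise of sd ``spec.noise_sigma`` on the signal.  Returns
    (trace, ground_truth).
    """
    if k_obs <= 0:
        raise ValueError("k_obs must be positive")
    if spec.n_points < 5:
        raise ValueError("a kinetic trace needs at least 5 points")
    horizon = 5.0 / k_obs
    # log-spaced interior + t=0 anchor
    times = np.concatenate(
        [[0.0], np.geomspace(horizon / 200.0, horizon, spec.n_points - 1)]
    )
    if kind == "hd_exchange":
        clean = amplitude * (1.0 - np.exp(-k_obs * times))
    else:
        clean = baseline + amplitude * np.exp(-k_obs * times)
    noise = (
        spec.rng().normal(0.0, spec.noise_sigma, times.size)
        if spec.noise_sigma > 0
        else np.zeros_like(times)
    )
    trace = KineticTrace(times_s=times, signal=clean + noise, kind=kind)
    truth = {
        "k_obs": k_obs,
        "amplitude": amplitude,
        "baseline": baseline,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
    }
    return trace, truth


def gen_buffer_series(
    kgb: float,
    intercept: float,
    concentrations: Sequence[float],
    spec: FixtureSpec = FixtureSpec(),
    relative_noise: bool = False,
) -> tuple[list[RateMeasurement], dict]:
    """Synthetic buffer-dilution series: k_obs = intercept + kgb*[B] + noise.

    The default noise is homoscedastic — Gaussian sd equal to ``noise_sigma``
    times the mean clean k_obs of the series — matching the equal-variance
    assumption of the OLS analysis these series feed.  ``relative_noise``
    switches to per-point proportional scatter (sd = noise_sigma * clean
    k_obs) for stress-testing heteroscedastic data.
    """
    conc = np.asarray(list(concentrations), float)
    if np.unique(conc).size < 2:
        raise ValueError("need >= 2 distinct concentrations")
    clean = intercept + kgb * conc
    rng = spec.rng()
    if relative_noise:
        sd = spec.noise_sigma * np.abs(clean)
    else:
        sd = np.full_like(clean, spec.noise_sigma * float(np.mean(np.abs(clean))))
    if spec.noise_sigma > 0:
        noisy = clean + rng.normal(0.0, 1.0, conc.size) * sd
    else:
        noisy = clean
    noisy = np.clip(noisy, 0.0, None)  # measured first-order constants are non-negative
    meas = [
        RateMeasurement(base_concentration=float(c), k_obs=float(k), k_obs_se=float(s))
        for c, k, s in zip(conc, noisy, sd)
    ]
    truth = {"kgb": kgb, "intercept": intercept, "seed": spec.seed}
    return meas, truth


def gen_calibration_dataset(
    line: CalibrationLine,
    n_classes: int = 12,
    members_per_class: int = 2,
    noise_sigma: float = 0.39,
    spec: FixtureSpec = FixtureSpec(),
    x_range: tuple[float, float] = (-75.0, -35.0),
) -> tuple[CalibrationDataset, dict]:
    """Synthetic calibration data mimicking a center-type-classed rate/energy plot.

    Class centers are drawn uniformly over ``x_range`` (kcal/mol); members of
    a class share the class x up to a small deterministic offset, and each
    member's log k carries Gaussian noise of sd ``noise_sigma`` log units
    about the line.
    """
    if n_classes < 2:
        raise ValueError("need >= 2 classes")
    if members_per_class < 1:
        raise ValueError("need >= 1 member per class")
    rng = spec.rng()
    lo, hi = x_range
    centers = rng.uniform(lo, hi, n_classes)
    points = []
    for ci, cx in enumerate(centers):
        offsets = np.linspace(-0.5, 0.5, members_per_class) if members_per_class > 1 else [0.0]
        for off in offsets:
            x = float(cx + off)
            y = line.slope * x + line.intercept
            if noise_sigma > 0:
                y += float(rng.normal(0.0, noise_sigma))
            points.append(
                CalibrationPoint(x_kcal_mol=x, log_kgb=float(y), class_label=f"class{ci}")
            )
    truth = {"slope": line.slope, "intercept": line.intercept, "seed": spec.seed}
    return CalibrationDataset(points=points), truth
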