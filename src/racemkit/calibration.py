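"""Calibrated linear free-energy relationships: deprotonation energy -> log k_gb.

Second-order rate constants for general-base-catalyzed racemization
correlate linearly with computed deprotonation energies.  Three calibration
lines are shipped, each of the form

    log10(k_gb / M^-1 s^-1) = slope * x + intercept,

where x is the deprotonation energy in kcal/mol:

=================  =========================================  ======  =========  =====  ====
domain             x                                          slope   intercept  RMSE   R^2
=================  =========================================  ======  =========  =====  ====
qm                 full quantum-chemical ddG(R1,R2,R3)        -0.20   -14.28     0.61   0.68
gc_nonaromatic     sigma-ddG, non-aromatic carbanions         -0.11    -9.81     0.40   0.78
gc_aromatic        sigma-ddG, cyclic aromatic carbanions      -0.26   -16.95     0.39   0.92
=================  =========================================  ======  =========  =====  ====

The RMSE (log units) expresses the prediction uncertainty as a
multiplicative factor 10^RMSE on k_gb (about 4-fold for the QM line).

Refitting utilities mirror how the shipped lines were built: ordinary least
squares, optionally after collapsing all representatives of one center-type
class to their (mean x, mean log k) so no class dominates the fit, and
honoring per-point exclusion flags.  A Hammett helper compares sigma vs
sigma-minus correlations of a reaction series — a better sigma-minus fit
indicates negative-charge buildup conjugated to the ring in the transition
state.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationLine",
    "CalibrationDataset",
    "CalibrationPoint",
    "HammettSeries",
    "SHIPPED_LINES",
    "predict_log_kgb",
    "fit_line",
    "prediction_interval",
    "fit_hammett",
]


@dataclass(frozen=True)
class CalibrationLine:
    """One log10(k_gb) vs energy line with its fit diagnostics."""

    domain: str  # qm | gc_nonaromatic | gc_aromatic | user
    slope: float  # log10(M^-1 s^-1) per kcal/mol
    intercept: float  # log10(M^-1 s^-1)
    rmse: float  # log units
    r2: float

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "CalibrationLine":
        return cls(**json.loads(text))


SHIPPED_LINES: dict[str, CalibrationLine] = {
    "qm": CalibrationLine("qm", slope=-0.20, intercept=-14.28, rmse=0.61, r2=0.68),
    "gc_nonaromatic": CalibrationLine(
        "gc_nonaromatic", slope=-0.11, intercept=-9.81, rmse=0.40, r2=0.78
    ),
    "gc_aromatic": CalibrationLine(
        "gc_aromatic", slope=-0.26, intercept=-16.95, rmse=0.39, r2=0.92
    ),
}


@dataclass(frozen=True)
class CalibrationPoint:
    x_kcal_mol: float
    log_kgb: float
    class_label: str = ""
    excluded: bool = False


@dataclass
class CalibrationDataset:
    points: list[CalibrationPoint]

    @classmethod
    def from_csv(cls, path) -> "CalibrationDataset":
        df = pd.read_csv(path)
        pts = [
            CalibrationPoint(
                x_kcal_mol=float(r["x_kcal_mol"]),
                log_kgb=float(r["log_kgb"]),
                class_label=str(r.get("class_label", "")) if "class_label" in df.columns else "",
                excluded=bool(r["excluded"]) if "excluded" in df.columns else False,
            )
            for _, r in df.iterrows()
        ]
        return cls(points=pts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(p) for p in self.points])


def predict_log_kgb(x: float, line: CalibrationLine) -> float:
    """Evaluate the line: log10 k_gb at deprotonation energy ``x`` (kcal/mol)."""
    if not math.isfinite(x):
        raise ValueError(f"deprotonation energy must be finite, got {x}")
    return line.slope * x + line.intercept


def prediction_interval(
    log_kgb: float, line: CalibrationLine
) -> tuple[float, float, float]:
    """(k_low, k_point, k_high) in M^-1 s^-1; bounds are k_point / f and k_point * f
    with the multiplicative uncertainty factor f = 10^RMSE."""
    k_point = 10.0**log_kgb
    f = 10.0**line.rmse
    return (k_point / f, k_point, k_point * f)


def _aggregate_by_class(df: pd.DataFrame) -> pd.DataFrame:
    # points sharing a class label collapse to their mean x / mean y;
    # unlabeled points stay individual
    labeled = df[df["class_label"] != ""]
    unlabeled = df[df["class_label"] == ""]
    means = (
        labeled.groupby("class_label", as_index=False)[["x_kcal_mol", "log_kgb"]].mean()
        if len(labeled)
        else labeled
    )
    return pd.concat([means[["x_kcal_mol", "log_kgb"]], unlabeled[["x_kcal_mol", "log_kgb"]]])


def fit_line(
    data: CalibrationDataset,
    aggregate_by_class: bool = False,
    domain: str = "user",
    rmse_ddof: int = 0,
) -> CalibrationLine:
    """OLS refit of a calibration line.

    ``aggregate_by_class`` replaces all points of one class by their mean
    before fitting so that heavily replicated classes cannot dominate.
    Excluded points never enter the fit.  The RMSE divides by n - rmse_ddof
    (default n, the plain root-mean-square residual).
    """
    df = data.to_frame()
    df = df[~df["excluded"]]
    if aggregate_by_class:
        df = _aggregate_by_class(df)
    x = df["x_kcal_mol"].to_numpy(float)
    y = df["log_kgb"].to_numpy(float)
    if len(x) < 2:
        raise ValueError(f"need >= 2 points after aggregation/exclusion, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: cannot fit a line")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    n = len(x)
    if n - rmse_ddof <= 0:
        raise ValueError("rmse_ddof too large for dataset size")
    rmse = float(np.sqrt(np.sum(resid**2) / (n - rmse_ddof)))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationLine(
        domain=domain,
        slope=float(res.slope),
        intercept=float(res.intercept),
        rmse=rmse,
        r2=r2,
    )


@dataclass(frozen=True)
class HammettEntry:
    substituent: str
    sigma: float
    sigma_minus: float
    log_k: float


@dataclass
class HammettSeries:
    entries: list[HammettEntry]

    @classmethod
    def from_csv(cls, path) -> "HammettSeries":
        df = pd.read_csv(path)
        return cls(
            entries=[
                HammettEntry(
                    substituent=str(r["substituent"]),
                    sigma=float(r["sigma"]),
                    sigma_minus=float(r["sigma_minus"]),
                    log_k=float(r["log_k"]),
                )
                for _, r in df.iterrows()
            ]
        )


def _ols_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)


def fit_hammett(series: HammettSeries) -> dict:
    """Fit log k against sigma and sigma-minus; report both rho values and
    which scale correlates better.

    A higher R^2 for sigma-minus (with positive rho) is the kinetic signature
    of an S_E1-type mechanism: negative charge develops on the benzylic
    center and is delocalized into the ring in the rate-determining
    deprotonation.
    """
    if len(series.entries) < 3:
        raise ValueError(f"need >= 3 substituents for a Hammett fit, got {len(series.entries)}")
    sig = np.array([e.sigma for e in series.entries])
    sig_m = np.array([e.sigma_minus for e in series.entries])
    logk = np.array([e.log_k for e in series.entries])
    rho_s, r2_s = _ols_r2(sig, logk)
    rho_sm, r2_sm = _ols_r2(sig_m, logk)
    if r2_sm == r2_s:
        warnings.warn(
            "sigma and sigma-minus fit equally well; preferring sigma_minus by convention"
        )
        preferred = "sigma_minus"
    else:
        preferred = "sigma_minus" if r2_sm > r2_s else "sigma"
    return {
        "rho_sigma": rho_s,
        "r2_sigma": r2_s,
        "rho_sigma_minus": rho_sm,
        "r2_sigma_minus": r2_sm,
        "preferred": preferred,
    }
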