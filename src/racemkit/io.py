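"""CSV dialects, configuration, and report writing.

All tabular interchange goes through pandas with fixed, documented headers:

- SMILES input: one SMILES per line, optionally ``SMILES<TAB>identifier``;
  blank lines and ``#`` comments ignored.
- Kinetic trace: ``time_s,signal``.
- Buffer series: ``base_concentration_M,k_obs_s,k_obs_se``.
- Calibration dataset: ``x_kcal_mol,log_kgb,class_label,excluded``.
- Hammett series: ``substituent,sigma,sigma_minus,log_k``.
- Prediction report: ``identifier,center,center_type,sigma_ddg,log_kgb,
  k_low,k_high,k_obs,half_life_h,frac_racemized_24h,pct_racemized,risk``
  (percent rounded to one decimal; the raw fraction is kept alongside).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .kinetics import (
    BLOOD_EQUIVALENT_BUFFER,
    DEFAULT_RISK_THRESHOLDS,
    BufferSpec,
    ExposureScenario,
    KineticTrace,
    RateMeasurement,
)

__all__ = [
    "RunConfig",
    "read_smiles_file",
    "read_trace_csv",
    "write_trace_csv",
    "read_buffer_series_csv",
    "write_buffer_series_csv",
    "write_report",
    "read_report",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = [
    "identifier",
    "center",
    "center_type",
    "sigma_ddg",
    "log_kgb",
    "k_low",
    "k_high",
    "k_obs",
    "half_life_h",
    "frac_racemized_24h",
    "pct_racemized",
    "risk",
]


@dataclass
class RunConfig:
    """Workflow configuration; the defaults reproduce the physiological
    screening scenario (0.15 M phosphate pH 7.2, pKa2 6.80, 37 C, 24 h)."""

    group_table_path: str | None = None
    pattern_file_path: str | None = None
    calibration: str = "shipped"  # "shipped" or a JSON file of lines
    buffer: BufferSpec = field(default_factory=lambda: BLOOD_EQUIVALENT_BUFFER)
    duration_s: float = 86400.0
    risk_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_RISK_THRESHOLDS))
    strict_mode: bool = False
    cross_conjugation_factor: float = 0.5
    cross_conjugation_mode: str = "scale_all_but_strongest"
    seed: int = 0

    def scenario(self) -> ExposureScenario:
        return ExposureScenario(buffer=self.buffer, duration_s=self.duration_s)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text) or {}
        buf = doc.pop("buffer", None)
        cfg = cls(**{k: v for k, v in doc.items() if k in cls.__dataclass_fields__})
        if buf is not None:
            cfg.buffer = BufferSpec(
                total_concentration=float(buf.get("total_concentration", 0.15)),
                ph=float(buf.get("ph", 7.2)),
                pka=float(buf.get("pka", 6.80)),
                temperature_K=float(buf.get("temperature_K", 310.15)),
            )
        return cfg


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """(smiles, identifier) pairs; identifier defaults to the SMILES itself."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smiles = parts[0].strip()
        ident = parts[1].strip() if len(parts) > 1 and parts[1].strip() else smiles
        out.append((smiles, ident))
    return out


def read_trace_csv(path: str | Path, kind: str = "cd_decay") -> KineticTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "signal"):
        if col not in df.columns:
            raise ValueError(f"trace CSV {path}: missing column {col!r}")
    return KineticTrace(
        times_s=df["time_s"].to_numpy(float), signal=df["signal"].to_numpy(float), kind=kind
    )


def write_trace_csv(trace: KineticTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times_s, "signal": trace.signal}).to_csv(path, index=False)


def read_buffer_series_csv(path: str | Path) -> list[RateMeasurement]:
    df = pd.read_csv(path)
    for col in ("base_concentration_M", "k_obs_s"):
        if col not in df.columns:
            raise ValueError(f"buffer-series CSV {path}: missing column {col!r}")
    has_se = "k_obs_se" in df.columns
    return [
        RateMeasurement(
            base_concentration=float(r["base_concentration_M"]),
            k_obs=float(r["k_obs_s"]),
            k_obs_se=float(r["k_obs_se"]) if has_se else 0.0,
        )
        for _, r in df.iterrows()
    ]


def write_buffer_series_csv(measurements: Sequence[RateMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        {
            "base_concentration_M": [m.base_concentration for m in measurements],
            "k_obs_s": [m.k_obs for m in measurements],
            "k_obs_se": [m.k_obs_se for m in measurements],
        }
    ).to_csv(path, index=False)


def write_report(rows: Sequence[Mapping], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(list(rows), columns=REPORT_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"report {path}: missing columns {sorted(missing)}")
    return df
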