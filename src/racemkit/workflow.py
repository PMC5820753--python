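"""End-to-end screening: structure (or energy score) -> risk report rows.

This is the triage workflow as a library: the cheap group-contribution score
flags compounds whose predicted physiological racemization is fast enough to
matter, so that expensive quantum-chemical refinement and experiments are
spent only where the risk is real.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .calibration import SHIPPED_LINES, CalibrationLine, predict_log_kgb, prediction_interval
from .groups import CrossConjugationPolicy, GroupContributionTable, sigma_ddg_for_molecule
from .io import RunConfig
from .kinetics import ExposureScenario, predict
from .structures import MoleculeRecord, load_pattern_rules

__all__ = ["predict_from_energy", "predict_molecule", "predict_batch"]

logger = logging.getLogger(__name__)


def _line_for(domain: str, config: RunConfig | None = None) -> CalibrationLine:
    if domain not in SHIPPED_LINES:
        raise ValueError(
            f"unknown calibration domain {domain!r}; expected one of {sorted(SHIPPED_LINES)}"
        )
    return SHIPPED_LINES[domain]


def _row(identifier, center, center_type, sigma_ddg, line, scenario, thresholds):
    log_kgb = predict_log_kgb(sigma_ddg, line)
    k_low, _, k_high = prediction_interval(log_kgb, line)
    pred = predict(log_kgb, rmse=line.rmse, scenario=scenario, thresholds=thresholds)
    return {
        "identifier": identifier,
        "center": center,
        "center_type": center_type,
        "sigma_ddg": sigma_ddg,
        "log_kgb": pred.log_kgb,
        "k_low": k_low,
        "k_high": k_high,
        "k_obs": pred.k_obs,
        "half_life_h": pred.half_life_s / 3600.0,
        "frac_racemized_24h": pred.fraction_racemized,
        "pct_racemized": round(100.0 * pred.fraction_racemized, 1),
        "risk": pred.risk_class,
    }


def predict_from_energy(
    energy_kcal_mol: float,
    domain: str = "gc_nonaromatic",
    scenario: ExposureScenario | None = None,
    thresholds: Mapping[str, float] | None = None,
    identifier: str = "",
) -> dict:
    """One report row from a precomputed energy score.

    ``domain`` picks the calibration line: "qm" expects a full
    ddG(R1,R2,R3); "gc_nonaromatic"/"gc_aromatic" expect a sigma-ddG.
    """
    from .kinetics import DEFAULT_RISK_THRESHOLDS, PHYSIOLOGICAL_SCENARIO

    line = _line_for(domain)
    return _row(
        identifier or f"x={energy_kcal_mol:g}",
        center=-1,
        center_type="",
        sigma_ddg=energy_kcal_mol,
        line=line,
        scenario=scenario or PHYSIOLOGICAL_SCENARIO,
        thresholds=thresholds or DEFAULT_RISK_THRESHOLDS,
    )


def predict_molecule(
    record: MoleculeRecord,
    table: GroupContributionTable | None = None,
    policy: CrossConjugationPolicy | None = None,
    config: RunConfig | None = None,
) -> list[dict]:
    """Report rows for every candidate stereocenter of one molecule.

    The calibration line is chosen per center: the aromatic-anion line when
    deprotonation gives a cyclic aromatic anion, the non-aromatic line
    otherwise.
    """
    cfg = config or RunConfig()
    if table is None:
        table = (
            GroupContributionTable.from_csv(cfg.group_table_path)
            if cfg.group_table_path
            else GroupContributionTable.builtin()
        )
    if policy is None:
        policy = CrossConjugationPolicy(
            factor=cfg.cross_conjugation_factor, mode=cfg.cross_conjugation_mode
        )
    rules = load_pattern_rules(cfg.pattern_file_path)
    scenario = cfg.scenario()
    rows = []
    for report, score in sigma_ddg_for_molecule(
        record, table, policy, strict=cfg.strict_mode, rules=rules
    ):
        domain = "gc_aromatic" if report.aromatic_anion else "gc_nonaromatic"
        rows.append(
            _row(
                record.identifier,
                center=report.atom_index,
                center_type=report.center_type_code,
                sigma_ddg=score.value_kcal_mol,
                line=_line_for(domain),
                scenario=scenario,
                thresholds=cfg.risk_thresholds,
            )
        )
    return rows


def predict_batch(
    pairs: Sequence[tuple[str, str]],
    config: RunConfig | None = None,
) -> tuple[list[dict], int]:
    """Screen (smiles, identifier) pairs; returns (rows, n_failed).

    One unparsable SMILES never aborts the batch: the failure is logged with
    its identifier and counted.
    """
    cfg = config or RunConfig()
    table = (
        GroupContributionTable.from_csv(cfg.group_table_path)
        if cfg.group_table_path
        else GroupContributionTable.builtin()
    )
    policy = CrossConjugationPolicy(
        factor=cfg.cross_conjugation_factor, mode=cfg.cross_conjugation_mode
    )
    rows: list[dict] = []
    n_failed = 0
    for smiles, ident in pairs:
        record = MoleculeRecord.from_smiles(smiles, ident)
        if record.parse_status != "ok":
            logger.error("failed to parse SMILES for %r: %r", ident, smiles)
            n_failed += 1
            continue
        rows.extend(predict_molecule(record, table=table, policy=policy, config=cfg))
    return rows, n_failed
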