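"""Group-contribution carbanion-stabilization scores (sigma-delta-delta-G).

Each substituent type R carries a group contribution ddG(R,H,H): the aqueous
deprotonation free-energy difference (kcal/mol) of the model compound
R-CH3 relative to methane, i.e. how much R stabilizes an adjacent carbanion.
A stereocenter's score is the sum over its three non-H substituents,

    sigma_ddg = ddG(R1,H,H) + ddG(R2,H,H) + ddG(R3,H,H),

with a cross-conjugation correction: when two or three substituents stabilize
the anion by charge delocalization, the second (and third) delocalizing
group cannot stabilize as effectively as the first, so every delocalizing
contribution other than the strongest is scaled by a factor in [0,1]
(default 0.5).  Non-delocalizing (inductive) groups always count in full.

The shipped contribution table is provisional (placeholder magnitudes in a
chemically sensible order); quantitative work should load a table of
quantum-chemically computed values via :func:`GroupContributionTable.from_csv`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .structures import MoleculeRecord, StereocenterReport, analyze_molecule

__all__ = [
    "GroupContributionTable",
    "CrossConjugationPolicy",
    "SigmaDdg",
    "sum_ddg",
    "sigma_ddg_for_molecule",
]

logger = logging.getLogger(__name__)


class GroupTableError(KeyError):
    """A substituent label has no entry in the contribution table (strict mode)."""


@dataclass(frozen=True)
class GroupEntry:
    ddg_kcal_mol: float
    delocalizing: bool


@dataclass
class GroupContributionTable:
    """Map of substituent type label -> (ddG(R,H,H) in kcal/mol, delocalizing flag)."""

    entries: dict[str, GroupEntry]
    provenance: str = ""

    def __post_init__(self) -> None:
        for label, e in self.entries.items():
            if not math.isfinite(e.ddg_kcal_mol):
                raise ValueError(f"non-finite ddG for {label!r}")

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def __getitem__(self, label: str) -> GroupEntry:
        return self.entries[label]

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, tuple[float, bool]], provenance: str = ""
    ) -> "GroupContributionTable":
        return cls(
            entries={k: GroupEntry(float(v[0]), bool(v[1])) for k, v in mapping.items()},
            provenance=provenance,
        )

    @classmethod
    def from_csv(cls, path) -> "GroupContributionTable":
        df = pd.read_csv(path)
        required = {"type_label", "ddg_kcal_mol", "delocalizing"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"group table {path}: missing columns {sorted(missing)}")
        entries = {}
        for _, row in df.iterrows():
            deloc = row["delocalizing"]
            if isinstance(deloc, str):
                deloc = deloc.strip().lower() in ("true", "1", "yes")
            entries[str(row["type_label"])] = GroupEntry(float(row["ddg_kcal_mol"]), bool(deloc))
        prov = ""
        if "provenance" in df.columns and len(df):
            prov = str(df["provenance"].iloc[0])
        return cls(entries=entries, provenance=prov)

    @classmethod
    def from_json(cls, path) -> "GroupContributionTable":
        with open(path) as fh:
            doc = json.load(fh)
        return cls.from_mapping(
            {k: (v["ddg_kcal_mol"], v["delocalizing"]) for k, v in doc["entries"].items()},
            provenance=doc.get("provenance", ""),
        )

    @classmethod
    def builtin(cls) -> "GroupContributionTable":
        """The shipped provisional table."""
        with resources.as_file(
            resources.files("racemkit.data").joinpath("group_contributions.csv")
        ) as p:
            return cls.from_csv(p)

    def to_csv(self, path) -> None:
        rows = [
            {
                "type_label": k,
                "ddg_kcal_mol": e.ddg_kcal_mol,
                "delocalizing": e.delocalizing,
                "provenance": self.provenance,
            }
            for k, e in self.entries.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class CrossConjugationPolicy:
    """How to down-weight the 2nd+ charge-delocalizing substituent.

    mode="scale_all_but_strongest": the most stabilizing (most negative ddG)
    delocalizing group counts in full; every other delocalizing group's ddG
    is multiplied by ``factor``.  mode="none" disables the correction.
    """

    factor: float = 0.5
    mode: str = "scale_all_but_strongest"

    def __post_init__(self) -> None:
        if not 0.0 <= self.factor <= 1.0:
            raise ValueError("cross-conjugation factor must lie in [0, 1]")
        if self.mode not in ("scale_all_but_strongest", "none"):
            raise ValueError(f"unknown cross-conjugation mode {self.mode!r}")


@dataclass(frozen=True)
class SigmaDdg:
    """A stereocenter's summed stabilization score with its bookkeeping."""

    value_kcal_mol: float
    corrected: bool
    contributions: tuple[tuple[str, float, float], ...]  # (label, raw, applied)


def _resolve(
    labels: Sequence[str], table: GroupContributionTable, strict: bool
) -> list[tuple[str, float, bool]]:
    out = []
    for label in labels:
        if label in table:
            e = table[label]
            out.append((label, e.ddg_kcal_mol, e.delocalizing))
        elif strict:
            raise GroupTableError(f"no group contribution for substituent type {label!r}")
        else:
            logger.warning(
                "no group contribution for %r; substituting 0 kcal/mol (lenient mode)", label
            )
            out.append((label, 0.0, False))
    return out


def sum_ddg(
    labels: Sequence[str],
    table: GroupContributionTable,
    policy: CrossConjugationPolicy = CrossConjugationPolicy(),
    strict: bool = True,
) -> SigmaDdg:
    """Cross-conjugation-corrected sum of three group contributions.

    With at most one delocalizing group the result is the plain sum.  With
    two or more, the strongest (most negative ddG; ties broken by
    lexicographic type label for reproducibility) keeps full weight and the
    rest are scaled by ``policy.factor``.
    """
    if len(labels) != 3:
        raise ValueError(f"expected exactly 3 substituent labels, got {len(labels)}")
    resolved = _resolve(labels, table, strict)
    deloc = [(ddg, label) for label, ddg, d in resolved if d]
    apply_correction = policy.mode != "none" and len(deloc) >= 2
    full_weight_label = None
    if apply_correction:
        # strongest stabilizer = most negative ddG; lexicographic label breaks ties
        full_weight_label = min(deloc, key=lambda t: (t[0], t[1]))[1]
    contributions = []
    used_full = False
    for label, raw, d in resolved:
        applied = raw
        if apply_correction and d:
            if label == full_weight_label and not used_full:
                used_full = True  # only one instance keeps full weight on duplicates
            else:
                applied = policy.factor * raw
        contributions.append((label, raw, applied))
    value = math.fsum(c[2] for c in contributions)
    return SigmaDdg(
        value_kcal_mol=value,
        corrected=apply_correction,
        contributions=tuple(contributions),
    )


def sigma_ddg_for_molecule(
    mol: MoleculeRecord,
    table: GroupContributionTable,
    policy: CrossConjugationPolicy = CrossConjugationPolicy(),
    strict: bool = True,
    rules=None,
    overrides=None,
) -> list[tuple[StereocenterReport, SigmaDdg]]:
    """Score every candidate stereocenter of a molecule.

    Per-center failures (e.g. a missing table entry in strict mode) are
    logged and skipped so one bad center never aborts the rest.
    """
    out = []
    for report in analyze_molecule(mol, rules=rules, overrides=overrides):
        try:
            score = sum_ddg(
                [s.type_label for s in report.substituents], table, policy, strict=strict
            )
        except GroupTableError as exc:
            logger.error(
                "molecule %r center %d: %s", mol.identifier, report.atom_index, exc
            )
            continue
        out.append((report, score))
    return out
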