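"""Perception and classification of racemization-prone stereogenic C-H centers.

A stereogenic carbon bearing exactly one hydrogen can racemize by
general-base-catalyzed deprotonation: the base removes the alpha H, the
resulting carbanion is planar (or rapidly inverting), and reprotonation is
not stereospecific.  The first step of risk assessment is therefore purely
structural — find every carbon that (a) carries exactly one hydrogen and
(b) has four mutually distinguishable substituents, then classify the three
non-H substituents into a controlled vocabulary of substituent types and the
resulting triple into one of fourteen named center types (A-N).

Substituent classification is rule-based: an ordered list of single-atom
recursive SMARTS patterns, each anchored at the neighbor atom as seen from
the center.  The first matching rule wins; a neighbor matching no rule is
labelled ``other``.  The built-in rule file covers the substituent types of
the center-type catalogue and can be replaced or extended by a user pattern
file with the same schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

from rdkit import Chem
from rdkit.Chem import FindMolChiralCenters

__all__ = [
    "MoleculeRecord",
    "SubstituentAssignment",
    "StereocenterReport",
    "SubstituentRule",
    "load_pattern_rules",
    "load_center_types",
    "find_candidate_stereocenters",
    "classify_substituent",
    "assign_center_type",
    "assess_aromatic_anion",
    "analyze_molecule",
    "TYPE_VOCABULARY",
]

#: Controlled vocabulary for substituent type labels.
TYPE_VOCABULARY = frozenset(
    {
        "alkyl",
        "phenyl",
        "ester",
        "reversed_secondary_amide",
        "acidic_secondary_amide",
        "primary_amide",
        "five_membered_aromatic",
        "ketone",
        "carboxylic_acid",
        "thioether",
        "imide",
        "dialkyl_tertiary_amine",
        "primary_amine",
        "reversed_secondary_thioamide",
        "aminothiooxo_imide",
        "other",
    }
)


class StructureError(ValueError):
    """Raised for parse failures and contract violations on molecular input."""


@dataclass
class MoleculeRecord:
    """A molecule parsed from SMILES.

    ``parse_status`` is ``"ok"`` when RDKit accepted the SMILES; the RDKit
    ``Mol`` is kept on the record so downstream operations never re-parse.
    """

    identifier: str
    smiles: str
    parse_status: str = "failed"
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_smiles(cls, smiles: str, identifier: str | None = None) -> "MoleculeRecord":
        ident = identifier if identifier else smiles
        if not ident:
            raise StructureError("molecule identifier must be non-empty")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return cls(identifier=ident, smiles=smiles, parse_status="failed")
        return cls(identifier=ident, smiles=smiles, parse_status="ok", mol=mol)

    def require_ok(self) -> Chem.Mol:
        if self.parse_status != "ok" or self.mol is None:
            raise StructureError(
                f"molecule {self.identifier!r}: SMILES {self.smiles!r} failed to parse"
            )
        return self.mol


@dataclass(frozen=True)
class SubstituentAssignment:
    """One classified non-H substituent of a stereocenter."""

    neighbor_atom_index: int
    type_label: str
    matched_rule_id: str

    def __post_init__(self) -> None:
        if self.type_label not in TYPE_VOCABULARY:
            raise StructureError(f"unknown type label {self.type_label!r}")
        if self.type_label == "other" and self.matched_rule_id != "fallback":
            # user rule files may map custom patterns onto "other" deliberately;
            # only the built-in contract insists on the fallback marker
            pass


@dataclass(frozen=True)
class StereocenterReport:
    """A candidate stereogenic C-H center with its classified substituents."""

    atom_index: int
    h_count: int
    substituents: tuple[SubstituentAssignment, SubstituentAssignment, SubstituentAssignment]
    center_type_code: str
    aromatic_anion: bool

    def __post_init__(self) -> None:
        if self.h_count != 1:
            raise StructureError("stereocenter must carry exactly one hydrogen")
        if len(self.substituents) != 3:
            raise StructureError("stereocenter must have exactly three non-H substituents")

    @property
    def type_labels(self) -> tuple[str, str, str]:
        return tuple(sorted(s.type_label for s in self.substituents))  # type: ignore[return-value]


@dataclass(frozen=True)
class SubstituentRule:
    rule_id: str
    smarts: str
    type_label: str
    delocalizing: bool
    pattern: Chem.Mol = field(compare=False, repr=False, default=None)


def _compile_rule(raw: Mapping) -> SubstituentRule:
    patt = Chem.MolFromSmarts(raw["smarts"])
    if patt is None:
        raise StructureError(f"rule {raw['rule_id']!r}: invalid SMARTS {raw['smarts']!r}")
    if patt.GetNumAtoms() < 1:
        raise StructureError(f"rule {raw['rule_id']!r}: empty pattern")
    return SubstituentRule(
        rule_id=raw["rule_id"],
        smarts=raw["smarts"],
        type_label=raw["type_label"],
        delocalizing=bool(raw["delocalizing"]),
        pattern=patt,
    )


def load_pattern_rules(path: str | None = None) -> list[SubstituentRule]:
    """Load classification rules, in application order, from ``path`` or the built-in file."""
    if path is None:
        text = resources.files("racemkit.data").joinpath("substituent_patterns.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = json.loads(text)
    raw_rules = doc["rules"] if isinstance(doc, dict) else doc
    return [_compile_rule(r) for r in raw_rules]


def load_center_types(path: str | None = None) -> dict[str, tuple[str, str, str]]:
    """Center-type catalogue: letter code -> sorted triple of type labels."""
    if path is None:
        text = resources.files("racemkit.data").joinpath("center_types.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = json.loads(text)
    return {code: tuple(sorted(labels)) for code, labels in doc["types"].items()}


def load_aromatic_anion_overrides(path: str | None = None) -> dict[str, bool]:
    if path is None:
        text = resources.files("racemkit.data").joinpath("center_types.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return dict(json.loads(text).get("aromatic_anion_overrides", {}))


def find_candidate_stereocenters(mol: MoleculeRecord) -> list[int]:
    """Atom indices of tetrahedral carbons with exactly one H and four distinguishable branches.

    Centers are reported whether or not stereochemistry is drawn in the input:
    racemization risk attaches to the center itself, not to the depiction.
    Indices are returned in ascending order.
    """
    m = mol.require_ok()
    if m.GetNumAtoms() == 0:
        return []
    found = FindMolChiralCenters(
        m, includeUnassigned=True, useLegacyImplementation=False
    )
    out = []
    for idx, _code in found:
        atom = m.GetAtomWithIdx(idx)
        if atom.GetAtomicNum() == 6 and atom.GetTotalNumHs() == 1:
            out.append(idx)
    return sorted(out)


def classify_substituent(
    mol: MoleculeRecord,
    center: int,
    neighbor: int,
    rules: Sequence[SubstituentRule] | None = None,
) -> SubstituentAssignment:
    """Classify one neighbor of a stereocenter by first-match-wins rule order."""
    m = mol.require_ok()
    if rules is None:
        rules = load_pattern_rules()
    bond = m.GetBondBetweenAtoms(center, neighbor)
    if bond is None:
        raise StructureError(
            f"molecule {mol.identifier!r}: atom {neighbor} is not bonded to center {center}"
        )
    for rule in rules:
        for match in m.GetSubstructMatches(rule.pattern, uniquify=False):
            if match[0] == neighbor:
                return SubstituentAssignment(
                    neighbor_atom_index=neighbor,
                    type_label=rule.type_label,
                    matched_rule_id=rule.rule_id,
                )
    return SubstituentAssignment(
        neighbor_atom_index=neighbor, type_label="other", matched_rule_id="fallback"
    )


def assign_center_type(
    labels: Sequence[str],
    catalogue: Mapping[str, tuple[str, str, str]] | None = None,
) -> str:
    """Map an (unordered) triple of substituent labels to its center-type letter code."""
    if len(labels) != 3:
        raise StructureError(f"expected exactly 3 substituent labels, got {len(labels)}")
    if catalogue is None:
        catalogue = load_center_types()
    key = tuple(sorted(labels))
    for code, triple in catalogue.items():
        if triple == key:
            return code
    return "unclassified"


def _pi_electrons_after_deprotonation(m: Chem.Mol, ring: tuple[int, ...], center: int) -> int | None:
    """Hueckel pi-electron count of the ring anion formed by removing the center's H.

    Returns None when some ring atom cannot contribute a p orbital to a
    conjugated cycle (an sp3 carbon other than the center breaks conjugation).
    """
    ringset = set(ring)
    electrons = 2  # the carbanion lone pair at the deprotonated center
    accounted = {center}
    # endocyclic multiple bonds contribute one pi pair each
    for bond in m.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in ringset and j in ringset and bond.GetBondTypeAsDouble() >= 1.5:
            if i in accounted or j in accounted:
                return None  # cumulated/clashing assignment, not a simple conjugated cycle
            electrons += 2
            accounted.update((i, j))
    for idx in ring:
        if idx in accounted:
            continue
        atom = m.GetAtomWithIdx(idx)
        exo_double = any(
            b.GetBondTypeAsDouble() >= 2.0 and b.GetOtherAtomIdx(idx) not in ringset
            for b in atom.GetBonds()
        )
        if exo_double:
            accounted.add(idx)  # empty-ish p orbital, 0 electrons (e.g. ring C=O carbon)
        elif atom.GetAtomicNum() in (7, 8, 16):
            electrons += 2  # heteroatom lone pair enters the ring
            accounted.add(idx)
        else:
            return None  # saturated ring carbon: no p orbital available
    return electrons


def assess_aromatic_anion(
    mol: MoleculeRecord,
    center: int,
    center_type_code: str | None = None,
    overrides: Mapping[str, bool] | None = None,
) -> bool:
    """Would deprotonation at ``center`` give a cyclic 4n+2 aromatic anion?

    Centers whose conjugate carbanion is aromatic racemize on a distinct,
    steeper rate/energy relationship, so the flag selects the calibration
    line.  The decision is a Hueckel electron-count heuristic on every ring
    of size <= 6 through the center; a per-center-type ``overrides`` map
    (letter code -> bool) wins over the heuristic when provided.
    """
    if overrides and center_type_code is not None and center_type_code in overrides:
        return bool(overrides[center_type_code])
    m = mol.require_ok()
    for ring in m.GetRingInfo().AtomRings():
        if center in ring and len(ring) <= 6:
            electrons = _pi_electrons_after_deprotonation(m, ring, center)
            if electrons is not None and electrons % 4 == 2:
                return True
    return False


def analyze_molecule(
    mol: MoleculeRecord,
    rules: Sequence[SubstituentRule] | None = None,
    catalogue: Mapping[str, tuple[str, str, str]] | None = None,
    overrides: Mapping[str, bool] | None = None,
) -> list[StereocenterReport]:
    """Full structural pass: one StereocenterReport per candidate center."""
    if rules is None:
        rules = load_pattern_rules()
    if catalogue is None:
        catalogue = load_center_types()
    m = mol.require_ok()
    reports = []
    for center in find_candidate_stereocenters(mol):
        atom = m.GetAtomWithIdx(center)
        subs = tuple(
            classify_substituent(mol, center, nb.GetIdx(), rules=rules)
            for nb in atom.GetNeighbors()
        )
        labels = [s.type_label for s in subs]
        code = assign_center_type(labels, catalogue=catalogue)
        aromatic = assess_aromatic_anion(
            mol, center, center_type_code=code, overrides=overrides
        )
        reports.append(
            StereocenterReport(
                atom_index=center,
                h_count=atom.GetTotalNumHs(),
                substituents=subs,  # type: ignore[arg-type]
                center_type_code=code,
                aromatic_anion=aromatic,
            )
        )
    return reports
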