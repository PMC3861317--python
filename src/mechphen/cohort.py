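"""Cohort data model and mechanistic-phenotype construction.

A *mechanistic phenotype* is an aggregate case definition: the set of all
clinical diagnoses presumed to arise from perturbation of one cellular or
physiological mechanism (e.g. every vessel-occlusive diagnosis for a
"thrombosis" phenotype).  Raw ICD-9 codes are first collapsed many-to-one
into *constituent groups* of related codes; each group belongs to one or
more mechanistic phenotypes.  A subject is a case for a phenotype iff they
carry at least one of its constituent groups; everyone else in the cohort
roster is a control (absence of a recorded diagnosis means control).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd
import yaml

__all__ = [
    "normalize_icd9",
    "GroupMap",
    "MechanisticPhenotypeDef",
    "map_to_groups",
    "assign_phenotype",
    "load_group_map",
    "load_phenotype_defs",
]

_CANONICAL_RE = re.compile(r"^[VE]?[0-9]+$")


def normalize_icd9(code: str) -> str:
    """Canonicalise an ICD-9 code string.

    Dots are removed, the code is upper-cased (preserving V/E prefixes) and
    surrounding whitespace is stripped.  Leading zeros are significant in
    ICD-9 and are preserved.  The transform is idempotent.

    Raises ``ValueError`` for empty or malformed codes (anything that is not
    an optional V/E prefix followed by digits after cleaning).
    """
    if code is None:
        raise ValueError("ICD-9 code must be non-empty")
    cleaned = str(code).strip().upper().replace(".", "")
    if not cleaned or not _CANONICAL_RE.match(cleaned):
        raise ValueError(f"malformed ICD-9 code: {code!r}")
    return cleaned


@dataclass(frozen=True)
class GroupMap:
    """Two-level diagnosis mapping.

    ``code_to_group`` maps a canonical ICD-9 code to exactly one constituent
    group; ``group_to_phenotypes`` maps a group to the (possibly several)
    mechanistic phenotypes it belongs to.  Groups with no phenotype
    assignment are allowed (explicitly unassigned).
    """

    code_to_group: dict[str, str]
    group_to_phenotypes: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.code_to_group:
            raise ValueError("GroupMap has no ICD-9 → group entries")

    @property
    def groups(self) -> frozenset[str]:
        known = set(self.code_to_group.values()) | set(self.group_to_phenotypes)
        return frozenset(known)

    def phenotype_def(self, phenotype_id: str) -> "MechanisticPhenotypeDef":
        groups = {
            g for g, phens in self.group_to_phenotypes.items() if phenotype_id in phens
        }
        return MechanisticPhenotypeDef(phenotype_id, frozenset(groups))


@dataclass(frozen=True)
class MechanisticPhenotypeDef:
    """A named mechanistic phenotype: a non-empty set of constituent groups."""

    phenotype_id: str
    constituent_groups: frozenset[str]

    def __post_init__(self) -> None:
        if not self.constituent_groups:
            raise ValueError(
                f"phenotype {self.phenotype_id!r} has an empty constituent set"
            )


def map_to_groups(
    diagnoses: pd.DataFrame, group_map: GroupMap
) -> tuple[pd.DataFrame, int]:
    """Map raw (subject_id, icd9) rows to a diagnosis table of constituent groups.

    Codes are normalised before lookup.  Duplicate (subject, group) pairs
    collapse to one row (set semantics).  Codes absent from the map are
    counted and reported in the second return value, not fatal.

    Returns ``(diagnosis_table, n_unmapped)`` where the table has columns
    ``subject_id`` and ``group_id``.
    """
    if not isinstance(diagnoses, pd.DataFrame) or not {
        "subject_id",
        "icd9",
    } <= set(diagnoses.columns):
        raise ValueError("diagnoses must be a DataFrame with subject_id/icd9 columns")
    codes = diagnoses["icd9"].map(normalize_icd9)
    groups = codes.map(group_map.code_to_group)
    mapped = pd.DataFrame(
        {"subject_id": diagnoses["subject_id"].astype(str), "group_id": groups}
    )
    n_unmapped = int(mapped["group_id"].isna().sum())
    table = (
        mapped.dropna(subset=["group_id"])
        .drop_duplicates()
        .sort_values(["subject_id", "group_id"], kind="stable")
        .reset_index(drop=True)
    )
    return table, n_unmapped


def assign_phenotype(
    diagnosis_table: pd.DataFrame,
    phenotype: MechanisticPhenotypeDef,
    cohort: "pd.Index | list[str]",
) -> pd.Series:
    """Derive the case/control vector for one mechanistic phenotype.

    A subject is a case iff they carry >= 1 constituent group of the
    phenotype; every other subject on the cohort roster is a control, so the
    result partitions the cohort.  Subjects appearing in the diagnosis table
    but missing from the roster indicate inconsistent inputs and raise.

    Returns a boolean Series (True = case) indexed by subject_id.
    """
    roster = pd.Index([str(s) for s in cohort], name="subject_id")
    if roster.has_duplicates:
        raise ValueError("cohort roster contains duplicate subject ids")
    dx_subjects = pd.Index(diagnosis_table["subject_id"].astype(str).unique())
    stray = dx_subjects.difference(roster)
    if len(stray):
        raise ValueError(
            f"{len(stray)} diagnosed subject(s) missing from cohort roster, "
            f"e.g. {sorted(stray)[:3]}"
        )
    hits = diagnosis_table.loc[
        diagnosis_table["group_id"].isin(phenotype.constituent_groups), "subject_id"
    ].astype(str)
    cases = pd.Series(False, index=roster, name=phenotype.phenotype_id)
    cases.loc[cases.index.isin(set(hits))] = True
    if len(cases) and cases.all():
        warnings.warn(
            f"phenotype {phenotype.phenotype_id}: every subject is a case "
            "(degenerate, no controls)",
            stacklevel=2,
        )
    return cases


# ---------------------------------------------------------------------------
# file loaders


def load_group_map(
    code_path: str, membership_path: str | None = None
) -> GroupMap:
    """Load a GroupMap from TSV files.

    ``code_path``: two columns ``icd9<TAB>group_id``.  ``membership_path``
    (optional): ``group_id<TAB>phenotype_id``, one row per membership.
    """
    codes = pd.read_csv(code_path, sep="\t", dtype=str, header=0)
    codes.columns = [c.lower() for c in codes.columns]
    code_to_group = {
        normalize_icd9(r.icd9): str(r.group_id) for r in codes.itertuples()
    }
    group_to_phen: dict[str, frozenset[str]] = {}
    if membership_path is not None:
        mem = pd.read_csv(membership_path, sep="\t", dtype=str, header=0)
        mem.columns = [c.lower() for c in mem.columns]
        grouped = mem.groupby("group_id")["phenotype_id"].agg(lambda s: frozenset(s))
        group_to_phen = grouped.to_dict()
    return GroupMap(code_to_group, group_to_phen)


def load_phenotype_defs(path: str) -> dict[str, MechanisticPhenotypeDef]:
    """Load phenotype definitions from a YAML/JSON config.

    Expected shape: ``{phenotype_id: [group_id, ...], ...}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"no phenotype definitions found in {path}")
    return {
        str(pid): MechanisticPhenotypeDef(str(pid), frozenset(map(str, groups)))
        for pid, groups in raw.items()
    }
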