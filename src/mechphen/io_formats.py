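"""Readers and writers for genotype, covariate, annotation and result files.

Genotypes are held as minor-allele dosage (0/1/2, -1 for missing) in a
:class:`GenotypeMatrix`.  On load from PLINK text PED/MAP the alleles of
each SNP are re-polarised so that dosage counts copies of the *minor*
allele (the less frequent allele in the loaded cohort); an exact 50/50
frequency tie is broken deterministically by taking the lexicographically
larger allele as minor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "OntologyAnnotation",
    "read_ped_map",
    "write_ped_map",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_genotypes",
    "read_covariates",
    "read_annotation",
    "write_results",
    "read_results",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Per-subject minor-allele dosages for a panel of SNPs.

    dosages: int8 array of shape (n_subjects, n_snps); -1 marks a missing
    genotype.  ``alleles`` maps snp_id -> (major, minor) when known (PED/MAP
    input); plain dosage TSVs carry no allele labels.
    """

    subject_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    alleles: dict[str, tuple[str, str]] | None = None
    gene_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_ids.index(snp_id)]

    def gene_of(self, snp_id: str) -> str:
        return self.gene_map.get(snp_id, snp_id)


@dataclass
class OntologyAnnotation:
    """gene -> set of ontology term ids, plus optional term names.

    Genes with zero annotations are permitted; they still count in the
    Fisher universe.  The universe size ``m`` for FDR is the number of
    distinct terms annotating >= 1 gene of a given gene set.
    """

    gene_to_terms: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def terms_of(self, gene_id: str) -> frozenset[str]:
        return self.gene_to_terms.get(gene_id, frozenset())

    def universe_terms(self, genes) -> set[str]:
        out: set[str] = set()
        for g in genes:
            out |= self.terms_of(g)
        return out


# ---------------------------------------------------------------------------
# PLINK text PED/MAP


def read_ped_map(ped_path: str, map_path: str) -> GenotypeMatrix:
    """Load a PLINK text PED/MAP pair as minor-allele dosages.

    PED rows: FID IID PAT MAT SEX PHENO then two space-separated alleles per
    SNP; "0 0" marks a missing genotype.  Raises with a line number on
    ragged rows or SNPs with more than two distinct alleles.
    """
    snp_ids: list[str] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f"{map_path}:{ln}: expected 4 MAP columns")
            snp_ids.append(parts[1])
    n_snps = len(snp_ids)

    subject_ids: list[str] = []
    rows: list[np.ndarray] = []
    allele_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snps} fields, "
                    f"got {len(parts)}"
                )
            subject_ids.append(parts[1])
            alleles = parts[6:]
            allele_pairs.append(
                [(alleles[2 * j], alleles[2 * j + 1]) for j in range(n_snps)]
            )

    n = len(subject_ids)
    dosages = np.full((n, n_snps), MISSING, dtype=np.int8)
    allele_labels: dict[str, tuple[str, str]] = {}
    for j, snp in enumerate(snp_ids):
        counts: dict[str, int] = {}
        for i in range(n):
            for a in allele_pairs[i][j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise ValueError(f"{ped_path}: SNP {snp} has >2 alleles: {sorted(counts)}")
        if not counts:  # fully missing SNP
            allele_labels[snp] = ("0", "0")
            continue
        # minor = least frequent; 50/50 tie broken by lexicographically larger
        if len(counts) == 1:
            (major,) = (minor,) = counts
        else:
            a, b = sorted(counts)  # a < b lexicographically
            if counts[a] == counts[b]:
                major, minor = a, b
            elif counts[a] < counts[b]:
                major, minor = b, a
            else:
                major, minor = a, b
        allele_labels[snp] = (major, minor)
        for i in range(n):
            a1, a2 = allele_pairs[i][j]
            if a1 == "0" or a2 == "0":
                continue
            dosages[i, j] = (a1 == minor) + (a2 == minor)
    return GenotypeMatrix(subject_ids, snp_ids, dosages, allele_labels)


def write_ped_map(gm: GenotypeMatrix, ped_path: str, map_path: str) -> None:
    """Write a GenotypeMatrix back to PLINK text PED/MAP.

    SNPs without allele labels are written with synthetic alleles A (major)
    and B (minor).
    """
    with open(map_path, "w") as fh:
        for j, snp in enumerate(gm.snp_ids):
            fh.write(f"1\t{snp}\t0\t{j + 1}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.subject_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j, snp in enumerate(gm.snp_ids):
                major, minor = (gm.alleles or {}).get(snp, ("A", "B"))
                if major == "0":
                    major, minor = "A", "B"
                d = gm.dosages[i, j]
                if d == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [minor] * int(d) + [major] * (2 - int(d))
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# wide dosage TSV


def read_dosage_tsv(path: str) -> GenotypeMatrix:
    """Read a wide dosage TSV: first column subject_id, one column per SNP,
    cells 0/1/2 or NA."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    dos = df.to_numpy(dtype=float)
    dosages = np.where(np.isnan(dos), MISSING, dos).astype(np.int8)
    return GenotypeMatrix(
        [str(s) for s in df.index], [str(c) for c in df.columns], dosages
    )


def write_dosage_tsv(gm: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(
        np.where(gm.dosages == MISSING, np.nan, gm.dosages),
        index=pd.Index(gm.subject_ids, name="subject_id"),
        columns=gm.snp_ids,
    )
    df.to_csv(path, sep="\t", float_format="%.0f")


def read_genotypes(path: str, fmt: str = "ped_map") -> GenotypeMatrix:
    """Dispatching reader.  ``fmt``: ``ped_map`` (``path`` is the prefix of
    ``<path>.ped``/``<path>.map``) or ``dosage_tsv``."""
    if fmt == "ped_map":
        p = Path(path)
        return read_ped_map(str(p.with_suffix(".ped")), str(p.with_suffix(".map")))
    if fmt == "dosage_tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# covariates, annotation, results


def read_covariates(path: str) -> pd.DataFrame:
    """Covariate TSV: subject_id, age, gender, dataset."""
    cov = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "age", "gender", "dataset"}
    if not required <= set(cov.columns):
        raise ValueError(f"covariate file must have columns {sorted(required)}")
    return cov.set_index("subject_id")


def read_annotation(path: str) -> OntologyAnnotation:
    """Read a two-column ``gene_id<TAB>ontology_id`` annotation export
    (optional third column: term name).  Duplicate rows collapse."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if df.empty:
        raise ValueError(f"annotation file {path} is empty")
    gene_col, term_col = df.columns[0], df.columns[1]
    gene_to_terms = {
        str(g): frozenset(sub[term_col].astype(str))
        for g, sub in df.groupby(gene_col)
    }
    term_names: dict[str, str] = {}
    if df.shape[1] >= 3:
        name_col = df.columns[2]
        named = df.dropna(subset=[name_col])
        term_names = dict(zip(named[term_col].astype(str), named[name_col].astype(str)))
    return OntologyAnnotation(gene_to_terms, term_names)


def write_results(results: pd.DataFrame, path: str) -> None:
    """Write a result table as TSV with full float precision (shortest
    round-tripping repr).  Output is bit-identical for identical inputs."""
    results.to_csv(path, sep="\t", index=False)


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
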