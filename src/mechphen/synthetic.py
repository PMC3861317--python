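"""Synthetic EMR cohort generator.

Generates cohorts with the statistical structure the association analyses
assume: subjects with covariates (age, gender, source dataset), a panel
of low-MAF SNPs drawn independently of phenotype (null by construction),
and multi-diagnosis constituent-group indicators with realistic
co-occurrence.

Default profiles reproduce the marginal structure of the two study
populations: a thrombosis cohort (n = 1,655; any-thrombosis 27.4%, with
constituent prevalences anticoagulation 10.8%, stroke 10.0%, myocardial
infarction 9.0%, venous 7.0%, pulmonary 2.8%, other 2.7%, arterial 2.2%,
spontaneous abortion 1.9%) and a cancer cohort (n = 3,009; any 42.4%,
CA 35.8%, HEM 12.3%, MET 12.0%, SKN 3.6%).

Within-subject diagnosis correlation uses a shared logistic frailty: a
per-subject normal deviate u enters every group's logit.  The frailty
scale sigma is not a free dial — it is calibrated (with the per-group
intercepts) so that every constituent marginal matches its target AND the
induced any-phenotype prevalence matches the printed aggregate, which
pins the co-occurrence strength to the published margins.

``plant_effect`` adds a genotype-dependent diagnosis excess to one SNP's
minor-allele homozygotes for power/recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import GroupMap, MechanisticPhenotypeDef
from .io_formats import GenotypeMatrix

__all__ = [
    "CohortSpec",
    "Cohort",
    "PlantedEffect",
    "generate_cohort",
    "plant_effect",
    "write_cohort",
    "THROMBOSIS_PREVALENCES",
    "CANCER_PREVALENCES",
]

THROMBOSIS_PREVALENCES = {
    "ANTICOAG": 0.108,
    "STROKE": 0.100,
    "AMI": 0.090,
    "VENOUS": 0.070,
    "PULMONARY": 0.028,
    "OTHER": 0.027,
    "ARTERIAL": 0.022,
    "SPONT_AB": 0.019,
}
CANCER_PREVALENCES = {"CA": 0.358, "HEM": 0.123, "MET": 0.120, "SKN": 0.036}


@dataclass(frozen=True)
class CohortSpec:
    """Conditions of a synthetic cohort draw."""

    n_subjects: int = 1_655
    prevalences: tuple[tuple[str, float], ...] = tuple(THROMBOSIS_PREVALENCES.items())
    any_prevalence: float | None = 0.274
    phenotype_id: str = "THROMBOSIS"
    n_snps: int = 433
    maf_range: tuple[float, float] = (0.05, 0.10)
    mean_age: float = 52.3
    sd_age: float = 17.7
    frac_female: float = 0.64
    dataset_labels: tuple[str, ...] = ("VGER", "VESPA")
    dataset_probs: tuple[float, ...] = (0.4, 0.6)

    def __post_init__(self) -> None:
        if isinstance(self.prevalences, dict):
            object.__setattr__(self, "prevalences", tuple(self.prevalences.items()))
        for g, p in self.prevalences:
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence of {g} outside [0, 1]")
        if self.any_prevalence is not None:
            pmax = max((p for _, p in self.prevalences), default=0.0)
            if self.any_prevalence < pmax:
                raise ValueError(
                    "any-phenotype prevalence below the largest constituent prevalence"
                )

    @classmethod
    def thrombosis(cls, **kw) -> "CohortSpec":
        return cls(**kw)

    @classmethod
    def cancer(cls, **kw) -> "CohortSpec":
        defaults = dict(
            n_subjects=3_009,
            prevalences=tuple(CANCER_PREVALENCES.items()),
            any_prevalence=0.424,
            phenotype_id="ALL",
            n_snps=833,
            frac_female=0.435,
            mean_age=51.4,
            sd_age=18.7,
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: pd.DataFrame  # subject_id, age, gender, dataset
    genotypes: GenotypeMatrix
    diagnoses: pd.DataFrame  # subject_id, group_id (set semantics)
    groups: list[str]
    phenotype: MechanisticPhenotypeDef
    group_map: GroupMap
    sigma: float  # calibrated frailty scale

    def carrier_matrix(self) -> np.ndarray:
        """Boolean (n_subjects x n_groups) indicator of constituent groups."""
        from .reverse import carrier_matrix

        return carrier_matrix(
            self.diagnoses, self.subjects["subject_id"].tolist(), self.groups
        )


# ---------------------------------------------------------------------------
# frailty calibration

_GH_X, _GH_W = np.polynomial.hermite.hermgauss(61)
_GH_Z = np.sqrt(2.0) * _GH_X
_GH_WN = _GH_W / np.sqrt(np.pi)


def _marginal(alpha: float, sigma: float) -> float:
    return float(np.sum(_GH_WN * expit(alpha + sigma * _GH_Z)))


def _alphas_for(prevs: np.ndarray, sigma: float) -> np.ndarray:
    def solve(p: float) -> float:
        if p <= 0.0:
            return -np.inf
        if p >= 1.0:
            return np.inf
        return brentq(lambda a: _marginal(a, sigma) - p, -40.0, 40.0)

    return np.array([solve(p) for p in prevs])


def _any_prevalence(alphas: np.ndarray, sigma: float) -> float:
    P = expit(alphas[:, None] + sigma * _GH_Z[None, :])
    none = np.prod(1.0 - P, axis=0)
    return float(np.sum(_GH_WN * (1.0 - none)))


@lru_cache(maxsize=32)
def _calibrate(prevs_key: tuple[float, ...], any_target: float | None):
    """Solve the frailty scale and intercepts matching the target margins."""
    prevs = np.array(prevs_key)
    if any_target is None or len(prevs) == 0:
        return 0.0, tuple(_alphas_for(prevs, 0.0)) if len(prevs) else ()
    indep = _any_prevalence(_alphas_for(prevs, 0.0), 0.0)
    if any_target > indep + 1e-9:
        raise ValueError(
            f"any-prevalence {any_target} exceeds the independence bound {indep:.4f}; "
            "infeasible prevalence combination"
        )

    def f(sigma: float) -> float:
        return _any_prevalence(_alphas_for(prevs, sigma), sigma) - any_target

    if abs(f(0.0)) < 1e-12:
        sigma = 0.0
    else:
        hi = 1.0
        while f(hi) > 0 and hi < 64:
            hi *= 2.0
        if f(hi) > 0:
            raise ValueError(
                "any-prevalence target unattainably low for these constituent margins"
            )
        sigma = brentq(f, 0.0, hi, xtol=1e-10)
    return sigma, tuple(_alphas_for(prevs, sigma))


# ---------------------------------------------------------------------------


def generate_cohort(spec: CohortSpec, seed: int = 0) -> Cohort:
    """Draw a cohort: genotypes independent of diagnoses (null by
    construction), diagnoses with the calibrated frailty co-occurrence,
    deterministic under (spec, seed)."""
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    groups = [g for g, _ in spec.prevalences]
    prevs = np.array([p for _, p in spec.prevalences])
    sigma, alphas = _calibrate(tuple(prevs), spec.any_prevalence)
    alphas = np.array(alphas)

    subject_ids = [f"S{i:06d}" for i in range(1, n + 1)]
    age = np.clip(rng.normal(spec.mean_age, spec.sd_age, n), 18, 90).round().astype(int)
    gender = np.where(rng.random(n) < spec.frac_female, "F", "M")
    dataset = rng.choice(spec.dataset_labels, size=n, p=spec.dataset_probs)
    subjects = pd.DataFrame(
        {"subject_id": subject_ids, "age": age, "gender": gender, "dataset": dataset}
    )

    if groups:
        u = rng.standard_normal(n)
        P = expit(alphas[None, :] + sigma * u[:, None])
        D = rng.random((n, len(groups))) < P
        si, gi = np.nonzero(D)
        diagnoses = pd.DataFrame(
            {
                "subject_id": [subject_ids[i] for i in si],
                "group_id": [groups[j] for j in gi],
            }
        )
    else:
        diagnoses = pd.DataFrame(columns=["subject_id", "group_id"])

    mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], spec.n_snps)
    dosages = rng.binomial(2, mafs[None, :], size=(n, spec.n_snps)).astype(np.int8)
    snp_ids = [f"snp{j:06d}" for j in range(1, spec.n_snps + 1)]
    gene_map = {s: f"GENE{j + 1:06d}" for j, s in enumerate(snp_ids)}
    gm = GenotypeMatrix(
        subject_ids,
        snp_ids,
        dosages,
        alleles={s: ("A", "B") for s in snp_ids},
        gene_map=gene_map,
    )

    code_to_group = {str(100 + j): g for j, g in enumerate(groups)}
    group_to_phen = {g: frozenset({spec.phenotype_id}) for g in groups}
    group_map = GroupMap(code_to_group or {"000": "UNUSED"}, group_to_phen)
    phenotype = MechanisticPhenotypeDef(
        spec.phenotype_id, frozenset(groups) or frozenset({"UNUSED"})
    )
    return Cohort(spec, subjects, gm, diagnoses, groups, phenotype, group_map, sigma)


@dataclass(frozen=True)
class PlantedEffect:
    """A pleiotropic diagnosis excess among one SNP's minor homozygotes.

    modes: ``single_diagnosis`` (every penetrant homozygote gains the one
    target group), ``multi_diagnosis`` (each gains one target group chosen
    uniformly), ``random_diagnosis`` (each gains a uniformly random
    constituent group).
    """

    snp_id: str
    mode: str = "single_diagnosis"
    penetrance: float = 0.4
    target_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.penetrance <= 1:
            raise ValueError("penetrance must lie in [0, 1]")
        if self.mode not in ("single_diagnosis", "multi_diagnosis", "random_diagnosis"):
            raise ValueError(f"unknown planted-effect mode {self.mode!r}")
        if self.mode in ("single_diagnosis", "multi_diagnosis") and not self.target_groups:
            raise ValueError(f"mode {self.mode} requires target groups")


def plant_effect(cohort: Cohort, eff: PlantedEffect, seed: int = 0) -> Cohort:
    """Return a copy of the cohort where each minor-allele homozygote of
    the effect SNP independently gains a target-group diagnosis with the
    stated penetrance.  Non-homozygote subjects are untouched."""
    if eff.snp_id not in cohort.genotypes.snp_ids:
        raise ValueError(f"unknown SNP {eff.snp_id}")
    d = cohort.genotypes.column(eff.snp_id)
    hzma = np.nonzero(d == 2)[0]
    if len(hzma) == 0:
        raise ValueError(f"SNP {eff.snp_id} has no minor-allele homozygotes")
    rng = np.random.default_rng(seed)
    pool = (
        list(eff.target_groups)
        if eff.mode != "random_diagnosis"
        else list(cohort.groups)
    )
    if not pool:
        raise ValueError("no groups available to plant")
    new_rows = []
    sids = cohort.subjects["subject_id"].tolist()
    for i in hzma:
        if rng.random() < eff.penetrance:
            g = pool[0] if eff.mode == "single_diagnosis" else pool[rng.integers(len(pool))]
            new_rows.append({"subject_id": sids[i], "group_id": g})
    if not new_rows:
        return replace_diagnoses(cohort, cohort.diagnoses.copy())
    dx = (
        pd.concat([cohort.diagnoses, pd.DataFrame(new_rows)], ignore_index=True)
        .drop_duplicates()
        .reset_index(drop=True)
    )
    return replace_diagnoses(cohort, dx)


def replace_diagnoses(cohort: Cohort, diagnoses: pd.DataFrame) -> Cohort:
    return Cohort(
        cohort.spec,
        cohort.subjects,
        cohort.genotypes,
        diagnoses,
        cohort.groups,
        cohort.phenotype,
        cohort.group_map,
        cohort.sigma,
    )


def write_cohort(cohort: Cohort, outdir: str) -> dict[str, str]:
    """Write the file bundle the pipeline stages consume; returns paths."""
    from pathlib import Path

    from .io_formats import write_ped_map

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": str(out / "genotypes.ped"),
        "map": str(out / "genotypes.map"),
        "diagnoses": str(out / "diagnoses.tsv"),
        "covariates": str(out / "covariates.tsv"),
        "icd9_groups": str(out / "icd9_groups.tsv"),
        "group_phenotypes": str(out / "group_phenotypes.tsv"),
        "gene_map": str(out / "gene_map.tsv"),
    }
    write_ped_map(cohort.genotypes, paths["ped"], paths["map"])
    group_to_code = {g: c for c, g in cohort.group_map.code_to_group.items()}
    dx = cohort.diagnoses.copy()
    dx["icd9"] = dx["group_id"].map(group_to_code)
    dx[["subject_id", "icd9"]].to_csv(paths["diagnoses"], sep="\t", index=False)
    cohort.subjects.to_csv(paths["covariates"], sep="\t", index=False)
    pd.DataFrame(
        [(c, g) for c, g in cohort.group_map.code_to_group.items()],
        columns=["icd9", "group_id"],
    ).to_csv(paths["icd9_groups"], sep="\t", index=False)
    pd.DataFrame(
        [
            (g, p)
            for g, phens in cohort.group_map.group_to_phenotypes.items()
            for p in sorted(phens)
        ],
        columns=["group_id", "phenotype_id"],
    ).to_csv(paths["group_phenotypes"], sep="\t", index=False)
    pd.DataFrame(
        sorted(cohort.genotypes.gene_map.items()), columns=["snp_id", "gene_id"]
    ).to_csv(paths["gene_map"], sep="\t", index=False)
    return paths
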