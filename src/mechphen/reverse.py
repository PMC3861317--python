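"""Reverse-genetics association statistics and their permutation null.

These models condition the working phenotype definition on what is seen
among the minor-allele homozygotes (HZMA) of a SNP, and compare only the
two homozygote classes (heterozygotes are excluded, since an additive
variant would have affected heterozygotes that dilute the contrast):

* model ``rg1``: among the constituent diagnosis groups of the mechanistic
  phenotype, keep those carried by >= ``min_count`` (default 2) distinct
  HZMA subjects; the statistic T is the number of HZMA subjects carrying
  at least one kept group.
* model ``rg2``: additionally require each kept group to be over-
  represented in HZMA vs common-allele homozygotes at one-sided Fisher
  exact p < 0.1 (the threshold is deliberately lenient: it discards groups
  present at chance levels while keeping sub-significant excesses).
* model ``recessive_perm``: reference model; T counts every HZMA subject
  with any constituent diagnosis (no selection), p still by permutation.

Because the qualifying-diagnosis set is *optimised on the observed HZMA
subjects*, naive p-values would be anti-conservative (a winner's-curse
selection).  Significance therefore comes from a stratified genotype
permutation: genotype vectors are randomly reassigned among subjects
within strata (study/dataset, age bin, gender), which preserves per-
stratum genotype counts and hence the MAF, and the qualifying set is
re-derived inside every permutation so the null undergoes the same
optimisation.  The p-value is the proportion of permutations with a tally
equalling or exceeding the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING

__all__ = [
    "HomozygoteSplit",
    "PermutationConfig",
    "TallyResult",
    "carrier_matrix",
    "split_homozygotes",
    "multiply_occurring",
    "diagnosis_fisher",
    "rg_tally",
    "stratified_permutation_p",
    "make_strata",
]

RG_MODELS = ("rg1", "rg2", "recessive_perm")


@dataclass(frozen=True)
class HomozygoteSplit:
    """Index sets of minor-allele (dosage 2) and common-allele (dosage 0)
    homozygotes; heterozygous and missing subjects are excluded."""

    hzma: np.ndarray
    hzca: np.ndarray

    @property
    def n_hzma(self) -> int:
        return len(self.hzma)

    @property
    def n_hzca(self) -> int:
        return len(self.hzca)


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the permutation null.

    estimator "plain" is count/B (can return 0, the literal definition);
    "anchored" is (count+1)/(B+1), never zero and preferable for ranking.
    """

    B: int = 10_000
    seed: int = 0
    estimator: str = "plain"
    min_count: int = 2
    fisher_threshold: float = 0.1
    age_bin: int = 10

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.estimator not in ("plain", "anchored"):
            raise ValueError("estimator must be 'plain' or 'anchored'")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass
class TallyResult:
    snp_id: str
    model: str
    tally: int
    n_hzma: int
    qualifying_groups: list[str]
    p_perm: float = float("nan")
    n_perm: int = 0
    n_ge: int = 0  # permutations with tally >= observed


def carrier_matrix(
    diagnosis_table: pd.DataFrame, subject_ids, groups
) -> np.ndarray:
    """Boolean (n_subjects x n_groups) carrier matrix from a diagnosis
    table restricted to the given constituent groups."""
    sub_pos = {str(s): i for i, s in enumerate(subject_ids)}
    grp_pos = {str(g): j for j, g in enumerate(groups)}
    D = np.zeros((len(sub_pos), len(grp_pos)), dtype=bool)
    for s, g in zip(
        diagnosis_table["subject_id"].astype(str),
        diagnosis_table["group_id"].astype(str),
    ):
        j = grp_pos.get(g)
        i = sub_pos.get(s)
        if i is not None and j is not None:
            D[i, j] = True
    return D


def split_homozygotes(dosages: np.ndarray) -> HomozygoteSplit:
    d = np.asarray(dosages)
    return HomozygoteSplit(
        hzma=np.nonzero(d == 2)[0], hzca=np.nonzero(d == 0)[0]
    )


def multiply_occurring(
    D: np.ndarray, hzma: np.ndarray, min_count: int = 2
) -> np.ndarray:
    """Boolean mask over groups carried by >= min_count distinct HZMA
    subjects."""
    if min_count < 2:
        raise ValueError("min_count must be >= 2 for multiply-occurring groups")
    return D[hzma].sum(axis=0) >= min_count


def diagnosis_fisher(
    a: int, n_hzma: int, c: int, n_hzca: int, alternative: str = "greater"
) -> float:
    """Fisher exact p for one diagnosis group between homozygote classes.

    The 2x2 table is (carries group vs not) x (HZMA vs HZCA) with ``a``
    carriers among ``n_hzma`` minor homozygotes and ``c`` among ``n_hzca``
    common homozygotes.  Default one-sided (HZMA excess), matching the
    filter's purpose of detecting diagnoses over-represented among minor
    homozygotes; ``alternative="two-sided"`` is available.
    """
    if alternative == "greater":
        # P(X >= a), X ~ Hypergeom(N=n_hzma+n_hzca, K=a+c, n=n_hzma)
        return float(stats.hypergeom.sf(a - 1, n_hzma + n_hzca, a + c, n_hzma))
    table = [[a, n_hzma - a], [c, n_hzca - c]]
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def _qualifying_mask(
    counts: np.ndarray,
    c_counts: np.ndarray | None,
    n_hzma,
    n_hzca,
    model: str,
    min_count: int,
    fisher_threshold: float,
) -> np.ndarray:
    """Vectorised qualifying-group mask; works on (..., G) count arrays."""
    if model == "recessive_perm":
        return counts >= 1
    qual = counts >= min_count
    if model == "rg2":
        with np.errstate(invalid="ignore"):
            p = stats.hypergeom.sf(
                counts - 1,
                np.asarray(n_hzma) + np.asarray(n_hzca),
                counts + c_counts,
                np.asarray(n_hzma),
            )
        qual &= p < fisher_threshold
    elif model != "rg1":
        raise ValueError(f"unknown reverse-genetics model {model!r}")
    return qual


def rg_tally(
    D: np.ndarray,
    split: HomozygoteSplit,
    model: str = "rg1",
    min_count: int = 2,
    fisher_threshold: float = 0.1,
    groups: list[str] | None = None,
    snp_id: str = "",
) -> TallyResult:
    """Observed tally for one SNP (no p-value).

    ``D`` is the carrier matrix over the phenotype's constituent groups.
    """
    if split.n_hzma == 0:
        raise ValueError("no minor-allele homozygotes: statistic undefined")
    counts = D[split.hzma].sum(axis=0)
    c_counts = D[split.hzca].sum(axis=0) if model == "rg2" else None
    qual = _qualifying_mask(
        counts, c_counts, split.n_hzma, split.n_hzca, model, min_count,
        fisher_threshold,
    )
    tally = int((D[split.hzma][:, qual].any(axis=1)).sum()) if qual.any() else 0
    names = (
        [groups[j] for j in np.nonzero(qual)[0]]
        if groups is not None
        else [str(j) for j in np.nonzero(qual)[0]]
    )
    return TallyResult(snp_id, model, tally, split.n_hzma, names)


def _permute_within_strata(
    values: np.ndarray, strata_codes: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """B independent permutations of ``values``, each shuffling only within
    strata.  Returns a (B, n) array."""
    n = len(values)
    out = np.empty((B, n), dtype=values.dtype)
    for code in np.unique(strata_codes):
        idx = np.nonzero(strata_codes == code)[0]
        if len(idx) == 0:
            continue
        keys = rng.random((B, len(idx)))
        order = np.argsort(keys, axis=1, kind="stable")
        out[:, idx] = values[idx][order]
    return out


def _perm_tallies(
    perm_dosages: np.ndarray,
    D: np.ndarray,
    model: str,
    min_count: int,
    fisher_threshold: float,
) -> np.ndarray:
    """Tallies for a (B, n) block of permuted dosage vectors, re-deriving
    the qualifying-diagnosis set inside each permutation."""
    hzma = perm_dosages == 2  # (B, n)
    Df = D.astype(np.float32)
    counts = (hzma.astype(np.float32) @ Df).astype(np.int64)  # (B, G)
    if model == "rg2":
        hzca = perm_dosages == 0
        c_counts = (hzca.astype(np.float32) @ Df).astype(np.int64)
        n2 = hzma.sum(axis=1, keepdims=True)
        n0 = hzca.sum(axis=1, keepdims=True)
    else:
        c_counts, n2, n0 = None, hzma.sum(axis=1, keepdims=True), 0
    qual = _qualifying_mask(
        counts, c_counts, n2, n0, model, min_count, fisher_threshold
    )
    carries = (Df @ qual.T.astype(np.float32)) > 0  # (n, B)
    return (hzma & carries.T).sum(axis=1)


def stratified_permutation_p(
    dosages: np.ndarray,
    D: np.ndarray,
    strata: np.ndarray | pd.Series | None,
    model: str = "rg1",
    cfg: PermutationConfig = PermutationConfig(),
    groups: list[str] | None = None,
    snp_id: str = "",
    snp_index: int = 0,
    block: int = 2_000,
) -> TallyResult:
    """Reverse-genetics permutation p-value for one SNP.

    Dosage vectors (0/1/2, -1 missing) are reassigned among subjects within
    each stratum ``cfg.B`` times; heterozygotes exist in the permuted data
    but are ignored by the statistic.  Missing-dosage subjects keep the
    missing label through the shuffle (complete-case per SNP).  The RNG is
    seeded per SNP from (seed, snp_index) so results are reproducible and
    independent of execution order.
    """
    d = np.asarray(dosages, dtype=np.int8)
    n = len(d)
    if strata is None:
        codes = np.zeros(n, dtype=np.int64)
    else:
        codes = pd.factorize(np.asarray(strata))[0]
        if len(codes) != n:
            raise ValueError("strata length must match number of subjects")
    obs = rg_tally(
        D, split_homozygotes(d), model, cfg.min_count, cfg.fisher_threshold,
        groups, snp_id,
    )
    rng = np.random.default_rng([cfg.seed, snp_index])
    n_ge = 0
    done = 0
    while done < cfg.B:
        b = min(block, cfg.B - done)
        perm = _permute_within_strata(d, codes, b, rng)
        tallies = _perm_tallies(
            perm, D, model, cfg.min_count, cfg.fisher_threshold
        )
        n_ge += int((tallies >= obs.tally).sum())
        done += b
    obs.n_perm = cfg.B
    obs.n_ge = n_ge
    if cfg.estimator == "plain":
        obs.p_perm = n_ge / cfg.B
    else:
        obs.p_perm = (n_ge + 1) / (cfg.B + 1)
    return obs


def make_strata(covariates: pd.DataFrame, age_bin: int = 10) -> pd.Series:
    """Permutation strata labels from dataset x age bin x gender.

    Age bins default to decades; the bin width is configurable since the
    original stratification granularity for age is not fixed by theory.
    """
    age = (covariates["age"].astype(float) // age_bin).astype(int)
    return (
        covariates["dataset"].astype(str)
        + "|" + age.astype(str)
        + "|" + covariates["gender"].astype(str)
    )
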