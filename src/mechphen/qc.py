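"""SNP selection filters for low-MAF nsSNP panels.

The analysis targets low-frequency variants with enough minor-allele
homozygotes to carry a homozygote-based statistic: MAF below ``maf_max``
(default 0.10), at least ``min_hzma`` dosage-2 subjects (default 10), call
rate >= 98%.  Hardy-Weinberg departures (exact conditional test) are
flagged rather than excluded by default; an explicit switch removes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import MISSING, GenotypeMatrix

__all__ = [
    "QCThresholds",
    "minor_allele_frequency",
    "genotype_counts",
    "hwe_exact_p",
    "select_snps",
]


@dataclass(frozen=True)
class QCThresholds:
    maf_max: float = 0.10
    min_hzma: int = 10
    call_rate_min: float = 0.98
    hwe_alpha: float = 0.001  # report-only by default

    def __post_init__(self) -> None:
        if not 0 < self.maf_max <= 0.5:
            raise ValueError("maf_max must be in (0, 0.5]")
        if self.min_hzma < 1:
            raise ValueError("min_hzma must be >= 1")


def minor_allele_frequency(dosages: np.ndarray) -> float:
    """MAF of one SNP from dosages, ignoring missing values.

    f = (sum of dosages) / (2 * n_nonmissing), folded to min(f, 1-f).
    All-missing input returns NaN.
    """
    d = np.asarray(dosages)
    valid = d != MISSING
    n = int(valid.sum())
    if n == 0:
        return float("nan")
    f = float(d[valid].sum()) / (2.0 * n)
    return min(f, 1.0 - f)


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(n_common_hom, n_het, n_minor_hom) ignoring missing."""
    d = np.asarray(dosages)
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def hwe_exact_p(n_aa_major: int, n_het: int, n_aa_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed count.  Used instead of a chi-square test because
    minor-homozygote counts are small by design in a low-MAF panel.
    """
    if min(n_aa_major, n_het, n_aa_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_major + n_het + n_aa_minor
    if n < 1:
        raise ValueError("at least one genotype required")
    n_rare = 2 * min(n_aa_major, n_aa_minor) + n_het
    if n_rare == 0 or n_rare == 2 * n:  # monomorphic: degenerate, p = 1
        return 1.0
    # possible het counts share parity with n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hets = hets[(n_rare - hets) % 2 == 0]
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    ok = hom_common >= 0
    hets, hom_rare, hom_common = hets[ok], hom_rare[ok], hom_common[ok]
    # P(het = h | allele counts) ∝ n! 2^h / (hom_c! h! hom_r!)
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_common + 1)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def select_snps(
    gm: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    hwe_exclude: bool = False,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the selection filters to every SNP of a genotype matrix.

    Retained SNPs satisfy MAF < maf_max, minor-homozygote count >=
    min_hzma and call rate >= call_rate_min.  HWE failures (exact p <
    hwe_alpha) are flagged in the report and removed only when
    ``hwe_exclude`` is set.  The report lists, per SNP, its statistics and
    a comma-joined list of exclusion reasons (empty = retained).
    """
    rows = []
    retained: list[str] = []
    for j, snp in enumerate(gm.snp_ids):
        d = gm.dosages[:, j]
        valid = d != MISSING
        call_rate = float(valid.mean()) if len(d) else 0.0
        maf = minor_allele_frequency(d)
        n0, n1, n2 = genotype_counts(d)
        reasons = []
        hwe_p = float("nan")
        if np.isnan(maf):
            reasons.append("all_missing")
        else:
            hwe_p = hwe_exact_p(n0, n1, n2)
            if not maf < thresholds.maf_max:
                reasons.append("maf")
            if n2 < thresholds.min_hzma:
                reasons.append("hzma_count")
            if call_rate < thresholds.call_rate_min:
                reasons.append("call_rate")
            hwe_fail = hwe_p < thresholds.hwe_alpha
            if hwe_fail and hwe_exclude:
                reasons.append("hwe")
        rows.append(
            {
                "snp_id": snp,
                "reason": ",".join(reasons),
                "maf": maf,
                "hzma_count": n2,
                "call_rate": call_rate,
                "hwe_p": hwe_p,
                "hwe_flag": bool(hwe_p < thresholds.hwe_alpha)
                if not np.isnan(hwe_p)
                else False,
            }
        )
        if not reasons:
            retained.append(snp)
    report = pd.DataFrame(rows)
    if not retained:
        warnings.warn("no SNPs passed QC", stacklevel=2)
    return retained, report
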