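"""Operating characteristics of the association models by simulation.

Two studies:

* **Type-I error** — genotype labels of a QC-passing low-MAF SNP panel are
  shuffled to make large sets of null SNPs (shuffling preserves genotype
  counts, hence the MAF spectrum); each randomized SNP is scored with a
  reverse-genetics permutation p-value, and the empirical rate at a
  nominal level alpha is the fraction of randomized SNPs with p < alpha.
* **ROC discrimination** — repeated samples of ``sample_size`` subjects
  (default 13, a typical minor-homozygote count for the panel) play the
  role of a SNP's minor-allele homozygotes; a spiked copy assigns
  ``k_added`` of them a new constituent diagnosis under one of four
  scenarios, and each model's ability to separate spiked from unspiked
  samples is summarised as a Mann-Whitney AUC over the paired p-values.

Simulations run with a single collapsed permutation stratum: under the
null, genotypes are exchangeable across subjects, so a within-stratum
shuffle and a global shuffle induce the same tally distribution, and a
global genotype shuffle makes the homozygote sets uniformly random
subject subsets.  The engine therefore samples homozygote index sets
directly, which is what makes half a million permutation tests tractable;
its equivalence with the general stratified permutation path is covered
by tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScenarioSpec",
    "roc_auc",
    "assign_cases",
    "scenario_scores",
    "empirical_type1",
    "roc_study",
    "SampleInfeasible",
]

SCENARIOS = {
    "random_uniform": 1,
    "frequency_weighted": 2,
    "already_present": 3,
    "same_random": 4,
}
_SCENARIO_BY_NUM = {v: k for k, v in SCENARIOS.items()}


class SampleInfeasible(RuntimeError):
    """A drawn sample cannot host the requested case assignment (e.g. no
    diagnosis present for the already-present scenario); callers redraw."""


@dataclass(frozen=True)
class ScenarioSpec:
    scenario: str = "random_uniform"
    k_added: int = 3
    sample_size: int = 13
    n_samples: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.scenario, int):
            object.__setattr__(self, "scenario", _SCENARIO_BY_NUM[self.scenario])
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0 <= self.k_added <= self.sample_size:
            raise ValueError("k_added must lie in [0, sample_size]")


# ---------------------------------------------------------------------------
# sampling and tally kernels


def _sample_index_sets(
    rng: np.random.Generator, n: int, k: int, size: int
) -> np.ndarray:
    """``size`` uniform k-subsets of range(n) as a (size, k) int array.

    Draws with replacement and redraws rows containing duplicates; for
    k**2 << n the redraw fraction is tiny.
    """
    if k > n:
        raise ValueError("cannot sample more indices than subjects")
    idx = rng.integers(0, n, size=(size, k), dtype=np.int32)
    while True:
        s = np.sort(idx, axis=1)
        bad = (np.diff(s, axis=1) == 0).any(axis=1)
        n_bad = int(bad.sum())
        if n_bad == 0:
            return idx
        idx[bad] = rng.integers(0, n, size=(n_bad, k), dtype=np.int32)


def _fisher_table(totals: np.ndarray, n: int, k: int) -> np.ndarray:
    """(G, k+1) one-sided Fisher p table: entry [g, a] is the p-value of
    seeing ``a`` carriers of group g among k minor homozygotes when the
    remaining n-k subjects are the common homozygotes."""
    a = np.arange(k + 1)
    return stats.hypergeom.sf(a[None, :] - 1, n, totals[:, None], k)


def _tallies(
    sub: np.ndarray,
    model: str,
    min_count: int,
    fisher_threshold: float,
    p_tab: np.ndarray | None = None,
    rg2_sampler=None,
) -> np.ndarray:
    """Tallies for a (M, k, G) block of sampled homozygote carrier rows.

    ``p_tab`` provides the rest-as-common-homozygote Fisher lookup (ROC
    mode); ``rg2_sampler(rows, gs, a)`` instead samples the common-
    homozygote carrier comparison when heterozygotes exist (type-I mode).
    """
    counts = sub.sum(axis=1)
    if model == "recessive_perm":
        qual = counts >= 1
    elif model in ("rg1", "rg2"):
        qual = counts >= min_count
        if model == "rg2":
            qual = qual.copy()
            rows, gs = np.nonzero(qual)
            if len(rows):
                a = counts[rows, gs]
                if rg2_sampler is not None:
                    qual[rows, gs] = rg2_sampler(rows, gs, a)
                else:
                    qual[rows, gs] = p_tab[gs, a] < fisher_threshold
    else:
        raise ValueError(f"unknown model {model!r}")
    return (sub & qual[:, None, :]).any(axis=2).sum(axis=1)


def _p_from_tallies(T: np.ndarray, B: int, estimator: str = "plain") -> np.ndarray:
    """Rows of shape (R, B+1): column 0 observed, rest permuted."""
    n_ge = (T[:, 1:] >= T[:, :1]).sum(axis=1)
    if estimator == "anchored":
        return (n_ge + 1) / (B + 1)
    return n_ge / B


# ---------------------------------------------------------------------------
# type-I error


def _rg2_cutoffs(h: int, n0: int, n_rest: int, threshold: float) -> np.ndarray:
    """For each carrier count a among h minor homozygotes, the largest
    common-homozygote carrier count c with one-sided Fisher p < threshold
    (-1 when no c qualifies).  Monotonicity of p in c makes this a simple
    search."""
    a = np.arange(h + 1)
    c = np.arange(min(n0, n_rest) + 1)
    p = stats.hypergeom.sf(a[:, None] - 1, h + n0, a[:, None] + c[None, :], h)
    ok = p < threshold
    cut = np.where(ok.any(axis=1), ok.sum(axis=1) - 1, -1)
    return cut.astype(np.int64)


def empirical_type1(
    D: np.ndarray,
    dosages: np.ndarray,
    models: tuple[str, ...] = ("rg1", "rg2"),
    n_shuffles_per_snp: int = 100,
    B: int = 1_000,
    levels: tuple[float, ...] = (0.05, 0.01, 0.001),
    seed: int = 0,
    min_count: int = 2,
    fisher_threshold: float = 0.1,
    estimator: str = "plain",
    max_block: int = 250_000,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Empirical type-I error of the reverse-genetics models.

    ``D`` is the cohort carrier matrix over the phenotype's constituent
    groups; ``dosages`` an (n_subjects, n_snps) panel (already
    QC-filtered).  Each SNP contributes ``n_shuffles_per_snp`` randomized
    copies, each scored with a B-permutation p-value; rate(alpha) is the
    fraction of randomized SNPs with p < alpha.

    Returns (rate table, per-model p-value arrays).
    """
    D = np.asarray(D, dtype=bool)
    n = D.shape[0]
    totals = D.sum(axis=0).astype(np.int64)
    if B < 1.0 / min(levels):
        warnings.warn(
            f"B={B} cannot resolve the smallest level {min(levels)}", stacklevel=2
        )
    pvals: dict[str, list[np.ndarray]] = {mdl: [] for mdl in models}
    n_skipped = 0
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        h = int((col == 2).sum())
        n0 = int((col == 0).sum())
        if h == 0:
            n_skipped += 1
            continue
        rng = np.random.default_rng([seed, j])
        cut = (
            _rg2_cutoffs(h, n0, n - h, fisher_threshold) if "rg2" in models else None
        )

        def rg2_sampler(rows, gs, a, _rng=rng, _cut=cut, _h=h, _n0=n0):
            ngood = totals[gs] - a
            nbad = (n - _h) - ngood
            c = _rng.hypergeometric(ngood, nbad, _n0)
            return c <= _cut[a]

        R = n_shuffles_per_snp
        per_row = B + 1
        rows_per_block = max(1, max_block // per_row)
        done = 0
        parts: dict[str, list[np.ndarray]] = {mdl: [] for mdl in models}
        while done < R:
            r = min(rows_per_block, R - done)
            idx = _sample_index_sets(rng, n, h, r * per_row)
            sub = D[idx]  # (M, h, G)
            for mdl in models:
                T = _tallies(
                    sub,
                    mdl,
                    min_count,
                    fisher_threshold,
                    rg2_sampler=rg2_sampler if mdl == "rg2" else None,
                ).reshape(r, per_row)
                parts[mdl].append(_p_from_tallies(T, B, estimator))
            done += r
        for mdl in models:
            pvals[mdl].append(np.concatenate(parts[mdl]))
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} SNP(s) with no minor-allele homozygotes",
            stacklevel=2,
        )
    out = {mdl: np.concatenate(v) if v else np.array([]) for mdl, v in pvals.items()}
    rows = [
        {
            "model": mdl,
            "alpha": a,
            "rate": float((out[mdl] < a).mean()) if len(out[mdl]) else float("nan"),
            "n_snps": len(out[mdl]),
        }
        for mdl in models
        for a in levels
    ]
    return pd.DataFrame(rows), out


# ---------------------------------------------------------------------------
# case-assignment scenarios and ROC


def assign_cases(
    D: np.ndarray,
    sample_idx: np.ndarray,
    rng: np.random.Generator,
    scenario: str,
    k_added: int,
    group_freqs: np.ndarray | None = None,
    max_retries: int = 100,
) -> list[tuple[int, int]]:
    """Choose the (subject, group) additions for one spiked sample.

    Each of ``k_added`` distinct sampled subjects gains one constituent
    group it does not already carry (existing diagnoses are retained).
    Scenario ``random_uniform`` draws the group uniformly per subject;
    ``frequency_weighted`` draws it with probability proportional to the
    group's carrier frequency in the data set; ``already_present``
    restricts to groups already present among the sampled subjects (raises
    :class:`SampleInfeasible` when none is, so the caller can redraw);
    ``same_random`` draws one group and gives it to all ``k_added``
    subjects.  Returns global (subject_index, group_index) pairs.
    """
    if isinstance(scenario, int):
        scenario = _SCENARIO_BY_NUM[scenario]
    G = D.shape[1]
    if G == 0:
        raise ValueError("no constituent groups to assign")
    if k_added == 0:
        return []
    s_rows = D[sample_idx]
    if scenario == "same_random":
        for _ in range(max_retries):
            g = int(rng.integers(G))
            eligible = np.nonzero(~s_rows[:, g])[0]
            if len(eligible) >= k_added:
                pick = rng.choice(len(eligible), size=k_added, replace=False)
                return [(int(sample_idx[i]), g) for i in eligible[pick]]
        raise SampleInfeasible("no group with enough non-carriers in sample")
    if scenario == "already_present":
        pool_groups = np.nonzero(s_rows.any(axis=0))[0]
        if len(pool_groups) == 0:
            raise SampleInfeasible("no diagnosis present among sampled subjects")
    elif scenario in ("random_uniform", "frequency_weighted"):
        pool_groups = np.arange(G)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "frequency_weighted":
        if group_freqs is None:
            group_freqs = D.mean(axis=0)
        weights = np.asarray(group_freqs, dtype=float)
    else:
        weights = np.ones(G)
    eligible_subj = np.nonzero((~s_rows[:, pool_groups]).any(axis=1))[0]
    if len(eligible_subj) < k_added:
        raise SampleInfeasible("not enough subjects with an assignable group")
    chosen = rng.choice(len(eligible_subj), size=k_added, replace=False)
    out = []
    for i in eligible_subj[chosen]:
        opts = pool_groups[~s_rows[i, pool_groups]]
        w = weights[opts]
        if w.sum() <= 0:
            w = np.ones(len(opts))
        out.append((int(sample_idx[i]), int(rng.choice(opts, p=w / w.sum()))))
    return out


def _paired_p(
    D: np.ndarray,
    totals: np.ndarray,
    sample_idx: np.ndarray,
    B: int,
    rng: np.random.Generator,
    models: tuple[str, ...],
    min_count: int,
    fisher_threshold: float,
    p_tabs: dict[str, np.ndarray],
    estimator: str,
) -> dict[str, float]:
    """One sample's permutation p per model, sample-vs-rest design."""
    n, _ = D.shape
    k = len(sample_idx)
    idx = np.vstack([sample_idx[None, :], _sample_index_sets(rng, n, k, B)])
    sub = D[idx]
    out = {}
    for mdl in models:
        T = _tallies(
            sub, mdl, min_count, fisher_threshold,
            p_tab=p_tabs.get(mdl),
        ).reshape(1, B + 1)
        out[mdl] = float(_p_from_tallies(T, B, estimator)[0])
    return out


def scenario_scores(
    D: np.ndarray,
    spec: ScenarioSpec,
    models: tuple[str, ...] = ("recessive_perm", "rg1", "rg2"),
    B: int = 1_000,
    min_count: int = 2,
    fisher_threshold: float = 0.1,
    estimator: str = "plain",
    max_sample_retries: int = 1_000,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Paired null/spiked permutation p-values under one scenario.

    For each of ``spec.n_samples`` draws of ``sample_size`` subjects the
    sample is scored as-is (null) and after the scenario's case additions
    (spiked); in both cases the sampled subjects act as a SNP's minor
    homozygotes with the remaining cohort as common homozygotes, and the
    permutation null redraws the homozygote sample from the same (spiked
    or unspiked) diagnosis data, so the qualifying-diagnosis optimisation
    is applied to null and observed alike.

    Returns ``{model: (p_null, p_spiked)}``.
    """
    D = np.asarray(D, dtype=bool)
    n, G = D.shape
    totals = D.sum(axis=0).astype(np.int64)
    freqs = D.mean(axis=0)
    rng = np.random.default_rng(spec.seed)
    null_tab = {"rg2": _fisher_table(totals, n, spec.sample_size)}
    p_null = {mdl: np.empty(spec.n_samples) for mdl in models}
    p_spiked = {mdl: np.empty(spec.n_samples) for mdl in models}
    n_redrawn = 0
    for r in range(spec.n_samples):
        for _ in range(max_sample_retries):
            sample_idx = rng.choice(n, size=spec.sample_size, replace=False)
            try:
                additions = assign_cases(
                    D, sample_idx, rng, spec.scenario, spec.k_added, freqs
                )
                break
            except SampleInfeasible:
                n_redrawn += 1
        else:
            raise SampleInfeasible("could not draw a feasible sample")
        res = _paired_p(
            D, totals, sample_idx, B, rng, models, min_count,
            fisher_threshold, null_tab, estimator,
        )
        for mdl in models:
            p_null[mdl][r] = res[mdl]
        D_sp = D.copy()
        totals_sp = totals.copy()
        for i, g in additions:
            if not D_sp[i, g]:
                D_sp[i, g] = True
                totals_sp[g] += 1
        sp_tab = {"rg2": _fisher_table(totals_sp, n, spec.sample_size)}
        res = _paired_p(
            D_sp, totals_sp, sample_idx, B, rng, models, min_count,
            fisher_threshold, sp_tab, estimator,
        )
        for mdl in models:
            p_spiked[mdl][r] = res[mdl]
    if n_redrawn:
        warnings.warn(f"redrew {n_redrawn} infeasible sample(s)", stacklevel=2)
    return {mdl: (p_null[mdl], p_spiked[mdl]) for mdl in models}


def roc_auc(null_scores: np.ndarray, case_scores: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank ties; lower p-value = more case-like.

    AUC = P(p_case < p_null) + 0.5 * P(tie).
    """
    null_scores = np.asarray(null_scores, dtype=float)
    case_scores = np.asarray(case_scores, dtype=float)
    if len(null_scores) == 0 or len(case_scores) == 0:
        raise ValueError("both score sets must be non-empty")
    combined = np.concatenate([case_scores, null_scores])
    ranks = stats.rankdata(combined)
    r_case = ranks[: len(case_scores)].sum()
    n_c, n_n = len(case_scores), len(null_scores)
    u_case_greater = r_case - n_c * (n_c + 1) / 2.0
    return float(1.0 - u_case_greater / (n_c * n_n))


def roc_study(
    D: np.ndarray,
    scenarios=("random_uniform", "frequency_weighted", "already_present", "same_random"),
    k_values=(1, 2, 3, 4, 5),
    models: tuple[str, ...] = ("recessive_perm", "rg1", "rg2"),
    n_samples: int = 10_000,
    sample_size: int = 13,
    B: int = 1_000,
    seed: int = 0,
    **kw,
) -> pd.DataFrame:
    """AUC table over scenarios x k_added x models."""
    rows = []
    for s_i, scen in enumerate(scenarios):
        for k in k_values:
            spec = ScenarioSpec(
                scenario=scen, k_added=k, sample_size=sample_size,
                n_samples=n_samples, seed=int(np.random.default_rng([seed, s_i, k]).integers(2**31)),
            )
            scores = scenario_scores(D, spec, models=models, B=B, **kw)
            for mdl, (pn, ps) in scores.items():
                rows.append(
                    {
                        "model": mdl,
                        "scenario": spec.scenario,
                        "k_added": k,
                        "auc": roc_auc(pn, ps),
                        "n_samples": n_samples,
                    }
                )
    return pd.DataFrame(rows)
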