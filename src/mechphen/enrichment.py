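"""Sequential top-k ontology enrichment over association-ranked genes.

Genes are ranked by their best association p-value with a mechanistic
phenotype.  For every nested top-k prefix of the ranking (k up to the
number of genes below an association-p cutoff, default 0.05, or a fixed
top-n in GWAS mode), each ontology term is tested for over-representation
among the selected genes against the rest of the gene universe with a
one-sided Fisher exact (hypergeometric tail) test.  Each term reports the
minimum Fisher p over the scan together with the k and association-p
threshold attaining it, and the minima are adjusted over the full
ontology universe with a Benjamini-Hochberg step-up FDR.

A term is called significantly enriched iff its FDR q < 0.05 AND at least
two selected genes carry it.  Note the scan's min-p is anti-conservative
by construction (it is a minimum over nested tests); the FDR values
inherit that, which is why the two-gene rule and the whole-universe
correction are part of the significance call.  An optional rank-shuffling
permutation calibration is available for the min-p (off by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .forward import FORWARD_MODELS
from .io_formats import OntologyAnnotation

__all__ = [
    "rank_genes",
    "ontology_fisher",
    "sequential_scan",
    "bh_adjust",
    "scan_minp_permutation_calibration",
]


def rank_genes(results: pd.DataFrame, mode: str = "single_phenotype") -> pd.DataFrame:
    """Rank genes by their best (minimum) association p-value.

    ``results`` rows carry gene_id, phenotype_id and p from one model
    (forward-model rows are expected pre-filtered to OR>1).  A gene with
    several nsSNPs is ranked at its minimum p.  In ``pooled`` mode the
    minimum is additionally taken across phenotypes (each gene appears
    once) and the phenotype supplying the best p is recorded.  Order is
    ascending p with ties broken by gene_id, so rankings are stable.
    """
    if results.empty:
        raise ValueError("no association results to rank")
    if mode not in ("single_phenotype", "pooled", "pooled_pairs"):
        raise ValueError(f"unknown ranking mode {mode!r}")
    df = results.dropna(subset=["p"]).copy()
    if mode == "single_phenotype" and df["phenotype_id"].nunique() > 1:
        raise ValueError("single_phenotype ranking got results from several phenotypes")
    if df.empty:
        raise ValueError("all association p-values are missing")
    if mode == "pooled_pairs":
        # alternative pooled universe: one entry per gene x phenotype pair
        idx = df.groupby(["gene_id", "phenotype_id"])["p"].idxmin()
    else:
        idx = df.groupby("gene_id")["p"].idxmin()
    ranked = df.loc[idx, ["gene_id", "p", "phenotype_id"]].rename(
        columns={"phenotype_id": "source"}
    )
    return ranked.sort_values(["p", "gene_id"], kind="stable").reset_index(drop=True)


def ontology_fisher(k_selected: int, a_annotated: int, universe: int, annotated: int) -> float:
    """One-sided enrichment p for a 2x2 gene table.

    ``a_annotated`` of the ``k_selected`` top genes carry the term;
    ``annotated`` of the ``universe`` genes carry it overall.  p = P(X >=
    a), X ~ Hypergeometric(universe, annotated, k_selected).
    """
    if not (0 <= a_annotated <= min(k_selected, annotated) and k_selected <= universe):
        raise ValueError("impossible enrichment table")
    return float(stats.hypergeom.sf(a_annotated - 1, universe, annotated, k_selected))


def _k_grid(pvals: np.ndarray, k_max: int) -> np.ndarray:
    """Nested prefix sizes: every k where the next gene has a strictly
    larger p, so ties at a p boundary are always included together."""
    n = len(pvals)
    ks = [
        k
        for k in range(1, min(k_max, n) + 1)
        if k == n or pvals[k] > pvals[k - 1]
    ]
    if not ks:
        ks = [min(k_max, n)]
    return np.asarray(ks, dtype=int)


def sequential_scan(
    ranked: pd.DataFrame,
    annotation: OntologyAnnotation,
    p_cut: float = 0.05,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Run the sequential enrichment scan for every ontology term.

    The universe is every gene in ``ranked`` (the full analysed gene set);
    m for the FDR step is the number of distinct terms annotating >= 1
    universe gene.  Selection depth: all genes with association p < p_cut,
    or a fixed ``top_n`` (GWAS mode) when given.  Returns one row per term
    with the scan minimum Fisher p, the attaining k and p threshold, the
    annotated selected genes, the BH q-value and the significance call
    (q < 0.05 and >= 2 annotated genes), sorted by (fdr_q, fisher_p,
    ontology_id).
    """
    if ranked.empty:
        raise ValueError("ranked gene list is empty")
    genes = ranked["gene_id"].tolist()
    pvals = ranked["p"].to_numpy(dtype=float)
    N = len(genes)
    terms = sorted(annotation.universe_terms(genes))
    m = len(terms)
    if top_n is not None:
        k_max = min(top_n, N)
    else:
        k_max = int((pvals < p_cut).sum())
    if k_max == 0 or m == 0:
        return pd.DataFrame(
            columns=[
                "ontology_id", "term_name", "p_threshold", "k_selected",
                "a_annotated", "total_annotated", "fisher_p", "fdr_q",
                "significant", "genes",
            ]
        )
    term_pos = {t: j for j, t in enumerate(terms)}
    A = np.zeros((N, m), dtype=np.int32)
    for i, g in enumerate(genes):
        for t in annotation.terms_of(g):
            A[i, term_pos[t]] = 1
    totals = A.sum(axis=0)  # K per term
    ks = _k_grid(pvals, k_max)
    cum = np.cumsum(A, axis=0)  # a at prefix k is cum[k-1]
    a_at_k = cum[ks - 1]  # (n_k, m)
    with np.errstate(invalid="ignore"):
        P = stats.hypergeom.sf(a_at_k - 1, N, totals[None, :], ks[:, None])
    best = P.argmin(axis=0)
    fisher_p = P[best, np.arange(m)]
    k_best = ks[best]
    a_best = a_at_k[best, np.arange(m)]
    q = bh_adjust(fisher_p, m)
    rows = []
    for j, t in enumerate(terms):
        k = int(k_best[j])
        sel = genes[:k]
        annotated_sel = [g for g in sel if t in annotation.terms_of(g)]
        rows.append(
            {
                "ontology_id": t,
                "term_name": annotation.term_names.get(t, ""),
                "p_threshold": float(pvals[k - 1]),
                "k_selected": k,
                "a_annotated": int(a_best[j]),
                "total_annotated": int(totals[j]),
                "fisher_p": float(fisher_p[j]),
                "fdr_q": float(q[j]),
                "significant": bool(q[j] < 0.05 and a_best[j] >= 2),
                "genes": ",".join(annotated_sel),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["fdr_q", "fisher_p", "ontology_id"], kind="stable"
    )
    return out.reset_index(drop=True)


def bh_adjust(pvals, m: int) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over a universe of ``m`` tests.

    ``m`` may exceed the list length (untested hypotheses implicitly have
    p = 1); it must not be smaller.  q_(i) = min_{j>=i} p_(j) * m / j,
    capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < len(p):
        raise ValueError(f"universe m={m} smaller than number of p-values {len(p)}")
    padded = np.concatenate([p, np.ones(m - len(p))])
    q = multipletests(padded, method="fdr_bh")[1]
    return q[: len(p)]


def scan_minp_permutation_calibration(
    ranked: pd.DataFrame,
    annotation: OntologyAnnotation,
    n_perm: int = 200,
    p_cut: float = 0.05,
    top_n: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Optional calibration of the scan minimum by rank shuffling.

    The gene ranking (p-values kept in place) is permuted ``n_perm``
    times and the scan re-run; each term receives the fraction of
    shuffles whose min Fisher p is <= the observed one (anchored
    estimator).  This addresses the min-over-k anti-conservatism; it is
    not part of the default significance rule.
    """
    obs = sequential_scan(ranked, annotation, p_cut=p_cut, top_n=top_n)
    if obs.empty:
        return obs
    rng = np.random.default_rng(seed)
    counts = pd.Series(0, index=obs["ontology_id"].to_numpy())
    for _ in range(n_perm):
        shuffled = ranked.copy()
        shuffled["gene_id"] = rng.permutation(shuffled["gene_id"].to_numpy())
        null = sequential_scan(shuffled, annotation, p_cut=p_cut, top_n=top_n)
        null_p = null.set_index("ontology_id")["fisher_p"]
        obs_p = obs.set_index("ontology_id")["fisher_p"]
        counts += (null_p.reindex(counts.index) <= obs_p.reindex(counts.index)).astype(int)
    obs = obs.copy()
    obs["perm_calibrated_p"] = (
        (counts.reindex(obs["ontology_id"]).to_numpy() + 1) / (n_perm + 1)
    )
    return obs
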