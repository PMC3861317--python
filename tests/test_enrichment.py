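import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mechphen.enrichment import (
    bh_adjust,
    ontology_fisher,
    rank_genes,
    sequential_scan,
)
from mechphen.io_formats import OntologyAnnotation
from oracle_utils import bh_stepup, hyper_sf_ge


def _results(rows):
    return pd.DataFrame(rows, columns=["gene_id", "phenotype_id", "p", "model"])


def test_rank_genes_min_convention():
    df = _results(
        [("G1", "P", 0.20, "rg1"), ("G1", "P", 0.04, "rg1"), ("G2", "P", 0.10, "rg1")]
    )
    ranked = rank_genes(df)
    assert ranked["gene_id"].tolist() == ["G1", "G2"]
    assert ranked["p"].tolist() == [0.04, 0.10]


def test_rank_genes_pooled_records_source():
    df = _results([("G1", "CA", 0.01, "rg1"), ("G1", "SKN", 0.8, "rg1")])
    ranked = rank_genes(df, mode="pooled")
    assert len(ranked) == 1
    assert ranked.loc[0, "p"] == 0.01 and ranked.loc[0, "source"] == "CA"


def test_rank_genes_pooled_pairs_keeps_pairs():
    df = _results([("G1", "CA", 0.01, "rg1"), ("G1", "SKN", 0.8, "rg1")])
    assert len(rank_genes(df, mode="pooled_pairs")) == 2


def test_rank_genes_sort_oracle(rng):
    genes = [f"g{i}" for i in range(40)]
    df = _results(
        [(g, "P", p, "rg1") for g, p in zip(genes, rng.random(40).round(2))]
    )
    ranked = rank_genes(df)
    expected = sorted(zip(df["p"], df["gene_id"]))
    assert list(zip(ranked["p"], ranked["gene_id"])) == expected


def test_rank_genes_empty_errors():
    with pytest.raises(ValueError):
        rank_genes(_results([]))


def test_ontology_fisher_printed_configuration():
    # both of the only 2 annotated genes in a 748-gene universe in the top 2
    assert ontology_fisher(2, 2, 748, 2) == pytest.approx(3.6e-6, rel=0.01)


def test_ontology_fisher_zero_overlap_is_one():
    assert ontology_fisher(5, 0, 100, 10) == 1.0


def test_ontology_fisher_impossible_table():
    with pytest.raises(ValueError):
        ontology_fisher(2, 3, 100, 10)


def test_ontology_fisher_vs_bruteforce_oracle(rng):
    for _ in range(200):
        N = int(rng.integers(5, 60))
        K = int(rng.integers(0, N + 1))
        k = int(rng.integers(1, N + 1))
        a = int(rng.integers(max(0, k + K - N), min(k, K) + 1))
        assert ontology_fisher(k, a, N, K) == pytest.approx(
            hyper_sf_ge(a, N, K, k), abs=1e-12
        )


def _annotation(mapping, names=None):
    return OntologyAnnotation(
        {g: frozenset(ts) for g, ts in mapping.items()}, names or {}
    )


def test_scan_term_on_every_gene_is_never_enriched():
    genes = [f"g{i}" for i in range(6)]
    ranked = pd.DataFrame(
        {"gene_id": genes, "p": np.linspace(0.001, 0.04, 6), "source": "P"}
    )
    ann = _annotation({g: {"T"} for g in genes})
    out = sequential_scan(ranked, ann)
    assert out.loc[0, "fisher_p"] == pytest.approx(1.0)


def test_scan_toy_min_at_k2():
    # term carried only by the top-2 of 6 genes: min p at k=2 is 1/C(6,2)
    genes = [f"g{i}" for i in range(6)]
    ranked = pd.DataFrame(
        {"gene_id": genes, "p": np.linspace(0.001, 0.04, 6), "source": "P"}
    )
    ann = _annotation({"g0": {"T"}, "g1": {"T"}})
    out = sequential_scan(ranked, ann)
    row = out.set_index("ontology_id").loc["T"]
    assert row["fisher_p"] == pytest.approx(1 / 15)
    assert row["k_selected"] == 2
    assert row["a_annotated"] == 2
    assert row["p_threshold"] == pytest.approx(ranked["p"][1])
    assert row["genes"] == "g0,g1"


def test_scan_reports_seeded_geometry():
    """Coagulation-like fixture: a term carried by 3 genes seeded into the
    top 8 of 404 is recovered at k=8 with exactly those genes."""
    rng = np.random.default_rng(5)
    genes = [f"gene{i:03d}" for i in range(404)]
    p = np.sort(rng.uniform(0.05, 1.0, 404))
    p[:8] = np.linspace(0.001, 0.012, 8)
    ranked = pd.DataFrame({"gene_id": genes, "p": p, "source": "THROMBOSIS"})
    seeded = [genes[2], genes[5], genes[7]]
    mapping = {g: {"GO:COAG"} for g in seeded}
    # background annotations so the universe has more than one term
    for g in genes[50:80]:
        mapping[g] = {"GO:OTHER"}
    out = sequential_scan(ranked, _annotation(mapping)).set_index("ontology_id")
    row = out.loc["GO:COAG"]
    assert row["k_selected"] == 8
    assert row["a_annotated"] == 3
    assert sorted(row["genes"].split(",")) == sorted(seeded)
    assert row["p_threshold"] == pytest.approx(0.012)
    assert row["significant"]


def test_scan_tie_jump_includes_all_tied_genes():
    genes = [f"g{i}" for i in range(5)]
    ranked = pd.DataFrame(
        {"gene_id": genes, "p": [0.01, 0.02, 0.02, 0.02, 0.03], "source": "P"}
    )
    ann = _annotation({"g1": {"T"}, "g2": {"T"}})
    out = sequential_scan(ranked, ann).set_index("ontology_id")
    # k can only be 1, 4 or 5: the three tied genes enter together
    assert out.loc["T", "k_selected"] in (1, 4, 5)
    assert out.loc["T", "k_selected"] == 4


def test_scan_no_genes_below_cut_returns_empty_with_columns():
    ranked = pd.DataFrame({"gene_id": ["g"], "p": [0.5], "source": "P"})
    out = sequential_scan(ranked, _annotation({"g": {"T"}}), p_cut=0.05)
    assert out.empty and "fisher_p" in out.columns


def test_scan_top_n_mode():
    genes = [f"g{i}" for i in range(10)]
    ranked = pd.DataFrame(
        {"gene_id": genes, "p": np.linspace(0.2, 0.9, 10), "source": "P"}
    )
    ann = _annotation({"g0": {"T"}, "g1": {"T"}})
    out = sequential_scan(ranked, ann, top_n=5).set_index("ontology_id")
    assert out.loc["T", "k_selected"] <= 5
    assert out.loc["T", "fisher_p"] == pytest.approx(1 / 45)  # C(10,2)


def test_scan_minp_not_above_any_scan_point():
    rng = np.random.default_rng(8)
    genes = [f"g{i}" for i in range(30)]
    ranked = pd.DataFrame(
        {"gene_id": genes, "p": np.sort(rng.uniform(0, 0.05, 30)), "source": "P"}
    )
    mapping = {g: {"T"} for g in rng.choice(genes, 8, replace=False)}
    out = sequential_scan(ranked, _annotation(mapping)).set_index("ontology_id")
    annotated = set(mapping)
    for k in range(1, 31):
        a = sum(1 for g in genes[:k] if g in annotated)
        assert out.loc["T", "fisher_p"] <= ontology_fisher(k, a, 30, 8) + 1e-12


def test_significance_rule_requires_two_genes():
    genes = [f"g{i}" for i in range(50)]
    ranked = pd.DataFrame(
        {"gene_id": genes, "p": np.linspace(1e-4, 0.04, 50), "source": "P"}
    )
    ann = _annotation({"g0": {"SOLO"}, "g1": {"OTHER"}, "g2": {"OTHER"}})
    out = sequential_scan(ranked, ann).set_index("ontology_id")
    assert not out.loc["SOLO", "significant"]  # single gene can never qualify
    assert out.loc["SOLO", "a_annotated"] <= 1


def test_bh_printed_example():
    q = bh_adjust([2e-5, 3e-5, 3e-5], 2623)
    assert round(q[0], 2) == 0.03


def test_bh_single_p_m_one():
    assert bh_adjust([0.04], 1)[0] == pytest.approx(0.04)


def test_bh_m_smaller_than_list_errors():
    with pytest.raises(ValueError):
        bh_adjust([0.1, 0.2], 1)


@given(
    st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
    st.integers(min_value=0, max_value=3000),
)
def test_bh_matches_stepup_oracle(pvals, extra):
    m = len(pvals) + extra
    ours = bh_adjust(pvals, m)
    theirs = bh_stepup(pvals, m)
    assert np.max(np.abs(ours - theirs)) < 1e-12


def test_bh_monotone_in_rank(rng):
    for _ in range(50):
        p = np.sort(rng.random(rng.integers(1, 20)))
        q = bh_adjust(p, len(p) + int(rng.integers(0, 100)))
        assert (np.diff(q) >= -1e-15).all()
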