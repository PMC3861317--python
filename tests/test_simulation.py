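import numpy as np
import pytest
from scipy import stats

from mechphen.simulate import (
    SampleInfeasible,
    ScenarioSpec,
    _fisher_table,
    _sample_index_sets,
    _tallies,
    assign_cases,
    empirical_type1,
    roc_auc,
    scenario_scores,
)
from oracle_utils import auc_by_pairs, hyper_sf_ge


# ---------------------------------------------------------------- roc_auc


def test_auc_identical_distributions_half():
    s = np.array([0.1, 0.2, 0.3, 0.4])
    assert roc_auc(s, s) == pytest.approx(0.5)


def test_auc_pairwise_enumeration_example():
    assert roc_auc(np.array([0.2, 0.8]), np.array([0.1, 0.8])) == pytest.approx(0.625)


def test_auc_matches_pairwise_oracle(rng):
    for _ in range(25):
        null = rng.choice([0.0, 0.001, 0.05, 0.2, 1.0], size=30)
        case = rng.choice([0.0, 0.001, 0.05, 0.2, 1.0], size=20)
        assert roc_auc(null, case) == pytest.approx(
            auc_by_pairs(null, case), abs=1e-12
        )


def test_auc_empty_errors():
    with pytest.raises(ValueError):
        roc_auc(np.array([]), np.array([0.5]))


# ------------------------------------------------------------ assign_cases


def test_assign_cases_zero_added_is_noop(carriers, rng):
    assert assign_cases(carriers, np.arange(13), rng, "random_uniform", 0) == []


def test_assign_cases_adds_new_distinct_subjects(carriers, rng):
    for scen in ("random_uniform", "frequency_weighted", "same_random"):
        sample = rng.choice(carriers.shape[0], 13, replace=False)
        adds = assign_cases(carriers, sample, rng, scen, 3)
        assert len(adds) == 3
        subjects = [s for s, _ in adds]
        assert len(set(subjects)) == 3
        for s, g in adds:
            assert s in sample
            assert not carriers[s, g]  # genuinely new diagnosis


def test_assign_cases_same_random_one_group_gains_k(carriers, rng):
    sample = rng.choice(carriers.shape[0], 13, replace=False)
    adds = assign_cases(carriers, sample, rng, "same_random", 5)
    groups = {g for _, g in adds}
    assert len(groups) == 1 and len(adds) == 5
    g = groups.pop()
    assert all(not carriers[s, g] for s, _ in adds)


def test_assign_cases_already_present_restricts_pool(carriers, rng):
    for _ in range(20):
        sample = rng.choice(carriers.shape[0], 13, replace=False)
        try:
            adds = assign_cases(carriers, sample, rng, "already_present", 3)
        except SampleInfeasible:
            assert not carriers[sample].any()
            continue
        present = set(np.nonzero(carriers[sample].any(axis=0))[0])
        assert {g for _, g in adds} <= present


def test_assign_cases_infeasible_raises():
    D = np.zeros((20, 3), dtype=bool)
    with pytest.raises(SampleInfeasible):
        assign_cases(
            D, np.arange(13), np.random.default_rng(0), "already_present", 2
        )


def test_assign_cases_frequency_weighted_tracks_dataset_frequencies(carriers, rng):
    """Scenario-2 assignment frequencies should be proportional to carrier
    frequencies (chi-square GOF not rejected at p > 0.001)."""
    freqs = carriers.mean(axis=0)
    counts = np.zeros(carriers.shape[1])
    n_draws = 4_000
    for _ in range(n_draws):
        sample = rng.choice(carriers.shape[0], 13, replace=False)
        for _, g in assign_cases(carriers, sample, rng, "frequency_weighted", 1, freqs):
            counts[g] += 1
    expected = freqs / freqs.sum() * counts.sum()
    # the not-already-carried restriction perturbs frequencies only mildly
    _, p = stats.chisquare(counts, expected * counts.sum() / expected.sum())
    assert p > 0.001


# --------------------------------------------------------------- engines


def test_sample_index_sets_are_distinct_and_uniform(rng):
    idx = _sample_index_sets(rng, 30, 5, 4_000)
    assert idx.shape == (4_000, 5)
    s = np.sort(idx, axis=1)
    assert (np.diff(s, axis=1) > 0).all()  # all distinct within a row
    # uniform marginal inclusion: each subject appears ~ 4000*5/30 times
    counts = np.bincount(idx.ravel(), minlength=30)
    _, p = stats.chisquare(counts)
    assert p > 0.001


def test_fast_tallies_match_direct_computation(rng):
    D = rng.random((50, 4)) < 0.3
    idx = _sample_index_sets(rng, 50, 8, 200)
    totals = D.sum(axis=0)
    p_tab = _fisher_table(totals.astype(np.int64), 50, 8)
    for model in ("recessive_perm", "rg1", "rg2"):
        T = _tallies(D[idx], model, 2, 0.1, p_tab=p_tab)
        for row in range(0, 200, 37):
            hz = idx[row]
            qual = []
            for g in range(4):
                cnt = int(D[hz, g].sum())
                if model == "recessive_perm":
                    ok = cnt >= 1
                else:
                    ok = cnt >= 2
                    if ok and model == "rg2":
                        c = int(totals[g] - cnt)
                        ok = hyper_sf_ge(cnt, 50, cnt + c, 8) < 0.1
                if ok:
                    qual.append(g)
            expect = sum(1 for i in hz if any(D[i, g] for g in qual))
            assert T[row] == expect


def test_fast_engine_matches_exhaustive_subset_null(rng):
    """On a small cohort the sampled null tally distribution matches the
    exhaustive enumeration over all homozygote subsets."""
    from itertools import combinations

    D = rng.random((9, 3)) < 0.4
    k = 3
    exact = {}
    subsets = list(combinations(range(9), k))
    for sub in subsets:
        hz = np.array(sub)
        cnt = D[hz].sum(axis=0)
        qual = cnt >= 2
        t = int(D[hz][:, qual].any(axis=1).sum()) if qual.any() else 0
        exact[t] = exact.get(t, 0) + 1
    idx = _sample_index_sets(rng, 9, k, 40_000)
    T = _tallies(D[idx], "rg1", 2, 0.1)
    for t, cnt in exact.items():
        p_exact = cnt / len(subsets)
        p_mc = float((T == t).mean())
        se = np.sqrt(p_exact * (1 - p_exact) / 40_000)
        assert abs(p_mc - p_exact) < 4 * se + 1e-9


def test_empirical_type1_rate_at_one_is_one(carriers):
    dosages = np.array([[2] * 30 + [0] * (carriers.shape[0] - 30)]).T.astype(np.int8)
    rates, pv = empirical_type1(
        carriers, dosages, n_shuffles_per_snp=20, B=50, levels=(1.1,), seed=3
    )
    assert (rates["rate"] == 1.0).all()


def test_empirical_type1_near_nominal_small(carriers, thrombosis_cohort):
    """Reduced-scale check that empirical type-I error tracks alpha."""
    from mechphen.qc import QCThresholds, select_snps

    retained, _ = select_snps(thrombosis_cohort.genotypes, QCThresholds())
    cols = [thrombosis_cohort.genotypes.snp_ids.index(s) for s in retained[:10]]
    dosages = thrombosis_cohort.genotypes.dosages[:, cols]
    rates, pv = empirical_type1(
        carriers, dosages, n_shuffles_per_snp=60, B=200,
        levels=(0.05, 0.2), seed=5,
    )
    for _, row in rates.iterrows():
        se = np.sqrt(row["alpha"] * (1 - row["alpha"]) / row["n_snps"])
        assert row["rate"] < row["alpha"] + 4 * se  # validity (not anti-conservative)


def test_empirical_type1_skips_snps_without_homozygotes(carriers):
    dosages = np.zeros((carriers.shape[0], 1), dtype=np.int8)
    with pytest.warns(UserWarning, match="skipped"):
        rates, pv = empirical_type1(
            carriers, dosages, n_shuffles_per_snp=5, B=20, seed=1
        )
    assert all(len(v) == 0 for v in pv.values())


# -------------------------------------------------------- scenario scores


def test_spiked_tally_never_below_null_for_recessive(carriers, rng):
    """Adding cases can only raise the all-affected tally of the sample."""
    for _ in range(50):
        sample = rng.choice(carriers.shape[0], 13, replace=False)
        adds = assign_cases(carriers, sample, rng, "random_uniform", 3)
        t_null = int(carriers[sample].any(axis=1).sum())
        D_sp = carriers.copy()
        for s, g in adds:
            D_sp[s, g] = True
        t_sp = int(D_sp[sample].any(axis=1).sum())
        assert t_sp >= t_null


def test_auc_half_when_nothing_added(carriers):
    spec = ScenarioSpec(scenario=1, k_added=0, n_samples=250, seed=21)
    scores = scenario_scores(carriers, spec, B=250)
    for model, (pn, ps) in scores.items():
        auc = roc_auc(pn, ps)
        assert abs(auc - 0.5) < 0.075, model


def test_saturated_cohort_degenerates_to_half():
    D = np.ones((120, 1), dtype=bool)  # everyone carries the one diagnosis
    spec = ScenarioSpec(scenario=2, k_added=0, n_samples=60, seed=2)
    scores = scenario_scores(D, spec, B=100)
    for model, (pn, ps) in scores.items():
        assert roc_auc(pn, ps) == pytest.approx(0.5, abs=0.1)


def test_auc_grows_with_added_cases(carriers):
    """Spiking only adds signal: AUC at k=4 exceeds AUC at k=1 for the
    recessive-permutation model under the same-diagnosis scenario."""
    aucs = {}
    for k in (1, 4):
        spec = ScenarioSpec(scenario=4, k_added=k, n_samples=250, seed=31)
        scores = scenario_scores(carriers, spec, B=250, min_count=2)
        pn, ps = scores["recessive_perm"]
        aucs[k] = roc_auc(pn, ps)
    assert aucs[4] > aucs[1]


def test_scenario_spec_validation():
    with pytest.raises(ValueError):
        ScenarioSpec(scenario="bogus")
    with pytest.raises(ValueError):
        ScenarioSpec(k_added=20, sample_size=13)
    assert ScenarioSpec(scenario=3).scenario == "already_present"
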