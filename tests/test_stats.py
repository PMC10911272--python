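"""Blocked ANOVA, BH adjustment, Tukey contrasts, embedding, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import ribomethdiff as rmd
from ribomethdiff.design import Sample, StudyDesign
from ribomethdiff.scoring import RMSScoreTable
from ribomethdiff.simulate import PLANTED_VARIABLE_SITES
from ribomethdiff.stats import (
    bh_adjust,
    blocked_anova_arrays,
    classify_sites,
    eliminate_factor,
    embed_samples,
    fit_blocked_anova,
    nearest_neighbor_label_agreement,
    silhouette_optimal_k,
    tukey_pairwise,
    SiteTestResult,
)

STATES = ("P", "Q", "SIPS")
DONORS = ("d1", "d2", "d3")


def toy_design():
    return StudyDesign(
        tuple(Sample(f"{d}.{s}", d, s) for d in DONORS for s in STATES)
    )


def toy_scores(values_by_state, site="SITE-X"):
    """values_by_state: state -> (d1, d2, d3) values."""
    data = {
        f"{d}.{s}": [values_by_state[s][i]]
        for i, d in enumerate(DONORS)
        for s in STATES
    }
    return pd.DataFrame(data, index=[site])


def brute_force_anova(y):
    """Independent sums-of-squares oracle: explicit loops, no vectorization.

    y[i][j] = observation for state i, donor j."""
    a, b = len(y), len(y[0])
    grand = sum(sum(row) for row in y) / (a * b)
    state_means = [sum(row) / b for row in y]
    donor_means = [sum(y[i][j] for i in range(a)) / a for j in range(b)]
    ss_state = b * sum((m - grand) ** 2 for m in state_means)
    ss_donor = a * sum((m - grand) ** 2 for m in donor_means)
    ss_total = sum((y[i][j] - grand) ** 2 for i in range(a) for j in range(b))
    ss_resid = ss_total - ss_state - ss_donor
    f = (ss_state / (a - 1)) / (ss_resid / ((a - 1) * (b - 1)))
    p = sps.f.sf(f, a - 1, (a - 1) * (b - 1))
    return f, p


TOY_TABLE = {"P": (0.80, 0.82, 0.84), "Q": (0.90, 0.93, 0.94), "SIPS": (0.90, 0.92, 0.94)}


def test_blocked_anova_matches_brute_force_on_toy_table():
    res = fit_blocked_anova(RMSScoreTable(toy_scores(TOY_TABLE)), toy_design())[0]
    f_ref, p_ref = brute_force_anova([list(TOY_TABLE[s]) for s in STATES])
    assert res.f_state == pytest.approx(f_ref, rel=1e-10)
    assert res.p_state == pytest.approx(p_ref, rel=1e-10)
    assert res.group_means["P"] == pytest.approx(0.82)


def test_blocked_anova_matches_statsmodels():
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rows = [
        (d, s, TOY_TABLE[s][i]) for s in STATES for i, d in enumerate(DONORS)
    ]
    df = pd.DataFrame(rows, columns=["donor", "state", "y"])
    tab = sm.stats.anova_lm(ols("y ~ C(donor) + C(state)", df).fit(), typ=2)
    res = fit_blocked_anova(RMSScoreTable(toy_scores(TOY_TABLE)), toy_design())[0]
    assert res.f_state == pytest.approx(tab.loc["C(state)", "F"], rel=1e-8)
    assert res.p_state == pytest.approx(tab.loc["C(state)", "PR(>F)"], rel=1e-8)


@given(
    st.lists(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=4),
        min_size=2,
        max_size=4,
    ).filter(lambda y: len({len(r) for r in y}) == 1)
)
def test_blocked_anova_agrees_with_oracle_on_random_tables(y):
    stats = blocked_anova_arrays(np.array(y))
    if stats["zero_residual"]:
        return  # degenerate tables have their own contract
    f_ref, p_ref = brute_force_anova(y)
    assert stats["f"] == pytest.approx(f_ref, rel=1e-10, abs=1e-10)
    assert stats["p"] == pytest.approx(p_ref, rel=1e-8, abs=1e-12)


def test_constant_table_gives_f_zero_p_one():
    stats = blocked_anova_arrays(np.full((3, 3), 0.7))
    assert stats["f"] == 0.0 and stats["p"] == 1.0


def test_perfectly_additive_table_flags_zero_residual():
    donor_eff = np.array([0.0, 0.01, 0.02])
    state_eff = np.array([0.0, 0.05, 0.10])
    y = 0.8 + state_eff[:, None] + donor_eff[None, :]
    design = toy_design()
    table = {s: tuple(y[i]) for i, s in enumerate(STATES)}
    res = fit_blocked_anova(RMSScoreTable(toy_scores(table)), toy_design())[0]
    assert "zero_residual" in res.flags
    assert res.p_state == 0.0 and np.isinf(res.f_state)


def test_missing_cell_skips_site_with_reason():
    scores = toy_scores(TOY_TABLE)
    scores.loc["SITE-X", "d2.Q"] = np.nan
    res = fit_blocked_anova(RMSScoreTable(scores), toy_design())[0]
    assert res.skipped and "missing" in res.skipped_reason


def test_incomplete_crossing_rejected():
    # a donor observed in only one state cannot be blocked out
    design = StudyDesign(
        tuple(Sample(f"{d}.{s}", d, s) for d in ("d1", "d2") for s in STATES)
        + (Sample("d3.P", "d3", "P"),)
    )
    scores = pd.DataFrame(
        {s.sample_id: [0.5] for s in design}, index=["SITE-X"]
    )
    with pytest.raises(ValueError, match="complete donor x state crossing"):
        fit_blocked_anova(RMSScoreTable(scores), design)


def test_bh_worked_examples():
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_adjust([1.0]) == pytest.approx([1.0])
    assert bh_adjust([0.5, 0.5, 0.5]) == pytest.approx([0.5] * 3)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


def test_bh_propagates_missing_without_counting_them():
    q = bh_adjust([0.01, np.nan, 0.04])
    assert np.isnan(q[1])
    assert q[[0, 2]] == pytest.approx(bh_adjust([0.01, 0.04]))


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    p = rng.uniform(size=50)
    ref = multipletests(p, method="fdr_bh")[1]
    assert bh_adjust(p) == pytest.approx(ref, rel=1e-12)


@given(st.permutations(list(range(8))))
def test_bh_invariant_under_permutation(perm):
    p = np.array([0.001, 0.02, 0.02, 0.3, 0.5, 0.77, 0.9, 1.0])
    q = bh_adjust(p)
    q_perm = bh_adjust(p[perm])
    assert q_perm == pytest.approx(q[perm])


def test_tukey_matches_studentized_range_oracle():
    # oracle: group means over donors, MS_resid from the additive fit,
    # p = sf of the studentized range with k=3 groups, 4 residual df
    tk = tukey_pairwise(RMSScoreTable(toy_scores(TOY_TABLE)), toy_design(), "SITE-X")
    y = [list(TOY_TABLE[s]) for s in STATES]
    a, b = 3, 3
    grand = np.mean(y)
    ss_resid = (
        np.sum((np.array(y) - grand) ** 2)
        - b * np.sum((np.mean(y, axis=1) - grand) ** 2)
        - a * np.sum((np.mean(y, axis=0) - grand) ** 2)
    )
    ms = ss_resid / 4
    for (s1, s2), p in tk.items():
        i, j = STATES.index(s1), STATES.index(s2)
        q_obs = abs(np.mean(y[i]) - np.mean(y[j])) / np.sqrt(ms / b)
        assert p == pytest.approx(sps.studentized_range.sf(q_obs, 3, 4), rel=1e-8)
    assert tk[("P", "Q")] < 0.001 and tk[("Q", "SIPS")] > 0.1


def test_tukey_equal_means_give_p_one():
    # equal state means with positive residual variance (latin-square values)
    table = {"P": (1.0, 2.0, 3.0), "Q": (2.0, 3.0, 1.0), "SIPS": (3.0, 1.0, 2.0)}
    scores = toy_scores({k: tuple(np.array(v) / 10) for k, v in table.items()})
    tk = tukey_pairwise(RMSScoreTable(scores), toy_design(), "SITE-X")
    assert all(p >= 0.999 for p in tk.values())


def test_tukey_detects_large_shift_only_in_shifted_pairs():
    rng = np.random.default_rng(4)
    noise = rng.normal(0, 0.005, size=(3, 3))
    y = 0.8 + noise
    y[0] += 0.1  # P shifted ~ 10+ residual sd
    table = {s: tuple(y[i]) for i, s in enumerate(STATES)}
    tk = tukey_pairwise(RMSScoreTable(toy_scores(table)), toy_design(), "SITE-X")
    assert tk[("P", "Q")] < 0.001 and tk[("P", "SIPS")] < 0.001
    assert tk[("Q", "SIPS")] > 0.9


def test_classification_thresholds():
    scores = pd.DataFrame(
        {"s1": [0.95, 0.60, 0.70]}, index=["high", "var", "stable"]
    )
    results = [
        SiteTestResult("high", q_state=0.5),
        SiteTestResult("var", q_state=0.05),
        SiteTestResult("stable", q_state=0.5),
    ]
    classify_sites(results, scores)
    assert [r.classification for r in results] == [
        "constitutive_high", "variable", "substoichiometric_stable",
    ]


def test_eliminate_factor_removes_pure_donor_effects():
    donor_eff = {"d1": 0.0, "d2": 0.05, "d3": -0.04}
    scores = pd.DataFrame(
        {f"{d}.{s}": [0.8 + donor_eff[d]] for d in DONORS for s in STATES},
        index=["SITE-X"],
    )
    adj = eliminate_factor(scores, toy_design(), "donor")
    assert np.allclose(adj.to_numpy(), adj.to_numpy()[0, 0])


def test_eliminate_factor_is_identity_without_donor_effects_and_idempotent():
    scores = toy_scores({"P": (0.8,) * 3, "Q": (0.9,) * 3, "SIPS": (0.85,) * 3})
    adj = eliminate_factor(scores, toy_design(), "donor")
    pd.testing.assert_frame_equal(adj, scores.astype(float))
    twice = eliminate_factor(adj, toy_design(), "donor")
    pd.testing.assert_frame_equal(twice, adj)


def test_eliminate_factor_improves_state_silhouette(preset_data, design):
    from sklearn.metrics import silhouette_score

    _, _, scores = preset_data
    bio = design.biological_design()
    states = [bio.sample(c).state for c in scores.scores.columns]
    adj = eliminate_factor(scores, design, "donor")
    raw_sil = silhouette_score(scores.scores.to_numpy().T, states)
    adj_sil = silhouette_score(adj.to_numpy().T, states)
    assert adj_sil > raw_sil


def test_embedding_requires_three_samples():
    with pytest.raises(ValueError, match="3 samples"):
        embed_samples(pd.DataFrame({"a": [0.1], "b": [0.2]}), seed=0)


def test_identical_samples_embed_together():
    rng = np.random.default_rng(2)
    base = rng.uniform(size=(30, 6))
    df = pd.DataFrame(base, columns=[f"s{i}" for i in range(6)])
    df["dup"] = df["s0"]
    emb = embed_samples(df, seed=0)
    span = np.ptp(emb.coords.to_numpy(), axis=0).max()
    d = np.linalg.norm(emb.coords.loc["s0"] - emb.coords.loc["dup"])
    assert d < 0.01 * span


def test_raw_embedding_clusters_by_donor_when_donor_dominant(donor_dominant_data, design):
    _, scores = donor_dominant_data
    bio = design.biological_design()
    donors = [bio.sample(c).donor for c in scores.scores.columns]
    states = [bio.sample(c).state for c in scores.scores.columns]
    emb = embed_samples(scores, seed=1)
    donor_agree = nearest_neighbor_label_agreement(emb.coords, donors)
    state_agree = nearest_neighbor_label_agreement(emb.coords, states)
    assert donor_agree >= 7 / 9
    assert donor_agree > state_agree


def test_donor_elimination_flips_embedding_to_state_clusters(donor_dominant_data, design):
    _, scores = donor_dominant_data
    bio = design.biological_design()
    states = [bio.sample(c).state for c in scores.scores.columns]
    adj = eliminate_factor(scores, design, "donor")
    emb = embed_samples(adj, seed=1, eliminated_factor="donor")
    assert nearest_neighbor_label_agreement(emb.coords, states) >= 7 / 9


def test_silhouette_optimal_k_on_separated_triplets():
    rng = np.random.default_rng(0)
    centers = np.array([[0, 0], [10, 0], [0, 10]])
    pts = np.vstack([c + rng.normal(0, 0.1, size=(3, 2)) for c in centers])
    res = silhouette_optimal_k(pts, (2, 5), seed=0)
    assert res.best_k == 3 and not res.weak


def test_silhouette_single_blob_is_weak():
    rng = np.random.default_rng(1)
    pts = rng.normal(0, 1.0, size=(30, 2))
    res = silhouette_optimal_k(pts, (2, 5), seed=0)
    assert res.weak


def test_silhouette_optimal_k_needs_three_points():
    with pytest.raises(ValueError):
        silhouette_optimal_k(np.zeros((2, 2)))


def test_type_one_error_calibrated_on_null_tables():
    """Donor effects but no state effects: the state F-test rejects at the
    nominal 5% rate (exact binomial 99% band, 2000 replicate tables)."""
    rng = np.random.default_rng(123)
    n_rep = 2000
    donor = rng.normal(0, 0.02, size=(n_rep, 1, 3))
    noise = rng.normal(0, 0.01, size=(n_rep, 3, 3))
    y = 0.8 + donor + noise
    p = blocked_anova_arrays(y)["p"]
    hits = int((p < 0.05).sum())
    lo, hi = sps.binom.interval(0.99, n_rep, 0.05)
    assert lo <= hits <= hi


def test_fdr_controlled_at_planted_truth(catalog, design):
    """9 planted positives among 104 sites: mean realized false-discovery
    proportion at q < 0.1 stays at or below 0.1 over 200 simulations."""
    planted = set(PLANTED_VARIABLE_SITES)
    fdps = []
    for rep in range(200):
        seed = 1000 + rep
        truth = rmd.build_truth(catalog, design, seed=seed, **rmd.growth_arrest_preset())
        profiles = rmd.simulate_end_counts(
            truth, rmd.FragmentationParams(seed=seed), catalog
        )
        scores = rmd.compute_rms_scores(
            rmd.merge_technical_replicates(profiles, design), catalog
        )
        results = fit_blocked_anova(scores, design)
        q = bh_adjust([r.p_state for r in results])
        discovered = {r.site for r, qv in zip(results, q) if qv < 0.1}
        fdps.append(len(discovered - planted) / max(len(discovered), 1))
    assert float(np.mean(fdps)) <= 0.1
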