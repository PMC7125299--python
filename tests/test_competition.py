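import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

import cyanoscreen as cs
from cyanoscreen.competition import (
    cluster_trajectories,
    delta_fitness,
    estimate_growth_rate,
    fitness_score,
    gene_fitness,
    generations,
    log2fc_trajectory,
    significance_test,
    size_factors,
    trajectory_features,
)
from oracles import brute_bh, brute_size_factors, trapezoid_by_hand


# ------------------------------------------------------------- size factors


def test_size_factor_closed_cases():
    counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
    assert np.allclose(size_factors(counts), [1, 1])
    counts2 = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
    f = size_factors(counts2)
    assert f["b"] / f["a"] == pytest.approx(2.0)


def test_size_factors_match_definition_on_random_counts():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.negative_binomial(5, 0.05, size=(200, 6)),
        columns=[f"s{i}" for i in range(6)],
    )
    assert np.allclose(size_factors(counts), brute_size_factors(counts.to_numpy()))


def test_size_factors_fallback_without_common_guide():
    counts = pd.DataFrame({"a": [10, 0], "b": [0, 10]})
    with pytest.warns(UserWarning, match="total-count"):
        f = size_factors(counts)
    assert (f > 0).all()


# -------------------------------------------------------------- trajectories


def _meta(condition, times, reps, mu_pop=0.0693):
    rows = []
    for r in range(1, reps + 1):
        for t in times:
            rows.append(
                {
                    "sample_id": f"{condition}_t{t}_r{r}",
                    "condition": condition,
                    "time_h": float(t),
                    "replicate": r,
                    "induced": True,
                    "mu_pop": mu_pop,
                    "n_gen": generations(mu_pop, t),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def test_unchanged_clone_has_flat_trajectory():
    meta = _meta("L100", [0, 10, 20], reps=2)
    counts = pd.DataFrame(100, index=["g1", "g2"], columns=meta.index)
    traj = log2fc_trajectory(counts, meta, "L100")
    assert np.allclose(traj["log2fc"], 0)
    assert traj.loc[traj["time_h"] == 0, "log2fc"].eq(0).all()


def test_halving_per_generation_gives_slope_minus_one():
    mu = 0.0693
    times = [0, 10, 20, 30]  # ~1 generation per 10 h
    meta = _meta("L100", times, reps=1, mu_pop=mu)
    gens = np.array([generations(mu, t) for t in times])
    g1 = 1000 * 2.0 ** (-gens)
    # many stable guides pin the median-of-ratios normalization
    counts = pd.DataFrame(
        {m: [g1[i]] + [10_000] * 50 for i, m in enumerate(meta.index)},
        index=["g1"] + [f"stable{j}" for j in range(50)],
    ).astype(int)
    traj = log2fc_trajectory(counts, meta, "L100", pseudocount=0)
    got = traj[traj["guide_id"] == "g1"].sort_values("n_gen")
    slope = np.polyfit(got["n_gen"], got["log2fc"], 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.02)


def test_trajectory_is_mean_of_replicates():
    meta = _meta("L100", [0, 10], reps=4)
    rng = np.random.default_rng(2)
    counts = pd.DataFrame(
        rng.integers(50, 150, size=(5, len(meta))), index=list("abcde"),
        columns=meta.index,
    )
    traj = log2fc_trajectory(counts, meta, "L100")
    per_rep = []
    norm = counts / size_factors(counts)
    for r in range(1, 5):
        base = norm[f"L100_t0_r{r}"] + 0.5
        per_rep.append(np.log2((norm[f"L100_t10_r{r}"] + 0.5) / base))
    expected = pd.concat(per_rep, axis=1).mean(axis=1)
    got = traj[traj["time_h"] == 10].set_index("guide_id")["log2fc"]
    assert np.allclose(got[expected.index], expected)


def test_missing_t0_raises():
    meta = _meta("L100", [10, 20], reps=2)
    counts = pd.DataFrame(100, index=["g1"], columns=meta.index)
    with pytest.raises(ValueError, match="t=0"):
        log2fc_trajectory(counts, meta, "L100")


# -------------------------------------------------------------- significance


def test_identical_groups_are_nonsignificant():
    rng = np.random.default_rng(3)
    counts = pd.DataFrame(
        rng.poisson(100, size=(300, 8)), columns=[f"s{i}" for i in range(8)]
    )
    res = significance_test(counts, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
    assert res["p_adj"].min() > 0.05
    assert 0.2 < res["p"].median() < 0.8  # roughly uniform nulls


def test_true_depletions_detected_with_low_fdr():
    rng = np.random.default_rng(5)
    n, n_tp = 1000, 10
    base = rng.gamma(20, 5, n)
    tp = rng.choice(n, n_tp, replace=False)
    alt_mean = base.copy()
    alt_mean[tp] /= 8  # 8-fold depletion
    noise = rng.gamma(50, 1 / 50, (n, 8))
    ref = rng.poisson(base[:, None] * noise[:, :4])
    alt = rng.poisson(alt_mean[:, None] * noise[:, 4:])
    counts = pd.DataFrame(
        np.hstack([ref, alt]), index=[f"g{i}" for i in range(n)],
        columns=[f"r{i}" for i in range(4)] + [f"a{i}" for i in range(4)],
    )
    res = significance_test(counts, [f"r{i}" for i in range(4)], [f"a{i}" for i in range(4)])
    tp_ids = counts.index[tp]
    assert (res.loc[tp_ids, "p_adj"] < 0.005).mean() >= 0.95
    null = res.drop(index=tp_ids)
    assert (null["p_adj"] < 0.005).mean() <= 0.01


def test_bh_adjustment_matches_definition():
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.poisson(80, size=(100, 4)), columns=["a1", "a2", "b1", "b2"]
    )
    res = significance_test(counts, ["a1", "a2"], ["b1", "b2"])
    assert np.allclose(res["p_adj"], brute_bh(res["p"]))


# --------------------------------------------------------------- generations


@pytest.mark.parametrize(
    "mu,t,expected,tol",
    [(0.0693, 10, 1.0, 1e-3), (0.03, 768, 33.2, 0.1), (0.5, 0, 0.0, 0)],
)
def test_generations_from_growth_rate(mu, t, expected, tol):
    assert generations(mu, t) == pytest.approx(expected, abs=tol)


def test_generations_rejects_negative_inputs():
    with pytest.raises(ValueError):
        generations(-0.1, 10)


# ------------------------------------------------------------------- fitness


def test_fitness_of_constant_trajectory_is_the_constant():
    gens = [0, 4, 8, 16, 32]
    assert fitness_score(gens, [-2] * 5) == pytest.approx(-2.0)
    assert fitness_score(gens, [0] * 5) == 0.0


def test_fitness_of_linear_depletion():
    gens = np.linspace(0, 16, 5)
    lfc = np.linspace(0, -8, 5)
    assert trapezoid_by_hand(gens, lfc) == pytest.approx(-64.0)
    assert fitness_score(gens, lfc) == pytest.approx(-4.0)


def test_fitness_requires_two_points_and_positive_span():
    with pytest.raises(ValueError):
        fitness_score([0], [0])
    with pytest.raises(ValueError):
        fitness_score([0, 0], [1, 2])


@given(
    st.lists(st.floats(-10, 10), min_size=3, max_size=8),
    st.lists(st.floats(-10, 10), min_size=3, max_size=8),
    st.floats(-3, 3),
    st.floats(-3, 3),
)
@settings(max_examples=50, deadline=None)
def test_fitness_is_linear_in_the_trajectory(y1, y2, a, b):
    m = min(len(y1), len(y2))
    y1, y2 = np.array(y1[:m]), np.array(y2[:m])
    gens = np.linspace(0, 32, m)
    combo = fitness_score(gens, a * y1 + b * y2)
    parts = a * fitness_score(gens, y1) + b * fitness_score(gens, y2)
    assert combo == pytest.approx(parts, abs=1e-9)


def test_delta_fitness_flags_and_antisymmetry():
    d, flag = delta_fitness(-4.0, -0.5)
    assert d == pytest.approx(-3.5) and flag
    d2, flag2 = delta_fitness(-1.0, -1.0)
    assert d2 == 0.0 and not flag2
    a = np.array([-4.0, -1.0, 2.0])
    b = np.array([-0.5, -1.0, -2.0])
    dab, _ = delta_fitness(a, b)
    dba, _ = delta_fitness(b, a)
    assert np.allclose(dab, -dba)


def test_delta_flag_count_matches_brute_threshold():
    rng = np.random.default_rng(11)
    fa, fb = rng.normal(0, 3, 100), rng.normal(0, 3, 100)
    _, flags = delta_fitness(fa, fb)
    assert flags.sum() == sum(1 for x, y in zip(fa, fb) if abs(x - y) >= 3)


def test_gene_fitness_mean_and_same_cluster_rule():
    recs = pd.DataFrame(
        {
            "gene_id": ["gA", "gA", "gB", "gB", "gC"],
            "guide_id": ["gA_1", "gA_2", "gB_1", "gB_2", "gC_1"],
            "F": [-2.0, -4.0, -1.0, -1.0, -5.0],
            "cluster": [2, 2, 2, 5, 1],
        }
    )
    out = gene_fitness(recs).set_index("gene_id")
    assert out.loc["gA", "F"] == pytest.approx(-3.0) and out.loc["gA", "eligible"]
    assert not out.loc["gB", "eligible"]  # guides in different clusters
    assert out.loc["gC", "F"] == pytest.approx(-5.0) and not out.loc["gC", "eligible"]


# --------------------------------------------------------------- growth rate


def test_flat_fractions_recover_population_rate():
    est = estimate_growth_rate([0, 12, 24], [0.01, 0.01, 0.01], mu_pop=0.07)
    assert est.mu_mut == pytest.approx(0.07)
    assert not est.lower_bound


def test_noiseless_model_trajectory_inverts_exactly():
    raw, _ = cs.depletion_fractions(
        np.array([1e-4, 1 - 1e-4]), np.array([0.035, 0.07]), 0.07, [0, 6, 12, 24]
    )
    est = estimate_growth_rate([0, 6, 12, 24], raw.iloc[0].to_numpy(), 0.07)
    assert abs(est.mu_mut - 0.035) <= 1e-10
    assert est.residual <= 1e-18


def test_vanished_clone_flagged_as_lower_bound():
    est = estimate_growth_rate([0, 12, 24], [1e-3, 0.0, 0.0], mu_pop=0.07)
    assert est.lower_bound
    assert np.isfinite(est.mu_mut)
    assert est.mu_mut < 0.07


def test_sampled_competition_recovers_growth_rates():
    n, mu_pop = 1000, 0.07
    rng = np.random.default_rng(42)
    mu = np.full(n, mu_pop)
    dep = rng.random(n) < 0.10
    mu[dep] = mu_pop * rng.uniform(0.3, 1.0, dep.sum())
    ids = [f"c{i}" for i in range(n)]
    truth = cs.make_truth(ids, mu)
    cfg = cs.CompetitionSimConfig(
        mu_pop=mu_pop, timepoints_h=tuple(np.linspace(0, 28, 8)),
        replicates=1, depth=1_000_000, overdispersion=np.inf, seed=1,
    )
    sim = cs.simulate_competition(ids, truth, cfg)
    fr = sim.counts / sim.counts.sum(axis=0)
    times = sim.meta["time_h"].to_numpy()
    errs = [
        abs(estimate_growth_rate(times, fr.loc[c].to_numpy(), mu_pop).mu_mut - m)
        for c, m in zip(ids, mu)
    ]
    assert np.median(errs) < 0.05 * mu_pop


# ---------------------------------------------------------------- clustering

GENS = np.linspace(0, 32, 8)


def _archetypes():
    lin = lambda end: end * GENS / GENS.max()
    bump = np.concatenate([np.r_[0, 0.25, 0.25, np.zeros(5)], np.zeros(8)])
    late = np.where(GENS < 16, 0.0, lin(-5))
    return {
        "fast": np.concatenate([lin(-8), lin(-8)]),
        "cond2": np.concatenate([lin(-2), lin(-8)]),
        "slow": np.concatenate([lin(-3), lin(-3)]),
        "late": np.concatenate([late, late]),
        "zero": np.zeros(16),
        "zero_bump": bump,
    }


def _archetype_data(sigma, seed):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for name, vec in _archetypes().items():
        truth = "unchanged" if name.startswith("zero") else name
        for _ in range(100):
            rows.append(vec + rng.normal(0, sigma, 16))
            labels.append(truth)
    X = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
    return X, labels


def test_noiseless_archetypes_recovered_exactly():
    X, labels = _archetype_data(0.0, 1)
    res = cluster_trajectories(X, k=6, merge_eps=0.5)
    assert adjusted_rand_score(labels, res.labels) == 1.0
    assert res.labels.nunique() == 5  # two near-zero clusters merged
    assert len(res.merged_raw_clusters) == 2


def test_noisy_archetypes_recovered():
    X, labels = _archetype_data(0.5, 1)
    res = cluster_trajectories(X, k=6, merge_eps=0.5)
    assert adjusted_rand_score(labels, res.labels) > 0.9


def test_cluster_labels_partition_guides():
    X, _ = _archetype_data(0.5, 2)
    res = cluster_trajectories(X, k=6)
    assert res.labels.index.equals(X.index)
    assert set(res.labels) == set(range(1, res.labels.nunique() + 1))


def test_cluster_needs_more_guides_than_k():
    X = pd.DataFrame(np.zeros((4, 6)))
    with pytest.raises(ValueError):
        cluster_trajectories(X, k=6)


def test_trajectory_features_pivot():
    traj = pd.DataFrame(
        {
            "guide_id": ["g1", "g1", "g2", "g2"],
            "condition": ["L100"] * 4,
            "time_h": [0.0, 10.0, 0.0, 10.0],
            "n_gen": [0.0, 1.0, 0.0, 1.0],
            "log2fc": [0.0, -1.0, 0.0, -2.0],
        }
    )
    wide = trajectory_features(traj)
    assert list(wide.columns) == ["L100_0", "L100_10"]
    assert wide.loc["g2", "L100_10"] == -2.0
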