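"""Competition statistics: estimates, tournaments, reversals, correlations."""

from itertools import combinations, permutations, product

import numpy as np
import pandas as pd
import pytest

from remiscreen import competition_analysis as ca
from remiscreen import synthetic_data as synth
from remiscreen.competition_analysis import (
    constraint_threshold,
    detect_reversals,
    estimate_means,
    pairwise_tournament,
    rank_correlation_matrix,
    relative_growth,
    reversal_permutation_test,
    strain_variance_anova,
)

from conftest import make_estimates


def test_relative_growth_examples():
    obs = pd.DataFrame(
        {
            "strain": ["A", "A", "B"],
            "bacterium": ["Ka", "Ka", "Ka"],
            "block": [1, 1, 1],
            "start_freq": [0.5, 0.5, 0.5],
            "end_freq": [0.5, 0.7, 0.4],
        }
    )
    scored = relative_growth(obs)
    assert scored["rel_growth"].tolist() == pytest.approx([0.0, 0.2, -0.1])


def test_total_growth_failure_gets_floor_score():
    obs = pd.DataFrame(
        {
            "strain": ["A", "A", "B"],
            "bacterium": ["Bs", "Bs", "Bs"],
            "block": [1, 2, 1],
            "start_freq": [0.5, 0.48, 0.5],
            "end_freq": [0.0, 0.0, 0.6],
        }
    )
    scored = relative_growth(obs)
    assert (scored.loc[scored["strain"] == "A", "rel_growth"] == -0.5).all()
    assert scored.loc[scored["strain"] == "B", "rel_growth"].iloc[0] == pytest.approx(0.1)


def test_relative_growth_rejects_invalid_frequencies():
    obs = pd.DataFrame(
        {"strain": ["A"], "bacterium": ["Ka"], "block": [1],
         "start_freq": [0.5], "end_freq": [1.2]}
    )
    with pytest.raises(ValueError):
        relative_growth(obs)


def test_estimate_means_single_block_reduces_to_cell_means():
    effects = pd.DataFrame([[0.1, -0.2], [0.0, 0.3]], index=["S1", "S2"],
                           columns=["A", "B"])
    obs = relative_growth(
        synth.simulate_competition(
            effects, n_blocks=1, n_replicates=4, noise_sd=0.01,
            block_sd=0.0, bacterium_block_sd=0.0, start_jitter_sd=0.0, seed=1,
        )
    )
    est = estimate_means(obs)
    cell = obs.groupby(["strain", "bacterium"])["rel_growth"].mean().reset_index()
    merged = est.merge(cell, on=["strain", "bacterium"])
    assert np.allclose(merged["mean"], merged["rel_growth"])


def test_estimate_means_zero_variance_is_exact():
    effects = pd.DataFrame([[0.1, -0.2], [0.0, 0.3]], index=["S1", "S2"],
                           columns=["A", "B"])
    obs = synth.simulate_competition(
        effects, n_blocks=1, n_replicates=3, noise_sd=0.0,
        block_sd=0.0, bacterium_block_sd=0.0, start_jitter_sd=0.0, seed=1,
    )
    est = estimate_means(relative_growth(obs)).set_index(["strain", "bacterium"])
    for strain in effects.index:
        for bacterium in effects.columns:
            row = est.loc[(strain, bacterium)]
            assert row["mean"] == pytest.approx(effects.loc[strain, bacterium], abs=1e-12)
            assert row["se"] == pytest.approx(0.0, abs=1e-12)


def test_estimate_means_recovers_truth_with_block_structure():
    rng = np.random.default_rng(5)
    effects = pd.DataFrame(
        rng.normal(0.0, 0.15, size=(8, 4)),
        index=[f"S{i}" for i in range(8)], columns=list("ABCD"),
    )
    obs = relative_growth(
        synth.simulate_competition(
            effects, n_blocks=3, n_replicates=3, noise_sd=0.03,
            block_sd=0.05, bacterium_block_sd=0.02, seed=6,
        )
    )
    est = estimate_means(obs)
    truth = effects.stack().rename("true").reset_index()
    truth.columns = ["strain", "bacterium", "true"]
    merged = est.merge(truth)
    # a shared block intercept shifts every cell; compare after centring
    err = merged["mean"] - merged["true"]
    err = err - err.mean()
    assert (err.abs() <= 2 * merged["se"] + 0.01).all()


def _bh_stepup(pvalues, alpha):
    """Independent Benjamini–Hochberg step-up oracle."""
    order = np.argsort(pvalues)
    m = len(pvalues)
    reject = np.zeros(m, dtype=bool)
    max_k = 0
    for rank, idx in enumerate(order, start=1):
        if pvalues[idx] <= rank * alpha / m:
            max_k = rank
    for rank, idx in enumerate(order, start=1):
        reject[idx] = rank <= max_k
    return reject


def test_bh_stepup_literal_example():
    pvals = np.array([0.01, 0.02, 0.04, 0.2])
    from statsmodels.stats.multitest import multipletests

    assert _bh_stepup(pvals, 0.05).tolist() == [True, True, False, False]
    assert multipletests(pvals, alpha=0.05, method="fdr_bh")[0].tolist() == [
        True, True, False, False,
    ]


def test_tournament_outcomes_match_bh_oracle(rng):
    est = make_estimates({"Ka": rng.normal(0, 0.08, 6)}, se=0.03, df=8.0)
    result = pairwise_tournament(est, fdr=0.05)["Ka"]
    pvals, pairs = [], []
    for a, b in combinations(result.strains, 2):
        pvals.append(result.pvalues.loc[a, b])
        pairs.append((a, b))
    reject = _bh_stepup(np.array(pvals), 0.05)
    for (a, b), rej in zip(pairs, reject):
        expected = int(np.sign(result.means[a] - result.means[b])) if rej else 0
        assert result.outcomes.loc[a, b] == expected


def test_tournament_identical_strains_all_ns():
    est = make_estimates({"Ka": [0.1, 0.1, 0.1, 0.1]}, se=0.05)
    result = pairwise_tournament(est)["Ka"]
    assert (result.outcomes.to_numpy() == 0).all()
    assert result.rank.nunique() == 1  # all tied


def test_tournament_win_loss_to_rank():
    est = make_estimates({"Ka": [0.4, 0.3, 0.2, 0.1]}, se=0.005, df=10.0)
    result = pairwise_tournament(est)["Ka"]
    assert result.win_loss.tolist() == [3, 1, -1, -3]
    assert result.rank.tolist() == [1, 2, 3, 4]


def test_tournament_matrix_properties(rng):
    est = make_estimates(
        {b: rng.normal(0, 0.1, 7) for b in "ABC"}, se=0.03, df=6.0
    )
    for result in pairwise_tournament(est).values():
        matrix = result.outcomes.to_numpy()
        assert (matrix == -matrix.T).all()
        assert result.win_loss.sum() == 0


def test_bh_monotonicity_in_fdr(rng):
    est = make_estimates({"Ka": rng.normal(0, 0.06, 8)}, se=0.03, df=8.0)
    strict = pairwise_tournament(est, fdr=0.01)["Ka"].outcomes.to_numpy()
    loose = pairwise_tournament(est, fdr=0.05)["Ka"].outcomes.to_numpy()
    assert ((strict != 0) <= (loose != 0)).all()


def test_detect_reversals_examples():
    est = make_estimates({"P1": [0.3, 0.0], "P2": [0.0, 0.3]}, se=0.01, df=10.0)
    flags = detect_reversals(pairwise_tournament(est)).iloc[0]
    assert flags["any_swap"] and flags["significant_swap"]

    est2 = make_estimates({"P1": [0.3, 0.0], "P2": [0.4, 0.1]}, se=0.01, df=10.0)
    flags2 = detect_reversals(pairwise_tournament(est2)).iloc[0]
    assert not flags2["any_swap"] and not flags2["significant_swap"]


def test_detect_reversals_matches_bruteforce_enumeration(rng):
    est = make_estimates(
        {b: rng.normal(0, 0.12, 4) for b in ("P1", "P2", "P3")}, se=0.02, df=8.0
    )
    tournaments = pairwise_tournament(est)
    flags = detect_reversals(tournaments).set_index(["strain_a", "strain_b"])
    strains = tournaments["P1"].strains
    for a, b in combinations(strains, 2):
        signs = set()
        sig = set()
        for t in tournaments.values():
            signs.add(np.sign(t.rank[a] - t.rank[b]))
            sig.add(t.outcomes.loc[a, b])
        assert flags.loc[(a, b), "any_swap"] == ({-1, 1} <= signs)
        assert flags.loc[(a, b), "significant_swap"] == ({-1, 1} <= sig)


def test_swap_count_invariant_to_relabelling(rng):
    means = {b: rng.normal(0, 0.1, 5) for b in ("P1", "P2", "P3")}
    base = pairwise_tournament(make_estimates(means, se=0.02))
    observed = int(detect_reversals(base)["any_swap"].sum())
    # relabel bacteria and apply one common strain permutation
    perm = rng.permutation(5)
    relabelled = {f"Q{j}": means[b][perm] for j, b in enumerate(means)}
    again = pairwise_tournament(make_estimates(relabelled, se=0.02))
    assert int(detect_reversals(again)["any_swap"].sum()) == observed


def test_permutation_test_single_bacterium_degenerate():
    est = make_estimates({"Ka": [0.3, 0.1, 0.0]}, se=0.01)
    result = reversal_permutation_test(pairwise_tournament(est), n_perm=299, seed=0)
    assert result.observed_any == 0
    assert result.p_one_tailed == 1.0


def test_permutation_p_matches_exhaustive_enumeration_oracle():
    """3 strains × 2 prey: exact tail probability by brute-force enumeration."""
    est = make_estimates({"P1": [0.3, 0.1, -0.2], "P2": [-0.1, 0.25, 0.0]},
                         se=0.02, df=5.0)
    tournaments = pairwise_tournament(est)
    observed = int(detect_reversals(tournaments)["any_swap"].sum())

    ranks = {b: t.rank.to_numpy() for b, t in tournaments.items()}
    strains = tournaments["P1"].strains
    null_counts = []
    for p1, p2 in product(permutations(range(3)), repeat=2):
        count = 0
        for i, j in combinations(range(3), 2):
            d1 = ranks["P1"][list(p1)][i] - ranks["P1"][list(p1)][j]
            d2 = ranks["P2"][list(p2)][i] - ranks["P2"][list(p2)][j]
            if (d1 < 0 and d2 > 0) or (d1 > 0 and d2 < 0):
                count += 1
        null_counts.append(count)
    exact_p = sum(c <= observed for c in null_counts) / len(null_counts)

    result = reversal_permutation_test(tournaments, exhaustive=True)
    assert result.p_one_tailed == pytest.approx(exact_p)
    mc = reversal_permutation_test(tournaments, n_perm=9999, seed=3)
    assert mc.p_one_tailed == pytest.approx(exact_p, abs=0.02)


def test_permutation_warns_on_tiny_n_perm():
    est = make_estimates({"P1": [0.3, 0.1, -0.2], "P2": [-0.1, 0.25, 0.0]}, se=0.02)
    with pytest.warns(UserWarning):
        reversal_permutation_test(pairwise_tournament(est), n_perm=99, seed=0)


def test_rank_correlation_matrix():
    est = make_estimates({"P1": [0.4, 0.3, 0.2, 0.1], "P2": [0.4, 0.3, 0.2, 0.1],
                          "P3": [0.1, 0.2, 0.3, 0.4]})
    rho, p = rank_correlation_matrix(est)
    assert rho.loc["P1", "P2"] == pytest.approx(1.0)
    assert rho.loc["P1", "P3"] == pytest.approx(-1.0)
    assert np.isfinite(p.loc["P1", "P3"])
    # p suppressed below 4 strains
    small = make_estimates({"P1": [0.3, 0.1, 0.0], "P2": [0.1, 0.3, 0.0]})
    _, p_small = rank_correlation_matrix(small)
    assert np.isnan(p_small.loc["P1", "P2"])


def _one_bacterium_obs(group_means, n_per_group, sd, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for i, mu in enumerate(group_means):
        for _ in range(n_per_group):
            end = 0.5 + mu + rng.normal(0, sd)
            rows.append({"strain": f"S{i}", "bacterium": "Ka", "block": 1,
                         "start_freq": 0.5, "end_freq": float(np.clip(end, 0, 1))})
    return pd.DataFrame(rows)


def test_anova_null_behaviour():
    obs = _one_bacterium_obs([0.1] * 6, n_per_group=10, sd=0.05, seed=8)
    result = strain_variance_anova(obs)
    assert result["p"] > 0.01
    assert result["df_between"] == 5 and result["df_within"] == 54


def test_anova_two_group_closed_form():
    obs = _one_bacterium_obs([0.0, 0.2], n_per_group=10, sd=0.02, seed=9)
    result = strain_variance_anova(obs)
    scored = relative_growth(obs)
    g = [grp["rel_growth"].to_numpy() for _, grp in scored.groupby("strain")]
    grand = np.concatenate(g).mean()
    ss_between = sum(len(x) * (x.mean() - grand) ** 2 for x in g)
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in g)
    f_closed = (ss_between / 1) / (ss_within / 18)
    assert result["F"] == pytest.approx(f_closed)
    assert result["p"] < 1e-6


def test_anova_zero_within_variance():
    obs = _one_bacterium_obs([0.0, 0.2], n_per_group=5, sd=0.0, seed=1)
    result = strain_variance_anova(obs)
    assert np.isinf(result["F"]) and result["p"] == 0.0


def test_anova_input_validation():
    single = _one_bacterium_obs([0.1], n_per_group=5, sd=0.01, seed=1)
    with pytest.raises(ValueError):
        strain_variance_anova(single)


@pytest.mark.parametrize("n,expected", [(6, -0.2), (2, -1.0), (11, -0.1)])
def test_constraint_threshold(n, expected):
    assert constraint_threshold(n) == pytest.approx(expected)


def test_constraint_threshold_needs_two_prey():
    with pytest.raises(ValueError):
        constraint_threshold(1)
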