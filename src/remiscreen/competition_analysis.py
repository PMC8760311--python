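"""Strain × prey competition analysis: tournaments, reversals, correlations.

Each observation is one head-to-head competition of a focal strain against a
common labelled reference on one bacterial prey, scored as the change in the
focal strain's frequency (end − start) over the assay.  The pipeline:

1. :func:`relative_growth` — score observations, flooring total growth
   failures at −0.5 (the theoretical minimum when starting at frequency 0.5);
2. :func:`estimate_means` — strain × bacterium expected values from a mixed
   model (strain, bacterium, strain×bacterium fixed; block and
   bacterium×block random), falling back to a fixed-effect block-adjusted fit
   when the REML fit is unavailable;
3. :func:`pairwise_tournament` — all pairwise two-sample t-tests per
   bacterium with Benjamini–Hochberg FDR control, win−loss records and ranks
   (1 = best);
4. :func:`detect_reversals` / :func:`reversal_permutation_test` — strain
   pairs whose rank order flips across prey, and a permutation null for the
   number of such reversals;
5. :func:`rank_correlation_matrix` and :func:`strain_variance_anova`.

:func:`constraint_threshold` gives the average cross-prey correlation,
−1/(N−1), at or below which adaptive evolution of overall predatory success
is completely constrained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, permutations, product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

OBSERVATION_COLUMNS = ("strain", "bacterium", "block", "start_freq", "end_freq")

#: Floor score for a strain that fails to grow at all on a bacterium —
#: the largest possible frequency drop from a 50:50 start.
GROWTH_FAILURE_FLOOR = -0.5


def relative_growth(observations: pd.DataFrame) -> pd.DataFrame:
    """Score each competition as end frequency minus start frequency.

    Strain × bacterium groups in which the strain failed to grow in every
    replicate (end frequency 0 throughout) are assigned the floor score of
    −0.5, the theoretical minimum from a 1:1 start, so total failures can be
    retained in downstream ranking.
    """
    obs = observations.copy()
    for col in ("start_freq", "end_freq"):
        vals = obs[col].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any() or np.isnan(vals).any():
            raise ValueError(f"{col} values must lie in [0, 1]")
    obs["rel_growth"] = obs["end_freq"] - obs["start_freq"]
    failed = obs.groupby(["strain", "bacterium"])["end_freq"].transform("max") == 0
    obs.loc[failed, "rel_growth"] = GROWTH_FAILURE_FLOOR
    return obs


def _cell_stats(obs: pd.DataFrame) -> pd.DataFrame:
    grouped = obs.groupby(["strain", "bacterium"])["rel_growth"]
    out = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out["df"] = np.maximum(out["n"] - 1, 1).astype(float)
    out["single_observation"] = out["n"] == 1
    return out


def estimate_means(observations: pd.DataFrame) -> pd.DataFrame:
    """Estimate strain × bacterium mean relative growth with standard errors.

    Multi-block data are fitted with a linear mixed model (REML): cell-mean
    fixed effects for every strain × bacterium combination, a random block
    intercept and a bacterium-by-block variance component.  If the mixed fit
    fails (or there is a single block, where the random effects are not
    identifiable) a fixed-effect fit with sum-coded block contrasts is used,
    which on balanced single-block data reduces to the raw cell means.

    Returns one row per cell: ``strain, bacterium, mean, se, df, n,
    single_observation``.  The degrees of freedom are the within-cell
    replicate df, used later for Welch-style pairwise tests.
    """
    if "rel_growth" not in observations.columns:
        observations = relative_growth(observations)
    obs = observations.copy()
    obs["cell"] = obs["strain"].astype(str) + "\x1f" + obs["bacterium"].astype(str)
    cells = _cell_stats(obs)
    n_blocks = obs["block"].nunique()

    fitted: pd.Series | None = None
    fitted_se: pd.Series | None = None
    if n_blocks > 1:
        fitted, fitted_se = _fit_mixed(obs)
        if fitted is None:
            fitted, fitted_se = _fit_block_adjusted(obs)
    if fitted is not None:
        key = cells["cell"] = cells["strain"].astype(str) + "\x1f" + cells[
            "bacterium"
        ].astype(str)
        cells["mean"] = key.map(fitted).to_numpy()
        model_se = key.map(fitted_se)
        # keep replicate-based se where the model can't provide one
        cells["se"] = model_se.fillna(cells["se"]).to_numpy()
        cells = cells.drop(columns="cell")
    return cells.drop(columns="sd")


def _fit_mixed(obs: pd.DataFrame) -> tuple[pd.Series | None, pd.Series | None]:
    import statsmodels.formula.api as smf

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "rel_growth ~ 0 + C(cell)",
                data=obs,
                groups=obs["block"],
                re_formula="1",
                vc_formula={"bacterium_block": "0 + C(bacterium)"},
            )
            fit = model.fit(reml=True, method="lbfgs", maxiter=200)
        if not np.all(np.isfinite(fit.fe_params)):
            return None, None
        means, ses = {}, {}
        for name, value in fit.fe_params.items():
            cell = name.split("[", 1)[1].rstrip("]")
            means[cell] = value
            ses[cell] = fit.bse_fe[name]
        return pd.Series(means), pd.Series(ses)
    except Exception:
        return None, None


def _fit_block_adjusted(obs: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.ols("rel_growth ~ 0 + C(cell) + C(block, Sum)", data=obs).fit()
    means, ses = {}, {}
    for name, value in fit.params.items():
        if name.startswith("C(cell)"):
            cell = name.split("[", 1)[1].rstrip("]")
            means[cell] = value
            ses[cell] = fit.bse[name]
    return pd.Series(means), pd.Series(ses)


@dataclass
class TournamentResult:
    """Pairwise significance structure and ranking on one bacterium.

    ``outcomes[i, j]`` is +1 when strain i grows significantly faster than
    strain j (after FDR control), −1 when significantly slower, 0 otherwise;
    the matrix is antisymmetric.  ``rank`` is 1 for the best win−loss record,
    with ties broken by mean relative growth (remaining ties share their
    average rank).
    """

    bacterium: str
    strains: list[str]
    outcomes: pd.DataFrame
    pvalues: pd.DataFrame
    win_loss: pd.Series
    means: pd.Series
    rank: pd.Series


def _welch_df(se1, se2, df1, df2):
    num = (se1**2 + se2**2) ** 2
    den = se1**4 / df1 + se2**4 / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, 1.0)


def pairwise_tournament(
    estimates: pd.DataFrame,
    fdr: float = 0.05,
    pool_across_bacteria: bool = False,
) -> dict[str, TournamentResult]:
    """Run all pairwise two-sample t-tests and rank strains per bacterium.

    The statistic for a pair is (m₁ − m₂)/√(se₁² + se₂²) with
    Welch–Satterthwaite degrees of freedom.  Benjamini–Hochberg control is
    applied over all pairs within each bacterium (default) or jointly across
    bacteria (``pool_across_bacteria=True``, for an experiment-wide FDR).
    """
    tests: list[dict] = []
    for bacterium, group in estimates.groupby("bacterium"):
        idx = group.set_index("strain")
        for a, b in combinations(sorted(idx.index), 2):
            m1, m2 = idx.loc[a, "mean"], idx.loc[b, "mean"]
            se1, se2 = idx.loc[a, "se"], idx.loc[b, "se"]
            df1, df2 = idx.loc[a, "df"], idx.loc[b, "df"]
            pooled_se = np.sqrt(se1**2 + se2**2)
            if pooled_se == 0:
                t = np.inf * np.sign(m1 - m2) if m1 != m2 else 0.0
                p = 0.0 if m1 != m2 else 1.0
            else:
                t = (m1 - m2) / pooled_se
                p = 2 * stats.t.sf(abs(t), _welch_df(se1, se2, df1, df2))
            tests.append(
                {"bacterium": bacterium, "a": a, "b": b, "t": t, "p": float(p)}
            )
    if not tests:
        return {}
    frame = pd.DataFrame(tests)

    if pool_across_bacteria:
        frame["reject"] = multipletests(frame["p"], alpha=fdr, method="fdr_bh")[0]
    else:
        frame["reject"] = False
        for bacterium, group in frame.groupby("bacterium"):
            frame.loc[group.index, "reject"] = multipletests(
                group["p"], alpha=fdr, method="fdr_bh"
            )[0]

    results: dict[str, TournamentResult] = {}
    for bacterium, group in estimates.groupby("bacterium"):
        strains = sorted(group["strain"])
        means = group.set_index("strain")["mean"].reindex(strains)
        sub = frame[frame["bacterium"] == bacterium]
        outcomes = pd.DataFrame(0, index=strains, columns=strains, dtype=int)
        pvals = pd.DataFrame(np.nan, index=strains, columns=strains, dtype=float)
        for row in sub.itertuples():
            sign = int(np.sign(row.t)) if row.reject else 0
            outcomes.loc[row.a, row.b] = sign
            outcomes.loc[row.b, row.a] = -sign
            pvals.loc[row.a, row.b] = pvals.loc[row.b, row.a] = row.p
        win_loss = outcomes.sum(axis=1)
        rank = _rank_strains(win_loss, means)
        results[bacterium] = TournamentResult(
            bacterium=bacterium,
            strains=strains,
            outcomes=outcomes,
            pvalues=pvals,
            win_loss=win_loss,
            means=means,
            rank=rank,
        )
    return results


def _rank_strains(win_loss: pd.Series, means: pd.Series) -> pd.Series:
    """Rank 1 = best win−loss; ties broken by mean, residual ties averaged."""
    order = pd.DataFrame({"wl": win_loss, "mean": means})
    order = order.sort_values(["wl", "mean"], ascending=False, kind="mergesort")
    ranks = pd.Series(np.arange(1, len(order) + 1, dtype=float), index=order.index)
    ranks = order.groupby(["wl", "mean"], sort=False)["wl"].transform(
        lambda g: ranks.loc[g.index].mean()
    )
    return ranks.reindex(win_loss.index)


def detect_reversals(
    tournaments: Mapping[str, TournamentResult],
) -> pd.DataFrame:
    """Flag every strain pair whose relative order flips across prey.

    ``any_swap``: the pair's rank order differs between at least two
    bacteria.  ``significant_swap``: there is a bacterium where A
    significantly out-grows B and another where B significantly out-grows A.
    """
    bacteria = list(tournaments)
    if len(bacteria) < 2:
        strains = tournaments[bacteria[0]].strains if bacteria else []
        return pd.DataFrame(
            [
                {"strain_a": a, "strain_b": b, "any_swap": False, "significant_swap": False}
                for a, b in combinations(strains, 2)
            ]
        )
    strains = tournaments[bacteria[0]].strains
    rows = []
    for a, b in combinations(strains, 2):
        diffs = [tournaments[x].rank[a] - tournaments[x].rank[b] for x in bacteria]
        any_swap = any(d < 0 for d in diffs) and any(d > 0 for d in diffs)
        outs = [tournaments[x].outcomes.loc[a, b] for x in bacteria]
        significant_swap = (1 in outs) and (-1 in outs)
        rows.append(
            {
                "strain_a": a,
                "strain_b": b,
                "any_swap": any_swap,
                "significant_swap": significant_swap,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ReversalResult:
    observed_any: int
    observed_significant: int
    null_median: float
    p_one_tailed: float
    n_permutations: int
    seed: int | None
    null_counts: np.ndarray


def _swap_counts_from_ranks(rank_matrix: np.ndarray, pair_idx: np.ndarray) -> np.ndarray:
    """Any-swap counts for a stack of rank matrices (…, n_bacteria, n_strains)."""
    d = (
        rank_matrix[..., pair_idx[:, 0]] - rank_matrix[..., pair_idx[:, 1]]
    )  # (..., B, n_pairs)
    return ((d < 0).any(axis=-2) & (d > 0).any(axis=-2)).sum(axis=-1)


def reversal_permutation_test(
    tournaments: Mapping[str, TournamentResult],
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> ReversalResult:
    """Permutation null for the number of cross-prey rank reversals.

    Strain labels are permuted independently within each bacterium —
    scrambling which strain carries which per-bacterium performance while
    preserving each bacterium's performance structure — and the any-swap
    count is recomputed per permutation.  Because the pairwise tests depend
    only on the (mean, se, df) tuples, which travel with the labels, this is
    identical to recomputing the tournaments from permuted estimates.

    One-tailed p = (#{null ≤ observed} + 1)/(n_perm + 1), testing whether
    fewer reversals are observed than expected under random cross-prey
    performance.  ``exhaustive=True`` enumerates the full permutation space
    (one bacterium's labelling fixed; a common relabelling cannot change the
    count) and returns the exact tail probability.
    """
    bacteria = list(tournaments)
    observed_frame = detect_reversals(tournaments)
    observed = int(observed_frame["any_swap"].sum()) if len(observed_frame) else 0
    observed_sig = (
        int(observed_frame["significant_swap"].sum()) if len(observed_frame) else 0
    )
    if len(bacteria) < 2:
        return ReversalResult(0, 0, 0.0, 1.0, 0, seed, np.zeros(0, dtype=int))

    strains = tournaments[bacteria[0]].strains
    n = len(strains)
    rank_matrix = np.vstack(
        [tournaments[b].rank.reindex(strains).to_numpy() for b in bacteria]
    )  # (B, n)
    pair_idx = np.array(list(combinations(range(n), 2)))

    if exhaustive:
        perms = list(permutations(range(n)))
        null_counts = []
        for combo in product(perms, repeat=len(bacteria) - 1):
            permuted = np.vstack(
                [rank_matrix[0]]
                + [rank_matrix[i + 1][list(p)] for i, p in enumerate(combo)]
            )
            null_counts.append(int(_swap_counts_from_ranks(permuted, pair_idx)))
        null_counts = np.asarray(null_counts)
        p = float((null_counts <= observed).sum() / len(null_counts))
        return ReversalResult(
            observed, observed_sig, float(np.median(null_counts)), p,
            len(null_counts), seed, null_counts,
        )

    if n_perm < 199:
        warnings.warn(
            f"n_perm={n_perm} gives a coarse permutation p-value; 199+ recommended",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    B = len(bacteria)
    permuted = np.empty((n_perm, B, n))
    for b in range(B):
        idx = np.argsort(rng.random((n_perm, n)), axis=1)
        permuted[:, b, :] = rank_matrix[b][idx]
    null_counts = _swap_counts_from_ranks(permuted, pair_idx)
    p = float(((null_counts <= observed).sum() + 1) / (n_perm + 1))
    return ReversalResult(
        observed, observed_sig, float(np.median(null_counts)), p, n_perm, seed,
        null_counts,
    )


def rank_correlation_matrix(
    estimates: pd.DataFrame, min_strains_for_p: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlation of mean performance between bacteria pairs.

    Returns (ρ matrix, unadjusted two-sided p matrix); p-values are
    suppressed (NaN) when fewer than ``min_strains_for_p`` strains are
    shared.
    """
    wide = estimates.pivot(index="strain", columns="bacterium", values="mean")
    bacteria = list(wide.columns)
    rho = pd.DataFrame(np.nan, index=bacteria, columns=bacteria, dtype=float)
    pmat = pd.DataFrame(np.nan, index=bacteria, columns=bacteria, dtype=float)
    for a in bacteria:
        rho.loc[a, a] = 1.0
    for a, b in combinations(bacteria, 2):
        paired = wide[[a, b]].dropna()
        if len(paired) < 2:
            continue
        result = stats.spearmanr(paired[a], paired[b])
        rho.loc[a, b] = rho.loc[b, a] = float(result.statistic)
        if len(paired) >= min_strains_for_p:
            pmat.loc[a, b] = pmat.loc[b, a] = float(result.pvalue)
    return rho, pmat


def strain_variance_anova(observations: pd.DataFrame) -> dict:
    """One-way ANOVA of relative growth by strain on a single bacterium.

    With zero within-group variance and distinct means the F statistic is
    reported as ``inf`` with p = 0.
    """
    if "rel_growth" not in observations.columns:
        observations = relative_growth(observations)
    if observations["bacterium"].nunique() > 1:
        raise ValueError("supply observations for a single bacterium")
    groups = [g["rel_growth"].to_numpy() for _, g in observations.groupby("strain")]
    if len(groups) < 2:
        raise ValueError("need at least two strains")
    if all(len(g) < 2 for g in groups):
        raise ValueError("need replicate observations for at least one strain")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):
        means = [g.mean() for g in groups]
        f, p = (np.inf, 0.0) if len(set(means)) > 1 else (np.nan, np.nan)
    return {
        "F": float(f),
        "df_between": k - 1,
        "df_within": n_total - k,
        "p": float(p),
    }


def constraint_threshold(n_prey: int) -> float:
    """Average cross-prey correlation below which adaptation is fully constrained.

    With N prey types contributing equally to overall predatory success, a
    mean pairwise performance correlation of −1/(N−1) drives the variance of
    the average to zero, so selection cannot improve performance on all prey
    simultaneously.  For N = 6 the threshold is −0.2.
    """
    if n_prey < 2:
        raise ValueError("need at least two prey types")
    return -1.0 / (n_prey - 1)
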