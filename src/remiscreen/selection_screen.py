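"""Fitness phenotype calling and pleiotropy taxonomy for pooled selections.

A pooled insertion-mutant library is passaged serially on several bacterial
prey; mutants that gain (lose) frequency over the selection relative to the
bulk are advantaged (disadvantaged) on that prey.  Because sampling noise is
strongly depth-dependent, mutants are first binned by mean normalised
starting read count (<100, 100–1000, >1000), log-fold changes are computed
per endpoint replicate, and each bin × endpoint sample group is standardised
to mean 0 / sd 1 (z-scores).

Calling rules (on normalised counts):

- *advantaged*: mean z across replicates > 1.5 and every endpoint replicate
  count > 100;
- *disadvantaged*: mean z < −1 and mean start count > 100;
- *excluded*: start count < 100 and the mutant dropped out (count 0 in an
  endpoint replicate) — such dropouts are dominated by technical loss;
- *neutral*: everything else.

Across prey, mutants are classified as positively pleiotropic (same-direction
effect on ≥2 prey, no opposite effect), antagonistically pleiotropic
(advantaged on ≥1 prey and disadvantaged on ≥1 other), conditionally neutral
(effect on exactly one prey), or none.  :func:`tranche_swap_analysis`
estimates how much cross-prey rank switching mere measurement error would
produce, using within-prey replicate pairs as the yardstick.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .read_processing import CountTable

CALL_LEVELS = ("advantaged", "disadvantaged", "neutral", "excluded")
CLASS_LEVELS = ("positive", "antagonistic", "conditional", "none")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and transforms for phenotype calling.

    ``bin_edges`` split mutants on mean normalised starting counts into
    low [0, e0), mid [e0, e1], high (e1, ∞).  ``min_reads`` is the normalised
    read-count gate used both for endpoint replicates (advantaged calls) and
    the starting library (disadvantaged calls).
    """

    bin_edges: tuple[float, float] = (100.0, 1000.0)
    z_advantaged: float = 1.5
    z_disadvantaged: float = -1.0
    min_reads: float = 100.0
    pseudocount: float = 1.0
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if not self.z_advantaged > 0 > self.z_disadvantaged:
            raise ValueError("need z_advantaged > 0 > z_disadvantaged")
        if not self.bin_edges[0] < self.bin_edges[1]:
            raise ValueError("bin edges must be increasing")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


def bin_by_start(start_mean: pd.Series, config: ScreenConfig | None = None) -> pd.Series:
    """Label each mutant low/mid/high by mean normalised starting count."""
    config = config or ScreenConfig()
    if start_mean.empty:
        raise ValueError("no start samples supplied")
    e0, e1 = config.bin_edges
    labels = pd.Series("mid", index=start_mean.index, dtype=object)
    labels[start_mean < e0] = "low"
    labels[start_mean > e1] = "high"
    return labels


def log_fold_change(
    end: pd.DataFrame | pd.Series,
    start_mean: pd.Series,
    config: ScreenConfig | None = None,
) -> pd.DataFrame | pd.Series:
    """log_base((end + pseudocount) / (start_mean + pseudocount)), elementwise."""
    config = config or ScreenConfig()
    if (np.asarray(end) < 0).any() or (start_mean < 0).any():
        raise ValueError("counts must be non-negative")
    denom = start_mean + config.pseudocount
    if isinstance(end, pd.DataFrame):
        ratio = end.add(config.pseudocount).div(denom, axis=0)
    else:
        ratio = (end + config.pseudocount) / denom
    return np.log(ratio) / np.log(config.log_base)


def zscore_by_bin(lfc: pd.DataFrame, bins: pd.Series) -> pd.DataFrame:
    """Standardise log-fold changes to mean 0 / sd 1 within each bin × column.

    Uses the sample standard deviation (n−1); groups with zero variance (or a
    single member) map to z = 0.
    """
    z = pd.DataFrame(index=lfc.index, columns=lfc.columns, dtype=float)
    for label in bins.unique():
        members = bins.index[bins == label]
        if len(members) == 0:
            continue
        block = lfc.loc[members]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        centred = block.sub(mu, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            zb = centred.div(sd, axis=1)
        zb[centred == 0] = 0.0
        zb = zb.where(np.isfinite(zb), 0.0)
        z.loc[members] = zb
    return z


def call_phenotypes(
    start_norm: pd.DataFrame,
    end_norm: Mapping[str, pd.DataFrame],
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Call a phenotype for every mutant on every prey.

    Parameters
    ----------
    start_norm
        Normalised starting-library counts, one column per start replicate.
    end_norm
        Per prey: normalised endpoint counts, one column per selection
        replicate (the design uses duplicates; ≥2 required).

    Returns a long-format frame with columns ``mutant, prey, mean_z, call,
    start_ok, end_ok`` plus one ``z_rep{i}`` column per replicate.
    """
    config = config or ScreenConfig()
    start_mean = start_norm.mean(axis=1)
    bins = bin_by_start(start_mean, config)

    records: list[pd.DataFrame] = []
    for prey, end in end_norm.items():
        if end.shape[1] < 2:
            raise ValueError(f"prey {prey!r}: missing replicate (need ≥2 endpoint samples)")
        end = end.reindex(start_mean.index)
        if end.isna().any().any():
            raise ValueError(f"prey {prey!r}: mutant universe differs from start table")
        lfc = log_fold_change(end, start_mean, config)
        z = zscore_by_bin(lfc, bins)
        mean_z = z.mean(axis=1)

        start_ok = start_mean > config.min_reads
        end_ok = (end > config.min_reads).all(axis=1)
        dropped = (end == 0).any(axis=1)

        call = pd.Series("neutral", index=start_mean.index, dtype=object)
        call[(mean_z > config.z_advantaged) & end_ok] = "advantaged"
        call[(mean_z < config.z_disadvantaged) & start_ok & (call == "neutral")] = (
            "disadvantaged"
        )
        call[(start_mean < config.min_reads) & dropped] = "excluded"

        frame = pd.DataFrame(
            {
                "mutant": start_mean.index,
                "prey": prey,
                "mean_z": mean_z.to_numpy(),
                "call": call.to_numpy(),
                "start_ok": start_ok.to_numpy(),
                "end_ok": end_ok.to_numpy(),
            }
        )
        for i, col in enumerate(z.columns, start=1):
            frame[f"z_rep{i}"] = z[col].to_numpy()
        records.append(frame)
    return pd.concat(records, ignore_index=True)


def classify_pleiotropy(calls: pd.DataFrame) -> pd.DataFrame:
    """Assign each mutant a pleiotropy class from its per-prey call vector.

    Excluded calls carry no directional information and are treated as
    no-call.  Classes partition the mutants: antagonistic (≥1 advantaged and
    ≥1 disadvantaged), positive (same direction on ≥2 prey, no opposite),
    conditional (exactly one non-neutral call), none (no non-neutral call).
    """
    wide = calls.pivot(index="mutant", columns="prey", values="call")
    n_adv = (wide == "advantaged").sum(axis=1)
    n_dis = (wide == "disadvantaged").sum(axis=1)
    n_effect = n_adv + n_dis

    cls = pd.Series("none", index=wide.index, dtype=object)
    cls[(n_adv >= 1) & (n_dis >= 1)] = "antagonistic"
    cls[(n_effect >= 2) & ((n_adv == 0) | (n_dis == 0))] = "positive"
    cls[n_effect == 1] = "conditional"

    out = wide.copy()
    out.insert(0, "n_advantaged", n_adv)
    out.insert(1, "n_disadvantaged", n_dis)
    out.insert(2, "pleiotropy_class", cls)
    return out.reset_index()


def screen_summary(
    calls: pd.DataFrame,
    classes: pd.DataFrame,
    start_mean: pd.Series,
    config: ScreenConfig | None = None,
) -> dict:
    """Headline counts of a screen, on the confident (start > min_reads) set.

    Reports the library size, the number of mutants with any phenotype, and —
    restricted to mutants with mean normalised start count above the gate —
    the pleiotropy-class breakdown, including how many positively pleiotropic
    mutants are advantaged (disadvantaged) on more than one prey.
    """
    config = config or ScreenConfig()
    classes = classes.set_index("mutant")
    confident = start_mean.index[start_mean > config.min_reads]

    any_effect = classes["pleiotropy_class"] != "none"
    conf = classes.loc[classes.index.intersection(confident)]
    conf_called = conf[conf["pleiotropy_class"] != "none"]

    n_positive = int((conf_called["pleiotropy_class"] == "positive").sum())
    positive = conf_called[conf_called["pleiotropy_class"] == "positive"]
    n_pos_adv_multi = int((positive["n_advantaged"] >= 2).sum())
    n_pos_dis_multi = int((positive["n_disadvantaged"] >= 2).sum())
    n_antagonistic = int((conf_called["pleiotropy_class"] == "antagonistic").sum())
    n_conditional = int((conf_called["pleiotropy_class"] == "conditional").sum())

    return {
        "n_mutants": int(len(classes)),
        "n_with_phenotype": int(any_effect.sum()),
        "n_confident_called": int(len(conf_called)),
        "n_positive": n_positive,
        "n_antagonistic": n_antagonistic,
        "n_conditional": n_conditional,
        "n_non_positive": n_antagonistic + n_conditional,
        "n_positive_advantaged_multi": n_pos_adv_multi,
        "n_positive_disadvantaged_multi": n_pos_dis_multi,
    }


def _tranche_members(values: pd.Series) -> tuple[set, set]:
    """Top-25% and bottom-25% membership by value (descending order)."""
    n = len(values)
    if n < 4:
        raise ValueError("tranches undefined for fewer than 4 mutants")
    k = max(1, int(round(n / 4)))
    order = values.sort_values(ascending=False, kind="mergesort")
    return set(order.index[:k]), set(order.index[-k:])


def tranche_swap_analysis(
    z_by_prey: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Observed cross-prey tranche swaps versus the measurement-error expectation.

    Mutants are split into top 25% / middle 50% / bottom 25% tranches of mean
    z per prey.  For each prey pair the number of mutants leaving the top
    (bottom) tranche between the two prey is the *observed* swap count; the
    same count computed between the two biological replicates of a single
    prey estimates the swaps *expected* from measurement error alone (the
    pair's expectation is the mean of its two within-prey counts).  A prey
    pair whose observed count exceeds the expectation shows more cross-prey
    switching than error can explain.

    ``z_by_prey`` maps each prey to a mutants × replicates frame of z-scores.
    """
    mean_z = {prey: frame.mean(axis=1) for prey, frame in z_by_prey.items()}
    within: dict[str, tuple[float, float]] = {}
    for prey, frame in z_by_prey.items():
        if frame.shape[1] < 2:
            raise ValueError(f"prey {prey!r}: need ≥2 replicates")
        reps = list(frame.columns)
        top_counts, bot_counts = [], []
        for a, b in combinations(reps, 2):
            ta, ba = _tranche_members(frame[a])
            tb, bb = _tranche_members(frame[b])
            top_counts.append(len(ta - tb) + len(tb - ta))
            bot_counts.append(len(ba - bb) + len(bb - ba))
        within[prey] = (float(np.mean(top_counts)), float(np.mean(bot_counts)))

    rows = []
    for prey_a, prey_b in combinations(mean_z, 2):
        ta, ba = _tranche_members(mean_z[prey_a])
        tb, bb = _tranche_members(mean_z[prey_b])
        obs_top = len(ta - tb) + len(tb - ta)
        obs_bot = len(ba - bb) + len(bb - ba)
        exp_top = (within[prey_a][0] + within[prey_b][0]) / 2
        exp_bot = (within[prey_a][1] + within[prey_b][1]) / 2
        rows.append(
            {
                "prey_a": prey_a,
                "prey_b": prey_b,
                "observed_top": obs_top,
                "observed_bottom": obs_bot,
                "expected_top": exp_top,
                "expected_bottom": exp_bot,
                "excess_top": obs_top > exp_top,
                "excess_bottom": obs_bot > exp_bot,
            }
        )
    return pd.DataFrame(rows)


def run_screen(
    counts: CountTable, config: ScreenConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full screen analysis on a normalised count table with sample metadata.

    Sample metadata must carry ``role`` ("start"/"end"), ``prey`` and
    ``replicate`` columns.  Returns (calls, pleiotropy classes, summary).
    """
    config = config or ScreenConfig()
    if counts.norm is None:
        raise ValueError("count table must be normalised first")
    meta = counts.samples
    start_cols = list(meta.index[meta["role"] == "start"])
    if not start_cols:
        raise ValueError("no start samples in metadata")
    start_norm = counts.norm[start_cols]
    end_norm = {
        prey: counts.norm[list(group.index)]
        for prey, group in meta[meta["role"] == "end"].groupby("prey")
    }
    calls = call_phenotypes(start_norm, end_norm, config)
    classes = classify_pleiotropy(calls)
    summary = screen_summary(calls, classes, start_norm.mean(axis=1), config)
    return calls, classes, summary
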