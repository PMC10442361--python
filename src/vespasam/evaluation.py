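"""Evaluation statistics, replicated model comparison, rank-sum variant
selection, category-discrimination testing and correlation tests.

Metrics follow the accuracy/discrimination framework used for abundance
models: accuracy is the mean absolute error scaled by the mean observed
abundance (ideal 0); discrimination is the Pearson correlation and the
slope of a linear model between prediction and observation (ideal 1 and 1);
occurrence models are additionally scored by AUC, and their probabilities
are compared against relative abundance (observed abundance scaled by its
maximum) when judged as abundance predictors.
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    CATEGORIES,
    categorize,
    fit_sam,
    fit_sdm,
    presence_labels,
    stratified_split,
)

__all__ = [
    "standardized_mae",
    "discrimination",
    "auc",
    "replicate_evaluation",
    "rank_select",
    "select_best_sdm",
    "kruskal_dunn",
    "CorrelationTestResult",
    "correlation_test",
    "t_from_r",
    "SAM_VARIANTS",
    "SDM_VARIANTS",
]

SAM_VARIANTS = ["rf_raw", "rf_log1p", "gbm_raw", "gbm_log1p"]
SDM_VARIANTS = ["sdm_rf", "sdm_gbm"]


def standardized_mae(pred, obs) -> float:
    """Mean absolute error scaled by the mean observed value (ideal 0).

    Scale-invariant: rescaling predictions and observations by the same
    positive constant leaves it unchanged.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 1:
        raise ValueError("pred and obs must be equal-length, nonempty")
    mobs = obs.mean()
    if mobs <= 0:
        raise ValueError("mean observed value must be positive to scale the MAE")
    return float(np.mean(np.abs(pred - obs)) / mobs)


def discrimination(pred, obs, slope_convention: str = "obs_on_pred") -> tuple[float, float]:
    """(Pearson r, linear-model slope) between prediction and observation.

    The default slope is the calibration slope — observations regressed on
    predictions — whose ideal value is 1; ``slope_convention="pred_on_obs"``
    gives the reverse regression.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 3:
        raise ValueError("pred and obs must be equal-length with >= 3 points")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.corrcoef(pred, obs)[0, 1])
    if slope_convention == "obs_on_pred":
        x, y = pred, obs
    elif slope_convention == "pred_on_obs":
        x, y = obs, pred
    else:
        raise ValueError("slope_convention must be 'obs_on_pred' or 'pred_on_obs'")
    xc = x - x.mean()
    slope = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
    return r, slope


def auc(scores, labels) -> float:
    """Area under the ROC curve, P(score+ > score-) + 0.5 P(tie).

    Computed via the Mann-Whitney rank-sum identity; invariant under any
    strictly increasing transform of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# --------------------------------------------------------------------------
# Replicated evaluation
# --------------------------------------------------------------------------


def _variant_spec(variant: str) -> tuple[str, str, str]:
    """(task, algorithm, transform) of a variant id."""
    if variant in SAM_VARIANTS:
        alg, transform = variant.split("_")
        return "sam", alg, transform
    if variant in SDM_VARIANTS:
        return "sdm", variant.split("_")[1], "binary"
    raise ValueError(f"unknown variant {variant!r}")


def evaluate_variant_on_split(
    variant: str,
    train: pd.DataFrame,
    test: pd.DataFrame,
    covariate_names: list[str],
    seed: int,
    scale_max: float | None = None,
    sam_eval_scale: str = "count",
) -> dict:
    """Fit one variant on the training half and score it on the test half.

    Occurrence variants are scored twice: by AUC on the presence/absence
    labels, and — as abundance predictors — by comparing their establishment
    probability against observed abundance scaled by ``scale_max`` (default:
    the maximum observed abundance over train and test combined).
    """
    task, alg, transform = _variant_spec(variant)
    obs = test["mean_count"].to_numpy(dtype=float)
    row: dict = {"variant": variant, "task": task}
    if task == "sam":
        model = fit_sam(train, covariate_names, algorithm=alg, transform=transform, seed=seed)
        if sam_eval_scale == "count":
            pred = model.predict(test[covariate_names])
            obs_eval = obs
        elif sam_eval_scale == "transformed":
            # score the log1p variant on its own fitting scale
            pred = model.predict_transformed(test[covariate_names])
            obs_eval = np.log1p(obs) if transform == "log1p" else obs
        else:
            raise ValueError("sam_eval_scale must be 'count' or 'transformed'")
        row["accuracy"] = standardized_mae(pred, obs_eval)
        row["pearson_r"], row["slope"] = discrimination(pred, obs_eval)
        row["auc"] = np.nan
    else:
        model = fit_sdm(train, covariate_names, algorithm=alg, seed=seed)
        prob = model.predict_proba_presence(test[covariate_names])
        labels = presence_labels(obs)
        row["auc"] = auc(prob, labels)
        if scale_max is None:
            scale_max = float(
                max(train["mean_count"].max(), test["mean_count"].max())
            )
        rel_obs = obs / scale_max
        row["accuracy"] = standardized_mae(prob, rel_obs)
        row["pearson_r"], row["slope"] = discrimination(prob, rel_obs)
    return row


def replicate_evaluation(
    sites: pd.DataFrame,
    covariate_names: list[str],
    variants: list[str] | None = None,
    n_rep: int = 100,
    base_seed: int = 0,
    train_fraction: float = 0.7,
    sam_eval_scale: str = "count",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicated stratified-split evaluation of all model variants.

    Each replicate draws an independent category-stratified 70/30 split,
    fits every variant on the training half and scores it on the test half.
    Failures of a single replicate are recorded in an ``error`` column
    rather than aborting the run.

    Returns
    -------
    (rows, summary) : per-replicate long table, and a per-variant summary
    with mean and s.d. of each metric plus ``selected`` flags from the
    rank-sum rule (abundance variants) and the AUC rule (occurrence
    variants).
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if variants is None:
        variants = SAM_VARIANTS + SDM_VARIANTS
    scale_max = float(sites["mean_count"].max())
    ss = np.random.SeedSequence([int(base_seed), 404])
    rep_seeds = ss.generate_state(2 * n_rep) % (2**31)

    rows = []
    for rep in range(n_rep):
        split_seed = int(rep_seeds[2 * rep])
        fit_seed = int(rep_seeds[2 * rep + 1])
        try:
            train, test = stratified_split(sites, train_fraction, seed=split_seed)
        except ValueError as exc:  # stratification failure is per-replicate
            for variant in variants:
                rows.append({"replicate": rep, "variant": variant, "error": str(exc)})
            continue
        for variant in variants:
            try:
                row = evaluate_variant_on_split(
                    variant, train, test, covariate_names, fit_seed,
                    scale_max=scale_max, sam_eval_scale=sam_eval_scale,
                )
                row.update({"replicate": rep, "error": ""})
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                row = {"replicate": rep, "variant": variant, "error": str(exc)}
            rows.append(row)
    rows_df = pd.DataFrame(rows)

    ok = rows_df[rows_df.get("error", "") == ""] if "error" in rows_df else rows_df
    metrics = ["accuracy", "pearson_r", "slope", "auc"]
    summary = (
        ok.groupby("variant")[metrics]
        .agg(["mean", "std"])
        .reindex(variants)
    )
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    summary = summary.reset_index()

    summary["selected"] = False
    sam_rows = summary[summary["variant"].isin(SAM_VARIANTS)]
    if len(sam_rows) >= 2:
        best = rank_select(
            sam_rows.rename(
                columns={
                    "accuracy_mean": "accuracy",
                    "pearson_r_mean": "pearson_r",
                    "slope_mean": "slope",
                }
            )[["variant", "accuracy", "pearson_r", "slope"]]
        )
        summary.loc[summary["variant"] == best, "selected"] = True
    sdm_rows = summary[summary["variant"].isin(SDM_VARIANTS)]
    if len(sdm_rows) >= 2:
        best_sdm = select_best_sdm(sdm_rows.set_index("variant")["auc_mean"])
        summary.loc[summary["variant"] == best_sdm, "selected"] = True
    return rows_df, summary


def rank_select(summary: pd.DataFrame, variant_col: str = "variant") -> str:
    """Best abundance variant by summed metric ranks.

    Per-metric ranks: accuracy ascending (toward the ideal 0), Pearson r
    descending (toward 1), slope by ascending |slope - 1|. The variant with
    the smallest rank sum wins; ties break by accuracy rank, then by listed
    order.
    """
    if len(summary) == 0:
        raise ValueError("empty summary table")
    for col in ("accuracy", "pearson_r", "slope"):
        if summary[col].isna().any():
            raise ValueError(f"missing values in metric {col!r}")
    acc_rank = stats.rankdata(summary["accuracy"])
    r_rank = stats.rankdata(-summary["pearson_r"].to_numpy())
    slope_rank = stats.rankdata(np.abs(summary["slope"].to_numpy() - 1.0))
    total = acc_rank + r_rank + slope_rank
    order = np.lexsort((np.arange(len(summary)), acc_rank, total))
    return str(summary[variant_col].to_numpy()[order[0]])


def select_best_sdm(auc_by_variant: pd.Series) -> str:
    """Occurrence variant with the higher mean AUC."""
    if auc_by_variant.isna().any():
        raise ValueError("missing AUC values")
    return str(auc_by_variant.idxmax())


# --------------------------------------------------------------------------
# Kruskal-Wallis + Dunn post hoc
# --------------------------------------------------------------------------


def _dunn_pairwise(values: np.ndarray, groups: np.ndarray, labels: list) -> pd.DataFrame:
    """Dunn z tests on joint ranks with tie correction and Bonferroni."""
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1)))
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {"group_a": a, "group_b": b, "z": z, "p": p, "p_adjusted": min(1.0, p * m)}
        )
    return pd.DataFrame(rows)


def _compact_letters(labels: list, differs) -> dict:
    """Greedy insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; ``differs``
    maps a frozen pair to True when the pair is significantly different.
    """
    letter_sets: list[set] = []
    for g in labels:
        placed = False
        for s in letter_sets:
            if all(not differs(frozenset((g, h))) for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb redundant sets
    letter_sets = [
        s
        for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    out = {g: "" for g in labels}
    for s, letter in zip(letter_sets, string.ascii_lowercase):
        for g in sorted(s, key=labels.index):
            out[g] += letter
    return {g: "".join(sorted(out[g])) for g in labels}


def kruskal_dunn(values, group_labels, alpha: float = 0.05) -> dict:
    """Kruskal-Wallis rank-sum test with Dunn/Bonferroni post hoc letters.

    Returns a dict with the tie-corrected H statistic, its degrees of
    freedom (groups - 1), the overall p value, the pairwise Dunn table and
    a compact letter display (groups sharing a letter are not significantly
    different at Bonferroni-adjusted p < ``alpha``).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(group_labels)
    labels = [g for g in (CATEGORIES if set(groups) <= set(CATEGORIES) else sorted(set(groups), key=str)) if g in set(groups)]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if np.ptp(values) == 0:
        h_stat, p_overall = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h_stat, p_overall = stats.kruskal(*samples)
    df = len(labels) - 1
    pairwise = _dunn_pairwise(values, groups, labels)
    sig = {
        frozenset((row.group_a, row.group_b)): row.p_adjusted < alpha
        for row in pairwise.itertuples()
    }
    letters = _compact_letters(labels, lambda pair: sig.get(pair, False))
    return {
        "H": float(h_stat),
        "df": df,
        "p": float(p_overall),
        "pairwise": pairwise,
        "letters": letters,
    }


# --------------------------------------------------------------------------
# Correlation tests
# --------------------------------------------------------------------------


@dataclass
class CorrelationTestResult:
    """Pearson correlation with its t test (df = n - 2, two-sided)."""

    r: float
    t: float
    df: int
    p: float


def t_from_r(r: float, df: int) -> float:
    """t statistic of a Pearson correlation: t = r sqrt(df) / sqrt(1 - r^2)."""
    if not -1 <= r <= 1:
        raise ValueError("r must be in [-1, 1]")
    if abs(r) == 1:
        return math.inf if r > 0 else -math.inf
    return r * math.sqrt(df) / math.sqrt(1.0 - r * r)


def correlation_test(x, y) -> CorrelationTestResult:
    """Pearson correlation between two samples with its two-sided t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    df = x.size - 2
    t = t_from_r(r, df)
    if math.isinf(t):
        p = 0.0
    else:
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationTestResult(r=r, t=t, df=df, p=p)
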