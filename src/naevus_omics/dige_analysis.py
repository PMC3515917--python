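"""Differential protein-spot analysis of paired 2D-DIGE data.

The pipeline starts from a spot-volume table (one volume per spot, gel set
and channel, with a presence mask) and proceeds:

1. within-gel normalization — each volume divided by the total spot volume
   of its gel channel, removing loading and labelling differences;
2. across-gel normalization — each gel set median-scaled to the global
   median so gels are comparable, with within-gel DNMC/MC ratios preserved
   exactly;
3. presence filtering — only spots quantified in both channels of at least
   `min_sets` gel sets are analysed;
4. per-spot Welch unequal-variance t-tests on log-transformed normalized
   volumes, with step-down Westfall–Young maxT adjustment computed from
   whole-gel-set sign flips of the log-ratios (all spots flipped jointly);
5. the headline selection: spots with raw p < 0.03, at least 2-fold change
   in either direction, and presence in >= 15 gel sets.

Note the maxT procedure controls family-wise error (the strong sense of
"no false positives"), which is stricter than false-discovery-rate control;
the raw Welch p-value, not the adjusted one, drives the headline filter.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SpotTable

P_CUT = 0.03
FOLD_CUT = 2.0
MIN_SETS = 15


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_within_gel(table: SpotTable) -> SpotTable:
    """Divide each present volume by the total spot volume of its gel channel.

    After this step the present volumes of every gel channel sum to 1.
    """
    vols = table.volumes.copy()
    present3 = np.repeat(table.present[:, :, None], 2, axis=2)
    masked = np.where(present3, vols, 0.0)
    totals = masked.sum(axis=0)  # (n_gel_sets, 2)
    has_spots = present3.any(axis=0)
    if (totals[has_spots] <= 0).any():
        g, c = np.argwhere(has_spots & (totals <= 0))[0]
        raise ValueError(
            f"zero total volume in gel set {table.gel_set_ids[g]!r} channel {c}"
        )
    with np.errstate(invalid="ignore"):
        vols = vols / totals[None, :, :]
    vols[~present3] = np.nan
    return table.copy_with(vols)


def normalize_across_gels(table: SpotTable) -> SpotTable:
    """Median-scale each gel set so spot volumes are comparable across gels.

    One factor per gel set (both channels pooled) maps the gel's median
    present volume onto the global median; a single per-gel factor keeps all
    within-gel DNMC/MC ratios exactly unchanged.
    """
    vols = table.volumes.copy()
    present3 = np.repeat(table.present[:, :, None], 2, axis=2)
    all_present = vols[present3]
    if all_present.size == 0:
        raise ValueError("no present spots")
    global_median = float(np.median(all_present))
    for j in range(table.n_gel_sets):
        gel_vals = vols[:, j, :][present3[:, j, :]]
        if gel_vals.size < 3:
            warnings.warn(
                f"gel set {table.gel_set_ids[j]!r} has {gel_vals.size} present "
                "spots; median scaling is unstable"
            )
        if gel_vals.size == 0:
            continue
        med = float(np.median(gel_vals))
        if med <= 0:
            raise ValueError(
                f"non-positive median volume in gel set {table.gel_set_ids[j]!r}"
            )
        vols[:, j, :] *= global_median / med
    vols[~present3] = np.nan
    return table.copy_with(vols)


def presence_filter(table: SpotTable, min_sets: int = MIN_SETS) -> SpotTable:
    """Keep spots present (both channels) in at least `min_sets` gel sets."""
    if min_sets > table.n_gel_sets:
        raise ValueError(
            f"min_sets={min_sets} exceeds the {table.n_gel_sets} gel sets"
        )
    keep = table.present.sum(axis=1) >= min_sets
    return SpotTable(
        spot_ids=[s for s, k in zip(table.spot_ids, keep) if k],
        gel_set_ids=list(table.gel_set_ids),
        volumes=table.volumes[keep],
        present=table.present[keep],
        dye_swap=table.dye_swap.copy(),
    )


# ---------------------------------------------------------------------------
# Per-spot testing
# ---------------------------------------------------------------------------

def welch_ttest(dnmc_values, mc_values) -> tuple[float, float, float]:
    """Welch unequal-variance two-sample t-test (two-sided).

    Returns (t, Welch–Satterthwaite df, p). The statistic is
    (mean(dnmc) - mean(mc)) / sqrt(v1/n1 + v2/n2).
    """
    x = np.asarray(dnmc_values, dtype=float)
    y = np.asarray(mc_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    n1, n2 = x.size, y.size
    se2 = v1 / n1 + v2 / n2
    if se2 <= 0:
        return 0.0, float(n1 + n2 - 2), 1.0
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def spot_log_ratios(table: SpotTable) -> np.ndarray:
    """Natural-log DNMC/MC volume ratios, (n_spots, n_gel_sets); NaN = absent."""
    out = np.full((table.n_spots, table.n_gel_sets), np.nan)
    pres = table.present
    dn = table.volumes[:, :, 1]
    mc = table.volumes[:, :, 0]
    if ((dn[pres] <= 0) | (mc[pres] <= 0)).any():
        raise ValueError("present volumes must be positive to form log-ratios")
    out[pres] = np.log(dn[pres]) - np.log(mc[pres])
    return out


def _paired_t_rows(M: np.ndarray, n_i: np.ndarray, sumsq: np.ndarray,
                   signs: np.ndarray) -> np.ndarray:
    """One-sample t per spot for each sign-flip column; (n_spots, B)."""
    means = (M @ signs.T) / n_i[:, None]
    var = (sumsq[:, None] - n_i[:, None] * means ** 2) / (n_i[:, None] - 1.0)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n_i[:, None])
    t[~np.isfinite(t)] = np.where(means[~np.isfinite(t)] == 0, 0.0, np.inf)
    return t


def westfall_young_stepdown(
    log_ratios: np.ndarray, n_perm: int = 10_000, seed: int | None = None
) -> np.ndarray:
    """Step-down maxT adjusted p-values from whole-gel-set sign flips.

    `log_ratios` is (n_spots, n_gel_sets) with NaN where a spot is absent.
    The per-spot statistic is the one-sample t of its log-ratios; each
    permutation flips the sign of whole gel-set columns, all spots jointly,
    preserving inter-spot correlation. All 2^G flips are enumerated when
    that is within `n_perm`; otherwise flips are sampled and the add-one
    estimator is used. Monotonicity of the adjusted p-values down the |t|
    ranking is enforced.
    """
    L = np.asarray(log_ratios, dtype=float)
    if L.ndim != 2:
        raise ValueError("log_ratios must be 2-D (spots x gel sets)")
    if n_perm < 100:
        warnings.warn("n_perm < 100: adjusted p-values will be coarse")
    S, G = L.shape
    mask = np.isfinite(L)
    n_i = mask.sum(axis=1).astype(float)
    if (n_i < 2).any():
        raise ValueError("every spot needs log-ratios in at least 2 gel sets")
    M = np.where(mask, L, 0.0)
    sumsq = (M ** 2).sum(axis=1)

    exhaustive = 2 ** G <= n_perm
    if exhaustive:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=G)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, G))
    B = signs.shape[0]

    t_obs = np.abs(_paired_t_rows(M, n_i, sumsq, np.ones((1, G)))[:, 0])
    T_perm = np.abs(_paired_t_rows(M, n_i, sumsq, signs))  # (S, B)

    order = np.argsort(-t_obs, kind="stable")
    # q[i, b] = max over ranks >= i of the permuted |t| (successive maxima
    # over the tail of the observed ranking)
    q = np.maximum.accumulate(T_perm[order][::-1], axis=0)[::-1]
    tol = 1e-12
    counts = (q >= t_obs[order][:, None] - tol).sum(axis=1)
    if exhaustive:
        p_ord = counts / B
    else:
        p_ord = (counts + 1) / (B + 1)
    p_ord = np.maximum.accumulate(p_ord)
    p_adj = np.empty(S)
    p_adj[order] = p_ord
    return p_adj


# ---------------------------------------------------------------------------
# Full spot table analysis
# ---------------------------------------------------------------------------

def analyze_spots(
    table: SpotTable,
    n_perm: int = 10_000,
    seed: int | None = None,
    p_cut: float = P_CUT,
    fold_cut: float = FOLD_CUT,
    min_sets: int = MIN_SETS,
    normalize: bool = True,
) -> pd.DataFrame:
    """Normalize, test and adjust every spot; one result row per spot.

    Columns: spot_id, n_present, ratio (geometric-mean DNMC/MC), t_welch,
    df, p_raw, p_adj, passes_filter. Spots failing the presence filter are
    dropped before testing.
    """
    if normalize:
        table = normalize_across_gels(normalize_within_gel(table))
    table = presence_filter(table, min_sets=min_sets)
    if table.n_spots == 0:
        return pd.DataFrame(
            columns=["spot_id", "n_present", "ratio", "t_welch", "df",
                     "p_raw", "p_adj", "passes_filter"]
        )
    L = spot_log_ratios(table)
    ratios = np.exp(np.nanmean(L, axis=1))  # geometric mean DNMC/MC
    n_present = table.present.sum(axis=1)

    t_w = np.empty(table.n_spots)
    df_w = np.empty(table.n_spots)
    p_raw = np.empty(table.n_spots)
    logv = np.log(table.volumes)
    for i in range(table.n_spots):
        pres = table.present[i]
        t_w[i], df_w[i], p_raw[i] = welch_ttest(logv[i, pres, 1], logv[i, pres, 0])

    p_adj = westfall_young_stepdown(L, n_perm=n_perm, seed=seed)
    result = pd.DataFrame(
        {
            "spot_id": table.spot_ids,
            "n_present": n_present,
            "ratio": ratios,
            "t_welch": t_w,
            "df": df_w,
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )
    result["passes_filter"] = (
        (result["p_raw"] < p_cut)
        & ((result["ratio"] >= fold_cut) | (result["ratio"] <= 1.0 / fold_cut))
        & (result["n_present"] >= min_sets)
    )
    return result


def select_top_proteins(
    results: pd.DataFrame,
    p_cut: float = P_CUT,
    fold_cut: float = FOLD_CUT,
    min_sets: int = MIN_SETS,
) -> pd.DataFrame:
    """Headline selection: raw p < p_cut, >= fold_cut change, presence >= min_sets."""
    if fold_cut <= 1:
        raise ValueError("fold_cut must exceed 1")
    keep = (
        (results["p_raw"] < p_cut)
        & ((results["ratio"] >= fold_cut) | (results["ratio"] <= 1.0 / fold_cut))
        & (results["n_present"] >= min_sets)
    )
    return results.loc[keep].sort_values("p_raw", kind="stable").reset_index(drop=True)
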