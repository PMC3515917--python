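"""Functional class scoring of GO gene sets with LS/KS permutation statistics.

Rather than selecting individual genes first, each GO class is scored from
the p-values of all of its member genes:

* **LS** — the mean negative natural logarithm of the members' p-values
  (a Fisher-style aggregate; large when members are collectively small);
* **KS** — the one-sample Kolmogorov–Smirnov distance between the members'
  p-values and the uniform distribution (large when the p-values deviate
  from the no-signal shape in either direction).

Significance is assessed against a gene-sampling null: random gene subsets
of the same size drawn from the analysis universe. Classes with fewer than
5 or more than 100 members represented in the expression data are excluded
to avoid very small and very large classes. A class is flagged significant
when either permutation p-value is below the nominal 0.005 level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .io_formats import GeneSet, GeneSetCollection

P_FLOOR = 1e-300  # clamp before -ln to avoid infinities
SIGNIFICANCE_LEVEL = 0.005
DEFAULT_N_PERM = 100_000
EXHAUSTIVE_LIMIT = 10 ** 6  # max C(N, k) for exhaustive enumeration


@dataclass
class ClassScore:
    term_id: str
    term_name: str
    namespace: str
    n_genes: int
    ls: float
    ks: float
    ls_p: float
    ks_p: float
    significant: bool


def filter_gene_sets(
    collection: GeneSetCollection, min_size: int = 5, max_size: int = 100
) -> GeneSetCollection:
    """Drop classes with < min_size or > max_size members in the universe.

    Membership of the retained sets is restricted to the universe, so
    downstream scores see only genes that were actually measured.
    """
    if collection.universe is None or len(collection.universe) == 0:
        raise ValueError("collection must carry a non-empty gene universe")
    kept: dict[str, GeneSet] = {}
    for term_id, gs in collection.sets.items():
        members = gs.genes & collection.universe
        if min_size <= len(members) <= max_size:
            kept[term_id] = GeneSet(
                term_id=gs.term_id, name=gs.name, namespace=gs.namespace,
                genes=frozenset(members),
            )
    return GeneSetCollection(sets=kept, universe=collection.universe)


def _check_pvals(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return p


def ls_statistic(pvals) -> float:
    """Mean negative natural log of the per-gene p-values."""
    p = _check_pvals(pvals)
    return float(np.mean(-np.log(np.maximum(p, P_FLOOR))))


def ks_statistic(pvals) -> float:
    """Two-sided one-sample KS distance of the p-values to U(0,1)."""
    p = np.sort(_check_pvals(pvals))
    n = p.size
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - p)
    d_minus = np.max(p - (i - 1) / n)
    return float(max(d_plus, d_minus))


def _ls_rows(P: np.ndarray) -> np.ndarray:
    """Row-wise LS over a (B, k) matrix of p-values."""
    return np.mean(-np.log(np.maximum(P, P_FLOOR)), axis=1)


def _ks_rows(P: np.ndarray) -> np.ndarray:
    """Row-wise two-sided KS-to-uniform over a (B, k) matrix of p-values."""
    Ps = np.sort(P, axis=1)
    k = P.shape[1]
    i = np.arange(1, k + 1)
    d_plus = np.max(i / k - Ps, axis=1)
    d_minus = np.max(Ps - (i - 1) / k, axis=1)
    return np.maximum(d_plus, d_minus)


_ROW_FN = {ls_statistic: _ls_rows, ks_statistic: _ks_rows}
_TIE_TOL = 1e-12  # floating-point guard so exact ties count as >= observed


def _null_statistics(
    row_fn: Callable[[np.ndarray], np.ndarray],
    set_size: int,
    universe_pvals: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    chunk_elems: int = 20_000_000,
) -> np.ndarray:
    """Sampled null: statistics of random same-size gene subsets.

    Subsets are drawn uniformly without replacement via the random-keys
    trick (argpartition of a uniform matrix), chunked to bound memory.
    """
    N = universe_pvals.size
    out = np.empty(n_perm)
    chunk = max(1, min(n_perm, chunk_elems // max(N, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, N))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        out[done:done + b] = row_fn(universe_pvals[idx])
        done += b
    return out


def class_permutation_pvalue(
    stat_fn: Callable,
    observed: float,
    set_size: int,
    universe_pvals,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    exhaustive: bool = False,
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> float:
    """Permutation p-value of an observed class statistic.

    Sampled mode uses the add-one estimator ``(k + 1) / (n_perm + 1)``;
    exhaustive mode enumerates all C(N, set_size) subsets and returns the
    exact fraction with statistic >= observed (ties count as >=).
    """
    universe_pvals = _check_pvals(universe_pvals)
    N = universe_pvals.size
    if set_size > N:
        raise ValueError("set_size exceeds universe size")
    if exhaustive:
        n_subsets = math.comb(N, set_size)
        if n_subsets > exhaustive_limit:
            raise ValueError(
                f"C({N},{set_size}) = {n_subsets} exceeds the exhaustive "
                f"enumeration limit {exhaustive_limit}"
            )
        count = sum(
            1
            for idx in combinations(range(N), set_size)
            if stat_fn(universe_pvals[list(idx)]) >= observed - _TIE_TOL
        )
        return count / n_subsets
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1 in sampled mode")
    rng = np.random.default_rng(seed)
    row_fn = _ROW_FN.get(stat_fn)
    if row_fn is not None:
        null = _null_statistics(row_fn, set_size, universe_pvals, n_perm, rng)
    else:  # arbitrary statistic: per-draw loop
        null = np.empty(n_perm)
        for b in range(n_perm):
            idx = rng.choice(N, size=set_size, replace=False)
            null[b] = stat_fn(universe_pvals[idx])
    count = int((null >= observed - _TIE_TOL).sum())
    return (count + 1) / (n_perm + 1)


def score_all_classes(
    collection: GeneSetCollection,
    gene_pvals: Mapping[str, float] | pd.Series,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    significance_level: float = SIGNIFICANCE_LEVEL,
) -> pd.DataFrame:
    """Score every retained class with LS and KS permutation p-values.

    `gene_pvals` must cover the collection's universe (the per-gene p-values
    of the univariate paired test). Null statistics are shared across classes
    of the same size through a single seeded stream per statistic, so the
    whole table costs one pass of subset draws per distinct class size.

    Returns a DataFrame sorted by LS permutation p-value (ties broken by the
    LS statistic, largest first), one row per class.
    """
    if collection.universe is None:
        raise ValueError("collection must carry a gene universe")
    pv = pd.Series(gene_pvals)
    missing = [g for g in collection.universe if g not in pv.index]
    if missing:
        raise KeyError(f"genes missing from gene_pvals: {sorted(missing)[:5]} ...")
    universe_genes = sorted(collection.universe)
    upv = _check_pvals(pv.loc[universe_genes].to_numpy())
    gene_pos = {g: i for i, g in enumerate(universe_genes)}

    sizes = sorted({len(gs.genes) for gs in collection.sets.values()})
    ss = np.random.SeedSequence(seed)
    ls_seed, ks_seed = ss.spawn(2)
    ls_rngs = dict(zip(sizes, [np.random.default_rng(s) for s in ls_seed.spawn(len(sizes))]))
    ks_rngs = dict(zip(sizes, [np.random.default_rng(s) for s in ks_seed.spawn(len(sizes))]))
    ls_null = {
        k: _null_statistics(_ls_rows, k, upv, n_perm, ls_rngs[k]) for k in sizes
    }
    ks_null = {
        k: _null_statistics(_ks_rows, k, upv, n_perm, ks_rngs[k]) for k in sizes
    }

    rows = []
    for term_id in sorted(collection.sets):
        gs = collection.sets[term_id]
        idx = [gene_pos[g] for g in gs.genes]
        member_p = upv[idx]
        ls = ls_statistic(member_p)
        ks = ks_statistic(member_p)
        k = len(idx)
        ls_p = (int((ls_null[k] >= ls - _TIE_TOL).sum()) + 1) / (n_perm + 1)
        ks_p = (int((ks_null[k] >= ks - _TIE_TOL).sum()) + 1) / (n_perm + 1)
        rows.append(
            ClassScore(
                term_id=term_id,
                term_name=gs.name,
                namespace=gs.namespace,
                n_genes=k,
                ls=ls,
                ks=ks,
                ls_p=ls_p,
                ks_p=ks_p,
                significant=(ls_p < significance_level or ks_p < significance_level),
            )
        )
    df = pd.DataFrame([vars(r) for r in rows])
    df = df.sort_values(["ls_p", "ls"], ascending=[True, False], kind="stable")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)


def member_gene_table(
    collection: GeneSetCollection,
    gene_results: pd.DataFrame,
    term_ids,
) -> pd.DataFrame:
    """Per-gene parametric p-values for the members of selected classes."""
    rows = []
    for term_id in term_ids:
        gs = collection.sets[term_id]
        for gene in sorted(gs.genes):
            rows.append(
                {
                    "term_id": term_id,
                    "term_name": gs.name,
                    "gene": gene,
                    "parametric_p": float(gene_results.loc[gene, "p"]),
                }
            )
    return pd.DataFrame(rows)
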