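"""Permutation-based multivariate tests and indicator-feature analysis.

* :func:`permanova` — multi-term sequential (Type I) PERMANOVA on a distance
  matrix, in the style of vegan's ``adonis2``: sums of squares are obtained
  by projecting the Gower-centred inner-product matrix onto the dummy-coded
  design, term by term; significance by free permutation of sample labels.
* :func:`distance_group_test` — one-way ANOVA on per-sample distance values
  with all pairwise least-squares-mean contrasts, Holm-adjusted.
* :func:`indval` — group-size-corrected indicator value IndVal.g
  (√(specificity × fidelity)) over single groups and group combinations,
  with a permutation (or exhaustive) test per feature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests
from sympy.utilities.iterables import multiset_permutations

from .tables import FeatureTable, SampleMetadata

__all__ = [
    "PermanovaResult",
    "DistanceAnovaResult",
    "permanova",
    "distance_group_test",
    "indval",
]


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Sequential-SS PERMANOVA table plus run parameters.

    ``table`` has one row per model term, a Residual and a Total row, with
    columns df, SS, R2, F and p (p is NaN for Residual/Total).
    """

    table: pd.DataFrame
    n_permutations: int
    seed: int | None


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    a = -0.5 * d**2
    return j @ a @ j


def _orth_basis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing via SVD)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    return u[:, s > tol]


def _dummy_code(values: pd.Series) -> np.ndarray:
    levels = pd.unique(values)
    return (values.to_numpy()[:, None] == levels[None, :]).astype(float)


def permanova(dm: DistanceMatrix, metadata: SampleMetadata | pd.DataFrame,
              terms: list[str], n_perm: int = 999, seed: int | None = None,
              ) -> PermanovaResult:
    """Multi-factor PERMANOVA with sequential sums of squares.

    Terms enter the model in the given order; each term's SS is the increase
    in explained inner-product trace when its dummy columns are added.  The
    pseudo-F for every term uses the full-model residual.  p-values come from
    free permutation of the rows/columns of the distance matrix, with the
    observed statistic included: p = (1 + #{F* ≥ F}) / (1 + n_perm).
    """
    meta = metadata.frame if isinstance(metadata, SampleMetadata) else metadata
    ids = list(dm.ids)
    missing = [s for s in ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    meta = meta.loc[ids]
    n = len(ids)
    for term in terms:
        if term not in meta.columns:
            raise KeyError(f"unknown metadata factor {term!r}")
        if meta[term].nunique() < 2:
            raise ValueError(f"term {term!r} has fewer than 2 levels")

    g = _gower_center(np.asarray(dm.data, dtype=float))
    ss_total = float(np.trace(g))

    # cumulative orthonormal bases: intercept, then + term1, + term2, ...
    design = np.ones((n, 1))
    bases = [_orth_basis(design)]
    dfs = []
    for term in terms:
        design = np.hstack([design, _dummy_code(meta[term])])
        basis = _orth_basis(design)
        df_term = basis.shape[1] - bases[-1].shape[1]
        if df_term == 0:
            raise ValueError(
                f"term {term!r} is confounded with preceding terms "
                f"({terms[:terms.index(term)]}) — singular design"
            )
        dfs.append(df_term)
        bases.append(basis)
    df_resid = n - bases[-1].shape[1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    # hat matrices per cumulative design; SS via tr(H G) differences
    hats = [b @ b.T for b in bases]

    def _ss_terms(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        traces = np.array([float(np.sum(h * gmat)) for h in hats])
        ss = np.diff(traces)
        ss_resid = float(np.trace(gmat)) - traces[-1]
        return ss, ss_resid

    ss_obs, ss_resid_obs = _ss_terms(g)
    ms_resid = ss_resid_obs / df_resid
    f_obs = (ss_obs / np.array(dfs)) / ms_resid

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_resid_p = _ss_terms(gp)
        f_p = (ss_p / np.array(dfs)) / (ss_resid_p / df_resid)
        # tolerance so permutations tied with the observed statistic count
        # (recomputation on a permuted matrix jitters in the last bits)
        exceed += f_p >= f_obs - 1e-8 * (1.0 + np.abs(f_obs))
    pvals = (1 + exceed) / (1 + n_perm)

    rows = []
    for term, df_t, ss_t, f_t, p_t in zip(terms, dfs, ss_obs, f_obs, pvals):
        rows.append({"term": term, "df": df_t, "SS": ss_t,
                     "R2": ss_t / ss_total, "F": f_t, "p": p_t})
    rows.append({"term": "Residual", "df": df_resid, "SS": ss_resid_obs,
                 "R2": ss_resid_obs / ss_total, "F": math.nan, "p": math.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total,
                 "R2": 1.0, "F": math.nan, "p": math.nan})
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table=table, n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# One-way ANOVA on distances with pairwise contrasts
# ---------------------------------------------------------------------------

@dataclass
class DistanceAnovaResult:
    """One-way ANOVA on distance values plus Holm-adjusted pairwise contrasts."""

    F: float
    df_between: int
    df_within: int
    p: float
    contrasts: pd.DataFrame
    excluded_groups: list[str]


def distance_group_test(distances, groups) -> DistanceAnovaResult:
    """One-way ANOVA of per-sample distance values across groups.

    Pairwise contrasts are least-squares mean differences with
    pooled-variance t statistics (df = N − k), Holm-adjusted.  Groups with
    fewer than two values are excluded with a warning.
    """
    values = np.asarray(distances, dtype=float)
    labels = np.asarray(groups)
    if values.shape != labels.shape:
        raise ValueError("distances and groups must have equal length")
    excluded = []
    keep_levels = []
    for level in pd.unique(labels):
        if (labels == level).sum() < 2:
            excluded.append(str(level))
        else:
            keep_levels.append(level)
    if excluded:
        warnings.warn(f"groups with <2 values excluded: {excluded}", stacklevel=2)
    if len(keep_levels) < 2:
        raise ValueError("need at least 2 groups with >= 2 values")
    mask = np.isin(labels, keep_levels)
    values, labels = values[mask], labels[mask]

    n_total = len(values)
    k = len(keep_levels)
    grand = values.mean()
    ss_between = sum(
        (labels == lv).sum() * (values[labels == lv].mean() - grand) ** 2
        for lv in keep_levels
    )
    ss_within = sum(
        ((values[labels == lv] - values[labels == lv].mean()) ** 2).sum()
        for lv in keep_levels
    )
    df_b, df_w = k - 1, n_total - k
    ms_within = ss_within / df_w
    f_stat = (ss_between / df_b) / ms_within if ms_within > 0 else math.inf
    p = float(sps.f.sf(f_stat, df_b, df_w)) if math.isfinite(f_stat) else 0.0

    rows = []
    for a, b in combinations(keep_levels, 2):
        xa, xb = values[labels == a], values[labels == b]
        est = xb.mean() - xa.mean()
        se = math.sqrt(ms_within * (1 / len(xa) + 1 / len(xb)))
        t = est / se if se > 0 else (0.0 if est == 0 else math.copysign(math.inf, est))
        p_raw = float(2 * sps.t.sf(abs(t), df_w)) if math.isfinite(t) else 0.0
        rows.append({"contrast": f"{b} - {a}", "estimate": est, "SE": se,
                     "t": t, "df": df_w, "p_raw": p_raw})
    contrasts = pd.DataFrame(rows)
    if len(contrasts):
        contrasts["p_adj"] = multipletests(contrasts["p_raw"], method="holm")[1]
    return DistanceAnovaResult(F=float(f_stat), df_between=df_b, df_within=df_w,
                               p=p, contrasts=contrasts, excluded_groups=excluded)


# ---------------------------------------------------------------------------
# IndVal.g indicator analysis
# ---------------------------------------------------------------------------

def _indval_stats(values: np.ndarray, group_indices: list[np.ndarray],
                  combos: list[tuple[int, ...]]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A, B, stat arrays of shape (n_features, n_combos).

    A (specificity, group-size corrected): sum of the per-group *mean*
    abundances inside the combination over the sum across all groups.
    B (fidelity): fraction of the combination's samples where the feature
    occurs.  stat = sqrt(A·B).
    """
    group_means = np.stack([values[:, idx].mean(axis=1) for idx in group_indices],
                           axis=1)  # features × groups
    total_means = group_means.sum(axis=1)
    a_all = np.zeros((values.shape[0], len(combos)))
    b_all = np.zeros_like(a_all)
    with np.errstate(invalid="ignore", divide="ignore"):
        for c, combo in enumerate(combos):
            a_all[:, c] = group_means[:, list(combo)].sum(axis=1) / total_means
            samples = np.concatenate([group_indices[k] for k in combo])
            b_all[:, c] = (values[:, samples] > 0).mean(axis=1)
    a_all = np.nan_to_num(a_all, nan=0.0)
    stat = np.sqrt(a_all * b_all)
    return a_all, b_all, stat


def indval(table: FeatureTable, groups, max_order: int | None = None,
           n_perm: int | str = 999, seed: int | None = None) -> pd.DataFrame:
    """IndVal.g indicator analysis of every feature against a grouping factor.

    For each feature, every non-empty proper subset of group levels of size
    ≤ ``max_order`` is scored; the best-scoring combination is reported with
    a permutation p-value for its statistic (labels permuted, the maximum
    statistic recomputed each time).  ``n_perm="exhaustive"`` enumerates all
    distinct label assignments instead, giving an exact p-value.

    Features with zero total abundance are dropped with a warning.
    """
    labels = pd.Series(np.asarray(groups), index=table.sample_ids)
    levels = list(pd.unique(labels))
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if max_order is None:
        max_order = k - 1
    if max_order >= k:
        warnings.warn(f"max_order capped at {k - 1} (all-groups set excluded)",
                      stacklevel=2)
        max_order = k - 1

    values = table.values
    nonzero = values.sum(axis=1) > 0
    if not nonzero.all():
        warnings.warn(f"dropped {int((~nonzero).sum())} zero-total features",
                      stacklevel=2)
    values = values[nonzero]
    feature_ids = [f for f, keep in zip(table.feature_ids, nonzero) if keep]

    label_array = labels.to_numpy()
    combos = [c for order in range(1, max_order + 1)
              for c in combinations(range(k), order)]

    def _group_indices(lab: np.ndarray) -> list[np.ndarray]:
        return [np.flatnonzero(lab == lv) for lv in levels]

    a_obs, b_obs, stat_obs = _indval_stats(values, _group_indices(label_array), combos)
    best = stat_obs.argmax(axis=1)
    rows_idx = np.arange(len(feature_ids))
    best_stat = stat_obs[rows_idx, best]

    if n_perm == "exhaustive":
        perms = list(multiset_permutations(list(label_array)))
        exceed = np.zeros(len(feature_ids), dtype=int)
        for perm_labels in perms:
            _, _, stat_p = _indval_stats(
                values, _group_indices(np.asarray(perm_labels)), combos)
            exceed += stat_p.max(axis=1) >= best_stat - 1e-12
        pvals = exceed / len(perms)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(feature_ids), dtype=int)
        for _ in range(int(n_perm)):
            perm_labels = label_array[rng.permutation(len(label_array))]
            _, _, stat_p = _indval_stats(values, _group_indices(perm_labels), combos)
            exceed += stat_p.max(axis=1) >= best_stat - 1e-12
        pvals = (1 + exceed) / (1 + int(n_perm))
        n_used = int(n_perm)

    out = pd.DataFrame({
        "feature_id": feature_ids,
        "group_combination": ["+".join(str(levels[i]) for i in combos[b])
                              for b in best],
        "A": a_obs[rows_idx, best],
        "B": b_obs[rows_idx, best],
        "stat": best_stat,
        "p": pvals,
    })
    out.attrs["n_permutations"] = n_used
    out.attrs["seed"] = seed
    return out
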