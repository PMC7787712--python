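"""Rank and permutation statistics: Kruskal–Wallis H with Dunn's post hoc,
and a distance-matrix PERMANOVA with sequential pseudo-F statistics.

Kruskal–Wallis compares the monthly body-temperature distributions of the
four sex-by-size classes without a normality assumption; Dunn's procedure
(Bonferroni-adjusted) localises which pairs differ.  PERMANOVA replaces
the parametric ANCOVA where residuals resist transformation (the large
males): it partitions the total sum of squared interpoint distances
sequentially over the model terms per McArdle & Anderson's trace identity
and assesses each term's pseudo-F by freely permuting the observations.
For a univariate response under Euclidean distance the pseudo-F is
algebraically identical to the classical least-squares F, which is the
main correctness oracle in the test suite.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .linmod import design_matrices

__all__ = [
    "KruskalResult",
    "DunnResult",
    "PermanovaResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "permanova",
]


@dataclass(frozen=True)
class KruskalResult:
    h_statistic: float
    df: int
    p_value: float
    group_ns: tuple[int, ...]

    def to_dict(self) -> dict:
        return {"h": self.h_statistic, "df": self.df, "p": self.p_value,
                "group_ns": list(self.group_ns)}


@dataclass(frozen=True)
class DunnResult:
    """All-pairs Dunn z statistics with Bonferroni-adjusted p-values.

    Keys of the mappings are (i, j) group-index pairs, i < j.
    """

    z: dict[tuple[int, int], float]
    p_raw: dict[tuple[int, int], float]
    p_adjusted: dict[tuple[int, int], float]
    n_comparisons: int

    def to_dict(self) -> dict:
        return {
            f"{i}-{j}": {"z": self.z[(i, j)], "p_raw": self.p_raw[(i, j)],
                         "p_adj": self.p_adjusted[(i, j)]}
            for (i, j) in sorted(self.z)
        }


@dataclass(frozen=True)
class PermanovaResult:
    terms: tuple[str, ...]
    df: dict[str, int]
    ss: dict[str, float]
    pseudo_f: dict[str, float]
    p_perm: dict[str, float]
    ss_residual: float
    df_residual: int
    ss_total: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "terms": [
                {"term": t, "df": self.df[t], "ss": self.ss[t],
                 "pseudo_f": self.pseudo_f[t], "p_perm": self.p_perm[t]}
                for t in self.terms
            ],
            "residual": {"df": self.df_residual, "ss": self.ss_residual},
            "total_ss": self.ss_total,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _tie_term(all_values: np.ndarray) -> float:
    """Σ(t³ - t) over tied groups of the pooled sample."""
    _, counts = np.unique(all_values, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t ** 3 - t).sum())


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Kruskal–Wallis H with average ranks for ties and tie correction.

    H = 12 / (N(N+1)) · Σ n_i (R̄_i - (N+1)/2)², divided by the tie
    correction 1 - Σ(t³ - t)/(N³ - N); p from chi-square on k - 1 df.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)  # average ranks for ties
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start:start + a.size]
        h += a.size * (r.mean() - (n_total + 1) / 2.0) ** 2
        start += a.size
    h *= 12.0 / (n_total * (n_total + 1))
    correction = 1.0 - _tie_term(pooled) / (n_total ** 3 - n_total)
    if correction <= 0:  # every observation identical
        h = 0.0
    else:
        h /= correction
    df = len(arrays) - 1
    p = float(stats.chi2.sf(h, df)) if h > 0 else 1.0
    return KruskalResult(h_statistic=float(h), df=df, p_value=p,
                         group_ns=tuple(a.size for a in arrays))


def dunn_posthoc(groups: Sequence[Sequence[float]],
                 alpha: float = 0.05) -> DunnResult:
    """Dunn's all-pairs comparisons on pooled ranks, Bonferroni adjusted.

    z_ij = (R̄_i - R̄_j) / sqrt(V · (1/n_i + 1/n_j)) with the
    tie-corrected variance V = N(N+1)/12 - Σ(t³-t) / (12(N-1));
    adjusted p = min(1, raw two-sided p × number of pairs).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start:start + a.size].mean())
        start += a.size
    var = (n_total * (n_total + 1) / 12.0
           - _tie_term(pooled) / (12.0 * (n_total - 1)))
    k = len(arrays)
    pairs = list(itertools.combinations(range(k), 2))
    z: dict[tuple[int, int], float] = {}
    p_raw: dict[tuple[int, int], float] = {}
    p_adj: dict[tuple[int, int], float] = {}
    for i, j in pairs:
        denom = math.sqrt(var * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        zij = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        praw = 2.0 * float(stats.norm.sf(abs(zij)))
        z[(i, j)] = zij
        p_raw[(i, j)] = min(1.0, praw)
        p_adj[(i, j)] = min(1.0, praw * len(pairs))
    return DunnResult(z=z, p_raw=p_raw, p_adjusted=p_adj,
                      n_comparisons=len(pairs))


def _gower_center(response: np.ndarray) -> np.ndarray:
    """Gower-centred matrix G of -½ d²_ij for Euclidean distances.

    For Euclidean distance G equals the centred inner-product matrix of
    the (column-centred) response, the quantity whose trace partitions
    exactly like raw-space sums of squares.
    """
    y = np.asarray(response, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    d2 = ((y[:, None, :] - y[None, :, :]) ** 2).sum(axis=2)
    a = -0.5 * d2
    n = a.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def permanova(
    response,
    factor,
    covariate=None,
    include_interaction: bool = True,
    distance: str = "euclidean",
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential PERMANOVA of a response on (covariate, factor[, interaction]).

    With ``covariate=None`` the model is factor-only (any number of
    levels): the permutational one-way analysis, whose pseudo-F for a
    univariate Euclidean response equals the classical ANOVA F.

    The total sum of squared interpoint distances is partitioned over the
    nested model sequence via SS(term) = tr((H_i - H_{i-1}) G), where H_i
    are the hat matrices of the nested designs and G the Gower-centred
    distance matrix.  Pseudo-F per term uses the residual mean square of
    the largest model.  Significance comes from ``n_perm`` free
    permutations of the observations (rows of the response), with
    p = (#{F_perm ≥ F_obs} + 1) / (n_perm + 1); the permutation stream is
    fully determined by ``seed``.
    """
    if distance != "euclidean":
        raise ValueError("only the euclidean distance is supported")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    y = np.asarray(response, dtype=float)
    n = y.shape[0]
    if n < 5:
        raise ValueError("need at least 5 observations")
    factor = np.asarray(factor)
    g = _gower_center(y)
    if np.allclose(g, 0.0):
        raise ValueError("degenerate distance matrix: all distances are zero")

    if covariate is None:
        levels = np.unique(factor)
        if levels.size < 2:
            raise ValueError("factor must have at least 2 levels")
        dummies = np.column_stack(
            [(factor == lev).astype(float) for lev in levels[1:]])
        ones = np.ones((n, 1))
        mats = [ones, np.hstack([ones, dummies])]
        term_names = ["factor"]
    else:
        covariate = np.asarray(covariate, dtype=float)
        mats = design_matrices(factor, covariate, include_interaction)
        term_names = ["covariate", "factor"]
        if include_interaction:
            term_names.append("interaction")
    hats = []
    for X in mats:
        # H = X (X'X)^+ X'; pinv guards rank deficiency
        hats.append(X @ np.linalg.pinv(X.T @ X) @ X.T)
    df_model = [X.shape[1] for X in mats]
    df_res = n - df_model[-1]
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")

    # tr(A @ B) = Σ A∘Bᵀ; with symmetric projectors this turns each
    # permutation's partition into elementwise products.
    diffs = [hats[i] - hats[i - 1] for i in range(1, len(hats))]
    resid_proj = np.eye(n) - hats[-1]

    def partition(gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([float(np.sum(d * gm)) for d in diffs])
        ss_res = float(np.sum(resid_proj * gm))
        return ss_terms, ss_res

    ss_obs, ss_res_obs = partition(g)
    dfs = np.array([df_model[i] - df_model[i - 1] for i in range(1, len(hats))])
    ms_res = ss_res_obs / df_res
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss_obs / dfs) / ms_res if ms_res > 0 else np.where(
            ss_obs > 0, np.inf, 0.0)

    rng = np.random.default_rng(seed)
    exceed = np.ones(len(term_names))  # the identity permutation counts once
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = partition(gp)
        ms_res_p = ss_res_p / df_res
        with np.errstate(divide="ignore", invalid="ignore"):
            f_p = (ss_p / dfs) / ms_res_p if ms_res_p > 0 else np.where(
                ss_p > 0, np.inf, 0.0)
        exceed += f_p >= f_obs
    p_perm = exceed / (n_perm + 1.0)

    ss_total = float(np.trace(g))
    return PermanovaResult(
        terms=tuple(term_names),
        df={t: int(d) for t, d in zip(term_names, dfs)},
        ss={t: float(s) for t, s in zip(term_names, ss_obs)},
        pseudo_f={t: float(f) for t, f in zip(term_names, f_obs)},
        p_perm={t: float(p) for t, p in zip(term_names, p_perm)},
        ss_residual=ss_res_obs, df_residual=df_res, ss_total=ss_total,
        n_perm=n_perm, seed=seed,
    )
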