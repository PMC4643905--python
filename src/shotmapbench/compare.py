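"""Cross-sample comparison of family abundance profiles.

Given a families x samples abundance matrix with per-sample metadata, this
module tests each protein family for association with a covariate
(Kruskal-Wallis for categorical covariates, Kendall's tau for continuous
ones, with exact small-sample p-values), controls the false discovery rate
with Storey q-values, tests significant families for pathway enrichment with
one-sided Fisher's exact tests, and summarizes community structure with
PERMANOVA on a dissimilarity matrix and PCA on scaled abundances.

Default significance conventions: families at q <= 0.10 and pathways at
q <= 0.25.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SampleMatrix",
    "TestResult",
    "prevalence_filter",
    "family_association_tests",
    "storey_qvalues",
    "pathway_enrichment",
    "permanova",
    "pca_profiles",
    "FAMILY_FDR",
    "PATHWAY_FDR",
]

FAMILY_FDR = 0.10
PATHWAY_FDR = 0.25

EXACT_TEST_MAX_N = 10  # exact permutation p-values at or below this total n


@dataclass
class SampleMatrix:
    """A families x samples abundance table with sample metadata."""

    values: pd.DataFrame  # index: family ids, columns: sample ids
    sample_meta: pd.DataFrame  # index: sample ids

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate family ids in abundance matrix")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")

    @classmethod
    def from_tsv(cls, matrix_path, meta_path) -> "SampleMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values, meta)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class TestResult:
    family_id: str
    statistic: float
    p: float
    q: float = float("nan")


def prevalence_filter(
    matrix: SampleMatrix, mode: str = "fully_observed", min_fraction: float = 1.0
) -> SampleMatrix:
    """Keep families detected in enough samples.

    ``fully_observed`` keeps only families with a positive abundance in every
    sample — a simple way to cut the multiple-testing burden;
    ``min_fraction`` keeps families present in at least that fraction of
    samples (0 is the identity).
    """
    if mode == "fully_observed":
        frac = 1.0
    elif mode == "min_fraction":
        frac = min_fraction
    else:
        raise ValueError(f"unknown prevalence filter mode {mode!r}")
    present = (matrix.values > 0).mean(axis=1)
    keep = present >= frac
    if not keep.any():
        warnings.warn("prevalence filter removed every family")
    return SampleMatrix(matrix.values.loc[keep], matrix.sample_meta)


# ---------------------------------------------------------------------------
# per-family association tests


def _kruskal_statistic(values: np.ndarray, group_codes: np.ndarray, n_groups: int) -> float:
    ranks = stats.rankdata(values)
    n = len(values)
    h = 0.0
    for g in range(n_groups):
        r = ranks[group_codes == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def _exact_kruskal_p(values: np.ndarray, group_codes: np.ndarray) -> float:
    """Exact permutation p-value: enumerate all assignments of values to groups."""
    n_groups = group_codes.max() + 1
    observed = _kruskal_statistic(values, group_codes, n_groups)
    total = 0
    extreme = 0
    for perm in _distinct_label_permutations(group_codes):
        total += 1
        if _kruskal_statistic(values, perm, n_groups) >= observed - 1e-12:
            extreme += 1
    return extreme / total


def _distinct_label_permutations(codes: np.ndarray):
    """All distinct orderings of a multiset of group labels."""
    seen_positions = sorted(codes.tolist())
    for perm in _multiset_permutations(seen_positions):
        yield np.array(perm)


def _multiset_permutations(items: list):
    # classic lexicographic multiset permutation generator
    items = sorted(items)
    n = len(items)
    while True:
        yield list(items)
        i = n - 2
        while i >= 0 and items[i] >= items[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while items[j] <= items[i]:
            j -= 1
        items[i], items[j] = items[j], items[i]
        items[i + 1 :] = reversed(items[i + 1 :])


def _exact_kendall_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p-value for Kendall's tau (small n)."""
    observed = abs(stats.kendalltau(x, y).statistic)
    total = 0
    extreme = 0
    for perm in itertools.permutations(range(len(y))):
        total += 1
        tau = stats.kendalltau(x, y[list(perm)]).statistic
        if abs(tau) >= observed - 1e-12:
            extreme += 1
    return extreme / total


def family_association_tests(
    matrix: SampleMatrix, covariate: str
) -> list[TestResult]:
    """Rank-based association test of every family against one covariate.

    Categorical covariates use Kruskal-Wallis; numeric covariates use
    Kendall's tau.  Exact permutation p-values are used when the total
    sample count is at most 10 (small cohorts make asymptotics unreliable);
    constant-abundance families are reported with p = 1.
    """
    if covariate not in matrix.sample_meta.columns:
        raise KeyError(f"covariate {covariate!r} absent from sample metadata")
    cov = matrix.sample_meta.loc[matrix.samples, covariate]
    numeric = pd.api.types.is_numeric_dtype(cov)
    n = len(cov)

    if numeric:
        y = cov.to_numpy(dtype=float)
        if len(np.unique(y)) < 3:
            raise ValueError("continuous covariate needs >= 3 distinct values")
    else:
        codes, uniques = pd.factorize(cov)
        if len(uniques) < 2:
            raise ValueError("categorical covariate needs >= 2 groups")
        codes = np.asarray(codes)

    results = []
    for family_id, row in matrix.values.iterrows():
        values = row.to_numpy(dtype=float)
        if np.allclose(values, values[0]):
            results.append(TestResult(family_id, 0.0, 1.0))
            continue
        if numeric:
            tau, p_asym = stats.kendalltau(values, y)
            no_ties = len(np.unique(values)) == n and len(np.unique(y)) == n
            if n <= EXACT_TEST_MAX_N and no_ties:
                p = float(stats.kendalltau(values, y, method="exact").pvalue)
            elif n <= 7:
                # ties: full permutation enumeration (feasible up to 7! orderings)
                p = _exact_kendall_p(values, y)
            else:
                p = p_asym
            results.append(TestResult(family_id, float(tau), float(p)))
        else:
            groups = [values[codes == g] for g in range(len(uniques))]
            h, p_asym = stats.kruskal(*groups)
            if n <= EXACT_TEST_MAX_N:
                p = _exact_kruskal_p(values, codes)
            else:
                p = p_asym
            results.append(TestResult(family_id, float(h), float(p)))
    return results


# ---------------------------------------------------------------------------
# multiple testing


def estimate_pi0(pvals: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey-Tibshirani smoother estimate of the null proportion pi0.

    Computes pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over a lambda
    grid, fits a cubic polynomial and evaluates it at the largest lambda;
    the result is clipped to (0, 1].
    """
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = len(pvals)
    pi0_lambda = np.array(
        [(pvals > lam).sum() / (m * (1.0 - lam)) for lam in lambdas]
    )
    if len(lambdas) >= 4:
        coeffs = np.polyfit(lambdas, pi0_lambda, 3)
        pi0 = float(np.polyval(coeffs, lambdas.max()))
    else:
        pi0 = float(pi0_lambda[-1])
    return min(max(pi0, 1.0 / m), 1.0)


def storey_qvalues(pvals: Sequence[float], pi0: float | None = None) -> np.ndarray:
    """Storey q-values for a vector of p-values.

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j over the sorted p-values, with
    pi0 estimated by the smoother unless given.  With ``pi0=1`` the result
    equals Benjamini-Hochberg adjusted p-values exactly.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty 1-d p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if pi0 is None:
        pi0 = estimate_pi0(p) if m >= 20 else 1.0
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must be in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def attach_qvalues(results: list[TestResult], pi0: float | None = None) -> list[TestResult]:
    qvals = storey_qvalues([r.p for r in results], pi0=pi0)
    return [
        TestResult(r.family_id, r.statistic, r.p, float(q))
        for r, q in zip(results, qvals)
    ]


# ---------------------------------------------------------------------------
# pathway enrichment


def pathway_enrichment(
    significant: set[str],
    universe: set[str],
    pathway_map: Mapping[str, set[str]],
    pi0: float | None = 1.0,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of significant families per pathway.

    For each pathway the 2x2 table (sig & in, sig & out, nonsig & in,
    nonsig & out) is tested with a one-sided (greater) Fisher exact test;
    q-values are attached across pathways.  Pathways with no member in the
    universe are skipped.
    """
    if not significant <= universe:
        raise ValueError("significant families must be a subset of the universe")
    rows = []
    for pathway, members in sorted(pathway_map.items()):
        members_in = members & universe
        if not members_in:
            continue
        a = len(significant & members_in)
        b = len(significant) - a
        c = len(members_in) - a
        d = len(universe) - len(significant) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"pathway": pathway, "odds": odds, "p": p,
                     "n_significant": a, "n_members": len(members_in)})
    if not rows:
        return pd.DataFrame(columns=["pathway", "odds", "p", "q"])
    frame = pd.DataFrame(rows).set_index("pathway")
    frame["q"] = storey_qvalues(frame["p"].to_numpy(), pi0=pi0)
    return frame


# ---------------------------------------------------------------------------
# community-level structure


def permanova(
    dist: np.ndarray | pd.DataFrame,
    groups: Sequence,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutational multivariate ANOVA (Anderson's pseudo-F) on a distance matrix.

    pseudo-F = (SS_among / (a - 1)) / (SS_within / (N - a)) computed from
    squared dissimilarities; the p-value is (1 + #{F_perm >= F_obs}) /
    (1 + n_perm) under random relabelling.  Deterministic given ``seed``.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with a zero diagonal")
    labels, counts = np.unique(np.asarray(groups), return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group must contain at least 2 samples")

    n = d.shape[0]
    a = len(labels)
    d2 = d**2
    sst = d2[np.triu_indices(n, 1)].sum() / n
    codes = np.searchsorted(labels, np.asarray(groups))

    def pseudo_f(codes_: np.ndarray) -> float:
        ssw = 0.0
        for g in range(a):
            idx = np.nonzero(codes_ == g)[0]
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ssa = sst - ssw
        return (ssa / (a - 1)) / (ssw / (n - a))

    observed = pseudo_f(codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = codes.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if pseudo_f(perm) >= observed - 1e-12:
            exceed += 1
    return observed, (1 + exceed) / (1 + n_perm)


def pca_profiles(
    matrix: SampleMatrix, scale: bool = True, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on their family abundance profiles.

    Samples are observations and families variables; abundances are centered
    and (by default) scaled to zero mean and unit variance, with
    zero-variance families dropped first.  Returns per-sample scores and
    explained-variance fractions (non-increasing, summing to <= 1).
    """
    if len(matrix.samples) < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = matrix.values.T  # samples x families
    variable = x.std(axis=0, ddof=0) > 0
    x = x.loc[:, variable]
    if x.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant families")
    data = x.to_numpy(dtype=float)
    if scale:
        data = StandardScaler().fit_transform(data)
    else:
        data = data - data.mean(axis=0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(data)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=x.index, columns=cols),
        pca.explained_variance_ratio_,
    )
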