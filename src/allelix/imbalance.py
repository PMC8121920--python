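"""Beta-binomial allelic-imbalance testing with Storey FDR control.

The null model for a heterozygous site is that reads sample the two
alleles like a fair coin, with extra-binomial variance from enrichment
and depth heterogeneity captured by a per-condition beta-binomial
dispersion. The test asks, for each site, whether the reference-allele
fraction deviates from 0.5 beyond what that null allows.

Parameterization: beta-binomial with mean ``mu`` and dispersion
``rho = 1/(alpha+beta+1)``; ``rho -> 0`` recovers the binomial. The
dispersion is fitted per condition by maximum likelihood (``mu`` fixed at
0.5 so that true imbalance is not absorbed into the null) on deep sites,
then applied to all tested sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BetaBinomNull",
    "ImbalanceCall",
    "PoolingScheme",
    "PoolingLevel",
    "CallThresholds",
    "betabinom_params",
    "betabinom_logpmf",
    "betabinom_pvalue",
    "betabinom_pvalues",
    "sample_betabinom",
    "pool_counts",
    "fit_dispersion",
    "storey_pi0",
    "storey_qvalues",
    "call_imbalance",
]

# ---------------------------------------------------------------------------
# beta-binomial primitives


def betabinom_params(mu: float, rho: float) -> tuple[float, float]:
    """Convert (mean, dispersion) to (alpha, beta).

    rho = 1/(alpha+beta+1), mu = alpha/(alpha+beta). rho must be in [0, 1);
    rho == 0 has no finite (alpha, beta) and callers fall back to the
    binomial limit.
    """
    if not 0 <= rho < 1:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if rho == 0:
        raise ValueError("rho=0 is the binomial limit; no finite (alpha, beta)")
    s = 1.0 / rho - 1.0  # alpha + beta
    return mu * s, (1.0 - mu) * s


def betabinom_logpmf(k, n, mu: float, rho: float):
    """Log-pmf under beta-binomial(n, mu, rho); binomial when rho == 0."""
    k = np.asarray(k)
    n = np.asarray(n)
    if rho < 1e-12:  # binomial limit (avoids alpha+beta overflow)
        return stats.binom.logpmf(k, n, mu)
    a, b = betabinom_params(mu, rho)
    return stats.betabinom.logpmf(k, n, a, b)


def sample_betabinom(rng: np.random.Generator, n, mu, rho):
    """Draw beta-binomial counts; vectorized over n and mu."""
    n = np.asarray(n)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), n.shape)
    if rho < 1e-12:
        return rng.binomial(n, mu)
    s = 1.0 / rho - 1.0
    p = rng.beta(mu * s, (1.0 - mu) * s)
    return rng.binomial(n, p)


def betabinom_pvalue(k: int, n: int, rho: float) -> float:
    """Two-sided p-value for k reference reads of n against mu = 0.5.

    Tail-doubling: p = min(1, 2 * min(P(X <= k), P(X >= k))). Because the
    null is symmetric about n/2, the smaller tail is always the one toward
    min(k, n-k), so only the lower tail at m = min(k, n-k) is accumulated
    (from the extreme end inward, in log space).
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"require 0 <= k <= n, n >= 1; got k={k}, n={n}")
    return float(betabinom_pvalues(np.array([k]), np.array([n]), rho)[0])


def betabinom_pvalues(k: np.ndarray, n: np.ndarray, rho: float) -> np.ndarray:
    """Vectorized two-sided beta-binomial p-values against mu = 0.5.

    Work is grouped by unique depth so the pmf over 0..n is evaluated once
    per depth; tails are accumulated from the extreme end inward for
    numerical stability.
    """
    if not 0 <= rho < 1:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if np.any((k < 0) | (k > n) | (n < 1)):
        raise ValueError("require 0 <= k <= n and n >= 1")
    m = np.minimum(k, n - k)  # symmetric null: smaller tail is toward m
    out = np.empty(len(k), dtype=float)
    for depth in np.unique(n):
        idx = np.flatnonzero(n == depth)
        ks = np.arange(depth + 1)
        logpmf = betabinom_logpmf(ks, depth, 0.5, rho)
        # lower-tail CDF accumulated from k=0 (the extreme end) upward
        pmf = np.exp(logpmf)
        lower_cdf = np.cumsum(pmf)
        p = 2.0 * lower_cdf[m[idx]]
        out[idx] = np.minimum(p, 1.0)
    return out


# ---------------------------------------------------------------------------
# pooling


class PoolingLevel(str, Enum):
    SAMPLE = "sample"
    CELL_TYPE = "cell_type"
    STRAIN = "strain"
    AGGREGATE = "aggregate"


@dataclass
class PoolingScheme:
    """Maps sample_id -> (cell_type, strain); drives count pooling."""

    mapping: dict[str, tuple[str, str]]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PoolingScheme":
        return cls({
            str(r.sample_id): (str(r.cell_type), str(r.strain))
            for r in df.itertuples(index=False)
        })

    def group_of(self, sample_id: str, level: PoolingLevel | str) -> str:
        level = PoolingLevel(level)
        if sample_id not in self.mapping:
            raise KeyError(f"sample {sample_id!r} not in pooling scheme")
        cell, strain = self.mapping[sample_id]
        if level is PoolingLevel.SAMPLE:
            return sample_id
        if level is PoolingLevel.CELL_TYPE:
            return cell
        if level is PoolingLevel.STRAIN:
            return strain
        return "all"


def pool_counts(counts: pd.DataFrame, scheme: PoolingScheme,
                level: PoolingLevel | str) -> pd.DataFrame:
    """Sum ref/nonref counts within pooling groups.

    `counts` is long-form (snv_id, condition_id, ref_count, nonref_count)
    with condition_id a sample id in the scheme. Grand totals are conserved.
    """
    level = PoolingLevel(level)
    df = counts.copy()
    df["group_id"] = [scheme.group_of(s, level) for s in df["condition_id"]]
    pooled = (
        df.groupby(["snv_id", "group_id"], as_index=False)[["ref_count", "nonref_count"]]
        .sum()
    )
    return pooled


# ---------------------------------------------------------------------------
# dispersion fitting


@dataclass(frozen=True)
class BetaBinomNull:
    """Fitted per-condition null: mu fixed at 0.5, dispersion rho."""

    condition_id: str
    rho: float
    n_sites_used: int
    loglik: float
    mu: float = 0.5


def fit_dispersion(ref_counts, totals, condition_id: str = "",
                   min_fit_depth: int = 101, min_sites: int = 50,
                   rho_bounds: tuple[float, float] = (0.0, 0.5)) -> BetaBinomNull:
    """Maximum-likelihood dispersion for one condition, mu fixed at 0.5.

    Only sites with total >= `min_fit_depth` reads (default: strictly more
    than 100) inform the fit; the resulting rho is later applied to all
    tested sites. Bounded scalar search on rho in `rho_bounds`.
    """
    ref = np.asarray(ref_counts, dtype=np.int64)
    tot = np.asarray(totals, dtype=np.int64)
    deep = tot >= min_fit_depth
    if deep.sum() < min_sites:
        raise ValueError(
            f"condition {condition_id!r}: only {int(deep.sum())} sites with "
            f">= {min_fit_depth} reads (need {min_sites}); pool conditions "
            f"further or supply an explicit rho"
        )
    k, n = ref[deep], tot[deep]

    def negll(rho: float) -> float:
        return -float(np.sum(betabinom_logpmf(k, n, 0.5, rho)))

    lo = max(rho_bounds[0], 0.0)
    res = optimize.minimize_scalar(
        negll, bounds=(max(lo, 1e-9), rho_bounds[1]), method="bounded",
        options={"xatol": 1e-7},
    )
    rho_hat, ll = float(res.x), -float(res.fun)
    # the interior optimum may be a boundary artifact: compare with rho -> 0
    ll0 = -negll(0.0)
    if ll0 >= ll:
        rho_hat, ll = 0.0, ll0
    return BetaBinomNull(condition_id=condition_id, rho=rho_hat,
                         n_sites_used=int(deep.sum()), loglik=ll)


# ---------------------------------------------------------------------------
# Storey q-values


def storey_pi0(p_values, lambdas=None) -> float:
    """Estimate the null proportion pi0 by Storey's smoother.

    pi0(lambda) = #{p > lambda} / (m (1-lambda)) is evaluated on the
    standard grid lambda = 0.05..0.95, smoothed by a cubic fit, and read
    off at the largest lambda. Fewer than 100 p-values -> pi0 = 1
    (Benjamini-Hochberg fallback).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return 1.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size < 100:
        return 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas)
    m = p.size
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    return float(np.clip(pi0, max(1.0 / m, 1e-8), 1.0))


def storey_qvalues(p_values, pi0: float | None = None) -> np.ndarray:
    """Storey q-values; with pi0 forced to 1 these equal BH adjusted p."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([])
    if pi0 is None:
        pi0 = storey_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    # enforce monotonicity in p (running minimum from the largest p down)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# calling


@dataclass(frozen=True)
class CallThresholds:
    """Significance and magnitude thresholds for flagging imbalance."""

    fdr: float = 0.10
    ratio: float = 0.70  # strict: max(ratio, 1-ratio) must exceed this
    min_reads: int = 30


@dataclass(frozen=True)
class ImbalanceCall:
    snv_id: str
    level: str
    group_id: str
    ref_count: int
    nonref_count: int
    allelic_ratio: float
    p_value: float
    q_value: float
    imbalanced: bool


def call_imbalance(pooled: pd.DataFrame, nulls: dict[str, BetaBinomNull],
                   thresholds: CallThresholds = CallThresholds(),
                   level: PoolingLevel | str = PoolingLevel.CELL_TYPE,
                   per_group_fdr: bool = False) -> pd.DataFrame:
    """Test every pooled (SNV, group) entry with enough reads.

    Entries with fewer than `min_reads` total reads are not tested and do
    not appear in the output. q-values are computed jointly over all tests
    of the pooling analysis (the per-analysis multiple-testing universe);
    `per_group_fdr=True` switches to within-group q-values. A site is
    flagged imbalanced when q <= fdr AND max(ratio, 1-ratio) > ratio
    threshold (strict) AND total >= min_reads.
    """
    level = PoolingLevel(level).value
    df = pooled.copy()
    df["total"] = df["ref_count"] + df["nonref_count"]
    df = df[df["total"] >= thresholds.min_reads].reset_index(drop=True)
    if df.empty:
        return pd.DataFrame(columns=[
            "snv_id", "level", "group_id", "ref_count", "nonref_count",
            "allelic_ratio", "p_value", "q_value", "imbalanced",
        ])
    missing = set(df["group_id"].unique()) - set(nulls)
    if missing:
        raise ValueError(f"no fitted null for condition(s): {sorted(missing)}")
    df["allelic_ratio"] = df["ref_count"] / df["total"]
    p = np.empty(len(df))
    for gid, sub in df.groupby("group_id"):
        p[sub.index] = betabinom_pvalues(
            sub["ref_count"].to_numpy(), sub["total"].to_numpy(), nulls[gid].rho
        )
    df["p_value"] = p
    if per_group_fdr:
        q = np.empty(len(df))
        for _, sub in df.groupby("group_id"):
            q[sub.index] = storey_qvalues(sub["p_value"].to_numpy())
        df["q_value"] = q
    else:
        df["q_value"] = storey_qvalues(df["p_value"].to_numpy())
    major = np.maximum(df["allelic_ratio"], 1.0 - df["allelic_ratio"])
    df["imbalanced"] = (df["q_value"] <= thresholds.fdr) & (major > thresholds.ratio)
    df["level"] = level
    return df[[
        "snv_id", "level", "group_id", "ref_count", "nonref_count", "total",
        "allelic_ratio", "p_value", "q_value", "imbalanced",
    ]]


def fit_all_nulls(pooled: pd.DataFrame, min_fit_depth: int = 101,
                  min_sites: int = 50, fallback_rho: float | None = None
                  ) -> dict[str, BetaBinomNull]:
    """Fit one BetaBinomNull per pooled group.

    Groups with too few deep sites raise unless `fallback_rho` is given,
    in which case they receive that dispersion with n_sites_used = 0.
    """
    totals = pooled["ref_count"] + pooled["nonref_count"]
    nulls = {}
    for gid, sub in pooled.groupby("group_id"):
        try:
            nulls[gid] = fit_dispersion(
                sub["ref_count"].to_numpy(),
                totals[sub.index].to_numpy(),
                condition_id=str(gid),
                min_fit_depth=min_fit_depth,
                min_sites=min_sites,
            )
        except ValueError:
            if fallback_rho is None:
                raise
            nulls[gid] = BetaBinomNull(condition_id=str(gid), rho=fallback_rho,
                                       n_sites_used=0, loglik=float("nan"))
    return nulls
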