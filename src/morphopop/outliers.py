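"""F_ST-outlier screening and the consensus neutral locus set.

Two complementary scans:

* a trimmed-χ² scan in the spirit of OutFLANK: per-locus Weir–Cockerham
  F_ST, a null χ² distribution fitted by truncated maximum likelihood on
  the two-sided-trimmed bulk, right-tail p-values and BH q-values;
* a PCA–Mahalanobis scan in the spirit of pcadapt: per-locus z-scores of
  regressions onto the leading principal components, robust Mahalanobis
  distances rescaled by a genomic inflation factor, χ²_K p-values.

Loci flagged by at least ``min_methods`` scans form the putatively selected
set; the complement is the neutral set used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .popgen import GenotypeMatrix, PopulationMap, bh_adjust, wc_fst

__all__ = [
    "MethodReport",
    "OutlierReport",
    "trimmed_chisq_outliers",
    "pca_mahalanobis_outliers",
    "consensus",
]


@dataclass
class MethodReport:
    method: str
    table: pd.DataFrame              # index locus; columns statistic, p, q, flagged
    params: dict = field(default_factory=dict)

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["flagged"]])


@dataclass
class OutlierReport:
    per_method: dict[str, pd.DataFrame]
    consensus_flagged: list[str]
    neutral_set: list[str]
    min_methods: int


def trimmed_chisq_outliers(
    g: GenotypeMatrix,
    pm: PopulationMap,
    trim: float = 0.05,
    he_min: float = 0.1,
    q_thresh: float = 0.05,
) -> MethodReport:
    """Trimmed-χ² F_ST outlier scan.

    The null model is F_ST·df/F̄ ~ χ²_df; F̄ and the effective df are fitted
    by maximum likelihood on the loci between the ``trim`` and ``1-trim``
    F_ST quantiles (likelihood properly truncated at the observed trim
    bounds).  Loci with pooled expected heterozygosity below ``he_min`` are
    excluded from the fit but still receive p-values.
    """
    res = wc_fst(g, pm)
    fst = res.per_locus_fst()
    p_hat = g.allele_freq()
    he = 2 * p_hat * (1 - p_hat)

    usable = ~np.isnan(fst)
    fit_mask = usable & (he >= he_min)
    x = np.sort(fst[fit_mask])
    if len(x) < 20:
        raise ValueError("too few loci to fit the null distribution")
    lo_i, hi_i = int(np.floor(trim * len(x))), int(np.ceil((1 - trim) * len(x)))
    trimmed = x[lo_i:hi_i]
    lo_b, hi_b = trimmed[0], trimmed[-1]
    if np.isclose(trimmed.var(), 0.0):
        # degenerate: all (trimmed) F_ST identical -> no tail to test
        tab = pd.DataFrame({"statistic": fst, "p": 1.0, "q": 1.0,
                            "flagged": False}, index=g.loci)
        return MethodReport("trimmed_chisq", tab,
                            {"fbar": float(trimmed.mean()), "df": np.inf,
                             "degenerate": True})

    fbar0 = trimmed.mean()
    df0 = max(2.0 * fbar0**2 / trimmed.var(), 0.5)

    def nll(params: np.ndarray) -> float:
        log_fbar, log_df = params
        fbar, df = np.exp(log_fbar), np.exp(log_df)
        scale = df / fbar
        z = trimmed * scale
        if (z <= 0).any():
            return np.inf
        logpdf = stats.chi2.logpdf(z, df) + np.log(scale)
        mass = stats.chi2.cdf(hi_b * scale, df) - stats.chi2.cdf(lo_b * scale, df)
        if mass <= 0:
            return np.inf
        return -(logpdf.sum() - len(trimmed) * np.log(mass))

    with np.errstate(invalid="ignore", over="ignore"):
        opt = optimize.minimize(nll, np.log([fbar0, df0]), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-8,
                                         "maxiter": 2000})
    fbar, df = np.exp(opt.x)
    if not np.isfinite(df) or df <= 0:
        raise RuntimeError("null-distribution fit failed (df <= 0)")

    pvals = np.full(len(fst), np.nan)
    pvals[usable] = stats.chi2.sf(np.maximum(fst[usable], 0.0) * df / fbar, df)
    qvals = np.full(len(fst), np.nan)
    qvals[usable] = bh_adjust(pvals[usable])
    tab = pd.DataFrame({
        "statistic": fst, "p": pvals, "q": qvals,
        "flagged": (qvals <= q_thresh) & usable,
    }, index=g.loci)
    return MethodReport("trimmed_chisq", tab,
                        {"fbar": float(fbar), "df": float(df),
                         "he_min": he_min, "trim": trim, "q_thresh": q_thresh})


def pca_mahalanobis_outliers(
    g: GenotypeMatrix,
    K: int = 2,
    q_thresh: float = 0.05,
) -> MethodReport:
    """PCA–Mahalanobis outlier scan.

    Genotypes are centered at 2p̂ and scaled by sqrt(2p̂(1−p̂)); each locus is
    regressed on the first K principal components of the individuals, the
    K-vector of regression z-scores is scored by Mahalanobis distance (mean
    and covariance from the central 5th–95th percentile bulk, iterated
    twice), distances are divided by the genomic inflation factor, and
    p-values come from χ²_K.
    """
    n, L = g.genotypes.shape
    if not 0 < K < min(n, L):
        raise ValueError("K must satisfy 0 < K < min(n_individuals, n_loci)")
    X = g.genotypes.copy()
    p_hat = np.nanmean(X, axis=0) / 2.0
    sd = np.sqrt(2 * p_hat * (1 - p_hat))
    ok = sd > 0
    mu = 2 * p_hat
    X = (X - mu) / np.where(ok, sd, 1.0)
    X[np.isnan(X)] = 0.0
    X[:, ~ok] = 0.0

    u, s, _ = np.linalg.svd(X, full_matrices=False)
    U = u[:, :K]                                     # orthonormal PC scores
    B = U.T @ X                                      # (K, L) regression coefficients
    rss = np.maximum((X**2).sum(axis=0) - (B**2).sum(axis=0), 0.0)
    dof = max(n - K - 1, 1)
    sigma = np.sqrt(rss / dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = np.where(sigma > 0, B / sigma, 0.0).T    # (L, K)

    informative = ok & (sigma > 0)
    idx = np.flatnonzero(informative)
    z = Z[idx]
    center = z.mean(axis=0)
    cov = np.cov(z.T)
    for _ in range(2):
        try:
            d2 = _mahalanobis2(z, center, cov)
        except np.linalg.LinAlgError as e:
            raise ValueError("singular covariance; try a smaller K") from e
        lo, hi = np.percentile(d2, [5, 95])
        bulk = z[(d2 >= lo) & (d2 <= hi)]
        center = bulk.mean(axis=0)
        cov = np.cov(bulk.T)
    d2 = _mahalanobis2(z, center, cov)
    gif = float(np.median(d2) / stats.chi2.ppf(0.5, K))
    pvals = np.full(L, np.nan)
    pvals[idx] = stats.chi2.sf(d2 / gif, K)
    qvals = np.full(L, np.nan)
    qvals[idx] = bh_adjust(pvals[idx])
    stat = np.full(L, np.nan)
    stat[idx] = d2
    tab = pd.DataFrame({
        "statistic": stat, "p": pvals, "q": qvals,
        "flagged": np.where(np.isnan(qvals), False, qvals <= q_thresh),
    }, index=g.loci)
    return MethodReport("pca_mahalanobis", tab,
                        {"K": K, "gif": gif, "q_thresh": q_thresh})


def _mahalanobis2(z: np.ndarray, center: np.ndarray, cov: np.ndarray) -> np.ndarray:
    cov = np.atleast_2d(cov)
    dev = z - center
    sol = np.linalg.solve(cov, dev.T)
    return (dev.T * sol).sum(axis=0)


def consensus(reports: list[MethodReport], min_methods: int = 2) -> OutlierReport:
    """Combine per-method flags: loci flagged by >= min_methods are removed.

    With only two scans available the "flagged by any two" rule degenerates
    to the intersection; ``min_methods`` stays configurable.
    """
    if len(reports) < 2:
        raise ValueError("consensus needs at least two method reports")
    loci = list(reports[0].table.index)
    for r in reports[1:]:
        if list(r.table.index) != loci:
            raise ValueError("method reports cover different locus sets")
    counts = sum(r.table["flagged"].astype(int) for r in reports)
    flagged = list(counts.index[counts >= min_methods])
    neutral = [l for l in loci if l not in set(flagged)]
    return OutlierReport(
        per_method={r.method: r.table for r in reports},
        consensus_flagged=flagged,
        neutral_set=neutral,
        min_methods=min_methods,
    )
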