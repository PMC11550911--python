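"""SNP quality control, diversity, Weir–Cockerham F_ST, and population structure.

Genotypes are held as an individuals × loci matrix of minor-allele dosages
(0, 1, 2) with NaN for missing calls.  All estimators exclude missing calls
per locus; only the PCA used for clustering mean-imputes.

The F_ST estimator is Weir & Cockerham's (1984) θ: per-locus variance
components a (among populations), b (among individuals within populations)
and c (within individuals), combined as a ratio of sums over loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenotypeMatrix",
    "PopulationMap",
    "FstResult",
    "FilterReport",
    "DapcResult",
    "filter_snps",
    "diversity",
    "wc_fst",
    "pairwise_fst",
    "bootstrap_fst_ci",
    "mantel",
    "diversity_contrast",
    "dapc_cluster",
    "he_distance_regression",
    "haversine_km",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes: individuals × loci, dosages 0/1/2, NaN missing."""

    genotypes: np.ndarray            # float array (n_ind, n_loci)
    individuals: list[str]
    loci: list[str]
    tags: list[str]                  # sequence-tag ID per locus

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x loci)")
        n, L = self.genotypes.shape
        if len(self.individuals) != n or len(self.loci) != L or len(self.tags) != L:
            raise ValueError("metadata lengths do not match genotype matrix")
        if any(not t for t in self.tags):
            raise ValueError("every locus needs a non-empty tag ID")
        with np.errstate(invalid="ignore"):
            bad = np.logical_and(~np.isnan(self.genotypes),
                                 ~np.isin(self.genotypes, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype value {self.genotypes[i, j]!r} at "
                f"individual {self.individuals[i]!r}, locus {self.loci[j]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def locus_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.genotypes).mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.genotypes).mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per locus, over called genotypes."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.genotypes, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.genotypes[:, keep],
            list(self.individuals),
            [self.loci[j] for j in keep],
            [self.tags[j] for j in keep],
        )

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.genotypes[keep, :],
            [self.individuals[i] for i in keep],
            list(self.loci),
            list(self.tags),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.genotypes.copy(), list(self.individuals),
                              list(self.loci), list(self.tags))


@dataclass
class PopulationMap:
    """Individual → population assignment with optional region labels and site coordinates."""

    population_of: dict[str, str]
    region_of: dict[str, str] = field(default_factory=dict)
    coords_of: dict[str, tuple[float, float]] = field(default_factory=dict)  # (lat, lon)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population_of.values():
            seen.setdefault(p, None)
        return list(seen)

    def labels_for(self, individuals: list[str]) -> np.ndarray:
        missing = [i for i in individuals if i not in self.population_of]
        if missing:
            raise KeyError(f"individuals missing from population map: {missing[:5]}")
        return np.array([self.population_of[i] for i in individuals])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind, pop in self.population_of.items():
            lat, lon = self.coords_of.get(pop, (np.nan, np.nan))
            rows.append((ind, pop, self.region_of.get(pop, ""), lat, lon))
        return pd.DataFrame(rows, columns=["individual", "population", "region", "lat", "lon"])


@dataclass
class FstResult:
    """Weir–Cockerham variance components and θ for a set of populations."""

    a: np.ndarray                    # among-population component, per locus
    b: np.ndarray                    # among-individual-within component
    c: np.ndarray                    # within-individual component
    loci: list[str]
    populations: list[str]
    theta: float
    pairwise: pd.DataFrame | None = None
    ci: tuple[float, float] | None = None

    def per_locus_fst(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)


@dataclass
class FilterReport:
    """Removed loci/individuals partitioned by the rule that removed them."""

    removed: dict[str, list[str]]
    counts: dict[str, int]
    empty: bool = False

    def all_removed_loci(self) -> set[str]:
        out: set[str] = set()
        for rule, items in self.removed.items():
            if rule != "individual_call_rate":
                out.update(items)
        return out


@dataclass
class DapcResult:
    bic: pd.Series                   # indexed by k
    best_k: int
    assignments: pd.Series           # indexed by individual
    discriminant_scores: pd.DataFrame | None
    n_pcs: int


# ---------------------------------------------------------------------------
# SNP filtering


def filter_snps(
    g: GenotypeMatrix,
    locus_call_min: float = 0.95,
    ind_call_min: float = 0.85,
    maf_min: float = 0.05,
    one_per_tag: bool = True,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the standard DArT-style QC cascade in a fixed order.

    Order: locus call rate → individual call rate → (recompute locus stats)
    → MAF → monomorphic → one SNP per sequence tag.  The report assigns each
    removed item to exactly the first rule that removed it.
    """
    for thr in (locus_call_min, ind_call_min, maf_min):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("filter thresholds must lie in [0, 1]")
    removed: dict[str, list[str]] = {
        "locus_call_rate": [], "individual_call_rate": [],
        "maf": [], "monomorphic": [], "one_per_tag": [],
    }

    cur = g
    keep = cur.locus_call_rate() >= locus_call_min
    removed["locus_call_rate"] = [l for l, k in zip(cur.loci, keep) if not k]
    cur = cur.subset_loci(keep)

    keep_ind = cur.individual_call_rate() >= ind_call_min
    removed["individual_call_rate"] = [i for i, k in zip(cur.individuals, keep_ind) if not k]
    cur = cur.subset_individuals(keep_ind)

    if cur.n_individuals == 0:
        warnings.warn("all individuals removed by call-rate filter", UserWarning)
        rep = FilterReport(removed, {k: len(v) for k, v in removed.items()}, empty=True)
        return cur, rep

    # locus statistics recomputed on the retained individuals
    maf = cur.maf()
    keep = np.isnan(maf) | (maf >= maf_min) if maf_min == 0 else (~np.isnan(maf)) & (maf >= maf_min)
    keep = np.asarray(keep, dtype=bool)
    removed["maf"] = [l for l, k in zip(cur.loci, keep) if not k]
    cur = cur.subset_loci(keep)

    keep = cur.maf() > 0
    removed["monomorphic"] = [l for l, k in zip(cur.loci, keep) if not k]
    cur = cur.subset_loci(keep)

    if one_per_tag:
        call = cur.locus_call_rate()
        best_for_tag: dict[str, int] = {}
        for j, tag in enumerate(cur.tags):
            i = best_for_tag.get(tag)
            # highest call rate wins; ties broken by lowest position (first seen)
            if i is None or call[j] > call[i]:
                best_for_tag[tag] = j
        keep = np.zeros(cur.n_loci, dtype=bool)
        keep[list(best_for_tag.values())] = True
        removed["one_per_tag"] = [l for l, k in zip(cur.loci, keep) if not k]
        cur = cur.subset_loci(keep)

    rep = FilterReport(removed, {k: len(v) for k, v in removed.items()},
                       empty=(cur.n_loci == 0 or cur.n_individuals == 0))
    if rep.empty:
        warnings.warn("filtering removed every locus or individual", UserWarning)
    return cur, rep


# ---------------------------------------------------------------------------
# diversity


def _per_pop_locus_stats(g: GenotypeMatrix, pm: PopulationMap):
    """Per population, per locus: n called, allele freq, observed het."""
    labels = pm.labels_for(g.individuals)
    pops = [p for p in pm.populations() if p in set(labels)]
    out = {}
    for p in pops:
        sub = g.genotypes[labels == p]
        called = ~np.isnan(sub)
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n > 0, np.nansum(sub, axis=0) / (2 * n), np.nan)
            ho = np.where(n > 0, (sub == 1).sum(axis=0) / n, np.nan)
        out[p] = (n, freq, ho)
    return pops, out


def diversity(g: GenotypeMatrix, pm: PopulationMap) -> pd.DataFrame:
    """Per-population Ho, unbiased He (Nei, 2n/(2n−1) correction) and F_IS.

    Population values are means over loci with SE = sd/√L; F_IS is computed
    from the locus-averaged Ho and He (1 − H̄o/H̄e), reported missing when
    H̄e = 0.
    """
    pops, st = _per_pop_locus_stats(g, pm)
    rows = []
    for p in pops:
        n, freq, ho = st[p]
        ok = n >= 2
        if not ok.any():
            warnings.warn(f"population {p!r} has <2 called individuals at every locus; excluded")
            continue
        n, freq, ho = n[ok], freq[ok], ho[ok]
        he = 2.0 * freq * (1.0 - freq) * (2 * n) / (2 * n - 1)
        L = len(he)
        he_m, ho_m = float(np.mean(he)), float(np.mean(ho))
        fis = 1.0 - ho_m / he_m if he_m > 0 else np.nan
        rows.append({
            "population": p,
            "n": int(np.max(n)),
            "He": he_m, "He_se": float(np.std(he, ddof=1) / np.sqrt(L)) if L > 1 else np.nan,
            "Ho": ho_m, "Ho_se": float(np.std(ho, ddof=1) / np.sqrt(L)) if L > 1 else np.nan,
            "Fis": fis,
        })
    return pd.DataFrame(rows).set_index("population")


def per_locus_he(g: GenotypeMatrix, pm: PopulationMap) -> pd.DataFrame:
    """Locus × population table of unbiased expected heterozygosity."""
    pops, st = _per_pop_locus_stats(g, pm)
    cols = {}
    for p in pops:
        n, freq, _ = st[p]
        with np.errstate(invalid="ignore", divide="ignore"):
            he = np.where(n >= 2, 2 * freq * (1 - freq) * (2 * n) / (2 * n - 1), np.nan)
        cols[p] = he
    return pd.DataFrame(cols, index=g.loci)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST


def _wc_components(g: GenotypeMatrix, labels: np.ndarray, pops: list[str]):
    """Per-locus WC (1984) a, b, c for the given populations, vectorized over loci."""
    r = len(pops)
    geno = g.genotypes
    n_pl = np.zeros((r, geno.shape[1]))     # called individuals per pop per locus
    p_pl = np.zeros_like(n_pl)              # allele frequency
    h_pl = np.zeros_like(n_pl)              # observed het proportion
    for i, p in enumerate(pops):
        sub = geno[labels == p]
        called = ~np.isnan(sub)
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_pl[i] = np.where(n > 0, np.nansum(sub, axis=0) / (2 * n), np.nan)
            h_pl[i] = np.where(n > 0, (sub == 1).sum(axis=0) / n, np.nan)
        n_pl[i] = n

    informative = (n_pl > 0).all(axis=0) & (n_pl.sum(axis=0) > r)
    nbar = n_pl.mean(axis=0)
    s2_n = ((n_pl**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - s2_n / (r * nbar)) / (r - 1)
        pbar = (n_pl * p_pl).sum(axis=0) / (r * nbar)
        s2 = (n_pl * (p_pl - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_pl * h_pl).sum(axis=0) / (r * nbar)
        a = nbar / nc * (s2 - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    for arr in (a, b, c):
        arr[~informative] = np.nan
    # nc == 0 can only occur for degenerate single-individual totals
    return a, b, c


def wc_fst(g: GenotypeMatrix, pm: PopulationMap, pops: list[str] | None = None) -> FstResult:
    """Global (or restricted) Weir–Cockerham θ with per-locus components.

    θ = Σa / Σ(a+b+c) over informative loci; loci with zero total variance
    in the selected populations are skipped.
    """
    labels = pm.labels_for(g.individuals)
    present = [p for p in pm.populations() if (labels == p).any()]
    if pops is not None:
        missing = set(pops) - set(present)
        if missing:
            raise ValueError(f"populations not present in data: {sorted(missing)}")
        present = list(pops)
    if len(present) < 2:
        raise ValueError("F_ST requires at least two populations")
    a, b, c = _wc_components(g, labels, present)
    tot = a + b + c
    use = ~np.isnan(tot) & (tot != 0)
    if not use.any():
        warnings.warn("no informative loci; θ undefined")
        theta = np.nan
    else:
        theta = float(np.sum(a[use]) / np.sum(tot[use]))
    return FstResult(a=a, b=b, c=c, loci=list(g.loci), populations=present, theta=theta)


def per_locus_fst(g: GenotypeMatrix, pm: PopulationMap) -> np.ndarray:
    return wc_fst(g, pm).per_locus_fst()


def pairwise_fst(
    g: GenotypeMatrix,
    pm: PopulationMap,
    n_boot: int = 0,
    level: float = 0.95,
    seed: int | None = None,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise WC θ (optionally with bootstrap significance).

    With ``n_boot > 0`` a second DataFrame of BH-adjusted bootstrap
    significance flags is derivable from the returned per-pair CIs; here we
    return the θ matrix and attach CIs in ``.attrs['ci']``.
    """
    labels = pm.labels_for(g.individuals)
    pops = [p for p in pm.populations() if (labels == p).any()]
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    cis: dict[tuple[str, str], tuple[float, float]] = {}
    rng = np.random.default_rng(seed)
    for i, p in enumerate(pops):
        for q in pops[i + 1:]:
            res = wc_fst(g, pm, pops=[p, q])
            mat.loc[p, q] = mat.loc[q, p] = res.theta
            if n_boot:
                lo, hi = bootstrap_fst_ci(res, n_boot=n_boot, level=level,
                                          seed=int(rng.integers(2**31)))
                cis[(p, q)] = (lo, hi)
    mat.attrs["ci"] = cis
    return mat


def bootstrap_fst_ci(
    r: FstResult, n_boot: int = 1000, level: float = 0.95, seed: int | None = None
) -> tuple[float, float]:
    """Percentile CI for θ from resampling loci with replacement."""
    tot = r.a + r.b + r.c
    use = np.flatnonzero(~np.isnan(tot) & (tot != 0))
    if len(use) < 20:
        warnings.warn("fewer than 20 informative loci; bootstrap CI unstable")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(use), size=(n_boot, len(use)))
    a_s = r.a[use][idx].sum(axis=1)
    t_s = tot[use][idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        thetas = a_s / t_s
    alpha = (1 - level) / 2
    lo, hi = np.nanquantile(thetas, [alpha, 1 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Mantel, diversity contrasts, clustering, IBD helpers


def mantel(
    d1: np.ndarray | pd.DataFrame,
    d2: np.ndarray | pd.DataFrame,
    n_perm: int = 9999,
    seed: int | None = None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel test: Pearson r of off-diagonal distances, permutation p-value.

    p = (1 + #{permuted r at least as extreme}) / (n_perm + 1), permuting rows
    and columns of ``d2`` jointly.  ``alternative`` is 'greater' (the
    isolation-by-distance convention), 'less', or 'two-sided'.
    """
    m1 = np.asarray(d1, dtype=float)
    m2 = np.asarray(d2, dtype=float)
    if m1.shape != m2.shape or m1.shape[0] != m1.shape[1]:
        raise ValueError("distance matrices must be square and of equal size")
    n = m1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = m1[iu]

    def corr(mat: np.ndarray) -> float:
        y = mat[iu]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(m2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(m2[np.ix_(perm, perm)])
        if alternative == "greater":
            count += r_p >= r_obs
        elif alternative == "less":
            count += r_p <= r_obs
        elif alternative == "two-sided":
            count += abs(r_p) >= abs(r_obs)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + count) / (n_perm + 1)
    return r_obs, float(p)


def diversity_contrast(he_by_pop: pd.DataFrame) -> dict:
    """Kruskal–Wallis across populations on per-locus He, with Dunn/BH post hoc.

    ``he_by_pop``: loci × populations (as from :func:`per_locus_he`).
    Returns the KW statistic/p and a pairwise table with Dunn z and
    Benjamini–Hochberg adjusted p-values.
    """
    pops = list(he_by_pop.columns)
    samples = [he_by_pop[p].dropna().to_numpy() for p in pops]
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    try:
        kw_stat, kw_p = stats.kruskal(*samples)
    except ValueError:      # all observations identical: no evidence of contrast
        kw_stat, kw_p = 0.0, 1.0
    if kw_stat < 0:         # rounding can push an exactly-null statistic negative
        kw_stat, kw_p = 0.0, 1.0

    # Dunn's z from pooled midranks with tie correction
    pooled = np.concatenate(samples)
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    mean_ranks, sizes = {}, {}
    start = 0
    for p, s in zip(pops, samples):
        mean_ranks[p] = ranks[start:start + len(s)].mean()
        sizes[p] = len(s)
        start += len(s)
    rows = []
    for i, p in enumerate(pops):
        for q in pops[i + 1:]:
            se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[p] + 1.0 / sizes[q]))
            z = (mean_ranks[p] - mean_ranks[q]) / se
            rows.append({"pop1": p, "pop2": q, "z": z,
                         "p": 2 * stats.norm.sf(abs(z))})
    tab = pd.DataFrame(rows)
    tab["p_adj"] = bh_adjust(tab["p"].to_numpy())
    return {"kw_statistic": float(kw_stat), "kw_p": float(kw_p), "pairwise": tab}


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def dapc_cluster(
    g: GenotypeMatrix,
    k_max: int = 10,
    n_pcs: int = 40,
    seed: int | None = None,
    n_init: int = 25,
) -> DapcResult:
    """Cluster discovery in the style of DAPC's find.clusters.

    Center/scale genotypes (mean-imputing missing calls), PCA, k-means for
    k = 1..k_max on the retained PCs, BIC = n·log(WSS/n) + k·log(n); the best
    k minimizes BIC.  Linear discriminant axes are then computed on the PCs
    for the chosen clustering (k > 1).
    """
    n = g.n_individuals
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of individuals")
    X = g.genotypes.copy()
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd

    n_pcs = min(n_pcs, n - 1, g.n_loci)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)

    rng = np.random.default_rng(seed)
    bic = {}
    labels_by_k = {}
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(((pcs - pcs.mean(axis=0)) ** 2).sum())
            labels_by_k[1] = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_init,
                        random_state=int(rng.integers(2**31))).fit(pcs)
            wss = float(km.inertia_)
            labels_by_k[k] = km.labels_
        bic[k] = n * np.log(wss / n) + k * np.log(n)
    bic_s = pd.Series(bic, name="BIC")
    best_k = int(bic_s.idxmin())
    labels = labels_by_k[best_k]

    scores = None
    if best_k > 1:
        lda = LinearDiscriminantAnalysis(n_components=min(best_k - 1, n_pcs))
        s = lda.fit_transform(pcs, labels)
        scores = pd.DataFrame(s, index=g.individuals,
                              columns=[f"LD{i+1}" for i in range(s.shape[1])])
    assignments = pd.Series(labels, index=g.individuals, name="cluster")
    return DapcResult(bic=bic_s, best_k=best_k, assignments=assignments,
                      discriminant_scores=scores, n_pcs=n_pcs)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (mean Earth radius 6371.0088 km)."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return float(2 * 6371.0088 * np.arcsin(np.sqrt(h)))


def geographic_distance_matrix(pm: PopulationMap, log: bool = False) -> pd.DataFrame:
    """Pairwise great-circle distances (km) between population sites.

    With ``log=True``, natural log of km (the isolation-by-distance
    convention); log distances of coincident sites are undefined.
    """
    pops = [p for p in pm.populations() if p in pm.coords_of]
    missing = [p for p in pm.populations() if p not in pm.coords_of]
    if missing:
        raise ValueError(f"populations without coordinates: {missing}")
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, p in enumerate(pops):
        for q in pops[i + 1:]:
            d = haversine_km(*pm.coords_of[p], *pm.coords_of[q])
            mat.loc[p, q] = mat.loc[q, p] = np.log(d) if log else d
    return mat


def he_distance_regression(
    div: pd.DataFrame, pm: PopulationMap, origin: tuple[float, float]
) -> dict:
    """OLS of population He on great-circle distance (km) to an origin site."""
    pops = list(div.index)
    missing = [p for p in pops if p not in pm.coords_of]
    if missing:
        raise ValueError(f"populations without coordinates: {missing}")
    if len(pops) < 3:
        raise ValueError("regression needs at least 3 populations (error df >= 1)")
    dist = np.array([haversine_km(*origin, *pm.coords_of[p]) for p in pops])
    he = div["He"].to_numpy()
    if np.ptp(he) == 0:     # constant response: flat line, no evidence
        return {"slope": 0.0, "intercept": float(he[0]), "F": 0.0,
                "df": (1, len(pops) - 2), "p": 1.0}
    res = stats.linregress(dist, he)
    df_den = len(pops) - 2
    F = res.rvalue**2 / (1 - res.rvalue**2) * df_den if abs(res.rvalue) < 1 else np.inf
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "F": float(F), "df": (1, df_den), "p": float(res.pvalue)}
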