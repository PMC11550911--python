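"""Synthetic data with known ground truth for every downstream stage.

Three generators mirror the three data streams of a phenotype-vs-genotype
divergence study:

* genotypes under the Balding–Nichols model, whose divergence parameter F
  is on the F_ST scale, with optional within-population inbreeding and a
  degradation helper that plants loci the QC filters must remove;
* 2-D landmark configurations (12 fixed + 10 sliding points) deformed along
  a single fixed direction in tangent shape space, so the first relative
  warp should capture the planted between/within-population variance ratio;
* aligned haplotype sequences with an exact planted number of segregating
  sites and a duplication profile.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morpho import LandmarkConfiguration, centroid_size
from .popgen import GenotypeMatrix, PopulationMap

__all__ = [
    "SimTruth",
    "simulate_genotypes",
    "degrade_genotypes",
    "simulate_landmarks",
    "simulate_haplotypes",
    "plant_outlier_loci",
]

#: raw-offset-to-shape-space scale for landmark deformation: one unit of the
#: trait offset moves the shape 0.05 Procrustes units along the deformation
#: axis, keeping the planted variance ratio well above digitization jitter.
DEFORMATION_SCALE = 0.05


@dataclass
class SimTruth:
    """Ground-truth parameters behind a simulated dataset."""

    fst_true: float = 0.0
    sigma2_B_true: float = 0.0
    sigma2_W_true: float = 0.0
    n_segsites_true: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst_true < 1.0:
            raise ValueError("fst_true must lie in [0, 1)")
        if self.sigma2_B_true < 0 or self.sigma2_W_true < 0:
            raise ValueError("variances must be non-negative")


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    n_pops: int = 12,
    n_per_pop: int = 15,
    n_loci: int = 2000,
    fst_true: float = 0.118,
    seed: int = 0,
    f_within: float = 0.0,
) -> tuple[GenotypeMatrix, PopulationMap, SimTruth]:
    """Balding–Nichols island-model genotypes with target divergence F.

    Ancestral allele frequencies are Uniform(0.05, 0.95) per locus;
    population frequencies are Beta(p(1−F)/F, (1−p)(1−F)/F) (a point mass at
    p when F = 0); genotypes are Binomial(2, freq), or drawn with a
    within-population inbreeding coefficient ``f_within`` when non-zero
    (heterozygote probability deflated by 1−f).
    """
    if n_pops < 2 or n_loci < 1 or n_per_pop < 1:
        raise ValueError("need n_pops >= 2, n_per_pop >= 1, n_loci >= 1")
    if not 0.0 <= fst_true < 1.0:
        raise ValueError("fst_true must lie in [0, 1)")
    if not 0.0 <= f_within < 1.0:
        raise ValueError("f_within must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=n_loci)
    if fst_true > 0:
        ratio = (1.0 - fst_true) / fst_true
        p_pop = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio, size=(n_pops, n_loci))
    else:
        p_pop = np.broadcast_to(p_anc, (n_pops, n_loci)).copy()

    n_ind = n_pops * n_per_pop
    geno = np.empty((n_ind, n_loci), dtype=float)
    for i in range(n_pops):
        p = p_pop[i]
        sl = slice(i * n_per_pop, (i + 1) * n_per_pop)
        if f_within == 0.0:
            geno[sl] = rng.binomial(2, p, size=(n_per_pop, n_loci))
        else:
            q = 1.0 - p
            probs = np.stack([q * q + f_within * p * q,
                              2 * p * q * (1 - f_within),
                              p * p + f_within * p * q])
            u = rng.random((n_per_pop, n_loci))
            geno[sl] = (u > probs[0]).astype(float) + (u > probs[0] + probs[1])

    pops = [f"P{i+1:02d}" for i in range(n_pops)]
    individuals = [f"{p}_i{j+1:02d}" for p in pops for j in range(n_per_pop)]
    loci = [f"L{j+1:05d}" for j in range(n_loci)]
    tags = [f"tag{j+1:05d}" for j in range(n_loci)]
    g = GenotypeMatrix(geno, individuals, loci, tags)
    pm = PopulationMap({ind: ind.split("_")[0] for ind in individuals})
    truth = SimTruth(fst_true=fst_true, seed=seed)
    return g, pm, truth


def plant_outlier_loci(
    g: GenotypeMatrix,
    pm: PopulationMap,
    n_outliers: int,
    fst_outlier: float = 0.6,
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[str]]:
    """Append high-divergence loci (Balding–Nichols at ``fst_outlier``) to a matrix.

    Emulates loci under strong spatially divergent selection for testing
    outlier scans; returns the augmented matrix and the planted locus IDs.
    """
    rng = np.random.default_rng(seed)
    labels = pm.labels_for(g.individuals)
    pops = [p for p in pm.populations() if (labels == p).any()]
    p_anc = rng.uniform(0.05, 0.95, size=n_outliers)
    ratio = (1.0 - fst_outlier) / fst_outlier
    geno = np.empty((g.n_individuals, n_outliers))
    for p in pops:
        pf = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio)
        mask = labels == p
        geno[mask] = rng.binomial(2, pf, size=(mask.sum(), n_outliers))
    ids = [f"OUT{j+1:04d}" for j in range(n_outliers)]
    new = GenotypeMatrix(
        np.hstack([g.genotypes, geno]),
        list(g.individuals),
        list(g.loci) + ids,
        list(g.tags) + [f"tagout{j+1:04d}" for j in range(n_outliers)],
    )
    return new, ids


def degrade_genotypes(
    g: GenotypeMatrix,
    locus_dropout: float = 0.0,
    ind_dropout: float = 0.0,
    n_low_maf: int = 0,
    n_monomorphic: int = 0,
    n_multi_per_tag: int = 0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Plant QC failures into a clean matrix; return the planted removal lists.

    * ``locus_dropout``: proportion of loci pushed below a 95% call rate
      (10% of their calls set missing);
    * ``ind_dropout``: proportion of individuals pushed below an 85% call
      rate (20% of their calls set missing);
    * ``n_low_maf``: appended polymorphic loci with a single minor-allele
      copy (MAF < 0.05 for n > 10);
    * ``n_monomorphic``: appended invariant loci;
    * ``n_multi_per_tag``: appended extra SNPs sharing an existing tag ID,
      each with one more missing call than the tag's original SNP.
    """
    if not (0 <= locus_dropout <= 1 and 0 <= ind_dropout <= 1):
        raise ValueError("dropout proportions must lie in [0, 1]")
    if n_multi_per_tag > g.n_loci:
        raise ValueError("cannot plant more tag duplicates than existing loci")
    rng = np.random.default_rng(seed)
    geno = g.genotypes.copy()
    n, L = geno.shape
    planted: dict[str, list[str]] = {
        "low_call_loci": [], "low_call_individuals": [],
        "low_maf": [], "monomorphic": [], "multi_per_tag": [],
    }

    n_drop_loci = int(round(locus_dropout * L))
    if n_drop_loci:
        cols = rng.choice(L, size=n_drop_loci, replace=False)
        n_miss = max(int(np.ceil(0.10 * n)), int(np.floor(0.05 * n)) + 1)
        for j in cols:
            rows = rng.choice(n, size=n_miss, replace=False)
            geno[rows, j] = np.nan
        planted["low_call_loci"] = [g.loci[j] for j in cols]

    n_drop_ind = int(round(ind_dropout * n))
    if n_drop_ind:
        rows = rng.choice(n, size=n_drop_ind, replace=False)
        n_miss = max(int(np.ceil(0.20 * L)), int(np.floor(0.15 * L)) + 1)
        for i in rows:
            cols = rng.choice(L, size=n_miss, replace=False)
            geno[i, cols] = np.nan
        planted["low_call_individuals"] = [g.individuals[i] for i in rows]

    extra_cols, extra_loci, extra_tags = [], [], []
    for j in range(n_low_maf):
        col = np.zeros(n)
        col[rng.integers(n)] = 1.0          # one heterozygote: MAF = 1/(2n)
        extra_cols.append(col)
        extra_loci.append(f"LOWMAF{j+1:03d}")
        extra_tags.append(f"taglowmaf{j+1:03d}")
        planted["low_maf"].append(extra_loci[-1])
    for j in range(n_monomorphic):
        extra_cols.append(np.zeros(n))
        extra_loci.append(f"MONO{j+1:03d}")
        extra_tags.append(f"tagmono{j+1:03d}")
        planted["monomorphic"].append(extra_loci[-1])
    if n_multi_per_tag:
        hosts = rng.choice(L, size=n_multi_per_tag, replace=False)
        for j, h in enumerate(hosts):
            col = geno[:, h].copy()
            called = np.flatnonzero(~np.isnan(col))
            if len(called):
                col[rng.choice(called)] = np.nan   # strictly lower call rate
            extra_cols.append(col)
            extra_loci.append(f"DUP{j+1:03d}")
            extra_tags.append(g.tags[h])
            planted["multi_per_tag"].append(extra_loci[-1])

    if extra_cols:
        geno = np.hstack([geno, np.column_stack(extra_cols)])
    out = GenotypeMatrix(geno, list(g.individuals),
                         list(g.loci) + extra_loci, list(g.tags) + extra_tags)
    return out, planted


# ---------------------------------------------------------------------------
# landmarks


def _template() -> tuple[np.ndarray, tuple]:
    """Deterministic 22-point template: 12 fixed on an outer outline, 10
    sliding along an inner arc, centered and scaled to unit centroid size."""
    ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    outer = np.column_stack([2.0 * np.cos(ang), 1.0 * np.sin(ang)])
    t = np.linspace(0.08, 0.92, 10)
    arc = np.column_stack([1.6 * np.cos(np.pi * t), 0.55 * np.sin(np.pi * t)])
    pts = np.vstack([outer, arc])
    pts -= pts.mean(axis=0)
    pts /= np.sqrt((pts**2).sum())
    roles: list = ["fixed"] * 12
    for i in range(12, 22):
        pred = i - 1 if i > 12 else 0
        succ = i + 1 if i < 21 else 6
        roles.append((pred, succ))
    return pts, tuple(roles)


def _deformation_direction(template: np.ndarray) -> np.ndarray:
    """Fixed unit direction in tangent shape space (orthogonal to similarity
    transforms of the template)."""
    k = template.shape[0]
    rng = np.random.default_rng(987654321)   # fixed: part of the template definition
    v = rng.standard_normal(2 * k)
    flat = template.T.reshape(-1)            # x block then y block
    tx = np.concatenate([np.ones(k), np.zeros(k)])
    ty = np.concatenate([np.zeros(k), np.ones(k)])
    scale = flat.copy()
    rot = np.concatenate([-template[:, 1], template[:, 0]])
    basis = []
    for b in (tx, ty, scale, rot):
        for prev in basis:
            b = b - (b @ prev) * prev
        b = b / np.linalg.norm(b)
        basis.append(b)
    for b in basis:
        v -= (v @ b) * b
    return v / np.linalg.norm(v)


def simulate_landmarks(
    n_pops: int = 12,
    n_per_pop: int = 15,
    sigma2_B: float = 2.0,
    sigma2_W: float = 1.0,
    iso_noise: float | None = None,
    nuisance: bool = False,
    seed: int = 0,
) -> tuple[list[LandmarkConfiguration], SimTruth]:
    """Landmark sets with controlled between/within-population shape variance.

    Each specimen's shape is the template deformed along one fixed unit
    direction in tangent shape space by (population offset + individual
    offset) × DEFORMATION_SCALE, with offsets N(0, σ²B) and N(0, σ²W).
    ``iso_noise`` adds isotropic landmark jitter (default 1% of the template
    centroid size).  With ``nuisance=True`` each configuration is randomly
    rotated U(0, 2π), translated, and scaled log-normally; the underlying
    shapes are identical for the same seed with nuisance on or off.
    """
    if sigma2_B < 0 or sigma2_W < 0:
        raise ValueError("variances must be non-negative")
    tpl, roles = _template()
    direction = _deformation_direction(tpl).reshape(2, -1).T   # (k, 2)
    cs_tpl = centroid_size(tpl)
    if iso_noise is None:
        iso_noise = 0.01 * cs_tpl

    rng_shape = np.random.default_rng([seed, 1])
    rng_nuis = np.random.default_rng([seed, 2])
    pop_off = rng_shape.normal(0.0, np.sqrt(sigma2_B), size=n_pops)
    configs = []
    for i in range(n_pops):
        pop = f"P{i+1:02d}"
        for j in range(n_per_pop):
            off = pop_off[i] + rng_shape.normal(0.0, np.sqrt(sigma2_W))
            shape = tpl + DEFORMATION_SCALE * off * direction
            shape = shape + rng_shape.normal(0.0, iso_noise, size=shape.shape)
            if nuisance:
                th = rng_nuis.uniform(0, 2 * np.pi)
                R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
                s = rng_nuis.lognormal(np.log(100.0), 0.3)   # "pixel"-scale sizes
                tr = rng_nuis.uniform(-50, 50, size=2)
                shape = s * shape @ R.T + tr
            else:
                # draw the same nuisance variates so streams stay in step
                rng_nuis.uniform(0, 2 * np.pi)
                rng_nuis.lognormal(np.log(100.0), 0.3)
                rng_nuis.uniform(-50, 50, size=2)
            configs.append(LandmarkConfiguration(
                specimen_id=f"{pop}_s{j+1:02d}", coords=shape, roles=roles,
                population=pop))
    truth = SimTruth(sigma2_B_true=sigma2_B, sigma2_W_true=sigma2_W, seed=seed)
    return configs, truth


# ---------------------------------------------------------------------------
# haplotypes


def simulate_haplotypes(
    n_seqs: int = 60,
    length_bp: int = 612,
    n_segsites: int = 42,
    dup_profile: list[int] | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], SimTruth]:
    """Aligned haplotype sequences with an exact planted number of segregating sites.

    ``dup_profile`` gives the copy number of each unique haplotype (summing
    to ``n_seqs``); the default mimics a star-like sample: one common
    haplotype plus a tail of rarer ones (15 uniques for 60 sequences).
    Segregating sites are private to one haplotype each, so uniqueness
    requires ``n_segsites >= len(dup_profile) - 1``.
    """
    if dup_profile is None:
        n_uniq = min(15, n_seqs)
        dup_profile = [1] * n_uniq
        dup_profile[0] += n_seqs - n_uniq
    if sum(dup_profile) != n_seqs or any(d < 1 for d in dup_profile):
        raise ValueError("dup_profile must be positive counts summing to n_seqs")
    h = len(dup_profile)
    if n_segsites > length_bp:
        raise ValueError("cannot plant more segregating sites than positions")
    if h > 1 and n_segsites < h - 1:
        raise ValueError("need at least len(dup_profile)-1 segregating sites for uniqueness")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=length_bp)
    seqs = np.tile(ref, (h, 1))
    if n_segsites and h > 1:
        pos = rng.choice(length_bp, size=n_segsites, replace=False)
        carriers = np.arange(1, h)[np.arange(n_segsites) % (h - 1)]
        for site, hap in zip(pos, carriers):
            alt = (ref[site] + rng.integers(1, 4)) % 4
            seqs[hap, site] = alt

    out: dict[str, str] = {}
    idx = 1
    for hi, copies in enumerate(dup_profile):
        s = "".join(bases[seqs[hi]])
        for _ in range(copies):
            out[f"seq{idx:03d}"] = s
            idx += 1
    truth = SimTruth(n_segsites_true=int(n_segsites if h > 1 else 0), seed=seed)
    return out, truth
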