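"""Landmark-based geometric morphometrics.

Generalized Procrustes analysis (translation, unit-centroid-size scaling,
proper rotation) with optional bending-energy sliding of semilandmarks,
relative warps (PCA of aligned coordinates), thin-plate-spline deformation
grids, repeatability (two-way mixed ICC), and the size-controlled group
tests (MANCOVA with Pillai's trace; Tukey–Kramer post hocs with a compact
letter display).

Shapes are k × 2 arrays.  Semilandmark roles are per-landmark: ``"fixed"``
or a ``(predecessor, successor)`` index pair giving the neighbours that
define the chord tangent the point may slide along.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.manova import MANOVA
from statsmodels.stats.libqsturng import psturng

__all__ = [
    "LandmarkConfiguration",
    "AlignedShapeSet",
    "RelativeWarpScores",
    "centroid_size",
    "gpa_align",
    "relative_warps",
    "tps_grid",
    "icc_repeatability",
    "mancova_shape",
    "tukey_hsd",
]

Role = str | tuple[int, int]


@dataclass
class LandmarkConfiguration:
    """One specimen's 2-D landmarks with fixed/sliding roles."""

    specimen_id: str
    coords: np.ndarray                    # (k, 2)
    roles: tuple[Role, ...] | None = None  # None -> all fixed
    population: str = ""
    region: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (k, 2)")
        k = self.coords.shape[0]
        if self.roles is not None:
            if len(self.roles) != k:
                raise ValueError("one role per landmark required")
            for i, r in enumerate(self.roles):
                if r == "fixed":
                    continue
                pred, succ = r
                if not (0 <= pred < k and 0 <= succ < k) or pred == i or succ == i:
                    raise ValueError(f"invalid slider neighbours for landmark {i}: {r}")
        d = self.coords[:, None, :] - self.coords[None, :, :]
        dist = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        if (dist < 1e-12).any():
            raise ValueError(f"coincident landmarks in specimen {self.specimen_id!r}")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def sliding_indices(self) -> list[int]:
        if self.roles is None:
            return []
        return [i for i, r in enumerate(self.roles) if r != "fixed"]


@dataclass
class AlignedShapeSet:
    """Procrustes-aligned shapes with the consensus and original centroid sizes."""

    consensus: np.ndarray                 # (k, 2), centroid at origin, CS = 1
    aligned: np.ndarray                   # (n, k, 2)
    centroid_size: np.ndarray             # (n,), in input units
    specimen_ids: list[str]

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]


@dataclass
class RelativeWarpScores:
    scores: pd.DataFrame                  # specimens × axes
    pct_variance: np.ndarray
    loadings: np.ndarray                  # axes × 2k
    consensus: np.ndarray


def centroid_size(coords: np.ndarray | LandmarkConfiguration) -> float:
    """CS = sqrt of the summed squared landmark distances from their centroid."""
    x = coords.coords if isinstance(coords, LandmarkConfiguration) else np.asarray(coords, float)
    if x.shape[0] < 3:
        raise ValueError("centroid size needs at least 3 landmarks")
    c = x - x.mean(axis=0)
    cs = float(np.sqrt((c**2).sum()))
    if cs == 0:
        raise ValueError("degenerate configuration: all landmarks coincident")
    return cs


def _rotate_onto(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation of centered x onto centered target (SVD)."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return x @ r


def _bending_energy_matrix(ref: np.ndarray) -> np.ndarray:
    """Upper-left k×k block of L⁻¹ for the TPS of the reference shape."""
    k = ref.shape[0]
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(d2 > 0, d2 * np.log(d2), 0.0)
    Q = np.hstack([np.ones((k, 1)), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    Linv = np.linalg.inv(L)
    return Linv[:k, :k]


def _slide_one(spec: np.ndarray, consensus: np.ndarray, be: np.ndarray,
               sliders: list[int], tangents: np.ndarray) -> np.ndarray:
    """Slide semilandmarks along tangents to minimize bending energy vs consensus.

    Solves d = −(TᵀET)⁻¹TᵀE v for the per-slider displacement magnitudes,
    where E = I₂ ⊗ BE and v is the deviation from the consensus.
    """
    k = spec.shape[0]
    v = (spec - consensus).T.reshape(-1)      # x block then y block
    T = np.zeros((2 * k, len(sliders)))
    for j, i in enumerate(sliders):
        T[i, j] = tangents[j, 0]
        T[k + i, j] = tangents[j, 1]
    E = np.kron(np.eye(2), be)
    A = T.T @ E @ T
    rhs = -(T.T @ E @ v)
    d = np.linalg.lstsq(A, rhs, rcond=None)[0]
    out = spec.copy()
    for j, i in enumerate(sliders):
        out[i] += d[j] * tangents[j]
    return out


def _chord_tangents(spec: np.ndarray, roles: tuple[Role, ...], sliders: list[int]) -> np.ndarray:
    t = np.zeros((len(sliders), 2))
    for j, i in enumerate(sliders):
        pred, succ = roles[i]
        chord = spec[succ] - spec[pred]
        norm = np.linalg.norm(chord)
        t[j] = chord / norm if norm > 0 else (1.0, 0.0)
    return t


def gpa_align(
    configs: list[LandmarkConfiguration],
    slide: bool = False,
    max_iter: int = 100,
    tol: float = 1e-10,
    slide_rounds: int = 5,
) -> AlignedShapeSet:
    """Generalized Procrustes superimposition of a set of configurations.

    Translate to a common centroid, scale each to unit centroid size, and
    iteratively rotate (proper rotations only) to the running consensus
    until the consensus moves less than ``tol``.  With ``slide=True`` the
    semilandmarks additionally slide along chord tangents minimizing the
    thin-plate-spline bending energy against the consensus, alternating
    with re-superimposition for ``slide_rounds`` rounds.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least two configurations")
    k = configs[0].k
    roles = configs[0].roles
    for c in configs[1:]:
        if c.k != k or c.roles != roles:
            raise ValueError("all configurations must share landmark count and roles")

    cs = np.array([centroid_size(c) for c in configs])
    X = np.stack([c.coords - c.coords.mean(axis=0) for c in configs]) / cs[:, None, None]

    def superimpose(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cons = X[0].copy()
        for it in range(max_iter):
            X = np.stack([_rotate_onto(x, cons) for x in X])
            new = X.mean(axis=0)
            new -= new.mean(axis=0)
            new /= np.sqrt((new**2).sum())
            if np.sqrt(((new - cons) ** 2).sum()) < tol:
                cons = new
                break
            cons = new
        else:
            warnings.warn("GPA did not converge; returning last iterate")
        return X, cons

    def canonicalize(X: np.ndarray, cons: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # orientation of the consensus is arbitrary after GPA; rotate the whole
        # set so the consensus principal axes lie along x/y (proper rotation,
        # sign fixed by landmark 0) to make output orientation-canonical
        cov = cons.T @ cons
        evals, evecs = np.linalg.eigh(cov)
        R = evecs[:, ::-1]                       # major axis first
        if np.linalg.det(R) < 0:
            R[:, 1] *= -1
        cons_r = cons @ R
        if cons_r[0, 0] < 0:
            R = R @ np.diag([-1.0, -1.0])        # rotate by pi, still proper
            cons_r = cons @ R
        return X @ R, cons_r

    X, cons = superimpose(X)

    if slide:
        sliders = configs[0].sliding_indices()
        if not sliders:
            raise ValueError("slide=True but no sliding landmarks defined")
        for _ in range(slide_rounds):
            be = _bending_energy_matrix(cons)
            newX = []
            for x in X:
                t = _chord_tangents(x, roles, sliders)
                newX.append(_slide_one(x, cons, be, sliders, t))
            X = np.stack(newX)
            # re-superimpose after sliding
            X = np.stack([x - x.mean(axis=0) for x in X])
            X /= np.sqrt((X**2).sum(axis=(1, 2)))[:, None, None]
            X, cons = superimpose(X)

    X, cons = canonicalize(X, cons)
    return AlignedShapeSet(consensus=cons, aligned=X, centroid_size=cs,
                           specimen_ids=[c.specimen_id for c in configs])


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two shapes (after centering/scaling/rotation)."""
    a = np.asarray(a, float) - np.asarray(a, float).mean(axis=0)
    b = np.asarray(b, float) - np.asarray(b, float).mean(axis=0)
    a /= np.sqrt((a**2).sum())
    b /= np.sqrt((b**2).sum())
    a = _rotate_onto(a, b)
    return float(np.sqrt(((a - b) ** 2).sum()))


def relative_warps(a: AlignedShapeSet, alpha: float = 0.0) -> RelativeWarpScores:
    """Relative warps: PCA of the aligned-coordinate deviations from consensus.

    With α = 0 (the default here) this is an ordinary principal component
    analysis of the Procrustes residuals including the uniform component.
    Axis signs are fixed so each axis's largest-magnitude loading is
    positive.  Axes with numerically zero variance are dropped; the
    percentages sum to 100 over the returned axes.
    """
    if a.n < 3:
        raise ValueError("relative warps need at least 3 specimens")
    if alpha != 0.0:
        raise NotImplementedError("only alpha = 0 (uniform-inclusive PCA) is supported")
    X = a.aligned.reshape(a.n, -1) - a.consensus.reshape(-1)
    u, s, vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    var = s**2
    keep = var > var[0] * 1e-12 if var[0] > 0 else np.zeros(len(var), bool)
    u, s, vt, var = u[:, keep], s[keep], vt[keep], var[keep]
    # sign convention: largest-|loading| entry positive per axis
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u * s
    pct = 100.0 * var / var.sum()
    cols = [f"RW{i+1}" for i in range(scores.shape[1])]
    return RelativeWarpScores(
        scores=pd.DataFrame(scores, index=a.specimen_ids, columns=cols),
        pct_variance=pct, loadings=vt, consensus=a.consensus,
    )


# ---------------------------------------------------------------------------
# thin-plate splines


def _tps_solve(reference: np.ndarray, target: np.ndarray):
    k = reference.shape[0]
    d2 = ((reference[:, None, :] - reference[None, :, :]) ** 2).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(d2 > 0, d2 * np.log(d2), 0.0)
    Q = np.hstack([np.ones((k, 1)), reference])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    if np.linalg.matrix_rank(L) < k + 3:
        raise ValueError("singular TPS system (collinear landmarks?)")
    sol = np.linalg.solve(L, np.vstack([target, np.zeros((3, 2))]))
    w, aff = sol[:k], sol[k:]
    bending = float(np.trace(w.T @ K @ w))
    return w, aff, K


def tps_grid(reference: np.ndarray, target: np.ndarray, grid: int = 20) -> dict:
    """Thin-plate-spline map from reference to target, evaluated on a grid.

    Returns the source grid, its deformed image, the mapped landmark
    positions (exact interpolation), and the bending energy (zero for a
    purely affine deformation: the affine term is in the TPS null space).
    """
    reference = np.asarray(reference, float)
    target = np.asarray(target, float)
    if reference.shape != target.shape or reference.shape[1] != 2:
        raise ValueError("reference and target must be matching (k, 2) shapes")
    w, aff, _ = _tps_solve(reference, target)

    def transform(pts: np.ndarray) -> np.ndarray:
        d2 = ((pts[:, None, :] - reference[None, :, :]) ** 2).sum(-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            U = np.where(d2 > 0, d2 * np.log(d2), 0.0)
        return np.hstack([np.ones((len(pts), 1)), pts]) @ aff + U @ w

    lo = reference.min(axis=0)
    hi = reference.max(axis=0)
    pad = 0.05 * (hi - lo + 1e-12)
    gx, gy = np.meshgrid(np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid),
                         np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid))
    src = np.column_stack([gx.ravel(), gy.ravel()])
    return {
        "grid_source": src,
        "grid_mapped": transform(src),
        "landmarks_mapped": transform(reference),
        "bending_energy": float(np.trace(w.T @ _tps_solve(reference, target)[2] @ w)),
        "transform": transform,
    }


# ---------------------------------------------------------------------------
# repeatability and group tests


def icc_repeatability(replicates: np.ndarray) -> float:
    """ICC(3,1): two-way mixed-effects, consistency, single measurement.

    ``replicates``: specimens × replicate sessions (balanced).  Computed from
    the two-way ANOVA mean squares as (MS_specimen − MS_error) /
    (MS_specimen + (k−1)·MS_error).
    """
    x = np.asarray(replicates, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 specimens with >= 2 replicates each, balanced")
    if np.isnan(x).any():
        raise ValueError("balanced design required: no missing replicates")
    n, k = x.shape
    grand = x.mean()
    ms_rows = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand
    ms_err = (resid**2).sum() / ((n - 1) * (k - 1))
    if ms_rows + (k - 1) * ms_err == 0:
        return 1.0
    return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))


def mancova_shape(scores: pd.DataFrame | np.ndarray, cs: np.ndarray,
                  group: np.ndarray) -> dict:
    """MANCOVA of shape scores on centroid size + group (Pillai's trace).

    Returns the Pillai statistic, its standard F approximation, the degrees
    of freedom and p-value for the group term.  Sums of squares are the
    default partial (type III-style) tests of the additive model.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]         # single response: Pillai reduces to ANCOVA
    if S.ndim != 2 or S.shape[1] < 1:
        raise ValueError("need at least 1 response axis")
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    n, m = S.shape
    if n <= m + len(levels):
        raise ValueError("too few specimens for the model")
    df = pd.DataFrame(S, columns=[f"y{i}" for i in range(m)])
    df["cs"] = np.asarray(cs, dtype=float)
    df["grp"] = group
    if m == 1:
        # Pillai with one response is the ordinary ANCOVA partial F
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        ols = smf.ols("y0 ~ cs + C(grp)", data=df).fit()
        tab = anova_lm(ols, typ=3)
        ssh = float(tab.loc["C(grp)", "sum_sq"])
        sse = float(tab.loc["Residual", "sum_sq"])
        return {
            "statistic": ssh / (ssh + sse),
            "F": float(tab.loc["C(grp)", "F"]),
            "df_num": float(tab.loc["C(grp)", "df"]),
            "df_den": float(tab.loc["Residual", "df"]),
            "p": float(tab.loc["C(grp)", "PR(>F)"]),
        }
    lhs = " + ".join(df.columns[:m])
    mv = MANOVA.from_formula(f"{lhs} ~ cs + C(grp)", data=df)
    tab = mv.mv_test().results["C(grp)"]["stat"]
    row = tab.loc["Pillai's trace"]
    return {
        "statistic": float(row["Value"]),
        "F": float(row["F Value"]),
        "df_num": float(row["Num DF"]),
        "df_den": float(row["Den DF"]),
        "p": float(row["Pr > F"]),
    }


def tukey_hsd(values: np.ndarray, group: np.ndarray) -> dict:
    """Tukey–Kramer all-pair comparisons with a compact letter display.

    Studentized-range p-values on the pooled within-group variance; letter
    groups by the standard insert-and-absorb algorithm (groups sharing a
    letter are not significantly different at alpha = 0.05).
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    levels = list(pd.unique(group))
    sizes = {g: int((group == g).sum()) for g in levels}
    if min(sizes.values()) < 2:
        raise ValueError("every group needs at least 2 observations")
    means = {g: values[group == g].mean() for g in levels}
    df_err = len(values) - len(levels)
    sse = sum(((values[group == g] - means[g]) ** 2).sum() for g in levels)
    mse = sse / df_err
    k = len(levels)
    rows = []
    for g1, g2 in combinations(levels, 2):
        se = np.sqrt(mse / 2 * (1 / sizes[g1] + 1 / sizes[g2]))
        q = abs(means[g1] - means[g2]) / se
        p = float(np.atleast_1d(psturng(q, k, df_err))[0])
        rows.append({"group1": g1, "group2": g2,
                     "diff": means[g1] - means[g2], "q": q, "p_adj": p})
    tab = pd.DataFrame(rows)
    letters = _letter_display(levels, means, tab, alpha=0.05)
    return {"pairwise": tab, "letters": letters, "mse": mse, "df": df_err}


def _letter_display(levels, means, tab: pd.DataFrame, alpha: float) -> dict[str, str]:
    """Insert-and-absorb compact letter display from pairwise adjusted p-values."""
    order = sorted(levels, key=lambda g: means[g])
    sig = {}
    for _, r in tab.iterrows():
        sig[frozenset((r["group1"], r["group2"]))] = r["p_adj"] < alpha

    cols: list[set] = [set(order)]
    for pair, is_sig in sig.items():
        if not is_sig:
            continue
        g1, g2 = tuple(pair)
        new_cols = []
        for col in cols:
            if g1 in col and g2 in col:
                new_cols.append(col - {g1})
                new_cols.append(col - {g2})
            else:
                new_cols.append(col)
        # absorb: drop columns that are subsets of others
        cols = []
        for c in new_cols:
            if not any(c < o for o in new_cols if o is not c) and c not in cols:
                cols.append(c)
    cols.sort(key=lambda c: min(order.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in levels}
    for letter, col in zip(alphabet, cols):
        for g in col:
            out[g] += letter
    return {g: "".join(sorted(out[g])) for g in levels}
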