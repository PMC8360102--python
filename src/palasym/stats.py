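"""Group-level statistics: Procrustes ANOVA, PERMANOVA, dispersion tests,
rank tests and post-hoc procedures.

The shape-specific machinery (Procrustes ANOVA with residual-randomisation
permutation, PERMANOVA on a Procrustes distance matrix, multivariate
dispersion homogeneity via principal coordinates) is implemented here;
classical univariate procedures (one-way ANOVA, Tukey HSD, Kruskal-Wallis,
Mann-Whitney, Spearman) delegate to scipy where scipy provides them.
Every permutation procedure takes an explicit seed and reports
p = (count extreme + 1) / (n_perm + 1), bounded below by 1/(n_perm + 1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "procrustes_anova_symmetry",
    "oneway_anova",
    "tukey_hsd",
    "permanova",
    "dispersion_homogeneity",
    "kruskal_wallis",
    "dunn_posthoc",
    "spearman_matrix",
    "mann_whitney",
    "bonferroni",
    "PermanovaResult",
    "DispersionResult",
]


# ---------------------------------------------------------------------------
# Procrustes ANOVA for object symmetry (one group)
# ---------------------------------------------------------------------------


def _symmetry_ss(Y_orig: np.ndarray, Y_refl: np.ndarray) -> tuple[float, float, float, float]:
    """Sums of squares of the individuals x reflection decomposition.

    Observations are the flattened shape coordinates.  With means m_i per
    individual and mean asymmetry a-bar = mean(O - RR):
      SS_ind   = 2 * sum_i ||m_i - grand||^2
      SS_refl  = n * ||a-bar||^2 / 2
      SS_inter = sum_i ||a_i - a-bar||^2 / 2
    """
    n = Y_orig.shape[0]
    M = (Y_orig + Y_refl) / 2.0
    A = Y_orig - Y_refl
    grand = M.mean(axis=0)
    ss_ind = 2.0 * float(((M - grand) ** 2).sum())
    abar = A.mean(axis=0)
    ss_refl = n * float((abar**2).sum()) / 2.0
    ss_inter = float(((A - abar) ** 2).sum()) / 2.0
    ss_total = ss_ind + ss_refl + ss_inter
    return ss_ind, ss_refl, ss_inter, ss_total


def procrustes_anova_symmetry(
    originals: np.ndarray,
    reflected: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Procrustes ANOVA of shape variation within one group.

    Decomposes deviations from the group mean configuration into individual
    variability (df n-1), reflection / directional asymmetry (df 1) and the
    individual x reflection interaction / fluctuating asymmetry (df n-1,
    the error term).  F ratios use the interaction mean square; p values
    come from residual randomisation under the reduced model: the reflection
    effect permutes individual-centred residuals (random O/RR sign flips per
    individual), the individual effect permutes reflection-centred residuals
    across all 2n observations.

    Parameters
    ----------
    originals, reflected
        (n, n_points, 3) superimposed coordinates, row i of ``reflected``
        being the reflected/relabelled partner of row i of ``originals``.
    """
    O = np.asarray(originals, dtype=float)
    R = np.asarray(reflected, dtype=float)
    if O.shape != R.shape:
        raise ValueError("originals and reflected must have the same shape")
    n = O.shape[0]
    if n < 2:
        raise ValueError("need >= 2 individuals (interaction is the error term)")
    Yo = O.reshape(n, -1)
    Yr = R.reshape(n, -1)
    ss_ind, ss_refl, ss_inter, ss_total = _symmetry_ss(Yo, Yr)
    df_ind, df_refl, df_inter = n - 1, 1, n - 1
    ms_ind = ss_ind / df_ind
    ms_refl = ss_refl / df_refl
    ms_inter = ss_inter / df_inter
    f_ind = ms_ind / ms_inter if ms_inter > 0 else np.inf
    f_refl = ms_refl / ms_inter if ms_inter > 0 else np.inf

    rng = np.random.default_rng(seed)
    # Reflection effect: sign-flip the per-individual asymmetry vectors.
    A = Yo - Yr
    abar_obs = A.mean(axis=0)
    count_refl = 0
    for _ in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        Ap = A * signs[:, None]
        abar = Ap.mean(axis=0)
        ss_r = n * float((abar**2).sum()) / 2.0
        ss_i = float(((Ap - abar) ** 2).sum()) / 2.0
        f_star = (ss_r / df_refl) / (ss_i / df_inter) if ss_i > 0 else np.inf
        if f_star >= f_refl - 1e-12:
            count_refl += 1
    p_refl = (count_refl + 1) / (n_perm + 1)

    # Individual effect: RRPP under the reflection-only reduced model.
    Y = np.vstack([Yo, Yr])
    mean_o = Yo.mean(axis=0)
    mean_r = Yr.mean(axis=0)
    fitted = np.vstack([np.tile(mean_o, (n, 1)), np.tile(mean_r, (n, 1))])
    resid = Y - fitted
    count_ind = 0
    for _ in range(n_perm):
        perm = rng.permutation(2 * n)
        Yp = fitted + resid[perm]
        ssi, ssr, ssx, _ = _symmetry_ss(Yp[:n], Yp[n:])
        f_star = (ssi / df_ind) / (ssx / df_inter) if ssx > 0 else np.inf
        if f_star >= f_ind - 1e-12:
            count_ind += 1
    p_ind = (count_ind + 1) / (n_perm + 1)

    rows = [
        ("Ind", df_ind, ss_ind, ms_ind, ss_ind / ss_total if ss_total else 0.0, f_ind, p_ind),
        ("Reflections", df_refl, ss_refl, ms_refl, ss_refl / ss_total if ss_total else 0.0, f_refl, p_refl),
        ("Ind X Reflections", df_inter, ss_inter, ms_inter, ss_inter / ss_total if ss_total else 0.0, np.nan, np.nan),
    ]
    return pd.DataFrame(rows, columns=["effect", "df", "SS", "MS", "Rsq", "F", "p"])


# ---------------------------------------------------------------------------
# classical one-way ANOVA and Tukey HSD
# ---------------------------------------------------------------------------


def _group_split(values, labels) -> tuple[list[str], list[np.ndarray]]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels differ in length")
    uniq = sorted(map(str, set(labels.tolist())))
    groups = [values[labels.astype(str) == u] for u in uniq]
    for u, g in zip(uniq, groups):
        if len(g) == 0:
            raise ValueError(f"label {u!r} has no observations")
    return uniq, groups


def oneway_anova(values, labels) -> pd.DataFrame:
    """Classical one-way ANOVA table with a parametric F p-value."""
    uniq, groups = _group_split(values, labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("need >= 2 groups")
    values = np.asarray(values, dtype=float)
    N = len(values)
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_total = ss_between + ss_within
    df_b, df_w = k - 1, N - k
    if df_w < 1:
        raise ValueError("no residual degrees of freedom")
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    f = ms_b / ms_w if ms_w > 0 else (0.0 if ms_b == 0 else np.inf)
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    rows = [
        ("group", df_b, ss_between, ms_b, ss_between / ss_total if ss_total else 0.0, f, p),
        ("Residuals", df_w, ss_within, ms_w, ss_within / ss_total if ss_total else 0.0, np.nan, np.nan),
    ]
    return pd.DataFrame(rows, columns=["effect", "df", "SS", "MS", "Rsq", "F", "p"])


def tukey_hsd(values, labels, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-Kramer honestly-significant-difference intervals for all pairs.

    Rows are labelled ``b-a`` (difference mean(b) - mean(a)) for groups in
    sorted label order, matching the conventional post-hoc table layout.
    """
    uniq, groups = _group_split(values, labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    res = sps.tukey_hsd(*groups)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    rows = []
    for j, i in itertools.combinations(range(len(uniq)), 2):
        # difference group[i-th later] - group[j-th earlier]
        rows.append(
            {
                "pair": f"{uniq[i]}-{uniq[j]}",
                "diff": float(groups[i].mean() - groups[j].mean()),
                "lwr": float(ci.low[i, j]),
                "upr": float(ci.high[i, j]),
                "p_adj": float(res.pvalue[i, j]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distance-matrix methods
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    f: float
    rsq: float
    p: float
    n_perm: int


def _check_distance_matrix(dist: np.ndarray) -> np.ndarray:
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    return D


def _permanova_f(D2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> tuple[float, float]:
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for u in uniq:
        idx = np.where(labels == u)[0]
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    k = len(uniq)
    f = (ss_among / (k - 1)) / (ss_within / (n - k)) if ss_within > 0 else np.inf
    rsq = ss_among / ss_total if ss_total > 0 else 0.0
    return f, rsq


def permanova(
    dist: np.ndarray, labels, n_perm: int = 999, seed: int | None = None
) -> PermanovaResult:
    """Permutational multivariate ANOVA (pseudo-F) on a distance matrix.

    The pseudo-F comes from the Gower-centred decomposition of squared
    distances into among- and within-group sums of squares; the p value
    from random label permutations.  On univariate Euclidean distances the
    pseudo-F equals the classical one-way ANOVA F exactly.
    """
    D = _check_distance_matrix(dist)
    labels = np.asarray(labels)
    if len(labels) != D.shape[0]:
        raise ValueError("labels length does not match the distance matrix")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    D2 = D**2
    f_obs, rsq = _permanova_f(D2, labels, uniq)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(labels))
        f_star, _ = _permanova_f(D2, labels[perm], uniq)
        if f_star >= f_obs - 1e-12:
            count += 1
    return PermanovaResult(
        f=float(f_obs), rsq=float(rsq), p=(count + 1) / (n_perm + 1), n_perm=n_perm
    )


@dataclass
class DispersionResult:
    f: float
    p: float
    group_dispersion: dict[str, float]
    n_perm: int


def _pcoa_embedding(D: np.ndarray, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding split into real and imaginary parts.

    Returns (pos, neg): coordinates on axes with positive eigenvalues and
    coordinates on axes with negative eigenvalues (the 'imaginary' axes of a
    non-Euclidean matrix); squared distances in the embedding are
    ||dz_pos||^2 - ||dz_neg||^2.
    """
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2.0
    w, V = np.linalg.eigh(G)
    scale = np.abs(w) > tol * max(abs(w).max(), 1.0)
    pos_axes = V[:, (w > 0) & scale] * np.sqrt(w[(w > 0) & scale])
    neg_axes = V[:, (w < 0) & scale] * np.sqrt(-w[(w < 0) & scale])
    return pos_axes, neg_axes


def _dispersion_distances(pos, neg, labels, uniq) -> np.ndarray:
    d2 = np.zeros(pos.shape[0])
    for u in uniq:
        idx = labels == u
        cp = pos[idx].mean(axis=0)
        d2[idx] += ((pos[idx] - cp) ** 2).sum(axis=1)
        if neg.shape[1]:
            cn = neg[idx].mean(axis=0)
            d2[idx] -= ((neg[idx] - cn) ** 2).sum(axis=1)
    return np.sqrt(np.clip(d2, 0.0, None))


def _anova_f(values: np.ndarray, labels: np.ndarray, uniq) -> float:
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for u in uniq:
        g = values[labels == u]
        ssb += len(g) * (g.mean() - grand) ** 2
        ssw += ((g - g.mean()) ** 2).sum()
    k = len(uniq)
    n = len(values)
    if ssw <= 0:
        return 0.0 if ssb <= 0 else np.inf
    return (ssb / (k - 1)) / (ssw / (n - k))


def dispersion_homogeneity(
    dist: np.ndarray, labels, n_perm: int = 999, seed: int | None = None
) -> DispersionResult:
    """Homogeneity of multivariate dispersion (distance to group centroid).

    Embeds the distance matrix by principal coordinates (negative
    eigenvalues handled as imaginary axes), measures each point's distance
    to its group centroid in the embedding, and tests equality of mean
    dispersion with a one-way F whose null distribution comes from label
    permutations (distances recomputed to the permuted-group centroids).
    """
    D = _check_distance_matrix(dist)
    labels = np.asarray(labels)
    if len(labels) != D.shape[0]:
        raise ValueError("labels length does not match the distance matrix")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    pos, neg = _pcoa_embedding(D)
    d_obs = _dispersion_distances(pos, neg, labels, uniq)
    f_obs = _anova_f(d_obs, labels, uniq)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        lp = labels[rng.permutation(len(labels))]
        d_star = _dispersion_distances(pos, neg, lp, uniq)
        if _anova_f(d_star, lp, uniq) >= f_obs - 1e-12:
            count += 1
    disp = {
        str(u): float(d_obs[labels == u].mean()) for u in uniq
    }
    return DispersionResult(
        f=float(f_obs), p=(count + 1) / (n_perm + 1), group_dispersion=disp, n_perm=n_perm
    )


# ---------------------------------------------------------------------------
# rank-based tests
# ---------------------------------------------------------------------------


def kruskal_wallis(values, labels) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = k - 1)."""
    uniq, groups = _group_split(values, labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    df = len(uniq) - 1
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        warnings.warn("all values tied; H = 0", stacklevel=2)
        return 0.0, df, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), df, float(p)


def dunn_posthoc(values, labels, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise post-hoc test after Kruskal-Wallis.

    Z statistics are differences of mean midranks scaled by the
    tie-corrected variance; p values are two-sided normal, adjusted by
    Bonferroni over the number of pairs.
    """
    uniq, _ = _group_split(values, labels)
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(str)
    N = len(values)
    ranks = sps.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (N - 1))) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term
    mean_rank = {u: ranks[labels == u].mean() for u in uniq}
    n_of = {u: int((labels == u).sum()) for u in uniq}
    pairs = list(itertools.combinations(uniq, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / n_of[a] + 1.0 / n_of[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        if adjust == "bonferroni":
            p_adj = min(1.0, p * m)
        elif adjust in (None, "none"):
            p_adj = p
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        rows.append({"pair": f"{a}-{b}", "Z": float(z), "p_unadj": float(p), "p_adj": float(p_adj)})
    return pd.DataFrame(rows)


def spearman_matrix(da_table: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Spearman rank correlation between the per-landmark profiles of each
    pair of groups.

    ``da_table``: rows = groups, columns = landmarks (wide format), or a
    DataFrame indexed by group.  Constant rows yield NaN entries (flagged by
    a warning).
    """
    if isinstance(da_table, pd.DataFrame):
        mat = da_table.to_numpy(dtype=float)
        names = [str(i) for i in da_table.index]
    else:
        mat = np.asarray(da_table, dtype=float)
        names = [f"group_{i + 1}" for i in range(mat.shape[0])]
    if np.isnan(mat).any():
        raise ValueError("missing values in the DA table")
    k = mat.shape[0]
    out = np.eye(k)
    for i, j in itertools.combinations(range(k), 2):
        if np.ptp(mat[i]) == 0 or np.ptp(mat[j]) == 0:
            warnings.warn(f"constant profile for {names[i]} or {names[j]}", stacklevel=2)
            rho = np.nan
        else:
            rho = sps.spearmanr(mat[i], mat[j]).statistic
        out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=names, columns=names)


def mann_whitney(
    x, y, exact_threshold: int = 8
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution (full enumeration) when both samples
    have at most ``exact_threshold`` observations and no ties across the
    pooled sample; otherwise the normal approximation with tie and
    continuity corrections.  Returns (U, p, method).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= exact_threshold and len(y) <= exact_threshold and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue), "asymptotic"


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, p * m), m defaulting to the
    family size."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    return np.minimum(1.0, p * m)
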