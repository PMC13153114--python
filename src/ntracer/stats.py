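"""Inferential layer: normality-gated factorial tests, correlations, and
permutation statistics on community distance matrices.

The workflow mirrors a standard bloom-ecology analysis: rates are compared
across plankton group x N form with a two-way ANOVA (rank-transformed,
Scheirer-Ray-Hare style, when a Shapiro-Wilk gate rejects normality);
environment/rate associations use Spearman matrices with an ln(x + eps)
screen; community structure is tested with Mantel, PERMANOVA and SIMPER on
Bray-Curtis distances and related to rates by canonical correspondence
analysis (CCA).

Permutation tests enumerate *all* label permutations exactly when that is
feasible (<= ``exhaustive_limit`` samples) and otherwise Monte-Carlo sample
them with a seeded generator, reporting p = (b + 1) / (m + 1).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as spla
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "AssociationResult",
    "GateResult",
    "AnovaResult",
    "CCAResult",
    "normality_gate",
    "two_way_anova",
    "correlation_matrix",
    "mantel",
    "permanova",
    "simper",
    "cca",
    "pcoa",
]

_EXHAUSTIVE_LIMIT = 7  # <= 7! = 5040 permutations enumerated exactly
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of a permutation test."""

    statistic: float
    p_value: float
    n_permutations: int
    method: str
    exhaustive: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exhaustive and self.p_value < 1.0 / (self.n_permutations + 1) - _TIE_EPS:
            raise ValueError("permutation p-value below its attainable minimum")


# ---------------------------------------------------------------------------
# Normality gate and factorial tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateResult:
    route: str  # "parametric" | "rank"
    w_statistic: Optional[float]
    p_value: Optional[float]


def normality_gate(values: Sequence[float], alpha: float = 0.05) -> GateResult:
    """Shapiro-Wilk route decision: parametric if normality is not rejected."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        warnings.warn("fewer than 3 observations: defaulting to the rank route")
        return GateResult("rank", None, None)
    if np.ptp(x) == 0:
        warnings.warn("constant responses (zero variance): rank route")
        return GateResult("rank", None, None)
    w, p = sps.shapiro(x)
    return GateResult("parametric" if p >= alpha else "rank", float(w), float(p))


@dataclass(frozen=True)
class AnovaResult:
    route: str
    effects: pd.DataFrame  # index: factor_a, factor_b, interaction; columns statistic/df/p_value
    tukey: dict
    gate: GateResult


def _srh(df: pd.DataFrame, response: str, a: str, b: str) -> pd.DataFrame:
    """Scheirer-Ray-Hare: rank-transform responses, factorial SS against MS_total."""
    work = df.copy()
    work["_rank"] = sps.rankdata(work[response])
    n = len(work)
    ms_total = work["_rank"].var(ddof=1)  # = SS_total / (n - 1), ties included
    model = smf.ols(f"_rank ~ C({a}) * C({b})", data=work).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    rows = {}
    for label, key in ((a, f"C({a})"), (b, f"C({b})"), ("interaction", f"C({a}):C({b})")):
        if key not in tab.index:
            continue
        h = tab.loc[key, "sum_sq"] / ms_total
        dof = tab.loc[key, "df"]
        rows[label] = {
            "statistic": h,
            "df": dof,
            "p_value": sps.chi2.sf(h, dof),
        }
    return pd.DataFrame(rows).T


def two_way_anova(
    df: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    *,
    alpha: float = 0.05,
    route: Optional[str] = None,
) -> AnovaResult:
    """Two-way factorial comparison with a Shapiro-Wilk normality gate.

    Parametric route: ordinary two-way ANOVA (type-II) with interaction.
    Rank route: responses rank-transformed across all observations before
    the factorial fit, effects tested against the total rank mean square
    (chi-square reference). Tukey HSD pairwise comparisons are reported per
    factor on the routed responses.
    """
    work = df[[response, factor_a, factor_b]].dropna().copy()
    if work.empty:
        raise ValueError("no complete observations")
    if np.ptp(work[response].to_numpy(dtype=float)) == 0:
        raise ValueError("all responses identical: no variance to partition")
    gate = normality_gate(work[response], alpha=alpha)
    chosen = route or gate.route
    if chosen == "parametric":
        model = smf.ols(f"{response} ~ C({factor_a}) * C({factor_b})", data=work).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        effects = pd.DataFrame(
            {
                factor_a: {
                    "statistic": tab.loc[f"C({factor_a})", "F"],
                    "df": tab.loc[f"C({factor_a})", "df"],
                    "p_value": tab.loc[f"C({factor_a})", "PR(>F)"],
                },
                factor_b: {
                    "statistic": tab.loc[f"C({factor_b})", "F"],
                    "df": tab.loc[f"C({factor_b})", "df"],
                    "p_value": tab.loc[f"C({factor_b})", "PR(>F)"],
                },
                "interaction": {
                    "statistic": tab.loc[f"C({factor_a}):C({factor_b})", "F"],
                    "df": tab.loc[f"C({factor_a}):C({factor_b})", "df"],
                    "p_value": tab.loc[f"C({factor_a}):C({factor_b})", "PR(>F)"],
                },
            }
        ).T
        routed = work[response]
    else:
        effects = _srh(work, response, factor_a, factor_b)
        routed = pd.Series(sps.rankdata(work[response]), index=work.index)
    tukey = {}
    for fac in (factor_a, factor_b):
        if work[fac].nunique() >= 2:
            tukey[fac] = pairwise_tukeyhsd(routed, work[fac], alpha=alpha)
    return AnovaResult(route=chosen, effects=effects, tukey=tukey, gate=gate)


# ---------------------------------------------------------------------------
# Correlation matrix with the ln-transform screen
# ---------------------------------------------------------------------------

def _ln_eps(x: pd.Series) -> pd.Series:
    pos = x[x > 0]
    eps = 0.5 * pos.min() if len(pos) else 1.0
    return np.log(x + eps)


def correlation_matrix(
    df: pd.DataFrame,
    *,
    transform: bool = True,
    alpha_levels: Sequence[float] = (0.05, 0.01, 0.001),
) -> dict:
    """Spearman rho matrix with significance stars.

    Variables failing a Shapiro-Wilk normality screen are ln(x + eps)
    transformed first (eps = half the smallest positive value, admitting
    zeros). Spearman rho is rank-based and hence invariant to this monotone
    transform; the screen is retained so the returned ``transformed`` map
    documents which variables a parametric follow-up would need logged.
    Constant variables are dropped with a warning.
    """
    num = df.select_dtypes("number").copy()
    dropped = [c for c in num.columns if num[c].dropna().nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant variable(s): {dropped}")
        num = num.drop(columns=dropped)
    transformed = {}
    for c in num.columns:
        x = num[c].dropna()
        ok = len(x) >= 3 and sps.shapiro(x)[1] >= 0.05
        transformed[c] = bool(transform and not ok and (x >= 0).all())
        if transformed[c]:
            num[c] = _ln_eps(num[c])
    rho = pd.DataFrame(np.eye(len(num.columns)), index=num.columns, columns=num.columns)
    pval = pd.DataFrame(np.zeros((len(num.columns),) * 2), index=num.columns, columns=num.columns)
    for i, ci in enumerate(num.columns):
        for cj in num.columns[i + 1:]:
            pair = num[[ci, cj]].dropna()
            if len(pair) < 3:
                r, p = np.nan, np.nan
            else:
                r, p = sps.spearmanr(pair[ci], pair[cj])
            rho.loc[ci, cj] = rho.loc[cj, ci] = r
            pval.loc[ci, cj] = pval.loc[cj, ci] = p
    stars = pval.map(
        lambda p: "" if pd.isna(p) else "*" * sum(p < a for a in sorted(alpha_levels, reverse=True))
    )
    np.fill_diagonal(stars.values, "")
    return {"rho": rho, "p": pval, "stars": stars, "transformed": transformed}


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

def _as_square(d) -> np.ndarray:
    m = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    return m


def _perm_pvalue(obs: float, perm_stats: np.ndarray, exhaustive: bool) -> float:
    hits = int(np.sum(perm_stats >= obs - _TIE_EPS))
    if exhaustive:
        return hits / perm_stats.size
    return (hits + 1) / (perm_stats.size + 1)


def _permutations(n: int, n_perm: int, seed, exhaustive: Optional[bool]):
    """Yield (perms, exhaustive_flag): all n! orderings, or n_perm random ones."""
    if exhaustive is None:
        exhaustive = n <= _EXHAUSTIVE_LIMIT
    if exhaustive:
        return list(itertools.permutations(range(n))), True
    rng = np.random.default_rng(seed)
    return [rng.permutation(n) for _ in range(n_perm)], False


def mantel(
    dist_a,
    dist_b,
    n_perm: int = 999,
    *,
    method: str = "spearman",
    seed: Optional[int] = None,
    exhaustive: Optional[bool] = None,
) -> AssociationResult:
    """Mantel test: correlation of two distance matrices' off-diagonal entries.

    The permutation null shuffles rows and columns of the second matrix
    jointly. On small instances (n <= 7 by default) all n! relabelings are
    enumerated and the p-value is exact.
    """
    a = _as_square(dist_a)
    b = _as_square(dist_b)
    if a.shape != b.shape:
        raise ValueError("distance matrices must have identical shape")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    corr = sps.spearmanr if method == "spearman" else sps.pearsonr

    def stat(bm: np.ndarray) -> float:
        return float(corr(a[iu], bm[iu])[0])

    obs = stat(b)
    perms, exh = _permutations(n, n_perm, seed, exhaustive)
    perm_stats = np.array([stat(b[np.ix_(p, p)]) for p in perms])
    return AssociationResult(
        statistic=obs,
        p_value=_perm_pvalue(obs, perm_stats, exh),
        n_permutations=len(perms),
        method=f"mantel-{method}",
        exhaustive=exh,
    )


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """PERMANOVA pseudo-F and R^2 from squared distances and group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    f = (ss_among / df_among) / (ss_within / df_within)
    return f, ss_among / ss_total


def permanova(
    dist,
    grouping: Sequence,
    n_perm: int = 999,
    *,
    seed: Optional[int] = None,
    exhaustive: Optional[bool] = None,
) -> AssociationResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Reports the pseudo-F, the permutation p-value, and the variance
    explained (R^2 = SS_among / SS_total). Singleton groups are excluded
    with a warning; the test needs >= 2 groups with >= 2 samples each.
    """
    d = _as_square(dist)
    labels = pd.Series(list(grouping))
    if len(labels) != d.shape[0]:
        raise ValueError("grouping length must match distance matrix size")
    counts = labels.value_counts()
    singletons = counts[counts < 2].index
    if len(singletons):
        warnings.warn(f"excluding singleton group(s): {list(singletons)}")
        keep = labels.isin(counts[counts >= 2].index).to_numpy()
        d = d[np.ix_(keep, keep)]
        labels = labels[keep].reset_index(drop=True)
    codes, uniques = pd.factorize(labels)
    if len(uniques) < 2:
        raise ValueError("need at least two groups with >= 2 samples")
    d2 = d**2
    obs, r2 = _pseudo_f(d2, codes, len(uniques))
    perms, exh = _permutations(len(codes), n_perm, seed, exhaustive)
    codes = np.asarray(codes)
    perm_stats = np.array(
        [_pseudo_f(d2, codes[np.asarray(p)], len(uniques))[0] for p in perms]
    )
    return AssociationResult(
        statistic=obs,
        p_value=_perm_pvalue(obs, perm_stats, exh),
        n_permutations=len(perms),
        method="permanova",
        exhaustive=exh,
        extras={"r_squared": r2, "n_groups": len(uniques)},
    )


def simper(
    abundance: pd.DataFrame,
    grouping: Sequence,
) -> pd.DataFrame:
    """Similarity-percentage decomposition of between-group Bray-Curtis.

    ``abundance`` is taxa x samples. For each between-group sample pair the
    Bray-Curtis dissimilarity splits additively over taxa as
    |x_k - y_k| / sum_k (x_k + y_k); contributions are averaged over all
    pairs, so per-taxon contributions sum to the mean between-group
    dissimilarity and percentages sum to 100. With more than two groups each
    pair of groups is decomposed separately (``pair`` column).
    """
    labels = pd.Series(list(grouping))
    if len(labels) != abundance.shape[1]:
        raise ValueError("grouping length must match sample count")
    groups = labels.unique()
    if len(groups) < 2:
        raise ValueError("SIMPER needs at least two groups")
    out = []
    mat = abundance.to_numpy(dtype=float)
    for ga, gb in itertools.combinations(groups, 2):
        ia = np.flatnonzero((labels == ga).to_numpy())
        ib = np.flatnonzero((labels == gb).to_numpy())
        contrib = np.zeros(abundance.shape[0])
        for i in ia:
            for j in ib:
                denom = (mat[:, i] + mat[:, j]).sum()
                if denom > 0:
                    contrib += np.abs(mat[:, i] - mat[:, j]) / denom
        contrib /= len(ia) * len(ib)
        mean_bc = contrib.sum()
        for k, taxon in enumerate(abundance.index):
            out.append(
                {
                    "pair": f"{ga} vs {gb}",
                    "taxon": taxon,
                    "contribution": contrib[k],
                    "contribution_pct": 100.0 * contrib[k] / mean_bc if mean_bc > 0 else 0.0,
                    "mean_dissimilarity": mean_bc,
                }
            )
    df = pd.DataFrame(out)
    return df.sort_values(["pair", "contribution_pct"], ascending=[True, False]).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# Constrained ordination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CCAResult:
    eigenvalues: np.ndarray  # constrained axes, non-increasing
    proportion_explained: np.ndarray  # of constrained inertia, sums to 1
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    total_inertia: float
    constrained_inertia: float
    dropped_constraints: tuple[str, ...] = ()


def cca(
    abundance: pd.DataFrame,
    constraints: pd.DataFrame,
) -> CCAResult:
    """Canonical correspondence analysis of a community table on constraints.

    ``abundance``: sites x species non-negative matrix (sites as rows here).
    ``constraints``: sites x variables (e.g. uptake rates). The community
    matrix is chi-square transformed and regressed on the weighted, centered
    constraints; the SVD of the fitted matrix yields the constrained axes.
    Collinear constraint columns are dropped with a warning.
    """
    Y = abundance.to_numpy(dtype=float)
    if (Y < 0).any():
        raise ValueError("abundances must be non-negative")
    if Y.sum() <= 0:
        raise ValueError("empty community matrix")
    if abundance.shape[0] != constraints.shape[0]:
        raise ValueError("abundance and constraints must share the site dimension")

    P = Y / Y.sum()
    r = P.sum(axis=1)  # site weights
    c = P.sum(axis=0)
    if (r <= 0).any() or (c <= 0).any():
        raise ValueError("every site and species needs a positive total")
    Qbar = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))

    X = constraints.to_numpy(dtype=float)
    names = list(constraints.columns)
    # weighted centering, then drop collinear columns by pivoted rank
    Xc = X - (r @ X)[None, :]
    Xw = Xc * np.sqrt(r)[:, None]
    if np.allclose(Xw, 0):
        raise ValueError("constraints carry no constrained inertia (all zero/constant)")
    dropped: list[str] = []
    q, rr, piv = spla.qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(rr))
    rank = int(np.sum(diag > diag[0] * 1e-10)) if diag.size else 0
    if rank < Xw.shape[1]:
        keep_idx = sorted(piv[:rank])
        dropped = [names[i] for i in piv[rank:]]
        warnings.warn(f"dropping collinear constraint(s): {dropped}")
        Xw = Xw[:, keep_idx]
        names = [names[i] for i in keep_idx]

    # projection of Qbar onto the span of the weighted constraints
    coef, *_ = np.linalg.lstsq(Xw, Qbar, rcond=None)
    fitted = Xw @ coef
    U, S, Vt = np.linalg.svd(fitted, full_matrices=False)
    eig = S**2
    keep = eig > max(eig[0], 1e-300) * 1e-12
    U, S, Vt, eig = U[:, keep], S[keep], Vt[keep], eig[keep]
    n_axes = min(len(eig), Xw.shape[1])
    U, S, Vt, eig = U[:, :n_axes], S[:n_axes], Vt[:n_axes], eig[:n_axes]

    axes = [f"CCA{i + 1}" for i in range(n_axes)]
    site = pd.DataFrame(
        (U * S) / np.sqrt(r)[:, None], index=abundance.index, columns=axes
    )
    species = pd.DataFrame(Vt.T / np.sqrt(c)[:, None], index=abundance.columns, columns=axes)
    # biplot scores: weighted correlation of constraints with site axes (LC scores)
    lc = U * S
    bip = np.array(
        [
            [
                float(np.corrcoef(Xw[:, j], lc[:, k])[0, 1]) if np.ptp(lc[:, k]) > 0 else 0.0
                for k in range(n_axes)
            ]
            for j in range(Xw.shape[1])
        ]
    )
    biplot = pd.DataFrame(bip, index=names, columns=axes)

    total_inertia = float((Qbar**2).sum())
    constrained = float(eig.sum())
    return CCAResult(
        eigenvalues=eig,
        proportion_explained=eig / constrained,
        site_scores=site,
        species_scores=species,
        biplot_scores=biplot,
        total_inertia=total_inertia,
        constrained_inertia=constrained,
        dropped_constraints=tuple(dropped),
    )


def pcoa(dist, n_axes: int = 2) -> pd.DataFrame:
    """Principal coordinates of a distance matrix (classical MDS)."""
    d = _as_square(dist)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.clip(vals, 0, None)
    coords = vecs[:, :n_axes] * np.sqrt(pos[:n_axes])
    idx = dist.index if isinstance(dist, pd.DataFrame) else range(n)
    return pd.DataFrame(coords, index=idx, columns=[f"PCo{i + 1}" for i in range(n_axes)])
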