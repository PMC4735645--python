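"""Group-comparison statistics for connectivity networks.

Covers the between-group machinery of the analysis: physical (Euclidean,
MNI-mm) distance matrices, edge-wise regressions of connectivity or
functional distance on physical distance, Fisher r-to-z comparisons of
correlations, cross-frequency coupling of shortest-path structure, an
edgewise significance map, and a two-way mixed (split-plot) ANOVA with
group as the between factor and frequency band as the within factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform


def physical_distance(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance (mm) between coordinate triples."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
        raise ValueError("coords must be (n >= 2, 3)")
    return squareform(pdist(coords))


def _edge_vector(mat: np.ndarray) -> np.ndarray:
    """Upper-triangle (unordered-edge) vector of a square matrix."""
    mat = np.asarray(mat, dtype=float)
    iu = np.triu_indices_from(mat, k=1)
    return mat[iu]


@dataclass
class RegressionResult:
    """Edge-wise OLS of a per-edge quantity on physical distance."""

    slope: float
    intercept: float
    r: float
    n: int
    t: float
    p: float
    n_excluded: int = 0


def distance_regression(values: np.ndarray, p_mat: np.ndarray,
                        ) -> RegressionResult:
    """Regress a per-edge quantity on physical distance over unordered edges.

    Infinite or NaN entries (e.g. unreachable functional distances) are
    excluded; the number removed is reported.
    """
    y = _edge_vector(values)
    x = _edge_vector(p_mat)
    ok = np.isfinite(y) & np.isfinite(x)
    n_excluded = int((~ok).sum())
    y, x = y[ok], x[ok]
    if y.size < 3:
        raise ValueError("need at least 3 finite edges")
    res = sps.linregress(x, y)
    df = y.size - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = res.slope / res.stderr if res.stderr > 0 else np.inf
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r=float(res.rvalue), n=int(y.size),
                            t=float(t), p=float(res.pvalue),
                            n_excluded=n_excluded)


@dataclass
class SlopeInteraction:
    """Between-group difference in an edge-wise regression slope."""

    t: float
    p: float
    df: float
    slope_diff: float  # slope_B - slope_A


def compare_regression_slopes(values_a: np.ndarray, p_a: np.ndarray,
                              values_b: np.ndarray, p_b: np.ndarray,
                              ) -> SlopeInteraction:
    """Test whether the value-vs-distance slope differs between groups.

    Pooled OLS with a group dummy and group x distance interaction; the
    interaction t (two-sided p) is the test statistic. Positive t means
    group B has the larger (more positive) slope.
    """
    pairs = []
    for values, pmat, g in ((values_a, p_a, 0.0), (values_b, p_b, 1.0)):
        y = _edge_vector(values)
        x = _edge_vector(pmat)
        ok = np.isfinite(y) & np.isfinite(x)
        if ok.sum() < 3:
            raise ValueError("need at least 3 finite edges per group")
        pairs.append((x[ok], y[ok], np.full(ok.sum(), g)))
    x = np.concatenate([p[0] for p in pairs])
    y = np.concatenate([p[1] for p in pairs])
    g = np.concatenate([p[2] for p in pairs])
    design = sm.add_constant(np.column_stack([x, g, x * g]))
    fit = sm.OLS(y, design).fit()
    return SlopeInteraction(t=float(fit.tvalues[3]),
                            p=float(fit.pvalues[3]),
                            df=float(fit.df_resid),
                            slope_diff=float(fit.params[3]))


def fisher_z(r: float, n: int) -> tuple[float, float]:
    """Fisher r-to-z transform and its standard error 1/sqrt(n-3)."""
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1")
    if n <= 3:
        raise ValueError("need n > 3")
    return float(np.arctanh(r)), float(1.0 / np.sqrt(n - 3))


def compare_correlations(r1: float, n1: int, r2: float, n2: int,
                         ) -> tuple[float, float]:
    """Two-sample z test for a difference between independent correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided p.
    """
    z1, se1 = fisher_z(r1, n1)
    z2, se2 = fisher_z(r2, n2)
    z = (z1 - z2) / np.sqrt(se1 ** 2 + se2 ** 2)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class CrossFrequencyResult:
    """Edge-wise coupling of shortest-path structure across two bands."""

    low_band: str
    high_band: str
    r: float
    n: int


def cross_frequency_coupling(d_low: np.ndarray, d_high: np.ndarray,
                             low_band: str = "", high_band: str = "",
                             ) -> CrossFrequencyResult:
    """Pearson correlation of functional distances between two bands.

    Correlates the unordered-edge vectors of the two distance matrices over
    edges finite in both bands.
    """
    x = _edge_vector(d_low)
    y = _edge_vector(d_high)
    if x.size != y.size:
        raise ValueError("distance matrices must share the node set")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 common finite edges")
    r = sps.pearsonr(x[ok], y[ok]).statistic
    return CrossFrequencyResult(low_band=low_band, high_band=high_band,
                                r=float(r), n=int(ok.sum()))


@dataclass
class EdgewiseMap:
    """Tri-valued edgewise group-difference map.

    ``map`` holds +1 where group A's functional distance is significantly
    longer, -1 where group B's is, 0 otherwise. Significance comes from a
    Fisher z comparison of the bounded connectivity weights (|w| < 1,
    correlation-like), Bonferroni-corrected over edges; the direction label
    comes from the functional-distance matrices.
    """

    map: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n_a_longer: int
    n_b_longer: int
    n_not_significant: int


def edgewise_group_map(w_a: np.ndarray, w_b: np.ndarray,
                       d_a: np.ndarray, d_b: np.ndarray,
                       n_a: int, n_b: int,
                       alpha_level: float = 0.05) -> EdgewiseMap:
    """Edge-by-edge group comparison with Bonferroni control."""
    w_a = np.asarray(w_a, float)
    w_b = np.asarray(w_b, float)
    if w_a.shape != w_b.shape:
        raise ValueError("groups must share the node set")
    if n_a <= 3 or n_b <= 3:
        raise ValueError("need n > 3 per group")
    n = w_a.shape[0]
    n_edges = n * (n - 1) // 2
    crit = alpha_level / n_edges
    zmat = np.zeros((n, n))
    pmat = np.ones((n, n))
    out = np.zeros((n, n), dtype=int)
    se = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    for i in range(n):
        for j in range(i + 1, n):
            z = (np.arctanh(w_a[i, j]) - np.arctanh(w_b[i, j])) / se
            p = 2.0 * sps.norm.sf(abs(z))
            zmat[i, j] = zmat[j, i] = z
            pmat[i, j] = pmat[j, i] = p
            if p < crit:
                da, db = d_a[i, j], d_b[i, j]
                if da > db:
                    out[i, j] = out[j, i] = 1
                elif db > da:
                    out[i, j] = out[j, i] = -1
    iu = np.triu_indices(n, k=1)
    vals = out[iu]
    return EdgewiseMap(map=out, z=zmat, p=pmat,
                       n_a_longer=int((vals == 1).sum()),
                       n_b_longer=int((vals == -1).sum()),
                       n_not_significant=int((vals == 0).sum()))


@dataclass
class AnovaEffect:
    f: float
    p: float
    df1: float
    df2: float


@dataclass
class BandContrast:
    """Per-band simple contrast between groups (one-tailed)."""

    band: str
    f: float
    p_one_tailed: float
    direction: str  # "A>B", "B>A", or "tie"
    df: float


@dataclass
class MixedAnovaResult:
    group: AnovaEffect
    band: AnovaEffect
    interaction: AnovaEffect
    contrasts: list[BandContrast] = field(default_factory=list)


def group_band_anova(values_a: np.ndarray, values_b: np.ndarray,
                     band_names: list[str] | None = None,
                     ) -> MixedAnovaResult:
    """Two-way mixed ANOVA: group (between) x band (within).

    ``values_a`` and ``values_b`` are (n_units, n_bands) arrays — one row
    per observational unit (node or edge), one column per band, complete
    for every unit. Returns the group main effect (error term: units
    within groups), the band main effect and group x band interaction
    (error term: band x unit within groups), and per-band simple contrasts
    tested one-tailed in the direction of the observed difference.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be 2-D with a common band structure")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 units per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("values must be finite (complete band structure)")
    n_bands = a.shape[1]
    if band_names is None:
        band_names = [f"band{k}" for k in range(n_bands)]
    if len(band_names) != n_bands:
        raise ValueError("band_names length mismatch")

    groups = [a, b]
    ns = [g.shape[0] for g in groups]
    n_total = sum(ns)
    grand = np.concatenate([g.ravel() for g in groups]).mean()

    g_means = [g.mean() for g in groups]
    ss_group = n_bands * sum(n * (m - grand) ** 2
                             for n, m in zip(ns, g_means))
    ss_subj_within = n_bands * sum(
        ((g.mean(axis=1) - m) ** 2).sum() for g, m in zip(groups, g_means))

    band_means = (a.sum(axis=0) + b.sum(axis=0)) / n_total
    ss_band = n_total * ((band_means - grand) ** 2).sum()
    ss_inter = sum(
        n * ((g.mean(axis=0) - m - band_means + grand) ** 2).sum()
        for g, n, m in zip(groups, ns, g_means))
    ss_error = sum(
        ((g - g.mean(axis=0)[None, :] - g.mean(axis=1)[:, None] + m) ** 2)
        .sum() for g, m in zip(groups, g_means))

    df_group = 1.0
    df_subj = float(n_total - 2)
    df_band = float(n_bands - 1)
    df_inter = float(n_bands - 1)
    df_error = float((n_total - 2) * (n_bands - 1))

    def _effect(ss: float, df1: float, ss_err: float, df2: float,
                ) -> AnovaEffect:
        ms, ms_err = ss / df1, ss_err / df2
        f = ms / ms_err if ms_err > 0 else np.inf
        return AnovaEffect(f=float(f), p=float(sps.f.sf(f, df1, df2)),
                           df1=df1, df2=df2)

    result = MixedAnovaResult(
        group=_effect(ss_group, df_group, ss_subj_within, df_subj),
        band=_effect(ss_band, df_band, ss_error, df_error),
        interaction=_effect(ss_inter, df_inter, ss_error, df_error),
    )
    for k, name in enumerate(band_names):
        t_res = sps.ttest_ind(a[:, k], b[:, k])
        diff = a[:, k].mean() - b[:, k].mean()
        direction = "A>B" if diff > 0 else ("B>A" if diff < 0 else "tie")
        result.contrasts.append(BandContrast(
            band=name, f=float(t_res.statistic ** 2),
            p_one_tailed=float(t_res.pvalue / 2.0),
            direction=direction, df=float(n_total - 2)))
    return result
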