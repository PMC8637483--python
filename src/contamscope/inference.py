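"""Hypothesis tests for the controls-first analysis.

Covers the statistical layer of the pipeline: Wilcoxon rank-sum with Holm
correction for alpha-diversity comparisons, distance-based PERMANOVA with
sequential (Type-I) sums of squares and optional interactions, two-way
ANOVA on alpha indices, a simplified per-genus negative-binomial Wald test
for differential abundance with Benjamini-Hochberg adjustment, and the
Gehan-(Breslow-)Wilcoxon weighted log-rank test for survival curves.

The differential-abundance stage is a deliberate simplification of the
DESeq2-style workflow: median-of-ratios size factors, method-of-moments
dispersion per genus (no shrinkage across genera), an IRLS fit of the
two-group log-linear model, and a Wald z on the group coefficient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import DistanceMatrix
from .tables import FeatureTable, SampleMetadata, ValidationError

__all__ = [
    "wilcoxon_rank_sum",
    "holm_adjust",
    "bh_adjust",
    "permanova",
    "PermanovaResult",
    "two_way_anova",
    "nb_wald_diff_abundance",
    "DiffAbundanceResult",
    "gehan_wilcoxon_test",
]


# ---------------------------------------------------------------------------
# Rank tests and p-value adjustment
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y, exact_if_small: bool = True) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses exact enumeration when the pooled size is at most 12 and there are
    no ties; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (exact_if_small and pooled.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def _check_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.size == 0 or np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return p


def holm_adjust(pvals) -> np.ndarray:
    """Step-down Holm adjustment, monotone and capped at 1.

    Output preserves input order.
    """
    p = _check_pvals(pvals)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    stepped = np.maximum.accumulate(scaled)
    out = np.empty(m)
    out[order] = np.minimum(stepped, 1.0)
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjustment, monotone and capped at 1."""
    p = _check_pvals(pvals)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / (np.arange(m) + 1)
    stepped = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(stepped, 1.0)
    return out


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    """Per-term pseudo-F table from a distance-based permutation ANOVA."""

    table: pd.DataFrame  # index term; columns df, ss, ms, pseudo_F, p_perm
    ss_total: float
    ss_residual: float
    df_residual: int
    n_permutations: int
    seed: int = None

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _dummy(labels: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    levels = pd.unique(labels)
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((labels.size, 0))


def _gower(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    return (g + g.T) / 2.0


def permanova(
    d: DistanceMatrix,
    factors,
    include_interaction: bool = False,
    n_permutations: int = 999,
    seed: int = None,
    exact: bool = False,
) -> PermanovaResult:
    """Distance-based permutational multivariate ANOVA (pseudo-F).

    ``factors`` is a mapping of factor name to per-sample labels aligned
    with ``d.sample_ids`` (one or two factors). Sums of squares follow the
    trace formulation of distance-based redundancy analysis: the Gower
    matrix G of -d^2/2 is projected on hat matrices of sequentially nested
    design matrices (Type-I SS, factors in the stated order, interaction
    last). p-values come from free permutation of sample labels with the
    add-one convention p = (1 + #{F* >= F}) / (1 + n_permutations).

    With ``exact=True`` (or whenever ``n_permutations`` is at least the
    number of distinct reorderings minus one) all permutations are
    enumerated instead of sampled, which makes the add-one p identical to
    the exhaustive-enumeration p including the identity.
    """
    names = list(factors)
    if not 1 <= len(names) <= 2:
        raise ValidationError("permanova supports one or two factors")
    n = len(d.sample_ids)
    labels = {k: np.asarray(list(factors[k])) for k in names}
    for k, lab in labels.items():
        if lab.size != n:
            raise ValidationError(f"factor {k!r} length does not match samples")
        levels, counts = np.unique(lab, return_counts=True)
        if len(levels) < 2:
            raise ValidationError(f"factor {k!r} has a single level")
        if counts.min() < 2:
            raise ValidationError(f"factor {k!r} has a level with fewer than 2 samples")
    if n_permutations < 99:
        warnings.warn("fewer than 99 permutations gives a very coarse p-value")

    # sequential design matrices: intercept, +A, +B, +A:B
    intercept = np.ones((n, 1))
    blocks = [intercept]
    term_names = []
    da = _dummy(labels[names[0]])
    blocks.append(da)
    term_names.append(names[0])
    if len(names) == 2:
        db = _dummy(labels[names[1]])
        blocks.append(db)
        term_names.append(names[1])
        if include_interaction:
            inter = np.einsum("ij,ik->ijk", da, db).reshape(n, -1)
            blocks.append(inter)
            term_names.append(f"{names[0]}:{names[1]}")

    hats, ranks = [], []
    x = np.empty((n, 0))
    for b in blocks:
        x = np.hstack([x, b])
        hats.append(x @ np.linalg.pinv(x))
        ranks.append(np.linalg.matrix_rank(x))
    df_terms = np.diff(ranks)
    if np.any(df_terms == 0):
        bad = term_names[int(np.argmin(df_terms))]
        raise ValidationError(f"term {bad!r} is aliased (empty design cell?)")
    df_resid = n - ranks[-1]
    if df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")

    g = _gower(d.values)
    ss_total = float(np.trace(g))

    def _stats_for(gmat3):
        """Per-term SS and F for a stack of (possibly permuted) G matrices."""
        tr = np.stack([np.einsum("ij,kji->k", h, gmat3) for h in hats])  # (n_hat, k)
        ss_model = tr[1:] - tr[:-1]  # sequential SS per term
        tot = np.einsum("kii->k", gmat3)
        ss_res = tot - tr[-1]
        ms_res = ss_res / df_resid
        f = (ss_model / df_terms[:, None]) / ms_res
        return ss_model, ss_res, f

    g3 = g[None]
    ss_obs, ss_res_obs, f_obs = _stats_for(g3)
    ss_obs = ss_obs[:, 0]
    f_obs = f_obs[:, 0]

    # permutations
    n_distinct = math.factorial(n) if n <= 12 else None
    if exact or (n_distinct is not None and n_permutations >= n_distinct - 1):
        perms = np.array([p for p in _iter_permutations(range(n))][1:])  # drop identity
        n_used = perms.shape[0]
    else:
        rng = np.random.default_rng(seed)
        perms = np.stack([rng.permutation(n) for _ in range(n_permutations)])
        n_used = n_permutations
    # batch to bound memory on larger sample sets
    exceed = np.zeros(len(term_names), dtype=np.int64)
    batch = max(1, int(2e7 // (n * n)))
    for start in range(0, n_used, batch):
        pp = perms[start:start + batch]
        gp = g[pp[:, :, None], pp[:, None, :]]
        _, _, f_perm = _stats_for(gp)
        exceed += (f_perm >= f_obs[:, None] - 1e-12).sum(axis=1)
    p_perm = (1.0 + exceed) / (1.0 + n_used)

    tab = pd.DataFrame(
        {
            "df": df_terms.astype(int),
            "ss": ss_obs,
            "ms": ss_obs / df_terms,
            "pseudo_F": f_obs,
            "p_perm": p_perm,
        },
        index=pd.Index(term_names, name="term"),
    )
    return PermanovaResult(
        table=tab,
        ss_total=ss_total,
        ss_residual=float(ss_res_obs[0]),
        df_residual=int(df_resid),
        n_permutations=int(n_used),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Two-way ANOVA
# ---------------------------------------------------------------------------

def two_way_anova(response, factor_a, factor_b,
                  names: tuple = ("A", "B")) -> pd.DataFrame:
    """Two-way ANOVA with interaction, sequential (Type-I) SS.

    Terms are fitted in the order A, B, A:B against the residual mean
    square. Returns a per-term table with df, sum_sq, F and p.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    y = np.asarray(response, dtype=float)
    a = np.asarray(list(factor_a))
    b = np.asarray(list(factor_b))
    if len(pd.unique(a)) < 2 or len(pd.unique(b)) < 2:
        raise ValidationError("both factors need at least two levels")
    cells = pd.crosstab(a, b)
    empty = [(str(i), str(j)) for i in cells.index for j in cells.columns
             if cells.loc[i, j] == 0]
    if empty:
        raise ValidationError(f"empty design cell(s) make the interaction "
                              f"inestimable: {empty}")
    df = pd.DataFrame({"y": y, "fa": a, "fb": b})
    fit = smf.ols("y ~ C(fa) + C(fb) + C(fa):C(fb)", data=df).fit()
    if fit.df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")
    tab = sm.stats.anova_lm(fit, typ=1)
    tab = tab.rename(index={
        "C(fa)": names[0],
        "C(fb)": names[1],
        "C(fa):C(fb)": f"{names[0]}:{names[1]}",
        "Residual": "residual",
    })
    return tab.rename(columns={"sum_sq": "ss", "PR(>F)": "p"})


# ---------------------------------------------------------------------------
# Negative-binomial Wald differential abundance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffAbundanceResult:
    """Per-genus Wald test results for a two-group contrast.

    ``table`` columns: base_mean, log2_fc (level_b relative to level_a),
    se (of log2_fc), wald_z, p, padj, boundary (True when one group had
    zero counts and the pseudo-count estimate was used).
    """

    table: pd.DataFrame
    field: str
    level_a: str
    level_b: str
    dropped: list = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> list:
        t = self.table
        return t.index[t["padj"] < alpha].tolist()


def _size_factors(k: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (geometric-mean reference).

    Uses genera with all-positive counts; if none exist, falls back to
    geometric means computed over positive entries only.
    """
    with np.errstate(divide="ignore"):
        logk = np.log(k.astype(float))
    all_pos = np.all(k > 0, axis=1)
    if all_pos.any():
        ref = logk[all_pos].mean(axis=1)
        ratios = logk[all_pos] - ref[:, None]
        sf = np.exp(np.median(ratios, axis=0))
    else:
        pos = k > 0
        ref = np.where(pos.any(axis=1),
                       np.where(pos, logk, 0.0).sum(axis=1) / np.maximum(pos.sum(axis=1), 1),
                       0.0)
        with np.errstate(invalid="ignore"):
            ratios = np.where(pos, logk - ref[:, None], np.nan)
        sf = np.exp(np.nanmedian(ratios, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return sf


def _irls_nb(kg: np.ndarray, x: np.ndarray, logs: np.ndarray, alpha: float,
             max_iter: int = 60, tol: float = 1e-10):
    """Fit log mu = b0 + b1 x + log s for one genus by IRLS; return b, cov."""
    mean_a = max(kg[x == 0].mean(), 0.1)
    mean_b = max(kg[x == 1].mean(), 0.1)
    beta = np.array([np.log(mean_a), np.log(mean_b) - np.log(mean_a)])
    xm = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    for _ in range(max_iter):
        eta = xm @ beta + logs
        mu = np.clip(np.exp(eta), 1e-10, 1e12)
        w = mu / (1.0 + alpha * mu)
        z = (eta - logs) + (kg - mu) / mu
        xtw = xm.T * w
        try:
            new = np.linalg.solve(xtw @ xm, xtw @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    eta = xm @ beta + logs
    mu = np.clip(np.exp(eta), 1e-10, 1e12)
    w = mu / (1.0 + alpha * mu)
    cov = np.linalg.inv((xm.T * w) @ xm)
    return beta, cov


def nb_wald_diff_abundance(
    genus_table: FeatureTable,
    metadata: SampleMetadata,
    contrast: tuple,
    min_dispersion: float = 1e-8,
    size_factors=None,
) -> DiffAbundanceResult:
    """Per-genus negative-binomial Wald test between two groups.

    ``contrast = (field, level_a, level_b)``: the reported log2 fold change
    is level_b relative to level_a (baseline). Size factors are
    median-of-ratios; per-genus dispersion is a method-of-moments estimate
    on normalized counts floored at ``min_dispersion``; the two-group
    log-linear model is fitted by IRLS and the group coefficient tested
    with a Wald z. p-values are BH-adjusted across genera.

    A genus observed in only one group is estimated with a 0.5 pseudo-count
    on the normalized group means and flagged ``boundary``.

    ``size_factors`` overrides the median-of-ratios estimate: ``"unit"``
    fixes every factor at 1 (appropriate when library sizes are known to be
    equal, or when a global composition shift would otherwise be absorbed
    as apparent depth), or an array gives externally computed factors.
    """
    field_name, level_a, level_b = contrast
    metadata.check_paired(genus_table)
    md = metadata.data.loc[genus_table.sample_ids]
    if field_name not in md.columns:
        raise ValidationError(f"unknown metadata field {field_name!r}")
    sel_a = md.index[md[field_name] == level_a].tolist()
    sel_b = md.index[md[field_name] == level_b].tolist()
    for lev, sel in ((level_a, sel_a), (level_b, sel_b)):
        if len(sel) < 2:
            raise ValidationError(
                f"contrast level {lev!r} has fewer than 2 samples"
            )
    sub = genus_table.select_samples(sel_a + sel_b)
    k = sub.counts
    x = np.array([0] * len(sel_a) + [1] * len(sel_b))

    nonzero = k.sum(axis=1) > 0
    dropped = [g for g, keep in zip(sub.taxon_ids, nonzero) if not keep]
    genera = [g for g, keep in zip(sub.taxon_ids, nonzero) if keep]
    k = k[nonzero]

    if size_factors is None:
        sf = _size_factors(k)
    elif isinstance(size_factors, str) and size_factors == "unit":
        sf = np.ones(k.shape[1])
    else:
        sf = np.asarray(size_factors, dtype=float)
        if sf.shape != (k.shape[1],) or np.any(sf <= 0):
            raise ValidationError("size_factors must be positive, one per sample")
    logs = np.log(sf)
    y = k / sf  # normalized counts
    inv_s_mean = float(np.mean(1.0 / sf))

    rows = []
    for gi, g in enumerate(genera):
        kg = k[gi].astype(float)
        yg = y[gi]
        mu_hat = yg.mean()
        var_hat = yg.var(ddof=1)
        alpha = max((var_hat - mu_hat * inv_s_mean) / mu_hat**2, min_dispersion)
        tot_a = kg[x == 0].sum()
        tot_b = kg[x == 1].sum()
        boundary = (tot_a == 0) or (tot_b == 0)
        if boundary:
            ma = yg[x == 0].mean() + 0.5
            mb = yg[x == 1].mean() + 0.5
            b1 = np.log(mb / ma)
            na, nb = (x == 0).sum(), (x == 1).sum()
            var_a = (ma * inv_s_mean + alpha * ma**2) / na
            var_b = (mb * inv_s_mean + alpha * mb**2) / nb
            se_b1 = np.sqrt(var_a / ma**2 + var_b / mb**2)
        else:
            beta, cov = _irls_nb(kg, x, logs, alpha)
            b1 = beta[1]
            se_b1 = np.sqrt(max(cov[1, 1], 1e-300))
        z = b1 / se_b1
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "genus": g,
                "base_mean": mu_hat,
                "dispersion": alpha,
                "log2_fc": b1 / np.log(2.0),
                "se": se_b1 / np.log(2.0),
                "wald_z": z,
                "p": max(p, np.nextafter(0, 1)),
                "boundary": boundary,
            }
        )
    tab = pd.DataFrame(rows).set_index("genus")
    tab["padj"] = bh_adjust(tab["p"].to_numpy()) if len(tab) else []
    return DiffAbundanceResult(
        table=tab, field=field_name, level_a=level_a, level_b=level_b,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def gehan_wilcoxon_test(records: pd.DataFrame) -> dict:
    """Gehan-Breslow-Wilcoxon weighted log-rank test across groups.

    ``records`` needs columns ``time`` (positive), ``event`` (1/``death``
    for observed deaths, 0/``censored`` otherwise) and ``group``. Weights
    equal the number at risk at each event time, emphasising early deaths.
    Returns the chi-square statistic, its p-value on (groups - 1) df, and
    the median survival time per group.
    """
    from lifelines.statistics import multivariate_logrank_test
    from lifelines import KaplanMeierFitter

    df = records.copy()
    for col in ("time", "event", "group"):
        if col not in df.columns:
            raise ValidationError(f"survival records missing column {col!r}")
    if (df["time"] <= 0).any():
        raise ValidationError("survival times must be positive")
    ev = df["event"].map(
        lambda e: 1 if e in (1, "1", "death", True) else 0
    )
    if ev.sum() == 0:
        raise ValidationError("all observations censored: test undefined")
    groups = pd.unique(df["group"])
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    res = multivariate_logrank_test(
        df["time"], df["group"], ev, weightings="wilcoxon"
    )
    medians = {}
    for g in groups:
        m = df["group"] == g
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[m, "time"], ev[m])
        medians[str(g)] = float(kmf.median_survival_time_)
    return {
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
        "df": int(len(groups) - 1),
        "median_survival": medians,
    }
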