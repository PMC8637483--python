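"""Alpha and beta diversity with negative controls retained throughout.

Alpha diversity: observed richness, the bias-corrected Chao1 richness
estimator with its standard error, and Shannon entropy (natural log).
Beta diversity: Bray-Curtis dissimilarity (on proportions by default),
classical-scaling PCoA with negative eigenvalues reported uncorrected, and
the sample-to-matched-control proximity screen that quantifies how close
each specimen sits to its replicate's extraction blank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import (
    CompositionTable,
    FeatureTable,
    SampleMetadata,
    ValidationError,
    relative_abundance,
)

__all__ = [
    "chao1",
    "shannon",
    "alpha_diversity_table",
    "bray_curtis",
    "pcoa",
    "control_proximity",
    "DistanceMatrix",
    "OrdinationResult",
    "ControlProximityReport",
]


def chao1(counts) -> tuple:
    """Bias-corrected Chao1 richness estimate and its standard error.

    S_chao1 = S_obs + F1 (F1 - 1) / (2 (F2 + 1)), with F1/F2 the numbers of
    singletons/doubletons. The variance uses the standard bias-corrected
    formula; with F1 = 0 the estimate collapses to S_obs with SE 0.
    An all-zero vector returns (0.0, 0.0) with a warning.
    """
    c = np.asarray(counts)
    if c.size and not np.issubdtype(c.dtype, np.integer):
        if np.any(c != np.floor(c)):
            raise ValidationError("Chao1 requires integer counts, not proportions")
        c = c.astype(np.int64)
    if np.any(c < 0):
        raise ValidationError("counts must be non-negative")
    if c.sum() == 0:
        warnings.warn("Chao1 on an all-zero sample: returning 0")
        return 0.0, 0.0
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    est = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f1 == 0:
        return float(est), 0.0
    if f2 > 0:
        var = (
            f1 * (f1 - 1) / (2.0 * (f2 + 1))
            + f1 * (2 * f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 2)
            + f1**2 * f2 * (f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 4)
        )
    else:
        var = (
            f1 * (f1 - 1) / 2.0
            + f1 * (2 * f1 - 1) ** 2 / 4.0
            - f1**4 / (4.0 * est)
        )
    return float(est), float(np.sqrt(max(var, 0.0)))


def shannon(vector, base: float = np.e) -> float:
    """Shannon entropy H = -sum p_i log p_i over nonzero proportions.

    Accepts counts or proportions; natural log by default.
    """
    v = np.asarray(vector, dtype=float)
    if np.any(v < 0):
        raise ValidationError("entries must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValidationError("Shannon entropy undefined on a zero-sum vector")
    p = v[v > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base != np.e:
        h /= np.log(base)
    # clamp the -0.0 of a single-taxon sample
    return max(h, 0.0)


def alpha_diversity_table(table: FeatureTable, metadata: SampleMetadata = None) -> pd.DataFrame:
    """Per-sample observed richness, Chao1 (with SE) and Shannon index.

    Negative controls are never excluded; when metadata is supplied the
    sample role is copied into the output so controls stay identifiable.
    """
    rows = []
    for s in table.sample_ids:
        c = table.data[s].to_numpy()
        est, se = chao1(c) if c.sum() > 0 else (0.0, 0.0)
        h = shannon(c) if c.sum() > 0 else np.nan
        rows.append(
            {
                "sample_id": s,
                "observed_richness": int((c > 0).sum()),
                "chao1": est,
                "chao1_se": se,
                "shannon": h,
            }
        )
    out = pd.DataFrame(rows).set_index("sample_id")
    if metadata is not None:
        metadata.check_paired(table)
        out["role"] = metadata.data.loc[out.index, "role"]
    return out


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric dissimilarity matrix with zero diagonal."""

    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        d = self.values
        if d.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")

    def between(self, a, b) -> float:
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def subset(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)])


def bray_curtis(table, use_proportions: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    d_xy = sum_i |x_i - y_i| / sum_i (x_i + y_i). By default each sample is
    first converted to proportions, neutralising sequencing-depth
    differences; ``use_proportions=False`` computes on raw counts.
    """
    if isinstance(table, CompositionTable):
        mat = table.proportions
        ids = table.sample_ids
    elif isinstance(table, FeatureTable):
        if (table.sample_totals() == 0).any():
            bad = table.sample_totals()
            raise ValidationError(
                f"zero-total samples: {bad[bad == 0].index.tolist()}"
            )
        ids = table.sample_ids
        if use_proportions:
            mat = relative_abundance(table).proportions
        else:
            mat = table.counts.astype(float)
    else:
        raise ValidationError("expected FeatureTable or CompositionTable")
    if mat.shape[1] < 2:
        raise ValidationError("Bray-Curtis needs at least two samples")
    x = mat.T  # samples x taxa
    # |x_i - y_i| summed, over pairwise sums
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(ids), d)


@dataclass(frozen=True)
class OrdinationResult:
    """PCoA embedding: coordinates for positive axes, full eigenvalue list."""

    sample_ids: list
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # per positive axis
    n_negative_eigenvalues: int = 0

    def coordinates_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(d: DistanceMatrix, eps: float = 1e-10) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centres -d^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their (positive) eigenvalues. Negative eigenvalues —
    inevitable for semi-metric dissimilarities like Bray-Curtis — are
    reported as-is, with no Lingoes/Cailliez correction; proportion
    explained is taken relative to the sum of positive eigenvalues.
    """
    n = len(d.sample_ids)
    a = -0.5 * d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    g = (g + g.T) / 2.0
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    scale = max(abs(vals[0]), 1.0) if n else 1.0
    pos = vals > eps * scale
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    pos_sum = vals[pos].sum()
    prop = vals[pos] / pos_sum if pos_sum > 0 else np.zeros(int(pos.sum()))
    n_neg = int((vals < -eps * scale).sum())
    return OrdinationResult(
        sample_ids=list(d.sample_ids),
        coordinates=coords,
        eigenvalues=vals,
        proportion_explained=prop,
        n_negative_eigenvalues=n_neg,
    )


@dataclass(frozen=True)
class ControlProximityReport:
    """Per-specimen distance to the matched extraction blank.

    ``per_specimen`` holds one row per specimen with
    ``d_to_matched_control`` and ``flag_low_biomass_suspect``; ``summary``
    the mean +/- SEM for the flagged subset and for all specimens.
    """

    per_specimen: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def flagged(self) -> list:
        col = self.per_specimen["flag_low_biomass_suspect"]
        return self.per_specimen.index[col].tolist()


def _mean_sem(values: np.ndarray) -> tuple:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return float("nan"), float("nan")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return mean, sem


def control_proximity(table: FeatureTable, metadata: SampleMetadata,
                      k: int = None, threshold: float = None) -> ControlProximityReport:
    """Bray-Curtis proximity of each specimen to its replicate's blank.

    Flags low-biomass suspects either as the ``k`` specimens closest to
    their matched control (count rule) or as those below a dissimilarity
    ``threshold``. Exactly one rule must be given. A replicate with several
    controls uses the mean distance to them.
    """
    if (k is None) == (threshold is None):
        raise ValidationError("specify exactly one of k= or threshold=")
    metadata.check_paired(table, require_controls=True)
    md = metadata.data.loc[table.sample_ids]
    dm = bray_curtis(table)
    specs = md.index[md["role"] == "specimen"].tolist()
    rows = []
    for s in specs:
        rep = md.loc[s, "replicate"]
        ctrls = md.index[(md["role"] == "negative_control") & (md["replicate"] == rep)]
        dists = [dm.between(s, c) for c in ctrls]
        rows.append(
            {
                "sample_id": s,
                "replicate": rep,
                "d_to_matched_control": float(np.mean(dists)),
            }
        )
    per = pd.DataFrame(rows).set_index("sample_id")
    d = per["d_to_matched_control"]
    if k is not None:
        if not 0 < k <= len(per):
            raise ValidationError(f"k must be in 1..{len(per)}")
        # stable tie-break: distance, then sample order
        order = d.reset_index().sort_values(
            ["d_to_matched_control", "sample_id"], kind="stable"
        )["sample_id"]
        flagged = set(order.head(k))
        per["flag_low_biomass_suspect"] = [s in flagged for s in per.index]
        rule = {"rule": "count", "k": k}
    else:
        per["flag_low_biomass_suspect"] = (d < threshold).to_numpy()
        rule = {"rule": "threshold", "threshold": threshold}
    m_all, sem_all = _mean_sem(d.to_numpy())
    flagged_d = d[per["flag_low_biomass_suspect"]].to_numpy()
    m_fl, sem_fl = _mean_sem(flagged_d)
    summary = {
        **rule,
        "n_specimens": int(len(per)),
        "n_flagged": int(per["flag_low_biomass_suspect"].sum()),
        "mean_flagged": m_fl,
        "sem_flagged": sem_fl,
        "mean_all": m_all,
        "sem_all": sem_all,
    }
    return ControlProximityReport(per_specimen=per, summary=summary)
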