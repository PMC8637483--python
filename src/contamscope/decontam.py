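"""Contaminant classification for low-biomass amplicon tables.

Two classifiers are provided. The *major-contaminant* rule flags an ASV when
it is prevalent among specimens (present in at least a fraction ``tau`` of
them, default 0.8) **and** its mean abundance across the negative controls
strictly exceeds its mean abundance across the specimens; abundance is
either relative (per-sample proportions) or raw read counts. The
*prevalence rule* is the simplified blank-prevalence criterion popularised
by reagent-decontamination packages: at the default 0.5 threshold an ASV is
flagged when it is present in a higher fraction of negative controls than
of specimens; other thresholds shift the decision boundary monotonically on
``P_ctrl / (P_ctrl + P_spec)``.

Both produce a :class:`ContaminantReport` carrying the per-taxon evidence,
so classifications can be compared and the removal step logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import (
    FeatureTable,
    SampleMetadata,
    ValidationError,
    relative_abundance,
)

__all__ = [
    "ContaminantReport",
    "classify_major_contaminants",
    "classify_prevalence_rule",
    "compare_classifications",
    "remove_contaminants",
]

FLAG_COLUMNS = ("flag_major_relative", "flag_major_raw", "flag_prevalence_rule")


@dataclass(frozen=True)
class ContaminantReport:
    """Per-taxon contaminant evidence and classification flags.

    ``evidence`` has one row per taxon with columns
    ``prevalence_specimens``, ``prevalence_controls``,
    ``mean_abund_controls``, ``mean_abund_specimens`` and whichever
    ``flag_*`` columns the producing classifier set. Rows are sorted by
    ``mean_abund_controls`` descending.
    """

    evidence: pd.DataFrame
    thresholds: dict = field(default_factory=dict)
    mode: str = "relative"

    def __post_init__(self):
        ev = self.evidence
        if ev["prevalence_specimens"].min() < 0 or ev["prevalence_specimens"].max() > 1:
            raise ValidationError("prevalence_specimens outside [0, 1]")
        if (ev[["mean_abund_controls", "mean_abund_specimens"]].to_numpy() < 0).any():
            raise ValidationError("abundance means must be non-negative")

    def flagged(self, which: str) -> list:
        if which not in self.evidence.columns:
            raise ValidationError(f"no flag column {which!r} in report")
        col = self.evidence[which]
        return self.evidence.index[col.astype(bool)].tolist()

    @property
    def taxon_ids(self) -> list:
        return self.evidence.index.tolist()

    def to_tsv(self, path) -> None:
        out = self.evidence.copy()
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "thresholds": dict(self.thresholds),
            "n_taxa": int(len(self.evidence)),
            "n_flagged": {
                c: int(self.evidence[c].sum())
                for c in self.evidence.columns
                if c.startswith("flag_")
            },
        }


def _split_roles(table: FeatureTable, metadata: SampleMetadata):
    metadata.check_paired(table)
    md = metadata.data.loc[table.sample_ids]
    spec = md.index[md["role"] == "specimen"].tolist()
    ctrl = md.index[md["role"] == "negative_control"].tolist()
    if not ctrl:
        raise ValidationError(
            "no negative controls among samples: control-based classification "
            "is undefined"
        )
    if not spec:
        raise ValidationError("no specimens among samples")
    return spec, ctrl


def _evidence_frame(table: FeatureTable, spec, ctrl, mode: str) -> pd.DataFrame:
    counts = table.data
    present = counts > 0
    prev_spec = present[spec].mean(axis=1)
    prev_ctrl = present[ctrl].mean(axis=1)
    if mode == "relative":
        comp = relative_abundance(table).data
        abund = comp
    elif mode == "raw":
        abund = counts.astype(float)
    else:
        raise ValidationError(f"unknown mode {mode!r}; expected 'relative' or 'raw'")
    # zeros count toward the means: absent taxa dilute the group average
    mean_ctrl = abund[ctrl].mean(axis=1)
    mean_spec = abund[spec].mean(axis=1)
    return pd.DataFrame(
        {
            "prevalence_specimens": prev_spec,
            "prevalence_controls": prev_ctrl,
            "mean_abund_controls": mean_ctrl,
            "mean_abund_specimens": mean_spec,
        }
    )


def _exact_enrichment(table: FeatureTable, spec, ctrl, mode: str) -> pd.Series:
    """Exact evaluation of mean_controls > mean_specimens.

    The strict inequality sits on a knife edge when the two means are
    mathematically equal, and float summation order can tip it either way.
    Comparing integer counts over a common denominator (the lcm of the
    sample totals in relative mode) makes the decision exact.
    """
    from math import lcm

    counts = table.data
    n_s, n_c = len(spec), len(ctrl)
    if mode == "relative":
        totals = {s: int(counts[s].sum()) for s in spec + ctrl}
        common = lcm(*totals.values())
        weight = {s: common // totals[s] for s in spec + ctrl}
    else:
        weight = {s: 1 for s in spec + ctrl}
    col = {s: i for i, s in enumerate(counts.columns)}
    arr = counts.to_numpy()
    w_ctrl = [(col[s], weight[s]) for s in ctrl]
    w_spec = [(col[s], weight[s]) for s in spec]
    out = []
    for row in arr:
        a = n_s * sum(int(row[j]) * w for j, w in w_ctrl)
        b = n_c * sum(int(row[j]) * w for j, w in w_spec)
        out.append(a > b)
    return pd.Series(out, index=counts.index)


def classify_major_contaminants(
    table: FeatureTable,
    metadata: SampleMetadata,
    mode: str = "relative",
    prevalence_threshold: float = 0.8,
    strict_prevalence: bool = False,
    prevalence_include_controls: bool = False,
) -> ContaminantReport:
    """Flag major contaminants: prevalent in specimens, enriched in blanks.

    A taxon is flagged when both hold:

    1. its presence fraction among specimens is >= ``prevalence_threshold``
       (``strict_prevalence`` switches the comparison to strict >);
    2. its mean abundance over negative controls strictly exceeds its mean
       abundance over specimens, in the requested ``mode`` (``relative``
       proportions or ``raw`` counts), with zeros counted in the means.

    ``prevalence_include_controls`` computes the prevalence over all
    sequenced libraries rather than specimens only.
    """
    spec, ctrl = _split_roles(table, metadata)
    ev = _evidence_frame(table, spec, ctrl, mode)
    if prevalence_include_controls:
        present = table.data > 0
        prev = present[spec + ctrl].mean(axis=1)
    else:
        prev = ev["prevalence_specimens"]
    if strict_prevalence:
        prevalent = prev > prevalence_threshold
    else:
        prevalent = prev >= prevalence_threshold
    enriched = _exact_enrichment(table, spec, ctrl, mode)
    flag_col = "flag_major_relative" if mode == "relative" else "flag_major_raw"
    ev[flag_col] = (prevalent & enriched).astype(bool)
    ev = ev.sort_values("mean_abund_controls", ascending=False, kind="stable")
    return ContaminantReport(
        evidence=ev,
        thresholds={
            "prevalence_threshold": prevalence_threshold,
            "strict_prevalence": strict_prevalence,
            "prevalence_include_controls": prevalence_include_controls,
        },
        mode=mode,
    )


def classify_prevalence_rule(
    table: FeatureTable,
    metadata: SampleMetadata,
    threshold: float = 0.5,
) -> ContaminantReport:
    """Blank-prevalence contaminant rule.

    At the default 0.5 threshold a taxon is flagged iff its presence
    fraction among negative controls exceeds its presence fraction among
    specimens. General thresholds flag when
    ``P_ctrl / (P_ctrl + P_spec) > threshold`` (a taxon absent everywhere is
    never flagged).

    This implements the prevalence *rule* as commonly described, not the
    score-based statistic of the original decontam package.
    """
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie in (0, 1)")
    spec, ctrl = _split_roles(table, metadata)
    # presence-based rule: raw-count evidence avoids the no-zero-total
    # precondition of the relative mode
    ev = _evidence_frame(table, spec, ctrl, "raw")
    p_c = ev["prevalence_controls"].to_numpy()
    p_s = ev["prevalence_specimens"].to_numpy()
    denom = p_c + p_s
    ratio = np.divide(p_c, denom, out=np.zeros_like(denom), where=denom > 0)
    ev["flag_prevalence_rule"] = ratio > threshold
    ev = ev.sort_values("mean_abund_controls", ascending=False, kind="stable")
    return ContaminantReport(
        evidence=ev,
        thresholds={"prevalence_rule_threshold": threshold},
        mode="raw",
    )


def compare_classifications(a: ContaminantReport, b: ContaminantReport,
                            flag_a: str = None, flag_b: str = None) -> dict:
    """Symmetric overlap summary of two contaminant classifications.

    Returns counts flagged by each, the intersection, and a per-taxon
    agreement table. The two reports must cover the same taxa.
    """
    if set(a.taxon_ids) != set(b.taxon_ids):
        raise ValidationError("reports cover different taxon sets")
    if flag_a is None:
        flag_a = _single_flag(a)
    if flag_b is None:
        flag_b = _single_flag(b)
    set_a = set(a.flagged(flag_a))
    set_b = set(b.flagged(flag_b))
    agreement = pd.DataFrame(
        {
            flag_a: [t in set_a for t in a.taxon_ids],
            flag_b: [t in set_b for t in a.taxon_ids],
        },
        index=a.taxon_ids,
    )
    return {
        "n_flagged_a": len(set_a),
        "n_flagged_b": len(set_b),
        "n_intersection": len(set_a & set_b),
        "n_union": len(set_a | set_b),
        "flag_a": flag_a,
        "flag_b": flag_b,
        "agreement": agreement,
    }


def _single_flag(report: ContaminantReport) -> str:
    flags = [c for c in report.evidence.columns if c.startswith("flag_")]
    if len(flags) != 1:
        raise ValidationError(
            f"ambiguous flag column, specify one of {flags}"
        )
    return flags[0]


def remove_contaminants(table: FeatureTable, report: ContaminantReport,
                        which: str) -> tuple:
    """Remove flagged taxa from every sample, controls included.

    Samples are never dropped. Returns the polished table and a removal log
    (one dict per removed taxon with its evidence row).
    """
    flagged = report.flagged(which)
    log = [
        {"taxon_id": t, **report.evidence.loc[t].to_dict()}
        for t in flagged
    ]
    if not flagged:
        return table, log
    present = [t for t in flagged if t in set(table.taxon_ids)]
    return table.drop_taxa(present), log
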