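"""Feature tables, sample metadata and taxonomy: containers, validation and I/O.

The central object is the :class:`FeatureTable`, a taxa-by-samples matrix of
non-negative integer read counts (an ASV table or a rank-aggregated table).
Every downstream stage — contaminant classification, diversity, differential
abundance — consumes only the types defined here, so validation happens once,
at the boundary.

TSV is the canonical on-disk format (first column taxon id, header row sample
ids); the BIOM 1.0 JSON schema is supported as an alternative interchange
format. Sample metadata and taxonomy are TSV keyed by sample id / taxon id.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "CompositionTable",
    "SampleMetadata",
    "TaxonomyTable",
    "RANKS",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "read_taxonomy",
    "relative_abundance",
    "filter_taxa_by_lineage",
    "aggregate_by_rank",
    "subset_samples",
]

#: Recognised taxonomic ranks, ordered from domain downward.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

ROLE_SPECIMEN = "specimen"
ROLE_CONTROL = "negative_control"
_VALID_ROLES = frozenset({ROLE_SPECIMEN, ROLE_CONTROL})


class ValidationError(ValueError):
    """Raised when an input table or metadata file violates an invariant."""


@dataclass(frozen=True)
class FeatureTable:
    """Taxa-by-samples matrix of non-negative integer read counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by taxon id, columns by sample id, integer dtype.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            # accept float input only if exactly integral
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                i, j = _first_offender(arr != np.floor(arr))
                raise ValidationError(
                    f"non-integer count at taxon {df.index[i]!r}, "
                    f"sample {df.columns[j]!r}: {arr[i, j]!r}"
                )
            object.__setattr__(self, "data", df.astype(np.int64))
            arr = self.data.to_numpy()
        if arr.size and arr.min() < 0:
            i, j = _first_offender(arr < 0)
            raise ValidationError(
                f"negative count at taxon {df.index[i]!r}, "
                f"sample {df.columns[j]!r}: {arr[i, j]}"
            )

    @property
    def taxon_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def drop_taxa(self, taxon_ids) -> "FeatureTable":
        return FeatureTable(self.data.drop(index=list(taxon_ids)))

    def select_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[:, list(sample_ids)])


def _first_offender(mask: np.ndarray) -> tuple:
    idx = np.argwhere(mask)
    return tuple(idx[0])


@dataclass(frozen=True)
class CompositionTable:
    """Relative abundances; each sample column sums to one."""

    data: pd.DataFrame

    def __post_init__(self):
        arr = self.data.to_numpy(dtype=float)
        if arr.size:
            if arr.min() < 0 or arr.max() > 1 + 1e-12:
                raise ValidationError("relative abundances must lie in [0, 1]")
            sums = arr.sum(axis=0)
            bad = np.abs(sums - 1.0) > 1e-9
            if bad.any():
                names = self.data.columns[bad].tolist()
                raise ValidationError(
                    f"sample columns do not sum to 1: {names}"
                )

    @property
    def taxon_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def proportions(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample design variables.

    Required columns: ``role`` (specimen / negative_control) and
    ``replicate`` (the collection-campaign / blood-donor code linking each
    specimen to its extraction blank). Optional study variables such as
    ``treatment``, ``timepoint_h``, ``infection`` and ``species`` are carried
    through untouched.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        for col in ("role", "replicate"):
            if col not in df.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        bad = set(df["role"]) - _VALID_ROLES
        if bad:
            raise ValidationError(f"unknown role values: {sorted(bad)}")

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    def specimens(self) -> list:
        return self.data.index[self.data["role"] == ROLE_SPECIMEN].tolist()

    def controls(self) -> list:
        return self.data.index[self.data["role"] == ROLE_CONTROL].tolist()

    def check_paired(self, table: FeatureTable, require_controls: bool = False):
        """Verify every table sample has exactly one metadata row.

        With ``require_controls`` additionally verify that every replicate
        holding a specimen also holds at least one negative control, the
        precondition for matched-control analyses.
        """
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        if require_controls:
            sub = self.data.loc[table.sample_ids]
            spec_reps = set(sub.loc[sub["role"] == ROLE_SPECIMEN, "replicate"])
            ctrl_reps = set(sub.loc[sub["role"] == ROLE_CONTROL, "replicate"])
            orphans = sorted(spec_reps - ctrl_reps)
            if orphans:
                raise ValidationError(
                    f"replicates without a negative control: {orphans}"
                )

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)])


@dataclass(frozen=True)
class TaxonomyTable:
    """Ranked lineages (domain…genus), possibly truncated at any rank.

    ``lineages`` maps taxon id to a list of rank labels ordered from domain
    downward; a lineage may stop early when deeper ranks were not assigned.
    """

    lineages: dict = field(default_factory=dict)

    def __post_init__(self):
        for tid, lin in self.lineages.items():
            if len(lin) > len(RANKS):
                raise ValidationError(
                    f"lineage for {tid!r} has more than {len(RANKS)} ranks"
                )

    def lineage(self, taxon_id) -> list:
        return self.lineages.get(taxon_id, [])

    def label_at(self, taxon_id, rank: str, fallback: bool = True):
        """Label of a taxon at ``rank``; optionally fall back to the deepest
        available label when the taxon is unannotated at that rank."""
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        lin = [x for x in self.lineage(taxon_id) if x]
        depth = RANKS.index(rank)
        if depth < len(lin):
            return lin[depth]
        if fallback and lin:
            return lin[-1]
        return None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(path, format: str = "tsv") -> FeatureTable:
    """Read a feature table from TSV or BIOM 1.0 JSON.

    TSV dialect: first column taxon id, header row sample ids, tab-separated
    integer counts. Duplicate ids, negative or non-integer counts are
    rejected with an error naming the offending row/column.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom":
        return _read_biom(path)
    raise ValidationError(f"unknown feature-table format {format!r}")


def _read_tsv(path) -> FeatureTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ValidationError(f"{path}: malformed header (need >=2 columns)")
    sample_ids = header[1:]
    seen = pd.Index(sample_ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate sample ids in header: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = sample_ids
    num = df.apply(pd.to_numeric, errors="coerce")
    if num.isna().to_numpy().any():
        i, j = _first_offender(num.isna().to_numpy())
        raise ValidationError(
            f"{path}: non-numeric count at taxon {df.index[i]!r}, "
            f"sample {df.columns[j]!r}: {df.iat[i, j]!r}"
        )
    return FeatureTable(num)


def write_feature_table(table: FeatureTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        out = table.data.copy()
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")
    elif format == "biom":
        _write_biom(table, path)
    else:
        raise ValidationError(f"unknown feature-table format {format!r}")


def _write_biom(table: FeatureTable, path) -> None:
    """Write the BIOM 1.0 JSON schema (sparse representation)."""
    arr = table.counts
    nz = np.argwhere(arr != 0)
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "contamscope",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": list(arr.shape),
        "rows": [{"id": str(t), "metadata": None} for t in table.taxon_ids],
        "columns": [{"id": str(s), "metadata": None} for s in table.sample_ids],
        "data": [[int(i), int(j), int(arr[i, j])] for i, j in nz],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _read_biom(path) -> FeatureTable:
    with open(path) as fh:
        doc = json.load(fh)
    shape = tuple(doc["shape"])
    rows = [r["id"] for r in doc["rows"]]
    cols = [c["id"] for c in doc["columns"]]
    arr = np.zeros(shape, dtype=np.int64)
    if doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            arr[i, j] = v
    else:
        arr[:] = np.asarray(doc["data"], dtype=np.int64)
    return FeatureTable(pd.DataFrame(arr, index=rows, columns=cols))


def read_metadata(path) -> SampleMetadata:
    """Read sample metadata TSV (first column sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    out = metadata.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyTable:
    """Read taxonomy TSV: taxon id + semicolon-separated ranked lineage."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate taxon ids: {dups}")
    col = df.columns[0]
    lineages = {
        tid: [p.strip() for p in str(lin).split(";") if p.strip()]
        for tid, lin in df[col].items()
    }
    return TaxonomyTable(lineages)


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon_id\tlineage\n")
        for tid, lin in taxonomy.lineages.items():
            fh.write(f"{tid}\t{';'.join(lin)}\n")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def relative_abundance(table: FeatureTable, drop_empty: bool = False) -> CompositionTable:
    """Convert counts to per-sample relative abundances.

    Samples with zero total reads are rejected (every diversity formula is
    undefined on them) unless ``drop_empty`` removes them.
    """
    totals = table.sample_totals()
    empty = totals[totals == 0].index.tolist()
    df = table.data
    if empty:
        if not drop_empty:
            raise ValidationError(
                f"zero-total samples (pass drop_empty=True to drop): {empty}"
            )
        df = df.drop(columns=empty)
        totals = totals.drop(index=empty)
    props = df.astype(float) / totals.to_numpy()
    return CompositionTable(props)


def filter_taxa_by_lineage(table: FeatureTable, taxonomy: TaxonomyTable,
                           exclude_terms) -> tuple:
    """Remove taxa whose lineage matches any exclusion term.

    Matching is a case-insensitive substring test against every rank label
    (the convention used to strip mitochondrial and chloroplast 16S hits
    from host-associated amplicon tables). Never drops samples.

    Returns
    -------
    (FeatureTable, list)
        The filtered table and the ids that were removed.
    """
    terms = [str(t).lower() for t in exclude_terms]
    if not terms:
        raise ValidationError("exclude_terms must be non-empty")
    removed = []
    for tid in table.taxon_ids:
        labels = [str(x).lower() for x in taxonomy.lineage(tid)]
        if any(term in lab for term in terms for lab in labels):
            removed.append(tid)
    if not removed:
        return table, []
    if len(removed) == len(table.taxon_ids):
        warnings.warn("lineage filter removed every taxon")
    return table.drop_taxa(removed), removed


def aggregate_by_rank(table: FeatureTable, taxonomy: TaxonomyTable,
                      rank: str = "genus") -> FeatureTable:
    """Sum rows by taxonomic label at ``rank``.

    Taxa unannotated at the requested rank are grouped under their deepest
    available label rather than dropped; taxa with no lineage at all go to
    ``"Unassigned"``. Per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = []
    for tid in table.taxon_ids:
        lab = taxonomy.label_at(tid, rank, fallback=True)
        labels.append(lab if lab is not None else "Unassigned")
    # deterministic output order: first appearance
    order = list(dict.fromkeys(labels))
    grouped = table.data.groupby(pd.Index(labels, name="taxon_id"), sort=False).sum()
    grouped = grouped.loc[order]
    return FeatureTable(grouped)


def subset_samples(table: FeatureTable, metadata: SampleMetadata, where: dict,
                   keep_controls: bool = False) -> FeatureTable:
    """Restrict sample columns by metadata predicate.

    ``where`` maps metadata field -> value or list of admissible values.
    With ``keep_controls`` every negative control is retained regardless of
    the predicate (controls-first reporting). Selecting zero specimens is an
    error.
    """
    metadata.check_paired(table)
    md = metadata.data.loc[table.sample_ids]
    mask = pd.Series(True, index=md.index)
    for field_name, value in where.items():
        if field_name not in md.columns:
            raise ValidationError(f"unknown metadata field {field_name!r}")
        values = value if isinstance(value, (list, tuple, set)) else [value]
        mask &= md[field_name].isin(list(values))
    selected = md.index[mask]
    n_specimens = (md.loc[selected, "role"] == ROLE_SPECIMEN).sum()
    if n_specimens == 0:
        raise ValidationError(f"predicate {where!r} selects zero specimens")
    if keep_controls:
        ctrl = md.index[md["role"] == ROLE_CONTROL]
        selected = selected.union(ctrl, sort=False)
    keep = [s for s in table.sample_ids if s in set(selected)]
    return table.select_samples(keep)
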