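"""Core containers and file I/O for amplicon count tables.

The analyses in this package start from a sample x OTU read-count matrix
(an integer table produced upstream by OTU clustering), a per-OTU taxonomy
table (seven-rank lineage strings) and a per-sample metadata table giving
the experimental factors of the grafting field trial: rootstock ``variety``
(eight rootstock genotypes plus ungrafted controls), ``location`` (the
replicate set, a spatial block in the field) and ``line`` (planting row).

Counts travel as :class:`CountMatrix`, a thin validated wrapper around a
samples-as-rows :class:`pandas.DataFrame`.  Two on-disk dialects are
supported: plain TSV (header row = feature ids, first column = sample ids)
and sparse BIOM v1 JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
UNIDENTIFIED = "unidentified"

#: coarseness index used to check that collapsing refines the input rank;
#: larger = finer.  "otu" is finer than any named rank.
_RANK_DEPTH = {rank: i for i, rank in enumerate(RANKS)}
_RANK_DEPTH["otu"] = len(RANKS)


class FormatError(ValueError):
    """A file violates the expected table format."""


class ValidationError(ValueError):
    """In-memory data violates a container invariant."""


def _check_unique(ids: Sequence, what: str) -> None:
    if len(set(ids)) != len(ids):
        counts = pd.Series(list(ids)).value_counts()
        dups = counts[counts > 1].index.tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


def _check_no_tabs(ids: Iterable, what: str) -> None:
    for i in ids:
        if "\t" in str(i):
            raise ValidationError(f"tab character in {what} {i!r}")


@dataclass
class CountMatrix:
    """Integer read counts, samples x features.

    Parameters
    ----------
    data:
        DataFrame with sample ids as the index and feature ids (OTUs or
        collapsed taxa) as columns; cells are non-negative integers.
    rank:
        What the features are: ``"otu"`` or a taxonomic rank such as
        ``"genus"`` or ``"order"``.
    """

    data: pd.DataFrame
    rank: str = "otu"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("data must be a DataFrame")
        if self.rank not in _RANK_DEPTH:
            raise ValidationError(f"unknown rank {self.rank!r}")
        _check_unique(list(self.data.index), "sample ids")
        _check_unique(list(self.data.columns), "feature ids")
        _check_no_tabs(self.data.index, "sample id")
        _check_no_tabs(self.data.columns, "feature id")
        values = self.data.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                if not np.allclose(values, np.round(values)):
                    bad = np.argwhere(values != np.round(values))[0]
                    raise ValidationError(
                        f"non-integer count at sample {self.data.index[bad[0]]!r}, "
                        f"feature {self.data.columns[bad[1]]!r}"
                    )
                values = values.astype(np.int64)
            if (values < 0).any():
                bad = np.argwhere(values < 0)[0]
                raise ValidationError(
                    f"negative count at sample {self.data.index[bad[0]]!r}, "
                    f"feature {self.data.columns[bad[1]]!r}"
                )
        self.data = pd.DataFrame(
            values.astype(np.int64).reshape(self.data.shape),
            index=self.data.index.astype(str),
            columns=self.data.columns.astype(str),
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as an (n_samples, n_features) int array (a copy)."""
        return self.data.to_numpy(dtype=np.int64, copy=True)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def select_samples(self, ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.data.loc[list(ids)], rank=self.rank)

    def select_features(self, ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.data[list(ids)], rank=self.rank)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.rank == other.rank and self.data.equals(other.data)


@dataclass
class SampleMetadata:
    """Per-sample experimental factors of the grafting trial.

    ``data`` is indexed by sample id with (at least) columns ``variety``,
    ``location`` and ``line``.  Declared level sets, when given, pin the
    admissible factor levels; otherwise they are inferred from the data.
    """

    data: pd.DataFrame
    variety_levels: tuple[str, ...] = field(default=())
    location_levels: tuple[str, ...] = field(default=())
    line_levels: tuple[str, ...] = field(default=())

    REQUIRED = ("variety", "location", "line")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"metadata missing column(s): {missing}")
        _check_unique(list(self.data.index), "sample ids")
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        for col in self.REQUIRED:
            self.data[col] = self.data[col].astype(str)
        for col, levels in (
            ("variety", self.variety_levels),
            ("location", self.location_levels),
            ("line", self.line_levels),
        ):
            if levels:
                unknown = set(self.data[col]) - set(levels)
                if unknown:
                    raise ValidationError(
                        f"unknown {col} level(s): {sorted(unknown)}"
                    )
        if not self.variety_levels:
            self.variety_levels = tuple(sorted(self.data["variety"].unique()))
        if not self.location_levels:
            self.location_levels = tuple(sorted(self.data["location"].unique()))
        if not self.line_levels:
            self.line_levels = tuple(sorted(self.data["line"].unique()))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def variety(self) -> pd.Series:
        return self.data["variety"]

    def location(self) -> pd.Series:
        return self.data["location"]

    def select_samples(self, ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(
            self.data.loc[list(ids)],
            variety_levels=self.variety_levels,
            location_levels=self.location_levels,
            line_levels=self.line_levels,
        )


@dataclass
class TaxonomyTable:
    """Feature id -> ranked lineage (kingdom ... genus).

    Unassigned ranks carry the sentinel ``"unidentified"``; once a rank is
    unassigned every lower rank must be as well.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.data.columns]
        if missing:
            raise FormatError(f"taxonomy missing rank column(s): {missing}")
        _check_unique(list(self.data.index), "feature ids")
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        for r in RANKS:
            self.data[r] = self.data[r].fillna(UNIDENTIFIED).astype(str)
            self.data.loc[self.data[r] == "", r] = UNIDENTIFIED
        arr = self.data[list(RANKS)].to_numpy()
        unassigned = arr == UNIDENTIFIED
        # once unidentified, stay unidentified at lower ranks
        bad = (~unassigned[:, 1:]) & unassigned[:, :-1]
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"feature {self.data.index[i]!r} assigned at {RANKS[j + 1]} "
                f"but unidentified at {RANKS[j]}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    def lineage(self, feature_id: str) -> dict[str, str]:
        return self.data.loc[feature_id, list(RANKS)].to_dict()

    def name_at(self, rank: str) -> pd.Series:
        """Collapsing bin name at ``rank`` for every feature.

        A feature unassigned at ``rank`` maps to
        ``"unidentified <deepest assigned name>"`` so that unassigned taxa
        are binned per parent lineage rather than pooled globally.
        """
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        names = self.data[rank].copy()
        depth = RANKS.index(rank)
        for fid in names.index[names == UNIDENTIFIED]:
            deepest = "root"
            for r in RANKS[:depth]:
                v = self.data.at[fid, r]
                if v != UNIDENTIFIED:
                    deepest = v
            names.at[fid] = f"{UNIDENTIFIED} {deepest}"
        return names

    def select_features(self, ids: Sequence[str]) -> "TaxonomyTable":
        return TaxonomyTable(self.data.loc[list(ids)])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _orient(df: pd.DataFrame, orientation: str, metadata_ids=None) -> pd.DataFrame:
    """Normalize a raw table to samples-as-rows.

    ``orientation`` is ``"samples-rows"``, ``"samples-columns"`` or
    ``"auto"``.  Auto-detection matches ``metadata_ids`` against both axes
    and transposes if the ids sit on the columns; without metadata it keeps
    rows-as-samples.
    """
    if orientation == "samples-columns":
        return df.T
    if orientation == "samples-rows":
        return df
    if orientation != "auto":
        raise ValueError(f"unknown orientation {orientation!r}")
    if metadata_ids is not None:
        ids = set(map(str, metadata_ids))
        row_hits = len(ids & set(map(str, df.index)))
        col_hits = len(ids & set(map(str, df.columns)))
        if col_hits > row_hits:
            return df.T
    return df


def read_count_table(
    path,
    dialect: str = "tsv",
    rank: str = "otu",
    orientation: str = "auto",
    metadata_ids=None,
) -> CountMatrix:
    """Read a count matrix from ``path``.

    ``dialect`` is ``"tsv"`` (header row = feature ids, first column =
    sample ids) or ``"biom-json"`` (sparse BIOM v1 JSON, where rows are
    observations/OTUs and columns are samples).
    """
    path = Path(path)
    if dialect == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        except Exception as exc:  # noqa: BLE001 - rewrap as format error
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        df.index = df.index.astype(str)
        num = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
        for col in df.columns:
            try:
                num[col] = pd.to_numeric(df[col])
            except ValueError as exc:
                raise FormatError(f"non-numeric cell in column {col!r}: {exc}") from exc
        vals = num.to_numpy()
        if vals.size and not np.array_equal(vals, np.round(vals)):
            i, j = np.argwhere(vals != np.round(vals))[0]
            raise FormatError(
                f"non-integer count at row {num.index[i]!r}, column {num.columns[j]!r}"
            )
        if vals.size and (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative count at row {num.index[i]!r}, column {num.columns[j]!r}"
            )
        num = num.astype(np.int64)
        num = _orient(num, orientation, metadata_ids)
        try:
            return CountMatrix(num, rank=rank)
        except ValidationError as exc:
            raise FormatError(str(exc)) from exc
    if dialect == "biom-json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        try:
            samples = [r["id"] for r in doc["columns"]]
            features = [r["id"] for r in doc["rows"]]
            shape = doc["shape"]
            mtype = doc.get("matrix_type", "sparse")
            data = doc["data"]
        except (KeyError, TypeError) as exc:
            raise FormatError(f"not a BIOM v1 JSON file: {path}") from exc
        if shape != [len(features), len(samples)]:
            raise FormatError("BIOM shape does not match row/column lists")
        dense = np.zeros((len(features), len(samples)))
        if mtype == "sparse":
            for i, j, v in data:
                dense[int(i), int(j)] = v
        else:
            dense = np.asarray(data, dtype=float)
        if dense.size and not np.array_equal(dense, np.round(dense)):
            raise FormatError(f"non-integer count in BIOM file {path}")
        if dense.size and (dense < 0).any():
            raise FormatError(f"negative count in BIOM file {path}")
        df = pd.DataFrame(dense.T.astype(np.int64), index=samples, columns=features)
        try:
            return CountMatrix(df, rank=rank)
        except ValidationError as exc:
            raise FormatError(str(exc)) from exc
    raise ValueError(f"unknown dialect {dialect!r}")


def write_count_table(matrix: CountMatrix, path, dialect: str = "tsv") -> None:
    """Write ``matrix`` to ``path``; the output re-reads to an equal matrix
    and is byte-stable for a fixed matrix and dialect."""
    path = Path(path)
    if dialect == "tsv":
        matrix.data.to_csv(path, sep="\t", index_label="sample_id")
        return
    if dialect == "biom-json":
        counts = matrix.counts.T  # BIOM rows are observations
        data = [
            [int(i), int(j), int(counts[i, j])]
            for i, j in np.argwhere(counts > 0)
        ]
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "graftmicrobe",
            "date": "1970-01-01T00:00:00",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [matrix.n_features, matrix.n_samples],
            "rows": [{"id": f, "metadata": None} for f in matrix.feature_ids],
            "columns": [{"id": s, "metadata": None} for s in matrix.sample_ids],
            "data": data,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, sort_keys=True)
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def read_sample_metadata(
    path,
    variety_levels: Sequence[str] = (),
    location_levels: Sequence[str] = (),
    line_levels: Sequence[str] = (),
) -> SampleMetadata:
    """Read a TSV with columns sample_id, variety, location, line."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError("metadata missing column(s): ['sample_id']")
    df = df.set_index("sample_id")
    return SampleMetadata(
        df,
        variety_levels=tuple(variety_levels),
        location_levels=tuple(location_levels),
        line_levels=tuple(line_levels),
    )


def write_sample_metadata(metadata: SampleMetadata, path) -> None:
    metadata.data.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> TaxonomyTable:
    """Read a TSV of (feature_id, semicolon-delimited lineage).

    Short lineages are padded with the ``unidentified`` sentinel.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["feature_id", "lineage"]:
        raise FormatError("taxonomy TSV must have columns feature_id, lineage")
    rows = {}
    for fid, lineage in zip(df["feature_id"], df["lineage"]):
        parts = [p.strip() for p in str(lineage).split(";")]
        parts = (parts + [UNIDENTIFIED] * len(RANKS))[: len(RANKS)]
        rows[fid] = parts
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    return TaxonomyTable(out)


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    lineages = taxonomy.data[list(RANKS)].agg(";".join, axis=1)
    pd.DataFrame({"feature_id": taxonomy.feature_ids, "lineage": lineages.values}).to_csv(
        path, sep="\t", index=False
    )


def write_result_table(table: pd.DataFrame, path) -> None:
    """Write a generic result table; round-trips through
    :func:`read_result_table`."""
    table.to_csv(path, sep="\t", index_label=table.index.name or "row")


def read_result_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignmentReport:
    dropped_samples: list[str]
    dropped_features: list[str]


def align(
    matrix: CountMatrix,
    metadata: SampleMetadata | None = None,
    taxonomy: TaxonomyTable | None = None,
) -> tuple[CountMatrix, SampleMetadata | None, TaxonomyTable | None, AlignmentReport]:
    """Restrict matrix/metadata/taxonomy to their shared sample and feature
    ids, preserving the matrix's ordering. Idempotent."""
    samples = list(matrix.sample_ids)
    features = list(matrix.feature_ids)
    dropped_samples: list[str] = []
    dropped_features: list[str] = []
    if metadata is not None:
        meta_ids = set(metadata.sample_ids)
        dropped_samples = [s for s in samples if s not in meta_ids]
        samples = [s for s in samples if s in meta_ids]
    if taxonomy is not None:
        tax_ids = set(taxonomy.feature_ids)
        dropped_features = [f for f in features if f not in tax_ids]
        features = [f for f in features if f in tax_ids]
    if not samples or not features:
        raise ValidationError("alignment leaves no shared samples or features")
    out_matrix = matrix.select_samples(samples).select_features(features)
    out_meta = metadata.select_samples(samples) if metadata is not None else None
    out_tax = taxonomy.select_features(features) if taxonomy is not None else None
    return out_matrix, out_meta, out_tax, AlignmentReport(dropped_samples, dropped_features)
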