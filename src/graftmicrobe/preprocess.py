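"""Preprocessing cascade from a raw OTU table to analysis-ready matrices.

The stages, in the fixed order the pipeline applies them:

1. per-sample low-abundance cell filter (cells below a fraction of the
   sample's total are zeroed — a guard against PCR/sequencing bleed-through),
2. rarefaction without replacement to a common depth, dropping samples
   whose total falls below the depth,
3. optional collapsing of OTUs to a named taxonomic rank,
4. occurrence filter keeping taxa present in at least a minimum number of
   samples.

Each stage is a pure function of a :class:`~graftmicrobe.data_model.CountMatrix`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    RANKS,
    _RANK_DEPTH,
    CountMatrix,
    TaxonomyTable,
    ValidationError,
)


@dataclass
class PreprocessConfig:
    """Knobs of the preprocessing cascade.

    cell_filter_fraction:
        cells with count < fraction x (sample total) are zeroed; 0.001 (0.1%)
        by default.
    rarefaction_depth:
        reads per sample after rarefaction; samples below it are discarded.
    occurrence_min_samples:
        minimum number of samples a taxon must occur in (nonzero) to be kept.
    collapse_rank:
        rank to collapse OTUs to ("genus", "order", ...) or None.
    """

    cell_filter_fraction: float = 0.001
    rarefaction_depth: int = 500
    occurrence_min_samples: int = 30
    collapse_rank: str | None = None
    keep_unidentified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.cell_filter_fraction < 1:
            raise ValueError("cell_filter_fraction must be in [0, 1)")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if self.occurrence_min_samples < 0:
            raise ValueError("occurrence_min_samples must be >= 0")
        if self.collapse_rank is not None and self.collapse_rank not in RANKS:
            raise ValueError(f"unknown collapse_rank {self.collapse_rank!r}")


def filter_low_abundance_cells(matrix: CountMatrix, fraction: float) -> CountMatrix:
    """Zero cells whose count is less than ``fraction`` of the sample total.

    The threshold is computed against each sample's total BEFORE any cell
    is zeroed (single pass), so the operation is exactly idempotent at a
    fixed fraction.  All-zero features are retained.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    counts = matrix.counts
    totals = counts.sum(axis=1, keepdims=True)
    thresholds = fraction * totals
    out = np.where((counts > 0) & (counts < thresholds), 0, counts)
    return CountMatrix(
        pd.DataFrame(out, index=matrix.sample_ids, columns=matrix.feature_ids),
        rank=matrix.rank,
    )


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # per-sample stream keyed on (master seed, stable hash of the id), so
    # dropping one sample never shifts another sample's subsample
    digest = hashlib.sha256(sample_id.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def rarefy(
    matrix: CountMatrix, depth: int, seed: int = 0
) -> tuple[CountMatrix, list[str]]:
    """Subsample each sample's reads, uniformly WITHOUT replacement, down to
    exactly ``depth``; samples with fewer than ``depth`` reads are dropped.

    Returns the rarefied matrix and the list of discarded sample ids.
    Reproducible given ``seed``; each sample has its own random stream
    derived from ``(seed, sample_id)``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    counts = matrix.counts
    totals = counts.sum(axis=1)
    kept_rows = []
    kept_ids = []
    discarded = []
    for i, sid in enumerate(matrix.sample_ids):
        if totals[i] < depth:
            discarded.append(sid)
            continue
        if totals[i] == depth:
            kept_rows.append(counts[i])
        else:
            rng = _sample_rng(seed, sid)
            kept_rows.append(rng.multivariate_hypergeometric(counts[i], depth))
        kept_ids.append(sid)
    if kept_rows:
        data = pd.DataFrame(
            np.asarray(kept_rows), index=kept_ids, columns=matrix.feature_ids
        )
    else:
        data = pd.DataFrame(
            np.zeros((0, matrix.n_features), dtype=np.int64),
            index=[],
            columns=matrix.feature_ids,
        )
    return CountMatrix(data, rank=matrix.rank), discarded


def collapse_to_rank(
    matrix: CountMatrix,
    taxonomy: TaxonomyTable,
    rank: str,
    keep_unidentified: bool = True,
) -> CountMatrix:
    """Sum features sharing the same lineage down to ``rank``.

    Features unassigned at ``rank`` are binned as
    ``"unidentified <deepest assigned name>"`` (one bin per parent lineage)
    or dropped when ``keep_unidentified`` is False.  Per-sample totals are
    conserved when unidentified bins are kept.  ``rank`` must strictly
    refine the matrix's current rank (e.g. otu -> genus, genus -> order).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if _RANK_DEPTH[rank] >= _RANK_DEPTH[matrix.rank]:
        raise ValueError(
            f"cannot collapse a {matrix.rank!r}-level matrix to {rank!r}: "
            "the target rank must be coarser than the input rank"
        )
    missing = set(matrix.feature_ids) - set(taxonomy.feature_ids)
    if missing:
        raise ValidationError(f"features without lineage: {sorted(missing)[:5]}")
    names = taxonomy.name_at(rank).loc[matrix.feature_ids]
    df = matrix.data.T.groupby(names.values, sort=True).sum().T
    if not keep_unidentified:
        keep = [c for c in df.columns if not c.startswith("unidentified")]
        df = df[keep]
    return CountMatrix(df, rank=rank)


def filter_by_occurrence(matrix: CountMatrix, min_samples: int) -> CountMatrix:
    """Keep features with a nonzero count in at least ``min_samples``
    samples; samples are untouched."""
    if min_samples < 0:
        raise ValueError("min_samples must be >= 0")
    occ = (matrix.data > 0).sum(axis=0)
    keep = occ.index[occ >= min_samples]
    return CountMatrix(matrix.data[list(keep)], rank=matrix.rank)


def to_relative_abundance(matrix: CountMatrix) -> pd.DataFrame:
    """Counts -> per-sample proportions (rows sum to 1)."""
    totals = matrix.data.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(f"zero-total sample(s): {list(zero)[:5]}")
    return matrix.data.div(totals, axis=0)


@dataclass
class PreprocessResult:
    matrix: CountMatrix
    discarded_samples: list[str] = field(default_factory=list)


def run_preprocess(
    matrix: CountMatrix,
    config: PreprocessConfig,
    taxonomy: TaxonomyTable | None = None,
) -> PreprocessResult:
    """Apply the full cascade in the fixed order:
    cell filter -> rarefy -> (collapse) -> occurrence filter."""
    m = filter_low_abundance_cells(matrix, config.cell_filter_fraction)
    m, discarded = rarefy(m, config.rarefaction_depth, seed=config.seed)
    if config.collapse_rank is not None:
        if taxonomy is None:
            raise ValueError("collapse_rank set but no taxonomy supplied")
        m = collapse_to_rank(
            m, taxonomy, config.collapse_rank, keep_unidentified=config.keep_unidentified
        )
    m = filter_by_occurrence(m, config.occurrence_min_samples)
    return PreprocessResult(matrix=m, discarded_samples=discarded)
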