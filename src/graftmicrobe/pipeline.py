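"""End-to-end orchestration: preprocessing, community tests and the
preference analysis, with TSV outputs and a run manifest.

A run takes a sample x OTU count table plus metadata and taxonomy (from
files or from the synthetic generator), applies the preprocessing cascade,
and writes tables mirroring the analyses of the field study: retained-
sample report, order- and genus-level composition summaries, PERMANOVA
tables on Raup-Crick dissimilarities, per-genus ANOVA tables and genus- and
OTU-level preference tables.  Every stochastic stage derives its stream
from the single master seed, so a rerun with the same inputs and seed
yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .community_stats import composition_summary, permanova, raup_crick, taxon_anova
from .data_model import (
    CountMatrix,
    SampleMetadata,
    TaxonomyTable,
    align,
    read_count_table,
    read_sample_metadata,
    read_taxonomy,
    write_result_table,
)
from .preference import preference_analysis, preference_report
from .preprocess import (
    PreprocessConfig,
    collapse_to_rank,
    filter_by_occurrence,
    filter_low_abundance_cells,
    rarefy,
    to_relative_abundance,
)


@dataclass
class PipelineConfig:
    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    permanova_terms: tuple[str, str] = ("variety", "location")
    permanova_n_perm: int = 10_000
    raup_crick_n_sim: int = 999
    preference_n_perm: int = 100_000
    preference_alpha: float = 0.05
    min_occurrence: int = 30
    out_dir: str = "results"
    seed: int = 0


def validate_inputs(
    matrix: CountMatrix, metadata: SampleMetadata, taxonomy: TaxonomyTable | None = None
) -> list[str]:
    """Cross-check ids and factor levels; returns a list of report lines
    (empty = consistent)."""
    report: list[str] = []
    meta_ids = set(metadata.sample_ids)
    unmatched = [s for s in matrix.sample_ids if s not in meta_ids]
    if unmatched:
        report.append(f"WARNING: {len(unmatched)} sample(s) without metadata: {unmatched[:10]}")
    orphan_meta = [s for s in metadata.sample_ids if s not in set(matrix.sample_ids)]
    if orphan_meta:
        report.append(
            f"WARNING: {len(orphan_meta)} metadata row(s) without counts: {orphan_meta[:10]}"
        )
    if taxonomy is not None:
        tax_ids = set(taxonomy.feature_ids)
        orphan = [f for f in matrix.feature_ids if f not in tax_ids]
        if orphan:
            report.append(f"WARNING: {len(orphan)} feature(s) without taxonomy: {orphan[:10]}")
    return report


def _config_hash(config: PipelineConfig) -> str:
    doc = json.dumps(
        {**config.__dict__, "preprocess": config.preprocess.__dict__}, sort_keys=True, default=str
    )
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    matrix: CountMatrix | None = None,
    metadata: SampleMetadata | None = None,
    taxonomy: TaxonomyTable | None = None,
) -> Path:
    """Run the whole analysis; returns the output directory.

    Inputs come either as in-memory objects or from the paths in
    ``config``.  Any stage failure is re-raised with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name: str, fn, *args, **kwargs):
        t0 = time.monotonic()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.append({"stage": name, "elapsed_s": round(time.monotonic() - t0, 3)})
        return result

    if matrix is None:
        matrix = stage("read_counts", read_count_table, config.counts_path)
    if metadata is None:
        metadata = stage("read_metadata", read_sample_metadata, config.metadata_path)
    if taxonomy is None and config.taxonomy_path:
        taxonomy = stage("read_taxonomy", read_taxonomy, config.taxonomy_path)

    matrix, metadata, taxonomy, rep = stage("align", align, matrix, metadata, taxonomy)

    pp = config.preprocess
    filtered = stage("cell_filter", filter_low_abundance_cells, matrix, pp.cell_filter_fraction)
    rarefied, discarded = stage("rarefy", rarefy, filtered, pp.rarefaction_depth, pp.seed or config.seed)
    metadata_kept = metadata.select_samples(rarefied.sample_ids)
    pd.DataFrame({"discarded_sample": discarded}).to_csv(
        out / "discarded_samples.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {
            "n_input_samples": [matrix.n_samples],
            "n_retained_samples": [rarefied.n_samples],
            "n_retained_features": [int((rarefied.data.sum(axis=0) > 0).sum())],
        }
    ).to_csv(out / "retention_report.tsv", sep="\t", index=False)

    rank_matrices: dict[str, CountMatrix] = {"otu": rarefied}
    if taxonomy is not None:
        for rank in ("genus", "order"):
            rank_matrices[rank] = stage(
                f"collapse_{rank}", collapse_to_rank, rarefied, taxonomy, rank
            )

    for rank in ("genus", "order"):
        if rank not in rank_matrices:
            continue
        m = rank_matrices[rank]
        stage(
            f"composition_{rank}",
            lambda m=m, rank=rank: write_result_table(
                composition_summary(m, metadata_kept), out / f"composition_{rank}.tsv"
            ),
        )
        dist = stage(
            f"raup_crick_{rank}",
            raup_crick,
            m,
            "null-model",
            config.raup_crick_n_sim,
            config.seed,
        )
        pd.DataFrame(dist.data, index=dist.ids, columns=dist.ids).to_csv(
            out / f"raup_crick_{rank}.tsv", sep="\t"
        )
        res = stage(
            f"permanova_{rank}",
            permanova,
            dist,
            metadata_kept,
            list(config.permanova_terms),
            config.permanova_n_perm,
            config.seed,
        )
        write_result_table(res.table, out / f"permanova_{rank}.tsv")

    if "genus" in rank_matrices:
        genus_kept = stage(
            "occurrence_filter_genus",
            filter_by_occurrence,
            rank_matrices["genus"],
            config.min_occurrence,
        )
        props = stage("relative_abundance", to_relative_abundance, rank_matrices["genus"])
        anova = stage("taxon_anova", taxon_anova, props[genus_kept.feature_ids], metadata_kept)
        write_result_table(anova, out / "anova_genus.tsv")

    for rank in ("genus", "otu"):
        if rank not in rank_matrices:
            continue
        pref = stage(
            f"preference_{rank}",
            preference_analysis,
            rank_matrices[rank],
            metadata_kept,
            config.preference_n_perm,
            config.seed,
            config.min_occurrence,
            config.preference_alpha,
        )
        write_result_table(pref.preference, out / f"preference_z_{rank}.tsv")
        write_result_table(pref.p_empirical, out / f"preference_p_{rank}.tsv")
        write_result_table(pref.significant, out / f"preference_significant_{rank}.tsv")
        report = preference_report(pref, taxonomy if rank == "otu" else None)
        report.to_csv(out / f"preference_report_{rank}.tsv", sep="\t", index=False)

    manifest = {
        "package": "graftmicrobe",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "dropped_samples_at_align": rep.dropped_samples,
        "dropped_features_at_align": rep.dropped_features,
        "discarded_low_depth_samples": discarded,
        "stages": log,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
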