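"""Synthetic field-experiment datasets.

Emulates the grafting trial's data-generating process well enough to
exercise every analysis stage: a crossed design of rootstock varieties x
replicate-set locations, compositional counts with taxon-specific baseline
abundances, multiplicative variety-preference and location effects,
Dirichlet-multinomial overdispersion and variable sequencing depth (a
configurable fraction of samples is forced below the rarefaction cutoff so
the sample-discard path is exercised).

Baseline relative abundances are log-normal and assigned to taxa in
decreasing order, so taxon ``t_001`` is always the most abundant and a
statement like "plant an 8-fold effect on taxon 10" refers to a taxon of
stable, moderate abundance across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .data_model import RANKS, UNIDENTIFIED, CountMatrix, SampleMetadata, TaxonomyTable

__all__ = ["SyntheticConfig", "generate_dataset", "null_config", "planted_config"]


@dataclass
class SyntheticConfig:
    """Parameters of the generator.

    Effects are ``(taxon_id, level, fold_change)`` triples, multiplicative
    on expected relative abundance before renormalization.  ``overdispersion``
    is the Dirichlet concentration: the realized composition of a sample is
    ``Dirichlet(overdispersion * expected)``, so smaller values mean noisier
    compositions (~50 is moderate for leaf amplicon data).  Sequencing depth
    is log-normal (median ``depth_mean``, log-sd ``depth_sd``); with
    probability ``low_depth_fraction`` a sample's depth is instead drawn
    uniformly below ``low_depth_below``, emulating failed libraries.
    """

    n_varieties: int = 9
    n_locations: int = 15
    samples_per_cell: int = 1
    n_taxa: int = 150
    baseline_log_mean_sd: float = 1.5
    preference_effects: list[tuple[str, str, float]] = field(default_factory=list)
    location_effects: list[tuple[str, str, float]] = field(default_factory=list)
    overdispersion: float = 50.0
    depth_mean: float = 2000.0
    depth_sd: float = 0.5
    low_depth_fraction: float = 0.07
    low_depth_below: int = 500
    unassigned_genus_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_varieties < 1 or self.n_locations < 1 or self.samples_per_cell < 1:
            raise ValueError("design dimensions must be >= 1")
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be > 0")
        if not 0 <= self.low_depth_fraction <= 1:
            raise ValueError("low_depth_fraction must be in [0, 1]")
        for name, effects in (
            ("preference_effects", self.preference_effects),
            ("location_effects", self.location_effects),
        ):
            for taxon, level, fold in effects:
                if fold <= 0:
                    raise ValueError(f"{name}: fold-change for ({taxon}, {level}) must be > 0")

    # -- level names -------------------------------------------------------
    def variety_names(self) -> list[str]:
        return ["ungrafted"] + [f"rootstock_{k:02d}" for k in range(1, self.n_varieties)]

    def location_names(self) -> list[str]:
        return [f"set_{k:02d}" for k in range(1, self.n_locations + 1)]

    def taxon_names(self) -> list[str]:
        return [f"t_{k:03d}" for k in range(1, self.n_taxa + 1)]

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["preference_effects"] = [list(e) for e in self.preference_effects]
        doc["location_effects"] = [list(e) for e in self.location_effects]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        doc["preference_effects"] = [tuple(e) for e in doc.get("preference_effects", [])]
        doc["location_effects"] = [tuple(e) for e in doc.get("location_effects", [])]
        return cls(**doc)


def null_config(**overrides) -> SyntheticConfig:
    """Config with no planted effects (drives the calibration suites)."""
    return SyntheticConfig(**overrides)


def planted_config(
    effects: list[tuple[str, str, float]], **overrides
) -> SyntheticConfig:
    """Config with the given (taxon, variety, fold) preference effects."""
    return SyntheticConfig(preference_effects=list(effects), **overrides)


def expected_composition(config: SyntheticConfig) -> pd.DataFrame:
    """Expected relative abundance per (variety, location) cell, taxa as
    columns — the closed-form target the Dirichlet-multinomial noise is
    centred on (used by the generator and by oracle tests)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    baseline = np.sort(rng.lognormal(0.0, config.baseline_log_mean_sd, config.n_taxa))[::-1]
    taxa = config.taxon_names()
    t_index = {t: k for k, t in enumerate(taxa)}
    varieties = config.variety_names()
    locations = config.location_names()
    rows = []
    index = []
    for v in varieties:
        for l in locations:
            w = baseline.copy()
            for taxon, level, fold in config.preference_effects:
                if level == v:
                    w[t_index[taxon]] *= fold
            for taxon, level, fold in config.location_effects:
                if level == l:
                    w[t_index[taxon]] *= fold
            rows.append(w / w.sum())
            index.append((v, l))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["variety", "location"]), columns=taxa
    )


def _taxonomy(config: SyntheticConfig, rng: np.random.Generator) -> TaxonomyTable:
    taxa = config.taxon_names()
    n_genera = max(1, config.n_taxa // 3)
    n_orders = min(10, n_genera)
    rows = {}
    unassigned = rng.random(config.n_taxa) < config.unassigned_genus_fraction
    for k, t in enumerate(taxa):
        genus = k % n_genera
        order = genus % n_orders
        lineage = {
            "kingdom": "Fungi",
            "phylum": f"Phylum_{order % 4 + 1:02d}",
            "class": f"Class_{order % 6 + 1:02d}",
            "order": f"Order_{order + 1:02d}",
            "family": f"Family_{genus % 20 + 1:02d}",
            "genus": f"Genus_{genus + 1:02d}",
        }
        if unassigned[k]:
            lineage["genus"] = UNIDENTIFIED
        rows[t] = [lineage[r] for r in RANKS]
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[CountMatrix, SampleMetadata, TaxonomyTable]:
    """Draw one synthetic dataset; byte-identical for a fixed config.

    Per sample with variety v and location l the expected composition is
    ``baseline_i * fold_pref(i, v) * fold_loc(i, l)`` renormalized; the
    realized composition is Dirichlet(overdispersion x expected) and counts
    are multinomial at the sample's depth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    tax_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    expected = expected_composition(config)
    varieties = config.variety_names()
    locations = config.location_names()
    n_lines = 3
    sets_per_line = max(1, config.n_locations // n_lines)

    sample_rows = []
    meta_rows = []
    sid = 0
    for l_idx, l in enumerate(locations):
        for v in varieties:
            for _ in range(config.samples_per_cell):
                sid += 1
                sample_id = f"S{sid:03d}"
                p = expected.loc[(v, l)].to_numpy()
                realized = rng.dirichlet(config.overdispersion * p)
                if rng.random() < config.low_depth_fraction:
                    depth = int(rng.integers(50, max(51, config.low_depth_below)))
                else:
                    depth = max(1, int(round(rng.lognormal(np.log(config.depth_mean), config.depth_sd))))
                counts = rng.multinomial(depth, realized)
                sample_rows.append((sample_id, counts))
                meta_rows.append(
                    {
                        "sample_id": sample_id,
                        "variety": v,
                        "location": l,
                        "line": f"line_{min(l_idx // sets_per_line, n_lines - 1) + 1}",
                    }
                )
    matrix = CountMatrix(
        pd.DataFrame(
            np.asarray([c for _, c in sample_rows]),
            index=[s for s, _ in sample_rows],
            columns=config.taxon_names(),
        ),
        rank="otu",
    )
    metadata = SampleMetadata(
        pd.DataFrame(meta_rows).set_index("sample_id"),
        variety_levels=tuple(varieties),
        location_levels=tuple(locations),
    )
    taxonomy = _taxonomy(config, tax_rng)
    return matrix, metadata, taxonomy
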