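"""Randomization-based host-genotype preference analysis.

For each taxon *i* and rootstock variety *j*, the preference index is the
z-score of the observed mean read count of *i* over the variety-*j* samples
against the permutation null obtained by shuffling the variety labels
across all samples::

    Preference(i, j) = [N_obs(i, j) - Mean(N_rand(i, j))] / SD(N_rand(i, j))

where ``N_obs(i, j)`` is the mean count of taxon *i* across the samples of
variety *j*, and the null moments are taken over label permutations (one
joint shuffle per iteration, shared by all taxa, preserving group sizes).
Significance is decided on the empirical upper-tail p-value
``(1 + #{permuted mean >= observed mean}) / (1 + n_perm)`` with a
Bonferroni correction over the variety conditions (m = number of
varieties) applied per taxon.  The z-scores are descriptive.

Counts should be rarefied beforehand so means are comparable across
samples; taxa occurring in fewer than ``min_occurrence`` samples are
excluded before testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CountMatrix, SampleMetadata, TaxonomyTable, ValidationError
from .preprocess import filter_by_occurrence

__all__ = ["observed_group_means", "preference_analysis", "preference_report", "PreferenceResult"]


def observed_group_means(matrix: CountMatrix, metadata: SampleMetadata) -> pd.DataFrame:
    """Taxon x variety matrix of mean read counts.

    Cell (i, j) is the arithmetic mean of taxon i's counts over the samples
    of variety j.  Every declared variety level must have at least one
    sample in the matrix.
    """
    ids = list(matrix.sample_ids)
    missing = set(ids) - set(metadata.sample_ids)
    if missing:
        raise ValidationError(f"samples without metadata: {sorted(missing)[:5]}")
    variety = metadata.data.loc[ids, "variety"]
    empty = [v for v in metadata.variety_levels if (variety == v).sum() == 0]
    if empty:
        raise ValidationError(f"variety level(s) with no samples: {empty}")
    means = matrix.data.groupby(variety.values).mean().T
    return means[list(metadata.variety_levels)]


@dataclass
class PreferenceResult:
    """Everything the preference analysis produced.

    All matrices are taxa x varieties DataFrames: observed group means,
    the permutation-null mean and SD of the group means, the z-score
    ``preference`` index, the empirical p and the Bonferroni significance
    flags.  Where the null SD is zero (a taxon constant across samples) the
    convention is preference = 0 and p = 1.
    """

    taxa: list[str]
    varieties: list[str]
    n_observed: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    preference: pd.DataFrame
    p_empirical: pd.DataFrame
    significant: pd.DataFrame
    n_permutations: int
    seed: int
    alpha: float
    m_comparisons: int
    tail: str = "upper"


def _group_boundaries(variety: pd.Series, levels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Sample order grouping varieties into contiguous blocks, plus the
    reduceat boundaries. Permuting sample order against fixed blocks is
    equivalent to shuffling the labels."""
    codes = pd.Categorical(variety, categories=levels).codes
    order = np.argsort(codes, kind="stable")
    sizes = np.bincount(codes, minlength=len(levels))
    bounds = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    return order, bounds


def preference_analysis(
    matrix: CountMatrix,
    metadata: SampleMetadata,
    n_perm: int = 100_000,
    seed: int = 0,
    min_occurrence: int = 30,
    alpha: float = 0.05,
    tail: str = "upper",
    chunk_size: int = 256,
) -> PreferenceResult:
    """Run the randomization preference test on every retained taxon.

    One label shuffle per iteration serves every taxon, preserving the
    cross-taxon dependence structure of the data.  ``tail="upper"``
    (default) tests for preference; ``tail="lower"`` for avoidance.  The
    null SD is the population (divide-by-B) standard deviation of the
    permuted group means.  Reproducible given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    kept = filter_by_occurrence(matrix, min_occurrence)
    levels = list(metadata.variety_levels)
    obs = observed_group_means(kept, metadata)  # taxa x varieties
    ids = list(kept.sample_ids)
    variety = metadata.data.loc[ids, "variety"]
    sizes = np.array([(variety == v).sum() for v in levels], dtype=np.int64)
    if (sizes < 1).any():
        raise ValidationError("every variety level needs at least one sample")

    x = kept.counts.astype(np.float64)  # samples x taxa
    n, t = x.shape
    v = len(levels)
    order, bounds = _group_boundaries(variety, levels)
    obs_arr = obs.to_numpy().T  # varieties x taxa

    rng = np.random.default_rng(seed)
    sum_ = np.zeros((v, t))
    sumsq = np.zeros((v, t))
    exceed = np.zeros((v, t))
    done = 0
    while done < n_perm:
        c = min(chunk_size, n_perm - done)
        # c permutations of the sample order; fixed contiguous blocks then
        # define the shuffled variety assignment
        perms = np.argsort(rng.random((c, n)), axis=1)
        gathered = x[perms]  # (c, n, t)
        group_sums = np.add.reduceat(gathered, bounds, axis=1)  # (c, v, t)
        group_means = group_sums / sizes[None, :, None]
        sum_ += group_means.sum(axis=0)
        sumsq += (group_means**2).sum(axis=0)
        if tail == "upper":
            exceed += (group_means >= obs_arr[None]).sum(axis=0)
        else:
            exceed += (group_means <= obs_arr[None]).sum(axis=0)
        done += c

    null_mean = sum_ / n_perm
    null_var = np.maximum(sumsq / n_perm - null_mean**2, 0.0)
    null_sd = np.sqrt(null_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null_sd > 0, (obs_arr - null_mean) / np.where(null_sd > 0, null_sd, 1.0), 0.0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    p = np.where(null_sd > 0, p, 1.0)
    m = v
    signif = p < alpha / m

    def as_df(a: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(a.T, index=obs.index, columns=levels)

    return PreferenceResult(
        taxa=list(obs.index),
        varieties=levels,
        n_observed=obs,
        null_mean=as_df(null_mean),
        null_sd=as_df(null_sd),
        preference=as_df(z),
        p_empirical=as_df(p),
        significant=as_df(signif),
        n_permutations=n_perm,
        seed=seed,
        alpha=alpha,
        m_comparisons=m,
        tail=tail,
    )


def preference_report(
    result: PreferenceResult, taxonomy: TaxonomyTable | None = None
) -> pd.DataFrame:
    """Flat report of significant (taxon, variety) pairs, sorted by p.

    One row per significant pair with the preference z-score, empirical p
    and, when a taxonomy is given, the lineage columns phylum...genus.
    """
    rows = []
    for taxon in result.taxa:
        for variety in result.varieties:
            if bool(result.significant.at[taxon, variety]):
                row = {
                    "taxon": taxon,
                    "preferred_variety": variety,
                    "preference": float(result.preference.at[taxon, variety]),
                    "p": float(result.p_empirical.at[taxon, variety]),
                }
                if taxonomy is not None and taxon in set(taxonomy.feature_ids):
                    lin = taxonomy.lineage(taxon)
                    for rank in ("phylum", "class", "order", "family", "genus"):
                        row[rank] = lin[rank]
                rows.append(row)
    cols = ["taxon", "preferred_variety", "preference", "p"]
    if taxonomy is not None:
        cols += ["phylum", "class", "order", "family", "genus"]
    if not rows:
        return pd.DataFrame(columns=cols)
    report = pd.DataFrame(rows)
    for c in cols:
        if c not in report.columns:
            report[c] = ""
    return report[cols].sort_values("p", kind="stable").reset_index(drop=True)
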