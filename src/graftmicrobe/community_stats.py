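"""Community-level statistics.

* :func:`raup_crick` — presence/absence beta-diversity expressed as the
  probability, under a null assembly model that fixes each sample's
  richness, of a null pair sharing more taxa than the observed pair.
* :func:`permanova` — sequential (order-of-entry) multi-term PERMANOVA on a
  distance matrix, pseudo-F and R^2 per term, permutation p-values.
* :func:`taxon_anova` — per-taxon two-way fixed-effects ANOVA of relative
  abundance on variety + location (sequential sums of squares, parametric p).
* :func:`diversity_curves` — per-sample rarefaction curves (exact
  hypergeometric expectation) and sample-accumulation curves.
* :func:`composition_summary` — per-variety pooled taxon proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom
from skbio import DistanceMatrix

from .data_model import CountMatrix, SampleMetadata, ValidationError

__all__ = [
    "raup_crick",
    "permanova",
    "PermanovaResult",
    "taxon_anova",
    "diversity_curves",
    "composition_summary",
]


# ---------------------------------------------------------------------------
# Raup-Crick
# ---------------------------------------------------------------------------


def _null_presence(
    richness: np.ndarray, weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One null community per sample: fixed richness, species drawn without
    replacement with probability proportional to ``weights``.

    Weighted sampling without replacement via the exponential-keys trick:
    the ``k`` smallest Exp(w_i) arrivals are a weighted draw.
    """
    n, s = len(richness), len(weights)
    keys = rng.exponential(size=(n, s)) / weights
    order = np.argsort(keys, axis=1)
    presence = np.zeros((n, s), dtype=np.float64)
    for i in range(n):
        presence[i, order[i, : richness[i]]] = 1.0
    return presence


def raup_crick(
    matrix: CountMatrix,
    variant: str = "null-model",
    n_sim: int = 999,
    seed: int = 0,
) -> DistanceMatrix:
    """Raup-Crick dissimilarity between all sample pairs.

    The matrix is binarized internally (presence = count > 0).  For a pair
    with observed shared richness ``x`` the dissimilarity is::

        (#{null shared > x} + 0.5 * #{null shared = x}) / n_sim

    under a null that fixes each sample's richness and draws species with
    probability proportional to their occurrence frequency across samples
    (``variant="null-model"``).  ``variant="analytic"`` replaces the
    simulation with the equiprobable-species hypergeometric closed form:
    ``P(X > x) + 0.5 P(X = x)`` with ``X ~ Hypergeom(S, n1, n2)`` over the
    ``S`` species present in the matrix.  Values lie in [0, 1]; ~0.5 means
    "as shared as chance", small values mean more shared than chance.
    """
    presence = (matrix.counts > 0)
    richness = presence.sum(axis=1)
    if (richness == 0).any():
        bad = [matrix.sample_ids[i] for i in np.flatnonzero(richness == 0)]
        raise ValidationError(f"zero-richness sample(s): {bad[:5]}")
    n = matrix.n_samples

    if variant == "analytic":
        # equiprobable pool = every taxon column of the matrix
        s_pool = presence.shape[1]
        presence = presence.astype(np.float64)
        shared_obs = presence @ presence.T
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                x = shared_obs[i, j]
                dist = hypergeom(s_pool, richness[i], richness[j])
                vals[i, j] = vals[j, i] = dist.sf(x) + 0.5 * dist.pmf(x)
        return DistanceMatrix(vals, ids=matrix.sample_ids)

    if variant != "null-model":
        raise ValueError(f"unknown variant {variant!r}")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    # zero-occurrence taxa can never be drawn under the weighted null
    presence = presence[:, presence.any(axis=0)].astype(np.float64)
    shared_obs = presence @ presence.T
    rng = np.random.default_rng(seed)
    weights = presence.sum(axis=0)  # occurrence frequency across samples
    gt = np.zeros((n, n))
    eq = np.zeros((n, n))
    for _ in range(n_sim):
        null = _null_presence(richness, weights, rng)
        shared_null = null @ null.T
        gt += shared_null > shared_obs
        eq += shared_null == shared_obs
    vals = (gt + 0.5 * eq) / n_sim
    np.fill_diagonal(vals, 0.0)
    # enforce exact symmetry against floating noise
    vals = (vals + vals.T) / 2.0
    return DistanceMatrix(vals, ids=matrix.sample_ids)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table.

    ``table`` has one row per term plus a Residual and Total row with
    columns df, SS, pseudo_F, R2, p.
    """

    table: pd.DataFrame
    n_permutations: int
    seed: int

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    centered = a - a.mean(axis=0, keepdims=True) - a.mean(axis=1, keepdims=True) + a.mean()
    return centered


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def permanova(
    dist: DistanceMatrix,
    metadata: SampleMetadata,
    terms: list[str] = ["variety", "location"],
    n_perm: int = 10000,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential sums of squares.

    The distance matrix is Gower-centered; each term's SS is the increment
    in explained trace when the term's dummy block enters the model after
    the preceding terms (order of entry = order of ``terms``).  Pseudo-F
    uses the residual mean square of the full model.  p-values come from
    free permutation of sample labels, ``p = (1 + #{F* >= F}) / (1 + n_perm)``.
    """
    if not terms:
        raise ValueError("terms must be non-empty")
    ids = list(dist.ids)
    missing = set(ids) - set(metadata.sample_ids)
    if missing:
        raise ValidationError(f"samples without metadata: {sorted(missing)[:5]}")
    meta = metadata.data.loc[ids]
    n = len(ids)
    g = _gower_center(np.asarray(dist.data, dtype=float))
    ss_total = np.trace(g)
    if ss_total <= 0:
        raise ValidationError("degenerate distances: total sum of squares is zero")

    # nested hat matrices: intercept, +term1, +term1+term2, ...
    blocks = [np.ones((n, 1))]
    dfs = []
    hats = [_hat(np.ones((n, 1)))]
    rank_prev = 1
    for term in terms:
        if term not in meta.columns:
            raise ValueError(f"unknown term {term!r}")
        dummies = pd.get_dummies(meta[term], dtype=float).to_numpy()
        blocks.append(dummies)
        x = np.hstack(blocks)
        hats.append(_hat(x))
        rank = np.linalg.matrix_rank(x)
        dfs.append(rank - rank_prev)
        rank_prev = rank
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValidationError("no residual degrees of freedom")

    def term_ss(gmat: np.ndarray) -> np.ndarray:
        explained = np.array([np.sum(h * gmat) for h in hats])  # tr(H G)
        return np.diff(explained)

    ss_terms = term_ss(g)
    ss_res = ss_total - ss_terms.sum() - np.sum(hats[0] * g)
    f_obs = (ss_terms / np.array(dfs)) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        gp = g[np.ix_(p, p)]
        ss_t = term_ss(gp)
        ss_r = ss_total - ss_t.sum() - np.sum(hats[0] * gp)
        f_perm = (ss_t / np.array(dfs)) / (ss_r / df_res)
        exceed += f_perm >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for k, term in enumerate(terms):
        rows.append(
            {
                "df": dfs[k],
                "SS": ss_terms[k],
                "pseudo_F": f_obs[k],
                "R2": ss_terms[k] / ss_total,
                "p": pvals[k],
            }
        )
    rows.append(
        {"df": df_res, "SS": ss_res, "pseudo_F": np.nan, "R2": ss_res / ss_total, "p": np.nan}
    )
    rows.append({"df": n - 1, "SS": ss_total, "pseudo_F": np.nan, "R2": 1.0, "p": np.nan})
    table = pd.DataFrame(rows, index=[*terms, "Residual", "Total"])
    return PermanovaResult(table=table, n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# per-taxon ANOVA
# ---------------------------------------------------------------------------


def taxon_anova(
    props: pd.DataFrame,
    metadata: SampleMetadata,
    min_occurrence: int = 0,
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA (variety + location, no interaction) of
    each taxon's relative abundance, sequential SS with variety first.

    ``props`` is a samples x taxa proportion table.  Taxa occurring
    (nonzero) in fewer than ``min_occurrence`` samples are dropped.  A taxon
    with a constant response gets NaN F/p and ``degenerate=True`` rather
    than an exception.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    ids = list(props.index)
    meta = metadata.data.loc[ids]
    occ = (props > 0).sum(axis=0)
    taxa = [t for t in props.columns if occ[t] >= min_occurrence]
    rows = []
    for taxon in taxa:
        frame = pd.DataFrame(
            {
                "y": props[taxon].to_numpy(dtype=float),
                "variety": meta["variety"].to_numpy(),
                "location": meta["location"].to_numpy(),
            }
        )
        if frame["y"].nunique() <= 1:
            rows.append(
                {
                    "taxon": taxon,
                    "variety_df": np.nan,
                    "variety_F": np.nan,
                    "variety_p": np.nan,
                    "location_df": np.nan,
                    "location_F": np.nan,
                    "location_p": np.nan,
                    "residual_df": np.nan,
                    "degenerate": True,
                }
            )
            continue
        fit = ols("y ~ C(variety) + C(location)", data=frame).fit()
        tab = sm.stats.anova_lm(fit, typ=1)
        rows.append(
            {
                "taxon": taxon,
                "variety_df": int(tab.loc["C(variety)", "df"]),
                "variety_F": float(tab.loc["C(variety)", "F"]),
                "variety_p": float(tab.loc["C(variety)", "PR(>F)"]),
                "location_df": int(tab.loc["C(location)", "df"]),
                "location_F": float(tab.loc["C(location)", "F"]),
                "location_p": float(tab.loc["C(location)", "PR(>F)"]),
                "residual_df": int(tab.loc["Residual", "df"]),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows).set_index("taxon")


# ---------------------------------------------------------------------------
# Diversity curves
# ---------------------------------------------------------------------------


def _expected_richness(counts: np.ndarray, depth: int) -> float:
    """Exact expected number of taxa observed in a uniform without-replacement
    subsample of ``depth`` reads: sum_i [1 - C(N - n_i, d) / C(N, d)]."""
    n_total = counts.sum()
    nz = counts[counts > 0]
    # log C(N - n_i, d) - log C(N, d), guarded where N - n_i < d
    with np.errstate(invalid="ignore"):
        log_miss = (
            gammaln(n_total - nz + 1)
            - gammaln(depth + 1)
            - gammaln(n_total - nz - depth + 1)
            - (gammaln(n_total + 1) - gammaln(depth + 1) - gammaln(n_total - depth + 1))
        )
    p_miss = np.where(n_total - nz < depth, 0.0, np.exp(log_miss))
    return float(np.sum(1.0 - p_miss))


def diversity_curves(
    matrix: CountMatrix,
    step: int = 50,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rarefaction and sample-accumulation curves.

    Returns ``(rarefaction, accumulation)``: the first is a long table
    (sample_id, depth, expected_richness) with the exact hypergeometric
    expectation at depths ``step, 2*step, ..., total``; the second gives the
    mean (+SD) cumulative richness over ``n_perm`` random sample orderings.
    """
    counts = matrix.counts
    totals = counts.sum(axis=1)
    if step < 1 or (totals.size and step > totals.min()):
        raise ValueError("step must be >= 1 and <= the smallest sample total")
    rows = []
    for i, sid in enumerate(matrix.sample_ids):
        depths = list(range(step, int(totals[i]) + 1, step))
        if not depths or depths[-1] != totals[i]:
            depths.append(int(totals[i]))
        for d in depths:
            rows.append(
                {
                    "sample_id": sid,
                    "depth": d,
                    "expected_richness": _expected_richness(counts[i], d),
                }
            )
    rarefaction = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    n = matrix.n_samples
    presence = counts > 0
    rich = np.zeros((n_perm, n))
    for b in range(n_perm):
        order = rng.permutation(n)
        seen = np.zeros(matrix.n_features, dtype=bool)
        for k, idx in enumerate(order):
            seen |= presence[idx]
            rich[b, k] = seen.sum()
    accumulation = pd.DataFrame(
        {
            "n_samples": np.arange(1, n + 1),
            "mean_richness": rich.mean(axis=0),
            "sd_richness": rich.std(axis=0, ddof=0),
        }
    )
    return rarefaction, accumulation


# ---------------------------------------------------------------------------
# Composition summaries
# ---------------------------------------------------------------------------


def composition_summary(matrix: CountMatrix, metadata: SampleMetadata) -> pd.DataFrame:
    """Per-variety taxon proportions.

    For each variety the ``pooled`` proportion of a taxon is (its reads
    summed over that variety's samples) / (all reads of those samples); the
    ``mean`` column is the average of per-sample proportions.  Long format:
    (variety, taxon, pooled_proportion, mean_proportion).
    """
    ids = list(matrix.sample_ids)
    variety = metadata.data.loc[ids, "variety"]
    rows = []
    for v, sub in matrix.data.groupby(variety.values):
        total = sub.to_numpy().sum()
        pooled = sub.sum(axis=0) / total
        per_sample = sub.div(sub.sum(axis=1), axis=0).mean(axis=0)
        for taxon in matrix.feature_ids:
            rows.append(
                {
                    "variety": v,
                    "taxon": taxon,
                    "pooled_proportion": float(pooled[taxon]),
                    "mean_proportion": float(per_sample[taxon]),
                }
            )
    return pd.DataFrame(rows)
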