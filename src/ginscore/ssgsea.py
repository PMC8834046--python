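"""Single-sample gene-set enrichment (ssGSEA) — the GIN score engine.

For each sample, expression values are rank-normalized (ascending, ties
averaged).  Genes are then walked in decreasing rank order; in-set steps are
weighted by ``rank ** alpha`` (normalized to sum to one over the set genes
present), out-of-set steps are uniform ``1/(N - m)``.  The enrichment score
(ES) is the sum over all positions of the difference between the two running
empirical CDFs — the integrated-difference (Barbie-style) statistic, not the
max-deviation GSEA statistic.  ``alpha`` defaults to 0.25.

The ES of a sample depends only on that sample's ranks: it is invariant to
any strictly increasing per-sample transform, and (unnormalized) independent
of which other samples are in the matrix.  The optional ``normalize`` flag
divides all scores by their range across the table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .exprio import MIN_SET_OVERLAP, GeneSet, match_genes

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25


class SsgseaError(ValueError):
    pass


@dataclass
class RankedSample:
    """Tie-averaged ascending ranks (1 = lowest expression) of one sample."""

    sample_id: str
    ranks: pd.Series  # gene id -> rank


@dataclass
class ScoreTable:
    """Per-sample enrichment scores of one gene set."""

    gene_set_name: str
    scores: pd.Series  # sample id -> ES
    alpha: float
    normalized: bool

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


def rank_normalize_sample(expr_column: pd.Series, sample_id: str = "") -> RankedSample:
    """Ascending, tie-averaged ranks of one sample's expression values."""
    values = expr_column.to_numpy(dtype=float)
    if values.size < 2:
        raise SsgseaError("need >= 2 genes to rank")
    if not np.isfinite(values).all():
        raise SsgseaError("non-finite expression values")
    if np.ptp(values) == 0:
        raise SsgseaError("all expression values identical; ranking degenerate")
    ranks = rankdata(values, method="average")
    sid = sample_id or str(getattr(expr_column, "name", ""))
    return RankedSample(sid, pd.Series(ranks, index=expr_column.index))


def _walk_order(ranks: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices in walk order: decreasing rank, ties by ascending gene id."""
    return np.lexsort((gene_ids, -ranks))


def _es_from_ranks(
    ranks: np.ndarray, gene_ids: np.ndarray, in_set: np.ndarray, alpha: float
) -> float:
    """Integrated ECDF-difference ES from rank vector and set membership mask."""
    n = ranks.size
    m = int(in_set.sum())
    if m == 0:
        raise SsgseaError("no gene of the set is present in the ranked genes")
    if m == n:
        raise SsgseaError("gene set covers the entire gene universe")
    order = _walk_order(ranks, gene_ids)
    hit = in_set[order]
    w = np.zeros(n)
    w[hit] = ranks[order][hit] ** alpha
    w[hit] /= w[hit].sum()
    miss_step = 1.0 / (n - m)
    p_in = np.cumsum(w)
    p_out = np.cumsum(np.where(hit, 0.0, miss_step))
    return float((p_in - p_out).sum())


def enrichment_score_sample(
    ranked: RankedSample, gene_set: GeneSet, alpha: float = DEFAULT_ALPHA
) -> float:
    """ES of one gene set in one rank-normalized sample."""
    gene_ids = np.asarray(ranked.ranks.index.astype(str))
    in_set = np.isin(gene_ids, list(gene_set.genes))
    return _es_from_ranks(ranked.ranks.to_numpy(dtype=float), gene_ids, in_set, alpha)


def score_matrix(
    expr: pd.DataFrame,
    gene_set: GeneSet,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = False,
    min_overlap: float = MIN_SET_OVERLAP,
) -> ScoreTable:
    """ES of ``gene_set`` in every sample (column) of ``expr``.

    Requires at least ``min_overlap`` of the set's genes to be present in the
    matrix; missing genes are otherwise ignored.  With ``normalize=True`` all
    scores are divided by their range (max - min) across the table.
    """
    present, missing = match_genes(expr, gene_set)
    if len(present) < min_overlap * len(gene_set):
        raise SsgseaError(
            f"only {len(present)}/{len(gene_set)} genes of set {gene_set.name!r} present "
            f"(floor {min_overlap:.0%}); missing: {missing}"
        )
    if missing:
        logger.info(
            "set %s: %d/%d gene(s) absent from the matrix and ignored: %s",
            gene_set.name,
            len(missing),
            len(gene_set),
            missing,
        )
    gene_ids = np.asarray(expr.index.astype(str))
    in_set = np.isin(gene_ids, present)
    X = expr.to_numpy(dtype=float)
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if not np.isfinite(col).all():
            raise SsgseaError(f"sample {expr.columns[j]!r}: non-finite values")
        if np.ptp(col) == 0:
            raise SsgseaError(f"sample {expr.columns[j]!r}: constant expression")
        ranks = rankdata(col, method="average")
        scores[j] = _es_from_ranks(ranks, gene_ids, in_set, alpha)
    if normalize:
        rng = scores.max() - scores.min()
        if rng == 0:
            raise SsgseaError("cannot range-normalize: all scores identical")
        scores = scores / rng
    return ScoreTable(gene_set.name, pd.Series(scores, index=expr.columns), alpha, normalize)


class SsgseaScorer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: expression -> single-sample enrichment score.

    Follows the sklearn orientation (rows = samples, columns = genes); pass a
    DataFrame so gene symbols are available as column names.  ``transform``
    returns an ``(n_samples, 1)`` array of enrichment scores, so the scorer
    composes with sklearn pipelines; :func:`score_matrix` is the
    genes-x-samples functional equivalent.
    """

    def __init__(
        self,
        gene_set: GeneSet | None = None,
        alpha: float = DEFAULT_ALPHA,
        normalize: bool = False,
        min_overlap: float = MIN_SET_OVERLAP,
    ):
        self.gene_set = gene_set
        self.alpha = alpha
        self.normalize = normalize
        self.min_overlap = min_overlap

    def _check_set(self) -> GeneSet:
        if self.gene_set is None:
            raise SsgseaError("gene_set must be provided")
        return self.gene_set

    def fit(self, X: pd.DataFrame, y=None) -> "SsgseaScorer":
        gene_set = self._check_set()
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with gene symbols as columns")
        present, _ = match_genes(X.T, gene_set)
        if len(present) < self.min_overlap * len(gene_set):
            raise SsgseaError(
                f"only {len(present)}/{len(gene_set)} set genes present (floor "
                f"{self.min_overlap:.0%})"
            )
        self.genes_present_ = tuple(present)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        table = score_matrix(
            X.T,
            self._check_set(),
            alpha=self.alpha,
            normalize=self.normalize,
            min_overlap=self.min_overlap,
        )
        return table.scores.to_numpy()[:, None]
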