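"""Derive a genomic-instability gene signature from two cohorts.

Every gene is correlated (Pearson) with per-sample FGA in each cohort; the
signature is the set of genes whose correlation clears a threshold in *both*
cohorts.  A grid of thresholds (0.2, 0.3, 0.35, 0.4 by default) is swept to
audit how the overlap count shrinks, and a size window (10-50 genes) flags
selections outside the useful range for a single-sample enrichment score.

Only positively correlated genes are eligible by default (``r >= t``);
``absolute=True`` switches to ``|r| >= t``.  Selection is by effect size
only — no p-value screening or multiplicity correction is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exprio import GeneSet
from .seg import FgaValue

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.35
DEFAULT_GRID = (0.2, 0.3, 0.35, 0.4)
DEFAULT_SIZE_WINDOW = (10, 50)


class SignatureError(ValueError):
    pass


@dataclass
class CorrelationTable:
    """Per-gene Pearson correlation with FGA in one cohort."""

    cohort_id: str
    entries: pd.Series  # gene id -> r
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise SignatureError(f"cohort {self.cohort_id!r}: need >= 3 samples")
        if not np.isfinite(self.entries.to_numpy(dtype=float)).all():
            raise SignatureError(f"cohort {self.cohort_id!r}: non-finite correlation(s)")


@dataclass
class SignatureSelection:
    """A selected signature plus its threshold-sweep audit trail."""

    threshold: float
    genes: GeneSet
    sweep: dict[float, int]
    cohorts: tuple[str, str]


def _as_fga_series(fga) -> pd.Series:
    """Accept a Series, mapping, DataFrame with an ``fga`` column, or FgaValue iterable."""
    if isinstance(fga, pd.Series):
        return fga.astype(float)
    if isinstance(fga, pd.DataFrame):
        return fga["fga"].astype(float)
    if isinstance(fga, Mapping):
        return pd.Series(fga, dtype=float)
    values = list(fga)
    if values and isinstance(values[0], FgaValue):
        return pd.Series({v.sample_id: v.fga for v in values})
    raise TypeError("fga must be a Series, mapping, FGA table or iterable of FgaValue")


def compute_gene_fga_correlations(
    expr: pd.DataFrame, fga, cohort_id: str
) -> CorrelationTable:
    """Pearson r between each gene's expression and FGA across shared samples.

    Samples are intersected by id (dropped count logged).  Genes with zero
    variance across the shared samples are excluded with a logged count.
    """
    f = _as_fga_series(fga)
    shared = [s for s in expr.columns if s in set(f.index)]
    n_dropped = (expr.shape[1] - len(shared)) + (len(f) - len(shared))
    if n_dropped:
        logger.info(
            "cohort %s: %d sample(s) without both expression and FGA dropped",
            cohort_id,
            n_dropped,
        )
    if len(shared) < 3:
        raise SignatureError(
            f"cohort {cohort_id!r}: only {len(shared)} overlapping sample(s), need >= 3"
        )
    X = expr[shared].to_numpy(dtype=float)
    y = f.loc[shared].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise SignatureError(f"cohort {cohort_id!r}: FGA is constant across samples")

    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    x_ss = (Xc**2).sum(axis=1)
    nonconstant = x_ss > 0
    n_const = int((~nonconstant).sum())
    if n_const:
        logger.info("cohort %s: %d constant-expression gene(s) excluded", cohort_id, n_const)
    if not nonconstant.any():
        raise SignatureError(f"cohort {cohort_id!r}: all genes constant")
    r = (Xc[nonconstant] @ yc) / np.sqrt(x_ss[nonconstant] * (yc**2).sum())
    entries = pd.Series(r, index=expr.index[nonconstant], name=cohort_id)
    return CorrelationTable(cohort_id, entries, len(shared))


def _eligible(table: CorrelationTable, threshold: float, absolute: bool) -> set[str]:
    r = table.entries
    mask = r.abs() >= threshold if absolute else r >= threshold
    return set(r.index[mask])


def sweep_thresholds(
    table_a: CorrelationTable,
    table_b: CorrelationTable,
    grid: Sequence[float] = DEFAULT_GRID,
    absolute: bool = False,
) -> dict[float, int]:
    """Overlap gene count (clearing the threshold in both cohorts) per grid value."""
    grid = tuple(grid)
    if not grid:
        raise SignatureError("threshold grid is empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise SignatureError("threshold grid must be strictly increasing")
    return {
        t: len(_eligible(table_a, t, absolute) & _eligible(table_b, t, absolute)) for t in grid
    }


def select_signature(
    table_a: CorrelationTable,
    table_b: CorrelationTable,
    threshold: float = DEFAULT_THRESHOLD,
    size_window: tuple[int, int] = DEFAULT_SIZE_WINDOW,
    grid: Sequence[float] = DEFAULT_GRID,
    absolute: bool = False,
    name: str | None = None,
) -> SignatureSelection:
    """Genes clearing ``threshold`` in both cohorts, with the sweep recorded.

    Warns (does not fail) when the selection size falls outside
    ``size_window``; raises when the selection is empty.
    """
    if not 0 < threshold < 1:
        raise SignatureError("threshold must be in (0, 1)")
    selected = sorted(_eligible(table_a, threshold, absolute) & _eligible(table_b, threshold, absolute))
    if not selected:
        raise SignatureError(
            f"no gene clears r >= {threshold} in both cohorts; try a lower threshold "
            f"(sweep: {sweep_thresholds(table_a, table_b, grid, absolute)})"
        )
    lo, hi = size_window
    if not lo <= len(selected) <= hi:
        warnings.warn(
            f"signature has {len(selected)} genes, outside the target window {size_window}",
            stacklevel=2,
        )
    name = name or f"GIN_{table_a.cohort_id}_{table_b.cohort_id}_r{threshold:g}"
    genes = GeneSet(
        name,
        f"genes with r >= {threshold:g} vs FGA in {table_a.cohort_id} and {table_b.cohort_id}",
        tuple(selected),
    )
    sweep = sweep_thresholds(table_a, table_b, grid, absolute)
    return SignatureSelection(threshold, genes, sweep, (table_a.cohort_id, table_b.cohort_id))


class SignatureSelector(BaseEstimator):
    """Learn a dual-cohort FGA-correlation gene signature.

    Parameters mirror :func:`select_signature`.  ``fit`` accepts exactly two
    cohorts, each either a :class:`CorrelationTable` or an
    ``(expression, fga, cohort_id)`` triple.

    Attributes
    ----------
    tables_ : list of CorrelationTable
    selection_ : SignatureSelection
    genes_ : GeneSet
    sweep_ : dict mapping threshold -> overlap count
    """

    def __init__(
        self,
        threshold: float = DEFAULT_THRESHOLD,
        grid: Sequence[float] = DEFAULT_GRID,
        size_window: tuple[int, int] = DEFAULT_SIZE_WINDOW,
        absolute: bool = False,
    ):
        self.threshold = threshold
        self.grid = grid
        self.size_window = size_window
        self.absolute = absolute

    def fit(self, cohorts: Iterable, y=None) -> "SignatureSelector":
        cohorts = list(cohorts)
        if len(cohorts) != 2:
            raise SignatureError(f"need exactly 2 cohorts, got {len(cohorts)}")
        tables = [
            c if isinstance(c, CorrelationTable) else compute_gene_fga_correlations(*c)
            for c in cohorts
        ]
        self.tables_ = tables
        self.selection_ = select_signature(
            tables[0],
            tables[1],
            threshold=self.threshold,
            size_window=tuple(self.size_window),
            grid=tuple(self.grid),
            absolute=self.absolute,
        )
        self.genes_ = self.selection_.genes
        self.sweep_ = self.selection_.sweep
        return self
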