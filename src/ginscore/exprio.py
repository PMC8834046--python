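"""Expression-matrix and gene-set (GMT) I/O.

Expression matrices are plain pandas DataFrames with gene symbols as the
index and sample ids as columns (genes x samples, normalized values on any
monotone scale — the downstream enrichment score is rank-based).  Gene sets
use the Broad GMT dialect: one set per line, ``name<TAB>description<TAB>
gene1<TAB>gene2...``.

Gene matching between matrices and sets is exact, case-sensitive symbol
comparison; scoring requires at least half of a set's genes to be present
(:data:`MIN_SET_OVERLAP`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Minimum fraction of a gene set that must be present in the expression
#: matrix for scoring to proceed.
MIN_SET_OVERLAP = 0.5


class GmtParseError(ValueError):
    """A GMT line does not have at least name, description and one gene."""


@dataclass(frozen=True)
class GeneSet:
    """A named gene set; ``genes`` preserves file order but holds no duplicates."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a genes-x-samples TSV (first column gene id, header sample ids).

    Rows containing any non-finite value are dropped (count logged).
    Duplicate gene ids keep the row with the highest mean (logged).
    Duplicate sample ids are an error, as is an empty matrix after filtering.
    """
    path = Path(path)
    with open(path) as fh:  # pandas mangles duplicate headers, so check raw
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate sample id(s) {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")

    finite = np.isfinite(df.to_numpy()).all(axis=1)
    n_bad = int((~finite).sum())
    if n_bad:
        logger.info("read_expression_table(%s): dropped %d row(s) with non-finite values", path, n_bad)
        df = df.loc[finite]

    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.info(
            "read_expression_table(%s): %d duplicate gene id row(s), keeping highest-mean row",
            path,
            n_dup,
        )
        means = df.mean(axis=1).to_numpy()
        best: dict[str, int] = {}
        for pos, gene in enumerate(df.index):
            if gene not in best or means[pos] > means[best[gene]]:
                best[gene] = pos
        df = df.iloc[sorted(best.values())]

    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix after filtering")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    df.columns = df.columns.astype(str)
    return df


def write_expression_table(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(Path(path), sep="\t", index_label="gene_id")


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file; duplicate genes within a line are dropped with a warning."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}, line {line_no}: expected name, description and >=1 gene, "
                    f"got {len(fields)} field(s)"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    logger.warning(
                        "read_gene_sets(%s), line %d: duplicate gene %r dropped", path, line_no, g
                    )
                seen.setdefault(g, None)
            sets.append(GeneSet(name, description, tuple(seen)))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets in GMT format; round-trips through :func:`read_gene_sets`."""
    with open(Path(path), "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def _data_path(name: str):
    return resources.files("ginscore.data").joinpath(name)


def load_gin20() -> GeneSet:
    """The packaged 20-gene genomic-instability signature."""
    with resources.as_file(_data_path("gin20.gmt")) as p:
        return read_gene_sets(p)[0]


def load_signature_correlations() -> pd.DataFrame:
    """Published per-gene FGA correlations of the 20-gene signature.

    Columns ``cor_ccle`` (cell-line cohort, n=32) and ``cor_tcga`` (tumor
    cohort, n=520), indexed by gene symbol.
    """
    with resources.as_file(_data_path("table1_correlations.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="symbol")


def match_genes(expr: pd.DataFrame, gene_set: GeneSet) -> tuple[list[str], list[str]]:
    """Split a gene set into (present, missing) relative to a matrix index."""
    idx = set(expr.index)
    present = [g for g in gene_set.genes if g in idx]
    missing = [g for g in gene_set.genes if g not in idx]
    return present, missing
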