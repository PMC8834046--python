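"""Synthetic cohorts with the statistical structure the pipeline assumes.

Three coupled generators, all driven by one seeded ``numpy`` Generator
(PCG64), so a fixed seed reproduces a cohort exactly:

* copy number — per sample, a target FGA is drawn from a Beta distribution
  (Beta(2, 3) by default, mean 0.4, the instability scale of head-and-neck
  tumors); a 22-chromosome toy genome of 3 Gb is partitioned into 50-200
  segments and segments are greedily flagged as altered (|log2 ratio| > 0.2)
  until the altered fraction reaches the target, so the realized FGA matches
  the target to within one segment's resolution;
* expression — a planted subset of genes follows ``beta * FGA + noise`` with
  ``beta`` calibrated to a chosen population correlation with FGA
  (``target_r``); background genes are independent Gaussian noise;
* survival — exponential event times whose hazard scales as
  ``exp(log_hr_per_sd * standardized score)``, independent uniform censoring
  on (0, censor_horizon), plus randomized 3-level treatment-arm and 2-level
  histology covariates mimicking a chemoprevention-trial design.

The generators model only the structure the pipeline detects (a linear
gene-FGA coupling, a proportional-hazards score effect); they make no
attempt at realistic co-expression, array noise or subtype structure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exprio import GeneSet, write_expression_table, write_gene_sets
from .seg import Segment, SegmentProfile, compute_fga, write_seg
from .ssgsea import DEFAULT_ALPHA, score_matrix

logger = logging.getLogger(__name__)

#: Toy genome: 22 chromosomes with linearly decreasing lengths, 3 Gb total.
_CHROM_WEIGHTS = np.arange(22, 0, -1, dtype=float)
CHROMOSOME_LENGTHS = {
    f"chr{i + 1}": int(round(3e9 * w / _CHROM_WEIGHTS.sum()))
    for i, w in enumerate(_CHROM_WEIGHTS)
}

TREATMENT_ARMS = ("13cRA", "RP", "RP+BC")
HISTOLOGIES = ("hyperplasia", "dysplasia")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``target_r`` is the population Pearson correlation between a planted
    gene's expression and FGA; ``log_hr_per_sd`` the log hazard ratio per
    standard deviation of the driving score; ``censor_horizon`` the uniform
    censoring window in months.  ``fixed_fga`` short-circuits the Beta draw
    (used for degenerate designs such as a fully stable genome).
    """

    n_samples: int = 200
    n_genes: int = 1000
    n_planted: int = 25
    planted_genes: tuple[str, ...] | None = None
    target_r: float = 0.5
    fga_distribution: tuple[float, float] = (2.0, 3.0)
    noise_sd: float = 1.0
    hazard_baseline: float = 0.01
    log_hr_per_sd: float = 0.7
    censor_horizon: float = 84.0
    seed: int = 0
    fixed_fga: float | None = None

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0 or self.n_planted < 0:
            raise ValueError("counts must be positive")
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted must be <= n_genes")
        if self.planted_genes is not None and len(self.planted_genes) != self.n_planted:
            raise ValueError("planted_genes length must equal n_planted")
        if not 0 < self.target_r < 1:
            raise ValueError("target_r must be in (0, 1)")
        if self.noise_sd <= 0 or self.hazard_baseline <= 0 or self.censor_horizon <= 0:
            raise ValueError("scale parameters must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimulatedCohort:
    profiles: list[SegmentProfile]
    expr: pd.DataFrame
    true_fga: pd.Series
    planted_genes: GeneSet
    survival: pd.DataFrame
    config: SimulationConfig


def _partition_chromosome(length: int, n_segments: int, rng: np.random.Generator) -> list[int]:
    """Split ``length`` into ``n_segments`` positive integer pieces."""
    if n_segments == 1:
        return [length]
    props = rng.dirichlet(np.full(n_segments, 2.0))
    sizes = np.maximum(1, np.round(props * length).astype(int))
    sizes[-1] = length - sizes[:-1].sum()
    if sizes[-1] < 1:  # rounding pushed past the end; rebalance from the largest
        deficit = 1 - sizes[-1]
        sizes[np.argmax(sizes[:-1])] -= deficit
        sizes[-1] = 1
    return sizes.tolist()


def simulate_copy_number(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[SegmentProfile], pd.Series]:
    """Segmented profiles with known FGA.

    Returns the profiles and the realized altered fraction per sample (which
    :func:`ginscore.seg.compute_fga` reproduces exactly); the realized value
    sits within one segment's length of the Beta-drawn target.
    """
    rng = config.rng() if rng is None else rng
    profiles: list[SegmentProfile] = []
    fga: dict[str, float] = {}
    a, b = config.fga_distribution
    for i in range(config.n_samples):
        sid = f"S{i + 1:04d}"
        target = config.fixed_fga if config.fixed_fga is not None else rng.beta(a, b)
        n_seg_total = int(rng.integers(50, 201))
        # allocate segment counts per chromosome proportionally to length
        lengths = np.array(list(CHROMOSOME_LENGTHS.values()), dtype=float)
        counts = np.maximum(1, np.round(n_seg_total * lengths / lengths.sum()).astype(int))
        seg_lengths: list[int] = []
        seg_chroms: list[str] = []
        for (chrom, length), m in zip(CHROMOSOME_LENGTHS.items(), counts):
            for piece in _partition_chromosome(length, int(m), rng):
                seg_lengths.append(piece)
                seg_chroms.append(chrom)
        seg_lengths_arr = np.array(seg_lengths, dtype=np.int64)
        total = int(seg_lengths_arr.sum())

        # greedy subset-sum, largest first in shuffled order: final deficit is
        # smaller than any unused segment, i.e. within one segment's resolution
        shuffled = rng.permutation(len(seg_lengths_arr))
        by_size = shuffled[np.argsort(-seg_lengths_arr[shuffled], kind="stable")]
        budget = target * total
        altered_idx: set[int] = set()
        acc = 0
        for idx in by_size:
            if acc + seg_lengths_arr[idx] <= budget:
                altered_idx.add(int(idx))
                acc += int(seg_lengths_arr[idx])

        segments: list[Segment] = []
        pos: dict[str, int] = {c: 0 for c in CHROMOSOME_LENGTHS}
        for idx, (chrom, length) in enumerate(zip(seg_chroms, seg_lengths)):
            start = pos[chrom]
            end = start + length
            pos[chrom] = end
            if idx in altered_idx:
                magnitude = rng.uniform(0.25, 1.2)
                value = magnitude * (1 if rng.random() < 0.5 else -1)
            else:
                value = rng.uniform(-0.18, 0.18)
            segments.append(Segment(chrom, start, end, float(value)))
        profiles.append(SegmentProfile(sid, segments))
        fga[sid] = acc / total
    return profiles, pd.Series(fga, name="fga")


def simulate_expression(
    true_fga: pd.Series, config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, GeneSet]:
    """Expression matrix with a planted FGA-coupled gene subset.

    Planted genes follow ``beta * FGA + N(0, noise_sd)`` with ``beta`` set
    from the realized FGA spread so the population correlation equals
    ``target_r``; background genes are independent ``N(mu_g, noise_sd)``
    noise with gene-specific intercepts.
    """
    rng = config.rng() if rng is None else rng
    n = len(true_fga)
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    if config.planted_genes is not None:
        planted = sorted(config.planted_genes)
        unknown = set(planted) - set(genes)
        if unknown:
            raise ValueError(f"planted_genes not in the gene universe: {sorted(unknown)}")
    else:
        # deterministic evenly-spaced choice: two cohorts simulated with the
        # same gene universe plant the same subset, as a dual-cohort design needs
        positions = np.round(np.linspace(0, config.n_genes - 1, config.n_planted)).astype(int)
        planted = sorted(genes[p] for p in positions)
    f = true_fga.to_numpy(dtype=float)
    sigma_f = f.std()
    if sigma_f == 0:
        raise ValueError("FGA is constant; cannot plant a correlated signal")
    r = config.target_r
    # slope calibrated against unit noise: population correlation equals
    # target_r at noise_sd = 1, and tightens toward 1 as noise_sd -> 0
    beta = (1.0 / sigma_f) * r / np.sqrt(1.0 - r**2)

    X = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
    X += rng.normal(5.0, 1.0, size=(config.n_genes, 1))  # gene-specific baseline
    planted_pos = [genes.index(g) for g in planted]
    X[planted_pos, :] += beta * f[None, :]
    expr = pd.DataFrame(X, index=pd.Index(genes, name="gene_id"), columns=true_fga.index)
    gene_set = GeneSet("planted", f"planted FGA-coupled genes (target r={r:g})", tuple(planted))
    return expr, gene_set


def simulate_survival(
    scores: pd.Series, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Exponential survival with hazard increasing in the standardized score."""
    rng = config.rng() if rng is None else rng
    z = (scores - scores.mean()) / scores.std(ddof=0)
    hazard = config.hazard_baseline * np.exp(config.log_hr_per_sd * z.to_numpy(dtype=float))
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0.0, config.censor_horizon, size=len(scores))
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return pd.DataFrame(
        {
            "time": time,
            "event": event,
            "arm": rng.choice(TREATMENT_ARMS, size=len(scores)),
            "histology": rng.choice(HISTOLOGIES, size=len(scores)),
        },
        index=scores.index.copy(),
    )


def simulate_cohort(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> SimulatedCohort:
    """Compose copy number, expression and survival into one cohort.

    Survival hazard is driven by the single-sample enrichment score of the
    planted gene set, so the cohort carries the full structure the pipeline
    is meant to recover.  When ``out_dir`` is given, writes ``expr.tsv``,
    ``segments.seg``, ``clinical.tsv``, ``planted.gmt`` and ``truth.json``.
    """
    rng = config.rng()
    profiles, true_fga = simulate_copy_number(config, rng)
    expr, planted = simulate_expression(true_fga, config, rng)
    score_table = score_matrix(expr, planted, alpha=alpha)
    survival = simulate_survival(score_table.scores, config, rng)
    cohort = SimulatedCohort(profiles, expr, true_fga, planted, survival, config)

    for prof in profiles:
        realized = compute_fga(prof).fga
        assert abs(realized - true_fga[prof.sample_id]) < 1e-12

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_expression_table(expr, out_dir / "expr.tsv")
        write_seg(profiles, out_dir / "segments.seg")
        survival.to_csv(out_dir / "clinical.tsv", sep="\t", index_label="sample_id")
        write_gene_sets([planted], out_dir / "planted.gmt")
        truth = {
            "config": asdict(config),
            "true_fga": {k: float(v) for k, v in true_fga.items()},
            "planted_genes": list(planted.genes),
        }
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return cohort
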