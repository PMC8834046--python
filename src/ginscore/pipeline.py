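"""End-to-end orchestration: derive -> score -> validate -> survive.

A :class:`RunConfig` names the input files (two derivation cohorts, one
validation cohort, optionally clinical follow-up) and the analysis settings.
:func:`run_pipeline` executes the stages in order, writes the signature
(GMT), per-sample scores (TSV), a GIN-vs-FGA correlation report and — when
clinical data are present — a survival report (maxstat cutoff, log-rank p,
Cox HR/CI), plus one machine-readable JSON summary.  Reports contain no
timestamps, so a rerun with the same config and seed is byte-identical;
per-stage timing goes to the log only.  Any stage failure removes the
partial outputs of the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import exprio, seg, signature, ssgsea, stats, survival

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    expr_a: str
    seg_a: str
    expr_b: str
    seg_b: str
    expr_valid: str
    seg_valid: str
    out_dir: str
    clinical_valid: str | None = None
    threshold: float = signature.DEFAULT_THRESHOLD
    grid: tuple[float, ...] = signature.DEFAULT_GRID
    size_window: tuple[int, int] = signature.DEFAULT_SIZE_WINDOW
    alpha: float = ssgsea.DEFAULT_ALPHA
    normalize: bool = False
    fga_threshold: float = seg.DEFAULT_ALTERATION_THRESHOLD
    linear_cna: bool = False
    minprop: float = survival.DEFAULT_MINPROP
    n_perm: int = survival.DEFAULT_N_PERM
    covariates: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("grid", "size_window", "covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def input_paths(self) -> dict[str, str]:
        paths = {
            "expr_a": self.expr_a,
            "seg_a": self.seg_a,
            "expr_b": self.expr_b,
            "seg_b": self.seg_b,
            "expr_valid": self.expr_valid,
            "seg_valid": self.seg_valid,
        }
        if self.clinical_valid:
            paths["clinical_valid"] = self.clinical_valid
        return paths


def _load_cohort(expr_path: str, seg_path: str, config: RunConfig, label: str):
    expr = exprio.read_expression_table(expr_path)
    profiles = seg.read_seg(seg_path)
    fga = seg.compute_fga_table(profiles, config.fga_threshold, config.linear_cna)
    return expr, fga["fga"]


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the JSON-serializable run report."""
    for name, path in config.input_paths().items():
        if not Path(path).is_file():
            raise PipelineError(f"validation: input {name} not found: {path}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict = {"seed": config.seed, "stages": []}
    current = "derive"
    t0 = time.perf_counter()

    def done():
        nonlocal t0
        logger.info("stage %s finished in %.2fs", current, time.perf_counter() - t0)
        report["stages"].append(current)
        t0 = time.perf_counter()

    try:
        expr_a, fga_a = _load_cohort(config.expr_a, config.seg_a, config, "A")
        expr_b, fga_b = _load_cohort(config.expr_b, config.seg_b, config, "B")
        selector = signature.SignatureSelector(
            threshold=config.threshold, grid=config.grid, size_window=config.size_window
        )
        selector.fit([(expr_a, fga_a, "cohortA"), (expr_b, fga_b, "cohortB")])
        sig_path = out_dir / "signature.gmt"
        exprio.write_gene_sets([selector.genes_], sig_path)
        written.append(sig_path)
        sweep_path = out_dir / "sweep.tsv"
        pd.Series(selector.sweep_, name="n_overlap").rename_axis("threshold").to_csv(
            sweep_path, sep="\t"
        )
        written.append(sweep_path)
        report["signature"] = {
            "n_genes": len(selector.genes_),
            "genes": list(selector.genes_.genes),
            "threshold": config.threshold,
            "sweep": {str(k): v for k, v in selector.sweep_.items()},
        }
        done()

        current = "score"
        expr_v, fga_v = _load_cohort(config.expr_valid, config.seg_valid, config, "valid")
        scores = ssgsea.score_matrix(
            expr_v, selector.genes_, alpha=config.alpha, normalize=config.normalize
        )
        scores_path = out_dir / "scores.tsv"
        scores.scores.rename("score").rename_axis("sample_id").to_csv(scores_path, sep="\t")
        written.append(scores_path)
        done()

        current = "validate"
        shared = [s for s in scores.scores.index if s in set(fga_v.index)]
        corr = stats.pearson_r(scores.scores.loc[shared], fga_v.loc[shared])
        corr_path = out_dir / "correlation_report.tsv"
        pd.DataFrame(
            {
                "cohort": ["validation"],
                "n": [len(shared)],
                "pearson_r": [corr.statistic],
                "p_value": [corr.p_value],
            }
        ).to_csv(corr_path, sep="\t", index=False)
        written.append(corr_path)
        report["validation"] = {
            "n": len(shared),
            "pearson_r": corr.statistic,
            "p_value": corr.p_value,
        }
        done()

        if config.clinical_valid:
            current = "survive"
            clin = survival.read_clinical_table(config.clinical_valid)
            shared = [s for s in clin.index if s in set(scores.scores.index)]
            clin = clin.loc[shared]
            cut = survival.MaxstatCutpoint(
                minprop=config.minprop, n_perm=config.n_perm, random_state=config.seed
            ).fit(scores.scores.loc[shared], clin)
            groups = survival.dichotomize(scores.scores.loc[shared], cut.cutoff_)
            lr = survival.logrank_test(clin[groups == "high"], clin[groups == "low"])
            clin_cox = clin.copy()
            clin_cox["gin_group"] = (groups == "high").astype(float)
            covs = ["gin_group", *[c for c in config.covariates if c in clin.columns]]
            fit = survival.cox_fit(clin_cox, covs)
            km_high = survival.km_estimate(clin[groups == "high"])
            km_low = survival.km_estimate(clin[groups == "low"])
            surv_path = out_dir / "survival_report.tsv"
            pd.DataFrame(
                {
                    "covariate": fit.hazard_ratios.index,
                    "hazard_ratio": fit.hazard_ratios.to_numpy(),
                    "ci95_lower": fit.ci95["lower"].to_numpy(),
                    "ci95_upper": fit.ci95["upper"].to_numpy(),
                    "p_value": fit.p_values.to_numpy(),
                }
            ).to_csv(surv_path, sep="\t", index=False)
            written.append(surv_path)
            report["survival"] = {
                "cutoff": cut.cutoff_,
                "maxstat_statistic": cut.statistic_,
                "maxstat_p": cut.p_value_,
                "n_high": int((groups == "high").sum()),
                "n_low": int((groups == "low").sum()),
                "logrank_p": lr.p_value,
                "cox": {
                    name: {
                        "hr": float(fit.hazard_ratios[name]),
                        "ci95": [float(fit.ci95.loc[name, "lower"]), float(fit.ci95.loc[name, "upper"])],
                        "p": float(fit.p_values[name]),
                    }
                    for name in fit.hazard_ratios.index
                },
                "km": {
                    "high": {"times": km_high.event_times.tolist(), "surv": km_high.survival_probs.tolist()},
                    "low": {"times": km_low.event_times.tolist(), "surv": km_low.survival_probs.tolist()},
                },
            }
            done()

        summary_path = out_dir / "report.json"
        summary_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        written.append(summary_path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc
    return report
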