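"""End-to-end orchestration: per-subject metrics and cohort comparison.

``run_subject`` composes the stages — trim, epoch-average, zero-phase
band-pass, rescale, JDistEn coupling, fixed-density binarization, graph
metrics with random-reference normalization — into one metrics row.
``run_cohort`` maps it over a labelled cohort, skipping subjects that fail
with a structured message, and runs the gated two-group comparison plus
outlier screens on the four network metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, JDNetError
from .graphs import network_metrics
from .jdisten import EmbeddingConfig, coupling_matrix
from .preprocess import EpochedRecording, FilterSpec, preprocess_subject
from .stats import ComparisonResult, OutlierReport, compare_groups, outlier_report

log = logging.getLogger("jdnet")

METRIC_COLUMNS = ("clustering", "path_length", "small_world_q", "eccentricity")

__all__ = ["PipelineConfig", "CohortResult", "run_subject", "run_cohort", "METRIC_COLUMNS"]


@dataclass
class PipelineConfig:
    """All tunable knobs of the pipeline; defaults are the study settings.

    Band 9-34 Hz with single-pass orders 4/8, embedding m=2 tau=1, edge
    density 0.10, ten random reference graphs, 5% significance.
    """

    hp_order: int = 4
    hp_half_power_hz: float = 9.0
    lp_order: int = 8
    lp_half_power_hz: float = 34.0
    m: int = 2
    tau: int = 1
    distance_norm: str = "range"
    density: float = 0.10
    n_rand: int = 10
    alpha: float = 0.05
    eccentricity_summary: str = "mean"
    welch: bool = False
    exclude_outliers: bool = False
    seed: int = 0
    output_dir: str = ""

    @property
    def filter_spec(self) -> FilterSpec:
        return FilterSpec(
            hp_order=self.hp_order,
            hp_half_power_hz=self.hp_half_power_hz,
            lp_order=self.lp_order,
            lp_half_power_hz=self.lp_half_power_hz,
        )

    @property
    def embedding(self) -> EmbeddingConfig:
        return EmbeddingConfig(m=self.m, tau=self.tau, norm=self.distance_norm)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


@dataclass
class CohortResult:
    """Cohort outputs: per-subject table, comparisons, outliers, skips."""

    metrics: pd.DataFrame
    comparisons: list[ComparisonResult]
    outliers: list[OutlierReport]
    skipped: list[tuple[str, str]] = field(default_factory=list)
    labels: tuple[str, str] = ("A", "B")


def _subject_seed(config_seed: int, index: int) -> int:
    """Per-subject substream for the random reference graphs (< 2**31)."""
    ss = np.random.SeedSequence([config_seed, index])
    return int(ss.generate_state(1)[0] % (2**31))


def run_subject(
    rec: EpochedRecording,
    config: PipelineConfig = PipelineConfig(),
    subject_index: int = 0,
    intermediates: dict | None = None,
) -> dict:
    """Full per-subject chain, returning one metrics row as a dict.

    ``intermediates``, if given, collects the rescaled recording, coupling
    matrix and binary metrics object for caching or inspection.
    """
    rescaled = preprocess_subject(rec, config.filter_spec)
    w = coupling_matrix(rescaled, config.embedding)
    metrics = network_metrics(
        w,
        density=config.density,
        n_rand=config.n_rand,
        seed=_subject_seed(config.seed, subject_index),
        ecc_summary=config.eccentricity_summary,
    )
    if intermediates is not None:
        intermediates["rescaled"] = rescaled
        intermediates["coupling"] = w
        intermediates["metrics"] = metrics
    return {
        "subject": rec.subject_id or f"s{subject_index:02d}",
        "group": rec.group,
        "clustering": metrics.c_actual,
        "path_length": metrics.l_actual,
        "eccentricity": metrics.eccentricity,
        "c_random": metrics.c_random,
        "l_random": metrics.l_random,
        "small_world_q": metrics.q,
        "n_edges": metrics.n_edges,
        "component_size": metrics.component_size,
    }


def compare_metric_table(
    metrics: pd.DataFrame,
    alpha: float = 0.05,
    welch: bool = False,
    exclude_outliers: bool = False,
) -> tuple[list[ComparisonResult], list[OutlierReport], tuple[str, str]]:
    """Gated comparison + outlier screens for each network metric column."""
    labels = sorted(metrics["group"].unique())
    if len(labels) != 2:
        raise ConfigError(f"need exactly two groups, found {labels}")
    results, reports = [], []
    for col in METRIC_COLUMNS:
        a = metrics.loc[metrics["group"] == labels[0], col].to_numpy()
        b = metrics.loc[metrics["group"] == labels[1], col].to_numpy()
        rep_a = outlier_report(f"{col}/{labels[0]}", a)
        rep_b = outlier_report(f"{col}/{labels[1]}", b)
        reports.extend([rep_a, rep_b])
        if exclude_outliers:
            drop_a = set(rep_a.chauvenet) | set(rep_a.iqr)
            drop_b = set(rep_b.chauvenet) | set(rep_b.iqr)
            a = np.delete(a, sorted(drop_a))
            b = np.delete(b, sorted(drop_b))
        results.append(compare_groups(a, b, alpha=alpha, metric=col, welch=welch))
    return results, reports, (labels[0], labels[1])


def run_cohort(
    cohort: list[tuple[EpochedRecording, str]],
    config: PipelineConfig = PipelineConfig(),
) -> CohortResult:
    """Per-subject metrics plus the two-group comparison for a cohort.

    Subjects failing any stage are skipped with a structured message; the
    comparison requires at least three survivors per group.
    """
    rows = []
    skipped: list[tuple[str, str]] = []
    for idx, (rec, group) in enumerate(cohort):
        rec.group = rec.group or group
        try:
            rows.append(run_subject(rec, config, subject_index=idx))
        except JDNetError as exc:
            sid = rec.subject_id or f"s{idx:02d}"
            log.warning("skipping subject %s: %s", sid, exc)
            skipped.append((sid, str(exc)))
    metrics = pd.DataFrame(rows)
    if metrics.empty or metrics["group"].value_counts().min() < 3 or (
        metrics["group"].nunique() != 2
    ):
        raise ConfigError("need >= 3 processed subjects in each of two groups")
    results, reports, labels = compare_metric_table(
        metrics,
        alpha=config.alpha,
        welch=config.welch,
        exclude_outliers=config.exclude_outliers,
    )
    return CohortResult(
        metrics=metrics,
        comparisons=results,
        outliers=reports,
        skipped=skipped,
        labels=labels,
    )
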