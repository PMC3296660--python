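"""Per-species and cross-species analysis orchestration.

``run_species`` chains the stages on one proteome — curation (dedup and
optional keyword filter), descriptive statistics, competitive model
fitting, amino-acid length-bias correlations and annotation diagnostics —
collecting per-stage errors instead of aborting, so a short proteome still
yields its summary even when model fitting is infeasible.
``run_cross_species`` synthesises the per-species reports: best-model
tally, the pooled gamma-shape test, protein-number-vs-mean-size
correlations and group-averaged bias profiles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import composition, summary
from .annotation import AnnotationFlag, PeakCall, classify_annotation, detect_peaks
from .composition import BiasProfile
from .distributions import ModelComparison, compare_models, params_to_dict
from .io import Proteome, deduplicate, filter_by_keywords, read_fasta
from .shape_test import ShapeTestResult, pooled_shape_test, shape_standard_error
from .summary import LengthSummary, PearsonResult, cross_species_correlation, length_summary

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "SpeciesReport",
    "CrossSpeciesResult",
    "run_species",
    "run_cross_species",
    "report_to_dict",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the per-species pipeline; defaults match the analysis
    conventions used throughout the package."""

    fit_range: tuple[float, float] = (0.0, 1500.0)
    pareto_threshold: float = 1500.0
    peak_threshold: float = 5.0
    peak_min_n: int = 1000
    cutoff_window: tuple[int, int] = (20, 60)
    percentiles: tuple[int, ...] = (10, 25, 50, 75, 90)
    keywords: tuple[str, ...] = ()
    dedup: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        d = json.loads(Path(path).read_text())
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


@dataclass
class SpeciesReport:
    """All per-species results, computed from one deduplicated record set."""

    species_code: str
    taxon_group: str = ""
    n_raw: int = 0
    n_duplicates_removed: int = 0
    n_keyword_removed: int = 0
    n_kept: int = 0
    summary: LengthSummary | None = None
    comparison: ModelComparison | None = None
    shape_se: float | None = None
    bias: BiasProfile | None = None
    annotation: AnnotationFlag | None = None
    peaks: list[PeakCall] | None = None
    gc: float | None = None
    errors: dict[str, str] = field(default_factory=dict)


def _stage(report: SpeciesReport, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                report.errors[name] = f"{exc_type.__name__}: {exc}"
                logger.warning("stage %s failed after %.2fs: %s", name, dt, exc)
                return True  # swallow; report carries the failure
            logger.info("stage %s done in %.2fs", name, dt)
            return False

    return _Ctx()


def run_species(
    proteome: Proteome | str | Path,
    config: AnalysisConfig | None = None,
    cds_records: Sequence | None = None,
) -> SpeciesReport:
    """Run the full per-species pipeline; failed stages are recorded in
    ``report.errors`` and their sections left ``None``."""
    config = config or AnalysisConfig()
    if not isinstance(proteome, Proteome):
        path = Path(proteome)
        code = path.name.split(".")[0]
        proteome = Proteome(species_code=code, records=read_fasta(path), source=str(path))

    report = SpeciesReport(species_code=proteome.species_code, taxon_group=proteome.taxon_group)
    report.n_raw = len(proteome.records)

    records = proteome.records
    with _stage(report, "curate"):
        if config.dedup:
            records, n_dup = deduplicate(records)
            report.n_duplicates_removed = n_dup
        if config.keywords:
            records, removed = filter_by_keywords(records, config.keywords)
            report.n_keyword_removed = len(removed)
    report.n_kept = len(records)
    lengths = np.array([r.length for r in records], dtype=np.int64)

    with _stage(report, "summary"):
        report.summary = length_summary(lengths, config.percentiles)

    with _stage(report, "models"):
        report.comparison = compare_models(lengths, config.fit_range)
        gamma_fit = report.comparison.fits["gamma_free"]
        if gamma_fit.converged:
            report.shape_se = shape_standard_error(gamma_fit)

    with _stage(report, "bias"):
        report.bias = composition.length_bias_correlations(records)

    with _stage(report, "annotation"):
        report.annotation = classify_annotation(lengths, config.cutoff_window)

    with _stage(report, "peaks"):
        if report.comparison is None:
            raise RuntimeError("no fitted model available for peak detection")
        report.peaks = detect_peaks(
            lengths,
            report.comparison.best_fit,
            threshold=config.peak_threshold,
            min_n=config.peak_min_n,
        )

    if cds_records is not None:
        with _stage(report, "gc"):
            report.gc = summary.gc_content(cds_records)

    return report


@dataclass
class CrossSpeciesResult:
    best_model_tally: dict[str, int]
    shape_test: ShapeTestResult | None
    correlations: dict[str, PearsonResult]
    bias_summary: pd.DataFrame | None
    n_species: int


def run_cross_species(
    reports: Sequence[SpeciesReport],
    grouping: Mapping[str, str] | None = None,
) -> CrossSpeciesResult:
    """Synthesise per-species reports into cross-species tables."""
    if len(reports) < 2:
        raise ValueError("need at least 2 species reports")
    grouping = grouping or {r.species_code: (r.taxon_group or "all") for r in reports}

    tally: dict[str, int] = {}
    for r in reports:
        if r.comparison is not None:
            tally[r.comparison.best_model] = tally.get(r.comparison.best_model, 0) + 1

    thetas, ses = [], []
    for r in reports:
        if r.comparison is None or r.shape_se is None:
            continue
        fit = r.comparison.fits.get("gamma_free")
        if fit is not None and fit.converged:
            thetas.append(fit.params.shape)
            ses.append(r.shape_se)
    shape_result = pooled_shape_test(thetas, ses) if len(thetas) >= 2 else None

    table = pd.DataFrame(
        {
            "species_code": [r.species_code for r in reports],
            "taxon_group": [grouping.get(r.species_code, "all") for r in reports],
            "n_proteins": [r.n_kept for r in reports],
            "mean_size": [r.summary.mean if r.summary else np.nan for r in reports],
        }
    )
    correlations: dict[str, PearsonResult] = {}
    try:
        correlations["all"] = cross_species_correlation(table, "n_proteins", "mean_size")
    except ValueError as exc:
        logger.warning("overall size/number correlation unavailable: %s", exc)
    for group, sub in table.groupby("taxon_group"):
        if len(sub) >= 3:
            try:
                correlations[str(group)] = cross_species_correlation(sub, "n_proteins", "mean_size")
            except ValueError as exc:
                logger.warning("correlation for %s unavailable: %s", group, exc)

    profiles = {r.species_code: r.bias for r in reports if r.bias is not None}
    bias_summary = (
        composition.group_bias_summary(profiles, grouping) if profiles else None
    )

    return CrossSpeciesResult(
        best_model_tally=tally,
        shape_test=shape_result,
        correlations=correlations,
        bias_summary=bias_summary,
        n_species=len(reports),
    )


def report_to_dict(report: SpeciesReport) -> dict:
    """JSON-serialisable view of a species report (deterministic layout)."""
    d: dict = {
        "species_code": report.species_code,
        "taxon_group": report.taxon_group,
        "curation": {
            "n_raw": report.n_raw,
            "n_duplicates_removed": report.n_duplicates_removed,
            "n_keyword_removed": report.n_keyword_removed,
            "n_kept": report.n_kept,
        },
        "errors": dict(report.errors),
    }
    if report.summary is not None:
        d["summary"] = {
            "n": report.summary.n,
            "mean": report.summary.mean,
            "sd": report.summary.sd,
            "percentiles": {str(k): v for k, v in report.summary.percentiles.items()},
        }
    if report.comparison is not None:
        d["models"] = {
            "best_model": report.comparison.best_model,
            "fits": {
                name: {
                    "params": params_to_dict(
                        "gamma_free" if name == "gamma_fixed2" else name, fit.params
                    ),
                    "k": fit.k,
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                    "n": fit.n,
                    "converged": fit.converged,
                }
                for name, fit in report.comparison.fits.items()
            },
        }
        if report.shape_se is not None:
            d["models"]["gamma_shape_se"] = report.shape_se
    if report.bias is not None:
        d["bias"] = {"n": report.bias.n, "r_by_aa": report.bias.r_by_aa}
    if report.annotation is not None:
        d["annotation"] = {
            "classification": report.annotation.classification,
            "min_length": report.annotation.min_length,
            "sharp_cutoff": report.annotation.sharp_cutoff,
            "bin_counts": report.annotation.bin_counts,
        }
    if report.peaks is not None:
        d["peaks"] = [
            {
                "position": p.position,
                "observed": p.observed,
                "expected": p.expected,
                "excess_score": p.excess_score,
            }
            for p in report.peaks
        ]
    if report.gc is not None:
        d["gc"] = report.gc
    return d
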