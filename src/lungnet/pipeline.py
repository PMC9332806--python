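"""End-to-end orchestration: crop → layers → graphs → analysis → cohort stats.

These functions are the programmatic face of the tool; the CLI wraps them
thinly. Every run is determined by its inputs plus a single integer seed, and
all outputs are plain CSV so reruns can be compared byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import cohort_stats, degree_analysis, hu_layers, pixel_graph
from .cohort_stats import CohortRecord, welch_metric_test
from .degree_analysis import (
    degree_distribution,
    fit_distribution,
    network_metrics,
)
from .dicom_io import CropSample, write_crop_csv
from .errors import InsufficientDataError, UndefinedStatisticError
from .hu_layers import HUBandTable, default_band_table, split_layers
from .pixel_graph import GraphParams, build_graph, export_graph
from .synthetic_fixtures import cohort_manifest, make_cohort

log = logging.getLogger("lungnet")


@dataclass
class SampleAnalysis:
    """Per-band results of one crop."""

    sample_id: str
    band_name: str
    graph: pixel_graph.PixelGraph
    distribution: degree_analysis.DegreeDistribution
    metrics: degree_analysis.NetworkMetrics
    fits: dict[str, degree_analysis.FitResult]


def analyze_crop(
    crop: CropSample,
    table: HUBandTable | None = None,
    params: GraphParams | None = None,
    bands=hu_layers.PATHOLOGICAL_BANDS,
    sample_id: str = "sample",
    fit_families=("logarithmic", "power", "polynomial"),
) -> list[SampleAnalysis]:
    """Run the per-sample method on one crop, one result per selected band.

    Fits that are impossible on a given layer (too few distinct degrees,
    constant counts) are simply absent from ``fits``.
    """
    table = table or default_band_table()
    params = params or GraphParams()
    log.info(
        "analyze %s: bands=%s rd_max=%s delta_max=%s",
        sample_id, list(bands), params.rd_max, params.delta_max,
    )
    out = []
    for layer in split_layers(crop, table, bands):
        g = build_graph(layer, params)
        dist = degree_distribution(g)
        fits = {}
        for fam in fit_families:
            try:
                fits[fam] = fit_distribution(dist, fam)
            except (InsufficientDataError, UndefinedStatisticError):
                continue
        out.append(
            SampleAnalysis(
                sample_id=sample_id,
                band_name=layer.band_name,
                graph=g,
                distribution=dist,
                metrics=network_metrics(g),
                fits=fits,
            )
        )
    return out


def write_sample_outputs(
    crop: CropSample,
    analyses: list[SampleAnalysis],
    out_dir: str | Path,
) -> None:
    """Write crop CSV, per-band masks, graph exports, histograms, and reports."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_crop_csv(crop, out_dir / "crop_hu.csv")

    metric_rows, fit_rows = [], []
    for a in analyses:
        export_graph(a.graph, out_dir, stem=a.band_name)
        a.distribution.as_frame().to_csv(
            out_dir / f"{a.band_name}_degree_histogram.csv", index=False
        )
        metric_rows.append(
            {
                "sample_id": a.sample_id,
                "band": a.band_name,
                "n_nodes": a.graph.n_nodes,
                "n_edges": a.graph.n_edges,
                "total_count": a.metrics.total_count,
                "average_count": a.metrics.average_count,
                "max_degree": a.metrics.max_degree,
            }
        )
        for fam, fit in a.fits.items():
            fit_rows.append(
                {
                    "sample_id": a.sample_id,
                    "band": a.band_name,
                    "family": fam,
                    "poly_degree": fit.poly_degree,
                    "r2": fit.r2,
                    "coefficients": ";".join(f"{c:.12g}" for c in fit.coefficients),
                }
            )
    pd.DataFrame(metric_rows).to_csv(out_dir / "metrics.csv", index=False)
    pd.DataFrame(
        fit_rows, columns=["sample_id", "band", "family", "poly_degree", "r2",
                           "coefficients"]
    ).to_csv(out_dir / "fit_report.csv", index=False)


def cohort_records(
    cohort: list[tuple[CropSample, str]],
    table: HUBandTable | None = None,
    params: GraphParams | None = None,
    bands=hu_layers.PATHOLOGICAL_BANDS,
) -> tuple[list[CohortRecord], list[list[SampleAnalysis]]]:
    """Analyse every sample of a cohort; returns records plus full analyses."""
    records, all_analyses = [], []
    for i, (crop, group) in enumerate(cohort):
        sid = f"S{i:03d}"
        analyses = analyze_crop(crop, table, params, bands, sample_id=sid)
        all_analyses.append(analyses)
        for a in analyses:
            records.append(
                CohortRecord(
                    sample_id=sid,
                    group=group,
                    band_name=a.band_name,
                    metrics=a.metrics,
                )
            )
    return records, all_analyses


def run_cohort(
    cohort: list[tuple[CropSample, str]],
    out_dir: str | Path,
    table: HUBandTable | None = None,
    params: GraphParams | None = None,
    alpha: float = 0.05,
) -> dict:
    """Full lot analysis: cohort table, Welch reports, SD separation.

    Returns the in-memory results; writes ``cohort.csv``, ``welch_report.csv``
    and ``sd_separation.csv`` under ``out_dir``. If a group has fewer than
    two samples the statistical reports are skipped with a warning and the
    metrics table is still produced.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, _ = cohort_records(cohort, table, params)
    frame = cohort_stats.records_to_frame(records)
    frame.to_csv(out_dir / "cohort.csv", index=False)

    results: dict = {"records": records, "frame": frame}
    try:
        welch_rows, sd_rows = [], []
        for metric in cohort_stats.METRIC_NAMES:
            w = welch_metric_test(records, metric, band=None, alpha=alpha)
            s = w.as_series()
            s["metric"] = metric
            welch_rows.append(s)
            sd_d, sd_n, rel_d, rel_n = cohort_stats.sd_separation(
                records, metric, band=None
            )
            sd_rows.append(
                {
                    "metric": metric,
                    "band": "combined_pathological",
                    "sd_dild": sd_d,
                    "sd_normal": sd_n,
                    "rel_pct_dild": rel_d,
                    "rel_pct_normal": rel_n,
                }
            )
            results[f"welch_{metric}"] = w
        pd.DataFrame(welch_rows).to_csv(out_dir / "welch_report.csv",
                                        index=False)
        pd.DataFrame(sd_rows).to_csv(out_dir / "sd_separation.csv",
                                     index=False)
    except InsufficientDataError as exc:
        log.warning("statistical reports skipped: %s", exc)
        results["warning"] = str(exc)
    return results


def run_phantom_cohort(
    n_normal: int,
    n_dild: int,
    seed: int,
    out_dir: str | Path,
    params: GraphParams | None = None,
) -> dict:
    """Generate a phantom lot, analyse it, and write all cohort reports."""
    cohort = make_cohort(n_normal, n_dild, seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_manifest(cohort).to_csv(out_dir / "manifest.csv", index=False)
    log.info("phantom cohort: %d normal + %d dild, seed=%d",
             n_normal, n_dild, seed)
    results = run_cohort(cohort, out_dir, params=params)
    results["cohort"] = cohort
    return results
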