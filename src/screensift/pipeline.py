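"""End-to-end glue: score two bundles, derive the counter cutoff, run the
cascade, and compare against simulator truth."""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .deconvolution import Classification, classify_fold_table
from .filtering import CascadeConfig, CascadeReport, run_cascade
from .io import CounterScreenTable, ExpressionTable, ScreenBundle
from .scoring import GeneScore, score_bundle


def score_screens(
    primary_bundle: ScreenBundle, counter_bundle: ScreenBundle
) -> tuple[list[GeneScore], CounterScreenTable]:
    """Score the primary and counter screens with the default scheme.

    The counter-screen table carries per-pool mean Z plus the scrambled
    control well Z values the elimination cutoff is derived from (controls
    are scored against the sample location/scale of their replicate).
    """
    primary_scores, _ = score_bundle(primary_bundle)
    counter_scores, control_z = score_bundle(counter_bundle)
    counter = CounterScreenTable(
        pool_z={s.pool_id: s.mean_z for s in counter_scores},
        control_z=[float(z) for z in control_z],
    )
    return primary_scores, counter


def run_screen_pipeline(
    primary_bundle: ScreenBundle,
    counter_bundle: ScreenBundle,
    expression: ExpressionTable,
    config: CascadeConfig | None = None,
    deconvolution_table=None,
    rescue_fold: float = 2.0,
) -> CascadeReport:
    """Full pipeline from raw bundles to a cascade report.

    ``deconvolution_table`` is an optional long-format fold table (pool_id,
    sirna_id, fold_rescue); its classifications are attached per gene.
    """
    primary_scores, counter = score_screens(primary_bundle, counter_bundle)
    scores = {s.pool_id: s.mean_z for s in primary_scores}
    pool_gene = {s.pool_id: s.gene for s in primary_scores}

    deconv: Mapping[str, Classification] | None = None
    if deconvolution_table is not None:
        by_pool = classify_fold_table(deconvolution_table, rescue_fold)
        deconv = {
            pool_gene[pid]: res.classification
            for pid, res in by_pool.items()
            if pid in pool_gene
        }
    return run_cascade(scores, pool_gene, counter, expression, config, deconv)


def mean_control_ratio(bundle: ScreenBundle, role: str = "scrambled_control") -> float:
    """Mean normalized ratio of the given control wells across the bundle."""
    from .scoring import normalize_plate

    ratios = []
    for (plate_id, rep), layout in bundle.layouts.items():
        plate = normalize_plate(bundle.measurements.for_plate(plate_id, rep), layout)
        ratios += [
            r
            for well, r in plate.control_ratios.items()
            if layout.wells[well].role == role
        ]
    return float(np.mean(ratios))
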