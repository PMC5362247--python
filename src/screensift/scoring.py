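"""Plate normalization and robust Z scoring.

The scoring scheme is the classic plate-screen "median method":

1. per plate (and replicate), each sample-well signal is divided by the
   median of that plate's sample-well signals (controls never enter the
   median);
2. per replicate, a robust Z is computed over all sample ratios of the
   experiment: ``Z = (x - median(x)) / (1.4826 * MAD(x))``;
3. pools are summarized over replicates by the arithmetic mean of their
   per-replicate Z (with min/max retained) and the mean normalized ratio
   ("fold rescue").

An additive normalization (signal minus plate median) and per-plate Z
scaling are available for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import DegeneratePlateError, InsufficientDataError, ZeroDispersionError
from .io import PlateLayout, ScreenBundle, SiRNALibrary

#: Consistency constant making 1.4826 * MAD estimate sigma for a Gaussian.
MAD_SCALE = 1.4826

NormalizationMode = Literal["multiplicative", "additive"]
ZScope = Literal["experiment", "plate"]


@dataclass
class NormalizedPlate:
    plate_id: str
    replicate_id: str
    ratios: dict[str, float]          # sample well -> normalized value
    control_ratios: dict[str, float]  # control well -> normalized value (same scale)
    mode: NormalizationMode = "multiplicative"


@dataclass
class GeneScore:
    pool_id: str
    gene: str
    replicate_z: list[float]
    mean_z: float
    min_z: float
    max_z: float
    fold_rescue: float
    n_replicates: int = field(default=0)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.n_replicates:
            self.n_replicates = len(self.replicate_z)


def robust_z(values: Sequence[float]) -> np.ndarray:
    """Median/MAD Z-scores of ``values``: (x - med) / (1.4826 * MAD).

    Raises :class:`ZeroDispersionError` when the MAD is zero rather than
    silently dividing.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"robust Z needs >= 3 values, got {x.size}")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ZeroDispersionError("MAD is zero; robust Z undefined")
    return (x - med) / (MAD_SCALE * mad)


def robust_location_scale(values: Sequence[float]) -> tuple[float, float]:
    """(median, 1.4826*MAD) of ``values``; scale may be zero."""
    x = np.asarray(values, dtype=float)
    med = float(np.median(x))
    return med, MAD_SCALE * float(np.median(np.abs(x - med)))


def normalize_plate(
    signals: Mapping[str, float],
    layout: PlateLayout,
    mode: NormalizationMode = "multiplicative",
) -> NormalizedPlate:
    """Normalize one plate x replicate against its sample-well median.

    ``signals`` maps well address to raw signal. Control wells are normalized
    on the same scale but reported separately and never contribute to the
    median.
    """
    sample_wells = [w for w in layout.sample_wells if w in signals]
    if not sample_wells:
        raise DegeneratePlateError(
            f"plate {layout.plate_id} replicate {layout.replicate_id}: "
            "no measured sample wells"
        )
    sample_values = np.array([signals[w] for w in sample_wells], dtype=float)
    med = float(np.median(sample_values))
    if mode == "multiplicative":
        if med <= 0:
            raise DegeneratePlateError(
                f"plate {layout.plate_id}: sample median {med} <= 0"
            )
        norm = lambda v: v / med  # noqa: E731
    else:
        norm = lambda v: v - med  # noqa: E731

    ratios = {w: norm(signals[w]) for w in sample_wells}
    control_ratios = {
        w: norm(signals[w])
        for w, well in layout.wells.items()
        if well.role not in ("sample", "empty") and w in signals
    }
    return NormalizedPlate(
        plate_id=layout.plate_id,
        replicate_id=layout.replicate_id,
        ratios=ratios,
        control_ratios=control_ratios,
        mode=mode,
    )


def score_replicate(ratios: Mapping[str, float]) -> dict[str, float]:
    """Robust Z of every entry against the whole mapping (experiment-wide).

    Keys are arbitrary identifiers (wells or pools); values are normalized
    ratios of one replicate.
    """
    keys = list(ratios)
    z = robust_z([ratios[k] for k in keys])
    return dict(zip(keys, map(float, z)))


def summarize_scores(
    replicate_z: Sequence[Mapping[str, float]],
    replicate_ratios: Sequence[Mapping[str, float]],
    library: SiRNALibrary,
) -> tuple[list[GeneScore], list[str]]:
    """Summarize per-replicate pool Z maps and ratio maps into GeneScores.

    Pools absent from every replicate are returned in the exclusion list;
    pools present in only some replicates are flagged.
    """
    scores: list[GeneScore] = []
    excluded: list[str] = []
    n_reps = len(replicate_z)
    for pool_id in library.pools:
        zs = [zmap[pool_id] for zmap in replicate_z if pool_id in zmap]
        rs = [rmap[pool_id] for rmap in replicate_ratios if pool_id in rmap]
        if not zs:
            excluded.append(pool_id)
            continue
        flags = []
        if len(zs) == 1:
            flags.append("n=1")
        elif len(zs) < n_reps:
            flags.append(f"n={len(zs)}")
        scores.append(
            GeneScore(
                pool_id=pool_id,
                gene=library.gene_of(pool_id),
                replicate_z=[float(z) for z in zs],
                mean_z=float(np.mean(zs)),
                min_z=float(np.min(zs)),
                max_z=float(np.max(zs)),
                fold_rescue=float(np.mean(rs)) if rs else math.nan,
                n_replicates=len(zs),
                flags=flags,
            )
        )
    return scores, excluded


def score_bundle(
    bundle: ScreenBundle,
    mode: NormalizationMode = "multiplicative",
    scope: ZScope = "experiment",
    control_role: str = "scrambled_control",
) -> tuple[list[GeneScore], list[float]]:
    """End-to-end scoring of a screen bundle.

    Returns the pool GeneScores and the per-(control well, replicate) Z values
    of ``control_role`` wells, scored against the sample location/scale of
    their replicate (or plate, when ``scope='plate'``).
    """
    replicate_pool_z: list[dict[str, float]] = []
    replicate_pool_ratio: list[dict[str, float]] = []
    control_z: list[float] = []

    for rep in bundle.replicate_ids:
        plates = [
            normalize_plate(bundle.measurements.for_plate(p, rep), bundle.layouts[(p, rep)], mode)
            for p in bundle.plate_ids
            if (p, rep) in bundle.layouts
        ]
        pool_ratio: dict[str, float] = {}
        for plate in plates:
            layout = bundle.layouts[(plate.plate_id, rep)]
            for well, ratio in plate.ratios.items():
                pool_ratio[layout.wells[well].content_id] = ratio

        if scope == "experiment":
            pool_z = score_replicate(pool_ratio)
            med, scale = robust_location_scale(list(pool_ratio.values()))
            if scale > 0:
                for plate in plates:
                    layout = bundle.layouts[(plate.plate_id, rep)]
                    for well, ratio in plate.control_ratios.items():
                        if layout.wells[well].role == control_role:
                            control_z.append((ratio - med) / scale)
        else:  # per-plate scaling
            pool_z = {}
            for plate in plates:
                layout = bundle.layouts[(plate.plate_id, rep)]
                plate_z = score_replicate(plate.ratios)
                med, scale = robust_location_scale(list(plate.ratios.values()))
                for well, z in plate_z.items():
                    pool_z[layout.wells[well].content_id] = z
                if scale > 0:
                    for well, ratio in plate.control_ratios.items():
                        if layout.wells[well].role == control_role:
                            control_z.append((ratio - med) / scale)
        replicate_pool_z.append(pool_z)
        replicate_pool_ratio.append(pool_ratio)

    scores, _ = summarize_scores(replicate_pool_z, replicate_pool_ratio, bundle.library)
    return scores, control_z


def write_scores(scores: Sequence[GeneScore], path) -> None:
    """Write GeneScores as the canonical scores schema plus fold_rescue."""
    from .io import _write_tsv  # local import to keep io writer conventions

    rows = [
        [
            s.pool_id,
            s.gene,
            format(s.mean_z, ".6g"),
            format(s.fold_rescue, ".6g"),
            format(s.min_z, ".6g"),
            format(s.max_z, ".6g"),
            str(s.n_replicates),
        ]
        for s in sorted(scores, key=lambda s: -s.mean_z)
    ]
    _write_tsv(
        path,
        ["pool_id", "gene", "zscore", "fold_rescue", "min_z", "max_z", "n_replicates"],
        rows,
    )
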