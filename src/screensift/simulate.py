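"""Synthetic screen generator with known ground truth.

Emulates the statistical structure of an inducible-toxicity rescue screen:

- a lethal induction reduces non-rescued sample wells to a few percent of
  the uninduced signal (``kill_fraction``, default 4.7%);
- planted rescuer pools restore 30-75% viability;
- off-target pools score in the primary screen but owe their rescue to a
  single siRNA;
- induction-inhibitor pools rescue in BOTH screens and are driven negative
  in the reporter counter-screen;
- per-plate lognormal scale factors and multiplicative lognormal well noise.

Everything is driven by one integer seed through ``numpy.random.default_rng``
and is fully deterministic (no time or OS entropy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .deconvolution import Classification
from .errors import ConfigError, CrossReferenceError
from .filtering import CascadeReport
from .io import (
    ExpressionTable,
    MeasurementSet,
    PlateLayout,
    Pool,
    ScreenBundle,
    SiRNALibrary,
    Well,
)
from .kinetics import DecayTimeCourse

ROWS = "ABCDEFGHIJKLMNOP"
N_COLS = 24

CLASSES = ("true_rescuer", "offtarget_single", "dox_inhibitor", "null")


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and the requested CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


@dataclass
class SimConfig:
    """Knobs of the synthetic screen. ``seed`` is mandatory."""

    seed: int
    n_genes: int = 1000
    n_replicates: int = 3
    n_scrambled_per_plate: int = 16
    n_pos_control_per_plate: int = 4
    kill_fraction: float = 0.047
    rescue_range: tuple[float, float] = (0.30, 0.75)
    proportions: dict[str, float] = field(
        default_factory=lambda: {
            "true_rescuer": 0.02,
            "offtarget_single": 0.01,
            "dox_inhibitor": 0.01,
            "null": 0.96,
        }
    )
    synergy_fraction: float = 0.10        # of true rescuers
    low_expression_fraction: float = 0.10  # of non-rescuer genes
    plate_scale_sd: float = 0.05
    well_cv: float = 0.10
    pos_control_ratio: float = 80.0
    counter_inhibition_range: tuple[float, float] = (0.10, 0.40)
    baseline: float = 1.0e6

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if set(self.proportions) != set(CLASSES):
            raise ConfigError(f"proportions must cover exactly {CLASSES}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class proportions sum to {total}, expected 1")
        for name in ("kill_fraction", "synergy_fraction", "low_expression_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.well_cv < 0 or self.plate_scale_sd < 0:
            raise ConfigError("noise parameters must be >= 0")

    @property
    def samples_per_plate(self) -> int:
        return len(ROWS) * N_COLS - self.n_scrambled_per_plate - self.n_pos_control_per_plate


@dataclass
class TruthRecord:
    gene: str
    pool_id: str
    label: str                       # one of CLASSES
    survival: float                  # induced viability as fraction of uninduced
    sirna_folds: tuple[float, ...]   # noiseless per-siRNA fold rescue
    triple_fold: float               # noiseless fold of the 3 weakest siRNAs pooled
    expected_deconv: Classification
    fpkm: tuple[float, float]
    low_expression: bool


@dataclass
class SimTruth:
    records: dict[str, TruthRecord]  # gene -> record

    def genes_with_label(self, label: str) -> set[str]:
        return {g for g, r in self.records.items() if r.label == label}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "pool_id": r.pool_id,
                    "label": r.label,
                    "survival": r.survival,
                    "fpkm_minus_dox": r.fpkm[0],
                    "fpkm_plus_dox": r.fpkm[1],
                    "low_expression": r.low_expression,
                    "expected_deconv": r.expected_deconv.value,
                }
                for r in self.records.values()
            ]
        )


@dataclass
class SimScreen:
    dux4: ScreenBundle
    counter: ScreenBundle
    expression: ExpressionTable
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# Screen simulation
# ---------------------------------------------------------------------------


def _assign_classes(cfg: SimConfig, rng: np.random.Generator) -> list[str]:
    """Exact class counts (largest remainder), order shuffled by the rng."""
    raw = {c: cfg.proportions[c] * cfg.n_genes for c in CLASSES}
    counts = {c: int(math.floor(raw[c])) for c in CLASSES}
    short = cfg.n_genes - sum(counts.values())
    for c in sorted(CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    labels = [c for c in CLASSES for _ in range(counts[c])]
    return [labels[i] for i in rng.permutation(len(labels))]


def _make_layouts(cfg: SimConfig, n_plates: int) -> dict[str, dict[str, Well]]:
    """One plate map shared by all replicates: scrambled controls fill column
    1, positive controls the top of column 24, samples the rest row-major."""
    wells_template: list[tuple[str, str]] = []  # (address, role)
    scr = pos = 0
    for r, row in enumerate(ROWS):
        for col in range(1, N_COLS + 1):
            addr = f"{row}{col}"
            if col == 1 and scr < cfg.n_scrambled_per_plate:
                wells_template.append((addr, "scrambled_control"))
                scr += 1
            elif col == N_COLS and pos < cfg.n_pos_control_per_plate and r < cfg.n_pos_control_per_plate:
                wells_template.append((addr, "pos_control"))
                pos += 1
            else:
                wells_template.append((addr, "sample"))
    return {
        f"P{p + 1:02d}": {addr: role for addr, role in wells_template}
        for p in range(n_plates)
    }


def simulate_screen(config: SimConfig) -> SimScreen:
    """Generate matched primary and counter-screen bundles plus truth.

    Deterministic given ``config.seed``; calling twice with the same config
    yields identical bundles.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    labels = _assign_classes(cfg, rng)
    genes = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    pool_ids = [f"POOL{i + 1:04d}" for i in range(cfg.n_genes)]

    records: dict[str, TruthRecord] = {}
    for gene, pool_id, label in zip(genes, pool_ids, labels):
        if label == "null":
            survival = cfg.kill_fraction
        else:
            survival = float(rng.uniform(*cfg.rescue_range))
        fold_pool = survival / cfg.kill_fraction

        synergy = label == "true_rescuer" and rng.uniform() < cfg.synergy_fraction
        if label == "true_rescuer" and not synergy:
            folds = (fold_pool, fold_pool, fold_pool, 1.0)
            triple, expected = fold_pool, Classification.ON_TARGET_MULTI
        elif label == "true_rescuer":
            folds = (fold_pool, 1.2, 1.1, 1.0)
            triple, expected = fold_pool, Classification.ON_TARGET_SYNERGY
        elif label == "offtarget_single":
            folds = (fold_pool, 1.0, 1.0, 1.0)
            triple, expected = 1.0, Classification.SINGLE_DOMINANT
        elif label == "dox_inhibitor":
            folds = (fold_pool, fold_pool, fold_pool, 1.0)
            triple, expected = fold_pool, Classification.ON_TARGET_MULTI
        else:
            folds = (1.0, 1.0, 1.0, 1.0)
            triple, expected = 1.0, Classification.NO_RESCUE

        # Rescuers are by construction expressed genes; low expression is
        # planted only among the other classes (expression itself noiseless).
        low = label != "true_rescuer" and rng.uniform() < cfg.low_expression_fraction
        if low:
            fpkm = (float(rng.uniform(0.0, 0.45)), float(rng.uniform(0.0, 0.45)))
        else:
            fpkm = (float(rng.uniform(1.0, 50.0)), float(rng.uniform(1.0, 50.0)))
        records[gene] = TruthRecord(
            gene=gene,
            pool_id=pool_id,
            label=label,
            survival=survival,
            sirna_folds=folds,
            triple_fold=triple,
            expected_deconv=expected,
            fpkm=fpkm,
            low_expression=low,
        )
    truth = SimTruth(records)

    library = SiRNALibrary(
        {
            pid: Pool(gene=g, sirna_ids=tuple(f"{g}_s{j + 1}" for j in range(4)))
            for g, pid in zip(genes, pool_ids)
        }
    )

    n_plates = math.ceil(cfg.n_genes / cfg.samples_per_plate)
    plate_maps = _make_layouts(cfg, n_plates)

    # Assign pools to sample wells plate by plate, row-major; leftover sample
    # wells on the last plate are marked empty.
    pool_iter = iter(pool_ids)
    content: dict[tuple[str, str], tuple[str, str]] = {}  # (plate, addr) -> (role, content)
    for plate_id in sorted(plate_maps):
        for addr, role in plate_maps[plate_id].items():
            if role == "sample":
                pid = next(pool_iter, None)
                if pid is None:
                    content[(plate_id, addr)] = ("empty", "")
                else:
                    content[(plate_id, addr)] = ("sample", pid)
            elif role == "scrambled_control":
                content[(plate_id, addr)] = (role, "SCRAMBLED")
            else:
                content[(plate_id, addr)] = (role, "DUX4_SI1")

    rep_ids = [f"R{r + 1}" for r in range(cfg.n_replicates)]
    layouts = {
        (plate_id, rep): PlateLayout(
            plate_id=plate_id,
            replicate_id=rep,
            wells={
                addr: Well(role=content[(plate_id, addr)][0], content_id=content[(plate_id, addr)][1])
                for addr, _ in plate_maps[plate_id].items()
            },
        )
        for plate_id in sorted(plate_maps)
        for rep in rep_ids
    }

    pool_record = {r.pool_id: r for r in records.values()}

    def build_measurements(channel: str) -> MeasurementSet:
        rows = []
        for rep in rep_ids:
            for plate_id in sorted(plate_maps):
                factor = float(np.exp(rng.normal(0.0, cfg.plate_scale_sd))) if cfg.plate_scale_sd else 1.0
                for addr in plate_maps[plate_id]:
                    role, cid = content[(plate_id, addr)]
                    if role == "empty":
                        continue
                    if channel == "dux4":
                        if role == "sample":
                            v = pool_record[cid].survival
                        elif role == "scrambled_control":
                            v = cfg.kill_fraction
                        else:  # pos_control: anchored to the printed rescue ratio
                            v = cfg.kill_fraction * cfg.pos_control_ratio
                    else:  # counter-screen: only induction inhibitors move
                        if role == "sample" and pool_record[cid].label == "dox_inhibitor":
                            v = float(rng.uniform(*cfg.counter_inhibition_range))
                        else:
                            v = 1.0
                    noise = float(_mean_one_lognormal(rng, cfg.well_cv))
                    rows.append((plate_id, rep, addr, cfg.baseline * factor * v * noise))
        return MeasurementSet(
            pd.DataFrame(rows, columns=["plate_id", "replicate_id", "well", "signal"])
        )

    dux4 = ScreenBundle(layouts=layouts, measurements=build_measurements("dux4"), library=library)
    counter = ScreenBundle(
        layouts={k: replace(v) for k, v in layouts.items()},
        measurements=build_measurements("counter"),
        library=library,
    )
    expression = ExpressionTable({g: records[g].fpkm for g in genes})
    return SimScreen(dux4=dux4, counter=counter, expression=expression, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Deconvolution simulation
# ---------------------------------------------------------------------------


def simulate_deconvolution(
    truth: SimTruth, cv: float = 0.10, seed: int = 0
) -> pd.DataFrame:
    """Per-siRNA fold-rescue table for every pool in ``truth``.

    Output columns: pool_id, sirna_id, fold_rescue; each pool carries four
    siRNA rows plus one "POOL3" row for the pooled non-rescuing siRNAs.
    Noise is multiplicative mean-one lognormal with the given CV.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene in sorted(truth.records):
        r = truth.records[gene]
        for j, fold in enumerate(r.sirna_folds):
            rows.append((r.pool_id, f"{gene}_s{j + 1}", fold * float(_mean_one_lognormal(rng, cv))))
        rows.append((r.pool_id, "POOL3", r.triple_fold * float(_mean_one_lognormal(rng, cv))))
    return pd.DataFrame(rows, columns=["pool_id", "sirna_id", "fold_rescue"])


# ---------------------------------------------------------------------------
# Time-course simulation
# ---------------------------------------------------------------------------


def simulate_timecourse(
    half_life_min: float | None,
    times: Sequence[float],
    cv: float = 0.0,
    seed: int = 0,
    label: str = "sim",
) -> DecayTimeCourse:
    """Exponential-decay time course with multiplicative lognormal noise.

    ``half_life_min=None`` (or inf) simulates a non-decaying species. The
    series is renormalized so the first point is exactly 1.
    """
    if half_life_min is not None and not half_life_min > 0:
        raise ConfigError(f"half-life must be > 0, got {half_life_min}")
    if cv < 0:
        raise ConfigError("cv must be >= 0")
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    if half_life_min is None or math.isinf(half_life_min):
        clean = np.ones_like(t)
    else:
        clean = np.exp(-math.log(2.0) * t / half_life_min)
    noisy = clean * _mean_one_lognormal(rng, cv, size=t.size)
    noisy = noisy / noisy[0]
    return DecayTimeCourse(label=label, times=t, abundances=noisy)


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------


@dataclass
class RecoveryStats:
    sensitivity: float
    fdr: float
    confusion: dict[str, dict[str, int]]  # class -> {"positive": n, "negative": n}

    @property
    def total(self) -> int:
        return sum(v["positive"] + v["negative"] for v in self.confusion.values())


def evaluate_recovery(
    report: CascadeReport | Mapping[str, bool] | Sequence[str],
    truth: SimTruth,
) -> RecoveryStats:
    """Compare pipeline verdicts with planted truth.

    ``report`` may be a CascadeReport (final_pass per gene; genes missing from
    the report count as negative), a gene->bool mapping, or a collection of
    positive gene names. Sensitivity is computed over the true_rescuer class;
    FDR = FP/(TP+FP), defined as 0 when nothing is called positive.
    """
    if isinstance(report, CascadeReport):
        positives = set(report.final_genes)
    elif isinstance(report, Mapping):
        positives = {g for g, flag in report.items() if flag}
    else:
        positives = set(report)
    unknown = positives - set(truth.records)
    if unknown:
        raise CrossReferenceError(
            f"verdicts reference genes absent from truth: {sorted(unknown)[:5]}"
        )

    confusion = {c: {"positive": 0, "negative": 0} for c in CLASSES}
    for gene, rec in truth.records.items():
        key = "positive" if gene in positives else "negative"
        confusion[rec.label][key] += 1

    tp = confusion["true_rescuer"]["positive"]
    fn = confusion["true_rescuer"]["negative"]
    fp = len(positives) - tp
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    return RecoveryStats(sensitivity=sensitivity, fdr=fdr, confusion=confusion)
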