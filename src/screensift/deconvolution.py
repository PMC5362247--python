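"""Pool deconvolution: on-target vs single-siRNA-dominated classification.

A pool of (typically four) siRNAs is retested one siRNA at a time. Each
siRNA's viability fold rescue is measured relative to the non-silencing
control under induction. Rules, with the rescue threshold defaulting to
2-fold (inclusive):

- >= 2 rescuing siRNAs            -> on_target_multi
- exactly 1 rescuing siRNA        -> single_dominant (off-target suspect)
- 0 rescuing siRNAs               -> no_rescue

A single_dominant pool can be promoted to on_target_synergy when the pool of
its individually non-rescuing siRNAs rescues at or above the threshold.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import DomainError, InsufficientDataError, StateError


class Classification(str, enum.Enum):
    NO_RESCUE = "no_rescue"
    SINGLE_DOMINANT = "single_dominant"
    ON_TARGET_MULTI = "on_target_multi"
    ON_TARGET_SYNERGY = "on_target_synergy"


#: Ordering used by the monotonicity property: raising a fold value may only
#: move a pool rightward in this sequence.
CLASS_ORDER = {
    Classification.NO_RESCUE: 0,
    Classification.SINGLE_DOMINANT: 1,
    Classification.ON_TARGET_MULTI: 2,
    Classification.ON_TARGET_SYNERGY: 2,
}


@dataclass
class DeconvolutionResult:
    pool_id: str
    fold_rescue_per_sirna: list[float]
    classification: Classification
    synergy_fold: float | None = None


def _validate_folds(folds: Sequence[float]) -> None:
    if len(folds) < 2:
        raise InsufficientDataError(f"deconvolution needs >= 2 siRNA folds, got {len(folds)}")
    for f in folds:
        if not math.isfinite(f) or f < 0:
            raise DomainError(f"fold rescue must be finite and >= 0, got {f}")


def classify_deconvolution(
    fold_rescues: Sequence[float], rescue_fold: float = 2.0
) -> Classification:
    """Classify a deconvoluted pool from its per-siRNA fold rescues.

    Order-invariant; the comparator is inclusive (fold >= rescue_fold counts
    as rescuing).
    """
    _validate_folds(fold_rescues)
    n_rescuing = sum(f >= rescue_fold for f in fold_rescues)
    if n_rescuing >= 2:
        return Classification.ON_TARGET_MULTI
    if n_rescuing == 1:
        return Classification.SINGLE_DOMINANT
    return Classification.NO_RESCUE


def classify_synergy(
    prior: Classification, triple_pool_fold: float, rescue_fold: float = 2.0
) -> Classification:
    """Resolve a single_dominant pool using its non-rescuing-siRNA pool.

    ``triple_pool_fold`` is the fold rescue of the individually non-rescuing
    siRNAs re-transfected as one pool. At or above ``rescue_fold`` the pool is
    promoted to on_target_synergy; below, it stays single_dominant.
    """
    if prior is not Classification.SINGLE_DOMINANT:
        raise StateError(f"classify_synergy requires a single_dominant prior, got {prior}")
    if not math.isfinite(triple_pool_fold) or triple_pool_fold < 0:
        raise DomainError(f"triple pool fold must be finite and >= 0, got {triple_pool_fold}")
    if triple_pool_fold >= rescue_fold:
        return Classification.ON_TARGET_SYNERGY
    return Classification.SINGLE_DOMINANT


def classify_pool(
    pool_id: str,
    fold_rescues: Sequence[float],
    triple_pool_fold: float | None = None,
    rescue_fold: float = 2.0,
) -> DeconvolutionResult:
    """Full per-pool classification, applying the synergy rule when a triple
    pool measurement is available."""
    classification = classify_deconvolution(fold_rescues, rescue_fold)
    if classification is Classification.SINGLE_DOMINANT and triple_pool_fold is not None:
        classification = classify_synergy(classification, triple_pool_fold, rescue_fold)
    return DeconvolutionResult(
        pool_id=pool_id,
        fold_rescue_per_sirna=list(fold_rescues),
        classification=classification,
        synergy_fold=triple_pool_fold,
    )


def classify_fold_table(table, rescue_fold: float = 2.0) -> dict[str, DeconvolutionResult]:
    """Classify every pool in a long-format fold table.

    ``table`` is a pandas DataFrame with columns (pool_id, sirna_id,
    fold_rescue); rows whose sirna_id is "POOL3" carry the pooled
    non-rescuing-siRNA measurement used by the synergy rule.
    """
    results: dict[str, DeconvolutionResult] = {}
    for pool_id, group in table.groupby("pool_id", sort=True):
        triple_rows = group[group["sirna_id"] == "POOL3"]
        singles = group[group["sirna_id"] != "POOL3"]
        triple = float(triple_rows["fold_rescue"].iloc[0]) if len(triple_rows) else None
        results[pool_id] = classify_pool(
            pool_id,
            [float(f) for f in singles["fold_rescue"]],
            triple_pool_fold=triple,
            rescue_fold=rescue_fold,
        )
    return results


def normalize_to_control(
    viabilities: Mapping[str, float], control_viability: float
) -> dict[str, float]:
    """Convert raw viability readings into fold rescues relative to the
    non-silencing control under induction."""
    if not math.isfinite(control_viability) or control_viability <= 0:
        raise DomainError(f"control viability must be > 0, got {control_viability}")
    return {k: v / control_viability for k, v in viabilities.items()}
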