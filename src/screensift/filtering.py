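"""Hit calling and the secondary-screen filter cascade.

The cascade runs, in order:

1. primary threshold hit calling on pool mean Z (enhancers ``Z >=`` cutoff,
   sensitizers ``Z <`` cutoff);
2. counter-screen elimination of pools whose reporter-induction Z is at or
   below a cutoff derived from scrambled controls (``min(control Z)``);
3. collapse to gene level (best pool per gene) and an expression filter
   (pass iff either condition's mean FPKM strictly exceeds the cutoff);
4. optional deconvolution verdicts attached per gene: genes classified as
   single-siRNA-dominated (or non-rescuing) fail.

Candidates missing from the counter-screen or deconvolution tables are
retained with a flag, never silently dropped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, NamedTuple

from scipy import stats

from .deconvolution import Classification
from .errors import ConfigError, InsufficientDataError
from .io import CounterScreenTable, ExpressionTable

ExpressionRule = Literal["either", "overall_mean"]


class HitSets(NamedTuple):
    enhancers: set[str]
    sensitizers: set[str]


class FilterResult(NamedTuple):
    retained: set[str]
    eliminated: set[str]
    flagged: set[str]  # retained-with-flag subset (untested / no data)


def call_hits(
    scores: Mapping[str, float],
    z_enhancer: float = 3.0,
    z_sensitizer: float = -2.0,
) -> HitSets:
    """Split pools into enhancers (Z >= z_enhancer) and sensitizers
    (Z < z_sensitizer, strict)."""
    if not (math.isfinite(z_enhancer) and math.isfinite(z_sensitizer)):
        raise ConfigError("thresholds must be finite")
    if z_enhancer <= z_sensitizer:
        raise ConfigError("z_enhancer must exceed z_sensitizer")
    enhancers = {p for p, z in scores.items() if z >= z_enhancer}
    sensitizers = {p for p, z in scores.items() if z < z_sensitizer}
    return HitSets(enhancers, sensitizers)


def counterscreen_threshold(control_z: Iterable[float]) -> float:
    """Elimination cutoff: the minimum scrambled-control Z."""
    control_z = list(control_z)
    if not control_z:
        raise ConfigError(
            "cannot derive counter-screen cutoff: no control Z values "
            "(supply a manual threshold)"
        )
    return min(control_z)


def apply_counterscreen(
    candidates: Iterable[str],
    counter: CounterScreenTable,
    threshold: float | None = None,
) -> FilterResult:
    """Eliminate candidates with counter-screen Z <= threshold (inclusive).

    Candidates absent from the counter table are retained and flagged
    "untested". When ``threshold`` is None it is derived from the table's
    scrambled controls.
    """
    if threshold is None:
        threshold = counterscreen_threshold(counter.control_z)
    retained, eliminated, untested = set(), set(), set()
    for pool in candidates:
        z = counter.pool_z.get(pool)
        if z is None:
            retained.add(pool)
            untested.add(pool)
        elif z <= threshold:
            eliminated.add(pool)
        else:
            retained.add(pool)
    return FilterResult(retained, eliminated, untested)


def apply_expression_filter(
    genes: Iterable[str],
    expression: ExpressionTable,
    min_fpkm: float = 0.5,
    rule: ExpressionRule = "either",
) -> FilterResult:
    """Keep genes expressed above ``min_fpkm`` (strict >).

    ``rule='either'``: pass iff either condition's mean FPKM exceeds the
    cutoff. ``rule='overall_mean'``: pass iff the mean of the two condition
    means exceeds it. Genes absent from the table fail, flagged
    "no expression data".
    """
    if min_fpkm < 0:
        raise ConfigError("min_fpkm must be >= 0")
    retained, eliminated, missing = set(), set(), set()
    for gene in genes:
        fpkm = expression.get(gene)
        if fpkm is None:
            eliminated.add(gene)
            missing.add(gene)
            continue
        lo, hi = fpkm
        value = max(lo, hi) if rule == "either" else (lo + hi) / 2.0
        (retained if value > min_fpkm else eliminated).add(gene)
    return FilterResult(retained, eliminated, missing)


def screen_correlation(
    primary: Mapping[str, float], counter: Mapping[str, float]
) -> tuple[float, int]:
    """Spearman rank correlation of the two Z maps over their shared pools.

    Uses average ranks for ties. Returns (rho, n_shared).
    """
    shared = sorted(set(primary) & set(counter))
    if len(shared) < 3:
        raise InsufficientDataError(
            f"screen correlation needs >= 3 shared pools, got {len(shared)}"
        )
    rho = stats.spearmanr([primary[p] for p in shared], [counter[p] for p in shared]).statistic
    return float(rho), len(shared)


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

_PASSING_DECONV = {Classification.ON_TARGET_MULTI, Classification.ON_TARGET_SYNERGY}


@dataclass
class CascadeConfig:
    z_enhancer: float = 3.0
    z_sensitizer: float = -2.0
    counter_threshold: float | None = None  # None -> derive from controls
    min_fpkm: float = 0.5
    expression_rule: ExpressionRule = "either"


@dataclass
class GeneVerdict:
    gene: str
    pool_id: str
    primary_z: float
    primary_hit: bool
    counter_z: float | None
    counter_pass: bool
    fpkm: tuple[float, float] | None
    expression_pass: bool
    deconvolution_status: str | None
    final_pass: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class CascadeReport:
    verdicts: list[GeneVerdict]           # ordered by primary_z descending
    stage_counts: dict[str, int]
    counter_threshold: float

    @property
    def final_genes(self) -> list[str]:
        return [v.gene for v in self.verdicts if v.final_pass]

    def to_dict(self) -> dict:
        return {
            "counter_threshold": self.counter_threshold,
            "stage_counts": self.stage_counts,
            "final_genes": self.final_genes,
            "genes": [
                {
                    "gene": v.gene,
                    "pool_id": v.pool_id,
                    "primary_z": v.primary_z,
                    "primary_hit": v.primary_hit,
                    "counter_z": v.counter_z,
                    "counter_pass": v.counter_pass,
                    "fpkm_minus_dox": None if v.fpkm is None else v.fpkm[0],
                    "fpkm_plus_dox": None if v.fpkm is None else v.fpkm[1],
                    "expression_pass": v.expression_pass,
                    "deconvolution_status": v.deconvolution_status,
                    "final_pass": v.final_pass,
                    "flags": v.flags,
                }
                for v in self.verdicts
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def to_table(self, path) -> None:
        """Write a summary TSV of the passing genes, best pool first."""
        from .io import _write_tsv

        rows = [
            [
                v.gene,
                format(v.primary_z, ".6g"),
                "" if v.counter_z is None else format(v.counter_z, ".6g"),
                "" if v.fpkm is None else format(v.fpkm[0], ".6g"),
                "" if v.fpkm is None else format(v.fpkm[1], ".6g"),
            ]
            for v in self.verdicts
            if v.final_pass
        ]
        _write_tsv(
            path,
            ["gene", "primary_z", "counter_z", "fpkm_minus_dox", "fpkm_plus_dox"],
            rows,
        )


def run_cascade(
    scores: Mapping[str, float],
    pool_gene: Mapping[str, str],
    counter: CounterScreenTable,
    expression: ExpressionTable,
    config: CascadeConfig | None = None,
    deconvolution: Mapping[str, Classification] | None = None,
) -> CascadeReport:
    """Run the full filter cascade and produce a per-gene report.

    ``scores`` maps pool -> mean primary Z; ``pool_gene`` maps pool -> gene.
    ``deconvolution`` optionally maps gene -> Classification; genes with a
    verdict outside the on-target classes fail, genes without one pass
    through with a flag.
    """
    cfg = config or CascadeConfig()
    threshold = (
        cfg.counter_threshold
        if cfg.counter_threshold is not None
        else counterscreen_threshold(counter.control_z)
    )

    enhancers, _ = call_hits(scores, cfg.z_enhancer, cfg.z_sensitizer)
    counter_result = apply_counterscreen(enhancers, counter, threshold)

    # Collapse surviving pools to gene level: best pool (highest primary Z).
    best_pool: dict[str, str] = {}
    for pool in counter_result.retained:
        gene = pool_gene[pool]
        if gene not in best_pool or scores[pool] > scores[best_pool[gene]]:
            best_pool[gene] = pool
    expr_result = apply_expression_filter(
        best_pool, expression, cfg.min_fpkm, cfg.expression_rule
    )

    verdicts: list[GeneVerdict] = []
    # Report at gene level over all enhancer pools (eliminated ones included).
    gene_pools: dict[str, list[str]] = {}
    for pool in enhancers:
        gene_pools.setdefault(pool_gene[pool], []).append(pool)
    for gene, pools in gene_pools.items():
        pool = best_pool.get(gene) or max(pools, key=lambda p: scores[p])
        counter_pass = pool in counter_result.retained
        expression_pass = gene in expr_result.retained
        status = deconvolution.get(gene) if deconvolution else None
        deconv_pass = status is None or status in _PASSING_DECONV
        flags = []
        if pool in counter_result.flagged:
            flags.append("counter_untested")
        if gene in expr_result.flagged:
            flags.append("no expression data")
        if deconvolution is not None and status is None:
            flags.append("no deconvolution data")
        verdicts.append(
            GeneVerdict(
                gene=gene,
                pool_id=pool,
                primary_z=scores[pool],
                primary_hit=True,
                counter_z=counter.pool_z.get(pool),
                counter_pass=counter_pass,
                fpkm=expression.get(gene),
                expression_pass=expression_pass,
                deconvolution_status=None if status is None else status.value,
                final_pass=counter_pass and expression_pass and deconv_pass,
                flags=flags,
            )
        )
    verdicts.sort(key=lambda v: -v.primary_z)

    stage_counts = {
        "scored_pools": len(scores),
        "primary_hits": len(enhancers),
        "counter_retained": len(counter_result.retained),
        "counter_eliminated": len(counter_result.eliminated),
        "genes_after_counter": len(best_pool),
        "expression_retained": len(expr_result.retained),
        "final": sum(v.final_pass for v in verdicts),
    }
    return CascadeReport(verdicts=verdicts, stage_counts=stage_counts, counter_threshold=threshold)
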