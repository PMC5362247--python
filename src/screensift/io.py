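"""Tabular I/O for screen artifacts.

All files are delimited text with a mandatory header row. The canonical
dialect is tab-separated UTF-8; comma-separated input is accepted via the
``sep`` argument. Well addresses are canonicalized to row letter plus column
number without leading zeros ("A01" -> "A1").

Schemas (canonical column names):

========== =====================================================
layout       plate_id, replicate_id, well, role, content_id
measurements plate_id, replicate_id, well, signal
library      pool_id, gene, sirna_id, isoform_note
scores       pool_id, gene, zscore  (writer adds fold_rescue)
expression   gene, fpkm_minus_dox, fpkm_plus_dox
========== =====================================================
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import (
    ConfigError,
    CrossReferenceError,
    EmptyInputError,
    ParseError,
    SchemaError,
)

logger = logging.getLogger(__name__)

ROLES = frozenset({"sample", "pos_control", "neg_control", "scrambled_control", "empty"})

_WELL_RE = re.compile(r"^([A-Pa-p])0*([1-9]\d?)$")

#: Values treated as missing in numeric columns.
NA_STRINGS = frozenset({"", "NA", "NaN", "nan", "na", "N/A"})


def canonical_well(address: str) -> str:
    """Canonicalize a 384-well address (rows A-P, columns 1-24).

    Leading zeros in the column are tolerated ("B07" == "B7"); output never
    carries them.

    >>> canonical_well("a01")
    'A1'
    """
    m = _WELL_RE.match(str(address).strip())
    if not m:
        raise SchemaError(f"invalid well address {address!r} (expected A1..P24)")
    row, col = m.group(1).upper(), int(m.group(2))
    if col > 24:
        raise SchemaError(f"invalid well address {address!r}: column {col} > 24")
    return f"{row}{col}"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Well:
    role: str
    content_id: str


@dataclass
class PlateLayout:
    """Well-role map of one physical plate in one replicate."""

    plate_id: str
    replicate_id: str
    wells: dict[str, Well]

    def __post_init__(self) -> None:
        for addr, well in self.wells.items():
            if well.role not in ROLES:
                raise SchemaError(
                    f"plate {self.plate_id}: well {addr} has invalid role {well.role!r}"
                )
            if well.role == "sample" and not well.content_id:
                raise SchemaError(
                    f"plate {self.plate_id}: sample well {addr} lacks a pool identifier"
                )
        if not self.sample_wells:
            raise SchemaError(f"plate {self.plate_id}: no sample wells")

    @property
    def sample_wells(self) -> dict[str, Well]:
        return {a: w for a, w in self.wells.items() if w.role == "sample"}

    def wells_with_role(self, role: str) -> dict[str, Well]:
        return {a: w for a, w in self.wells.items() if w.role == role}


@dataclass
class MeasurementSet:
    """Long-format luminescence records, one per (plate, replicate, well)."""

    table: pd.DataFrame  # columns plate_id, replicate_id, well, signal

    def __post_init__(self) -> None:
        required = ["plate_id", "replicate_id", "well", "signal"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise SchemaError(f"measurement table missing columns {missing}")
        dup = self.table.duplicated(["plate_id", "replicate_id", "well"])
        if dup.any():
            row = self.table[dup].iloc[0]
            raise SchemaError(
                "duplicate measurement for plate "
                f"{row['plate_id']} replicate {row['replicate_id']} well {row['well']}"
            )
        sig = self.table["signal"]
        if not (sig.map(math.isfinite)).all() or (sig < 0).any():
            raise SchemaError("measurement signals must be finite and >= 0")

    def for_plate(self, plate_id: str, replicate_id: str) -> Mapping[str, float]:
        sub = self.table[
            (self.table["plate_id"] == plate_id)
            & (self.table["replicate_id"] == replicate_id)
        ]
        return dict(zip(sub["well"], sub["signal"].astype(float)))


@dataclass(frozen=True)
class Pool:
    gene: str
    sirna_ids: tuple[str, ...]
    isoform_notes: tuple[str, ...] = ()


@dataclass
class SiRNALibrary:
    pools: dict[str, Pool]

    def __post_init__(self) -> None:
        for pool_id, pool in self.pools.items():
            if len(pool.sirna_ids) < 1:
                raise SchemaError(f"pool {pool_id} has no siRNAs")

    def gene_of(self, pool_id: str) -> str:
        return self.pools[pool_id].gene

    @property
    def pool_to_gene(self) -> dict[str, str]:
        return {pid: p.gene for pid, p in self.pools.items()}


@dataclass
class ExpressionTable:
    """Mean FPKM per gene in the uninduced / induced conditions."""

    values: dict[str, tuple[float, float]]  # gene -> (fpkm_minus_dox, fpkm_plus_dox)

    def __post_init__(self) -> None:
        for gene, (lo, hi) in self.values.items():
            if not (math.isfinite(lo) and math.isfinite(hi)) or lo < 0 or hi < 0:
                raise SchemaError(f"gene {gene}: FPKM values must be finite and >= 0")

    def __contains__(self, gene: str) -> bool:
        return gene in self.values

    def get(self, gene: str) -> tuple[float, float] | None:
        return self.values.get(gene)


@dataclass
class ScreenBundle:
    """Validated, cross-referenced in-memory screen."""

    layouts: dict[tuple[str, str], PlateLayout]  # (plate_id, replicate_id) -> layout
    measurements: MeasurementSet
    library: SiRNALibrary

    @property
    def replicate_ids(self) -> list[str]:
        return sorted({rep for _, rep in self.layouts})

    @property
    def plate_ids(self) -> list[str]:
        return sorted({plate for plate, _ in self.layouts})


@dataclass
class CounterScreenTable:
    """Mean counter-screen Z per pool plus the scrambled-control Z values the
    elimination cutoff is derived from."""

    pool_z: dict[str, float]
    control_z: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, columns: list[str], sep: str = "\t") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    return df


def _to_float(value: str, path: Path, line: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(
            f"{path.name} line {line}: non-numeric {column} value {value!r}"
        ) from None


def read_layouts(path: str | Path, sep: str = "\t") -> dict[tuple[str, str], PlateLayout]:
    df = _read_table(path, ["plate_id", "replicate_id", "well", "role", "content_id"], sep)
    layouts: dict[tuple[str, str], dict[str, Well]] = {}
    for _, row in df.iterrows():
        key = (row["plate_id"], row["replicate_id"])
        addr = canonical_well(row["well"])
        wells = layouts.setdefault(key, {})
        if addr in wells:
            raise SchemaError(
                f"duplicate well address {addr} on plate {key[0]} replicate {key[1]}"
            )
        wells[addr] = Well(role=row["role"], content_id=row["content_id"])
    return {
        key: PlateLayout(plate_id=key[0], replicate_id=key[1], wells=wells)
        for key, wells in layouts.items()
    }


def read_measurements(path: str | Path, sep: str = "\t") -> MeasurementSet:
    path = Path(path)
    df = _read_table(path, ["plate_id", "replicate_id", "well", "signal"], sep)
    signals = [
        _to_float(v, path, i + 2, "signal")  # +2: header is line 1
        for i, v in enumerate(df["signal"])
    ]
    out = df.assign(well=[canonical_well(w) for w in df["well"]], signal=signals)
    return MeasurementSet(out[["plate_id", "replicate_id", "well", "signal"]])


def read_library(path: str | Path, sep: str = "\t") -> SiRNALibrary:
    df = _read_table(path, ["pool_id", "gene", "sirna_id"], sep)
    if "isoform_note" not in df.columns:
        df = df.assign(isoform_note="")
    pools: dict[str, Pool] = {}
    for pool_id, group in df.groupby("pool_id", sort=False):
        genes = set(group["gene"])
        if len(genes) > 1:
            raise SchemaError(f"pool {pool_id} maps to multiple genes {sorted(genes)}")
        pools[pool_id] = Pool(
            gene=genes.pop(),
            sirna_ids=tuple(group["sirna_id"]),
            isoform_notes=tuple(group["isoform_note"]),
        )
    return SiRNALibrary(pools)


def load_screen_bundle(
    layout_path: str | Path,
    measurement_path: str | Path,
    library_path: str | Path,
    sep: str = "\t",
) -> ScreenBundle:
    """Load and cross-validate a layout/measurements/library triple.

    Raises :class:`CrossReferenceError` if a measurement addresses a well not
    present in its layout, or a sample well carries a pool identifier absent
    from the library.
    """
    layouts = read_layouts(layout_path, sep)
    measurements = read_measurements(measurement_path, sep)
    library = read_library(library_path, sep)

    for _, row in measurements.table.iterrows():
        key = (row["plate_id"], row["replicate_id"])
        if key not in layouts:
            raise CrossReferenceError(
                f"measurement references unknown plate {key[0]} replicate {key[1]}"
            )
        if row["well"] not in layouts[key].wells:
            raise CrossReferenceError(
                f"measurement references unknown well {row['well']} on plate {key[0]}"
            )
    for layout in layouts.values():
        for addr, well in layout.sample_wells.items():
            if well.content_id not in library.pools:
                raise CrossReferenceError(
                    f"plate {layout.plate_id} well {addr}: pool "
                    f"{well.content_id!r} not in library"
                )
    return ScreenBundle(layouts=layouts, measurements=measurements, library=library)


# ---------------------------------------------------------------------------
# Score / expression tables (supplementary-style exports)
# ---------------------------------------------------------------------------

DEFAULT_COLUMN_MAP = {
    "pool_id": "pool_id",
    "gene": "gene",
    "zscore": "zscore",
    "fpkm_minus_dox": "fpkm_minus_dox",
    "fpkm_plus_dox": "fpkm_plus_dox",
}

#: Gene label marking scrambled-control rows in a counter-screen score export.
CONTROL_GENE_LABEL = "SCRAMBLED"


def read_score_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
    control_label: str = CONTROL_GENE_LABEL,
) -> tuple[dict[str, float], dict[str, str], list[float], int]:
    """Read a (pool, gene, zscore) export.

    Returns ``(pool_z, pool_gene, control_z, n_dropped)``. Rows whose gene
    equals ``control_label`` are collected into ``control_z`` instead of the
    pool map; rows with a missing Z are dropped and counted.
    """
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    df = pd.read_csv(Path(path), sep=sep, dtype=str, keep_default_na=False)
    for logical in ("pool_id", "gene", "zscore"):
        if cmap[logical] not in df.columns:
            raise ConfigError(
                f"{Path(path).name}: column {cmap[logical]!r} (for {logical}) not found; "
                "adjust the column mapping"
            )
    pool_z: dict[str, float] = {}
    pool_gene: dict[str, str] = {}
    control_z: list[float] = []
    dropped = 0
    for _, row in df.iterrows():
        raw = row[cmap["zscore"]].strip()
        if raw in NA_STRINGS:
            dropped += 1
            continue
        z = float(raw)
        gene = row[cmap["gene"]]
        if gene == control_label:
            control_z.append(z)
        else:
            pool_z[row[cmap["pool_id"]]] = z
            pool_gene[row[cmap["pool_id"]]] = gene
    if not pool_z and not control_z:
        raise EmptyInputError(f"{Path(path).name}: zero parseable score rows")
    if dropped:
        logger.info("%s: dropped %d rows with missing Z", Path(path).name, dropped)
    return pool_z, pool_gene, control_z, dropped


def read_expression_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> ExpressionTable:
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    df = pd.read_csv(Path(path), sep=sep, dtype=str, keep_default_na=False)
    for logical in ("gene", "fpkm_minus_dox", "fpkm_plus_dox"):
        if cmap[logical] not in df.columns:
            raise ConfigError(
                f"{Path(path).name}: column {cmap[logical]!r} (for {logical}) not found"
            )
    values: dict[str, tuple[float, float]] = {}
    dropped = 0
    for _, row in df.iterrows():
        lo, hi = row[cmap["fpkm_minus_dox"]].strip(), row[cmap["fpkm_plus_dox"]].strip()
        if lo in NA_STRINGS or hi in NA_STRINGS:
            dropped += 1
            continue
        values[row[cmap["gene"]]] = (float(lo), float(hi))
    if not values:
        raise EmptyInputError(f"{Path(path).name}: zero parseable expression rows")
    if dropped:
        logger.info("%s: dropped %d rows with missing FPKM", Path(path).name, dropped)
    return ExpressionTable(values)


def load_score_tables(
    primary_path: str | Path,
    counter_path: str | Path,
    expression_path: str | Path,
    column_maps: Mapping[str, Mapping[str, str]] | None = None,
    sep: str = "\t",
) -> tuple[dict[str, float], dict[str, str], CounterScreenTable, ExpressionTable]:
    """Ingest primary-score, counter-score, and expression exports.

    ``column_maps`` may carry per-file mappings under keys ``primary``,
    ``counter`` and ``expression``.
    """
    maps = column_maps or {}
    primary_z, pool_gene, _, _ = read_score_table(primary_path, maps.get("primary"), sep)
    counter_z, _, control_z, _ = read_score_table(counter_path, maps.get("counter"), sep)
    expression = read_expression_table(expression_path, maps.get("expression"), sep)
    return primary_z, pool_gene, CounterScreenTable(counter_z, control_z), expression


# ---------------------------------------------------------------------------
# Writers (canonical TSV: sorted rows, no leading zeros, trailing newline)
# ---------------------------------------------------------------------------


def _write_tsv(path: str | Path, header: list[str], rows: Iterable[list[str]]) -> None:
    lines = ["\t".join(header)]
    lines += ["\t".join(r) for r in rows]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _well_sort_key(addr: str) -> tuple[str, int]:
    return addr[0], int(addr[1:])


def write_layouts(layouts: Mapping[tuple[str, str], PlateLayout], path: str | Path) -> None:
    rows = []
    for (plate, rep) in sorted(layouts):
        layout = layouts[(plate, rep)]
        for addr in sorted(layout.wells, key=_well_sort_key):
            w = layout.wells[addr]
            rows.append([plate, rep, addr, w.role, w.content_id])
    _write_tsv(path, ["plate_id", "replicate_id", "well", "role", "content_id"], rows)


def write_measurements(measurements: MeasurementSet, path: str | Path) -> None:
    df = measurements.table.copy()
    df["_wk"] = df["well"].map(_well_sort_key)
    df = df.sort_values(["plate_id", "replicate_id", "_wk"])
    rows = [
        [r["plate_id"], r["replicate_id"], r["well"], format(r["signal"], ".10g")]
        for _, r in df.iterrows()
    ]
    _write_tsv(path, ["plate_id", "replicate_id", "well", "signal"], rows)


def write_library(library: SiRNALibrary, path: str | Path) -> None:
    rows = []
    for pool_id in sorted(library.pools):
        pool = library.pools[pool_id]
        notes = pool.isoform_notes or ("",) * len(pool.sirna_ids)
        for sid, note in zip(pool.sirna_ids, notes):
            rows.append([pool_id, pool.gene, sid, note])
    _write_tsv(path, ["pool_id", "gene", "sirna_id", "isoform_note"], rows)


def write_expression(expression: ExpressionTable, path: str | Path) -> None:
    rows = [
        [gene, format(lo, ".10g"), format(hi, ".10g")]
        for gene, (lo, hi) in sorted(expression.values.items())
    ]
    _write_tsv(path, ["gene", "fpkm_minus_dox", "fpkm_plus_dox"], rows)


def write_bundle(bundle: ScreenBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_layouts(bundle.layouts, out / "layout.tsv")
    write_measurements(bundle.measurements, out / "measurements.tsv")
    write_library(bundle.library, out / "library.tsv")


def read_bundle(in_dir: str | Path) -> ScreenBundle:
    d = Path(in_dir)
    return load_screen_bundle(d / "layout.tsv", d / "measurements.tsv", d / "library.tsv")
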