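"""QTL compendium: data model, TSV I/O and confidence-interval standardization.

A meta-QTL analysis starts from a table of published QTLs curated from
independent mapping studies. Each record carries the study's population
design (type and size), the QTL peak position on that study's genetic map,
the phenotypic variance explained (PVE, written R²), and, when the source
reported one, a 95% positional confidence interval. Records lacking a
reported interval get one from the population-specific empirical relation
between interval width, population size N and R²:

    width = 530 / (N * R²)            F2-like designs (F2, F2:3, BC)
    width = 163 / (N * R²)            inbred-line designs (RIL, BIL)
    width = 97.462 / (N * R²)^0.835   doubled haploids (DH)

The width shrinks with both mapping-population size and QTL effect, which
is what makes pooling many small studies worthwhile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "POPULATION_TYPES",
    "QTLRecord",
    "StudyPanel",
    "QTLFormatError",
    "estimate_ci_width",
    "standardize_qtl",
    "read_qtl_table",
    "write_qtl_table",
]

POPULATION_TYPES = ("F2", "F2:3", "BC", "BIL", "RIL", "DH")

#: CI-width rule per population type: ("inverse", numerator) means
#: numerator/(N·R²); ("power", a, b) means a/(N·R²)**b. Remappable by users
#: who follow a different population-specific CI calibration.
CI_FORMULAS: dict[str, tuple] = {
    "F2": ("inverse", 530.0),
    "F2:3": ("inverse", 530.0),
    "BC": ("inverse", 530.0),
    "RIL": ("inverse", 163.0),
    "BIL": ("inverse", 163.0),
    "DH": ("power", 97.462, 0.835),
}

#: Canonical column order of the on-disk QTL table.
QTL_COLUMNS = [
    "qtl_id", "study_id", "trait", "chr", "peak_cM", "ci_low_cM",
    "ci_high_cM", "lod", "pve", "pop_type", "pop_size",
    "marker_left", "marker_right", "map_id", "condition",
]


class QTLFormatError(ValueError):
    """Raised when a QTL table is malformed (missing columns, bad values)."""


@dataclass(frozen=True)
class QTLRecord:
    """One published QTL with its positional and study metadata."""

    qtl_id: str
    study_id: str
    trait: str
    chromosome: int
    peak_cm: float
    pve: float
    population_type: str
    population_size: int
    flanking_markers: tuple[str, str]
    map_id: str
    ci_low_cm: float | None = None
    ci_high_cm: float | None = None
    lod: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.chromosome <= 12:
            raise ValueError(
                f"{self.qtl_id}: chromosome {self.chromosome} outside 1-12"
            )
        if not 0.0 < self.pve <= 1.0:
            raise ValueError(f"{self.qtl_id}: pve {self.pve} outside (0, 1]")
        if self.population_type not in POPULATION_TYPES:
            raise ValueError(
                f"{self.qtl_id}: unknown population type {self.population_type!r}"
            )
        if self.population_size < 2:
            raise ValueError(f"{self.qtl_id}: population_size < 2")
        if self.lod is not None and self.lod < 0:
            raise ValueError(f"{self.qtl_id}: negative LOD")
        if (self.ci_low_cm is None) != (self.ci_high_cm is None):
            raise ValueError(f"{self.qtl_id}: CI bounds must be both set or both absent")
        if self.ci_low_cm is not None:
            if not self.ci_low_cm <= self.peak_cm <= self.ci_high_cm:
                raise ValueError(
                    f"{self.qtl_id}: peak {self.peak_cm} outside CI "
                    f"[{self.ci_low_cm}, {self.ci_high_cm}]"
                )

    @property
    def has_ci(self) -> bool:
        return self.ci_low_cm is not None

    @property
    def ci_width_cm(self) -> float | None:
        if self.ci_low_cm is None:
            return None
        return self.ci_high_cm - self.ci_low_cm


@dataclass(frozen=True)
class StudyPanel:
    """Study-level metadata shared by a study's QTL records."""

    study_id: str
    parents: str
    population_type: str
    population_size: int
    marker_types: frozenset[str] = field(default_factory=frozenset)


def estimate_ci_width(population_type: str, n: int, r2: float) -> float:
    """95% CI width (cM) from population type, size ``n`` and PVE ``r2``.

    Strictly decreasing in both ``n`` and ``r2`` for every population type.
    """
    try:
        rule = CI_FORMULAS[population_type]
    except KeyError:
        raise ValueError(f"unknown population type {population_type!r}") from None
    if n < 2:
        raise ValueError("population size must be >= 2")
    if not 0.0 < r2 <= 1.0:
        raise ValueError(f"r2 {r2} outside (0, 1]")
    nr2 = n * r2
    if nr2 == 0:
        raise ValueError("n * r2 must be positive")
    if rule[0] == "inverse":
        return rule[1] / nr2
    return rule[1] / nr2 ** rule[2]


def standardize_qtl(record: QTLRecord, policy: str = "prefer_reported") -> QTLRecord:
    """Fill or replace a record's CI bounds.

    ``prefer_reported`` keeps reported bounds when present; otherwise (and
    always under ``always_formula``) bounds become a symmetric interval
    ``peak ± width/2`` with the width from :func:`estimate_ci_width`.
    """
    if policy not in ("prefer_reported", "always_formula"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "prefer_reported" and record.has_ci:
        return record
    half = estimate_ci_width(
        record.population_type, record.population_size, record.pve
    ) / 2.0
    return replace(
        record,
        ci_low_cm=record.peak_cm - half,
        ci_high_cm=record.peak_cm + half,
    )


def _optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def read_qtl_table(
    path,
    dialect: Mapping[str, object] | None = None,
) -> list[QTLRecord]:
    """Read a QTL compendium TSV into validated records.

    ``dialect`` maps canonical column names to the file's column names and
    may set ``percent: True`` when the PVE column is in percent. Rows whose
    ``condition`` column is present and differs from ``"drought"`` (a
    well-watered control detection) are dropped. Records are returned
    sorted by chromosome, then peak position.
    """
    dialect = dict(dialect or {})
    percent = bool(dialect.pop("percent", False))
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = {canon: dialect.get(canon, canon) for canon in QTL_COLUMNS}
    required = [c for c in QTL_COLUMNS if c not in ("lod", "ci_low_cM", "ci_high_cM", "condition")]
    for canon in required:
        if colmap[canon] not in df.columns:
            raise QTLFormatError(f"missing required column {colmap[canon]!r}")

    records: list[QTLRecord] = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # 1-based, after the header line
        cond_col = colmap["condition"]
        if cond_col in df.columns and row[cond_col].strip().lower() != "drought":
            continue
        try:
            pve = float(row[colmap["pve"]])
        except ValueError:
            raise QTLFormatError(f"row {rownum}: unparseable pve {row[colmap['pve']]!r}")
        if percent:
            pve /= 100.0
        if not 0.0 < pve <= 1.0:
            raise QTLFormatError(f"row {rownum}: pve {pve} outside (0, 1]")
        chrom = int(row[colmap["chr"]])
        if not 1 <= chrom <= 12:
            raise QTLFormatError(f"row {rownum}: chromosome {chrom} outside 1-12")
        lod_col = colmap["lod"]
        lod = _optional_float(row[lod_col]) if lod_col in df.columns else None
        lo = _optional_float(row.get(colmap["ci_low_cM"]))
        hi = _optional_float(row.get(colmap["ci_high_cM"]))
        records.append(
            QTLRecord(
                qtl_id=row[colmap["qtl_id"]],
                study_id=row[colmap["study_id"]],
                trait=row[colmap["trait"]],
                chromosome=chrom,
                peak_cm=float(row[colmap["peak_cM"]]),
                ci_low_cm=lo,
                ci_high_cm=hi,
                lod=lod,
                pve=pve,
                population_type=row[colmap["pop_type"]],
                population_size=int(row[colmap["pop_size"]]),
                flanking_markers=(row[colmap["marker_left"]], row[colmap["marker_right"]]),
                map_id=row[colmap["map_id"]],
            )
        )
    records.sort(key=lambda r: (r.chromosome, r.peak_cm, r.qtl_id))
    return records


def write_qtl_table(records: Iterable[QTLRecord], path) -> None:
    """Write records in the canonical TSV dialect (round-trips with the reader)."""

    def fmt(v) -> str:
        if v is None:
            return ""
        return repr(float(v))  # full precision for lossless round-trips

    rows = [
        {
            "qtl_id": r.qtl_id,
            "study_id": r.study_id,
            "trait": r.trait,
            "chr": r.chromosome,
            "peak_cM": fmt(r.peak_cm),
            "ci_low_cM": fmt(r.ci_low_cm),
            "ci_high_cM": fmt(r.ci_high_cm),
            "lod": fmt(r.lod),
            "pve": fmt(r.pve),
            "pop_type": r.population_type,
            "pop_size": r.population_size,
            "marker_left": r.flanking_markers[0],
            "marker_right": r.flanking_markers[1],
            "map_id": r.map_id,
            "condition": "drought",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=QTL_COLUMNS).to_csv(path, sep="\t", index=False)
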