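"""Physical anchoring of MQTLs and co-localization with GWAS associations.

An MQTL lives on the genetic (cM) map; to compare it with GWAS hits it is
anchored to physical coordinates through the nearest anchorable flanking
marker of its highest-membership member QTL, and given a window of peak
+/- 0.5 Mb (clipped at chromosome ends). An MQTL counts as validated when
its window contains at least one marker-trait association (MTA) with
-log10(p) >= 5.0; both the window boundaries and the significance
threshold are inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .meta_qtl import MQTL

__all__ = [
    "MarkerAnchor",
    "MTARecord",
    "PhysicalWindow",
    "ValidationReport",
    "anchor_mqtl",
    "anchor_mqtls",
    "colocalize",
    "read_anchor_table",
    "read_mta_table",
]

logger = logging.getLogger(__name__)

HALF_WINDOW_BP = 500_000
MTA_THRESHOLD = 5.0


@dataclass(frozen=True)
class MarkerAnchor:
    """A marker's 1-based physical coordinate on the reference genome."""

    marker: str
    chromosome: int
    position_bp: int

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"{self.marker}: position_bp must be >= 1")


@dataclass(frozen=True)
class MTARecord:
    """One marker-trait association from a GWAS panel."""

    snp_id: str
    chromosome: int
    position_bp: int
    neg_log10_p: float
    trait: str = ""
    panel_id: str = ""

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"{self.snp_id}: position_bp must be >= 1")
        if self.neg_log10_p < 0:
            raise ValueError(f"{self.snp_id}: negative -log10(p)")


@dataclass(frozen=True)
class PhysicalWindow:
    """An MQTL's physical interval (1-based, inclusive on both ends)."""

    mqtl_id: str
    chromosome: int
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.mqtl_id}: start > end")


@dataclass
class ValidationReport:
    """Per-MQTL supporting MTAs and the validated summary."""

    support: dict[str, list[MTARecord]]
    unanchored: list[str] = field(default_factory=list)

    @property
    def validated_ids(self) -> list[str]:
        return sorted(m for m, hits in self.support.items() if hits)

    @property
    def n_windows(self) -> int:
        return len(self.support)

    @property
    def validated_fraction(self) -> float:
        if not self.support:
            return 0.0
        return len(self.validated_ids) / len(self.support)


def _marker_candidates(
    mqtl: MQTL, qtl_lookup: Mapping[str, object]
) -> list[tuple[float, str]]:
    """Flanking markers of members, best membership first, with |cM offset|."""
    out = []
    for qtl_id, prob in sorted(mqtl.members, key=lambda m: -m[1]):
        proj = qtl_lookup.get(qtl_id)
        if proj is None:
            continue
        for marker in proj.qtl.flanking_markers:
            out.append((prob, marker))
    return out


def anchor_mqtl(
    mqtl: MQTL,
    anchors: Mapping[str, MarkerAnchor],
    qtl_lookup: Mapping[str, object],
    half_window: int = HALF_WINDOW_BP,
    chrom_length: int | None = None,
    marker_cm: Mapping[str, float] | None = None,
) -> PhysicalWindow | None:
    """Build the peak +/- ``half_window`` physical window for one MQTL.

    The anchor is a flanking marker of the highest-membership member QTL
    that has a physical coordinate on the MQTL's chromosome; among that
    member's markers, the one nearest the MQTL peak on the genetic map
    (when ``marker_cm`` is supplied) wins. Lower-membership members are
    fallbacks. Returns ``None`` (with a warning) when nothing anchors.
    """
    for _, group in _group_by_member(mqtl, qtl_lookup):
        usable = [
            m for m in group
            if m in anchors and anchors[m].chromosome == mqtl.chromosome
        ]
        if not usable:
            continue
        if marker_cm:
            usable.sort(
                key=lambda m: abs(marker_cm.get(m, np.inf) - mqtl.peak_cm)
            )
        anchor = anchors[usable[0]]
        start = max(1, anchor.position_bp - half_window)
        end = anchor.position_bp + half_window
        if chrom_length is not None:
            end = min(end, chrom_length)
        return PhysicalWindow(mqtl.mqtl_id, mqtl.chromosome, start, end)
    logger.warning("MQTL %s has no anchorable flanking marker; excluded "
                   "from validation", mqtl.mqtl_id)
    return None


def _group_by_member(mqtl: MQTL, qtl_lookup: Mapping[str, object]):
    for qtl_id, prob in sorted(mqtl.members, key=lambda m: (-m[1], m[0])):
        proj = qtl_lookup.get(qtl_id)
        if proj is not None:
            yield prob, list(proj.qtl.flanking_markers)


def anchor_mqtls(
    mqtls: Sequence[MQTL],
    anchors: Mapping[str, MarkerAnchor],
    qtl_lookup: Mapping[str, object],
    half_window: int = HALF_WINDOW_BP,
    chrom_lengths: Mapping[int, int] | None = None,
    marker_cm: Mapping[str, float] | None = None,
) -> tuple[list[PhysicalWindow], list[str]]:
    """Anchor a batch of MQTLs; returns (windows, unanchored mqtl_ids)."""
    windows, unanchored = [], []
    for m in mqtls:
        length = chrom_lengths.get(m.chromosome) if chrom_lengths else None
        w = anchor_mqtl(m, anchors, qtl_lookup, half_window, length, marker_cm)
        if w is None:
            unanchored.append(m.mqtl_id)
        else:
            windows.append(w)
    return windows, unanchored


def colocalize(
    windows: Sequence[PhysicalWindow],
    mtas: Sequence[MTARecord],
    threshold: float = MTA_THRESHOLD,
) -> ValidationReport:
    """Count significant MTAs inside each MQTL window.

    An MTA supports a window iff it sits on the same chromosome, its
    position lies in [start_bp, end_bp] (inclusive) and its -log10(p) is
    >= ``threshold`` (inclusive). Sorted-array search per chromosome; the
    result is identical to the brute-force double loop.
    """
    by_chrom: dict[int, list[MTARecord]] = {}
    for m in mtas:
        if m.neg_log10_p >= threshold:
            by_chrom.setdefault(m.chromosome, []).append(m)
    pos_by_chrom = {}
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: r.position_bp)
        pos_by_chrom[chrom] = np.array([r.position_bp for r in recs])

    support: dict[str, list[MTARecord]] = {}
    for w in windows:
        recs = by_chrom.get(w.chromosome, [])
        if recs:
            pos = pos_by_chrom[w.chromosome]
            lo = int(np.searchsorted(pos, w.start_bp, side="left"))
            hi = int(np.searchsorted(pos, w.end_bp, side="right"))
            support[w.mqtl_id] = recs[lo:hi]
        else:
            support[w.mqtl_id] = []
    return ValidationReport(support=support)


def read_anchor_table(path) -> dict[str, MarkerAnchor]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.marker): MarkerAnchor(str(r.marker), int(r.chr), int(r.position_bp))
        for r in df.itertuples()
    }


def read_mta_table(path) -> list[MTARecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        MTARecord(
            snp_id=str(r.snp_id), chromosome=int(r.chr),
            position_bp=int(r.position_bp), neg_log10_p=float(r.neg_log10_p),
            trait=str(getattr(r, "trait", "")), panel_id=str(getattr(r, "panel_id", "")),
        )
        for r in df.itertuples()
    ]
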