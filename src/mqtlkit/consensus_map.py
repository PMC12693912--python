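"""Consensus genetic maps and QTL projection.

Studies report QTLs on their own linkage maps, so positions are not
directly comparable. This module merges per-study maps into one consensus
frame and re-expresses each QTL on it.

The merge is a rescaled-mean consensus: per chromosome, the map with the
most markers is the reference frame; every other map is rescaled onto it
by a least-squares linear fit through shared markers, and a marker's
consensus position is the mean of its rescaled positions. Marker-order
conflicts between a map and the reference are resolved by majority: the
conflicted marker is dropped from the smaller map. This is a deliberate,
dependency-free stand-in for linear-programming map merging — the
projection contract downstream (positions comparable across studies, order
preserved) is the same.

Projection maps a QTL peak and its CI through the linear transform defined
by the nearest shared markers bracketing the peak. The projected CI yields
the positional standard deviation s = width/3.92 (two-sided Gaussian 95%)
that the mixture model consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .qtl_compendium import QTLRecord

__all__ = [
    "GeneticMap",
    "ConsensusMap",
    "ProjectedQTL",
    "ProjectionError",
    "merge_maps",
    "project_qtl",
    "read_map_table",
    "write_map_table",
]

logger = logging.getLogger(__name__)

#: width of a 95% two-sided Gaussian interval in standard deviations
Z95_WIDTH = 3.92


@dataclass
class GeneticMap:
    """An ordered genetic map: (marker, chromosome, position cM) entries."""

    map_id: str
    entries: list[tuple[str, int, float]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for marker, _, _ in self.entries:
            if marker in seen:
                raise ValueError(f"map {self.map_id}: duplicate marker {marker!r}")
            seen.add(marker)
        for chrom in self.chromosomes():
            pos = [p for _, c, p in self.entries if c == chrom]
            if any(b < a for a, b in zip(pos, pos[1:])):
                raise ValueError(
                    f"map {self.map_id}: positions not non-decreasing on chr {chrom}"
                )

    def chromosomes(self) -> list[int]:
        return sorted({c for _, c, _ in self.entries})

    def positions(self, chromosome: int) -> dict[str, float]:
        return {m: p for m, c, p in self.entries if c == chromosome}

    def n_markers(self, chromosome: int) -> int:
        return sum(1 for _, c, _ in self.entries if c == chromosome)


@dataclass
class ConsensusMap(GeneticMap):
    """A merged map; ``provenance`` lists the contributing map_ids per marker."""

    provenance: dict[str, list[str]] = field(default_factory=dict)


@dataclass(frozen=True)
class ProjectedQTL:
    """A QTL re-expressed on the consensus map.

    ``sd_cm`` is the positional standard deviation implied by the projected
    95% interval (width/3.92); it feeds the mixture model as the known
    per-observation sigma.
    """

    qtl: QTLRecord
    position_cm: float
    ci_low_cm: float
    ci_high_cm: float
    sd_cm: float

    def __post_init__(self) -> None:
        if self.sd_cm <= 0:
            raise ValueError(f"{self.qtl.qtl_id}: non-positive projected sd")

    @property
    def chromosome(self) -> int:
        return self.qtl.chromosome


class ProjectionError(ValueError):
    """A QTL could not be projected (insufficient shared markers or too far
    outside the shared span); such QTLs are excluded from the meta-analysis."""


def _resolve_order_conflicts(
    ref_pos: dict[str, float],
    other_pos: dict[str, float],
    ref_size: int,
    other_size: int,
    ref_id: str,
    other_id: str,
) -> dict[str, float]:
    """Drop markers from the minority map until shared-marker orders agree."""
    other_pos = dict(other_pos)
    while True:
        shared = sorted(set(ref_pos) & set(other_pos), key=ref_pos.get)
        conflicts: dict[str, int] = {}
        for i, a in enumerate(shared):
            for b in shared[i + 1:]:
                if other_pos[a] > other_pos[b]:
                    conflicts[a] = conflicts.get(a, 0) + 1
                    conflicts[b] = conflicts.get(b, 0) + 1
        if not conflicts:
            return other_pos
        worst = max(conflicts, key=lambda m: (conflicts[m], m))
        # majority order wins: the conflicted marker leaves the smaller map
        loser = other_id if other_size <= ref_size else ref_id
        logger.warning(
            "marker order conflict between %s and %s at %r: dropped from %s",
            ref_id, other_id, worst, loser,
        )
        del other_pos[worst]  # consensus is built map-by-map; drop from incoming


def merge_maps(maps: Sequence[GeneticMap]) -> ConsensusMap:
    """Merge genetic maps into a consensus by rescaled-mean averaging.

    Per chromosome the map with the most markers anchors the frame; other
    maps are rescaled onto it through shared markers (>=2 required, else
    that map's chromosome is skipped with a warning).
    """
    if not maps:
        raise ValueError("need at least one map")
    chromosomes = sorted({c for m in maps for c in m.chromosomes()})
    entries: list[tuple[str, int, float]] = []
    provenance: dict[str, list[str]] = {}

    for chrom in chromosomes:
        with_chrom = [m for m in maps if m.n_markers(chrom) > 0]
        ref = max(with_chrom, key=lambda m: (m.n_markers(chrom), m.map_id))
        ref_pos = ref.positions(chrom)
        rescaled: dict[str, list[float]] = {m: [p] for m, p in ref_pos.items()}
        prov: dict[str, list[str]] = {m: [ref.map_id] for m in ref_pos}

        for gm in with_chrom:
            if gm is ref:
                continue
            other_pos = _resolve_order_conflicts(
                ref_pos, gm.positions(chrom),
                ref.n_markers(chrom), gm.n_markers(chrom),
                ref.map_id, gm.map_id,
            )
            shared = sorted(set(ref_pos) & set(other_pos), key=other_pos.get)
            if len(shared) < 2:
                logger.warning(
                    "map %s shares <2 markers with consensus on chr %d; skipped",
                    gm.map_id, chrom,
                )
                continue
            # line through the terminal shared markers: maps sharing anchors
            # at identical positions rescale by the identity
            x0, x1 = other_pos[shared[0]], other_pos[shared[-1]]
            y0, y1 = ref_pos[shared[0]], ref_pos[shared[-1]]
            if x1 == x0:
                slope, intercept = 1.0, y0 - x0
            else:
                slope = (y1 - y0) / (x1 - x0)
                intercept = y0 - slope * x0
            for marker, pos in other_pos.items():
                rescaled.setdefault(marker, []).append(slope * pos + intercept)
                prov.setdefault(marker, []).append(gm.map_id)

        for marker, positions in rescaled.items():
            entries.append((marker, chrom, float(np.mean(positions))))
            provenance[marker] = prov[marker]

    entries.sort(key=lambda e: (e[1], e[2], e[0]))
    return ConsensusMap(map_id="consensus", entries=entries, provenance=provenance)


def _transform(pos: float, left: tuple[float, float], right: tuple[float, float]) -> float:
    """Map ``pos`` through the segment (L, L') -> (R, R'); degenerate -> L'."""
    (l_src, l_dst), (r_src, r_dst) = left, right
    if r_src == l_src:
        return l_dst
    return l_dst + (pos - l_src) * (r_dst - l_dst) / (r_src - l_src)


def project_qtl(
    qtl: QTLRecord,
    source: GeneticMap,
    consensus: GeneticMap,
    extrapolation_limit: float = 5.0,
) -> ProjectedQTL:
    """Project a standardized QTL from its source map onto the consensus.

    The peak is interpolated between the nearest shared markers bracketing
    it; the CI bounds go through the same segment transform. Peaks more
    than ``extrapolation_limit`` cM outside the shared span raise
    :class:`ProjectionError`.
    """
    if not qtl.has_ci:
        raise ValueError(f"{qtl.qtl_id}: standardize CI bounds before projection")
    src = source.positions(qtl.chromosome)
    dst = consensus.positions(qtl.chromosome)
    shared = sorted(set(src) & set(dst), key=src.get)
    if len(shared) < 2:
        raise ProjectionError(
            f"{qtl.qtl_id}: <2 shared markers on chr {qtl.chromosome}"
        )
    xs = [src[m] for m in shared]
    peak = qtl.peak_cm
    if peak < xs[0] - extrapolation_limit or peak > xs[-1] + extrapolation_limit:
        raise ProjectionError(
            f"{qtl.qtl_id}: peak {peak} cM is >{extrapolation_limit} cM outside "
            f"shared span [{xs[0]}, {xs[-1]}]"
        )
    # nearest bracketing pair; outside the span fall back to the edge segment
    idx = int(np.clip(np.searchsorted(xs, peak) - 1, 0, len(xs) - 2))
    left = (xs[idx], dst[shared[idx]])
    right = (xs[idx + 1], dst[shared[idx + 1]])
    pos = _transform(peak, left, right)
    lo = _transform(qtl.ci_low_cm, left, right)
    hi = _transform(qtl.ci_high_cm, left, right)
    lo, hi = min(lo, hi), max(lo, hi)
    sd = (hi - lo) / Z95_WIDTH
    if sd <= 0:  # collapsed interval after a degenerate segment
        sd = 1e-6
        hi = lo + sd * Z95_WIDTH
    return ProjectedQTL(qtl=qtl, position_cm=pos, ci_low_cm=lo, ci_high_cm=hi, sd_cm=sd)


def read_map_table(path) -> list[GeneticMap]:
    """Read genetic maps from a TSV with columns map_id, chr, marker, position_cM."""
    df = pd.read_csv(path, sep="\t")
    maps = []
    for map_id, grp in df.groupby("map_id", sort=True):
        grp = grp.sort_values(["chr", "position_cM"], kind="stable")
        entries = [
            (str(r.marker), int(r.chr), float(r.position_cM))
            for r in grp.itertuples()
        ]
        maps.append(GeneticMap(map_id=str(map_id), entries=entries))
    return maps


def write_map_table(maps: Iterable[GeneticMap], path) -> None:
    rows = []
    for gm in maps:
        prov = getattr(gm, "provenance", {})
        for marker, chrom, pos in gm.entries:
            row = {
                "map_id": gm.map_id, "chr": chrom,
                "marker": marker, "position_cM": repr(pos),
            }
            if prov:
                row["n_maps"] = len(prov.get(marker, []))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
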