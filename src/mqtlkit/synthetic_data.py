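"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates a literature-derived multi-study QTL panel —
QTL peaks scattered around planted true loci with positional noise implied
by their formula-derived confidence intervals — together with per-study
genetic maps, a marker physical-anchor table, GWAS association panels with
significant SNPs planted inside a configurable fraction of the true
physical windows, and a genome/annotation/expression bundle in which the
intended candidate genes satisfy every funnel condition while each decoy
class violates exactly one. Every generated object carries a truth record,
so parameter-recovery and funnel-recovery tests have exact ground truth.

Expression time courses are built from nine temporal archetypes — every
combination of a rising, falling or flat trend in the tolerant mutant and
in the drought-sensitive wild type — so a nine-cluster fuzzy c-means has a
natural structure to find; the candidate archetype is the
up-in-mutant/down-in-wildtype signature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .consensus_map import GeneticMap, write_map_table
from .gwas_validation import MarkerAnchor, MTARecord
from .integration import (
    DEGStats,
    ExpressionRecord,
    GeneModel,
    write_gene_models_gff3,
    write_genome,
)
from .qtl_compendium import QTLRecord, estimate_ci_width, write_qtl_table

__all__ = [
    "SimulationConfig",
    "SimulatedPanel",
    "SimulatedBundle",
    "simulate_qtl_panel",
    "simulate_mtas",
    "simulate_genome_and_expression",
    "simulate_bundle",
    "write_bundle",
]

Z95_WIDTH = 3.92

#: temporal trend -> expression slope per day (FPKM units)
TREND_SLOPES = {"up": 0.5, "down": -0.5, "flat": 0.0}
#: nine archetypes: (mutant trend, wildtype trend); the first is the signature
ARCHETYPES = [
    ("up", "down"),
    ("up", "up"), ("up", "flat"),
    ("down", "up"), ("down", "down"), ("down", "flat"),
    ("flat", "up"), ("flat", "down"), ("flat", "flat"),
]
SIGNATURE_ARCHETYPE = ("up", "down")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic inputs.

    Positional noise: each QTL peak is drawn Normal(true locus, s²) with s
    implied by its formula-derived CI; ``sd_range_cm`` sets the range that
    implied s is sampled to land in (population size is back-solved from
    the CI formula). Physical and genetic coordinates are coupled by a
    fixed ``bp_per_cm`` scale so windows and genes co-locate predictably.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chrom_len_cm: float = 120.0
    bp_per_cm: int = 250_000
    true_loci_cm: tuple[float, ...] = (20.0, 60.0, 100.0)
    min_locus_sep_cm: float = 10.0
    n_studies: int = 8
    qtls_per_locus: tuple[int, int] = (5, 10)
    population_mix: dict = field(default_factory=lambda: {
        "F2": 0.3, "BC": 0.2, "RIL": 0.4, "DH": 0.1,
    })
    n_range: tuple[int, int] = (100, 300)
    r2_range: tuple[float, float] = (0.05, 0.30)
    sd_range_cm: tuple[float, float] | None = (0.5, 2.0)
    marker_spacing_cm: float = 2.0
    marker_jitter_cm: float = 0.2
    n_mta_panels: int = 7
    snps_per_panel: int = 60
    mta_planted_fraction: float = 0.3
    mta_per_locus: tuple[int, int] = (1, 2)
    half_window_bp: int = 500_000
    n_planted_genes: int = 8
    n_decoys_per_class: int = 8
    n_filler_per_archetype: int = 2
    expression_noise_sd: float = 0.3
    n_replicates: int = 3
    base_fpkm: float = 4.0
    motif_plant_rate: float = 1.0

    def __post_init__(self) -> None:
        loci = sorted(self.true_loci_cm)
        if any(b - a < self.min_locus_sep_cm for a, b in zip(loci, loci[1:])):
            raise ValueError(
                f"planted loci {loci} violate the {self.min_locus_sep_cm} cM "
                "minimum separation"
            )
        if loci and (loci[0] < 0 or loci[-1] > self.chrom_len_cm):
            raise ValueError("planted loci outside the chromosome span")

    @property
    def chrom_len_bp(self) -> int:
        return int(self.chrom_len_cm * self.bp_per_cm)

    def locus_bp(self, pos_cm: float) -> int:
        return int(round(pos_cm * self.bp_per_cm)) + 1


@dataclass
class SimulatedPanel:
    """QTL compendium + maps + anchors with per-QTL ground truth."""

    studies: list[str]
    maps: list[GeneticMap]
    qtls: list[QTLRecord]
    anchors: dict[str, MarkerAnchor]
    truth: dict  # loci per chromosome, qtl -> locus assignment


@dataclass
class SimulatedBundle:
    """Everything the pipeline consumes, plus the truth record."""

    panel: SimulatedPanel
    mtas: list[MTARecord]
    mta_truth: dict
    genome: dict[str, str]
    genes: list[GeneModel]
    deg_stats: list[DEGStats]
    expression: list[ExpressionRecord]
    gene_truth: dict


def _draw_population(cfg: SimulationConfig, rng: np.random.Generator):
    """Sample (pop_type, N, R²); when sd_range_cm is set, back-solve N so the
    implied positional sd lands in that range."""
    types = list(cfg.population_mix)
    probs = np.array([cfg.population_mix[t] for t in types], dtype=float)
    probs /= probs.sum()
    ptype = str(rng.choice(types, p=probs))
    r2 = float(rng.uniform(*cfg.r2_range))
    if cfg.sd_range_cm is None:
        n = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
    else:
        target_width = Z95_WIDTH * rng.uniform(*cfg.sd_range_cm)
        if ptype in ("F2", "F2:3", "BC"):
            n = 530.0 / (target_width * r2)
        elif ptype in ("RIL", "BIL"):
            n = 163.0 / (target_width * r2)
        else:  # DH
            n = (97.462 / target_width) ** (1.0 / 0.835) / r2
        n = int(np.clip(round(n), 10, 5000))
    return ptype, n, r2


def _study_map(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    map_id: str,
    ref_positions: dict[int, np.ndarray],
) -> GeneticMap:
    entries = []
    for chrom, ref in ref_positions.items():
        jit = ref + rng.normal(0.0, cfg.marker_jitter_cm, size=ref.size)
        jit = np.maximum.accumulate(jit)  # keep the reference marker order
        jit -= jit[0]  # chromosome-local origin at the first marker
        for i, pos in enumerate(jit):
            entries.append((f"M{chrom}_{i}", chrom, float(pos)))
    return GeneticMap(map_id=map_id, entries=entries)


def simulate_qtl_panel(cfg: SimulationConfig) -> SimulatedPanel:
    """Multi-study QTL compendium clustered around the planted true loci."""
    rng = np.random.default_rng(cfg.seed)
    n_markers = int(cfg.chrom_len_cm / cfg.marker_spacing_cm) + 1
    ref_positions = {
        chrom: np.linspace(0.0, cfg.chrom_len_cm, n_markers)
        for chrom in range(1, cfg.n_chromosomes + 1)
    }
    studies = [f"S{i+1:02d}" for i in range(cfg.n_studies)]
    maps = [_study_map(cfg, rng, f"map_{s}", ref_positions) for s in studies]
    map_by_study = dict(zip(studies, maps))

    anchors = {
        f"M{chrom}_{i}": MarkerAnchor(
            f"M{chrom}_{i}", chrom, cfg.locus_bp(ref_positions[chrom][i])
        )
        for chrom in ref_positions
        for i in range(n_markers)
    }

    qtls: list[QTLRecord] = []
    assignment: dict[str, list] = {}
    loci_truth = []
    counter = 0
    for chrom in range(1, cfg.n_chromosomes + 1):
        for locus_cm in cfg.true_loci_cm:
            loci_truth.append({
                "chromosome": chrom, "position_cm": locus_cm,
                "position_bp": cfg.locus_bp(locus_cm),
            })
            n_qtls = int(rng.integers(cfg.qtls_per_locus[0],
                                      cfg.qtls_per_locus[1] + 1))
            for _ in range(n_qtls):
                counter += 1
                study = studies[int(rng.integers(len(studies)))]
                ptype, n, r2 = _draw_population(cfg, rng)
                width = estimate_ci_width(ptype, n, r2)
                sd = width / Z95_WIDTH
                peak_ref = float(np.clip(
                    rng.normal(locus_cm, sd), 0.0, cfg.chrom_len_cm
                ))
                # express the peak in the study-map frame
                gm = map_by_study[study]
                pos = gm.positions(chrom)
                mnames = sorted(pos, key=pos.get)
                ref = ref_positions[chrom]
                idx = int(np.clip(np.searchsorted(ref, peak_ref) - 1,
                                  0, ref.size - 2))
                l_src, r_src = ref[idx], ref[idx + 1]
                l_dst = pos[f"M{chrom}_{idx}"]
                r_dst = pos[f"M{chrom}_{idx + 1}"]
                if r_src == l_src:
                    peak = l_dst
                else:
                    peak = l_dst + (peak_ref - l_src) * (r_dst - l_dst) / (r_src - l_src)
                span = max(p for p in pos.values())
                lo = max(0.0, peak - width / 2)
                hi = min(span, peak + width / 2)
                qtl_id = f"q{counter:04d}"
                qtls.append(QTLRecord(
                    qtl_id=qtl_id, study_id=study,
                    trait="drought tolerance", chromosome=chrom,
                    peak_cm=peak, ci_low_cm=lo, ci_high_cm=hi,
                    lod=float(np.round(rng.uniform(2.0, 15.0), 2)),
                    pve=r2, population_type=ptype, population_size=n,
                    flanking_markers=(f"M{chrom}_{idx}", f"M{chrom}_{idx + 1}"),
                    map_id=gm.map_id,
                ))
                assignment[qtl_id] = [chrom, locus_cm]
    qtls.sort(key=lambda q: (q.chromosome, q.peak_cm, q.qtl_id))
    truth = {"loci": loci_truth, "qtl_locus": assignment}
    return SimulatedPanel(studies=studies, maps=maps, qtls=qtls,
                          anchors=anchors, truth=truth)


def simulate_mtas(
    cfg: SimulationConfig,
    loci: Sequence[dict],
    seed_offset: int = 1,
) -> tuple[list[MTARecord], dict]:
    """GWAS panels: significant SNPs planted near a fraction of true loci,
    sub-threshold background elsewhere."""
    rng = np.random.default_rng(cfg.seed + seed_offset)
    n_planted = int(round(cfg.mta_planted_fraction * len(loci)))
    planted_idx = sorted(
        rng.choice(len(loci), size=n_planted, replace=False).tolist()
    ) if n_planted else []
    mtas: list[MTARecord] = []
    counter = 0
    for i in planted_idx:
        locus = loci[i]
        for _ in range(int(rng.integers(cfg.mta_per_locus[0],
                                        cfg.mta_per_locus[1] + 1))):
            counter += 1
            offset = int(rng.integers(-100_000, 100_001))
            panel = f"panel{int(rng.integers(cfg.n_mta_panels)) + 1}"
            mtas.append(MTARecord(
                snp_id=f"snp{counter:05d}", chromosome=locus["chromosome"],
                position_bp=max(1, locus["position_bp"] + offset),
                neg_log10_p=float(np.round(rng.uniform(5.0, 10.0), 3)),
                trait="drought tolerance", panel_id=panel,
            ))
    for p in range(cfg.n_mta_panels):
        for _ in range(cfg.snps_per_panel):
            counter += 1
            chrom = int(rng.integers(cfg.n_chromosomes)) + 1
            mtas.append(MTARecord(
                snp_id=f"snp{counter:05d}", chromosome=chrom,
                position_bp=int(rng.integers(1, cfg.chrom_len_bp + 1)),
                neg_log10_p=float(np.round(rng.uniform(0.0, 4.9), 3)),
                trait="drought tolerance", panel_id=f"panel{p + 1}",
            ))
    truth = {"planted_loci": [
        {"chromosome": loci[i]["chromosome"], "position_bp": loci[i]["position_bp"]}
        for i in planted_idx
    ]}
    return mtas, truth


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_chromosome(rng: np.random.Generator, length: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())


def _promoter_span(gene: GeneModel) -> tuple[int, int]:
    upstream = 1500 if gene.utr5_len > 100 else 2000
    if gene.strand == "+":
        return gene.atg_bp - upstream, gene.tss_bp
    return gene.tss_bp, gene.atg_bp + upstream


def _plant_motif(chrom_seq: bytearray, span: tuple[int, int],
                 motif: str, rng: np.random.Generator) -> None:
    lo, hi = span
    off = int(rng.integers(lo + 10, hi - len(motif) - 10))
    chrom_seq[off - 1 : off - 1 + len(motif)] = motif.encode()


def _scrub_motif(chrom_seq: bytearray, span: tuple[int, int], motif: str) -> None:
    """Remove every plus/minus-strand occurrence of ``motif`` in the span."""
    from .integration import revcomp

    lo, hi = span
    targets = {motif.encode(), revcomp(motif).encode()}
    for _ in range(200):
        region = bytes(chrom_seq[lo - 1 : hi])
        dirty = False
        for t in targets:
            pos = region.find(t)
            if pos >= 0:
                mid = lo - 1 + pos + len(t) // 2
                # a base absent from both target words breaks the match
                for b in b"ACGT":
                    trial = bytes([b])
                    if all(trial != t[len(t) // 2 : len(t) // 2 + 1] for t in targets):
                        chrom_seq[mid] = b
                        break
                dirty = True
        if not dirty:
            return
    raise RuntimeError("could not scrub motif from promoter span")


def _archetype_profiles(
    archetype: tuple[str, str], cfg: SimulationConfig, rng: np.random.Generator,
    timepoints=(0.0, 3.0, 6.0),
) -> list[ExpressionRecord]:
    recs = []
    for genotype, trend in zip(("mutant", "wildtype"), archetype):
        slope = TREND_SLOPES[trend]
        for t in timepoints:
            mean = cfg.base_fpkm + slope * t
            for rep in range(1, cfg.n_replicates + 1):
                val = max(0.0, mean + rng.normal(0.0, cfg.expression_noise_sd))
                recs.append(("", genotype, t, rep, val))
    return recs


def simulate_genome_and_expression(
    cfg: SimulationConfig,
    loci: Sequence[dict],
    seed_offset: int = 2,
) -> tuple[dict[str, str], list[GeneModel], list[DEGStats],
           list[ExpressionRecord], dict]:
    """Genome, gene models, DE stats and time courses with planted candidates.

    Planted candidates satisfy every funnel condition. Each decoy class
    violates exactly one: (A) in-window but not differentially expressed;
    (B) differentially expressed with the signature and an ABRE but outside
    every window; (C) in-window signature DEG whose promoter is scrubbed of
    ABRE; (D) in-window DEG with an ABRE but a non-signature time course.
    Filler genes populate the remaining temporal archetypes so the
    nine-cluster structure is realized.
    """
    rng = np.random.default_rng(cfg.seed + seed_offset)
    chrom_seqs = {
        str(c): _random_chromosome(rng, cfg.chrom_len_bp)
        for c in range(1, cfg.n_chromosomes + 1)
    }

    genes: list[GeneModel] = []
    deg_stats: list[DEGStats] = []
    expression: list[ExpressionRecord] = []
    gene_truth: dict = {"planted_decgs": [], "decoys": {
        "in_window_non_deg": [], "deg_out_of_window": [],
        "signature_no_abre": [], "abre_no_signature": [],
    }, "fillers": []}
    used_spans: dict[int, list[tuple[int, int]]] = {}

    def place_gene(gene_id: str, in_window: bool) -> GeneModel:
        for _ in range(100):
            locus = loci[int(rng.integers(len(loci)))]
            chrom = locus["chromosome"]
            if in_window:
                center = locus["position_bp"] + int(rng.integers(-100_000, 100_001))
            else:
                direction = rng.choice([-1, 1])
                center = locus["position_bp"] + int(direction) * int(
                    rng.integers(2_000_000, 4_000_000)
                )
            length = int(rng.integers(2000, 5001))
            start = max(3000, min(center, cfg.chrom_len_bp - length - 3000))
            end = start + length
            if any(s - 2500 < end and start < e + 2500
                   for s, e in used_spans.get(chrom, [])):
                continue
            if not in_window and any(
                abs(start - l["position_bp"]) < 1_500_000
                for l in loci if l["chromosome"] == chrom
            ):
                continue
            used_spans.setdefault(chrom, []).append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            utr5 = int(rng.integers(120, 301)) if rng.random() < 0.3 \
                else int(rng.integers(20, 81))
            if strand == "+":
                tss, atg = start, start + utr5
            else:
                tss, atg = end, end - utr5
            return GeneModel(gene_id=gene_id, chromosome=chrom,
                             start_bp=start, end_bp=end, strand=strand,
                             atg_bp=atg, tss_bp=tss, utr5_len=utr5)
        raise RuntimeError("could not place gene without collision")

    def add_deg(gene_id: str, is_deg: bool) -> None:
        for contrast in ("d3_vs_d0", "d6_vs_d0"):
            if is_deg:
                lfc = float(rng.uniform(1.5, 4.0)) * (1 if rng.random() < 0.7 else -1)
                fdr = float(rng.uniform(1e-6, 0.01))
            else:
                lfc = float(rng.uniform(-0.5, 0.5))
                fdr = float(rng.uniform(0.2, 1.0))
            deg_stats.append(DEGStats(gene_id, lfc, fdr, contrast))

    def add_expression(gene_id: str, archetype: tuple[str, str]) -> None:
        for _, genotype, t, rep, val in _archetype_profiles(archetype, cfg, rng):
            expression.append(ExpressionRecord(gene_id, genotype, t, rep, val))

    gene_no = 0

    def next_id() -> str:
        nonlocal gene_no
        gene_no += 1
        return f"G{gene_no:04d}"

    # planted candidates: every funnel condition holds
    for _ in range(cfg.n_planted_genes):
        gid = next_id()
        g = place_gene(gid, in_window=True)
        genes.append(g)
        add_deg(gid, True)
        add_expression(gid, SIGNATURE_ARCHETYPE)
        span = _promoter_span(g)
        if rng.random() < cfg.motif_plant_rate:
            _plant_motif(chrom_seqs[str(g.chromosome)], span, "ACGTG", rng)
        gene_truth["planted_decgs"].append(gid)

    # decoy class A: in window, flat expression, not a DEG
    for _ in range(cfg.n_decoys_per_class):
        gid = next_id()
        genes.append(place_gene(gid, in_window=True))
        add_deg(gid, False)
        add_expression(gid, ("flat", "flat"))
        gene_truth["decoys"]["in_window_non_deg"].append(gid)

    # decoy class B: signature DEG with ABRE, but outside every window
    for _ in range(cfg.n_decoys_per_class):
        gid = next_id()
        g = place_gene(gid, in_window=False)
        genes.append(g)
        add_deg(gid, True)
        add_expression(gid, SIGNATURE_ARCHETYPE)
        _plant_motif(chrom_seqs[str(g.chromosome)], _promoter_span(g), "ACGTG", rng)
        gene_truth["decoys"]["deg_out_of_window"].append(gid)

    # decoy class C: in-window signature DEG, promoter scrubbed of ABRE
    for _ in range(cfg.n_decoys_per_class):
        gid = next_id()
        g = place_gene(gid, in_window=True)
        genes.append(g)
        add_deg(gid, True)
        add_expression(gid, SIGNATURE_ARCHETYPE)
        _scrub_motif(chrom_seqs[str(g.chromosome)], _promoter_span(g), "ACGTG")
        gene_truth["decoys"]["signature_no_abre"].append(gid)

    # decoy class D: in-window DEG with ABRE, opposite temporal signature
    for _ in range(cfg.n_decoys_per_class):
        gid = next_id()
        g = place_gene(gid, in_window=True)
        genes.append(g)
        add_deg(gid, True)
        add_expression(gid, ("down", "up"))
        _plant_motif(chrom_seqs[str(g.chromosome)], _promoter_span(g), "ACGTG", rng)
        gene_truth["decoys"]["abre_no_signature"].append(gid)

    # fillers: in-window DEGs spanning the remaining temporal archetypes
    for archetype in ARCHETYPES:
        if archetype == SIGNATURE_ARCHETYPE:
            continue
        for _ in range(cfg.n_filler_per_archetype):
            gid = next_id()
            genes.append(place_gene(gid, in_window=True))
            add_deg(gid, True)
            add_expression(gid, archetype)
            gene_truth["fillers"].append(gid)

    genome = {k: v.decode() for k, v in
              ((k, bytes(s)) for k, s in chrom_seqs.items())}
    genes.sort(key=lambda g: (g.chromosome, g.start_bp))
    return genome, genes, deg_stats, expression, gene_truth


def simulate_bundle(cfg: SimulationConfig) -> SimulatedBundle:
    """Generate the full input bundle (panel, MTAs, genome/expression)."""
    panel = simulate_qtl_panel(cfg)
    mtas, mta_truth = simulate_mtas(cfg, panel.truth["loci"])
    genome, genes, deg_stats, expression, gene_truth = \
        simulate_genome_and_expression(cfg, panel.truth["loci"])
    return SimulatedBundle(panel=panel, mtas=mtas, mta_truth=mta_truth,
                           genome=genome, genes=genes, deg_stats=deg_stats,
                           expression=expression, gene_truth=gene_truth)


def write_bundle(bundle: SimulatedBundle, outdir) -> dict[str, str]:
    """Write the bundle as the pipeline's file formats; returns the path map."""
    import pandas as pd

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "qtl_table": out / "qtls.tsv",
        "maps": out / "maps.tsv",
        "anchors": out / "anchors.tsv",
        "mtas": out / "mtas.tsv",
        "genome": out / "genome.fa",
        "gff3": out / "genes.gff3",
        "deg_stats": out / "deg_stats.tsv",
        "expression": out / "expression.tsv",
        "truth": out / "truth.json",
    }
    write_qtl_table(bundle.panel.qtls, paths["qtl_table"])
    write_map_table(bundle.panel.maps, paths["maps"])
    pd.DataFrame(
        [{"marker": a.marker, "chr": a.chromosome, "position_bp": a.position_bp}
         for a in bundle.panel.anchors.values()]
    ).to_csv(paths["anchors"], sep="\t", index=False)
    pd.DataFrame(
        [{"snp_id": m.snp_id, "chr": m.chromosome, "position_bp": m.position_bp,
          "neg_log10_p": m.neg_log10_p, "trait": m.trait, "panel_id": m.panel_id}
         for m in bundle.mtas]
    ).to_csv(paths["mtas"], sep="\t", index=False)
    write_genome(bundle.genome, paths["genome"])
    write_gene_models_gff3(bundle.genes, paths["gff3"])
    pd.DataFrame(
        [{"gene_id": d.gene_id, "log2fc": d.log2fc, "fdr": d.fdr,
          "contrast": d.contrast} for d in bundle.deg_stats]
    ).to_csv(paths["deg_stats"], sep="\t", index=False)
    pd.DataFrame(
        [{"gene_id": e.gene_id, "genotype": e.genotype, "timepoint": e.timepoint,
          "replicate": e.replicate, "fpkm": e.fpkm} for e in bundle.expression]
    ).to_csv(paths["expression"], sep="\t", index=False)
    truth = {
        "panel": bundle.panel.truth,
        "mtas": bundle.mta_truth,
        "genes": bundle.gene_truth,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
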