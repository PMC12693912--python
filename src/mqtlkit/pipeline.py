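"""End-to-end orchestration: compendium → consensus → meta-analysis →
GWAS validation → candidate-gene funnel, from one declarative config.

The config is a YAML mapping with a section per stage; every screening
threshold (60% membership, 0.5 cM bins, ±0.5 Mb windows, −log10 p ≥ 5,
|log2FC| ≥ 1, FDR < 0.05, c = 9 clusters, fuzzifier m = 2) is surfaced
there with the analysis defaults. A ``simulate`` section generates the
whole input bundle instead of reading files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus_map as cmap
from . import gwas_validation as gwas
from . import integration as integ
from . import meta_qtl as meta
from . import qtl_compendium as qc
from . import synthetic_data as synth

__all__ = ["PipelineReport", "ConfigError", "PipelineError", "run_pipeline",
           "DEFAULT_CONFIG"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline configuration is unusable."""


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "mqtlkit_out",
    "compendium": {"policy": "prefer_reported", "dialect": {}},
    "consensus": {"extrapolation_limit": 5.0},
    "meta": {
        "kmax_cap": 12, "n_starts": 20, "tol": 1e-8,
        "membership_threshold": 0.60, "bin_width_cm": 0.5,
    },
    "validation": {"half_window_bp": 500_000, "mta_threshold": 5.0},
    "integration": {
        "lfc_min": 1.0, "fdr_max": 0.05, "containment": "any",
        "c": 9, "m": 2.0, "membership_min": 0.5,
        "required_motif": "ABRE",
    },
}


@dataclass
class PipelineReport:
    """Counts and summary statistics of one pipeline run."""

    n_qtls_in: int = 0
    n_qtls_projected: int = 0
    n_mqtls: int = 0
    mean_input_ci_cm: float = float("nan")
    mean_mqtl_ci_cm: float = float("nan")
    ci_reduction_pct: float = float("nan")
    reduction_fold_range: tuple[float, float] | None = None
    n_mqtls_validated: int = 0
    validated_fraction: float = 0.0
    n_genes_in_windows: int = 0
    n_degs: int = 0
    n_intersection: int = 0
    signature_cluster_size: int = 0
    n_decgs: int = 0
    decg_ids: list[str] = field(default_factory=list)
    signature_gene_ids: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=str)

    def to_text(self) -> str:
        lines = [
            f"QTLs read:                 {self.n_qtls_in}",
            f"QTLs projected:            {self.n_qtls_projected}",
            f"MQTLs:                     {self.n_mqtls}",
            f"mean input CI (cM):        {self.mean_input_ci_cm:.2f}",
            f"mean MQTL CI (cM):         {self.mean_mqtl_ci_cm:.2f}",
            f"CI reduction (%):          {self.ci_reduction_pct:.1f}",
            f"MQTLs validated by MTAs:   {self.n_mqtls_validated}"
            f" ({100 * self.validated_fraction:.1f}%)",
            f"genes in MQTL windows:     {self.n_genes_in_windows}",
            f"DEGs (union):              {self.n_degs}",
            f"window ∩ DEG genes:        {self.n_intersection}",
            f"signature-cluster genes:   {self.signature_cluster_size}",
            f"candidate genes (DECGs):   {self.n_decgs}",
        ]
        if self.reduction_fold_range:
            lo, hi = self.reduction_fold_range
            lines.insert(6, f"CI reduction fold range:   {lo:.2f}-{hi:.2f}")
        return "\n".join(lines) + "\n"


def _merge_config(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return _merge_config(path_or_dict)
    try:
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    except FileNotFoundError as exc:
        raise ConfigError(str(exc)) from exc
    if not isinstance(user, dict):
        raise ConfigError("config must be a YAML mapping")
    return _merge_config(user)


def run_pipeline(config) -> PipelineReport:
    """Run every stage in order, writing each stage's outputs as it finishes."""
    cfg = load_config(config)
    outdir = Path(cfg["output_dir"])
    report = PipelineReport()
    seed = int(cfg.get("seed", 0))
    if "simulate" not in cfg and not cfg.get("inputs"):
        raise ConfigError("config needs an 'inputs' or 'simulate' section")

    sim_cfg = None
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"] or {})
        sim_kwargs.setdefault("seed", seed)
        for key in ("true_loci_cm", "qtls_per_locus", "sd_range_cm",
                    "n_range", "r2_range", "mta_per_locus"):
            if key in sim_kwargs and sim_kwargs[key] is not None:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        try:
            sim_cfg = synth.SimulationConfig(**sim_kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"simulate section: {exc}") from exc
    else:
        inputs = cfg["inputs"]
        missing = [k for k, v in inputs.items() if v and not Path(v).exists()]
        if missing:
            raise ConfigError(f"input files not found: {missing}")

    outdir.mkdir(parents=True, exist_ok=True)
    if sim_cfg is not None:
        bundle = synth.simulate_bundle(sim_cfg)
        inputs = synth.write_bundle(bundle, outdir / "inputs")

    # ---- stage 1: compendium -------------------------------------------
    try:
        records = qc.read_qtl_table(
            inputs["qtl_table"], cfg["compendium"].get("dialect") or {}
        )
        records = [qc.standardize_qtl(r, cfg["compendium"]["policy"])
                   for r in records]
    except (qc.QTLFormatError, ValueError, KeyError) as exc:
        raise PipelineError(f"compendium stage: {exc}") from exc
    report.n_qtls_in = len(records)
    qc.write_qtl_table(records, outdir / "standardized_qtls.tsv")

    # ---- stage 2: consensus map and projection -------------------------
    try:
        maps = cmap.read_map_table(inputs["maps"])
        consensus = cmap.merge_maps(maps)
    except (ValueError, KeyError) as exc:
        raise PipelineError(f"consensus stage: {exc}") from exc
    cmap.write_map_table([consensus], outdir / "consensus_map.tsv")
    map_by_id = {m.map_id: m for m in maps}
    projected: list[cmap.ProjectedQTL] = []
    for rec in records:
        source = map_by_id.get(rec.map_id)
        if source is None:
            report.warnings.append(f"{rec.qtl_id}: unknown map {rec.map_id}")
            continue
        try:
            projected.append(cmap.project_qtl(
                rec, source, consensus,
                cfg["consensus"]["extrapolation_limit"],
            ))
        except cmap.ProjectionError as exc:
            report.warnings.append(str(exc))
    report.n_qtls_projected = len(projected)
    pd.DataFrame(
        [{"qtl_id": p.qtl.qtl_id, "chr": p.chromosome,
          "position_cM": p.position_cm, "ci_low_cM": p.ci_low_cm,
          "ci_high_cM": p.ci_high_cm, "sd_cM": p.sd_cm}
         for p in projected]
    ).to_csv(outdir / "projected_qtls.tsv", sep="\t", index=False)

    # ---- stage 3: meta-analysis ----------------------------------------
    mc = cfg["meta"]
    by_chrom: dict[int, list[cmap.ProjectedQTL]] = {}
    for p in projected:
        by_chrom.setdefault(p.chromosome, []).append(p)
    mqtls: list[meta.MQTL] = []
    selection_rows = []
    overview_frames = []
    proj_lookup = {p.qtl.qtl_id: p for p in projected}
    for chrom in sorted(by_chrom):
        qtls = by_chrom[chrom]
        result = meta.run_chromosome(
            qtls, kmax_cap=mc["kmax_cap"], n_starts=mc["n_starts"],
            tol=mc["tol"], seed=seed + 1000 * chrom,
            threshold=mc["membership_threshold"],
        )
        mqtls.extend(result.mqtls)
        for row in result.criteria:
            selection_rows.append({
                "chr": chrom, "K": row.k, "p": row.p_free, "n": row.n_obs,
                "AIC": row.aic, "AICc": row.aicc, "AIC3": row.aic3,
                "BIC": row.bic, "AWE": row.awe,
                "chosen": int(row.k == result.selected_k),
            })
        for qtl_id in result.unassigned:
            report.warnings.append(f"{qtl_id}: unassigned (chr {chrom})")
        span = (min(q.ci_low_cm for q in qtls), max(q.ci_high_cm for q in qtls))
        ov = meta.overview_index(qtls, span, mc["bin_width_cm"])
        overview_frames.append(pd.DataFrame(
            [{"chr": chrom, "start_cM": a, "end_cM": b, "index": v}
             for a, b, v in ov.bins]
        ))
    report.n_mqtls = len(mqtls)
    pd.DataFrame(
        [{"mqtl_id": m.mqtl_id, "chr": m.chromosome, "peak_cM": m.peak_cm,
          "ci_low": m.ci_low_cm, "ci_high": m.ci_high_cm,
          "n_members": m.n_members,
          "member_ids": ";".join(q for q, _ in m.members)}
         for m in mqtls]
    ).to_csv(outdir / "mqtls.tsv", sep="\t", index=False)
    pd.DataFrame(selection_rows).to_csv(
        outdir / "model_selection.tsv", sep="\t", index=False)
    if overview_frames:
        pd.concat(overview_frames).to_csv(
            outdir / "overview_index.tsv", sep="\t", index=False)

    if projected:
        report.mean_input_ci_cm = float(np.mean(
            [p.ci_high_cm - p.ci_low_cm for p in projected]))
    if mqtls:
        report.mean_mqtl_ci_cm = float(np.mean(
            [m.ci_high_cm - m.ci_low_cm for m in mqtls]))
        report.ci_reduction_pct = 100.0 * (
            1.0 - report.mean_mqtl_ci_cm / report.mean_input_ci_cm)
        folds = []
        for m in mqtls:
            member_mean = np.mean([
                proj_lookup[q].ci_high_cm - proj_lookup[q].ci_low_cm
                for q, _ in m.members
            ])
            width = m.ci_high_cm - m.ci_low_cm
            if width > 0:
                folds.append(member_mean / width)
        if folds:
            report.reduction_fold_range = (float(min(folds)), float(max(folds)))

    # ---- stage 4: GWAS validation --------------------------------------
    vc = cfg["validation"]
    try:
        anchors = gwas.read_anchor_table(inputs["anchors"])
        mtas = gwas.read_mta_table(inputs["mtas"])
    except (ValueError, KeyError) as exc:
        raise PipelineError(f"validation stage: {exc}") from exc
    marker_cm = {m: p for m, _, p in consensus.entries}
    windows, unanchored = gwas.anchor_mqtls(
        mqtls, anchors, proj_lookup,
        half_window=vc["half_window_bp"], marker_cm=marker_cm,
    )
    for mqtl_id in unanchored:
        report.warnings.append(f"{mqtl_id}: unanchored")
    validation = gwas.colocalize(windows, mtas, vc["mta_threshold"])
    report.n_mqtls_validated = len(validation.validated_ids)
    report.validated_fraction = validation.validated_fraction
    pd.DataFrame(
        [{"mqtl_id": w.mqtl_id, "chr": w.chromosome,
          "start_bp": w.start_bp, "end_bp": w.end_bp,
          "n_mtas": len(validation.support[w.mqtl_id]),
          "mta_ids": ";".join(m.snp_id for m in validation.support[w.mqtl_id]),
          "validated": int(bool(validation.support[w.mqtl_id]))}
         for w in windows]
    ).to_csv(outdir / "validation.tsv", sep="\t", index=False)
    with open(outdir / "validation.json", "w") as fh:
        json.dump({
            "validated": validation.validated_ids,
            "validated_fraction": validation.validated_fraction,
            "unanchored": unanchored,
        }, fh, indent=1)

    # ---- stage 5: candidate-gene funnel --------------------------------
    ic = cfg["integration"]
    try:
        genes = integ.read_gene_models_gff3(inputs["gff3"])
        genome = integ.load_genome(inputs["genome"])
        deg_stats = integ.read_deg_table(inputs["deg_stats"])
        expression = integ.read_expression_table(inputs["expression"])
    except (ValueError, KeyError, OSError) as exc:
        raise PipelineError(f"integration stage: {exc}") from exc

    gene_windows = integ.genes_in_windows(genes, windows, ic["containment"])
    report.n_genes_in_windows = len(gene_windows)
    degs = integ.filter_degs(deg_stats, ic["lfc_min"], ic["fdr_max"])
    report.n_degs = len(degs)
    intersection = sorted(set(gene_windows) & degs)
    report.n_intersection = len(intersection)

    decgs: list[integ.CandidateGene] = []
    signature_genes: list[str] = []
    cluster_id = None
    if intersection:
        ids, mut, wt = integ.expression_profiles(expression)
        keep_ids = [i for i, g in enumerate(ids) if g in set(intersection)]
        ids = [ids[i] for i in keep_ids]
        concat = np.hstack([mut[keep_ids], wt[keep_ids]])
        Z, mask = integ.standardize_profiles(concat)
        ids = [g for g, keep in zip(ids, mask) if keep]
        if len(ids) >= 1:
            c = min(int(ic["c"]), len(ids))
            result = integ.fuzzy_cmeans(
                Z, c=c, m=ic["m"], seed=seed + 7, gene_ids=ids,
            )
            T = mut.shape[1]
            cluster_id, signature_genes = integ.select_signature_cluster(
                result, Z[:, :T], Z[:, T:],
                membership_min=ic["membership_min"],
            )
        report.signature_cluster_size = len(signature_genes)
        report.signature_gene_ids = sorted(signature_genes)
        gene_by_id = {g.gene_id: g for g in genes}
        promoters = {
            g: integ.extract_promoter(gene_by_id[g], genome)
            for g in signature_genes if g in gene_by_id
        }
        contrasts: dict[str, list[str]] = {}
        for s in deg_stats:
            if abs(s.log2fc) >= ic["lfc_min"] and s.fdr < ic["fdr_max"]:
                contrasts.setdefault(s.gene_id, []).append(s.contrast)
        decgs = integ.screen_decgs(
            signature_genes, promoters,
            required_motif=ic["required_motif"],
            cluster_id=-1 if cluster_id is None else cluster_id,
            gene_windows=gene_windows, deg_contrasts=contrasts,
        )
    report.n_decgs = len(decgs)
    report.decg_ids = [g.gene_id for g in decgs]
    pd.DataFrame(
        [{"gene_id": g.gene_id, "mqtl_id": g.mqtl_id,
          "cluster": g.cluster_id,
          "contrasts": ";".join(g.deg_contrasts),
          "n_cre_hits": len(g.cre_hits),
          "abre_hits": sum(1 for h in g.cre_hits if h.motif == ic["required_motif"])}
         for g in decgs]
    ).to_csv(outdir / "decgs.tsv", sep="\t", index=False)

    with open(outdir / "report.json", "w") as fh:
        fh.write(report.to_json())
    with open(outdir / "report.txt", "w") as fh:
        fh.write(report.to_text())
    logger.info("pipeline finished: %d QTLs -> %d MQTLs -> %d DECGs",
                report.n_qtls_in, report.n_mqtls, report.n_decgs)
    return report
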