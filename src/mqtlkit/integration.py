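"""Candidate-gene funnel: MQTL windows ∩ DEGs → temporal clustering →
promoter cis-element screen.

Genes inside MQTL physical windows are intersected with the union of
differentially expressed genes (|log2FC| >= 1, FDR < 0.05). Their
two-genotype (drought-sensitive wild type vs tolerant mutant) expression
time courses over 0/3/6 days of osmotic stress are soft-clustered by fuzzy
c-means; the signature cluster is the one whose genes rise in the mutant
while falling in the wild type. Genes of that cluster whose promoter
(2 kb upstream of ATG to the TSS; 1.5 kb when the 5'UTR exceeds 100 bp)
carries an ABA-responsive element (ABRE) become differentially expressed
candidate genes (DECGs).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .gwas_validation import PhysicalWindow

__all__ = [
    "GeneModel",
    "DEGStats",
    "ExpressionRecord",
    "ClusterResult",
    "Motif",
    "CREHit",
    "CandidateGene",
    "compute_fpkm",
    "filter_degs",
    "genes_in_windows",
    "standardize_profiles",
    "fuzzy_cmeans",
    "select_signature_cluster",
    "extract_promoter",
    "scan_cres",
    "screen_decgs",
    "cre_enrichment",
    "default_motifs",
    "load_genome",
    "read_gene_models_gff3",
    "write_gene_models_gff3",
]

logger = logging.getLogger(__name__)

TIMEPOINTS = (0.0, 3.0, 6.0)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class GeneModel:
    """A gene's coordinates plus what the promoter rule needs (TSS, ATG, 5'UTR)."""

    gene_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    strand: str
    atg_bp: int
    tss_bp: int
    utr5_len: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.utr5_len < 0:
            raise ValueError(f"{self.gene_id}: negative 5'UTR length")
        if abs(self.atg_bp - self.tss_bp) != self.utr5_len:
            raise ValueError(
                f"{self.gene_id}: utr5_len {self.utr5_len} inconsistent with "
                f"|ATG - TSS| = {abs(self.atg_bp - self.tss_bp)}"
            )


@dataclass(frozen=True)
class DEGStats:
    gene_id: str
    log2fc: float
    fdr: float
    contrast: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"{self.gene_id}: fdr outside [0, 1]")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    genotype: str  # mutant | wildtype
    timepoint: float
    replicate: int
    fpkm: float

    def __post_init__(self) -> None:
        if self.fpkm < 0:
            raise ValueError(f"{self.gene_id}: negative FPKM")
        if self.genotype not in ("mutant", "wildtype"):
            raise ValueError(f"{self.gene_id}: genotype {self.genotype!r}")


@dataclass
class ClusterResult:
    """Fuzzy c-means output on standardized profiles."""

    c: int
    m: float
    centers: np.ndarray  # c x T
    memberships: np.ndarray  # genes x c, rows sum to 1
    gene_ids: list[str]
    objective: float
    objective_path: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class Motif:
    """A promoter cis-regulatory element as an IUPAC consensus."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad or not self.iupac:
            raise ValueError(f"motif {self.name}: invalid IUPAC symbols {sorted(bad)}")


@dataclass(frozen=True)
class CREHit:
    motif: str
    offset: int  # 0-based, plus-strand-equivalent
    strand: str


@dataclass
class CandidateGene:
    """A gene that survived the whole funnel, with its evidence trail."""

    gene_id: str
    mqtl_id: str
    deg_contrasts: list[str]
    cluster_id: int
    cre_hits: list[CREHit]
    passes_abre: bool = True


# --------------------------------------------------------------------------
# expression arithmetic and DEG filtering

def compute_fpkm(c_frags: int, n_mapped: int, l_bp: int) -> float:
    """FPKM = 10^6 C / (N L / 10^3) = 10^9 C / (N L).

    C: fragments assigned to the gene; N: total mapped fragments;
    L: gene length in bp.
    """
    if n_mapped <= 0 or l_bp <= 0:
        raise ValueError("n_mapped and l_bp must be positive")
    if c_frags < 0:
        raise ValueError("fragment count must be non-negative")
    return 1e9 * c_frags / (n_mapped * l_bp)


def filter_degs(
    stats: Iterable[DEGStats], lfc_min: float = 1.0, fdr_max: float = 0.05
) -> set[str]:
    """Union of DEGs over contrasts: |log2FC| >= lfc_min and FDR < fdr_max."""
    return {
        s.gene_id for s in stats
        if abs(s.log2fc) >= lfc_min and s.fdr < fdr_max
    }


# --------------------------------------------------------------------------
# gene / window intersection

def genes_in_windows(
    genes: Sequence[GeneModel],
    windows: Sequence[PhysicalWindow],
    containment: str = "any",
) -> dict[str, list[str]]:
    """Map gene_id -> list of overlapping window (MQTL) ids.

    ``containment="any"`` requires >=1 bp of overlap; ``"full"`` requires
    the gene to lie entirely inside the window. Only genes with at least
    one match appear in the result.
    """
    if containment not in ("any", "full"):
        raise ValueError(f"unknown containment rule {containment!r}")
    by_chrom: dict[int, list[PhysicalWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chromosome, []).append(w)
    out: dict[str, list[str]] = {}
    for g in genes:
        for w in by_chrom.get(g.chromosome, []):
            if containment == "any":
                hit = g.start_bp <= w.end_bp and g.end_bp >= w.start_bp
            else:
                hit = w.start_bp <= g.start_bp and g.end_bp <= w.end_bp
            if hit:
                out.setdefault(g.gene_id, []).append(w.mqtl_id)
    return out


# --------------------------------------------------------------------------
# fuzzy c-means clustering of temporal profiles

def standardize_profiles(
    profiles: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardize profiles to zero mean, unit variance.

    Returns (standardized rows with nonzero variance, boolean keep-mask).
    Flat profiles carry no temporal signal and are excluded from
    clustering.
    """
    X = np.asarray(profiles, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    Z = np.zeros_like(X)
    Z[keep] = (X[keep] - mu[keep]) / sd[keep]
    return Z[keep], keep


def _fcm_once(
    X: np.ndarray, c: int, m: float, tol: float, max_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    from sklearn.cluster import kmeans_plusplus

    n = X.shape[0]
    # k-means++ seeding spreads the initial centers across the blobs;
    # memberships then follow from the distance update
    centers0, _ = kmeans_plusplus(
        X, n_clusters=c, random_state=int(rng.integers(2**31 - 1))
    )
    d2 = ((X[:, None, :] - centers0[None, :, :]) ** 2).sum(axis=2)
    U = np.zeros((n, c))
    zero = d2 <= 1e-300
    any_zero = zero.any(axis=1)
    if any_zero.any():
        U[np.where(any_zero)[0], np.argmax(zero[any_zero], axis=1)] = 1.0
    ok = ~any_zero
    if ok.any():
        inv = d2[ok] ** (-1.0 / (m - 1.0))
        U[ok] = inv / inv.sum(axis=1, keepdims=True)
    path: list[float] = []
    centers = centers0
    for _ in range(max_iter):
        Um = U**m
        colsum = Um.sum(axis=0)
        # an empty cluster (all its mass captured by a coincident twin)
        # keeps its previous center instead of dividing by zero
        centers = np.where(
            colsum[:, None] > 1e-300,
            (Um.T @ X) / np.maximum(colsum, 1e-300)[:, None],
            centers,
        )
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        obj = float((Um * d2).sum())
        path.append(obj)
        zero = d2 <= 1e-300
        U_new = np.zeros_like(U)
        any_zero = zero.any(axis=1)
        if any_zero.any():
            # coincident point: full membership to the first zero-distance center
            first = np.argmax(zero[any_zero], axis=1)
            U_new[np.where(any_zero)[0], first] = 1.0
        ok = ~any_zero
        if ok.any():
            inv = d2[ok] ** (-1.0 / (m - 1.0))
            U_new[ok] = inv / inv.sum(axis=1, keepdims=True)
        delta = float(np.abs(U_new - U).max())
        U = U_new
        if delta < tol:
            break
    Um = U**m
    colsum = Um.sum(axis=0)
    centers = np.where(
        colsum[:, None] > 1e-300,
        (Um.T @ X) / np.maximum(colsum, 1e-300)[:, None],
        centers,
    )
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    obj = float((Um * d2).sum())
    path.append(obj)
    return U, centers, obj, path


def fuzzy_cmeans(
    profiles: np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = None,
    n_init: int = 5,
    gene_ids: Sequence[str] | None = None,
) -> ClusterResult:
    """Bezdek fuzzy c-means on (already standardized) profiles.

    u_ij = 1 / sum_l (d_ij / d_il)^(2/(m-1)); centers are u^m-weighted
    means. Multi-start; the run with the lowest objective wins.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("profiles must be a genes x timepoints matrix, T >= 2")
    if c < 1:
        raise ValueError("c must be >= 1")
    if c > X.shape[0]:
        raise ValueError(f"c={c} exceeds number of genes {X.shape[0]}")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_init)):
        U, centers, obj, path = _fcm_once(X, c, m, tol, max_iter, rng)
        if best is None or obj < best[2]:
            best = (U, centers, obj, path)
    U, centers, obj, path = best
    ids = list(gene_ids) if gene_ids is not None else [str(i) for i in range(X.shape[0])]
    return ClusterResult(c=c, m=m, centers=centers, memberships=U,
                         gene_ids=ids, objective=obj, objective_path=path)


def _slope(t: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(t, y, 1)[0])


def select_signature_cluster(
    result: ClusterResult,
    mutant_profiles: np.ndarray,
    wildtype_profiles: np.ndarray,
    membership_min: float = 0.5,
    timepoints: Sequence[float] = TIMEPOINTS,
) -> tuple[int | None, list[str]]:
    """Find the cluster that rises in the mutant and falls in the wild type.

    Genes join a cluster by maximum membership >= ``membership_min``. For
    each non-empty cluster the per-genotype mean profile gets a
    least-squares slope over the timepoints; the winner maximizes
    (mutant slope) - (wildtype slope) subject to mutant slope > 0 and
    wildtype slope < 0. Returns (cluster id or None, member gene ids).
    """
    t = np.asarray(timepoints, dtype=float)
    labels = np.argmax(result.memberships, axis=1)
    maxmem = result.memberships[np.arange(len(labels)), labels]
    assigned = maxmem >= membership_min
    best_id, best_score = None, -np.inf
    for k in range(result.c):
        idx = np.where(assigned & (labels == k))[0]
        if idx.size == 0:
            continue
        ms = _slope(t, mutant_profiles[idx].mean(axis=0))
        ws = _slope(t, wildtype_profiles[idx].mean(axis=0))
        if ms > 0 and ws < 0 and ms - ws > best_score:
            best_id, best_score = k, ms - ws
    if best_id is None:
        logger.warning("no cluster satisfies the up-in-mutant/down-in-wildtype "
                       "signature; empty selection")
        return None, []
    idx = np.where(assigned & (labels == best_id))[0]
    return best_id, [result.gene_ids[i] for i in idx]


# --------------------------------------------------------------------------
# promoters and cis-regulatory elements

def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def extract_promoter(
    gene: GeneModel,
    genome: Mapping[str, str],
    long_utr_bp: int = 100,
    upstream_default: int = 2000,
    upstream_long_utr: int = 1500,
) -> str:
    """Promoter sequence in transcription orientation.

    Default region: 2000 bp upstream of the ATG through the TSS. When the
    5'UTR exceeds ``long_utr_bp`` (100 bp), the region shrinks to 1500 bp
    upstream of the ATG through the 5'UTR start, keeping long UTRs from
    diluting the element scan. Minus-strand genes are
    reverse-complemented; out-of-sequence spans are clipped with a warning.
    """
    key = str(gene.chromosome)
    if key not in genome:
        raise KeyError(f"chromosome {key!r} absent from genome")
    seq = genome[key]
    upstream = upstream_long_utr if gene.utr5_len > long_utr_bp else upstream_default
    if gene.strand == "+":
        lo, hi = gene.atg_bp - upstream, gene.tss_bp  # 1-based inclusive
    else:
        lo, hi = gene.tss_bp, gene.atg_bp + upstream
    clipped_lo, clipped_hi = max(1, lo), min(len(seq), hi)
    if (clipped_lo, clipped_hi) != (lo, hi):
        warnings.warn(
            f"{gene.gene_id}: promoter span [{lo}, {hi}] clipped to "
            f"[{clipped_lo}, {clipped_hi}]", RuntimeWarning, stacklevel=2,
        )
    region = seq[clipped_lo - 1 : clipped_hi].upper()
    return revcomp(region) if gene.strand == "-" else region


def _iupac_regex(motif: str):
    # character classes exclude N, so N in the sequence never matches
    return re.compile("(?=" + "".join(f"[{IUPAC[m]}]" for m in motif) + ")")


def scan_cres(
    sequence: str,
    motifs: Sequence[Motif],
    both_strands: bool = True,
) -> list[CREHit]:
    """Exact IUPAC-degenerate motif scan (overlapping matches included).

    Reverse-strand occurrences are found by scanning for the
    reverse-complemented motif on the plus strand; they are reported with
    strand "-" and the plus-strand offset of the matched window. A
    palindromic motif therefore hits both strands at the same offset.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-DNA symbols {sorted(bad)}")
    hits: list[CREHit] = []
    for motif in motifs:
        pats = [(motif.iupac.upper(), "+")]
        if both_strands:
            pats.append((revcomp(motif.iupac), "-"))
        for pat, strand in pats:
            for m in _iupac_regex(pat).finditer(seq):
                hits.append(CREHit(motif.name, m.start(), strand))
    hits.sort(key=lambda h: (h.offset, h.motif, h.strand))
    return hits


def default_motifs() -> list[Motif]:
    """The shipped catalog of drought-associated promoter elements."""
    text = resources.files("mqtlkit").joinpath("data/cre_motifs.tsv").read_text()
    motifs = []
    for line in text.strip().splitlines()[1:]:
        name, iupac = line.split("\t")[:2]
        motifs.append(Motif(name, iupac))
    return motifs


def screen_decgs(
    signature_genes: Sequence[str],
    promoters: Mapping[str, str],
    motifs: Sequence[Motif] | None = None,
    required_motif: str = "ABRE",
    cluster_id: int = -1,
    gene_windows: Mapping[str, list[str]] | None = None,
    deg_contrasts: Mapping[str, list[str]] | None = None,
) -> list[CandidateGene]:
    """Final funnel stage: signature-cluster genes with the required element.

    A gene becomes a DECG iff it belongs to the signature cluster and its
    promoter carries at least one hit of ``required_motif`` (on either
    strand). The evidence trail records the hosting MQTL(s), the DE
    contrasts, the cluster and the hits.
    """
    motifs = list(motifs) if motifs is not None else default_motifs()
    req = [m for m in motifs if m.name == required_motif]
    if not req:
        raise ValueError(f"required motif {required_motif!r} not in catalog")
    out: list[CandidateGene] = []
    for gene_id in signature_genes:
        promoter = promoters.get(gene_id)
        if promoter is None:
            logger.warning("gene %s has no promoter sequence; skipped", gene_id)
            continue
        hits = scan_cres(promoter, motifs)
        if not any(h.motif == required_motif for h in hits):
            continue
        wins = (gene_windows or {}).get(gene_id, [])
        out.append(
            CandidateGene(
                gene_id=gene_id,
                mqtl_id=";".join(wins),
                deg_contrasts=(deg_contrasts or {}).get(gene_id, []),
                cluster_id=cluster_id,
                cre_hits=hits,
            )
        )
    out.sort(key=lambda g: g.gene_id)
    return out


def cre_enrichment(
    promoters: Mapping[str, str],
    motifs: Sequence[Motif] | None = None,
    seed: int | None = None,
    n_shuffles: int = 5,
) -> pd.DataFrame:
    """Presence counts per element plus a one-sided binomial enrichment test.

    The background rate is the fraction of composition-preserving shuffled
    promoters containing the element; the test asks whether the observed
    promoter count exceeds it.
    """
    motifs = list(motifs) if motifs is not None else default_motifs()
    rng = np.random.default_rng(seed)
    seqs = list(promoters.values())
    n = len(seqs)
    shuffled: list[str] = []
    for seq in seqs:
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        for _ in range(n_shuffles):
            rng.shuffle(arr)
            shuffled.append(arr.tobytes().decode())
    rows = []
    for motif in motifs:
        observed = sum(
            1 for s in seqs if any(h.motif == motif.name for h in scan_cres(s, [motif]))
        )
        bg_hits = sum(
            1 for s in shuffled if any(h.motif == motif.name for h in scan_cres(s, [motif]))
        )
        p_bg = bg_hits / len(shuffled) if shuffled else 0.0
        if n > 0 and 0.0 < p_bg < 1.0:
            pval = binomtest(observed, n, p_bg, alternative="greater").pvalue
        else:
            pval = 1.0 if observed <= p_bg * n else 0.0
        rows.append({
            "motif": motif.name, "iupac": motif.iupac,
            "n_promoters_with_hit": observed, "n_promoters": n,
            "background_rate": p_bg, "p_value": pval,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# file formats: FASTA genomes, GFF3 gene models, TSV stats

def load_genome(path) -> dict[str, str]:
    """Load a FASTA genome keyed by chromosome id (leading 'chr' stripped)."""
    from Bio import SeqIO

    genome = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            key = rec.id[3:] if rec.id.lower().startswith("chr") else rec.id
            genome[key] = str(rec.seq).upper()
    return genome


def write_genome(genome: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for key in sorted(genome):
            fh.write(f">chr{key}\n")
            seq = genome[key]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_gene_models_gff3(path) -> list[GeneModel]:
    """Parse gene models from GFF3; 5'UTR length from five_prime_UTR features."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        utr5 = sum(
            u.end - u.start + 1
            for u in db.children(g, featuretype="five_prime_UTR")
        )
        chrom = g.seqid[3:] if g.seqid.lower().startswith("chr") else g.seqid
        if g.strand == "+":
            tss = g.start
            atg = tss + utr5
        else:
            tss = g.end
            atg = tss - utr5
        genes.append(
            GeneModel(
                gene_id=g.id, chromosome=int(chrom),
                start_bp=g.start, end_bp=g.end, strand=g.strand,
                atg_bp=atg, tss_bp=tss, utr5_len=utr5,
            )
        )
    genes.sort(key=lambda g: (g.chromosome, g.start_bp, g.gene_id))
    return genes


def write_gene_models_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"chr{g.chromosome}\tmqtlkit\tgene\t{g.start_bp}\t{g.end_bp}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            if g.utr5_len > 0:
                if g.strand == "+":
                    lo, hi = g.tss_bp, g.atg_bp - 1
                else:
                    lo, hi = g.atg_bp + 1, g.tss_bp
                fh.write(
                    f"chr{g.chromosome}\tmqtlkit\tfive_prime_UTR\t{lo}\t{hi}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.utr5;Parent={g.gene_id}\n"
                )


def read_deg_table(path) -> list[DEGStats]:
    df = pd.read_csv(path, sep="\t")
    return [
        DEGStats(str(r.gene_id), float(r.log2fc), float(r.fdr),
                 str(getattr(r, "contrast", "")))
        for r in df.itertuples()
    ]


def read_expression_table(path) -> list[ExpressionRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        ExpressionRecord(str(r.gene_id), str(r.genotype), float(r.timepoint),
                         int(r.replicate), float(r.fpkm))
        for r in df.itertuples()
    ]


def expression_profiles(
    records: Sequence[ExpressionRecord],
    timepoints: Sequence[float] = TIMEPOINTS,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Replicate-averaged FPKM profiles per gene and genotype.

    Returns (gene_ids, mutant genes x T, wildtype genes x T); genes missing
    a genotype/timepoint cell are dropped with a warning.
    """
    df = pd.DataFrame(
        [(r.gene_id, r.genotype, r.timepoint, r.fpkm) for r in records],
        columns=["gene_id", "genotype", "timepoint", "fpkm"],
    )
    mean = df.groupby(["gene_id", "genotype", "timepoint"])["fpkm"].mean()
    wide = mean.unstack(["genotype", "timepoint"])
    cols = [("mutant", t) for t in timepoints] + [("wildtype", t) for t in timepoints]
    missing = [c for c in cols if c not in wide.columns]
    if missing:
        raise ValueError(f"expression table missing cells: {missing}")
    complete = wide[cols].dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.warning("%d genes with incomplete profiles dropped", n_dropped)
    ids = [str(i) for i in complete.index]
    T = len(timepoints)
    mat = complete.to_numpy()
    return ids, mat[:, :T], mat[:, T:]
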