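"""Candidate-gene funnel stages: FPKM, DEG filter, overlap, clustering,
promoters and cis-element scanning."""

import numpy as np
import pytest

from mqtlkit.gwas_validation import PhysicalWindow
from mqtlkit.integration import (
    DEGStats,
    GeneModel,
    IUPAC,
    Motif,
    compute_fpkm,
    default_motifs,
    extract_promoter,
    filter_degs,
    fuzzy_cmeans,
    genes_in_windows,
    revcomp,
    scan_cres,
    screen_decgs,
    select_signature_cluster,
    standardize_profiles,
)


class TestFpkm:
    def test_zero_fragments(self):
        assert compute_fpkm(0, 10**6, 1000) == 0.0

    def test_worked_example(self):
        assert compute_fpkm(100, 10**6, 1000) == pytest.approx(100.0)

    def test_doubling_length_halves_fpkm(self):
        assert compute_fpkm(50, 10**6, 2000) == pytest.approx(
            compute_fpkm(50, 10**6, 1000) / 2)

    def test_linear_in_counts(self):
        for c in (1, 7, 300):
            assert compute_fpkm(c, 10**6, 500) == pytest.approx(
                c * compute_fpkm(1, 10**6, 500))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_fpkm(1, 0, 100)
        with pytest.raises(ValueError):
            compute_fpkm(-1, 10, 100)


class TestFilterDegs:
    @pytest.mark.parametrize("lfc,fdr,kept", [
        (1.0, 0.049, True),    # both thresholds inclusive/strict as defined
        (0.99, 0.001, False),  # below fold threshold
        (-2.0, 0.05, False),   # FDR is a strict inequality
        (-1.0, 0.01, True),    # down-regulation counts via |log2FC|
    ])
    def test_threshold_rules(self, lfc, fdr, kept):
        got = filter_degs([DEGStats("g", lfc, fdr)])
        assert (got == {"g"}) is kept

    def test_union_over_contrasts(self):
        stats = [DEGStats("g", 0.2, 0.9, "c1"), DEGStats("g", 2.0, 0.001, "c2"),
                 DEGStats("h", 0.1, 0.9, "c1")]
        assert filter_degs(stats) == {"g"}


def gene(gene_id, chrom, start, end, strand="+", utr5=50):
    if strand == "+":
        tss, atg = start, start + utr5
    else:
        tss, atg = end, end - utr5
    return GeneModel(gene_id, chrom, start, end, strand, atg, tss, utr5)


class TestGenesInWindows:
    def test_containment_rules(self):
        w = PhysicalWindow("M1", 1, 1000, 2000)
        inside = gene("in", 1, 1200, 1800)
        edge = gene("edge", 1, 500, 1000)  # 1 bp overlap
        outside = gene("out", 1, 2001, 2500)
        got = genes_in_windows([inside, edge, outside], [w])
        assert got == {"in": ["M1"], "edge": ["M1"]}
        full = genes_in_windows([inside, edge], [w], containment="full")
        assert full == {"in": ["M1"]}

    def test_equals_brute_force(self, rng):
        windows = [PhysicalWindow(f"M{i}", int(rng.integers(1, 3)),
                                  s := int(rng.integers(1, 90_000)),
                                  s + int(rng.integers(100, 20_000)))
                   for i in range(40)]
        genes = [gene(f"g{i}", int(rng.integers(1, 3)),
                      s := int(rng.integers(1, 100_000)),
                      s + int(rng.integers(100, 5_000)))
                 for i in range(120)]
        got = genes_in_windows(genes, windows)
        expected = {}
        for g in genes:
            for w in windows:
                if (g.chromosome == w.chromosome
                        and g.start_bp <= w.end_bp and g.end_bp >= w.start_bp):
                    expected.setdefault(g.gene_id, []).append(w.mqtl_id)
        assert got == expected


class TestFuzzyCmeans:
    def test_single_cluster_is_mean_profile(self, rng):
        X, _ = standardize_profiles(rng.normal(size=(10, 4)))
        res = fuzzy_cmeans(X, c=1, seed=0)
        np.testing.assert_allclose(res.centers[0], X.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(res.memberships, 1.0)

    def test_two_planted_groups_recovered(self, rng):
        rise = np.array([0.0, 1.0, 2.0])
        fall = rise[::-1]
        X = np.vstack([rise + rng.normal(0, 0.1, 3) for _ in range(15)]
                      + [fall + rng.normal(0, 0.1, 3) for _ in range(15)])
        Z, _ = standardize_profiles(X)
        res = fuzzy_cmeans(Z, c=2, seed=0)
        labels = np.argmax(res.memberships, axis=1)
        truth = np.array([0] * 15 + [1] * 15)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_membership_rows_sum_to_one(self, rng):
        Z, _ = standardize_profiles(rng.normal(size=(20, 6)))
        res = fuzzy_cmeans(Z, c=4, seed=1)
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_objective_non_increasing(self, rng):
        Z, _ = standardize_profiles(rng.normal(size=(25, 6)))
        res = fuzzy_cmeans(Z, c=3, seed=2, n_init=1)
        assert all(b <= a + 1e-8 for a, b in
                   zip(res.objective_path, res.objective_path[1:]))

    def test_coincident_point_gets_full_membership(self):
        X = np.array([[0.0, 1.0], [0.0, 1.0], [5.0, 6.0], [5.0, 6.0]])
        res = fuzzy_cmeans(X, c=2, seed=0)
        assert res.memberships.max(axis=1).min() == pytest.approx(1.0)

    def test_too_many_clusters_rejected(self, rng):
        with pytest.raises(ValueError):
            fuzzy_cmeans(rng.normal(size=(3, 4)), c=5)

    def test_flat_profiles_excluded_by_standardization(self):
        X = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        Z, keep = standardize_profiles(X)
        assert keep.tolist() == [False, True]
        assert Z.shape == (1, 3)


class TestSignatureCluster:
    def make_result(self, memberships, gene_ids):
        from mqtlkit.integration import ClusterResult
        U = np.asarray(memberships, dtype=float)
        return ClusterResult(c=U.shape[1], m=2.0,
                             centers=np.zeros((U.shape[1], 3)),
                             memberships=U, gene_ids=gene_ids, objective=0.0)

    def test_planted_signature_selected(self):
        # cluster 0: mutant rises, wildtype falls; cluster 1: both rise
        res = self.make_result([[1, 0], [1, 0], [0, 1]], ["a", "b", "c"])
        mut = np.array([[0, 1, 2], [0, 1.2, 2.2], [0, 1, 2]])
        wt = np.array([[2, 1, 0], [2.2, 1.2, 0.2], [0, 1, 2]])
        cid, genes = select_signature_cluster(res, mut, wt)
        assert cid == 0 and genes == ["a", "b"]

    def test_all_flat_returns_empty(self, caplog):
        res = self.make_result([[1, 0], [0, 1]], ["a", "b"])
        flat = np.zeros((2, 3))
        cid, genes = select_signature_cluster(res, flat, flat)
        assert cid is None and genes == []

    def test_single_signature_cluster_selected(self):
        res = self.make_result([[1.0]], ["a"])
        cid, genes = select_signature_cluster(
            res, np.array([[0, 3, 6]]), np.array([[6, 3, 0]]))
        assert cid == 0 and genes == ["a"]

    def test_low_membership_genes_not_assigned(self):
        res = self.make_result([[0.4, 0.3, 0.3]], ["a"])
        cid, genes = select_signature_cluster(
            res, np.array([[0, 1, 2]]), np.array([[2, 1, 0]]))
        assert genes == []


class TestExtractPromoter:
    def make_genome(self, n=20_000, seed=0):
        rng = np.random.default_rng(seed)
        return {"1": "".join(rng.choice(list("ACGT"), n))}

    def test_plus_strand_short_utr_span(self):
        genome = self.make_genome()
        g = GeneModel("g", 1, 9950, 12000, "+", atg_bp=10_000, tss_bp=9950,
                      utr5_len=50)
        prom = extract_promoter(g, genome)
        assert prom == genome["1"][7999:9950]  # genomic span [8000, 9950]
        assert len(prom) == 1951

    def test_long_utr_uses_1500_bp_rule(self):
        genome = self.make_genome()
        g = GeneModel("g", 1, 9899, 12000, "+", atg_bp=10_000, tss_bp=9899,
                      utr5_len=101)
        prom = extract_promoter(g, genome)
        assert prom == genome["1"][8499:9899]  # [ATG-1500, TSS]

    def test_minus_strand_reverse_complemented(self):
        genome = self.make_genome()
        g = GeneModel("g", 1, 5000, 10_050, "-", atg_bp=10_000, tss_bp=10_050,
                      utr5_len=50)
        prom = extract_promoter(g, genome)
        assert prom == revcomp(genome["1"][10_049:12_000])

    def test_clipped_at_sequence_start_with_warning(self):
        genome = self.make_genome(n=5000)
        g = GeneModel("g", 1, 250, 4000, "+", atg_bp=300, tss_bp=250,
                      utr5_len=50)
        with pytest.warns(RuntimeWarning, match="clipped"):
            prom = extract_promoter(g, genome)
        assert prom == genome["1"][:250]

    def test_missing_chromosome(self):
        g = GeneModel("g", 2, 100, 200, "+", atg_bp=150, tss_bp=100,
                      utr5_len=50)
        with pytest.raises(KeyError):
            extract_promoter(g, {"1": "ACGT"})


def oracle_scan(seq, motifs):
    hits = []
    seq = seq.upper()
    for motif in motifs:
        for pat, strand in [(motif.iupac.upper(), "+"),
                            (revcomp(motif.iupac), "-")]:
            for off in range(len(seq) - len(pat) + 1):
                if all(b in IUPAC[m] for b, m in zip(seq[off:off + len(pat)], pat)):
                    hits.append((motif.name, off, strand))
    return sorted(hits)


class TestScanCres:
    def test_gbox_hit_at_offset_zero(self):
        hits = scan_cres("CACGTG", [Motif("Gbox", "CACGTG")])
        # the G-box core is palindromic: one hit per strand at offset 0
        assert {(h.motif, h.offset, h.strand) for h in hits} == {
            ("Gbox", 0, "+"), ("Gbox", 0, "-")}

    def test_empty_sequence(self):
        assert scan_cres("", default_motifs()) == []

    def test_n_in_sequence_never_matches(self):
        assert scan_cres("ACNTG", [Motif("ABRE", "ACGTG")]) == []
        # but N in the motif matches any base
        assert scan_cres("CATTTG", [Motif("MYC", "CANNTG")],
                         both_strands=False) != []

    def test_degenerate_symbols(self):
        hits = scan_cres("GCCGAC", [Motif("DRE_core", "RCCGAC")],
                         both_strands=False)
        assert [(h.offset, h.strand) for h in hits] == [(0, "+")]

    def test_matches_naive_oracle_on_random_sequences(self, rng):
        motifs = default_motifs()
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGTN"), 2000,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            got = sorted((h.motif, h.offset, h.strand)
                         for h in scan_cres(seq, motifs))
            assert got == oracle_scan(seq, motifs)

    def test_strand_symmetry(self, rng):
        motifs = default_motifs()
        seq = "".join(rng.choice(list("ACGT"), 500))
        fwd = {(h.motif, h.strand) for h in scan_cres(seq, motifs)}
        swapped = {(m, "+-"[s == "+"]) for m, s in fwd}
        rev = {(h.motif, h.strand) for h in scan_cres(revcomp(seq), motifs)}
        assert rev == swapped

    def test_invalid_sequence_and_motif_rejected(self):
        with pytest.raises(ValueError):
            scan_cres("ACGU", default_motifs())
        with pytest.raises(ValueError):
            Motif("bad", "ACGTX")


class TestScreenDecgs:
    def test_requires_signature_and_abre(self):
        promoters = {"with": "TTTACGTGTTT", "without": "TTTTTTTTTTT"}
        decgs = screen_decgs(["with", "without"], promoters)
        assert [g.gene_id for g in decgs] == ["with"]
        assert decgs[0].cre_hits  # evidence trail retained

    def test_non_signature_gene_never_screened(self):
        promoters = {"sig": "ACGTG", "other": "ACGTG"}
        decgs = screen_decgs(["sig"], promoters)
        assert [g.gene_id for g in decgs] == ["sig"]

    def test_unknown_required_motif(self):
        with pytest.raises(ValueError):
            screen_decgs([], {}, required_motif="XYZ")
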