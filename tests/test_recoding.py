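import itertools

import numpy as np
import pytest

from conftest import flip_genome
from magrecode.io import Contig, Feature
from magrecode.recoding import (
    PYL_REQUIRED,
    detect_pyl_machinery,
    detect_sec_machinery,
    fuse_stop_readthrough,
    pair_selenoprotein_secis,
    parse_cloverleaf,
    recoding_report,
    stop_codon_usage,
)
from magrecode.simulate import build_trna


def cds(contig_id, start, end, strand="+", product="", fids=None, fid=None, **attrs):
    return Feature(
        contig_id, start, end, strand, "CDS",
        product=product, function_ids=fids or set(), attrs=attrs, id=fid,
    )


# ---------------------------------------------------------------------------
# stop codon usage


class TestStopCodonUsage:
    def test_hand_counts(self):
        stops = ["TAA"] * 5 + ["TAG"] * 3 + ["TGA"] * 2
        seq = "".join("ATGAAA" + s for s in stops)
        contig = Contig("c1", seq)
        feats = [cds("c1", i * 9, i * 9 + 9) for i in range(10)]
        usage = stop_codon_usage([contig], feats)
        assert (usage.f_UAA, usage.f_UAG, usage.f_UGA) == (0.5, 0.3, 0.2)
        assert usage.n_complete_cds == 10

    def test_single_cds_uaa(self):
        contig = Contig("c1", "ATGAAATAA")
        usage = stop_codon_usage([contig], [cds("c1", 0, 9)])
        assert usage.f_UAA == 1.0

    def test_minus_strand_revcomp(self):
        # genomic 5' triplet TTA on '-' reads as UAA
        contig = Contig("c1", "TTATTTCAT")
        usage = stop_codon_usage([contig], [cds("c1", 0, 9, strand="-")])
        assert usage.f_UAA == 1.0

    def test_partial_and_noncanonical_excluded(self):
        contig = Contig("c1", "ATGAAATAA" + "ATGAAATAG" + "ATGAAAGGG")
        feats = [
            cds("c1", 0, 9),
            cds("c1", 9, 18, partial="1"),
            cds("c1", 18, 27),  # ends GGG: no stop
        ]
        usage = stop_codon_usage([contig], feats)
        assert usage.n_complete_cds == 1
        assert usage.n_excluded_partial == 2

    def test_tiny_cds_excluded_with_warning(self):
        contig = Contig("c1", "ATGTAAAAA")
        with pytest.warns(UserWarning, match="shorter than 6"):
            usage = stop_codon_usage([contig], [cds("c1", 0, 3)])
        assert usage.n_excluded_partial == 1

    def test_fractions_sum_to_one(self, default_genome):
        contigs, features, _ = default_genome
        usage = stop_codon_usage(
            contigs, [f for f in features if f.kind == "CDS"]
        )
        assert usage.f_UAA + usage.f_UAG + usage.f_UGA == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# machinery classification


def sec_feature(gene, contig="c1"):
    products = {
        "SerRS": "seryl-tRNA synthetase",
        "PSTK": "phosphoseryl-tRNA kinase",
        "SepSecS": "O-phosphoseryl-tRNA:selenocysteinyl-tRNA synthase",
        "SPS": "selenophosphate synthetase",
        "SelB": "selenocysteine-specific elongation factor",
    }
    return cds(contig, 0, 9, product=products[gene])


def trna_feature(isotype, contig="c1"):
    return Feature(
        contig, 0, 72, "+", "tRNA", attrs={"isotype": isotype}, id=f"t_{isotype}"
    )


class TestSecMachinery:
    def test_full_set_with_trna_is_complete(self):
        feats = [sec_feature(g) for g in ("PSTK", "SepSecS", "SPS", "SelB")]
        feats.append(trna_feature("sec"))
        assert detect_sec_machinery(feats).status == "complete"

    def test_subset_is_partial(self):
        feats = [sec_feature("SelB"), sec_feature("SPS")]
        status = detect_sec_machinery(feats)
        assert status.status == "partial"
        assert status.detected_genes == {"SelB", "SPS"}

    def test_trna_only(self):
        status = detect_sec_machinery([trna_feature("sec")])
        assert status.status == "trna_only"
        assert status.detected_genes == set()

    def test_absent(self):
        assert detect_sec_machinery([]).status == "absent"

    def test_serrs_reported_but_not_required(self):
        feats = [sec_feature(g) for g in ("PSTK", "SepSecS", "SPS", "SelB")]
        feats.append(trna_feature("sec"))
        status = detect_sec_machinery(feats)
        assert status.status == "complete" and not status.notes["serrs_present"]
        status2 = detect_sec_machinery(feats + [sec_feature("SerRS")])
        assert status2.notes["serrs_present"]
        # SerRS + tRNA alone is still only a tRNA remnant
        status3 = detect_sec_machinery([sec_feature("SerRS"), trna_feature("sec")])
        assert status3.status == "trna_only"


def pyl_features(subset, colocated, with_trna):
    feats = []
    if "PylS" in subset:
        feats.append(cds("s1", 0, 9, product="pyrrolysyl-tRNA synthetase"))
    bcd = sorted(subset & {"PylB", "PylC", "PylD"})
    for i, gene in enumerate(bcd):
        contig = "b1" if colocated else f"b{i + 1}"
        feats.append(cds(contig, i * 100, i * 100 + 9, product=gene.lower()))
    if with_trna:
        feats.append(trna_feature("pyl", contig="t1"))
    return feats


def expected_pyl(subset, colocated, with_trna):
    """Independent statement of the classification rules."""
    bcd = subset & {"PylB", "PylC", "PylD"}
    kept = bcd if (colocated and len(bcd) >= 2) else set()
    detected = kept | ({"PylS"} & subset)
    if detected == PYL_REQUIRED and with_trna:
        status = "complete"
    elif detected:
        status = "partial"
    elif with_trna:
        status = "trna_only"
    else:
        status = "absent"
    return detected, status, len(detected) >= 2


class TestPylMachinery:
    def test_complete_cluster(self):
        feats = pyl_features(PYL_REQUIRED, colocated=True, with_trna=True)
        status = detect_pyl_machinery(feats)
        assert status.status == "complete" and status.included

    def test_two_colocated_genes_included(self):
        feats = pyl_features({"PylB", "PylC"}, colocated=True, with_trna=False)
        status = detect_pyl_machinery(feats)
        assert status.status == "partial" and status.included

    def test_scattered_genes_discarded(self):
        feats = pyl_features({"PylB", "PylC"}, colocated=False, with_trna=False)
        status = detect_pyl_machinery(feats)
        assert status.status == "absent" and not status.included

    def test_pylsn_plus_pylsc_count_as_pyls(self):
        feats = [
            cds("s1", 0, 9, fids={"TIGR03912"}),
            cds("s1", 100, 109, fids={"TIGR02367"}),
        ]
        assert detect_pyl_machinery(feats).detected_genes == {"PylS"}
        # one half alone does not count
        assert detect_pyl_machinery(feats[:1]).detected_genes == set()

    def test_exhaustive_truth_table(self):
        """All subsets x tRNA presence x co-location reproduce the
        status scheme, inclusion flag and same-contig exclusion rule."""
        genes = ["PylS", "PylB", "PylC", "PylD"]
        for r in range(5):
            for subset in itertools.combinations(genes, r):
                subset = set(subset)
                for with_trna in (False, True):
                    for colocated in (False, True):
                        feats = pyl_features(subset, colocated, with_trna)
                        got = detect_pyl_machinery(feats)
                        detected, status, included = expected_pyl(
                            subset, colocated, with_trna
                        )
                        case = f"{sorted(subset)} trna={with_trna} coloc={colocated}"
                        assert got.detected_genes & PYL_REQUIRED == detected, case
                        assert got.status == status, case
                        assert got.included == included, case


# ---------------------------------------------------------------------------
# readthrough fusion


def _pair_genome(
    up_stop="TAG", gap=3, down_product="dimethylamine methyltransferase",
    up_product="dimethylamine methyltransferase", strand="+",
    up_fids=None, down_fids=None,
):
    up_seq = "ATGAAACCC" + up_stop  # 12 nt
    down_seq = "AAATTTGGGTAA"  # 12 nt
    seq = "G" * 10 + up_seq + "A" * gap + down_seq + "G" * 10
    up = cds("c1", 10, 22, strand="+", product=up_product,
             fids=up_fids, fid="up")
    down = cds("c1", 22 + gap, 34 + gap, strand="+", product=down_product,
               fids=down_fids, fid="down")
    contigs, feats = [Contig("c1", seq)], [up, down]
    if strand == "-":
        contigs, feats = flip_genome(contigs, feats)
    return contigs, feats


class TestFuseStopReadthrough:
    def test_matching_pair_found(self):
        contigs, feats = _pair_genome()
        (cand,) = fuse_stop_readthrough(contigs, feats, "UAG")
        assert (cand.upstream_id, cand.downstream_id) == ("up", "down")
        assert cand.gap_nt == 3 and cand.in_frame
        assert cand.match_basis == "product"
        assert cand.fused_start == 10 and cand.fused_end == 37

    def test_minus_strand_pair_found(self):
        contigs, feats = _pair_genome(strand="-")
        (cand,) = fuse_stop_readthrough(contigs, feats, "UAG")
        assert {cand.upstream_id, cand.downstream_id} == {"up", "down"}
        assert cand.strand == "-" and cand.gap_nt == 3

    def test_no_uag_terminating_cds(self):
        contigs, feats = _pair_genome(up_stop="TAA")
        assert fuse_stop_readthrough(contigs, feats, "UAG") == []

    def test_mismatched_annotation_skipped(self):
        contigs, feats = _pair_genome(down_product="hypothetical protein")
        assert fuse_stop_readthrough(contigs, feats, "UAG") == []

    def test_function_id_match(self):
        contigs, feats = _pair_genome(
            up_product="mttB", down_product="trimethylamine methyltransferase",
            up_fids={"K14083"}, down_fids={"K14083"},
        )
        (cand,) = fuse_stop_readthrough(contigs, feats, "UAG")
        assert cand.match_basis == "function_id"

    def test_frame_shift_rejected(self):
        contigs, feats = _pair_genome(gap=4)
        assert fuse_stop_readthrough(contigs, feats, "UAG") == []

    def test_gap_beyond_max_rejected(self):
        contigs, feats = _pair_genome(gap=303)
        assert fuse_stop_readthrough(contigs, feats, "UAG") == []
        assert len(fuse_stop_readthrough(contigs, feats, "UAG", max_gap=303)) == 1

    def test_uga_codon_selected(self):
        contigs, feats = _pair_genome(up_stop="TGA")
        assert fuse_stop_readthrough(contigs, feats, "UAG") == []
        (cand,) = fuse_stop_readthrough(contigs, feats, "UGA")
        assert cand.recoded_codon == "UGA"

    def test_planted_pairs_recovered_exactly(self):
        from magrecode.experiments import planted_recovery

        rec = planted_recovery(range(1, 11))
        assert rec.fusion_precision == 1.0
        assert rec.fusion_recall == 1.0


# ---------------------------------------------------------------------------
# SECIS pairing


def _secis(contig, start, strand="+", fid="secis1"):
    return Feature(contig, start, start + 60, strand, "SECIS", id=fid)


def _uga_candidate(fused_start=0, fused_end=100, strand="+", cid="cand1"):
    from magrecode.recoding import FusedCandidate

    return FusedCandidate(
        upstream_id=cid, downstream_id=cid + "_b", contig_id="c1",
        fused_start=fused_start, fused_end=fused_end, strand=strand,
        recoded_codon="UGA", gap_nt=0, in_frame=True, match_basis="product",
    )


class TestPairSelenoproteinSecis:
    def test_in_range_paired(self):
        pairs = pair_selenoprotein_secis(
            [_uga_candidate()], [_secis("c1", 200)]
        )
        assert len(pairs) == 1 and pairs[0].distance_nt == 100

    @pytest.mark.parametrize("d,paired", [(30, True), (29, False), (500, True), (501, False)])
    def test_distance_boundaries(self, d, paired):
        pairs = pair_selenoprotein_secis(
            [_uga_candidate()], [_secis("c1", 100 + d)]
        )
        assert bool(pairs) == paired

    def test_opposite_strand_unpaired(self):
        pairs = pair_selenoprotein_secis(
            [_uga_candidate()], [_secis("c1", 200, strand="-")]
        )
        assert pairs == []

    def test_minus_strand_distance(self):
        cand = _uga_candidate(fused_start=600, fused_end=700, strand="-")
        # on '-', downstream means lower coordinates: SECIS ends at 500,
        # d = 600 - 500 = 100
        pairs = pair_selenoprotein_secis([cand], [_secis("c1", 440, strand="-")])
        assert len(pairs) == 1 and pairs[0].distance_nt == 100

    def test_secis_pairs_with_nearest_candidate_only(self):
        near = _uga_candidate(fused_start=0, fused_end=150, cid="near")
        far = _uga_candidate(fused_start=0, fused_end=100, cid="far")
        (pair,) = pair_selenoprotein_secis([near, far], [_secis("c1", 200)])
        assert pair.cds_id == "near"

    def test_matches_bruteforce_on_simulated_genomes(self, default_genome):
        contigs, features, _ = default_genome
        cds_feats = [f for f in features if f.kind == "CDS"]
        secis_feats = [f for f in features if f.kind == "SECIS"]
        cands = fuse_stop_readthrough(contigs, cds_feats, "UGA")
        got = {
            (p.cds_id, p.secis_id)
            for p in pair_selenoprotein_secis(cands, secis_feats)
        }
        # brute force: all-pairs filter, then nearest per SECIS
        best = {}
        for s in secis_feats:
            for c in cands:
                if c.contig_id != s.contig_id or c.strand != s.strand:
                    continue
                d = (
                    s.start - c.fused_end
                    if c.strand == "+"
                    else c.fused_start - s.end
                )
                if 30 <= d <= 500 and (s.id not in best or d < best[s.id][0]):
                    best[s.id] = (d, c.upstream_id)
        assert got == {(cid, sid) for sid, (_, cid) in best.items()}


# ---------------------------------------------------------------------------
# cloverleaf parsing


class TestParseCloverleaf:
    def test_four_armed_trna_with_variable_arm(self):
        rng = np.random.default_rng(3)
        seq, struct = build_trna(rng, anticodon="CUA", tail="CCA", d_stem_bp=4)
        # splice a variable arm between the anticodon and T arms
        anchor = struct.index("(" * 5 + "." * 7 + ")" * 5) + 17
        var_seq, var_struct = "GGGAAAACCC", "(((....)))"
        seq2 = seq[:anchor + 1] + var_seq + seq[anchor + 1:]
        struct2 = struct[:anchor + 1] + var_struct + struct[anchor + 1:]
        feats = parse_cloverleaf(seq2, struct2)
        assert set(feats.arms) == {"acceptor", "D", "anticodon", "variable", "T"}
        assert feats.anticodon == "CUA"

    def test_anticodon_lookup(self):
        rng = np.random.default_rng(4)
        seq, struct = build_trna(rng, anticodon="CUA")
        assert parse_cloverleaf(seq, struct).isotype == "Pyl-amber"
        seq, struct = build_trna(rng, anticodon="GUA")
        assert parse_cloverleaf(seq, struct).isotype == "other"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            parse_cloverleaf("ACGU", "(((")

    def test_not_cloverleaf_rejected(self):
        with pytest.raises(ValueError, match="not cloverleaf"):
            parse_cloverleaf("GGGGAAAACCCC", "((((....))))")

    def test_unbalanced_structure_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            parse_cloverleaf("ACGU", "((..")

    def test_invalid_pair_rejected(self):
        # position 0 (A) is paired with position 11 (C): not WC and not G.U
        with pytest.raises(ValueError, match="invalid base pair"):
            parse_cloverleaf("AGGGAAAACCCC", "((((....))))")

    def test_gu_wobble_pair_accepted(self):
        # outermost pair G-T reads as a G.U wobble, a valid RNA pair;
        # the single-hairpin shape still fails the cloverleaf test
        with pytest.raises(ValueError, match="not cloverleaf"):
            parse_cloverleaf("GGGGAAAACCCT", "((((....))))")


# ---------------------------------------------------------------------------
# strand invariance and report


class TestStrandInvariance:
    def test_detectors_invariant_under_reverse_complement(self, small_genome):
        contigs, features, _ = small_genome
        flipped_contigs, flipped_features = flip_genome(contigs, features)
        cds_a = [f for f in features if f.kind == "CDS"]
        cds_b = [f for f in flipped_features if f.kind == "CDS"]
        ua = stop_codon_usage(contigs, cds_a)
        ub = stop_codon_usage(flipped_contigs, cds_b)
        assert (ua.f_UAA, ua.f_UAG, ua.f_UGA) == (ub.f_UAA, ub.f_UAG, ub.f_UGA)
        for codon in ("UAG", "UGA"):
            ca = fuse_stop_readthrough(contigs, cds_a, codon)
            cb = fuse_stop_readthrough(flipped_contigs, cds_b, codon)
            assert {(c.upstream_id, c.downstream_id) for c in ca} == {
                (c.upstream_id, c.downstream_id) for c in cb
            }
        sa = pair_selenoprotein_secis(
            fuse_stop_readthrough(contigs, cds_a, "UGA"),
            [f for f in features if f.kind == "SECIS"],
        )
        sb = pair_selenoprotein_secis(
            fuse_stop_readthrough(flipped_contigs, cds_b, "UGA"),
            [f for f in flipped_features if f.kind == "SECIS"],
        )
        assert {(p.cds_id, p.secis_id, p.distance_nt) for p in sa} == {
            (p.cds_id, p.secis_id, p.distance_nt) for p in sb
        }


class TestRecodingReport:
    def test_planted_genome_reported_complete(self, default_genome):
        genome_id, (contigs, features, _) = "sim1", default_genome
        report = recoding_report([(genome_id, contigs, features)])
        row = report.iloc[0]
        assert row["sec_status"] == "complete"
        assert row["pyl_status"] == "complete"
        assert row["pyl_included"]
        assert row["n_fused_uag"] == 2 and row["n_fused_uga"] == 3
        assert row["n_selenoproteins"] == 3
        assert row["trna_isotypes"] == "pyl,sec"

    def test_bare_genome_all_absent(self):
        contigs = [Contig("c1", "ATGAAATAA" + "G" * 100)]
        feats = [cds("c1", 0, 9, product="hypothetical protein")]
        report = recoding_report([("bare", contigs, feats)])
        row = report.iloc[0]
        assert row["sec_status"] == "absent" and row["pyl_status"] == "absent"
        assert row["n_fused_uag"] == 0 and row["n_selenoproteins"] == 0

    def test_row_per_genome(self, small_genome, default_genome):
        g1 = ("a", small_genome[0], small_genome[1])
        g2 = ("b", default_genome[0], default_genome[1])
        report = recoding_report([g1, g2])
        assert list(report["genome_id"]) == ["a", "b"]
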