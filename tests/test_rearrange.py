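import pytest

from karyokit import fragments as fr
from karyokit import rearrange as rr
from karyokit import simulate as sim
from karyokit.model import (EBRInterval, GenomeAssembly, Karyotype,
                            SignedFragment, SyntenyBlock)


def frag(c, s, e, sign=1):
    return SignedFragment(c, s, e, sign)


def linear_karyotype(name, n_chrom=2, size=10_000_000):
    return Karyotype(name, {f"c{i+1}": [frag(f"c{i+1}", 0, size)]
                            for i in range(n_chrom)})


class TestCompare:
    def test_identity_yields_no_events(self):
        a = linear_karyotype("a")
        assert rr.compare_karyotypes(a, linear_karyotype("b")) == []

    def test_single_flipped_fragment_is_one_inversion(self):
        a = Karyotype("a", {"c1": [frag("c1", 0, 3), frag("c1", 3, 6),
                                   frag("c1", 6, 9)]})
        b = Karyotype("b", {"c1": [frag("c1", 0, 3), frag("c1", 3, 6, -1),
                                   frag("c1", 6, 9)]})
        ev = rr.compare_karyotypes(a, b)
        assert [e.event_type for e in ev] == ["inversion"]
        assert ev[0].affected == (("c1", 3, 6),)

    def test_overlapping_inversions_are_one_complex(self):
        a = linear_karyotype("a", n_chrom=1)
        b = sim.apply_inversion(a, "c1", 2_000_000, 7_000_000)
        b = sim.apply_inversion(b, "c1", 4_000_000, 9_000_000)
        ev = rr.compare_karyotypes(a, b)
        counts = rr.event_counts(ev)
        assert counts["complex"] == 1 and counts["inversion"] == 0
        assert ev[0].lower_bound >= 2

    def test_fission_and_fusion_from_degrees(self):
        a = Karyotype("a", {"x": [frag("x", 0, 10)],
                            "y": [frag("y", 0, 10)]})
        # x split in two; the right half fused with y
        b = Karyotype("b", {"x1": [frag("x", 0, 4)],
                            "x2y": [frag("x", 4, 10), frag("y", 0, 10)]})
        counts = rr.event_counts(rr.compare_karyotypes(a, b))
        assert counts == {"inversion": 0, "fission": 1, "fusion": 1,
                          "complex": 0}

    def test_wholly_flipped_chromosome_is_not_an_event(self):
        a = Karyotype("a", {"c1": [frag("c1", 0, 5), frag("c1", 5, 9)]})
        b = Karyotype("b", {"c1": [frag("c1", 5, 9, -1), frag("c1", 0, 5, -1)]})
        assert rr.compare_karyotypes(a, b) == []

    def test_flipped_fusion_operand_counts_one_fusion(self):
        a = Karyotype("a", {"x": [frag("x", 0, 10)], "y": [frag("y", 0, 8)]})
        b = Karyotype("b", {"xy": [frag("x", 0, 10), frag("y", 0, 8, -1)]})
        counts = rr.event_counts(rr.compare_karyotypes(a, b))
        assert counts == {"inversion": 0, "fission": 0, "fusion": 1,
                          "complex": 0}

    def test_inversion_inside_flipped_fusion_operand(self):
        a = Karyotype("a", {"x": [frag("x", 0, 10)],
                            "y": [frag("y", 0, 3), frag("y", 3, 6),
                                  frag("y", 6, 9)]})
        b = Karyotype("b", {"xy": [frag("x", 0, 10),
                                   frag("y", 6, 9, -1),
                                   frag("y", 3, 6, 1),   # inverted within flipped y
                                   frag("y", 0, 3, -1)]})
        counts = rr.event_counts(rr.compare_karyotypes(a, b))
        assert counts == {"inversion": 1, "fission": 0, "fusion": 1,
                          "complex": 0}

    def test_content_mismatch_rejected(self):
        a = Karyotype("a", {"c1": [frag("c1", 0, 10)]})
        b = Karyotype("b", {"c1": [frag("c1", 0, 8)]})
        with pytest.raises(ValueError, match="content"):
            rr.compare_karyotypes(a, b)

    def test_restrict_mode_tolerates_partial_coverage(self):
        a = Karyotype("a", {"c1": [frag("c1", 0, 10)]})
        b = Karyotype("b", {"c1": [frag("c1", 0, 8)]})
        assert rr.compare_karyotypes(a, b, restrict=True) == []

    def test_sum_rule(self):
        root = sim.simulate_ancestor(10, 500_000_000, seed=21)
        ks, log = sim.simulate_lineage(
            root, nodes=[("anc", 10.0), ("ref", 0.0)],
            spec={"ref": {"inversion": 6, "fission": 2, "fusion": 2}},
            seed=21, inv_len_median=5e6)
        em = sim.emit_synteny(ks, "ref", seed=21)
        sfs = fr.merge_blocks(em.blocks["anc"], 300_000)
        ev = rr.compare_karyotypes(rr.karyotype_from_sfs(sfs, "anc"),
                                   rr.reference_self_karyotype(em.assembly))
        c = rr.event_counts(ev)
        assert len(ev) == sum(c.values())

    def test_invariance_to_chromosome_renaming(self):
        root = sim.simulate_ancestor(6, 200_000_000, seed=22)
        ks, _ = sim.simulate_lineage(
            root, nodes=[("anc", 10.0), ("ref", 0.0)],
            spec={"ref": {"inversion": 3, "fusion": 1}}, seed=22,
            inv_len_median=5e6)
        em = sim.emit_synteny(ks, "ref", seed=22)
        sfs = fr.merge_blocks(em.blocks["anc"], 300_000)
        anc = rr.karyotype_from_sfs(sfs, "anc")
        ref = rr.reference_self_karyotype(em.assembly)
        base = rr.event_counts(rr.compare_karyotypes(anc, ref))
        renamed = Karyotype("anc", {f"Z{i}": v for i, (k, v) in
                                    enumerate(anc.chromosomes.items())})
        assert rr.event_counts(rr.compare_karyotypes(renamed, ref)) == base


class TestBranchAssignment:
    def test_events_land_on_the_changing_branch(self):
        k0 = linear_karyotype("n0", n_chrom=1)
        k1 = k0.copy()
        k2 = sim.apply_inversion(k1, "c1", 2_000_000, 5_000_000)
        events = rr.assign_event_branches([("n0", k0), ("n1", k1), ("n2", k2)])
        assert {e.branch for e in events} == {("n1", "n2")}

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            rr.assign_event_branches([("n0", linear_karyotype("n0"))])

    def test_paper_like_branch_spectrum(self):
        """A branch carrying 1 fusion + 7 inversions yields exactly 8 events."""
        root = sim.simulate_ancestor(26, 1_500_000_000, seed=23)
        ks, _ = sim.simulate_lineage(
            root, nodes=[("PAK", 26.0), ("BOVIN", 16.0)],
            spec={"BOVIN": {"inversion": 7, "fusion": 1}}, seed=23)
        em = sim.emit_synteny(ks, "BOVIN", seed=23)
        sfs = fr.merge_blocks(em.blocks["PAK"], 300_000)
        ev = rr.compare_karyotypes(rr.karyotype_from_sfs(sfs, "PAK"),
                                   rr.reference_self_karyotype(em.assembly))
        assert len(ev) == 8
        assert rr.event_counts(ev)["inversion"] == 7
        assert rr.event_counts(ev)["fusion"] == 1

    def test_per_branch_truth_recovery_on_lineage(self):
        spec = {"PAK": {"inversion": 4, "fission": 1, "fusion": 1},
                "BOCE": {"inversion": 2},
                "BOMO": {"fission": 1},
                "BOVIN": {"inversion": 1, "fusion": 1},
                "reference": {"inversion": 2, "fission": 1}}
        root = sim.simulate_ancestor(14, 700_000_000, seed=24)
        ks, log = sim.simulate_lineage(root, spec=spec, seed=24,
                                       inv_len_median=4e6)
        em = sim.emit_synteny(ks, "reference", seed=24)
        series = []
        for name, _ in sim.DEFAULT_LINEAGE[:-1]:
            sfs = fr.merge_blocks(em.blocks[name], 300_000)
            series.append((name, rr.karyotype_from_sfs(sfs, name)))
        series.append(("reference",
                       rr.reference_self_karyotype(em.assembly)))
        got = rr.branch_counts(rr.assign_event_branches(series))
        want = {b: {t: n for t, n in c.items() if n}
                for b, c in log.counts().items()}
        assert got == want


def series_with_inversion_on(branch_idx, n_nodes=4):
    """Reference-frame lineage where one inversion occurs on branch_idx:
    nodes at or above the event show the pre-event (inverted-relative-to-
    reference) arrangement, younger nodes match the reference identity."""
    plain = Karyotype("n", {"c1": [frag("c1", 0, 9_000_000)]})
    inverted = sim.apply_inversion(plain, "c1", 3_000_000, 6_000_000)
    return [(f"n{i}", inverted if i <= branch_idx else plain)
            for i in range(n_nodes)]


class TestEbrLineage:
    EBR = EBRInterval("c1", 3_000_000, 3_000_000, "well_defined", "S1", "S2")

    def test_oldest_branch_origin(self):
        series = series_with_inversion_on(0)
        ba = rr.classify_ebr_lineage(self.EBR, series)
        assert ba.branch == ("n0", "n1")
        assert ba.origin_label == "n0_specific"
        assert ba.confidence == "clean"

    def test_reference_specific(self):
        series = series_with_inversion_on(2)  # terminal branch of 4 nodes
        ba = rr.classify_ebr_lineage(self.EBR, series)
        assert ba.branch == ("n2", "n3")
        assert ba.origin_label == "reference_specific"

    def test_reuse_flagged_on_non_nested_pattern(self):
        plain = Karyotype("n", {"c1": [frag("c1", 0, 9_000_000)]})
        inverted = sim.apply_inversion(plain, "c1", 3_000_000, 6_000_000)
        # intact - broken - intact along the ancestors: breakpoint reuse
        series = [("n0", plain), ("n1", inverted), ("n2", plain),
                  ("n3", plain)]
        ebr = EBRInterval("c1", 3_000_000, 3_000_000, "well_defined", "a", "b")
        ba = rr.classify_ebr_lineage(ebr, series)
        assert ba.confidence == "reuse_flagged"
        assert ba.branch == ("n1", "n2")

    def test_unassignable_when_flank_missing(self):
        holed = Karyotype("n", {"c1": [frag("c1", 0, 2_000_000)]})
        full = Karyotype("n", {"c1": [frag("c1", 0, 9_000_000)]})
        series = [("n0", holed), ("n1", full)]
        ba = rr.classify_ebr_lineage(self.EBR, series)
        assert ba.origin_label == "unassignable"


class TestEbrType:
    def test_inversion_flank(self):
        a = linear_karyotype("a", n_chrom=1)
        b = sim.apply_inversion(a, "c1", 2_000_000, 5_000_000)
        ev = rr.compare_karyotypes(a, b)
        ebr = EBRInterval("c1", 2_000_000, 2_000_000, "well_defined", "x", "y")
        assert rr.classify_ebr_type(ebr, ev) == "inversion_ebr"

    def test_fusion_junction(self):
        a = Karyotype("a", {"x": [frag("x", 0, 10)], "y": [frag("y", 0, 8)]})
        b = Karyotype("b", {"xy": [frag("x", 0, 10), frag("y", 0, 8)]})
        ev = rr.compare_karyotypes(a, b)
        ebr = EBRInterval("x", 10, 10, "well_defined", "x", "y")
        assert rr.classify_ebr_type(ebr, ev) == "interchromosomal_ebr"

    def test_dual_hit_resolves_interchromosomal(self):
        inv = rr.RearrangementEvent("inversion", breakpoints=(("c1", 5),))
        fis = rr.RearrangementEvent("fission", breakpoints=(("c1", 5),))
        ebr = EBRInterval("c1", 5, 5, "well_defined", "a", "b")
        assert rr.classify_ebr_type(ebr, [inv, fis]) == "interchromosomal_ebr"

    def test_unmatched_is_unassigned(self):
        ebr = EBRInterval("c1", 5, 5, "well_defined", "a", "b")
        assert rr.classify_ebr_type(ebr, []) == "unassigned"


class TestSfHistory:
    def test_no_events_all_collinear(self):
        asm = GenomeAssembly("g", [("c1", 2_000_000)])
        sfs = fr.merge_blocks(
            [SyntenyBlock("c1", 0, 2_000_000, "anc", "A", 0, 2_000_000, 1)],
            300_000)
        df, fracs = rr.classify_sf_history(sfs, [], asm)
        assert set(df["label"]) == {"collinear"}
        assert fracs == {"collinear": 1.0}

    def test_truth_labels_recovered_on_lineage(self):
        spec = {"PAK": {"inversion": 3, "fission": 1, "fusion": 1},
                "BOCE": {"inversion": 1},
                "BOMO": {"fission": 1},
                "BOVIN": {"inversion": 1},
                "reference": {"fusion": 1}}
        root = sim.simulate_ancestor(12, 600_000_000, seed=25)
        ks, _ = sim.simulate_lineage(root, spec=spec, seed=25,
                                     inv_len_median=4e6)
        em = sim.emit_synteny(ks, "reference", seed=25)
        series, sfs_by = [], {}
        for name, _ in sim.DEFAULT_LINEAGE[:-1]:
            sfs_by[name] = fr.merge_blocks(em.blocks[name], 300_000)
            series.append((name, rr.karyotype_from_sfs(sfs_by[name], name)))
        series.append(("reference",
                       rr.reference_self_karyotype(em.assembly)))
        events = rr.assign_event_branches(series)
        hist, fracs = rr.classify_sf_history(sfs_by["RAK"], events,
                                             em.assembly)
        truth = sim.truth_sf_labels(ks, "reference")
        for row in hist.itertuples():
            labels = {t.label for t in truth.itertuples()
                      if t.chrom == row.ref_chrom
                      and t.start < row.ref_end and row.ref_start < t.end}
            assert labels == {row.label}
        cov = fr.compute_coverage(sfs_by["RAK"], em.assembly)
        assert sum(fracs.values()) == pytest.approx(cov)


class TestRates:
    def test_zero_events_zero_rate(self):
        df = rr.rearrangement_rates({("a", "b"): {}}, {("a", "b"): 5.0})
        assert df.loc[0, "total_rate"] == 0.0

    def test_simple_arithmetic(self):
        df = rr.rearrangement_rates({("a", "b"): {"inversion": 10}},
                                    {("a", "b"): 5.0})
        assert df.loc[0, "inversion_rate"] == 2.00

    def test_deep_branch_rates(self):
        """15 interchromosomal + 44 inversions over 16 My give the
        0.94 / 2.75 / 3.69 events-per-My split."""
        counts = {("RAK", "PAK"): {"inversion": 44, "fission": 12,
                                   "fusion": 3}}
        df = rr.rearrangement_rates(counts, {("RAK", "PAK"): 16.0})
        assert df.loc[0, "interchromosomal_rate"] == 0.94
        assert df.loc[0, "inversion_rate"] == 2.75
        assert df.loc[0, "total_rate"] == 3.69

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            rr.rearrangement_rates({("a", "b"): {"inversion": 1}},
                                   {("a", "b"): 0.0})
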