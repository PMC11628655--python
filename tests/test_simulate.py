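import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from karyokit import simulate as sim
from karyokit.model import Karyotype, SignedFragment


def chrom_signs(k, chrom):
    return [(f.ref_start, f.ref_end, f.sign) for f in k.chromosomes[chrom]]


class TestAncestor:
    def test_single_chromosome(self):
        k = sim.simulate_ancestor(1, 10 ** 6, seed=0)
        assert k.n_chromosomes == 1 and k.total_length == 10 ** 6

    @pytest.mark.parametrize("seed", [0, 1, 42])
    def test_total_size_conserved(self, seed):
        k = sim.simulate_ancestor(12, 50_000_000, seed=seed)
        assert k.total_length == 50_000_000

    def test_same_seed_identical(self):
        a = sim.simulate_ancestor(8, 10_000_000, seed=5)
        b = sim.simulate_ancestor(8, 10_000_000, seed=5)
        assert {c: chrom_signs(a, c) for c in a.chromosomes} == \
            {c: chrom_signs(b, c) for c in b.chromosomes}

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_ancestor(10, 5, seed=0)


class TestOperators:
    def test_inversion_is_involution(self, three_frag_karyotype):
        k = three_frag_karyotype
        once = sim.apply_inversion(k, "chr1", 1_000_000, 2_000_000)
        twice = sim.apply_inversion(once, "chr1", 1_000_000, 2_000_000)
        assert chrom_signs(twice, "chr1") == chrom_signs(k, "chr1")

    def test_invert_whole_single_fragment_chromosome(self, three_frag_karyotype):
        k = sim.apply_inversion(three_frag_karyotype, "chr1", 0, 3_000_000)
        assert chrom_signs(k, "chr1") == [(0, 3_000_000, -1)]

    def test_invert_middle_third(self, three_frag_karyotype):
        k = sim.apply_inversion(three_frag_karyotype, "chr1",
                                1_000_000, 2_000_000)
        assert chrom_signs(k, "chr1") == [
            (0, 1_000_000, 1), (1_000_000, 2_000_000, -1),
            (2_000_000, 3_000_000, 1)]

    def test_out_of_bounds_inversion(self, three_frag_karyotype):
        with pytest.raises(ValueError):
            sim.apply_inversion(three_frag_karyotype, "chr1", 0, 4_000_000)

    def test_fission_then_fusion_restores(self, three_frag_karyotype):
        k = three_frag_karyotype
        split = sim.apply_fission(k, "chr1", 1_200_000)
        names = list(split.chromosomes)
        fused = sim.apply_fusion(split, names[0], names[1])
        assert chrom_signs(fused, list(fused.chromosomes)[0]) == \
            chrom_signs(k, "chr1")

    def test_fission_increments_chromosome_count(self):
        k = sim.simulate_ancestor(5, 10_000_000, seed=1)
        chrom = next(iter(k.chromosomes))
        out = sim.apply_fission(k, chrom, k.chrom_length(chrom) // 2)
        assert out.n_chromosomes == 6

    def test_fission_at_end_rejected(self, three_frag_karyotype):
        with pytest.raises(ValueError):
            sim.apply_fission(three_frag_karyotype, "chr1", 0)
        with pytest.raises(ValueError):
            sim.apply_fission(three_frag_karyotype, "chr1", 3_000_000)

    def test_fusion_flip_reverses_operand(self):
        k = Karyotype("r", {
            "a": [SignedFragment("a", 0, 100, 1)],
            "b": [SignedFragment("b", 0, 60, 1), SignedFragment("b", 60, 90, 1)],
        })
        fused = sim.apply_fusion(k, "a", "b", flip_b=True)
        frags = fused.chromosomes["a+b"]
        # the reversed operand's two contiguous pieces coalesce into one
        assert [(f.ref_chrom, f.ref_start, f.ref_end, f.sign) for f in frags] == [
            ("a", 0, 100, 1), ("b", 0, 90, -1)]

    def test_fusion_operands_distinct(self, three_frag_karyotype):
        with pytest.raises(ValueError):
            sim.apply_fusion(three_frag_karyotype, "chr1", "chr1")


@st.composite
def event_sequences(draw):
    return draw(st.lists(st.sampled_from(["inversion", "fission", "fusion"]),
                         min_size=0, max_size=12))


class TestLineage:
    NODES = [("anc", 10.0), ("ref", 0.0)]

    def test_no_events_identity(self):
        root = sim.simulate_ancestor(6, 30_000_000, seed=2)
        ks, log = sim.simulate_lineage(root, nodes=self.NODES,
                                       spec={"ref": {}}, seed=2)
        assert len(log) == 0
        assert {c: chrom_signs(ks["ref"], c) for c in ks["ref"].chromosomes} \
            == {c: chrom_signs(root, c) for c in root.chromosomes}

    def test_single_fission_adds_chromosome(self):
        root = sim.simulate_ancestor(6, 60_000_000, seed=3)
        ks, log = sim.simulate_lineage(root, nodes=self.NODES,
                                       spec={"ref": {"fission": 1}}, seed=3,
                                       resolution=100_000)
        assert ks["ref"].n_chromosomes == 7
        assert log.counts() == {("anc", "ref"): {"fission": 1}}

    def test_poisson_rate_mode_mean(self):
        """Counts on a 16-My branch at 2 events/My average 32 over
        replicates (within 3 standard errors of the Poisson mean)."""
        rng = np.random.default_rng(99)
        draws = [sim.draw_event_counts({"inversion": 2.0}, 16.0, rng)
                 ["inversion"] for _ in range(2000)]
        mean = np.mean(draws)
        se = np.sqrt(32 / 2000)
        assert abs(mean - 32) < 3 * se

    @settings(max_examples=25, deadline=None)
    @given(events=event_sequences(), seed=st.integers(0, 10 ** 6))
    def test_conservation_and_chromosome_count(self, events, seed):
        """Total reference bases are conserved by any event sequence, and
        chromosome count = initial + fissions - fusions."""
        root = sim.simulate_ancestor(8, 80_000_000, seed=0)
        counts = {t: events.count(t) for t in set(events)}
        if counts.get("fusion", 0) >= 8 - counts.get("fission", 0):
            counts["fusion"] = 1
        try:
            ks, log = sim.simulate_lineage(
                root, nodes=self.NODES, spec={"ref": counts}, seed=seed,
                resolution=200_000, inv_len_median=2e6, inv_len_min=500_000)
        except RuntimeError:
            return  # placement genuinely infeasible at this genome size
        ref = ks["ref"]
        assert ref.total_length == root.total_length
        got = log.counts().get(("anc", "ref"), {})
        assert ref.n_chromosomes == 8 + got.get("fission", 0) - got.get("fusion", 0)

    def test_same_seed_byte_identical(self):
        root = sim.simulate_ancestor(8, 80_000_000, seed=4)
        spec = {"ref": {"inversion": 3, "fission": 1, "fusion": 1}}
        out = []
        for _ in range(2):
            ks, log = sim.simulate_lineage(root, nodes=self.NODES, spec=spec,
                                           seed=77, resolution=200_000,
                                           inv_len_median=2e6,
                                           inv_len_min=500_000)
            out.append(({c: chrom_signs(ks["ref"], c)
                         for c in ks["ref"].chromosomes},
                        [(e.event_type, e.breakpoints) for e in log.events]))
        assert out[0] == out[1]


class TestEmission:
    def make(self, spec, seed=5, jitter=0, **kw):
        root = sim.simulate_ancestor(6, 120_000_000, seed=seed)
        ks, log = sim.simulate_lineage(root, nodes=[("anc", 10.0), ("ref", 0.0)],
                                       spec={"ref": spec}, seed=seed,
                                       resolution=300_000, inv_len_median=5e6,
                                       inv_len_min=1_000_000)
        em = sim.emit_synteny(ks, "ref", jitter_bp=jitter, seed=seed, **kw)
        return ks, log, em

    def test_no_events_one_block_per_chromosome(self):
        ks, log, em = self.make({})
        assert len(em.blocks["anc"]) == 6
        assert em.truth_ebrs["anc"] == []
        assert all(b.orientation == 1 for b in em.blocks["anc"])

    def test_single_inversion_three_blocks_two_truth_ebrs(self):
        ks, log, em = self.make({"inversion": 1})
        blocks = em.blocks["anc"]
        assert len(blocks) == 6 + 2
        minus = [b for b in blocks if b.orientation == -1]
        assert len(minus) == 1
        assert len(em.truth_ebrs["anc"]) == 2
        assert all(s == e for _, s, e in em.truth_ebrs["anc"])

    def test_jitter_bounds_truth_ebr_width(self):
        ks, log, em = self.make({"inversion": 4, "fusion": 1}, jitter=25_000)
        widths = [e - s for _, s, e in em.truth_ebrs["anc"]]
        assert widths and all(0 <= w <= 50_000 for w in widths)

    def test_unknown_reference_rejected(self):
        root = sim.simulate_ancestor(3, 3_000_000, seed=0)
        with pytest.raises(ValueError):
            sim.emit_synteny({"root": root}, "nope")


class TestAnnotations:
    def test_fold_zero_excludes(self, small_assembly):
        bias = [("c1", 1_000_000, 1_200_000), ("c2", 0, 500_000)]
        ann = sim.simulate_annotations(
            small_assembly, te_spec={"X": {"n": 200, "mean_len": 2000,
                                           "fold": 0.0}},
            bias_intervals=bias, seed=0)
        for c, s, e, *_ in ann["TE"].df.itertuples(index=False):
            assert not any(c == bc and s < be and bs < e for bc, bs, be in bias)

    def test_fold_one_uniform(self, small_assembly):
        """Density inside vs outside the bias intervals matches the area
        ratio under fold=1 (two-proportion comparison over replicates)."""
        bias = [("c1", 0, 3_000_000)]  # 15% of the genome
        inside = total = 0
        for seed in range(200):
            ann = sim.simulate_annotations(
                small_assembly, te_spec={"X": {"n": 30, "mean_len": 1000,
                                               "fold": 1.0}},
                bias_intervals=bias, seed=seed)
            df = ann["TE"].df
            total += len(df)
            inside += ((df["chrom"] == "c1") & (df["start"] < 3_000_000)).sum()
        p = 3_000_000 / small_assembly.total_size
        se = np.sqrt(p * (1 - p) / total)
        assert abs(inside / total - p) < 4 * se

    def test_no_genes_empty_set(self, small_assembly):
        ann = sim.simulate_annotations(small_assembly, n_genes=0, seed=0)
        assert len(ann["gene"]) == 0

    def test_genes_non_overlapping(self, small_assembly):
        ann = sim.simulate_annotations(small_assembly, n_genes=80, seed=1)
        df = ann["gene"].df.sort_values(["chrom", "start"])
        for (_, a), (_, b) in zip(df.iterrows(), df.iloc[1:].iterrows()):
            if a["chrom"] == b["chrom"]:
                assert a["end"] <= b["start"]

    def test_gc_delta_raises_biased_windows(self, small_assembly):
        bias = [("c1", 0, 1_000_000)]
        ann = sim.simulate_annotations(small_assembly,
                                       gc_spec={"delta": 0.3},
                                       bias_intervals=bias, seed=2)
        gc = ann["gc_windows"]
        hot = gc[(gc["chrom"] == "c1") & (gc["end"] <= 1_000_000)]["gc"].mean()
        cold = gc[gc["chrom"] == "c2"]["gc"].mean()
        assert hot > cold + 0.2


class TestExpression:
    def test_same_seed_identical(self):
        a, _, _ = sim.simulate_expression(30, 9, hk_fraction=0.5, seed=1)
        b, _, _ = sim.simulate_expression(30, 9, hk_fraction=0.5, seed=1)
        for sp in a:
            assert a[sp].values.equals(b[sp].values)

    def test_too_few_tissues(self):
        with pytest.raises(ValueError):
            sim.simulate_expression(10, 1, hk_fraction=0.5, seed=0)

    def test_ortholog_table_is_one_to_one(self):
        _, truth, ortho = sim.simulate_expression(20, 5, hk_fraction=0.5,
                                                  seed=3)
        assert len(ortho) == 20
        for sp in ("cattle", "sheep", "pig", "human"):
            assert ortho[sp].is_unique

    def test_focal_only_fraction(self):
        mats, truth, _ = sim.simulate_expression(
            400, 9, hk_fraction=0.0, species_specific_fraction=1.0, seed=4)
        from karyokit.housekeeping import call_housekeeping
        cattle = call_housekeeping(mats["cattle"])["housekeeping"]
        sheep = call_housekeeping(mats["sheep"])["housekeeping"]
        assert cattle.mean() > 0.9 and sheep.mean() < 0.1
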