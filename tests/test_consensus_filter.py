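"""Filtering cascade: per-stage rules, oracle equivalence, consensus Venn."""

import numpy as np
import pytest

from salmonsnp.consensus_filter import (
    FilterConfig,
    consensus_intersect,
    filter_biallelic_snp,
    filter_depth,
    filter_dh_het,
    filter_indel_proximity,
    filter_missingness,
    filter_qual,
    mask_repeats,
    recall_genotype,
    recall_record,
    run_cascade,
)
from salmonsnp.model import MISSING, CallSet, IntervalSet

from conftest import mk_record, mk_roster, random_callset


def brute_recall(ref_d, alt_d, min_alt=2, min_ref=1):
    """Independent spelling of the read-support rule."""
    alt_ok, ref_ok = alt_d >= min_alt, ref_d >= min_ref
    if alt_ok and ref_ok:
        return "het"
    if alt_ok:
        return "hom_alt"
    if ref_ok:
        return "hom_ref"
    return "missing"


class TestRecall:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [(5, 0, "hom_ref"), (1, 2, "het"), (0, 2, "hom_alt"),
         (0, 1, "missing"), (0, 0, "missing"), (1, 1, "hom_ref")],
    )
    def test_rule_examples(self, ref, alt, expected):
        assert recall_genotype(ref, alt) == expected

    def test_exhaustive_grid_matches_enumerated_rule(self):
        for r in range(11):
            for a in range(11):
                assert recall_genotype(r, a) == brute_recall(r, a)

    def test_vectorized_recall_matches_scalar(self, rng):
        rec = mk_record(calls=np.zeros(20, dtype=np.int8),
                        ref_depths=rng.integers(0, 6, 20),
                        alt_depths=rng.integers(0, 6, 20))
        out = recall_record(rec)
        from salmonsnp.model import GENOTYPE_LABELS

        for i in range(20):
            assert GENOTYPE_LABELS[int(out.calls[i])] == brute_recall(
                int(rec.ref_depths[i]), int(rec.alt_depths[i])
            )


class TestStageBoundaries:
    def test_biallelic_definition(self):
        roster = mk_roster(4)
        recs = [mk_record(pos=10, ref="A", alts=("T",)),
                mk_record(pos=20, ref="A", alts=("T", "G")),
                mk_record(pos=30, ref="A", alts=("AT",))]
        out, rep = filter_biallelic_snp(CallSet("gatk", roster, recs))
        assert [r.pos for r in out.records] == [10]
        assert (rep.records_in, rep.records_removed, rep.records_out) == (3, 2, 1)

    @pytest.mark.parametrize("indel_pos,expect_kept", [(105, False), (106, True)])
    def test_indel_gap_boundary(self, indel_pos, expect_kept):
        roster = mk_roster(4)
        snp = mk_record(pos=100)
        indel = mk_record(pos=indel_pos, ref="A", alts=("AT",))
        out, _ = filter_indel_proximity(CallSet("gatk", roster, [snp]), [indel], 5)
        assert (len(out) == 1) == expect_kept

    def test_snp_inside_deletion_span_removed(self):
        roster = mk_roster(4)
        snp = mk_record(pos=103)
        deletion = mk_record(pos=100, ref="ACGTT", alts=("A",))  # span [100,104]
        out, _ = filter_indel_proximity(CallSet("gatk", roster, [snp]), [deletion], 5)
        assert len(out) == 0

    def test_negative_distance_rejected(self):
        cs = CallSet("gatk", mk_roster(2), [mk_record(calls=(0, 0))])
        with pytest.raises(ValueError):
            filter_indel_proximity(cs, [], -1)

    @pytest.mark.parametrize("qual,kept", [(30.0, False), (30.01, True)])
    def test_qual_strictly_greater(self, qual, kept):
        cs = CallSet("gatk", mk_roster(4), [mk_record(qual=qual)])
        out, _ = filter_qual(cs, 30.0)
        assert (len(out) == 1) == kept

    @pytest.mark.parametrize("pos,kept", [(11, False), (10, True), (20, False), (21, True)])
    def test_repeat_mask_coordinate_conversion(self, pos, kept):
        cs = CallSet("gatk", mk_roster(4), [mk_record(pos=pos)])
        out, _ = mask_repeats(cs, IntervalSet([("chr1", 10, 20)]))
        assert (len(out) == 1) == kept

    @pytest.mark.parametrize("depth,kept", [(3000, True), (3001, False), (0, True)])
    def test_depth_cap_inclusive(self, depth, kept):
        cs = CallSet("gatk", mk_roster(4), [mk_record(site_depth=depth)])
        out, _ = filter_depth(cs, 3000)
        assert (len(out) == 1) == kept


class TestMissingness:
    def test_discovery_panel_allows_one_missing(self):
        """One missing NA genotype passes; two fail (>= 79 of 80 callable)."""
        roster = mk_roster(n_na=80, n_dh=2)
        for n_missing, kept in [(1, True), (2, False)]:
            depths = np.full(82, 10)
            alt = np.full(82, 5)
            depths[:n_missing] = 0
            alt[:n_missing] = 0
            rec = mk_record(calls=np.zeros(82, dtype=np.int8),
                            ref_depths=depths, alt_depths=alt)
            cs = CallSet("gatk", roster, [rec])
            out, _ = filter_missingness(cs, max_missing_samples=1)
            assert (len(out) == 1) == kept

    def test_missing_counted_over_na_subset_only(self):
        roster = mk_roster(n_na=4, n_eu=3)
        # all EU missing, all NA called: site passes the NA-panel cut
        ref = np.array([10, 10, 10, 10, 0, 0, 0])
        alt = np.array([5, 5, 5, 5, 0, 0, 0])
        rec = mk_record(calls=np.zeros(7, dtype=np.int8), ref_depths=ref, alt_depths=alt)
        out, _ = filter_missingness(CallSet("gatk", roster, [rec]), 1)
        assert len(out) == 1

    def test_empty_subset_is_an_error(self):
        roster = mk_roster(n_na=0, n_eu=2)
        cs = CallSet("gatk", roster, [mk_record(calls=(0, 0))])
        with pytest.raises(ValueError, match="empty"):
            filter_missingness(cs, 1)


class TestDhHet:
    def test_het_in_any_dh_removes(self):
        roster = mk_roster(n_na=2, n_dh=4)
        calls = np.array([0, 2, 0, 0, 1, 0], dtype=np.int8)  # one DH het
        out, _ = filter_dh_het(CallSet("gatk", roster, [mk_record(calls=calls)]))
        assert len(out) == 0

    def test_hom_and_missing_dh_kept(self):
        roster = mk_roster(n_na=2, n_dh=4)
        calls = np.array([1, 1, 2, 2, 0, MISSING], dtype=np.int8)
        out, _ = filter_dh_het(CallSet("gatk", roster, [mk_record(calls=calls)]))
        assert len(out) == 1

    def test_no_dh_passthrough_warns(self):
        cs = CallSet("gatk", mk_roster(3), [mk_record(calls=(1, 1, 1))])
        with pytest.warns(UserWarning):
            out, rep = filter_dh_het(cs)
        assert len(out) == 1 and rep.records_removed == 0


class TestOracleEquivalence:
    """Each stage equals an independent brute-force predicate scan."""

    def test_stages_match_brute_force(self, rng):
        cs = random_callset(rng, n_records=150, n_samples=10)
        recs = cs.records
        mask_raw = [("chr1", 200, 900), ("chr2", 0, 5000), ("chr1", 850, 1200)]
        mask = IntervalSet(mask_raw)
        indels = [r for r in recs if r.variant_class == "indel"]

        out, _ = filter_biallelic_snp(cs)
        assert out.site_keys == [r.key for r in recs if r.is_biallelic_snp]

        out, _ = filter_qual(cs, 30.0)
        assert out.site_keys == [r.key for r in recs if r.qual > 30.0]

        out, _ = filter_depth(cs, 2000)
        assert out.site_keys == [r.key for r in recs if r.site_depth <= 2000]

        out, _ = mask_repeats(cs, mask)
        assert out.site_keys == [
            r.key for r in recs
            if not any(c == r.chrom and s <= r.pos - 1 < e for c, s, e in mask_raw)
        ]

        def gap(snp, indel):
            if snp.chrom != indel.chrom:
                return 10**9
            lo, hi = indel.ref_span
            return max(lo - snp.pos, snp.pos - hi, 0)

        out, _ = filter_indel_proximity(cs, indels, 5)
        assert out.site_keys == [
            r.key for r in recs if all(gap(r, ind) > 5 for ind in indels)
        ]

        from conftest import mk_roster as _  # noqa: F401
        na_idx = [i for i, s in enumerate(cs.samples) if s.continent == "NA"]
        out, _ = filter_missingness(cs, 1)
        expected = []
        for r in recs:
            n_missing = sum(
                recall_genotype(int(r.ref_depths[i]), int(r.alt_depths[i])) == "missing"
                for i in na_idx
            )
            if n_missing <= 1:
                expected.append(r.key)
        assert out.site_keys == expected

        dh_idx = [i for i, s in enumerate(cs.samples) if s.is_doubled_haploid]
        out, _ = filter_dh_het(cs)
        assert out.site_keys == [
            r.key for r in recs if not any(r.calls[i] == 1 for i in dh_idx)
        ]

    def test_stage_reports_conserve_counts(self, rng):
        cs = random_callset(rng, n_records=200, n_samples=8)
        _, report = run_cascade(cs, IntervalSet([("chr1", 100, 2000)]))
        n = len(cs)
        for st in report.stages:
            assert st.records_in == n
            assert st.records_out == st.records_in - st.records_removed
            n = st.records_out

    def test_stages_idempotent_and_order_invariant(self, rng):
        cs = random_callset(rng, n_records=120, n_samples=8)
        mask = IntervalSet([("chr2", 0, 3000)])
        indels = [r for r in cs.records if r.variant_class == "indel"]
        once, _ = run_cascade(cs, mask)
        again, _ = run_cascade(once, mask, indels=indels)
        assert again.site_keys == once.site_keys

        # permuting input record order leaves the output set unchanged
        perm = list(cs.records)
        np.random.default_rng(1).shuffle(perm)
        shuffled = CallSet(cs.caller, cs.samples, [r.copy() for r in perm])
        out2, _ = run_cascade(shuffled, mask)
        assert set(out2.site_keys) == set(once.site_keys)

    def test_degenerate_config_keeps_all_biallelic_snps(self, rng):
        # roster without DH controls: with zero read-support thresholds every
        # genotype re-calls as het, which would otherwise trip the DH screen
        cs = random_callset(rng, n_records=100, roster=mk_roster(n_na=6))
        for r in cs.records:
            r.qual = 50.0  # lift every record above the (kept) quality floor
        loose = FilterConfig(indel_distance=0, min_qual=0, max_site_depth=10**9,
                             max_missing_samples=len(cs.samples),
                             min_alt_reads=0, min_ref_reads=0)
        snps = CallSet(cs.caller, cs.samples,
                       [r for r in cs.records if r.is_biallelic_snp
                        and not any(lo - 0 <= r.pos <= hi + 0
                                    for lo, hi in [i.ref_span for i in cs.records
                                                   if i.variant_class == "indel"
                                                   and i.chrom == r.chrom])])
        with pytest.warns(UserWarning):  # no DH controls in this roster
            out, _ = run_cascade(cs, IntervalSet(), loose)
        assert set(out.site_keys) == set(snps.site_keys)


class TestConsensus:
    def _mini(self, caller, positions):
        roster = mk_roster(4)
        recs = [mk_record(pos=p) for p in positions]
        return CallSet(caller, roster, recs)

    def test_set_algebra_example(self):
        cs1 = self._mini("freebayes", [1, 2])  # {A, B}
        cs2 = self._mini("gatk", [2, 3])  # {B, C}
        cs3 = self._mini("mpileup", [2])  # {B}
        res = consensus_intersect([cs1, cs2, cs3])
        assert [r.pos for r in res.callset.records] == [2]
        assert res.venn == {
            "freebayes_only": 1, "gatk_only": 1, "mpileup_only": 0,
            "freebayes_gatk": 0, "freebayes_mpileup": 0, "gatk_mpileup": 0,
            "all_three": 1,
        }
        assert res.reference_caller == "freebayes"

    def test_identical_callsets_all_shared(self):
        css = [self._mini(c, [5, 6, 7]) for c in ("freebayes", "gatk", "mpileup")]
        res = consensus_intersect(css)
        assert res.venn["all_three"] == 3
        assert sum(v for k, v in res.venn.items() if k != "all_three") == 0

    def test_symmetric_in_caller_order(self, rng):
        css = [random_callset(rng, n_records=50, caller=c, n_samples=6)
               for c in ("freebayes", "gatk", "mpileup")]
        a = consensus_intersect(css)
        b = consensus_intersect([css[2], css[0], css[1]])
        assert a.venn == b.venn
        assert a.callset.site_keys == b.callset.site_keys

    def test_venn_matches_brute_force_and_sums_to_union(self, rng):
        css = [random_callset(rng, n_records=80, caller=c, n_samples=6)
               for c in ("freebayes", "gatk", "mpileup")]
        res = consensus_intersect(css)
        sets = {c.caller: set(c.site_keys) for c in css}
        union = sets["freebayes"] | sets["gatk"] | sets["mpileup"]
        assert sum(res.venn.values()) == len(union)
        assert res.venn["all_three"] == len(
            sets["freebayes"] & sets["gatk"] & sets["mpileup"]
        )

    def test_wrong_arity_or_roster_rejected(self, rng):
        css = [random_callset(rng, n_records=10, caller=c, n_samples=6)
               for c in ("freebayes", "gatk")]
        with pytest.raises(ValueError, match="exactly 3"):
            consensus_intersect(css)
        other = random_callset(rng, n_records=10, caller="mpileup",
                               roster=mk_roster(n_na=3, n_dh=2, strain="GNB"))
        with pytest.raises(ValueError, match="roster"):
            consensus_intersect(css + [other])


class TestSimulatedTruth:
    def test_planted_violations_removed_at_designated_stages(self, noiseless_pipeline):
        sim = noiseless_pipeline["sim"]
        truth = sim.truth
        for name, rep in noiseless_pipeline["reports"].items():
            by_stage = {s.stage: s.records_removed for s in rep.stages}
            counts = truth.config.class_counts()
            assert by_stage["biallelic_snp"] == counts["indel"] + counts["near_indel_snp"] \
                + counts["multiallelic"]  # partner indels counted under 'indel'
            assert by_stage["indel_proximity"] == counts["near_indel_snp"]
            assert by_stage["repeat_mask"] == counts["masked_snp"]
            assert by_stage["site_depth"] == counts["deep_repeat"]
            assert by_stage["dh_het"] == counts["psv"]

    def test_consensus_equals_clean_plus_fixed_truth(self, noiseless_pipeline):
        sim = noiseless_pipeline["sim"]
        expected = set(sim.truth.keys_of_class("clean_snp")) | set(
            sim.truth.keys_of_class("continental_fixed")
        )
        assert set(noiseless_pipeline["consensus"].callset.site_keys) == expected
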