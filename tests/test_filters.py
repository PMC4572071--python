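"""The artifact-filter cascade: unit behaviour, oracles, planted recovery."""

import numpy as np
import pandas as pd
import pytest
from intervaltree import IntervalTree

from conftest import candidate_by_key
from hlofpipe.annotation import (
    HlofCandidate, TranscriptModel, TranscriptSet, VariantRecord,
)
from hlofpipe.config import RunConfig
from hlofpipe.filters import (
    Resources, build_snv_index, filter_ancestral, filter_capture_intersection,
    filter_coverage, filter_frameshift_rescue, filter_hwe, filter_mapability,
    filter_min_samples, filter_mnp_codon, filter_near_fixed,
    filter_relative_position, hwe_excess_test, run_cascade,
)
from oracles import hwe_excess_by_counts, hwe_excess_by_subsets


def make_candidate(pos=150, ref="C", alt="T", gts=(2, 1, 0, 0), depths=None,
                   consequences=None, rels=None, known=False, contig="ctg1",
                   pops=None):
    gts = np.array(gts, dtype=np.int8)
    depths = np.full(len(gts), 30) if depths is None else np.array(depths)
    v = VariantRecord(contig, pos, ref, alt, gts, depths)
    pops = pops or {"P1": (int(np.sum(gts == 0)), int(np.sum(gts == 1)),
                           int(np.sum(gts == 2)))}
    return HlofCandidate(
        variant=v,
        consequences=consequences or {"T1": "stop_gain"},
        relative_positions=rels if rels is not None else {"T1": 0.5},
        carriers=np.flatnonzero(gts == 2),
        pop_counts=pops, known=known)


def tree(*intervals, scored=False):
    t = IntervalTree()
    for iv in intervals:
        t.addi(iv[0], iv[1] + 1, iv[2] if scored else None)
    return t


# ---------------------------------------------------------------------------
# exact HWE test
# ---------------------------------------------------------------------------

class TestHweExcess:
    @pytest.mark.parametrize("counts", [(0, 2, 0), (1, 0, 1), (2, 0, 2),
                                        (3, 2, 0), (0, 1, 2), (1, 2, 2)])
    def test_matches_subset_enumeration(self, counts):
        """Agreement with the dumbest possible oracle: enumerate every
        placement of the alternate alleles over the 2n allele slots."""
        assert hwe_excess_test(*counts) == pytest.approx(
            hwe_excess_by_subsets(*counts), abs=1e-12)

    def test_large_sample_excess_matches_count_oracle(self):
        assert hwe_excess_test(98, 0, 2) == pytest.approx(
            hwe_excess_by_counts(98, 0, 2), abs=1e-12)

    def test_matches_count_enumeration_all_small_instances(self):
        """Exhaustive agreement with the brute-force enumeration oracle for
        every genotype configuration with n <= 12."""
        for n in range(1, 13):
            for n_hom_alt in range(n + 1):
                for n_het in range(n - n_hom_alt + 1):
                    n_hom_ref = n - n_hom_alt - n_het
                    got = hwe_excess_test(n_hom_ref, n_het, n_hom_alt)
                    want = hwe_excess_by_counts(n_hom_ref, n_het, n_hom_alt)
                    assert got == pytest.approx(want, abs=1e-10), \
                        (n_hom_ref, n_het, n_hom_alt)

    def test_monomorphic_returns_one(self):
        assert hwe_excess_test(10, 0, 0) == 1.0
        assert hwe_excess_test(0, 0, 7) == 1.0

    def test_excess_homozygotes_small_p(self):
        assert hwe_excess_test(98, 0, 2) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            hwe_excess_test(0, 0, 0)


# ---------------------------------------------------------------------------
# single filters
# ---------------------------------------------------------------------------

class TestRelativePosition:
    def test_any_transcript_past_cutoff_fails(self):
        cand = make_candidate(rels={"T1": 0.5, "T2": 0.95})
        assert not filter_relative_position(cand).passed

    def test_start_of_sole_transcript_passes(self):
        assert filter_relative_position(make_candidate(rels={"T1": 0.0})).passed

    def test_exact_boundary_fails(self):
        assert not filter_relative_position(make_candidate(rels={"T1": 0.9})).passed

    def test_no_coding_transcript_fails_with_reason(self):
        d = filter_relative_position(make_candidate(rels={}))
        assert not d.passed and "no coding transcript" in d.reason

    def test_permissive_mode_needs_only_one_transcript(self):
        cand = make_candidate(rels={"T1": 0.5, "T2": 0.95})
        assert filter_relative_position(cand, mode="any").passed


class TestMapability:
    def test_inside_score_one_region_passes(self):
        tracks = [{"ctg1": tree((1, 1000, 1.0), scored=True)}]
        assert filter_mapability(make_candidate(), tracks, {}).passed

    def test_low_score_region_fails(self):
        tracks = [{"ctg1": tree((140, 160, 0.5), scored=True)}]
        assert not filter_mapability(make_candidate(), tracks, {}).passed

    def test_deletion_straddling_blacklist_by_one_bp_fails(self):
        cand = make_candidate(pos=150, ref="CTTTT", alt="C")  # ref span 150-154
        overlapping = {"ctg1": tree((154, 200, None))}
        assert not filter_mapability(cand, [], overlapping).passed
        adjacent = {"ctg1": tree((155, 200, None))}
        assert filter_mapability(cand, [], adjacent).passed


class TestMinSamples:
    @pytest.mark.parametrize("n_called,expected", [(199, False), (200, True)])
    def test_boundary(self, n_called, expected):
        gts = np.zeros(250, dtype=np.int8)
        gts[n_called:] = -1
        gts[0] = 2
        cand = make_candidate(gts=gts)
        assert filter_min_samples(cand, 200).passed is expected

    def test_all_missing_fails(self):
        cand = make_candidate(gts=np.full(250, -1, dtype=np.int8))
        assert not filter_min_samples(cand, 200).passed


class TestCaptureIntersection:
    def test_padding_covers_30bp_gap(self):
        # kitA target ends 30 bp before the site; kitB covers it directly
        a = {"ctg1": tree((50, 119, None))}
        b = {"ctg1": tree((100, 200, None))}
        assert filter_capture_intersection(make_candidate(pos=149), a, b).passed

    def test_60bp_outside_kit_fails(self):
        a = {"ctg1": tree((50, 89, None))}
        b = {"ctg1": tree((100, 200, None))}
        assert not filter_capture_intersection(make_candidate(pos=150), a, b).passed

    def test_empty_bed_fails_with_reason(self):
        d = filter_capture_intersection(make_candidate(), {}, {"c": tree((1, 2, None))})
        assert not d.passed and "empty" in d.reason


def primate_df(rows):
    cols = ["contig", "pos", "ref", "alt", "species", "aligned", "allele",
            "indel_type", "indel_len", "pos_offset", "flank_match"]
    return pd.DataFrame(rows, columns=cols)


def make_resources(primates=None, transcripts=None, snv_index=None, pops=None):
    return Resources(
        alignability_tracks=[], blacklist={}, capture_a={}, capture_b={},
        primates=primates if primates is not None else primate_df([]),
        transcripts=transcripts or TranscriptSet({}),
        sample_pops=pops if pops is not None else np.array(["P1"] * 4),
        snv_index=snv_index or {})


class TestAncestral:
    def test_stop_gain_chimp_carries_alt_fails(self):
        cand = make_candidate(pos=150, ref="C", alt="T")
        res = make_resources(primate_df(
            [("ctg1", 150, "C", "T", "chimp", 1, "T", "", 0, 0, 0)]))
        assert not filter_ancestral(cand, res).passed

    def test_stop_gain_primates_carry_ref_passes(self):
        cand = make_candidate()
        res = make_resources(primate_df(
            [("ctg1", 150, "C", "T", s, 1, "C", "", 0, 0, 0)
             for s in ("chimp", "gorilla")]))
        assert filter_ancestral(cand, res).passed

    def test_frameshift_single_aligned_species_passes(self):
        cand = make_candidate(ref="CT", alt="C",
                              consequences={"T1": "frameshift"})
        res = make_resources(primate_df(
            [("ctg1", 150, "CT", "C", "chimp", 1, "", "deletion", 1, 0, 1),
             ("ctg1", 150, "CT", "C", "gorilla", 0, "", "", 0, 0, 0)]))
        assert filter_ancestral(cand, res).passed

    def test_frameshift_two_matching_species_fails(self):
        cand = make_candidate(ref="CT", alt="C",
                              consequences={"T1": "frameshift"})
        res = make_resources(primate_df(
            [("ctg1", 150, "CT", "C", s, 1, "", "deletion", 1, 0, 1)
             for s in ("chimp", "gorilla")]))
        assert not filter_ancestral(cand, res).passed

    def test_absent_site_passes(self):
        assert filter_ancestral(make_candidate(), make_resources()).passed


class TestMnpCodon:
    def setup_method(self):
        self.t = TranscriptModel("G1", "T1", "ctg1", "+",
                                 [(101, 109)], "ATGCGAGGC")
        self.ts = TranscriptSet({"T1": self.t})

    def cand(self):
        return make_candidate(pos=104, ref="C", alt="T",
                              consequences={"T1": "stop_gain"})

    def test_snp_in_same_codon_fails(self):
        res = make_resources(transcripts=self.ts,
                             snv_index={("ctg1", 106): {("A", "G")}})
        assert not filter_mnp_codon(self.cand(), res).passed

    def test_snp_in_neighbouring_codon_passes(self):
        res = make_resources(transcripts=self.ts,
                             snv_index={("ctg1", 107): {("G", "A")}})
        assert filter_mnp_codon(self.cand(), res).passed

    def test_frameshift_passes_unconditionally(self):
        cand = make_candidate(pos=104, ref="CG", alt="C",
                              consequences={"T1": "frameshift"})
        res = make_resources(transcripts=self.ts,
                             snv_index={("ctg1", 105): {("G", "T")}})
        assert filter_mnp_codon(cand, res).passed


class TestFrameshiftRescue:
    def setup_method(self):
        seq = "".join(["GCT"] * 100)
        self.t = TranscriptModel("G1", "T1", "ctg1", "+", [(101, 400)], seq)
        self.res = make_resources(transcripts=TranscriptSet({"T1": self.t}))

    def fs(self, codon, indel_len, pos, carriers=(0,)):
        gts = np.zeros(4, dtype=np.int8)
        for c in carriers:
            gts[c] = 2
        ref, alt = ("A", "AG") if indel_len > 0 else ("AG", "A")
        cand = make_candidate(pos=pos, ref=ref, alt=alt, gts=gts,
                              consequences={"T1": "frameshift"},
                              rels={"T1": codon / 100})
        return cand

    def test_restoring_pair_both_fail(self):
        a, b = self.fs(10, +1, 131), self.fs(14, -1, 143)
        dec = filter_frameshift_rescue([a, b], self.res)
        assert not dec[a.key].passed and not dec[b.key].passed

    def test_non_restoring_pair_passes(self):
        a, b = self.fs(10, +1, 131), self.fs(14, +1, 143)
        dec = filter_frameshift_rescue([a, b], self.res)
        assert dec[a.key].passed and dec[b.key].passed

    def test_distant_pair_passes(self):
        a, b = self.fs(10, +1, 131), self.fs(20, -1, 161)
        dec = filter_frameshift_rescue([a, b], self.res)
        assert dec[a.key].passed and dec[b.key].passed

    def test_three_in_vicinity_all_fail(self):
        cands = [self.fs(10, +1, 131), self.fs(13, -2, 140), self.fs(16, +1, 149)]
        dec = filter_frameshift_rescue(cands, self.res)
        assert all(not dec[c.key].passed for c in cands)

    def test_carrier_mode_requires_shared_homozygote(self):
        a, b = self.fs(10, +1, 131, carriers=(0,)), self.fs(14, -1, 143, carriers=(1,))
        dec = filter_frameshift_rescue([a, b], self.res, mode="carrier")
        assert dec[a.key].passed and dec[b.key].passed
        b2 = self.fs(14, -1, 143, carriers=(0,))
        dec = filter_frameshift_rescue([a, b2], self.res, mode="carrier")
        assert not dec[a.key].passed and not dec[b2.key].passed

    def test_lone_frameshift_passes(self):
        a = self.fs(10, +1, 131)
        assert filter_frameshift_rescue([a], self.res)[a.key].passed


class TestHweFilter:
    def test_singleton_homozygote_matches_enumeration(self):
        gts = np.zeros(200, dtype=np.int8)
        gts[0] = 2
        cand = make_candidate(gts=gts, depths=np.full(200, 30))
        pops = np.array(["P1"] * 200)
        p = hwe_excess_test(199, 0, 1)
        decision = filter_hwe(cand, pops, alpha=0.01)
        assert decision.passed is (p >= 0.01)
        assert p == pytest.approx(hwe_excess_by_counts(199, 0, 1), abs=1e-10)

    def test_low_depth_individuals_excluded(self):
        gts = np.array([2] * 5 + [0] * 95, dtype=np.int8)
        depths = np.array([30] * 5 + [2] * 95)
        cand = make_candidate(gts=gts, depths=depths)
        # only the 5 homozygotes pass the depth floor -> monomorphic, P = 1
        assert filter_hwe(cand, np.array(["P1"] * 100)).passed


class TestCoverageAndNearFixed:
    def test_novel_depth_19_fails(self):
        cand = make_candidate(gts=(2, 0), depths=(19, 30))
        assert not filter_coverage(cand).passed

    def test_known_low_depth_passes(self):
        cand = make_candidate(gts=(2, 0), depths=(8, 30), known=True)
        assert filter_coverage(cand).passed

    def test_novel_depth_20_passes(self):
        cand = make_candidate(gts=(2, 0), depths=(20, 30))
        assert filter_coverage(cand).passed

    def test_all_hom_alt_is_near_fixed(self):
        cand = make_candidate(gts=(2, 2, 2, 2))
        assert not filter_near_fixed(cand).passed

    def test_single_het_rest_hom_alt_is_near_fixed(self):
        cand = make_candidate(gts=(2, 2, 1, 2))
        assert not filter_near_fixed(cand).passed

    def test_two_hets_pass(self):
        cand = make_candidate(gts=(2, 1, 1, 2))
        assert filter_near_fixed(cand).passed


# ---------------------------------------------------------------------------
# cascade on the planted study
# ---------------------------------------------------------------------------

class TestCascade:
    def test_survivors_are_exactly_the_true_hlofs(self, study, pipeline_run,
                                                  survivor_keys):
        assert survivor_keys == study.truth_keys("TRUE_HLOF")

    def test_each_artifact_fails_exactly_its_intended_filter(self, study,
                                                             pipeline_run):
        for row in study.truth.itertuples(index=False):
            if row.category in ("TRUE_HLOF", "INFRAME"):
                continue
            cand = candidate_by_key(pipeline_run,
                                    (row.contig, row.pos, row.ref, row.alt))
            assert cand is not None, row
            fails = pipeline_run.cascade.failing_filters(cand.key)
            assert fails == [row.intended_filter], (row.category, fails)

    def test_all_filters_count_bounded_by_single_filter_minimum(self, pipeline_run):
        audit = pipeline_run.cascade.audit.set_index("filter")["total"]
        single = audit.drop(["none", "all_filters"])
        assert audit["all_filters"] <= single.min()

    def test_cascade_is_deterministic(self, study, pipeline_run):
        from hlofpipe.pipeline import run_study
        again = run_study(study.directory, RunConfig())
        assert again.cascade.audit.equals(pipeline_run.cascade.audit)
        assert {str(c.key) for c in again.survivors} == \
            {str(c.key) for c in pipeline_run.survivors}

    def test_neutral_hwe_rejection_within_bound(self, study):
        """The HWE excess filter rejects neutral variants at no more than
        its five-population nominal bound (union of five 1% tests)."""
        df = pd.read_csv(study.paths["neutral"], sep="\t")
        pops = [p.name for p in study.config.populations]
        rej = 0
        for r in df.itertuples(index=False):
            ps = [hwe_excess_test(getattr(r, f"{p}_hom_ref"),
                                  getattr(r, f"{p}_het"),
                                  getattr(r, f"{p}_hom_alt")) for p in pops]
            rej += any(x < 0.01 for x in ps)
        frac = rej / len(df)
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(df))
        assert frac <= bound
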