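"""Variant normalisation, consequence classification, relative position."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hlofpipe.annotation import (
    HET, HOM_ALT, HOM_REF, MISSING, RawVariant, TranscriptModel, TranscriptSet,
    VariantRecord, classify_consequence, decompose_multiallelic,
    identify_candidates, relative_position,
)
from oracles import retranslate_consequence


def make_transcript(seq: str, strand: str = "+", contig: str = "ctg1",
                    segments=None, tid: str = "T1", gene: str = "G1"):
    if segments is None:
        segments = [(101, 100 + len(seq))]
    return TranscriptModel(gene_id=gene, transcript_id=tid, contig=contig,
                           strand=strand, cds_segments=segments, cds_seq=seq)


def snv(contig, pos, ref, alt, gts=(2,), depth=None):
    gts = np.array(gts, dtype=np.int8)
    depth = np.full(len(gts), 30) if depth is None else np.array(depth)
    return VariantRecord(contig, pos, ref, alt, gts, depth)


# ---------------------------------------------------------------------------
# multi-allelic decomposition
# ---------------------------------------------------------------------------

class TestDecompose:
    def test_biallelic_unchanged(self):
        raw = RawVariant("ctg1", 10, "A", ("G",),
                         np.array([[0, 0], [0, 1], [1, 1], [-1, -1]]),
                         np.full(4, 30))
        (rec,) = decompose_multiallelic([raw])
        assert rec.ref == "A" and rec.alt == "G"
        assert list(rec.genotypes) == [HOM_REF, HET, HOM_ALT, MISSING]

    def test_het_alt_alt_splits_to_two_hets(self):
        raw = RawVariant("ctg1", 10, "A", ("G", "T"),
                         np.array([[1, 2]]), np.full(1, 30))
        recs = decompose_multiallelic([raw])
        assert [r.alt for r in recs] == ["G", "T"]
        assert all(r.genotypes[0] == HET for r in recs)

    def test_symbolic_allele_skipped(self):
        raw = RawVariant("ctg1", 10, "A", ("<DEL>", "G"),
                         np.array([[0, 2]]), np.full(1, 30))
        recs = decompose_multiallelic([raw])
        assert [r.alt for r in recs] == ["G"]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(-1, 3), st.integers(-1, 3)),
                    min_size=1, max_size=8))
    def test_dosage_conserved(self, pairs):
        """Per-sample alternate-allele dosage is conserved across the split."""
        pairs = np.array([(-1, -1) if -1 in p else p for p in pairs])
        raw = RawVariant("c", 5, "A", ("C", "G", "T"), pairs,
                         np.full(len(pairs), 20))
        recs = decompose_multiallelic([raw])
        for si, (a, b) in enumerate(pairs):
            if a < 0:
                assert all(r.genotypes[si] == MISSING for r in recs)
                continue
            for ai, rec in enumerate(recs, start=1):
                expected = int(a == ai) + int(b == ai)
                assert rec.genotypes[si] == expected


# ---------------------------------------------------------------------------
# consequence classification
# ---------------------------------------------------------------------------

class TestClassify:
    def test_cga_to_tga_is_stop_gain(self):
        t = make_transcript("ATG" + "CGA" + "GGC")
        assert classify_consequence(snv("ctg1", 104, "C", "T"), t) == "stop_gain"

    def test_inframe_deletion_of_three_bases(self):
        t = make_transcript("ATGCGAGGCTTA"[:12])
        v = snv("ctg1", 104, "CGAG", "C")
        assert classify_consequence(v, t) == "inframe"

    def test_single_base_deletion_is_frameshift(self):
        t = make_transcript("ATGCGAGGC")
        assert classify_consequence(snv("ctg1", 104, "CG", "C"), t) == "frameshift"

    def test_outside_cds_is_non_coding(self):
        t = make_transcript("ATGCGAGGC")
        assert classify_consequence(snv("ctg1", 50, "A", "T"), t) == "non_coding"

    def test_minus_strand_stop_gain(self):
        # transcript CGA codon; on the genome ('-' strand) the C of the codon
        # is the complement G at the highest genomic coordinate of the codon
        t = make_transcript("ATGCGAGGC", strand="-")
        idx = 3  # the C of CGA
        pos = t.cds_to_genomic(idx)
        assert classify_consequence(snv("ctg1", pos, "G", "A"), t) == "stop_gain"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_random_variants_match_retranslation_oracle(self, strand, rng):
        """Classification agrees with a codon-walk translator on the mutated
        spliced CDS, for random SNVs and indels on both strands."""
        codons = [c for c in map("".join, zip(*[iter(
            "".join(rng.choice(list("ACGT"), 600)))] * 3))]
        seq = "".join(c for c in codons)[:300]
        segments = [(1001, 1120), (1301, 1420), (2001, 2060)]
        t = make_transcript(seq, strand=strand, segments=segments)
        checked = 0
        for _ in range(200):
            idx = int(rng.integers(1, 298))
            kind = rng.choice(["SNV", "deletion", "insertion"])
            g = t.cds_to_genomic(idx)
            if kind == "SNV":
                ref = t.genomic_base(g)
                alt = rng.choice([b for b in "ACGT" if b != ref])
                v = snv(t.contig, g, ref, str(alt))
                alt_t = str(alt) if strand == "+" else str(alt).translate(
                    str.maketrans("ACGT", "TGCA"))
                expect = retranslate_consequence(seq, "SNV", idx, alt_t)
            elif kind == "deletion":
                length = int(rng.integers(1, 5))
                span = [t.genomic_to_cds(g + k) for k in range(length)]
                if any(s is None for s in span) or t.genomic_to_cds(g - 1) is None:
                    continue
                anchor = t.genomic_base(g - 1)
                ref = anchor + "".join(t.genomic_base(g + k) for k in range(length))
                v = snv(t.contig, g - 1, ref, anchor)
                expect = retranslate_consequence(seq, "deletion", span)
            else:
                if t.genomic_to_cds(g + 1) is None:
                    continue
                length = int(rng.integers(1, 5))
                ins = "".join(rng.choice(list("ACGT"), length))
                ref = t.genomic_base(g)
                v = snv(t.contig, g, ref, ref + ins)
                junction = max(t.genomic_to_cds(g), t.genomic_to_cds(g + 1))
                ins_t = ins if strand == "+" else ins.translate(
                    str.maketrans("ACGT", "TGCA"))[::-1]
                expect = retranslate_consequence(seq, "insertion", junction, ins_t)
            got = classify_consequence(v, t)
            if expect in ("frameshift", "inframe"):
                assert got == expect, (kind, idx, v.ref, v.alt)
            else:
                assert got == expect, (kind, idx, v.ref, v.alt)
            checked += 1
        assert checked > 100


# ---------------------------------------------------------------------------
# relative position
# ---------------------------------------------------------------------------

class TestRelativePosition:
    def test_start_codon_is_zero(self):
        t = make_transcript("ATGCGAGGC")
        assert relative_position(snv("ctg1", 101, "A", "T"), t) == 0.0

    def test_codon_91_of_100_is_090(self):
        seq = "".join(["GCT"] * 100)
        t = make_transcript(seq)
        pos = t.cds_to_genomic(3 * 90)    # 91st codon, 1-based
        v = snv("ctg1", pos, "G", "A")
        assert relative_position(v, t) == pytest.approx(0.90)

    def test_spliced_equals_linearized_oracle(self, rng):
        seq = "".join(rng.choice(["GCT", "TTA", "CAA"], 80))
        segments = [(500, 559), (700, 819), (1000, 1059)]
        t = make_transcript(seq, segments=segments)
        for _ in range(50):
            idx = int(rng.integers(0, len(seq)))
            g = t.cds_to_genomic(idx)
            v = snv("ctg1", g, t.genomic_base(g), "A" if t.genomic_base(g) != "A" else "C")
            assert relative_position(v, t) == pytest.approx((idx // 3) / 80)

    def test_invariant_under_strand_flip(self, rng):
        """Mirroring the whole fixture to the other strand leaves the
        relative position of every variant unchanged."""
        seq = "".join(rng.choice(["GCT", "TTA", "CAA"], 60))
        fwd = make_transcript(seq, strand="+", segments=[(200, 289), (400, 489)])
        rev = make_transcript(seq, strand="-", segments=[(200, 289), (400, 489)])
        for idx in [0, 10, 59, 100, 179]:
            gf = fwd.cds_to_genomic(idx)
            gr = rev.cds_to_genomic(idx)
            vf = snv("ctg1", gf, fwd.genomic_base(gf), _other(fwd.genomic_base(gf)))
            vr = snv("ctg1", gr, rev.genomic_base(gr), _other(rev.genomic_base(gr)))
            assert relative_position(vf, fwd) == relative_position(vr, rev)


def _other(base: str) -> str:
    return "A" if base != "A" else "C"


# ---------------------------------------------------------------------------
# candidate identification
# ---------------------------------------------------------------------------

class TestIdentifyCandidates:
    def make_ts(self):
        return TranscriptSet({"T1": make_transcript("ATG" + "CGA" + "GGC")})

    def test_het_only_variant_excluded(self):
        ts = self.make_ts()
        v = snv("ctg1", 104, "C", "T", gts=(1, 1, 0))
        assert identify_candidates([v], ts) == []

    def test_hom_stop_gain_included_and_unknown(self):
        ts = self.make_ts()
        v = snv("ctg1", 104, "C", "T", gts=(2, 1, 0))
        (cand,) = identify_candidates([v], ts)
        assert cand.consequences["T1"] == "stop_gain"
        assert cand.known is False
        assert list(cand.carriers) == [0]

    def test_known_catalogue_lookup(self):
        ts = self.make_ts()
        v = snv("ctg1", 104, "C", "T", gts=(2,))
        (cand,) = identify_candidates([v], ts, {("ctg1", 104, "C", "T")})
        assert cand.known is True

    def test_candidates_cover_planted_truth(self, study, pipeline_run):
        cand_keys = {(c.variant.contig, c.variant.pos, c.variant.ref, c.variant.alt)
                     for c in pipeline_run.candidates}
        assert study.truth_keys("TRUE_HLOF") <= cand_keys

    def test_inframe_plants_never_candidates(self, study, pipeline_run):
        cand_keys = {(c.variant.contig, c.variant.pos, c.variant.ref, c.variant.alt)
                     for c in pipeline_run.candidates}
        assert not (study.truth_keys("INFRAME") & cand_keys)
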