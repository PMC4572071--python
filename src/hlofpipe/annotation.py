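"""Variant normalisation and loss-of-function consequence classification.

A candidate homozygous loss-of-function (HLOF) variant is a biallelic
stop-gain or frameshift call that is homozygous for the alternate allele in
at least one individual.  This module turns raw multi-sample variant records
into normalised biallelic :class:`VariantRecord` objects, classifies their
coding consequence against :class:`TranscriptModel` CDS structures, computes
the relative position of the first affected codon, and assembles the
candidate list consumed by the filter cascade.

Splice-disrupting variants are out of scope by design: they cannot be
validated without expression data and are excluded from the candidate
definition.  Single-allele (hemizygous-style) genotype calls are treated as
homozygous and flagged on the record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_CODON_TABLE = {
    # standard genetic code, '*' = stop
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# genotype codes used throughout (int8 arrays, one entry per sample)
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

# consequence labels
STOP_GAIN = "stop_gain"
FRAMESHIFT = "frameshift"
INFRAME = "inframe"
MISSENSE = "missense"
SYNONYMOUS = "synonymous"
NON_CODING = "non_coding"

LOF_LABELS = frozenset({STOP_GAIN, FRAMESHIFT})


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    try:
        return _CODON_TABLE[codon.upper()]
    except KeyError:
        raise ValueError(f"incomplete or invalid codon context: {codon!r}")


class IncompleteCodonError(ValueError):
    """Raised when a codon cannot be reconstructed from the CDS sequence."""


@dataclass(frozen=True)
class VariantKey:
    contig: str
    pos: int            # 1-based VCF position
    ref: str
    alt: str

    def __str__(self) -> str:  # used in audit tables
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class VariantRecord:
    """One normalised biallelic site with per-sample genotype and depth.

    ``genotypes`` holds int8 codes (0 hom-ref, 1 het, 2 hom-alt, -1 missing);
    ``depth`` holds per-sample read depth.  Both are indexed by the sample
    order of the cohort.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray
    depth: np.ndarray
    hemizygous_flagged: bool = False

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        if not self.ref or not self.alt:
            raise ValueError("empty allele string")

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.contig, self.pos, self.ref, self.alt)

    @property
    def vtype(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def indel_length(self) -> int:
        """Signed length change: >0 insertion, <0 deletion, 0 SNV."""
        return len(self.alt) - len(self.ref)

    def n_called(self) -> int:
        return int(np.sum(self.genotypes != MISSING))

    def carriers(self) -> np.ndarray:
        """Sample indices homozygous for the alternate allele."""
        return np.flatnonzero(self.genotypes == HOM_ALT)


@dataclass
class TranscriptModel:
    """CDS structure of one transcript.

    ``cds_segments`` are 1-based inclusive genomic intervals ordered along
    the genome; ``cds_seq`` is the spliced coding sequence in transcript
    (5'->3') orientation, whose length is a multiple of three.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    cds_segments: list[tuple[int, int]]
    cds_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.cds_segments = sorted(self.cds_segments)
        total = sum(e - s + 1 for s, e in self.cds_segments)
        if total != len(self.cds_seq):
            raise ValueError(
                f"{self.transcript_id}: CDS segments span {total} bp but "
                f"sequence has {len(self.cds_seq)} bp")
        if total % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length {total} not divisible by 3")
        for (s1, e1), (s2, e2) in zip(self.cds_segments, self.cds_segments[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: overlapping CDS segments")
        # cumulative genomic-order offsets for coordinate mapping
        self._offsets = np.cumsum([0] + [e - s + 1 for s, e in self.cds_segments])

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)

    @property
    def protein_length(self) -> int:
        return len(self.cds_seq) // 3

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_segments[0][0], self.cds_segments[-1][1]

    def genomic_to_cds(self, pos: int) -> int | None:
        """Map a genomic position to a 0-based index into ``cds_seq``.

        Returns None when the position is not coding in this transcript.
        """
        for i, (s, e) in enumerate(self.cds_segments):
            if s <= pos <= e:
                fwd = self._offsets[i] + (pos - s)
                if self.strand == "+":
                    return int(fwd)
                return int(self.cds_length - 1 - fwd)
        return None

    def cds_to_genomic(self, idx: int) -> int:
        """Inverse of :meth:`genomic_to_cds` (0-based CDS index -> genomic pos)."""
        if not 0 <= idx < self.cds_length:
            raise IndexError(idx)
        fwd = idx if self.strand == "+" else self.cds_length - 1 - idx
        seg = int(np.searchsorted(self._offsets, fwd, side="right")) - 1
        s, _ = self.cds_segments[seg]
        return s + (fwd - self._offsets[seg])

    def genomic_base(self, pos: int) -> str | None:
        """Genomic-strand reference base at ``pos`` (None outside the CDS)."""
        idx = self.genomic_to_cds(pos)
        if idx is None:
            return None
        base = self.cds_seq[idx]
        return base if self.strand == "+" else base.translate(_COMPLEMENT)

    def codon(self, codon_index: int) -> str:
        c = self.cds_seq[3 * codon_index: 3 * codon_index + 3]
        if len(c) != 3:
            raise IncompleteCodonError(
                f"{self.transcript_id}: codon {codon_index} incomplete")
        return c


@dataclass
class TranscriptSet:
    """All transcripts of the study, with per-gene and positional lookup."""

    transcripts: dict[str, TranscriptModel]
    _by_gene: dict[str, list[TranscriptModel]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_gene = {}
        for t in self.transcripts.values():
            self._by_gene.setdefault(t.gene_id, []).append(t)

    def __iter__(self):
        return iter(self.transcripts.values())

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def gene(self, gene_id: str) -> list[TranscriptModel]:
        return self._by_gene[gene_id]

    def overlapping(self, contig: str, start: int, end: int) -> list[TranscriptModel]:
        """Transcripts whose CDS span intersects [start, end] (1-based incl.)."""
        out = []
        for t in self.transcripts.values():
            if t.contig != contig:
                continue
            s, e = t.span
            if s <= end and start <= e:
                out.append(t)
        return out


# ---------------------------------------------------------------------------
# multi-allelic decomposition
# ---------------------------------------------------------------------------

@dataclass
class RawVariant:
    """A raw (possibly multi-allelic) site: per-sample allele-index pairs.

    ``allele_pairs`` is an (n_samples, 2) int array of allele indices
    (0 = ref, 1.. = alts, -1 = missing).
    """

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    allele_pairs: np.ndarray
    depth: np.ndarray


SYMBOLIC_PREFIXES = ("<", "[", "]")


def decompose_multiallelic(records: list[RawVariant]) -> list[VariantRecord]:
    """Split multi-allelic sites into biallelic records.

    For each alternate allele the per-sample genotype is the count of that
    allele in the sample's allele pair (0 -> hom-ref, 1 -> het, 2 -> hom-alt),
    so total alternate-allele dosage per sample is conserved across the
    split.  Symbolic and breakend alleles are skipped with a log entry.
    Single-allele calls (e.g. male X) are doubled and flagged hemizygous.
    """
    out: list[VariantRecord] = []
    for rec in records:
        pairs = np.asarray(rec.allele_pairs)
        hemi = False
        if pairs.ndim == 2 and pairs.shape[1] == 1:
            pairs = np.repeat(pairs, 2, axis=1)
            hemi = True
        for ai, alt in enumerate(rec.alts, start=1):
            if alt is None or any(alt.startswith(p) for p in SYMBOLIC_PREFIXES) or "." in alt:
                log.info("skipping symbolic allele %s at %s:%d", alt, rec.contig, rec.pos)
                continue
            missing = np.any(pairs < 0, axis=1)
            dosage = np.sum(pairs == ai, axis=1).astype(np.int8)
            gts = np.where(missing, np.int8(MISSING), dosage)
            out.append(VariantRecord(
                contig=rec.contig, pos=rec.pos, ref=rec.ref, alt=alt,
                genotypes=gts, depth=rec.depth, hemizygous_flagged=hemi))
    return out


# ---------------------------------------------------------------------------
# consequence classification
# ---------------------------------------------------------------------------

def _affected_cds_indices(variant: VariantRecord, transcript: TranscriptModel) -> list[int]:
    """0-based CDS indices touched by the variant (first-changed-base logic).

    SNV: the substituted base.  Deletion (left-anchored VCF): the deleted
    genomic bases that are coding.  Insertion: the first coding base 3' (in
    transcript orientation) of the insertion junction.
    """
    if variant.vtype == "SNV":
        idx = transcript.genomic_to_cds(variant.pos)
        return [] if idx is None else [idx]
    if variant.vtype == "deletion":
        span = range(variant.pos + len(variant.alt), variant.pos + len(variant.ref))
        idxs = [transcript.genomic_to_cds(p) for p in span]
        return sorted(i for i in idxs if i is not None)
    # insertion between pos and pos+1
    left = transcript.genomic_to_cds(variant.pos)
    right = transcript.genomic_to_cds(variant.pos + 1)
    if left is None or right is None:
        return []
    return [max(left, right)]


def classify_consequence(variant: VariantRecord, transcript: TranscriptModel) -> str:
    """Classify a variant's coding consequence in one transcript.

    SNVs are translated strand-aware through the affected codon: an
    alternate codon that is a stop (while the reference codon is not) is a
    stop-gain.  Coding indels are frameshifts when the number of inserted or
    deleted coding bases is not a multiple of three, and in-frame otherwise
    -- an in-frame indel is never a frameshift, however long.
    """
    affected = _affected_cds_indices(variant, transcript)
    if not affected:
        return NON_CODING
    if variant.vtype == "SNV":
        idx = affected[0]
        codon_i = idx // 3
        ref_codon = transcript.codon(codon_i)
        within = idx % 3
        alt_base = variant.alt if transcript.strand == "+" else variant.alt.translate(_COMPLEMENT)
        ref_base = variant.ref if transcript.strand == "+" else variant.ref.translate(_COMPLEMENT)
        if ref_codon[within].upper() != ref_base.upper():
            raise IncompleteCodonError(
                f"reference mismatch at {variant.key} in {transcript.transcript_id}")
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
        if alt_codon.upper() in STOP_CODONS:
            return STOP_GAIN if ref_codon.upper() not in STOP_CODONS else SYNONYMOUS
        if translate_codon(alt_codon) == translate_codon(ref_codon):
            return SYNONYMOUS
        return MISSENSE
    if variant.vtype == "deletion":
        n_coding_removed = len(affected)
        return FRAMESHIFT if n_coding_removed % 3 else INFRAME
    # insertion: all inserted bases land inside the CDS
    return FRAMESHIFT if variant.indel_length % 3 else INFRAME


def relative_position(variant: VariantRecord, transcript: TranscriptModel) -> float:
    """Fraction of the protein preceding the first affected codon.

    Defined as (first affected codon index, 0-based) / protein length, hence
    in [0, 1); a variant in the start codon maps to 0.0.  Used by the
    relative-position filter, which removes variants at >= 0.9.
    """
    affected = _affected_cds_indices(variant, transcript)
    if not affected:
        raise ValueError(f"{variant.key} is not coding in {transcript.transcript_id}")
    if transcript.protein_length == 0:
        raise ValueError(f"{transcript.transcript_id} has zero-length protein")
    return (affected[0] // 3) / transcript.protein_length


# ---------------------------------------------------------------------------
# candidate assembly
# ---------------------------------------------------------------------------

@dataclass
class HlofCandidate:
    """A variant homozygous-alt in >=1 individual with a LOF consequence."""

    variant: VariantRecord
    consequences: dict[str, str]            # transcript id -> label
    relative_positions: dict[str, float]    # transcript id -> fraction
    carriers: np.ndarray                    # sample indices, hom-alt
    pop_counts: dict[str, tuple[int, int, int]]  # pop -> (hom_ref, het, hom_alt)
    known: bool = False
    cscore: float | None = None

    @property
    def key(self) -> VariantKey:
        return self.variant.key

    @property
    def lof_transcripts(self) -> list[str]:
        return [t for t, c in self.consequences.items() if c in LOF_LABELS]

    @property
    def is_frameshift(self) -> bool:
        return FRAMESHIFT in self.consequences.values()

    @property
    def is_stop_gain(self) -> bool:
        return STOP_GAIN in self.consequences.values()

    def allele_frequency(self, min_depth: int = 5) -> float:
        """Alternate allele frequency over individuals with depth >= min_depth."""
        gt = self.variant.genotypes
        ok = (gt != MISSING) & (self.variant.depth >= min_depth)
        n = int(ok.sum())
        if n == 0:
            return float("nan")
        return float(gt[ok].sum()) / (2 * n)


def genotype_counts_by_population(
        variant: VariantRecord, sample_pops: np.ndarray) -> dict[str, tuple[int, int, int]]:
    out = {}
    for pop in np.unique(sample_pops):
        gt = variant.genotypes[sample_pops == pop]
        out[str(pop)] = (int(np.sum(gt == HOM_REF)),
                        int(np.sum(gt == HET)),
                        int(np.sum(gt == HOM_ALT)))
    return out


def identify_candidates(
        records: list[VariantRecord],
        transcripts: TranscriptSet,
        known_catalogue: set[tuple[str, int, str, str]] | None = None,
        sample_pops: np.ndarray | None = None,
        cscores: dict[VariantKey, float] | None = None) -> list[HlofCandidate]:
    """Select records homozygous-alt in >=1 individual with a LOF consequence.

    Every returned candidate carries per-transcript consequences and
    relative positions, the carrier list, per-population genotype counts,
    the known-catalogue flag and an optional deleteriousness score.
    """
    known_catalogue = known_catalogue or set()
    cscores = cscores or {}
    out: list[HlofCandidate] = []
    for rec in records:
        carriers = rec.carriers()
        if carriers.size == 0:
            continue
        start = rec.pos
        end = rec.pos + max(len(rec.ref), 1) - 1
        cons: dict[str, str] = {}
        rels: dict[str, float] = {}
        for t in transcripts.overlapping(rec.contig, start, end + 1):
            label = classify_consequence(rec, t)
            cons[t.transcript_id] = label
            if label != NON_CODING:
                rels[t.transcript_id] = relative_position(rec, t)
        if not (set(cons.values()) & LOF_LABELS):
            continue
        pops = sample_pops if sample_pops is not None else np.array(["all"] * len(rec.genotypes))
        out.append(HlofCandidate(
            variant=rec,
            consequences=cons,
            relative_positions=rels,
            carriers=carriers,
            pop_counts=genotype_counts_by_population(rec, pops),
            known=(rec.contig, rec.pos, rec.ref, rec.alt) in known_catalogue,
            cscore=cscores.get(rec.key)))
    return out
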