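"""Synthetic exome-cohort generator with planted ground truth.

Generates a complete, internally consistent study — transcript models with
coding sequence, a multi-sample VCF, mapability/blacklist/capture tracks,
per-individual runs of homozygosity, a primate allele table, deleteriousness
scores, phenotypes, and a truth table — so that every downstream stage of
the HLOF pipeline can be tested without any real data.

The cohort emulates the structure of a multi-population exome study: five
populations (one large cosmopolitan sample, four smaller isolates with more
and longer ROHs), an allele-frequency spectrum dominated by rare variants,
autozygous homozygotes created inside carriers' ROHs, and sequencing-error
homozygotes violating Hardy-Weinberg equilibrium.  Each planted artifact
category is constructed to fail exactly one filter of the cascade and pass
all the others; TRUE_HLOF variants pass everything.  The truth table maps
every planted variant to its category and intended filter and is the oracle
for the recovery tests.

All randomness flows from ``SimConfig.seed``; a fixed seed reproduces every
output file byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .annotation import HET, HOM_ALT, HOM_REF, MISSING, TranscriptModel, TranscriptSet
from .filters import hwe_excess_test

log = logging.getLogger(__name__)

# planted categories
TRUE_HLOF = "TRUE_HLOF"
LAST10PCT = "LAST10PCT"
LOW_MAPABILITY = "LOW_MAPABILITY"
OFF_TARGET = "OFF_TARGET"
FEW_SAMPLES = "FEW_SAMPLES"
ANCESTRAL = "ANCESTRAL"
MNP_CODON = "MNP_CODON"
FRAME_RESCUE = "FRAME_RESCUE"
INFRAME = "INFRAME"
HWE_EXCESS = "HWE_EXCESS"
LOW_COVERAGE = "LOW_COVERAGE"
NEAR_FIXED = "NEAR_FIXED"

INTENDED_FILTER = {
    TRUE_HLOF: "",
    LAST10PCT: "relative_position",
    LOW_MAPABILITY: "mapability",
    OFF_TARGET: "capture_intersection",
    FEW_SAMPLES: "min_samples",
    ANCESTRAL: "ancestral",
    MNP_CODON: "mnp_codon",
    FRAME_RESCUE: "frameshift_rescue",
    INFRAME: "candidate_identification",   # removed before the cascade
    HWE_EXCESS: "hwe",
    LOW_COVERAGE: "coverage",
    NEAR_FIXED: "near_fixed",
}

_SENSE_CODONS = sorted(set(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")
    - {"TAA", "TAG", "TGA"})

_COMP = str.maketrans("ACGT", "TGCA")

PRIMATE_SPECIES = ("chimp", "gorilla", "orangutan")


class SimulationError(ValueError):
    """Raised when a configuration cannot be satisfied, naming the category."""


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    size: int
    roh_genome_fraction: float
    mean_roh_length_bp: float
    mean_depth: float


def _default_populations() -> tuple[PopulationSpec, ...]:
    # one cosmopolitan cohort plus four isolates; sizes follow the study
    # design this generator emulates, depths span the 19x-86x regime.
    # Genome fractions in long (>1.5 Mb) ROHs are ~0.5% for cosmopolitan
    # Europeans and 1.5-3% for isolates, which reproduces overall
    # HLOF-in-ROH frequencies in the observed 3-10% range.
    return (
        PopulationSpec("COSMO", 844, 0.005, 2.0e6, 60.0),
        PopulationSpec("ISL_VIS", 193, 0.020, 2.5e6, 59.0),
        PopulationSpec("ISL_ORC", 197, 0.015, 2.5e6, 45.0),
        PopulationSpec("ISL_NOR", 98, 0.030, 2.5e6, 59.0),
        PopulationSpec("ISL_KOR", 100, 0.030, 2.5e6, 30.0),
    )


def _default_artifacts() -> dict[str, int]:
    return {
        LAST10PCT: 8, LOW_MAPABILITY: 8, OFF_TARGET: 8, FEW_SAMPLES: 8,
        ANCESTRAL: 8, MNP_CODON: 8, FRAME_RESCUE: 8, INFRAME: 8,
        HWE_EXCESS: 8, LOW_COVERAGE: 8, NEAR_FIXED: 4,
    }


@dataclass
class SimConfig:
    seed: int = 0
    populations: tuple[PopulationSpec, ...] = field(default_factory=_default_populations)
    n_contigs: int = 6
    contig_length: int = 5_000_000
    n_genes: int = 150
    transcripts_per_gene: tuple[int, int] = (1, 2)
    n_true_hlof: int = 40
    artifact_counts: dict[str, int] = field(default_factory=_default_artifacts)
    n_neutral_sites: int = 2500
    min_roh_length_bp: float = 1.5e6
    error_hom_rate: float = 0.8       # het->hom-alt miscall rate at HWE_EXCESS sites
    missing_rate: float = 0.01
    trait_count: int = 150
    trait_missing_rate: float = 0.02
    burden_effect_beta: float = 0.0   # extra extreme traits per HLOF carried
    known_fraction: float = 0.56      # TRUE_HLOFs present in the known catalogue
    true_af_range: tuple[float, float] = (0.002, 0.35)
    neutral_af_range: tuple[float, float] = (0.002, 0.5)

    def __post_init__(self) -> None:
        for p in (self.error_hom_rate, self.missing_rate, self.known_fraction,
                  self.trait_missing_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for pop in self.populations:
            if pop.size < 1:
                raise ValueError(f"population {pop.name} has size < 1")
            if not 0 <= pop.roh_genome_fraction <= 1:
                raise ValueError("roh_genome_fraction must lie in [0, 1]")
        unknown = set(self.artifact_counts) - set(INTENDED_FILTER)
        if unknown:
            raise ValueError(f"unknown artifact categories: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return sum(p.size for p in self.populations)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["populations"] = [asdict(p) for p in self.populations]
        return d


@dataclass
class StudyBundle:
    """In-memory view of a generated study plus the paths of its files."""

    config: SimConfig
    directory: Path
    samples: list[str]
    sample_pops: np.ndarray
    transcripts: TranscriptSet
    truth: pd.DataFrame
    roh: dict[str, list[tuple[str, int, int]]]
    paths: dict[str, Path]

    def truth_keys(self, category: str) -> set[tuple[str, int, str, str]]:
        sub = self.truth[self.truth["category"] == category]
        return {(r.contig, int(r.pos), r.ref, r.alt) for r in sub.itertuples(index=False)}


# ---------------------------------------------------------------------------
# gene scaffolds
# ---------------------------------------------------------------------------

@dataclass
class _Gene:
    gene_id: str
    contig: str
    strand: str
    segments: list[tuple[int, int]]          # genomic order, 1-based inclusive
    n_transcripts: int
    codons: list[str] = field(default_factory=list)  # transcript orientation

    @property
    def n_codons(self) -> int:
        return sum(e - s + 1 for s, e in self.segments) // 3

    @property
    def span(self) -> tuple[int, int]:
        return self.segments[0][0], self.segments[-1][1]

    def transcript_models(self) -> list[TranscriptModel]:
        seq = "".join(self.codons)
        t_segments = self.segments if self.strand == "+" else self.segments[::-1]
        models = []
        for j in range(self.n_transcripts):
            drop = min(j, len(self.segments) - 1)
            kept = t_segments[drop:]
            dropped_bp = sum(e - s + 1 for s, e in t_segments[:drop])
            models.append(TranscriptModel(
                gene_id=self.gene_id,
                transcript_id=f"{self.gene_id}.t{j + 1}",
                contig=self.contig, strand=self.strand,
                cds_segments=sorted(kept), cds_seq=seq[dropped_bp:]))
        return models

    def _codon_bounds(self) -> np.ndarray:
        return np.cumsum([0] + [e - s + 1 for s, e in
                                (self.segments if self.strand == "+"
                                 else self.segments[::-1])])

    def slot_ok(self, c: int, margin: int = 4) -> bool:
        """True when codon c's bases plus a margin sit inside one segment."""
        bounds = self._codon_bounds()
        start, end = 3 * c - margin, 3 * c + 2 + margin
        if start < 0 or end >= bounds[-1]:
            return False
        seg_lo = np.searchsorted(bounds, start, side="right") - 1
        seg_hi = np.searchsorted(bounds, end, side="right") - 1
        return bool(seg_lo == seg_hi)

    def pick_codon(self, rng: np.random.Generator, lo_frac: float, hi_frac: float,
                   used: set[int], margin: int = 4, category: str = "") -> int:
        """A codon index whose bases (plus a margin) sit inside one segment."""
        lo = max(1, int(np.ceil(lo_frac * self.n_codons)))
        hi = min(self.n_codons - 2, int(hi_frac * self.n_codons))
        if hi <= lo:
            raise SimulationError(
                f"{category or 'variant'}: transcript {self.gene_id} too short "
                f"for a codon in [{lo_frac}, {hi_frac}]")
        for _ in range(200):
            c = int(rng.integers(lo, hi + 1))
            if c not in used and self.slot_ok(c, margin):
                used.add(c)
                return c
        raise SimulationError(
            f"{category or 'variant'}: no usable codon slot in {self.gene_id}")


def _build_genes(cfg: SimConfig, rng: np.random.Generator) -> list[_Gene]:
    genes: list[_Gene] = []
    gi = 0
    per_contig = int(np.ceil(cfg.n_genes / cfg.n_contigs))
    for ci in range(cfg.n_contigs):
        contig = f"ctg{ci + 1}"
        cursor = 50_000
        for _ in range(per_contig):
            if gi >= cfg.n_genes:
                break
            n_seg = int(rng.integers(2, 5))
            seg_lens = 3 * rng.integers(40, 130, size=n_seg)
            segments = []
            pos = cursor
            for L in seg_lens:
                segments.append((pos, pos + int(L) - 1))
                pos += int(L) + int(rng.integers(200, 1500))
            lo, hi = cfg.transcripts_per_gene
            genes.append(_Gene(
                gene_id=f"G{gi + 1:04d}", contig=contig,
                strand="+" if rng.random() < 0.5 else "-",
                segments=segments,
                n_transcripts=int(rng.integers(lo, hi + 1))))
            gi += 1
            cursor = pos + int(rng.integers(20_000, 40_000))
            if cursor > cfg.contig_length - 100_000:
                raise SimulationError("contig too short for requested gene count")
    if gi < cfg.n_genes:
        raise SimulationError("could not place all genes")
    for g in genes:
        g.codons = [str(c) for c in rng.choice(_SENSE_CODONS, size=g.n_codons)]
    return genes


# ---------------------------------------------------------------------------
# variant plans
# ---------------------------------------------------------------------------

@dataclass
class _Plan:
    category: str
    gene: _Gene
    kind: str                 # stop_gain | insertion | deletion1 | deletion3 | snv
    codon: int
    partner_of: int | None = None   # index into plan list (rescue pairs, MNP)
    af: float = 0.01
    # filled in once transcripts exist
    contig: str = ""
    pos: int = 0
    ref: str = ""
    alt: str = ""


def _genomic_base(t: TranscriptModel, idx: int) -> str:
    base = t.cds_seq[idx]
    return base if t.strand == "+" else base.translate(_COMP)


def _plan_coordinates(plan: _Plan, t: TranscriptModel) -> None:
    """Convert a (gene, codon, kind) plan into VCF (pos, ref, alt)."""
    plan.contig = t.contig
    c = plan.codon
    if plan.kind == "stop_gain":
        # codon was overwritten to CGA; C->T at base 0 gives the stop TGA
        idx = 3 * c
        g = t.cds_to_genomic(idx)
        plan.pos = g
        plan.ref = _genomic_base(t, idx)
        plan.alt = "T" if t.strand == "+" else "A"
    elif plan.kind == "snv":
        # companion SNP at base 2 of a CGA codon: CGA->CGG (synonymous)
        idx = 3 * c + 2
        g = t.cds_to_genomic(idx)
        plan.pos = g
        plan.ref = _genomic_base(t, idx)
        plan.alt = "G" if t.strand == "+" else "C"
    elif plan.kind == "deletion1":
        idx = 3 * c + 1
        g = t.cds_to_genomic(idx)
        anchor_idx = t.genomic_to_cds(g - 1)
        plan.pos = g - 1
        plan.ref = _genomic_base(t, anchor_idx) + _genomic_base(t, idx)
        plan.alt = plan.ref[0]
    elif plan.kind == "deletion3":
        g0 = min(t.cds_to_genomic(3 * c), t.cds_to_genomic(3 * c + 2))
        anchor_idx = t.genomic_to_cds(g0 - 1)
        bases = "".join(_genomic_base(t, t.genomic_to_cds(g0 + k)) for k in range(3))
        plan.pos = g0 - 1
        plan.ref = _genomic_base(t, anchor_idx) + bases
        plan.alt = plan.ref[0]
    elif plan.kind == "insertion":
        # +1 insertion at the junction inside codon c (between bases 0 and 1)
        g = min(t.cds_to_genomic(3 * c), t.cds_to_genomic(3 * c + 1))
        anchor_idx = t.genomic_to_cds(g)
        plan.pos = g
        plan.ref = _genomic_base(t, anchor_idx)
        plan.alt = plan.ref + "A"
    else:
        raise ValueError(plan.kind)


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def _loguniform(rng, lo, hi, size=None):
    return lo * (hi / lo) ** rng.random(size)


def generate_study(config: SimConfig, outdir: str | Path) -> StudyBundle:
    """Generate the full study into ``outdir`` and return its bundle."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    samples: list[str] = []
    pops: list[str] = []
    for pop in cfg.populations:
        samples += [f"{pop.name}_{i:04d}" for i in range(pop.size)]
        pops += [pop.name] * pop.size
    sample_pops = np.array(pops)
    n = len(samples)
    pop_slices = {}
    start = 0
    for pop in cfg.populations:
        pop_slices[pop.name] = slice(start, start + pop.size)
        start += pop.size

    genes = _build_genes(cfg, rng)
    order = rng.permutation(len(genes))
    free_genes = [genes[i] for i in order]

    def take_gene(category: str) -> _Gene:
        if not free_genes:
            raise SimulationError(f"{category}: not enough genes configured")
        return free_genes.pop()

    # ----- plan all planted variants ------------------------------------
    plans: list[_Plan] = []
    lo_af, hi_af = cfg.true_af_range

    def add(plan: _Plan) -> int:
        plans.append(plan)
        return len(plans) - 1

    for _ in range(cfg.n_true_hlof):
        g = take_gene(TRUE_HLOF)
        used: set[int] = set()
        kind = "stop_gain" if rng.random() < 0.5 else (
            "insertion" if rng.random() < 0.5 else "deletion1")
        c = g.pick_codon(rng, 0.05, 0.85, used, category=TRUE_HLOF)
        add(_Plan(TRUE_HLOF, g, kind, c, af=float(_loguniform(rng, lo_af, hi_af))))

    for category, count in sorted(cfg.artifact_counts.items()):
        for _ in range(count):
            g = take_gene(category)
            used = set()
            if category == LAST10PCT:
                c = g.pick_codon(rng, 0.92, 0.99, used, category=category)
                add(_Plan(category, g, "stop_gain", c,
                          af=float(_loguniform(rng, lo_af, 0.05))))
            elif category in (LOW_MAPABILITY, OFF_TARGET, FEW_SAMPLES, ANCESTRAL,
                              HWE_EXCESS, LOW_COVERAGE, NEAR_FIXED):
                kind = "stop_gain"
                if category == ANCESTRAL and rng.random() < 0.5:
                    kind = "deletion1"
                c = g.pick_codon(rng, 0.05, 0.85, used, category=category)
                af = {HWE_EXCESS: float(rng.uniform(0.10, 0.20)),
                      NEAR_FIXED: 1.0,
                      LOW_COVERAGE: 0.003}.get(category,
                                               float(_loguniform(rng, lo_af, 0.05)))
                add(_Plan(category, g, kind, c, af=af))
            elif category == MNP_CODON:
                c = g.pick_codon(rng, 0.05, 0.85, used, category=category)
                i = add(_Plan(category, g, "stop_gain", c,
                              af=float(_loguniform(rng, lo_af, 0.05))))
                # companion SNP in the same codon; any frequency, not a LOF
                plans.append(_Plan("COMPANION", g, "snv", c, partner_of=i,
                                   af=float(rng.uniform(0.05, 0.2))))
            elif category == FRAME_RESCUE:
                if g.n_codons < 40:
                    raise SimulationError(
                        f"{FRAME_RESCUE}: transcript {g.gene_id} too short for a "
                        "frame-restoring pair")
                for _ in range(200):
                    c1 = g.pick_codon(rng, 0.10, 0.70, used, category=category)
                    if g.slot_ok(c1 + 4):
                        break
                else:
                    raise SimulationError(
                        f"{FRAME_RESCUE}: no codon pair 4 apart within one "
                        f"segment of {g.gene_id}")
                # +1 insertion and -1 deletion 4 codons apart: net length
                # change 0 (mod 3), i.e. the reading frame is restored
                af = float(_loguniform(rng, lo_af, 0.02))
                i = add(_Plan(category, g, "insertion", c1, af=af))
                add(_Plan(category, g, "deletion1", c1 + 4, partner_of=i, af=af))
            elif category == INFRAME:
                c = g.pick_codon(rng, 0.05, 0.85, used, category=category)
                add(_Plan(category, g, "deletion3", c,
                          af=float(_loguniform(rng, lo_af, 0.05))))
            else:
                raise SimulationError(f"unsupported category {category}")

    # overwrite planted stop-gain/companion codons with CGA so a single C->T
    # (or A->G for the companion) produces TGA / CGG
    for plan in plans:
        if plan.kind in ("stop_gain", "snv"):
            plan.gene.codons[plan.codon] = "CGA"

    transcripts = TranscriptSet({
        m.transcript_id: m for g in genes for m in g.transcript_models()})
    for plan in plans:
        t1 = transcripts[f"{plan.gene.gene_id}.t1"]
        _plan_coordinates(plan, t1)

    # rescue-pair sanity: the deletion codon must still sit inside a segment
    for plan in plans:
        if plan.category == FRAME_RESCUE and plan.kind == "deletion1":
            t1 = transcripts[f"{plan.gene.gene_id}.t1"]
            if t1.genomic_to_cds(plan.pos) is None or \
               t1.genomic_to_cds(plan.pos + 1) is None:
                raise SimulationError(
                    f"{FRAME_RESCUE}: rescue partner fell outside a CDS segment "
                    f"in {plan.gene.gene_id}")

    # ----- runs of homozygosity -----------------------------------------
    genome_bp = cfg.n_contigs * cfg.contig_length
    contigs = {f"ctg{i + 1}": cfg.contig_length for i in range(cfg.n_contigs)}
    roh: dict[str, list[tuple[str, int, int]]] = {s: [] for s in samples}
    for pop in cfg.populations:
        lam = pop.roh_genome_fraction * genome_bp / pop.mean_roh_length_bp
        for si in range(pop_slices[pop.name].start, pop_slices[pop.name].stop):
            k = int(rng.poisson(lam))
            for _ in range(k):
                length = int(cfg.min_roh_length_bp
                             + rng.exponential(pop.mean_roh_length_bp
                                               - cfg.min_roh_length_bp))
                contig = f"ctg{int(rng.integers(cfg.n_contigs)) + 1}"
                length = min(length, cfg.contig_length - 2)
                s0 = int(rng.integers(1, cfg.contig_length - length))
                roh[samples[si]].append((contig, s0, s0 + length - 1))

    # forced carriers: each planted LOF variant is guaranteed one homozygote;
    # rare TRUE_HLOF carriers are made autozygous (ROH added over the site),
    # matching how rare homozygotes arise in real cohorts
    pop_weights = np.array([p.size * p.roh_genome_fraction for p in cfg.populations])
    pop_weights = pop_weights / pop_weights.sum()
    forced_carrier: dict[int, int] = {}
    for pi, plan in enumerate(plans):
        if plan.category in (INFRAME, "COMPANION", NEAR_FIXED):
            continue
        if plan.partner_of is not None and plan.partner_of in forced_carrier:
            # rescue pairs share their homozygous carrier
            forced_carrier[pi] = forced_carrier[plan.partner_of]
            continue
        pop = cfg.populations[int(rng.choice(len(cfg.populations), p=pop_weights))]
        sl = pop_slices[pop.name]
        si = int(rng.integers(sl.start, sl.stop))
        forced_carrier[pi] = si
        if plan.category == TRUE_HLOF and plan.af < 0.05 and rng.random() < 0.6:
            half = int(rng.uniform(0.8e6, 1.6e6))
            s0 = max(1, plan.pos - half)
            e0 = min(cfg.contig_length - 1, plan.pos + half)
            roh[samples[si]].append((plan.contig, s0, e0))

    # ----- genotypes -----------------------------------------------------
    # per-contig index of (sample index, starts, ends) for fast membership
    roh_index: dict[str, list[tuple[int, np.ndarray, np.ndarray]]] = {}
    for si, s in enumerate(samples):
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, s0, e0 in hio.merge_intervals(roh[s]):
            by_contig.setdefault(contig, []).append((s0, e0))
        for contig, pairs in by_contig.items():
            pairs.sort()
            roh_index.setdefault(contig, []).append(
                (si, np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs])))

    def roh_members(contig: str, pos: int) -> np.ndarray:
        out = np.zeros(n, dtype=bool)
        for si, starts, ends in roh_index.get(contig, []):
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i >= 0 and pos <= ends[i]:
                out[si] = True
        return out

    def draw_site(contig: str, pos: int, p: float) -> np.ndarray:
        in_roh = roh_members(contig, pos)
        auto = np.where(rng.random(n) < p, HOM_ALT, HOM_REF).astype(np.int8)
        dosage = ((rng.random(n) < p).astype(np.int8)
                  + (rng.random(n) < p).astype(np.int8))
        return np.where(in_roh, auto, dosage).astype(np.int8), in_roh

    def draw_depth() -> np.ndarray:
        d = np.empty(n, dtype=np.int32)
        for pop in cfg.populations:
            sl = pop_slices[pop.name]
            d[sl] = np.round(rng.gamma(6.0, pop.mean_depth / 6.0,
                                       size=pop.size)).astype(np.int32)
        return np.maximum(d, 1)

    def enforce_hwe(gts: np.ndarray, depth: np.ndarray, in_roh: np.ndarray,
                    alpha_floor: float = 0.02) -> None:
        """Convert hom-refs (outside ROHs) to hets until no population shows
        an excess-homozygote P below ``alpha_floor``."""
        for pop in cfg.populations:
            sl = pop_slices[pop.name]
            for _ in range(400):
                sub = gts[sl]
                ok = (sub != MISSING) & (depth[sl] >= 5)
                p = hwe_excess_test(int(np.sum(sub[ok] == HOM_REF)),
                                    int(np.sum(sub[ok] == HET)),
                                    int(np.sum(sub[ok] == HOM_ALT)))
                if p >= alpha_floor:
                    break
                cand = np.flatnonzero((sub == HOM_REF) & ~in_roh[sl] & ok)
                if cand.size == 0:
                    raise SimulationError(
                        f"cannot balance HWE in {pop.name}: no hom-ref left")
                gts[sl.start + cand[int(rng.integers(cand.size))]] = HET

    rows: list[tuple[str, int, str, str, np.ndarray, np.ndarray]] = []
    truth_rows: list[dict] = []
    cscore_rows: list[dict] = []
    known_rows: list[dict] = []
    primate_rows: list[dict] = []
    low_map_intervals: list[tuple[str, int, int, float]] = []
    capture_holes: dict[str, tuple[int, int]] = {}   # gene id -> hole (kit A)

    for pi, plan in enumerate(plans):
        gts, in_roh = draw_site(plan.contig, plan.pos, plan.af)
        depth = draw_depth()
        missing = rng.random(n) < cfg.missing_rate
        gts[missing] = MISSING

        if pi in forced_carrier:
            si = forced_carrier[pi]
            gts[si] = HOM_ALT
        if plan.category == NEAR_FIXED:
            gts[:] = HOM_ALT
            gts[rng.random(n) < cfg.missing_rate] = MISSING
            if rng.random() < 0.5:   # "only one heterozygote" flavour
                het_i = int(rng.integers(n))
                if not in_roh[het_i]:
                    gts[het_i] = HET
        if plan.category == FEW_SAMPLES:
            keep = np.zeros(n, dtype=bool)
            keep[rng.choice(n, size=min(150, n - 1), replace=False)] = True
            keep[forced_carrier[pi]] = True
            gts[~keep] = MISSING
        if plan.category == HWE_EXCESS:
            # het->hom-alt miscalls in the largest population
            big = max(cfg.populations, key=lambda p: p.size)
            sl = pop_slices[big.name]
            hets = np.flatnonzero(gts[sl] == HET)
            flip = hets[rng.random(hets.size) < cfg.error_hom_rate]
            gts[sl.start + flip] = HOM_ALT

        # depth adjustments: guarantee (or deny) a >=20x homozygote
        carriers = np.flatnonzero(gts == HOM_ALT)
        if plan.category == LOW_COVERAGE:
            depth[carriers] = rng.integers(8, 20, size=carriers.size)
        elif plan.category not in (INFRAME, "COMPANION") and carriers.size:
            ci = forced_carrier.get(pi, int(carriers[0]))
            depth[ci] = max(int(depth[ci]), 25)

        if plan.category not in (HWE_EXCESS,):
            enforce_hwe(gts, depth, in_roh)

        rows.append((plan.contig, plan.pos, plan.ref, plan.alt, gts, depth))

        if plan.category != "COMPANION":
            truth_rows.append({
                "contig": plan.contig, "pos": plan.pos, "ref": plan.ref,
                "alt": plan.alt, "category": plan.category,
                "intended_filter": INTENDED_FILTER[plan.category]})

        # side tables -----------------------------------------------------
        is_lof = plan.category not in (INFRAME, "COMPANION")
        if is_lof:
            n_car = max(1, int(np.sum(gts == HOM_ALT)))
            score = float(np.clip(26.0 - 3.0 * np.log2(1 + n_car)
                                  + rng.normal(0, 5), 1.4, 44.0))
            cscore_rows.append({"contig": plan.contig, "pos": plan.pos,
                                "ref": plan.ref, "alt": plan.alt,
                                "cscore": round(score, 1)})
        if plan.category == TRUE_HLOF and rng.random() < cfg.known_fraction:
            known_rows.append({"contig": plan.contig, "pos": plan.pos,
                               "ref": plan.ref, "alt": plan.alt})
        if plan.category == LOW_MAPABILITY:
            low_map_intervals.append((plan.contig, plan.pos - 10, plan.pos + 10, 0.5))
        if plan.category == OFF_TARGET:
            capture_holes[plan.gene.gene_id] = (plan.pos - 60, plan.pos + 60)

        if is_lof:
            is_indel = plan.kind in ("insertion", "deletion1")
            for k, species in enumerate(PRIMATE_SPECIES):
                if plan.category == ANCESTRAL:
                    aligned, allele = 1, plan.alt if not is_indel else ""
                    row = {"indel_type": ("insertion" if plan.kind == "insertion"
                                          else "deletion") if is_indel else "",
                           "indel_len": 1 if is_indel else 0,
                           "pos_offset": 0, "flank_match": 1 if is_indel else 0}
                else:
                    # at most one aligned species, carrying the reference
                    aligned = 1 if k == 0 else 0
                    allele = plan.ref if not is_indel else ""
                    row = {"indel_type": "", "indel_len": 0,
                           "pos_offset": 0, "flank_match": 0}
                primate_rows.append({
                    "contig": plan.contig, "pos": plan.pos, "ref": plan.ref,
                    "alt": plan.alt, "species": species, "aligned": aligned,
                    "allele": allele, **row})

    # ----- neutral sites -------------------------------------------------
    gene_spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        s, e = g.span
        gene_spans.setdefault(g.contig, []).append((s - 200, e + 200))
    lo_n, hi_n = cfg.neutral_af_range
    neutral_positions: set[tuple[str, int]] = set()
    neutral_counts: list[dict] = []
    bases = np.array(list("ACGT"))
    for _ in range(cfg.n_neutral_sites):
        for _ in range(100):
            contig = f"ctg{int(rng.integers(cfg.n_contigs)) + 1}"
            pos = int(rng.integers(10_000, cfg.contig_length - 10_000))
            if (contig, pos) in neutral_positions:
                continue
            if any(s <= pos <= e for s, e in gene_spans.get(contig, [])):
                continue
            break
        else:
            raise SimulationError("could not place neutral site")
        neutral_positions.add((contig, pos))
        p = float(_loguniform(rng, lo_n, hi_n))
        gts, _ = draw_site(contig, pos, p)
        depth = draw_depth()
        gts[rng.random(n) < cfg.missing_rate] = MISSING
        ref, alt = rng.choice(4, size=2, replace=False)
        rows.append((contig, pos, str(bases[ref]), str(bases[alt]), gts, depth))
        counts = {}
        for pop in cfg.populations:
            sl = pop_slices[pop.name]
            sub, dsub = gts[sl], depth[sl]
            ok = (sub != MISSING) & (dsub >= 5)
            counts[pop.name] = (int(np.sum(sub[ok] == HOM_REF)),
                                int(np.sum(sub[ok] == HET)),
                                int(np.sum(sub[ok] == HOM_ALT)))
        neutral_counts.append({"contig": contig, "pos": pos, "af": p,
                               "counts": counts})

    # ----- tracks ---------------------------------------------------------
    capture_a: list[tuple[str, int, int]] = []
    capture_b: list[tuple[str, int, int]] = []
    for g in genes:
        s, e = g.span
        if g.gene_id in capture_holes:
            hs, he = capture_holes[g.gene_id]
            capture_a += [(g.contig, s - 100, hs - 1), (g.contig, he + 1, e + 100)]
        else:
            capture_a.append((g.contig, s - 100, e + 100))
        capture_b.append((g.contig, s - 80, e + 80))
    # decorative fully-alignable intervals plus the planted low-score regions
    align_duke = [(f"ctg{i + 1}", 1, cfg.contig_length, 1.0)
                  for i in range(cfg.n_contigs)] + low_map_intervals
    align_crg = [(f"ctg{i + 1}", 1, cfg.contig_length, 1.0)
                 for i in range(cfg.n_contigs)]
    blacklist: list[tuple[str, int, int]] = [("ctg1", 10, 500)]  # away from genes

    # ----- phenotypes -----------------------------------------------------
    truth = pd.DataFrame(truth_rows,
                         columns=["contig", "pos", "ref", "alt", "category",
                                  "intended_filter"])
    true_keys = {(r.contig, r.pos, r.ref, r.alt)
                 for r in truth.itertuples(index=False) if r.category == TRUE_HLOF}
    burden = np.zeros(n, dtype=int)
    for contig, pos, ref, alt, gts, _ in rows:
        if (contig, pos, ref, alt) in true_keys:
            burden += (gts == HOM_ALT).astype(int)
    traits = simulate_phenotypes(burden, cfg.trait_count, cfg.burden_effect_beta,
                                 rng, missing_rate=cfg.trait_missing_rate)
    traits.index = samples

    # ----- write ----------------------------------------------------------
    paths = {
        "vcf": outdir / "cohort.vcf",
        "gtf": outdir / "transcripts.gtf",
        "cds_fasta": outdir / "cds.fasta",
        "populations": outdir / "populations.tsv",
        "align_duke": outdir / "alignability_duke.bed",
        "align_crg": outdir / "alignability_crg.bed",
        "blacklist": outdir / "blacklist.bed",
        "capture_a": outdir / "capture_kitA.bed",
        "capture_b": outdir / "capture_kitB.bed",
        "roh": outdir / "roh.hom",
        "primates": outdir / "primate_alleles.tsv",
        "known": outdir / "known_catalogue.tsv",
        "cscores": outdir / "cscores.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.tsv",
        "neutral": outdir / "neutral_counts.tsv",
        "config": outdir / "sim_config.yaml",
    }
    hio.write_vcf(paths["vcf"], contigs, samples, rows)
    all_models = [m for g in genes for m in g.transcript_models()]
    hio.write_gtf(paths["gtf"], all_models)
    hio.write_cds_fasta(paths["cds_fasta"], all_models)
    hio.write_tsv(paths["populations"],
                  pd.DataFrame({"sample": samples, "population": pops}))
    hio.write_bed(paths["align_duke"], sorted(align_duke))
    hio.write_bed(paths["align_crg"], sorted(align_crg))
    hio.write_bed(paths["blacklist"], blacklist)
    hio.write_bed(paths["capture_a"], sorted(capture_a))
    hio.write_bed(paths["capture_b"], sorted(capture_b))
    hio.write_plink_hom(paths["roh"], roh)
    cols = ["contig", "pos", "ref", "alt", "species", "aligned", "allele",
            "indel_type", "indel_len", "pos_offset", "flank_match"]
    hio.write_tsv(paths["primates"],
                  pd.DataFrame(primate_rows, columns=cols).sort_values(
                      ["contig", "pos", "species"]).reset_index(drop=True))
    hio.write_tsv(paths["known"], pd.DataFrame(
        known_rows, columns=["contig", "pos", "ref", "alt"]))
    hio.write_tsv(paths["cscores"], pd.DataFrame(
        cscore_rows, columns=["contig", "pos", "ref", "alt", "cscore"]))
    traits.to_csv(paths["phenotypes"], sep="\t", index_label="sample")
    hio.write_tsv(paths["truth"], truth.sort_values(["contig", "pos"]))
    neutral_cols = ["contig", "pos", "af"] + [
        f"{p.name}_{lab}" for p in cfg.populations
        for lab in ("hom_ref", "het", "hom_alt")]
    neutral_df = pd.DataFrame([
        {"contig": d["contig"], "pos": d["pos"], "af": d["af"],
         **{f"{pn}_{lab}": d["counts"][pn][i]
            for pn in [p.name for p in cfg.populations]
            for i, lab in enumerate(("hom_ref", "het", "hom_alt"))}}
        for d in neutral_counts], columns=neutral_cols)
    hio.write_tsv(paths["neutral"], neutral_df.sort_values(["contig", "pos"]))
    cfg_text = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    digest = hashlib.sha256(cfg_text.encode()).hexdigest()
    paths["config"].write_text(cfg_text + f"# config_hash: {digest}\n")

    return StudyBundle(config=cfg, directory=outdir, samples=samples,
                       sample_pops=sample_pops, transcripts=transcripts,
                       truth=truth, roh=roh, paths=paths)


def simulate_phenotypes(burden: np.ndarray, n_traits: int, beta: float,
                        rng: np.random.Generator,
                        missing_rate: float = 0.0) -> pd.DataFrame:
    """Null-normal trait matrix with a linear burden effect on outlier counts.

    Traits are standard normal.  With ``beta`` > 0 each individual gets, in
    expectation, ``beta * burden`` traits pushed into a far tail (|z| > 4,
    far beyond the 1% empirical quantile of any realistic cohort), so the
    expected number of extreme trait values rises by ~beta per HLOF carried.
    """
    n = len(burden)
    values = rng.normal(size=(n, n_traits))
    missing = (rng.random(values.shape) < missing_rate) if missing_rate > 0 \
        else np.zeros_like(values, dtype=bool)
    if beta > 0:
        # the planted effect acts on *measured* traits: an unmeasured trait
        # can never be counted extreme, so pushes go to observed cells only
        for i in range(n):
            observed = np.flatnonzero(~missing[i])
            if observed.size == 0:
                continue
            p_push = min(1.0, beta * burden[i] / observed.size)
            k = int(rng.binomial(observed.size, p_push))
            if k == 0:
                continue
            cols = rng.choice(observed, size=k, replace=False)
            signs = np.where(rng.random(k) < 0.5, -1.0, 1.0)
            values[i, cols] = signs * (4.0 + np.abs(rng.normal(0, 0.5, size=k)))
    df = pd.DataFrame(values, columns=[f"trait{j + 1:03d}" for j in range(n_traits)])
    return df.mask(missing) if missing_rate > 0 else df


def write_roh(path: str | Path, roh: dict[str, list[tuple[str, int, int]]]) -> None:
    """PLINK ``.hom``-style writer (see :func:`hlofpipe.io.write_plink_hom`)."""
    hio.write_plink_hom(path, roh)
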