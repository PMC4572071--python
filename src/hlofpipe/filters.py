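"""The artifact-filter cascade for putative HLOF variants.

Each filter is a pure predicate producing a :class:`FilterDecision`, and the
cascade runner reports both the "applied individually" count per filter and
the count surviving all filters, mirroring the audit style of the original
analysis.  The survivor set is the intersection of single-filter pass sets,
so the result is order-independent.

Filters
-------
relative_position     variant before 90% of every coding transcript
mapability            outside sub-unity alignability and blacklist regions
min_samples           called in at least 200 individuals
capture_intersection  inside both capture kits' padded target regions
ancestral             allele not shared with primate outgroups
mnp_codon             no second SNP in the same codon (stop-gains)
frameshift_rescue     reading frame not restored by nearby frameshifts
hwe                   no excess of homozygotes vs Hardy-Weinberg (P < 0.01)
coverage              novel variants need a 20x homozygote
near_fixed            not (nearly) fixed for the alternate allele
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.special import gammaln

from .annotation import (
    FRAMESHIFT, HET, HOM_ALT, HOM_REF, MISSING, STOP_GAIN,
    HlofCandidate, TranscriptSet, VariantKey,
)
from .config import RunConfig

log = logging.getLogger(__name__)

FILTER_NAMES = [
    "relative_position",
    "mapability",
    "min_samples",
    "capture_intersection",
    "ancestral",
    "mnp_codon",
    "frameshift_rescue",
    "hwe",
    "coverage",
    "near_fixed",
]


@dataclass(frozen=True)
class FilterDecision:
    variant_key: VariantKey
    filter_name: str
    passed: bool
    reason: str = ""


@dataclass
class Resources:
    """Everything the cascade needs besides the candidates themselves."""

    alignability_tracks: list[dict[str, IntervalTree]]   # scored trees
    blacklist: dict[str, IntervalTree]
    capture_a: dict[str, IntervalTree]
    capture_b: dict[str, IntervalTree]
    primates: pd.DataFrame
    transcripts: TranscriptSet
    sample_pops: np.ndarray
    # all called SNVs: (contig, pos) -> set of (ref, alt); used by mnp_codon
    snv_index: dict[tuple[str, int], set[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.primates.empty:
            self._primate_groups = {
                k: g for k, g in self.primates.groupby(["contig", "pos", "ref", "alt"])}
        else:
            self._primate_groups = {}

    def primate_rows(self, key: VariantKey) -> pd.DataFrame | None:
        return self._primate_groups.get((key.contig, key.pos, key.ref, key.alt))


def build_snv_index(records) -> dict[tuple[str, int], set[tuple[str, str]]]:
    """Index all biallelic SNV calls by genomic position for the MNP filter."""
    idx: dict[tuple[str, int], set[tuple[str, str]]] = {}
    for rec in records:
        if rec.vtype == "SNV":
            idx.setdefault((rec.contig, rec.pos), set()).add((rec.ref, rec.alt))
    return idx


# ---------------------------------------------------------------------------
# exact HWE excess-homozygote test
# ---------------------------------------------------------------------------

def hwe_excess_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-sided exact test for an excess of homozygotes.

    Conditional on the sample size ``n`` and the alternate-allele count, the
    number of heterozygotes follows the Levene-Haldane distribution

        P(h) = n! / (n_aa! h! n_bb!) * 2^h * n_alt! n_ref! / (2n)!

    over heterozygote counts ``h`` of the same parity as the allele count.
    The returned P-value is the probability of observing the realised
    heterozygote count *or fewer* (fewer heterozygotes = more homozygotes).
    A monomorphic site returns 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("empty sample")
    n_alt = n_het + 2 * n_hom_alt
    n_ref = 2 * n - n_alt
    if n_alt == 0 or n_ref == 0:
        return 1.0
    rare = min(n_alt, n_ref)
    h = np.arange(rare % 2, rare + 1, 2)
    n_aa = (n_alt - h) // 2
    n_bb = (n_ref - h) // 2
    logp = (gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(h + 1) - gammaln(n_bb + 1)
            + h * np.log(2.0)
            + gammaln(n_alt + 1) + gammaln(n_ref + 1) - gammaln(2 * n + 1))
    p = np.exp(logp)
    p /= p.sum()  # guard against rounding drift; analytically sums to 1
    return float(np.clip(p[h <= n_het].sum(), 0.0, 1.0))


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def filter_relative_position(candidate: HlofCandidate,
                             max_fraction: float = 0.9,
                             mode: str = "all") -> FilterDecision:
    """Keep variants in the first 90% of the coding transcripts of a gene.

    In "all" mode (default) the variant must lie before the cutoff in every
    transcript in which it is coding; "any" requires only one transcript.
    """
    rels = candidate.relative_positions
    if not rels:
        return FilterDecision(candidate.key, "relative_position", False,
                              "no coding transcript")
    agg = max(rels.values()) if mode == "all" else min(rels.values())
    ok = agg < max_fraction
    return FilterDecision(candidate.key, "relative_position", ok,
                          "" if ok else f"relative position {agg:.3f} >= {max_fraction}")


def _span(candidate: HlofCandidate) -> tuple[str, int, int]:
    v = candidate.variant
    return v.contig, v.pos, v.pos + len(v.ref) - 1


def filter_mapability(candidate: HlofCandidate,
                      alignability_tracks: list[dict[str, IntervalTree]],
                      blacklist: dict[str, IntervalTree]) -> FilterDecision:
    """Remove variants overlapping low-alignability or blacklisted regions.

    Fails when any base of the reference span overlaps an interval with
    alignability score < 1.0 in any track, or any blacklist interval.
    """
    contig, start, end = _span(candidate)
    for track in alignability_tracks:
        tree = track.get(contig)
        if tree is None:
            continue
        for iv in tree.overlap(start, end + 1):
            if iv.data is not None and iv.data < 1.0:
                return FilterDecision(candidate.key, "mapability", False,
                                      f"alignability {iv.data} < 1.0")
    bl = blacklist.get(contig)
    if bl is not None and bl.overlap(start, end + 1):
        return FilterDecision(candidate.key, "mapability", False, "blacklisted region")
    return FilterDecision(candidate.key, "mapability", True)


def filter_min_samples(candidate: HlofCandidate, min_called: int = 200,
                       min_depth: int = 5, mode: str = "called") -> FilterDecision:
    """Require the variant to have been sampled in enough individuals."""
    v = candidate.variant
    if mode == "depth":
        n = int(np.sum((v.genotypes != MISSING) & (v.depth >= min_depth)))
    else:
        n = v.n_called()
    ok = n >= min_called
    return FilterDecision(candidate.key, "min_samples", ok,
                          "" if ok else f"called in {n} < {min_called} individuals")


def filter_capture_intersection(candidate: HlofCandidate,
                                capture_a: dict[str, IntervalTree],
                                capture_b: dict[str, IntervalTree],
                                pad: int = 50) -> FilterDecision:
    """Keep variants captured by both exome kits (targets padded by 50 bp)."""
    if not capture_a or not capture_b:
        return FilterDecision(candidate.key, "capture_intersection", False,
                              "empty capture track")
    contig, pos = candidate.variant.contig, candidate.variant.pos
    for name, track in (("kitA", capture_a), ("kitB", capture_b)):
        tree = track.get(contig)
        if tree is None or not tree.overlap(pos - pad, pos + pad + 1):
            return FilterDecision(candidate.key, "capture_intersection", False,
                                  f"outside padded {name} targets")
    return FilterDecision(candidate.key, "capture_intersection", True)


def filter_ancestral(candidate: HlofCandidate, resources: Resources) -> FilterDecision:
    """Remove variants shared with primate outgroups (likely reference errors
    or ancient polymorphism rather than derived loss of function).

    Stop-gains fail when any primate carries the human alternate allele.
    Frameshifts fail only when (1) at least two primates align over the
    site, (2) every aligned primate carries the non-reference variant and
    (3) its position, length and type match the human indel within the 5 bp
    flank comparison.  Sites absent from the table pass (no primate
    evidence) with a log entry.
    """
    rows = resources.primate_rows(candidate.key)
    if rows is None:
        log.info("no primate alignment for %s", candidate.key)
        return FilterDecision(candidate.key, "ancestral", True, "no primate data")
    aligned = rows[rows["aligned"] == 1]
    if candidate.is_stop_gain and not candidate.is_frameshift:
        hit = aligned[aligned["allele"].astype(str) == candidate.key.alt]
        if len(hit):
            return FilterDecision(candidate.key, "ancestral", False,
                                  f"primate carries alt ({','.join(hit['species'])})")
        return FilterDecision(candidate.key, "ancestral", True)
    # frameshift
    if len(aligned) < 2:
        return FilterDecision(candidate.key, "ancestral", True,
                              "fewer than two primates aligned")
    vtype = candidate.variant.vtype
    vlen = abs(candidate.variant.indel_length)
    match = ((aligned["indel_type"].astype(str) == vtype)
             & (aligned["indel_len"].astype(int) == vlen)
             & (aligned["pos_offset"].astype(int) == 0)
             & (aligned["flank_match"].astype(int) == 1))
    if match.all():
        return FilterDecision(candidate.key, "ancestral", False,
                              "all aligned primates carry matching indel")
    return FilterDecision(candidate.key, "ancestral", True)


def filter_mnp_codon(candidate: HlofCandidate, resources: Resources) -> FilterDecision:
    """Remove stop-gains sharing a codon with another called SNP.

    Adjacent SNPs in one codon form a multi-nucleotide polymorphism whose
    joint effect may not be a stop; such stop-gain calls are unreliable.
    Frameshifts pass unconditionally.
    """
    if not candidate.is_stop_gain:
        return FilterDecision(candidate.key, "mnp_codon", True)
    v = candidate.variant
    for tid, label in candidate.consequences.items():
        if label != STOP_GAIN:
            continue
        t = resources.transcripts[tid]
        idx = t.genomic_to_cds(v.pos)
        if idx is None:
            continue
        codon_i = idx // 3
        for k in range(3 * codon_i, 3 * codon_i + 3):
            gpos = t.cds_to_genomic(k)
            if gpos == v.pos:
                continue
            others = resources.snv_index.get((v.contig, gpos), set())
            if others:
                return FilterDecision(candidate.key, "mnp_codon", False,
                                      f"SNP at {v.contig}:{gpos} in same codon ({tid})")
    return FilterDecision(candidate.key, "mnp_codon", True)


def filter_frameshift_rescue(candidates: list[HlofCandidate],
                             resources: Resources,
                             vicinity_aa: int = 10,
                             mode: str = "transcript") -> dict[VariantKey, FilterDecision]:
    """Remove frameshifts whose reading frame is restored by nearby frameshifts.

    Per transcript, homozygous frameshifts are chained when consecutive
    variants are fewer than ``vicinity_aa`` amino acids apart (distances in
    affected-codon indices on the linearised CDS).  A lone frameshift
    passes; a pair in one chain fails when the signed indel-length sum is a
    multiple of three (frame restored) and passes otherwise; chains of three
    or more all fail, since frame-restoring subsets are possible.  In
    "carrier" mode two variants are additionally chained only when they
    share a homozygous carrier.
    """
    decisions: dict[VariantKey, FilterDecision] = {}
    per_transcript: dict[str, list[tuple[HlofCandidate, int, int]]] = {}
    for cand in candidates:
        if not cand.is_frameshift:
            decisions[cand.key] = FilterDecision(cand.key, "frameshift_rescue", True)
            continue
        for tid, label in cand.consequences.items():
            if label != FRAMESHIFT:
                continue
            t = resources.transcripts[tid]
            codon = int(cand.relative_positions[tid] * t.protein_length + 0.5)
            per_transcript.setdefault(tid, []).append(
                (cand, codon, cand.variant.indel_length))

    failed: set[VariantKey] = set()
    reasons: dict[VariantKey, str] = {}
    for tid, entries in per_transcript.items():
        entries.sort(key=lambda e: (e[1], str(e[0].key)))
        # chain consecutive entries within the vicinity window
        chains: list[list[tuple[HlofCandidate, int, int]]] = []
        for entry in entries:
            linked = (chains
                      and entry[1] - chains[-1][-1][1] < vicinity_aa
                      and (mode != "carrier"
                           or _share_carrier(chains[-1][-1][0], entry[0])))
            if linked:
                chains[-1].append(entry)
            else:
                chains.append([entry])
        for chain in chains:
            if len(chain) == 1:
                continue
            keys = [c.key for c, _, _ in chain]
            if len(chain) == 2:
                total = sum(l for _, _, l in chain)
                if total % 3 == 0:
                    failed.update(keys)
                    for k in keys:
                        reasons[k] = f"frame restored by nearby frameshift in {tid}"
            else:
                failed.update(keys)
                for k in keys:
                    reasons[k] = f">=3 frameshifts in close vicinity in {tid}"

    for cand in candidates:
        if cand.is_frameshift:
            ok = cand.key not in failed
            decisions[cand.key] = FilterDecision(
                cand.key, "frameshift_rescue", ok, "" if ok else reasons[cand.key])
    return decisions


def _share_carrier(a: HlofCandidate, b: HlofCandidate) -> bool:
    return bool(np.intersect1d(a.carriers, b.carriers).size)


def filter_hwe(candidate: HlofCandidate, sample_pops: np.ndarray,
               alpha: float = 0.01, min_depth: int = 5) -> FilterDecision:
    """Remove variants with a significant excess of homozygotes in any
    population (exact one-sided test, individuals with depth >= 5x only)."""
    v = candidate.variant
    for pop in np.unique(sample_pops):
        sel = (sample_pops == pop) & (v.genotypes != MISSING) & (v.depth >= min_depth)
        gt = v.genotypes[sel]
        if gt.size == 0:
            log.info("population %s empty at %s; skipped", pop, candidate.key)
            continue
        p = hwe_excess_test(int(np.sum(gt == HOM_REF)), int(np.sum(gt == HET)),
                            int(np.sum(gt == HOM_ALT)))
        if p < alpha:
            return FilterDecision(candidate.key, "hwe", False,
                                  f"homozygote excess in {pop} (P={p:.2e})")
    return FilterDecision(candidate.key, "hwe", True)


def filter_coverage(candidate: HlofCandidate, min_hom_depth: int = 20) -> FilterDecision:
    """Novel variants need one homozygote covered at >= 20x; variants already
    validated by earlier surveys (known catalogue) pass regardless."""
    if candidate.known:
        return FilterDecision(candidate.key, "coverage", True, "known variant")
    depths = candidate.variant.depth[candidate.carriers]
    if depths.size and int(depths.max()) >= min_hom_depth:
        return FilterDecision(candidate.key, "coverage", True)
    best = int(depths.max()) if depths.size else 0
    return FilterDecision(candidate.key, "coverage", False,
                          f"best homozygote depth {best} < {min_hom_depth}")


def filter_near_fixed(candidate: HlofCandidate) -> FilterDecision:
    """Remove variants fixed or nearly fixed for the alternate allele across
    all populations (zero hom-ref and at most one het): these are likely
    errors or rare alleles in the reference sequence."""
    hom_ref = sum(c[0] for c in candidate.pop_counts.values())
    het = sum(c[1] for c in candidate.pop_counts.values())
    if hom_ref == 0 and het <= 1:
        return FilterDecision(candidate.key, "near_fixed", False,
                              f"near-fixed (hom_ref=0, het={het})")
    return FilterDecision(candidate.key, "near_fixed", True)


# ---------------------------------------------------------------------------
# cascade runner
# ---------------------------------------------------------------------------

@dataclass
class CascadeResult:
    survivors: list[HlofCandidate]
    decisions: dict[VariantKey, dict[str, FilterDecision]]
    audit: pd.DataFrame

    def failing_filters(self, key: VariantKey) -> list[str]:
        return [f for f, d in self.decisions[key].items() if not d.passed]


def run_cascade(candidates: list[HlofCandidate], resources: Resources,
                config: RunConfig | None = None) -> CascadeResult:
    """Apply every filter to every candidate and assemble the audit.

    The audit reports, per filter, the number of candidates that would
    survive that filter applied alone, split by consequence class, plus the
    count surviving all filters; survivors are the candidates passing every
    filter, so the outcome does not depend on filter order.
    """
    config = config or RunConfig()
    decisions: dict[VariantKey, dict[str, FilterDecision]] = {
        c.key: {} for c in candidates}

    rescue = filter_frameshift_rescue(
        candidates, resources, mode=config.rescue_mode)
    for cand in candidates:
        d = decisions[cand.key]
        d["relative_position"] = filter_relative_position(
            cand, config.max_relative_position, config.relative_position_mode)
        d["mapability"] = filter_mapability(
            cand, resources.alignability_tracks, resources.blacklist)
        d["min_samples"] = filter_min_samples(
            cand, config.min_called, config.min_depth, config.min_samples_mode)
        d["capture_intersection"] = filter_capture_intersection(
            cand, resources.capture_a, resources.capture_b, config.capture_pad)
        d["ancestral"] = filter_ancestral(cand, resources)
        d["mnp_codon"] = filter_mnp_codon(cand, resources)
        d["frameshift_rescue"] = rescue[cand.key]
        d["hwe"] = filter_hwe(
            cand, resources.sample_pops, config.hwe_alpha, config.min_depth)
        d["coverage"] = filter_coverage(cand, config.min_hom_depth)
        d["near_fixed"] = filter_near_fixed(cand)

    survivors = [c for c in candidates
                 if all(d.passed for d in decisions[c.key].values())]

    rows = []
    stop = [c for c in candidates if c.is_stop_gain and not c.is_frameshift]
    frame = [c for c in candidates if c.is_frameshift]
    rows.append({"filter": "none",
                 "stop_gain": len(stop), "frameshift": len(frame),
                 "total": len(candidates)})
    for fname in FILTER_NAMES:
        rows.append({
            "filter": fname,
            "stop_gain": sum(decisions[c.key][fname].passed for c in stop),
            "frameshift": sum(decisions[c.key][fname].passed for c in frame),
            "total": sum(decisions[c.key][fname].passed for c in candidates)})
    rows.append({
        "filter": "all_filters",
        "stop_gain": sum(1 for c in survivors if c.is_stop_gain and not c.is_frameshift),
        "frameshift": sum(1 for c in survivors if c.is_frameshift),
        "total": len(survivors)})
    audit = pd.DataFrame(rows, columns=["filter", "stop_gain", "frameshift", "total"])
    return CascadeResult(survivors=survivors, decisions=decisions, audit=audit)
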