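"""Runs of homozygosity (ROH) and their relationship with HLOF variants.

Long ROHs mark autozygous segments inherited identical-by-descent; rare
alleles inside them surface as homozygotes that would otherwise almost
never be observed.  This module localises each carrier's homozygous call
relative to their ROHs, summarises per-population in-ROH frequencies,
classifies each variant as inside- or outside-ROH biased with one-sided
binomial tests at alpha 0.1, and contrasts the allele frequencies of the
two classes with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import HlofCandidate
from .io import merge_intervals, read_plink_hom

log = logging.getLogger(__name__)

INSIDE_BIASED = "inside_biased"
OUTSIDE_BIASED = "outside_biased"
UNCLASSIFIED = "unclassified"


class RohSet:
    """Per-individual autozygous intervals (1-based inclusive, merged)."""

    def __init__(self, intervals: dict[str, list[tuple[str, int, int]]]):
        self._data = {iid: merge_intervals(ivs) for iid, ivs in intervals.items()}
        # sorted arrays per (iid, contig) for fast membership checks
        self._index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for iid, ivs in self._data.items():
            by_contig: dict[str, list[tuple[int, int]]] = {}
            for contig, s, e in ivs:
                by_contig.setdefault(contig, []).append((s, e))
            for contig, pairs in by_contig.items():
                pairs.sort()
                starts = np.array([p[0] for p in pairs])
                ends = np.array([p[1] for p in pairs])
                self._index[(iid, contig)] = (starts, ends)

    @classmethod
    def from_plink(cls, path) -> "RohSet":
        return cls(read_plink_hom(path))

    def intervals(self, iid: str) -> list[tuple[str, int, int]]:
        return self._data.get(iid, [])

    def individuals(self) -> list[str]:
        return sorted(self._data)

    def contains(self, iid: str, contig: str, pos: int) -> bool:
        key = (iid, contig)
        if key not in self._index:
            if iid not in self._data:
                log.debug("individual %s absent from ROH set", iid)
            return False
        starts, ends = self._index[key]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos <= ends[i]


def carrier_in_roh(variant_contig: str, variant_pos: int, carrier: str,
                   roh_set: RohSet) -> bool:
    """True iff the variant position lies inside any ROH of that carrier.

    ROH bounds are inclusive; a carrier absent from the ROH set simply has
    no ROHs.
    """
    return roh_set.contains(carrier, variant_contig, variant_pos)


def population_roh_frequency(survivors: list[HlofCandidate], population: str,
                             roh_set: RohSet, samples: list[str],
                             sample_pops: np.ndarray) -> float:
    """Fraction of carrier-variant observations falling inside ROHs, over
    the carriers belonging to one population."""
    inside = total = 0
    for cand in survivors:
        v = cand.variant
        for ci in cand.carriers:
            if sample_pops[ci] != population:
                continue
            total += 1
            inside += carrier_in_roh(v.contig, v.pos, samples[ci], roh_set)
    if total == 0:
        raise ValueError(f"no carrier-variant observations in {population}")
    return inside / total


@dataclass
class RohBiasResult:
    variant_key: object
    carriers_in_roh: int
    carriers_total: int
    p_inside: float
    p_outside: float
    bias_class: str
    allele_frequency: float


def classify_roh_bias(key, k_inside: int, n_carriers: int, expected_freq: float,
                      allele_frequency: float = float("nan"),
                      alpha: float = 0.1) -> RohBiasResult:
    """Classify a variant's carriers as ROH-enriched or ROH-depleted.

    One-sided binomial tails of ``k_inside`` out of ``n_carriers`` at the
    population's expected in-ROH frequency: the upper tail below alpha
    means inside-biased, the lower tail below alpha outside-biased.  Both
    cannot be significant for alpha <= 0.5.
    """
    if n_carriers <= 0:
        raise ValueError("variant without carriers")
    if not 0 <= k_inside <= n_carriers:
        raise ValueError("k_inside outside [0, n_carriers]")
    p_in = stats.binomtest(k_inside, n_carriers, expected_freq,
                           alternative="greater").pvalue
    p_out = stats.binomtest(k_inside, n_carriers, expected_freq,
                            alternative="less").pvalue
    if p_in < alpha:
        cls = INSIDE_BIASED
    elif p_out < alpha:
        cls = OUTSIDE_BIASED
    else:
        cls = UNCLASSIFIED
    return RohBiasResult(key, k_inside, n_carriers, float(p_in), float(p_out),
                         cls, allele_frequency)


@dataclass
class RankSumResult:
    statistic: float
    pvalue: float
    median_inside: float
    median_outside: float
    direction: str           # "inside_lower", "inside_higher" or "tied"
    testable: bool
    note: str = ""


def compare_af_by_bias(results: list[RohBiasResult], min_group: int = 3) -> RankSumResult:
    """Wilcoxon rank-sum of allele frequencies, inside- vs outside-biased.

    Flagged untestable when either class has fewer than ``min_group``
    variants (a two-variant class cannot reach significance).
    """
    af_in = [r.allele_frequency for r in results if r.bias_class == INSIDE_BIASED]
    af_out = [r.allele_frequency for r in results if r.bias_class == OUTSIDE_BIASED]
    med_in = float(np.median(af_in)) if af_in else float("nan")
    med_out = float(np.median(af_out)) if af_out else float("nan")
    if len(af_in) < min_group or len(af_out) < min_group:
        return RankSumResult(float("nan"), float("nan"), med_in, med_out,
                             "untested", False,
                             f"class sizes {len(af_in)}/{len(af_out)} below {min_group}")
    exact_ok = (len(af_in) <= 25 and len(af_out) <= 25
                and len(set(af_in + af_out)) == len(af_in) + len(af_out))
    res = stats.mannwhitneyu(af_in, af_out, alternative="two-sided",
                             method="exact" if exact_ok else "asymptotic")
    if med_in < med_out:
        direction = "inside_lower"
    elif med_in > med_out:
        direction = "inside_higher"
    else:
        direction = "tied"
    return RankSumResult(float(res.statistic), float(res.pvalue),
                         med_in, med_out, direction, True)


def compare_populations_roh(counts_pop_a: tuple[int, int],
                            counts_pop_b: tuple[int, int]) -> float:
    """Two-sided Fisher exact P for the 2x2 table of (inside, outside) ROH
    carrier-variant counts in two populations.  A zero margin gives P = 1."""
    table = np.array([counts_pop_a, counts_pop_b])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def analyze_roh(survivors: list[HlofCandidate], roh_set: RohSet,
                samples: list[str], sample_pops: np.ndarray,
                alpha: float = 0.1, min_depth: int = 5,
                mode: str = "pooled") -> pd.DataFrame:
    """Per-variant ROH-bias table over the survivor set.

    In "pooled" mode carriers are pooled across populations and judged
    against the pooled expected in-ROH frequency; "per_population" keeps one
    row per (variant, population), each using that population's expected
    frequency.
    """
    pops = sorted(set(map(str, sample_pops)))
    pop_freq: dict[str, float] = {}
    for pop in pops:
        try:
            pop_freq[pop] = population_roh_frequency(
                survivors, pop, roh_set, samples, sample_pops)
        except ValueError:
            pop_freq[pop] = float("nan")

    obs: list[tuple] = []   # (key, pop, in_roh) per carrier-variant
    for cand in survivors:
        v = cand.variant
        for ci in cand.carriers:
            obs.append((cand, str(sample_pops[ci]),
                        carrier_in_roh(v.contig, v.pos, samples[ci], roh_set)))

    rows = []
    if mode == "pooled":
        total = len(obs)
        inside_all = sum(o[2] for o in obs)
        expected = inside_all / total if total else float("nan")
        for cand in survivors:
            mine = [o for o in obs if o[0] is cand]
            r = classify_roh_bias(cand.key, sum(o[2] for o in mine), len(mine),
                                  expected, cand.allele_frequency(min_depth), alpha)
            rows.append({"variant": str(cand.key), "population": "pooled",
                         "carriers_in_roh": r.carriers_in_roh,
                         "carriers_total": r.carriers_total,
                         "p_inside": r.p_inside, "p_outside": r.p_outside,
                         "class": r.bias_class, "af": r.allele_frequency})
    else:
        for cand in survivors:
            for pop in pops:
                mine = [o for o in obs if o[0] is cand and o[1] == pop]
                if not mine:
                    continue
                r = classify_roh_bias(cand.key, sum(o[2] for o in mine), len(mine),
                                      pop_freq[pop], cand.allele_frequency(min_depth),
                                      alpha)
                rows.append({"variant": str(cand.key), "population": pop,
                             "carriers_in_roh": r.carriers_in_roh,
                             "carriers_total": r.carriers_total,
                             "p_inside": r.p_inside, "p_outside": r.p_outside,
                             "class": r.bias_class, "af": r.allele_frequency})
    return pd.DataFrame(rows)


def singleton_roh_fraction(survivors: list[HlofCandidate], roh_set: RohSet,
                           samples: list[str]) -> tuple[int, int]:
    """(singletons inside ROHs, singletons) where a singleton HLOF is
    homozygous in exactly one individual across all populations."""
    n_in = n_single = 0
    for cand in survivors:
        if len(cand.carriers) != 1:
            continue
        n_single += 1
        ci = int(cand.carriers[0])
        n_in += carrier_in_roh(cand.variant.contig, cand.variant.pos,
                               samples[ci], roh_set)
    return n_in, n_single
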