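"""Brute-force reference implementations used as independent test oracles.

Everything here favours transparency over speed: direct enumeration,
explicit combinatorics, naive scans.  None of it shares code paths with the
package implementation it checks.
"""

from itertools import combinations
from math import comb, factorial


def hwe_excess_by_subsets(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """P(het <= observed) by enumerating every placement of the alternate
    alleles over the 2n ordered allele slots (feasible for n <= 5)."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    if n_alt == 0 or n_alt == 2 * n:
        return 1.0
    total = le = 0
    for alt_slots in combinations(range(2 * n), n_alt):
        s = set(alt_slots)
        het = sum((2 * i in s) != (2 * i + 1 in s) for i in range(n))
        total += 1
        le += het <= n_het
    return le / total


def hwe_excess_by_counts(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """P(het <= observed) by enumerating genotype-count configurations,
    weighting each by the number of ordered allele assignments realising it
    (n!/(n_aa! h! n_bb!) arrangements of individuals, 2^h allele orders
    within heterozygotes)."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    n_ref = 2 * n - n_alt
    if n_alt == 0 or n_ref == 0:
        return 1.0
    weights = {}
    for h in range(min(n_alt, n_ref) + 1):
        if (n_alt - h) % 2:
            continue
        n_aa, n_bb = (n_alt - h) // 2, (n_ref - h) // 2
        weights[h] = (factorial(n) // (factorial(n_aa) * factorial(h) * factorial(n_bb))
                      * 2 ** h)
    total = sum(weights.values())
    return sum(w for h, w in weights.items() if h <= n_het) / total


def binomial_tail(k: int, n: int, p: float, upper: bool) -> float:
    """Direct summation of binomial probabilities."""
    rng = range(k, n + 1) if upper else range(0, k + 1)
    return sum(comb(n, i) * p ** i * (1 - p) ** (n - i) for i in rng)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P by hypergeometric enumeration: sum the
    probabilities of all tables (same margins) no more likely than observed."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (comb(col1, x) * comb(n - col1, row1 - x)) / comb(n, row1)

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def hypergeom_upper_tail(N: int, B: int, n: int, b: int) -> float:
    """P(X >= b) for X ~ Hypergeom(N, B, n), by direct summation."""
    return sum(comb(B, i) * comb(N - B, n - i) / comb(N, n)
               for i in range(b, min(B, n) + 1)
               if 0 <= n - i <= N - B)


def bh_stepup(p_values):
    """Benjamini-Hochberg q-values straight from the step-up definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p_values[i] * m / rank)
        q[i] = prev
    return q


def retranslate_consequence(cds: str, variant_kind: str,
                            affected, alt_base: str | None = None) -> str:
    """Codon-walk translator over the mutated spliced CDS.

    ``cds`` is the reference spliced CDS (transcript orientation);
    ``affected`` is the 0-based CDS index (SNV / insertion junction) or the
    list of removed CDS indices (deletion).  Returns the consequence label
    by comparing the translated mutant against the reference protein.
    """
    stops = {"TAA", "TAG", "TGA"}
    if variant_kind == "SNV":
        mutated = cds[:affected] + alt_base + cds[affected + 1:]
    elif variant_kind == "deletion":
        keep = [i for i in range(len(cds)) if i not in set(affected)]
        mutated = "".join(cds[i] for i in keep)
    elif variant_kind == "insertion":
        mutated = cds[:affected] + alt_base + cds[affected:]
    else:
        raise ValueError(variant_kind)
    if len(mutated) != len(cds):
        return "frameshift" if len(mutated) % 3 else "inframe"
    ref_codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    alt_codons = [mutated[i:i + 3] for i in range(0, len(mutated), 3)]
    for rc, ac in zip(ref_codons, alt_codons):
        if rc == ac:
            continue
        if ac in stops and rc not in stops:
            return "stop_gain"
        from Bio.Seq import Seq
        return "synonymous" if str(Seq(rc).translate()) == str(Seq(ac).translate()) \
            else "missense"
    return "synonymous"


def linear_scan_in_roh(intervals, contig, pos) -> bool:
    return any(c == contig and s <= pos <= e for c, s, e in intervals)
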