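"""Gene-set enrichment, tissue-expression, per-population yield and
deleteriousness-score summaries for a survivor set of HLOF variants.

The enrichment statistic for a term with B background-annotated genes out
of N total, of which b fall in an n-gene target set, is the ratio

    enrichment = (b / n) / (B / N)

with an upper-tail hypergeometric P-value P(X >= b) and Benjamini-Hochberg
FDR control across terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import HOM_ALT, HlofCandidate

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------

def enrichment_ratio(N: int, B: int, n: int, b: int) -> float:
    """(b/n)/(B/N): fold-enrichment of a term in the target set."""
    if N <= 0 or n <= 0:
        raise ValueError("N and n must be positive")
    if B < 0 or b < 0 or b > min(B, n):
        raise ValueError(f"invalid quadruple (N={N}, B={B}, n={n}, b={b})")
    if B == 0:
        raise ValueError("term has no background genes (B = 0)")
    return (b / n) / (B / N)


def hypergeometric_enrichment_p(N: int, B: int, n: int, b: int) -> float:
    """Upper tail P(X >= b) for X ~ Hypergeom(N, B, n)."""
    if not (0 <= B <= N and 0 <= n <= N and 0 <= b <= min(B, n)):
        raise ValueError(f"invalid margins (N={N}, B={B}, n={n}, b={b})")
    return float(stats.hypergeom.sf(b - 1, N, B, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("P-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentRow:
    term: str
    N: int
    B: int
    n: int
    b: int
    enrichment: float
    p: float
    q: float


def enrich_gene_sets(target_genes: set[str], background_genes: set[str],
                     term_to_genes: dict[str, set[str]]) -> pd.DataFrame:
    """Term-by-term enrichment of a target gene set against a background.

    Genes outside the background are ignored; terms with no background
    gene are dropped with a log entry.
    """
    target = target_genes & background_genes
    N, n = len(background_genes), len(target)
    rows = []
    for term in sorted(term_to_genes):
        genes = term_to_genes[term] & background_genes
        B = len(genes)
        if B == 0:
            log.info("term %s has no background genes; dropped", term)
            continue
        b = len(genes & target)
        rows.append({"term": term, "N": N, "B": B, "n": n, "b": b,
                     "enrichment": round(enrichment_ratio(N, B, n, b), 2),
                     "p": hypergeometric_enrichment_p(N, B, n, b)})
    df = pd.DataFrame(rows, columns=["term", "N", "B", "n", "b", "enrichment", "p"])
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    return df


# ---------------------------------------------------------------------------
# tissue expression
# ---------------------------------------------------------------------------

def tissue_summary(expression: pd.DataFrame, gene_set: set[str],
                   expressed_threshold: float = 0.0,
                   focus_tissue: str | None = None) -> dict:
    """Where is each target gene expressed most highly?

    ``expression`` is a genes x tissues matrix.  For every target gene
    present in the matrix the argmax tissue is credited one count (ties
    split equally, 0.5 each for a two-way tie); counts and proportions per
    tissue are returned, which therefore sum to the number of genes scored
    (proportions to 1).  When ``focus_tissue`` is given, the fraction of
    genes with expression above ``expressed_threshold`` in that tissue is
    reported as well.  Genes absent from the matrix are excluded from all
    denominators with a log entry.
    """
    present = sorted(gene_set & set(expression.index))
    missing = gene_set - set(expression.index)
    if missing:
        log.info("%d genes absent from expression matrix", len(missing))
    if not present:
        raise ValueError("no target gene present in the expression matrix")
    sub = expression.loc[present]
    counts = pd.Series(0.0, index=expression.columns)
    for _, row in sub.iterrows():
        top = row[row == row.max()].index
        counts[top] += 1.0 / len(top)
    out = {
        "n_genes": len(present),
        "top_tissue_counts": counts,
        "top_tissue_proportions": counts / len(present),
    }
    if focus_tissue is not None:
        expressed = int((sub[focus_tissue] > expressed_threshold).sum())
        out["focus_tissue"] = focus_tissue
        out["n_expressed_in_focus"] = expressed
        out["fraction_expressed_in_focus"] = expressed / len(present)
    return out


# ---------------------------------------------------------------------------
# per-population yield and sharing
# ---------------------------------------------------------------------------

@dataclass
class PopulationSummary:
    population: str
    n_individuals: int
    n_hlofs: int
    yield_per_individual: float
    private_lofs: int
    private_hlofs: int
    burden_median: float


def population_yield(n_individuals: int, n_hlofs: int) -> float:
    """HLOF variants discovered per individual sampled, to 2 decimals."""
    if n_individuals <= 0:
        raise ValueError("population without individuals")
    return round(n_hlofs / n_individuals, 2)


def summarize_populations(survivors: list[HlofCandidate],
                          sample_pops: np.ndarray) -> pd.DataFrame:
    """Per-population summary: the number of HLOFs observed
    there, the yield per individual, the private LOF and private HLOF
    counts and the median per-individual burden.

    A private LOF is carried (het or hom) in exactly one population; a
    private HLOF is homozygous in exactly one population while being
    shared as heterozygotes with at least one other.
    """
    pops = sorted(set(map(str, sample_pops)))
    n_ind = {p: int(np.sum(sample_pops == p)) for p in pops}
    rows = []
    burden = {p: np.zeros(n_ind[p], dtype=int) for p in pops}
    for cand in survivors:
        for p in pops:
            gt = cand.variant.genotypes[sample_pops == p]
            burden[p] += (gt == HOM_ALT).astype(int)
    for pop in pops:
        n_hlof = priv_lof = priv_hlof = 0
        for cand in survivors:
            counts = cand.pop_counts
            hom_here = counts.get(pop, (0, 0, 0))[2]
            if hom_here > 0:
                n_hlof += 1
            carrier_pops = {p for p, (_, het, hom) in counts.items() if het + hom > 0}
            hom_pops = {p for p, (_, _, hom) in counts.items() if hom > 0}
            if carrier_pops == {pop}:
                priv_lof += 1
            elif hom_pops == {pop} and len(carrier_pops) > 1:
                priv_hlof += 1
        rows.append({
            "population": pop,
            "n_individuals": n_ind[pop],
            "n_hlofs": n_hlof,
            "yield": population_yield(n_ind[pop], n_hlof),
            "private_lofs": priv_lof,
            "private_hlofs": priv_hlof,
            "burden_median": float(np.median(burden[pop])) if n_ind[pop] else float("nan"),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deleteriousness scores and paralogue comparison
# ---------------------------------------------------------------------------

@dataclass
class CscoreSummary:
    median: float
    spearman_rho: float
    spearman_p: float
    n_scored: int
    testable: bool
    note: str = ""


def cscore_summary(survivors: list[HlofCandidate]) -> CscoreSummary:
    """Median deleteriousness score and its Spearman correlation (average
    ranks for ties) with the number of carriers per variant."""
    scored = [(c.cscore, len(c.carriers)) for c in survivors if c.cscore is not None]
    if not scored:
        return CscoreSummary(float("nan"), float("nan"), float("nan"), 0,
                             False, "no scored variants")
    scores = np.array([s for s, _ in scored], dtype=float)
    carriers = np.array([k for _, k in scored], dtype=float)
    med = float(np.median(scores))
    if len(scored) < 3:
        return CscoreSummary(med, float("nan"), float("nan"), len(scored),
                             False, "fewer than 3 scored variants")
    if np.all(scores == scores[0]) or np.all(carriers == carriers[0]):
        return CscoreSummary(med, float("nan"), float("nan"), len(scored),
                             False, "constant input, correlation undefined")
    rho, p = stats.spearmanr(scores, carriers)
    return CscoreSummary(med, float(rho), float(p), len(scored), True)


def compare_paralogues(hlof_counts: dict[str, int], background_counts: dict[str, int],
                       cutoffs: dict[str, tuple[dict[str, int], dict[str, int]]] | None = None,
                       exclude_genes: set[str] | None = None) -> pd.DataFrame:
    """Rank-sum comparison of paralogue counts, HLOF genes vs background.

    ``hlof_counts`` / ``background_counts`` map gene -> paralogue count at
    one identity cutoff; pass ``cutoffs`` as {label: (hlof, background)} to
    test several cutoffs at once.  ``exclude_genes`` (e.g. the olfactory
    receptor set) is removed from the target genes before testing.
    """
    if cutoffs is None:
        cutoffs = {"default": (hlof_counts, background_counts)}
    exclude = exclude_genes or set()
    rows = []
    for label in sorted(cutoffs):
        h, bg = cutoffs[label]
        target = {g: c for g, c in h.items() if g not in exclude}
        if not target or not bg:
            raise ValueError(f"empty input at cutoff {label}")
        x = np.array(sorted(target.values()), dtype=float)
        y = np.array(sorted(bg.values()), dtype=float)
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        med_x, med_y = float(np.median(x)), float(np.median(y))
        rows.append({"cutoff": label, "n_hlof": len(x), "n_background": len(y),
                     "median_hlof": med_x, "median_background": med_y,
                     "direction": ("hlof_lower" if med_x < med_y
                                   else "hlof_higher" if med_x > med_y else "tied"),
                     "p": float(res.pvalue)})
    return pd.DataFrame(rows)
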