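"""HLOF burden versus extreme quantitative phenotypes.

Rather than testing each rare variant against each trait (hopelessly
under-powered at one or two carriers per variant), the per-individual HLOF
burden is regressed on the number of the individual's trait values falling
in the top or bottom 1% of the within-population trait distribution, with
the number of traits measured as a covariate:

    n_extreme ~ burden + n_traits_measured        (OLS, per population)

A burden coefficient indistinguishable from zero is the expected outcome
for largely neutral HLOF variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .annotation import HOM_ALT, HlofCandidate


def count_burden(sample_index: int, survivors: list[HlofCandidate],
                 cscore_min: float | None = None,
                 exclude_genes: set[str] | None = None,
                 transcripts=None) -> int:
    """Number of surviving HLOF variants homozygous in one individual.

    ``cscore_min`` keeps only variants with a deleteriousness score above
    the threshold; ``exclude_genes`` (with the transcript set for gene
    lookup) drops variants in the named genes, e.g. olfactory receptors.
    """
    if survivors and not 0 <= sample_index < len(survivors[0].variant.genotypes):
        raise IndexError(f"unknown individual index {sample_index}")
    exclude = exclude_genes or set()
    n = 0
    for cand in survivors:
        if cscore_min is not None and (cand.cscore is None or cand.cscore <= cscore_min):
            continue
        if exclude and transcripts is not None:
            genes = {transcripts[t].gene_id for t in cand.consequences}
            if genes & exclude:
                continue
        if cand.variant.genotypes[sample_index] == HOM_ALT:
            n += 1
    return n


def burden_vector(survivors: list[HlofCandidate], n_samples: int,
                  cscore_min: float | None = None,
                  exclude_genes: set[str] | None = None,
                  transcripts=None) -> np.ndarray:
    """Vectorised :func:`count_burden` over the whole cohort."""
    burden = np.zeros(n_samples, dtype=int)
    exclude = exclude_genes or set()
    for cand in survivors:
        if cscore_min is not None and (cand.cscore is None or cand.cscore <= cscore_min):
            continue
        if exclude and transcripts is not None:
            genes = {transcripts[t].gene_id for t in cand.consequences}
            if genes & exclude:
                continue
        burden += (cand.variant.genotypes == HOM_ALT).astype(int)
    return burden


def extreme_trait_counts(traits: pd.DataFrame, populations: pd.Series,
                         q: float = 0.01) -> pd.DataFrame:
    """Per individual: traits measured and traits in an extreme tail.

    A trait value is extreme when it is <= the within-population q-quantile
    or >= the (1-q)-quantile of that trait (empirical quantiles over the
    population including the focal individual; ties at the threshold count
    as extreme).  Missing values are ignored.
    """
    populations = populations.reindex(traits.index)
    n_extreme = pd.Series(0, index=traits.index, dtype=int)
    n_measured = traits.notna().sum(axis=1)
    for _, idx in traits.groupby(populations).groups.items():
        sub = traits.loc[idx]
        lo = sub.quantile(q)
        hi = sub.quantile(1 - q)
        extreme = sub.le(lo) | sub.ge(hi)
        n_extreme.loc[idx] = extreme.sum(axis=1).astype(int)
    return pd.DataFrame({"n_traits_measured": n_measured, "n_extreme": n_extreme})


def count_extreme_traits(traits: pd.DataFrame, populations: pd.Series,
                         individual: str, q: float = 0.01) -> int:
    """Extreme-trait count for a single individual (see
    :func:`extreme_trait_counts`)."""
    if individual not in traits.index:
        raise KeyError(f"individual {individual!r} absent from trait matrix")
    return int(extreme_trait_counts(traits, populations, q).loc[individual, "n_extreme"])


@dataclass
class BurdenFit:
    population: str
    slope: float
    slope_se: float
    slope_p: float
    intercept: float
    n: int
    ok: bool
    note: str = ""


def fit_burden_model(records: pd.DataFrame, population: str | None = None) -> BurdenFit:
    """OLS of n_extreme on (burden, n_traits_measured).

    ``records`` needs columns burden, n_traits_measured, n_extreme (and
    population when ``population`` is given).  A rank-deficient design --
    e.g. constant burden -- is flagged instead of estimated.
    """
    df = records
    if population is not None:
        df = df[df["population"] == population]
    label = population or "all"
    if len(df) < 3:
        return BurdenFit(label, *[float("nan")] * 4, len(df), False, "too few records")
    y = df["n_extreme"].to_numpy(dtype=float)
    X = sm.add_constant(df[["burden", "n_traits_measured"]].to_numpy(dtype=float),
                        has_constant="add")
    if np.allclose(y, 0):
        return BurdenFit(label, 0.0, 0.0, float("nan"), 0.0, len(df), True,
                         "response identically zero")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return BurdenFit(label, *[float("nan")] * 4, len(df), False,
                         "rank-deficient design (constant predictor)")
    fit = sm.OLS(y, X).fit()
    return BurdenFit(label, float(fit.params[1]), float(fit.bse[1]),
                     float(fit.pvalues[1]), float(fit.params[0]), len(df), True)


def burden_report(survivors: list[HlofCandidate], traits: pd.DataFrame,
                  samples: list[str], sample_pops: np.ndarray,
                  q: float = 0.01, cscore_min: float | None = None,
                  exclude_genes: set[str] | None = None,
                  transcripts=None) -> tuple[pd.DataFrame, list[BurdenFit]]:
    """Assemble per-individual burden records and fit the model per population."""
    burden = burden_vector(survivors, len(samples), cscore_min, exclude_genes,
                           transcripts)
    pops = pd.Series(np.asarray(sample_pops, dtype=object), index=samples)
    counts = extreme_trait_counts(traits, pops, q)
    records = counts.reindex(samples).assign(
        burden=burden, population=np.asarray(sample_pops, dtype=object))
    records.index.name = "individual"
    fits = [fit_burden_model(records, p) for p in sorted(set(map(str, sample_pops)))]
    return records, fits
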