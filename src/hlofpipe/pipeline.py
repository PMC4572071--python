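"""End-to-end driver: study directory -> candidates -> cascade -> reports.

Binds the readers, the annotation stage and the filter cascade into one
reproducible run over a study directory laid out like the output of
:func:`hlofpipe.synthetic_data.generate_study`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .annotation import (
    HlofCandidate, TranscriptSet, decompose_multiallelic, identify_candidates,
)
from .config import RunConfig
from .filters import CascadeResult, Resources, build_snv_index, run_cascade

log = logging.getLogger(__name__)

STUDY_FILES = {
    "vcf": "cohort.vcf",
    "gtf": "transcripts.gtf",
    "cds_fasta": "cds.fasta",
    "populations": "populations.tsv",
    "align_duke": "alignability_duke.bed",
    "align_crg": "alignability_crg.bed",
    "blacklist": "blacklist.bed",
    "capture_a": "capture_kitA.bed",
    "capture_b": "capture_kitB.bed",
    "roh": "roh.hom",
    "primates": "primate_alleles.tsv",
    "known": "known_catalogue.tsv",
    "cscores": "cscores.tsv",
    "phenotypes": "phenotypes.tsv",
}


@dataclass
class PipelineRun:
    samples: list[str]
    sample_pops: np.ndarray
    transcripts: TranscriptSet
    records: list
    candidates: list[HlofCandidate]
    cascade: CascadeResult

    @property
    def survivors(self) -> list[HlofCandidate]:
        return self.cascade.survivors


def study_paths(directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    paths = {}
    for key, name in STUDY_FILES.items():
        p = directory / name
        if not p.exists():
            raise FileNotFoundError(f"missing study input: {p}")
        paths[key] = p
    return paths


def run_study(directory: str | Path, config: RunConfig | None = None) -> PipelineRun:
    """Annotate and filter a study directory, returning the full run state."""
    config = config or RunConfig()
    paths = study_paths(directory)

    samples, raw = hio.read_vcf(paths["vcf"])
    records = decompose_multiallelic(raw)
    transcripts = hio.read_transcripts(paths["gtf"], paths["cds_fasta"])
    pops_df = hio.read_populations(paths["populations"])
    pop_of = dict(zip(pops_df["sample"], pops_df["population"]))
    sample_pops = np.array([pop_of[s] for s in samples])
    known = hio.read_known_catalogue(paths["known"])
    cscores = hio.read_cscores(paths["cscores"])

    candidates = identify_candidates(records, transcripts, known,
                                     sample_pops, cscores)
    resources = Resources(
        alignability_tracks=[hio.read_bed(paths["align_duke"], scored=True),
                             hio.read_bed(paths["align_crg"], scored=True)],
        blacklist=hio.read_bed(paths["blacklist"]),
        capture_a=hio.read_bed(paths["capture_a"]),
        capture_b=hio.read_bed(paths["capture_b"]),
        primates=hio.read_primate_table(paths["primates"]),
        transcripts=transcripts,
        sample_pops=sample_pops,
        snv_index=build_snv_index(records),
    )
    cascade = run_cascade(candidates, resources, config)
    log.info("cascade: %d candidates -> %d survivors",
             len(candidates), len(cascade.survivors))
    return PipelineRun(samples=samples, sample_pops=sample_pops,
                       transcripts=transcripts, records=records,
                       candidates=candidates, cascade=cascade)


def survivors_table(run: PipelineRun) -> pd.DataFrame:
    rows = []
    for cand in run.survivors:
        v = cand.variant
        rows.append({
            "contig": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "consequence": ("stop_gain" if cand.is_stop_gain else "frameshift"),
            "n_carriers": len(cand.carriers),
            "af": cand.allele_frequency(),
            "known": cand.known,
            "cscore": cand.cscore if cand.cscore is not None else "",
        })
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt",
                                       "consequence", "n_carriers", "af",
                                       "known", "cscore"])
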