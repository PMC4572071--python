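"""Readers and writers for the pipeline's file formats.

Coordinate conventions: VCF and GTF are 1-based inclusive, BED is 0-based
half-open, PLINK ``.hom`` intervals are 1-based inclusive.  All internal
positions are 1-based; conversion happens only here, at the I/O boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

from .annotation import (
    MISSING, RawVariant, TranscriptModel, TranscriptSet, VariantKey,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(path: str | Path, contigs: dict[str, int], samples: list[str],
              rows: list[tuple[str, int, str, str, np.ndarray, np.ndarray]]) -> None:
    """Write a biallelic multi-sample VCF 4.2 with GT and DP FORMAT fields.

    ``rows`` are (contig, pos, ref, alt, genotypes, depth) tuples using the
    internal genotype codes.  Rows are sorted by (contig, pos) on output.
    """
    rows = sorted(rows, key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for contig, pos, ref, alt, gts, dps in rows:
            fields = [f"{_GT_STR[int(g)]}:{int(d)}" for g, d in zip(gts, dps)]
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:DP\t"
                     + "\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> tuple[list[str], list[RawVariant]]:
    """Read a multi-sample VCF into raw records (cyvcf2 backend).

    Returns the sample list and one :class:`RawVariant` per site; sites stay
    multi-allelic here and are split by
    :func:`hlofpipe.annotation.decompose_multiallelic`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    records: list[RawVariant] = []
    for v in vcf:
        gt = np.asarray(v.genotype.array(), dtype=np.int32)
        pairs = gt[:, :-1]  # drop phasing column
        dp = v.format("DP")
        depth = (np.zeros(len(samples), dtype=np.int32) if dp is None
                 else np.asarray(dp, dtype=np.int32).reshape(len(samples)))
        records.append(RawVariant(
            contig=v.CHROM, pos=v.POS, ref=v.REF, alts=tuple(v.ALT),
            allele_pairs=pairs, depth=depth))
    return samples, records


# ---------------------------------------------------------------------------
# transcripts: GTF (CDS features) + spliced CDS FASTA
# ---------------------------------------------------------------------------

def write_gtf(path: str | Path, transcripts: list[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.contig, t.span[0], t.transcript_id)):
            for s, e in t.cds_segments:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(f"{t.contig}\tsim\tCDS\t{s}\t{e}\t.\t{t.strand}\t0\t{attrs}\n")


def write_cds_fasta(path: str | Path, transcripts: list[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: t.transcript_id):
            fh.write(f">{t.transcript_id}\n")
            for i in range(0, len(t.cds_seq), 60):
                fh.write(t.cds_seq[i:i + 60] + "\n")


def read_transcripts(gtf_path: str | Path, cds_fasta_path: str | Path) -> TranscriptSet:
    """Load transcript models from a CDS-feature GTF plus a spliced-CDS FASTA."""
    cols = ["contig", "source", "feature", "start", "end", "score", "strand",
            "frame", "attributes"]
    df = pd.read_csv(gtf_path, sep="\t", comment="#", header=None, names=cols)
    df = df[df["feature"] == "CDS"]
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta_path), "fasta")}

    def attr(s: str, key: str) -> str:
        for part in s.split(";"):
            part = part.strip()
            if part.startswith(key + " "):
                return part.split(" ", 1)[1].strip('"')
        raise ValueError(f"attribute {key} missing in {s!r}")

    models: dict[str, TranscriptModel] = {}
    df = df.assign(
        gene_id=df["attributes"].map(lambda s: attr(s, "gene_id")),
        transcript_id=df["attributes"].map(lambda s: attr(s, "transcript_id")))
    for tid, grp in df.groupby("transcript_id", sort=True):
        segs = sorted(zip(grp["start"].astype(int), grp["end"].astype(int)))
        models[tid] = TranscriptModel(
            gene_id=grp["gene_id"].iloc[0], transcript_id=str(tid),
            contig=grp["contig"].iloc[0], strand=grp["strand"].iloc[0],
            cds_segments=segs, cds_seq=seqs[str(tid)])
    return TranscriptSet(models)


# ---------------------------------------------------------------------------
# BED interval tracks
# ---------------------------------------------------------------------------

def write_bed(path: str | Path, intervals: list[tuple[str, int, int]] |
              list[tuple[str, int, int, float]]) -> None:
    """Write intervals as BED.  Input intervals are 1-based inclusive and are
    converted to BED 0-based half-open; a 4th element becomes the score column."""
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            contig, start, end = iv[0], iv[1], iv[2]
            line = f"{contig}\t{start - 1}\t{end}"
            if len(iv) > 3:
                line += f"\t{iv[3]}"
            fh.write(line + "\n")


def read_bed(path: str | Path, scored: bool = False) -> dict[str, IntervalTree]:
    """Read a BED file into per-contig interval trees keyed on 1-based
    inclusive coordinates (tree intervals are [start, end+1)).  With
    ``scored=True`` the 4th column is attached as interval data."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            contig, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            data = float(parts[3]) if scored and len(parts) > 3 else None
            trees.setdefault(contig, IntervalTree()).addi(start0 + 1, end0 + 1, data)
    return trees


# ---------------------------------------------------------------------------
# PLINK .hom runs of homozygosity
# ---------------------------------------------------------------------------

def write_plink_hom(path: str | Path,
                    roh: dict[str, list[tuple[str, int, int]]]) -> None:
    """Write per-individual ROH intervals in PLINK ``.hom`` layout.

    Intervals are 1-based inclusive; overlapping intervals of one individual
    are merged with a logged warning before writing, so the file round-trips
    losslessly through :func:`read_plink_hom`.
    """
    with open(path, "w") as fh:
        fh.write("FID\tIID\tCHR\tPOS1\tPOS2\tKB\n")
        for iid in sorted(roh):
            merged = merge_intervals(roh[iid])
            if len(merged) != len(roh[iid]):
                log.warning("merged %d overlapping ROH intervals for %s",
                            len(roh[iid]) - len(merged), iid)
            for contig, s, e in merged:
                kb = (e - s + 1) / 1000.0
                fh.write(f"{iid}\t{iid}\t{contig}\t{s}\t{e}\t{kb:.4g}\n")


def read_plink_hom(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    df = pd.read_csv(path, sep=r"\s+")
    out: dict[str, list[tuple[str, int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.IID), []).append(
            (str(row.CHR), int(row.POS1), int(row.POS2)))
    return {iid: merge_intervals(ivs) for iid, ivs in out.items()}


def merge_intervals(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merge overlapping or touching 1-based inclusive intervals."""
    out: list[tuple[str, int, int]] = []
    for contig, s, e in sorted(intervals):
        if out and out[-1][0] == contig and s <= out[-1][2] + 1:
            prev = out.pop()
            out.append((contig, prev[1], max(prev[2], e)))
        else:
            out.append((contig, s, e))
    return out


# ---------------------------------------------------------------------------
# simple TSV tables
# ---------------------------------------------------------------------------

def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_populations(path: str | Path) -> pd.DataFrame:
    """Columns: sample, population."""
    return pd.read_csv(path, sep="\t", dtype=str)


def read_known_catalogue(path: str | Path) -> set[tuple[str, int, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "pos": int})
    return {(r.contig, int(r.pos), r.ref, r.alt) for r in df.itertuples(index=False)}


def read_cscores(path: str | Path) -> dict[VariantKey, float]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "pos": int})
    return {VariantKey(r.contig, int(r.pos), r.ref, r.alt): float(r.cscore)
            for r in df.itertuples(index=False)}


def read_primate_table(path: str | Path) -> pd.DataFrame:
    """Primate alignment table.

    Columns: contig, pos, ref, alt, species, aligned (0/1), allele,
    indel_type, indel_len, flank_up, flank_down.  For SNVs only ``allele``
    is meaningful; for indels the type/length/flank columns describe the
    primate's variant relative to the human reference.
    """
    return pd.read_csv(path, sep="\t", dtype={"contig": str, "pos": int},
                       keep_default_na=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Individuals x traits matrix, indexed by sample id; NA allowed."""
    return pd.read_csv(path, sep="\t", index_col=0)
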