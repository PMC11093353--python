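"""Readers and writers for the flat-file formats the pipeline exchanges.

TSV for matrices/sample sheets/phenotypes/truth tables, GFF3 for gene
models, FASTA for genome sequence (via Bio.SeqIO), bedGraph for bin tracks
and BED for peaks/regions.  BED and bedGraph are 0-based half-open; GFF3 is
1-based inclusive, converted on the fly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chip import BindingRegion, BinTrack, PeakCall
from .errors import DataError
from .expression import ExpressionStudy
from .targets import GeneModel


# --- expression -----------------------------------------------------------

def write_expression(study: ExpressionStudy, matrix_path, samples_path) -> None:
    study.matrix.to_csv(matrix_path, sep="\t", index_label="probeset")
    study.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_expression(matrix_path, samples_path, probe_map_path=None) -> ExpressionStudy:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    probe_map = (
        pd.read_csv(probe_map_path, sep="\t") if probe_map_path else None
    )
    return ExpressionStudy(matrix, samples, probe_map)


# --- genome ---------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


_FEATURE_TYPES = {
    "five_utr": "five_prime_UTR",
    "three_utr": "three_prime_UTR",
    "cds": "CDS",
}


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id}"
        lines.append(
            "\t".join(
                [g.chrom, "hifseek", "gene", str(g.start + 1), str(g.end),
                 ".", g.strand, ".", attrs]
            )
        )
        for k, (attr, ftype) in enumerate(
            [("exons", "exon"), ("five_utr", "five_prime_UTR"),
             ("three_utr", "three_prime_UTR"), ("cds", "CDS")]
        ):
            for s, e in getattr(g, attr):
                lines.append(
                    "\t".join(
                        [g.chrom, "hifseek", ftype, str(s + 1), str(e), ".",
                         g.strand, ".", f"Parent={g.gene_id}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> list[GeneModel]:
    rows = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand",
               "phase", "attrs"],
    )
    genes: dict[str, GeneModel] = {}
    feature_map = {"exon": "exons", "five_prime_UTR": "five_utr",
                   "three_prime_UTR": "three_utr", "CDS": "cds"}
    for _, r in rows.iterrows():
        attrs = dict(kv.split("=", 1) for kv in str(r["attrs"]).split(";") if "=" in kv)
        if r["type"] == "gene":
            gid = attrs["ID"]
            genes[gid] = GeneModel(
                gene_id=gid, chrom=r["chrom"], start=int(r["start"]) - 1,
                end=int(r["end"]), strand=r["strand"],
            )
    for _, r in rows.iterrows():
        if r["type"] in feature_map:
            attrs = dict(kv.split("=", 1) for kv in str(r["attrs"]).split(";") if "=" in kv)
            parent = attrs.get("Parent")
            if parent not in genes:
                raise DataError(f"feature with unknown Parent {parent!r}")
            getattr(genes[parent], feature_map[r["type"]]).append(
                (int(r["start"]) - 1, int(r["end"]))
            )
    return list(genes.values())


# --- bin tracks -----------------------------------------------------------

def write_bedgraph(tracks: Mapping[str, BinTrack], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            t = tracks[chrom]
            for i, c in enumerate(t.counts):
                fh.write(f"{chrom}\t{i * t.bin_size}\t{(i + 1) * t.bin_size}\t{int(c)}\n")


def read_bedgraph(path, library_total: int | None = None) -> dict[str, BinTrack]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "count"])
    total = int(df["count"].sum()) if library_total is None else library_total
    tracks = {}
    for chrom, sub in df.groupby("chrom"):
        sub = sub.sort_values("start")
        bin_size = int(sub["end"].iloc[0] - sub["start"].iloc[0])
        if not ((sub["end"] - sub["start"]) == bin_size).all():
            raise DataError(f"ragged bins in bedGraph on {chrom}")
        tracks[str(chrom)] = BinTrack(str(chrom), bin_size,
                                      sub["count"].to_numpy(np.int64), total)
    return tracks


# --- peaks and regions ----------------------------------------------------

def peaks_to_frame(calls: Iterable[PeakCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": c.chrom, "start": c.start, "end": c.end,
             "size": c.end - c.start, "avg_chip": c.avg_chip,
             "avg_input": c.avg_input, "avg_input_norm": c.avg_input_norm,
             "fold_enrichment": c.fold_enrichment, "min_adj_p": c.min_adj_p,
             "replicate": c.replicate}
            for c in calls
        ]
    )


def write_peaks(calls: Iterable[PeakCall], bed_path, tsv_path=None) -> None:
    df = peaks_to_frame(calls)
    bed = df[["chrom", "start", "end"]].copy()
    bed["name"] = [f"peak{i + 1}" for i in range(len(bed))]
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)


def regions_to_frame(regions: Iterable[BindingRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        row = {"chrom": r.chrom, "start": r.start, "end": r.end,
               "size": r.end - r.start, "coords_1based": r.report_coords(),
               "genes": ",".join(r.genes)}
        for rep, calls in sorted(r.support.items()):
            if calls:
                row[f"avg_chip_{rep}"] = float(np.mean([c.avg_chip for c in calls]))
                row[f"fold_enrichment_{rep}"] = float(
                    np.mean([c.fold_enrichment for c in calls])
                )
        rows.append(row)
    return pd.DataFrame(rows)


def write_regions(regions: Iterable[BindingRegion], bed_path, tsv_path=None) -> None:
    frame = regions_to_frame(regions)
    if len(frame) == 0:
        Path(bed_path).write_text("")
        if tsv_path is not None:
            frame.to_csv(tsv_path, sep="\t", index=False)
        return
    bed = frame[["chrom", "start", "end"]].copy()
    bed["name"] = [f"region{i + 1}" for i in range(len(bed))]
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    if tsv_path is not None:
        frame.to_csv(tsv_path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "name"],
                       usecols=[0, 1, 2, 3])
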