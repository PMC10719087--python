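"""Readers and writers for the package's plain-text interchange formats.

Conventions: genomic intervals are 0-based half-open BED; tables are UTF-8 TSV
with a header; count matrices travel as sparse triplet text with columns
(feature_id, cell_id, mc, cov); DMR sequences as FASTA; motifs as MEME
minimal.  Validation is strict — malformed rows are rejected with the line
number — because silent coordinate or count corruption is worse than a crash.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .methylome import FeatureSet, MethylCountMatrix

__all__ = [
    "write_counts_triplet",
    "read_counts_triplet",
    "write_bed",
    "read_bed",
    "write_fasta",
    "read_fasta",
    "write_tsv",
    "read_tsv",
    "write_bundle",
]


def write_counts_triplet(counts: MethylCountMatrix, path) -> None:
    """Write nonzero-coverage entries as (feature_id, cell_id, mc, cov) TSV."""
    rows_i, cols_j = np.nonzero(counts.cov)
    df = pd.DataFrame(
        {
            "feature_id": counts.features.ids[cols_j],
            "cell_id": counts.cells[rows_i],
            "mc": counts.mc[rows_i, cols_j],
            "cov": counts.cov[rows_i, cols_j],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_counts_triplet(
    path, features: FeatureSet, cells: np.ndarray | None = None, context: str = "CH"
) -> MethylCountMatrix:
    """Rebuild a count matrix from triplet text; entries with mc > cov or
    unknown feature ids are rejected with their line number."""
    df = pd.read_csv(path, sep="\t")
    bad = df.index[df["mc"] > df["cov"]]
    if len(bad):
        raise ValueError(f"mc > cov at line {bad[0] + 2} of {path}")
    feat_pos = {f: i for i, f in enumerate(features.ids)}
    unknown = ~df["feature_id"].isin(feat_pos)
    if unknown.any():
        line = df.index[unknown][0] + 2
        raise ValueError(f"unknown feature id at line {line} of {path}")
    if cells is None:
        cells = df["cell_id"].drop_duplicates().to_numpy()
    cell_pos = {c: i for i, c in enumerate(cells)}
    mc = np.zeros((len(cells), len(features)), dtype=int)
    cov = np.zeros_like(mc)
    ii = df["cell_id"].map(cell_pos).to_numpy()
    jj = df["feature_id"].map(feat_pos).to_numpy()
    mc[ii, jj] = df["mc"].to_numpy()
    cov[ii, jj] = df["cov"].to_numpy()
    return MethylCountMatrix(np.asarray(cells), features, mc, cov, context)


def write_bed(features: FeatureSet, path) -> None:
    t = features.table
    cols = pd.DataFrame(
        {
            "chrom": t["chrom"],
            "start": t["start"],
            "end": t["end"],
            "name": t["feature_id"],
            "score": 0,
            "strand": t["strand"] if "strand" in t else ".",
        }
    )
    cols.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path, kind: str = "interval") -> FeatureSet:
    """Read a BED file (0-based half-open); start >= end rejects with the
    offending line number."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((name, chrom, start, end, kind, strand))
    return FeatureSet(
        pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end", "kind", "strand"])
    )


def write_fasta(ids: list[str], sequences: list[str], path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in zip(ids, sequences)]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> tuple[list[str], list[str]]:
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    return ids, seqs


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_bundle(
    out_dir,
    counts: MethylCountMatrix | None = None,
    metadata: pd.DataFrame | None = None,
    features: FeatureSet | None = None,
    dmr_records: pd.DataFrame | None = None,
    dmr_sequences: list[str] | None = None,
    ground_truth_tables: dict | None = None,
) -> dict:
    """Write a synthetic-cohort fixture bundle; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if counts is not None:
        paths["counts"] = out / "counts.triplet.tsv"
        write_counts_triplet(counts, paths["counts"])
        paths["features_bed"] = out / "features.bed"
        write_bed(counts.features, paths["features_bed"])
    if features is not None:
        paths["features_bed"] = out / "features.bed"
        write_bed(features, paths["features_bed"])
    if metadata is not None:
        paths["metadata"] = out / "metadata.tsv"
        write_tsv(metadata, paths["metadata"])
    if dmr_records is not None:
        paths["dmrs_bed"] = out / "dmrs.bed"
        bed = dmr_records.rename(columns={"dmr_id": "feature_id"}).copy()
        bed["kind"] = "dmr"
        bed["strand"] = "."
        write_bed(FeatureSet(bed[["feature_id", "chrom", "start", "end", "kind", "strand"]]),
                  paths["dmrs_bed"])
        if dmr_sequences is not None:
            paths["dmr_fasta"] = out / "dmrs.fa"
            write_fasta(list(dmr_records["dmr_id"]), dmr_sequences, paths["dmr_fasta"])
    for name, table in (ground_truth_tables or {}).items():
        paths[name] = out / f"truth_{name}.tsv"
        write_tsv(table, paths[name])
    return paths
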