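"""Readers/writers for the plain-text formats the pipeline consumes and
emits: narrowPeak, GMT gene sets, JASPAR position frequency matrices,
FASTA sequences, BED6-like gene annotation, and TSV tables with stable
float formatting (so identical runs produce byte-identical files)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peaks_regulatory import MotifModel

FLOAT_FORMAT = "%.6g"


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT,
              lineterminator="\n")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


# ---------------------------------------------------------------------------
# narrowPeak (10-column BED extension; column 10 = summit offset from start)


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    """Write chrom/start/end(/summit/score) records as narrowPeak."""
    df = peaks.copy().reset_index(drop=True)
    name = df["peak_id"] if "peak_id" in df else pd.Series(
        [f"peak_{i + 1}" for i in range(len(df))])
    score = df["score"] if "score" in df else 0.0
    summit_off = (df["summit"] - df["start"]).astype(int) if "summit" in df else -1
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "name": name,
            "score": np.round(pd.Series(score, index=df.index).astype(float), 3),
            "strand": ".",
            "signalValue": np.round(pd.Series(score, index=df.index).astype(float), 3),
            "pValue": -1,
            "qValue": -1,
            "peak": summit_off,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


def read_narrowpeak(path) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "signalValue", "pValue", "qValue", "peak"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    df["summit"] = df["start"] + df["peak"]
    return df


# ---------------------------------------------------------------------------
# genes (BED6-like TSV with TSS)


def write_genes(genes: pd.DataFrame, path) -> None:
    write_tsv(genes[["gene_id", "chrom", "start", "end", "strand", "tss"]], path)


def read_genes(path) -> pd.DataFrame:
    return read_tsv(path)


# ---------------------------------------------------------------------------
# GMT


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets


# ---------------------------------------------------------------------------
# JASPAR PFM


def write_jaspar(motifs: list[MotifModel], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.id} {m.id}\n")
            for base, row in zip("ACGT", m.pfm):
                vals = " ".join(FLOAT_FORMAT % v for v in row)
                fh.write(f"{base}  [ {vals} ]\n")


def read_jaspar(path) -> list[MotifModel]:
    motifs: list[MotifModel] = []
    current_id = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current_id is not None and rows:
                    motifs.append(MotifModel(id=current_id, pfm=np.array(rows)))
                current_id = line[1:].split()[0]
                rows = []
            else:
                inner = line.split("[", 1)[1].rsplit("]", 1)[0]
                rows.append([float(x) for x in inner.split()])
    if current_id is not None and rows:
        motifs.append(MotifModel(id=current_id, pfm=np.array(rows)))
    return motifs


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# network


def write_network(edges: pd.DataFrame, path) -> None:
    write_tsv(edges[["source", "target", "sign"]], path)


def read_network(path) -> pd.DataFrame:
    return read_tsv(path)
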