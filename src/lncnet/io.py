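"""Readers and writers for the plain-text formats the pipeline consumes.

Counts and sample tables are TSV, sequences FASTA, annotation GTF
(Ensembl attribute dialect), gene sets GMT.  Everything round-trips
through pandas / Biopython; the GTF reader only extracts what the
catalog needs (gene_id, transcript_biotype, exon counts per transcript).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a transcripts x samples count matrix (first column = transcript_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate transcript ids in {path}: {dups[:5]}")
    if (df.values < 0).any():
        raise ValueError(f"negative counts in {path}")
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="transcript_id")


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read a sample table with columns sample_id, group, trait (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    required = {"sample_id", "group", "trait"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample table {path} must have columns {sorted(required)}")
    if not set(df["trait"].unique()) <= {0, 1}:
        raise ValueError("trait column must be 0 (control) or 1 (treated)")
    return df


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def parse_gtf_attributes(field: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(field))


def read_gtf_transcripts(path: str | Path) -> pd.DataFrame:
    """Summarize a GTF into one row per transcript.

    Returns a DataFrame indexed by transcript_id with columns
    gene_id, transcript_biotype (None when absent) and exon_count.
    Exons are counted from ``exon`` feature lines; a transcript with a
    ``transcript`` line but no exon lines gets exon_count 1.
    """
    gene_id: dict[str, str] = {}
    biotype: dict[str, str | None] = {}
    exon_count: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line: {line!r}")
            feature, attrs = fields[2], parse_gtf_attributes(fields[8])
            tid = attrs.get("transcript_id")
            if tid is None:
                continue
            if feature == "transcript":
                gene_id[tid] = attrs.get("gene_id", tid)
                biotype[tid] = attrs.get("transcript_biotype")
                exon_count.setdefault(tid, 0)
            elif feature == "exon":
                gene_id.setdefault(tid, attrs.get("gene_id", tid))
                biotype.setdefault(tid, attrs.get("transcript_biotype"))
                exon_count[tid] = exon_count.get(tid, 0) + 1
    rows = {
        tid: (gene_id[tid], biotype.get(tid), max(exon_count.get(tid, 0), 1))
        for tid in gene_id
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["gene_id", "transcript_biotype", "exon_count"]
    )
    df.index.name = "transcript_id"
    return df


def write_gtf(features: Iterable[tuple], path: str | Path) -> None:
    """Write pre-built GTF rows (9-tuples) to *path*."""
    with open(path, "w") as fh:
        for row in features:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> gene ids."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            sets[name] = {g for g in genes if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
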