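"""Stepwise transcript cataloguing: partition assembled transcripts into
known lncRNA, known mRNA, novel lncRNA and discarded classes.

The cascade order is significant: annotation biotype trumps coding
evidence, the length filter precedes the ORF filter, and coding-potential
flags are consulted last.  ``longest_orf_length`` scans the three forward
reading frames by default (assembled transcripts are strand-resolved); a
six-frame mode is available behind a flag.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from . import io

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID_NT = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: annotation biotypes accepted as known long non-coding, after normalization
LNC_BIOTYPES = frozenset({"antisense", "non coding", "processed transcript", "lincrna"})
#: annotation biotypes accepted as known protein-coding
CODING_BIOTYPES = frozenset({"protein coding", "mrna"})

MIN_LNC_LENGTH_NT = 200  # keep only transcripts strictly longer than this
MAX_NONCODING_ORF_AA = 100  # peptide >= this many aa => treated as coding


class TranscriptClass(str, Enum):
    KNOWN_LNCRNA = "known_lncRNA"
    KNOWN_MRNA = "known_mRNA"
    CODING_DISCARD = "coding_discard"
    SHORT_DISCARD = "short_discard"
    ORF_DISCARD = "orf_discard"
    NOVEL_LNCRNA = "novel_lncRNA"
    UNCLASSIFIED = "unclassified"


#: classes that make up the lncRNA set used downstream
LNCRNA_CLASSES = frozenset({TranscriptClass.KNOWN_LNCRNA, TranscriptClass.NOVEL_LNCRNA})


@dataclass
class CodingEvidence:
    """Stand-in flags for external coding-potential searches.

    ``protein_db_hit`` summarizes protein-database alignment evidence,
    ``cpc_coding`` and ``pfam_hit`` summarize coding-potential and protein
    domain predictions.  All default to False when no evidence is supplied.
    """

    protein_db_hit: bool = False
    cpc_coding: bool = False
    pfam_hit: bool = False


@dataclass
class TranscriptRecord:
    transcript_id: str
    gene_id: str
    sequence: Optional[str] = None
    length_nt: Optional[int] = None
    exon_count: int = 1
    known_biotype: Optional[str] = None
    evidence: CodingEvidence = field(default_factory=CodingEvidence)
    assigned_class: Optional[TranscriptClass] = None
    longest_orf_aa: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if self.length_nt is None:
                self.length_nt = len(self.sequence)
            elif self.length_nt != len(self.sequence):
                raise ValueError(
                    f"{self.transcript_id}: length_nt {self.length_nt} != "
                    f"sequence length {len(self.sequence)}"
                )


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - _VALID_NT
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq


def _scan_forward_frames(seq: str) -> tuple[int, int, int]:
    """Return (longest peptide aa, frame, start offset) over 3 forward frames.

    An ORF starts at ATG and runs to the first in-frame stop (excluded);
    without an in-frame stop it runs to the last complete codon.  Codons
    containing N match neither start nor stop.
    """
    best_len, best_frame, best_start = 0, -1, -1
    n = len(seq)
    for frame in range(3):
        open_start = -1  # earliest still-open ATG in this frame
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if open_start >= 0:
                    length = (pos - open_start) // 3
                    if length > best_len:
                        best_len, best_frame, best_start = length, frame, open_start
                    open_start = -1
            elif codon == START_CODON and open_start < 0:
                open_start = pos
            pos += 3
        if open_start >= 0:  # ran off the end without a stop
            length = (pos - open_start) // 3
            if length > best_len:
                best_len, best_frame, best_start = length, frame, open_start
    return best_len, best_frame, best_start


def longest_orf_length(sequence: str, both_strands: bool = False) -> int:
    """Longest ATG-initiated open reading frame, in amino acids.

    The peptide length excludes the stop codon; ORFs lacking an in-frame
    stop still count, ending at the last complete codon.  Returns 0 when
    no ATG-initiated ORF exists.  With ``both_strands`` the reverse
    complement's three frames are scanned as well.
    """
    seq = _validate_sequence(sequence)
    best = _scan_forward_frames(seq)[0]
    if both_strands:
        rc = seq.translate(_COMPLEMENT)[::-1]
        best = max(best, _scan_forward_frames(rc)[0])
    return best


def normalize_biotype(biotype: Optional[str]) -> Optional[str]:
    """Lower-case and collapse underscores/hyphens to single spaces."""
    if biotype is None:
        return None
    return " ".join(biotype.lower().replace("_", " ").replace("-", " ").split())


def classify_transcript(record: TranscriptRecord) -> TranscriptClass:
    """Assign a class by the ordered cascade; sets ``record.assigned_class``.

    Order: known lncRNA biotype (length > 200 nt) -> known mRNA biotype ->
    protein-database hit -> length filter -> ORF filter -> coding-potential
    flags -> novel lncRNA.  Absent fields count as negative evidence.
    """
    biotype = normalize_biotype(record.known_biotype)
    length = record.length_nt if record.length_nt is not None else 0

    if biotype in LNC_BIOTYPES and length > MIN_LNC_LENGTH_NT:
        cls = TranscriptClass.KNOWN_LNCRNA
    elif biotype in CODING_BIOTYPES:
        cls = TranscriptClass.KNOWN_MRNA
    elif record.evidence.protein_db_hit:
        cls = TranscriptClass.CODING_DISCARD
    elif length <= MIN_LNC_LENGTH_NT:
        cls = TranscriptClass.SHORT_DISCARD
    else:
        if record.longest_orf_aa is None:
            record.longest_orf_aa = (
                longest_orf_length(record.sequence) if record.sequence else 0
            )
        if record.longest_orf_aa >= MAX_NONCODING_ORF_AA:
            cls = TranscriptClass.ORF_DISCARD
        elif record.evidence.cpc_coding or record.evidence.pfam_hit:
            cls = TranscriptClass.CODING_DISCARD
        else:
            cls = TranscriptClass.NOVEL_LNCRNA

    record.assigned_class = cls
    return cls


def build_catalog(records: Sequence[TranscriptRecord]) -> pd.DataFrame:
    """Classify every record; return the per-transcript catalog table.

    Columns: gene_id, assigned_class, length_nt, exon_count,
    longest_orf_aa; indexed by transcript_id.  Class counts are attached
    as ``df.attrs["class_counts"]``.
    """
    seen = Counter(r.transcript_id for r in records)
    dups = [t for t, c in seen.items() if c > 1]
    if dups:
        raise ValueError(f"duplicate transcript ids: {dups[:5]}")

    rows = []
    for rec in records:
        cls = classify_transcript(rec)
        if rec.longest_orf_aa is None:
            rec.longest_orf_aa = (
                longest_orf_length(rec.sequence) if rec.sequence else 0
            )
        rows.append(
            (rec.transcript_id, rec.gene_id, cls.value, rec.length_nt,
             rec.exon_count, rec.longest_orf_aa)
        )
    df = pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_id", "assigned_class", "length_nt",
                 "exon_count", "longest_orf_aa"],
    ).set_index("transcript_id")
    counts = Counter(df["assigned_class"]) if len(df) else Counter()
    df.attrs["class_counts"] = {c.value: counts.get(c.value, 0) for c in TranscriptClass}
    return df


def is_lncrna(assigned_class: str | TranscriptClass) -> bool:
    return TranscriptClass(assigned_class) in LNCRNA_CLASSES


def records_from_files(
    fasta: str, gtf: str, evidence: Optional[str] = None
) -> list[TranscriptRecord]:
    """Join FASTA sequences, GTF annotation and an optional evidence TSV
    (columns transcript_id, protein_db_hit, cpc_coding, pfam_hit as 0/1)
    into TranscriptRecords.  A transcript missing from the evidence table
    gets all-False evidence.
    """
    sequences = io.read_fasta(fasta)
    annot = io.read_gtf_transcripts(gtf)
    ev = {}
    if evidence is not None:
        ev_df = pd.read_csv(evidence, sep="\t", index_col="transcript_id")
        for tid, row in ev_df.iterrows():
            ev[tid] = CodingEvidence(
                protein_db_hit=bool(row.get("protein_db_hit", 0)),
                cpc_coding=bool(row.get("cpc_coding", 0)),
                pfam_hit=bool(row.get("pfam_hit", 0)),
            )
    records = []
    for tid, seq in sequences.items():
        if tid in annot.index:
            row = annot.loc[tid]
            gene, biotype, n_exons = row["gene_id"], row["transcript_biotype"], int(row["exon_count"])
        else:
            gene, biotype, n_exons = tid, None, 1
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=gene,
                sequence=seq,
                exon_count=n_exons,
                known_biotype=biotype,
                evidence=ev.get(tid, CodingEvidence()),
            )
        )
    return records


def write_catalog(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="transcript_id")


def read_catalog(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="transcript_id")
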