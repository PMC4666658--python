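"""Readers and writers for the formats the pipeline touches.

FASTA goes through Biopython; tabular hit files (BLAST outfmt-6 dialect),
truth-pair tables and annotation tables are plain TSV handled with pandas.
Coordinates are 1-based inclusive everywhere, matching BLAST tabular output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

#: 20 standard amino acids plus the ambiguity code X.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

_OS_RE = re.compile(r"\bOS=(.+?)(?:\s+[A-Z]{2}=|$)")


@dataclass(frozen=True)
class SequenceRecord:
    """One named protein sequence with a source-organism label."""

    accession: str
    residues: str
    description: str = ""
    organism: str = "unknown"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.accession!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ProteinDatabase:
    """Ordered collection of unique-accession protein records.

    ``total_residues`` is the search-space size used for expect values.
    """

    records: list[SequenceRecord] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            seen.add(rec.accession)

    @property
    def total_residues(self) -> int:
        return sum(len(r) for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, accession: str) -> SequenceRecord:
        for rec in self.records:
            if rec.accession == accession:
                return rec
        raise KeyError(accession)

    def __contains__(self, accession: str) -> bool:
        return any(r.accession == accession for r in self.records)

    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]


@dataclass
class AlignmentHit:
    """One scored local alignment between a query/profile and a subject.

    ``aln_length`` counts alignment columns (the L of the identity/length
    curve); coordinates are 1-based inclusive.
    """

    query_id: str
    subject_id: str
    identity_pct: float
    aln_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    raw_score: float
    bit_score: float
    evalue: float
    aligned_query: str = ""
    aligned_subject: str = ""
    mismatch: int = 0
    gapopen: int = 0


def parse_organism(description: str) -> str:
    """Extract the organism from a FASTA description.

    Follows the UniProt convention ``OS=<name>`` terminated by the next
    ``XX=`` token; returns ``"unknown"`` when absent.
    """
    m = _OS_RE.search(description)
    if m:
        return m.group(1).strip()
    return "unknown"


def _validate_residues(accession: str, residues: str) -> str:
    residues = residues.upper().replace("*", "")
    if "-" in residues:
        raise ValueError(f"record {accession!r}: gap character '-' not allowed")
    for pos, aa in enumerate(residues, start=1):
        if aa not in VALID_RESIDUES:
            raise ValueError(
                f"record {accession!r}: illegal residue {aa!r} at position {pos}"
            )
    return residues


def read_fasta(path: str | Path, name: str | None = None) -> ProteinDatabase:
    """Read a protein FASTA file into a :class:`ProteinDatabase`.

    The accession is the first whitespace-delimited header token; residues
    are upper-cased and ``*`` stripped. Raises on empty files, duplicate
    accessions and non-amino-acid characters.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for bio in SeqIO.parse(str(path), "fasta"):
        desc = bio.description
        # Biopython puts the full header into .description (id included).
        rest = desc[len(bio.id):].strip() if desc.startswith(bio.id) else desc
        residues = _validate_residues(bio.id, str(bio.seq))
        if not residues:
            raise ValueError(f"record {bio.id!r}: empty sequence")
        records.append(
            SequenceRecord(
                accession=bio.id,
                residues=residues,
                description=rest,
                organism=parse_organism(desc),
            )
        )
    if not records:
        raise ValueError(f"no sequences in {path}")
    return ProteinDatabase(records=records, name=name or path.stem)


def write_fasta(db: ProteinDatabase | Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA with ``accession description`` headers."""
    records = list(db.records if isinstance(db, ProteinDatabase) else db)
    if not records:
        raise ValueError("refusing to write an empty database")
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.accession} {r.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(r.residues), 60):
                fh.write(r.residues[i:i + 60] + "\n")


_TAB_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits_tab(path: str | Path) -> list[AlignmentHit]:
    """Read 12-column BLAST tabular (outfmt 6) hits.

    Lines starting with ``#`` are skipped. Percent identity is kept on the
    0-100 scale; coordinates stay 1-based inclusive.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                hit = AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    identity_pct=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    raw_score=float(fields[11]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            if not 0.0 <= hit.identity_pct <= 100.0:
                raise ValueError(f"{path}:{lineno}: pident outside [0, 100]")
            hits.append(hit)
    return hits


def write_hits_tab(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 12-column BLAST tabular dialect read by :func:`read_hits_tab`."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity_pct:.2f}",
                        str(h.aln_length),
                        str(h.mismatch),
                        str(h.gapopen),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:.3g}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


def read_truth_pairs(path: str | Path) -> dict[str, set[str]]:
    """Read a truth-pair TSV (query accession TAB true ortholog accession)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["query", "ortholog"],
                     dtype=str, comment="#")
    truth: dict[str, set[str]] = {}
    for q, o in zip(df["query"], df["ortholog"]):
        truth.setdefault(q, set()).add(o)
    return truth
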