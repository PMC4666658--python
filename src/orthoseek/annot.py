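"""Functional-annotation frequency summaries for a result set.

Annotations arrive as a user-supplied TSV (no live database lookups):

    accession <TAB> pfam1;pfam2 <TAB> kegg1;kegg2 <TAB> GO:x|IEA;GO:y|IDA

Each namespace column is ';'-joined; GO entries carry an optional
``|EVIDENCE`` suffix. The summary reports, per namespace, the percentage
of result sequences carrying each term — counted once per sequence, with
unannotated sequences still in the denominator — optionally dropping GO
terms whose only evidence is electronic (IEA), and hiding terms at or
below a display cutoff (strictly "higher than", default 5%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

NAMESPACES = ("pfam", "kegg", "go")


@dataclass
class AnnotationTable:
    """accession -> per-namespace term lists; GO terms are (term, evidence)."""

    entries: dict[str, dict] = field(default_factory=dict)

    def add(self, accession: str, pfam=(), kegg=(), go=()) -> None:
        if accession in self.entries:
            raise ValueError(f"duplicate accession {accession!r}")
        self.entries[accession] = {
            "pfam": list(pfam),
            "kegg": list(kegg),
            "go": [tuple(t) for t in go],
        }


@dataclass
class FrequencySummary:
    """Per namespace: (term, percentage) sorted by descending frequency."""

    pfam: list[tuple[str, float]] = field(default_factory=list)
    kegg: list[tuple[str, float]] = field(default_factory=list)
    go: list[tuple[str, float]] = field(default_factory=list)


def read_annotation_tsv(path: str | Path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#",
                     names=["accession", "pfam", "kegg", "go"], keep_default_na=False)
    table = AnnotationTable()
    for _, row in df.iterrows():
        go_entries = []
        for item in filter(None, row["go"].split(";")):
            term, _, evidence = item.partition("|")
            go_entries.append((term, evidence))
        table.add(
            row["accession"],
            pfam=list(filter(None, row["pfam"].split(";"))),
            kegg=list(filter(None, row["kegg"].split(";"))),
            go=go_entries,
        )
    return table


def write_annotation_tsv(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, entry in table.entries.items():
            go = ";".join(f"{t}|{e}" if e else t for t, e in entry["go"])
            fh.write(f"{acc}\t{';'.join(entry['pfam'])}\t{';'.join(entry['kegg'])}\t{go}\n")


def summarize_annotations(
    result_ids: list[str],
    table: AnnotationTable,
    drop_iea: bool = False,
    min_pct: float = 5.0,
) -> FrequencySummary:
    """Term frequencies over a result set (see module docstring).

    Duplicate term listings on one sequence count once; a term survives
    only if its percentage is strictly greater than ``min_pct``.
    """
    if not result_ids:
        raise ValueError("result_ids must be non-empty")
    n = len(result_ids)
    summary = FrequencySummary()
    for ns in NAMESPACES:
        carriers: dict[str, int] = {}
        for acc in result_ids:
            entry = table.entries.get(acc)
            if entry is None:
                continue
            if ns == "go":
                terms = {t for t, ev in entry["go"] if not (drop_iea and ev == "IEA")}
            else:
                terms = set(entry[ns])
            for t in terms:
                carriers[t] = carriers.get(t, 0) + 1
        rows = [
            (term, 100.0 * count / n)
            for term, count in carriers.items()
            if 100.0 * count / n > min_pct
        ]
        rows.sort(key=lambda r: (-r[1], r[0]))
        setattr(summary, ns, rows)
    return summary


def write_summary_tsv(summary: FrequencySummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("namespace\tterm\tpercentage\n")
        for ns in NAMESPACES:
            for term, pct in getattr(summary, ns):
                fh.write(f"{ns}\t{term}\t{pct:.2f}\n")
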