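"""Synthetic protein families with known truth labels.

Every pipeline stage is testable without downloads: a seeded generator
plants a family around an ancestral domain, emits per-species homologs
(the domain mutated at a configured per-site rate, embedded in fresh
random linkers), decoys of matched composition and length, and three
kinds of adversarial paralogs:

* a *truncated* paralog — a domain fragment, shorter than the shortest
  homolog by more than the minimal domain length, which the length filter
  must remove;
* an *extra-domain* paralog — the shared domain plus a long unrelated
  C-terminal domain, which must either be trimmed back to the family's
  length band or (when diverged) rejected by the identity curve;
* an *out-paralog* — a more diverged family member whose best reciprocal
  hit is a second, closer gene planted in the source proteome, so RBHB
  must keep it as a homolog but exclude it from the orthologs.

The substitution model is per-site replacement with a uniform choice
among the other 19 residues and no indels inside the domain (length
variation lives entirely in the linkers), so the expected identity of a
mutant to the ancestor is exactly ``1 - rate``. The PRNG is numpy's
PCG64 via ``default_rng``, fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .align import BACKGROUND_FREQS
from .annot import AnnotationTable, write_annotation_tsv
from .seqio import AMINO_ACIDS, ProteinDatabase, SequenceRecord, write_fasta

_AA = np.array(list(AMINO_ACIDS))


@dataclass(frozen=True)
class ParalogSpec:
    """Which adversarial paralogs a family carries."""

    truncated: bool = True
    extra_domain: bool = True
    out_paralog: bool = True
    #: per-site divergence of the extra-domain paralog's shared domain
    extra_domain_rate: float = 0.5
    #: per-site divergence of the out-paralog (and its proteome partner base)
    out_paralog_rate: float = 0.35
    #: extra C-terminal domain length of the extra-domain paralog
    extra_domain_length: int = 120


@dataclass(frozen=True)
class FamilyConfig:
    """Study conditions for one synthetic family."""

    n_species: int = 5
    domain_length: int = 180
    linker_length_range: tuple[int, int] = (15, 60)
    substitution_rate: float = 0.25
    n_decoys: int = 5
    paralogs: ParalogSpec | None = field(default_factory=ParalogSpec)
    family_id: str = "fam0"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_rate <= 0.9):
            raise ValueError("substitution_rate must be in [0, 0.9]")
        if self.domain_length <= 0:
            raise ValueError("domain_length must be positive")
        lo, hi = self.linker_length_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid linker_length_range")
        if self.n_species < 1:
            raise ValueError("need at least one species")


@dataclass
class FamilyTruth:
    """Truth labels for one family; the label sets are disjoint."""

    reference: str
    homologs: set[str] = field(default_factory=set)  # per-species orthologs
    decoys: set[str] = field(default_factory=set)
    paralogs: dict[str, str] = field(default_factory=dict)  # accession -> type
    ortholog_by_species: dict[str, str] = field(default_factory=dict)

    @property
    def expected_members(self) -> set[str]:
        """Accessions an ideal same-architecture homolog search returns.

        The out-paralog shares the domain and the architecture, so it
        belongs here; the truncated and extra-domain paralogs do not.
        """
        out = {acc for acc, kind in self.paralogs.items() if kind == "out-paralog"}
        return {self.reference} | self.homologs | out

    @property
    def expected_orthologs(self) -> set[str]:
        return set(self.homologs)

    def all_labels(self) -> dict[str, str]:
        labels = {self.reference: "reference"}
        labels.update({a: "homolog" for a in self.homologs})
        labels.update({a: "decoy" for a in self.decoys})
        labels.update(self.paralogs)
        return labels


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length, p=BACKGROUND_FREQS))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-site replacement at the given rate, uniform over the 19 others."""
    out = list(seq)
    hit = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hit):
        alternatives = [aa for aa in AMINO_ACIDS if aa != out[i]]
        out[i] = alternatives[rng.integers(19)]
    return "".join(out)


def _rec(accession: str, residues: str, organism: str) -> SequenceRecord:
    # Carry the organism in the description so it survives FASTA round trips.
    return SequenceRecord(accession, residues, f"OS={organism}", organism)


def _with_linkers(rng: np.random.Generator, domain: str,
                  linker_range: tuple[int, int]) -> str:
    lo, hi = linker_range
    n_len = int(rng.integers(lo, hi + 1))
    c_len = int(rng.integers(lo, hi + 1))
    return _random_seq(rng, n_len) + domain + _random_seq(rng, c_len)


def generate_family(
    config: FamilyConfig,
) -> tuple[ProteinDatabase, ProteinDatabase, FamilyTruth, AnnotationTable]:
    """Generate one family: (database, source proteome, truth, annotations).

    The database holds the reference, the per-species homologs, the decoys
    and the in-database paralogs. The source proteome holds the reference,
    the out-paralog's closer partner gene and a few unrelated genes of the
    reference's organism (what RBHB aligns against).
    """
    rng = np.random.default_rng(config.seed)
    fam = config.family_id
    ancestor = _random_seq(rng, config.domain_length)

    records: list[SequenceRecord] = []
    truth = FamilyTruth(reference=f"{fam}_REF")

    ref_seq = _with_linkers(rng, ancestor, config.linker_length_range)
    reference = _rec(f"{fam}_REF", ref_seq, "species0")
    records.append(reference)

    for i in range(1, config.n_species + 1):
        domain = _mutate(rng, ancestor, config.substitution_rate)
        acc = f"{fam}_S{i}"
        records.append(_rec(
            acc, _with_linkers(rng, domain, config.linker_length_range),
            f"species{i}"))
        truth.homologs.add(acc)
        truth.ortholog_by_species[f"species{i}"] = acc

    homolog_lengths = [len(r) for r in records]
    for j in range(1, config.n_decoys + 1):
        length = int(rng.choice(homolog_lengths))
        acc = f"{fam}_D{j}"
        records.append(_rec(acc, _random_seq(rng, length), f"decoyland{j}"))
        truth.decoys.add(acc)

    proteome: list[SequenceRecord] = [reference]
    spec = config.paralogs
    if spec is not None:
        if spec.truncated:
            frag_len = config.domain_length // 2
            start = int(rng.integers(0, config.domain_length - frag_len + 1))
            domain = _mutate(rng, ancestor[start:start + frag_len],
                             config.substitution_rate)
            acc = f"{fam}_PT"
            records.append(_rec(acc, domain, "speciesT"))
            truth.paralogs[acc] = "truncated"
        if spec.extra_domain:
            domain = _mutate(rng, ancestor, spec.extra_domain_rate)
            extra = _random_seq(rng, spec.extra_domain_length)
            body = _with_linkers(rng, domain, config.linker_length_range)
            acc = f"{fam}_PX"
            records.append(_rec(acc, body + extra, "speciesX"))
            truth.paralogs[acc] = "extra-domain"
        if spec.out_paralog:
            out_domain = _mutate(rng, ancestor, spec.out_paralog_rate)
            acc = f"{fam}_PO"
            records.append(_rec(
                acc, _with_linkers(rng, out_domain, config.linker_length_range),
                "speciesO"))
            truth.paralogs[acc] = "out-paralog"
            # The closer partner lives only in the source proteome, so the
            # out-paralog's best reciprocal hit is not the reference.
            partner = _mutate(rng, out_domain, 0.05)
            proteome.append(_rec(
                f"{fam}_PO2",
                _with_linkers(rng, partner, config.linker_length_range),
                "species0"))

    for k in range(3):  # unrelated genes of the reference's organism
        proteome.append(_rec(
            f"{fam}_G{k}", _random_seq(rng, int(rng.choice(homolog_lengths))),
            "species0"))

    annotations = AnnotationTable()
    shared_pfam = f"PF_{fam}"
    shared_kegg = f"path_{fam}"
    for rec in records:
        if rec.accession in truth.expected_members or rec.accession in truth.paralogs:
            go = [(f"GO:{fam}:proc", "IDA" if rng.random() < 0.5 else "IEA")]
            annotations.add(rec.accession, pfam=[shared_pfam],
                            kegg=[shared_kegg], go=go)
        else:
            annotations.add(rec.accession, pfam=[f"PF_bg{rng.integers(5)}"])

    db = ProteinDatabase(records=records, name=fam)
    source = ProteinDatabase(records=proteome, name=f"{fam}_proteome")
    return db, source, truth, annotations


# ---------------------------------------------------------------------------
# Benchmarks
# ---------------------------------------------------------------------------

@dataclass
class Benchmark:
    """A set of families sharing one merged database and source proteome."""

    families: list[tuple[SequenceRecord, FamilyTruth]]  # (reference, truth)
    db: ProteinDatabase
    source_proteome: ProteinDatabase
    annotations: AnnotationTable


def generate_benchmark(
    n_families: int = 20,
    template: FamilyConfig = FamilyConfig(),
    seed: int = 0,
    domain_length_range: tuple[int, int] = (120, 300),
    out_dir: str | Path | None = None,
) -> Benchmark:
    """Generate independent families against one merged database.

    Family domain lengths are spread over ``domain_length_range`` to mimic
    heterogeneous query lengths; each family derives its own child seed
    from the master seed, so truth-set sizes are stable across re-runs.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    master = np.random.default_rng(seed)
    lengths = np.linspace(*domain_length_range, n_families).astype(int)
    all_records: list[SequenceRecord] = []
    proteome_records: list[SequenceRecord] = []
    seen_proteome: set[str] = set()
    families: list[tuple[SequenceRecord, FamilyTruth]] = []
    merged_annot = AnnotationTable()
    for i in range(n_families):
        cfg = replace(
            template,
            family_id=f"fam{i}",
            seed=int(master.integers(2**31 - 1)),
            domain_length=int(lengths[i]),
        )
        db, source, truth, annot = generate_family(cfg)
        all_records.extend(db.records)
        for rec in source:
            if rec.accession not in seen_proteome:
                proteome_records.append(rec)
                seen_proteome.add(rec.accession)
        families.append((db[truth.reference], truth))
        for acc, entry in annot.entries.items():
            merged_annot.add(acc, entry["pfam"], entry["kegg"], entry["go"])

    bench = Benchmark(
        families=families,
        db=ProteinDatabase(records=all_records, name="benchmark"),
        source_proteome=ProteinDatabase(records=proteome_records, name="source"),
        annotations=merged_annot,
    )
    if out_dir is not None:
        _write_benchmark(bench, Path(out_dir))
    return bench


def _write_benchmark(bench: Benchmark, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bench.db, out / "db.fasta")
    write_fasta([ref for ref, _ in bench.families], out / "queries.fasta")
    write_fasta(bench.source_proteome, out / "source_proteome.fasta")
    with open(out / "truth.tsv", "w") as fh:
        for ref, truth in bench.families:
            for acc in sorted(truth.expected_orthologs):
                fh.write(f"{ref.accession}\t{acc}\n")
    with open(out / "truth_members.tsv", "w") as fh:
        for ref, truth in bench.families:
            for acc in sorted(truth.expected_members):
                fh.write(f"{ref.accession}\t{acc}\n")
    write_annotation_tsv(bench.annotations, out / "annotations.tsv")
    manifest = {
        "n_families": len(bench.families),
        "files": ["db.fasta", "queries.fasta", "source_proteome.fasta",
                  "truth.tsv", "truth_members.tsv", "annotations.tsv"],
        "queries": [ref.accession for ref, _ in bench.families],
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
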