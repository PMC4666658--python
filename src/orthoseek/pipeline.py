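"""Orchestration of the homolog/ortholog discovery run.

The run starts from one or more query sequences (the first is the
*reference*; identities and expect values are always reported against it),
finds initial candidates by pairwise local alignment of the reference
against the database, admits them through the identity-curve and length
filters, then iterates: a PSSM built from the reference plus everything
accepted so far is searched against the database to pull in remoter
homologs, filtered the same way, until an iteration adds nothing new (or a
safety cap is reached). Accepted homologs are finally classified as
orthologs by reciprocal best hit: a homolog is orthologous when its best
hit back in the reference's source proteome is the reference itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import seqio
from .align import ScoringScheme, build_pssm, local_align, profile_search
from .filters import FilterDecision, FilterParams, identity_filter, length_filter
from .seqio import AlignmentHit, ProteinDatabase, SequenceRecord, write_fasta

logger = logging.getLogger("orthoseek")


@dataclass(frozen=True)
class SearchParams:
    """Run parameters; defaults are the optimised values (5e-05, m=28, n=33)."""

    evalue_cutoff: float = 5e-05
    filter: FilterParams = field(default_factory=FilterParams)
    max_iterations: int = 10
    engine: str = "internal"  # internal | precomputed-hits
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    hits_files: tuple[str, ...] = ()  # per-iteration outfmt-6 files (precomputed-hits)
    pseudocount_weight: float = 5.0

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.engine not in ("internal", "precomputed-hits"):
            raise ValueError(f"unknown engine {self.engine!r}")


@dataclass
class HomologMember:
    """One accepted homolog with its provenance."""

    record: SequenceRecord
    hit: AlignmentHit  # alignment to the reference (or profile thereof)
    iteration_found: int
    trimmed_range: tuple[int, int] | None = None

    @property
    def effective_length(self) -> int:
        if self.trimmed_range is None:
            return len(self.record)
        lo, hi = self.trimmed_range
        return hi - lo + 1


@dataclass
class HomologResult:
    reference_id: str
    members: list[HomologMember]
    iterations_run: int
    decisions: list[FilterDecision] = field(default_factory=list)

    def accessions(self) -> set[str]:
        return {m.record.accession for m in self.members}


@dataclass
class OrthologResult:
    members: list[HomologMember]
    reciprocity_evidence: dict[str, str] = field(default_factory=dict)

    def accessions(self) -> set[str]:
        return {m.record.accession for m in self.members}


def _passes_cutoff(hits, cutoff):
    return [h for h in hits if h.evalue <= cutoff]


def find_homologs(
    queries: list[SequenceRecord],
    db: ProteinDatabase,
    params: SearchParams = SearchParams(),
) -> HomologResult:
    """Iterative homolog search (see module docstring).

    Iteration 0 aligns the reference pairwise against every database
    sequence; iterations >= 1 search a PSSM built from the reference and
    all accepted members. Each iteration applies the expect-value cutoff,
    the identity-curve filter and the length filter, and accepts only new
    accessions. Queries present in the database are always members.
    """
    if not queries:
        raise ValueError("need at least one query sequence")
    if len(db) == 0:
        raise ValueError("empty database")
    reference = queries[0]

    members: dict[str, HomologMember] = {}
    decisions: list[FilterDecision] = []
    # Extra queries align to the reference to seed the first profile, per
    # the multiple-homologous-queries input mode.
    seed_hits: list[AlignmentHit] = []
    for q in queries[1:]:
        h = local_align(reference, q, params.scheme, db.total_residues)
        if h is not None:
            seed_hits.append(h)

    accepted_lengths = [len(q) for q in queries]

    def admit(candidates: list[AlignmentHit], iteration: int) -> int:
        """Filter candidate hits and add survivors; returns number added."""
        fresh = [
            h for h in candidates
            if h.subject_id not in members and h.subject_id in db
        ]
        fresh = _passes_cutoff(fresh, params.evalue_cutoff)
        kept_i, dec_i = identity_filter(fresh, params.filter)
        decisions.extend(dec_i)
        with_recs = [(db[h.subject_id], h) for h in kept_i]
        kept_l, dec_l = length_filter(with_recs, accepted_lengths, params.filter)
        decisions.extend(dec_l)
        added = 0
        for rec, hit, trimmed in kept_l:
            members[rec.accession] = HomologMember(rec, hit, iteration, trimmed)
            accepted_lengths.append(
                members[rec.accession].effective_length
            )
            added += 1
        return added

    # Queries that are themselves database entries are members by definition.
    for q in queries:
        if q.accession in db:
            self_hit = local_align(reference, db[q.accession], params.scheme,
                                   db.total_residues)
            if self_hit is None:  # no positive-scoring pair at all
                self_hit = AlignmentHit(
                    query_id=reference.accession, subject_id=q.accession,
                    identity_pct=0.0, aln_length=max(len(q), 1),
                    q_start=1, q_end=1, s_start=1, s_end=1,
                    raw_score=0.0, bit_score=0.0, evalue=1.0,
                )
            members[q.accession] = HomologMember(db[q.accession], self_hit, 0)

    iterations_run = 0
    if params.engine == "precomputed-hits":
        for iteration, path in enumerate(params.hits_files):
            added = admit(seqio.read_hits_tab(path), iteration)
            iterations_run = iteration
            if iteration > 0 and added == 0:
                break
        return HomologResult(reference.accession, list(members.values()),
                             iterations_run, decisions)

    # Iteration 0: pairwise search with the reference.
    initial = []
    for rec in db:
        h = local_align(reference, rec, params.scheme, db.total_residues)
        if h is not None:
            initial.append(h)
    admit(initial, 0)

    # Iterations >= 1: profile search with the growing accepted set.
    for iteration in range(1, params.max_iterations + 1):
        profile_input = seed_hits + [
            m.hit for m in members.values()
            if m.hit.aligned_query and m.record.accession != reference.accession
        ]
        pssm = build_pssm(reference, profile_input, params.pseudocount_weight,
                          scheme=params.scheme)
        hits = profile_search(pssm, db, params.scheme)
        added = admit(hits, iteration)
        iterations_run = iteration
        if added == 0:
            break
    else:
        logger.info("iteration cap (%d) reached", params.max_iterations)

    return HomologResult(reference.accession, list(members.values()),
                         iterations_run, decisions)


def classify_orthologs(
    hres: HomologResult,
    source_proteome: ProteinDatabase,
    params: SearchParams = SearchParams(),
) -> OrthologResult:
    """Reciprocal-best-hit classification against the reference's proteome.

    Each homolog (except the reference itself) is aligned against every
    sequence of the source proteome; it is an ortholog exactly when its
    best hit — highest bit score, ties broken by lower expect value, higher
    identity, then accession — is the reference.
    """
    if hres.reference_id not in source_proteome:
        raise ValueError(
            f"reference {hres.reference_id!r} not found in the source proteome"
        )
    members: list[HomologMember] = []
    evidence: dict[str, str] = {}
    for m in hres.members:
        if m.record.accession == hres.reference_id:
            continue
        best: tuple | None = None
        best_id: str | None = None
        for target in source_proteome:
            h = local_align(m.record, target, params.scheme,
                            source_proteome.total_residues)
            if h is None:
                continue
            key = (-h.bit_score, h.evalue, -h.identity_pct, target.accession)
            if best is None or key < best:
                best = key
                best_id = target.accession
        if best_id is None:
            continue
        evidence[m.record.accession] = best_id
        if best_id == hres.reference_id:
            members.append(m)
    return OrthologResult(members, evidence)


# ---------------------------------------------------------------------------
# Run-directory output
# ---------------------------------------------------------------------------

_TSV_HEADER = "accession\torganism\tlength\tidentity_to_reference\tevalue\titeration_found\ttrimmed_range\n"


def _members_tsv(members: list[HomologMember], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        for m in sorted(members, key=lambda m: (m.iteration_found, m.record.accession)):
            trange = "-" if m.trimmed_range is None else f"{m.trimmed_range[0]}..{m.trimmed_range[1]}"
            fh.write(
                f"{m.record.accession}\t{m.record.organism}\t{len(m.record)}\t"
                f"{m.hit.identity_pct:.2f}\t{m.hit.evalue:.3g}\t"
                f"{m.iteration_found}\t{trange}\n"
            )


def write_run_outputs(
    out_dir: str | Path,
    hres: HomologResult,
    ores: OrthologResult | None,
    params: SearchParams,
    annotation_summary=None,
) -> None:
    """Write the standard run directory (TSVs, FASTAs, audit trail, config)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _members_tsv(hres.members, out / "homologs.tsv")
    if hres.members:
        write_fasta([m.record for m in sorted(
            hres.members, key=lambda m: (m.iteration_found, m.record.accession))],
            out / "homologs.fasta")
    if ores is not None:
        _members_tsv(ores.members, out / "orthologs.tsv")
        if ores.members:
            write_fasta([m.record for m in sorted(
                ores.members, key=lambda m: (m.iteration_found, m.record.accession))],
                out / "orthologs.fasta")
    with open(out / "filter_decisions.tsv", "w") as fh:
        fh.write("candidate_id\tkept\treason\ttrimmed_range\n")
        for d in hres.decisions:
            trange = "-" if d.trimmed_range is None else f"{d.trimmed_range[0]}..{d.trimmed_range[1]}"
            fh.write(f"{d.candidate_id}\t{str(d.kept).lower()}\t{d.reason}\t{trange}\n")
    if annotation_summary is not None:
        from .annot import write_summary_tsv
        write_summary_tsv(annotation_summary, out / "annotation_summary.tsv")
    config = {
        "evalue_cutoff": params.evalue_cutoff,
        "rost_n": params.filter.rost_n,
        "min_domain_len": params.filter.min_domain_len,
        "decay_constant": params.filter.decay_constant,
        "max_iterations": params.max_iterations,
        "engine": params.engine,
        "matrix": params.scheme.matrix_name,
        "gap_open": params.scheme.gap_open,
        "gap_extend": params.scheme.gap_extend,
    }
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    with open(out / "run.log", "a") as fh:
        fh.write(
            f"reference={hres.reference_id} members={len(hres.members)} "
            f"iterations={hres.iterations_run}"
            + (f" orthologs={len(ores.members)}" if ores is not None else "")
            + "\n"
        )
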