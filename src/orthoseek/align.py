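"""Local-alignment search engine.

Affine-gap Smith–Waterman with substitution matrices, a Karlin–Altschul
expect-value estimate, position-specific scoring matrices (PSSMs) built from
accepted homologs, and profile search of a PSSM against a database. The
engine stands in for BLAST/PSI-BLAST at desk scale; precomputed BLAST
tabular output can be ingested instead through :mod:`orthoseek.seqio`.

Gap cost model: a gap of length k costs ``gap_open + (k-1)*gap_extend``
(so ``gap_open == gap_extend`` gives linear gaps). Traceback is fully
deterministic: the highest-scoring cell with the smallest (row, column)
index starts the trace, and ties between moves prefer diagonal over up
(gap in subject) over left (gap in query); within a gap state, closing the
gap is preferred over extending it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import AMINO_ACIDS, AlignmentHit, ProteinDatabase, SequenceRecord

_NEG_INF = -1e30

#: residue -> index over the 20 standard amino acids plus X (index 20)
_ALPHA = AMINO_ACIDS + "X"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHA)}


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin–Altschul constants.

    Defaults are standard protein-search settings (BLOSUM62, 11/1 gaps);
    K and lambda are ungapped-style estimates applied uniformly, which is an
    approximation — only relative hit ordering and a cutoff matter here.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_K: float = 0.041
    karlin_lambda: float = 0.267

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")
        if self.karlin_lambda <= 0 or self.karlin_K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    @property
    def matrix(self) -> np.ndarray:
        return load_matrix(self.matrix_name)


@lru_cache(maxsize=8)
def load_matrix(name: str) -> np.ndarray:
    """Return a 21x21 substitution matrix over AMINO_ACIDS + X.

    X scores 0 against everything (real proteomes contain X, and an
    ambiguous residue should neither reward nor penalise an alignment).
    """
    src = substitution_matrices.load(name)
    mat = np.zeros((21, 21))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            mat[i, j] = src[a, b]
    return mat


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as indices into the 21-letter alphabet."""
    return np.array([_AA_INDEX[aa] for aa in residues], dtype=np.intp)


# ---------------------------------------------------------------------------
# Core dynamic programming
# ---------------------------------------------------------------------------

def _sw_matrices(scores: np.ndarray, gap_open: float, gap_extend: float):
    """Fill the three affine-gap Smith–Waterman matrices.

    ``scores[i, j]`` is the substitution (or profile) score for pairing
    query position i with subject position j. Rows are vectorised; the
    within-row horizontal-gap recurrence is solved with a running maximum,
    which is exact whenever gap_open >= gap_extend (openings out of a
    horizontal-gap state are then dominated by extensions).
    """
    # Quantise to a 1/64 grid (PSI-BLAST-style scaled scores). All DP values
    # are then exact dyadic rationals, so the vectorised fill and the
    # traceback's equality checks agree bit-for-bit.
    scores = np.round(np.asarray(scores, dtype=float) * 64.0) / 64.0
    gap_open = round(gap_open * 64.0) / 64.0
    gap_extend = round(gap_extend * 64.0) / 64.0
    m, n = scores.shape
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), _NEG_INF)  # gap in query (left moves)
    F = np.full((m + 1, n + 1), _NEG_INF)  # gap in subject (up moves)
    if n == 0 or m == 0:
        return H, E, F
    ext_ramp = np.arange(n + 1) * gap_extend
    for i in range(1, m + 1):
        F[i, 1:] = np.maximum(H[i - 1, 1:] - gap_open, F[i - 1, 1:] - gap_extend)
        diag = H[i - 1, :-1] + scores[i - 1, :]
        h_ne = np.maximum(np.maximum(diag, F[i, 1:]), 0.0)
        # E[i, j] = max_{k<j} (h_ne[k] - gap_open - (j-1-k) * gap_extend)
        run = np.maximum.accumulate(np.concatenate(([0.0], h_ne[:-1])) + ext_ramp[:-1])
        E[i, 1:] = run - gap_open - ext_ramp[:-1]
        H[i, 1:] = np.maximum(h_ne, E[i, 1:])
    return H, E, F


def _traceback(H, E, F, scores, gap_open, gap_extend, q_sym, s_sym):
    """Recover the optimal local alignment with deterministic tie-breaking."""
    m, n = scores.shape
    flat = int(np.argmax(H))  # row-major: smallest i then smallest j on ties
    i, j = divmod(flat, n + 1)
    best = H[i, j]
    if best <= 0:
        return None
    q_end, s_end = i, j
    aq: list[str] = []
    asub: list[str] = []
    state = "H"
    while True:
        if state == "H":
            v = H[i, j]
            if v == 0:
                break
            if i > 0 and j > 0 and v == H[i - 1, j - 1] + scores[i - 1, j - 1]:
                aq.append(q_sym[i - 1])
                asub.append(s_sym[j - 1])
                i, j = i - 1, j - 1
            elif v == F[i, j]:
                state = "F"
            elif v == E[i, j]:
                state = "E"
            else:  # pragma: no cover - forward/backward mismatch
                raise AssertionError("inconsistent traceback")
        elif state == "F":
            aq.append(q_sym[i - 1])
            asub.append("-")
            if F[i, j] == H[i - 1, j] - gap_open:
                state = "H"
            i -= 1
        else:  # state == "E"
            aq.append("-")
            asub.append(s_sym[j - 1])
            if E[i, j] == H[i, j - 1] - gap_open:
                state = "H"
            j -= 1
    aligned_q = "".join(reversed(aq))
    aligned_s = "".join(reversed(asub))
    return best, i + 1, q_end, j + 1, s_end, aligned_q, aligned_s


def _sw_align(scores, gap_open, gap_extend, q_sym, s_sym):
    """Quantise, fill and trace one local alignment (None if score <= 0)."""
    scores = np.round(np.asarray(scores, dtype=float) * 64.0) / 64.0
    gap_open = round(gap_open * 64.0) / 64.0
    gap_extend = round(gap_extend * 64.0) / 64.0
    H, E, F = _sw_matrices(scores, gap_open, gap_extend)
    return _traceback(H, E, F, scores, gap_open, gap_extend, q_sym, s_sym)


def _count_identities(aligned_q: str, aligned_s: str) -> int:
    return sum(1 for a, b in zip(aligned_q, aligned_s) if a == b and a != "-")


def _make_hit(query_id, subject_id, res, scheme, query_len, db_residues) -> AlignmentHit:
    raw, q_start, q_end, s_start, s_end, aq, asub = res
    ident = _count_identities(aq, asub)
    length = len(aq)
    gapopen = 0
    prev_gap = False
    for a, b in zip(aq, asub):
        gap = a == "-" or b == "-"
        if gap and not prev_gap:
            gapopen += 1
        prev_gap = gap
    evalue = estimate_evalue(raw, query_len, db_residues, scheme)
    bit = _bit_score(raw, scheme)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        identity_pct=100.0 * ident / length,
        aln_length=length,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        raw_score=float(raw),
        bit_score=bit,
        evalue=evalue,
        aligned_query=aq,
        aligned_subject=asub,
        mismatch=sum(
            1 for a, b in zip(aq, asub) if a != "-" and b != "-" and a != b
        ),
        gapopen=gapopen,
    )


DEFAULT_SCHEME = ScoringScheme()


def _bit_score(raw: float, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    return (scheme.karlin_lambda * raw - math.log(scheme.karlin_K)) / math.log(2)


def local_align(
    query: SequenceRecord,
    subject: SequenceRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    db_residues: int | None = None,
) -> AlignmentHit | None:
    """Optimal affine-gap Smith–Waterman local alignment, or None if score <= 0.

    ``db_residues`` sets the search-space size n for the expect value
    (defaults to the subject length when aligning a single pair).
    """
    mat = scheme.matrix
    qi = encode(query.residues)
    si = encode(subject.residues)
    scores = mat[np.ix_(qi, si)]
    res = _sw_align(scores, scheme.gap_open, scheme.gap_extend,
                    query.residues, subject.residues)
    if res is None:
        return None
    return _make_hit(query.accession, subject.accession, res, scheme,
                     len(query), db_residues or len(subject))


def percent_identity(hit: AlignmentHit) -> float:
    """Percent identical columns; gap columns count in the denominator only."""
    if hit.aln_length == 0:
        raise ValueError("alignment of length 0 has no identity")
    if hit.aligned_query:
        return 100.0 * _count_identities(hit.aligned_query, hit.aligned_subject) / hit.aln_length
    return hit.identity_pct


def estimate_evalue(
    raw_score: float,
    query_len: int,
    db_residues: int,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> float:
    """Karlin–Altschul expect value E = K * m * n * exp(-lambda * S).

    Non-positive scores return the cap E = K * m * n (the expected count of
    zero-score alignments is not meaningful beyond "many").
    """
    if query_len <= 0 or db_residues <= 0:
        raise ValueError("lengths must be positive")
    kmn = scheme.karlin_K * query_len * db_residues
    if raw_score <= 0:
        return kmn
    return kmn * math.exp(-scheme.karlin_lambda * raw_score)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

#: Robinson & Robinson style background frequencies over AMINO_ACIDS order.
BACKGROUND_FREQS = np.array([
    0.0787, 0.0151, 0.0535, 0.0668, 0.0397, 0.0696, 0.0220, 0.0590, 0.0596,
    0.0964, 0.0241, 0.0414, 0.0484, 0.0395, 0.0516, 0.0677, 0.0541, 0.0673,
    0.0113, 0.0341,
])
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()


@dataclass
class PSSM:
    """Position-specific scoring matrix in bits, one column per reference residue."""

    columns: np.ndarray  # shape (consensus_length, 20)
    consensus: str
    source_ids: list[str] = field(default_factory=list)

    @property
    def consensus_length(self) -> int:
        return len(self.consensus)

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.shape != (len(self.consensus), 20):
            raise ValueError("PSSM needs one 20-score column per consensus residue")
        if not np.all(np.isfinite(self.columns)):
            raise ValueError("PSSM scores must be finite")


def build_pssm(
    reference: SequenceRecord,
    homolog_hits: list[AlignmentHit],
    pseudocount_weight: float = 5.0,
    background: np.ndarray = BACKGROUND_FREQS,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> PSSM:
    """Build a log-odds PSSM from hits aligned to the reference.

    Column score for residue a is ``log2(((c_a + beta*p_a) / (N + beta)) / p_a)``
    with counts taken from hit subject residues aligned to that reference
    position, the reference residue included. Columns no hit covers fall
    back to the substitution-matrix row of the reference residue rescaled
    to bits; hit gap columns contribute nothing.
    """
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or not math.isclose(background.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background must be 20 frequencies summing to 1")
    beta = float(pseudocount_weight)
    if beta < 0:
        raise ValueError("pseudocount_weight must be >= 0")

    L = len(reference)
    counts = np.zeros((L, 20))
    covered = np.zeros(L, dtype=bool)
    for hit in homolog_hits:
        if not hit.aligned_query:
            raise ValueError(f"hit {hit.subject_id} carries no aligned strings")
        pos = hit.q_start - 1  # 0-based reference position of next query column
        for qa, sa in zip(hit.aligned_query, hit.aligned_subject):
            if qa != "-":
                if sa != "-" and sa != "X":
                    counts[pos, _AA_INDEX[sa]] += 1
                    covered[pos] = True
                pos += 1
        if pos != hit.q_end:
            raise ValueError(
                f"hit {hit.subject_id} does not align the reference "
                f"({hit.q_start}..{hit.q_end} vs {pos} columns walked)"
            )

    mat = scheme.matrix
    bits_per_unit = scheme.karlin_lambda / math.log(2)
    cols = np.empty((L, 20))
    for i, ref_aa in enumerate(reference.residues):
        if not covered[i]:
            cols[i] = mat[_AA_INDEX[ref_aa], :20] * bits_per_unit
            continue
        c = counts[i].copy()
        if ref_aa != "X":
            c[_AA_INDEX[ref_aa]] += 1
        n_col = c.sum()
        if beta == 0 and np.any(c == 0):
            raise ValueError(
                "pseudocount_weight=0 with unobserved residues yields -inf; use beta > 0"
            )
        freqs = (c + beta * background) / (n_col + beta)
        cols[i] = np.log2(freqs / background)
    return PSSM(columns=cols, consensus=reference.residues,
                source_ids=[reference.accession] + [h.subject_id for h in homolog_hits])


def profile_search(
    pssm: PSSM,
    db: ProteinDatabase,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[AlignmentHit]:
    """Smith–Waterman of a profile against every database sequence.

    Profile scores are in bits, so the expect value uses the bit-score
    form E = K * m * n * 2**(-S). Hits are sorted by ascending expect
    value (ties by accession) and carry the profile consensus as the
    aligned query, so identity is identity to the reference.
    """
    n_space = db.total_residues
    hits: list[AlignmentHit] = []
    ref_id = pssm.source_ids[0] if pssm.source_ids else "profile"
    for rec in db:
        si = encode(rec.residues)
        scores = np.where(si[None, :] < 20, pssm.columns[:, np.minimum(si, 19)], 0.0)
        res = _sw_align(scores, scheme.gap_open, scheme.gap_extend,
                        pssm.consensus, rec.residues)
        if res is None:
            continue
        raw, q_start, q_end, s_start, s_end, aq, asub = res
        ident = _count_identities(aq, asub)
        evalue = scheme.karlin_K * pssm.consensus_length * n_space * 2.0 ** (-raw)
        hits.append(AlignmentHit(
            query_id=ref_id,
            subject_id=rec.accession,
            identity_pct=100.0 * ident / len(aq),
            aln_length=len(aq),
            q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
            raw_score=float(raw), bit_score=float(raw), evalue=evalue,
            aligned_query=aq, aligned_subject=asub,
        ))
    hits.sort(key=lambda h: (h.evalue, h.subject_id))
    return hits
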