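"""Admission filters applied to candidate homologs.

Two filters gate every candidate before it joins the homolog set:

1. An identity/length threshold curve (Rost's twilight-zone curve): a hit
   of alignment length L is kept only when its percent identity reaches
   ``pI(L) = n + 480 * L**(-0.32 * (1 + exp(-L / decay)))``, where ``n`` is
   an additive stringency offset. With ``n = 0`` the curve levels off near
   20% identity for long alignments; the optimised default ``n = 33``
   raises the floor to about 53%.

2. A length filter that uses whole-protein length as a proxy for domain
   architecture: candidates shorter than the shortest accepted homolog by
   more than the minimal domain length ``m`` are assumed to lack a domain
   and are removed; candidates longer than the longest accepted homolog by
   more than ``m`` are assumed to carry an extra domain, which is trimmed
   away (unaligned terminal overhangs only, recorded as a retained range,
   never mutating the database).

Defaults are the optimised parameter values: ``n = 33``, ``m = 28``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .seqio import AlignmentHit, SequenceRecord

#: Exponential decay length of the identity curve. 1000 reproduces the
#: curve's documented ~20% long-alignment floor (and hence the 53% minimal
#: identity at n=33); 100 is a commonly reprinted variant, selectable.
DEFAULT_DECAY = 1000.0


@dataclass(frozen=True)
class FilterParams:
    """Tunable filter settings: stringency offset n, minimal domain length m."""

    rost_n: float = 33.0
    min_domain_len: int = 28
    decay_constant: float = DEFAULT_DECAY

    def __post_init__(self) -> None:
        if self.rost_n < 0:
            raise ValueError("rost_n must be non-negative")
        if self.min_domain_len < 0:
            raise ValueError("min_domain_len must be non-negative")
        if self.decay_constant <= 0:
            raise ValueError("decay_constant must be positive")


@dataclass(frozen=True)
class FilterDecision:
    """Audit record for one candidate: kept or not, and why."""

    candidate_id: str
    kept: bool
    reason: str  # below-rost-curve | too-short | kept | kept-trimmed
    trimmed_range: tuple[int, int] | None = None  # 1-based inclusive, subject coords

    def __post_init__(self) -> None:
        if (self.reason == "kept-trimmed") != (self.trimmed_range is not None):
            raise ValueError("trimmed_range present iff reason == kept-trimmed")


def rost_threshold(L: float, n: float = 0.0, decay: float = DEFAULT_DECAY) -> float:
    """Identity threshold (percent) for an alignment of L columns.

    May exceed 100 for very short alignments, in which case nothing of that
    length can pass. Raises for L < 1.
    """
    if L < 1:
        raise ValueError("alignment length must be >= 1")
    return n + 480.0 * L ** (-0.32 * (1.0 + math.exp(-L / decay)))


def identity_filter(
    hits: list[AlignmentHit],
    params: FilterParams = FilterParams(),
) -> tuple[list[AlignmentHit], list[FilterDecision]]:
    """Keep hits whose identity reaches the curve threshold at their length."""
    kept: list[AlignmentHit] = []
    decisions: list[FilterDecision] = []
    for hit in hits:
        threshold = rost_threshold(hit.aln_length, params.rost_n, params.decay_constant)
        if hit.identity_pct >= threshold:
            kept.append(hit)
            decisions.append(FilterDecision(hit.subject_id, True, "kept"))
        else:
            decisions.append(FilterDecision(hit.subject_id, False, "below-rost-curve"))
    return kept, decisions


def _trim_overhangs(
    length: int, s_start: int, s_end: int, max_len: int
) -> tuple[int, int]:
    """Drop unaligned terminal overhangs, longest first, until <= max_len.

    Returns the retained 1-based inclusive range. Aligned residues
    (s_start..s_end) are never removed.
    """
    lo, hi = 1, length
    while hi - lo + 1 > max_len:
        left = s_start - lo  # unaligned residues on the N side
        right = hi - s_end  # unaligned residues on the C side
        if left <= 0 and right <= 0:
            break
        excess = (hi - lo + 1) - max_len
        if left >= right:
            lo += min(left, excess)
        else:
            hi -= min(right, excess)
    return lo, hi


def length_filter(
    candidates: list[tuple[SequenceRecord, AlignmentHit]],
    accepted_lengths: list[int],
    params: FilterParams = FilterParams(),
) -> tuple[list[tuple[SequenceRecord, AlignmentHit, tuple[int, int] | None]], list[FilterDecision]]:
    """Apply the domain-architecture length band [S - m, G + m].

    S and G are the shortest and longest lengths in the current homolog set
    (the query lengths on the first iteration). A candidate of length
    <= S - m is removed; one longer than G + m is kept but trimmed.
    """
    if not accepted_lengths:
        raise ValueError("accepted_lengths must be non-empty")
    if params.min_domain_len == 0:
        # m = 0 switches the length filter off (no domain-length proxy).
        kept0 = [(rec, hit, None) for rec, hit in candidates]
        dec0 = [FilterDecision(rec.accession, True, "kept") for rec, _ in candidates]
        return kept0, dec0
    s_min = min(accepted_lengths)
    g_max = max(accepted_lengths)
    m = params.min_domain_len
    kept: list[tuple[SequenceRecord, AlignmentHit, tuple[int, int] | None]] = []
    decisions: list[FilterDecision] = []
    for rec, hit in candidates:
        length = len(rec)
        if length <= s_min - m:
            decisions.append(FilterDecision(rec.accession, False, "too-short"))
            continue
        if length > g_max + m:
            lo, hi = _trim_overhangs(length, hit.s_start, hit.s_end, g_max + m)
            if (lo, hi) != (1, length):
                kept.append((rec, hit, (lo, hi)))
                decisions.append(
                    FilterDecision(rec.accession, True, "kept-trimmed", (lo, hi))
                )
                continue
        kept.append((rec, hit, None))
        decisions.append(FilterDecision(rec.accession, True, "kept"))
    return kept, decisions
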