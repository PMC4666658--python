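"""Accuracy bookkeeping and parameter optimisation.

Predictions and truth are sets of accessions. A prediction in the truth
set is a true positive (TP), one outside it a false positive (FP), and a
truth item never predicted a false negative (FN). Derived statistics:

* sensitivity  Sn = TP / (TP + FN)
* specificity  Sp = TP / (TP + FP)
* REQ (Relative Error Quotient) = (FN + FP) / (2 * TP)

REQ folds both error kinds into one number; lower is better, and it is
undefined when TP = 0.

The optimiser tunes the three search parameters coordinate-wise, in a
fixed order — expect-value cutoff first (with both filters neutralised:
m = 0, n = 0), then the minimal domain length m, then the identity
offset n — each stage picking the grid value with the
lowest REQ pooled (micro-averaged) over the benchmark, ties going to the
more stringent value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

from .pipeline import SearchParams, find_homologs
from .seqio import ProteinDatabase, SequenceRecord


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class AccuracyReport:
    counts: EvalCounts
    sensitivity: float
    specificity: float
    req: float | None  # None when undefined (tp == 0)


def confusion_counts(predicted: Iterable[str], truth: Iterable[str]) -> EvalCounts:
    """TP/FP/FN from predicted and true accession sets."""
    predicted = set(predicted)
    truth = set(truth)
    return EvalCounts(
        tp=len(predicted & truth),
        fp=len(predicted - truth),
        fn=len(truth - predicted),
    )


def evaluate(counts: EvalCounts) -> AccuracyReport:
    """Sensitivity, specificity and REQ from a count triple.

    Requires at least one truth item and one prediction; REQ is reported
    as None (undefined) when there are no true positives.
    """
    if counts.tp + counts.fn == 0:
        raise ValueError("no truth items: sensitivity undefined")
    if counts.tp + counts.fp == 0:
        raise ValueError("no predictions: specificity undefined")
    sn = counts.tp / (counts.tp + counts.fn)
    sp = counts.tp / (counts.tp + counts.fp)
    req = None if counts.tp == 0 else (counts.fn + counts.fp) / (2 * counts.tp)
    return AccuracyReport(counts, sn, sp, req)


# ---------------------------------------------------------------------------
# Parameter optimisation
# ---------------------------------------------------------------------------

BenchmarkItem = tuple[list[SequenceRecord], ProteinDatabase, set[str]]


def pooled_counts(
    benchmark: Sequence[BenchmarkItem],
    params: SearchParams,
    runner: Callable[[BenchmarkItem, SearchParams], set[str]] | None = None,
) -> EvalCounts:
    """Sum confusion counts over benchmark items (micro-averaging)."""
    total = EvalCounts(0, 0, 0)
    for item in benchmark:
        if runner is not None:
            predicted = runner(item, params)
        else:
            queries, db, _ = item
            predicted = find_homologs(queries, db, params).accessions()
        total = total + confusion_counts(predicted, item[2])
    return total


def _pooled_req(counts: EvalCounts) -> float | None:
    if counts.tp == 0:
        return None
    return (counts.fn + counts.fp) / (2 * counts.tp)


@dataclass
class OptimizationTrace:
    """REQ measured at every visited grid point, stage by stage."""

    stages: list[dict]  # {"parameter": str, "values": [...], "req": [...], "chosen": value}


def optimize_parameters(
    benchmark: Sequence[BenchmarkItem],
    evalue_grid: Sequence[float],
    m_grid: Sequence[int],
    n_grid: Sequence[float],
    base_params: SearchParams | None = None,
    runner: Callable[[BenchmarkItem, SearchParams], set[str]] | None = None,
) -> tuple[SearchParams, OptimizationTrace]:
    """Coordinate-wise grid optimisation of (e-value cutoff, m, n).

    Stage 1 scans the e-value grid with m = 0 (length filter off) and
    n = 0 (bare identity curve); stage 2 fixes the winning e-value and
    scans m (still at n = 0); stage 3 scans n. Each stage minimises pooled REQ;
    ties prefer the more stringent setting (smaller e-value, larger m,
    larger n). Raises if every grid value of a stage leaves REQ undefined.
    """
    if not (evalue_grid and m_grid and n_grid):
        raise ValueError("all three grids must be non-empty")
    base = base_params or SearchParams()

    def with_values(ev: float, m: int, n: float) -> SearchParams:
        return replace(
            base,
            evalue_cutoff=ev,
            filter=replace(base.filter, min_domain_len=m, rost_n=n),
        )

    trace = OptimizationTrace(stages=[])

    def sweep(name, values, make_params, prefer_key):
        reqs = []
        best_val, best_req = None, None
        for v in values:
            counts = pooled_counts(benchmark, make_params(v), runner)
            req = _pooled_req(counts)
            reqs.append(req)
            if req is None:
                continue
            if (
                best_req is None
                or req < best_req
                or (req == best_req and prefer_key(v) < prefer_key(best_val))
            ):
                best_val, best_req = v, req
        if best_val is None:
            raise ValueError(f"REQ undefined over the whole {name} grid (tp=0 everywhere)")
        trace.stages.append(
            {"parameter": name, "values": list(values), "req": reqs, "chosen": best_val}
        )
        return best_val

    # Stage 1 runs with both filters neutralised (m=0 disables the length
    # filter, n=0 leaves the bare identity curve).
    best_ev = sweep("evalue", sorted(evalue_grid),
                    lambda ev: with_values(ev, 0, 0.0),
                    prefer_key=lambda v: v)
    best_m = sweep("m", sorted(m_grid),
                   lambda m: with_values(best_ev, m, 0.0),
                   prefer_key=lambda v: -v)
    best_n = sweep("n", sorted(n_grid),
                   lambda n: with_values(best_ev, best_m, n),
                   prefer_key=lambda v: -v)
    return with_values(best_ev, best_m, best_n), trace
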