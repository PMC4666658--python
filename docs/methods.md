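# Methods

This document records the model implemented by `orthoseek`, the default
parameters and why they are what they are, the numerical choices that
make the pipeline deterministic, and the limits of what the shipped
benchmark demonstrates.

## Model

### Local alignment

Pairwise search is Smith–Waterman with affine gaps: a gap of length k
costs `gap_open + (k - 1) * gap_extend`, so setting open = extend gives
a linear gap penalty. The default scoring scheme is BLOSUM62 with
open 11 / extend 1. The alphabet is the 20 standard residues plus `X`,
which scores 0 against everything (unknown residues neither help nor
hurt).

Expect values follow Karlin–Altschul statistics,
`E = K * m * n * exp(-lambda * S)` with the standard gapped BLOSUM62
11/1 constants K = 0.041 and lambda = 0.267, where m is the query length
and n the total residue count of the database. Non-positive scores are
capped at `E = K * m * n`.

### Profile search

From iteration 1 on, the pipeline searches with a position-specific
scoring matrix (PSSM) built over the reference sequence. The column
score for residue a is

    log2( ((c_a + beta * p_a) / (N + beta)) / p_a )

with counts c taken from hit residues aligned to that reference
position (the reference residue included), background frequencies p
(Robinson-style composition), and pseudocount weight beta (default 5).
Columns no hit covers fall back to the reference residue's
substitution-matrix row rescaled to bits; gap columns in hits contribute
nothing; `X` is excluded from counts. Profile scores are already in
bits, so `E = K * m * n * 2**(-S)`.

### Admission filters

**Identity curve.** A hit of alignment length L is kept only if its
percent identity exceeds

    p(L) = n + 480 * L**(-0.32 * (1 + exp(-L / d)))

the classical twilight-zone threshold with additive offset n. The
default decay length is d = 1000: with that value the curve has the
properties usually quoted for it — it levels off near 20% identity for
long alignments at n = 0, and near 53% at the default n = 33. With
d = 100 the exponential term dies away within ~300 residues and the
long-length floor sits far lower, which contradicts those quoted
anchors; d = 100 remains selectable (`decay_constant`) for anyone who
wants the literal short-decay variant. Identity counts identical
columns over all alignment columns (gap columns in the denominator).

**Length filter.** Identical domain architecture is proxied by sequence
length. Let S and G be the shortest and longest *effective* length
among the queries and everything accepted so far, and m the minimal
domain length (default 28):

* candidates with length <= S - m are rejected (`too-short`);
* candidates with length > G + m are trimmed: unaligned overhangs are
  removed longest-first until the retained span fits G + m, but aligned
  residues are never removed (`kept-trimmed`, with the retained 1-based
  range recorded);
* everything else is kept unchanged.

`m = 0` disables the filter entirely. This is the natural reading of a
zero-slack setting and is what the optimiser's first stage uses to
neutralise the filter (see below); it also means "reject candidates
shorter than S" is not expressible, which in practice only matters for
pathological length ties.

### Iteration

Iteration 0 aligns the reference pairwise against every database
sequence; each later iteration builds the PSSM from the reference plus
all accepted members (plus any extra input queries aligned to the
reference) and searches it against the database. Every iteration applies
the e-value cutoff, the identity curve and the length filter, in that
order, to hits whose subject is not yet a member. The loop stops when an
iteration adds nothing, or after `max_iterations` (default 10) profile
passes. Queries that are themselves database entries are members by
definition. `iterations_run` is the index of the last iteration
executed, so a database equal to the query set reports 1 (one profile
pass that added nothing).

### Orthology (RBHB)

Each accepted homolog is aligned against every sequence of the
reference's source proteome. Its best hit is chosen by highest bit
score, with ties broken by lower expect value, then higher identity,
then lexicographic accession. The homolog is an ortholog exactly when
that best hit is the reference.

## Accuracy metrics and optimisation

With predictions and truth as accession sets: Sn = TP/(TP+FN),
Sp = TP/(TP+FP), REQ = (FN+FP)/(2*TP). REQ is undefined at TP = 0 and is
reported as such rather than coerced.

`optimize_parameters` tunes (e-value cutoff, m, n) coordinate-wise: the
e-value grid is scanned first with both filters neutralised (m = 0,
n = 0), then m at n = 0, then n — each stage minimising REQ pooled
(micro-averaged) over all benchmark families, with ties resolved toward
the more stringent value (smaller cutoff, larger m, larger n). The
shipped defaults (5e-05, m = 28, n = 33) are the optimised operating
point.

## Synthetic benchmark

The generator (`orthoseek.simdata`) plants families with known truth:
per-species homologs are the ancestral domain mutated at a per-site rate
(default 0.25; uniform choice among the other 19 residues, no indels, so
expected identity to the ancestor is exactly 1 - rate) inside fresh
random linkers (15-60 residues per side); decoys are composition- and
length-matched background. Three adversaries probe the three decision
mechanisms:

* a *truncated* paralog (half the domain) for the length filter;
* an *extra-domain* paralog (domain at 0.5 divergence plus a 120-residue
  unrelated C-terminal domain) for the identity curve and the trimming
  rule;
* an *out-paralog* (0.35 divergence) whose closer partner gene exists
  only in the source proteome, so reciprocal best hit must demote it
  from ortholog to mere homolog.

The stock benchmark is 20 such families with domain lengths spread over
120-300 residues, merged into one database, with child seeds drawn from
a master PCG64 stream so everything is reproducible from one integer.

What passing the benchmark shows: the default parameters separate
planted homologs from decoys and adversaries at >= 0.9 sensitivity and
specificity, and the full pipeline is deterministic. What it does not
show: performance on real proteomes. The substitution model has no
indels, no rate heterogeneity across sites, no compositional bias, and
linkers are random rather than homologous, so real twilight-zone
behaviour (and the value of the profile iterations on deeply diverged
families) is only coarsely represented.

## Numerical determinism

The alignment engine fills the dynamic-programming matrices row-wise
with a vectorised prefix-scan for the horizontal-gap state (exact
whenever gap_open >= gap_extend, which the scoring scheme enforces).
Traceback re-derives moves by exact floating-point equality, so all
scores and gap penalties are first quantised to a 1/64 grid (dyadic, so
sums are exact in double precision); substitution-matrix and integer gap
parameters are unchanged by this. Traceback starts at the
highest-scoring cell with the smallest (row, column), prefers
diagonal over vertical over horizontal moves, and closes gaps before
extending them. Profile hits are sorted by (expect value, accession).
All randomness in the package lives in `simdata` and flows from explicit
integer seeds through numpy's PCG64. Given the same inputs, every
output file is byte-identical across runs.

## Limitations

* E-value constants are fixed per scheme, not recomputed per
  matrix/gap combination; e-values for non-default schemes are
  approximate.
* Identity is measured against the reference (or profile consensus),
  not pairwise among members.
* The length filter's trimming never splits a sequence into multiple
  retained segments; a candidate with two distant homologous regions is
  trimmed to one window.
* RBHB uses a single source proteome; lineage-specific duplications in
  *other* species are still reported as orthologs if their best
  reciprocal hit is the reference.
* The optimiser is coordinate descent on a grid: it inherits the sweep
  order and will not find optima off the grid or ones requiring joint
  moves.
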