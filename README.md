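# orthoseek

Iterative homolog discovery and reciprocal-best-hit ortholog
classification for protein sequences, with explicit, auditable admission
filters.

## The problem

Given a query protein (or a small set of homologous queries) and a
protein database, find every database sequence that shares the query's
domain and architecture (the *homologs*), and decide which of those are
*orthologs* — homologs related to the query by speciation rather than
duplication. Plain similarity search errs in both directions: it pulls in
twilight-zone chance hits and multi-domain proteins that merely share one
domain, and it misses remote family members a single pairwise comparison
cannot reach.

`orthoseek` addresses both with a small, fully deterministic pipeline:

1. **Search.** Smith–Waterman local alignment (affine gaps, BLOSUM62 by
   default) of the reference against the database seeds the candidate
   set; subsequent iterations build a position-specific scoring matrix
   (PSSM) from everything accepted so far and search with the profile,
   pulling in remoter members, until an iteration adds nothing new.
   Expect values follow Karlin–Altschul statistics,
   E = K·m·n·e^(−λS) for raw scores and E = K·m·n·2^(−S) for profile
   bit scores.
2. **Identity curve.** A hit of alignment length L must exceed the
   length-dependent identity threshold
   `p(L) = n + 480·L^(−0.32·(1 + exp(−L/d)))` — the classical
   twilight-zone curve with an additive stringency offset *n*
   (default 33) and decay length *d* (default 1000, see
   `docs/methods.md`).
3. **Length filter.** Architecture is proxied by length: with minimal
   domain length *m* (default 28), candidates shorter than the shortest
   accepted homolog minus *m* are rejected; candidates longer than the
   longest accepted homolog plus *m* are trimmed back from their longest
   unaligned overhang. `m = 0` disables the filter.
4. **RBHB.** A homolog is an ortholog exactly when its best hit back in
   the reference's source proteome (highest bit score; ties by expect
   value, identity, accession) is the reference itself.

Accuracy is reported as sensitivity Sn = TP/(TP+FN), specificity
Sp = TP/(TP+FP), and the relative error quotient
REQ = (FN+FP)/(2·TP), and the three search parameters (e-value cutoff,
*m*, *n*) can be optimised coordinate-wise against any benchmark with
known truth. A seeded synthetic-family generator provides such
benchmarks, complete with adversarial paralogs (truncated, extra-domain,
out-paralog) and composition-matched decoys.

## Worked example

Generate a small labelled benchmark, then search one family:

```sh
orthoseek simulate --families 1 --seed 5 --out bench/
orthoseek search \
    --query bench/queries.fasta \
    --db bench/db.fasta \
    --rbhb-proteome bench/source_proteome.fasta \
    --annot bench/annotations.tsv \
    --out run/
```

which prints:

```
homologs: 7 (iterations: 2)
orthologs: 5
results written to run/
```

(the seven homologs are the reference, its five per-species orthologs
and one out-paralog; reciprocal best hit removes the out-paralog and the
reference itself from the ortholog list).

The run directory contains `homologs.tsv` / `orthologs.tsv` (one row per
member with identity, expect value, iteration found and any trimmed
range), the corresponding FASTA files, `filter_decisions.tsv` (every
candidate with the reason it was kept, trimmed or rejected),
`annotation_summary.tsv` and `run_config.yaml`. Score a prediction
against truth with:

```sh
cut -f1 run/orthologs.tsv | tail -n +2 > predicted.txt
orthoseek evaluate --pred predicted.txt --truth bench/truth.tsv
```

The same machinery is available as a library:

```python
from orthoseek import SearchParams, find_homologs, classify_orthologs, read_fasta

db = read_fasta("bench/db.fasta")
queries = list(read_fasta("my_query.fasta"))
result = find_homologs(queries, db, SearchParams())
orthologs = classify_orthologs(result, read_fasta("bench/source_proteome.fasta"))
```

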