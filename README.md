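# rnamodcensus

A curated, machine-readable census of epitranscriptomic marks — the chemical
modifications cells deposit on RNA — together with the staged "modification
forest" that organizes them, a parser for modification short names, annotation
queries, and graph exporters.

## The problem and the model

Over 150 distinct modified ribonucleosides have been described across
eukarya, bacteria and archaea, in tRNA, rRNA, mRNA and most other RNA
classes, with names like m6A, Ψ, m2,2G or mcm5s2U. The census organizes the
placeable ones as a rooted forest:

* Each of the four ribonucleosides A, C, G, U is a virtual **stage-0 root**.
* A mark at **stage *n*** derives from a stage-*(n−1)* substrate by one
  chemical step, so the stage of a mark equals the cumulative number of
  modifications separating it from its unmodified base (m6A is stage 1,
  m6Am — N6,2′-O-dimethyladenosine — is stage 2, peroxywybutosine o2yW sits
  at stage 9 at the end of the wyosine pathway).
* A handful of between-tree conversions (cytidine derivatives enzymatically
  deaminated to uridine derivatives, e.g. m3C → m3U) are recorded as
  **cross-talk edges** that never enter stage computation or counts.

The packaged census holds 158 records: 134 placed marks (32 adenosine-,
18 cytidine-, 29 guanosine- and 55 uridine-derived), 3 marks whose
biosynthesis is too poorly known to place (ac6A, cm5s2U, cnm5U), and 21
nascent-transcript 5′/3′-end modifications that cannot be rooted to a single
internal ribonucleoside. Each record carries kingdoms, RNA classes, tRNA
positions (text labels such as 34, 47b, 20A), mRNA regions and motifs
(DRACH, AGAUC, UCCUC, ...), writer/reader/eraser proteins, and
reversibility.

A second, independent view of every name is the **nomenclature
decomposition**: short names are tokenized (greedy longest-match over a
registered token table) into a root base plus a multiset of chemical
operations — e.g. `m2,2,7G` is guanosine + methylation@N2 ×2 +
methylation@N7. Family symbols with idiosyncratic multi-step chemistry
(queuosine and wyosine families) are treated as atomic cores. The parsed
root must agree with the curated lineage for every placed record, and for
non-atomic cores the operation count is a lower bound on the curated stage —
both are enforced by `check_consistency`.

## Worked example

The stage-count matrix (the machine twin of the census summary scheme):

```text
$ rnamod stats packaged
stage   A       C       G       U       total
1       11      9       7       13      40
2       17      5       8       24      54
3       4       3       6       16      29
4       0       1       2       2       5
5       0       0       1       0       1
6       0       0       1       0       1
7       0       0       1       0       1
8       0       0       2       0       2
9       0       0       1       0       1
total   32      18      29      55      134
```

Reading it: uridine dominates (55 of 134 marks, and 24 of the 54 second-stage
marks), first-stage counts are similar across the four branches (7 to 13),
and only the guanosine tree reaches stage 9 — the wyosine pathway ending at
o2yW.

Parsing a short name:

```text
$ rnamod parse m2,2G
name:       m2,2G
root_base:  G
atomic:     no
op_count:   2
  methylation @ N2 x2
```

Other entry points: `rnamod validate` (census linting), `rnamod query`
(e.g. `--position 34`, `--motif DRACH`, `--enzyme FTO`), `rnamod tree`
(DOT, Newick, or node-link JSON export) and `rnamod convert` (TSV ↔ JSON).
Everything is also available as a library:

```python
from rnamodcensus import load_packaged_census, build_forest, descendants

forest = build_forest(load_packaged_census())
print(len(descendants(forest, "m1G")))   # 12 — the wyosine family below m1G37
```

## Layout

```
src/rnamodcensus/
  census.py        # domain types, TSV/JSON dialects, validation
  nomenclature.py  # short-name tokenizer and census consistency check
  forest.py        # staged forest, stage matrix, descendants/paths
  query.py         # annotation filters, tRNA/mRNA map projections
  export.py        # DOT / Newick / node-link JSON exporters
  cli.py           # the rnamod command
  data/            # census.json, census.schema.json, tokens.json
docs/methods.md    # model, curation rules, and design notes
```
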