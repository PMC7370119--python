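# Methods

## The staged-forest model

Every placed epitranscriptomic mark is assigned to exactly one of four trees
rooted at the unmodified ribonucleosides A, C, G and U. An edge means "one
chemical modification step": the child is produced by modifying the parent,
so a node's *stage* — its edge distance from the root — equals the total
number of modifications accumulated on the base. The model's assumptions:

* **Single primary parent.** Some marks have more than one biosynthetic
  route (m6Am can arise from Am or from m6A). The census records one primary
  parent and keeps the alternatives in `alt_parents`; any choice among
  same-stage parents leaves the stage unchanged. For m6Am the primary parent
  is Am, the route used at the cap-adjacent position where m6Am is obligate.
* **Cross-talk is annotation, not lineage.** Enzymatic conversions between
  trees (C → U deamination, m3C → m3U) are kept as dashed cross-talk edges
  that never contribute to stages, descendant sets, or counts.
* **Stages cap at 9.** The deepest known pathway is the wyosine route
  m1G → imG-14 → … → o2yW in the guanosine tree.

## What is curated and what is computed

The census data file is the single source of truth; everything else —
stage matrix, tree heights, descendant counts, exports — is computed from it
at run time. The placed names are exactly those in the published tree
legends for the four bases (two guanosine names are glossed twice there and
are deduplicated), and the per-branch totals the file reproduces
(A = 32, C = 18, G = 29, U = 55; 134 in all) are enforced as regression
tests rather than stored anywhere.

Parent edges are the genuinely curated content. The published material
prints the trees as figures, not as an edge list, so edges were curated from
the per-mark biosynthesis statements (e.g. hm5C as the oxidation product of
m5C; se2U by selenation of s2U; the bacterial queuosine pathway; the
wyosine chain below m1G37) plus standard pathway knowledge where the text is
silent, under hard constraints the accompanying text does print: 24 of the
54 second-stage marks are uridine-derived; first-stage counts range from 7
to 13 across the branches; only the guanosine tree reaches stage 9, at
o2yW; and m1G is the precursor of exactly 12 marks (the wyosine family).
Within those constraints the choices that remained open (for instance which
hydroxywybutosine intermediates lie on the stage-9 path, or attaching the
2-thio side-chain marks to the s2U hub rather than to their side-chain
parents) were fixed once and are guarded by the constraint suite; they
should be read as a consistent reconstruction, not as the only defensible
one.

Three inset marks (ac6A, cm5s2U, cnm5U) lack the biosynthetic information
to be placed and are carried with `status=unplaced`. The 21
nascent-transcript records are placeholders: the source appendix naming
them is not part of the packaged material, so standard 5′/3′-end
modification names (cap variants, metabolite caps, end phosphates) stand in,
each flagged `provenance=placeholder` in its notes; only their cardinality
is asserted anywhere in the package.

Known errata are resolved in favor of the tree legends: m3U is
3-methyluridine (one text passage glosses it as a cytidine), and cm5s2U
keeps the inset's "5-carboxymethyl-2-thiouridine" with the conflicting
tRNA-map gloss recorded in its notes.

Annotations (kingdoms, RNA classes, positions, motifs, enzymes,
reversibility) record the union-of-knowledge view across kingdoms; a
kingdom-restricted position is stored qualified ("22[bacteria]") and
matches both bare and qualified queries. Reversibility is "yes" only for
m1A, m6A, Am and m6Am, "no" for queuosine, otherwise "unknown".

## Name parsing

The tokenizer is data-driven (`data/tokens.json`): prefixes are matched
greedily, longest token first, each optionally followed by a comma-separated
locant list whose entries each count one application of the operation
(`m2,2` = methylation at N2, twice); the suffixes `m` and `r(p)` denote
ribose 2′-O-methylation and 2′-O-ribosylation. Compound side-chain tokens
(mcm5, cmnm5, ncm5, …) count as **one** operation even though their
biosynthesis is multi-step, so the parsed operation count is a lower bound
on the curated stage, never an upper bound; `check_consistency` enforces
`1 ≤ op_count ≤ stage` for non-atomic placed records and exact root
agreement for all of them.

Special cores: I (deamination of A), Ψ (isomerization of U), D (reduction
of U), C+ (agmatination) and k2C (lysidination) contribute one implied
operation each. Queuosine-family (Q, G+, preQ0/1, oQ, galQ, manQ, gluQ) and
wyosine-family symbols (imG-14 … o2yW) are *atomic cores*: their internal
chemistry is named idiosyncratically, so they are not decomposed and are
excluded from the op-count bound. Exact registry matches take precedence
over tokenization — otherwise mimG (methylwyosine) would also tokenize as
methyl + isopentenyl + methyl + G; within a prefix string, greedy
longest-match is the deterministic rule, and the parser raises (never
guesses) if distinct core/suffix splits survive with different
decompositions. Matching is case-sensitive and there is no fuzzy
correction. Whether mchm5U should count as one or two operations is not
decidable from the naming alone; it is registered as one token.

## Numerical and formatting choices

* All collections are ordered deterministically (children and query results
  by short name, positions numerically with letter suffixes after their
  number), so every export is byte-stable.
* TSV multi-valued cells join with ";" — short names themselves contain
  commas. The JSON dialect may omit empty/default keys; both dialects
  round-trip to identical records, and the JSON dialect also preserves the
  census-level version and source note.
* Short names are NFC-normalized Unicode (Ψ, ′); every record carries a
  pure-ASCII alias (Ψm ↔ psi-m) and lookups accept either.
* Newick labels containing reserved characters are single-quoted with
  internal quotes doubled; trees carry no branch lengths (an edge is one
  chemical step by definition).
* The DOT exporter colors node borders by stage from a fixed nine-entry
  palette keyed by stage index; the palette itself is arbitrary.
* Degenerate inputs: an empty census still builds a forest of four bare
  roots and exports valid DOT/JSON; cycles in parent links are reported as
  validation violations (and as errors at forest-build time) with the cycle
  spelled out.

## Testing strategy and limitations

Independent oracles back the main computations: stage computation is checked
against breadth-first distances on an explicitly constructed networkx
digraph; Newick output is round-tripped through dendropy and must preserve
node counts, labels and depths; `query` is compared against a naive
full-scan predicate on hundreds of randomized filters; the parser is checked
against a hand-frozen table of roots and methyl counts derived from the
printed full-name glosses. Structural invariants (status partition,
conservation of branch totals, stage recurrence) are exercised on randomized
synthetic censuses, which cover forest topology but not chemistry — passing
them says nothing about the correctness of any individual curated edge
beyond the printed constraints above.

Known limitations: the census stores motif *labels*, not genomic
coordinates — there is no sequence scanning; chemical structures
(SMILES/InChI) are out of scope; per-kingdom position differences beyond the
qualified-label mechanism live in free-text notes; and the tRNA position
inventory follows the survey text, which names fewer positions than the
published tRNA map shows.
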