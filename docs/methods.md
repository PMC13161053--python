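# Methods

## Scope and model

`magtriage` is a rule-based classifier, not a statistical model: it encodes
the decision procedure by which a metagenome-assembled genome (MAG) is
routed to a SeqCode nomenclatural action. All genomic comparisons
(ANI, AAI), quality estimates (CheckM, GUNC) and homology searches (HMMER)
are consumed as the producing tools' tabular outputs; the package never
recomputes them from sequences. This keeps the triage itself cheap,
deterministic and auditable.

## Thresholds and boundary semantics

| parameter | default | unit | rationale |
|---|---|---|---|
| `min_completeness` | 90 | % | SeqCode type-genome floor; strict (`> 90`) |
| `max_contamination` | 5 | % | SeqCode type-genome cap; strict (`< 5`) |
| `species_ani` | 95 | % | standard genomic species criterion; **inclusive** (`>= 95` is the same species) |
| `genus_aai` | 65 | % | genus floor; **inclusive** on the existing-genus side (`>= 65`) |
| `min_rank` | family | rank | shallowest rank at which three NCBI hits must agree |
| `link_threshold` | 95 | % | single-linkage cut for conspecific study MAGs |
| `max_evalue` | 1e-5 | — | full-sequence e-value for gene presence |

The species boundary is inclusive because the criterion is stated as
"at least 95% ANI" for identity and "below 95%" for novelty; the two
phrasings are consistent only with an inclusive boundary. The AAI boundary
carries no published boundary semantics; we chose inclusive-at-65 for the
existing-genus range and document it here. A `QualityPolicy.strict()`
preset raises the completeness floor to 95%, which some selections use;
both floors pass every genome in the bundled worked example, so the choice
is free there.

The three-hit congruence default of `min_rank=family` is a design choice:
descriptions always state at least a family-level placement, so an LCA
shallower than family cannot support one. It is configurable. Absent ranks
never match anything — including other absent ranks — so two unclassified
lineages cannot appear congruent.

## Decision-tree details

* A MAG with **no ANI hit at all** is vacuously below the species threshold
  and follows the novel-species (B) branch; its material index is 5 unless
  a registry entry says otherwise, so it still faces the congruence check.
* A reference **missing from the material registry** is treated as
  in-silico material with a warning: nothing vouches for a culture.
* For index-5 MAGs with **fewer than three** NCBI-classified hits,
  congruence cannot be established and the MAG is rejected (a config flag
  `allow_fewer_hits` relaxes this to checking whatever is available).
* B-side categories retain the material index (B1–B5) even though only B4
  occurs in the worked example: the index preserves evidence provenance,
  and all B categories map to "describe under SeqCode" with B1–B3 noting
  the related biological material.
* The dereplication score completeness − 5 × contamination is the common
  dereplication heuristic (the SeqCode itself does not prescribe one);
  ties break by larger N50, larger genome size, then lexicographically
  smaller id, so representatives are deterministic under input permutation.
  When no pairwise MAG-vs-MAG ANI table is supplied, clustering falls back
  to shared-best-reference identity at ≥ 95% with a logged caveat.
* Placement overrides (`within_named_genus` / `outside_named_genera`) are
  **inputs**, not computations: resolving an unresolved genus requires a
  phylogenomic tree this package deliberately does not build.

## Gene panel

The panel is an external TSV (symbol, category, model id,
eukaryote-specific flag). The bundled default has 115 entries: the 49
individually named genes (apcABCDEF, cpcABCDEFG, cpeABCDERSTUYZ, cydABX,
petABCDLM + petGN, ctaCDEF, sdhCD, hoxE, psaGHNO, psbQRW) plus clearly
marked placeholder slots (`photosystem_slot_NN`, `etc_slot_NN`) standing in
for the F-type ATPase / NADH dehydrogenase / electron-transport block whose
symbols a given lab's roster enumerates; users with a concrete roster
supply their own TSV. Eukaryote-specific photosystem subunits are reported
as "expected absent" rather than counted as gaps. Presence defaults to a
full-sequence e-value ≤ 1e-5 with an optional per-run bitscore mode; the
parser accepts both hmmsearch and hmmscan column orientations (the model id
may sit in either the target or the query column; target wins on conflict).

## Synthetic data

The generator draws **labels first** (quality verdict, species/genus
status, material index, congruence) and then samples values inside
label-consistent ranges: ANI in [95, 100) for same-species MAGs and
[75, 95) for novel ones (half-open, truncated — not rounded — to four
decimals so a printed value can never cross the boundary), AAI in
[55, 64.9] for novel genera and [65, 90) otherwise, completeness/
contamination inside or outside the quality bounds per the drawn verdict.
One `random.Random(seed)` stream drives everything, so bundles are
byte-identical across runs. What it does *not* emulate: real ANI/AAI
correlation structure between related references, fragment-count
distributions, genuinely ambiguous taxonomy strings, or sequences with
realistic nucleotide composition (FASTA files are random contigs used only
for length statistics). Passing the end-to-end recovery suite therefore
shows the decision logic is faithful to its rules, not that the rules are
robust to noisy real-world reference databases.

The bundled worked example is a nine-MAG study set shipped as module
constants (quality, ANI, AAI, GTDB hit, material annotation and printed
category per MAG) and written out in exactly the formats the pipeline
reads. Its source table and the running text it comes from disagree on one
row's statistics (7.54 Mb / 97.41% / 0.71% in the table vs 6.8 Mb / 98.82%
/ 2.2% in the text for the same genome); the fixture follows the table.

## Problem sizes

The test suite and acceptance script run the pipeline on the nine-MAG
worked example and on 6–8-MAG synthetic bundles (100 seeds in the suite, 25
in the acceptance script — 200–600 MAG-level checks), with property tests
at up to 1,000 examples for the LCA invariants and 12-node graphs for the
dereplication oracle. These sizes exercise every branch of the decision
tree; the pipeline itself is linear in MAGs × hits and handles
database-scale hit tables (thousands of references per MAG) without
special handling.

## Known limitations

* Nomenclatural legality (Latin grammar, homonymy, priority between ICN,
  ICNP and SeqCode) is out of scope; name validation is purely structural.
* The congruence rank that best separates trustworthy from untrustworthy
  NCBI-only classifications is not empirically calibrated here; `family`
  is a documented default, not a claim.
* Whether an AAI ≥ 65% hit with a *named* genus should ever be overridden
  to a novel genus by phylogenetic placement alone is flagged as
  unresolved; the package keeps the hit's genus in that combination.
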