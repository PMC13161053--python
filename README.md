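# magtriage

Genome-based taxonomic triage of metagenome-assembled genomes (MAGs) under
the SeqCode, the nomenclatural code that lets a genome sequence serve as the
type material of a validly named prokaryotic species.

## The problem

Many bacteria — cyanobacteria from extreme habitats are a canonical case —
are known only from MAGs and cannot be deposited as living cultures. The
SeqCode makes them nameable, but deciding *whether and how* to describe a
given MAG requires combining several routine desk analyses that are usually
done by hand: the quality screen for type genomes, the 95% average
nucleotide identity (ANI) species rule, the 65% average amino-acid identity
(AAI) genus floor, the biological-material status of the closest reference
genome, and the reliability of that reference's taxonomy. `magtriage`
automates the whole decision as a reproducible pipeline over plain TSV
inputs (CheckM-style quality tables, fastANI/FastAAI best-hit tables,
GTDB/NCBI lineage strings, a material registry, HMMER `--tblout` files).

## The decision rules

For a quality-passing MAG (completeness > 90%, contamination < 5%, strict
bounds) with best ANI hit $a$ and the closest reference's material status:

* $a \geq 95\%$ — the species already has a genome (**Part A**):
  * **A1** type strain → no SeqCode registration, the species exists;
  * **A2** undescribed strain in a public culture collection → describe via
    the material, no SeqCode deposit (biological material has priority);
  * **A3** cultivated but undeposited strain → SeqCode description plus a
    recommendation to deposit the strain;
  * **A4** in-silico material with a GTDB classification → SeqCode description;
  * **A5** in-silico, NCBI-only → SeqCode description *iff* the lowest common
    ancestor (LCA) of the three closest NCBI hits reaches at least family;
    otherwise the MAG is rejected as taxonomically incongruent.
* $a < 95\%$ — a novel species (**Part B**): the same five material indices
  apply (B1–B5), but hits on biological material imply no priority and a
  SeqCode description proceeds; B5 requires the same three-hit congruence.
* **Part C** — when several study MAGs are conspecific (pairwise ANI ≥ 95%,
  single linkage), one representative is chosen by
  completeness − 5 × contamination (ties: N50, genome size, id).

Genus-level novelty uses the AAI floor: best AAI < 65% means a novel genus;
above it the genus follows the hit's taxonomy, or stays unresolved when the
hit is classified too shallowly — an external phylogenetic placement can
then decide. A 115-gene phycobilisome / photosystem / respiratory panel is
profiled from `hmmsearch` output to document the photosynthetic potential of
each candidate, and SeqCode-style protologues are rendered from the
collected evidence.

## Worked example

The package bundles a nine-MAG study set from volcanic steam-vent
metagenomes: one bin matching (ANI 99.68%) a cultivated but never deposited
strain, and eight bins below 95% ANI to any of ~9,000 reference genomes.

```bash
magtriage fixture --table2 --out demo
magtriage run --quality demo/quality.tsv --ani demo/ani.tsv \
    --aai demo/aai.tsv --taxonomy demo/taxonomy.tsv \
    --materials demo/materials.tsv --out demo/out
```

prints

```
{"A3": 1, "B4": 8}
```

meaning: one genome is described under SeqCode *with a recommendation to
deposit the existing culture* (A3), and eight are novel species described
directly from their genomes (B4) — nine describable genomes in total, eight
of them new species. `demo/out/report.json` holds the per-MAG evidence
(best hits, material index, LCA, cluster, action) and `demo/out/summary.tsv`
a one-line-per-MAG table.

Synthetic, ground-truth-labelled bundles for testing any part of the
decision tree come from the same command without `--table2`:

```bash
magtriage fixture --n-mags 12 --seed 7 --out synth
```

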