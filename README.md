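# primereval

Evaluate 16S rRNA gene primers by how much of the full-length gene's
information their short reads preserve. Given an aligned, nearly
full-length (NFL) 16S library — real or simulated — `primereval` measures,
for each primer:

- **coverage / non-coverage**: exact degenerate (IUPAC) matching on both
  strands, per taxon group;
- **phylogenetic signal**: short-read (SR) libraries are cut in silico at
  each primer site (280 bp, primer removed), neighbor-joining trees with
  bootstrap supports are built per library, and trees are compared by
  Pearson correlation of patristic distances, through-origin slope,
  MDS + Procrustes superposition (wRMSD), and the RF / WRF1 / WRF2
  bipartition metrics;
- **resolving power**: 0.01-binned mean/std profiles of SR vs NFL
  distances, plus a sliding-window re-placement profile (node distance of
  each taxon's least-squares re-attachment using only window data);
- **OTU richness**: average-linkage clustering at hard cutoffs
  (0.01/0.02/0.03) and SR/NFL richness ratios;
- **taxonomic fidelity**: a naive-Bayes 8-mer classifier with bootstrap
  confidence (80% cutoff), scored SR-vs-NFL per rank (correct incl/excl,
  false positives/negatives, unclassified).

A synthetic-data module generates 16S-like libraries: a seeded random tree
(Yule or coalescent), Jukes–Cantor evolution with slow conserved blocks
alternating with fast variable regions, ten well-known primer sites
(338f/r, 518f/r, 799f/r, 926f/r, 1062f/r) planted at E. coli-like
coordinates, and clade-derived taxonomy labels.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: independent
oracles (dendropy bipartitions, networkx path sums, regex/set-expansion
matching, from-scratch agglomeration), fixed-point and determinism
contracts, and seeded qualitative patterns.

## CLI

```sh
primereval simulate --n-taxa 50 --seed 1 --outdir sim/
primereval coverage sim/library.fasta --taxonomy sim/taxonomy.tsv \
    --rank phylum --out coverage.tsv
primereval extract sim/library.fasta --primer 518f --out sr_518f.fasta
primereval njtree sr_518f.fasta --bootstrap 500 --seed 1 --out sr.nwk
primereval treedist sr.nwk other.nwk
primereval compare nfl.nwk sr.nwk --dims 3
primereval otus sim/library.fasta --cutoffs 0.01,0.02,0.03 --out otus.tsv
primereval classify sr_518f.fasta --reference sim/library.fasta \
    --reference-taxonomy sim/taxonomy.tsv --out assignments.tsv
primereval run --seed 1 --n-taxa 40 --bootstrap 100 --outdir reports/
```

`primereval run` performs the whole evaluation and writes `coverage.tsv`,
`tree_comparison_within.tsv` (replicate-tree pairs per library, plus mean
rows), `tree_comparison_vs_nfl.tsv` (SR-vs-NFL comparisons including
pairwise-distance Pearson and slopes), `otu_richness.tsv`,
`taxonomy_performance.tsv`, `window_profile.tsv`, per-library binned
profiles, the simulated inputs, all replicate trees (Newick), and a
`manifest.json`. Reruns with the same `--seed` are byte-identical.

External inputs: gapped FASTA (aligned), taxonomy TSV
(`id<TAB>domain;phylum;...;genus`), primer TSV (`name sequence direction`),
Newick trees with supports as internal-node labels or bracketed branch
comments (values on a 0–100 scale are rescaled to [0, 1]).

## Layout

| module | contents |
| --- | --- |
| `primereval.io` | FASTA/Newick/TSV/config readers and writers, sequence library types |
| `primereval.tree` | tree structure, Newick via dendropy, support-dialect handling |
| `primereval.simulate` | region maps, tree simulation, JC evolution, clade taxonomy |
| `primereval.primers` | IUPAC matching, coverage tables, amplicon extraction |
| `primereval.phylo` | distances, neighbor joining, bootstrap supports, patristic, RF/WRF |
| `primereval.compare` | Pearson/slope/binning, MDS, Procrustes wRMSD, sliding window |
| `primereval.otu` | average-linkage OTUs, richness ratios |
| `primereval.classify` | naive-Bayes k-mer classifier, assignment scoring |
| `primereval.pipeline` | end-to-end orchestration, seed derivation, report TSVs |
| `primereval.cli` | `primereval` command group |
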