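# its2barcode

A toolkit for DNA-barcoding species identification from the **ITS2**
region (the second internal transcribed spacer of nuclear ribosomal DNA),
built for surveys of closely related plants — e.g. authenticating
medicinal *Ferula* species against their substitutes — where morphology
fails but a short, easily amplified barcode separates the taxa.

The pipeline covers every step between raw amplicons and an
identification verdict:

* **Amplicon handling** — labeled FASTA I/O, primer excision by
  minimum-Hamming search of the universal ITS2 primers, and fixed-flank
  annotation of the amplicon into partial 5.8S (84 bp) / ITS2 core /
  partial 28S (141 bp), with per-region length and GC statistics.
* **Alignment** — affine-gap global pairwise alignment (Gotoh) and a
  deterministic progressive multiple alignment over a neighbor-joining
  guide tree; the MSA's 1-based columns are the coordinate system for
  everything downstream.
* **Distances** — Kimura 2-parameter distances under pairwise deletion,

  d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q),

  with P and Q the transition and transversion proportions of each
  sequence pair, plus per-species intra/interspecific summaries
  (min–max and mean over sample pairs).
* **Variation** — disjoint column classification (monomorphic /
  substitution / indel), substitution-type tallies ({C,T}, {A,G}, …),
  haplotype collapsing, and detection of *diagnostic sites*: columns
  where one species is fixed for a state no other species carries.
* **Classification** — species assignment by nearest K2P distance and by
  BLAST1-style top hit (exact Smith–Waterman local alignment, megablast-like
  scoring), each evaluated by leave-one-out with ties scored as failures.
* **Trees** — neighbor joining with deterministic tie-breaking, column
  (Felsenstein) bootstrap supports, unrooted monophyly tests, Newick I/O
  and ASCII rendering.
* **Simulation** — a fully seeded generator of species-structured
  haplotype datasets (coalescent species tree, transition-biased K2P
  process, short indels, planted diagnostic substitutions, zero
  intraspecific variation) with a replayable event log, so every stage is
  testable end to end without downloads.

## Worked example

```python
from its2barcode import (
    Method, distance_matrix, leave_one_out_eval, progressive_msa,
    species_summaries,
)
from its2barcode.simulate import SimulationConfig, simulate_dataset

records, truth = simulate_dataset(SimulationConfig(seed=1))
msa = progressive_msa(records)
dm = distance_matrix(msa)
for s in species_summaries(dm, msa.labels)[:3]:
    print(s.species, s.n_samples, f"{s.intra.mean:.3f}",
          f"{s.inter.min:.3f}-{s.inter.max:.3f} ({s.inter.mean:.3f})")
print(leave_one_out_eval(records, Method.NEAREST_DISTANCE, msa=msa).success_rate)
```

prints

```
Species_01 13 0.000 0.007-0.053 (0.033)
Species_02 6 0.000 0.004-0.050 (0.027)
Species_03 14 0.000 0.009-0.060 (0.034)
100.0
```

— 74 samples of 10 species, each species a single haplotype
(intraspecific mean distance 0.000), interspecific means near 0.03
substitutions/site, and a 100% leave-one-out identification rate: the
ideal "barcoding gap" configuration in which every query's nearest
reference is a conspecific. The scripts in `examples/` walk through each
capability (simulation, trimming/annotation, distance tables,
classification, trees) and print a line of interpretation with each
number.

A thin CLI wraps the same functions for shell use:

```sh
its2barcode simulate --seed 1 --out data/
its2barcode report --simulate --seed 1 --replicates 1000 --out-dir out/
```

`report` writes the full artifact bundle (region stats, aligned FASTA,
distance matrices, species summary table, variable/diagnostic-site
tables, per-method classification reports, Newick tree with supports,
and a JSON manifest).

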