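# barcodepci

Figures of merit for DNA-barcode reference libraries.

DNA barcoding identifies an unknown specimen by finding its nearest
neighbors, under a sequence distance, in a reference database of
annotated barcode sequences (for fungi, typically the ITS region of
nuclear ribosomal DNA). The practical question for anyone curating such
a library — a herbarium, a sequence repository, a monographer of a
difficult genus — is: *if I queried this database with its own
contents, how often would it identify them correctly?* `barcodepci`
answers that question with four probabilities of correct identification
(PCIs) per species, computed by leave-one-out nearest-neighbor analysis
under p-distance, and with the statistics needed to compare annotation
sources and analysis pipelines.

## The four PCIs

Fix a species *s* with *n* ≥ 2 samples. For each sample σ let *f*σ be
the fraction of σ's nearest neighbors (self excluded, ties included)
annotated as *s*, and *U*(*f*σ) = 1 iff *f*σ = 1. Then

- **Barcode Gap PCI** `p_B,s` = 1 iff the maximum intraspecies
  p-distance is strictly less than the minimum distance to any sample
  of another species;
- **Unanimous PCI** `p_U,s` = min σ *U*(*f*σ);
- **Average Unanimous PCI** `p_A,s` = mean σ *U*(*f*σ);
- **Fractional PCI** `p_F,s` = mean σ *f*σ.

These provably satisfy `0 ≤ p_B,s ≤ p_U,s ≤ p_A,s ≤ p_F,s ≤ 1` —
progressively more optimistic notions of "correct identification".
Dataset-level PCIs are unweighted means over non-singleton species,
reported with standard errors and a separate count of singleton
species (those with a unique sequence are unidentifiable in principle
and must never be blended into the averages).

Beyond the PCIs, the package provides:

- a **taxonomic unanimity test**: a log-rank-style statistic over
  per-species 2×2 (group × unanimity) tables with hypergeometric
  variances, testing whether one annotation source (expert taxonomy vs
  plain repository records, long vs short sequences) yields unanimous
  identifications significantly more often;
- paired **Wilcoxon signed-rank** and **sign** tests over species PCI
  tables, for comparing two pipelines on the same species set;
- **database-growth curves**: mean ± SD of each PCI under uniform
  resampling without replacement;
- a **synthetic data generator** (controlled intra/inter-species
  divergence, replicates, singletons, ambiguities, gaps,
  misannotations) and a deterministic worked-example fixture, so the
  whole analysis is testable without downloading anything.

## Worked example

A real incident, reduced to nine sequences: species S has six samples,
two of which (s5, x) carry identical sequences — but x was annotated
with a misspelled species name, making it a singleton of a species that
does not exist.

```sh
python examples/worked_example.py
```

```
species S, singleton misannotated: p_B=0.000  p_U=0.000  p_A=0.667  p_F=0.750
species S, singleton relabeled   : p_B=1.000  p_U=1.000  p_A=1.000  p_F=1.000
```

One bad record annihilates the binary scores — the barcode gap
(`p_B`: the rogue sequence sits at interspecies distance 0) and
unanimity (`p_U`: two of S's six samples acquire a wrong-species
nearest neighbor) — while the averaged scores sag only to 4/6 ≈ 0.667
and 4.5/6 = 0.750. Correcting the label restores a perfect 1 for all
four. This asymmetry is the package's central lesson: `p_A` and `p_F`
are robust figures of merit; `p_B` and `p_U` are brittle diagnostics
whose collapse *flags* likely misannotations.

The same analysis from the shell:

```sh
pci fixture --out-dir fix/
pci compute --fasta fix/misannotation.fasta --meta fix/misannotation.tsv --out-dir out/
```

Other entry points: `pci unanimity-test`, `pci compare`, `pci resample`,
`pci simulate` (see `pci --help`), and the narrative scripts under
`examples/`.

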