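"""Score a simulated reference library with the four dataset-level PCIs.

Generates 10 species with controlled within/between-species divergence
and a 10% misannotation rate, then prints the species-averaged PCIs
with their standard errors and the singleton counts that must accompany
them.
"""

from barcodepci import GeneratorConfig, build_distance_matrix, generate_dataset, overall_pci

cfg = GeneratorConfig(n_species=10, samples_per_species=(1, 8), seq_length=150,
                      intra_divergence=0.02, inter_divergence=0.3,
                      misannotation_rate=0.10, replicate_rate=0.1, seed=7)
ds = generate_dataset(cfg)
summary = overall_pci(ds, build_distance_matrix(ds))

print(f"samples: {len(ds)}, non-singleton species: {summary.n_species}, "
      f"singletons: {summary.singleton_count} "
      f"({summary.unique_singleton_count} with unique sequences)")
for name in ("B", "U", "A", "F"):
    print(f"  p_{name} = {getattr(summary, f'p_{name}'):.3f} "
          f"+/- {getattr(summary, f'sem_{name}'):.3f}")

print("""
Each value is an unweighted mean over non-singleton species (so heavily
sampled species cannot dominate), +/- the standard error of that mean.
Misannotated samples pull every PCI below 1, hitting the strict
barcode-gap and unanimity criteria hardest.""")
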