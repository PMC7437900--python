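"""Compare two identification pipelines with paired species-PCI tests.

Pipeline 1 scores samples on only the first half of the alignment (a
deliberately degraded pipeline); pipeline 2 uses the full alignment.
The species Fractional PCIs are paired per species and compared with
the Wilcoxon matched-pair signed-rank test and the sign test.
"""

from barcodepci import (
    BarcodeDataset,
    GeneratorConfig,
    SampleRecord,
    build_distance_matrix,
    generate_dataset,
    sign_test_compare,
    signed_rank_compare,
    species_pci,
)

cfg = GeneratorConfig(n_species=15, samples_per_species=(2, 6), seq_length=120,
                      intra_divergence=0.04, inter_divergence=0.25,
                      misannotation_rate=0.1, seed=23)
full = generate_dataset(cfg)
half = BarcodeDataset(
    tuple(SampleRecord(s.sample_id, s.species, s.sequence[:60])
          for s in full.samples),
    60,
)

m_full, m_half = build_distance_matrix(full), build_distance_matrix(half)
pairs = [
    (sp,
     float(species_pci(half, m_half, sp).p_F),
     float(species_pci(full, m_full, sp).p_F))
    for sp in full.non_singleton_species()
]

n_sr, p_sr = signed_rank_compare(pairs)
n_st, p_st = sign_test_compare(pairs)
print(f"species compared: {len(pairs)}")
print(f"signed-rank: n_nonzero={n_sr}, two-sided p={p_sr:.4f}")
print(f"sign test:   n_nonzero={n_st}, two-sided p={p_st:.4f}")

print("""
n_nonzero counts species whose Fractional PCI changed between the
pipelines; species with identical scores carry no information and are
dropped.  A small p says the full-alignment pipeline identifies species
systematically better (or worse) than the half-alignment one, beyond
what coin-flip differences would produce.""")
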