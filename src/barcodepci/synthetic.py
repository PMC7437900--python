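"""Synthetic barcode datasets: a deterministic worked-example fixture, a
parameterized random generator, and an independent brute-force oracle.

The fixture reproduces, at desk scale, the neighbor topology of a real
misannotation incident: a species whose six samples include two
identical sequences, plus a singleton of a (misspelled, hence
non-existent) species carrying a sequence identical to one of them.
The singleton hijacks nearest-neighbor sets and spuriously drags the
species PCIs down; relabeling it restores a perfect score.

The random generator emulates the structure of curated ITS reference
sets — several species with 1-20 samples each, exact replicate
sequences, singleton decoys, ambiguous bases, gaps, short sequences and
occasional misannotations — without modelling real ITS evolution
(no indel dynamics or rate heterogeneity).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .errors import ConfigError, DomainError
from .io import BarcodeDataset, SampleRecord
from .pci import SpeciesPCI

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# the worked-example fixture


def make_misannotation_fixture() -> BarcodeDataset:
    """Nine aligned samples, width 10, exhibiting a misannotated singleton.

    Species S: s1-s4 identical, s5 and s6 two mutations away from them
    and one mutation from each other.  Sample x (species X) is a
    singleton whose sequence is identical to s5 — the misannotation.
    Species Y (y1, y2) sits far away (p-distance >= 0.8 to everything
    else) as a clean control.

    Expected structure: d(s5, x) = 0; d(s6, s5) = d(s6, x) = 0.1;
    d(s5 or s6, s1..s4) = 0.2.  Any alignment realizing these distances
    yields the same PCIs; this is the smallest convenient one.
    """
    rows = [
        ("s1", "S", "AAAAAAAAAA"),
        ("s2", "S", "AAAAAAAAAA"),
        ("s3", "S", "AAAAAAAAAA"),
        ("s4", "S", "AAAAAAAAAA"),
        ("s5", "S", "AAAAAAAACC"),
        ("s6", "S", "AAAAAAAACG"),
        ("x", "X", "AAAAAAAACC"),
        ("y1", "Y", "CCCCCCCCCC"),
        ("y2", "Y", "CCCCCCCCCC"),
    ]
    samples = tuple(SampleRecord(i, sp, seq) for i, sp, seq in rows)
    return BarcodeDataset(samples, 10)


def correct_misannotation_fixture() -> BarcodeDataset:
    """The fixture with the singleton relabeled to its true species."""
    return make_misannotation_fixture().relabel("x", "S")


def write_fixture(dataset: BarcodeDataset, fasta_path, metadata_path) -> None:
    """Write a dataset as aligned FASTA + metadata TSV (deterministic bytes)."""
    group_cols = sorted({g for s in dataset.samples for g in s.groups})
    with open(fasta_path, "w") as fa:
        for s in dataset.samples:
            fa.write(f">{s.sample_id}\n{s.sequence}\n")
    with open(metadata_path, "w") as tsv:
        header = ["sample_id", "species"] + group_cols
        tsv.write("\t".join(header) + "\n")
        for s in dataset.samples:
            row = [s.sample_id, s.species] + [
                "1" if g in s.groups else "0" for g in group_cols
            ]
            tsv.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# random generator


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the random dataset generator.

    intra_divergence / inter_divergence are target expected pairwise
    p-distances within and between species; the per-site mutation rates
    are half of each, since two lineages mutate independently from
    their common source (the attained divergence is approximate —
    coincident mutations make it slightly smaller).
    """

    n_species: int = 5
    samples_per_species: tuple[int, int] = (1, 6)  # inclusive range
    seq_length: int = 120
    intra_divergence: float = 0.02
    inter_divergence: float = 0.25
    ambiguity_rate: float = 0.0
    gap_rate: float = 0.0
    misannotation_rate: float = 0.0
    replicate_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        rates = {
            "intra_divergence": self.intra_divergence,
            "inter_divergence": self.inter_divergence,
            "ambiguity_rate": self.ambiguity_rate,
            "gap_rate": self.gap_rate,
            "misannotation_rate": self.misannotation_rate,
            "replicate_rate": self.replicate_rate,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"{name}={r} outside [0, 1]")
        if self.intra_divergence > self.inter_divergence:
            raise ConfigError(
                "intra_divergence exceeds inter_divergence: within-species "
                "spread beyond species separation is unattainable"
            )
        if self.n_species < 1 or self.seq_length < 1:
            raise ConfigError("need n_species >= 1 and seq_length >= 1")
        lo, hi = self.samples_per_species
        if not 1 <= lo <= hi:
            raise ConfigError("samples_per_species must be 1 <= lo <= hi")


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Per-site substitution at the given rate, uniformly to another base."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def generate_dataset(config: GeneratorConfig) -> BarcodeDataset:
    """Draw a random barcode dataset per the config; seed-deterministic.

    Species centroids mutate from a common ancestor; samples mutate
    from their centroid.  A rejection step regenerates any sample whose
    sequence coincides with a sample of another species, so identical
    cross-species sequences appear only through the explicit
    misannotation / replication knobs and the expected PCIs stay
    controllable.
    """
    rng = np.random.default_rng(config.seed)
    L = config.seq_length

    ancestor = rng.integers(0, 4, size=L)
    centroids = [
        _mutate(rng, ancestor, config.inter_divergence / 2)
        for _ in range(config.n_species)
    ]

    lo, hi = config.samples_per_species
    species_names = [f"sp{k + 1:03d}" for k in range(config.n_species)]
    seqs: list[np.ndarray] = []
    labels: list[str] = []
    for name, centroid in zip(species_names, centroids):
        n_k = int(rng.integers(lo, hi + 1))
        for _ in range(n_k):
            for _attempt in range(200):
                cand = _mutate(rng, centroid, config.intra_divergence / 2)
                clash = any(
                    np.array_equal(cand, s)
                    for s, lab in zip(seqs, labels)
                    if lab != name
                )
                if not clash:
                    break
            else:
                raise ConfigError(
                    "could not draw a sample distinct from other species; "
                    "divergences too small for the sequence length"
                )
            seqs.append(cand)
            labels.append(name)

    # exact replicates within species
    for i in range(len(seqs)):
        if rng.random() < config.replicate_rate:
            mates = [j for j in range(len(seqs))
                     if labels[j] == labels[i] and j != i]
            if mates:
                seqs[i] = seqs[int(rng.choice(mates))].copy()

    # decode, then inject ambiguities and gaps
    texts = []
    for arr in seqs:
        chars = np.array(list(_BASES))[arr]
        mask = rng.random(L)
        chars[mask < config.ambiguity_rate] = "N"
        gap_mask = (mask >= config.ambiguity_rate) & (
            mask < config.ambiguity_rate + config.gap_rate
        )
        chars[gap_mask] = "-"
        texts.append("".join(chars))

    # misannotation: wrong species label, drawn from the other species
    final_labels = list(labels)
    if config.n_species >= 2:
        for i in range(len(final_labels)):
            if rng.random() < config.misannotation_rate:
                others = [n for n in species_names if n != labels[i]]
                final_labels[i] = str(rng.choice(others))

    samples = tuple(
        SampleRecord(f"q{i + 1:04d}", final_labels[i], texts[i])
        for i in range(len(texts))
    )
    return BarcodeDataset(samples, L)


# ---------------------------------------------------------------------------
# brute-force oracle (shares no code with the pci module)


def _oracle_pdist(a: str, b: str) -> Fraction:
    mism = comp = 0
    for x, y in zip(a, b):
        if x in _BASES and y in _BASES:
            comp += 1
            if x != y:
                mism += 1
    if comp == 0:
        raise DomainError("oracle: incomparable pair")
    return Fraction(mism, comp)


def oracle_species_pci(dataset: BarcodeDataset, species: str) -> SpeciesPCI:
    """Naive recomputation of the four species PCIs by full enumeration.

    Quadratic scans everywhere, pure-Python p-distance, no shared code
    with the production path; intended for datasets of <= ~50 samples
    as an exactness cross-check.
    """
    recs = list(dataset.samples)
    mine = [r for r in recs if r.species == species]
    if len(mine) < 2:
        raise DomainError(f"oracle: species {species!r} is a singleton")

    fs: list[Fraction] = []
    us: list[int] = []
    for q in mine:
        dists = [
            (_oracle_pdist(q.sequence, r.sequence), r)
            for r in recs
            if r.sample_id != q.sample_id
        ]
        dmin = min(d for d, _ in dists)
        nbrs = [r for d, r in dists if d == dmin]
        f = Fraction(sum(1 for r in nbrs if r.species == species), len(nbrs))
        fs.append(f)
        us.append(1 if f == 1 else 0)

    intra = [
        _oracle_pdist(a.sequence, b.sequence)
        for i, a in enumerate(mine)
        for b in mine[i + 1:]
    ]
    outside = [r for r in recs if r.species != species]
    if outside:
        inter = [
            _oracle_pdist(a.sequence, r.sequence) for a in mine for r in outside
        ]
        gap = 1 if max(intra) < min(inter) else 0
    else:
        gap = 1  # no interspecies partner: the gap holds vacuously

    n = len(mine)
    return SpeciesPCI(
        species=species,
        n_samples=n,
        p_B=Fraction(gap),
        p_U=Fraction(min(us)),
        p_A=Fraction(sum(us), n),
        p_F=sum(fs, Fraction(0)) / n,
        per_sample=tuple(zip(fs, us)),
    )
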