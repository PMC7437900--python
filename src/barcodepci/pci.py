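"""The four probabilities of correct identification (PCIs).

For a species s with samples sigma = 1..n, let f_sigma be the fraction
of sigma's leave-one-out nearest neighbors annotated as s, and
U(f_sigma) = 1 iff f_sigma = 1.  Then

    p_F,s = mean of f_sigma          (Fractional)
    p_A,s = mean of U(f_sigma)       (Average Unanimous)
    p_U,s = min  of U(f_sigma)       (Unanimous)
    p_B,s = 1 iff s has a barcode gap (max intra < min inter, strict)

and 0 <= p_B,s <= p_U,s <= p_A,s <= p_F,s <= 1 always.  Dataset-level
PCIs are unweighted means over non-singleton species (taxonomic
normalization: over-sampled species must not dominate), with standard
errors from the unbiased sample variance.  Singletons are never blended
into the averages; they are reported as separate counts.

All species PCIs are exact rationals internally; floats appear only at
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .distance import DistanceMatrix, has_barcode_gap, nearest_neighbors
from .errors import DomainError
from .io import BarcodeDataset


@dataclass(frozen=True)
class SpeciesPCI:
    """The four PCIs of one species, plus the per-sample (f, U) pairs."""

    species: str
    n_samples: int
    p_B: Fraction  # 0 or 1
    p_U: Fraction  # 0 or 1
    p_A: Fraction
    p_F: Fraction
    per_sample: tuple[tuple[Fraction, int], ...]

    def __post_init__(self):
        if not 0 <= self.p_B <= self.p_U <= self.p_A <= self.p_F <= 1:
            raise AssertionError(
                f"PCI inequality violated for {self.species!r}: "
                f"{self.p_B}, {self.p_U}, {self.p_A}, {self.p_F}"
            )

    def as_tuple(self) -> tuple[Fraction, Fraction, Fraction, Fraction]:
        return (self.p_B, self.p_U, self.p_A, self.p_F)


@dataclass(frozen=True)
class PCISummary:
    """Dataset-level PCIs: unweighted species means with standard errors."""

    n_species: int
    p_B: float
    p_U: float
    p_A: float
    p_F: float
    sem_B: float
    sem_U: float
    sem_A: float
    sem_F: float
    singleton_count: int
    unique_singleton_count: int

    def to_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "p_B": self.p_B, "p_U": self.p_U,
            "p_A": self.p_A, "p_F": self.p_F,
            "sem_B": self.sem_B, "sem_U": self.sem_U,
            "sem_A": self.sem_A, "sem_F": self.sem_F,
            "singleton_count": self.singleton_count,
            "unique_singleton_count": self.unique_singleton_count,
        }


def species_pci(
    dataset: BarcodeDataset, matrix: DistanceMatrix, species: str
) -> SpeciesPCI:
    """Compute the four PCIs for one non-singleton species.

    Neighbors are drawn from the full dataset (leave-one-out: only the
    query itself is excluded), so singletons of other species act as
    decoys — including potentially misannotated ones.
    """
    positions = dataset.species_index.get(species)
    if positions is None:
        raise DomainError(f"species {species!r} not in dataset")
    if len(positions) < 2:
        raise DomainError(f"species {species!r} is a singleton")

    species_of = dataset.species_of
    per_sample = []
    for i in positions:
        nr = nearest_neighbors(matrix, dataset.samples[i].sample_id, species_of)
        per_sample.append((nr.f, nr.U))

    n = len(per_sample)
    p_F = sum(f for f, _ in per_sample) / n
    p_A = Fraction(sum(u for _, u in per_sample), n)
    p_U = Fraction(min(u for _, u in per_sample))
    p_B = Fraction(1 if has_barcode_gap(matrix, species, species_of) else 0)
    return SpeciesPCI(species, n, p_B, p_U, p_A, p_F, tuple(per_sample))


def sem_of_mean(values) -> float:
    """Standard error of the mean from the unbiased sample variance.

    sqrt(sum (p_i - pbar)^2 / (n-1)) / sqrt(n).  Requires n >= 2.
    """
    vals = np.asarray([float(v) for v in values], dtype=float)
    if vals.size < 2:
        raise DomainError("SEM needs at least 2 values")
    return float(np.std(vals, ddof=1) / math.sqrt(vals.size))


def overall_pci(
    dataset: BarcodeDataset,
    matrix: DistanceMatrix,
    species_results: list[SpeciesPCI] | None = None,
) -> PCISummary:
    """Dataset-level PCIs: unweighted means over non-singleton species.

    With one non-singleton species the SEM is reported as 0 by
    convention (a single value has no dispersion estimate).
    """
    if species_results is None:
        species_results = [
            species_pci(dataset, matrix, sp)
            for sp in dataset.non_singleton_species()
        ]
    if not species_results:
        raise DomainError("no non-singleton species: dataset PCIs undefined")

    n = len(species_results)

    def mean(attr: str) -> Fraction:
        return sum(getattr(r, attr) for r in species_results) / n

    def sem(attr: str) -> float:
        if n < 2:
            return 0.0
        return sem_of_mean([getattr(r, attr) for r in species_results])

    return PCISummary(
        n_species=n,
        p_B=float(mean("p_B")), p_U=float(mean("p_U")),
        p_A=float(mean("p_A")), p_F=float(mean("p_F")),
        sem_B=sem("p_B"), sem_U=sem("p_U"),
        sem_A=sem("p_A"), sem_F=sem("p_F"),
        singleton_count=len(dataset.singleton_species()),
        unique_singleton_count=dataset.unique_singleton_count(),
    )
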