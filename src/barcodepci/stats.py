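"""Taxonomic unanimity test and paired pipeline comparisons.

The unanimity test asks whether samples from one annotation source
(say, expert taxonomy) have unanimous nearest neighbors more often than
samples from another (say, plain GenBank records).  It borrows the
formal machinery of the log-rank test from survival analysis but
imposes no temporal structure: each 2x2 table is a species, not a time
point.  Per species s, with A/C the in-group unanimous/non-unanimous
counts and B/D the out-group ones (N = A+B+C+D):

    O_s = A,   E_s = (A+C)(A+B)/N
    sigma_s^2 = (A+C)(B+D)(A+B)(C+D) / (N^2 (N-1))   [hypergeometric]

X = sum(O_s - E_s) is approximately N(0, sigma^2 = sum sigma_s^2), and
Z = X/sigma gives a one-sided upper-tail p-value.  Because X lives on a
unit lattice (the margins fix E_s and A is an integer), a continuity
correction of 0.5/sigma toward zero is also reported; the paper's
convention of quoting "uncorrected Z minus its correction" is followed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats as sps

from .distance import DistanceMatrix, nearest_neighbors
from .errors import DegenerateTestError, DomainError, MetadataError
from .io import BarcodeDataset


@dataclass(frozen=True)
class SpeciesTable2x2:
    """Unanimity-by-group counts for one species.

    A: in-group unanimous; C: in-group non-unanimous;
    B: out-group unanimous; D: out-group non-unanimous.
    """

    species: str
    A: int
    B: int
    C: int
    D: int

    def __post_init__(self):
        if min(self.A, self.B, self.C, self.D) < 0:
            raise DomainError("negative count in 2x2 table")
        if self.N < 2:
            raise DomainError("2x2 table needs N >= 2 samples")

    @property
    def N(self) -> int:
        return self.A + self.B + self.C + self.D

    @property
    def expected(self) -> Fraction:
        """E_s: expected in-group unanimous count under independence."""
        return Fraction((self.A + self.C) * (self.A + self.B), self.N)

    @property
    def observed(self) -> int:
        return self.A

    @property
    def variance(self) -> Fraction:
        """Hypergeometric variance of A conditioned on all four margins."""
        n = self.N
        return Fraction(
            (self.A + self.C) * (self.B + self.D)
            * (self.A + self.B) * (self.C + self.D),
            n * n * (n - 1),
        )


@dataclass(frozen=True)
class UnanimityTestResult:
    """Outcome of the taxonomic unanimity test."""

    tables: tuple[SpeciesTable2x2, ...]
    X: float                    # sum over species of O_s - E_s
    sigma2: float               # sum of per-species hypergeometric variances
    Z_uncorrected: float
    continuity: float           # correction magnitude, 0.5/sigma
    Z_corrected: float
    p_one_sided: float          # upper tail, from Z_corrected
    p_one_sided_uncorrected: float

    @property
    def n_informative(self) -> int:
        """Species whose table has no zero margin (sigma_s^2 > 0)."""
        return sum(1 for t in self.tables if t.variance > 0)

    def to_dict(self) -> dict:
        return {
            "n_species": len(self.tables),
            "n_informative": self.n_informative,
            "X": self.X,
            "sigma2": self.sigma2,
            "Z_uncorrected": self.Z_uncorrected,
            "continuity": self.continuity,
            "Z_corrected": self.Z_corrected,
            "p_one_sided": self.p_one_sided,
            "p_one_sided_uncorrected": self.p_one_sided_uncorrected,
        }


def unanimity_test_from_flags(
    species: list[str], in_group: list[bool], unanimous: list[int]
) -> UnanimityTestResult:
    """Unanimity test from precomputed per-sample flags.

    The three lists are parallel over samples.  Species with a single
    sample are skipped (no table); species with any zero margin have
    sigma_s^2 = 0 and contribute nothing to X or sigma^2 but are kept in
    the output tables for scrutiny.
    """
    per_species: dict[str, list[int]] = {}
    for i, sp in enumerate(species):
        per_species.setdefault(sp, []).append(i)

    tables = []
    for sp, idx in per_species.items():
        if len(idx) < 2:
            continue
        a = sum(1 for i in idx if in_group[i] and unanimous[i])
        c = sum(1 for i in idx if in_group[i] and not unanimous[i])
        b = sum(1 for i in idx if not in_group[i] and unanimous[i])
        d = sum(1 for i in idx if not in_group[i] and not unanimous[i])
        tables.append(SpeciesTable2x2(sp, a, b, c, d))

    X = Fraction(0)
    sigma2 = Fraction(0)
    for t in tables:
        if t.variance > 0:
            X += t.observed - t.expected
            sigma2 += t.variance
    if sigma2 == 0:
        raise DegenerateTestError(
            "every species table has a zero margin; the unanimity test "
            "statistic has zero variance"
        )

    sigma = math.sqrt(float(sigma2))
    z = float(X) / sigma
    corr = 0.5 / sigma
    # toward zero, never past it
    z_corr = math.copysign(max(abs(z) - corr, 0.0), z) if z != 0 else 0.0
    return UnanimityTestResult(
        tables=tuple(tables),
        X=float(X),
        sigma2=float(sigma2),
        Z_uncorrected=z,
        continuity=corr,
        Z_corrected=z_corr,
        p_one_sided=float(sps.norm.sf(z_corr)),
        p_one_sided_uncorrected=float(sps.norm.sf(z)),
    )


def unanimity_test(
    dataset: BarcodeDataset, matrix: DistanceMatrix, group_tag: str
) -> UnanimityTestResult:
    """Taxonomic unanimity test on a dataset split by one group tag.

    Samples carrying ``group_tag`` form group 1 (hypothesized MORE
    unanimous; upper tail).  Unanimity is computed on the combined
    dataset: neighbors are drawn from all samples of both groups.
    """
    if not any(group_tag in s.groups for s in dataset.samples):
        raise MetadataError(f"group tag {group_tag!r} not present in dataset")
    species_of = dataset.species_of
    species, flags, unanim = [], [], []
    for s in dataset.samples:
        nr = nearest_neighbors(matrix, s.sample_id, species_of)
        species.append(s.species)
        flags.append(group_tag in s.groups)
        unanim.append(nr.U)
    return unanimity_test_from_flags(species, flags, unanim)


# ---------------------------------------------------------------------------
# paired pipeline comparisons over species PCIs


def _signed_rank_exact_p(diffs: np.ndarray) -> float:
    """Exact two-sided p for the Wilcoxon signed-rank statistic.

    Handles tied |differences| with midranks: the null distribution of
    W+ (sum of ranks of positive differences, each sign a fair coin) is
    built by convolution over doubled midranks, which are integers.
    """
    ranks = sps.rankdata(np.abs(diffs))          # midranks, possibly .5
    r2 = np.round(ranks * 2).astype(int)         # integer lattice
    w_obs = int(round(float(np.sum(r2[diffs > 0]))))

    dist = {0: 1}
    for r in r2:
        nxt: dict[int, int] = {}
        for w, c in dist.items():
            nxt[w] = nxt.get(w, 0) + c
            nxt[w + r] = nxt.get(w + r, 0) + c
        dist = nxt
    total = 2 ** len(r2)
    mean2 = sum(r2) / 2.0
    dev = abs(w_obs - mean2)
    extreme = sum(c for w, c in dist.items() if abs(w - mean2) >= dev - 1e-9)
    return min(1.0, extreme / total)


def signed_rank_compare(pci_pairs) -> tuple[int, float]:
    """Wilcoxon matched-pair signed-rank test on species PCI pairs.

    ``pci_pairs`` is an iterable of (species, p_s under pipeline 1,
    p_s under pipeline 2).  Zero differences are dropped; returns the
    number of species where the pipelines differ and the two-sided p
    (exact enumeration for n <= 25, normal approximation with tie
    correction above).
    """
    diffs = np.array([float(b) - float(a) for _, a, b in pci_pairs])
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        return 0, 1.0
    if n <= 25:
        return n, _signed_rank_exact_p(diffs)
    res = sps.wilcoxon(diffs, correction=False, method="approx")
    return n, float(res.pvalue)


def sign_test_compare(pci_pairs) -> tuple[int, float]:
    """Exact binomial sign test on species PCI pairs.

    Unlike the signed-rank test the sign test ignores the magnitudes of
    the differences, so sampling biases in how far apart the pipelines
    land do not affect it.
    """
    diffs = [float(b) - float(a) for _, a, b in pci_pairs]
    pos = sum(1 for d in diffs if d > 0)
    neg = sum(1 for d in diffs if d < 0)
    n = pos + neg
    if n == 0:
        return 0, 1.0
    return n, float(sps.binomtest(pos, n, 0.5).pvalue)


def species_fisher_exact(table: SpeciesTable2x2) -> float:
    """One-sided Fisher exact p for one species table.

    Upper-tail hypergeometric probability of seeing at least A in-group
    unanimous samples given the margins — flags individual species where
    the two sources disagree more than chance allows.
    """
    n = table.N
    return float(sps.hypergeom.sf(table.A - 1, n, table.A + table.B,
                                  table.A + table.C))


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni-adjusted p-values (optional; off by default everywhere)."""
    ps = list(p_values)
    m = m if m is not None else len(ps)
    return [min(1.0, p * m) for p in ps]
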