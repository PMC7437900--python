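"""p-distances, leave-one-out nearest neighbors, and barcode-gap extremes.

The p-distance between two aligned sequences is the fraction of
unambiguous nucleotide pairs that mismatch: alignment columns where
either sequence shows a gap or any IUPAC ambiguity code are excluded
from both numerator and denominator.

Distances are held internally as exact rationals — integer mismatch and
comparable-site counts — and every comparison (nearest-neighbor ties,
barcode-gap inequalities) is done by cross-multiplication of integers.
Tie detection by float equality is fragile; two pairs at 1/3 must tie
exactly even though 0.3333... does not round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .errors import AlignmentError, DomainError, IncomparablePairError
from .io import BarcodeDataset

_BASES = "ACGT"


def _encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3 and every other symbol (gap, ambiguity) as 255."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for code, base in enumerate(_BASES):
        out[arr == ord(base)] = code
    return out


def p_distance(seq_a: str, seq_b: str) -> float:
    """p-distance between two aligned sequences of equal length."""
    m, c = p_distance_counts(seq_a, seq_b)
    return m / c


def p_distance_counts(seq_a: str, seq_b: str) -> tuple[int, int]:
    """(mismatches, comparable positions) for one aligned pair.

    Raises :class:`IncomparablePairError` when no column is comparable.
    """
    if len(seq_a) != len(seq_b):
        raise AlignmentError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    a, b = _encode(seq_a), _encode(seq_b)
    valid = (a != 255) & (b != 255)
    comparable = int(valid.sum())
    if comparable == 0:
        raise IncomparablePairError("<seq_a>", "<seq_b>")
    mismatches = int((valid & (a != b)).sum())
    return mismatches, comparable


@dataclass(frozen=True)
class DistanceMatrix:
    """All pairwise p-distances of a dataset, held as exact rationals.

    ``mismatches[i, j] / comparable_sites[i, j]`` is the p-distance
    between samples i and j; ``comparable_sites`` counts the alignment
    columns used for each pair.
    """

    ids: tuple[str, ...]
    mismatches: np.ndarray       # (n, n) int64, zero diagonal
    comparable_sites: np.ndarray  # (n, n) int64, zero diagonal

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, sample_id: str) -> int:
        try:
            return self.ids.index(sample_id)
        except ValueError:
            raise DomainError(f"unknown sample id {sample_id!r}") from None

    def fraction(self, i: int, j: int) -> Fraction:
        """Exact p-distance between samples at positions i and j."""
        if i == j:
            return Fraction(0)
        return Fraction(int(self.mismatches[i, j]), int(self.comparable_sites[i, j]))

    @property
    def d(self) -> np.ndarray:
        """Float view of the distances (diagonal 0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.mismatches / np.where(self.comparable_sites == 0, 1,
                                             self.comparable_sites)
        np.fill_diagonal(out, 0.0)
        return out

    def subset(self, indices) -> "DistanceMatrix":
        """Slice the matrix to a subset of samples (no recomputation)."""
        idx = np.asarray(indices, dtype=int)
        return DistanceMatrix(
            tuple(self.ids[i] for i in idx),
            self.mismatches[np.ix_(idx, idx)].copy(),
            self.comparable_sites[np.ix_(idx, idx)].copy(),
        )

    # -- TSV round-trip ----------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write a square symmetric distance TSV (ids as header row/column)."""
        import pandas as pd

        pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids)).to_csv(
            path, sep="\t", float_format="%.12g"
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        """Read a square symmetric distance TSV.

        Decimal strings are converted to exact fractions, so ties among
        equal printed values are still detected exactly; per-pair
        comparable-site counts are not recoverable from a plain matrix
        and are set to the common denominator.
        """
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        if list(df.index) != list(df.columns):
            raise AlignmentError("distance TSV row and column ids differ")
        n = len(df)
        fracs = [[Fraction(df.iat[i, j]) for j in range(n)] for i in range(n)]
        for i in range(n):
            for j in range(n):
                if fracs[i][j] != fracs[j][i]:
                    raise AlignmentError("distance TSV is not symmetric")
                if not 0 <= fracs[i][j] <= 1:
                    raise AlignmentError("distances must lie in [0, 1]")
            if fracs[i][i] != 0:
                raise AlignmentError("distance TSV diagonal must be zero")
        denom = 1
        for i in range(n):
            for j in range(i + 1, n):
                denom = denom * fracs[i][j].denominator // np.gcd(
                    denom, fracs[i][j].denominator
                )
        mism = np.zeros((n, n), dtype=np.int64)
        comp = np.zeros((n, n), dtype=np.int64)
        for i in range(n):
            for j in range(n):
                if i != j:
                    mism[i, j] = int(fracs[i][j] * denom)
                    comp[i, j] = denom
        return cls(tuple(df.index), mism, comp)


def build_distance_matrix(dataset: BarcodeDataset) -> DistanceMatrix:
    """All pairwise p-distances of a dataset.

    Computed with one-hot matrix products: for each base b, the matrix
    of per-pair co-occurrences of b is ``M_b @ M_b.T``; comparable-site
    counts are ``V @ V.T`` over the validity mask.  Counts stay exact
    (they are small integers, far below float53 precision).
    """
    if len(dataset) < 2:
        raise DomainError("need at least 2 samples for a distance matrix")
    enc = np.stack([_encode(s.sequence) for s in dataset.samples])
    valid = (enc != 255).astype(np.float64)
    comparable = (valid @ valid.T).round().astype(np.int64)
    matches = np.zeros_like(comparable)
    for code in range(4):
        m = (enc == code).astype(np.float64)
        matches += (m @ m.T).round().astype(np.int64)
    mismatches = comparable - matches
    np.fill_diagonal(mismatches, 0)
    np.fill_diagonal(comparable, 0)

    off_diag_zero = (comparable == 0) & ~np.eye(len(dataset), dtype=bool)
    if off_diag_zero.any():
        i, j = map(int, np.argwhere(off_diag_zero)[0])
        raise IncomparablePairError(dataset.samples[i].sample_id,
                                    dataset.samples[j].sample_id)
    return DistanceMatrix(tuple(dataset.sample_ids), mismatches, comparable)


@dataclass(frozen=True)
class NeighborResult:
    """Leave-one-out nearest neighbors of one query sample.

    ``neighbor_ids`` holds every sample (query excluded) at the minimum
    p-distance — all ties included; ``f`` is the conspecific fraction of
    those neighbors and ``U`` is 1 iff f == 1 (unanimous).
    """

    sample_id: str
    neighbor_ids: frozenset[str]
    f: Fraction
    U: int

    def __post_init__(self):
        if not self.neighbor_ids:
            raise DomainError("neighbor set may not be empty")
        if self.sample_id in self.neighbor_ids:
            raise DomainError("query may not be its own neighbor")


def _min_distance_indices(matrix: DistanceMatrix, qi: int) -> list[int]:
    """Positions of all samples at minimal exact distance from query qi."""
    mism, comp = matrix.mismatches, matrix.comparable_sites
    best: list[int] = []
    bm = bc = None  # best mismatches/comparable as a rational bm/bc
    for j in range(len(matrix)):
        if j == qi:
            continue
        m, c = int(mism[qi, j]), int(comp[qi, j])
        if bm is None:
            best, bm, bc = [j], m, c
            continue
        # compare m/c with bm/bc exactly
        lhs, rhs = m * bc, bm * c
        if lhs < rhs:
            best, bm, bc = [j], m, c
        elif lhs == rhs:
            best.append(j)
    return best


def nearest_neighbors(
    matrix: DistanceMatrix, query_id: str, species_of: dict[str, str]
) -> NeighborResult:
    """Leave-one-out nearest-neighbor result for one query sample."""
    if len(matrix) < 2:
        raise DomainError("need at least 2 samples for nearest neighbors")
    qi = matrix.index_of(query_id)
    idx = _min_distance_indices(matrix, qi)
    species = species_of[query_id]
    same = sum(1 for j in idx if species_of[matrix.ids[j]] == species)
    f = Fraction(same, len(idx))
    return NeighborResult(
        sample_id=query_id,
        neighbor_ids=frozenset(matrix.ids[j] for j in idx),
        f=f,
        U=1 if f == 1 else 0,
    )


def gap_distances(
    matrix: DistanceMatrix, species: str, species_of: dict[str, str]
) -> tuple[float, float]:
    """(max intraspecies, min interspecies) p-distance for one species.

    The species has a barcode gap iff max_intra < min_inter strictly;
    equality means no gap.  Samples of every other species — singletons
    included — count as interspecies partners.
    """
    max_intra, min_inter = gap_distance_fractions(matrix, species, species_of)
    return float(max_intra), float(min_inter)


def gap_distance_fractions(
    matrix: DistanceMatrix, species: str, species_of: dict[str, str]
) -> tuple[Fraction, Fraction]:
    """Exact-rational version of :func:`gap_distances`."""
    inside = [i for i, sid in enumerate(matrix.ids) if species_of[sid] == species]
    outside = [i for i in range(len(matrix)) if i not in set(inside)]
    if len(inside) < 2:
        raise DomainError(
            f"species {species!r} needs >= 2 samples for a barcode gap"
        )
    if not outside:
        raise DomainError("no sample outside the species")
    max_intra = max(
        matrix.fraction(i, j) for k, i in enumerate(inside) for j in inside[k + 1:]
    )
    min_inter = min(matrix.fraction(i, j) for i in inside for j in outside)
    return max_intra, min_inter


def has_barcode_gap(
    matrix: DistanceMatrix, species: str, species_of: dict[str, str]
) -> bool:
    """Strict-inequality barcode gap decision on exact rationals.

    When the dataset holds no sample outside the species, the minimum
    interspecies distance is a minimum over an empty set (+infinity)
    and the gap holds vacuously.
    """
    try:
        max_intra, min_inter = gap_distance_fractions(matrix, species, species_of)
    except DomainError as exc:
        if "outside" in str(exc):
            return True
        raise
    return max_intra < min_inter
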