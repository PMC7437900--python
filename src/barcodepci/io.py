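"""Aligned barcode datasets: reading, validation, filtering, result tables.

A dataset is an aligned FASTA plus a tab-separated metadata table with
columns ``sample_id``, ``species`` and any number of optional 0/1 group
columns (e.g. ``taxonomic``, ``long``).  Species labels are compared
exactly and case-sensitively: one-letter differences between labels are
real (misspelled annotations must split species, they are exactly the
kind of error this package detects).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, EmptyDatasetError, InputError, MetadataError

_GAP = "-"
# IUPAC nucleotide one-letter codes after U->T mapping, plus gap.
_ALLOWED = set("ACGTRYSWKMBDHVN" + _GAP)

#: precision used when result tables are written and re-read
TABLE_SIGNIFICANT_DIGITS = 12


@dataclass(frozen=True)
class SampleRecord:
    """One barcode sample: an aligned sequence with its annotation."""

    sample_id: str
    species: str
    sequence: str
    groups: frozenset[str] = field(default_factory=frozenset)

    @property
    def ungapped_length(self) -> int:
        """Number of non-gap symbols (the sequence's real length)."""
        return len(self.sequence) - self.sequence.count(_GAP)

    def __post_init__(self):
        if not self.sample_id:
            raise MetadataError("empty sample_id")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise AlignmentError(
                f"sample {self.sample_id!r}: unexpected symbols {sorted(bad)!r}"
            )


@dataclass(frozen=True)
class BarcodeDataset:
    """An ordered collection of samples sharing one alignment.

    Replicate (identical) sequences are allowed and retained as distinct
    samples.  Singleton species (one sample) stay in the dataset — they
    act as decoys in nearest-neighbor searches — but are excluded from
    species-level PCI averages.
    """

    samples: tuple[SampleRecord, ...]
    alignment_width: int

    def __post_init__(self):
        if not self.samples:
            raise EmptyDatasetError("dataset has no samples")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise MetadataError(f"duplicate sample ids: {dupes}")
        for s in self.samples:
            if len(s.sequence) != self.alignment_width:
                raise AlignmentError(
                    f"sample {s.sample_id!r} has length {len(s.sequence)}, "
                    f"alignment width is {self.alignment_width}"
                )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def species_of(self) -> dict[str, str]:
        """Map sample_id -> species label."""
        return {s.sample_id: s.species for s in self.samples}

    @property
    def species_index(self) -> dict[str, list[int]]:
        """Map species -> positions of its samples, in dataset order."""
        index: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            index.setdefault(s.species, []).append(i)
        return index

    def non_singleton_species(self) -> list[str]:
        """Species with >= 2 samples, in first-appearance order."""
        return [sp for sp, pos in self.species_index.items() if len(pos) >= 2]

    def singleton_species(self) -> list[str]:
        return [sp for sp, pos in self.species_index.items() if len(pos) == 1]

    def unique_singleton_count(self) -> int:
        """Singletons whose sequence occurs nowhere else in the dataset.

        Dataset-level PCI reports should carry this count alongside the
        averages: a singleton with a unique sequence is unidentifiable
        by nearest neighbors no matter how good the pipeline is.
        """
        from collections import Counter

        seq_counts = Counter(s.sequence for s in self.samples)
        return sum(
            1
            for sp in self.singleton_species()
            for i in self.species_index[sp]
            if seq_counts[self.samples[i].sequence] == 1
        )

    def relabel(self, sample_id: str, species: str) -> "BarcodeDataset":
        """Return a copy with one sample's species label changed."""
        if sample_id not in self.species_of:
            raise MetadataError(f"unknown sample id {sample_id!r}")
        return BarcodeDataset(
            tuple(
                replace(s, species=species) if s.sample_id == sample_id else s
                for s in self.samples
            ),
            self.alignment_width,
        )


def _normalize_sequence(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_dataset(fasta_path, metadata_path) -> BarcodeDataset:
    """Read an aligned FASTA and its metadata TSV into a dataset.

    Every FASTA id must appear exactly once in the metadata; all
    sequences must share one length.  Sequences are uppercased and RNA
    ``U`` is mapped to ``T``.  Any metadata column other than
    ``sample_id``/``species`` is read as a 0/1 group flag.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {fasta_path}")

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("sample_id", "species"):
        if col not in meta.columns:
            raise MetadataError(f"metadata lacks required column {col!r}")
    if meta["sample_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"])
        raise MetadataError(f"duplicate sample ids in metadata: {dupes}")
    meta = meta.set_index("sample_id")
    group_cols = [c for c in meta.columns if c != "species"]

    width = len(records[0].seq)
    samples = []
    for rec in records:
        if rec.id not in meta.index:
            raise MetadataError(f"FASTA id {rec.id!r} missing from metadata")
        seq = _normalize_sequence(str(rec.seq))
        if len(seq) != width:
            raise AlignmentError(
                f"record {rec.id!r} has length {len(seq)}, expected {width}"
            )
        row = meta.loc[rec.id]
        groups = frozenset(
            c for c in group_cols if str(row[c]).strip() in ("1", "1.0", "true", "True")
        )
        samples.append(SampleRecord(rec.id, str(row["species"]), seq, groups))

    fasta_ids = {s.sample_id for s in samples}
    extra = set(meta.index) - fasta_ids
    if extra:
        raise MetadataError(f"metadata rows without FASTA records: {sorted(extra)}")
    return BarcodeDataset(tuple(samples), width)


def filter_by_group(dataset: BarcodeDataset, group: str, keep: bool) -> BarcodeDataset:
    """Subset a dataset by a group tag, keeping the original alignment columns.

    With ``keep=True`` samples carrying the tag are retained; with
    ``keep=False`` they are removed.  Columns are never re-aligned, so a
    filtered dataset is directly comparable with its parent (the
    "extract while maintaining the alignment" pipeline).
    """
    tagged = any(group in s.groups for s in dataset.samples)
    if not tagged:
        raise MetadataError(f"group tag {group!r} not present in dataset")
    kept = tuple(s for s in dataset.samples if (group in s.groups) == keep)
    if not kept:
        raise EmptyDatasetError(f"filtering on {group!r} removed every sample")
    return BarcodeDataset(kept, dataset.alignment_width)


def exclude_placeholder_species(
    dataset: BarcodeDataset, pattern: str = r"\bsp\.$"
) -> BarcodeDataset:
    """Drop samples whose species label is a non-specific placeholder.

    The default pattern matches labels ending in ``sp.`` ("Ramaria sp."
    and the like), which name no species and would otherwise enter the
    analysis as spurious decoys.
    """
    rx = re.compile(pattern)
    kept = tuple(s for s in dataset.samples if not rx.search(s.species))
    if not kept:
        raise EmptyDatasetError("placeholder filter removed every sample")
    return BarcodeDataset(kept, dataset.alignment_width)


# ---------------------------------------------------------------------------
# result tables

_PCI_COLUMNS = ["species", "n_samples", "p_B", "p_U", "p_A", "p_F"]


def write_species_pci_table(results, path) -> None:
    """Write per-species PCIs as a TSV, one row per non-singleton species.

    Values are written with enough digits to round-trip at
    ``TABLE_SIGNIFICANT_DIGITS`` significant digits.
    """
    rows = [
        {
            "species": r.species,
            "n_samples": r.n_samples,
            "p_B": float(r.p_B),
            "p_U": float(r.p_U),
            "p_A": float(r.p_A),
            "p_F": float(r.p_F),
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=_PCI_COLUMNS)
    df.to_csv(path, sep="\t", index=False,
              float_format=f"%.{TABLE_SIGNIFICANT_DIGITS}g")


def read_species_pci_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_species_pci_table`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_PCI_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"species PCI table lacks columns {sorted(missing)}")
    return df


def write_summary(summary, path) -> None:
    """Write a dataset-level PCI summary as JSON."""
    import json

    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
        fh.write("\n")
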