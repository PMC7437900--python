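"""Database-growth curves by uniform resampling without replacement.

How would the dataset-level PCIs look if the reference database were
smaller?  For each target size, samples are drawn uniformly without
replacement, the four dataset-level PCIs are recomputed over the
species that remain non-singleton IN THE RESAMPLE (neighbors drawn only
within the resample), and the mean and sample SD across replicates are
reported.  At the full dataset size every draw returns the whole
dataset, so the SD is exactly 0.

Distances are sliced from the precomputed matrix — no realignment per
replicate; reusing the alignment does not materially change
identifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix
from .errors import DomainError
from .io import BarcodeDataset
from .pci import overall_pci

_PCI_NAMES = ("p_B", "p_U", "p_A", "p_F")

#: redraws allowed when a replicate has no non-singleton species
_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class ResampleCurve:
    """Mean and sample SD of each dataset-level PCI per resample size."""

    sizes: tuple[int, ...]
    means: dict[str, np.ndarray]   # name -> array over sizes
    sds: dict[str, np.ndarray]
    n_replicates: int
    seed: int
    n_redraws: int                  # degenerate replicates that were redrawn

    def to_frame(self):
        import pandas as pd

        cols = {"size": list(self.sizes)}
        for name in _PCI_NAMES:
            cols[f"{name}_mean"] = self.means[name]
            cols[f"{name}_sd"] = self.sds[name]
        return pd.DataFrame(cols)


def resample_pcis(
    dataset: BarcodeDataset,
    matrix: DistanceMatrix,
    sizes,
    n_replicates: int = 1000,
    seed: int = 0,
) -> ResampleCurve:
    """Resampling curve of the four dataset-level PCIs.

    A replicate whose subset has no species with two or more samples
    carries no PCI; it is redrawn (the count of redraws is reported in
    the curve).  Reproducible: the same seed yields the same curve.
    """
    sizes = [int(k) for k in sizes]
    n = len(dataset)
    for k in sizes:
        if not 2 <= k <= n:
            raise DomainError(f"resample size {k} outside [2, {n}]")
    if n_replicates < 1:
        raise DomainError("need at least one replicate")

    rng = np.random.default_rng(seed)
    means = {name: np.empty(len(sizes)) for name in _PCI_NAMES}
    sds = {name: np.empty(len(sizes)) for name in _PCI_NAMES}
    n_redraws = 0

    for si, k in enumerate(sizes):
        values = {name: np.empty(n_replicates) for name in _PCI_NAMES}
        for rep in range(n_replicates):
            for attempt in range(_MAX_REDRAWS + 1):
                idx = np.sort(rng.choice(n, size=k, replace=False))
                sub = BarcodeDataset(
                    tuple(dataset.samples[i] for i in idx),
                    dataset.alignment_width,
                )
                if sub.non_singleton_species():
                    break
                n_redraws += 1
            else:
                raise DomainError(
                    f"size {k}: no draw with a non-singleton species after "
                    f"{_MAX_REDRAWS} redraws"
                )
            summary = overall_pci(sub, matrix.subset(idx))
            for name in _PCI_NAMES:
                values[name][rep] = getattr(summary, name)
        for name in _PCI_NAMES:
            v = values[name]
            means[name][si] = v.mean()
            # identical replicates have exactly zero spread; np.std's
            # rounding must not blur that (e.g. at the full dataset size)
            sds[name][si] = (
                v.std(ddof=1) if n_replicates > 1 and np.ptp(v) > 0 else 0.0
            )

    return ResampleCurve(tuple(sizes), means, sds, n_replicates, seed, n_redraws)


def plot_curve(curve: ResampleCurve, path) -> None:
    """Size-vs-PCI plot with SD error bars, four series."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = {
        "p_B": "Barcode Gap PCI",
        "p_U": "Unanimous PCI",
        "p_A": "Average Unanimous PCI",
        "p_F": "Fractional PCI",
    }
    fig, ax = plt.subplots(figsize=(6, 4))
    for name in _PCI_NAMES:
        ax.errorbar(curve.sizes, curve.means[name], yerr=curve.sds[name],
                    marker="s", capsize=3, label=labels[name])
    ax.set_xlabel("resampled dataset size")
    ax.set_ylabel("PCI")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
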