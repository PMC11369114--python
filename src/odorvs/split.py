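"""Iterative stratified train/test splitting for multi-label data.

Random splitting of heavily imbalanced multi-label data routinely drops
minority labels from one side of the split. Iterative stratification
(Sechidis-style greedy assignment) processes labels from rarest to most
frequent and assigns each remaining sample to the split whose desired quota
for that label is largest, keeping per-label train/test frequencies close.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from odorvs.labels import LabelMatrix


@dataclass
class SplitResult:
    train_indices: np.ndarray = field(repr=False)
    test_indices: np.ndarray = field(repr=False)
    train_frequencies: np.ndarray = field(repr=False)
    test_frequencies: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        if np.intersect1d(self.train_indices, self.test_indices).size:
            raise ValueError("train and test indices overlap")

    @property
    def frequency_gap(self) -> float:
        """Mean absolute per-label train/test frequency difference."""
        return float(np.abs(self.train_frequencies - self.test_frequencies).mean())

    def write(self, molecule_ids: list[str], path: str | Path, sep: str = "\t") -> None:
        split = np.empty(len(molecule_ids), dtype=object)
        split[self.train_indices] = "train"
        split[self.test_indices] = "test"
        pd.DataFrame({"molecule_id": molecule_ids, "split": split}).to_csv(
            path, sep=sep, index=False
        )


def _frequencies(labels: LabelMatrix, idx: np.ndarray) -> np.ndarray:
    if idx.size == 0:
        return np.zeros(labels.n_notes)
    return labels.matrix[idx].sum(axis=0) / idx.size


def iterative_stratified_split(
    labels: LabelMatrix, test_fraction: float = 0.2, seed: int = 0
) -> SplitResult:
    """Greedy iterative stratification into train/test.

    Repeatedly picks the label with fewest remaining positive samples and
    distributes its samples to the split with the greatest remaining desire
    for that label (ties: larger overall remaining capacity, then seeded
    shuffle). Deterministic for a fixed seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = labels.n_molecules
    if n < 2 or n * test_fraction < 1:
        raise ValueError(
            f"degenerate split: {n} samples at test_fraction {test_fraction}"
        )
    rng = np.random.default_rng(seed)
    y = labels.matrix.astype(bool)
    fracs = np.array([1.0 - test_fraction, test_fraction])
    # desired number of examples per split, and per (split, label)
    desired_total = fracs * n
    desired_label = fracs[:, None] * y.sum(axis=0)[None, :]
    assigned = np.full(n, -1)
    remaining = np.ones(n, dtype=bool)

    while remaining.any():
        label_counts = y[remaining].sum(axis=0)
        open_labels = np.flatnonzero(label_counts > 0)
        if open_labels.size == 0:
            # leftover samples (none under dataset convention): fill by quota
            for i in rng.permutation(np.flatnonzero(remaining)):
                s = int(np.argmax(desired_total))
                assigned[i] = s
                desired_total[s] -= 1
                remaining[i] = False
            break
        # rarest label among those still represented; ties -> lowest index
        lbl = open_labels[np.argmin(label_counts[open_labels])]
        members = np.flatnonzero(remaining & y[:, lbl])
        for i in rng.permutation(members):
            want = desired_label[:, lbl]
            best = np.flatnonzero(want == want.max())
            if best.size > 1:
                cap = desired_total[best]
                best = best[cap == cap.max()]
                s = int(rng.choice(best))
            else:
                s = int(best[0])
            assigned[i] = s
            desired_label[s, y[i]] -= 1
            desired_total[s] -= 1
            remaining[i] = False

    train_idx = np.sort(np.flatnonzero(assigned == 0))
    test_idx = np.sort(np.flatnonzero(assigned == 1))
    return SplitResult(
        train_idx,
        test_idx,
        _frequencies(labels, train_idx),
        _frequencies(labels, test_idx),
    )


def random_split(
    labels: LabelMatrix, test_fraction: float = 0.2, seed: int = 0
) -> SplitResult:
    """Plain random split (baseline for the stratification comparison)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = labels.n_molecules
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(int(round(n * test_fraction)), 1)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return SplitResult(
        train_idx,
        test_idx,
        _frequencies(labels, train_idx),
        _frequencies(labels, test_idx),
    )


def ks_representativeness(
    freqs_a: np.ndarray, freqs_b: np.ndarray
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test between class-frequency vectors.

    Used to check whether a subset's label-frequency distribution is
    representative of the full dataset's. Returns (D, p-value).
    """
    freqs_a = np.asarray(freqs_a, dtype=float)
    freqs_b = np.asarray(freqs_b, dtype=float)
    if freqs_a.shape != freqs_b.shape:
        raise ValueError("frequency vectors must have the same length")
    if freqs_a.size < 2:
        raise ValueError("need at least 2 classes")
    res = ks_2samp(freqs_a, freqs_b)
    return float(res.statistic), float(res.pvalue)


def read_split(
    path: str | Path, molecule_ids: list[str], sep: str = "\t"
) -> tuple[np.ndarray, np.ndarray]:
    """Read a (molecule_id, split) table back to index arrays."""
    df = pd.read_csv(path, sep=sep)
    pos = {m: i for i, m in enumerate(molecule_ids)}
    train, test = [], []
    for mid, s in zip(df["molecule_id"], df["split"]):
        (train if s == "train" else test).append(pos[str(mid)])
    return np.sort(train).astype(int), np.sort(test).astype(int)
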