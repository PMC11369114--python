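"""Synthetic odor-dataset generator: skew, band structure, determinism."""

import numpy as np
import pytest

from odorvs.featurize import read_peak_table, write_peak_table
from odorvs.labels import LabelMatrix
from odorvs.synthetic import (
    SyntheticConfig,
    constructed_evidence_dataset,
    generate_label_matrix,
    generate_spectra,
    igd_like_config,
)


class TestLabelMatrix:
    def test_single_class_forces_full_column(self):
        cfg = SyntheticConfig(n_molecules=50, n_classes=1, seed=0)
        labels = generate_label_matrix(cfg)
        assert labels.matrix.shape == (50, 1)
        assert labels.class_frequencies[0] == 1.0

    def test_every_molecule_has_a_label(self, small_dataset):
        _, labels, _, _ = small_dataset
        assert (labels.matrix.sum(axis=1) >= 1).all()

    def test_fixed_seed_reproduces_matrix_exactly(self):
        cfg = SyntheticConfig(n_molecules=100, n_classes=10, seed=3)
        a = generate_label_matrix(cfg)
        b = generate_label_matrix(cfg)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_imbalanced_conditions_match_real_odor_data(self):
        """Top class ~27% of molecules, rarest under 1% (109 classes)."""
        labels = generate_label_matrix(igd_like_config(seed=0))
        freqs = labels.class_frequencies
        assert freqs[0] == pytest.approx(0.27, abs=0.05)
        assert freqs.min() < 0.01

    def test_frequencies_decay_with_rank(self):
        cfg = SyntheticConfig(n_molecules=2000, n_classes=30, seed=1)
        freqs = generate_label_matrix(cfg).class_frequencies
        # expected ordering holds up to sampling noise: compare to sorted
        assert np.corrcoef(freqs, np.sort(freqs)[::-1])[0, 1] > 0.98
        # log-log slope close to -skew_exponent for the common classes
        ranks = np.arange(1, 16)
        slope = np.polyfit(np.log(ranks), np.log(freqs[:15]), 1)[0]
        assert slope == pytest.approx(-cfg.skew_exponent, abs=0.3)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_molecules=0, n_classes=1)
        with pytest.raises(ValueError):
            SyntheticConfig(n_molecules=5, n_classes=10)
        with pytest.raises(ValueError):
            SyntheticConfig(n_molecules=10, n_classes=2,
                            class_bands={0: [(3900.0, 4100.0)], 1: [(1.0, 2.0)]})


class TestSpectra:
    def test_single_label_molecule_has_peak_in_its_band(self):
        cfg = SyntheticConfig(
            n_molecules=30, n_classes=1, label_density=1.0,
            class_bands={0: [(1700.0, 1750.0)]}, seed=0)
        labels = generate_label_matrix(cfg)
        for spec in generate_spectra(labels, cfg):
            in_band = (spec.wavenumbers >= 1700) & (spec.wavenumbers <= 1750)
            assert in_band.any()

    def test_all_wavenumbers_within_bfs(self, small_dataset):
        _, _, spectra, _ = small_dataset
        for spec in spectra:
            assert (spec.wavenumbers > 0).all()
            assert (spec.wavenumbers <= 4000).all()
            assert (spec.intensities > 0).all()

    def test_shared_label_pairs_overlap_more_than_random_pairs(self):
        """Band-driven generation: same-label molecules share spectral bins."""
        cfg = SyntheticConfig(n_molecules=200, n_classes=8, label_density=1.0,
                              background_fraction=0.3, seed=5)
        labels = generate_label_matrix(cfg)
        spectra = generate_spectra(labels, cfg)
        occupancy = np.zeros((200, 40), dtype=bool)  # 100 cm^-1 bins
        for i, spec in enumerate(spectra):
            occupancy[i, np.minimum((spec.wavenumbers // 100).astype(int), 39)] = True

        def mean_jaccard(pairs):
            vals = []
            for i, j in pairs:
                inter = (occupancy[i] & occupancy[j]).sum()
                union = (occupancy[i] | occupancy[j]).sum()
                vals.append(inter / union)
            return np.mean(vals)

        cls = labels.matrix.argmax(axis=1)
        rng = np.random.default_rng(0)
        same, diff = [], []
        while len(same) < 100 or len(diff) < 100:
            i, j = rng.integers(0, 200, 2)
            if i == j:
                continue
            (same if cls[i] == cls[j] else diff).append((i, j))
        assert mean_jaccard(same[:100]) > mean_jaccard(diff[:100])

    def test_config_mismatch_rejected(self, small_dataset):
        _, labels, _, _ = small_dataset
        wrong = SyntheticConfig(n_molecules=200, n_classes=9, seed=0)
        with pytest.raises(ValueError):
            generate_spectra(labels, wrong)

    def test_round_trip_through_featurize_readers(self, tmp_path, small_dataset):
        _, labels, spectra, _ = small_dataset
        ppath, lpath = tmp_path / "p.tsv", tmp_path / "l.tsv"
        write_peak_table(spectra, ppath)
        labels.write(lpath)
        spectra_back = read_peak_table(ppath)
        labels_back = LabelMatrix.read(lpath)
        assert len(spectra_back) == len(spectra)
        assert labels_back.n_molecules == labels.n_molecules
        # reader orders notes by frequency; compare per-molecule note sets
        for i in range(labels.n_molecules):
            orig = {labels.notes[j] for j in np.flatnonzero(labels.matrix[i])}
            back = {labels_back.notes[j]
                    for j in np.flatnonzero(labels_back.matrix[i])}
            assert orig == back


class TestConstructedEvidence:
    def test_single_label_with_all_peaks_in_class_band(self):
        labels, spectra, bands = constructed_evidence_dataset(
            n_molecules=30, seed=0)
        assert (labels.matrix.sum(axis=1) == 1).all()
        for i, spec in enumerate(spectra):
            lo, hi = bands[int(labels.matrix[i].argmax())]
            assert ((spec.wavenumbers >= lo) & (spec.wavenumbers <= hi)).all()

    def test_descriptor_evidence_confined_to_band(self):
        from odorvs.featurize import compute_gs_vs_batch

        labels, spectra, bands = constructed_evidence_dataset(
            n_molecules=20, seed=1)
        gsvs = compute_gs_vs_batch(spectra)
        grid = np.arange(5, 4001, 5)
        for i in range(20):
            lo, hi = bands[int(labels.matrix[i].argmax())]
            outside = (grid < lo - 100) | (grid > hi + 100)
            assert gsvs[i, outside].max() < 0.05
            # unit max up to the 5 cm^-1 sampling offset from the apex
            assert gsvs[i].max() > 0.95
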