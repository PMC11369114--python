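"""Reproducible end-to-end experiments on synthetic data.

Each function runs one self-contained study — descriptor dimensionality,
image-encoding properties, cluster composition, loss identities, split
representativeness, cost-sensitivity direction, explainability recovery —
and returns a flat dict of computed numbers. They are the package's
acceptance surface: `scripts/acceptance.py` serializes their outputs and
the test suite asserts on them.
"""

from __future__ import annotations

import numpy as np

from odorvs.cluster import ClusterAssignment, odor_note_composition
from odorvs.explain import gradcam_pp, permutation_importance
from odorvs.featurize import (
    PeakSpectrum,
    SmoothingParams,
    compute_gs_vs,
    compute_gs_vs_batch,
)
from odorvs.imaging import encode_image, gadf, gasf, markov_matrix, to_polar
from odorvs.labels import LabelMatrix
from odorvs.model import (
    ClassWeights,
    LossParams,
    ModelConfig,
    combined_loss,
    combined_loss_grad,
    compute_class_weights,
    focal_loss,
    micro_metrics,
    train_csmlp,
    wbce_loss,
)
from odorvs.nn import SmallCNN
from odorvs.split import iterative_stratified_split, random_split
from odorvs.synthetic import (
    SyntheticConfig,
    constructed_evidence_dataset,
    generate_label_matrix,
    generate_spectra,
)


def gsvs_dimensionality(seed: int = 0, n_molecules: int = 20) -> dict:
    """Descriptor length of the default GS_VS transform on random peak lists."""
    rng = np.random.default_rng(seed)
    params = SmoothingParams()
    lengths = []
    for i in range(n_molecules):
        n_peaks = int(rng.integers(1, 40))
        peaks = np.column_stack([
            rng.uniform(1.0, 4000.0, n_peaks),
            rng.exponential(20.0, n_peaks) + 1e-3,
        ])
        vec = compute_gs_vs(PeakSpectrum(f"m{i}", peaks), params)
        lengths.append(vec.values.size)
    return {"gsvs_length": float(np.unique(lengths)[0]) if len(set(lengths)) == 1
            else float("nan")}


def image_shape_check(seed: int = 0) -> dict:
    """Image geometry and Gramian channel structure before rescale."""
    rng = np.random.default_rng(seed)
    series = rng.uniform(0, 1, 800)
    img = encode_image(series)
    ch0, ch1 = img.raw_channel(0), img.raw_channel(1)
    return {
        "image_side": float(img.pixels.shape[0]),
        "image_channels": float(img.pixels.shape[2]),
        "gasf_asymmetry": float(np.abs(ch0 - ch0.T).max()),
        "gadf_symmetry_residual": float(np.abs(ch1 + ch1.T).max()),
    }


def composition_worked_example() -> dict:
    """%ON / %OM for a cluster holding 201 of a note's 500 occurrences.

    Reconstructs the arithmetic on an explicit 2000-molecule dataset: one
    cluster of 1151 molecules containing 201 carriers of the note.
    """
    n, cluster_size, in_cluster, total = 2000, 1151, 201, 500
    note = np.zeros(n, dtype=np.int8)
    note[:in_cluster] = 1                       # carriers inside the cluster
    note[cluster_size:cluster_size + (total - in_cluster)] = 1   # outside
    labels = LabelMatrix(
        [f"m{i}" for i in range(n)], ["green", "other"],
        # second note on every molecule keeps the >=1-label convention
        np.column_stack([note, np.ones(n, dtype=np.int8)]),
    )
    assign = ClusterAssignment(
        "kmeans", 2,
        np.where(np.arange(n) < cluster_size, 1, 2),
    )
    table = odor_note_composition(assign, labels).table
    row = table[(table.cluster == 1) & (table.note == "green")].iloc[0]
    return {"pct_on_green": float(row.pct_on), "pct_om_green": float(row.pct_om)}


def loss_identity_errors(seed: int = 0, n_batches: int = 20) -> dict:
    """Brute-force and algebraic oracles for FL / WBCEL / CL."""
    rng = np.random.default_rng(seed)
    max_brute = max_fl_bce = max_wbce_bce = max_cl_wbce = 0.0
    for _ in range(n_batches):
        n, c = int(rng.integers(2, 12)), int(rng.integers(1, 8))
        y = (rng.random((n, c)) < 0.4).astype(float)
        p = rng.uniform(0.01, 0.99, (n, c))
        w = ClassWeights(rng.uniform(0.1, 0.9, c), rng.uniform(0.1, 0.9, c))
        params = LossParams(gamma=float(rng.uniform(0, 4)),
                            delta=float(rng.uniform(0, 2)),
                            lam=float(rng.uniform(0, 2)), eps=1e-7)
        # element-by-element accumulation
        fl_brute = wb_brute = 0.0
        for i in range(n):
            for j in range(c):
                fl_brute -= ((1 - p[i, j]) ** params.gamma * y[i, j]
                             * np.log(p[i, j] + params.eps)
                             + p[i, j] ** params.gamma * (1 - y[i, j])
                             * np.log(1 - p[i, j] + params.eps))
                wb_brute -= (w.w_pos[j] ** params.delta * y[i, j]
                             * np.log(p[i, j] + params.eps)
                             + w.w_neg[j] ** params.delta * (1 - y[i, j])
                             * np.log(1 - p[i, j] + params.eps))
        fl_brute /= n
        wb_brute /= n
        fl = focal_loss(y, p, params.gamma, params.eps)
        wb = wbce_loss(y, p, w, params.delta, params.eps)
        cl = combined_loss(y, p, w, params)
        max_brute = max(max_brute, abs(fl - fl_brute), abs(wb - wb_brute),
                        abs(cl - (wb_brute + params.lam * fl_brute)))
        # identities
        bce = -np.mean(np.sum(y * np.log(p + 1e-7)
                              + (1 - y) * np.log(1 - p + 1e-7), axis=1))
        max_fl_bce = max(max_fl_bce, abs(focal_loss(y, p, 0.0, 1e-7) - bce))
        max_wbce_bce = max(max_wbce_bce, abs(wbce_loss(y, p, w, 0.0, 1e-7) - bce))
        zero_lam = LossParams(gamma=params.gamma, delta=params.delta,
                              lam=0.0, eps=params.eps)
        max_cl_wbce = max(max_cl_wbce, abs(
            combined_loss(y, p, w, zero_lam)
            - wbce_loss(y, p, w, params.delta, params.eps)))
    return {
        "loss_bruteforce_max_error": max_brute,
        "focal_gamma0_vs_bce_max_error": max_fl_bce,
        "wbce_delta0_vs_bce_max_error": max_wbce_bce,
        "cl_lambda0_vs_wbce_max_error": max_cl_wbce,
    }


def field_property_errors(seed: int = 0, n_series: int = 100) -> dict:
    """GASF/GADF/MTF invariants on random series."""
    rng = np.random.default_rng(seed)
    worst = {"mtf_row_sum_max_error": 0.0, "gasf_diag_identity_max_error": 0.0,
             "gadf_diag_max_abs": 0.0, "gadf_antisymmetry_max_error": 0.0,
             "gasf_diag_recovery_max_error": 0.0}
    for _ in range(n_series):
        n = int(rng.integers(8, 120))
        series = rng.uniform(0, 1, n)
        polar = to_polar(series)
        gs = gasf(polar).matrix
        gd = gadf(polar).matrix
        mk = markov_matrix(series, n_bins=int(rng.integers(2, 12)))
        worst["mtf_row_sum_max_error"] = max(
            worst["mtf_row_sum_max_error"],
            float(np.abs(mk.markov_matrix.sum(axis=1) - 1).max()))
        worst["gasf_diag_identity_max_error"] = max(
            worst["gasf_diag_identity_max_error"],
            float(np.abs(np.diag(gs) - (2 * series ** 2 - 1)).max()))
        worst["gadf_diag_max_abs"] = max(
            worst["gadf_diag_max_abs"], float(np.abs(np.diag(gd)).max()))
        worst["gadf_antisymmetry_max_error"] = max(
            worst["gadf_antisymmetry_max_error"],
            float(np.abs(gd + gd.T).max()))
        recovered = np.sqrt((np.diag(gs) + 1) / 2)
        worst["gasf_diag_recovery_max_error"] = max(
            worst["gasf_diag_recovery_max_error"],
            float(np.abs(recovered - series).max()))
    return worst


def split_gap_comparison(seed: int = 0, n_seeds: int = 20) -> dict:
    """Mean per-label train/test frequency gap: stratified vs random.

    Uses the heavily imbalanced default conditions (3000 molecules, 109
    classes, top class near 27%, rarest under 1%).
    """
    labels = generate_label_matrix(SyntheticConfig(seed=seed))
    gaps_strat, gaps_rand = [], []
    for s in range(n_seeds):
        gaps_strat.append(
            iterative_stratified_split(labels, 0.2, seed + s).frequency_gap)
        gaps_rand.append(random_split(labels, 0.2, seed + s).frequency_gap)
    return {
        "top_class_frequency_pct": float(labels.class_frequencies[0] * 100),
        "rarest_class_frequency_pct": float(labels.class_frequencies.min() * 100),
        "stratified_mean_gap": float(np.mean(gaps_strat)),
        "random_mean_gap": float(np.mean(gaps_rand)),
    }


def minority_recall_comparison(
    seed: int = 0,
    n_seeds: int = 3,
    n_molecules: int = 1000,
    n_classes: int = 20,
    epochs: int = 100,
) -> dict:
    """Minority-class recall: combined loss vs plain BCE, paired by seed.

    Bottom-quartile prevalence classes are pooled; both models share the
    architecture, split and initialization, differing only in the loss.
    """
    recalls_cl, recalls_bce, wins = [], [], 0
    for s in range(n_seeds):
        cfg = SyntheticConfig(n_molecules=n_molecules, n_classes=n_classes,
                              seed=seed + s)
        lm = generate_label_matrix(cfg)
        x = compute_gs_vs_batch(generate_spectra(lm, cfg))
        split = iterative_stratified_split(lm, 0.2, seed + s)
        quart = np.argsort(lm.class_frequencies)[: max(n_classes // 4, 1)]
        rec = {}
        for name, lp in (("cl", LossParams()),
                         ("bce", LossParams(gamma=0, delta=0, lam=0))):
            net, _ = train_csmlp(
                x, lm, split, ModelConfig(epochs=epochs, seed=seed + s), lp)
            te = split.test_indices
            y_hat = net.predict_proba(x[te]) >= 0.5
            y_te = lm.matrix[te]
            tp = int((y_hat[:, quart] & (y_te[:, quart] == 1)).sum())
            fn = int((~y_hat[:, quart] & (y_te[:, quart] == 1)).sum())
            rec[name] = tp / max(tp + fn, 1)
        recalls_cl.append(rec["cl"])
        recalls_bce.append(rec["bce"])
        wins += rec["cl"] > rec["bce"]
    return {
        "minority_recall_cl": float(np.mean(recalls_cl)),
        "minority_recall_bce": float(np.mean(recalls_bce)),
        "minority_recall_paired_wins": float(wins),
        "minority_recall_n_seeds": float(n_seeds),
    }


def explainability_recovery(
    seed: int = 0,
    pfi_molecules: int = 600,
    cnn_molecules: int = 120,
    cnn_epochs: int = 15,
    n_eval_images: int = 50,
) -> dict:
    """Recover known generating bands with PFI and GradCAM++.

    PFI arm: a cost-sensitive MLP is trained on GS_VS of 4-class synthetic
    data whose classes live in known wavenumber bands; the enrichment of
    top-decile PFI features inside those bands over their grid coverage is
    reported. GradCAM++ arm: a small CNN is trained on constructed-evidence
    images (single-label molecules whose peaks all lie in the class band,
    so all class evidence sits in the band's image region — the rows and
    columns the band spans, about a quarter of the image); the mean
    top-decile saliency mass inside that evidence region is reported.
    """
    # --- PFI on band-generated GS_VS ---
    cfg = SyntheticConfig(n_molecules=pfi_molecules, n_classes=4,
                          label_density=1.5, seed=seed)
    lm = generate_label_matrix(cfg)
    x = compute_gs_vs_batch(generate_spectra(lm, cfg))
    split = iterative_stratified_split(lm, 0.2, seed)
    net, _ = train_csmlp(x, lm, split, ModelConfig(epochs=80, seed=seed),
                         LossParams())
    cw = compute_class_weights(lm.matrix[split.train_indices])
    lp = LossParams()
    err = lambda yt, yp: combined_loss(yt, yp, cw, lp)
    te = split.test_indices
    imp = permutation_importance(net, x[te].copy(),
                                 lm.matrix[te].astype(float), err,
                                 n_repeats=5, seed=seed)
    grid = SmoothingParams().sample_grid
    in_band = np.zeros(grid.size, dtype=bool)
    for bands in cfg.class_bands.values():
        for lo, hi in bands:
            in_band |= (grid >= lo) & (grid <= hi)
    top = imp.ranking()[: grid.size // 10]
    pfi_enrichment = float(in_band[top].mean() / in_band.mean())

    # --- GradCAM++ on constructed-evidence images ---
    labels, spectra, bands = constructed_evidence_dataset(
        n_molecules=cnn_molecules, seed=seed)
    gs = compute_gs_vs_batch(spectra)
    images = np.stack([encode_image(row).pixels for row in gs]).astype(
        np.float32)
    y = labels.matrix.astype(float)
    weights = compute_class_weights(y)
    params = LossParams()

    def loss_grad(y_true, y_prob):
        return (combined_loss(y_true, y_prob, weights, params),
                combined_loss_grad(y_true, y_prob, weights, params))

    cnn = SmallCNN(len(bands), seed=seed, lr=3e-3)
    rng = np.random.default_rng(seed + 1)
    for _ in range(cnn_epochs):
        cnn.train_epoch(images, y, loss_grad, rng)
    cnn_f1 = micro_metrics(y, cnn.predict_proba(images))[2]

    # a band spanning wavenumbers [lo, hi] occupies the image rows and
    # columns [lo, hi] * side / bfs_max: that cross region holds all of
    # the class's evidence (diagonal block plus its row/column stripes)
    side = images.shape[1]
    bfs_max = float(grid[-1])
    fractions, region_areas = [], []
    per_class = max(n_eval_images // len(bands), 1)
    for cls, (lo, hi) in enumerate(bands):
        a = int(round(lo * side / bfs_max))
        b = int(round(hi * side / bfs_max))
        region = np.zeros((side, side), dtype=bool)
        region[a:b, :] = True
        region[:, a:b] = True
        region_areas.append(region.mean())
        idx = np.flatnonzero(y[:, cls] == 1)[:per_class]
        for i in idx:
            sal = gradcam_pp(cnn, images[i], cls).relevance
            mask = sal >= np.quantile(sal, 0.9)
            total = sal[mask].sum()
            fractions.append(
                float(sal[region & mask].sum() / total) if total > 0 else 0.0)
    return {
        "pfi_band_enrichment": pfi_enrichment,
        "gradcam_band_region_mass_pct": float(np.mean(fractions) * 100),
        "gradcam_band_region_area_pct": float(np.mean(region_areas) * 100),
        "gradcam_train_micro_f1": float(cnn_f1),
    }
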