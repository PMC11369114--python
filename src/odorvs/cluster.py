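"""2-D embedding, clustering and odor-composition statistics.

High-dimensional spectral features are reduced to two dimensions
(PCA, t-SNE, UMAP or MDS), clustered with k-means or Ward agglomerative
clustering, and the clusters are profiled with two complementary
percentages per (cluster, odor note):

    %ON = 100 * (occurrences of the note in the cluster)
              / (total occurrences of the note in the dataset)
    %OM = 100 * (occurrences of the note in the cluster)
              / (number of molecules in the cluster)

%ON says how much of a note is captured by a cluster; %OM says how much of
the cluster carries the note. Summed over clusters, the numerators recover
each note's dataset total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import MDS, TSNE
from sklearn.metrics import silhouette_score

from odorvs.labels import LabelMatrix


@dataclass
class Embedding2D:
    method: str
    coordinates: np.ndarray = field(repr=False)  # (n, 2)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValueError("embedding must be (n, 2)")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("embedding contains non-finite coordinates")


@dataclass
class ClusterAssignment:
    """Cluster labels, canonicalized by decreasing cluster size (1-based)."""

    algorithm: str
    k: int
    labels: np.ndarray = field(repr=False)
    inertia: float | None = None
    merge_heights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if present.min() < 1 or present.max() > self.k:
            raise ValueError("cluster labels must lie in [1, k]")
        if present.size != self.k:
            raise ValueError("every cluster must be non-empty")

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def _canonicalize(raw: np.ndarray) -> tuple[np.ndarray, int]:
    """Relabel clusters 1..k by decreasing size (ties by first appearance)."""
    uniq, counts = np.unique(raw, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    mapping = {int(c): i + 1 for i, c in enumerate(order)}
    return np.array([mapping[int(c)] for c in raw]), uniq.size


def embed_2d(
    features: np.ndarray,
    method: str = "umap",
    params: dict | None = None,
    seed: int = 0,
) -> Embedding2D:
    """Reduce features to 2-D with pca, tsne, umap or mds.

    UMAP defaults to n_neighbors=15, min_dist=0.1; t-SNE to perplexity 30
    with PCA initialization. All methods are seeded.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 3:
        raise ValueError("need at least 3 samples to embed")
    params = dict(params or {})
    method = method.lower()
    if method == "pca":
        model = PCA(n_components=2, random_state=seed, **params)
        coords = model.fit_transform(features)
    elif method == "tsne":
        perplexity = params.pop(
            "perplexity", min(30.0, (features.shape[0] - 1) / 3.0)
        )
        model = TSNE(
            n_components=2, perplexity=perplexity, init="pca",
            random_state=seed, **params,
        )
        coords = model.fit_transform(features)
    elif method == "umap":
        import umap

        n_neighbors = params.pop("n_neighbors", 15)
        n_neighbors = min(n_neighbors, features.shape[0] - 1)
        min_dist = params.pop("min_dist", 0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = umap.UMAP(
                n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
                random_state=seed, **params,
            )
            coords = model.fit_transform(features)
    elif method == "mds":
        model = MDS(
            n_components=2, random_state=seed, normalized_stress="auto",
            **params,
        )
        coords = model.fit_transform(features)
    else:
        raise ValueError(f"unknown embedding method: {method!r}")
    return Embedding2D(method, np.asarray(coords, dtype=float),
                       {"seed": seed, **params})


def _coords(emb: Embedding2D | np.ndarray) -> np.ndarray:
    return emb.coordinates if isinstance(emb, Embedding2D) else np.asarray(emb)


def kmeans_cluster(
    emb: Embedding2D | np.ndarray, k: int, seed: int = 0
) -> ClusterAssignment:
    x = _coords(emb)
    if not 1 <= k <= x.shape[0]:
        raise ValueError(f"k={k} outside [1, n={x.shape[0]}]")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(x)
    labels, k_eff = _canonicalize(raw)
    return ClusterAssignment("kmeans", k_eff, labels, inertia=float(km.inertia_))


def ahc_cluster(emb: Embedding2D | np.ndarray, k: int) -> ClusterAssignment:
    """Agglomerative clustering with Ward linkage on Euclidean distances."""
    x = _coords(emb)
    if not 1 <= k <= x.shape[0]:
        raise ValueError(f"k={k} outside [1, n={x.shape[0]}]")
    z = linkage(x, method="ward")
    raw = fcluster(z, t=k, criterion="maxclust")
    labels, k_eff = _canonicalize(raw)
    return ClusterAssignment(
        "ahc", k_eff, labels, merge_heights=z[:, 2].copy()
    )


def elbow_curve(
    emb: Embedding2D | np.ndarray, k_range=range(1, 11), seed: int = 0
) -> pd.DataFrame:
    """k-means inertia (intra-cluster variability) for each k."""
    x = _coords(emb)
    rows = []
    for k in k_range:
        km = KMeans(n_clusters=int(k), n_init=10, random_state=seed).fit(x)
        rows.append((int(k), float(km.inertia_)))
    return pd.DataFrame(rows, columns=["k", "inertia"])


def silhouette(
    emb: Embedding2D | np.ndarray, assign: ClusterAssignment
) -> float:
    """Mean silhouette score of an assignment, in [-1, 1]."""
    if assign.k < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_score(_coords(emb), assign.labels))


@dataclass
class CompositionTable:
    """Per-(cluster, note) occurrence statistics with exact integer ratios."""

    table: pd.DataFrame = field(repr=False)
    # columns: cluster, note, occurrences_in_cluster,
    #          total_occurrences_of_note, cluster_size, pct_on, pct_om

    def top_notes(self, cluster: int, n: int = 10, by: str = "pct_on") -> pd.DataFrame:
        sub = self.table[self.table["cluster"] == cluster]
        return sub.sort_values(by, ascending=False).head(n)

    def write(self, path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index=False)


def odor_note_composition(
    assign: ClusterAssignment, labels: LabelMatrix
) -> CompositionTable:
    """%ON and %OM per (cluster, note) from exact integer counts."""
    if assign.labels.size != labels.n_molecules:
        raise ValueError("cluster assignment and label matrix are misaligned")
    totals = labels.class_counts
    absent = np.flatnonzero(totals == 0)
    if absent.size:
        warnings.warn(
            f"notes never observed, rows omitted: "
            f"{[labels.notes[j] for j in absent]}"
        )
    rows = []
    for cluster in range(1, assign.k + 1):
        members = assign.members(cluster)
        size = members.size
        occ = labels.matrix[members].sum(axis=0)
        for j in range(labels.n_notes):
            if totals[j] == 0:
                continue
            rows.append((
                cluster, labels.notes[j], int(occ[j]), int(totals[j]), size,
                100.0 * occ[j] / totals[j], 100.0 * occ[j] / size,
            ))
    df = pd.DataFrame(rows, columns=[
        "cluster", "note", "occurrences_in_cluster",
        "total_occurrences_of_note", "cluster_size", "pct_on", "pct_om",
    ])
    return CompositionTable(df)


def functional_group_profile(
    smiles: list[str],
    assign: ClusterAssignment,
    min_fraction: float = 0.05,
) -> pd.DataFrame:
    """Fraction of each cluster's molecules containing each fragment group.

    Uses RDKit's fragment-descriptor catalogue (fr_* functions, ~85
    substructures: esters, phenols, ketones, ...). Rows are filtered to
    groups reaching min_fraction in at least one cluster.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import Fragments
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "RDKit is required for functional-group profiling"
        ) from exc
    if len(smiles) != assign.labels.size:
        raise ValueError("SMILES list and cluster assignment are misaligned")
    mols, bad = [], []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            bad.append(smi)
        mols.append(mol)
    if bad:
        raise ValueError(f"invalid SMILES: {bad}")
    frag_fns = [
        (name, getattr(Fragments, name))
        for name in sorted(dir(Fragments))
        if name.startswith("fr_")
    ]
    presence = np.zeros((len(mols), len(frag_fns)), dtype=bool)
    for i, mol in enumerate(mols):
        for g, (_, fn) in enumerate(frag_fns):
            presence[i, g] = fn(mol) > 0
    data = {}
    for cluster in range(1, assign.k + 1):
        members = assign.members(cluster)
        data[f"cluster_{cluster}"] = 100.0 * presence[members].mean(axis=0)
    df = pd.DataFrame(data, index=[name for name, _ in frag_fns])
    df.index.name = "group"
    keep = (df.to_numpy() >= 100.0 * min_fraction).any(axis=1)
    return df[keep]
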