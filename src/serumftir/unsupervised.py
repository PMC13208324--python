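"""Unsupervised structure diagnostics: cosine distances, Ward-type
hierarchical clustering, classical MDS and a t-SNE embedding.

These stages are label-blind by construction — none of the functions
accept class labels.  "Ward-type" clustering applies the Lance-Williams
Ward update recursively to the supplied (generally non-Euclidean) cosine
distances, mirroring common chemometric practice; Ward's Euclidean
assumption is knowingly violated and the result is a similarity-structure
diagnostic, not a variance decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectra import SpectrumSet


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric n x n, zero diagonal, entries >= 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Dendrogram:
    """Merge list in scipy linkage convention.

    ``merges[k] = (node_a, node_b, height, size)``: nodes 0..n-1 are
    leaves, node n+k is the cluster formed at step k.
    """

    merges: list[tuple[int, int, float, int]]
    leaf_order: list[int]

    def linkage_matrix(self) -> np.ndarray:
        return np.array(self.merges, dtype=float)


def cosine_distance_matrix(sset: SpectrumSet) -> DistanceMatrix:
    """d(i, j) = 1 - cos(x_i, x_j), in [0, 2]."""
    m = sset.intensities
    norms = np.linalg.norm(m, axis=1)
    bad = np.nonzero(norms == 0)[0]
    if bad.size:
        raise ValueError(f"zero-norm spectrum: {sset.sample_ids[bad[0]]}")
    unit = m / norms[:, None]
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    d = 1.0 - sim
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(sset.sample_ids), d)


def agglomerative_cluster(dist: DistanceMatrix) -> Dendrogram:
    """Ward-type agglomeration via Lance-Williams updates on squared
    distances.

    Naive O(n^3) agglomeration: at each step merge the pair with the
    smallest current distance, ties broken by the smallest index pair;
    reported merge heights are on the original (unsquared) distance scale.
    """
    n = dist.n
    if n < 2:
        raise ValueError("need >= 2 samples to cluster")
    d2 = dist.values.astype(float) ** 2
    active = list(range(n))
    node_id = {i: i for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                key = (d2[i, j], min(node_id[i], node_id[j]), max(node_id[i], node_id[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        ni, nj = sizes[i], sizes[j]
        height = float(np.sqrt(d2[i, j]))
        a, b = sorted((node_id[i], node_id[j]))
        merges.append((a, b, height, ni + nj))
        # Lance-Williams Ward update into slot i
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            t = ni + nj + nk
            new = ((ni + nk) * d2[i, k] + (nj + nk) * d2[j, k] - nk * d2[i, j]) / t
            d2[i, k] = d2[k, i] = new
        active.remove(j)
        sizes[i] = ni + nj
        node_id[i] = next_id
        next_id += 1
    leaf_order = _leaf_order(merges, n)
    return Dendrogram(merges, leaf_order)


def _leaf_order(merges, n: int) -> list[int]:
    children = {n + k: (int(a), int(b)) for k, (a, b, _, _) in enumerate(merges)}

    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return walk(a) + walk(b)

    return walk(n + len(merges) - 1)


def classical_mds(dist: DistanceMatrix, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared-distance matrix, eigendecomposes, and keeps
    the top ``dims`` positive eigenpairs.  Negative eigenvalues — possible
    for non-Euclidean cosine distances — are clipped with a warning.  The
    embedding is centered at the origin.
    """
    n = dist.n
    if n <= dims:
        raise ValueError(f"need more than {dims} samples for {dims}-D MDS")
    d2 = dist.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if np.any(evals[:dims] < -1e-10 * max(abs(evals[0]), 1.0)):
        warnings.warn(
            "negative eigenvalues clipped (non-Euclidean distances)",
            RuntimeWarning,
            stacklevel=2,
        )
    pos = evals[:dims] > 1e-12 * max(abs(evals[0]), 1.0)
    if pos.sum() < dims:
        warnings.warn(
            f"only {int(pos.sum())} positive eigenvalues; "
            "returning lower-dimensional embedding",
            RuntimeWarning,
            stacklevel=2,
        )
    k = max(int(pos.sum()), 1)
    coords = evecs[:, :k] * np.sqrt(np.clip(evals[:k], 0.0, None))
    return coords - coords.mean(axis=0)


def tsne_embed(
    sset: SpectrumSet,
    perplexity: float = 5.0,
    seed: int = 0,
    n_iter: int = 500,
) -> tuple[np.ndarray, dict]:
    """2-D t-SNE of the intensity matrix (cosine metric), seeded.

    Visualization plumbing around scikit-learn's exact-method t-SNE;
    deterministic under a fixed seed.  Returns (coordinates, provenance).
    """
    from sklearn.manifold import TSNE

    n = sset.n_samples
    if n < 4:
        raise ValueError("t-SNE needs >= 4 samples")
    max_perp = (n - 1) / 3
    if perplexity >= max_perp:
        raise ValueError(
            f"perplexity {perplexity} infeasible for n={n}; "
            f"use a value below {max_perp:.2f}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="random",
        metric="cosine",
        method="exact",
        max_iter=n_iter,
    )
    coords = tsne.fit_transform(sset.intensities)
    prov = {"perplexity": perplexity, "seed": seed, "iterations": n_iter}
    return coords, prov
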