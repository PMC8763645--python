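"""Joint embedding of spatial and reference cells, and kNN cell typing.

The integration strategy mirrors the standard single-cell recipe for
merging an imaging panel with a dissociated atlas: cosine-normalize each
cell's expression vector, run batch-aware PCA (each batch weighted equally
in the covariance estimate), then align batches sequentially with mutual
nearest-neighbor (MNN) correction vectors smoothed by a Gaussian kernel.
Cell-type labels transfer by k-nearest neighbors in the corrected space
(k = 25), with a mapping score equal to the fraction of neighbors carrying
the modal label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import cdist, pdist
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "cosine_normalize",
    "joint_reduce",
    "mnn_correct",
    "transfer_labels",
    "integrate_datasets",
    "gene_subset_experiment",
    "JointEmbedding",
]


def cosine_normalize(matrix: np.ndarray) -> np.ndarray:
    """Scale each cell's expression vector to unit Euclidean norm.

    All-zero rows are left as zero.
    """
    X = np.asarray(matrix, dtype=float)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


@dataclass
class JointEmbedding:
    """Cells x components coordinates with batch/dataset provenance."""

    coords: np.ndarray
    batches: np.ndarray
    datasets: np.ndarray | None = None
    explained_variance: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.coords)


def joint_reduce(X: np.ndarray, batches, n_components: int = 50, datasets=None) -> JointEmbedding:
    """Batch-aware PCA with each batch weighted equally.

    The rotation diagonalizes the average of the per-batch covariance
    matrices (each computed about its own batch mean), and all cells are
    projected after centering on the mean of the batch means.  With a
    single batch this coincides with ordinary PCA up to component sign.
    """
    X = np.asarray(X, dtype=float)
    batches = np.asarray(batches)
    if len(batches) != len(X):
        raise ValueError("one batch label per cell is required")
    n_genes = X.shape[1]
    if n_genes < n_components:
        warnings.warn(
            f"only {n_genes} genes available; capping components at {n_genes}"
        )
        n_components = n_genes
    uniq = np.unique(batches)
    means = np.vstack([X[batches == b].mean(axis=0) for b in uniq])
    grand = means.mean(axis=0)
    cov = np.zeros((n_genes, n_genes))
    for b, mu in zip(uniq, means):
        Xb = X[batches == b] - mu
        denom = max(len(Xb) - 1, 1)
        cov += Xb.T @ Xb / denom
    cov /= len(uniq)
    vals, vecs = eigh(cov, subset_by_index=[n_genes - n_components, n_genes - 1])
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    coords = (X - grand) @ vecs
    return JointEmbedding(
        coords=coords,
        batches=batches,
        datasets=None if datasets is None else np.asarray(datasets),
        explained_variance=vals,
    )


def _mnn_pairs(ref: np.ndarray, new: np.ndarray, k: int):
    k_r = min(k, len(ref))
    k_n = min(k, len(new))
    nn_in_ref = NearestNeighbors(n_neighbors=k_r).fit(ref).kneighbors(new, return_distance=False)
    nn_in_new = NearestNeighbors(n_neighbors=k_n).fit(new).kneighbors(ref, return_distance=False)
    in_new_sets = [set(row) for row in nn_in_new]
    pairs = [
        (r, n)
        for n in range(len(new))
        for r in nn_in_ref[n]
        if n in in_new_sets[r]
    ]
    return pairs


def mnn_correct(
    embedding: JointEmbedding,
    merge_order=None,
    k_mnn: int = 20,
    sigma: float | None = None,
) -> JointEmbedding:
    """Sequential mutual-nearest-neighbor batch correction.

    Batches are merged in ``merge_order`` (default: decreasing size, which
    puts the largest reference batches first).  At each merge, mutual
    k-nearest-neighbor pairs between the accumulated reference and the
    incoming batch define correction vectors; each incoming cell receives a
    Gaussian-kernel-weighted average of the pair vectors (bandwidth
    ``sigma``, default 0.1 x the median pairwise distance of the current
    reference).  A single batch is returned unchanged.
    """
    coords = embedding.coords.copy()
    batches = embedding.batches
    uniq, counts = np.unique(batches, return_counts=True)
    if merge_order is None:
        merge_order = [b for _, b in sorted(zip(-counts, uniq), key=lambda t: (t[0], str(t[1])))]
    if set(map(str, merge_order)) != set(map(str, uniq)):
        raise ValueError("merge_order must cover exactly the batches present")
    if len(merge_order) == 1:
        return replace(embedding, coords=coords)

    idx_of = {str(b): np.nonzero(batches.astype(str) == str(b))[0] for b in merge_order}
    acc = list(idx_of[str(merge_order[0])])
    rng = np.random.default_rng(0)
    for b in merge_order[1:]:
        ref_idx = np.asarray(acc)
        new_idx = idx_of[str(b)]
        ref = coords[ref_idx]
        new = coords[new_idx]
        pairs = _mnn_pairs(ref, new, k_mnn)
        if not pairs:
            raise RuntimeError(
                f"no mutual nearest neighbors between accumulated reference and batch {b!r}"
            )
        if sigma is None:
            sub = ref if len(ref) <= 1000 else ref[rng.choice(len(ref), 1000, replace=False)]
            med = np.median(pdist(sub)) if len(sub) > 1 else 0.0
            sig = 0.1 * med if med > 0 else 1.0
        else:
            sig = sigma
        pr = np.array([p[0] for p in pairs])
        pn = np.array([p[1] for p in pairs])
        vec = ref[pr] - new[pn]
        anchors = new[pn]
        # kernel-smoothed correction field evaluated at each incoming cell
        d2 = cdist(new, anchors, "sqeuclidean")
        w = np.exp(-d2 / (2.0 * sig**2))
        wsum = w.sum(axis=1, keepdims=True)
        flat = wsum[:, 0] <= 1e-300
        w[flat] = 1.0
        wsum = w.sum(axis=1, keepdims=True)
        corr = (w @ vec) / wsum
        coords[new_idx] = new + corr
        acc.extend(new_idx)
    return replace(embedding, coords=coords)


@dataclass
class MappingResult:
    """Per query cell: reference neighbors, assigned label, mapping score."""

    labels: np.ndarray
    scores: np.ndarray
    neighbor_indices: np.ndarray  # query x k, into the reference
    neighbor_distances: np.ndarray

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "mapping_score": self.scores,
                "neighbor_ids": [list(r) for r in self.neighbor_indices],
            },
            index=index,
        )


def transfer_labels(query: np.ndarray, reference: np.ndarray, ref_labels, k: int = 25) -> MappingResult:
    """Assign each query cell the modal label of its k reference neighbors.

    Distances are Euclidean over all corrected components; neighbors are
    sorted by distance.  Modal-count ties are broken by the tied label whose
    member lies nearest the query, then lexicographically.  The mapping
    score is (modal label count) / k.
    """
    reference = np.asarray(reference, dtype=float)
    query = np.asarray(query, dtype=float)
    ref_labels = np.asarray(ref_labels)
    if len(reference) == 0:
        raise ValueError("reference is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    k_eff = min(k, len(reference))
    nn = NearestNeighbors(n_neighbors=k_eff).fit(reference)
    dist, idx = nn.kneighbors(query)
    labels = np.empty(len(query), dtype=ref_labels.dtype)
    scores = np.empty(len(query))
    for i in range(len(query)):
        neigh = ref_labels[idx[i]]
        vals, counts = np.unique(neigh, return_counts=True)
        top = counts.max()
        tied = vals[counts == top]
        if len(tied) == 1:
            winner = tied[0]
        else:
            # nearest member of each tied label; equal distances -> lexicographic
            best = []
            for lab in tied:
                j = np.nonzero(neigh == lab)[0][0]  # neighbors sorted by distance
                best.append((dist[i, j], str(lab), lab))
            best.sort(key=lambda t: (t[0], t[1]))
            winner = best[0][2]
        labels[i] = winner
        scores[i] = top / k_eff
    return MappingResult(labels=labels, scores=scores, neighbor_indices=idx, neighbor_distances=dist)


def integrate_datasets(
    query_lognorm: np.ndarray,
    ref_lognorm: np.ndarray,
    query_batches,
    ref_batches,
    n_components: int = 50,
    k_mnn: int = 20,
    sigma: float | None = None,
):
    """Full integration pipeline: cosine -> multibatch PCA -> MNN.

    Reference batches are merged first (by decreasing size), then the query
    batches.  Returns ``(query_coords, ref_coords)`` in the corrected space.
    """
    q = cosine_normalize(query_lognorm)
    r = cosine_normalize(ref_lognorm)
    X = np.vstack([r, q])
    rb = np.asarray([f"ref/{b}" for b in np.asarray(ref_batches).astype(str)])
    qb = np.asarray([f"query/{b}" for b in np.asarray(query_batches).astype(str)])
    batches = np.concatenate([rb, qb])
    datasets = np.array(["reference"] * len(r) + ["query"] * len(q))
    emb = joint_reduce(X, batches, n_components=n_components, datasets=datasets)

    def _order(names):
        u, c = np.unique(names, return_counts=True)
        return [b for _, b in sorted(zip(-c, u), key=lambda t: (t[0], str(t[1])))]

    merge_order = _order(rb) + _order(qb)
    emb = mnn_correct(emb, merge_order=merge_order, k_mnn=k_mnn, sigma=sigma)
    return emb.coords[len(r) :], emb.coords[: len(r)]


def gene_subset_experiment(
    query_lognorm: pd.DataFrame,
    ref_lognorm: pd.DataFrame,
    query_batches,
    ref_batches,
    ref_labels,
    panel=None,
    fractions=tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    n_reps: int = 5,
    k: int = 25,
    n_components: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-typing robustness to random gene-panel subsets.

    Labels from the full panel are treated as truth; for each fraction and
    replicate a random gene subset is drawn, the whole integration pipeline
    is rerun, and the relative classification accuracy is recorded for both
    the query dataset and the reference (resubstitution self-classification).

    Returns a tidy table (dataset, fraction, rep, relative_accuracy).
    """
    if panel is None:
        panel = list(query_lognorm.columns)
    panel = list(panel)
    rng = np.random.default_rng(seed)
    ref_labels = np.asarray(ref_labels)

    def classify(genes):
        q = query_lognorm[genes].to_numpy()
        r = ref_lognorm[genes].to_numpy()
        nc = min(n_components, len(genes))
        qc, rc = integrate_datasets(q, r, query_batches, ref_batches, n_components=nc)
        q_lab = transfer_labels(qc, rc, ref_labels, k=k).labels
        r_lab = transfer_labels(rc, rc, ref_labels, k=k).labels
        return q_lab, r_lab

    full_q, full_r = classify(panel)
    rows = []
    for frac in fractions:
        n_genes = int(round(frac * len(panel)))
        if n_genes < 2:
            warnings.warn(f"fraction {frac} yields fewer than 2 genes; skipped")
            continue
        for rep in range(n_reps):
            genes = list(rng.choice(panel, size=n_genes, replace=False))
            q_lab, r_lab = classify(genes)
            rows.append(
                {"dataset": "query", "fraction": frac, "rep": rep,
                 "relative_accuracy": float(np.mean(q_lab == full_q))}
            )
            rows.append(
                {"dataset": "reference", "fraction": frac, "rep": rep,
                 "relative_accuracy": float(np.mean(r_lab == full_r))}
            )
    return pd.DataFrame(rows)
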