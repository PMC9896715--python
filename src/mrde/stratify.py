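"""Categorical dysregulation matrices and latent-block-model co-clustering.

Per-patient DE results over a gene subset are reduced to a genes x patients
matrix with values -1 / 0 / +1 (down / no change / up).  Patients and genes
are then co-clustered with a categorical latent block model fitted by
classification EM (hard assignments, restarts, best fit by likelihood), and
patient clusters are relabelled canonically: ascending mean number of
up-regulated (+1) cells per patient, so the highest label is the
up-regulation-rich (poorer-prognosis) group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

CATEGORIES = (-1, 0, 1)


class CoclusterError(ValueError):
    pass


def build_lfc_matrix(
    per_patient_results: dict[str, pd.DataFrame], gene_subset
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes x patients log2 fold-change matrix over a gene subset.

    Returns (matrix, missing_mask); cells where a gene was absent from a
    patient's table are 0 with the mask bit set.
    """
    genes = list(gene_subset)
    patients = list(per_patient_results)
    lfc = pd.DataFrame(0.0, index=genes, columns=patients)
    missing = pd.DataFrame(True, index=genes, columns=patients)
    for p, table in per_patient_results.items():
        sub = table.set_index("gene_id")["log2fc"]
        present = [g for g in genes if g in sub.index]
        lfc.loc[present, p] = sub[present].to_numpy()
        missing.loc[present, p] = False
    return lfc, missing


def categorize(per_patient_results: dict[str, pd.DataFrame], gene_subset) -> pd.DataFrame:
    """Genes x patients categorical matrix: +1 up, -1 down, 0 otherwise."""
    genes = list(gene_subset)
    patients = list(per_patient_results)
    out = pd.DataFrame(0, index=genes, columns=patients, dtype=int)
    for p, table in per_patient_results.items():
        sub = table.set_index("gene_id")["call"]
        present = [g for g in genes if g in sub.index]
        calls = sub[present]
        out.loc[present, p] = np.where(calls == "up", 1, np.where(calls == "down", -1, 0))
    return out


@dataclass
class BlockModelFit:
    """Hard co-clustering fit of the categorical latent block model."""

    row_labels: np.ndarray  # gene cluster per row
    col_labels: np.ndarray  # patient cluster per column
    theta: np.ndarray  # (L, K, 3) category probabilities per block
    row_props: np.ndarray
    col_props: np.ndarray
    loglik: float  # complete-data log-likelihood of the final fit
    objective: float  # penalized objective (loglik + Dirichlet smoothing term)
    objective_path: list[float] = field(default_factory=list)
    n_restarts: int = 0
    seed: int | None = None


def _encode(M: np.ndarray) -> np.ndarray:
    codes = np.full(M.shape, -1, dtype=int)
    for i, c in enumerate(CATEGORIES):
        codes[M == c] = i
    if (codes < 0).any():
        raise CoclusterError(f"matrix values must be in {CATEGORIES}")
    return codes


def _block_counts(codes: np.ndarray, zr: np.ndarray, zc: np.ndarray, L: int, K: int) -> np.ndarray:
    """counts[l, k, c] of cells with row cluster l, column cluster k, category c."""
    counts = np.zeros((L, K, 3))
    for c in range(3):
        mask = codes == c
        # aggregate columns into col clusters, then rows into row clusters
        colagg = np.zeros((codes.shape[0], K))
        for k in range(K):
            colagg[:, k] = mask[:, zc == k].sum(axis=1)
        for l in range(L):
            counts[l, :, c] = colagg[zr == l].sum(axis=0)
    return counts


def _objective(counts: np.ndarray, theta: np.ndarray, zr, zc, logpi, logrho) -> tuple[float, float]:
    logtheta = np.log(theta)
    ll = float((counts * logtheta).sum() + logpi[zr].sum() + logrho[zc].sum())
    pen = float(0.5 * logtheta.sum())
    return ll, ll + pen


def lbm_cocluster(
    M,
    n_row_clusters: int = 3,
    n_col_clusters: int = 3,
    n_restarts: int = 20,
    max_iter: int = 200,
    tol: float = 1e-8,
    seed: int = 0,
) -> BlockModelFit:
    """Classification EM for the categorical latent block model.

    Rows (genes) and columns (patients) are alternately hard-assigned to the
    cluster maximizing the complete-data log-likelihood given the block
    category probabilities ``theta`` (updated as frequencies smoothed with a
    0.5 pseudo-count per category) and the mixing proportions.  Empty
    clusters are re-seeded with the worst-fitting row/column.  The best of
    ``n_restarts`` random restarts (by final objective) is returned.
    """
    frame = M if isinstance(M, pd.DataFrame) else pd.DataFrame(np.asarray(M))
    codes = _encode(frame.to_numpy())
    G, P = codes.shape
    L, K = n_row_clusters, n_col_clusters
    if L > G or K > P:
        raise CoclusterError(f"cannot fit {L}x{K} blocks to a {G}x{P} matrix")
    if L < 1 or K < 1 or n_restarts < 1:
        raise CoclusterError("cluster numbers and restarts must be positive")
    if G >= 2 and P >= 2 and (L > 1 or K > 1):
        if np.unique(codes, axis=0).shape[0] < 2 or np.unique(codes, axis=1).shape[1] < 2:
            warnings.warn("degenerate matrix: fewer than 2 distinct rows or columns",
                          stacklevel=2)

    onehot = np.eye(3)[codes]  # (G, P, 3)
    rng = np.random.default_rng(seed)
    best: BlockModelFit | None = None

    for restart in range(n_restarts):
        zr = rng.integers(0, L, size=G)
        zc = rng.integers(0, K, size=P)
        # guarantee non-empty initial clusters
        zr[rng.permutation(G)[:L]] = np.arange(L)
        zc[rng.permutation(P)[:K]] = np.arange(K)
        path: list[float] = []
        prev = -np.inf
        for _ in range(max_iter):
            counts = _block_counts(codes, zr, zc, L, K)
            theta = counts + 0.5
            theta /= theta.sum(axis=2, keepdims=True)
            logtheta = np.log(theta)
            pi = np.maximum(np.bincount(zr, minlength=L) / G, 1e-12)
            rho = np.maximum(np.bincount(zc, minlength=K) / P, 1e-12)
            logpi, logrho = np.log(pi), np.log(rho)

            # row step: counts of categories per (row, col-cluster)
            rowstats = np.stack(
                [onehot[:, zc == k, :].sum(axis=1) for k in range(K)], axis=1
            )  # (G, K, 3)
            scores = np.tensordot(rowstats, logtheta, axes=([1, 2], [1, 2])) + logpi[None, :]
            zr = scores.argmax(axis=1)
            zr = _fix_empty(zr, scores, L)

            # column step
            colstats = np.stack(
                [onehot[zr == l, :, :].sum(axis=0) for l in range(L)], axis=1
            )  # (P, L, 3)
            cscores = (
                np.tensordot(colstats, logtheta, axes=([1, 2], [0, 2])) + logrho[None, :]
            )
            zc = cscores.argmax(axis=1)
            zc = _fix_empty(zc, cscores, K)

            counts = _block_counts(codes, zr, zc, L, K)
            theta = counts + 0.5
            theta /= theta.sum(axis=2, keepdims=True)
            pi = np.maximum(np.bincount(zr, minlength=L) / G, 1e-12)
            rho = np.maximum(np.bincount(zc, minlength=K) / P, 1e-12)
            ll, obj = _objective(counts, theta, zr, zc, np.log(pi), np.log(rho))
            path.append(obj)
            if np.isfinite(prev) and abs(obj - prev) <= tol * max(1.0, abs(prev)):
                break
            prev = obj

        fit = BlockModelFit(
            row_labels=zr.copy(),
            col_labels=zc.copy(),
            theta=theta,
            row_props=pi,
            col_props=rho,
            loglik=ll,
            objective=obj,
            objective_path=path,
            n_restarts=n_restarts,
            seed=seed,
        )
        if best is None or fit.objective > best.objective:
            best = fit
    assert best is not None
    return best


def _fix_empty(labels: np.ndarray, scores: np.ndarray, k: int) -> np.ndarray:
    """Re-seed each empty cluster with the currently worst-fitting item."""
    labels = labels.copy()
    for cluster in range(k):
        if not (labels == cluster).any():
            fit_quality = scores[np.arange(len(labels)), labels]
            # pick the item least well explained by its current cluster,
            # among clusters that can spare an item
            order = np.argsort(fit_quality)
            for idx in order:
                if (labels == labels[idx]).sum() > 1:
                    labels[idx] = cluster
                    break
    return labels


@dataclass
class PatientGrouping:
    """patient -> PG label, canonically ordered by mean up-regulation."""

    assignments: pd.DataFrame  # patient_id, group (PG0..), cluster (raw)
    sizes: dict[str, int]

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.assignments["patient_id"], self.assignments["group"]))


def assign_groups(fit: BlockModelFit, M) -> PatientGrouping:
    """Canonical PG labels: clusters sorted by ascending mean count of +1 cells.

    PG0 is the least up-regulated cluster; the up-regulation-rich cluster
    gets the highest label (the poorer-prognosis group).
    """
    frame = M if isinstance(M, pd.DataFrame) else pd.DataFrame(np.asarray(M))
    up_per_patient = (frame.to_numpy() == 1).sum(axis=0)
    K = len(fit.col_props)
    means = np.array(
        [
            up_per_patient[fit.col_labels == k].mean() if (fit.col_labels == k).any() else np.inf
            for k in range(K)
        ]
    )
    order = np.argsort(means, kind="stable")
    label_of = {int(cluster): f"PG{rank}" for rank, cluster in enumerate(order)}
    groups = [label_of[int(c)] for c in fit.col_labels]
    assignments = pd.DataFrame(
        {"patient_id": list(frame.columns), "group": groups, "cluster": fit.col_labels}
    )
    sizes = assignments["group"].value_counts().to_dict()
    return PatientGrouping(assignments=assignments, sizes=sizes)


def order_heatmap(M, method: str = "complete", metric: str = "euclidean"):
    """Deterministic agglomerative row/column orderings for display."""
    frame = M if isinstance(M, pd.DataFrame) else pd.DataFrame(np.asarray(M))
    arr = frame.to_numpy(dtype=float)

    def _order(x: np.ndarray) -> np.ndarray:
        if x.shape[0] < 2:
            return np.arange(x.shape[0])
        return leaves_list(linkage(pdist(x, metric=metric), method=method))

    return _order(arr), _order(arr.T)
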