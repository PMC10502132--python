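"""Relationship matrix and population structure: PCA, Ward, DAPC.

The additive genomic relationship matrix follows VanRaden:

    G = Z Z' / (2 * sum_k p_k (1 - p_k)),   Z = M - 2p

with M the dosage matrix and p the panel-wide ALT frequencies. Missing
dosages are mean-imputed (2p) for this computation only. PCA is the
eigendecomposition of G; Ward clustering operates on the G-induced distances
d^2(i,j) = G_ii + G_jj - 2 G_ij; DAPC reduces the centered dosages by PCA,
discovers groups by k-means with BIC model selection, then builds linear
discriminants and Gaussian membership probabilities.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.linalg
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .core import GenotypeMatrix, PanelError
from .diversity_stats import allele_freq

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RelationshipMatrix:
    """VanRaden additive relationship matrix with its scaling denominator."""

    G: np.ndarray
    denominator: float
    samples: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.G, index=self.samples, columns=self.samples)


def _imputed_centered(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(Z, p): 2p-centered dosages with missing entries imputed at 2p."""
    p = allele_freq(gm)
    defined = np.isfinite(p)
    Z = gm.dosage[:, defined] - 2.0 * p[defined]
    Z[~np.isfinite(Z)] = 0.0  # missing -> mean (2p), i.e. centered 0
    return Z, p[defined]


def vanraden_g(gm: GenotypeMatrix) -> RelationshipMatrix:
    """Compute the VanRaden G matrix; raises on all-monomorphic input."""
    if gm.n_samples < 2:
        raise PanelError("VanRaden G needs at least 2 samples")
    Z, p = _imputed_centered(gm)
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom == 0.0:
        raise PanelError(
            "all loci monomorphic: VanRaden denominator 2*sum(p(1-p)) is zero"
        )
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0  # enforce exact symmetry
    return RelationshipMatrix(G=G, denominator=denom, samples=list(gm.samples))


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (reproducible sign)."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        k = int(np.argmax(np.abs(out[:, j])))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def pca(rel: RelationshipMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of G: (scores, variance_explained).

    Scores are eigenvectors scaled by sqrt(eigenvalue); negative eigenvalues
    (numerical) are clipped to zero in both the scores and the
    variance-explained denominator.
    """
    lam, vec = scipy.linalg.eigh(rel.G)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    lam_pos = np.clip(lam, 0.0, None)
    vec = _fix_signs(vec)
    scores = vec * np.sqrt(lam_pos)
    total = lam_pos.sum()
    var_exp = lam_pos / total if total > 0 else np.zeros_like(lam_pos)
    return scores, var_exp


@dataclasses.dataclass
class WardTree:
    """Ward hierarchy over G-induced distances with newick export."""

    linkage: np.ndarray
    labels: list[str]

    def cut(self, k: int) -> np.ndarray:
        """Hard assignments (0-based group indices) at k clusters."""
        return sch.fcluster(self.linkage, t=k, criterion="maxclust") - 1

    def newick(self) -> str:
        n = len(self.labels)
        Z = self.linkage

        def node(i: int) -> tuple[str, float]:
            if i < n:
                return self.labels[i], 0.0
            a, b, h = int(Z[i - n, 0]), int(Z[i - n, 1]), float(Z[i - n, 2])
            sa, ha = node(a)
            sb, hb = node(b)
            return f"({sa}:{h - ha:.8g},{sb}:{h - hb:.8g})", h

        s, _ = node(2 * n - 2)
        return s + ";"


def ward_tree(rel: RelationshipMatrix) -> WardTree:
    """Ward (squared-distance update) clustering on d^2 = G_ii + G_jj - 2 G_ij."""
    diag = np.diag(rel.G)
    d2 = diag[:, None] + diag[None, :] - 2.0 * rel.G
    np.clip(d2, 0.0, None, out=d2)  # clamp numerical negatives
    np.fill_diagonal(d2, 0.0)
    dist = squareform(np.sqrt(d2), checks=False)
    Z = sch.linkage(dist, method="ward")
    return WardTree(linkage=Z, labels=list(rel.samples))


@dataclasses.dataclass
class ClusterResult:
    """Output of a structure analysis (Ward cut or DAPC)."""

    method: str
    k: int
    assignments: np.ndarray  # 0-based group per sample
    membership: np.ndarray | None  # samples x k probabilities (DAPC)
    pc_scores: np.ndarray
    discriminant_scores: np.ndarray | None
    variance_explained: np.ndarray  # per retained PC, fraction of total
    bic_curve: pd.DataFrame | None
    samples: list[str]


def _pca_dosage(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the column-centered (mean-imputed) dosage matrix.

    Returns (scores = U*S, variance_explained per component of the total
    dosage variance).
    """
    Z, _ = _imputed_centered(gm)
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    scores = _fix_signs(U * S)
    var = S**2
    total = var.sum()
    return scores, var / total if total > 0 else var


def dapc(
    gm: GenotypeMatrix,
    n_pca: int = 45,
    n_da: int = 2,
    k_range=range(1, 9),
    seed: int = 0,
    ridge: float = 1e-8,
) -> ClusterResult:
    """Discriminant analysis of principal components with k-means/BIC.

    Steps: (1) PCA of the centered dosage matrix, retain ``n_pca`` score
    columns (capped at the matrix rank); (2) k-means over each candidate k
    with BIC(k) = n*ln(WSS_k/n) + k*ln(n), minimum BIC selects k; (3) linear
    discriminants of the retained scores on the selected groups (generalized
    eigenproblem of between vs within scatter, ridge-stabilized); (4)
    membership probabilities from Gaussian densities with shared within-group
    covariance and equal priors in discriminant space.
    """
    n = gm.n_samples
    if n < 3:
        raise PanelError("DAPC needs at least 3 samples")
    scores_full, var_exp = _pca_dosage(gm)
    n_pca_eff = int(min(n_pca, scores_full.shape[1], n - 1))
    X = scores_full[:, :n_pca_eff]
    if n_pca_eff < n_pca:
        logger.info("n_pca capped at %d (rank/sample limit)", n_pca_eff)

    bic_rows = []
    best = None
    for k in k_range:
        if k > n:
            continue
        if k == 1:
            wss = float(((X - X.mean(axis=0)) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
            wss = float(km.inertia_)
            labels = km.labels_
        wss = max(wss, 1e-12)
        bic = n * np.log(wss / n) + k * np.log(n)
        bic_rows.append((k, wss, bic))
        if best is None or bic < best[0]:
            best = (bic, k, labels)
    assert best is not None
    _, k_sel, labels = best
    bic_curve = pd.DataFrame(bic_rows, columns=["k", "wss", "bic"])

    if k_sel == 1:
        membership = np.ones((n, 1))
        return ClusterResult(
            method="kmeans_dapc",
            k=1,
            assignments=np.zeros(n, dtype=int),
            membership=membership,
            pc_scores=X,
            discriminant_scores=None,
            variance_explained=var_exp[:n_pca_eff],
            bic_curve=bic_curve,
            samples=list(gm.samples),
        )

    # linear discriminants: between vs within scatter on retained scores
    overall = X.mean(axis=0)
    d = X.shape[1]
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for g in range(k_sel):
        Xg = X[labels == g]
        mu = Xg.mean(axis=0)
        C = Xg - mu
        Sw += C.T @ C
        Sb += len(Xg) * np.outer(mu - overall, mu - overall)
    Sw += ridge * np.trace(Sw) / d * np.eye(d) + ridge * np.eye(d)
    lam, W = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(lam)[::-1]
    n_da_eff = int(min(n_da, k_sel - 1))
    W = _fix_signs(W[:, order[:n_da_eff]])
    D = X @ W

    # shared-covariance Gaussian memberships, equal priors
    mus = np.stack([D[labels == g].mean(axis=0) for g in range(k_sel)])
    Wn = np.zeros((n_da_eff, n_da_eff))
    for g in range(k_sel):
        C = D[labels == g] - mus[g]
        Wn += C.T @ C
    Wn /= max(n - k_sel, 1)
    Wn += ridge * np.eye(n_da_eff)
    Winv = np.linalg.inv(Wn)
    log_dens = np.empty((n, k_sel))
    for g in range(k_sel):
        diff = D - mus[g]
        log_dens[:, g] = -0.5 * np.einsum("ij,jk,ik->i", diff, Winv, diff)
    log_dens -= log_dens.max(axis=1, keepdims=True)
    membership = np.exp(log_dens)
    membership /= membership.sum(axis=1, keepdims=True)
    assignments = membership.argmax(axis=1)

    return ClusterResult(
        method="kmeans_dapc",
        k=k_sel,
        assignments=assignments,
        membership=membership,
        pc_scores=X,
        discriminant_scores=D,
        variance_explained=var_exp[:n_pca_eff],
        bic_curve=bic_curve,
        samples=list(gm.samples),
    )
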