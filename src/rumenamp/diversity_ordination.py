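"""Rarefaction, alpha diversity, Bray-Curtis PCoA, and CCA.

Conventions chosen to match the MOTHUR/vegan outputs the tables and figures
were built from: Simpson is reported as the dominance form
``sum n(n-1) / (N(N-1))`` (low = diverse), Chao1 uses the bias-corrected
estimator (defined when no doubletons exist), and rarefaction is a single
random draw without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlphaDiversity",
    "Ordination",
    "rarefy",
    "alpha_indices",
    "alpha_table",
    "bray_curtis",
    "pcoa",
    "cca",
]


@dataclass(frozen=True)
class AlphaDiversity:
    sample_id: str
    chao1: float
    observed_otus: int
    shannon: float
    simpson: float
    coverage: float

    def __post_init__(self) -> None:
        if self.observed_otus > self.chao1 + 1e-9:
            raise ValueError("chao1 cannot be below observed richness")
        if not (0.0 <= self.simpson <= 1.0) or not (0.0 <= self.coverage <= 1.0):
            raise ValueError("simpson and coverage must lie in [0, 1]")
        if self.shannon < 0:
            raise ValueError("shannon must be non-negative")


@dataclass
class Ordination:
    method: str                          # "pcoa" | "cca"
    site_coords: pd.DataFrame            # samples x axes
    eigenvalues: np.ndarray              # sorted descending
    proportion_explained: np.ndarray
    species_coords: pd.DataFrame | None = None   # cca only
    biplot_arrows: pd.DataFrame | None = None    # cca only
    total_inertia: float | None = None           # cca only
    constrained_inertia: float | None = None     # cca only
    negative_eigenvalues: np.ndarray | None = None  # pcoa only


def rarefy(counts: pd.DataFrame, depth: int = 1800, seed: int = 0) -> pd.DataFrame:
    """Subsample every sample column to exactly ``depth`` reads, without
    replacement (multivariate hypergeometric draw); deterministic given seed.

    ``counts`` is OTUs (rows) x samples (columns).  A sample with fewer than
    ``depth`` reads raises ``ValueError`` naming it.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy()
        total = int(col.sum())
        if total < depth:
            raise ValueError(
                f"sample {sample!r} has {total} reads, fewer than rarefaction depth {depth}"
            )
        out[sample] = rng.multivariate_hypergeometric(col.astype(np.int64), depth)
    return pd.DataFrame(out, index=counts.index)


def alpha_indices(counts: Sequence[int] | np.ndarray, sample_id: str = "") -> AlphaDiversity:
    """Alpha diversity of one (rarefied) count vector.

    observed = #nonzero; Chao1 = S + F1(F1-1)/(2(F2+1)); Shannon = -sum p ln p;
    Simpson dominance = sum n(n-1)/(N(N-1)); Good's coverage = 1 - F1/N.
    """
    n = np.asarray(counts, dtype=np.int64)
    if (n < 0).any():
        raise ValueError("negative counts")
    total = int(n.sum())
    if total == 0:
        raise ValueError("all-zero count vector")
    present = n[n > 0]
    s_obs = int(present.size)
    f1 = int((present == 1).sum())
    f2 = int((present == 2).sum())
    chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    p = present / total
    shannon = float(-(p * np.log(p)).sum())
    if total > 1:
        simpson = float((present * (present - 1)).sum() / (total * (total - 1)))
    else:
        simpson = 1.0
    coverage = 1.0 - f1 / total
    return AlphaDiversity(
        sample_id=sample_id, chao1=chao1, observed_otus=s_obs,
        shannon=shannon, simpson=simpson, coverage=coverage,
    )


def alpha_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample alpha indices (samples as rows) for an OTUs x samples table."""
    rows = []
    for sample in counts.columns:
        a = alpha_indices(counts[sample].to_numpy(), sample_id=sample)
        rows.append({
            "sample_id": a.sample_id, "chao1": a.chao1,
            "observed_otus": a.observed_otus, "shannon": a.shannon,
            "simpson": a.simpson, "coverage": a.coverage,
        })
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis distances between rows (samples) of a samples x OTUs table."""
    x = matrix.to_numpy(dtype=float)
    n = x.shape[0]
    d = np.zeros((n, n))
    totals = x.sum(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            shared = np.minimum(x[i], x[j]).sum()
            denom = totals[i] + totals[j]
            d[i, j] = d[j, i] = 1.0 - 2.0 * shared / denom if denom > 0 else 0.0
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude loading positive."""
    out = vectors.copy()
    for k in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, k])))
        if out[i, k] < 0:
            out[:, k] = -out[:, k]
    return out


def pcoa(distances: pd.DataFrame, eig_tol: float = 1e-10) -> Ordination:
    """Principal coordinates via Gower double-centering of -0.5 D^2.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues only; negative eigenvalues are reported but unused.
    """
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0)
    positive = eigvals > eig_tol * scale
    coords = _fix_signs(eigvecs[:, positive]) * np.sqrt(eigvals[positive])
    axes = [f"PC{k+1}" for k in range(coords.shape[1])]
    pos_sum = eigvals[positive].sum()
    return Ordination(
        method="pcoa",
        site_coords=pd.DataFrame(coords, index=distances.index, columns=axes),
        eigenvalues=eigvals[positive],
        proportion_explained=eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive],
        negative_eigenvalues=eigvals[eigvals < -eig_tol * scale],
    )


def cca(species: pd.DataFrame, env: pd.DataFrame, eig_tol: float = 1e-10) -> Ordination:
    """Canonical correspondence analysis (vegan-style).

    ``species`` is samples x OTUs counts; ``env`` is samples x covariates.
    The chi-square standardized matrix is regressed on weighted-standardized
    covariates (row weights = sample totals) and the fitted values decomposed
    by SVD.  Species scores are scaled by singular values (scaling 2); biplot
    arrows are weighted correlations of covariates with site axes scaled by
    the axis singular values.
    """
    if list(species.index) != list(env.index):
        raise ValueError("species and env must share the same sample order")
    y = species.to_numpy(dtype=float)
    x = env.to_numpy(dtype=float)
    n_samples, n_cov = x.shape
    if n_cov >= n_samples:
        raise ValueError("need fewer covariates than samples")

    grand = y.sum()
    if grand <= 0:
        raise ValueError("species table is empty")
    p = y / grand
    r = p.sum(axis=1)            # sample weights
    c = p.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise ValueError("empty sample or species column in CCA input")
    expected = np.outer(r, c)
    q = (p - expected) / np.sqrt(expected)
    total_inertia = float((q**2).sum())

    # weighted standardization of covariates
    means = r @ x
    centered = x - means
    variances = r @ centered**2
    if (variances <= 1e-15).any():
        bad = env.columns[np.where(variances <= 1e-15)[0][0]]
        raise ValueError(f"constant covariate: {bad!r}")
    x_std = centered / np.sqrt(variances)
    x_w = np.sqrt(r)[:, None] * x_std
    for jcol in range(1, n_cov):
        if np.linalg.matrix_rank(x_w[:, : jcol + 1]) <= jcol:
            raise ValueError(
                f"collinear covariate: {env.columns[jcol]!r} is linearly "
                "dependent on the preceding covariates"
            )

    beta, *_ = np.linalg.lstsq(x_w, q, rcond=None)
    q_hat = x_w @ beta
    u, s, vt = np.linalg.svd(q_hat, full_matrices=False)
    keep = s > eig_tol * max(s[0], 1.0)
    u, s, vt = u[:, keep], s[keep], vt[keep]
    # deterministic sign: largest-magnitude site loading positive per axis
    for k in range(u.shape[1]):
        i = int(np.argmax(np.abs(u[:, k])))
        if u[i, k] < 0:
            u[:, k] = -u[:, k]
            vt[k] = -vt[k]

    eigvals = s**2
    axes = [f"CCA{k+1}" for k in range(len(s))]
    site = (u / np.sqrt(r)[:, None]) * s
    spec = (vt.T / np.sqrt(c)[:, None]) * s
    arrows = (x_w.T @ u) * s
    return Ordination(
        method="cca",
        site_coords=pd.DataFrame(site, index=species.index, columns=axes),
        species_coords=pd.DataFrame(spec, index=species.columns, columns=axes),
        biplot_arrows=pd.DataFrame(arrows, index=env.columns, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=eigvals / total_inertia,
        total_inertia=total_inertia,
        constrained_inertia=float(eigvals.sum()),
    )
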