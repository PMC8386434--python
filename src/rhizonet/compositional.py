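"""Compositional transforms: Bayesian-multiplicative zero replacement, CLR,
Aitchison distances, classical PCoA, and the joint PCA projection feeding the
yield model."""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from rhizonet.study_io import OtuTable

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CompositionMatrix:
    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray  # samples x OTUs
    space: str  # "proportions" | "clr"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.space not in ("proportions", "clr"):
            raise ValueError(f"unknown space {self.space!r}")
        sums = self.values.sum(axis=1)
        if self.space == "proportions":
            if (self.values <= 0).any():
                raise ValueError("proportion matrix must be strictly positive")
            if not np.allclose(sums, 1.0, atol=1e-10):
                raise ValueError("proportion rows must sum to 1")
        else:
            if not np.allclose(sums, 0.0, atol=1e-8):
                raise ValueError("clr rows must sum to 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)


@dataclasses.dataclass
class OrdinationResult:
    scores: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # non-increasing; PCoA may include negatives (reported)
    axis_labels: list[str]
    loadings: pd.DataFrame | None = None  # features x axes, PCA-mode only


def replace_zeros(
    table: OtuTable,
    alpha: Sequence[float] | None = None,
    strength: float | None = None,
) -> CompositionMatrix:
    """Bayesian-multiplicative zero replacement under a Dirichlet prior.

    For a sample with total count n, each zero part j becomes
    ``alpha_j * s / (n + s)`` and nonzero parts are multiplicatively shrunk by
    the total mass given to zeros, preserving their ratios exactly.  Defaults:
    symmetric prior ``alpha_j = 1/D`` with ``s = D/2`` (0.5 pseudo-count per
    part).
    """
    counts = table.counts.astype(float)
    n_parts = counts.shape[1]
    if alpha is None:
        alpha = np.full(n_parts, 1.0 / n_parts)
    else:
        alpha = np.asarray(alpha, dtype=float)
        if alpha.shape != (n_parts,):
            raise ValueError(f"alpha must have one entry per OTU ({n_parts})")
        if not np.isclose(alpha.sum(), 1.0):
            raise ValueError("prior means alpha must sum to 1")
    s = n_parts / 2.0 if strength is None else float(strength)
    if s <= 0:
        raise ValueError("prior strength must be positive")

    totals = counts.sum(axis=1)
    dead = np.flatnonzero(totals == 0)
    if dead.size:
        raise ValueError(f"sample {table.sample_ids[dead[0]]!r} has all-zero counts")

    zero_mask = counts == 0
    repl = alpha[None, :] * s / (totals[:, None] + s)  # candidate replacement
    zero_mass = (repl * zero_mask).sum(axis=1)
    props = counts / totals[:, None]
    out = np.where(zero_mask, repl, props * (1.0 - zero_mass[:, None]))

    # warn when a replacement exceeds the smallest observed proportion
    with np.errstate(invalid="ignore"):
        min_obs = np.where(zero_mask, np.inf, props).min(axis=1)
    offenders = ((repl * zero_mask) >= min_obs[:, None]).any(axis=1)
    for i in np.flatnonzero(offenders):
        logger.warning(
            "zero replacement for sample %s is not smaller than its minimum "
            "observed proportion",
            table.sample_ids[i],
        )
    out /= out.sum(axis=1, keepdims=True)  # guard rounding drift
    return CompositionMatrix(
        sample_ids=list(table.sample_ids),
        otu_ids=list(table.otu_ids),
        values=out,
        space="proportions",
    )


def clr_transform(m: CompositionMatrix) -> CompositionMatrix:
    """Centered log-ratio: ln(p_ij) minus the row mean of logs."""
    if m.space != "proportions":
        raise ValueError("clr_transform expects a proportion matrix")
    logs = np.log(m.values)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return CompositionMatrix(
        sample_ids=list(m.sample_ids),
        otu_ids=list(m.otu_ids),
        values=clr,
        space="clr",
    )


def aitchison_distance(m: CompositionMatrix) -> pd.DataFrame:
    """Euclidean distance between CLR rows."""
    if m.space != "clr":
        raise ValueError("aitchison_distance expects a CLR matrix")
    d = squareform(pdist(m.values, metric="euclidean"))
    return pd.DataFrame(d, index=m.sample_ids, columns=m.sample_ids)


def pcoa(d: pd.DataFrame | np.ndarray, n_axes: int = 10) -> OrdinationResult:
    """Classical (metric) multidimensional scaling via Gower double-centering."""
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        dm = d.to_numpy(dtype=float)
    else:
        dm = np.asarray(d, dtype=float)
        ids = [f"s{i}" for i in range(dm.shape[0])]
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (dm**2) @ j
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    positive = eigvals > max(1e-10, 1e-10 * abs(eigvals[0]))
    k = min(n_axes, int(positive.sum()))
    scores = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    labels = [f"PCo{i + 1}" for i in range(k)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=ids, columns=labels),
        eigenvalues=eigvals,
        axis_labels=labels,
    )


def joint_projection(
    clr_16s: CompositionMatrix,
    clr_its: CompositionMatrix,
    n_components: int = 70,
) -> OrdinationResult:
    """PCA of the column-wise concatenation of the two CLR matrices.

    Features are column-centered (no unit-variance scaling) and decomposed by
    SVD; at most ``min(n_components, rank)`` axes are returned.
    """
    if clr_16s.space != "clr" or clr_its.space != "clr":
        raise ValueError("joint_projection expects CLR matrices")
    if clr_16s.sample_ids != clr_its.sample_ids:
        extra = set(clr_16s.sample_ids) ^ set(clr_its.sample_ids)
        raise ValueError(
            "sample sets differ between markers"
            + (f": {sorted(extra)[:5]}" if extra else " (ordering mismatch)")
        )
    x = np.hstack([clr_16s.values, clr_its.values])
    feature_ids = [f"16S:{o}" for o in clr_16s.otu_ids] + [
        f"ITS:{o}" for o in clr_its.otu_ids
    ]
    xc = x - x.mean(axis=0, keepdims=True)
    u, sv, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int((sv > sv[0] * 1e-12).sum()) if sv.size else 0
    k = min(n_components, rank)
    if k < n_components:
        logger.info("requested %d components but rank is %d", n_components, rank)
    # deterministic sign: largest-|loading| entry positive per axis
    for a in range(k):
        pivot = np.argmax(np.abs(vt[a]))
        if vt[a, pivot] < 0:
            vt[a] *= -1
            u[:, a] *= -1
    scores = u[:, :k] * sv[:k]
    labels = [f"PC{i + 1}" for i in range(k)]
    n = x.shape[0]
    eigvals = (sv**2) / max(n - 1, 1)
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=clr_16s.sample_ids, columns=labels),
        eigenvalues=eigvals,
        axis_labels=labels,
        loadings=pd.DataFrame(vt[:k].T, index=feature_ids, columns=labels),
    )
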