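"""Temporal ordering of samples from a small gene signature via k-means."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from scrhythm.io import CellCountMatrix, logger
from scrhythm.hurdle import normalized_log_expression


@dataclass
class SampleSignature:
    """Samples x signature-genes matrix of z-scored mean log expression."""

    matrix: np.ndarray
    sample_ids: np.ndarray
    timepoints: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("signature matrix shape mismatch")


@dataclass
class OrderingResult:
    """Cluster assignment per sample with majority-timepoint labels."""

    sample_ids: np.ndarray
    timepoints: np.ndarray
    cluster: np.ndarray
    inferred_timepoint: np.ndarray
    concordance: int
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_ids,
                "timepoint_hours": self.timepoints,
                "cluster": self.cluster,
                "inferred_timepoint": self.inferred_timepoint,
                "concordant": self.timepoints == self.inferred_timepoint,
            }
        )


def build_signature(
    cells: CellCountMatrix,
    gene_set: list[str],
    cell_type: str | None = None,
) -> SampleSignature:
    """Per-sample mean log2(1+normalized) over the signature genes, z-scored.

    Samples with zero cells of the requested type are dropped with a
    warning, as are genes constant across the remaining samples.
    """
    ccm = cells
    if cell_type is not None:
        mask = (ccm.cells["cell_type"] == cell_type).to_numpy()
        if not mask.any():
            raise ValueError(f"no cells of type {cell_type!r}")
        ccm = ccm.subset_cells(mask)
    gene_rows = ccm.gene_index(gene_set)
    log_expr = normalized_log_expression(ccm)[gene_rows]

    samples = []
    timepoints = []
    profiles = []
    for sample, sub in ccm.cells.groupby("sample", sort=True):
        idx = sub.index.to_numpy()
        if len(idx) == 0:  # pragma: no cover - groupby yields nonempty groups
            warnings.warn(f"sample {sample} has no cells; dropped", RuntimeWarning)
            continue
        samples.append(sample)
        timepoints.append(float(sub["timepoint_hours"].iloc[0]))
        profiles.append(log_expr[:, idx].mean(axis=1))
    mat = np.array(profiles)  # samples x genes

    sd = mat.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(gene_set, keep) if not k]
        warnings.warn(
            f"constant signature genes dropped: {dropped}", RuntimeWarning
        )
    mat = (mat[:, keep] - mat[:, keep].mean(axis=0)) / sd[keep]
    return SampleSignature(
        matrix=mat,
        sample_ids=np.array(samples, dtype=object),
        timepoints=np.array(timepoints),
        gene_ids=np.array([g for g, k in zip(gene_set, keep) if k], dtype=object),
    )


def _label_clusters(
    cluster: np.ndarray, timepoints: np.ndarray, k: int
) -> dict[int, float]:
    """Majority-timepoint labels with greedy resolution of conflicts.

    Clusters are processed in decreasing order of their best available
    majority fraction; each takes its most frequent timepoint among labels
    not yet claimed (ties toward the smaller timepoint). When every
    timepoint is claimed, remaining clusters reuse their overall majority.
    """
    levels = np.unique(timepoints)
    counts = {
        c: pd.Series(timepoints[cluster == c]).value_counts()
        for c in range(k)
        if (cluster == c).any()
    }
    available = set(levels)
    labels: dict[int, float] = {}
    unassigned = set(counts)
    while unassigned:
        best = None  # (fraction, smaller timepoint, cluster)
        for c in unassigned:
            vc = counts[c]
            size = vc.sum()
            pool = [t for t in vc.index if t in available] or list(vc.index)
            frac = max(vc[t] for t in pool) / size
            tp = min(t for t in pool if vc[t] == max(vc[t2] for t2 in pool))
            cand = (frac, -tp, -c)
            if best is None or cand > best[0]:
                best = (cand, c, tp)
        _, c, tp = best
        labels[c] = float(tp)
        available.discard(tp)
        unassigned.discard(c)
    return labels


def kmeans_order(
    signature: SampleSignature,
    k: int | None = None,
    seed: int = 0,
    n_restarts: int = 20,
) -> OrderingResult:
    """Cluster samples by signature and score concordance with true time.

    Runs Lloyd's k-means with ``n_restarts`` random initializations keeping
    the best inertia, labels each cluster with the majority timepoint of
    its members (greedy, distinct labels while timepoints remain), and
    counts samples whose inferred label equals their own timepoint.
    """
    n = len(signature.sample_ids)
    if k is None:
        k = len(np.unique(signature.timepoints))
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} samples")
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        random_state=seed,
        tol=1e-6,
        algorithm="lloyd",
    )
    cluster = km.fit_predict(signature.matrix)
    labels = _label_clusters(cluster, signature.timepoints, k)
    inferred = np.array([labels[c] for c in cluster])
    concordance = int(np.sum(inferred == signature.timepoints))
    logger.debug("kmeans ordering: %d/%d concordant", concordance, n)
    return OrderingResult(
        sample_ids=signature.sample_ids,
        timepoints=signature.timepoints,
        cluster=cluster,
        inferred_timepoint=inferred,
        concordance=concordance,
        total=n,
    )
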