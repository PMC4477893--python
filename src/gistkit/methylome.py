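"""Methylation-array normalization, variance filtering and clustering.

Bead-array methylation probes report raw intensities whose dynamic range
varies from probe to probe but is consistent across samples.  Each probe is
therefore rescaled linearly between reference intensities measured at the
fully unmethylated and fully methylated states, clipping to [0, 1] — a
value comparable to the conventional beta value.  A beta-value mode
(methylated / (methylated + unmethylated + offset)) is provided for data
shipped as two-channel intensities.

Samples are compared on the informative probes only (across-sample
variance above a cutoff, default 0.1) and clustered agglomeratively with
Pearson correlation distance ``d = 1 - r`` and complete linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ProbeReference",
    "ClusterResult",
    "normalize_probe",
    "normalize_matrix",
    "beta_values",
    "variance_filter",
    "correlation_distance_matrix",
    "cluster_samples",
]


@dataclass(frozen=True)
class ProbeReference:
    """Reference intensities of one probe at its two extreme states."""

    probe_id: str
    ref_low: float
    ref_high: float

    def __post_init__(self) -> None:
        if not self.ref_high > self.ref_low >= 0:
            raise ValueError(
                f"{self.probe_id}: need ref_high > ref_low >= 0, "
                f"got ({self.ref_low}, {self.ref_high})"
            )


def normalize_probe(raw_value: float, ref: ProbeReference) -> float:
    """Linear rescale of a raw read-out between the reference anchors.

    ``clip((raw - ref_low) / (ref_high - ref_low), 0, 1)``; monotone in the
    raw value and invariant to a common positive rescaling of all three
    intensities.
    """
    if raw_value < 0:
        raise ValueError(f"raw intensity must be >= 0, got {raw_value!r}")
    x = (raw_value - ref.ref_low) / (ref.ref_high - ref.ref_low)
    return float(np.clip(x, 0.0, 1.0))


def normalize_matrix(raw: pd.DataFrame, references: pd.DataFrame) -> pd.DataFrame:
    """Normalize a probes × samples intensity matrix per probe.

    ``references`` is indexed by probe id with columns ``ref_low`` and
    ``ref_high``; every probe of ``raw`` must have a reference row.
    """
    missing = raw.index.difference(references.index)
    if len(missing):
        raise ValueError(f"no reference signal for probes: {list(missing[:5])}")
    lo = references.loc[raw.index, "ref_low"].to_numpy()[:, None]
    hi = references.loc[raw.index, "ref_high"].to_numpy()[:, None]
    if np.any(hi <= lo):
        bad = raw.index[(hi <= lo).ravel()]
        raise ValueError(f"ref_high <= ref_low for probes: {list(bad[:5])}")
    out = (raw.to_numpy(dtype=float) - lo) / (hi - lo)
    return pd.DataFrame(np.clip(out, 0.0, 1.0), index=raw.index, columns=raw.columns)


def beta_values(
    methylated: pd.DataFrame, unmethylated: pd.DataFrame, offset: float = 100.0
) -> pd.DataFrame:
    """Conventional beta transform ``M / (M + U + offset)`` per probe."""
    if not methylated.index.equals(unmethylated.index) or not methylated.columns.equals(
        unmethylated.columns
    ):
        raise ValueError("methylated and unmethylated matrices must be aligned")
    m = methylated.to_numpy(dtype=float)
    u = unmethylated.to_numpy(dtype=float)
    return pd.DataFrame(
        m / (m + u + offset), index=methylated.index, columns=methylated.columns
    )


def variance_filter(
    matrix: pd.DataFrame, threshold: float = 0.1, ddof: int = 1
) -> pd.Index:
    """Probes whose across-sample variance strictly exceeds ``threshold``.

    Sample variance (``ddof=1``) by default; requires at least two samples.
    """
    if matrix.shape[1] < 2:
        raise ValueError("variance filter needs at least two samples")
    var = matrix.var(axis=1, ddof=ddof)
    return matrix.index[var > threshold]


def correlation_distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Condensed pairwise sample distances ``1 - Pearson r`` across probes."""
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValueError("need at least two samples and two probes")
    X = matrix.to_numpy(dtype=float).T  # samples in rows
    sds = X.std(axis=1)
    if np.any(sds == 0):
        bad = matrix.columns[np.where(sds == 0)[0][0]]
        raise ValueError(
            f"sample {bad!r} has zero variance across probes; "
            "correlation distance undefined"
        )
    return pdist(X, metric="correlation")


@dataclass
class ClusterResult:
    """Complete-linkage dendrogram over samples.

    ``linkage`` is a scipy linkage matrix with ``len(sample_ids) - 1``
    merges and non-decreasing heights.
    """

    linkage: np.ndarray
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def cut(self, k: int) -> pd.Series:
        """Flat labels (1..k) from cutting the tree into ``k`` clusters."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")

    def cophenetic_matrix(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.sample_ids, columns=self.sample_ids)

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.sample_ids)
        return str(tree)


def cluster_samples(matrix: pd.DataFrame) -> ClusterResult:
    """Agglomerate samples by ``1 - r`` distance with complete linkage.

    Deterministic for a given sample order; equal-height merge ties are
    resolved by scipy's fixed internal order.  A zero-variance sample
    column raises a ``ValueError`` naming the sample.
    """
    dist = correlation_distance_matrix(matrix)
    Z = hierarchy.linkage(dist, method="complete")
    return ClusterResult(linkage=Z, sample_ids=[str(c) for c in matrix.columns])
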