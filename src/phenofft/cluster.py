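"""Mode-of-action clustering of treatment conditions.

Conditions are compared through the Pearson correlation of their
22-dimensional dominant-Fourier signatures and grouped by agglomerative
clustering on the correlation distance d = 1 − r.  On the published
4-condition reference table this recovers the mode-of-action split:
the microtubule disruptors (CLC, VBL) group together, the control
groups with the stabilizer (PTX), and PTX anti-correlates with both
disruptors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .fft_profiler import FeatureMatrix, build_feature_matrix, spectral_features
from .timeseries import aggregate, center_scale

LINKAGE_METHODS = ("average", "single", "complete")


@dataclass
class ClusterResult:
    """Condition correlation matrix, linkage tree, and flat labels."""

    conditions: list[str]
    correlation: pd.DataFrame
    linkage_matrix: np.ndarray  # scipy linkage encoding, (n−1) × 4
    labels: dict[str, int]  # condition → flat cluster id at requested k
    k: int
    method: str

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for cond, lab in self.labels.items():
            out.setdefault(lab, []).append(cond)
        return out


def condition_correlation(matrix: FeatureMatrix) -> pd.DataFrame:
    """Pearson correlation between condition feature vectors.

    Columns are standardized (z-scored across conditions) before the
    row-wise correlation, so features on different scales contribute
    equally.  This is idempotent for an already-normalized matrix and
    makes the result well-defined for externally supplied tables whose
    column scaling is unknown.
    """
    data = matrix.data
    if data.shape[0] < 2:
        raise ValueError("need at least 2 conditions to correlate")
    sd = data.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError(
            f"zero-variance feature column(s): {list(sd[sd == 0].index)}"
        )
    z = (data - data.mean(axis=0)) / sd
    row_sd = z.std(axis=1, ddof=1)
    degenerate = list(row_sd[row_sd == 0].index)
    if degenerate:
        raise ValueError(f"zero-variance condition row(s): {degenerate}")
    corr = np.corrcoef(z.to_numpy())
    return pd.DataFrame(corr, index=data.index, columns=data.index)


def cluster_conditions(corr: pd.DataFrame, method: str = "average",
                       k: int = 2) -> ClusterResult:
    """Agglomerative clustering of conditions on distance d = 1 − r."""
    if method not in LINKAGE_METHODS:
        raise ValueError(
            f"unknown linkage {method!r}; supported: {', '.join(LINKAGE_METHODS)}"
        )
    c = corr.to_numpy(dtype=float)
    if c.shape[0] != c.shape[1] or not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    dist = 1.0 - c
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method=method)
    flat = fcluster(z, t=k, criterion="maxclust")
    conditions = list(corr.index)
    return ClusterResult(conditions=conditions, correlation=corr,
                         linkage_matrix=z,
                         labels=dict(zip(conditions, (int(v) for v in flat))),
                         k=k, method=method)


def archetype_recovery_report(records_by_replicate: dict[str, pd.DataFrame],
                              true_labels: dict[str, str],
                              method: str = "average") -> dict:
    """End-to-end validation: records → series → spectra → clustering.

    ``records_by_replicate`` maps replicate names (e.g. ``control#1``)
    to per-cell record tables; ``true_labels`` maps replicate names to
    archetype names.  Clusters at k = number of distinct archetypes and
    reports the adjusted Rand agreement with the truth.
    """
    archetypes = sorted(set(true_labels.values()))
    if len(archetypes) < 2:
        raise ValueError("recovery needs replicates from at least 2 archetypes")
    counts = {a: sum(1 for v in true_labels.values() if v == a) for a in archetypes}
    thin = [a for a, n in counts.items() if n < 2]
    if thin:
        raise ValueError(f"need ≥ 2 replicates per archetype; too few for {thin}")

    features = []
    for name, records in records_by_replicate.items():
        records = records.assign(condition=name)
        series = aggregate(records)[name]
        features.extend(spectral_features(center_scale(series)))
    matrix = build_feature_matrix(features, normalize=True)
    corr = condition_correlation(matrix)
    result = cluster_conditions(corr, method=method, k=len(archetypes))
    names = list(records_by_replicate)
    truth = [true_labels[n] for n in names]
    predicted = [result.labels[n] for n in names]
    return {
        "feature_matrix": matrix,
        "cluster_result": result,
        "agreement": float(adjusted_rand_score(truth, predicted)),
        "truth": dict(zip(names, truth)),
    }
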