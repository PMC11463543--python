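"""Clustering of protein abundance trajectories across differentiation.

Profiles are z-scored per protein and grouped by k-means over a range of
cluster counts, with k chosen by maximum mean silhouette.  The method is a
documented stand-in for whatever grouping produced published trajectory
figures: deterministic given a seed, standard, and easy to validate on
simulated trajectories with known labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

log = logging.getLogger("endolyso")


def zscore_profiles(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each row to mean 0, population sd 1.

    Missing timepoints are linearly interpolated within the row first
    (boundary gaps carried from the nearest observed value).  Rows with
    fewer than 3 finite values or zero variance are dropped and returned
    as the second element.
    """
    filled = profiles.interpolate(axis=1, limit_direction="both")
    enough = profiles.notna().sum(axis=1) >= 3
    sd = filled.std(axis=1, ddof=0)
    keep = enough & (sd > 0)
    dropped = profiles.index[~keep].tolist()
    if dropped:
        log.info("[profiles] dropped %d constant/sparse row(s)", len(dropped))
    z = filled.loc[keep]
    z = z.sub(z.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return z, dropped


@dataclass
class ClusterResult:
    """Cluster labels with the chosen k and per-k silhouette scores."""

    labels: pd.Series
    k: int
    silhouettes: dict[int, float]
    centroids: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [f"profile clustering: k = {self.k} "
                 f"(silhouette {self.silhouettes[self.k]:.3f})"]
        for c, cnt in self.labels.value_counts().sort_index().items():
            peak = self.centroids.columns[self.centroids.loc[c].argmax()]
            lines.append(f"  cluster {c}: {cnt} proteins, peak at {peak}")
        return "\n".join(lines)


def cluster_profiles(z: pd.DataFrame, k_range=range(2, 11), seed: int = 0,
                     n_init: int = 20) -> ClusterResult:
    """K-means over z-scored profiles with silhouette-based model selection.

    Clusters are renumbered by the timepoint of their centroid maximum
    (earliest-peaking cluster first) so labels are stable under row
    permutation of the input.
    """
    k_range = list(k_range)
    if len(z) < 2 * max(k_range):
        raise ValueError(f"{len(z)} profiles too few for k up to {max(k_range)}")
    X = z.to_numpy(dtype=float)
    scores: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(X)
        scores[k] = float(silhouette_score(X, lab)) if len(set(lab)) > 1 else -1.0
        fits[k] = lab
    best_k = max(k_range, key=lambda k: (scores[k], -k))
    lab = fits[best_k]

    cent = pd.DataFrame(
        [X[lab == c].mean(axis=0) for c in range(best_k)], columns=z.columns)
    # earliest-peaking first; tie-break on centroid values for determinism
    order = sorted(range(best_k),
                   key=lambda c: (int(cent.loc[c].argmax()), tuple(-cent.loc[c])))
    remap = {old: new for new, old in enumerate(order)}
    labels = pd.Series([remap[c] for c in lab], index=z.index, name="cluster")
    cent = cent.loc[order].reset_index(drop=True)
    return ClusterResult(labels=labels, k=best_k, silhouettes=scores, centroids=cent)
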