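"""Two-channel immunofluorescence cell typing and contact statistics.

Per-soma mean GlyT2-eGFP and neurogranin intensities are normalized per
channel (slope of a line fitted to the log pixel-intensity histogram
tail), clustered with 2-D k-means into a low-eGFP "GABAergic" and a
high-eGFP glycinergic Golgi-cell population, and axon-apposition counts
are summarized per population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans


def normalize_channel(pixel_intensities, tail_quantile: float = 0.8,
                      n_bins: int = 64):
    """Per-channel intensity normalization from the log-histogram slope.

    A line is fitted to ln(counts) of the histogram of the intensity tail
    above ``tail_quantile``; for an exponential intensity law with decay λ
    the fitted slope is −λ, and the channel is divided by the factor
    −1/slope (= 1/λ).  This makes the normalization gain-invariant: two
    channels identical up to a multiplicative gain normalize to the same
    values.

    Returns ``(factor, normalized_intensities)``.
    """
    x = np.asarray(pixel_intensities, dtype=float).ravel()
    if x.size < 1000:
        raise ValueError("need at least 1000 pixels")
    if np.allclose(x, x[0]):
        raise ValueError("constant channel cannot be normalized")
    lo = np.quantile(x, tail_quantile)
    hi = x.max()
    counts, edges = np.histogram(x[(x >= lo) & (x <= hi)], bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        raise ValueError("histogram tail too sparse to fit")
    slope, _ = np.polyfit(centers[keep], np.log(counts[keep]), 1)
    if slope >= 0:
        raise ValueError("non-decaying intensity tail; cannot normalize")
    factor = -1.0 / slope
    return float(factor), x / factor


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray     # 'GABAergic' | 'glycinergic' per cell
    centers: np.ndarray    # (2, 2): rows GABAergic, glycinergic; cols egfp, ngn
    fractions: dict        # population -> fraction of cells


class TwoPopulationKMeans(BaseEstimator, ClusterMixin):
    """Seeded 2-means on (eGFP, neurogranin) with deterministic
    farthest-point initialization; the lower-eGFP cluster is labeled
    "GABAergic", the other "glycinergic".

    Fitted attributes: ``labels_`` (strings), ``cluster_centers_`` (2×2,
    GABAergic first), ``fractions_``.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed

    @staticmethod
    def _farthest_point_init(X: np.ndarray, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        first = int(rng.integers(X.shape[0]))
        d = np.linalg.norm(X - X[first], axis=1)
        second = int(np.argmax(d))
        return X[[first, second]].astype(float)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected an (n_cells, 2) intensity array")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 cells")
        # farthest-point seeding plus seeded k-means++ restarts; the lower
        # inertia wins, deterministically for a fixed seed
        init = self._farthest_point_init(X, self.seed)
        km = KMeans(n_clusters=2, init=init, n_init=1, random_state=self.seed).fit(X)
        km_pp = KMeans(n_clusters=2, n_init=10, random_state=self.seed).fit(X)
        if km_pp.inertia_ < km.inertia_:
            km = km_pp
        gaba = int(np.argmin(km.cluster_centers_[:, 0]))  # lower eGFP
        names = np.where(km.labels_ == gaba, "GABAergic", "glycinergic")
        self.labels_ = names
        self.cluster_centers_ = km.cluster_centers_[[gaba, 1 - gaba]]
        n = X.shape[0]
        self.fractions_ = {"GABAergic": float(np.sum(names == "GABAergic") / n),
                           "glycinergic": float(np.sum(names == "glycinergic") / n)}
        self.inertia_ = float(km.inertia_)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_cells(table: pd.DataFrame, seed: int = 0) -> ClusterResult:
    """2-D k-means cell typing of an intensity table with columns
    ``egfp`` and ``neurogranin``."""
    est = TwoPopulationKMeans(seed=seed).fit(table[["egfp", "neurogranin"]].to_numpy())
    return ClusterResult(est.labels_, est.cluster_centers_, est.fractions_)


@dataclass(frozen=True)
class ContactSummary:
    n_cells: dict              # population -> cell count
    contacted: dict            # population -> cells with >= 1 apposition
    mean_appositions: dict     # population -> mean count among contacted cells
    max_appositions: dict
    total_appositions: dict
    apposition_fraction: dict  # share of all appositions on each population


def contact_summary(table: pd.DataFrame, labels) -> ContactSummary:
    """Apposition-count statistics per clustered population.

    A cell counts as contacted when it carries at least one apposition;
    totals are conserved: per-population apposition sums add up to the
    table total.
    """
    lab = np.asarray(labels)
    if lab.shape[0] != len(table):
        raise ValueError("labels must cover all cells")
    app = table["appositions"].to_numpy()
    grand_total = app.sum()
    n_cells, contacted, mean_a, max_a, tot, frac = {}, {}, {}, {}, {}, {}
    for pop in np.unique(lab):
        a = app[lab == pop]
        hit = a[a >= 1]
        n_cells[pop] = int(a.size)
        contacted[pop] = int(hit.size)
        mean_a[pop] = float(hit.mean()) if hit.size else 0.0
        max_a[pop] = int(hit.max()) if hit.size else 0
        tot[pop] = int(a.sum())
        frac[pop] = float(a.sum() / grand_total) if grand_total else 0.0
    return ContactSummary(n_cells, contacted, mean_a, max_a, tot, frac)
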