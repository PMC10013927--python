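"""Per-locus duration effects and longevity classification.

Each locus with at least one epimutation run receives a duration estimate:
by default the arithmetic mean of its run durations pooled across lineages
(the one-way fixed-effect OLS solution of ``duration ~ locus``), optionally
shrunk toward the grand mean with a ridge weight ``lam`` standing in for a
random-intercept fit:

    estimate = (sum(durations) + lam * grand_mean) / (n_runs + lam)

The estimates are then split with 1-D K-means (k = 2): among loci with at
least one inherited run, membership in the larger-centroid cluster marks a
locus as carrying *long-lived* epimutations, the rest as *short-lived*;
loci whose runs are all single-generation are *non-inherited* regardless of
clustering.  A two-component Gaussian-mixture EM fit provides an independent
cross-check of the long-lived set (Jaccard overlap reported).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .inheritance import Run

CLASSES = ("non_inherited", "short_lived", "long_lived")


@dataclass
class DurationEstimate:
    locus_id: str
    assay: str
    estimate: float
    n_runs: int
    lineages_observed: int
    any_inherited: bool


def estimate_duration_effects(
    runs: Iterable[Run], lam: float = 0.0
) -> pd.DataFrame:
    """Shrunken per-locus mean run duration (lam = 0: plain OLS mean).

    Censored runs contribute their observed length.  Returns a frame indexed
    by locus with columns estimate, n_runs, lineages_observed, any_inherited.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("empty run list")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    df = pd.DataFrame(
        {
            "locus_id": [r.locus_id for r in runs],
            "assay": [r.assay for r in runs],
            "lineage_id": [r.lineage_id for r in runs],
            "length": [r.length for r in runs],
            "inherited": [r.inherited for r in runs],
        }
    )
    grand_mean = df["length"].mean()
    grouped = df.groupby("locus_id", sort=True)
    out = pd.DataFrame(
        {
            "assay": grouped["assay"].first(),
            "estimate": (grouped["length"].sum() + lam * grand_mean)
            / (grouped["length"].count() + lam),
            "n_runs": grouped["length"].count(),
            "lineages_observed": grouped["lineage_id"].nunique(),
            "any_inherited": grouped["inherited"].any(),
        }
    )
    return out


def kmeans_longevity(
    estimates: pd.DataFrame,
    k: int = 2,
    restarts: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """1-D K-means split of duration estimates into longevity classes.

    Returns (classes frame with a ``longevity`` column, sorted centroids).
    Loci without any inherited run are ``non_inherited`` regardless of their
    cluster; among the rest, the larger-centroid cluster is ``long_lived``.
    """
    x = estimates["estimate"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("all duration estimates identical: no split possible")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(x.reshape(-1, 1))
    centroids = km.cluster_centers_.ravel()
    long_cluster = int(np.argmax(centroids))
    longevity = np.where(
        ~estimates["any_inherited"].to_numpy(),
        "non_inherited",
        np.where(labels == long_cluster, "long_lived", "short_lived"),
    )
    classes = pd.DataFrame(
        {
            "assay": estimates["assay"],
            "estimate": estimates["estimate"],
            "cluster": labels,
            "longevity": longevity,
        },
        index=estimates.index,
    )
    return classes, np.sort(centroids)


@dataclass
class MixtureCrosscheck:
    assignments: pd.Series  # component index per locus (1 = larger-mean component)
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    converged: bool
    jaccard_long_lived: float | None


def em_mixture_crosscheck(
    estimates: pd.DataFrame,
    seed: int = 0,
    kmeans_classes: pd.DataFrame | None = None,
    max_restarts: int = 10,
) -> MixtureCrosscheck:
    """Two-component univariate normal mixture fitted by EM.

    Convergence at log-likelihood gain < 1e-8 or 500 iterations; degenerate
    fits (a component variance collapsing) are retried with fresh random
    initializations, up to ``max_restarts``.  Assignment is by maximum
    posterior; when K-means classes are supplied the Jaccard overlap of the
    two long-lived sets is reported.
    """
    x = estimates["estimate"].to_numpy(dtype=float).reshape(-1, 1)
    if len(x) < 10:
        raise ValueError("need at least 10 estimates for the mixture cross-check")
    rng = np.random.default_rng(seed)
    gm = None
    for attempt in range(max_restarts):
        cand = GaussianMixture(
            n_components=2,
            covariance_type="full",
            tol=1e-8,
            max_iter=500,
            n_init=1,
            init_params="random_from_data",
            reg_covar=1e-10,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        cand.fit(x)
        sds = np.sqrt(cand.covariances_.ravel())
        if np.all(sds > 1e-6):
            gm = cand
            break
    if gm is None:
        raise RuntimeError("EM degenerate after jittered restarts")
    order = np.argsort(gm.means_.ravel())
    raw = gm.predict(x)
    # relabel so component 1 is the larger-mean ("long-lived") component
    assignments = pd.Series(
        np.where(raw == order[1], 1, 0), index=estimates.index, name="component"
    )
    jaccard = None
    if kmeans_classes is not None:
        em_long = set(assignments.index[(assignments == 1)
                                        & estimates["any_inherited"]])
        km_long = set(
            kmeans_classes.index[kmeans_classes["longevity"] == "long_lived"]
        )
        union = em_long | km_long
        jaccard = len(em_long & km_long) / len(union) if union else 1.0
    return MixtureCrosscheck(
        assignments=assignments,
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.ravel())[order],
        weights=gm.weights_.ravel()[order],
        converged=bool(gm.converged_),
        jaccard_long_lived=jaccard,
    )
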