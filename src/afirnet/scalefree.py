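"""Degree-distribution power-law fitting and the scale-free verdict.

A Barabási–Albert scale-free network satisfies two topological conditions:
a few hyper-connected hubs coexist with many poorly connected nodes (the
degree distribution follows a power law N(k) = a * k**gamma with gamma < 0),
and the clustering coefficient is uncorrelated with the degree.  Both are
assessed here the way the standard network-analysis toolchain does it:
ordinary least squares on the base-10 logged (degree, node count) pairs for
the power law, and plain untransformed OLS for the degree–clustering
independence check.  The verdict combines the two R² thresholds with the
presence of at least one hub.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .netio import MolecularNetwork


@dataclass
class DegreeDistribution:
    """Counts N(k) of nodes having each degree k >= 1 (zero-degree nodes excluded)."""

    ks: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.ks = np.asarray(self.ks, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.ks) <= 0):
            raise ValueError("degrees must be strictly increasing")

    @property
    def num_nodes(self) -> int:
        return int(self.counts.sum())


@dataclass
class PowerLawFit:
    """OLS fit of log10 N(k) on log10 k: N(k) = a * k**gamma."""

    a: float
    gamma: float
    pearson_r: float
    r_squared: float
    n_points: int

    def predict(self, ks) -> np.ndarray:
        return self.a * np.asarray(ks, dtype=float) ** self.gamma


@dataclass
class ScaleFreeAssessment:
    """The recorded inputs and thresholds behind a scale-free verdict."""

    fit: PowerLawFit
    degree_clustering_r_squared: float
    has_hubs: bool
    fit_r2_threshold: float
    independence_r2_threshold: float
    verdict: bool = field(init=False)

    def __post_init__(self):
        self.verdict = (
            self.fit.r_squared >= self.fit_r2_threshold
            and self.degree_clustering_r_squared <= self.independence_r2_threshold
            and self.has_hubs
        )


def degree_distribution(net: MolecularNetwork) -> DegreeDistribution:
    """Tally nodes by distinct-neighbor count, dropping degree-0 nodes."""
    degs = np.array([d for _, d in net.graph.degree if d > 0])
    if degs.size == 0:
        return DegreeDistribution(np.array([]), np.array([]))
    ks, counts = np.unique(degs, return_counts=True)
    return DegreeDistribution(ks, counts)


def fit_power_law(dist: DegreeDistribution) -> PowerLawFit:
    """Least-squares line through (log10 k, log10 N(k)).

    The exponent gamma is the slope and the prefactor a = 10**intercept;
    Pearson's r and R² = r² are reported on the logged data.  Degrees with
    zero count never enter (they have no log).
    """
    keep = dist.counts > 0
    ks, counts = dist.ks[keep], dist.counts[keep]
    if ks.size < 2:
        raise ValueError("power-law fit needs at least two distinct degrees")
    x, y = np.log10(ks), np.log10(counts)
    res = stats.linregress(x, y)
    r = float(res.rvalue) if np.all(np.isfinite([res.rvalue])) else 0.0
    if np.ptp(y) == 0:  # constant counts: flat line, no correlation
        r = 0.0
    return PowerLawFit(
        a=float(10**res.intercept),
        gamma=float(res.slope),
        pearson_r=r,
        r_squared=r * r,
        n_points=int(ks.size),
    )


def degree_clustering_correlation(metrics) -> float:
    """R² of OLS of clustering coefficient on degree, untransformed.

    Computed across all nodes with degree >= 1; a value near 0 means the
    clustering coefficient carries no information about connectivity, one of
    the two scale-free conditions.
    """
    sub = metrics[metrics["degree"] >= 1]
    x = sub["degree"].to_numpy(dtype=float)
    y = sub["clustering_coefficient"].to_numpy(dtype=float)
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    r = stats.linregress(x, y).rvalue
    return float(r * r)


def classify_scale_free(
    net: MolecularNetwork,
    metrics=None,
    fit_r2_threshold: float = 0.6,
    independence_r2_threshold: float = 0.1,
) -> ScaleFreeAssessment:
    """Run both scale-free conditions plus hub presence and combine them.

    The thresholds are configurable and echoed in the assessment so a
    verdict is always reproducible from its own report.
    """
    import networkx as nx
    import pandas as pd

    from .keynodes import find_hubs

    if metrics is None:
        # only degree and clustering are needed; skip the path-based metrics
        metrics = pd.DataFrame(
            {
                "degree": dict(net.graph.degree),
                "clustering_coefficient": nx.clustering(net.graph),
            }
        )
    dist = degree_distribution(net)
    try:
        fit = fit_power_law(dist)
    except ValueError:
        # a single-degree (e.g. regular) graph has no distribution to fit;
        # record a degenerate flat fit that cannot pass the R² threshold
        fit = PowerLawFit(
            a=float(dist.counts[0]) if dist.counts.size else 0.0,
            gamma=0.0,
            pearson_r=0.0,
            r_squared=0.0,
            n_points=int(dist.ks.size),
        )
    indep = degree_clustering_correlation(metrics)
    hubs = find_hubs(net)
    return ScaleFreeAssessment(
        fit=fit,
        degree_clustering_r_squared=indep,
        has_hubs=len(hubs.hubs) > 0,
        fit_r2_threshold=fit_r2_threshold,
        independence_r2_threshold=independence_r2_threshold,
    )
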