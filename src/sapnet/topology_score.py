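"""Topology score (T-score): cancer-gene proximity in the PPI network.

For a node *i* the raw score is the ratio

    T_i = (mean shortest-path length from i to neutral nodes)
        / (mean shortest-path length from i to cancer nodes)

over unweighted hop-count distances, so T > 1 means the node sits closer,
on average, to cancer-annotated proteins than to the rest of the network.
Raw scores are min-max normalized to [0, 1] using constants fitted over
all network nodes; the constants are part of the persisted calibration so
new proteins can be scored later (values outside the fitted range clip).

Conventions (degenerate cases):

* the source node is excluded from both target sets — a cancer-annotated
  source is scored by its distance to the *other* cancer nodes, so its
  own membership cannot inflate the score;
* unreachable targets are excluded from both averages;
* a protein absent from the network scores exactly 1 (indistinguishable
  from a random node), as does a node from which an entire target class
  is unreachable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import FormatError, PpiNetwork

#: raw T-score assigned to proteins outside the network
OFF_NETWORK_T = 1.0


@dataclass(frozen=True)
class TNormalizer:
    """Min-max constants for mapping raw T-scores into [0, 1]."""

    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t_min) and np.isfinite(self.t_max)):
            raise ValueError("normalizer constants must be finite")
        if self.t_min >= self.t_max:
            raise ValueError(
                f"degenerate normalizer: t_min {self.t_min} >= t_max {self.t_max}"
            )


def shortest_path_lengths(network: PpiNetwork, source: str) -> dict[str, int]:
    """Breadth-first hop counts from ``source`` to every reachable node.

    Unreachable nodes are absent from the returned map; the source maps
    to 0.
    """
    if source not in network:
        raise KeyError(f"source {source!r} not in network")
    idx = network.node_index
    row = network.distance_matrix()[idx[source]]
    order = sorted(idx, key=idx.get)
    return {n: int(row[i]) for i, n in enumerate(order) if np.isfinite(row[i])}


def _target_masks(network: PpiNetwork) -> tuple[np.ndarray, np.ndarray]:
    idx = network.node_index
    cancer = np.zeros(len(idx), dtype=bool)
    for n in network.cancer_nodes:
        cancer[idx[n]] = True
    return cancer, ~cancer


def raw_t_score(network: PpiNetwork, protein: str) -> float:
    """Raw cancer-proximity ratio (mean dist to neutral / mean dist to cancer).

    Returns :data:`OFF_NETWORK_T` for proteins not in the network and for
    nodes from which no cancer (or no neutral) node is reachable.
    """
    if not network.cancer_nodes:
        raise FormatError("cancer node set is empty; T-score undefined")
    if protein not in network:
        return OFF_NETWORK_T
    scores = _raw_t_scores_vector(network)
    return float(scores[network.node_index[protein]])


def _raw_t_scores_vector(network: PpiNetwork) -> np.ndarray:
    """Raw T-score for every node (sorted-node order), vectorized and cached."""
    cached = getattr(network, "_t_vector", None)
    if cached is not None:
        return cached
    if not network.cancer_nodes:
        raise FormatError("cancer node set is empty; T-score undefined")
    d = network.distance_matrix().copy()
    np.fill_diagonal(d, np.nan)           # source excluded from both sets
    d[~np.isfinite(d)] = np.nan           # unreachable targets excluded
    cancer, neutral = _target_masks(network)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN rows are a
        avg_c = np.nanmean(d[:, cancer], axis=1) if cancer.any() else np.full(len(d), np.nan)
        avg_n = np.nanmean(d[:, neutral], axis=1) if neutral.any() else np.full(len(d), np.nan)
        t = avg_n / avg_c                                 # defined fallback
    t[~np.isfinite(t)] = OFF_NETWORK_T    # whole target class unreachable
    network._t_vector = t
    return t


def fit_t_normalizer(network: PpiNetwork) -> TNormalizer:
    """Fit min-max constants over the raw T-scores of all network nodes.

    The off-network fallback value 1 does not enter the extremes unless
    some node actually attains it.  All-identical raw scores are an error
    (the normalizer would be degenerate).
    """
    t = _raw_t_scores_vector(network)
    t_min, t_max = float(np.min(t)), float(np.max(t))
    if t_min == t_max:
        raise FormatError(
            "all raw T-scores identical; min-max normalization is degenerate"
        )
    return TNormalizer(t_min=t_min, t_max=t_max)


def normalized_t(raw: float, norm: TNormalizer) -> float:
    """Min-max normalize a raw T-score, clipping into [0, 1]."""
    value = (raw - norm.t_min) / (norm.t_max - norm.t_min)
    return float(np.clip(value, 0.0, 1.0))


def proximity_contrast(
    network: PpiNetwork,
    protein: str,
    n_samples: int,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Sampled contrast of distances to cancer vs non-cancer nodes.

    Samples ``n_samples`` nodes uniformly without replacement (source
    excluded), splits them by cancer membership and compares the two
    reachable-distance samples with a two-sided Wilcoxon rank-sum test.

    Returns ``(mean distance to sampled cancer nodes, mean distance to
    sampled non-cancer nodes, rank-sum p-value)``.
    """
    if protein not in network:
        raise KeyError(f"{protein!r} not in network")
    idx = network.node_index
    candidates = [n for n in sorted(idx) if n != protein]
    if n_samples > len(candidates):
        raise ValueError(
            f"n_samples {n_samples} exceeds available nodes {len(candidates)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_samples, replace=False)
    row = network.distance_matrix()[idx[protein]]
    d_cancer, d_neutral = [], []
    for j in chosen:
        node = candidates[j]
        dist = row[idx[node]]
        if not np.isfinite(dist):
            continue
        (d_cancer if node in network.cancer_nodes else d_neutral).append(dist)
    if not d_cancer or not d_neutral:
        raise ValueError(
            "a sampled group is empty; increase n_samples to cover both "
            "cancer and non-cancer nodes"
        )
    stat = stats.ranksums(d_cancer, d_neutral)
    return float(np.mean(d_cancer)), float(np.mean(d_neutral)), float(stat.pvalue)
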