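"""Statistical significance of motif abundance.

Two z-score views of the most abundant motif of a given size:

* *within-graph* — its frequency against the frequencies of all motifs of
  the same size in the same graph, z = (x1 - mean) / sd;
* *versus a random ensemble* — its frequency against the top frequencies
  measured in degree-preserving randomizations of the graph (double-edge
  swaps), z = (x - mean(x_i)) / sd(x_i).

Defaults follow common practice for motif null models: 100 random
replicas, each randomized by 10 x |E| successful edge swaps.  |z| > 2 is
flagged significant.  The standard deviation is the sample sd (n - 1
denominator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .graph_core import NetworkGraph, edge_key
from .join_engine import DiscoveryConfig, find_motifs

log = logging.getLogger(__name__)

SIGNIFICANCE_THRESHOLD = 2.0


@dataclass
class ZScoreReport:
    motif_size: int
    top_frequency: int
    mean: float
    sd: float
    z: Optional[float]  # None when sd == 0 (undefined)
    mode: str = "within"
    n_samples: int = 0

    @property
    def undefined(self) -> bool:
        return self.z is None

    @property
    def significant(self) -> bool:
        return self.z is not None and abs(self.z) > SIGNIFICANCE_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "mode": self.mode, "motif_size": self.motif_size,
            "top_frequency": self.top_frequency, "mean": self.mean,
            "sd": self.sd, "z": self.z, "undefined": self.undefined,
            "significant": self.significant, "n_samples": self.n_samples,
        }


def _sample_sd(values: Sequence[float]) -> float:
    return float(np.std(np.asarray(values, dtype=float), ddof=1))


def zscore_within_graph(frequencies: Sequence[int],
                        motif_size: int = 0) -> ZScoreReport:
    """z-score of the largest frequency against all same-size frequencies."""
    if len(frequencies) < 2:
        raise ValueError("need at least two motif frequencies")
    top = max(frequencies)
    mean = float(np.mean(frequencies))
    sd = _sample_sd(frequencies)
    z = (top - mean) / sd if sd > 0 else None
    return ZScoreReport(motif_size=motif_size, top_frequency=top, mean=mean,
                        sd=sd, z=z, mode="within", n_samples=len(frequencies))


def degree_preserving_shuffle(g: NetworkGraph, swap_factor: int = 10,
                              seed: int = 0,
                              max_attempt_factor: int = 100) -> NetworkGraph:
    """Randomize by double-edge swaps, preserving every node's degree.

    Picks two edges (v1, v2), (u1, u2) uniformly at random and rewires to
    (v1, u2), (u1, v2).  Proposals creating self-loops or parallel edges
    (or picking overlapping edge pairs) are rejected and retried without
    counting; ``swap_factor`` x |E| *successful* swaps are performed, with
    at most ``max_attempt_factor`` x |E| proposals in total.
    """
    out = g.copy()
    n_edges = out.number_of_edges()
    if swap_factor == 0:
        return out
    if n_edges < 2:
        raise ValueError("need at least two edges to swap")
    rng = np.random.default_rng(seed)
    edges = out.sorted_edges()
    target = swap_factor * n_edges
    max_attempts = max_attempt_factor * n_edges
    done = attempts = 0
    while done < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        v1, v2 = edges[i]
        u1, u2 = edges[j]
        if len({v1, v2, u1, u2}) < 4:
            continue
        # rewire (v1,v2),(u1,u2) -> (v1,u2),(u1,v2)
        if out.has_edge(v1, u2) or out.has_edge(u1, v2):
            continue
        out._adj[v1].discard(v2); out._adj[v2].discard(v1)
        out._adj[u1].discard(u2); out._adj[u2].discard(u1)
        out.add_edge(v1, u2)
        out.add_edge(u1, v2)
        edges[i] = edge_key(v1, u2)
        edges[j] = edge_key(u1, v2)
        done += 1
    if done < target:
        log.warning("edge shuffle stalled after %d/%d swaps (%d proposals)",
                    done, target, attempts)
    return out


def top_motif_frequency(g: NetworkGraph, cfg: DiscoveryConfig) -> int:
    """Frequency of the most abundant motif of the configured size.

    Runs discovery with alpha = 1 so every motif of the size is visible;
    returns 0 when no motif of that size exists.
    """
    scan = DiscoveryConfig(mu=cfg.mu, alpha=1, size_mode=cfg.size_mode,
                           measure=cfg.measure, join_source=cfg.join_source,
                           seed=cfg.seed)
    freqs = find_motifs(g, scan).frequencies()
    return max(freqs) if freqs else 0


def zscore_within(g: NetworkGraph, cfg: DiscoveryConfig) -> ZScoreReport:
    """First approach, end to end: all motifs of size mu in g, then z."""
    scan = DiscoveryConfig(mu=cfg.mu, alpha=1, size_mode=cfg.size_mode,
                           measure=cfg.measure, join_source=cfg.join_source,
                           seed=cfg.seed)
    freqs = find_motifs(g, scan).frequencies()
    return zscore_within_graph(freqs, motif_size=cfg.mu)


def _replica_seed(seed: int, index: int) -> int:
    # independent, reproducible per-replica streams
    return int(np.random.SeedSequence(entropy=(seed, index)).generate_state(1)[0])


def zscore_vs_random(g: NetworkGraph, cfg: DiscoveryConfig,
                     n_random: int = 100, swap_factor: int = 10,
                     seed: int = 0) -> ZScoreReport:
    """Second approach: top frequency in g versus shuffled replicas."""
    if n_random < 2:
        raise ValueError("need at least two random replicas")
    x = top_motif_frequency(g, cfg)
    samples = []
    for i in range(n_random):
        replica = degree_preserving_shuffle(g, swap_factor,
                                            seed=_replica_seed(seed, i))
        assert replica.degree_sequence() == g.degree_sequence(), \
            "shuffle changed the degree sequence"
        samples.append(top_motif_frequency(replica, cfg))
    mean = float(np.mean(samples))
    sd = _sample_sd(samples)
    z = (x - mean) / sd if sd > 0 else None
    return ZScoreReport(motif_size=cfg.mu, top_frequency=x, mean=mean, sd=sd,
                        z=z, mode="random", n_samples=n_random)
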