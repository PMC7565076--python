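"""Greedy centroid clustering of sequences at a percent-identity threshold.

UCLUST/USEARCH-style: sequences are processed in canonical order
(descending length, then lexicographic id); each sequence joins the first
existing centroid it matches at or above the threshold, otherwise it founds
a new cluster.  Fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .align import pairwise_identity

__all__ = ["Clustering", "greedy_cluster"]

IdentityFn = Callable[[str, str], float]

# guards against float representation noise at integer grid thresholds
_EPS = 1e-9


@dataclass
class Clustering:
    """An OTU partition: centroid id -> member ids (centroid included)."""

    clusters: dict[str, list[str]]
    threshold: float
    method: str = "greedy-centroid"
    weights: Mapping[str, int] | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_sequences(self) -> int:
        return sum(len(m) for m in self.clusters.values())

    def sizes(self) -> dict[str, int]:
        """Cluster sizes; ``weights`` (e.g. dereplication counts) respected."""
        w = self.weights or {}
        return {
            cid: sum(w.get(m, 1) for m in members)
            for cid, members in self.clusters.items()
        }

    def membership(self) -> dict[str, str]:
        """Map each sequence id to its centroid id."""
        return {m: cid for cid, members in self.clusters.items() for m in members}


def canonical_order(seqs: Mapping[str, str]) -> list[str]:
    return sorted(seqs, key=lambda sid: (-len(seqs[sid]), sid))


def greedy_cluster(
    seqs: Mapping[str, str],
    threshold: float,
    identity_fn: IdentityFn = pairwise_identity,
    weights: Mapping[str, int] | None = None,
) -> Clustering:
    """Cluster ``{id: sequence}`` at ``threshold`` percent identity.

    A sequence joins the first centroid (in founding order) with
    ``identity >= threshold``; comparison at integer thresholds is exact for
    integer-percent identities.
    """
    if not 0 < threshold <= 100:
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    clusters: dict[str, list[str]] = {}
    centroid_ids: list[str] = []
    for sid in canonical_order(seqs):
        for cid in centroid_ids:
            if identity_fn(seqs[cid], seqs[sid]) + _EPS >= threshold:
                clusters[cid].append(sid)
                break
        else:
            centroid_ids.append(sid)
            clusters[sid] = [sid]
    return Clustering(clusters=clusters, threshold=threshold, weights=weights)
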