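"""Group high-likelihood carriers into putative distorter families.

Warp scores individuals, but close relatives of a true carrier score high
together; to count distinct putative distorters, high-likelihood
individuals (posterior strictly above a threshold, default 40%) are
clustered by graph traversal: two are in the same family when they lie
within ``link_radius`` parent-child edges of each other (default 2 —
grandparent-grandchild or sibling reach), and families extend through
chains and webs of such links.  Distances are measured in the full
pedigree, so low-likelihood individuals can serve as path intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .bp import CarrierPosterior
from .pedigree import Pedigree, within_radius


@dataclass(frozen=True)
class ClusterParams:
    likelihood_threshold: float = 0.40
    link_radius: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.likelihood_threshold <= 1.0):
            raise ValueError("likelihood_threshold must be in [0, 1]")
        if self.link_radius < 1:
            raise ValueError("link_radius must be >= 1")


@dataclass(frozen=True)
class FamilyCluster:
    member_ids: frozenset[str]
    representative_id: str


def high_likelihood_nodes(
    post: CarrierPosterior, params: ClusterParams = ClusterParams()
) -> set[str]:
    """Ids with posterior strictly above the threshold ("above 40%")."""
    thr = params.likelihood_threshold
    return {i for i, v in post.values.items() if v > thr}


def cluster_relatives(
    ped: Pedigree,
    nodes: Iterable[str],
    params: ClusterParams = ClusterParams(),
    post: Optional[CarrierPosterior] = None,
) -> list[FamilyCluster]:
    """Partition ``nodes`` into families (connected components of the
    within-``link_radius`` proximity graph).

    Singleton high-likelihood nodes form singleton clusters.  When a
    posterior is supplied the representative is the member with the
    maximum posterior (ties to the smallest id); otherwise the smallest
    id.  Output is sorted by representative id, invariant to the input
    iteration order.
    """
    node_set = set(nodes)
    for n in node_set:
        if n not in ped:
            raise KeyError(f"unknown individual id {n!r}")
    # adjacency: radius-limited BFS from each node through the full pedigree
    adj: dict[str, set[str]] = {}
    for n in node_set:
        adj[n] = within_radius(ped, n, params.link_radius) & node_set
    clusters = []
    seen: set[str] = set()
    for start in sorted(node_set):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        seen.add(start)
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    comp.add(nb)
                    stack.append(nb)
        if post is not None:
            rep = min(comp, key=lambda i: (-post.values.get(i, 0.0), i))
        else:
            rep = min(comp)
        clusters.append(
            FamilyCluster(member_ids=frozenset(comp), representative_id=rep)
        )
    clusters.sort(key=lambda c: c.representative_id)
    return clusters


def cluster_posteriors(
    ped: Pedigree,
    post: CarrierPosterior,
    params: ClusterParams = ClusterParams(),
) -> list[FamilyCluster]:
    """Threshold a Warp posterior and cluster the survivors."""
    return cluster_relatives(
        ped, high_likelihood_nodes(post, params), params, post=post
    )
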