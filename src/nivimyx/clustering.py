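"""Greedy centroid clustering of unique ribotypes and biological labelling.

The clustering mirrors classic greedy OTU pickers: ribotypes are scanned in
decreasing-abundance order and each joins the *first* existing centroid it
matches at or above the similarity threshold (default 99.1%), otherwise it
founds a new cluster. Clusters are labelled by the abundance-weighted
majority morphospecies of their members; morphospecies split over several
clusters get suffixes -a, -b, ... by decreasing cluster abundance, so one
cluster approximates one putative biospecies.
"""
from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ContractError
from .sequences import Ribotype, SequenceRecord, global_identity


@dataclass(frozen=True)
class ClusterPolicy:
    threshold: float = 0.991

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ContractError(f"threshold must be in (0, 1], got {self.threshold}")


@dataclass
class RibotypeCluster:
    cluster_id: str
    centroid_id: str
    member_ids: list[str] = field(default_factory=list)
    identities: dict[str, float] = field(default_factory=dict)  # member -> identity to centroid
    total_abundance: int = 0
    label: str | None = None


@dataclass
class LabelConflict:
    """A member whose own morphospecies disagrees with its cluster's label."""

    cluster_id: str
    member_id: str
    member_species: str
    cluster_label: str


def greedy_cluster(ribotypes: Sequence[Ribotype], policy: ClusterPolicy | None = None) -> list[RibotypeCluster]:
    """Cluster deduplicated ribotypes; input must be abundance-sorted.

    Returns clusters in centroid-creation order with per-member identities to
    the centroid. The member sets partition the input and abundance is
    conserved.
    """
    policy = policy or ClusterPolicy()
    if not ribotypes:
        raise ContractError("greedy_cluster: empty input")
    keys = [(-r.abundance, min(r.member_ids) if r.member_ids else r.id) for r in ribotypes]
    if keys != sorted(keys):
        raise ContractError("greedy_cluster: input must be sorted by decreasing abundance "
                            "(ties by lexicographic first-member id); use dedup_ribotypes()")
    clusters: list[RibotypeCluster] = []
    centroids: list[Ribotype] = []
    for rt in ribotypes:
        placed = False
        for cl, cen in zip(clusters, centroids):
            res = global_identity(rt.sequence, cen.sequence)
            if res.identity >= policy.threshold:
                cl.member_ids.append(rt.id)
                cl.identities[rt.id] = res.identity
                cl.total_abundance += rt.abundance
                placed = True
                break
        if not placed:
            cl = RibotypeCluster(
                cluster_id=f"C{len(clusters) + 1:03d}",
                centroid_id=rt.id,
                member_ids=[rt.id],
                identities={rt.id: 1.0},
                total_abundance=rt.abundance,
            )
            clusters.append(cl)
            centroids.append(rt)
    return clusters


def label_clusters(
    clusters: Sequence[RibotypeCluster],
    ribotypes: Sequence[Ribotype],
    records: Sequence[SequenceRecord],
) -> tuple[list[RibotypeCluster], list[LabelConflict]]:
    """Attach morphospecies labels (with -a..-e style suffixes) to clusters.

    The label is the abundance-weighted majority morphospecies over member
    records; members of a minority species are reported as conflicts (they
    stay in the cluster — exclusion is a downstream reporting decision).
    Clusters with no labelled member get ``unknown-<centroid_id>``.
    """
    rt_by_id = {r.id: r for r in ribotypes}
    rec_by_id = {r.id: r for r in records}
    conflicts: list[LabelConflict] = []
    species_weight: dict[str, dict[str, int]] = {}
    for cl in clusters:
        weights: dict[str, int] = {}
        for rt_id in cl.member_ids:
            for mem in rt_by_id[rt_id].member_ids:
                rec = rec_by_id.get(mem)
                if rec is not None and rec.morphospecies:
                    weights[rec.morphospecies] = weights.get(rec.morphospecies, 0) + rec.abundance
        species_weight[cl.cluster_id] = weights
        if weights:
            cl.label = max(weights, key=lambda s: (weights[s], s))
        else:
            cl.label = f"unknown-{cl.centroid_id}"
    # suffixes for morphospecies split over >1 cluster, by decreasing abundance
    by_species: dict[str, list[RibotypeCluster]] = {}
    for cl in clusters:
        if not cl.label.startswith("unknown-"):
            by_species.setdefault(cl.label, []).append(cl)
    for species, group in by_species.items():
        if len(group) > 1:
            group.sort(key=lambda c: (-c.total_abundance, c.cluster_id))
            for k, cl in enumerate(group):
                suffix = string.ascii_lowercase[k] if k < 26 else f"x{k}"
                cl.label = f"{species}-{suffix}"
    for cl in clusters:
        base = cl.label.rsplit("-", 1)[0] if "-" in (cl.label or "") else cl.label
        for rt_id in cl.member_ids:
            for mem in rt_by_id[rt_id].member_ids:
                rec = rec_by_id.get(mem)
                if rec is not None and rec.morphospecies and rec.morphospecies != base \
                        and not cl.label.startswith("unknown-"):
                    conflicts.append(LabelConflict(cl.cluster_id, mem, rec.morphospecies, cl.label))
    return list(clusters), conflicts


def clusters_to_frame(clusters: Sequence[RibotypeCluster], ribotypes: Sequence[Ribotype]) -> pd.DataFrame:
    """Long-format cluster table: one row per member ribotype."""
    rt_by_id = {r.id: r for r in ribotypes}
    rows = []
    for cl in clusters:
        for rt_id in cl.member_ids:
            rows.append({
                "cluster_id": cl.cluster_id,
                "label": cl.label,
                "centroid_id": cl.centroid_id,
                "member_id": rt_id,
                "identity_to_centroid": cl.identities[rt_id],
                "abundance": rt_by_id[rt_id].abundance,
            })
    return pd.DataFrame(rows)


def write_clusters(clusters: Sequence[RibotypeCluster], ribotypes: Sequence[Ribotype],
                   path: str | Path) -> None:
    clusters_to_frame(clusters, ribotypes).to_csv(path, sep="\t", index=False)
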