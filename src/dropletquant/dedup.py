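"""Removal of z-dimension doublets: the same droplet seen on several slices.

A droplet a few micrometres across intersects more than one optical section,
so the per-slice detector reports it repeatedly.  Particles on nearby slices
whose centroids fall within ``link_radius`` of each other are treated as
cross-sections of one physical object; each such cluster keeps only its
largest member.  Matching is by centroid distance rather than pixel overlap
because consecutive cross-sections of one droplet can differ markedly in
size.  Chains spanning more than two slices collapse to a single retained
particle — a droplet crossing three sections is still one droplet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .detect import Particle, ParticleSet

__all__ = ["LinkConfig", "link_doublets", "resolve_clusters", "deduplicate"]


@dataclass
class LinkConfig:
    """Linking rule: two particles are the same object when their slice
    indices differ by at most ``max_z_gap`` and their (y, x) centroid
    distance is at most ``link_radius`` pixels."""

    link_radius: float = 5.0
    max_z_gap: int = 1

    def __post_init__(self) -> None:
        if self.link_radius < 0:
            raise ValueError("link_radius must be >= 0")
        if self.max_z_gap < 1:
            raise ValueError("max_z_gap must be >= 1")


def link_doublets(particles: ParticleSet, cfg: LinkConfig) -> List[List[int]]:
    """Partition particle indices into clusters of putative doublets.

    Builds the graph with an edge between every pair satisfying the linking
    rule and returns its connected components (transitive chaining allowed),
    as lists of indices into ``particles.particles``.
    """
    plist = particles.particles
    n = len(plist)
    if n == 0:
        return []
    pts = np.array([p.centroid for p in plist], dtype=float)
    zs = np.array([p.slice_index for p in plist])

    tree = cKDTree(pts)
    pairs = tree.query_pairs(cfg.link_radius, output_type="ndarray")
    if len(pairs):
        dz = np.abs(zs[pairs[:, 0]] - zs[pairs[:, 1]])
        pairs = pairs[dz <= cfg.max_z_gap]
    if len(pairs):
        ones = np.ones(len(pairs))
        adj = coo_matrix((ones, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n)

    clusters: Dict[int, List[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    return list(clusters.values())


def _keep_key(p: Particle):
    # largest area wins; ties -> lower slice, then lower y, then lower x
    return (-p.pixel_count, p.slice_index, p.centroid[0], p.centroid[1])


def resolve_clusters(
    particles: ParticleSet, clusters: List[List[int]]
) -> ParticleSet:
    """Flag exactly one particle per cluster as retained (the largest).

    Discarded doublets stay in the set with ``kept_after_dedup = False`` so
    the output table remains auditable; summaries use retained ones only.
    """
    for p in particles.particles:
        p.kept_after_dedup = False
    for members in clusters:
        best = min(members, key=lambda i: _keep_key(particles.particles[i]))
        particles.particles[best].kept_after_dedup = True
    return particles


def deduplicate(particles: ParticleSet, cfg: LinkConfig | None = None) -> ParticleSet:
    """Link doublets and keep the largest candidate of each cluster."""
    cfg = cfg or LinkConfig()
    return resolve_clusters(particles, link_doublets(particles, cfg))
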