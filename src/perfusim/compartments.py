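"""Radius-threshold partition of a vascular tree into compartments.

Vessels with radius above the first threshold form the resolved *upper
hierarchy* (compartment 0); the remaining vessels are binned into N
homogenized compartments by half-open radius intervals
(r_thresh_i, r_thresh_{i-1}].  Interface sets between compartments are
built from shared nodes: a segment a = uv belongs to the interface
I_{i,k} when its proximal node u is shared by both compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree import VascularTree

__all__ = ["CompartmentScheme", "compartmentalize"]


class CompartmentError(ValueError):
    pass


@dataclass
class CompartmentScheme:
    tree: VascularTree
    thresholds: np.ndarray            # r_thresh_0 > ... > r_thresh_N >= 0
    segment_compartment: np.ndarray   # (n_segments,) in {0, .., N}
    node_membership: np.ndarray       # (n_nodes, N+1) bool
    interfaces: dict = field(default_factory=dict)       # (i,k) -> segment idx array
    connecting_nodes: dict = field(default_factory=dict)  # (i,k) -> node idx array

    @property
    def n_compartments(self) -> int:
        """Number of homogenized compartments (excludes the resolved hierarchy)."""
        return len(self.thresholds) - 1

    def segments_in(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.segment_compartment == i)

    def outlet_nodes(self, i: int = 1):
        """Connecting nodes between the resolved hierarchy and compartment i,
        with the net flow entering compartment i at each node.

        These carry the mass exchange between the resolved tree and the
        homogenized compartments (Gaussian sources for a supplying tree,
        pressure-dependent sinks for a draining one).
        """
        tree = self.tree
        nodes = self.connecting_nodes.get((0, i), np.empty(0, dtype=np.int64))
        flows = np.zeros(len(nodes))
        prox = tree.proximal
        for j, u in enumerate(nodes):
            segs = np.flatnonzero((prox == u) & (self.segment_compartment == i))
            flows[j] = tree.flows[segs].sum()
        keep = flows > 0
        return nodes[keep], flows[keep]


def compartmentalize(tree: VascularTree, thresholds) -> CompartmentScheme:
    """Assign every segment to a compartment by its radius.

    ``thresholds`` is the strictly decreasing sequence
    (r_thresh_0, ..., r_thresh_N); segment a goes to compartment i iff
    r_thresh_i < r_a <= r_thresh_{i-1}, to the resolved compartment 0 iff
    r_a > r_thresh_0.  All terminal segments must land in the lowest
    compartment N (the homogenized model drains through it).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 1 or len(thresholds) < 1:
        raise CompartmentError("need at least one threshold radius")
    if len(thresholds) == 1:
        # a lone threshold means "resolved above, one homogenized
        # compartment below"; the implicit lower bound is zero
        thresholds = np.array([thresholds[0], 0.0])
    if np.any(np.diff(thresholds) >= 0):
        raise CompartmentError("thresholds must be strictly decreasing")
    r = tree.radii
    if np.any(~np.isfinite(r)):
        raise CompartmentError("tree radii must be set before compartmentalization")
    if np.any(r <= thresholds[-1]):
        raise CompartmentError(
            "segments with radius at or below the last threshold "
            f"(min radius {r.min():.4g} <= {thresholds[-1]:.4g}); lower the last threshold"
        )
    n_comp = len(thresholds)  # compartments 1..N plus the resolved 0
    # interval assignment: searchsorted over descending thresholds
    # comp = number of thresholds >= r  (r > t0 -> 0; t_i < r <= t_{i-1} -> i)
    comp = np.searchsorted(-thresholds, -r, side="right")
    seg_comp = comp.astype(np.int64)

    n_lowest = n_comp - 1
    leaf_segs = tree._seg_of_node[tree.leaves]
    bad = leaf_segs[seg_comp[leaf_segs] != n_lowest]
    if len(bad):
        raise CompartmentError(
            f"{len(bad)} terminal segments fall outside the lowest compartment "
            f"{n_lowest} (first offending segment {int(bad[0])}); "
            "adjust the thresholds"
        )

    membership = np.zeros((tree.n_nodes, n_comp), dtype=bool)
    prox, dist = tree.proximal, tree.distal
    for i in range(n_comp):
        segs = seg_comp == i
        membership[prox[segs], i] = True
        membership[dist[segs], i] = True

    interfaces = {}
    connecting = {}
    for i in range(n_comp):
        for k in range(n_comp):
            if i == k:
                continue
            shared = np.flatnonzero(membership[:, i] & membership[:, k])
            if len(shared) == 0:
                continue
            connecting[(i, k)] = shared
            shared_mask = np.zeros(tree.n_nodes, dtype=bool)
            shared_mask[shared] = True
            in_union = (seg_comp == i) | (seg_comp == k)
            segs = np.flatnonzero(in_union & shared_mask[prox])
            if len(segs):
                interfaces[(i, k)] = segs

    return CompartmentScheme(
        tree=tree,
        thresholds=thresholds,
        segment_compartment=seg_comp,
        node_membership=membership,
        interfaces=interfaces,
        connecting_nodes=connecting,
    )
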