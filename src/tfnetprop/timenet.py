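"""Instantiation of time-specific networks from the template.

For each time point j the analyzed network G_j is the template restricted
to the node set ``V_j = (TGset ∩ DEGset_j) ∪ TFset`` (intersected with the
template's own nodes). TFs are always included, whether or not they are
differentially expressed: regulators with small expression changes can
still drive large downstream responses. Node weights carry the absolute
differential-expression statistic, DE(v) = |d_{v,j}| (0 for genes without
a value at time j).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = ["TimeNetwork", "instantiate", "instantiate_all"]


@dataclass
class TimeNetwork:
    """The template subgraph analyzed at one time point.

    Attributes
    ----------
    time_index : int
        Time point j >= 1.
    nodes : list of str
        V_j, sorted (the fixed node order used by all matrix code).
    tf_set : set of str
        TFs present in V_j (the full template TF set intersected with
        template nodes; isolated TFs are kept).
    edges : dict
        (source, target) -> weight; template edges with both endpoints in
        V_j. Signed weights are retained here; sign policy is applied by
        the influence and propagation modules.
    node_de : dict
        DE(v) = |d_{v,j}| per node (0 if unknown).
    deg_set : set of str
        DEGset_j ∩ TGset restricted to V_j (the genes selection must
        explain).
    flags : list of str
        Diagnostics, e.g. "empty_deg_set".
    """

    time_index: int
    nodes: list
    tf_set: set
    edges: dict
    node_de: dict
    deg_set: set
    flags: list = field(default_factory=list)
    dropped_degs: int = 0

    def __post_init__(self):
        self._index = {v: i for i, v in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, v) -> int:
        return self._index[v]

    def edge_arrays(self):
        """(src_idx, dst_idx, weight) int/float arrays in sorted edge order."""
        items = sorted(self.edges.items())
        src = np.array([self._index[u] for (u, _), _ in items], dtype=np.int32)
        dst = np.array([self._index[v] for (_, v), _ in items], dtype=np.int32)
        w = np.array([w for _, w in items], dtype=float)
        return src, dst, w

    def de_array(self) -> np.ndarray:
        return np.array([self.node_de.get(v, 0.0) for v in self.nodes], dtype=float)

    def tf_mask(self) -> np.ndarray:
        return np.array([v in self.tf_set for v in self.nodes], dtype=bool)

    def adjacency(self, weights=None) -> sparse.csr_matrix:
        src, dst, w = self.edge_arrays()
        if weights is not None:
            w = weights
        n = self.n_nodes
        return sparse.csr_matrix((w, (src, dst)), shape=(n, n))

    def out_neighbors(self, u) -> set:
        return {v for (s, v) in self.edges if s == u}


def _resolve_tg_set(net, tg_set):
    if isinstance(tg_set, str) and tg_set == "all":
        return net.nodes - net.tf_set
    return set(tg_set)


def instantiate(net, deg, tg_set="all", j=1, deg_set=None):
    """Build the time-specific network G_j.

    Parameters
    ----------
    net : TemplateNetwork
    deg : DEGProfile
    tg_set : "all" or iterable of gene ids
        User target-gene set; "all" means every non-TF template node
        (whole-DEG mode).
    j : int
        Time point, must be a column of the DEG profile.
    deg_set : set, optional
        Override for DEGset_j (used by the control-subtraction variant);
        defaults to ``deg.deg_set(j)``.
    """
    if j not in deg.times:
        raise ValueError(f"time point {j} out of range; profile has {deg.times}")
    degset = deg.deg_set(j) if deg_set is None else set(deg_set)
    tgs = _resolve_tg_set(net, tg_set)
    kept_targets = tgs & degset & net.nodes
    # coverage report: DEGs the template cannot analyze
    scope = degset if (isinstance(tg_set, str) and tg_set == "all") else (tgs & degset)
    dropped = len(scope - net.nodes)

    tf_in_template = net.tf_set & net.nodes
    v_j = kept_targets | tf_in_template
    nodes = sorted(v_j)
    edges = {e: w for e, w in net.edges.items() if e[0] in v_j and e[1] in v_j}
    node_de = {v: abs(deg.d_value(v, j)) for v in nodes}
    dset = kept_targets
    flags = []
    if not degset:
        flags.append("empty_deg_set")
    if not dset:
        flags.append("no_covered_targets")
    return TimeNetwork(
        time_index=j,
        nodes=nodes,
        tf_set=tf_in_template,
        edges=edges,
        node_de=node_de,
        deg_set=dset,
        flags=flags,
        dropped_degs=dropped,
    )


def instantiate_all(net, deg, tg_set="all"):
    """Instantiate G_j for every time point of the profile, ordered by j."""
    return [instantiate(net, deg, tg_set=tg_set, j=j) for j in deg.times]
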