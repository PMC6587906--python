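"""Random-walk-with-restart propagation and greedy major-TF selection.

Seed mass placed on a candidate TF set is diffused over the time-specific
network by iterating ``p_k = alpha * p0 + (1 - alpha) * W p_{k-1}`` until
the L1 change falls below a tolerance; the fixed point equals the closed
form ``alpha * (I - (1 - alpha) W)^{-1} p0``. The propagated vector IP(v)
is an inferred expression response; a candidate seed set is scored by the
Spearman rank correlation (SCC) between IP(v) and the observed DE(v) over
all network nodes.

Selection walks down the influence ranking: the top TF always seeds the
set; each further TF is kept only if adding it strictly increases the SCC;
the walk stops once the selected TFs directly cover more than half of the
time point's DEGs. The result is a minimal major-TF set plus its induced
TF -> DEG network.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats

__all__ = [
    "PropagationConfig",
    "SelectionResult",
    "TrialRecord",
    "build_transition_matrix",
    "rwr",
    "score_selection",
    "coverage",
    "select_major_tfs",
    "extract_mtfnet",
]


@dataclass
class PropagationConfig:
    """Knobs of the propagation step.

    alpha : restart rate in (0, 1]; low alpha favors network smoothing.
    tol : L1 convergence tolerance of the power iteration.
    max_iter : iteration cap (non-convergence warns, last iterate returned).
    normalization : "out_degree" divides each edge weight by the source's
        total (clamped) out-weight, so propagation follows the TF->target
        direction; "in_degree" normalizes by the target's in-weight.
    coverage_mode : "direct" counts DEGs that are direct targets of the
        selected TFs; "reachable" counts DEGs reachable by any directed
        path.
    """

    alpha: float = 0.1
    tol: float = 1e-9
    max_iter: int = 1000
    normalization: str = "out_degree"
    coverage_mode: str = "direct"

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")
        if self.normalization not in ("out_degree", "in_degree"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.coverage_mode not in ("direct", "reachable"):
            raise ValueError(f"unknown coverage_mode {self.coverage_mode!r}")


TrialRecord = namedtuple("TrialRecord", "candidate scc_before scc_after accepted")


@dataclass
class SelectionResult:
    """Outcome of greedy selection at one time point."""

    time_index: int
    accepted: list
    ip: dict
    scc_trace: list
    coverage_trace: list
    mtfnet: dict
    best_scc: float = float("nan")
    flags: list = field(default_factory=list)


def build_transition_matrix(tn, cfg=None) -> sparse.csr_matrix:
    """Column-stochastic transition matrix W with W[v, u] = w+(u->v)/sum.

    Negative weights are clamped to zero first (inhibitory edges do not
    propagate; random walks need nonnegative weights to converge). Columns
    of dangling nodes (no positive out-weight) are all zero, so their mass
    leaks -- restart replenishes it.
    """
    cfg = cfg or PropagationConfig()
    n = tn.n_nodes
    if n == 0:
        return sparse.csr_matrix((0, 0))
    src, dst, w = tn.edge_arrays()
    w = np.clip(w, 0.0, None)
    if cfg.normalization == "out_degree":
        norm = np.zeros(n)
        np.add.at(norm, src, w)
        denom = norm[src]
    else:  # in_degree
        norm = np.zeros(n)
        np.add.at(norm, dst, w)
        denom = norm[dst]
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, w / np.where(denom > 0, denom, 1.0), 0.0)
    # W rows = destination, cols = source: p_k(v) = sum_u W[v,u] p_{k-1}(u)
    return sparse.csr_matrix((vals, (dst, src)), shape=(n, n))


def rwr(W, p0, cfg=None, return_info=False):
    """Iterate the restart recursion to its fixed point.

    ``p0`` is normalized to sum 1 internally (it must be nonnegative with
    positive mass). With alpha = 1 the recursion degenerates to p0.
    """
    cfg = cfg or PropagationConfig()
    p0 = np.asarray(p0, dtype=float)
    if p0.min() < 0:
        raise ValueError("p0 must be nonnegative")
    total = p0.sum()
    if total <= 0:
        raise ValueError("p0 must have positive mass")
    p0 = p0 / total
    if cfg.alpha == 1.0:
        return (p0.copy(), True, 1) if return_info else p0.copy()
    p = p0.copy()
    converged = False
    k = 0
    for k in range(1, cfg.max_iter + 1):
        p_next = cfg.alpha * p0 + (1.0 - cfg.alpha) * (W @ p)
        if np.abs(p_next - p).sum() < cfg.tol:
            p = p_next
            converged = True
            break
        p = p_next
    if not converged:
        warnings.warn(
            f"RWR did not converge within {cfg.max_iter} iterations", stacklevel=2
        )
    return (p, converged, k) if return_info else p


def score_selection(ip, tn):
    """Spearman rank correlation between IP(v) and DE(v) over all of V_j.

    Average ranks for ties; 0.0 if either vector is constant (undefined).
    """
    de = tn.de_array()
    ip = np.asarray(ip, dtype=float)
    if np.all(ip == ip[0]) or np.all(de == de[0]):
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(ip, de).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def coverage(S, tn, mode="direct") -> int:
    """Number of deg_set genes explained by the TF set S."""
    S = set(S)
    if not S:
        return 0
    if mode == "direct":
        covered = {v for (u, v) in tn.edges if u in S and v in tn.deg_set}
        return len(covered)
    if mode == "reachable":
        adj = {}
        for (u, v) in tn.edges:
            adj.setdefault(u, []).append(v)
        seen = set()
        stack = [v for s in S for v in adj.get(s, ())]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(adj.get(v, ()))
        return len((seen - S) & tn.deg_set)
    raise ValueError(f"unknown coverage mode {mode!r}")


def _seed_vector(tn, seed_set):
    """p0: DE-weighted mass on the seed TFs; uniform if all seed DE are 0."""
    p0 = np.zeros(tn.n_nodes)
    idx = [tn.node_index(t) for t in seed_set]
    de = np.array([tn.node_de.get(t, 0.0) for t in seed_set])
    if de.sum() > 0:
        p0[idx] = de
    else:
        p0[idx] = 1.0
    return p0


def select_major_tfs(tn, ranking, cfg=None):
    """Greedy assembly of the minimal major-TF set at one time point.

    The first-ranked TF always seeds S; each later TF in ranking order is
    accepted iff its trial SCC strictly exceeds the current best. Stops
    once coverage(S) > |deg_set| / 2 (checked after every acceptance) or
    the ranking is exhausted.
    """
    cfg = cfg or PropagationConfig()
    j = tn.time_index
    if not ranking:
        return SelectionResult(j, [], {}, [], [], {}, flags=["empty_ranking"])
    flags = []
    if not tn.deg_set:
        flags.append("empty_deg_set")
    W = build_transition_matrix(tn, cfg)
    half = len(tn.deg_set) / 2.0

    S = [ranking[0]]
    ip = rwr(W, _seed_vector(tn, S), cfg)
    best = score_selection(ip, tn)
    trace = [TrialRecord(ranking[0], float("-inf"), best, True)]
    cov = coverage(S, tn, cfg.coverage_mode)
    cov_trace = [cov]
    stopped = tn.deg_set and cov > half

    if not stopped:
        for t in ranking[1:]:
            trial = S + [t]
            ip_try = rwr(W, _seed_vector(tn, trial), cfg)
            scc = score_selection(ip_try, tn)
            if scc > best:
                trace.append(TrialRecord(t, best, scc, True))
                S, best, ip = trial, scc, ip_try
                cov = coverage(S, tn, cfg.coverage_mode)
                cov_trace.append(cov)
                if tn.deg_set and cov > half:
                    break
            else:
                trace.append(TrialRecord(t, best, scc, False))

    mtfnet = extract_mtfnet(S, tn)
    return SelectionResult(
        time_index=j,
        accepted=S,
        ip={v: float(ip[i]) for i, v in enumerate(tn.nodes)},
        scc_trace=trace,
        coverage_trace=cov_trace,
        mtfnet=mtfnet,
        best_scc=best,
        flags=flags,
    )


def extract_mtfnet(S, tn):
    """Induced network of the selected TFs and the DEGs they reach.

    Nodes: S plus every deg_set gene reachable from S along paths whose
    intermediate nodes all lie in S (regulation is only explained through
    selected TFs). Edges: all G_j edges among those nodes. Every non-TF
    node of the result is a DEG.
    """
    S = set(S)
    if not S:
        return {}
    adj = {}
    for (u, v) in tn.edges:
        adj.setdefault(u, []).append(v)
    reached = set()
    seen = set()
    stack = [v for s in S for v in adj.get(s, ())]
    while stack:
        v = stack.pop()
        if v in seen:
            continue
        seen.add(v)
        if v in tn.deg_set:
            reached.add(v)
        if v in S:  # only selected TFs relay the path
            stack.extend(adj.get(v, ()))
    keep = S | reached
    return {e: w for e, w in tn.edges.items() if e[0] in keep and e[1] in keep}
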