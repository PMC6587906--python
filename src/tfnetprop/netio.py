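"""Input/output and the basic data containers.

The three inputs of a run are a *template network* (a static, directed
TF -> target edge list such as a PlantRegMap-style regulation table), a
time-series *expression matrix* (genes x samples, samples annotated with a
time point and a replicate index) and a per-time-point *differential
expression profile* (a statistic ``d`` -- a z-score or log2 fold change --
plus a p-value, per gene and time point, produced by an external DEG caller
such as limma or DESeq2).

Edge weights of the template can be replaced by the Pearson correlation
between the expression of the two endpoint genes over the post-baseline
samples (:func:`compute_pcc_weights`), which is how condition-specific
evidence enters the otherwise condition-agnostic template.
"""

from __future__ import annotations

import math
import os
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "TemplateNetwork",
    "ExpressionSeries",
    "DEGProfile",
    "NetworkParseError",
    "read_template_network",
    "read_expression",
    "read_deg_profile",
    "compute_pcc_weights",
    "write_networks",
    "read_network_file",
    "write_template_network",
    "write_expression",
    "write_deg_profile",
]


class NetworkParseError(ValueError):
    """Raised when an input file cannot be parsed; carries the line number."""


@dataclass
class TemplateNetwork:
    """A directed, weighted TF -> target graph.

    Parameters
    ----------
    tf_set : set of str
        Nodes flagged as transcription factors. Every edge source must be
        a member. Targets may themselves be TFs (TF->TF edges are allowed
        and are essential for indirect, multi-layer regulation).
    edges : dict
        Map ``(source, target) -> weight``. Weights are raw priors (1.0 by
        default) or signed correlations in [-1, 1] after PCC weighting.
    nodes : set of str, optional
        Node universe; defaults to the union of edge endpoints and
        ``tf_set``. Extra (isolated) nodes are permitted.
    """

    tf_set: set
    edges: dict
    nodes: set = field(default=None)

    def __post_init__(self):
        if self.nodes is None:
            self.nodes = set(self.tf_set)
            for (u, v) in self.edges:
                self.nodes.add(u)
                self.nodes.add(v)
        for (u, v) in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u}->{v} not allowed")
            if u not in self.tf_set:
                raise ValueError(f"edge source {u!r} is not in tf_set")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def copy(self) -> "TemplateNetwork":
        return TemplateNetwork(set(self.tf_set), dict(self.edges), set(self.nodes))

    def out_edges(self, u):
        return [(s, t) for (s, t) in self.edges if s == u]

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, weight=float(w))
        return g


@dataclass
class ExpressionSeries:
    """Expression values ``e[i, j, k]`` for gene i, time j, replicate k.

    Stored as a DataFrame with genes in rows and a (time, replicate)
    MultiIndex over columns. Time point 0 is the unstressed baseline.
    """

    data: pd.DataFrame

    def __post_init__(self):
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise ValueError("expression columns must be a (time, replicate) MultiIndex")
        if 0 not in self.time_points:
            raise ValueError("expression series must contain baseline time point 0")

    @property
    def genes(self):
        return list(self.data.index)

    @property
    def time_points(self):
        return sorted({t for t, _ in self.data.columns})

    @property
    def n_replicates(self) -> int:
        reps = {t: 0 for t in self.time_points}
        for t, _ in self.data.columns:
            reps[t] += 1
        return min(reps.values())

    def post_baseline(self) -> pd.DataFrame:
        """Columns for j >= 1 only (the samples used for PCC weighting)."""
        cols = [c for c in self.data.columns if c[0] != 0]
        return self.data[cols]


@dataclass
class DEGProfile:
    """Differential expression statistic d and p-value per (gene, time).

    ``d`` and ``pvalue`` are genes x times DataFrames on the same index and
    columns (times j = 1..T). A gene is a DEG at time j iff
    ``pvalue < alpha_deg`` (strict).
    """

    d: pd.DataFrame
    pvalue: pd.DataFrame
    alpha_deg: float = 0.05

    def __post_init__(self):
        if list(self.d.index) != list(self.pvalue.index) or list(self.d.columns) != list(
            self.pvalue.columns
        ):
            raise ValueError("d and pvalue must share index and columns")
        pv = self.pvalue.to_numpy(dtype=float)
        finite = pv[np.isfinite(pv)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("p-values outside [0, 1]")

    @property
    def times(self):
        return list(self.d.columns)

    @property
    def genes(self):
        return list(self.d.index)

    def deg_set(self, j, alpha=None) -> set:
        """DEGset_j: genes with p-value strictly below the threshold."""
        if j not in self.d.columns:
            raise KeyError(f"time point {j} not in profile (have {list(self.d.columns)})")
        a = self.alpha_deg if alpha is None else alpha
        col = self.pvalue[j]
        return set(col.index[col < a])

    def d_value(self, gene, j) -> float:
        try:
            v = self.d.at[gene, j]
        except KeyError:
            return 0.0
        return 0.0 if pd.isna(v) else float(v)


# ---------------------------------------------------------------------------
# readers


def read_template_network(path, tf_list=None, on_self_loop="skip"):
    """Read a 2-3 column TSV edge list into a :class:`TemplateNetwork`.

    Columns: source TF, target gene[, weight]. Missing weights default to
    1.0; duplicate edges are collapsed keeping the last weight. The TF set
    is the explicit one-per-line ``tf_list`` file if given, otherwise every
    node that appears as a source.

    ``on_self_loop`` is ``"skip"`` (drop with a warning) or ``"error"``.
    """
    edges = {}
    sources = set()
    nodes = set()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise NetworkParseError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
            u, v = parts[0].strip(), parts[1].strip()
            if not u or not v:
                raise NetworkParseError(f"{path}:{lineno}: empty node identifier")
            if len(parts) >= 3 and parts[2].strip() != "":
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise NetworkParseError(f"{path}:{lineno}: non-numeric weight {parts[2]!r}") from exc
            else:
                w = 1.0
            if u == v:
                if on_self_loop == "error":
                    raise NetworkParseError(f"{path}:{lineno}: self-loop {u}->{v}")
                n_self += 1
                continue
            edges[(u, v)] = w
            sources.add(u)
            nodes.update((u, v))
    if n_self:
        warnings.warn(f"{path}: skipped {n_self} self-loop(s)", stacklevel=2)
    if tf_list is not None:
        with open(tf_list) as fh:
            tf_set = {ln.strip() for ln in fh if ln.strip()}
        nodes |= tf_set
    else:
        tf_set = sources
    return TemplateNetwork(tf_set=tf_set, edges=edges, nodes=nodes)


_COL_RE = re.compile(r"^[Tt]?(\d+)[_.][Rr]?(\d+)$")


def read_expression(path, metadata=None):
    """Read a genes x samples TSV matrix into an :class:`ExpressionSeries`.

    Sample-to-(time, replicate) assignment comes from a sidecar ``metadata``
    TSV with columns ``sample``, ``time``, ``replicate``; without one,
    column names of the form ``T<j>_R<k>`` (or ``<j>_<k>``) are parsed.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if metadata is not None:
        meta = pd.read_csv(metadata, sep="\t", dtype={"sample": str})
        mapping = {
            str(r["sample"]): (int(r["time"]), int(r["replicate"])) for _, r in meta.iterrows()
        }
        try:
            cols = [mapping[str(c)] for c in mat.columns]
        except KeyError as exc:
            raise NetworkParseError(f"sample {exc} missing from metadata {metadata}") from exc
    else:
        cols = []
        for c in mat.columns:
            m = _COL_RE.match(str(c))
            if m is None:
                raise NetworkParseError(
                    f"cannot parse sample name {c!r}; provide a metadata sidecar"
                )
            cols.append((int(m.group(1)), int(m.group(2))))
    mat.columns = pd.MultiIndex.from_tuples(cols, names=["time", "replicate"])
    mat = mat.sort_index(axis=1)
    return ExpressionSeries(mat)


def _p_from_z(d: np.ndarray) -> np.ndarray:
    """Two-sided standard-normal p-value from a z-score array."""
    return special.erfc(np.abs(d) / math.sqrt(2.0))


def read_deg_profile(path, pvalue_path=None, alpha_deg=0.05):
    """Read a DEG profile.

    Long format (default): TSV with columns gene, time, d[, pvalue]. Wide
    format: ``path`` is a genes x times matrix of d and ``pvalue_path`` the
    matching matrix of p-values. If no p-values are supplied, a two-sided
    p is derived from d treated as a standard-normal z-score.
    """
    if pvalue_path is not None:
        d = pd.read_csv(path, sep="\t", index_col=0)
        p = pd.read_csv(pvalue_path, sep="\t", index_col=0)
        d.columns = [int(c) for c in d.columns]
        p.columns = [int(c) for c in p.columns]
        p = p.reindex(index=d.index, columns=d.columns)
        return DEGProfile(d=d.astype(float), pvalue=p.astype(float), alpha_deg=alpha_deg)

    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = [c.lower() for c in df.columns]
    if "gene" in cols:
        df.columns = cols
    else:  # headerless
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
        df.columns = ["gene", "time", "d", "pvalue"][: df.shape[1]]
    for c in ("gene", "time", "d"):
        if c not in df.columns:
            raise NetworkParseError(f"{path}: missing column {c!r}")
    try:
        df["time"] = df["time"].astype(int)
        df["d"] = df["d"].astype(float)
    except (TypeError, ValueError) as exc:
        raise NetworkParseError(f"{path}: non-numeric time or d value") from exc
    d = df.pivot_table(index="gene", columns="time", values="d", aggfunc="last")
    if "pvalue" in df.columns:
        try:
            df["pvalue"] = df["pvalue"].astype(float)
        except (TypeError, ValueError) as exc:
            raise NetworkParseError(f"{path}: non-numeric p-value") from exc
        if df["pvalue"].min() < 0 or df["pvalue"].max() > 1:
            raise NetworkParseError(f"{path}: p-value outside [0, 1]")
        p = df.pivot_table(index="gene", columns="time", values="pvalue", aggfunc="last")
        p = p.reindex(index=d.index, columns=d.columns)
    else:
        p = pd.DataFrame(_p_from_z(d.to_numpy(float)), index=d.index, columns=d.columns)
    d = d.fillna(0.0)
    p = p.fillna(1.0)
    d.columns = [int(c) for c in d.columns]
    p.columns = [int(c) for c in p.columns]
    return DEGProfile(d=d, pvalue=p, alpha_deg=alpha_deg)


def write_template_network(net: TemplateNetwork, path, tf_list=None):
    """Write a template as a 3-column TSV (+ optional one-column TF list)."""
    with open(path, "w") as fh:
        for (u, v), w in sorted(net.edges.items()):
            fh.write(f"{u}\t{v}\t{w:.10g}\n")
    if tf_list is not None:
        with open(tf_list, "w") as fh:
            for t in sorted(net.tf_set):
                fh.write(t + "\n")


def write_expression(ex: ExpressionSeries, path):
    """Write an expression matrix with self-describing T<j>_R<k> columns."""
    out = ex.data.copy()
    out.columns = [f"T{t}_R{k}" for t, k in out.columns]
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


def write_deg_profile(prof: DEGProfile, path):
    """Write a DEG profile in long format (gene, time, d, pvalue)."""
    with open(path, "w") as fh:
        fh.write("gene\ttime\td\tpvalue\n")
        for j in prof.times:
            for g in prof.genes:
                fh.write(f"{g}\t{j}\t{prof.d.at[g, j]:.10g}\t{prof.pvalue.at[g, j]:.10g}\n")


# ---------------------------------------------------------------------------
# PCC edge weighting


def compute_pcc_weights(net: TemplateNetwork, ex: ExpressionSeries):
    """Replace edge weights with the Pearson correlation of the endpoints.

    The correlation is computed over all post-baseline samples (j = 1..T,
    every replicate); the baseline is excluded. Edges with an endpoint
    missing from the expression matrix, or with a zero-variance series, get
    weight 0 and are counted in the returned report.

    Returns ``(weighted_network, report)`` where report is a dict with keys
    ``n_weighted``, ``n_missing``, ``n_zero_variance``.
    """
    mat = ex.post_baseline()
    if mat.shape[1] < 3:
        raise ValueError(
            f"need >= 3 post-baseline samples to compute correlations, have {mat.shape[1]}"
        )
    X = mat.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    xc = X - mu
    sd = np.sqrt((xc**2).sum(axis=1))
    idx = {g: i for i, g in enumerate(mat.index)}
    new = net.copy()
    n_missing = n_zero = n_ok = 0
    for (u, v) in net.edges:
        iu, iv = idx.get(u), idx.get(v)
        if iu is None or iv is None:
            new.edges[(u, v)] = 0.0
            n_missing += 1
            continue
        if sd[iu] == 0.0 or sd[iv] == 0.0:
            new.edges[(u, v)] = 0.0
            n_zero += 1
            continue
        r = float(np.dot(xc[iu], xc[iv]) / (sd[iu] * sd[iv]))
        new.edges[(u, v)] = max(-1.0, min(1.0, r))
        n_ok += 1
    report = {"n_weighted": n_ok, "n_missing": n_missing, "n_zero_variance": n_zero}
    return new, report


# ---------------------------------------------------------------------------
# result export

_FMT_EXT = {"tsv": ".tsv", "sif": ".sif", "graphml": ".graphml"}


def _write_edges(path, fmt, edges):
    """Write a single weighted edge list; edges is {(u, v): w}."""
    items = sorted(edges.items())
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for (u, v), w in items:
                fh.write(f"{u}\t{v}\t{w:.10g}\n")
    elif fmt == "sif":
        with open(path, "w") as fh:
            for (u, v), _ in items:
                fh.write(f"{u}\tregulates\t{v}\n")
        with open(str(path) + ".eda", "w") as fh:  # Cytoscape edge-attribute sidecar
            fh.write("weight\n")
            for (u, v), w in items:
                fh.write(f"{u} (regulates) {v} = {w:.10g}\n")
    elif fmt == "graphml":
        import networkx as nx

        g = nx.DiGraph()
        for (u, v), w in items:
            g.add_edge(u, v, weight=float(w))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_network_file(path, fmt="tsv"):
    """Read an edge list written by :func:`write_networks`; returns {(u,v): w}."""
    if fmt == "tsv":
        edges = {}
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                edges[(parts[0], parts[1])] = float(parts[2])
        return edges
    if fmt == "sif":
        edges = {}
        with open(path) as fh:
            for line in fh:
                u, _, v = line.rstrip("\n").split("\t")
                edges[(u, v)] = 1.0
        eda = str(path) + ".eda"
        if os.path.exists(eda):
            with open(eda) as fh:
                fh.readline()
                for line in fh:
                    lhs, w = line.rsplit(" = ", 1)
                    u, rest = lhs.split(" (regulates) ")
                    edges[(u, rest)] = float(w)
        return edges
    if fmt == "graphml":
        return _read_graphml(path)
    raise ValueError(f"unknown format {fmt!r}")


def _read_graphml(path):
    import networkx as nx

    g = nx.read_graphml(path)
    return {(str(u), str(v)): float(d.get("weight", 1.0)) for u, v, d in g.edges(data=True)}


def write_networks(results, out_dir, fmt="tsv", influence=None):
    """Serialize per-time-point result networks and the major-TF table.

    One edge-list file ``network_t<j>.<fmt>`` per selection result plus a
    single ``major_tfs.tsv`` table (TF, influence score, accepted rank,
    time). ``influence`` is an optional list of InfluenceScores aligned
    with ``results`` used to fill the score column.

    Returns the list of paths written.
    """
    if fmt not in _FMT_EXT:
        raise ValueError(f"unknown format {fmt!r}; choose from {sorted(_FMT_EXT)}")
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    il_by_time = {}
    if influence is not None:
        for sc in influence:
            il_by_time[sc.time_index] = sc.il
    for res in results:
        p = os.path.join(out_dir, f"network_t{res.time_index}{_FMT_EXT[fmt]}")
        _write_edges(p, fmt, res.mtfnet)
        paths.append(p)
    tf_path = os.path.join(out_dir, "major_tfs.tsv")
    with open(tf_path, "w") as fh:
        fh.write("tf\til_score\taccepted_rank\ttime\n")
        for res in results:
            il = il_by_time.get(res.time_index, {})
            for rank, tf in enumerate(res.accepted, start=1):
                fh.write(f"{tf}\t{il.get(tf, float('nan')):.10g}\t{rank}\t{res.time_index}\n")
    paths.append(tf_path)
    return paths
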