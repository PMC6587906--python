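import numpy as np
import pandas as pd
import pytest

from tfnetprop import DEGProfile, ExpressionSeries, TemplateNetwork
from tfnetprop.timenet import TimeNetwork


def make_template(edges, tfs=None):
    """edges: {(u, v): w} or [(u, v)] (weight 1). tfs default: all sources."""
    if not isinstance(edges, dict):
        edges = {e: 1.0 for e in edges}
    if tfs is None:
        tfs = {u for (u, _) in edges}
    return TemplateNetwork(tf_set=set(tfs), edges=dict(edges))


def make_profile(d, pvalue=None, times=None, alpha=0.05):
    """d: {gene: {time: value}}; pvalue analogous or None (all significant)."""
    genes = sorted(d)
    if times is None:
        times = sorted({j for g in d for j in d[g]})
    dm = pd.DataFrame(
        [[d[g].get(j, 0.0) for j in times] for g in genes], index=genes, columns=times
    )
    if pvalue is None:
        pm = pd.DataFrame(
            [[0.0 if j in d[g] else 1.0 for j in times] for g in genes],
            index=genes,
            columns=times,
        )
    else:
        pm = pd.DataFrame(
            [[pvalue[g].get(j, 1.0) for j in times] for g in genes],
            index=genes,
            columns=times,
        )
    return DEGProfile(d=dm, pvalue=pm, alpha_deg=alpha)


def make_time_network(edges, tfs, de, deg_set, j=1):
    """Directly assemble a TimeNetwork for unit tests of influence/propagation."""
    if not isinstance(edges, dict):
        edges = {e: 1.0 for e in edges}
    nodes = sorted({n for e in edges for n in e} | set(tfs) | set(de))
    return TimeNetwork(
        time_index=j,
        nodes=nodes,
        tf_set=set(tfs),
        edges=dict(edges),
        node_de={n: de.get(n, 0.0) for n in nodes},
        deg_set=set(deg_set),
    )


def random_time_network(rng, n_tf=3, n_tg=6, n_edges=10, signed=False):
    """Random small TimeNetwork with weights in [0,1] (or [-1,1]) and DE >= 0."""
    tfs = [f"T{i}" for i in range(n_tf)]
    tgs = [f"g{i}" for i in range(n_tg)]
    n_edges = min(n_edges, n_tf * (n_tf - 1 + n_tg))  # cannot exceed pair count
    edges = {}
    while len(edges) < n_edges:
        u = tfs[rng.integers(n_tf)]
        v = (tfs + tgs)[rng.integers(n_tf + n_tg)]
        if u != v:
            w = rng.uniform(-1, 1) if signed else rng.uniform(0, 1)
            edges[(u, v)] = float(w)
    de = {n: float(rng.uniform(0, 4)) for n in tfs + tgs}
    deg = {g for g in tgs if rng.random() < 0.5}
    return make_time_network(edges, tfs, de, deg)


def make_expression(values, times, reps):
    """values: {gene: flat list of len(times)*reps, time-major}."""
    cols = pd.MultiIndex.from_tuples(
        [(t, k) for t in times for k in range(1, reps + 1)], names=["time", "replicate"]
    )
    df = pd.DataFrame.from_dict(values, orient="index")
    df.columns = cols
    return ExpressionSeries(df.sort_index())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
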