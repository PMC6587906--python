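"""Synthetic benchmark generator with planted master regulators.

Emulates the statistical structure the method assumes: a directed TF ->
target template with heavy-tailed regulon sizes, a handful of *planted*
master TFs active at each time stage, target expression shifted while a
regulator is active (propagating two hops through TF -> TF edges at half
strength), Gaussian measurement noise, and differential-expression
statistics computed as exact two-sample z-scores so the DEG threshold has
known operating characteristics.

Two deliberate realism choices: an active regulator's *own* expression is
shifted (TF activity is visible in its transcript, so the correlation-based
edge weighting has signal to work with), and planted regulators are drawn
from the upper half of the fan-out distribution (master regulators have
large regulons). An optional *background* regulator oscillates (activity
sign alternates across time points) in both the stress and the control
series, emulating a circadian-style program the control-subtraction
variant should remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netio import DEGProfile, ExpressionSeries, TemplateNetwork, compute_pcc_weights

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_template",
    "choose_planted",
    "simulate_series",
    "simulate_control",
    "simulate",
]

_HOP_DAMPING = 0.5  # signal attenuation per extra regulatory hop (max 2 hops)


@dataclass
class SimulationSpec:
    """Parameters of one synthetic study.

    Defaults give 30 TFs regulating 300 target genes over 3 stages with 3
    planted master TFs per stage, an effect of 3 on the z scale against
    unit noise, 2 replicates per time point and a 1% spurious-DEG rate.
    """

    n_tf: int = 30
    n_tg: int = 300
    n_time: int = 3
    n_active: int = 3
    planted: dict = None  # stage j -> set of TF names; auto-chosen if None
    effect_size: float = 3.0
    noise_sd: float = 1.0
    background_rate: float = 0.01
    background_effect: float = 3.0  # magnitude of spurious DEG shifts (z units)
    replicates: int = 2
    baseline_mean: float = 8.0
    alpha_deg: float = 0.05
    tf_tf_edge_prob: float = 0.02
    out_degree_shape: float = 2.0  # Pareto tail exponent of regulon sizes
    out_degree_scale: float = None  # defaults to n_tg / 30
    out_degree_max: int = None  # truncation, defaults to n_tg / 15
    background_tf: bool = False  # include an oscillating background regulator
    background_tf_effect: float = 5.0  # amplitude of the background program (z units)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_tf < 1 or self.n_tg < 1:
            raise ValueError("need at least one TF and one target gene")
        if self.effect_size <= 0 and self.effect_size != 0.0:
            raise ValueError("effect_size must be >= 0")
        if not (0.0 <= self.background_rate < 1.0):
            raise ValueError("background_rate must be in [0, 1)")
        if self.out_degree_scale is None:
            self.out_degree_scale = max(1.0, self.n_tg / 30.0)
        if self.out_degree_max is None:
            self.out_degree_max = max(2, self.n_tg // 15)

    def seed_sequence(self) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.rng_seed)


@dataclass
class GroundTruth:
    """What was planted: per-stage active TFs and the genes they shifted."""

    active_tfs: dict  # stage j -> set of TF names
    true_targets: dict  # stage j -> set of shifted genes (regulators excluded)
    planted: dict
    background_tf: str = None
    shift_levels: dict = field(default_factory=dict)  # stage -> gene -> level


@dataclass
class SyntheticDataset:
    """Bundle of everything one run needs, all derived from (spec, seed)."""

    spec: SimulationSpec
    template: TemplateNetwork  # PCC-weighted
    raw_template: TemplateNetwork  # unit weights
    expression: ExpressionSeries
    deg: DEGProfile
    truth: GroundTruth
    control_deg: DEGProfile = None


def _tf_name(i):
    return f"TF{i:03d}"


def _tg_name(i):
    return f"G{i:04d}"


def simulate_template(spec: SimulationSpec, rng=None) -> TemplateNetwork:
    """Random directed TF -> gene template with power-law-like fan-out.

    Each TF regulates ``1 + floor(Pareto(shape) * scale)`` distinct target
    genes (clipped to the target universe) and targets every other TF
    independently with probability ``tf_tf_edge_prob``. Weights start at 1
    and are later replaced by correlations from the simulated expression.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed_sequence().spawn(1)[0])
    tfs = [_tf_name(i) for i in range(spec.n_tf)]
    tgs = [_tg_name(i) for i in range(spec.n_tg)]
    edges = {}
    for t in tfs:
        k = int(1 + math.floor(rng.pareto(spec.out_degree_shape) * spec.out_degree_scale))
        k = min(k, spec.out_degree_max, spec.n_tg)
        targets = rng.choice(spec.n_tg, size=k, replace=False)
        for gi in targets:
            edges[(t, tgs[gi])] = 1.0
        for t2 in tfs:
            if t2 != t and rng.random() < spec.tf_tf_edge_prob:
                edges[(t, t2)] = 1.0
    return TemplateNetwork(tf_set=set(tfs), edges=edges, nodes=set(tfs) | set(tgs))


def _tg_fanout(net):
    counts = {t: 0 for t in net.tf_set}
    for (u, v) in net.edges:
        if v not in net.tf_set:
            counts[u] += 1
    return counts


def choose_planted(spec, net, rng=None):
    """Pick per-stage master TFs (and the background regulator if enabled).

    Drawn without replacement from the upper half of the TG fan-out
    distribution, disjoint across stages. Returns (planted, background).
    """
    if spec.planted is not None:
        bg = None
        if spec.background_tf:
            raise ValueError("explicit planted map cannot be combined with background_tf=True")
        return {j: set(v) for j, v in spec.planted.items()}, bg
    if rng is None:
        rng = np.random.default_rng(spec.seed_sequence().spawn(2)[1])
    fan = _tg_fanout(net)
    # master regulators have sizeable regulons: require >= n_tg / 30 targets,
    # falling back to the largest regulons when the draw under-fills the quota
    floor = max(1, int(round(spec.n_tg / 30.0)))
    need = spec.n_time * spec.n_active + (1 if spec.background_tf else 0)
    if need > spec.n_tf:
        raise ValueError(f"cannot plant {need} regulators with only {spec.n_tf} TFs")
    eligible = sorted(t for t in fan if fan[t] >= floor)
    if len(eligible) < need:
        eligible = sorted(fan, key=lambda t: (-fan[t], t))[:need]
        eligible.sort()
    pick = list(rng.choice(len(eligible), size=need, replace=False))
    names = [eligible[i] for i in pick]
    bg = names.pop() if spec.background_tf else None
    planted = {
        j: set(names[(j - 1) * spec.n_active : j * spec.n_active])
        for j in range(1, spec.n_time + 1)
    }
    return planted, bg


def _shift_levels(spec, net, active, stage_sign=1.0):
    """Per-gene signed shift level for one stage given the active TF set.

    Direct targets (and the regulator itself) get level 1; targets of a
    regulated TF get level 0.5; the strongest single path wins.
    """
    adj = {}
    for (u, v) in net.edges:
        adj.setdefault(u, []).append(v)
    level = {}

    def bump(g, lv):
        if abs(lv) > abs(level.get(g, 0.0)):
            level[g] = lv

    for t in active:
        bump(t, stage_sign)
        for g in adj.get(t, ()):
            bump(g, stage_sign)
            if g in net.tf_set:
                for g2 in adj.get(g, ()):
                    bump(g2, stage_sign * _HOP_DAMPING)
    return level


def _bg_multiplier(j):
    """Square-wave activity of the background regulator: +1, -1, +1, ..."""
    return 1.0 if j % 2 == 1 else -1.0


def _build_series(spec, net, planted, background, rng, include_planted=True):
    """Simulate expression + z/p profile; returns (series, profile, levels)."""
    genes = sorted(net.nodes)
    gidx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    K = spec.replicates
    T = spec.n_time
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)  # per-gene, fixed

    shift = np.zeros((n, T + 1))
    levels = {}
    for j in range(1, T + 1):
        lv = {}  # gene -> signed z-scale shift
        if include_planted:
            for g, l in _shift_levels(spec, net, planted.get(j, ())).items():
                lv[g] = l * spec.effect_size
        if background is not None:
            m = _bg_multiplier(j)
            for g, l in _shift_levels(spec, net, {background}, stage_sign=m).items():
                z = l * spec.background_tf_effect
                if g not in lv or abs(z) > abs(lv[g]):
                    lv[g] = z
        for g, l in lv.items():
            shift[gidx[g], j] = l
        # spurious background DEGs on untouched genes, magnitude independent
        # of the planted effect (they emulate unmodeled biology)
        untouched = [g for g in genes if g not in lv]
        if spec.background_rate > 0 and untouched:
            hits = rng.random(len(untouched)) < spec.background_rate
            for g, h in zip(untouched, hits):
                if h:
                    shift[gidx[g], j] = spec.background_effect
                    lv[g] = None  # recorded as spurious
        levels[j] = {g: (shift[gidx[g], j]) for g in lv}

    # effect sizes are on the z scale of the induced two-sample test:
    # an expression-mean shift of effect * noise_sd * sqrt(2/K) gives E|d| = effect
    se = spec.noise_sd * math.sqrt(2.0 / K)
    mean = spec.baseline_mean + sign[:, None] * shift * se
    noise = rng.normal(0.0, spec.noise_sd, size=(n, T + 1, K))
    expr = mean[:, :, None] + noise

    cols = pd.MultiIndex.from_tuples(
        [(j, k) for j in range(T + 1) for k in range(1, K + 1)],
        names=["time", "replicate"],
    )
    data = pd.DataFrame(expr.reshape(n, (T + 1) * K), index=genes, columns=cols)
    series = ExpressionSeries(data)

    m_j = expr.mean(axis=2)
    z = (m_j[:, 1:] - m_j[:, [0]]) / se
    from scipy import special

    p = special.erfc(np.abs(z) / math.sqrt(2.0))
    times = list(range(1, T + 1))
    d = pd.DataFrame(z, index=genes, columns=times)
    pv = pd.DataFrame(p, index=genes, columns=times)
    profile = DEGProfile(d=d, pvalue=pv, alpha_deg=spec.alpha_deg)
    return series, profile, levels


def simulate_series(spec, net, planted=None, background=None, rng=None):
    """Stress-condition series: planted regulators (+ background) active.

    Returns ``(ExpressionSeries, DEGProfile, GroundTruth)``.
    """
    if planted is None:
        planted, background = choose_planted(spec, net)
    if rng is None:
        rng = np.random.default_rng(spec.seed_sequence().spawn(4)[3])
    series, profile, levels = _build_series(
        spec, net, planted, background, rng, include_planted=True
    )
    active = {j: set(planted.get(j, set())) for j in range(1, spec.n_time + 1)}
    true_targets = {}
    for j in range(1, spec.n_time + 1):
        lv = _shift_levels(spec, net, planted.get(j, ()))
        true_targets[j] = set(lv) - active[j]
    truth = GroundTruth(
        active_tfs=active,
        true_targets=true_targets,
        planted=planted,
        background_tf=background,
        shift_levels=levels,
    )
    return series, profile, truth


def simulate_control(spec, net, background=None, rng=None):
    """Non-stress control series: only the background regulator is active.

    Returns the control DEGProfile on the same time grid; without a
    background regulator its DEG sets are pure false positives (rate
    ~ alpha_deg + background_rate).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed_sequence().spawn(6)[5])
    _, profile, _ = _build_series(spec, net, {}, background, rng, include_planted=False)
    return profile


def simulate(spec: SimulationSpec) -> SyntheticDataset:
    """End-to-end generation: template, planting, series, PCC weighting.

    Everything derives deterministically from ``spec.rng_seed`` through
    independent seed-sequence children, so each stage is individually
    reproducible.
    """
    children = spec.seed_sequence().spawn(6)
    net = simulate_template(spec, rng=np.random.default_rng(children[0]))
    planted, background = choose_planted(spec, net, rng=np.random.default_rng(children[1]))
    series, profile, truth = simulate_series(
        spec, net, planted, background, rng=np.random.default_rng(children[3])
    )
    control = None
    if spec.background_tf:
        control = simulate_control(
            spec, net, background, rng=np.random.default_rng(children[5])
        )
    weighted, _ = compute_pcc_weights(net, series)
    return SyntheticDataset(
        spec=spec,
        template=weighted,
        raw_template=net,
        expression=series,
        deg=profile,
        truth=truth,
        control_deg=control,
    )
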