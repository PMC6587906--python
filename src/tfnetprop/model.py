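"""Model / Results interface orchestrating the full analysis.

:class:`TFNetworkModel` holds the inputs (template network, DEG profile,
optional expression series for correlation weighting, optional non-stress
control profile); :meth:`TFNetworkModel.fit` runs, independently for every
time point, the three stages -- time-network instantiation, Monte-Carlo
influence ranking, greedy propagation-scored selection -- and returns a
:class:`TFNetworkResults` carrying the per-time-point major-TF sets, their
induced networks, traces and diagnostics, with ``summary()``, evaluation
helpers and deterministic serialization.

Control subtraction: when a control DEG profile is supplied the seed DEG
set at time j becomes ``DEGset_j(stress) - DEGset_j(control)``, removing
background programs (e.g. circadian oscillation) present in both series;
all downstream steps are unchanged.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .influence import influence_maximization
from .netio import (
    compute_pcc_weights,
    read_deg_profile,
    read_expression,
    read_template_network,
    write_networks,
)
from .propagation import PropagationConfig, select_major_tfs
from .timenet import instantiate

__all__ = [
    "TFNetworkModel",
    "TFNetworkResults",
    "evaluate_f1",
    "adjacent_overlap",
    "time_point_seed",
]


def time_point_seed(master_seed: int, j: int) -> int:
    """Per-time-point RNG seed derived from the master seed.

    Deterministic and independent per j, so time points can be processed in
    any order (or re-run individually) with identical results.
    """
    return int(np.random.SeedSequence([int(master_seed), int(j)]).generate_state(1)[0] % (2**31))


def evaluate_f1(predicted, truth):
    """(precision, recall, F1) of a predicted gene set against a truth set.

    Zero-denominator cases (empty prediction or empty truth) yield 0.0.
    """
    pred, tru = set(predicted), set(truth)
    tp = len(pred & tru)
    prec = tp / len(pred) if pred else 0.0
    rec = tp / len(tru) if tru else 0.0
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
    return prec, rec, f1


def _net_nodes(mtfnet, accepted):
    nodes = set(accepted)
    for (u, v) in mtfnet:
        nodes.add(u)
        nodes.add(v)
    return nodes


def adjacent_overlap(results):
    """Jaccard overlap of node sets of consecutive time-point networks.

    ``o_j = |A ∩ B| / |A ∪ B]`` for the node sets of MTFnet_j and
    MTFnet_{j+1}; 0.0 when both are empty.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 time points for adjacent overlap")
    out = []
    for a, b in zip(results, results[1:]):
        na = _net_nodes(a.mtfnet, a.accepted)
        nb = _net_nodes(b.mtfnet, b.accepted)
        union = na | nb
        out.append(len(na & nb) / len(union) if union else 0.0)
    return out


class TFNetworkModel:
    """Time-varying major-TF selection model.

    Parameters
    ----------
    template : TemplateNetwork
        Directed TF -> target template. If ``expression`` is given, edge
        weights are replaced by Pearson correlations over the post-baseline
        samples; otherwise the template's own weights are used as edge
        retention probabilities / propagation weights.
    deg : DEGProfile
        Per-time-point differential expression (statistic + p-value).
    tg_set : "all" or iterable
        User target-gene set; "all" = every non-TF template node.
    expression : ExpressionSeries, optional
    control_deg : DEGProfile, optional
        Non-stress control profile on the same time grid; enables
        control-subtracted seeding.
    """

    def __init__(self, template, deg, tg_set="all", expression=None, control_deg=None):
        self.weight_report = None
        if expression is not None:
            template, self.weight_report = compute_pcc_weights(template, expression)
        self.template = template
        self.deg = deg
        self.tg_set = tg_set
        self.control_deg = control_deg
        overlap = set(deg.genes) & template.nodes
        if not overlap:
            raise ValueError(
                "no overlap between DEG profile genes and template nodes; "
                "check gene identifier conventions"
            )
        if control_deg is not None and list(control_deg.times) != list(deg.times):
            raise ValueError(
                f"control time grid {control_deg.times} does not match stress grid {deg.times}"
            )

    @classmethod
    def from_files(
        cls,
        network,
        deg,
        tf_list=None,
        expression=None,
        expression_meta=None,
        deg_pvalues=None,
        control_deg=None,
        control_deg_pvalues=None,
        tg_set="all",
        alpha_deg=0.05,
    ):
        """Construct the model from the standard TSV inputs."""
        net = read_template_network(network, tf_list=tf_list)
        prof = read_deg_profile(deg, pvalue_path=deg_pvalues, alpha_deg=alpha_deg)
        ex = None
        if expression is not None:
            ex = read_expression(expression, metadata=expression_meta)
        ctrl = None
        if control_deg is not None:
            ctrl = read_deg_profile(control_deg, pvalue_path=control_deg_pvalues, alpha_deg=alpha_deg)
        if isinstance(tg_set, str) and tg_set != "all":
            with open(tg_set) as fh:
                tg_set = {ln.strip() for ln in fh if ln.strip()}
        return cls(net, prof, tg_set=tg_set, expression=ex, control_deg=ctrl)

    def _seed_deg_set(self, j, subtract_control):
        degset = self.deg.deg_set(j)
        if subtract_control and self.control_deg is not None:
            degset = degset - self.control_deg.deg_set(j)
        return degset

    def fit(
        self,
        rounds=1000,
        alpha=0.1,
        seed=0,
        prob_map="clamp",
        tol=1e-9,
        max_iter=1000,
        normalization="out_degree",
        coverage_mode="direct",
        subtract_control=None,
    ):
        """Run the three-stage analysis at every time point.

        ``subtract_control`` defaults to True when a control profile was
        supplied. Returns a :class:`TFNetworkResults`.
        """
        if subtract_control is None:
            subtract_control = self.control_deg is not None
        if subtract_control and self.control_deg is None:
            raise ValueError("subtract_control=True but no control profile supplied")
        cfg = PropagationConfig(
            alpha=alpha,
            tol=tol,
            max_iter=max_iter,
            normalization=normalization,
            coverage_mode=coverage_mode,
        )
        selections, influences, networks, seeds = [], [], [], {}
        for j in self.deg.times:
            degset = self._seed_deg_set(j, subtract_control)
            tn = instantiate(self.template, self.deg, tg_set=self.tg_set, j=j, deg_set=degset)
            sj = time_point_seed(seed, j)
            seeds[j] = sj
            scores = influence_maximization(tn, rounds=rounds, rng_seed=sj, prob_map=prob_map)
            # only TFs with positive estimated influence are candidates: a TF
            # with IL = 0 has no sampled path to any DEG and cannot explain
            # them; the top-ranked TF still seeds the set unconditionally
            candidates = [t for t in scores.ranking if scores.il[t] > 0]
            if not candidates:
                candidates = scores.ranking[:1]
            sel = select_major_tfs(tn, candidates, cfg)
            selections.append(sel)
            influences.append(scores)
            networks.append(tn)
        params = {
            "rounds": rounds,
            "alpha": alpha,
            "seed": int(seed),
            "time_point_seeds": {str(j): s for j, s in seeds.items()},
            "prob_map": prob_map,
            "tol": tol,
            "max_iter": max_iter,
            "normalization": normalization,
            "coverage_mode": coverage_mode,
            "subtract_control": bool(subtract_control),
            "tg_set": "all" if isinstance(self.tg_set, str) else sorted(self.tg_set),
            "alpha_deg": self.deg.alpha_deg,
        }
        return TFNetworkResults(self, params, selections, influences, networks)


@dataclass
class TFNetworkResults:
    """Fitted per-time-point major-TF sets and their networks."""

    model: TFNetworkModel
    params: dict
    selections: list
    influence: list
    time_networks: list

    @property
    def times(self):
        return [s.time_index for s in self.selections]

    @property
    def major_tfs(self):
        """Ordered accepted TF list per time point."""
        return {s.time_index: list(s.accepted) for s in self.selections}

    def network_nodes(self, j):
        sel = self.selections[self.times.index(j)]
        return _net_nodes(sel.mtfnet, sel.accepted)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for tn, sel, sc in zip(self.time_networks, self.selections, self.influence):
            rows.append(
                {
                    "time": sel.time_index,
                    "n_deg": len(tn.deg_set),
                    "n_tf": len(tn.tf_set),
                    "n_candidates": len(sel.scc_trace),
                    "n_accepted": len(sel.accepted),
                    "best_scc": sel.best_scc,
                    "coverage": sel.coverage_trace[-1] if sel.coverage_trace else 0,
                    "n_net_edges": len(sel.mtfnet),
                    "top_tf": sel.accepted[0] if sel.accepted else "",
                }
            )
        return pd.DataFrame(rows).set_index("time")

    def summary(self) -> str:
        df = self.summary_frame()
        lines = [
            "Time-varying major-TF selection",
            "=" * 64,
            f"rounds={self.params['rounds']}  alpha={self.params['alpha']}  "
            f"seed={self.params['seed']}  prob_map={self.params['prob_map']}  "
            f"control_subtracted={self.params['subtract_control']}",
            "-" * 64,
            df.to_string(float_format=lambda x: f"{x:.4f}"),
            "-" * 64,
        ]
        for sel in self.selections:
            lines.append(f"t{sel.time_index}: {', '.join(sel.accepted) or '(none)'}")
        return "\n".join(lines)

    def adjacent_overlap(self):
        return adjacent_overlap(self.selections)

    def evaluate_f1(self, truth_by_time, level="tf") -> pd.DataFrame:
        """Precision/recall/F1 per time point against ground-truth sets.

        ``level="tf"`` compares the accepted TF sets; ``level="gene"``
        compares the non-TF nodes of the induced networks.
        """
        rows = []
        for sel in self.selections:
            truth = set(truth_by_time.get(sel.time_index, set()))
            if level == "tf":
                pred = set(sel.accepted)
            elif level == "gene":
                pred = _net_nodes(sel.mtfnet, sel.accepted) - self.model.template.tf_set
            else:
                raise ValueError(f"unknown level {level!r}")
            prec, rec, f1 = evaluate_f1(pred, truth)
            rows.append(
                {"time": sel.time_index, "precision": prec, "recall": rec, "f1": f1}
            )
        return pd.DataFrame(rows).set_index("time")

    def save(self, out_dir, fmt="tsv"):
        """Write networks, the TF table and a parameter manifest.

        Output is deterministic: identical fitted results produce
        byte-identical files.
        """
        os.makedirs(out_dir, exist_ok=True)
        paths = write_networks(self.selections, out_dir, fmt=fmt, influence=self.influence)
        manifest = dict(self.params)
        manifest["times"] = self.times
        manifest["n_accepted"] = {str(s.time_index): len(s.accepted) for s in self.selections}
        mpath = os.path.join(out_dir, "manifest.json")
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        spath = os.path.join(out_dir, "summary.txt")
        with open(spath, "w") as fh:
            fh.write(self.summary())
            fh.write("\n")
        return paths + [mpath, spath]
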