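"""End-to-end pipeline: simulate -> score -> associate -> estimate ->
communities -> bridge -> controllability -> predictability.

A single master seed drives every stochastic stage through a documented
counter scheme: stage k receives ``int(SeedSequence((master_seed, k)).
generate_state(1)[0] % 2**31)``, so any stage can be replayed in isolation
with identical randomness.  The run emits all tables plus a JSON manifest
with seeds, parameters, and SHA-256 checksums of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import association, bridge, communities, control, ggm, predictability, scoring, synthetic

logger = logging.getLogger("gestnet")

#: stage indices of the seed-derivation counter scheme
STAGE_SEEDS = {"simulate": 0, "estimate": 1, "bridge_bei": 2,
               "bridge_bcl": 3, "bridge_bbw": 4}


def stage_seed(master_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence((int(master_seed), STAGE_SEEDS[stage]))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Parameters of one reproducible pipeline run."""

    seed: int = 0
    n: int = 1094                    # participants to simulate
    n_boot: int = 5000               # edge-selection bootstrap replicates
    alpha: float = 0.05
    ci: float = 0.95
    bridge_n_boot: int = 5000        # bridge difference-test replicates
    attention_fail_rate: float = 0.04
    item_level: bool = True          # simulate items and score, vs subscales direct
    responses_csv: str | None = None  # score real/raw responses instead
    subscales_csv: str | None = None  # start from a ready subscale table
    signed_control: bool = True
    bridge_metrics: tuple[str, ...] = ("bei", "bcl", "bbw")
    allow_ci_alpha_mismatch: bool = False

    def validate(self) -> None:
        if not self.allow_ci_alpha_mismatch and abs(self.ci - (1 - self.alpha)) > 1e-12:
            raise ValueError("ci != 1 - alpha; set allow_ci_alpha_mismatch to override")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage, write all artifacts to ``out_dir``, return the manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in asdict(config).items()},
                      "stage_seeds": {s: stage_seed(config.seed, s)
                                      for s in STAGE_SEEDS},
                      "stages": {}}

    def timed(stage: str):
        t0 = time.perf_counter()

        def done():
            dt = time.perf_counter() - t0
            manifest["stages"][stage] = round(dt, 3)
            logger.info("stage %-12s %.2fs", stage, dt)
        return done

    # ---- input acquisition: load, or simulate -----------------------------
    report = None
    if config.subscales_csv:
        subscales = pd.read_csv(config.subscales_csv)
    else:
        done = timed("simulate")
        if config.responses_csv:
            responses = pd.read_csv(config.responses_csv)
        elif config.item_level:
            gt = synthetic.make_ground_truth()
            responses = synthetic.simulate_item_responses(
                gt, config.n, attention_fail_rate=config.attention_fail_rate,
                seed=stage_seed(config.seed, "simulate"))
            (out / "ground_truth.json").write_text(gt.to_json())
        else:
            gt = synthetic.make_ground_truth()
            subscales = synthetic.simulate_subscales(
                gt, config.n, seed=stage_seed(config.seed, "simulate"))
            (out / "ground_truth.json").write_text(gt.to_json())
            responses = None
        done()
        if config.responses_csv or config.item_level:
            responses.to_csv(out / "responses.csv", index=False)
            done = timed("score")
            subscales, report = scoring.score_responses(responses)
            done()
    subscales.to_csv(out / "subscales.csv", index=False)
    if report is not None:
        (out / "exclusions.json").write_text(json.dumps(
            {"n_input": report.n_input, "n_excluded": report.n_excluded,
             "n_retained": report.n_retained,
             "proportion_excluded": report.proportion_excluded}, indent=2))

    # ---- bivariate associations ------------------------------------------
    done = timed("associate")
    assoc_cols = [c for c in subscales.columns if c != "participant_id"]
    long = association.correlation_matrix(subscales, assoc_cols)
    long.to_csv(out / "correlations_long.csv", index=False)
    association.correlation_square(subscales, assoc_cols).to_csv(
        out / "correlations_square.csv")
    done()

    # ---- network estimation ----------------------------------------------
    done = timed("estimate")
    network = ggm.bootstrap_edge_selection(
        subscales, n_boot=config.n_boot, ci=config.ci, alpha=config.alpha,
        seed=stage_seed(config.seed, "estimate"),
        allow_mismatch=config.allow_ci_alpha_mismatch)
    network.edge_table().to_csv(out / "network_edges.tsv", sep="\t", index=False)
    (out / "network_meta.json").write_text(network.metadata_json())
    g = nx.Graph()
    g.add_nodes_from(network.node_labels)
    sel = network.selected_weights
    for i in range(network.n_nodes):
        for j in range(i + 1, network.n_nodes):
            if sel[i, j] != 0:
                g.add_edge(network.node_labels[i], network.node_labels[j],
                           weight=float(sel[i, j]))
    nx.write_graphml(g, out / "network_selected.graphml")
    done()

    # ---- community detection ----------------------------------------------
    done = timed("communities")
    partition = communities.fast_greedy(network)
    (out / "communities.json").write_text(partition.to_json())
    done()

    # ---- bridge centralities + difference tests ---------------------------
    done = timed("bridge")
    scores = bridge.bridge_scores(network, partition.membership)
    scores.to_csv(out / "bridge_scores.csv", index=False)
    for metric in config.bridge_metrics:
        res = bridge.bridge_difference_test(
            subscales, network, partition.membership, metric=metric,
            n_boot=config.bridge_n_boot, ci=config.ci,
            seed=stage_seed(config.seed, f"bridge_{metric}"))
        res.significance_table().to_csv(out / f"bridge_sig_{metric}.csv")
    (out / "bridge_meta.json").write_text(json.dumps(
        {"distance_convention": "length = 1 / |weight|",
         "n_boot": config.bridge_n_boot, "ci": config.ci}, indent=2))
    done()

    # ---- controllability ---------------------------------------------------
    done = timed("control")
    ctrl = control.controllability_scores(network, signed=config.signed_control)
    ctrl.table().to_csv(out / "controllability.csv", index=False)
    (out / "controllability_meta.json").write_text(ctrl.metadata_json())
    done()

    # ---- predictability ----------------------------------------------------
    done = timed("predict")
    pred = predictability.node_predictability(subscales, network)
    pred.to_csv(out / "predictability.csv", index=False)
    done()

    manifest["checksums"] = {p.name: _sha256(p)
                             for p in sorted(out.iterdir())
                             if p.is_file() and p.name != "manifest.json"}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
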