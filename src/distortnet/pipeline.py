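"""End-to-end pipeline: corpus -> pairs -> triads -> network -> stability
-> QAP -> noise sweep, from one configuration, with per-stage artifacts
and a consolidated JSON report.

All randomness flows from the explicit seeds in the configuration; no
stage reads a global generator. Bootstrap iterations, QAP permutations and
the noise design are scalable so reduced-replication runs share the same
code path as full-scale ones.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import synthetic
from .corpus import LabelMatrix, read_label_matrix, summarize_counts, write_label_matrix
from .network import build_network, centralities, write_network
from .noise import DEFAULT_LEVELS, noise_sweep
from .pairs import AssociationConfig, RESAMPLING_CONFIG, filter_edges, pair_stats
from .qap import split_half_qap, stratified_qap
from .stability import bootstrap_stability
from .triads import threshold_triads, triad_stats

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    output_dir: str | Path = "distortnet_out"
    input_path: str | Path | None = None
    synthetic: synthetic.SyntheticConfig | None = None
    association: AssociationConfig = field(default_factory=AssociationConfig)
    resampling: AssociationConfig = field(default_factory=lambda: RESAMPLING_CONFIG)
    triad_percentile: float = 99.0
    triad_cutoff: float | None = None
    bootstrap_k: int = 10_000
    bootstrap_seed: int = 0
    qap_permutations: int = 5000
    qap_seed: int = 0
    noise_levels: Sequence[float] = DEFAULT_LEVELS
    noise_replicates: int = 50
    noise_seed: int = 0
    run_stratified_qap: bool = False
    stratified_rule: str = "median"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of input_path or synthetic config")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file."""
    with open(path) as fh:
        raw: dict[str, Any] = yaml.safe_load(fh)
    syn = None
    if "synthetic" in raw:
        s = raw.pop("synthetic")
        bundles = tuple(
            synthetic.Bundle(tuple(b["members"]), float(b["weight"]))
            for b in s.get("bundles", [])
        )
        if s.get("study_defaults"):
            cfg = synthetic.study_config(
                n_texts=int(s.get("n_texts", 100_000)),
                seed=int(s.get("seed", 0)),
                group_count=s.get("group_count"),
            )
            syn = cfg
        else:
            syn = synthetic.SyntheticConfig(
                n_texts=int(s["n_texts"]),
                prevalences=s["prevalences"],
                count_distribution={int(k): float(v) for k, v in s["count_distribution"].items()},
                bundles=bundles,
                group_count=s.get("group_count"),
                seed=int(s.get("seed", 0)),
            )
    assoc = AssociationConfig(**raw.pop("association", {}))
    resamp = AssociationConfig(**{"apply_significance_filter": False, **raw.pop("resampling", {})})
    return PipelineConfig(synthetic=syn, association=assoc, resampling=resamp, **raw)


def _load_matrix(cfg: PipelineConfig) -> LabelMatrix:
    if cfg.input_path is not None:
        return read_label_matrix(cfg.input_path)
    assert cfg.synthetic is not None
    return synthetic.generate(cfg.synthetic)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; write per-stage artifacts and a consolidated report.

    Any stage failure aborts with the stage name in the exception message;
    artifacts written before the failure are retained.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"stages": {}}
    timings: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                res = fn()
            except Exception as exc:  # noqa: BLE001 - stage provenance
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            return res

        return deco

    m = stage("corpus")(lambda: _load_matrix(cfg))
    if cfg.synthetic is not None:
        write_label_matrix(m, out / "corpus.csv")
    report["stages"]["corpus"] = {
        "n_texts": m.n_texts,
        "n_labels": m.n_labels,
        "counts": summarize_counts(m).as_dict(),
    }

    pairs = stage("pairs")(lambda: pair_stats(m, cfg.association))
    pairs.to_csv(out / "pairs.csv", index=False)
    edges = filter_edges(pairs, cfg.association, m.n_labels)
    report["stages"]["pairs"] = {
        "n_pairs": len(pairs),
        "n_significant": len(edges),
        "corrected_alpha": cfg.association.corrected_alpha(m.n_labels),
    }

    triads = stage("triads")(lambda: triad_stats(m))
    triads.to_csv(out / "triads.csv", index=False)
    thr = threshold_triads(triads, cfg.triad_percentile, cfg.triad_cutoff)
    thr.significant.to_csv(out / "triads_significant.csv", index=False)
    report["stages"]["triads"] = {
        "n_triads": len(triads),
        "cutoff": thr.cutoff_value,
        "n_significant": thr.n_significant,
        "top": thr.significant.head(12).to_dict("records"),
    }

    net = stage("network")(
        lambda: build_network(edges, cfg.association, isolate_policy="drop")
    )
    write_network(net, out / "network.graphml")
    cent = centralities(net) if net.n_nodes >= 2 else None
    report["stages"]["network"] = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "metrics": cent.as_dict() if cent else None,
    }

    stab = stage("stability")(
        lambda: bootstrap_stability(
            m, k=cfg.bootstrap_k, cfg=cfg.resampling, seed=cfg.bootstrap_seed
        )
    )
    report["stages"]["stability"] = stab.as_dict()

    qap_res = stage("qap")(
        lambda: split_half_qap(
            m,
            cfg=cfg.association,
            n_permutations=cfg.qap_permutations,
            seed=cfg.qap_seed,
        )
    )
    report["stages"]["qap"] = qap_res.as_dict()
    if cfg.run_stratified_qap and m.groups is not None:
        strat = stage("stratified_qap")(
            lambda: stratified_qap(
                m,
                rule=cfg.stratified_rule,
                cfg=cfg.association,
                n_permutations=cfg.qap_permutations,
                seed=cfg.qap_seed,
            )
        )
        report["stages"]["stratified_qap"] = strat.as_dict()

    sweep = stage("noise")(
        lambda: noise_sweep(
            m,
            levels=cfg.noise_levels,
            replicates=cfg.noise_replicates,
            cfg=cfg.resampling,
            seed=cfg.noise_seed,
        )
    )
    report["stages"]["noise"] = sweep.as_dict()

    report["timings_s"] = timings
    report["seeds"] = {
        "bootstrap": cfg.bootstrap_seed,
        "qap": cfg.qap_seed,
        "noise": cfg.noise_seed,
        "synthetic": cfg.synthetic.seed if cfg.synthetic else None,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    logger.info("pipeline complete: %s", out / "report.json")
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
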