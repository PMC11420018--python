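"""End-to-end pipeline: generate/load -> score -> EGA -> MGM -> metrics ->
stability -> baseline -> 18 ESA sweeps -> serialized report.

A single integer seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``: child 0 drives the generator,
child 1 the mixed-model cross-validation folds, child 2 the stability
bootstrap, child 3 the unclamped baseline simulation, and children 4..21
the 18 strategy x scenario sweeps in order.  Any stage can therefore be
rerun in isolation with an identical stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .esa import (
    SCENARIOS,
    BaselineESA,
    ESAProfile,
    GibbsSettings,
    baseline_esa,
    esa_scenario_sweep,
)
from .estimate import EstimationSettings, ebic_glasso, estimate_mgm, walktrap_communities
from .estimate import correlation_matrix
from .generate import GeneratorConfig, generate_dataset
from .items import STRATEGIES, ItemResponseMatrix, default_nodes, network_table
from .io import (
    FLOAT_FORMAT,
    network_to_graphml,
    read_item_csv,
    write_edges_csv,
    write_item_csv,
    write_json,
    write_partition_csv,
)
from .metrics import GlobalProperties, centrality_table, global_properties
from .network import CommunityPartition, WeightedNetwork
from .stability import BootstrapResult, StabilitySettings, case_dropping_bootstrap

logger = logging.getLogger(__name__)


def _seed_int(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable, and with ``seed`` the complete
    determinant of every output file."""

    input_csv: str | None = None  # None -> synthetic data from `generator`
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    estimation: EstimationSettings = field(default_factory=EstimationSettings)
    gibbs: GibbsSettings = field(default_factory=GibbsSettings)
    stability: StabilitySettings = field(default_factory=StabilitySettings)
    run_stability: bool = True
    scenarios: tuple[str, ...] = ("minimum", "median", "maximum")
    seed: int = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"]["planted_cross_edges"] = [
            list(e) for e in self.generator.planted_cross_edges
        ]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    config: PipelineConfig
    data: ItemResponseMatrix
    scores: pd.DataFrame
    ega_network: WeightedNetwork
    partition: CommunityPartition
    mgm_network: WeightedNetwork
    centralities: pd.DataFrame
    globals_: GlobalProperties
    baseline: BaselineESA
    profiles: list[ESAProfile]
    stability: BootstrapResult | None
    timings: dict[str, float] = field(default_factory=dict)

    def provenance(self) -> dict:
        return {
            "package_version": __version__,
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "numpy_version": np.__version__,
        }


def mgm_strength_estimator(settings: EstimationSettings):
    """data -> node strength vector, refitting the mixed model per call."""
    nodes = default_nodes()

    def estimator(table: pd.DataFrame) -> np.ndarray:
        net = estimate_mgm(table, nodes, settings)
        return np.abs(net.weights).sum(axis=1)

    return estimator


def mgm_edge_estimator(settings: EstimationSettings):
    """data -> vectorized upper-triangle edge weights."""
    nodes = default_nodes()
    iu = np.triu_indices(len(nodes), k=1)

    def estimator(table: pd.DataFrame) -> np.ndarray:
        net = estimate_mgm(table, nodes, settings)
        return net.weights[iu]

    return estimator


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage in order; any failure aborts naming the stage."""
    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(22)
    timings: dict[str, float] = {}
    stage = "load_data"
    try:
        t0 = time.perf_counter()
        if config.input_csv is not None:
            data = read_item_csv(config.input_csv)
        else:
            gen = GeneratorConfig(**{**asdict(config.generator), "seed": _seed_int(children[0])})
            data = generate_dataset(gen)
        timings[stage] = time.perf_counter() - t0

        stage = "score_subscales"
        t0 = time.perf_counter()
        scores = network_table(data)
        timings[stage] = time.perf_counter() - t0

        stage = "ega"
        t0 = time.perf_counter()
        corr = correlation_matrix(data.ress_matrix(), method="pearson")
        ega_net = ebic_glasso(corr, n=data.n, settings=config.estimation)
        partition = walktrap_communities(ega_net)
        timings[stage] = time.perf_counter() - t0

        stage = "mgm"
        t0 = time.perf_counter()
        est = EstimationSettings(**{**asdict(config.estimation), "cv_seed": _seed_int(children[1])})
        nodes = default_nodes()
        mgm_net = estimate_mgm(scores, nodes, est)
        timings[stage] = time.perf_counter() - t0

        stage = "metrics"
        t0 = time.perf_counter()
        centralities = centrality_table(mgm_net)
        globals_ = global_properties(mgm_net)
        timings[stage] = time.perf_counter() - t0

        stage = "stability"
        stability = None
        if config.run_stability:
            t0 = time.perf_counter()
            stability = case_dropping_bootstrap(
                scores,
                mgm_strength_estimator(est),
                config.stability,
                seed=_seed_int(children[2]),
                statistic="strength",
            )
            timings[stage] = time.perf_counter() - t0

        stage = "baseline_esa"
        t0 = time.perf_counter()
        baseline = baseline_esa(
            data.symptom_matrix(), mgm_net, config.gibbs, np.random.default_rng(children[3])
        )
        timings[stage] = time.perf_counter() - t0

        stage = "esa_sweeps"
        t0 = time.perf_counter()
        profiles = []
        k = 4
        for scenario in config.scenarios:
            for strategy in STRATEGIES:
                profiles.append(
                    esa_scenario_sweep(
                        mgm_net,
                        strategy,
                        scenario,
                        baseline.observed,
                        config.gibbs,
                        seed=_seed_int(children[k]),
                    )
                )
                k += 1
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for name, dt in timings.items():
        logger.info("stage %-16s %.2fs", name, dt)

    return ReportBundle(
        config=config,
        data=data,
        scores=scores,
        ega_network=ega_net,
        partition=partition,
        mgm_network=mgm_net,
        centralities=centralities,
        globals_=globals_,
        baseline=baseline,
        profiles=profiles,
        stability=stability,
        timings=timings,
    )


def write_report(bundle: ReportBundle, out_dir) -> list[Path]:
    """Serialize the full bundle as CSV/GraphML/JSON files; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    def track(path: Path) -> Path:
        paths.append(path)
        return path

    write_item_csv(bundle.data, track(out / "item_responses.csv"))
    bundle.scores.to_csv(track(out / "network_table.csv"), index=False)
    write_edges_csv(bundle.ega_network, track(out / "ega_edges.csv"))
    write_edges_csv(bundle.mgm_network, track(out / "mgm_edges.csv"))
    network_to_graphml(bundle.mgm_network, track(out / "mgm_network.graphml"))
    write_partition_csv(bundle.partition, track(out / "ega_communities.csv"))
    bundle.centralities.round(6).to_csv(
        track(out / "centrality.csv"), float_format=FLOAT_FORMAT
    )

    esa_frames = [p.to_frame() for p in bundle.profiles]
    if esa_frames:
        pd.concat(esa_frames, ignore_index=True).to_csv(
            track(out / "esa_profiles.csv"), index=False, float_format=FLOAT_FORMAT
        )

    report = {
        "provenance": bundle.provenance(),
        "global_properties": bundle.globals_.to_dict(),
        "baseline_esa": {
            "observed": bundle.baseline.observed,
            "model_implied": bundle.baseline.model_implied,
            "discrepancy": bundle.baseline.discrepancy,
        },
        "n_communities": bundle.partition.n_communities,
        "mgm_sign_conflicts": bundle.mgm_network.sign_conflicts,
    }
    if bundle.stability is not None:
        report["cs_coefficient"] = {
            bundle.stability.statistic: bundle.stability.cs_coefficient
        }
        bundle.stability.summary_frame().to_csv(
            track(out / "stability.csv"), index=False, float_format=FLOAT_FORMAT
        )
    write_json(report, track(out / "report.json"))
    return paths
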