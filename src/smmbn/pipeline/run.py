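"""End-to-end, config-driven pipeline.

Stages, in order: load or generate the cohort, quartile-discretize flagged
numeric columns, split, under-sample the training partition, run replicate
ensembles for every roster algorithm, build the consensus table, select the
top algorithms, score their misclassification on the untouched test set,
bootstrap arc strengths with the best algorithm, rank node influence toward
the target and answer the odds-ratio query roster.  Every stage is seeded
from the config, and all artifacts are plain text (CSV / GraphML / JSON).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from .. import __version__
from ..bn_core.cpt import fit_cpts
from ..bn_core.dataset import DiscreteDataset
from ..bn_core.graph import Dag, consistent_extension
from ..bn_core.interchange import write_graphml
from ..ensemble_consensus import (
    averaged_network,
    bootstrap_arc_strength,
    build_consensus,
    misclassification_rate,
    run_replicates,
    score_algorithm_arcs,
    select_algorithms,
)
from ..exceptions import ConfigurationError
from ..influence_queries import odds_ratio, rank_influence
from ..structure_learning import (
    AlgorithmConfig,
    ConstraintSet,
    default_roster,
    learn_structure,
)
from ..synthetic_cohort import CohortConfig, generate_cohort
from .prep import quartile_discretize, train_test_split, undersample

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("smmbn.pipeline")

_DEFAULT_SEEDS = {
    "split": 11,
    "undersample": 12,
    "replicates": 13,
    "bootstrap": 14,
    "queries": 15,
}


@dataclasses.dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    input_csv: str | None = None
    layers: dict[str, int] = dataclasses.field(default_factory=dict)
    quartile_columns: tuple[str, ...] = ()
    cohort: CohortConfig | None = None
    target: str = "smm"
    positive_level: str = "yes"
    split_fraction: float = 0.7
    stratified: bool = False
    seeds: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_SEEDS)
    )
    roster: Sequence[AlgorithmConfig] = dataclasses.field(
        default_factory=default_roster
    )
    consensus_threshold: float = 0.7
    replicates_per_algorithm: int = 100
    k_select: int = 3
    smoothing: float = 1.0
    bootstrap_replicates: int = 1000
    bootstrap_size: int = 1000
    bootstrap_replace: bool = True
    strength_threshold: float = 0.5
    dwi_exclusions: tuple[tuple[str, str], ...] = ()
    dwi_directed_only: bool = False
    query_group_vars: tuple[str, ...] = ("race",)
    query_ref_levels: dict[str, str] = dataclasses.field(
        default_factory=lambda: {"race": "white"}
    )
    query_samples: int = 100_000
    query_replicates: int = 30
    extra_blacklist: tuple[tuple[str, str], ...] = ()
    extra_whitelist: tuple[tuple[str, str], ...] = ()
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ConfigurationError("split fraction must be in (0, 1)")
        if not 0.0 < self.consensus_threshold < 1.0:
            raise ConfigurationError("consensus threshold must be in (0, 1)")
        if self.k_select > len(self.roster):
            raise ConfigurationError("k_select exceeds the roster size")
        if self.input_csv is None and self.cohort is None:
            self.cohort = CohortConfig()
        missing = set(_DEFAULT_SEEDS) - set(self.seeds)
        if missing:
            self.seeds = {**_DEFAULT_SEEDS, **self.seeds}

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["roster"] = [cfg.to_dict() for cfg in self.roster]
        if self.cohort is not None:
            d["cohort"] = dataclasses.asdict(self.cohort)
        for key in ("quartile_columns", "dwi_exclusions", "query_group_vars",
                    "extra_blacklist", "extra_whitelist"):
            d[key] = [list(x) if isinstance(x, tuple) else x for x in d[key]]
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if d.get("roster"):
            d["roster"] = [AlgorithmConfig.from_dict(c) for c in d["roster"]]
        if d.get("cohort"):
            d["cohort"] = CohortConfig(**d["cohort"])
        for key in ("dwi_exclusions", "extra_blacklist", "extra_whitelist"):
            if key in d:
                d[key] = tuple(tuple(x) for x in d[key])
        for key in ("quartile_columns", "query_group_vars"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclasses.dataclass
class PipelineResult:
    config: PipelineConfig
    artifacts: dict[str, Path]
    consensus: Any
    selected: list[str]
    misclassification: dict[str, float]
    best_algorithm: str
    strengths: Any
    dwi: Any
    odds_ratios: list[Any]


def _load_data(config: PipelineConfig) -> DiscreteDataset:
    if config.input_csv is not None:
        frame = pd.read_csv(config.input_csv, keep_default_na=False)
        for col in config.quartile_columns:
            frame[col] = quartile_discretize(
                pd.to_numeric(frame[col]).to_numpy()
            )
        frame = frame.astype(str)
        return DiscreteDataset.from_dataframe(frame, layers=config.layers)
    return generate_cohort(config.cohort)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full procedure and write all artifacts to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    log.info("stage=load")
    data = _load_data(config)
    target = config.target
    data.index_of(target)

    constraints = ConstraintSet.from_variable_layers(
        data.variables,
        blacklist=config.extra_blacklist,
        whitelist=config.extra_whitelist,
    )

    log.info("stage=split seed=%s", config.seeds["split"])
    train, test = train_test_split(
        data,
        config.split_fraction,
        config.seeds["split"],
        stratify_by=target if config.stratified else None,
    )

    log.info("stage=undersample seed=%s", config.seeds["undersample"])
    balanced = undersample(train, target, config.seeds["undersample"])

    log.info(
        "stage=ensemble algorithms=%d B=%d",
        len(config.roster),
        config.replicates_per_algorithm,
    )
    scores_by_alg: dict[str, dict] = {}
    for i, alg in enumerate(config.roster):
        structures = run_replicates(
            balanced,
            alg,
            config.replicates_per_algorithm,
            seed=config.seeds["replicates"] + 997 * i,
            constraints=constraints,
        )
        scores_by_alg[alg.label] = score_algorithm_arcs(
            structures, config.consensus_threshold
        )
    consensus = build_consensus(
        scores_by_alg, [alg.label for alg in config.roster]
    )
    artifacts["consensus"] = out / "consensus.csv"
    consensus.to_csv(artifacts["consensus"])

    selected = select_algorithms(consensus, config.k_select)
    log.info("stage=select selected=%s", selected)

    log.info("stage=misclassification")
    rates: dict[str, float] = {}
    by_label = {alg.label: alg for alg in config.roster}
    for label in selected:
        structure = learn_structure(balanced, by_label[label], constraints)
        dag = structure if isinstance(structure, Dag) else consistent_extension(structure)
        rates[label] = misclassification_rate(
            dag, balanced, test, target, config.smoothing
        )
    best = min(selected, key=lambda lab: (rates[lab], selected.index(lab)))
    artifacts["misclassification"] = out / "misclassification.csv"
    pd.DataFrame(
        {"algorithm": list(rates), "misclassification_rate": list(rates.values())}
    ).to_csv(artifacts["misclassification"], index=False)
    artifacts["selection"] = out / "selection.json"
    artifacts["selection"].write_text(
        json.dumps(
            {
                "total_arcs": consensus.total_arcs,
                "selected": selected,
                "misclassification": rates,
                "best_algorithm": best,
            },
            indent=2,
            sort_keys=True,
        )
    )

    log.info(
        "stage=bootstrap algorithm=%s R=%d m=%d",
        best,
        config.bootstrap_replicates,
        config.bootstrap_size,
    )
    strengths = bootstrap_arc_strength(
        balanced,
        by_label[best],
        config.bootstrap_replicates,
        config.bootstrap_size,
        seed=config.seeds["bootstrap"],
        constraints=constraints,
        replace=config.bootstrap_replace,
    )
    artifacts["arc_strengths"] = out / "arc_strengths.csv"
    strengths.to_csv(artifacts["arc_strengths"])
    avg_net = averaged_network(strengths, config.strength_threshold)
    artifacts["network"] = out / "averaged_network.graphml"
    write_graphml(
        avg_net,
        artifacts["network"],
        arc_attrs={
            arc: {"strength": strengths.pair_strength(*arc)}
            for arc in avg_net.arcs()
        },
    )

    log.info("stage=influence target=%s", target)
    dwi_result = rank_influence(
        avg_net,
        target,
        strengths=strengths,
        exclusions=config.dwi_exclusions,
        directed_only=config.dwi_directed_only,
    )
    artifacts["dwi"] = out / "dwi.csv"
    pd.DataFrame(
        {
            "node": list(dwi_result.ranking),
            "dwi": [dwi_result.scores[n] for n in dwi_result.ranking],
        }
    ).to_csv(artifacts["dwi"], index=False)

    log.info("stage=queries seed=%s", config.seeds["queries"])
    cpts = fit_cpts(avg_net, train, config.smoothing)
    event = {target: config.positive_level}
    or_rows = []
    or_results = []
    for gi, group in enumerate(config.query_group_vars):
        ref = config.query_ref_levels.get(group, data.spec(group).levels[0])
        for li, level in enumerate(data.spec(group).levels):
            if level == ref:
                continue
            res = odds_ratio(
                avg_net,
                cpts,
                event,
                group,
                level,
                ref,
                n_samples=config.query_samples,
                replicates=config.query_replicates,
                seed=config.seeds["queries"] + 7919 * gi + li,
            )
            or_results.append(res)
            or_rows.append(
                {
                    "Event": f"{target}={config.positive_level}",
                    "Evidence": f"{group}={level} vs {group}={ref}",
                    "OddsRatio": res.odds_ratio,
                    "Lower": res.interval[0],
                    "Upper": res.interval[1],
                }
            )
    artifacts["odds_ratios"] = out / "odds_ratios.csv"
    pd.DataFrame(
        or_rows, columns=["Event", "Evidence", "OddsRatio", "Lower", "Upper"]
    ).to_csv(artifacts["odds_ratios"], index=False)

    config_echo = config.to_dict()
    config_echo.pop("out_dir")  # manifests are location-independent
    manifest = {
        "package_version": __version__,
        "config": config_echo,
        "artifacts": {k: p.name for k, p in artifacts.items()},
    }
    artifacts["manifest"] = out / "manifest.json"
    artifacts["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("stage=done artifacts=%d", len(artifacts))

    return PipelineResult(
        config=config,
        artifacts=artifacts,
        consensus=consensus,
        selected=selected,
        misclassification=rates,
        best_algorithm=best,
        strengths=strengths,
        dwi=dwi_result,
        odds_ratios=or_results,
    )
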