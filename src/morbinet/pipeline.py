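"""End-to-end orchestration: simulate/load -> filter -> fit -> describe.

A pipeline run executes, per stratum (default: the male/female split),
prevalence description, MGM estimation, predictability, centrality,
community detection with pattern labels, bootstrap stability, gamma
sensitivity, and multinomial profiling, writing TSV tables plus a JSON run
manifest. Identical configuration (including seeds) yields byte-identical
output bundles; every table carries the manifest hash in a leading comment
line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from morbinet._version import __version__
from morbinet.data_io import apply_multimorbidity_filter, load_cohort, prevalence_table
from morbinet.mgm import EstimationConfig, fit_mgm
from morbinet.network_analysis import centralities, fast_greedy_communities, label_patterns
from morbinet.predictability import predictability_table
from morbinet.profiling import assign_patterns, fit_multinomial
from morbinet.schema import Cohort, canonical_schema, generic_schema
from morbinet.stability import bootstrap_edges, gamma_sensitivity
from morbinet.synthetic import SimulationConfig, block_model, sample_cohort, survey_model

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Either ``input_path`` (a cohort CSV/TSV) or ``synthetic`` (a generator
    spec: preset "survey" or "block" plus n and seed) must be given.
    """

    input_path: Optional[str] = None
    synthetic: Optional[dict[str, Any]] = None
    schema: str = "canonical"  # "canonical" | "generic"
    min_conditions: int = 2
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    gammas: tuple[float, ...] = ()
    bootstrap_B: int = 0
    bootstrap_seed: int = 0
    stratify_by: Optional[str] = "sex"
    reference_pattern: str = "MP1"
    reference_class: Optional[Any] = None
    output_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        est = EstimationConfig(**raw.pop("estimation", {}))
        boot = raw.pop("bootstrap", {})
        cfg = cls(
            estimation=est,
            bootstrap_B=int(boot.get("B", 0)),
            bootstrap_seed=int(boot.get("seed", 0)),
            gammas=tuple(raw.pop("gammas", ())),
            **raw,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path / synthetic is required")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ValueError(f"input path {self.input_path!r} does not exist")

    def to_dict(self) -> dict[str, Any]:
        # output_dir is excluded: the manifest and its hash describe the
        # analysis, not where the bundle lands
        d = asdict(self)
        d["estimation"] = asdict(self.estimation)
        d["gammas"] = list(self.gammas)
        d.pop("output_dir", None)
        return d

    def manifest_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _make_cohort(config: PipelineConfig) -> Cohort:
    if config.input_path is not None:
        if config.schema == "canonical":
            schema = canonical_schema()
        else:
            from morbinet.data_io import infer_schema

            schema = infer_schema(config.input_path)
        return load_cohort(config.input_path, schema=schema)
    spec = dict(config.synthetic)
    preset = spec.pop("preset", "survey")
    n = int(spec.pop("n", 2000))
    seed = int(spec.pop("seed", 0))
    sim = SimulationConfig(
        n=n,
        burnin=int(spec.pop("burnin", 200)),
        thin=int(spec.pop("thin", 5)),
        seed=seed,
    )
    if preset == "survey":
        model = survey_model(**spec)
    elif preset == "block":
        model = block_model(**spec)
    else:
        raise ValueError(f"unknown synthetic preset {preset!r}")
    return sample_cohort(model, sim)


def _write_tsv(df: pd.DataFrame, path: Path, manifest_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest: {manifest_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_stratum(
    cohort: Cohort, config: PipelineConfig
) -> dict[str, Any]:
    """Execute every analysis stage on one (sub-)cohort."""
    out: dict[str, Any] = {}
    stage = "prevalence"
    try:
        out["prevalence"] = prevalence_table(cohort)
        stage = "fit"
        network = fit_mgm(cohort, config.estimation)
        out["network"] = network
        out["edges"] = network.edge_list()
        if config.estimation.k == 3:
            out["triples"] = network.triple_list()
        stage = "predictability"
        out["predictability"] = predictability_table(network, cohort)
        stage = "centrality"
        out["centrality"] = centralities(network)
        stage = "communities"
        partition = fast_greedy_communities(network)
        out["partition"] = partition
        out["membership"] = label_patterns(partition)
        out["merge_history"] = pd.DataFrame(
            partition.merge_history, columns=["into", "merged", "delta_q", "q"]
        )
        if config.bootstrap_B > 0:
            stage = "bootstrap"
            out["bootstrap"] = bootstrap_edges(
                cohort, config.estimation, B=config.bootstrap_B, seed=config.bootstrap_seed
            )
        if len(config.gammas) > 1:
            stage = "gamma_sensitivity"
            _, out["gamma_comparison"] = gamma_sensitivity(
                cohort, config.estimation, config.gammas
            )
        stage = "profiling"
        if {"age", "social_class"} <= set(cohort.data.columns):
            assignments = assign_patterns(cohort, partition)
            out["assignments"] = assignments
            try:
                out["profiling"] = fit_multinomial(
                    assignments,
                    cohort.data[["age", "social_class"]],
                    reference_pattern=config.reference_pattern,
                    reference_class=config.reference_class,
                )
            except ValueError as exc:
                logger.warning("profiling skipped: %s", exc)
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full analysis and (optionally) write the output bundle.

    Returns {"manifest": ..., "strata": {name: stage tables}}; with
    ``config.output_dir`` set, writes per-stratum TSVs and manifest.json.
    """
    config.validate()
    mhash = config.manifest_hash()
    cohort = _make_cohort(config)
    cohort = apply_multimorbidity_filter(cohort, config.min_conditions)
    strata: dict[str, Cohort] = {"all": cohort}
    if config.stratify_by:
        strata = cohort.stratify(config.stratify_by)
    results = {name: run_stratum(sub, config) for name, sub in strata.items()}
    manifest = {
        "package": "morbinet",
        "version": __version__,
        "manifest_hash": mhash,
        "config": config.to_dict(),
        "n_input": cohort.n,
        "strata": {name: sub.n for name, sub in strata.items()},
    }
    bundle = {"manifest": manifest, "strata": results}
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
        for name, tables in results.items():
            sdir = outdir / name
            sdir.mkdir(exist_ok=True)
            for key, value in tables.items():
                if isinstance(value, pd.DataFrame):
                    _write_tsv(value, sdir / f"{key}.tsv", mhash)
    return bundle
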