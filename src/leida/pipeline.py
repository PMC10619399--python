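"""End-to-end orchestration: cohort -> preprocessing -> phases ->
eigenvectors -> partition sweep -> state metrics -> group statistics.

A single :class:`PipelineConfig` drives everything and a master seed makes
the whole run deterministic: identical seeds give byte-identical output
tables.  The discovery (recurrent) arm defines the PL-states; the
validation (non-recurrent) arm is labelled against those fixed centroids;
a sensitivity pass optionally re-clusters the validation arm on its own.

Artifacts written to the output directory:

* ``cohort/`` — scan TSVs, manifest, ground-truth JSON (simulated runs)
* ``eigenvectors_<arm>.tsv`` + ``eigenvector_index_<arm>.tsv``
* ``models/k<k>.json`` + ``assignments_<arm>.tsv``
* ``metrics_<arm>.tsv`` and ``stats_<arm>.tsv``
* ``summary.txt`` and ``provenance.json`` (config + hash + versions)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import PartitionModel, assign_to_centroids, fit_partitions
from .data import RoiTimeSeries, read_cohort, scan_key, split_arms, write_cohort
from .metrics import build_metrics_table
from .phase import instantaneous_phase, pool_eigenvectors
from .preprocess import preprocess_scan
from .simulate import SynthConfig, generate_cohort
from .stats import DEFAULT_PRIOR_SCALE, analyze_cohort, summarize

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class PipelineConfig:
    """All knobs of one analysis run.

    Exactly one of ``synth`` (generate a cohort) or ``manifest`` (load an
    existing cohort) must be set.  ``n_discard`` defaults to 0 because the
    bundled generator emits analyzed frames directly; raw scanner exports
    (e.g. 208 acquired volumes) should use 4.
    """

    synth: SynthConfig | None = None
    manifest: str | Path | None = None
    n_discard: int = 0
    band: tuple[float, float] = (0.01, 0.1)
    trim_edges: int = 0
    k_min: int = 2
    k_max: int = 20
    n_replicates: int = 50
    distance: str = "cosine"
    n_perm: int = 5000
    alpha: float = 0.05
    bayes_direction: str = "greater"
    prior_scale: float = DEFAULT_PRIOR_SCALE
    sensitivity: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.manifest is None):
            raise ValueError("set exactly one of synth or manifest")
        if self.k_min < 2:
            raise ValueError("k_min must be at least 2")
        if self.n_perm < 1000:
            raise ValueError("n_perm must be at least 1000")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        if payload.get("synth") is not None:
            synth = dict(payload["synth"])
            if "effects" in synth:
                from .simulate import EffectSpec

                synth["effects"] = [EffectSpec(**e) for e in synth["effects"]]
            payload["synth"] = SynthConfig(**synth)
        if "band" in payload:
            payload["band"] = tuple(payload["band"])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        if self.synth is not None:
            synth = payload["synth"]
            synth["transition_matrix_baseline"] = np.asarray(
                synth["transition_matrix_baseline"]
            ).tolist()
            synth["effects"] = [dict(e) for e in synth["effects"]]
        if self.manifest is not None:
            payload["manifest"] = str(self.manifest)
        payload["band"] = list(self.band)
        return payload

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def default_synthetic_config(master_seed: int = 0, **overrides) -> PipelineConfig:
    """Pipeline config for the emulated study design, fully synthetic."""
    return PipelineConfig(synth=SynthConfig(), master_seed=master_seed, **overrides)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # tag and re-raise
            raise PipelineError(f"[{name}] {exc}") from exc

    return wrap


def _write_matrix_tsv(matrix: np.ndarray, path: Path) -> None:
    pd.DataFrame(matrix).to_csv(
        path, sep="\t", index=False, header=False, float_format="%.10g"
    )


def _analysis_for_arm(
    scans: list[RoiTimeSeries],
    models: list[PartitionModel],
    phases: dict,
    config: PipelineConfig,
    stats_seed: int,
    fit_pool=None,
):
    """Metrics + statistics for one arm against a fixed set of models."""
    pool = (
        fit_pool
        if fit_pool is not None
        else pool_eigenvectors(scans, trim_edges=config.trim_edges, phases=phases)
    )
    assignments = {}
    for model in models:
        if fit_pool is not None:
            assignments[model.k] = model.assignments
        else:
            assignments[model.k] = assign_to_centroids(
                pool, model.centroids, distance=config.distance
            )
    metrics = build_metrics_table(
        pool.index,
        assignments,
        {m.k: m.centroids for m in models},
        phases,
        tr=scans[0].tr,
    )
    stat_table = analyze_cohort(
        metrics,
        n_perm=config.n_perm,
        seed=stats_seed,
        alpha=config.alpha,
        bayes_direction=config.bayes_direction,
        prior_scale=config.prior_scale,
    )
    return pool, assignments, metrics, stat_table


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run the full analysis; returns the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    incomplete = out / "INCOMPLETE"
    incomplete.write_text("run in progress or aborted\n")

    seed_root = np.random.SeedSequence(config.master_seed)
    synth_seed, clust_seed, stats_seed, sens_clust_seed, sens_stats_seed, val_stats_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in seed_root.spawn(6)
    )

    # ---- cohort -----------------------------------------------------------
    def load() -> list[RoiTimeSeries]:
        if config.synth is not None:
            synth = config.synth
            if synth.seed is None:
                synth = dataclasses.replace(synth, seed=synth_seed)
            scans, _manifest, truth = generate_cohort(synth)
            cohort_dir = out / "cohort"
            write_cohort(scans, cohort_dir)
            truth.to_json(cohort_dir / "ground_truth.json")
            return scans
        return read_cohort(config.manifest)

    scans = _stage("cohort")(load)
    logger.info("cohort: %d scans", len(scans))

    # ---- preprocessing + phases ------------------------------------------
    def prep():
        processed = [
            preprocess_scan(ts, config.n_discard, *config.band) for ts in scans
        ]
        phases = {scan_key(ts): instantaneous_phase(ts) for ts in processed}
        return processed, phases

    processed, phases = _stage("preprocess")(prep)

    recurrent, non_recurrent = split_arms(processed)
    if not recurrent:
        raise PipelineError("[cohort] no recurrent (discovery) arm in the cohort")

    # ---- discovery arm: pool, partition sweep, metrics, stats ------------
    discovery_pool = _stage("eigenvectors")(
        pool_eigenvectors, recurrent, config.trim_edges, phases
    )
    models = _stage("clustering")(
        fit_partitions,
        discovery_pool,
        config.k_min,
        config.k_max,
        config.n_replicates,
        clust_seed,
        config.distance,
    )
    _, disc_assign, disc_metrics, disc_stats = _stage("discovery-stats")(
        _analysis_for_arm, recurrent, models, phases, config, stats_seed,
        discovery_pool,
    )

    results = {"discovery": (discovery_pool, disc_assign, disc_metrics, disc_stats)}

    # ---- validation arm: fixed centroids, plus optional re-clustering ----
    if non_recurrent:
        results["validation"] = _stage("validation-stats")(
            _analysis_for_arm, non_recurrent, models, phases, config,
            val_stats_seed,
        )
        if config.sensitivity:
            val_pool = results["validation"][0]
            sens_models = _stage("sensitivity-clustering")(
                fit_partitions,
                val_pool,
                config.k_min,
                config.k_max,
                config.n_replicates,
                sens_clust_seed,
                config.distance,
            )
            results["sensitivity"] = _stage("sensitivity-stats")(
                _analysis_for_arm, non_recurrent, sens_models, phases, config,
                sens_stats_seed, val_pool,
            )
            sens_dir = out / "models_sensitivity"
            sens_dir.mkdir(parents=True, exist_ok=True)
            for model in sens_models:
                model.to_json(sens_dir / f"k{model.k:02d}.json")

    # ---- artifacts --------------------------------------------------------
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    for model in models:
        model.to_json(models_dir / f"k{model.k:02d}.json")

    summary_parts = []
    for arm, (pool, assignments, metrics, stat_table) in results.items():
        _write_matrix_tsv(pool.vectors, out / f"eigenvectors_{arm}.tsv")
        pool.index.to_csv(out / f"eigenvector_index_{arm}.tsv", sep="\t", index=False)
        assign_frame = pool.index.copy()
        for k in sorted(assignments):
            assign_frame[f"k{k:02d}"] = assignments[k]
        assign_frame.to_csv(out / f"assignments_{arm}.tsv", sep="\t", index=False)
        metrics.to_csv(out / f"metrics_{arm}.tsv", sep="\t", index=False,
                       float_format="%.10g")
        stat_table.to_csv(out / f"stats_{arm}.tsv", sep="\t", index=False,
                          float_format="%.10g")
        summary_parts.append(
            f"== {arm} arm ({pool.vectors.shape[0]} pooled eigenvectors) ==\n"
            + summarize(stat_table, config.alpha)
        )
    (out / "summary.txt").write_text("\n".join(summary_parts))

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "derived_seeds": {
            "synth": synth_seed,
            "clustering": clust_seed,
            "stats": stats_seed,
            "sensitivity_clustering": sens_clust_seed,
            "sensitivity_stats": sens_stats_seed,
            "validation_stats": val_stats_seed,
        },
        "versions": {
            "leida": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    incomplete.unlink()
    return out
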