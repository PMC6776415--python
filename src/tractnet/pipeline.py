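"""End-to-end pipeline: simulate (or track+build) -> curves -> group stats.

RunConfig defaults mirror the analysis settings the pipeline is built
around: 40 threshold levels, 10000 permutations, 100 rewired null networks,
clusters of at least 3 consecutive thresholds.  Every stochastic stage takes
its seed from the config and the run manifest records the config hash, input
checksums, per-stage wall times and warnings, so identical configs reproduce
identical outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import curves as _curves
from . import gstats as _gstats
from . import io as _io
from . import synthio as _synthio

logger = logging.getLogger("tractnet")

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

#: settings with fixed analysis defaults; overrides are logged as such
_DEFAULTS = {"n_levels": 40, "n_perm": 10000, "n_null": 100, "cluster_min": 3}


@dataclass
class RunConfig:
    out_dir: str = "run"
    stages: tuple = ("simulate", "curves", "stats")
    strategy: str = "length_adjusted"
    n_levels: int = 40
    n_perm: int = 10000
    n_null: int = 100
    cluster_min: int = 3
    seed: int = 0
    covariate_preset: str = "length_adjusted"
    # synthetic cohort settings (used by the simulate stage)
    cohort: dict = field(default_factory=dict)
    # metric list for curves; None = all
    metrics: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.strategy not in ("length_adjusted", "volume_adjusted",
                                 "synthetic"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        for key, default in _DEFAULTS.items():
            val = getattr(self, key)
            if val != default:
                logger.info("override: %s=%s (analysis default %s)",
                            key, val, default)
            else:
                logger.debug("using analysis default %s=%s", key, default)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "metrics" in data and data["metrics"] is not None:
            data["metrics"] = tuple(data["metrics"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    input_checksums: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    outputs: list = field(default_factory=list)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in order, writing every stage's outputs
    under ``config.out_dir`` and a manifest.json at the end."""
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(),
                           package_version=__version__, seed=config.seed)

    connectomes = None
    table = None
    for stage in config.stages:
        t0 = time.perf_counter()
        logger.info("stage %s", stage)
        if stage == "simulate":
            spec = _synthio.CohortSpec(seed=config.seed, **config.cohort)
            connectomes, table = _synthio.simulate_cohort(spec)
            subj_dir = out / "subjects"
            for conn in connectomes:
                _io.write_connectome(conn, subj_dir / conn.subject_id)
            _io.write_cohort(table, out / "cohort.csv")
            manifest.outputs += ["subjects/", "cohort.csv"]
        elif stage == "curves":
            if connectomes is None:
                subj_dir = out / "subjects"
                if not subj_dir.exists():
                    raise FileNotFoundError(f"missing input: {subj_dir}")
                connectomes = [_io.read_connectome(d)
                               for d in sorted(subj_dir.iterdir())]
                table = _io.read_cohort(out / "cohort.csv")
            dens, wsched = _curves.make_schedules(connectomes,
                                                  n_levels=config.n_levels)
            _io.write_json({"density": dens.levels, "weight": wsched.levels,
                            "provenance": dens.provenance},
                           out / "schedules.json")
            rows = []
            auc_rows = []
            which = list(config.metrics) if config.metrics else None
            for i, conn in enumerate(connectomes):
                cvs, aucs = _curves.metric_curves(
                    conn, dens, wsched, which=which, n_null=config.n_null,
                    seed=config.seed + 1000 + i)
                for c in cvs:
                    for lv, v in zip(c.schedule.levels, c.values):
                        rows.append({"subject": c.subject_id,
                                     "metric": c.metric,
                                     "level": lv, "value": v})
                for m, a in aucs.items():
                    auc_rows.append({"subject": conn.subject_id,
                                     "metric": m, "auc_total": a})
            pd.DataFrame(rows).to_csv(out / "curves.csv", index=False)
            pd.DataFrame(auc_rows).to_csv(out / "auc.csv", index=False)
            manifest.outputs += ["schedules.json", "curves.csv", "auc.csv"]
        elif stage == "stats":
            auc = pd.read_csv(out / "auc.csv")
            curves_df = pd.read_csv(out / "curves.csv")
            if table is None:
                table = _io.read_cohort(out / "cohort.csv")
            cov = _gstats.covariate_preset(table, config.covariate_preset)
            metrics_list = sorted(auc["metric"].unique())
            m = len(metrics_list)
            auc_results = []
            mtpc_rows = []
            for j, met in enumerate(metrics_list):
                sub = auc[auc["metric"] == met].set_index("subject")
                y = sub.loc[table["id"], "auc_total"].to_numpy()
                if not np.all(np.isfinite(y)):
                    manifest.warnings.append(f"non-finite AUC for {met}")
                    continue
                res = _gstats.ancova_auc(
                    y, table["group"], cov, mode="permutation",
                    n_perm=config.n_perm, seed=config.seed + 7 + j,
                    m_comparisons=m, metric=met)
                auc_results.append({
                    "metric": met, "F": res.F, "df1": res.df1, "df2": res.df2,
                    "p": res.p, "p_bonferroni": res.p_bonferroni,
                    "kind": res.kind, "transform": res.transform})
                piv = (curves_df[curves_df["metric"] == met]
                       .pivot(index="subject", columns="level", values="value")
                       .loc[table["id"]])
                Y = piv.to_numpy()
                if np.all(np.isfinite(Y)):
                    r = _gstats.mtpc(Y, table["group"], cov,
                                     n_perm=config.n_perm,
                                     cluster_min=config.cluster_min,
                                     seed=config.seed + 31 + j,
                                     thresholds=piv.columns.to_numpy(float))
                    mtpc_rows.append({
                        "metric": met, "t_max": r.t_max, "df": r.df,
                        "p_FWE": r.p_fwe, "tau": r.tau,
                        "AUC_MTPC": (max(c.auc_mtpc for c in r.clusters)
                                     if r.clusters else np.nan),
                        "AUC_crit": r.auc_crit,
                        "MTPC_sig": "Y" if r.significant else "N"})
                else:
                    manifest.warnings.append(f"non-finite curve for {met}")
            pd.DataFrame(auc_results).to_csv(out / "stats_auc.csv", index=False)
            pd.DataFrame(mtpc_rows).to_csv(out / "stats_mtpc.csv", index=False)
            manifest.outputs += ["stats_auc.csv", "stats_mtpc.csv"]
        else:
            raise ValueError(f"unknown stage {stage!r}")
        manifest.timings[stage] = round(time.perf_counter() - t0, 3)

    for rel in manifest.outputs:
        p = out / rel
        if p.is_file():
            manifest.input_checksums[rel] = _checksum(p)
    _io.write_json(asdict(manifest), out / "manifest.json")
    return manifest
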