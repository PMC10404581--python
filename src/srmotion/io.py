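"""Trajectory CSV formats, run configuration and the end-to-end pipeline.

Trajectories are plain CSV with header ``t,x,y,theta,v,a`` (comma
separator, '.' decimal).  Files carrying only ``t,x,y`` are lifted into
the full feature space on read.  The pipeline composes
generate-or-load -> lift -> affinity -> Markov normalisation -> spectral
clustering -> boundary extraction, fully seeded, and reports its
parameters so a run is reproducible from its own report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import (ClusterResult, kmeans_baseline, mean_boundary_error,
                      spectral_cluster)
from .distance import DistanceWeights
from .fit import BellProfile
from .space import Trajectory
from .synthetic import (PursuitSpec, gen_center_out, gen_random_pursuit,
                        kinematics_from_path, speed_extrema_times)

__all__ = [
    "RunConfig",
    "read_trajectory",
    "write_trajectory",
    "run_pipeline",
]

logger = logging.getLogger("srmotion")

_COLUMNS = ["t", "x", "y", "theta", "v", "a"]


def read_trajectory(path) -> Trajectory:
    """Read a trajectory CSV; lift the kinematics when theta, v, a are absent.

    The header must contain at least ``t,x,y``; times must be strictly
    increasing and uniformly spaced.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed trajectory CSV {path}: {exc}") from exc
    missing = [c for c in ("t", "x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in df.columns:
        bad = df[df[col].isna()]
        if len(bad):
            raise ValueError(
                f"{path}: malformed value in column {col!r} at line "
                f"{int(bad.index[0]) + 2}")
    t = df["t"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    if set(_COLUMNS) <= set(df.columns):
        traj = Trajectory(df[_COLUMNS].to_numpy(float), {"source": str(path)})
    else:
        traj = kinematics_from_path(t, df["x"].to_numpy(float),
                                    df["y"].to_numpy(float))
        traj.meta["source"] = str(path)
    return traj


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV with header ``t,x,y,theta,v,a``."""
    df = pd.DataFrame(traj.data, columns=_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def write_truth(traj: Trajectory, path) -> None:
    """Write the generator's ground-truth labels (``t,segment,phase``)."""
    if "segment" not in traj.meta:
        raise ValueError("trajectory carries no ground-truth labels")
    df = pd.DataFrame({
        "t": traj.t,
        "segment": np.asarray(traj.meta["segment"], int),
        "phase": np.asarray(traj.meta["phase"], int),
    })
    df.to_csv(path, index=False, float_format="%.12g")


@dataclass
class RunConfig:
    """Validated configuration of one clustering run.

    ``generator`` is ``"center-out"``, ``"pursuit"`` or ``"file"`` (with
    ``input_path``).  ``distance`` is ``"subriemannian"``, ``"euclidean"``
    or ``"weighted-euclidean"``; the last two run the k-means baseline
    when ``method="kmeans"``.  ``k=None`` selects the cluster count by the
    eigengap.  Unknown keys in a config file are rejected.
    """

    generator: str = "center-out"
    input_path: str | None = None
    seed: int = 0
    distance: str = "subriemannian"
    method: str = "spectral"
    k: int | None = None
    c: tuple = (10.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    t_norm: float = 0.4
    sigma: float = 0.7071067811865476
    e3_mode: str = "sign"
    # generator parameters (metres, seconds)
    v0: float = 1.4
    T: float = 0.07
    dt: float = 0.01
    heading: float = 0.0
    targets: list = field(default_factory=list)
    v0_range: tuple = (0.6, 1.4)
    # outputs
    labels_out: str | None = None
    report_out: str | None = None

    def __post_init__(self) -> None:
        if self.generator not in ("center-out", "pursuit", "file"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if self.generator == "file" and not self.input_path:
            raise ValueError("generator='file' requires input_path")
        if self.distance not in ("subriemannian", "euclidean", "weighted-euclidean"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.method not in ("spectral", "kmeans"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "kmeans" and self.k is None:
            raise ValueError("kmeans method requires an explicit k")

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**d)

    @staticmethod
    def from_file(path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return RunConfig.from_dict(data)

    def weights(self) -> DistanceWeights:
        return DistanceWeights(c=tuple(self.c), t_norm=self.t_norm,
                               sigma=self.sigma, e3_mode=self.e3_mode)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["c"] = list(d["c"])
        d["v0_range"] = list(d["v0_range"])
        return d


def _make_trajectory(config: RunConfig) -> Trajectory:
    if config.generator == "center-out":
        return gen_center_out(heading=config.heading,
                              profile=BellProfile(config.v0, config.T),
                              dt=config.dt, seed=config.seed)
    if config.generator == "pursuit":
        targets = config.targets or [(0, 0), (0.1, 0), (0.1, 0.1), (0, 0.1)]
        spec = PursuitSpec(targets=targets, v0_range=tuple(config.v0_range),
                           dt=config.dt, seed=config.seed)
        return gen_random_pursuit(spec)
    return read_trajectory(config.input_path)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full decomposition pipeline and return a JSON-able report.

    Stages: generate or load the trajectory, lift if needed, build the
    affinity, normalise, cluster, extract boundaries.  Any stage failure
    is re-raised with the stage name.  The report carries the full config,
    eigenvalues, labels, boundaries, and boundary-to-extremum errors when
    ground-truth speed extrema are known.
    """
    stages = {}

    def run_stage(name, fn):
        start = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        stages[name] = time.perf_counter() - start
        logger.info("stage %s: %.3f s", name, stages[name])
        return out

    traj = run_stage("generate", lambda: _make_trajectory(config))
    w = config.weights()

    def do_cluster() -> ClusterResult:
        if config.method == "kmeans":
            return kmeans_baseline(traj, k=config.k, w=w, seed=config.seed)
        return spectral_cluster(traj, k=config.k, distance=config.distance,
                                w=w, seed=config.seed)

    result = run_stage("cluster", do_cluster)

    report = {
        "config": config.to_dict(),
        "method": result.method,
        "distance": config.distance,
        "k": result.k,
        "n_samples": len(traj),
        "eigenvalues": [float(v) for v in result.eigenvalues[:10]],
        "labels": [int(l) for l in result.labels],
        "times": [float(t) for t in traj.t],
        "boundaries": [float(b) for b in result.boundaries],
        "stage_seconds": stages,
    }
    extrema = speed_extrema_times(traj)
    if len(extrema):
        report["extrema_times"] = [float(e) for e in extrema]
        report["boundary_error_samples"] = mean_boundary_error(
            result.boundaries, extrema, traj.dt)
    if "truth_labels" in traj.meta:
        from sklearn.metrics import adjusted_rand_score
        report["ari"] = float(adjusted_rand_score(
            np.asarray(traj.meta["truth_labels"]), result.labels))

    if config.labels_out:
        pd.DataFrame({"t": traj.t, "label": result.labels}).to_csv(
            config.labels_out, index=False, float_format="%.12g")
    if config.report_out:
        Path(config.report_out).write_text(json.dumps(report, indent=2))
    return report
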