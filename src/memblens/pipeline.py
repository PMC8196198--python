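"""End-to-end orchestration: synthesize or load, analyze, report.

A :class:`RunConfig` (usually from YAML) names the input — either a
``synthetic`` block mirroring :class:`~memblens.synthetic.SynthConfig` or
coordinate/trajectory/topology file paths — and an ordered list of analyses
with their parameters.  :func:`run` executes the analyses, writes one TSV per
analysis plus a single ``summary.json`` with all aggregates, the resolved
configuration and the package version.  Results are deterministic for a fixed
config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .depth import density_profile, sterol_depth, sterol_tilt
from .frames import Trajectory
from .hill import fit_hill, read_isotherm
from .io import read_frames
from .order import compute_order
from .segregation import NeighborParams, segregation_series
from .synthetic import ChainTemplate, SynthConfig, generate_trajectory, synthetic_topology
from .topology import TopologySpec, builtin_topology, read_topology

__all__ = ["RunConfig", "run", "load_run_config"]

log = logging.getLogger("memblens")

ANALYSES = ("order", "depth", "profile", "tilt", "segregation", "hillfit")


@dataclass
class RunConfig:
    analyses: list[dict[str, Any]]
    synthetic: Mapping[str, Any] | None = None
    coords: str | None = None
    traj: str | None = None
    topology: str | None = None
    isotherm: str | None = None
    output_dir: str = "memblens_out"
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.analyses:
            raise ValueError("at least one analysis must be requested")
        for a in self.analyses:
            if a.get("kind") not in ANALYSES:
                raise ValueError(f"unknown analysis {a.get('kind')!r}")
        needs_frames = any(a["kind"] != "hillfit" for a in self.analyses)
        if needs_frames and self.synthetic is None and self.coords is None:
            raise ValueError("frame-based analyses need a synthetic block or coords")
        for path in (self.coords, self.traj, self.topology, self.isotherm):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


def _config_hash(config: RunConfig) -> str:
    # hash the scientific content only; where results land (and how chattily)
    # must not change their identity
    payload = dataclasses.asdict(config)
    payload.pop("output_dir", None)
    payload.pop("log_level", None)
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _prepare_input(config: RunConfig) -> tuple[Trajectory | None, TopologySpec]:
    if config.synthetic is not None:
        synth = dict(config.synthetic)
        if config.seed is not None:
            synth.setdefault("seed", config.seed)
        template_kw = synth.pop("template", None)
        template = ChainTemplate(**template_kw) if template_kw else ChainTemplate()
        sc = SynthConfig(**synth)
        return generate_trajectory(sc, template), synthetic_topology(sc, template)
    topology = read_topology(config.topology) if config.topology else builtin_topology()
    if config.coords is not None:
        return read_frames(config.coords, config.traj, topology), topology
    return None, topology


def _write_tsv(path: Path, df: pd.DataFrame, header: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run(config: RunConfig) -> dict[str, Any]:
    """Execute all requested analyses; returns the summary dict."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)
    provenance = [f"memblens {__version__}", f"config {cfg_hash}"]
    traj, topology = _prepare_input(config)
    summary: dict[str, Any] = {
        "version": __version__,
        "config_hash": cfg_hash,
        "config": dataclasses.asdict(config),
        "analyses": {},
    }

    for spec in config.analyses:
        kind = spec["kind"]
        params = {k: v for k, v in spec.items() if k != "kind"}
        log.info("running analysis %s", kind)
        try:
            if kind == "order":
                res = compute_order(
                    traj,
                    topology,
                    species=params.get("species", "DPPC"),
                    statistic=params.get("statistic", "median"),
                    phase_threshold=params.get("threshold", 0.7),
                )
                df = pd.DataFrame(
                    {
                        "lipid_id": res.lipid_ids,
                        "S": res.per_lipid_S,
                    }
                )
                _write_tsv(out_dir / "order.tsv", df, provenance)
                summary["analyses"]["order"] = {
                    "aggregate_S": res.aggregate_S,
                    "statistic": res.statistic,
                    "phase": res.phase,
                    "leaflet_tilt_deg": res.leaflet_tilt_deg,
                    "n_frames": res.n_frames_used,
                }
            elif kind == "depth":
                res = sterol_depth(traj, topology, params.get("species", "CHOL"))
                summary["analyses"]["depth"] = {
                    "species": res.species,
                    "delta_z_nm": res.delta_z_nm,
                    "se_nm": res.se_nm,
                    "per_leaflet_nm": res.per_leaflet_nm,
                }
            elif kind == "profile":
                classes = params.get("classes", ["P"])
                res = density_profile(
                    traj, topology, classes, params.get("bin_width_nm", 0.1)
                )
                df = pd.DataFrame({"z_nm": res.bin_centers_nm})
                for cls in classes:
                    df[cls] = res.density[cls]
                _write_tsv(
                    out_dir / "profile.tsv",
                    df,
                    provenance + ["z relative to the phosphate midplane (nm)"],
                )
                summary["analyses"]["profile"] = {
                    "classes": classes,
                    "integrals": {c: res.integral(c) for c in classes},
                }
            elif kind == "tilt":
                res = sterol_tilt(traj, topology, params.get("species", "CHOL"))
                df = pd.DataFrame(
                    {
                        "angle_deg": res.bin_centers_deg,
                        "density_per_deg": res.density_per_deg,
                    }
                )
                _write_tsv(out_dir / "tilt.tsv", df, provenance)
                summary["analyses"]["tilt"] = {
                    "species": res.species,
                    "mean_tilt_deg": res.mean_tilt_deg,
                    "se_deg": res.se_deg,
                }
            elif kind == "segregation":
                np_params = NeighborParams(
                    cutoff_nm=params.get("cutoff_nm", 1.0),
                    member_species=params.get("member_species", "DPPC"),
                )
                res = segregation_series(
                    traj,
                    topology,
                    center_species=params.get("center", "DPPC"),
                    params=np_params,
                    tail_fraction=params.get("tail_fraction", 0.25),
                )
                df = pd.DataFrame({"time_ns": res.times_ns, "f": res.f_t})
                _write_tsv(out_dir / "segregation.tsv", df, provenance)
                summary["analyses"]["segregation"] = {
                    "center": res.center_species,
                    "tail_mean": res.tail_mean,
                    "tail_se": res.tail_se,
                    "ref_segregated": res.ref_segregated,
                    "ref_random": res.ref_random,
                    "excluded_centers": res.excluded_centers,
                }
            elif kind == "hillfit":
                path = params.get("data", config.isotherm)
                if path is None:
                    raise ValueError("hillfit needs an isotherm CSV path")
                fit = fit_hill(read_isotherm(path))
                summary["analyses"]["hillfit"] = {
                    "n_hill": fit.n_hill,
                    "k_half": fit.k_half,
                    "b_max": fit.b_max,
                    "se_n": fit.se_n,
                    "se_k": fit.se_k,
                    "se_b": fit.se_b,
                    "r_squared": fit.r_squared,
                    "converged": fit.converged,
                    "summary": fit.summary() if fit.converged else fit.message,
                }
        except Exception:
            log.exception("analysis %s failed", kind)
            (out_dir / "summary.json").write_text(
                json.dumps(summary, indent=2, default=_jsonable)
            )
            raise

    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=_jsonable)
    )
    return summary


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
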