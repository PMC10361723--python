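"""End-to-end pipeline: simulate -> kinematics -> regression -> weight fit.

A single YAML config with per-stage blocks drives the run; all outputs
land in a run directory together with a manifest recording the config,
seeds and row counts, so a rerun with the same config is reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .kinematics import geometries_from_metadata, track_summaries, tracks_from_frame
from .regression import build_design, fit_mixed_model, report_effects
from .symmetry import fit_weights, paper_series
from .synthetic import GroupEffects, SyntheticFlowConfig, generate_tracks

log = logging.getLogger(__name__)

_KNOWN_KEYS = {"seed", "simulate", "regression", "weights", "stages"}


def _validate(config: dict) -> None:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the enabled stages and return the manifest.

    ``config`` keys: ``seed``; ``stages`` (list of stage names to run,
    default all); ``simulate`` (SyntheticFlowConfig overrides plus
    ``groups``: name -> effect-offset dict and ``n_embryos``);
    ``regression`` (``design``, ``time_origin``); ``weights``
    (``n_starts``, ``n_virtual``, ``restrict``).
    """
    _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    enabled = config.get("stages", ["simulate", "kinematics", "regress", "fit-weights"])
    manifest: dict = {"version": __version__, "seed": seed, "stages": {}}

    obs = None
    if "simulate" in enabled:
        sim = dict(config.get("simulate", {}))
        groups = {
            name: GroupEffects(**offs)
            for name, offs in sim.pop("groups", {"Sham": {}}).items()
        }
        n_embryos = sim.pop("n_embryos", 12)
        cfg = SyntheticFlowConfig(seed=seed, **sim)
        tracks, meta, _ = generate_tracks(cfg, groups, n_embryos=n_embryos)
        tracks.to_csv(out / "tracks.csv", index=False)
        meta.to_csv(out / "meta.csv", index=False)
        manifest["stages"]["simulate"] = {
            "n_embryos": n_embryos, "n_track_rows": len(tracks)
        }
        if "kinematics" in enabled:
            geoms = geometries_from_metadata(meta)
            group_of = dict(zip(meta["embryo_id"], meta["group"]))
            obs = track_summaries(tracks_from_frame(tracks), geoms, group_of)
            obs.to_csv(out / "observations.csv", index=False)
            manifest["stages"]["kinematics"] = {"n_obs": len(obs)}

    if "regress" in enabled and obs is not None and obs["group"].nunique() >= 2:
        reg = config.get("regression", {})
        frame = build_design(
            obs, design=reg.get("design", "suction"),
            time_origin=reg.get("time_origin", 6.0),
        )
        fit = fit_mixed_model(frame)
        report_effects(fit).to_csv(out / "coefficients.csv", index=False)
        manifest["stages"]["regress"] = {
            "n_obs": fit.n_obs, "n_embryos": fit.n_embryos,
            "loglik": fit.loglik, "downgraded": fit.downgraded,
        }

    if "fit-weights" in enabled:
        wcfg = config.get("weights", {})
        series = paper_series()
        result = fit_weights(
            series,
            restriction=frozenset(wcfg.get("restrict", ())),
            n_starts=int(wcfg.get("n_starts", 50)),
            n_virtual=int(wcfg.get("n_virtual", 1000)),
            seed=seed,
        )
        payload = {
            "weights": result.weights.W,
            "log_likelihood": result.log_likelihood,
            "predicted_defect_rate": result.predicted_defect_rate,
            "contributions": result.contributions,
        }
        (out / "weight_fit.json").write_text(json.dumps(payload, indent=2))
        manifest["stages"]["fit-weights"] = {
            "log_likelihood": result.log_likelihood,
            "n_starts": int(wcfg.get("n_starts", 50)),
        }

    manifest["config"] = config
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def load_flow_observations(path: str | Path) -> pd.DataFrame:
    """Load a flow-observation table (e.g. a published source-data file).

    Expects columns aav, lr, pa, stage, group, embryo_id (case-insensitive,
    AAV/LR/PA/Time aliases accepted).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: the published source-data file must be supplied"
        )
    df = pd.read_csv(path)
    alias = {"AAV": "aav", "LR": "lr", "PA": "pa", "Time": "stage",
             "Group": "group", "EmbryoID": "embryo_id", "Intervention": "group"}
    df = df.rename(columns=alias)
    required = {"aav", "lr", "pa", "stage", "group", "embryo_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    return df
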