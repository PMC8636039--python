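"""Run configuration: YAML blocks per stage, seeded, with a run manifest."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "write_manifest"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "out",
    "log_level": "INFO",
    "nmm": {
        "dt": 0.001,
        "burn_in_seconds": 2.0,
        "t_total_seconds": 10.0,
        "noise_mean": 60.0,
        "noise_variance": 100.0,
        "fast_inhibition": "state",
    },
    "forward": {
        "radii": [0.087, 0.092, 0.100],
        "conductivities": [0.33, 0.0042, 0.33],
        "subdivisions": 3,
        "reference": "CPz",
    },
    "gan": {
        "iterations": 200,
        "d_learning_rate": 0.0008,
        "g_learning_rate": 0.0004,
        "clip_value": 1.0,
        "decay": 1.0e-8,
        "batch_size": 64,
        "gen_batch": 8,
        "window_len": 100,
        "d_interval": 1,
        "g_interval": 1,
        "sim_negatives": 0.5,
    },
    "pipeline": {
        "band": [2.0, 55.0],
        "filter_order": 4,
        "window_len": 100,
        "csp_pairs": 3,
        "n_folds": 5,
        "mix_ratio": 1.0,
    },
    "synthetic": {
        "n_subjects": 2,
        "sessions": 4,
        "trials_per_session": 6,
        "task_seconds": 4.0,
        "snr_db": 10.0,
        "jitter": 0.1,
        "amplitude_uv": 10.0,
    },
}


def _merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Defaults overlaid with an optional YAML file."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ValueError("config file must contain a mapping")
        cfg = _merge(cfg, user)
    return json.loads(json.dumps(cfg))  # deep copy, plain types


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def write_manifest(out_dir, cfg: dict, seed: int, artifacts: dict) -> Path:
    """Machine-readable record sufficient to reproduce the run."""
    import mebci

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "version": mebci.__version__,
        "python": platform.python_version(),
        "artifacts": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
            for name, p in artifacts.items()
            if Path(p).exists()
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
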