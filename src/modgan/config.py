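"""Pipeline configuration, validation and orchestrated runs.

A single YAML file drives the simulate -> train -> reconstruct -> evaluate
pipeline; all randomness flows from one master seed through named
substreams.  Each stage records content hashes of its inputs in the run
manifest, so reruns with unchanged inputs are skipped ("cached").
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigError
from .losses import LossWeights
from .training import AugmentConfig, TrainConfig

__all__ = ["RunManifest", "validate_config", "load_config", "run_pipeline",
           "DEFAULT_CONFIG"]

_STAGES = ("simulate", "train", "reconstruct", "evaluate")
_AUG_NAMES = {"flip", "rotation", "warp", "intensity", "blur", "crop"}
_WEIGHT_KEYS = {"w1", "w2", "w3", "w4", "w5"}

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "image_size": 64,
    "stages": list(_STAGES),
    "simulate": {"n_train": 20, "n_test": 4, "n_angles": 120,
                 "kinds": ["ellipses", "polygons", "texture", "fractal"],
                 "noise_counts": None, "motion_angles": None},
    "train": {
        "module1": {"steps": 100, "width": 0.125, "augmentation": []},
        "module2": {"steps": 100, "width": 0.125, "style_embedding": True,
                    "augmentation": []},
    },
    "reconstruct": {"baselines": ["fbp", "osem"]},
    "evaluate": {},
}


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    seed: int
    version: str = __version__
    started: float = field(default_factory=time.time)
    finished: float | None = None
    stages: dict = field(default_factory=dict)  # name -> {status, hash, outputs}

    def to_json(self, path=None):
        text = json.dumps(asdict(self), indent=2, default=str)
        if path is None:
            return text
        Path(path).write_text(text)


def load_config(path) -> dict:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in raw.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            for k2, v2 in value.items():
                if isinstance(v2, dict) and isinstance(merged[key].get(k2), dict):
                    merged[key][k2].update(v2)
                else:
                    merged[key][k2] = v2
        else:
            merged[key] = value
    return merged


def validate_config(path_or_dict) -> list[str]:
    """Validate a pipeline config; returns a list of diagnostics (empty iff
    runnable).  Each diagnostic names the key, the offending value and the
    violated constraint."""
    try:
        cfg = (load_config(path_or_dict) if not isinstance(path_or_dict, dict)
               else path_or_dict)
    except (OSError, yaml.YAMLError, ConfigError) as exc:
        return [f"config: unreadable ({exc})"]
    diags: list[str] = []
    seed = cfg.get("seed")
    if not isinstance(seed, int) or seed < 0:
        diags.append(f"seed: {seed!r} must be a non-negative integer")
    size = cfg.get("image_size")
    if not isinstance(size, int) or size < 16 or size & (size - 1):
        diags.append(f"image_size: {size!r} must be a power of two >= 16")
    for stage in cfg.get("stages", []):
        if stage not in _STAGES:
            diags.append(f"stages: unknown stage {stage!r}")
    sim = cfg.get("simulate", {})
    for key in ("n_train", "n_test", "n_angles"):
        val = sim.get(key)
        if not isinstance(val, int) or val < 1:
            diags.append(f"simulate.{key}: {val!r} must be a positive integer")
    for module in ("module1", "module2"):
        mcfg = cfg.get("train", {}).get(module, {})
        steps = mcfg.get("steps")
        if not isinstance(steps, int) or steps < 1:
            diags.append(f"train.{module}.steps: {steps!r} must be >= 1")
        width = mcfg.get("width", 0.125)
        if not isinstance(width, (int, float)) or width <= 0:
            diags.append(f"train.{module}.width: {width!r} must be positive")
        for name in mcfg.get("augmentation", []):
            if name not in _AUG_NAMES:
                diags.append(
                    f"train.{module}.augmentation: unknown transform {name!r}"
                )
        for key, val in mcfg.get("loss_weights", {}).items():
            if key not in _WEIGHT_KEYS:
                diags.append(f"train.{module}.loss_weights: unknown key {key!r}")
            elif not isinstance(val, (int, float)) or val < 0:
                diags.append(
                    f"train.{module}.loss_weights.{key}: {val!r} must be >= 0"
                )
    return diags


def _train_config(cfg: dict, module_cfg: dict, seed: int) -> TrainConfig:
    aug_names = set(module_cfg.get("augmentation", []))
    aug = AugmentConfig(**{n: n in aug_names for n in _AUG_NAMES})
    weights = LossWeights(**module_cfg.get("loss_weights", {}))
    return TrainConfig(
        epochs=10**9,  # bounded by max_steps
        max_steps=module_cfg["steps"],
        seed=seed,
        image_size=cfg["image_size"],
        width=module_cfg.get("width", 0.125),
        loss_weights=weights,
        augmentation=aug,
        style_embedding=module_cfg.get("style_embedding", True),
    )


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config_path, out_dir, seed: int | None = None) -> RunManifest:
    """Execute the configured stages in order, skipping stages whose inputs
    are unchanged since the previous manifest in ``out_dir``."""
    diags = validate_config(config_path)
    if diags:
        raise ConfigError("invalid config: " + "; ".join(diags))
    cfg = load_config(config_path)
    if seed is not None:
        cfg["seed"] = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    previous: dict = {}
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text()).get("stages", {})
    manifest = RunManifest(config=cfg, seed=cfg["seed"])
    ss = np.random.SeedSequence(cfg["seed"])
    sub = {name: int(child.generate_state(1)[0] % (2**31))
           for name, child in zip(_STAGES, ss.spawn(len(_STAGES)))}

    from . import io as mio
    from .classical import OsemConfig, fbp, osem
    from .evaluation import MetricsReport, compare_images
    from .phantoms import make_training_set
    from .projection import MotionSpec, add_poisson_noise, simulate_motion_sinogram
    from .training import (make_module2_standin_dataset, reconstruct_modular,
                           train_module1, train_module2)

    train_h5, test_h5 = out / "train.h5", out / "test.h5"
    m1_ckpt, m2_ckpt = out / "module1", out / "module2"
    recon_dir = out / "recon"
    stage_inputs = {
        "simulate": [],
        "train": [train_h5],
        "reconstruct": [test_h5, m1_ckpt.with_suffix(".npz")],
        "evaluate": [test_h5],
    }

    def stage_hash(name: str) -> str:
        files = [
            _hash_file(p) for p in stage_inputs[name] if p.exists()
        ]
        return _hash_obj([cfg.get(name, {}), cfg["image_size"], sub[name], files])

    models: dict = {}
    for name in cfg["stages"]:
        h = stage_hash(name)
        prev = previous.get(name, {})
        outputs_exist = all(
            Path(p).exists() for p in prev.get("outputs", [])
        ) if prev.get("outputs") else False
        if prev.get("hash") == h and outputs_exist:
            manifest.stages[name] = {**prev, "status": "cached"}
            continue
        outputs: list[str] = []
        if name == "simulate":
            sim = cfg["simulate"]
            pairs = make_training_set(
                sim["n_train"], kinds=tuple(sim["kinds"]), seed=sub[name],
                image_size=cfg["image_size"], n_angles=sim["n_angles"],
            )
            test_pairs = make_training_set(
                sim["n_test"], kinds=tuple(sim["kinds"]), seed=sub[name] + 1,
                image_size=cfg["image_size"], n_angles=sim["n_angles"],
            )
            for tp in test_pairs:
                sino = tp.sinogram
                if sim.get("motion_angles"):
                    motion = MotionSpec(tuple(sim["motion_angles"]))
                    sino = simulate_motion_sinogram(
                        tp.target.denormalize(), motion, sino.angles_deg
                    )
                if sim.get("noise_counts"):
                    sino = add_poisson_noise(sino, float(sim["noise_counts"]),
                                             seed=sub[name])
                tp.sinogram = sino
            mio.save_training_set_h5(pairs, train_h5, seed=sub[name], params=sim)
            mio.save_training_set_h5(test_pairs, test_h5, seed=sub[name] + 1,
                                     params=sim)
            outputs = [str(train_h5), str(test_h5)]
        elif name == "train":
            pairs = mio.load_training_set_h5(train_h5)
            tc1 = _train_config(cfg, cfg["train"]["module1"], sub[name])
            gen1, hist1 = train_module1(pairs, tc1)
            mio.save_checkpoint(gen1, m1_ckpt, {"module": 1, "seed": sub[name],
                                                "steps": len(hist1)})
            m2_data = make_module2_standin_dataset(pairs, seed=sub[name])
            tc2 = _train_config(cfg, cfg["train"]["module2"], sub[name] + 1)
            gen2, mapping, hist2 = train_module2(m2_data, tc2)
            mio.save_checkpoint(gen2, m2_ckpt, {"module": 2, "seed": sub[name]})
            if mapping is not None:
                mio.save_checkpoint(mapping, out / "mapping", {"module": 2})
            models.update(gen1=gen1, gen2=gen2, mapping=mapping,
                          tc1=tc1, tc2=tc2)
            (out / "train_history.json").write_text(json.dumps(
                {"module1": hist1.records, "module2": hist2.records}, default=float
            ))
            outputs = [str(m1_ckpt.with_suffix(".npz")),
                       str(m2_ckpt.with_suffix(".npz")),
                       str(out / "train_history.json")]
        elif name == "reconstruct":
            test_pairs = mio.load_training_set_h5(test_h5)
            if "gen1" not in models:
                from .nn import StyleEnhancer, UNetGenerator

                tc1 = _train_config(cfg, cfg["train"]["module1"], sub["train"])
                gen1 = UNetGenerator(cfg["image_size"], width=tc1.width)
                mio.load_checkpoint(gen1, m1_ckpt)
                tc2 = _train_config(cfg, cfg["train"]["module2"], sub["train"] + 1)
                gen2 = StyleEnhancer(cfg["image_size"], width=tc2.width)
                mio.load_checkpoint(gen2, m2_ckpt)
                models.update(gen1=gen1, gen2=gen2, mapping=None)
            recon_dir.mkdir(exist_ok=True)
            for i, tp in enumerate(test_pairs):
                rec = reconstruct_modular(
                    tp.sinogram, models["gen1"], models["gen2"],
                    models.get("mapping"), seed=sub[name] + i,
                    norm=(tp.target.vmin, tp.target.vmax),
                )
                mio.save_phantom_nifti(rec, recon_dir / f"modular_{i}.nii")
                for method in cfg["reconstruct"].get("baselines", []):
                    base = (fbp(tp.sinogram) if method == "fbp"
                            else osem(tp.sinogram, OsemConfig(4, 5)))
                    mio.save_phantom_nifti(base, recon_dir / f"{method}_{i}.nii")
            outputs = [str(recon_dir)]
        elif name == "evaluate":
            test_pairs = mio.load_training_set_h5(test_h5)
            report = MetricsReport()
            for i, tp in enumerate(test_pairs):
                truth = tp.target.denormalize()
                for method in ["modular"] + cfg["reconstruct"].get("baselines", []):
                    path = recon_dir / f"{method}_{i}.nii"
                    if not path.exists():
                        continue
                    pred = mio.load_phantom_nifti(path).values
                    row = {"image": i, "method": method}
                    row.update(compare_images(pred, truth))
                    report.per_image.append(row)
            report.to_csv(out / "metrics.csv")
            report.to_json(out / "metrics.json")
            outputs = [str(out / "metrics.csv"), str(out / "metrics.json")]
        manifest.stages[name] = {"status": "ran", "hash": h, "outputs": outputs}
    manifest.finished = time.time()
    manifest.to_json(manifest_path)
    return manifest
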