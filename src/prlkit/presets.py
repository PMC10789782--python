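"""Bundled experiment presets.

One YAML file per emulated experiment design (group sizes, task variant,
between vs cross-over, generative group-level parameters). Group means are
written on the natural scale for readability and converted onto the
unconstrained scale (where the population normals live) when specs are
built; between-subject SDs are given directly on the unconstrained scale.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .inference import to_unconstrained
from .models import MODEL_PARAM_NAMES, ModelId
from .synth import GroupSpec
from .tasks import HumanTaskConfig, RatTaskConfig

__all__ = ["available_presets", "load_preset", "build_from_preset"]


def _preset_dir():
    return resources.files("prlkit") / "presets"


def available_presets() -> list[str]:
    return sorted(p.name[:-5] for p in _preset_dir().iterdir()
                  if p.name.endswith(".yaml"))


def load_preset(name_or_path: str) -> dict:
    """Load a bundled preset by name, or any YAML config by path."""
    p = Path(name_or_path)
    if p.exists():
        text = p.read_text()
    else:
        res = _preset_dir() / f"{name_or_path}.yaml"
        try:
            text = res.read_text()
        except FileNotFoundError:
            raise KeyError(f"unknown preset {name_or_path!r}; available: "
                           f"{available_presets()}") from None
    return yaml.safe_load(text)


def build_from_preset(preset: dict):
    """(GroupSpec list, task config) from a preset mapping."""
    task_kind = preset["task"]
    cfg = preset.get("task_config", {})
    if task_kind == "human":
        task = HumanTaskConfig(**cfg)
    elif task_kind == "rat":
        task = RatTaskConfig(**cfg)
    else:
        raise ValueError(f"unknown task kind {task_kind!r}")
    model = ModelId(preset["model"])
    names = MODEL_PARAM_NAMES[model]
    design = preset.get("design", "between")
    specs = []
    for grp in preset["groups"]:
        means = {nm: float(to_unconstrained(nm, grp["means_natural"][nm]))
                 for nm in names}
        sds = {nm: float(grp["sds_unconstrained"][nm]) for nm in names}
        specs.append(GroupSpec(label=grp["label"], n_subjects=int(grp["n_subjects"]),
                               model=model, means=means, sds=sds, design=design))
    return specs, task
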