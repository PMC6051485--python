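"""Application profiles and YAML config round-tripping.

Two named profiles carry the grid-searched test-time parameters:

* ``organ2d`` — 2D multi-organ segmentation: lambda 3.0, sigma 0.1,
  t0 0.2, t1 0.7, epsilon 0.2, omega 5.0, inputs resized so the minimum
  side is 96 pixels;
* ``tumor3d`` — 3D tumor segmentation: lambda 10.0, t1 0.6, inputs
  resized so the maximum side is 80 voxels (otherwise identical).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from .crf import CRFParams
from .errors import ConfigurationError
from .finetune import FineTuneConfig
from .uncertainty import UncertaintyParams


@dataclass(frozen=True)
class AppProfile:
    """Everything test-time segmentation needs beyond the checkpoint."""

    name: str
    resize_mode: str
    resize_target: int
    finetune: FineTuneConfig


def _profile(name, resize_mode, resize_target, lam, t1):
    return AppProfile(
        name=name,
        resize_mode=resize_mode,
        resize_target=resize_target,
        finetune=FineTuneConfig(
            crf=CRFParams(lam=lam, sigma=0.1),
            unc=UncertaintyParams(t0=0.2, t1=t1, epsilon=0.2, omega=5.0),
        ),
    )


PROFILES = {
    "organ2d": _profile("organ2d", "2d_min_side", 96, lam=3.0, t1=0.7),
    "tumor3d": _profile("tumor3d", "3d_max_side", 80, lam=10.0, t1=0.6),
}


def get_profile(name: str) -> AppProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown profile {name!r}; available: {sorted(PROFILES)}") from None


def profile_to_yaml(profile: AppProfile) -> str:
    return yaml.safe_dump(asdict(profile), sort_keys=True)


def profile_from_yaml(text: str) -> AppProfile:
    d = yaml.safe_load(text)
    ft = d["finetune"]
    return AppProfile(
        name=d["name"],
        resize_mode=d["resize_mode"],
        resize_target=int(d["resize_target"]),
        finetune=FineTuneConfig(
            rounds=ft["rounds"], lr=ft["lr"], steps=ft["steps"],
            momentum=ft["momentum"],
            crf=CRFParams(**ft["crf"]),
            unc=UncertaintyParams(**ft["unc"]),
            gamma=ft["gamma"],
            recompute_network_uncertainty=ft["recompute_network_uncertainty"],
            seed=ft["seed"],
        ),
    )


def load_profile(path) -> AppProfile:
    with open(path) as fh:
        return profile_from_yaml(fh.read())
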