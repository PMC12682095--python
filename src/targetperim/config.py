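"""YAML configuration for simulated observers and algorithm parameters.

A config file is a mapping with any of the (all optional) sections below;
unspecified keys fall back to package defaults.

.. code-block:: yaml

    normative:
      foveal_db: 33.0          # dB at the fovea
      eccentricity_slope: 0.25 # dB lost per degree of eccentricity
      age_reference: 45.0      # years
      age_slope: 0.06          # dB lost per year past the reference age
    observer:
      age: 45.0
      gh: 0.0                  # true general height, dB
      slope_sd: 1.5            # psychometric spread, dB
      fp_rate: 0.01
      fn_rate: 0.01
      shadows: default         # default | none
      blind_spot:
        centre: [15.0, -1.5]
        horizontal_radius: 2.7
        vertical_radius: 3.5
      defects:                 # optional arcuate defects -> glaucomatous eye
        - bundle_angle_centre: 120.0
          bundle_angle_halfwidth: 15.0
          distance_range: [6.0, 20.0]
          depth: 15.0
    bundle_model:
      kind: jansonius          # jansonius | spiral
    algorithm:
      offset: 5.0              # suprathreshold offset, dB
      grid_spacing: 2.0        # high-density candidate spacing, deg
      max_stage: 6             # operator-stop stage
      min_gap: 5               # presentations between a miss and its retest
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .bundles import BundleModel
from .observer import (
    ArcuateDefectSpec,
    BlindSpotSpec,
    Observer,
    make_glaucoma_field,
    make_healthy_field,
)
from .units import FieldLocation, NormativeModel


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def normative_from_config(cfg: dict) -> NormativeModel:
    return NormativeModel(**cfg.get("normative", {}))


def bundle_model_from_config(cfg: dict, bs_centre: FieldLocation | None = None) -> BundleModel:
    section = dict(cfg.get("bundle_model", {}))
    if bs_centre is not None:
        section["bs_centre"] = FieldLocation(*bs_centre)
    elif "bs_centre" in section:
        section["bs_centre"] = FieldLocation(*section["bs_centre"])
    return BundleModel(**section)


@dataclass(frozen=True)
class AlgorithmParams:
    offset: float = 5.0
    grid_spacing: float = 2.0
    max_stage: int = 6
    min_gap: int = 5


def algorithm_from_config(cfg: dict) -> AlgorithmParams:
    return AlgorithmParams(**cfg.get("algorithm", {}))


def observer_from_config(cfg: dict, seed: int) -> tuple[Observer, dict]:
    """Build a simulated observer; returns it with its ground-truth metadata."""
    section = dict(cfg.get("observer", {}))
    normative = normative_from_config(cfg)
    age = float(section.get("age", 45.0))
    gh = float(section.get("gh", 0.0))
    bs_section = section.get("blind_spot", {})
    centre = FieldLocation(*bs_section.get("centre", (15.0, -1.5)))
    blind_spot = BlindSpotSpec(
        centre=centre,
        horizontal_radius=float(bs_section.get("horizontal_radius", 2.7)),
        vertical_radius=float(bs_section.get("vertical_radius", 3.5)),
    )
    shadows = None if section.get("shadows", "default") == "default" else ()
    field = make_healthy_field(
        normative=normative, age=age, gh=gh, blind_spot=blind_spot, shadows=shadows
    )
    defects = [
        ArcuateDefectSpec(
            bundle_angle_centre=float(d["bundle_angle_centre"]),
            bundle_angle_halfwidth=float(d["bundle_angle_halfwidth"]),
            distance_range=tuple(d["distance_range"]),
            depth=float(d["depth"]),
        )
        for d in section.get("defects", [])
    ]
    if defects:
        field = make_glaucoma_field(
            field, defects, bundle_model_from_config(cfg, centre)
        )
    obs = Observer(
        true_field=field,
        slope_sd=float(section.get("slope_sd", 1.5)),
        fp_rate=float(section.get("fp_rate", 0.01)),
        fn_rate=float(section.get("fn_rate", 0.01)),
        rng_seed=seed,
    )
    meta = {
        "age": age,
        "gh": gh,
        "bs_centre": centre,
        "n_defects": len(defects),
    }
    return obs, meta
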