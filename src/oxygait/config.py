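"""YAML (de)serialization of the pipeline configuration.

One nested document with sections simulation / windowing / selection /
training / preprocessing; a single master seed can be propagated to every
stage.  Round-trips losslessly, and every pipeline run writes a config echo
next to its outputs.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .core import BandDefinition
from .features import WindowingPlan
from .model import TrainingConfig
from .pipeline import PipelineConfig
from .selection import SelectionConfig
from .synthetic import SimulationConfig


def config_to_dict(config: PipelineConfig) -> dict:
    sim = asdict(config.simulation)
    sim["bands"] = [
        {"name": b.name, "low_edge": b.low_edge, "high_edge": b.high_edge}
        for b in config.simulation.bands
    ]
    sim["informative_channels"] = list(config.simulation.informative_channels)
    sim["cycle_duration_range"] = list(config.simulation.cycle_duration_range)
    return {
        "simulation": sim,
        "windowing": asdict(config.windowing),
        "selection": asdict(config.selection),
        "training": asdict(config.training),
        "preprocessing": {
            "lowpass_cutoff": config.lowpass_cutoff,
            "smooth_window_s": config.smooth_window_s,
            "min_cycle_s": config.min_cycle_s,
        },
        "n_adapt_subjects": config.n_adapt_subjects,
    }


def config_from_dict(doc: dict) -> PipelineConfig:
    sim = dict(doc.get("simulation", {}))
    if "bands" in sim:
        sim["bands"] = tuple(
            BandDefinition(b["name"], b["low_edge"], b["high_edge"]) for b in sim["bands"]
        )
    if "informative_channels" in sim:
        sim["informative_channels"] = tuple(sim["informative_channels"])
    if "cycle_duration_range" in sim:
        sim["cycle_duration_range"] = tuple(sim["cycle_duration_range"])
    pp = doc.get("preprocessing", {})
    kwargs = {}
    for key in ("lowpass_cutoff", "smooth_window_s", "min_cycle_s"):
        if key in pp:
            kwargs[key] = pp[key]
    if "n_adapt_subjects" in doc:
        kwargs["n_adapt_subjects"] = doc["n_adapt_subjects"]
    return PipelineConfig(
        simulation=SimulationConfig(**sim),
        windowing=WindowingPlan(**doc.get("windowing", {})),
        selection=SelectionConfig(**doc.get("selection", {})),
        training=TrainingConfig(**doc.get("training", {})),
        **kwargs,
    )


def load_config(path: str | Path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(doc)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))
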