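"""YAML run configuration for the evolution pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evolution import RoundConfig
from .landscape import DEFAULT_ANALYTES, Anchor, Landscape, NoiseModel
from .sequences import KNOWN_SENSORS, SensorSequence, validate_sequence


@dataclass
class RunConfig:
    """Everything a pipeline run needs: start sequence, landscape, noise, rounds."""

    start: SensorSequence
    landscape: Landscape
    noise: NoiseModel
    rounds: RoundConfig
    n_rounds: int = 3
    output_dir: Path = Path("dnasensor_out")


def _landscape_from_dict(d: dict) -> Landscape:
    anchors = d.pop("anchors", None)
    kwargs = dict(d)
    if anchors is not None:
        kwargs["anchors"] = tuple(
            Anchor(
                bases=a["sequence"],
                analyte=a["analyte"],
                target=float(a["target"]),
                kd_um=a.get("kd_um"),
            )
            for a in anchors
        )
    if "analytes" in kwargs:
        kwargs["analytes"] = tuple(kwargs["analytes"])
    return Landscape(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML config file into a :class:`RunConfig`.

    The ``sequences.start`` entry may be a raw 30-mer or the name of a known
    sensor (``original``, ``N2-1``, ``L1-14``).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    seq_section = raw.get("sequences", {})
    start_spec = seq_section.get("start", "original")
    bases = KNOWN_SENSORS.get(start_spec, start_spec)
    start = validate_sequence(bases, name=start_spec if start_spec in KNOWN_SENSORS else "start")

    landscape = _landscape_from_dict(dict(raw.get("landscape", {})))
    noise = NoiseModel(**raw.get("noise", {}))
    rounds = RoundConfig(**raw.get("rounds", {}))
    return RunConfig(
        start=start,
        landscape=landscape,
        noise=noise,
        rounds=rounds,
        n_rounds=int(raw.get("n_rounds", 3)),
        output_dir=Path(raw.get("output", {}).get("dir", "dnasensor_out")),
    )


def default_config_yaml() -> str:
    """A template config users can edit."""
    return yaml.safe_dump(
        {
            "sequences": {"start": "original"},
            "landscape": {"seed": 0, "analytes": list(DEFAULT_ANALYTES),
                          "epistasis_density": 0.0},
            "noise": {"relative_sd": 0.05, "replicate_count": 3, "seed": 0},
            "rounds": {"objective": "sensitivity", "k_mut": 3, "k_top": 20,
                       "n_train": 500, "surrogate": "ensemble", "seed": 0},
            "n_rounds": 3,
            "output": {"dir": "dnasensor_out"},
        },
        sort_keys=False,
    )
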