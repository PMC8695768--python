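"""Plain-text (key: value) serialization of stand scenarios.

A scenario file holds one block per stand, blocks separated by blank lines,
``#`` starting a comment.  All ``StandScenario`` fields are accepted;
omitted fields take the dataclass defaults.  The shipped
``data/paper_presets.cfg`` holds the five plantation-stand presets.
"""

from __future__ import annotations

from dataclasses import fields
from importlib import resources
from pathlib import Path

from .simulate import StandScenario, paper_presets

__all__ = ["load_scenarios", "dump_scenarios", "preset_scenarios"]

_FIELD_TYPES = {f.name: f.type for f in fields(StandScenario)}
_INT_FIELDS = {"planting_year", "n_trees", "sampling_interval_days",
               "season_start_doy", "season_end_doy"}
_STR_FIELDS = {"stand_id", "noise_model"}


def _parse_value(key: str, raw: str):
    if key not in _FIELD_TYPES:
        raise KeyError(f"unknown scenario field {key!r}")
    if key in _STR_FIELDS:
        return raw
    if key in _INT_FIELDS:
        return int(raw)
    return float(raw)


def load_scenarios(path: str | Path) -> list[StandScenario]:
    """Parse a scenario config file into a list of StandScenario."""
    text = Path(path).read_text(encoding="utf-8")
    return _parse_blocks(text)


def _parse_blocks(text: str) -> list[StandScenario]:
    scenarios = []
    block: dict = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            if block:
                scenarios.append(StandScenario(**block))
                block = {}
            continue
        if ":" not in line:
            raise ValueError(f"line {lineno}: expected 'key: value', got {line!r}")
        key, raw = (part.strip() for part in line.split(":", 1))
        block[key] = _parse_value(key, raw)
    if block:
        scenarios.append(StandScenario(**block))
    if not scenarios:
        raise ValueError("no scenario blocks found")
    return scenarios


def dump_scenarios(scenarios: list[StandScenario], path: str | Path) -> None:
    """Write scenarios back out in the same block format."""
    chunks = []
    for sc in scenarios:
        lines = [f"{f.name}: {getattr(sc, f.name)}" for f in fields(StandScenario)]
        chunks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(chunks) + "\n", encoding="utf-8")


def preset_scenarios(name: str = "paper") -> list[StandScenario]:
    """Named scenario presets.

    ``"paper"`` — the five-stand campaign emulation (from the packaged
    config file when present, else built in code); ``"paper2012"`` ...
    ``"paper1969"`` — a single stand of it.
    """
    presets = {f"paper{sc.planting_year}": sc for sc in _packaged_presets()}
    if name == "paper":
        return list(_packaged_presets())
    if name in presets:
        return [presets[name]]
    raise KeyError(f"unknown preset {name!r}; known: paper, {', '.join(presets)}")


def _packaged_presets() -> list[StandScenario]:
    try:
        ref = resources.files("xylokin").joinpath("data/paper_presets.cfg")
        return _parse_blocks(ref.read_text(encoding="utf-8"))
    except (FileNotFoundError, ModuleNotFoundError):
        return paper_presets()
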