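"""Scenario preset registry.

Presets are shipped as TOML data files next to this module so users can copy
and edit them; :func:`load_preset` returns the raw mapping and
:func:`preset_names` lists what is available.
"""

from __future__ import annotations

import tomllib
from importlib import resources
from typing import List

from ..errors import ConfigurationError

__all__ = ["preset_names", "load_preset"]


def preset_names() -> List[str]:
    """Sorted names of the shipped scenario presets."""
    names = []
    for entry in resources.files(__package__).iterdir():
        if entry.name.endswith(".toml"):
            names.append(entry.name[: -len(".toml")])
    return sorted(names)


def load_preset(name: str) -> dict:
    """Load a preset's raw config mapping by name."""
    path = resources.files(__package__) / f"{name}.toml"
    if not path.is_file():
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {preset_names()}"
        )
    with path.open("rb") as fh:
        return tomllib.load(fh)
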