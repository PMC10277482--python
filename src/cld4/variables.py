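"""Variable registry: the five-category classification map.

Every variable recorded during a campaign belongs to exactly one of the
categories used throughout the pipeline: process_parameters, growth,
productivity, product_quality or metadata.  The registry (including unit,
source instrument and synonyms) ships as an editable YAML file so that
real instrument exports can be mapped without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

CATEGORIES = (
    "process_parameters",
    "growth",
    "productivity",
    "product_quality",
    "metadata",
)


class UnclassifiedVariableError(KeyError):
    """Raised when a variable name cannot be mapped to a category."""

    def __init__(self, name: str):
        super().__init__(f"unclassified variable: {name!r}")
        self.variable = name


@dataclass(frozen=True)
class VariableInfo:
    name: str
    category: str
    unit: str
    source: str
    cumulative: bool = False


@lru_cache(maxsize=None)
def _registry(path: str | None = None) -> dict[str, VariableInfo]:
    if path is None:
        text = resources.files("cld4.data").joinpath("variables.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    reg: dict[str, VariableInfo] = {}
    for category, variables in raw["categories"].items():
        if category not in CATEGORIES:
            raise ValueError(f"unknown category in registry: {category}")
        for name, meta in variables.items():
            meta = meta or {}
            info = VariableInfo(
                name=name,
                category=category,
                unit=meta.get("unit", ""),
                source=meta.get("source", ""),
                cumulative=bool(meta.get("cumulative", False)),
            )
            reg[name.lower()] = info
            for syn in meta.get("synonyms", []) or []:
                reg[str(syn).lower()] = info
    return reg


def variable_info(name: str, registry_path: str | None = None) -> VariableInfo:
    """Canonical info for a variable name (case-insensitive, synonyms ok)."""
    reg = _registry(registry_path)
    key = name.strip().lower()
    if key not in reg:
        raise UnclassifiedVariableError(name)
    return reg[key]


def classify_variable(name: str, registry_path: str | None = None) -> str:
    """Map a variable name to one of the five data categories."""
    return variable_info(name, registry_path).category


def canonical_name(name: str, registry_path: str | None = None) -> str:
    return variable_info(name, registry_path).name


def unit_of(name: str) -> str:
    return variable_info(name).unit


def source_of(name: str) -> str:
    return variable_info(name).source
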