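"""Service catalogue: the list of service categories and items an institution
is expected to deliver, split by service class.

The default catalogue mirrors the study design of the source survey: an
essential public health service package (NEPHSP) of 13 categories / 37 items,
and 5 primary-medical categories carrying 71 placeholder items (only
category-level granularity is used downstream for the medical side).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

NEPHSP = "nephsp"
PRIMARY_MEDICAL = "primary_medical"
SERVICE_CLASSES = (PRIMARY_MEDICAL, NEPHSP)


@dataclass(frozen=True)
class CatalogueCategory:
    name: str
    items: tuple[str, ...]


@dataclass(frozen=True)
class CatalogueSpec:
    """Expected categories/items per service class."""

    classes: dict[str, tuple[CatalogueCategory, ...]] = field(default_factory=dict)

    def categories(self, service_class: str) -> tuple[CatalogueCategory, ...]:
        return self.classes.get(service_class, ())

    def category_names(self, service_class: str) -> list[str]:
        return [c.name for c in self.categories(service_class)]

    def n_items(self, service_class: str) -> int:
        return sum(len(c.items) for c in self.categories(service_class))

    def items(self, service_class: str) -> list[tuple[str, str]]:
        """(category, item) pairs for one service class."""
        return [
            (cat.name, item)
            for cat in self.categories(service_class)
            for item in cat.items
        ]


def _expand_category(entry: dict) -> CatalogueCategory:
    name = entry["name"]
    if "items" in entry:
        return CatalogueCategory(name, tuple(entry["items"]))
    n = int(entry["n_placeholder_items"])
    width = len(str(n))
    return CatalogueCategory(
        name, tuple(f"{name} item {i:0{width}d}" for i in range(1, n + 1))
    )


def load_catalogue(path: str | Path | None = None) -> CatalogueSpec:
    """Read a catalogue YAML; with no path, the packaged default catalogue."""
    if path is None:
        text = (
            resources.files("equicost.fixtures").joinpath("catalogue.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    classes = {}
    for service_class, body in raw["service_classes"].items():
        if service_class not in SERVICE_CLASSES:
            raise ValueError(f"unknown service class in catalogue: {service_class!r}")
        classes[service_class] = tuple(
            _expand_category(e) for e in body["categories"]
        )
    return CatalogueSpec(classes)


def default_catalogue() -> CatalogueSpec:
    return load_catalogue(None)
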