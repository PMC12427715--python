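"""Composite quality index (Qi) from min-max-normalized quality attributes.

Each quality attribute x is rescaled to [0, 1] over the whole dataset,
X = (x - x_min) / (x_max - x_min), and reversed (1 - X) for attributes
where larger raw values mean worse quality (browning, color drift,
microbial counts).  Qi is the equal-weight mean of the normalized
attributes, so Qi = 1 is best possible quality and Qi = 0 the worst
observed.  The default attribute panel is the 14 used for stored date
fruits: 7 physicochemical + 7 sensory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HIGHER_IS_BETTER",
    "LOWER_IS_BETTER",
    "DEFAULT_DIRECTIONS",
    "PHYSICOCHEMICAL_ATTRIBUTES",
    "SENSORY_ATTRIBUTES",
    "DEFAULT_ATTRIBUTES",
    "SpecEntry",
    "NormalizationSpec",
    "QiValue",
    "build_normalization_spec",
    "normalize_attribute",
    "compute_qi",
    "qi_table",
]

HIGHER_IS_BETTER = "higher_is_better"
LOWER_IS_BETTER = "lower_is_better"

PHYSICOCHEMICAL_ATTRIBUTES = (
    "moisture_content",
    "aw",
    "tss",
    "bi",
    "delta_e",
    "ph",
    "hardness",
)
SENSORY_ATTRIBUTES = (
    "sensory_texture",
    "sensory_taste",
    "sensory_hardness",
    "sensory_color",
    "sensory_adhesion",
    "sensory_peelability",
    "sensory_overall",
)
DEFAULT_ATTRIBUTES = PHYSICOCHEMICAL_ATTRIBUTES + SENSORY_ATTRIBUTES

# Moisture retention and sensory scores improve quality as they grow;
# browning (bi), color drift (delta_e) and microbial counts worsen it.
# Storage degradation lowers aw, pH and hardness and concentrates TSS,
# so those four default to the matching direction; all are overridable.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "moisture_content": HIGHER_IS_BETTER,
    "aw": HIGHER_IS_BETTER,
    "tss": LOWER_IS_BETTER,
    "bi": LOWER_IS_BETTER,
    "delta_e": LOWER_IS_BETTER,
    "ph": HIGHER_IS_BETTER,
    "hardness": HIGHER_IS_BETTER,
    "tvc_log": LOWER_IS_BETTER,
    "ye_log": LOWER_IS_BETTER,
    **{a: HIGHER_IS_BETTER for a in SENSORY_ATTRIBUTES},
}


class DegenerateRangeError(ValueError):
    """An attribute has zero spread across the dataset."""


class MissingAttributeError(KeyError):
    """A requested attribute is absent from a record or spec."""


@dataclass(frozen=True)
class SpecEntry:
    x_min: float
    x_max: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (HIGHER_IS_BETTER, LOWER_IS_BETTER):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not (self.x_max > self.x_min):
            raise DegenerateRangeError(
                f"x_max ({self.x_max}) must exceed x_min ({self.x_min})"
            )


@dataclass
class NormalizationSpec:
    """Per-attribute min/max/direction, frozen on a training dataset."""

    entries: dict[str, SpecEntry] = field(default_factory=dict)

    def __contains__(self, attribute: str) -> bool:
        return attribute in self.entries

    def __getitem__(self, attribute: str) -> SpecEntry:
        try:
            return self.entries[attribute]
        except KeyError:
            raise MissingAttributeError(attribute) from None

    def to_json(self, path=None) -> str:
        payload = {
            name: {"x_min": e.x_min, "x_max": e.x_max, "direction": e.direction}
            for name, e in self.entries.items()
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "NormalizationSpec":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            entries={
                name: SpecEntry(d["x_min"], d["x_max"], d["direction"])
                for name, d in payload.items()
            }
        )


@dataclass(frozen=True)
class QiValue:
    qi: float
    n_parameters: int
    contributions: dict[str, float]


def build_normalization_spec(
    records: pd.DataFrame | Iterable[Mapping[str, float]],
    directions: Mapping[str, str] | None = None,
    attributes: Iterable[str] | None = None,
) -> NormalizationSpec:
    """Dataset-wide extrema per attribute.

    ``records`` is a DataFrame (or iterable of mappings) with one row per
    sample.  ``directions`` defaults to :data:`DEFAULT_DIRECTIONS`;
    ``attributes`` defaults to every direction-tagged column present.
    Constant attributes raise :class:`DegenerateRangeError`.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    dirs = dict(DEFAULT_DIRECTIONS)
    if directions:
        dirs.update(directions)
    if attributes is None:
        attributes = [c for c in df.columns if c in dirs]
    entries: dict[str, SpecEntry] = {}
    for attr in attributes:
        if attr not in df.columns:
            raise MissingAttributeError(attr)
        if attr not in dirs:
            raise ValueError(f"no direction configured for attribute {attr!r}")
        col = pd.to_numeric(df[attr], errors="raise").to_numpy(dtype=float)
        x_min, x_max = float(np.min(col)), float(np.max(col))
        if not x_max > x_min:
            raise DegenerateRangeError(
                f"attribute {attr!r} is constant at {x_min}; cannot normalize"
            )
        entries[attr] = SpecEntry(x_min, x_max, dirs[attr])
    return NormalizationSpec(entries)


def normalize_attribute(x: float, entry: SpecEntry) -> float:
    """Min-max normalize one value to [0, 1], direction-aware.

    Values outside [x_min, x_max] (possible when a frozen spec is applied
    to new data) are clipped after normalization.
    """
    z = (x - entry.x_min) / (entry.x_max - entry.x_min)
    if entry.direction == LOWER_IS_BETTER:
        z = 1.0 - z
    return float(min(1.0, max(0.0, z)))


def compute_qi(
    record: Mapping[str, float],
    spec: NormalizationSpec,
    attributes: Iterable[str] = DEFAULT_ATTRIBUTES,
) -> QiValue:
    """Equal-weight mean of the normalized attributes of one record."""
    attributes = list(attributes)
    missing = [a for a in attributes if a not in record or a not in spec]
    if missing:
        raise MissingAttributeError(
            f"attributes missing from record or spec: {missing}"
        )
    contrib = {a: normalize_attribute(float(record[a]), spec[a]) for a in attributes}
    n = len(attributes)
    return QiValue(qi=sum(contrib.values()) / n, n_parameters=n, contributions=contrib)


def qi_table(
    df: pd.DataFrame,
    spec: NormalizationSpec,
    attributes: Iterable[str] = DEFAULT_ATTRIBUTES,
) -> pd.Series:
    """Vectorized Qi for every row of a quality-record table."""
    attributes = list(attributes)
    missing = [a for a in attributes if a not in df.columns or a not in spec]
    if missing:
        raise MissingAttributeError(
            f"attributes missing from table or spec: {missing}"
        )
    acc = np.zeros(len(df), dtype=float)
    for a in attributes:
        e = spec[a]
        z = (df[a].to_numpy(dtype=float) - e.x_min) / (e.x_max - e.x_min)
        if e.direction == LOWER_IS_BETTER:
            z = 1.0 - z
        acc += np.clip(z, 0.0, 1.0)
    return pd.Series(acc / len(attributes), index=df.index, name="qi")
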