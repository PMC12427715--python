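"""Color-derivative indices from CIELAB readings.

Colorimeters report date-fruit surface color as CIELAB triplets
(L* lightness, a* red-green, b* yellow-blue).  Four scalar derivatives
summarize them: chroma (saturation), hue angle, the browning index BI
(tracks enzymatic/oxidative browning of the fruit skin), and the total
color difference dE*ab against a reference reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ColorReading",
    "ColorReferencePair",
    "ColorDerivatives",
    "chroma",
    "hue_angle",
    "browning_index",
    "delta_e",
    "derive_color_table",
]


class DegenerateColorError(ValueError):
    """BI denominator is non-positive or hue is undefined."""


@dataclass(frozen=True)
class ColorReading:
    """One CIELAB reading. L* must be non-negative; all fields finite."""

    L_star: float
    a_star: float
    b_star: float

    def __post_init__(self) -> None:
        for name in ("L_star", "a_star", "b_star"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.L_star < 0:
            raise ValueError(f"L_star must be >= 0, got {self.L_star}")


@dataclass(frozen=True)
class ColorReferencePair:
    """A sample reading paired with its reference (time-zero) reading."""

    reference: ColorReading
    sample: ColorReading


@dataclass(frozen=True)
class ColorDerivatives:
    chroma: float
    hue_angle: float
    browning_index: float
    delta_e: float


def chroma(reading: ColorReading) -> float:
    """Chroma (a*^2 + b*^2)^0.5, the radial distance in the a*-b* plane."""
    return math.hypot(reading.a_star, reading.b_star)


def hue_angle(reading: ColorReading) -> float:
    """Hue angle in degrees in [0, 360), via the two-argument arctangent.

    Raises DegenerateColorError for an achromatic reading (a* = b* = 0),
    where hue is undefined.
    """
    if reading.a_star == 0.0 and reading.b_star == 0.0:
        raise DegenerateColorError("hue angle undefined at a* = b* = 0")
    h = math.degrees(math.atan2(reading.b_star, reading.a_star)) % 360.0
    return 0.0 if h >= 360.0 else h  # tiny negative angles round up to 360


def browning_index(reading: ColorReading) -> float:
    """Browning index BI = 100 (x - 0.31) / 0.17 with
    x = (a* + 1.75 L*) / (5.645 L* + a* - 3.012 b*).

    The denominator must be positive; readings outside that domain
    (heavily blue, dark samples) have no meaningful BI and raise.
    """
    den = 5.645 * reading.L_star + reading.a_star - 3.012 * reading.b_star
    if den <= 0.0:
        raise DegenerateColorError(
            f"browning-index denominator must be > 0, got {den:.6g}"
        )
    x = (reading.a_star + 1.75 * reading.L_star) / den
    return 100.0 * (x - 0.31) / 0.17


def delta_e(pair: ColorReferencePair, *, strict_printed: bool = False) -> float:
    """Total color difference dE*ab between reference and sample.

    The standard form is the Euclidean distance
    ((dL)^2 + (da)^2 + (db)^2)^0.5.  ``strict_printed=True`` flips the sign
    of the (db)^2 term for auditing against sources that print the formula
    with a minus there; that variant raises DegenerateColorError when the
    radicand goes negative.
    """
    dl = pair.reference.L_star - pair.sample.L_star
    da = pair.reference.a_star - pair.sample.a_star
    db = pair.reference.b_star - pair.sample.b_star
    if strict_printed:
        rad = dl * dl + da * da - db * db
        if rad < 0.0:
            raise DegenerateColorError(
                f"strict-form radicand is negative ({rad:.6g})"
            )
        return math.sqrt(rad)
    return math.sqrt(dl * dl + da * da + db * db)


def derive_color_table(df: pd.DataFrame, *, strict_printed: bool = False) -> pd.DataFrame:
    """Compute all derivatives for a CSV-style color table.

    Expects columns ``L_star, a_star, b_star``; when ``L0_star, a0_star,
    b0_star`` are also present, ``delta_e`` is added.  Returns a copy with
    ``chroma``, ``hue_angle``, ``browning_index`` (and ``delta_e``) columns.
    """
    out = df.copy()
    readings = [
        ColorReading(L, a, b)
        for L, a, b in zip(df["L_star"], df["a_star"], df["b_star"])
    ]
    out["chroma"] = [chroma(r) for r in readings]
    out["hue_angle"] = [hue_angle(r) for r in readings]
    out["browning_index"] = [browning_index(r) for r in readings]
    if {"L0_star", "a0_star", "b0_star"} <= set(df.columns):
        refs = [
            ColorReading(L, a, b)
            for L, a, b in zip(df["L0_star"], df["a0_star"], df["b0_star"])
        ]
        out["delta_e"] = [
            delta_e(ColorReferencePair(ref, smp), strict_printed=strict_printed)
            for ref, smp in zip(refs, readings)
        ]
    return out


def derivatives(pair: ColorReferencePair) -> ColorDerivatives:
    """All four derivatives for one reference/sample pair."""
    s = pair.sample
    return ColorDerivatives(
        chroma=chroma(s),
        hue_angle=hue_angle(s),
        browning_index=browning_index(s),
        delta_e=delta_e(pair),
    )
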