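"""Synthetic storage-study generator.

Emulates a 12-month storage experiment on two date cultivars (Sukkary,
Khlass): six moisture-content groups (controlled hydration; dry-basis %
means/SDs as published for the two cultivars), three storage
temperatures (25, 5, -18 C), five packaging formats (OCC, CCC, CCSPB,
SSPC, PSSPC) and monthly sampling over months 0-12.

The generator works latent-first: each fruit-month carries a latent
quality state following the cultivar's quadratic decline
Qi(t) = a t^2 - b t + c, scaled by a temperature x packaging severity
multiplier (severity multipliers average to 1 over the full factorial,
so the design-mean trajectory equals the generating quadratic).
Physicochemical attributes, microbial log-counts (linear in time through
month-3/month-12 anchors shaped like the published count tables) and
9-point hedonic sensory scores are then derived from that state plus
noise, and reflectance spectra are synthesized from the attributes via
Gaussian absorption bands (water band near 970 nm, pigment bands in the
VIS, a sugar-linked band near 840 nm) over a baseline, with
multiplicative scatter and additive noise.  Spectra are built in
absorbance and emitted as percent reflectance so the preprocessing
conversion path is exercised.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import REFLECTANCE, SpectraMatrix, write_spectra_csv
from .quality_index import SENSORY_ATTRIBUTES

__all__ = [
    "StudyDesign",
    "TrajectoryParams",
    "SpectralGeneratorParams",
    "Band",
    "MOISTURE_TABLE",
    "generate_design",
    "generate_trajectories",
    "generate_spectra",
    "generate_study",
    "write_dataset",
    "desk_design",
]

CULTIVARS = ("Sukkary", "Khlass")
MOISTURE_GROUPS = ("Control", "A", "B", "C", "D", "E")
TEMPERATURES = (25, 5, -18)
PACKAGINGS = ("OCC", "CCC", "CCSPB", "SSPC", "PSSPC")

# Dry-basis moisture content (%) mean/SD per cultivar and hydration group.
MOISTURE_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "Sukkary": {
        "Control": (4.357, 0.015),
        "A": (10.531, 0.035),
        "B": (13.181, 0.011),
        "C": (16.606, 0.014),
        "D": (20.489, 0.054),
        "E": (27.343, 0.016),
    },
    "Khlass": {
        "Control": (6.235, 0.021),
        "A": (14.877, 0.023),
        "B": (21.781, 0.017),
        "C": (26.807, 0.036),
        "D": (32.062, 0.046),
        "E": (38.697, 0.025),
    },
}

# Quadratic decline coefficients (a, b, c) of Qi = a t^2 - b t + c.
QI_COEFFICIENTS: dict[str, tuple[float, float, float]] = {
    "Sukkary": (-0.0007, 0.0102, 0.9719),
    "Khlass": (0.0021, 0.0521, 0.9554),
}

# Severity multipliers scale the decline b t - a t^2; each family
# averages to 1.0 over the full factorial.
TEMPERATURE_SEVERITY: dict[int, float] = {25: 1.5, 5: 1.0, -18: 0.5}
PACKAGING_SEVERITY: dict[str, float] = {
    "OCC": 1.30,
    "CCC": 1.15,
    "CCSPB": 1.00,
    "SSPC": 0.90,
    "PSSPC": 0.65,
}

# Microbial month-3 / month-12 anchors, log10 CFU/g: (tvc3, tvc12, ye3, ye12).
# Sukkary grid covers all three temperatures in the reference packaging
# (PSSPC); Khlass is anchored at 25 C in CCC with the Sukkary temperature
# deltas transferred to 5 / -18 C.
SUKKARY_MICROBIAL_ANCHORS: dict[str, dict[int, tuple[float, float, float, float]]] = {
    "Control": {-18: (1.1, 1.4, 0.9, 1.2), 5: (2.0, 2.6, 1.8, 2.4), 25: (3.5, 4.3, 3.2, 3.8)},
    "A": {-18: (1.6, 2.2, 1.3, 1.9), 5: (3.0, 4.0, 2.6, 3.5), 25: (4.7, 5.6, 4.2, 5.1)},
    "B": {-18: (1.9, 2.6, 1.6, 2.2), 5: (3.4, 4.4, 3.1, 4.0), 25: (5.2, 6.2, 4.7, 5.6)},
    "C": {-18: (2.3, 3.0, 1.9, 2.6), 5: (4.2, 5.3, 3.8, 4.8), 25: (5.9, 6.9, 5.4, 6.4)},
    "D": {-18: (2.7, 3.7, 2.3, 3.1), 5: (4.8, 6.0, 4.3, 5.4), 25: (6.6, 7.9, 5.9, 7.1)},
    "E": {-18: (3.6, 4.5, 3.0, 3.9), 5: (5.8, 7.0, 5.3, 6.4), 25: (7.6, 8.9, 6.8, 8.1)},
}
KHLASS_MICROBIAL_ANCHORS_25C: dict[str, tuple[float, float, float, float]] = {
    "Control": (1.5, 2.5, 1.2, 2.2),
    "A": (2.0, 3.5, 1.8, 3.2),
    "B": (2.5, 4.0, 2.2, 3.7),
    "C": (3.0, 4.5, 2.7, 4.2),
    "D": (3.5, 5.0, 3.2, 4.7),
    "E": (4.0, 5.5, 3.7, 5.2),
}
# Packaging offsets (log CFU/g) relative to each cultivar's anchor packaging.
PACKAGING_MICROBIAL_OFFSET: dict[str, float] = {
    "PSSPC": 0.0,
    "SSPC": 0.25,
    "CCSPB": 0.5,
    "CCC": 0.8,
    "OCC": 1.1,
}

_TEMP_LABEL = {25: "25", 5: "05", -18: "F18"}


def _temp_label(t: int) -> str:
    return _TEMP_LABEL.get(int(t), str(int(t)).replace("-", "F"))


@dataclass
class StudyDesign:
    """Factorial layout of the storage study."""

    cultivars: tuple[str, ...] = CULTIVARS
    moisture_groups: tuple[str, ...] = MOISTURE_GROUPS
    temperatures: tuple[int, ...] = TEMPERATURES
    packagings: tuple[str, ...] = PACKAGINGS
    months: tuple[int, ...] = tuple(range(13))
    fruits_per_cell: int = 7
    scans_per_fruit: int = 3
    moisture_table: dict = field(default_factory=lambda: {
        c: dict(g) for c, g in MOISTURE_TABLE.items()
    })
    seed: int = 0

    def __post_init__(self) -> None:
        self.cultivars = tuple(self.cultivars)
        self.moisture_groups = tuple(self.moisture_groups)
        self.temperatures = tuple(int(t) for t in self.temperatures)
        self.packagings = tuple(self.packagings)
        self.months = tuple(int(m) for m in self.months)
        if self.fruits_per_cell < 1 or self.scans_per_fruit < 1:
            raise ValueError("counts must be >= 1")
        for cul in self.cultivars:
            for grp in self.moisture_groups:
                mean, sd = self.moisture_table[cul][grp]
                if sd <= 0:
                    raise ValueError(f"moisture SD must be > 0 for {cul}/{grp}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["moisture_table"] = {
            c: {g: list(v) for g, v in grp.items()}
            for c, grp in self.moisture_table.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        d = dict(d)
        d["moisture_table"] = {
            c: {g: tuple(v) for g, v in grp.items()}
            for c, grp in d["moisture_table"].items()
        }
        for key in ("cultivars", "moisture_groups", "packagings"):
            d[key] = tuple(d[key])
        d["temperatures"] = tuple(int(t) for t in d["temperatures"])
        d["months"] = tuple(int(m) for m in d["months"])
        return cls(**d)


def desk_design(seed: int = 0) -> StudyDesign:
    """Reduced desk-scale design: 2 cultivars x 3 moisture groups x
    2 temperatures x 2 packagings x 5 fruits x 13 months."""
    return StudyDesign(
        moisture_groups=("Control", "B", "E"),
        temperatures=(25, -18),
        packagings=("CCC", "PSSPC"),
        fruits_per_cell=5,
        seed=seed,
    )


@dataclass
class TrajectoryParams:
    """Shapes of the per-fruit time courses and their noise scales."""

    qi_coefficients: dict = field(default_factory=lambda: dict(QI_COEFFICIENTS))
    temperature_severity: dict = field(default_factory=lambda: dict(TEMPERATURE_SEVERITY))
    packaging_severity: dict = field(default_factory=lambda: dict(PACKAGING_SEVERITY))
    moisture_loss_frac: float = 0.20  # fraction of initial M lost per year at severity 1
    tss_base: dict = field(default_factory=lambda: {"Sukkary": 62.0, "Khlass": 58.0})
    tss_concentration_gain: float = 0.6  # Brix per % moisture lost
    bi_base: float = 32.0
    bi_gain: float = 180.0  # BI units per unit of Qi decline
    delta_e_gain: float = 80.0
    ph_base: float = 6.1
    ph_gain: float = 1.2
    hardness_base: dict = field(default_factory=lambda: {"Sukkary": 45.0, "Khlass": 30.0})
    hardness_gain: float = 40.0
    mass_base: dict = field(default_factory=lambda: {"Sukkary": 12.0, "Khlass": 10.0})
    mass_loss_frac: float = 0.06
    density_base: float = 1.21
    density_loss: float = 0.06
    aw_intercept: float = 0.35
    aw_per_moisture: float = 0.011
    sukkary_microbial_anchors: dict = field(
        default_factory=lambda: {g: dict(t) for g, t in SUKKARY_MICROBIAL_ANCHORS.items()}
    )
    khlass_microbial_anchors_25c: dict = field(
        default_factory=lambda: dict(KHLASS_MICROBIAL_ANCHORS_25C)
    )
    packaging_microbial_offset: dict = field(
        default_factory=lambda: dict(PACKAGING_MICROBIAL_OFFSET)
    )
    noise: dict = field(
        default_factory=lambda: {
            "qi": 0.015,
            "moisture": 0.15,
            "aw": 0.005,
            "tss": 0.5,
            "bi": 2.0,
            "delta_e": 1.0,
            "ph": 0.03,
            "hardness": 1.0,
            "mass": 0.15,
            "density": 0.005,
            "microbial": 0.1,
            "sensory": 0.5,  # on the 1-9 scale before discretization
        }
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["temperature_severity"] = {str(k): v for k, v in self.temperature_severity.items()}
        d["sukkary_microbial_anchors"] = {
            g: {str(t): list(v) for t, v in temps.items()}
            for g, temps in self.sukkary_microbial_anchors.items()
        }
        d["khlass_microbial_anchors_25c"] = {
            g: list(v) for g, v in self.khlass_microbial_anchors_25c.items()
        }
        d["qi_coefficients"] = {c: list(v) for c, v in self.qi_coefficients.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectoryParams":
        d = dict(d)
        d["temperature_severity"] = {int(k): v for k, v in d["temperature_severity"].items()}
        d["sukkary_microbial_anchors"] = {
            g: {int(t): tuple(v) for t, v in temps.items()}
            for g, temps in d["sukkary_microbial_anchors"].items()
        }
        d["khlass_microbial_anchors_25c"] = {
            g: tuple(v) for g, v in d["khlass_microbial_anchors_25c"].items()
        }
        d["qi_coefficients"] = {c: tuple(v) for c, v in d["qi_coefficients"].items()}
        return cls(**d)

    def zero_noise(self) -> "TrajectoryParams":
        out = TrajectoryParams.from_dict(self.to_dict())
        out.noise = {k: 0.0 for k in out.noise}
        return out


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band whose amplitude is affine (plus an
    optional quadratic term) in a linked quality attribute."""

    center_nm: float
    width_nm: float
    attribute: str
    linear: float
    quadratic: float = 0.0


@dataclass
class SpectralGeneratorParams:
    wavelengths_nm: np.ndarray = field(
        default_factory=lambda: np.arange(411.0, 991.0, 3.0)
    )
    bands: tuple[Band, ...] = (
        Band(970.0, 35.0, "moisture_content", 2.0e-3, 1.0e-4),  # water O-H
        Band(550.0, 60.0, "bi", 1.5e-3, 1.2e-5),  # browning pigments
        Band(450.0, 30.0, "bi", 8.0e-4),
        Band(660.0, 40.0, "delta_e", 2.0e-3),
        Band(840.0, 30.0, "tss", 8.0e-4),  # sugar C-H overtone
    )
    baseline_absorbance: float = 0.45
    baseline_slope_range: tuple[float, float] = (-0.05, 0.05)  # per 1000 nm tilt
    scatter_multiplicative_sd: float = 0.03
    scatter_additive_sd: float = 0.01
    noise_sd: float = 0.002

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        for b in self.bands:
            if not (lo <= b.center_nm <= hi):
                raise ValueError(f"band center {b.center_nm} outside the grid")
            if b.width_nm <= 0:
                raise ValueError("band widths must be > 0")

    def to_dict(self) -> dict:
        return {
            "wavelengths_nm": self.wavelengths_nm.tolist(),
            "bands": [asdict(b) for b in self.bands],
            "baseline_absorbance": self.baseline_absorbance,
            "baseline_slope_range": list(self.baseline_slope_range),
            "scatter_multiplicative_sd": self.scatter_multiplicative_sd,
            "scatter_additive_sd": self.scatter_additive_sd,
            "noise_sd": self.noise_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralGeneratorParams":
        return cls(
            wavelengths_nm=np.asarray(d["wavelengths_nm"], dtype=float),
            bands=tuple(Band(**b) for b in d["bands"]),
            baseline_absorbance=d["baseline_absorbance"],
            baseline_slope_range=tuple(d["baseline_slope_range"]),
            scatter_multiplicative_sd=d["scatter_multiplicative_sd"],
            scatter_additive_sd=d["scatter_additive_sd"],
            noise_sd=d["noise_sd"],
        )

    def zero_noise(self) -> "SpectralGeneratorParams":
        out = SpectralGeneratorParams.from_dict(self.to_dict())
        out.baseline_slope_range = (0.0, 0.0)
        out.scatter_multiplicative_sd = 0.0
        out.scatter_additive_sd = 0.0
        out.noise_sd = 0.0
        return out


# ---------------------------------------------------------------- design

def generate_design(design: StudyDesign) -> pd.DataFrame:
    """Full factorial fruit roster with initial moisture draws.

    One row per fruit: fruit_id, cultivar, moisture_group, temperature_C,
    packaging, moisture_initial (drawn from the cultivar/group mean/SD).
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for cul, grp, temp, pack in product(
        design.cultivars, design.moisture_groups, design.temperatures, design.packagings
    ):
        mean, sd = design.moisture_table[cul][grp]
        m0 = rng.normal(mean, sd, size=design.fruits_per_cell)
        for i in range(design.fruits_per_cell):
            rows.append(
                {
                    "fruit_id": f"{cul[:3].upper()}-{grp}-{_temp_label(temp)}-{pack}-F{i:03d}",
                    "cultivar": cul,
                    "moisture_group": grp,
                    "temperature_C": temp,
                    "packaging": pack,
                    "moisture_initial": float(m0[i]),
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------- trajectories

def _microbial_anchor(
    params: TrajectoryParams, cultivar: str, group: str, temp: int, pack: str
) -> tuple[float, float, float, float]:
    suk = params.sukkary_microbial_anchors[group]
    off = params.packaging_microbial_offset
    if cultivar == "Khlass":
        base = np.array(params.khlass_microbial_anchors_25c[group])
        delta_t = np.array(suk[temp]) - np.array(suk[25])
        shift = off[pack] - off["CCC"]
        vals = base + delta_t + shift
    else:
        vals = np.array(suk[temp]) + off[pack]
    return tuple(np.maximum(vals, 0.0))


def generate_trajectories(
    roster: pd.DataFrame, params: TrajectoryParams | None = None, seed: int = 0
) -> pd.DataFrame:
    """Quality-record time series: one row per fruit and month.

    The latent quality state follows the cultivar quadratic scaled by the
    treatment severity; every attribute is a documented deterministic map
    of that state (plus noise).  Microbial log-counts interpolate
    linearly through the month-3/month-12 anchors.
    """
    params = params or TrajectoryParams()
    rng = np.random.default_rng(seed)

    frames = []
    for month in range(13):
        df = roster.copy()
        df["month"] = month
        frames.append(df)
    rec = pd.concat(frames, ignore_index=True)
    n = len(rec)
    t = rec["month"].to_numpy(dtype=float)

    sev = (
        rec["temperature_C"].map(params.temperature_severity).to_numpy(dtype=float)
        * rec["packaging"].map(params.packaging_severity).to_numpy(dtype=float)
    )
    coef = np.array([params.qi_coefficients[c] for c in rec["cultivar"]])
    a_c, b_c, c_c = coef[:, 0], coef[:, 1], coef[:, 2]
    decline = b_c * t - a_c * t * t  # c - (a t^2 - b t + c)

    noise = params.noise

    def _n(scale_key: str) -> np.ndarray:
        s = noise[scale_key]
        return rng.normal(0.0, s, size=n) if s > 0 else np.zeros(n)

    q = np.clip(c_c - sev * decline + _n("qi"), 0.0, 1.0)

    m0 = rec["moisture_initial"].to_numpy(dtype=float)
    m_clean = m0 * (1.0 - params.moisture_loss_frac * sev * t / 12.0)
    rec["moisture_content"] = m_clean + _n("moisture")
    rec["aw"] = np.clip(
        params.aw_intercept + params.aw_per_moisture * m_clean + _n("aw"), 0.05, 0.95
    )
    tss_base = rec["cultivar"].map(params.tss_base).to_numpy(dtype=float)
    rec["tss"] = tss_base + params.tss_concentration_gain * (m0 - m_clean) + _n("tss")
    rec["bi"] = params.bi_base + params.bi_gain * sev * decline + _n("bi")
    rec["delta_e"] = np.maximum(
        params.delta_e_gain * sev * decline + _n("delta_e"), 0.0
    )
    rec["ph"] = params.ph_base - params.ph_gain * sev * decline + _n("ph")
    h_base = rec["cultivar"].map(params.hardness_base).to_numpy(dtype=float)
    rec["hardness"] = h_base - params.hardness_gain * sev * decline + _n("hardness")
    mass_base = rec["cultivar"].map(params.mass_base).to_numpy(dtype=float)
    rec["mass"] = mass_base * (1.0 - params.mass_loss_frac * sev * t / 12.0) + _n("mass")
    rec["density"] = (
        params.density_base - params.density_loss * sev * t / 12.0 + _n("density")
    )

    anchors = np.array(
        [
            _microbial_anchor(params, cul, grp, int(temp), pack)
            for cul, grp, temp, pack in zip(
                rec["cultivar"], rec["moisture_group"], rec["temperature_C"], rec["packaging"]
            )
        ]
    )
    frac = (t - 3.0) / 9.0  # linear through the month-3 and month-12 anchors
    tvc = anchors[:, 0] + (anchors[:, 1] - anchors[:, 0]) * frac
    ye = anchors[:, 2] + (anchors[:, 3] - anchors[:, 2]) * frac
    rec["tvc_log"] = np.maximum(tvc + _n("microbial"), 0.0)
    rec["ye_log"] = np.maximum(ye + _n("microbial"), 0.0)

    for attr in SENSORY_ATTRIBUTES:
        raw = 1.0 + 8.0 * q + _n("sensory")
        rec[attr] = np.clip(np.rint(raw), 1.0, 9.0)

    rec["qi"] = q  # reference composite quality state
    rec["sample_id"] = [
        f"{fid}-M{int(m):02d}" for fid, m in zip(rec["fruit_id"], rec["month"])
    ]
    cols = [
        "sample_id", "fruit_id", "cultivar", "moisture_group", "temperature_C",
        "packaging", "month", "moisture_initial", "mass", "density",
        "moisture_content", "aw", "tss", "bi", "delta_e", "ph", "hardness",
        "tvc_log", "ye_log", *SENSORY_ATTRIBUTES, "qi",
    ]
    return rec[cols].sort_values("sample_id", ignore_index=True)


# --------------------------------------------------------------- spectra

def generate_spectra(
    records: pd.DataFrame,
    params: SpectralGeneratorParams | None = None,
    seed: int = 0,
    scans_per_fruit: int = 3,
) -> SpectraMatrix:
    """Reflectance spectra for every quality record.

    Each record yields ``scans_per_fruit`` scans sharing its sample_id as
    replicate_group_id.  Absorbance = baseline + sum of Gaussian bands
    with attribute-linked amplitudes; each scan applies a multiplicative/
    additive scatter pair, a random baseline tilt and channel noise, and
    is emitted as R% = 100 * 10^-A.
    """
    params = params or SpectralGeneratorParams()
    rng = np.random.default_rng(seed)
    wl = params.wavelengths_nm
    n = len(records)

    for band in params.bands:
        if band.attribute not in records.columns:
            raise ValueError(
                f"records lack attribute {band.attribute!r} required by a band"
            )

    clean = np.full((n, wl.size), params.baseline_absorbance)
    for band in params.bands:
        x = records[band.attribute].to_numpy(dtype=float)
        amp = band.linear * x + band.quadratic * x * x
        shape = np.exp(-((wl - band.center_nm) ** 2) / (2.0 * band.width_nm**2))
        clean += np.outer(amp, shape)

    n_scans = n * scans_per_fruit
    rep = np.repeat(np.arange(n), scans_per_fruit)
    gamma = (
        rng.normal(1.0, params.scatter_multiplicative_sd, size=n_scans)
        if params.scatter_multiplicative_sd > 0
        else np.ones(n_scans)
    )
    delta = (
        rng.normal(0.0, params.scatter_additive_sd, size=n_scans)
        if params.scatter_additive_sd > 0
        else np.zeros(n_scans)
    )
    lo, hi = params.baseline_slope_range
    tilt = rng.uniform(lo, hi, size=n_scans) if hi > lo else np.full(n_scans, lo)
    ramp = (wl - wl.mean()) / 1000.0

    A = gamma[:, None] * clean[rep] + delta[:, None] + np.outer(tilt, ramp)
    if params.noise_sd > 0:
        A += rng.normal(0.0, params.noise_sd, size=A.shape)
    A = np.maximum(A, 1e-3)
    reflectance = 100.0 * np.power(10.0, -A)

    record_ids = records["sample_id"].astype(str).to_numpy()
    sample_ids = [
        f"{record_ids[i]}-S{k}" for i in range(n) for k in range(scans_per_fruit)
    ]
    meta_cols = [
        c
        for c in ("cultivar", "moisture_group", "temperature_C", "packaging", "month")
        if c in records.columns
    ]
    metadata = records[meta_cols].iloc[rep].reset_index(drop=True)
    return SpectraMatrix(
        sample_ids=sample_ids,
        replicate_group_ids=[record_ids[i] for i in rep],
        wavelengths_nm=wl,
        values=reflectance,
        mode=REFLECTANCE,
        metadata=metadata,
    )


# ------------------------------------------------------------ study + io

def generate_study(
    design: StudyDesign,
    trajectory_params: TrajectoryParams | None = None,
    spectral_params: SpectralGeneratorParams | None = None,
) -> tuple[pd.DataFrame, SpectraMatrix]:
    """Roster -> trajectories -> spectra, all seeded from ``design.seed``."""
    trajectory_params = trajectory_params or TrajectoryParams()
    spectral_params = spectral_params or SpectralGeneratorParams()
    roster = generate_design(design)
    records = generate_trajectories(roster, trajectory_params, seed=design.seed + 1)
    spectra = generate_spectra(
        records, spectral_params, seed=design.seed + 2,
        scans_per_fruit=design.scans_per_fruit,
    )
    return records, spectra


def write_dataset(
    records: pd.DataFrame,
    spectra: SpectraMatrix,
    outdir,
    design: StudyDesign | None = None,
    trajectory_params: TrajectoryParams | None = None,
    spectral_params: SpectralGeneratorParams | None = None,
) -> dict[str, Path]:
    """Emit quality.csv, spectra.csv, microbial.csv and manifest.json.

    The manifest captures every parameter and seed needed to regenerate
    the files bit-identically via :func:`regenerate_from_manifest`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record_ids = set(records["sample_id"].astype(str))
    orphan = [g for g in spectra.replicate_group_ids if g not in record_ids]
    if orphan:
        raise ValueError(
            f"spectra reference unknown quality records, e.g. {orphan[0]!r}"
        )
    paths = {
        "quality": outdir / "quality.csv",
        "spectra": outdir / "spectra.csv",
        "microbial": outdir / "microbial.csv",
        "manifest": outdir / "manifest.json",
    }
    records.to_csv(paths["quality"], index=False)
    write_spectra_csv(spectra, paths["spectra"])
    records[["sample_id", "tvc_log", "ye_log"]].to_csv(paths["microbial"], index=False)
    manifest = {
        "design": (design or StudyDesign()).to_dict() if design is not None else None,
        "trajectory_params": (trajectory_params or TrajectoryParams()).to_dict()
        if trajectory_params is not None
        else None,
        "spectral_params": (spectral_params or SpectralGeneratorParams()).to_dict()
        if spectral_params is not None
        else None,
        "n_records": int(len(records)),
        "n_scans": int(len(spectra.sample_ids)),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths


def regenerate_from_manifest(manifest_path) -> tuple[pd.DataFrame, SpectraMatrix]:
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if manifest["design"] is None:
        raise ValueError("manifest lacks the generating design; cannot replay")
    design = StudyDesign.from_dict(manifest["design"])
    tparams = (
        TrajectoryParams.from_dict(manifest["trajectory_params"])
        if manifest["trajectory_params"] is not None
        else None
    )
    sparams = (
        SpectralGeneratorParams.from_dict(manifest["spectral_params"])
        if manifest["spectral_params"] is not None
        else None
    )
    return generate_study(design, tparams, sparams)
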