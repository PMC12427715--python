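"""VIS-NIR spectral preprocessing.

Raw diffuse-reflectance spectra (percent reflectance on a uniform 3 nm
grid) are transformed into the representation used for calibration:

1. window to the informative 410-990 nm segment,
2. convert to apparent absorbance A = log10(100 / R%),
3. multiplicative scatter correction (MSC) against a reference spectrum
   fitted on training rows only,
4. Savitzky-Golay second derivative (local least-squares polynomial
   fits), trimmed to the fully-windowed interior so every reported point
   is a true local fit.

All stages are deterministic and never reorder samples.  The fitted
pipeline state (window, MSC reference, SG settings) serializes to JSON
so held-out data can be replayed through identical transforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_coeffs

__all__ = [
    "Spectrum",
    "SpectraMatrix",
    "PreprocessingPipeline",
    "window_spectrum",
    "reflectance_to_absorbance",
    "msc_correct",
    "savitzky_golay_d2",
    "read_spectra_csv",
    "write_spectra_csv",
]

REFLECTANCE = "reflectance_percent"
ABSORBANCE = "absorbance"
D2_ABSORBANCE = "d2_absorbance"

METADATA_COLUMNS = (
    "sample_id",
    "replicate_group_id",
    "cultivar",
    "moisture_group",
    "temperature_C",
    "packaging",
    "month",
)


class EmptySelectionError(ValueError):
    pass


class FlatSpectrumError(ValueError):
    pass


def _check_grid(wavelengths: np.ndarray) -> float:
    """Return the (uniform) grid spacing, validating monotonicity."""
    if wavelengths.ndim != 1 or wavelengths.size < 2:
        raise ValueError("wavelength grid must be 1-D with >= 2 points")
    steps = np.diff(wavelengths)
    if np.any(steps <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
        raise ValueError("wavelength grid must be uniform")
    return float(steps[0])


@dataclass(frozen=True)
class Spectrum:
    wavelengths_nm: np.ndarray
    values: np.ndarray
    mode: str = REFLECTANCE

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", v)
        _check_grid(wl)
        if v.shape != wl.shape:
            raise ValueError("values and wavelengths must have equal length")
        if self.mode == REFLECTANCE and np.any(v <= 0):
            raise ValueError("reflectance_percent values must be > 0")


@dataclass
class SpectraMatrix:
    """Samples x wavelengths block with per-sample metadata.

    ``replicate_group_ids`` identifies the measurement occasion each scan
    belongs to; scans sharing an id must never be separated across
    calibration subsets.
    """

    sample_ids: list[str]
    replicate_group_ids: list[str]
    wavelengths_nm: np.ndarray
    values: np.ndarray
    mode: str = REFLECTANCE
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _check_grid(self.wavelengths_nm)
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.replicate_group_ids) != n:
            raise ValueError("id lists must match the number of rows")
        if p != self.wavelengths_nm.size:
            raise ValueError("value columns must match the wavelength grid")

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths_nm, self.values[i], self.mode)

    def with_values(self, values: np.ndarray, wavelengths=None, mode=None) -> "SpectraMatrix":
        return SpectraMatrix(
            sample_ids=list(self.sample_ids),
            replicate_group_ids=list(self.replicate_group_ids),
            wavelengths_nm=self.wavelengths_nm if wavelengths is None else wavelengths,
            values=values,
            mode=self.mode if mode is None else mode,
            metadata=None if self.metadata is None else self.metadata.copy(),
        )


# ---------------------------------------------------------------- stages

def window_spectrum(s: Spectrum, lo_nm: float = 410.0, hi_nm: float = 990.0) -> Spectrum:
    """Retain grid points p with lo <= p <= hi."""
    mask = (s.wavelengths_nm >= lo_nm) & (s.wavelengths_nm <= hi_nm)
    if not mask.any():
        raise EmptySelectionError(
            f"window [{lo_nm}, {hi_nm}] selects no grid points"
        )
    return Spectrum(s.wavelengths_nm[mask], s.values[mask], s.mode)


def reflectance_to_absorbance(s: Spectrum) -> Spectrum:
    """A = log10(100 / R%)."""
    if s.mode != REFLECTANCE:
        raise ValueError(f"expected {REFLECTANCE} input, got {s.mode}")
    if np.any(s.values <= 0):
        raise ValueError("reflectance must be strictly positive")
    return Spectrum(s.wavelengths_nm, np.log10(100.0 / s.values), ABSORBANCE)


def _msc_rows(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    ref = reference - reference.mean()
    denom = float(ref @ ref)
    if denom <= 0:
        raise FlatSpectrumError("MSC reference spectrum is constant")
    out = np.empty_like(values)
    for i, x in enumerate(values):
        beta = float(ref @ (x - x.mean())) / denom
        if abs(beta) < 1e-12:
            raise FlatSpectrumError(f"row {i} is flat relative to the reference")
        alpha = x.mean() - beta * reference.mean()
        out[i] = (x - alpha) / beta
    return out


def msc_correct(
    m: SpectraMatrix, reference: np.ndarray | None = None
) -> tuple[SpectraMatrix, np.ndarray]:
    """Multiplicative scatter correction of an absorbance matrix.

    Each row x is regressed on the reference r (x ~ alpha + beta r) and
    corrected to (x - alpha)/beta.  The reference defaults to the column
    mean of ``m`` and is returned for reuse on held-out data.
    """
    if m.mode != ABSORBANCE:
        raise ValueError("MSC expects absorbance spectra")
    if reference is None:
        if m.values.shape[0] < 2:
            raise ValueError("need >= 2 rows to infer an MSC reference")
        reference = m.values.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (m.values.shape[1],):
        raise ValueError("reference length must match the wavelength grid")
    return m.with_values(_msc_rows(m.values, reference)), reference


def _sg_d2_matrix(
    values: np.ndarray, spacing: float, window_points: int, poly_order: int
) -> np.ndarray:
    if window_points % 2 == 0 or window_points < 5:
        raise ValueError("window_points must be odd and >= 5")
    if poly_order < 2:
        raise ValueError("poly_order must be >= 2 for a second derivative")
    if window_points > values.shape[-1]:
        raise ValueError("window_points exceeds spectrum length")
    # deriv=2 filter weights are symmetric, so correlation == convolution
    c = savgol_coeffs(window_points, poly_order, deriv=2, delta=spacing)
    win = np.lib.stride_tricks.sliding_window_view(values, window_points, axis=-1)
    return win @ c[::-1]


def savitzky_golay_d2(
    s: Spectrum, window_points: int = 13, poly_order: int = 2
) -> Spectrum:
    """Second derivative w.r.t. wavelength (units value nm^-2).

    Output is trimmed to the valid interior (half-window lost each side);
    exact for polynomials up to ``poly_order``.
    """
    spacing = _check_grid(s.wavelengths_nm)
    half = window_points // 2
    d2 = _sg_d2_matrix(s.values, spacing, window_points, poly_order)
    return Spectrum(s.wavelengths_nm[half:-half], d2, D2_ABSORBANCE)


# ------------------------------------------------------------- pipeline

@dataclass
class PreprocessingPipeline:
    """window -> absorbance -> MSC -> SG second derivative.

    ``fit_transform`` fits the MSC reference on the given (training)
    matrix; ``transform`` replays the stored state on new data.
    """

    lo_nm: float = 410.0
    hi_nm: float = 990.0
    sg_window_points: int = 13
    sg_poly_order: int = 2
    msc_reference_: np.ndarray | None = None
    wavelengths_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.msc_reference_ is not None

    def _window_absorbance(self, m: SpectraMatrix) -> SpectraMatrix:
        if m.mode != REFLECTANCE:
            raise ValueError("pipeline input must be percent reflectance")
        mask = (m.wavelengths_nm >= self.lo_nm) & (m.wavelengths_nm <= self.hi_nm)
        if not mask.any():
            raise EmptySelectionError("window selects no grid points")
        vals = m.values[:, mask]
        if np.any(vals <= 0):
            raise ValueError("reflectance must be strictly positive")
        return m.with_values(
            np.log10(100.0 / vals), wavelengths=m.wavelengths_nm[mask], mode=ABSORBANCE
        )

    def fit_transform(self, m: SpectraMatrix) -> SpectraMatrix:
        absorb = self._window_absorbance(m)
        corrected, ref = msc_correct(absorb)
        self.msc_reference_ = ref
        self.wavelengths_ = absorb.wavelengths_nm.copy()
        return self._derivative(corrected)

    def transform(self, m: SpectraMatrix) -> SpectraMatrix:
        if not self.fitted:
            raise RuntimeError("pipeline is not fitted; call fit_transform first")
        absorb = self._window_absorbance(m)
        if not np.array_equal(absorb.wavelengths_nm, self.wavelengths_):
            raise ValueError("wavelength grid differs from the fitted grid")
        corrected, _ = msc_correct(absorb, reference=self.msc_reference_)
        return self._derivative(corrected)

    def _derivative(self, m: SpectraMatrix) -> SpectraMatrix:
        spacing = _check_grid(m.wavelengths_nm)
        half = self.sg_window_points // 2
        d2 = _sg_d2_matrix(m.values, spacing, self.sg_window_points, self.sg_poly_order)
        return m.with_values(
            d2, wavelengths=m.wavelengths_nm[half:-half], mode=D2_ABSORBANCE
        )

    def to_json(self, path=None) -> str:
        payload = {
            "lo_nm": self.lo_nm,
            "hi_nm": self.hi_nm,
            "sg_window_points": self.sg_window_points,
            "sg_poly_order": self.sg_poly_order,
            "msc_reference": None
            if self.msc_reference_ is None
            else self.msc_reference_.tolist(),
            "wavelengths": None
            if self.wavelengths_ is None
            else self.wavelengths_.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PreprocessingPipeline":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        pipe = cls(
            lo_nm=payload["lo_nm"],
            hi_nm=payload["hi_nm"],
            sg_window_points=payload["sg_window_points"],
            sg_poly_order=payload["sg_poly_order"],
        )
        if payload["msc_reference"] is not None:
            pipe.msc_reference_ = np.asarray(payload["msc_reference"], dtype=float)
            pipe.wavelengths_ = np.asarray(payload["wavelengths"], dtype=float)
        return pipe


def preprocess_pipeline(m: SpectraMatrix, cfg: PreprocessingPipeline | None = None):
    """Convenience wrapper: fit on ``m`` and return (matrix, fitted pipeline)."""
    pipe = cfg or PreprocessingPipeline()
    return pipe.fit_transform(m), pipe


# ------------------------------------------------------------------- io

def _wl_column(wl: float) -> str:
    return f"wl_{int(round(wl)):04d}"


def write_spectra_csv(m: SpectraMatrix, path) -> None:
    """Wide CSV: metadata columns then one wl_#### column per grid point."""
    meta = m.metadata if m.metadata is not None else pd.DataFrame(index=range(len(m.sample_ids)))
    df = pd.DataFrame(
        {"sample_id": m.sample_ids, "replicate_group_id": m.replicate_group_ids}
    )
    for col in METADATA_COLUMNS[2:]:
        if meta is not None and col in meta.columns:
            df[col] = meta[col].to_numpy()
    spec = pd.DataFrame(
        m.values, columns=[_wl_column(w) for w in m.wavelengths_nm], index=df.index
    )
    pd.concat([df, spec], axis=1).to_csv(path, index=False)


def read_spectra_csv(path, mode: str = REFLECTANCE) -> SpectraMatrix:
    df = pd.read_csv(path)
    wl_cols = [c for c in df.columns if c.startswith("wl_")]
    if not wl_cols:
        raise ValueError(f"no wl_#### columns found in {path}")
    wl = np.array([float(c[3:]) for c in wl_cols])
    order = np.argsort(wl)
    wl_cols = [wl_cols[i] for i in order]
    meta_cols = [c for c in df.columns if not c.startswith("wl_")]
    return SpectraMatrix(
        sample_ids=df["sample_id"].astype(str).tolist(),
        replicate_group_ids=df["replicate_group_id"].astype(str).tolist(),
        wavelengths_nm=wl[order],
        values=df[wl_cols].to_numpy(dtype=float),
        mode=mode,
        metadata=df[meta_cols].copy(),
    )
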