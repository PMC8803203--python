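"""Spectrometer trace I/O, empty-sphere calibration and replicate statistics.

A *trace* is a two-column delimited text file (wavelength nm, intensity
counts); ``#`` starts a comment.  A *manifest* CSV maps trace files to their
acquisition metadata (mode, incident power, replicate).

Calibration follows the empty-sphere convention: the reference transmission
trace defines the 100% level, the reference reflection trace the reflectance
baseline (ideally zero for an empty sphere):

    t_d = band(sample_T) / band(ref_T)
    r_d = (band(sample_R) - band(ref_R)) / band(ref_T)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    BandRangeError,
    CalibrationError,
    InvalidParameterError,
    SpectrumParseError,
)

__all__ = [
    "SpectrumRecord",
    "ReplicateSummary",
    "MODES",
    "read_spectrum",
    "write_spectrum",
    "band_integral",
    "calibrate_fractions",
    "replicate_stats",
    "reduce_manifest",
]

MODES = (
    "transmission",
    "reflection",
    "reference_transmission",
    "reference_reflection",
)


@dataclass(frozen=True)
class SpectrumRecord:
    """One raw spectrometer trace with acquisition metadata."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    mode: str
    power_mw: float
    replicate_id: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "intensity", it)
        if self.mode not in MODES:
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size or wl.size < 2:
            raise InvalidParameterError(
                "wavelength and intensity must be equal-length 1-D arrays "
                f"of length >= 2 (got {wl.size} and {it.size})"
            )
        if not np.all(np.diff(wl) > 0):
            raise InvalidParameterError("wavelengths must be strictly ascending")
        if np.any(it < 0):
            raise InvalidParameterError("intensities must be non-negative")
        if self.replicate_id < 1:
            raise InvalidParameterError(
                f"replicate_id must be >= 1, got {self.replicate_id}"
            )


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and rms deviation (about the mean) over consecutive replicates."""

    mean_value: float
    rms_value: float
    n_replicates: int


def read_spectrum(
    path: str | Path,
    mode: str,
    power_mw: float,
    replicate_id: int,
    sample_id: str = "",
) -> SpectrumRecord:
    """Parse a two-column delimited trace file into a :class:`SpectrumRecord`.

    Accepts comma or whitespace delimiters and ``#`` comment lines.
    Malformed rows are reported with their 1-based line numbers.
    """
    path = Path(path)
    wavelengths: list[float] = []
    intensities: list[float] = []
    bad_rows: list[int] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            bad_rows.append(lineno)
            continue
        try:
            wavelengths.append(float(parts[0]))
            intensities.append(float(parts[1]))
        except ValueError:
            bad_rows.append(lineno)
    if bad_rows:
        raise SpectrumParseError(
            f"{path}: malformed rows at lines {bad_rows}"
        )
    if not wavelengths:
        raise SpectrumParseError(f"{path}: no data rows")
    try:
        return SpectrumRecord(
            wavelength_nm=np.array(wavelengths),
            intensity=np.array(intensities),
            mode=mode,
            power_mw=power_mw,
            replicate_id=replicate_id,
            sample_id=sample_id,
        )
    except InvalidParameterError as exc:
        raise SpectrumParseError(f"{path}: {exc}") from exc


def write_spectrum(path: str | Path, wavelength_nm, intensity) -> None:
    """Write a trace as two-column CSV (wavelength_nm, intensity)."""
    arr = np.column_stack([wavelength_nm, intensity])
    header = "wavelength_nm,intensity"
    np.savetxt(path, arr, delimiter=",", header=header, fmt="%.10g")


def band_integral(
    s: SpectrumRecord, center_nm: float, halfwidth_nm: float
) -> float:
    """Trapezoidal integral of the trace over ``[center - hw, center + hw]``.

    The band edges are added by linear interpolation so the result varies
    continuously with the band limits.
    """
    if halfwidth_nm <= 0:
        raise InvalidParameterError("halfwidth_nm must be positive")
    lo, hi = center_nm - halfwidth_nm, center_nm + halfwidth_nm
    wl, it = s.wavelength_nm, s.intensity
    if hi < wl[0] or lo > wl[-1]:
        raise BandRangeError(
            f"band [{lo}, {hi}] nm does not overlap trace range "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    lo_c, hi_c = max(lo, wl[0]), min(hi, wl[-1])
    inside = (wl > lo_c) & (wl < hi_c)
    grid = np.concatenate(([lo_c], wl[inside], [hi_c]))
    vals = np.interp(grid, wl, it)
    return float(np.trapezoid(vals, grid))


def calibrate_fractions(
    sample_t: SpectrumRecord,
    sample_r: SpectrumRecord,
    ref_t: SpectrumRecord,
    ref_r: SpectrumRecord,
    center_nm: float = 808.0,
    halfwidth_nm: float = 5.0,
) -> tuple[float, float]:
    """Empty-sphere calibration of band-integrated signals to (r_d, t_d).

    The reference transmission band sets the 100% level; the reference
    reflection band (ideally ~0 for an empty sphere) is subtracted from the
    sample reflection.  ``r_d`` is clipped at zero.  ``r_d + t_d >= 1`` is
    flagged with a warning and returned unmodified (downstream inversion
    raises on it).
    """
    ref_t_band = band_integral(ref_t, center_nm, halfwidth_nm)
    if ref_t_band <= 0:
        raise CalibrationError(
            "reference transmission band integral is not positive; cannot "
            "normalize"
        )
    ref_r_band = band_integral(ref_r, center_nm, halfwidth_nm)
    t_d = band_integral(sample_t, center_nm, halfwidth_nm) / ref_t_band
    r_d = (band_integral(sample_r, center_nm, halfwidth_nm) - ref_r_band) / ref_t_band
    r_d = max(r_d, 0.0)
    if r_d + t_d >= 1.0:
        warnings.warn(
            f"non-physical calibration: r_d + t_d = {r_d + t_d:.4g} >= 1",
            RuntimeWarning,
            stacklevel=2,
        )
    return r_d, t_d


def replicate_stats(values, mode: str = "population") -> ReplicateSummary:
    """Mean and rms deviation about the mean over replicate values.

    ``mode="population"`` (default) divides by n; ``mode="sample"`` by n - 1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidParameterError("replicate_stats requires at least one value")
    mean = float(arr.mean())
    if mode == "population":
        rms = float(np.sqrt(np.mean((arr - mean) ** 2)))
    elif mode == "sample":
        rms = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    return ReplicateSummary(mean_value=mean, rms_value=rms, n_replicates=arr.size)


def reduce_manifest(
    manifest_path: str | Path,
    center_nm: float = 808.0,
    halfwidth_nm: float = 5.0,
) -> pd.DataFrame:
    """Reduce a manifest of trace files to per-replicate diffuse fractions.

    The manifest CSV has columns ``path, mode, power_mw, replicate_id,
    sample_id``; paths are resolved relative to the manifest location.
    Reference traces (``reference_*`` modes) are matched per power; when a
    power has a single reference replicate it is shared across sample
    replicates.

    Returns a DataFrame with columns
    ``sample_id, power_mw, replicate_id, r_d, t_d``.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, comment="#")
    required = {"path", "mode", "power_mw", "replicate_id", "sample_id"}
    missing = required - set(manifest.columns)
    if missing:
        raise SpectrumParseError(
            f"{manifest_path}: manifest missing columns {sorted(missing)}"
        )
    base = manifest_path.parent

    def _load(row) -> SpectrumRecord:
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        return read_spectrum(
            p,
            mode=row["mode"],
            power_mw=float(row["power_mw"]),
            replicate_id=int(row["replicate_id"]),
            sample_id=str(row["sample_id"]),
        )

    rows = []
    for (sample_id, power), grp in manifest.groupby(["sample_id", "power_mw"]):
        by_mode = {m: grp[grp["mode"] == m] for m in MODES}
        for m in ("transmission", "reflection"):
            if by_mode[m].empty:
                raise CalibrationError(
                    f"sample {sample_id!r} power {power}: no {m} traces"
                )
        for m in ("reference_transmission", "reference_reflection"):
            if by_mode[m].empty:
                raise CalibrationError(
                    f"sample {sample_id!r} power {power}: no {m} trace"
                )
        refs_t = {
            int(r["replicate_id"]): _load(r)
            for _, r in by_mode["reference_transmission"].iterrows()
        }
        refs_r = {
            int(r["replicate_id"]): _load(r)
            for _, r in by_mode["reference_reflection"].iterrows()
        }
        sample_r_by_rep = {
            int(r["replicate_id"]): _load(r)
            for _, r in by_mode["reflection"].iterrows()
        }
        for _, trow in by_mode["transmission"].iterrows():
            rep = int(trow["replicate_id"])
            if rep not in sample_r_by_rep:
                raise CalibrationError(
                    f"sample {sample_id!r} power {power}: transmission "
                    f"replicate {rep} has no matching reflection trace"
                )
            ref_t = refs_t.get(rep, next(iter(refs_t.values())))
            ref_r = refs_r.get(rep, next(iter(refs_r.values())))
            r_d, t_d = calibrate_fractions(
                _load(trow),
                sample_r_by_rep[rep],
                ref_t,
                ref_r,
                center_nm=center_nm,
                halfwidth_nm=halfwidth_nm,
            )
            rows.append(
                {
                    "sample_id": sample_id,
                    "power_mw": float(power),
                    "replicate_id": rep,
                    "r_d": r_d,
                    "t_d": t_d,
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["sample_id", "power_mw", "replicate_id"], ignore_index=True
    )
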