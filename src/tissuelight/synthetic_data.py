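"""Synthetic integrating-sphere data with known ground truth.

Emulates the measurement campaign the analysis expects: an 808 nm diode
laser line probed through tissue slabs at six incident powers, five
replicates each, in transmission / reflection / empty-sphere reference
modes.  The reduced scattering coefficient decreases with incident power
(linearly between the published endpoints: skull 37 -> 9 cm^-1, skin
12 -> 5.8 cm^-1 over 150 -> 350 mW) while the absorption coefficient is
power-invariant.

The absorption, thickness and anisotropy values are *fixture choices*, not
published numbers: mu_a 0.5 cm^-1 (skull) / 0.8 cm^-1 (skin), thickness
0.1 cm (skull) / 0.2 cm (skin), g rising linearly 0.80 -> 0.90 with power.
Recovery tests should only rely on the mu_s' endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import spectra_io
from .exceptions import InvalidParameterError
from .km_model import OpticalProperties, forward_km, transport_to_km

__all__ = [
    "GroundTruthTrend",
    "POWERS_MW",
    "default_ground_truth",
    "make_rt_table",
    "make_spectra",
]

POWERS_MW = (150.0, 200.0, 225.0, 250.0, 300.0, 350.0)

#: (mu_s' at 150 mW, mu_s' at 350 mW) in cm^-1 — published endpoints.
_MUSP_ENDPOINTS = {"skull": (37.0, 9.0), "skin": (12.0, 5.8)}
#: fixture values (not published)
_MUA_FIXTURE = {"skull": 0.5, "skin": 0.8}
_THICKNESS_FIXTURE = {"skull": 0.1, "skin": 0.2}
_G_ENDPOINTS = (0.80, 0.90)

LINE_CENTER_NM = 808.0
LINE_FWHM_NM = 3.0


@dataclass(frozen=True)
class GroundTruthTrend:
    """Per-power ground-truth optical parameters for one tissue fixture."""

    tissue: str
    powers_mw: np.ndarray
    mu_s_prime_cm1: np.ndarray
    mu_a_cm1: np.ndarray
    thickness_cm: float
    g: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for name in ("powers_mw", "mu_s_prime_cm1", "mu_a_cm1", "g"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        n = self.powers_mw.size
        if any(
            getattr(self, name).size != n
            for name in ("mu_s_prime_cm1", "mu_a_cm1", "g")
        ):
            raise InvalidParameterError("per-power arrays must share length")
        if not np.all(np.diff(self.mu_s_prime_cm1) < 0):
            raise InvalidParameterError(
                "mu_s_prime must be strictly decreasing with power"
            )
        if not np.allclose(self.mu_a_cm1, self.mu_a_cm1[0]):
            raise InvalidParameterError("mu_a must be constant across powers")

    def optical_properties(self, i: int) -> OpticalProperties:
        """Transport parameters at power index ``i``."""
        g = float(self.g[i])
        return OpticalProperties(
            mu_a=float(self.mu_a_cm1[i]),
            mu_s_prime=float(self.mu_s_prime_cm1[i]),
            thickness_cm=self.thickness_cm,
            g=g,
            mu_s=float(self.mu_s_prime_cm1[i]) / (1.0 - g),
            power_mw=float(self.powers_mw[i]),
            wavelength_nm=LINE_CENTER_NM,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tissue": self.tissue,
                "power_mw": self.powers_mw,
                "mu_a_cm1": self.mu_a_cm1,
                "mu_s_prime_cm1": self.mu_s_prime_cm1,
                "g": self.g,
                "thickness_cm": self.thickness_cm,
            }
        )


def default_ground_truth(tissue: str) -> GroundTruthTrend:
    """Default per-power ground truth for ``tissue`` in {"skull", "skin"}.

    mu_s' interpolates linearly in power between the published endpoints;
    mu_a, thickness and g are fixture values.
    """
    if tissue not in _MUSP_ENDPOINTS:
        raise InvalidParameterError(
            f"unknown tissue {tissue!r}; expected one of {sorted(_MUSP_ENDPOINTS)}"
        )
    powers = np.array(POWERS_MW)
    frac = (powers - powers[0]) / (powers[-1] - powers[0])
    lo, hi = _MUSP_ENDPOINTS[tissue]
    musp = lo + (hi - lo) * frac
    g = _G_ENDPOINTS[0] + (_G_ENDPOINTS[1] - _G_ENDPOINTS[0]) * frac
    return GroundTruthTrend(
        tissue=tissue,
        powers_mw=powers,
        mu_s_prime_cm1=musp,
        mu_a_cm1=np.full(powers.size, _MUA_FIXTURE[tissue]),
        thickness_cm=_THICKNESS_FIXTURE[tissue],
        g=g,
    )


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multiplicative factors with coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def make_rt_table(
    truth: GroundTruthTrend,
    noise_cv: float = 0.0,
    n_replicates: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-replicate diffuse fractions for each power.

    The noise-free fractions are the forward two-flux prediction from the
    ground-truth transport parameters; replicates multiply r_d and t_d by
    independent unit-mean lognormal factors with coefficient of variation
    ``noise_cv``, rescaled where needed to keep ``r_d + t_d < 1``.
    """
    if noise_cv < 0:
        raise InvalidParameterError("noise_cv must be >= 0")
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i, power in enumerate(truth.powers_mw):
        k = transport_to_km(truth.optical_properties(i))
        r0, t0 = forward_km(k.s_km, k.a_km, truth.thickness_cm)
        r = r0 * _lognormal_factors(rng, noise_cv, n_replicates)
        t = t0 * _lognormal_factors(rng, noise_cv, n_replicates)
        # keep the pair physically invertible
        total = r + t
        bad = total >= 1.0
        scale = np.where(bad, (1.0 - 1e-9) / total, 1.0)
        r, t = r * scale, t * scale
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "tissue": truth.tissue,
                    "power_mw": float(power),
                    "replicate_id": rep,
                    "r_d": float(r[rep - 1]),
                    "t_d": float(t[rep - 1]),
                    "thickness_cm": truth.thickness_cm,
                }
            )
    return pd.DataFrame(rows)


def _gaussian_line(wl: np.ndarray, amplitude: float) -> np.ndarray:
    sigma = LINE_FWHM_NM / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return amplitude * np.exp(-0.5 * ((wl - LINE_CENTER_NM) / sigma) ** 2)


def make_spectra(
    truth: GroundTruthTrend,
    noise_cv: float = 0.0,
    n_replicates: int = 5,
    seed: int = 0,
    outdir: str | Path = ".",
    reference_counts: float = 50_000.0,
) -> Path:
    """Write synthetic trace files plus manifest and ground-truth key CSVs.

    Each trace is a Gaussian 808 nm line (FWHM 3 nm) on a 750-860 nm grid.
    Sample traces are the reference line scaled by the per-replicate r_d/t_d
    of :func:`make_rt_table` with the same seed, so reducing the spectra
    reproduces that table.  Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wl = np.arange(750.0, 860.0 + 0.25, 0.5)
    ref_line = _gaussian_line(wl, reference_counts)
    rt = make_rt_table(truth, noise_cv=noise_cv, n_replicates=n_replicates, seed=seed)

    manifest_rows = []

    def _write(name: str, intensity, mode: str, power: float, rep: int) -> None:
        spectra_io.write_spectrum(outdir / name, wl, intensity)
        manifest_rows.append(
            {
                "path": name,
                "mode": mode,
                "power_mw": power,
                "replicate_id": rep,
                "sample_id": truth.tissue,
            }
        )

    for power in truth.powers_mw:
        p_tag = f"{power:g}mW"
        _write(
            f"{truth.tissue}_{p_tag}_ref_T.csv", ref_line,
            "reference_transmission", float(power), 1,
        )
        _write(
            f"{truth.tissue}_{p_tag}_ref_R.csv", np.zeros_like(wl),
            "reference_reflection", float(power), 1,
        )
        sub = rt[rt["power_mw"] == power]
        for _, row in sub.iterrows():
            rep = int(row["replicate_id"])
            _write(
                f"{truth.tissue}_{p_tag}_rep{rep}_T.csv",
                row["t_d"] * ref_line, "transmission", float(power), rep,
            )
            _write(
                f"{truth.tissue}_{p_tag}_rep{rep}_R.csv",
                row["r_d"] * ref_line, "reflection", float(power), rep,
            )

    manifest = pd.DataFrame(manifest_rows)
    manifest_path = outdir / "manifest.csv"
    with open(manifest_path, "w") as fh:
        fh.write(f"# seed={seed} noise_cv={noise_cv} n_replicates={n_replicates}\n")
        manifest.to_csv(fh, index=False)
    truth.to_frame().to_csv(outdir / "ground_truth.csv", index=False)
    return manifest_path
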