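"""End-to-end analysis orchestration.

Chains the stages: synthesize (or load) integrating-sphere spectra ->
reduce to diffuse fractions -> invert to optical properties and
penetration depth -> diffusion fluence maps -> ROC power discrimination ->
Monte-Carlo anisotropy verification.  Every stage writes plain CSV/JSON
into the run directory so stages can be re-run and inspected
independently; a run manifest records the materialized configuration,
seeds and a config hash for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import StageError, TissueLightError
from .fluence_solver import profile_width, solve_fluence
from .km_model import (
    DiffuseMeasurement,
    OpticalProperties,
    estimate_optical_properties,
    invert_km,
    penetration_depth,
)
from .photon_mc import SlabModel, compare_anisotropy
from .roc_stats import DEFAULT_POWER_PAIRS, pairwise_power_report
from .spectra_io import reduce_manifest, replicate_stats
from .synthetic_data import default_ground_truth, make_spectra

logger = logging.getLogger("tissuelight")

__all__ = ["RunConfig", "run_analysis", "invert_rt_table"]


@dataclass
class RunConfig:
    """Materialized configuration of one pipeline run."""

    tissues: list[str] = field(default_factory=lambda: ["skull", "skin"])
    noise_cv: float = 0.02
    n_replicates: int = 5
    seed: int = 42
    band_center_nm: float = 808.0
    band_halfwidth_nm: float = 5.0
    fluence_fraction: float = float(np.exp(-1.0))
    mc_g_values: list[float] = field(default_factory=lambda: [0.8, 0.85, 0.9])
    mc_photons: int = 50_000
    mc_r_max_cm: float = 1.0
    mc_n_bins: int = 50
    roc_pairs: list[tuple[float, float]] = field(
        default_factory=lambda: [list(p) for p in DEFAULT_POWER_PAIRS]
    )
    outdir: str = "out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise StageError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def invert_rt_table(
    rt: pd.DataFrame, thickness_cm: float | None = None
) -> pd.DataFrame:
    """Invert a per-replicate (r_d, t_d) table to transport coefficients.

    Input columns: ``power_mw, r_d, t_d`` and either a ``thickness_cm``
    column or the ``thickness_cm`` argument.  Output adds
    ``mu_a_cm1, mu_s_prime_cm1, s_km_cm1, a_km_cm1, penetration_depth_cm``.
    """
    out_rows = []
    for _, row in rt.iterrows():
        d = thickness_cm if thickness_cm is not None else float(row["thickness_cm"])
        meas = DiffuseMeasurement(
            r_d=float(row["r_d"]),
            t_d=float(row["t_d"]),
            thickness_cm=d,
            power_mw=float(row["power_mw"]),
        )
        k = invert_km(meas)
        props = estimate_optical_properties(meas)
        rec = dict(row)
        rec.update(
            thickness_cm=d,
            mu_a_cm1=props.mu_a,
            mu_s_prime_cm1=props.mu_s_prime,
            s_km_cm1=k.s_km,
            a_km_cm1=k.a_km,
            penetration_depth_cm=(
                penetration_depth(props) if props.mu_a > 0 else np.inf
            ),
        )
        out_rows.append(rec)
    return pd.DataFrame(out_rows)


def _stage(name: str):
    """Decorator: time a stage, convert package errors to StageError."""

    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except StageError:
                raise
            except TissueLightError as exc:
                raise StageError(f"stage {name}: {exc}") from exc
            logger.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


@_stage("simulate")
def _simulate(cfg: RunConfig, outdir: Path) -> dict[str, Path]:
    manifests = {}
    for i, tissue in enumerate(cfg.tissues):
        truth = default_ground_truth(tissue)
        manifests[tissue] = make_spectra(
            truth,
            noise_cv=cfg.noise_cv,
            n_replicates=cfg.n_replicates,
            seed=cfg.seed + i,
            outdir=outdir / "data" / tissue,
        )
    return manifests


@_stage("reduce")
def _reduce(cfg: RunConfig, manifests: dict[str, Path], outdir: Path) -> pd.DataFrame:
    frames = []
    for tissue, manifest in manifests.items():
        df = reduce_manifest(
            manifest,
            center_nm=cfg.band_center_nm,
            halfwidth_nm=cfg.band_halfwidth_nm,
        )
        df.insert(0, "tissue", tissue)
        truth = default_ground_truth(tissue)
        df["thickness_cm"] = truth.thickness_cm
        frames.append(df)
    rt = pd.concat(frames, ignore_index=True)
    rt.to_csv(outdir / "rt_table.csv", index=False)
    return rt


@_stage("invert")
def _invert(rt: pd.DataFrame, outdir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    props = invert_rt_table(rt)
    props.to_csv(outdir / "optical_properties_replicates.csv", index=False)
    rows = []
    for (tissue, power), grp in props.groupby(["tissue", "power_mw"]):
        rec = {"tissue": tissue, "power_mw": power}
        for col in ("mu_a_cm1", "mu_s_prime_cm1", "t_d"):
            stats = replicate_stats(grp[col].to_numpy())
            rec[f"{col}_mean"] = stats.mean_value
            rec[f"{col}_rms"] = stats.rms_value
        mean_props = OpticalProperties(
            mu_a=rec["mu_a_cm1_mean"],
            mu_s_prime=rec["mu_s_prime_cm1_mean"],
            thickness_cm=float(grp["thickness_cm"].iloc[0]),
        )
        rec["penetration_depth_cm"] = (
            penetration_depth(mean_props) if mean_props.mu_a > 0 else np.inf
        )
        rec["thickness_cm"] = mean_props.thickness_cm
        rows.append(rec)
    summary = pd.DataFrame(rows).sort_values(
        ["tissue", "power_mw"], ignore_index=True
    )
    summary.to_csv(outdir / "optical_properties.csv", index=False)
    return props, summary


@_stage("fluence")
def _fluence(cfg: RunConfig, summary: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    fdir = outdir / "fluence"
    fdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for tissue, grp in summary.groupby("tissue"):
        deltas = grp["penetration_depth_cm"].to_numpy()
        spacing = float(deltas.min()) / 5.5
        domain = 10.5 * float(deltas.max())
        for _, row in grp.iterrows():
            props = OpticalProperties(
                mu_a=row["mu_a_cm1_mean"],
                mu_s_prime=row["mu_s_prime_cm1_mean"],
                thickness_cm=row["thickness_cm"],
            )
            f = solve_fluence(props, domain_cm=domain, spacing_cm=spacing)
            tag = f"{tissue}_{row['power_mw']:g}mW"
            np.savetxt(fdir / f"{tag}_phi.csv", f.phi, delimiter=",", fmt="%.8g")
            sidecar = {
                "grid_spacing_cm": f.grid_spacing_cm,
                "source_xy": list(f.source_xy),
                "diffusion_coeff_cm": f.diffusion_coeff_cm,
                "mu_eff_cm1": f.mu_eff_cm1,
                "source_strength": f.source_strength,
            }
            (fdir / f"{tag}_meta.json").write_text(json.dumps(sidecar, indent=1))
            rows.append(
                {
                    "tissue": tissue,
                    "power_mw": row["power_mw"],
                    "width_cm": profile_width(f, cfg.fluence_fraction),
                    "mu_eff_cm1": f.mu_eff_cm1,
                }
            )
    widths = pd.DataFrame(rows)
    widths.to_csv(outdir / "fluence_widths.csv", index=False)
    return widths


@_stage("roc")
def _roc(cfg: RunConfig, rt: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    frames = []
    for tissue, grp in rt.groupby("tissue"):
        values = grp.rename(columns={"t_d": "value"})[
            ["power_mw", "replicate_id", "value"]
        ]
        report = pairwise_power_report(
            values, pairs=[tuple(p) for p in cfg.roc_pairs]
        )
        report.insert(0, "tissue", tissue)
        frames.append(report)
    report = pd.concat(frames, ignore_index=True)
    report.to_csv(outdir / "roc_report.csv", index=False)
    return report


@_stage("mc")
def _mc(cfg: RunConfig, summary: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    frames = []
    totals_frames = []
    for i, tissue in enumerate(cfg.tissues):
        grp = summary[summary["tissue"] == tissue]
        row = grp.loc[grp["power_mw"].idxmin()]
        g0 = min(cfg.mc_g_values)
        base = SlabModel(
            mu_a=float(row["mu_a_cm1_mean"]),
            mu_s=float(row["mu_s_prime_cm1_mean"]) / (1.0 - g0),
            g=g0,
            thickness_cm=float(row["thickness_cm"]),
        )
        cmp_res = compare_anisotropy(
            base,
            cfg.mc_g_values,
            n_photons=cfg.mc_photons,
            seed=cfg.seed + 1000 + i,
            r_max_cm=cfg.mc_r_max_cm,
            n_bins=cfg.mc_n_bins,
        )
        prof = cmp_res.profiles.copy()
        prof.insert(0, "tissue", tissue)
        frames.append(prof)
        tot = cmp_res.totals.copy()
        tot.insert(0, "tissue", tissue)
        totals_frames.append(tot)
    profiles = pd.concat(frames, ignore_index=True)
    profiles.to_csv(outdir / "mc_profiles.csv", index=False)
    totals = pd.concat(totals_frames, ignore_index=True)
    totals.to_csv(outdir / "mc_totals.csv", index=False)
    return totals


def run_analysis(cfg: RunConfig) -> Path:
    """Run every stage and return the output directory.

    Writes ``rt_table.csv``, per-replicate and per-power optical-property
    tables, fluence maps with a width summary, a power-pair ROC report,
    Monte-Carlo anisotropy profiles, and ``run_manifest.json``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifests = _simulate(cfg, outdir)
    rt = _reduce(cfg, manifests, outdir)
    _, summary = _invert(rt, outdir)
    _fluence(cfg, summary, outdir)
    _roc(cfg, rt, outdir)
    _mc(cfg, summary, outdir)
    manifest = {
        "tissuelight_version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
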