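"""Configuration and orchestration of end-to-end analysis runs.

A run is described by a YAML/dict :class:`RunConfig` naming the stages to
execute (``simulate`` → ``morphometrics`` → ``rods`` → ``plasticity`` →
``biochem``), their parameters, a seed and an output directory. Each stage
writes CSV/JSON under ``out/<stage>/`` and never modifies another stage's
inputs; a manifest records config hash, package version, seeds and per-stage
status so that identical configs reproduce identical outputs (manifest
timestamp aside).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__, biochem, helical, morphometrics, plasticity, synthetic
from .models import write_pdb

__all__ = ["RunConfig", "run", "load_config"]

_STAGE_ORDER = ("simulate", "morphometrics", "rods", "plasticity", "biochem")


class SimulateConfig(BaseModel):
    n_vesicles: int = 60
    nested_fraction: float = Field(0.3, ge=0.0, le=1.0)
    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = Field(synthetic.DEFAULT_PIXEL_SIZE, gt=0)
    noise_sigma: float = Field(0.0, ge=0.0)
    contour_perturbation: float = Field(0.0, ge=0.0)
    profile_outer_radius: float = Field(107.5, gt=0)
    profile_leaflet_peaks: tuple[float, float] | None = None
    assembly_n_steps: int = Field(30, ge=1)
    assembly_cyclic_n: int = Field(2, ge=1)
    assembly_rise: float = Field(5.75, gt=0)
    assembly_twist: float = 34.4
    assembly_radius: float = Field(100.0, gt=0)


class MorphometricsConfig(BaseModel):
    mask: str = "simulate"  # path or "simulate" to consume the simulate stage
    image: str | None = "simulate"
    pixel_size: float = Field(synthetic.DEFAULT_PIXEL_SIZE, gt=0)
    min_perimeter_nm: float = 0.0
    thickness_window_A: tuple[float, float] = (20.0, 100.0)


class RodsConfig(BaseModel):
    profile: str = "simulate"  # path to a profile CSV or "simulate"
    cutoff: float = Field(0.3, gt=0.0, lt=1.0)
    increment: float = Field(5.0, gt=0)
    symmetry_table: str = "builtin"
    monomer_mass_kda: float = Field(helical.PSPA_MONOMER_MASS_KDA, gt=0)
    rod_length_um: float = Field(2.6, ge=0)


class PlasticityConfig(BaseModel):
    hinge2_angles_deg: list[float] = [-40.0, -20.0, 0.0, 10.0, 20.0]
    contact_pairs: list[list[int]] = [[44, 1, 126], [71, 1, 196]]
    threshold_A: float = Field(1.0, gt=0)


class BiochemConfig(BaseModel):
    measurements: str | None = None  # CSV path; None = synthetic demo table
    reference: str = "WT"


class RunConfig(BaseModel):
    """Validated end-to-end run configuration."""

    stages: list[Literal["simulate", "morphometrics", "rods", "plasticity", "biochem"]]
    out_dir: str = "out"
    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    morphometrics: MorphometricsConfig = MorphometricsConfig()
    rods: RodsConfig = RodsConfig()
    plasticity: PlasticityConfig = PlasticityConfig()
    biochem: BiochemConfig = BiochemConfig()

    @field_validator("stages")
    @classmethod
    def _nonempty(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("at least one stage must be requested")
        return v


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig.model_validate(data)


def _config_hash(config: RunConfig) -> str:
    # the output location is not an analysis parameter
    payload = config.model_dump(mode="json")
    payload.pop("out_dir", None)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the requested stages in pipeline order; return the manifest."""
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.model_dump(mode="json"),
        "config_hash": _config_hash(config),
        "package_version": __version__,
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    context: dict[str, Any] = {}
    for stage in _STAGE_ORDER:
        if stage not in config.stages:
            continue
        stage_dir = out_root / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        try:
            outputs = _STAGE_RUNNERS[stage](config, stage_dir, context)
            manifest["stages"][stage] = {
                "status": "completed",
                "outputs": sorted(str(p) for p in outputs),
            }
        except Exception as exc:  # record partial completion
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            manifest["status"] = "partial"
            break
    manifest.setdefault("status", "completed")
    (out_root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _run_simulate(config: RunConfig, out: Path, ctx: dict) -> list[Path]:
    cfg = config.simulate
    field = synthetic.generate_vesicle_field(
        cfg.n_vesicles,
        cfg.nested_fraction,
        image_shape=cfg.image_shape,
        pixel_size=cfg.pixel_size,
        noise_sigma=cfg.noise_sigma,
        contour_perturbation=cfg.contour_perturbation,
        seed=config.seed,
    )
    paths = list(field.save(out).values())
    ctx["field"] = field

    profile = synthetic.generate_radial_profile(
        cfg.profile_outer_radius,
        leaflet_peaks=cfg.profile_leaflet_peaks,
        seed=config.seed,
    )
    profile_path = out / "radial_profile.csv"
    pd.DataFrame(
        {"radius_A": profile.radii, "intensity": profile.intensities}
    ).to_csv(profile_path, index=False)
    ctx["profile"] = profile
    paths.append(profile_path)

    monomer = synthetic.default_toy_monomer()
    sym = helical.HelicalSymmetry(cfg.assembly_cyclic_n, cfg.assembly_rise, cfg.assembly_twist)
    assembly = synthetic.generate_helical_assembly(
        monomer, sym, cfg.assembly_n_steps, cfg.assembly_radius
    )
    pdb_path = out / "assembly.pdb"
    write_pdb(assembly, pdb_path)
    ctx["assembly"] = assembly
    paths.append(pdb_path)
    return paths


def _load_image(spec: str | None, ctx: dict, which: str) -> np.ndarray | None:
    import tifffile

    if spec is None:
        return None
    if spec == "simulate":
        if "field" not in ctx:
            raise ValueError(
                f"morphometrics.{which} = 'simulate' requires the simulate stage"
            )
        field = ctx["field"]
        return field.mask if which == "mask" else field.intensity
    return tifffile.imread(spec)


def _run_morphometrics(config: RunConfig, out: Path, ctx: dict) -> list[Path]:
    cfg = config.morphometrics
    mask = _load_image(cfg.mask, ctx, "mask")
    image = _load_image(cfg.image, ctx, "image")
    pixel_size = ctx["field"].pixel_size if cfg.mask == "simulate" else cfg.pixel_size
    records = morphometrics.analyze_field(
        np.asarray(mask), pixel_size, image,
        min_perimeter_nm=cfg.min_perimeter_nm,
        thickness_window_A=cfg.thickness_window_A,
    )
    table = morphometrics.summarize(records)
    csv_path = out / "vesicles.csv"
    table.table.to_csv(csv_path, index=False)
    json_path = out / "summary.json"
    json_path.write_text(json.dumps(table.summary, indent=2))
    return [csv_path, json_path]


def _run_rods(config: RunConfig, out: Path, ctx: dict) -> list[Path]:
    cfg = config.rods
    outputs: list[Path] = []
    if cfg.profile == "simulate":
        profile = ctx.get("profile")
        if profile is None:
            raise ValueError("rods.profile = 'simulate' requires the simulate stage")
    else:
        frame = pd.read_csv(cfg.profile)
        profile = helical.RadialProfile(
            frame["radius_A"].to_numpy(), frame["intensity"].to_numpy()
        )
    diameter = helical.diameter_at_cutoff(profile, cfg.cutoff, cfg.increment)

    table = (
        helical.atp_symmetry_table()
        if cfg.symmetry_table == "builtin"
        else helical.load_symmetry_table(cfg.symmetry_table)
    )
    rows = []
    for row in table.itertuples():
        sym = helical.HelicalSymmetry(int(row.cyclic_n), float(row.rise_A), float(row.twist_deg))
        rows.append(
            {
                "diameter_A": row.diameter_A,
                "cyclic_n": sym.n,
                "rise_A": sym.rise,
                "twist_deg": sym.twist,
                "per_asu_rise_A": helical.per_asu_rise(sym),
                "mass_per_length_kDa_per_A": helical.mass_per_length(sym, cfg.monomer_mass_kda),
                "monomers_in_rod": helical.monomer_count(cfg.rod_length_um, sym),
            }
        )
    lattice = pd.DataFrame(rows)
    lattice_path = out / "lattice.csv"
    lattice.to_csv(lattice_path, index=False)
    outputs.append(lattice_path)
    summary = {
        "measured_diameter_A": diameter,
        "cutoff": cfg.cutoff,
        "rod_length_um": cfg.rod_length_um,
        "mpl_diameter_pearson_r": float(
            np.corrcoef(lattice["diameter_A"], lattice["mass_per_length_kDa_per_A"])[0, 1]
        ),
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    outputs.append(summary_path)
    return outputs


def _run_plasticity(config: RunConfig, out: Path, ctx: dict) -> list[Path]:
    cfg = config.plasticity
    reference = synthetic.default_toy_monomer()
    hinge2 = plasticity.DEFAULT_HINGES[1]
    series = [
        synthetic.perturb_monomer(reference, hinge2.pivot_range[1], angle)
        for angle in cfg.hinge2_angles_deg
    ]
    rows = []
    for angle, monomer in zip(cfg.hinge2_angles_deg, series):
        measured = plasticity.hinge_angles(monomer, reference)
        rows.append(
            {
                "injected_hinge2_deg": angle,
                **{f"measured_{k}_deg": v for k, v in measured.items()},
                "end_to_end_82_187_A": plasticity.end_to_end(monomer),
            }
        )
    hinge_path = out / "hinges.csv"
    pd.DataFrame(rows).to_csv(hinge_path, index=False)

    sym = helical.HelicalSymmetry(1, 3.0, 140.0)
    assemblies = [
        synthetic.generate_helical_assembly(m, sym, n_steps=5, radius=90.0)
        for m in series
    ]
    pairs = [plasticity.ContactPair(*p) for p in cfg.contact_pairs]
    contacts = plasticity.contact_series(
        assemblies, pairs, threshold_A=cfg.threshold_A,
        class_labels=[f"{a:+.0f}deg" for a in cfg.hinge2_angles_deg],
    )
    contact_path = out / "contacts.csv"
    plasticity.contact_table(contacts).to_csv(contact_path, index=False)
    return [hinge_path, contact_path]


def _demo_measurements(seed: int) -> pd.DataFrame:
    """Synthetic activity table emulating a wild type and a slow mutant."""
    rng = np.random.default_rng(seed)
    rows = []
    for sample, mean_dpi in (("WT", 15.0), ("mutant", 4.5)):
        for rep in range(6):
            rows.append(
                {
                    "sample": sample,
                    "replicate": rep,
                    "delta_Pi_uM": max(rng.normal(mean_dpi, 1.0), 0.1),
                    "protein_uM": 5.0,
                    "time_h": 1.0,
                }
            )
    return pd.DataFrame(rows)


def _run_biochem(config: RunConfig, out: Path, ctx: dict) -> list[Path]:
    cfg = config.biochem
    frame = (
        pd.read_csv(cfg.measurements)
        if cfg.measurements
        else _demo_measurements(config.seed)
    )
    frame["activity_per_h"] = [
        biochem.atpase_activity(
            biochem.ActivityMeasurement(r.delta_Pi_uM, r.protein_uM, r.time_h)
        )
        for r in frame.itertuples()
    ]
    activity_path = out / "activity.csv"
    frame.to_csv(activity_path, index=False)

    reference = frame.loc[frame["sample"] == cfg.reference, "activity_per_h"]
    if reference.empty:
        raise ValueError(f"reference sample {cfg.reference!r} not in measurements")
    comparisons = {}
    for sample, group in frame.groupby("sample"):
        values = group["activity_per_h"]
        summary = biochem.group_summary(values)
        entry = {
            "n": summary.n,
            "mean_per_h": summary.mean,
            "sem_per_h": summary.sem,
            "p10": summary.p10,
            "p90": summary.p90,
        }
        if sample != cfg.reference and len(values) >= 2 and len(reference) >= 2:
            percent, reduction = biochem.relative_activity(values, reference)
            t, p = biochem.two_sample_ttest(values, reference)
            entry.update(
                {
                    "percent_of_reference": percent,
                    "percent_reduction": reduction,
                    "t_statistic": t,
                    "p_value": p,
                }
            )
        comparisons[sample] = entry
    compare_path = out / "comparison.json"
    compare_path.write_text(json.dumps(comparisons, indent=2))
    return [activity_path, compare_path]


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "morphometrics": _run_morphometrics,
    "rods": _run_rods,
    "plasticity": _run_plasticity,
    "biochem": _run_biochem,
}
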