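"""Configuration, orchestration and run records.

A pipeline run is described by a plain dict (usually loaded from JSON):
stage names under ``stages``, one parameter block per stage, a global
``seed`` and an output directory.  Unknown keys anywhere are rejected, and
every stage default equals the analysis parameters used throughout the
package (beta = 5 1/Å, lam = 1.5, cutoffs 4.5/3.5 Å, ratio threshold
1.115).  Reruns with identical config and seed reproduce byte-identical
outputs; the manifest records a hash of both the config and every output
file so this is checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import contacts, deer, fits, io, pore, shapes, synthetic
from .trajectory import Structure, parse_residue_range

STAGES = ("synth", "contacts", "pore", "shape", "fit_dsf", "fit_itc",
          "fit_mm", "deer")

_PARAM_TYPES = {
    "trajectory": synthetic.ToyTrajectoryParams,
    "melt": synthetic.MeltCurveParams,
    "itc": synthetic.ThermogramParams,
    "uptake": synthetic.UptakeParams,
    "image": synthetic.ClassImageParams,
}

_TOP_KEYS = {"stages", "seed", "outdir", "contact_spec", "deer", "pore",
             *_PARAM_TYPES}

_CONTACT_KEYS = {"native_cutoff", "lipid_cutoff", "beta", "lam", "residues"}
_DEER_KEYS = {"center", "sigma", "t_max", "dt", "modulation_depth",
              "background_rate", "background_dim", "noise_sd",
              "r_min", "r_max", "r_step"}
_PORE_KEYS = {"input", "step", "r_max", "search_halfwidth"}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class RunRecord:
    """Provenance of one pipeline run."""

    timestamp: str
    config_hash: str
    seed: int
    version: str
    outputs: dict

    def manifest_hash(self) -> str:
        """Hash of config + output hashes; identical across identical reruns."""
        blob = json.dumps({"config": self.config_hash,
                           "outputs": self.outputs}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def _reject_unknown(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def validate_config(config: dict) -> dict:
    """Validate a config dict; returns it with defaults filled in."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    _reject_unknown(config, _TOP_KEYS, "config")
    cfg = dict(config)
    cfg.setdefault("stages", list(STAGES))
    cfg.setdefault("seed", 0)
    cfg.setdefault("outdir", "ktrkit_out")
    for stage in cfg["stages"]:
        if stage not in STAGES:
            raise ConfigError(f"unknown stage: {stage!r}")
    for key, cls in _PARAM_TYPES.items():
        block = dict(cfg.get(key, {}))
        allowed = {f.name for f in dataclasses.fields(cls)}
        _reject_unknown(block, allowed, key)
        cfg[key] = block
    _reject_unknown(dict(cfg.get("contact_spec", {})), _CONTACT_KEYS,
                    "contact_spec")
    _reject_unknown(dict(cfg.get("deer", {})), _DEER_KEYS, "deer")
    _reject_unknown(dict(cfg.get("pore", {})), _PORE_KEYS, "pore")
    cfg.setdefault("contact_spec", {})
    cfg.setdefault("deer", {})
    cfg.setdefault("pore", {})
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _toy_pore_structure() -> Structure:
    """Hourglass of two dense atom rings: a wide vestibule over a
    constriction, a stand-in channel for the pore demo stage."""
    th = np.linspace(0, 2 * np.pi, 65)[:-1]
    wide = np.column_stack([5 * np.cos(th), 5 * np.sin(th),
                            np.zeros(64)])
    narrow = np.column_stack([3 * np.cos(th), 3 * np.sin(th),
                              np.full(64, 10.0)])
    coords = np.vstack([wide, narrow])
    return Structure(coords=coords, element=["C"] * len(coords),
                     vdw_radius=np.full(len(coords), 1.7))


def run_pipeline(config: dict, outdir: str | Path | None = None) -> RunRecord:
    """Execute the requested stages in dependency order.

    Writes every stage output plus a ``manifest.json`` under the output
    directory and returns the :class:`RunRecord`.
    """
    cfg = validate_config(config)
    out = Path(outdir if outdir is not None else cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = list(cfg["stages"])
    outputs: dict[str, str] = {}

    def emit(name: str, path: Path) -> None:
        outputs[name] = _file_hash(path)

    spec_block = cfg["contact_spec"]
    spec = contacts.ContactSpec(
        native_cutoff=spec_block.get("native_cutoff", 4.5),
        lipid_cutoff=spec_block.get("lipid_cutoff", 3.5),
        beta=spec_block.get("beta", 5.0),
        lam=spec_block.get("lam", 1.5))
    residues = parse_residue_range(spec_block.get("residues", "2-21"))

    deer_block = cfg["deer"]
    r_grid = np.arange(deer_block.get("r_min", 1.5),
                       deer_block.get("r_max", 8.0) + 1e-9,
                       deer_block.get("r_step", 0.02))
    truth = deer.gaussian_distribution(r_grid, deer_block.get("center", 3.3),
                                       deer_block.get("sigma", 0.15))

    traj = None
    if "synth" in stages:
        traj = synthetic.generate_idr_membrane_trajectory(
            synthetic.ToyTrajectoryParams(**{"seed": seed,
                                             **cfg["trajectory"]}))
        io.write_trajectory_pdb(traj, out / "trajectory.pdb")
        emit("trajectory", out / "trajectory.pdb")

        melt = synthetic.generate_melt_curve(
            synthetic.MeltCurveParams(**{"seed": seed, **cfg["melt"]}))
        io.write_melt_csv(melt, out / "melt_curve.csv")
        emit("melt_curve", out / "melt_curve.csv")

        tg = synthetic.generate_itc_thermogram(
            synthetic.ThermogramParams(**{"seed": seed, **cfg["itc"]}))
        import pandas as pd
        pd.DataFrame({"injection": np.arange(1, len(tg.heats) + 1),
                      "heat": tg.heats}).to_csv(out / "thermogram.csv",
                                                index=False)
        emit("thermogram", out / "thermogram.csv")

        uptake = synthetic.generate_uptake_timecourses(
            synthetic.UptakeParams(**{"seed": seed, **cfg["uptake"]}))
        pd.DataFrame(uptake.amounts.T, index=uptake.timepoints,
                     columns=[f"S_{s:g}_mM" for s in uptake.substrate_concs]
                     ).rename_axis("time_min").to_csv(out / "uptake.csv")
        emit("uptake", out / "uptake.csv")

        img = synthetic.generate_class_image(
            synthetic.ClassImageParams(**{"seed": seed, **cfg["image"]}))
        io.write_class_image(img, out / "class_average.png")
        emit("class_average", out / "class_average.png")

        trace = synthetic.generate_deer_trace(synthetic.DeerTraceParams(
            distribution=truth, seed=seed,
            t_max=deer_block.get("t_max", 3.0),
            dt=deer_block.get("dt", 0.008),
            modulation_depth=deer_block.get("modulation_depth", 0.3),
            background_rate=deer_block.get("background_rate", 0.05),
            background_dim=deer_block.get("background_dim", 3.0),
            noise_sd=deer_block.get("noise_sd", 0.0)))
        io.write_trace_csv(trace, out / "deer_trace.csv")
        emit("deer_trace", out / "deer_trace.csv")

    if "contacts" in stages:
        if traj is None:
            traj = io.read_trajectory_pdb(out / "trajectory.pdb")
        ncs = contacts.build_native_contacts(traj, spec)
        q = contacts.q_timeseries(traj, ncs, spec)
        io.write_timeseries_csv(q, out / "q_native.csv", "Q")
        emit("q_native", out / "q_native.csv")
        lc, _per = contacts.lipid_contacts(traj, residues, spec)
        io.write_timeseries_csv(lc, out / "lipid_contacts.csv", "contacts")
        emit("lipid_contacts", out / "lipid_contacts.csv")
        edges, density, _ = contacts.z_distance_distribution(traj, residues)
        io.write_histogram_csv(edges, density, out / "z_histogram.csv")
        emit("z_histogram", out / "z_histogram.csv")
        tl = contacts.terminus_length(traj, residues)
        io.write_timeseries_csv(tl, out / "terminus_length.csv", "length_A")
        emit("terminus_length", out / "terminus_length.csv")

    if "pore" in stages:
        pore_block = cfg["pore"]
        if pore_block.get("input"):
            st = io.read_structure(pore_block["input"])
        else:
            st = _toy_pore_structure()
        prof = pore.pore_radius_profile(
            st, step=pore_block.get("step", 1.0),
            r_max=pore_block.get("r_max", 10.0),
            search_halfwidth=pore_block.get("search_halfwidth", 2.5))
        io.write_profile_csv(prof, out / "pore_profile.csv")
        emit("pore_profile", out / "pore_profile.csv")

    if "shape" in stages:
        img = io.read_class_image(out / "class_average.png")
        long_nm, short_nm = shapes.measure_diameters(img)
        call = shapes.classify_shape(long_nm, short_nm)
        (out / "shape.json").write_text(json.dumps(
            {"long_nm": long_nm, "short_nm": short_nm,
             "ratio": call.ratio, "label": call.label}, indent=2))
        emit("shape", out / "shape.json")

    if "fit_dsf" in stages:
        curve = io.read_melt_csv(out / "melt_curve.csv")
        tm = fits.melting_temperature(curve)
        (out / "dsf_fit.json").write_text(json.dumps({"tm_C": tm}, indent=2))
        emit("dsf_fit", out / "dsf_fit.json")

    if "fit_itc" in stages:
        import pandas as pd
        df = pd.read_csv(out / "thermogram.csv")
        itc_cfg = synthetic.ThermogramParams(**{"seed": seed, **cfg["itc"]})
        tg = fits.Thermogram(
            heats=df["heat"].to_numpy(),
            injection_volumes=np.full(len(df), itc_cfg.inj_volume),
            cell_conc=itc_cfg.cell_conc, syringe_conc=itc_cfg.syringe_conc,
            cell_volume=itc_cfg.cell_volume)
        res = fits.fit_one_site_itc(tg)
        (out / "itc_fit.json").write_text(json.dumps(
            {"kd_uM": res.kd, "dh": res.dh, "n_sites": res.n_sites,
             "residual_norm": res.residual_norm}, indent=2))
        emit("itc_fit", out / "itc_fit.json")

    if "fit_mm" in stages:
        import pandas as pd
        df = pd.read_csv(out / "uptake.csv", index_col="time_min")
        S = np.array([float(c.split("_")[1]) for c in df.columns])
        ds = fits.KineticDataset(substrate_concs=S,
                                 timepoints=df.index.to_numpy(),
                                 amounts=df.to_numpy().T)
        v, se = ds.initial_velocities()
        res = fits.fit_michaelis_menten(S, v)
        (out / "mm_fit.json").write_text(json.dumps(
            {"vmax": res.vmax, "km": res.km, "vmax_se": res.vmax_se,
             "km_se": res.km_se}, indent=2))
        emit("mm_fit", out / "mm_fit.json")

    if "deer" in stages:
        trace = io.read_trace_csv(out / "deer_trace.csv")
        ff = deer.background_correct(
            trace, dim=deer_block.get("background_dim", 3.0))
        res = deer.tikhonov_invert(ff, r_grid=r_grid)
        io.write_distribution_csv(res.distribution,
                                  out / "deer_distribution.csv")
        emit("deer_distribution", out / "deer_distribution.csv")
        stats = res.stats()
        (out / "deer_report.json").write_text(json.dumps(
            {"alpha": res.alpha, "modulation_depth": ff.modulation_depth,
             "background_rate": ff.background_rate, **stats}, indent=2))
        emit("deer_report", out / "deer_report.json")

    from . import __version__
    record = RunRecord(timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
                       config_hash=_config_hash(cfg), seed=seed,
                       version=__version__, outputs=outputs)
    (out / "manifest.json").write_text(json.dumps(
        {"timestamp": record.timestamp, "config_hash": record.config_hash,
         "seed": record.seed, "version": record.version,
         "manifest_hash": record.manifest_hash(),
         "outputs": record.outputs}, indent=2))
    return record
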