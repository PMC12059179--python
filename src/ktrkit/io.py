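"""Readers and writers for the pipeline's on-disk formats.

Structures and trajectories travel as PDB (multi-frame trajectories as
MODEL/ENDMDL blocks, coordinates in Å, 1-based residue numbering);
tabular data as comma-delimited CSV with a header row; class images as
16-bit grayscale PNG with a JSON sidecar carrying the pixel size and
particle count.  PDB parsing and writing are delegated to biotite.
"""

from __future__ import annotations

import json
from pathlib import Path

import biotite.structure as struc
import numpy as np
import pandas as pd
from biotite.structure.io.pdb import PDBFile

from .pore import vdw_radii_for
from .shapes import ClassImage
from .trajectory import Structure, Trajectory

# segment label <-> (chain, residue-name, atom-name, element) conventions
_SEGMENT_CHAIN = {"tail": "T", "core": "C", "partner": "A",
                  "lipid-phosphate": "L", "lipid-acyl": "L"}
_SEGMENT_ATOM = {"tail": ("CA", "C"), "core": ("CA", "C"),
                 "partner": ("CA", "C"), "lipid-phosphate": ("P", "P"),
                 "lipid-acyl": ("C1", "C")}


def _check_model_sizes(path: str | Path) -> None:
    """Fail early, naming the offending MODEL, on ragged multi-model files."""
    sizes: list[tuple[int, int]] = []
    model, count = 0, 0
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
                model = int(line.split()[1])
                count = 0
            elif rec == "ENDMDL":
                sizes.append((model, count))
                in_model = False
            elif rec in ("ATOM", "HETATM") and in_model:
                count += 1
    if sizes:
        ref_model, ref = sizes[0]
        for m, n in sizes[1:]:
            if n != ref:
                raise ValueError(
                    f"inconsistent frame sizes: MODEL {m} has {n} atoms, "
                    f"MODEL {ref_model} has {ref}")


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-MODEL PDB file."""
    n = traj.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord = traj.coords.astype(np.float32)
    stack.chain_id = np.array([_SEGMENT_CHAIN[s] for s in traj.segment])
    stack.res_id = traj.residue_index.copy()
    stack.res_name = np.array([str(r)[:3] for r in traj.residue_name])
    names = [_SEGMENT_ATOM[s] for s in traj.segment]
    stack.atom_name = np.array([a for a, _ in names])
    stack.element = np.array([e for _, e in names])
    stack.hetero = np.array([s.startswith("lipid") for s in traj.segment])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_trajectory_pdb(path: str | Path) -> Trajectory:
    """Read a (multi-)MODEL PDB file back into a :class:`Trajectory`.

    Segment labels are recovered from the chain/residue-name conventions
    used by :func:`write_trajectory_pdb`; unknown chains default to
    ``partner`` so that externally produced bead files remain loadable.
    """
    _check_model_sizes(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    segs = []
    for chain, resname in zip(stack.chain_id, stack.res_name):
        if chain == "T":
            segs.append("tail")
        elif chain == "C":
            segs.append("core")
        elif chain == "L":
            segs.append("lipid-phosphate" if resname == "PHO"
                        else "lipid-acyl")
        else:
            segs.append("partner")
    heavy = stack.element != "H"
    return Trajectory(coords=np.asarray(stack.coord, dtype=float),
                      residue_index=np.asarray(stack.res_id),
                      residue_name=np.asarray(stack.res_name, dtype=object),
                      segment=np.array(segs, dtype=object),
                      heavy=heavy)


def read_structure(path: str | Path, include_hetero: bool = False,
                   vdw_table: dict | None = None) -> Structure:
    """Read a single-model PDB into a :class:`Structure` with Bondi radii.

    Waters, ions and other hetero records are stripped by default, as is
    conventional for pore profiling.
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    if not include_hetero:
        atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise ValueError(f"no atoms read from {path}")
    return Structure(coords=np.asarray(atoms.coord, dtype=float),
                     element=np.asarray(atoms.element, dtype=object),
                     vdw_radius=vdw_radii_for(atoms.element, vdw_table),
                     residue_index=np.asarray(atoms.res_id),
                     chain=np.asarray(atoms.chain_id, dtype=object))


# ---------------------------------------------------------------------------
# tabular formats


def write_timeseries_csv(ts, path: str | Path, value_name: str = "value") -> None:
    pd.DataFrame({"frame": ts.frame_index, value_name: ts.value}).to_csv(
        path, index=False)


def write_histogram_csv(edges: np.ndarray, density: np.ndarray,
                        path: str | Path) -> None:
    pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                  "density": density}).to_csv(path, index=False)


def write_profile_csv(profile, path: str | Path) -> None:
    pd.DataFrame({"z": profile.z, "radius": profile.radius,
                  "cx": profile.center_xy[:, 0],
                  "cy": profile.center_xy[:, 1]}).to_csv(path, index=False)


def write_trace_csv(trace, path: str | Path) -> None:
    pd.DataFrame({"t_us": trace.t, "V": trace.V}).to_csv(path, index=False)


def read_trace_csv(path: str | Path):
    from .deer import DipolarTrace
    df = pd.read_csv(path)
    return DipolarTrace(t=df["t_us"].to_numpy(), V=df["V"].to_numpy())


def write_distribution_csv(dist, path: str | Path) -> None:
    pd.DataFrame({"r_nm": dist.r, "p": dist.p}).to_csv(path, index=False)


def read_distribution_csv(path: str | Path):
    from .deer import DistanceDistribution
    df = pd.read_csv(path)
    return DistanceDistribution(r=df["r_nm"].to_numpy(),
                                p=df["p"].to_numpy())


def write_melt_csv(curve, path: str | Path) -> None:
    pd.DataFrame({"temperature": curve.temperature,
                  "fluorescence": curve.fluorescence}).to_csv(path, index=False)


def read_melt_csv(path: str | Path):
    from .fits import MeltCurve
    df = pd.read_csv(path)
    return MeltCurve(temperature=df["temperature"].to_numpy(),
                     fluorescence=df["fluorescence"].to_numpy())


# ---------------------------------------------------------------------------
# images


def write_class_image(image: ClassImage, path: str | Path) -> None:
    """16-bit grayscale PNG plus a JSON sidecar with the metadata."""
    import imageio.v3 as iio
    path = Path(path)
    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    scale = (hi - lo) or 1.0
    data = np.round((px - lo) / scale * 65535).astype(np.uint16)
    iio.imwrite(path, data)
    meta = {"pixel_size": image.pixel_size, "n_particles": image.n_particles,
            "intensity_min": lo, "intensity_max": hi, **image.meta}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_class_image(path: str | Path) -> ClassImage:
    import imageio.v3 as iio
    path = Path(path)
    data = iio.imread(path).astype(float)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    lo = meta.pop("intensity_min", 0.0)
    hi = meta.pop("intensity_max", 1.0)
    pixels = data / 65535.0 * (hi - lo) + lo
    return ClassImage(pixels=pixels,
                      pixel_size=meta.pop("pixel_size", 1.0),
                      n_particles=meta.pop("n_particles", None),
                      meta=meta)
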