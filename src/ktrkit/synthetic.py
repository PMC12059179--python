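"""Synthetic inputs for every analysis stage.

Each generator emulates the statistical structure of one experimental or
simulated data type consumed downstream, so the whole pipeline runs and
verifies at desk scale without any external download:

* a coarse-grained trajectory of a disordered N-terminal tail tethered
  below an anionic bilayer slab (one bead per residue; the charge
  character mimics a 45% POPE / 40% POPG / 15% cardiolipin membrane),
* two-state thermal melt curves,
* one-site titration thermograms,
* saturable uptake time courses at 0.1/0.2/0.4/1 mM substrate,
* elliptical-ring class images,
* dipolar evolution traces with intermolecular background.

Every generator takes an explicit integer seed and derives its own
random stream from it, so identical parameters give bit-identical output
and adding one generator call never shifts another's stream.  With the
noise amplitude at zero every generator is deterministic and round-trips
exactly with its matching analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import deer as _deer
from . import fits as _fits
from .shapes import ClassImage
from .trajectory import Trajectory

# tail residue numbering mirrors the pore subunit's N-terminal region
# (residues 2-21): hydrophobic patch V9-P13, basic cluster K16/R17/K19/K21.
HYDROPHOBIC_RESIDUES = frozenset(range(9, 14))
BASIC_RESIDUES = frozenset({16, 17, 19, 21})
TAIL_FIRST_RESIDUE = 2
BOND_LENGTH = 3.8  # Å, consecutive residue-bead spacing


# ---------------------------------------------------------------------------
# trajectory generator


@dataclass
class ToyTrajectoryParams:
    """Parameters of the tethered-tail / bilayer-slab toy system.

    ``anchor_z`` is the depth (Å) of the tail tether below the proximal
    phosphate plane at ``slab_z``; ``membrane_affinity`` (dimensionless,
    >= 0) sets the strength of the attraction pulling the tagged basic
    and hydrophobic tail beads toward the slab.
    """

    n_frames: int = 200
    timestep: float = 1.0  # ns per frame (labelling only)
    tail_length: int = 20
    anchor_z: float = 30.0
    membrane_affinity: float = 5.0
    slab_z: float = 0.0
    seed: int = 0
    membrane_halfwidth: float = 40.0  # lateral extent of the slab, Å
    lipid_spacing: float = 4.0  # head-group grid spacing, Å

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.tail_length < 2:
            raise ValueError("tail_length must be >= 2")
        if self.membrane_affinity < 0:
            raise ValueError("membrane_affinity must be >= 0")


def _tail_residue_names(residues: np.ndarray) -> np.ndarray:
    names = []
    for r in residues:
        if r in HYDROPHOBIC_RESIDUES:
            names.append("HPH")
        elif r in BASIC_RESIDUES:
            names.append("BAS")
        else:
            names.append("GLY")
    return np.array(names, dtype=object)


def _grow_tail(rng: np.random.Generator, anchor: np.ndarray,
               residues: np.ndarray, affinity: float,
               slab_z: float) -> np.ndarray:
    """One tail conformation: a tethered random walk from the anchor.

    Steps have fixed bond length and are Metropolis-filtered against the
    linear attraction U(z) = affinity * (slab_z - z) / bond_length (in
    thermal units) felt by the tagged basic/hydrophobic beads.  The pull
    on a tagged bead is transmitted through the tether, so the step that
    places bead k feels the attraction scaled by the fraction of tagged
    beads at or beyond k.  Beads never cross the phosphate plane: a step
    that would is reflected in z.
    """
    tagged = np.array([(r in HYDROPHOBIC_RESIDUES or r in BASIC_RESIDUES)
                       for r in residues])
    n_tagged = max(int(tagged.sum()), 1)
    # tension: tagged beads at or beyond the one being placed
    downstream = np.cumsum(tagged[::-1])[::-1]
    pos = np.empty((len(residues), 3))
    pos[0] = anchor
    for k in range(1, len(residues)):
        prev = pos[k - 1]
        a_k = affinity * downstream[k] / n_tagged
        for _ in range(64):
            step = rng.normal(size=3)
            step *= BOND_LENGTH / np.linalg.norm(step)
            if a_k > 0:
                # Metropolis acceptance on the vertical displacement
                du = a_k * (-step[2]) / BOND_LENGTH
                if du > 0 and rng.random() >= np.exp(-du):
                    continue
            break
        new = prev + step
        if new[2] > slab_z:  # reflect at the phosphate plane
            new[2] = 2.0 * slab_z - new[2]
        pos[k] = new
    return pos


def generate_idr_membrane_trajectory(params: ToyTrajectoryParams) -> Trajectory:
    """Bead-model trajectory of a disordered tail below a bilayer slab.

    The system contains a static rigid core (the transmembrane body), a
    static partner patch (the regulator-ring surface) laid alongside the
    docked tail, a two-leaflet slab of phosphate beads with acyl beads
    between them (one lipid molecule per grid site), and a flexible tail
    of ``tail_length`` beads tethered to the core.  Frame 0 is the docked
    reference pose lying along the partner patch; subsequent frames are
    independent tethered random walks biased toward the slab by the
    membrane affinity.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    anchor_abs = p.slab_z - p.anchor_z
    residues = np.arange(TAIL_FIRST_RESIDUE, TAIL_FIRST_RESIDUE + p.tail_length)

    # membrane: lower leaflet faces the protein; each grid site is one
    # lipid molecule (phosphate head bead + acyl bead above it)
    g = np.arange(-p.membrane_halfwidth, p.membrane_halfwidth + 1e-9,
                  p.lipid_spacing)
    gx, gy = np.meshgrid(g, g)
    sites = np.column_stack([gx.ravel(), gy.ravel()])
    n_sites = len(sites)
    thickness = 38.0
    lipid_xyz, lipid_res, lipid_seg = [], [], []
    rid = 1000
    for leaflet_z, acyl_dz in [(p.slab_z, 10.0),
                               (p.slab_z + thickness, -10.0)]:
        for s in sites:
            lipid_xyz.append([s[0], s[1], leaflet_z])
            lipid_seg.append("lipid-phosphate")
            lipid_res.append(rid)
            lipid_xyz.append([s[0], s[1], leaflet_z + acyl_dz])
            lipid_seg.append("lipid-acyl")
            lipid_res.append(rid)
            rid += 1
    lipid_xyz = np.array(lipid_xyz)

    # rigid core block below the anchor
    cg = np.arange(-4.0, 4.1, 4.0)
    cx, cy = np.meshgrid(cg, cg)
    core_xyz = np.column_stack([cx.ravel(), cy.ravel(),
                                np.full(cx.size, anchor_abs - 6.0)])

    # docked reference tail: straight along +x at the anchor depth
    docked = np.column_stack([
        np.arange(p.tail_length) * BOND_LENGTH,
        np.zeros(p.tail_length),
        np.full(p.tail_length, anchor_abs),
    ])
    anchor = docked[0].copy()
    # partner surface: beads alongside the docked tail, 4.0 Å off in y
    partner_xyz = docked + np.array([0.0, 4.0, 0.0])

    static = np.vstack([core_xyz, partner_xyz, lipid_xyz])
    n_static = len(static)
    n_atoms = p.tail_length + n_static

    coords = np.empty((p.n_frames, n_atoms, 3))
    for f in range(p.n_frames):
        if f == 0:
            tail = docked
        else:
            tail = _grow_tail(rng, anchor, residues, p.membrane_affinity,
                              p.slab_z)
        coords[f, :p.tail_length] = tail
        coords[f, p.tail_length:] = static

    residue_index = np.concatenate([
        residues,
        np.arange(100, 100 + len(core_xyz)),
        np.arange(200, 200 + len(partner_xyz)),
        np.asarray(lipid_res),
    ])
    residue_name = np.concatenate([
        _tail_residue_names(residues),
        np.array(["COR"] * len(core_xyz), dtype=object),
        np.array(["PAR"] * len(partner_xyz), dtype=object),
        np.array(["PHO" if s == "lipid-phosphate" else "ACY"
                  for s in lipid_seg], dtype=object),
    ])
    segment = np.concatenate([
        np.array(["tail"] * p.tail_length, dtype=object),
        np.array(["core"] * len(core_xyz), dtype=object),
        np.array(["partner"] * len(partner_xyz), dtype=object),
        np.asarray(lipid_seg, dtype=object),
    ])
    return Trajectory(coords=coords, residue_index=residue_index,
                      residue_name=residue_name, segment=segment,
                      timestep=p.timestep)


# ---------------------------------------------------------------------------
# melt curves


@dataclass
class MeltCurveParams:
    """Two-state (logistic) melt curve parameters; slope is the transition
    width in °C."""

    tm: float = 67.0
    baseline_low: float = 1000.0
    baseline_high: float = 9000.0
    slope: float = 2.0
    t_range: np.ndarray = field(
        default_factory=lambda: np.arange(25.0, 80.0 + 0.5, 1.0))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.t_range = np.asarray(self.t_range, dtype=float)
        if self.t_range.size == 0:
            raise ValueError("t_range is empty")
        if np.any(np.diff(self.t_range) <= 0):
            raise ValueError("t_range must be strictly increasing")
        if self.slope <= 0:
            raise ValueError("slope must be positive")


def generate_melt_curve(params: MeltCurveParams) -> _fits.MeltCurve:
    """Two-state sigmoid between the baselines, inflection at Tm."""
    p = params
    rng = np.random.default_rng(p.seed)
    T = p.t_range
    F = p.baseline_low + (p.baseline_high - p.baseline_low) / (
        1.0 + np.exp(-(T - p.tm) / p.slope))
    if p.noise_sd > 0:
        F = F + rng.normal(0.0, p.noise_sd, size=T.shape)
    return _fits.MeltCurve(temperature=T, fluorescence=F)


# ---------------------------------------------------------------------------
# ITC thermograms


@dataclass
class ThermogramParams:
    """Single-site titration parameters (µM, µL; dh per mole injectant)."""

    kd: float = 3.4
    dh: float = -10.0
    n_sites: float = 1.0
    cell_conc: float = 60.0
    syringe_conc: float = 800.0
    n_injections: int = 20
    inj_volume: float = 2.0
    cell_volume: float = 280.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.kd, self.cell_conc, self.syringe_conc,
               self.inj_volume, self.cell_volume) <= 0:
            raise ValueError("concentrations and volumes must be positive")
        if self.n_injections < 2:
            raise ValueError("need at least 2 injections")


def generate_itc_thermogram(params: ThermogramParams) -> _fits.Thermogram:
    """Per-injection heats from the exact single-site mass balance."""
    import logging
    p = params
    if p.syringe_conc <= p.cell_conc * p.n_sites / 100.0:
        logging.getLogger(__name__).warning(
            "syringe concentration %.3g µM cannot approach saturation of "
            "%.3g µM sites", p.syringe_conc, p.cell_conc * p.n_sites)
    rng = np.random.default_rng(p.seed)
    vols = np.full(p.n_injections, p.inj_volume)
    heats = _fits.itc_injection_heats(p.kd, p.dh, p.n_sites, p.cell_conc,
                                      p.syringe_conc, vols, p.cell_volume)
    if p.noise_sd > 0:
        heats = heats + rng.normal(0.0, p.noise_sd, size=heats.shape)
    return _fits.Thermogram(heats=heats, injection_volumes=vols,
                            cell_conc=p.cell_conc,
                            syringe_conc=p.syringe_conc,
                            cell_volume=p.cell_volume)


# ---------------------------------------------------------------------------
# uptake time courses


@dataclass
class UptakeParams:
    """Saturable uptake with Michaelis-Menten initial velocities.

    vmax in nmol/mg/min, km and substrate concentrations in mM,
    timepoints in min (defaults mirror sampling at 1,2,3,4,7,10 min).
    """

    vmax: float = 197.0
    km: float = 0.2
    substrate_concs: tuple = (0.1, 0.2, 0.4, 1.0)
    timepoints: tuple = (1.0, 2.0, 3.0, 4.0, 7.0, 10.0)
    linear_until: float = 4.0  # min; courses are exactly linear up to here
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("vmax and km must be positive")
        if len(self.substrate_concs) == 0:
            raise ValueError("substrate concentration list is empty")


def generate_uptake_timecourses(params: UptakeParams) -> _fits.KineticDataset:
    """Time courses whose initial slope is exactly Vmax*S/(Km + S).

    Each course rises linearly at the Michaelis-Menten velocity through
    ``linear_until`` (covering the early sampling window) and then relaxes
    exponentially toward a plateau, C1-continuously.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    t = np.asarray(p.timepoints, dtype=float)
    S = np.asarray(p.substrate_concs, dtype=float)
    amounts = np.empty((len(S), len(t)))
    for i, s in enumerate(S):
        v0 = _fits.michaelis_menten(s, p.vmax, p.km)
        plateau = 1.5 * v0 * p.linear_until
        a_lin = v0 * np.minimum(t, p.linear_until)
        tail = t > p.linear_until
        a = a_lin.copy()
        gap = plateau - v0 * p.linear_until
        a[tail] = plateau - gap * np.exp(-v0 * (t[tail] - p.linear_until) / gap)
        if p.noise_sd > 0:
            a = a + rng.normal(0.0, p.noise_sd, size=a.shape)
        amounts[i] = a
    return _fits.KineticDataset(substrate_concs=S, timepoints=t,
                                amounts=amounts)


# ---------------------------------------------------------------------------
# class images


@dataclass
class ClassImageParams:
    """Elliptical-ring class-average image (axes in nm)."""

    long_axis: float = 7.8
    short_axis: float = 6.3
    pixel_size: float = 0.05
    image_size: int = 220
    ring_thickness: float = 1.0
    angle_deg: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.long_axis >= self.short_axis > 0:
            raise ValueError("need long_axis >= short_axis > 0")
        if self.pixel_size <= 0 or self.image_size < 4:
            raise ValueError("invalid image geometry")
        if self.long_axis / self.pixel_size > self.image_size - 4:
            raise ValueError("ellipse exceeds the image bounds")


def generate_class_image(params: ClassImageParams,
                         supersample: int = 4) -> ClassImage:
    """Grayscale elliptical ring with ground-truth axes in the metadata.

    Rendered on a ``supersample``-times finer grid and block-averaged so
    edge pixels carry partial-volume intensities, as class averages do.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.image_size
    ss = supersample
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n * ss, 0:n * ss]
    # supersampled pixel centers in units of full-size pixels
    xs = (xx + 0.5) / ss - 0.5 - c
    ys = (yy + 0.5) / ss - 0.5 - c
    th = np.deg2rad(p.angle_deg)
    u = xs * np.cos(th) + ys * np.sin(th)
    v = -xs * np.sin(th) + ys * np.cos(th)
    a_out = p.long_axis / 2.0 / p.pixel_size
    b_out = p.short_axis / 2.0 / p.pixel_size
    t_px = p.ring_thickness / p.pixel_size
    a_in = max(a_out - t_px, 0.5)
    b_in = max(b_out - t_px, 0.5)
    outer = (u / a_out) ** 2 + (v / b_out) ** 2 <= 1.0
    inner = (u / a_in) ** 2 + (v / b_in) ** 2 <= 1.0
    fine = (outer & ~inner).astype(float)
    img = fine.reshape(n, ss, n, ss).mean(axis=(1, 3))
    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, size=img.shape)
    return ClassImage(pixels=img, pixel_size=p.pixel_size,
                      meta={"true_long_axis": p.long_axis,
                            "true_short_axis": p.short_axis,
                            "angle_deg": p.angle_deg,
                            "ring_thickness": p.ring_thickness})


# ---------------------------------------------------------------------------
# DEER traces


@dataclass
class DeerTraceParams:
    """Dipolar-evolution trace parameters.

    ``distribution`` is the ground-truth P(r); the trace is
    V(t) = [(1 - Delta) + Delta F(t)] * exp(-k t^(d/3)) with V(0) = 1.
    """

    distribution: _deer.DistanceDistribution = None  # type: ignore
    t_max: float = 3.0  # µs
    dt: float = 0.008  # µs
    modulation_depth: float = 0.3
    background_rate: float = 0.05  # 1/µs
    background_dim: float = 3.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distribution is None:
            raise ValueError("a ground-truth distribution is required")
        if not 0 <= self.modulation_depth <= 1:
            raise ValueError("modulation depth must lie in [0, 1]")
        if self.t_max <= 0 or self.dt <= 0:
            raise ValueError("t_max and dt must be positive")


def generate_deer_trace(params: DeerTraceParams) -> _deer.DipolarTrace:
    """Forward-simulate the primary dipolar trace, V(0) = 1 exactly."""
    p = params
    if not p.distribution.is_normalized(1e-6):
        raise ValueError("distribution must be normalized to unit integral")
    rng = np.random.default_rng(p.seed)
    t = np.arange(0.0, p.t_max + p.dt / 2, p.dt)
    F = _deer.form_factor_from_distribution(t, p.distribution)
    B = np.exp(-p.background_rate * t ** (p.background_dim / 3.0))
    V = ((1.0 - p.modulation_depth) + p.modulation_depth * F) * B
    if p.noise_sd > 0:
        noise = rng.normal(0.0, p.noise_sd, size=V.shape)
        noise[0] = 0.0  # keep the V(0) = 1 normalization exact
        V = V + noise
    return _deer.DipolarTrace(t=t, V=V)
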