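"""Trajectory observables for the IDR/membrane and IDR/partner interfaces.

Implements the standard MD observables used to characterize a flexible
N-terminal tail: the fraction of native contacts Q with a smooth logistic
switching function, residue–lipid contact counts, the distribution of
vertical distances to the membrane phosphate plane, and the end-to-end
terminus length.

The native-contact fraction of a configuration X is

    Q(X) = (1/N) * sum_{(i,j)} 1 / (1 + exp(beta * (r_ij(X) - lam * r_ij^0)))

over the N heavy-atom pairs (i, j) closer than the native cutoff in the
reference structure, with smoothing beta = 5 1/Å and padding lam = 1.5 by
default.  A residue and a lipid molecule are in contact in a frame when at
least one heavy-atom pair is within the lipid cutoff (3.5 Å); each
residue–lipid pair counts once per frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .trajectory import Trajectory

log = logging.getLogger(__name__)


@dataclass
class ContactSpec:
    """Parameters of the contact definitions.

    native_cutoff (Å) selects reference pairs; lipid_cutoff (Å) defines
    residue–lipid contacts; beta (1/Å) and lam are the logistic smoothing
    and padding of the Q switching function.
    """

    native_cutoff: float = 4.5
    lipid_cutoff: float = 3.5
    beta: float = 5.0
    lam: float = 1.5
    group_a: "range | list[int]" = field(default_factory=lambda: range(7, 14))
    group_b_segment: str = "partner"

    def __post_init__(self) -> None:
        if self.native_cutoff <= 0 or self.lipid_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.lam < 1:
            raise ValueError("lam must be >= 1")


@dataclass
class NativeContactSet:
    """Reference contact pairs (atom_i, atom_j, r0) with r0 < native cutoff."""

    atom_i: np.ndarray
    atom_j: np.ndarray
    r0: np.ndarray

    def __post_init__(self) -> None:
        self.atom_i = np.asarray(self.atom_i, dtype=int)
        self.atom_j = np.asarray(self.atom_j, dtype=int)
        self.r0 = np.asarray(self.r0, dtype=float)

    def __len__(self) -> int:
        return len(self.r0)


@dataclass
class TimeSeries:
    """A per-frame scalar observable."""

    frame_index: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        if self.frame_index.shape != self.value.shape:
            raise ValueError("frame_index and value must match in length")


def build_native_contacts(traj: Trajectory, spec: ContactSpec,
                          ref_frame: int = 0) -> NativeContactSet:
    """Heavy-atom pairs between the tail group and the partner segment
    closer than the native cutoff in the reference frame."""
    mask_a = traj.atom_mask(segment="tail", residues=spec.group_a)
    mask_b = traj.atom_mask(segment=spec.group_b_segment)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("native-contact groups must be non-empty")
    ia = np.flatnonzero(mask_a)
    ib = np.flatnonzero(mask_b)
    xyz = traj.frame(ref_frame)
    d = cdist(xyz[ia], xyz[ib])
    sel = d < spec.native_cutoff
    if not sel.any():
        log.warning("no native contacts below %.2f Å in the reference frame",
                    spec.native_cutoff)
    ii, jj = np.nonzero(sel)
    return NativeContactSet(atom_i=ia[ii], atom_j=ib[jj], r0=d[ii, jj])


def fraction_native_contacts(frame_xyz: np.ndarray,
                             contacts: NativeContactSet,
                             spec: ContactSpec) -> float:
    """Q of one configuration; strictly inside (0, 1)."""
    if len(contacts) == 0:
        raise ValueError("empty native-contact set (N = 0)")
    r = np.linalg.norm(frame_xyz[contacts.atom_i] - frame_xyz[contacts.atom_j],
                       axis=1)
    x = spec.beta * (r - spec.lam * contacts.r0)
    # clip the exponent for overflow safety only; the result is unchanged
    return float(np.mean(1.0 / (1.0 + np.exp(np.clip(x, -500, 500)))))


def q_timeseries(traj: Trajectory, contacts: NativeContactSet,
                 spec: ContactSpec) -> TimeSeries:
    """Per-frame fraction of native contacts Q(t)."""
    q = np.array([fraction_native_contacts(traj.frame(i), contacts, spec)
                  for i in range(traj.n_frames)])
    return TimeSeries(frame_index=np.arange(traj.n_frames), value=q)


def lipid_contacts(traj: Trajectory, residues, spec: ContactSpec
                   ) -> tuple[TimeSeries, dict[int, float]]:
    """Residue–lipid contact counts.

    Returns the per-frame total number of (residue, lipid-molecule) pairs
    within the lipid cutoff — each pair counted once per frame regardless
    of how many atom pairs qualify — and the mean per-residue contact
    count over the trajectory.
    """
    res_mask = traj.atom_mask(segment="tail", residues=residues)
    if not res_mask.any():
        raise ValueError("residue selection is empty")
    lip_mask = traj.atom_mask(segment="lipid-phosphate") | \
        traj.atom_mask(segment="lipid-acyl")
    if not lip_mask.any():
        raise ValueError("trajectory contains no lipid atoms")
    ires = np.flatnonzero(res_mask)
    ilip = np.flatnonzero(lip_mask)
    res_ids = traj.residue_index[ires]
    lip_ids = traj.residue_index[ilip]
    uniq_res = np.unique(res_ids)
    counts = np.empty(traj.n_frames)
    per_res = {int(r): 0.0 for r in uniq_res}
    for f in range(traj.n_frames):
        xyz = traj.frame(f)
        close = cdist(xyz[ires], xyz[ilip]) <= spec.lipid_cutoff
        n_frame = 0
        for r in uniq_res:
            row = close[res_ids == r]
            touched = np.unique(lip_ids[row.any(axis=0)])
            per_res[int(r)] += len(touched)
            n_frame += len(touched)
        counts[f] = n_frame
    for r in per_res:
        per_res[r] /= traj.n_frames
    return TimeSeries(np.arange(traj.n_frames), counts), per_res


def _residue_reference_points(traj: Trajectory, residues,
                              frame: int) -> np.ndarray:
    """Heavy-atom centroid of each selected tail residue, ordered by index."""
    mask = traj.atom_mask(segment="tail", residues=residues)
    if not mask.any():
        raise ValueError("residue selection outside the trajectory")
    idx = np.flatnonzero(mask)
    rids = traj.residue_index[idx]
    xyz = traj.frame(frame)
    return np.array([xyz[idx[rids == r]].mean(axis=0)
                     for r in np.unique(rids)])


def z_distance_distribution(traj: Trajectory, residues,
                            bin_width: float = 1.0
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed vertical distance of tail residues to the proximal phosphate
    plane, histogrammed over all frames.

    The proximal leaflet is the phosphate layer whose mean z is nearest
    the selection's mean z; z = 0 is that leaflet's mean phosphate
    position, and distances below the plane are negative.

    Returns ``(bin_edges, density, samples)``.
    """
    pho_mask = traj.atom_mask(segment="lipid-phosphate")
    if not pho_mask.any():
        raise ValueError("trajectory contains no phosphate atoms")
    ipho = np.flatnonzero(pho_mask)
    samples = []
    for f in range(traj.n_frames):
        pts = _residue_reference_points(traj, residues, f)
        zpho = traj.frame(f)[ipho, 2]
        # split phosphates into leaflets by z relative to their midpoint
        mid = 0.5 * (zpho.min() + zpho.max())
        lower, upper = zpho[zpho <= mid], zpho[zpho > mid]
        sel_z = pts[:, 2].mean()
        planes = [z.mean() for z in (lower, upper) if len(z)]
        plane = min(planes, key=lambda zp: abs(zp - sel_z))
        samples.append(pts[:, 2] - plane)
    samples = np.concatenate(samples)
    lo = np.floor(samples.min() / bin_width) * bin_width
    hi = np.ceil(samples.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    density, edges = np.histogram(samples, bins=edges, density=True)
    return edges, density, samples


def terminus_length(traj: Trajectory, residue_range) -> TimeSeries:
    """Per-frame end-to-end distance (Å) between the centroids of the
    first and last residues of the range."""
    residues = list(residue_range)
    if len(residues) < 2:
        raise ValueError("range must contain at least 2 residues")
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        pts = _residue_reference_points(traj, residues, f)
        if len(pts) < 2:
            raise ValueError("range must contain at least 2 residues "
                             "present in the trajectory")
        values[f] = np.linalg.norm(pts[-1] - pts[0])
    return TimeSeries(np.arange(traj.n_frames), values)
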