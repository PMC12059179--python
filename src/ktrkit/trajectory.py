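"""Lightweight containers for bead/atom coordinate data.

Coordinates are stored in ångström throughout the package; distance
distributions and ring axes that the field conventionally reports in
nanometre are converted at the reporting boundary only.

Segment labels partition the particles into the roles the downstream
analyses expect:

``tail``
    the flexible N-terminal region of the pore subunit (one bead or one
    residue's heavy atoms per residue),
``core``
    the rigid transmembrane body the tail is tethered to,
``partner``
    the cytosolic regulator surface (the RCK-ring side of the interface),
``lipid-phosphate`` / ``lipid-acyl``
    membrane head-group and acyl-chain particles; the mean phosphate plane
    of the leaflet facing a selection defines z = 0 for membrane-distance
    observables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SEGMENT_LABELS = ("tail", "core", "partner", "lipid-phosphate", "lipid-acyl")


@dataclass
class Trajectory:
    """An ordered stack of frames over a fixed particle topology.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Å.
    residue_index : ndarray of int, shape (n_atoms,)
        1-based residue numbering. Lipid particles use the residue index as
        the lipid-molecule identifier (one residue = one lipid molecule).
    residue_name : ndarray of str, shape (n_atoms,)
    segment : ndarray of str, shape (n_atoms,)
        One of :data:`SEGMENT_LABELS`.
    heavy : ndarray of bool, shape (n_atoms,)
        Heavy-atom flag; contact statistics only consider heavy atoms.
    timestep : float
        Nominal time per frame (ns), used only for axis labelling.
    """

    coords: np.ndarray
    residue_index: np.ndarray
    residue_name: np.ndarray
    segment: np.ndarray
    heavy: np.ndarray = None  # type: ignore[assignment]
    timestep: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n_atoms = self.coords.shape[1]
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.segment = np.asarray(self.segment, dtype=object)
        if self.heavy is None:
            self.heavy = np.ones(n_atoms, dtype=bool)
        self.heavy = np.asarray(self.heavy, dtype=bool)
        for arr, name in [
            (self.residue_index, "residue_index"),
            (self.residue_name, "residue_name"),
            (self.segment, "segment"),
            (self.heavy, "heavy"),
        ]:
            if arr.shape != (n_atoms,):
                raise ValueError(f"{name} must have one entry per atom")
        unknown = set(self.segment) - set(SEGMENT_LABELS)
        if unknown:
            raise ValueError(f"unknown segment labels: {sorted(unknown)}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        """Coordinates of frame ``i`` as an (n_atoms, 3) array."""
        return self.coords[i]

    def atom_mask(self, segment: str | None = None,
                  residues: "slice | range | list[int] | None" = None,
                  heavy_only: bool = True) -> np.ndarray:
        """Boolean mask selecting atoms by segment and residue index."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if segment is not None:
            mask &= self.segment == segment
        if residues is not None:
            mask &= np.isin(self.residue_index, np.asarray(list(residues)))
        if heavy_only:
            mask &= self.heavy
        return mask


@dataclass
class Structure:
    """A single-frame structure with per-atom van der Waals radii (Å)."""

    coords: np.ndarray
    element: np.ndarray
    vdw_radius: np.ndarray
    residue_index: np.ndarray = None  # type: ignore[assignment]
    chain: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = self.coords.shape[0]
        self.element = np.asarray(self.element, dtype=object)
        self.vdw_radius = np.asarray(self.vdw_radius, dtype=float)
        if self.vdw_radius.shape != (n,) or np.any(self.vdw_radius <= 0):
            raise ValueError("vdw_radius must be positive, one per atom")
        if self.residue_index is None:
            self.residue_index = np.arange(1, n + 1)
        if self.chain is None:
            self.chain = np.array(["A"] * n, dtype=object)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.chain = np.asarray(self.chain, dtype=object)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


def parse_residue_range(spec: str) -> range:
    """Parse a residue-range string such as ``"2-21"`` or ``"7-13"``.

    A single number is accepted as a one-residue range.
    """
    spec = spec.strip()
    if "-" in spec[1:]:
        head, tail = spec.rsplit("-", 1)
        lo, hi = int(head), int(tail)
    else:
        lo = hi = int(spec)
    if hi < lo:
        raise ValueError(f"empty residue range: {spec!r}")
    return range(lo, hi + 1)
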