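"""Pore-radius profiling along a channel axis.

A simplified inscribed-sphere scan in the spirit of HOLE: at each position
z along the channel axis the pore radius is the radius of the largest
probe sphere centred in that plane that touches no atom,

    R(z) = max_{(cx, cy)} min_i ( |c - x_i| - vdw_i ),

clamped to [0, r_max].  The in-plane maximization uses a coarse grid over
a search box around the axis followed by Nelder-Mead refinement; this
reproduces the radius-vs-z curve for near-axial channels without HOLE's
3D Monte Carlo path search.  Van der Waals radii default to the Bondi
element set, which differs slightly from HOLE's own table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .trajectory import Structure

#: Bondi van der Waals radii (Å) by element symbol.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "K": 2.75, "NA": 2.27, "MG": 1.73, "ZN": 1.39,
}
DEFAULT_VDW = 1.70

#: Pauling radius of a dehydrated K+ ion (Å), the reference line the
#: constriction is compared against.
K_ION_RADIUS = 1.33


@dataclass
class PoreProfile:
    """Radius (Å) of the largest probe sphere along the axis."""

    z: np.ndarray
    radius: np.ndarray
    center_xy: np.ndarray
    r_max: float

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.center_xy = np.asarray(self.center_xy, dtype=float)
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z must be strictly increasing")
        if np.any(self.radius < 0) or np.any(self.radius > self.r_max + 1e-9):
            raise ValueError("radii must lie in [0, r_max]")

    @property
    def diameter(self) -> np.ndarray:
        """2 * radius, the conventional constriction-size report."""
        return 2.0 * self.radius

    def plot(self, path=None, ax=None):
        """Radius-vs-z curve with the dehydrated-K+ radius as reference."""
        import matplotlib
        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        ax.plot(self.z, self.radius, color="teal")
        ax.axhline(K_ION_RADIUS, ls="--", color="gray",
                   label="dehydrated K$^+$")
        ax.set_xlabel("z along pore axis (Å)")
        ax.set_ylabel("pore radius (Å)")
        ax.legend(frameon=False)
        if path is not None:
            ax.figure.savefig(path, bbox_inches="tight", dpi=150)
            plt.close(ax.figure)
        return ax


def vdw_radii_for(elements, table: dict | None = None) -> np.ndarray:
    """Van der Waals radius per element from the (Bondi) table."""
    table = BONDI_RADII if table is None else table
    return np.array([table.get(str(e).upper(), DEFAULT_VDW) for e in elements])


def _clearance(center_xy, z, coords, vdw):
    c = np.array([center_xy[0], center_xy[1], z])
    return float(np.min(np.linalg.norm(coords - c, axis=1) - vdw))


def pore_radius_profile(structure: Structure,
                        z_range: tuple[float, float] | None = None,
                        step: float = 1.0,
                        r_max: float = 10.0,
                        axis_xy: tuple[float, float] | None = None,
                        search_halfwidth: float = 2.5,
                        coarse_step: float = 0.25) -> PoreProfile:
    """Scan the pore radius along the z axis.

    Parameters
    ----------
    structure : Structure
        Atoms with van der Waals radii; orient the channel along z first
        (or pass transformed coordinates).
    z_range : (float, float), optional
        Axis interval to scan; defaults to the structure's z extent.
    step : float
        Axis sampling step in Å.
    r_max : float
        Radius cap; planes with no atom within ``r_max + max(vdw)`` of the
        axis report ``r_max`` (open channel).
    axis_xy : (float, float), optional
        In-plane axis position; defaults to the atom centroid.
    search_halfwidth, coarse_step : float
        Half-width and coarse grid spacing of the in-plane search box
        around the axis; the coarse optimum is refined by Nelder-Mead.
        Keep the box narrow enough that the probe cannot escape the pore
        sideways around thin wall sections; widen it for channels whose
        lumen drifts far off the chosen axis.
    """
    if structure.n_atoms == 0:
        raise ValueError("empty structure")
    if step <= 0:
        raise ValueError("step must be positive")
    coords = structure.coords
    vdw = structure.vdw_radius
    if axis_xy is None:
        axis_xy = tuple(coords[:, :2].mean(axis=0))
    if z_range is None:
        z_range = (coords[:, 2].min(), coords[:, 2].max())
    z_grid = np.arange(z_range[0], z_range[1] + step / 2, step)
    if len(z_grid) < 2:
        z_grid = np.array([z_range[0], z_range[0] + step])

    offsets = np.arange(-search_halfwidth, search_halfwidth + coarse_step / 2,
                        coarse_step)
    gx, gy = np.meshgrid(axis_xy[0] + offsets, axis_xy[1] + offsets)
    grid = np.column_stack([gx.ravel(), gy.ravel()])

    reach = r_max + float(vdw.max())
    radii = np.empty(len(z_grid))
    centers = np.empty((len(z_grid), 2))
    for k, z in enumerate(z_grid):
        near = np.abs(coords[:, 2] - z) <= reach
        if not near.any():
            radii[k] = r_max
            centers[k] = axis_xy
            continue
        sub, subv = coords[near], vdw[near]
        # coarse scan (vectorized over the grid)
        d = np.linalg.norm(sub[None, :, :2] - grid[:, None, :], axis=2)
        dz = sub[:, 2] - z
        full = np.sqrt(d ** 2 + dz[None, :] ** 2) - subv[None, :]
        coarse = full.min(axis=1)
        best = grid[int(np.argmax(coarse))]

        def neg_clearance(c):
            # confine the refinement to the search box
            if (abs(c[0] - axis_xy[0]) > search_halfwidth
                    or abs(c[1] - axis_xy[1]) > search_halfwidth):
                return np.inf
            return -_clearance(c, z, sub, subv)

        res = minimize(neg_clearance, best, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6,
                                "maxiter": 400})
        r = max(-res.fun, coarse.max())
        radii[k] = float(np.clip(r, 0.0, r_max))
        centers[k] = res.x if -res.fun >= coarse.max() else best
    return PoreProfile(z=z_grid, radius=radii, center_xy=centers, r_max=r_max)


def min_constriction(profile: PoreProfile) -> tuple[float, float]:
    """(z, radius) of the global minimum; ties resolved to the smallest z."""
    if len(profile.z) == 0:
        raise ValueError("empty profile")
    i = int(np.argmin(profile.radius))  # argmin takes the first minimum
    return float(profile.z[i]), float(profile.radius[i])
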