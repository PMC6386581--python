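"""Single-cell mass, volume and density from two-fluid buoyant masses.

A suspended microchannel resonator (SMR) weighs a cell in a fluid,
yielding the buoyant mass

    m_b = V * (rho_cell - rho_fluid)      [1 pg = 1 fL * g/mL]

Weighing the same cell in two fluids of different density gives two
linear equations, from which absolute mass, volume and density follow:

    V   = (m_b1 - m_b2) / (rho_f2 - rho_f1)
    rho = rho_f1 + m_b1 / V
    m   = rho * V
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BuoyantPair",
    "CellPhysical",
    "solve_cell_physical",
    "normalize_excess_density",
    "density_volume_profile",
]


@dataclass(frozen=True)
class BuoyantPair:
    """Buoyant masses (pg) of one cell in two fluids (g/mL)."""

    m_b1: float
    m_b2: float
    rho_f1: float
    rho_f2: float

    def __post_init__(self) -> None:
        vals = (self.m_b1, self.m_b2, self.rho_f1, self.rho_f2)
        if not all(np.isfinite(vals)):
            raise ValueError("buoyant pair values must be finite")
        if self.rho_f1 == self.rho_f2:
            raise ValueError("the two fluid densities must differ")


@dataclass(frozen=True)
class CellPhysical:
    """Inferred absolute mass (pg), volume (fL) and density (g/mL).

    ``valid`` is False when the inferred volume is non-positive, which
    indicates an inconsistent measurement pair; such cells are flagged
    rather than dropped — filtering is the caller's decision.
    """

    mass: float
    volume: float
    density: float

    @property
    def valid(self) -> bool:
        return self.volume > 0


def solve_cell_physical(p: BuoyantPair) -> CellPhysical:
    """Invert the two-fluid buoyant-mass model for one cell.

    Raises
    ------
    ValueError
        If the two buoyant masses are equal (volume undefined).
    """
    if p.m_b1 == p.m_b2:
        raise ValueError(
            "equal buoyant masses in both fluids leave the volume undefined"
        )
    volume = (p.m_b1 - p.m_b2) / (p.rho_f2 - p.rho_f1)
    density = p.rho_f1 + p.m_b1 / volume
    return CellPhysical(mass=density * volume, volume=volume, density=density)


def normalize_excess_density(
    densities, baseline_fluid: float = 1.000, reference_index: int = 0
):
    """Normalize a density series to its excess over a baseline fluid.

    ``out_i = (rho_i - baseline) / (rho_ref - baseline)``, so the
    reference entry maps to 1 and the baseline fluid (water by default,
    1.000 g/mL) maps to 0.  This is the scale on which a decline "to
    60% of the initial value relative to the baseline density of water"
    is expressed.
    """
    rho = np.asarray(densities, dtype=float)
    ref = rho[reference_index]
    if ref <= baseline_fluid:
        raise ValueError(
            "reference density must exceed the baseline fluid density"
        )
    return (rho - baseline_fluid) / (ref - baseline_fluid)


def density_volume_profile(
    cells: list[CellPhysical], bin_edges, reference_bin: int = 0
) -> pd.DataFrame:
    """Median density per volume bin, normalized to a reference bin.

    Parameters
    ----------
    cells : list of CellPhysical
    bin_edges : array-like, fL
        Volume bin edges (left-inclusive, right-exclusive except the
        last bin which includes its right edge).
    reference_bin : int
        Bin whose median density divides the ``norm_density`` column;
        by default the first (smallest-volume) bin, matching the
        convention of normalizing to cells below a size cutoff.

    Returns
    -------
    DataFrame with columns bin_left, bin_right, n, median_density,
    norm_density; empty bins are reported with n=0 and NaN medians.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2:
        raise ValueError("need at least two bin edges")
    vols = np.array([c.volume for c in cells])
    dens = np.array([c.density for c in cells])
    idx = np.digitize(vols, edges) - 1
    idx[vols == edges[-1]] = edges.size - 2  # close the last bin
    rows = []
    for b in range(edges.size - 1):
        sel = dens[idx == b]
        rows.append(
            {
                "bin_left": edges[b],
                "bin_right": edges[b + 1],
                "n": sel.size,
                "median_density": float(np.median(sel)) if sel.size else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    ref_med = out.loc[reference_bin, "median_density"]
    if out.loc[reference_bin, "n"] == 0 or not np.isfinite(ref_med):
        raise ValueError("reference bin is empty")
    out["norm_density"] = out["median_density"] / ref_med
    return out
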