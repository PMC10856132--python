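"""2D free-energy surfaces over (Rg, interchain h-bonds per monomer).

The surface is a histogram estimate: F(bin) = -kT ln(count / max_count), so
the most populated bin (the global minimum, the assembled state for an
assembly trajectory) sits at zero and sparsely visited regions carry higher
free energy. Empty bins are undefined (NaN sentinel), not zero. No Jacobian
or reweighting is applied (samples are assumed unbiased).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Trajectory
from .hbonds import HBondCriteria, count_solute_monomers, detect_hbonds
from .order import DEFAULT_ADJACENCY_CUTOFF, find_assemblies, radius_of_gyration

#: kT in kcal/mol at 300 K
KT_300K = 0.596

DEFAULT_RG_BIN = 0.5    # A
DEFAULT_HB_BIN = 0.05   # h-bonds per monomer


@dataclass
class FESGrid:
    """Binned free energy; x = Rg (A), y = interchain h-bonds per monomer."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray        # shape (nx, ny)
    free_energy: np.ndarray   # kcal/mol, NaN where counts == 0
    kT: float

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def delta_f(self) -> float:
        """Free-energy difference between the least and most populated
        defined bins (max over defined bins; the minimum is 0 by
        construction)."""
        return float(np.nanmax(self.free_energy))

    def to_dataframe(self) -> pd.DataFrame:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame({
            "x_center": xx.ravel(), "y_center": yy.ravel(),
            "count": self.counts.ravel().astype(int),
            "free_energy": self.free_energy.ravel(),
        })

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)


def collect_cv_samples(traj: Trajectory,
                       criteria: HBondCriteria = HBondCriteria(),
                       assembly_cutoff: float = DEFAULT_ADJACENCY_CUTOFF
                       ) -> list[tuple[float, float]]:
    """Per-frame collective-variable samples (Rg, interchain h-bonds/monomer).

    Rg is computed over the chains of the frame's largest assembly (the
    nanofibril); when the largest assembly is a single chain (fully
    disassembled state) Rg falls back to all solute chains. The h-bond count
    is normalized by the total solute monomer count.
    """
    if not len(traj):
        raise ValueError("empty trajectory")
    samples = []
    n_monomers = count_solute_monomers(traj[0])
    for frame in traj:
        comps = find_assemblies(frame, assembly_cutoff)
        largest = comps[0] if comps else []
        solute = ~frame.is_water
        if len(largest) > 1:
            sel = np.flatnonzero(solute & np.isin(frame.chains, largest))
        else:
            sel = np.flatnonzero(solute)
        rg = radius_of_gyration(frame, sel)
        events = detect_hbonds(frame, criteria)
        hb = sum(e.scope == "interchain" for e in events) / n_monomers
        samples.append((rg, hb))
    return samples


def build_fes(samples, x_bins=None, y_bins=None, kT: float = KT_300K) -> FESGrid:
    """Histogram samples into a free-energy grid.

    ``x_bins``/``y_bins`` may be integers, explicit edge arrays, or None
    (default bin widths: 0.5 A in Rg, 0.05 in h-bonds per monomer).
    """
    if kT <= 0:
        raise ValueError("kT must be positive")
    pts = np.asarray(list(samples), float)
    if pts.ndim != 2 or pts.shape[0] < 1 or pts.shape[1] != 2:
        raise ValueError("need at least one (Rg, hb) sample")

    def default_edges(v: np.ndarray, width: float) -> np.ndarray:
        lo = np.floor(v.min() / width) * width
        hi = np.ceil(v.max() / width) * width
        if hi <= lo:
            hi = lo + width
        return np.arange(lo, hi + width / 2, width)

    if x_bins is None:
        x_bins = default_edges(pts[:, 0], DEFAULT_RG_BIN)
    if y_bins is None:
        y_bins = default_edges(pts[:, 1], DEFAULT_HB_BIN)
    counts, x_edges, y_edges = np.histogram2d(pts[:, 0], pts[:, 1],
                                              bins=(x_bins, y_bins))
    with np.errstate(divide="ignore"):
        fe = np.where(counts > 0, -kT * np.log(counts / counts.max()), np.nan)
    return FESGrid(x_edges, y_edges, counts.astype(int), fe, kT)


def delta_f_between(counts_a: float, counts_b: float, kT: float = KT_300K) -> float:
    """Closed-form free-energy difference F_b - F_a = -kT ln(n_b / n_a)."""
    if counts_a <= 0 or counts_b <= 0:
        raise ValueError("bin counts must be positive")
    return float(-kT * np.log(counts_b / counts_a))
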