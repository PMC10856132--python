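"""CHARMM-style dihedral energy terms and fitting to a torsion energy scan.

The torsional potential is the Fourier series

    E(phi) = sum_n K_n * (1 + cos(n*phi - delta_n))

with force constants K_n >= 0 (kcal/mol), integer multiplicities n and
phases delta_n (0 or 180 degrees by convention). Fitting replaces manual
parameter tuning with constrained least squares: for each allowed
multiplicity the signed cosine coefficient is solved together with a free
constant offset, then mapped to (K_n, delta_n) — a positive coefficient
gives delta = 0, a negative one delta = 180. The offset absorbs the target
scan's arbitrary energy zero.

Scans are plain two-column text (angle in degrees, energy in kcal/mol,
``#`` comments allowed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_MULTIPLICITIES = (1, 2, 3, 6)
DEFAULT_PHASES = (0.0, 180.0)


@dataclass(frozen=True)
class DihedralTerm:
    k: float            # kcal/mol, >= 0
    multiplicity: int   # 1..6
    phase: float        # degrees

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("force constant must be non-negative")
        if not 1 <= self.multiplicity <= 6:
            raise ValueError("multiplicity must be in 1..6")


@dataclass(frozen=True)
class DihedralParams:
    terms: tuple[DihedralTerm, ...]
    label: str = ""

    def __post_init__(self):
        mults = [t.multiplicity for t in self.terms]
        if len(mults) != len(set(mults)):
            raise ValueError("multiplicities must be unique within a parameter set")

    def to_charmm_lines(self, atom_types: str = "X    X    X    X") -> str:
        """CHARMM parameter-file style dihedral lines."""
        return "\n".join(
            f"{atom_types}  {t.k:10.6f}  {t.multiplicity:d}  {t.phase:8.2f}"
            for t in self.terms)


@dataclass(frozen=True)
class PESScan:
    """Tabulated potential-energy scan over a torsion angle."""

    angles: np.ndarray    # degrees in [-180, 180)
    energies: np.ndarray  # kcal/mol
    label: str = ""

    def __post_init__(self):
        angles = np.asarray(self.angles, float)
        energies = np.asarray(self.energies, float)
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "energies", energies)
        if angles.shape != energies.shape or angles.ndim != 1:
            raise ValueError("angles and energies must be 1-D and equally long")
        if not (np.all(np.isfinite(angles)) and np.all(np.isfinite(energies))):
            raise ValueError("scan contains non-finite values")
        if np.any(angles < -180.0) or np.any(angles >= 180.0):
            raise ValueError("angles must lie in [-180, 180)")

    @classmethod
    def from_file(cls, path: str, label: str = "") -> "PESScan":
        data = np.loadtxt(path, comments="#", ndmin=2)
        if data.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (degrees, kcal/mol)")
        angles = np.mod(data[:, 0] + 180.0, 360.0) - 180.0
        return cls(angles, data[:, 1], label=label or str(path))

    def to_file(self, path: str) -> None:
        header = f"torsion scan {self.label}\nangle_deg  energy_kcal_mol"
        np.savetxt(path, np.column_stack([self.angles, self.energies]),
                   fmt="%10.4f", header=header)


def dihedral_energy(params: DihedralParams, angle) -> np.ndarray | float:
    """Evaluate the Fourier series at angle(s) in degrees."""
    phi = np.deg2rad(np.asarray(angle, float))
    total = np.zeros_like(phi)
    for t in params.terms:
        total = total + t.k * (1.0 + np.cos(t.multiplicity * phi
                                            - np.deg2rad(t.phase)))
    return float(total) if np.ndim(angle) == 0 else total


def fit_dihedral(target: PESScan,
                 allowed_multiplicities=DEFAULT_MULTIPLICITIES,
                 phase_set=DEFAULT_PHASES,
                 drop_tolerance: float = 1e-10):
    """Least-squares fit of Fourier coefficients plus a constant offset.

    Returns ``(DihedralParams, offset, rmse)`` with
    ``dihedral_energy(params, angles) + offset ~= target.energies`` and all
    force constants non-negative. With the conventional phase set {0, 180}
    the non-negativity constraint is handled exactly by sign-to-phase
    mapping; other phase sets use bounded least squares.

    Raises when the scan has fewer points than free parameters + 1.
    """
    mults = tuple(dict.fromkeys(int(m) for m in allowed_multiplicities))
    if not mults:
        raise ValueError("need at least one allowed multiplicity")
    n_params = len(mults) + 1
    if len(target.angles) < n_params + 1:
        raise ValueError(
            f"underdetermined fit: {len(target.angles)} scan points for "
            f"{n_params} free parameters (need at least {n_params + 1})")
    phi = np.deg2rad(target.angles)
    y = np.asarray(target.energies, float)
    phases = tuple(float(p) for p in phase_set)

    if set(phases) <= {0.0, 180.0}:
        # signed coefficients c_n on cos(n phi): K(1+cos(n phi - d)) with
        # d in {0,180} and K >= 0 spans exactly c_n cos(n phi) + |c_n|
        a = np.column_stack([np.cos(m * phi) for m in mults]
                            + [np.ones_like(phi)])
        coef, *_ = np.linalg.lstsq(a, y, rcond=None)
        terms = []
        offset = float(coef[-1])
        for c, m in zip(coef[:-1], mults):
            if abs(c) <= drop_tolerance:
                continue
            if c >= 0:
                terms.append(DihedralTerm(float(c), m, 0.0))
                offset -= c
            else:
                terms.append(DihedralTerm(float(-c), m, 180.0))
                offset += c
    else:
        # general phase grid: one phase per multiplicity (uniqueness), so
        # enumerate every phase assignment and keep the best bounded fit
        import itertools

        from scipy.optimize import lsq_linear
        best_rmse, best_fit = np.inf, None
        for assignment in itertools.product(phases, repeat=len(mults)):
            cols = [np.cos(m * phi - np.deg2rad(p))
                    for m, p in zip(mults, assignment)]
            cols.append(np.ones_like(phi))
            a = np.column_stack(cols)
            lb = np.zeros(a.shape[1])
            ub = np.full(a.shape[1], np.inf)
            lb[-1] = -np.inf
            res = lsq_linear(a, y, bounds=(lb, ub))
            r = float(np.sqrt(np.mean((a @ res.x - y) ** 2)))
            if r < best_rmse:
                best_rmse, best_fit = r, (assignment, res.x)
        assignment, x = best_fit
        terms = [DihedralTerm(float(k), m, p)
                 for k, m, p in zip(x[:-1], mults, assignment)
                 if k > drop_tolerance]
        # y ~ b + sum K cos(...); as sum K(1+cos(...)) + offset
        offset = float(x[-1]) - sum(t.k for t in terms)

    params = DihedralParams(tuple(sorted(terms, key=lambda t: t.multiplicity)),
                            label=target.label)
    model = dihedral_energy(params, target.angles) + offset
    rmse = float(np.sqrt(np.mean((model - y) ** 2)))
    return params, offset, rmse


def compare_scans(a: PESScan, b: PESScan) -> float:
    """RMS difference (kcal/mol) after shifting both scans to minimum zero.

    The angle grids must match exactly; interpolation is refused.
    """
    if len(a.angles) != len(b.angles) or not np.allclose(a.angles, b.angles,
                                                         atol=1e-9):
        raise ValueError("angle grids differ; resample the scans upstream")
    da = a.energies - a.energies.min()
    db = b.energies - b.energies.min()
    return float(np.sqrt(np.mean((da - db) ** 2)))
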