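"""Uniaxial incompressible Mooney-Rivlin constitutive mathematics.

The Mooney-Rivlin strain-energy density

    W = C10 (I1 - 3) + C01 (I2 - 3)  [+ (1/D)(J - 1)^2]

describes isotropic, nonlinearly elastic solids such as soft tissue.  For a
uniaxial, incompressible deformation with principal stretch ``lam`` along the
load axis the lateral stretches are ``lam**-0.5`` and the axial Cauchy stress
reduces to

    sigma = 2 (lam^2 - 1/lam) (C10 + C01 / lam)

with the hydrostatic pressure eliminated by the traction-free lateral
boundary.  The small-strain limit links the constants to linear elasticity:
mu0 = 2 (C10 + C01) and, with nu = 0.5, E = 3 mu0 = 6 (C10 + C01).

This module houses the material parameter container, the stretch/invariant
kinematics, the uniaxial stress laws and the hyperelastic <-> linear-elastic
conversions, plus CSV I/O for material tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MRParams",
    "UniaxialState",
    "Invariants",
    "uniaxial_stretches",
    "invariants_from_stretches",
    "strain_energy",
    "cauchy_stress_uniaxial",
    "stress_from_strain",
    "stretch_from_stress",
    "youngs_from_mr",
    "mr_from_youngs",
    "BREAST_MATERIALS",
    "read_material_table",
    "write_material_table",
]


@dataclass(frozen=True)
class MRParams:
    """Mooney-Rivlin constants, in Pa.

    Parameters
    ----------
    c10, c01 : float
        The two hyperelastic constants.  Their sum must be positive so that
        the initial shear modulus ``mu0 = 2 (c10 + c01)`` is positive.
    d_vol : float or None
        Volumetric constant (1/Pa) of the compressible extension.  Stored for
        completeness; every law in this module assumes strict
        incompressibility (J = 1) and never uses it.
    """

    c10: float
    c01: float
    d_vol: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.c10) or not np.isfinite(self.c01):
            raise ValueError("c10 and c01 must be finite")
        if self.c10 + self.c01 <= 0.0:
            raise ValueError(
                f"c10 + c01 = {self.c10 + self.c01!r} must be positive "
                "(mu0 = 2(c10+c01) > 0)"
            )
        if self.d_vol is not None and self.d_vol < 0.0:
            raise ValueError("d_vol must be non-negative when present")

    @property
    def mu0(self) -> float:
        """Initial (small-strain) shear modulus, Pa."""
        return 2.0 * (self.c10 + self.c01)


@dataclass(frozen=True)
class UniaxialState:
    """Axial stretch/strain pair of a uniaxial deformation state."""

    stretch: float

    def __post_init__(self) -> None:
        if self.stretch <= 0.0:
            raise ValueError("stretch must be positive")

    @property
    def strain(self) -> float:
        return self.stretch - 1.0


@dataclass(frozen=True)
class Invariants:
    """Principal invariants (I1, I2, I3) of the deformation."""

    i1: float
    i2: float
    i3: float


def uniaxial_stretches(stretch: float) -> tuple[float, float, float]:
    """Principal stretches of an incompressible uniaxial deformation.

    Lateral symmetry and I3 = 1 force ``(lam, lam**-0.5, lam**-0.5)``.
    """
    stretch = float(stretch)
    if stretch <= 0.0:
        raise ValueError(f"stretch must be positive, got {stretch}")
    lat = stretch ** -0.5
    return (stretch, lat, lat)


def invariants_from_stretches(l1: float, l2: float, l3: float) -> Invariants:
    """Principal invariants I1, I2, I3 from the principal stretches."""
    if l1 <= 0.0 or l2 <= 0.0 or l3 <= 0.0:
        raise ValueError("all principal stretches must be positive")
    a, b, c = l1 * l1, l2 * l2, l3 * l3
    return Invariants(i1=a + b + c, i2=a * b + b * c + c * a, i3=a * b * c)


def strain_energy(params: MRParams, stretch: float) -> float:
    """Strain-energy density W (Pa) along the incompressible uniaxial path."""
    inv = invariants_from_stretches(*uniaxial_stretches(stretch))
    return params.c10 * (inv.i1 - 3.0) + params.c01 * (inv.i2 - 3.0)


def cauchy_stress_uniaxial(params: MRParams, stretch):
    """Axial Cauchy stress (Pa) of an incompressible uniaxial deformation.

    sigma = 2 (lam^2 - 1/lam) (C10 + C01/lam).  Tension (lam > 1) gives
    positive stress; compression negative.  ``stretch`` may be an array.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("stretch must be positive")
    sigma = 2.0 * (lam**2 - 1.0 / lam) * (params.c10 + params.c01 / lam)
    return sigma if sigma.ndim else float(sigma)


def stress_from_strain(params: MRParams, strain):
    """Axial Cauchy stress (Pa) as a function of engineering strain eps = lam - 1."""
    eps = np.asarray(strain, dtype=float)
    if np.any(eps <= -1.0):
        raise ValueError("strain must exceed -1")
    return cauchy_stress_uniaxial(params, eps + 1.0)


def stretch_from_stress(
    params: MRParams,
    sigma: float,
    bracket: tuple[float, float] = (0.2, 3.0),
) -> float:
    """Invert the uniaxial stress law: the stretch at which sigma(lam) = sigma.

    Uses a safeguarded Brent root search.  sigma(lam) is strictly increasing
    for mu0 > 0 over the physical range, so the root is unique when bracketed.
    """
    from scipy.optimize import brentq

    lo, hi = bracket
    f = lambda lam: cauchy_stress_uniaxial(params, lam) - sigma
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0.0:
        raise ValueError(
            f"stress {sigma:.6g} Pa not bracketed by stretches [{lo}, {hi}]"
        )
    return float(brentq(f, lo, hi, xtol=1e-14, rtol=1e-14))


def youngs_from_mr(params: MRParams) -> float:
    """Young's modulus (Pa) implied by the constants under incompressibility.

    mu0 = 2 (C10 + C01) and E = 3 mu0 (nu = 0.5), hence E = 6 (C10 + C01).
    """
    return 6.0 * (params.c10 + params.c01)


def mr_from_youngs(e: float, c01_fraction: float = 0.4) -> MRParams:
    """Constants with a given Young's modulus and C01/(C10+C01) split.

    The split is not determined by E alone; the default 0.4 matches the
    breast-tissue tables commonly used in the elastography literature.
    """
    if e <= 0.0:
        raise ValueError("Young's modulus must be positive")
    total = e / 6.0
    return MRParams(c10=total * (1.0 - c01_fraction), c01=total * c01_fraction)


#: Breast-tissue constants widely used to simulate fat / fibroglandular tissue
#: and tumor (C10, C01 in Pa; implied E = 20, 35, 100 kPa).
BREAST_MATERIALS: Mapping[str, MRParams] = {
    "fat": MRParams(c10=2000.0, c01=1333.0),
    "fibroglandular": MRParams(c10=3500.0, c01=2333.3),
    "tumor": MRParams(c10=10000.0, c01=6667.0),
}


def read_material_table(path) -> dict[str, MRParams]:
    """Read a material table CSV (columns: name, c10_pa, c01_pa[, e_pa]).

    When the optional ``e_pa`` column is present each row is validated
    against ``youngs_from_mr`` to the printed precision (0.5% relative).
    """
    df = pd.read_csv(path)
    required = {"name", "c10_pa", "c01_pa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"material table missing columns: {sorted(missing)}")
    out: dict[str, MRParams] = {}
    for row in df.itertuples(index=False):
        p = MRParams(c10=float(row.c10_pa), c01=float(row.c01_pa))
        if "e_pa" in df.columns and np.isfinite(getattr(row, "e_pa", np.nan)):
            e_claimed = float(row.e_pa)
            e_implied = youngs_from_mr(p)
            if abs(e_claimed - e_implied) > 0.005 * e_implied:
                raise ValueError(
                    f"material {row.name!r}: e_pa={e_claimed:.6g} inconsistent "
                    f"with 6(c10+c01)={e_implied:.6g}"
                )
        out[str(row.name)] = p
    return out


def write_material_table(path, materials: Mapping[str, MRParams]) -> None:
    """Write a material table CSV with the implied Young's modulus column."""
    df = pd.DataFrame(
        {
            "name": list(materials),
            "c10_pa": [m.c10 for m in materials.values()],
            "c01_pa": [m.c01 for m in materials.values()],
            "e_pa": [youngs_from_mr(m) for m in materials.values()],
        }
    )
    df.to_csv(path, index=False)
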