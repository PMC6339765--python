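"""Iterative Mooney-Rivlin parameter estimation from tumor displacements.

The estimator assumes nothing is known about the tumor except axial
displacements of a few interior points at a handful of instants of a slow
sinusoidal load.  It proceeds in the following loop:

1.  An *effective Young's modulus* ``E_realt`` is regressed from the ratio of
    the observed displacements to those of a simulated reference tumor of
    modulus 1 Pa (displacements scale as 1/E in the linear regime, so the
    least-squares slope of observation on reference is E_ref / E).
2.  A synthetic stress set sigma_i = E_realt * eps_i is built over a chosen
    strain set, optionally perturbed by small relative Gaussian jitter.
3.  (C10, C01) are fit to the uniaxial incompressible Mooney-Rivlin law by
    linear least squares.
4.  The candidate parameters are verified by re-running the forward model and
    comparing the simulated observations ``Y_estt`` (and the re-estimated
    modulus ``E_estt``) with the data.
5.  On failure the strain set is scaled down by a decay factor and the loop
    repeats; in ``exact`` mode convergence is judged against the data, in
    ``noisy`` mode against the change between successive iterates.

Identifiability caveat: because step 2 builds stresses *linearly* from
``E_realt``, the data constrain essentially the sum C10 + C01 (i.e. the
small-strain modulus E = 6 (C10 + C01)); the split between the two constants
is only weakly identified, through the forward-verification residual.  See
the methods note for the full analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .mr_core import MRParams
from .phantom_forward import (
    DisplacementField,
    LoadSpec,
    PhantomGeometry,
    displacement_field_at,
    sample_axial,
)

__all__ = [
    "ObservationSet",
    "StrainSchedule",
    "Tolerances",
    "IterationRecord",
    "EstimationResult",
    "assemble_observation",
    "estimate_modulus",
    "build_stress_set",
    "fit_mr",
    "observed_strains",
    "iterate",
    "percent_error",
]


@dataclass
class ObservationSet:
    """Observed and reference displacement vectors of the selected tumor points.

    ``y_realt`` holds axial displacements (mm) of ``points`` at ``times``,
    time-major point-minor; ``ref_disp`` is the congruent vector from the
    1 Pa linear-elastic reference tumor.  ``ref_depth_mm`` records the
    interface relative to which both were sampled (the tumor's distal face),
    or None for raw laboratory-frame displacements.

    ``baseline_first=True`` marks vectors differenced against the first
    instant's block (that block kept as zeros): the natural observable when
    displacements are tracked incrementally between load states, since no
    frame of the unloaded medium is usable as a correlation reference.  The
    reference vector and any re-simulated observation must be differenced
    identically (see :func:`assemble_observation`).
    """

    y_realt: np.ndarray
    ref_disp: np.ndarray
    points: Sequence[tuple[float, float]]
    times: Sequence[float]
    ref_depth_mm: float | None = None
    baseline_first: bool = False

    def __post_init__(self) -> None:
        self.y_realt = np.asarray(self.y_realt, dtype=float)
        self.ref_disp = np.asarray(self.ref_disp, dtype=float)
        if self.y_realt.shape != self.ref_disp.shape:
            raise ValueError("y_realt and ref_disp must be congruent")
        if len(self.y_realt) != len(self.points) * len(self.times):
            raise ValueError("vector length must equal n_points * n_times")
        if not np.any(self.ref_disp):
            raise ValueError("ref_disp must not be all zero")


@dataclass
class StrainSchedule:
    """Strain set used to synthesize stress-strain pairs, and its decay.

    The defaults span high compressive strains, shrunk geometrically each
    iteration.  With ``auto_sign`` the set's sign is flipped before the first
    iteration to match the sign of the tumor strain implied by the applied
    traction (compressive load -> negative strains, tensile -> positive).
    """

    initial_strains: np.ndarray = field(
        default_factory=lambda: -np.linspace(0.02, 0.20, 10)
    )
    decay: float = 0.9
    jitter_rel: float = 0.0
    seed: int = 0
    auto_sign: bool = True

    def __post_init__(self) -> None:
        self.initial_strains = np.asarray(self.initial_strains, dtype=float)
        if np.any(self.initial_strains <= -1.0) or np.any(self.initial_strains == 0.0):
            raise ValueError("strains must be nonzero and exceed -1")
        if not (0.0 < self.decay <= 1.0):
            raise ValueError("decay must be in (0, 1]")
        if self.jitter_rel < 0.0:
            raise ValueError("jitter must be non-negative")


@dataclass
class Tolerances:
    """Convergence tolerances; None entries are derived from the data.

    Absolute criteria (exact mode): max-abs displacement residual against the
    observations and absolute modulus residual.  Primed criteria (noisy
    mode): the same norms on successive-iterate differences.
    """

    e_displacement: float | None = None
    e_elastic: float | None = None
    e_displacement_prime: float | None = None
    e_elastic_prime: float | None = None
    max_iterations: int = 50

    def resolved(self, y_realt: np.ndarray, e_realt: float) -> "Tolerances":
        scale = float(np.max(np.abs(y_realt)))
        return Tolerances(
            e_displacement=self.e_displacement
            if self.e_displacement is not None else 0.01 * scale,
            e_elastic=self.e_elastic
            if self.e_elastic is not None else 0.01 * e_realt,
            e_displacement_prime=self.e_displacement_prime
            if self.e_displacement_prime is not None else 0.001 * scale,
            e_elastic_prime=self.e_elastic_prime
            if self.e_elastic_prime is not None else 0.001 * e_realt,
            max_iterations=self.max_iterations,
        )


@dataclass
class IterationRecord:
    k: int
    c10: float
    c01: float
    e_estt: float
    y_estt: np.ndarray
    disp_residual: float
    elastic_residual: float
    disp_change: float | None = None
    elastic_change: float | None = None
    strain_scale: float = 0.0  # max |strain| of the set used this iteration


@dataclass
class EstimationResult:
    """Full trace of the iterative estimation."""

    e_realt: float
    trace: list[IterationRecord]
    converged: bool
    iterations: int
    mode: str

    @property
    def best(self) -> IterationRecord:
        """The accepted iterate: the last one if converged, else the one with
        the smallest displacement residual."""
        if self.converged:
            return self.trace[-1]
        return min(self.trace, key=lambda r: r.disp_residual)

    @property
    def params(self) -> MRParams:
        return MRParams(c10=self.best.c10, c01=self.best.c01)

    def to_dict(self) -> dict:
        return {
            "e_realt_pa": self.e_realt,
            "converged": self.converged,
            "iterations": self.iterations,
            "mode": self.mode,
            "c10_pa": self.best.c10,
            "c01_pa": self.best.c01,
            "e_estt_pa": self.best.e_estt,
            "trace": [
                {
                    "k": r.k,
                    "c10_pa": r.c10,
                    "c01_pa": r.c01,
                    "e_estt_pa": r.e_estt,
                    "disp_residual_mm": r.disp_residual,
                    "elastic_residual_pa": r.elastic_residual,
                    "disp_change_mm": r.disp_change,
                    "elastic_change_pa": r.elastic_change,
                }
                for r in self.trace
            ],
        }


def assemble_observation(
    fields: Sequence[DisplacementField],
    points: Sequence[tuple[float, float]],
    ref_depth_mm: float | None = None,
    baseline_first: bool = False,
) -> np.ndarray:
    """Observation vector from simulated fields (time-major, point-minor).

    With ``baseline_first`` the first field's block is subtracted from every
    block (and kept in place as zeros), matching observations measured as
    changes from the first sampled instant.
    """
    vec = sample_axial(fields, points, relative_to_depth=ref_depth_mm)
    if baseline_first:
        blocks = vec.reshape(len(fields), len(points))
        vec = (blocks - blocks[0]).ravel()
    return vec


def estimate_modulus(ref_disp: np.ndarray, y: np.ndarray, e_ref: float = 1.0) -> float:
    """Effective Young's modulus from observation/reference displacement ratio.

    Displacements of a linear-elastic inclusion scale as 1/E, so with a
    reference of modulus ``e_ref`` generating ``ref_disp``, the least-squares
    slope s of y on ref_disp equals e_ref / E; the modulus is e_ref / s.
    """
    d = np.asarray(ref_disp, dtype=float)
    y = np.asarray(y, dtype=float)
    if d.shape != y.shape:
        raise ValueError("vectors must be congruent")
    dd = float(d @ d)
    if dd == 0.0:
        raise ValueError("reference displacement vector has zero norm")
    s = float(d @ y) / dd
    if s <= 0.0:
        raise ValueError(
            f"non-positive regression slope {s:.3g}: observations inconsistent "
            "with the reference (opposite sign or zero response)"
        )
    return e_ref / s


def build_stress_set(
    e_pa: float,
    strains: np.ndarray,
    jitter_rel: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Synthetic stresses sigma_i = E * eps_i, optionally jittered.

    With jitter each stress is multiplied by (1 + N(0, jitter_rel)),
    independently per element.
    """
    strains = np.asarray(strains, dtype=float)
    if np.any(strains == 0.0):
        raise ValueError("strains must be nonzero")
    sigma = e_pa * strains
    if jitter_rel > 0.0:
        if rng is None:
            rng = np.random.default_rng(0)
        sigma = sigma * (1.0 + rng.normal(0.0, jitter_rel, size=sigma.shape))
    return sigma


def _mr_design(strains: np.ndarray) -> np.ndarray:
    lam = 1.0 + np.asarray(strains, dtype=float)
    g = 2.0 * (lam**2 - 1.0 / lam)
    return np.column_stack([g, g / lam])


def fit_mr(strains: np.ndarray, stresses: np.ndarray) -> MRParams:
    """Least-squares Mooney-Rivlin constants from (strain, stress) pairs.

    Fits sigma = 2((1+eps)^2 - (1+eps)^-1) (C10 + C01/(1+eps)) linearly in
    (C10, C01).  Requires at least two distinct strains; raises if the fitted
    constants are nonphysical (C10 + C01 <= 0).
    """
    strains = np.asarray(strains, dtype=float)
    stresses = np.asarray(stresses, dtype=float)
    if strains.shape != stresses.shape:
        raise ValueError("strains and stresses must be congruent")
    if np.any(strains <= -1.0):
        raise ValueError("strains must exceed -1")
    if len(np.unique(strains)) < 2:
        raise ValueError("need at least two distinct strains")
    A = _mr_design(strains)
    coef, _, rank, _ = np.linalg.lstsq(A, stresses, rcond=None)
    if rank < 2:
        raise ValueError("design matrix rank-deficient: strains too degenerate")
    c10, c01 = map(float, coef)
    if c10 + c01 <= 0.0:
        raise ValueError(f"nonphysical fit: c10+c01 = {c10 + c01:.3g} <= 0")
    return MRParams(c10=c10, c01=c01)


def observed_strains(obs: ObservationSet) -> np.ndarray:
    """Per-sample tumor strain implied by the relative-displacement observations.

    Valid only for observations sampled relative to the tumor's distal face:
    y = -eps * (z_ref - z) for each point, so eps = -y / (z_ref - z).
    """
    if obs.ref_depth_mm is None:
        raise ValueError("observed strains require relative-sampled observations")
    if obs.baseline_first:
        raise ValueError(
            "baseline-differenced observations carry strain *changes*, "
            "not strains"
        )
    lever = np.array([obs.ref_depth_mm - z for z, _ in obs.points])
    lever = np.tile(lever, len(obs.times))
    return -obs.y_realt / lever


def iterate(
    obs: ObservationSet,
    geometry: PhantomGeometry,
    known_materials: Mapping[str, MRParams],
    load: LoadSpec,
    schedule: StrainSchedule | None = None,
    tol: Tolerances | None = None,
    mode: Literal["exact", "noisy"] = "exact",
    grid_step_mm: tuple[float, float] = (0.5, 1.0),
) -> EstimationResult:
    """Run the full iterative estimation loop (see module docstring).

    ``known_materials`` supplies the surrounding layers' constants; the tumor
    is treated as unknown.  Returns the full iteration trace; reaching the
    iteration cap without meeting the tolerances yields ``converged=False``
    rather than an exception.
    """
    schedule = schedule if schedule is not None else StrainSchedule()
    tol = tol if tol is not None else Tolerances()

    e_realt = estimate_modulus(obs.ref_disp, obs.y_realt)
    tol = tol.resolved(obs.y_realt, e_realt)
    rng = np.random.default_rng(schedule.seed)

    strains = schedule.initial_strains.copy()
    if schedule.auto_sign:
        tractions = [load.traction_at(t) for t in obs.times]
        t_star = tractions[int(np.argmax(np.abs(tractions)))]
        if t_star != 0.0:
            # positive (compressive) traction shortens the stack
            strains = -np.sign(t_star) * np.abs(strains)

    trace: list[IterationRecord] = []
    converged = False
    prev_y: np.ndarray | None = None
    prev_e: float | None = None

    for k in range(1, tol.max_iterations + 1):
        sigma = build_stress_set(e_realt, strains, schedule.jitter_rel, rng)
        try:
            params = fit_mr(strains, sigma)
        except ValueError:
            strains = strains * schedule.decay
            continue

        mats = dict(known_materials)
        mats[geometry.tumor_name] = params
        try:
            fields = [
                displacement_field_at(geometry, mats, load, t, grid_step_mm)
                for t in obs.times
            ]
            y_estt = assemble_observation(fields, obs.points,
                                          ref_depth_mm=obs.ref_depth_mm,
                                          baseline_first=obs.baseline_first)
            e_estt = estimate_modulus(obs.ref_disp, y_estt)
        except ValueError:
            # candidate constants outside the invertible range of the stress
            # law (possible with jittered fits); discard and decay
            strains = strains * schedule.decay
            continue

        disp_res = float(np.max(np.abs(y_estt - obs.y_realt)))
        elast_res = abs(e_estt - e_realt)
        dy = float(np.max(np.abs(y_estt - prev_y))) if prev_y is not None else None
        de = abs(e_estt - prev_e) if prev_e is not None else None
        trace.append(
            IterationRecord(k, params.c10, params.c01, e_estt, y_estt,
                            disp_res, elast_res, dy, de,
                            strain_scale=float(np.max(np.abs(strains))))
        )
        prev_y, prev_e = y_estt, e_estt

        if mode == "exact":
            converged = (disp_res <= tol.e_displacement
                         and elast_res <= tol.e_elastic)
        else:
            converged = (dy is not None and de is not None
                         and dy <= tol.e_displacement_prime
                         and de <= tol.e_elastic_prime)
        if converged:
            break
        strains = strains * schedule.decay

    return EstimationResult(
        e_realt=e_realt,
        trace=trace,
        converged=converged,
        iterations=len(trace),
        mode=mode,
    )


def percent_error(true: float, est: float) -> float:
    """Percent error 100 |true - est| / |true|."""
    if true == 0.0:
        raise ValueError("true value must be nonzero")
    return 100.0 * abs(true - est) / abs(true)
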