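"""End-to-end orchestration and noise-robustness evaluation.

``run_pipeline`` chains the full study: quasi-static forward simulation of
the layered phantom at eight instants of the sinusoidal load, RF frame
synthesis from a warped scatterer phantom, cross-correlation tracking of the
tumor region, assembly of the observation vector (12 tumor points x 8
instants, relative to the tumor's distal face), and the iterative
Mooney-Rivlin inversion.  A tracking-bypass mode samples the forward truth
directly, isolating the inversion from speckle-tracking noise.

``noise_sweep`` perturbs the observation vector with i.i.d. relative Gaussian
errors at several levels (the 2/5/8/10% protocol) over many seeds and tables
the recovered constants and their percent errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .mr_core import BREAST_MATERIALS, MRParams, youngs_from_mr
from .phantom_forward import (
    LoadSpec,
    PhantomGeometry,
    default_tumor_points,
    displacement_field_at,
    elastic_reference_field,
)
from .rf_sim import (
    ProbeConfig,
    RFFrame,
    displace_scatterers,
    envelope,
    seed_scatterers,
    synthesize_rf,
    to_probe_frame,
)
from .tracking import TrackingConfig, track_points
from .inverse import (
    EstimationResult,
    ObservationSet,
    StrainSchedule,
    Tolerances,
    assemble_observation,
    iterate,
    percent_error,
)

__all__ = [
    "RunConfig",
    "EvalReport",
    "build_observations",
    "locate_anechoic_band",
    "run_pipeline",
    "inject_displacement_noise",
    "noise_sweep",
]


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.

    ``true_tumor`` is the ground-truth tumor used only to *generate* data;
    the inversion never sees it.  ``known_materials`` are the surrounding
    layers assumed known.  ``use_tracking=False`` bypasses RF synthesis and
    speckle tracking, sampling the forward truth directly.
    """

    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    known_materials: Mapping[str, MRParams] = field(
        default_factory=lambda: {
            "fat": BREAST_MATERIALS["fat"],
            "fibroglandular": BREAST_MATERIALS["fibroglandular"],
        }
    )
    true_tumor: MRParams = field(default_factory=lambda: BREAST_MATERIALS["tumor"])
    load: LoadSpec = field(default_factory=LoadSpec)
    probe: ProbeConfig = field(default_factory=ProbeConfig)
    tracking: TrackingConfig | None = None
    schedule: StrainSchedule = field(default_factory=StrainSchedule)
    tolerances: Tolerances = field(default_factory=Tolerances)
    seed: int = 1
    use_tracking: bool = True
    scatterer_density_per_mm2: float = 10.0
    mode: str = "exact"
    grid_step_mm: tuple[float, float] = (0.5, 1.0)
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Build a RunConfig from a YAML file; absent sections keep defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw: dict = {}
        if "geometry" in raw:
            g = dict(raw["geometry"])
            if "layers" in g:
                g["layers"] = tuple((str(n), float(t)) for n, t in g["layers"])
            if "tumor_axial_mm" in g:
                g["tumor_axial_mm"] = tuple(g["tumor_axial_mm"])
            kw["geometry"] = PhantomGeometry(**g)
        if "materials" in raw:
            mats = {
                name: MRParams(c10=float(v["c10_pa"]), c01=float(v["c01_pa"]))
                for name, v in raw["materials"].items()
            }
            tumor_name = kw.get("geometry", PhantomGeometry()).tumor_name
            if tumor_name in mats:
                kw["true_tumor"] = mats.pop(tumor_name)
            kw["known_materials"] = mats
        if "load" in raw:
            ld = dict(raw["load"])
            if "sample_times_s" in ld:
                ld["sample_times_s"] = tuple(ld["sample_times_s"])
            kw["load"] = LoadSpec(**ld)
        if "probe" in raw:
            pr = dict(raw["probe"])
            if "axial_window_mm" in pr:
                pr["axial_window_mm"] = tuple(pr["axial_window_mm"])
            kw["probe"] = ProbeConfig(**pr)
        if "tracking" in raw:
            kw["tracking"] = TrackingConfig(**raw["tracking"])
        if "schedule" in raw:
            sc = dict(raw["schedule"])
            if "initial_strains" in sc:
                sc["initial_strains"] = np.asarray(sc["initial_strains"], dtype=float)
            kw["schedule"] = StrainSchedule(**sc)
        if "tolerances" in raw:
            kw["tolerances"] = Tolerances(**raw["tolerances"])
        for key in ("seed", "use_tracking", "scatterer_density_per_mm2", "mode",
                    "out_dir"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)


def _true_materials(cfg: RunConfig) -> dict[str, MRParams]:
    mats = dict(cfg.known_materials)
    mats[cfg.geometry.tumor_name] = cfg.true_tumor
    return mats


# Incremental-tracking search ranges (mm): the first frame pair is searched
# exhaustively over +/- FIRST_PAIR_SEARCH_MM; later pairs are seeded by each
# point's previous increment and searched over +/- INCREMENT_SEARCH_MM.
FIRST_PAIR_SEARCH_MM = 2.5
INCREMENT_SEARCH_MM = 0.8


def locate_anechoic_band(
    frame: RFFrame,
    probe: ProbeConfig,
    lateral_center_mm: float,
    lateral_halfwidth_mm: float = 2.0,
    threshold_rel: float = 0.35,
    min_band_mm: float = 2.0,
) -> tuple[float, float]:
    """Depth extent (mm, frame coordinates) of an anechoic band in one frame.

    Averages the echo envelope over the lines within ``lateral_halfwidth_mm``
    of ``lateral_center_mm``, smooths it over roughly a pulse length, and
    returns the longest contiguous depth run below ``threshold_rel`` times
    the median envelope — how an operator outlines a dark lesion on B-mode.
    Runs shorter than ``min_band_mm`` (a few pulse lengths) are rejected as
    speckle dropouts or window-edge roll-off rather than a lesion.
    """
    lines = probe.line_positions_mm
    sel = np.abs(lines - lateral_center_mm) <= lateral_halfwidth_mm
    if not np.any(sel):
        raise ValueError("no scan lines near the requested lateral position")
    env = envelope(frame)[sel].mean(axis=0)
    width = max(3, int(round(2.0 * probe.sampling_frequency_hz
                             / probe.center_frequency_hz)))
    kernel = np.ones(width) / width
    env = np.convolve(env, kernel, mode="same")
    low = env < threshold_rel * np.median(env)
    best_len, best_start, run_start = 0, -1, None
    for idx, flag in enumerate(np.append(low, False)):
        if flag and run_start is None:
            run_start = idx
        elif not flag and run_start is not None:
            if idx - run_start > best_len:
                best_len, best_start = idx - run_start, run_start
            run_start = None
    mm = probe.mm_per_sample
    if best_len * mm < min_band_mm:
        raise ValueError("no anechoic band found in the frame")
    z0 = frame.depth_origin_mm
    return (z0 + best_start * mm, z0 + (best_start + best_len - 1) * mm)


def build_observations(cfg: RunConfig) -> tuple[ObservationSet, dict]:
    """Generate the observation set for one run.

    Returns the observations plus a diagnostics dict (true fields, tracked
    estimates when tracking is used).  The observation vector holds axial
    displacements of the 12 tumor points at the 8 instants, relative to the
    tumor's distal interface; the reference vector comes from the 1 Pa
    elastic-reference simulation sampled identically.

    The tracked path works the way quasi-static elastography must: the bulk
    probe-frame motion between the *unloaded* medium and a loaded state is
    many millimetres with several-percent local strain, which decorrelates
    any correlation window, so RF frames are synthesized at the eight load
    states and tracked pairwise between *consecutive* states (sub-2% strain
    increments).  Correlation windows follow each material point's
    accumulated displacement (Lagrangian tracking).  Because the tumor is
    anechoic there is no speckle at the observation points themselves, so —
    as is standard for low-echogenicity inclusions — short columns of
    speckle just above and below the lesion are tracked, displacement is
    extrapolated linearly to the two interfaces, and the interior points are
    linearly interpolated between the interfaces.  The observation is the
    face-relative displacement differenced against the first instant
    (``baseline_first``); the reference vector is differenced identically.
    """
    geo, load = cfg.geometry, cfg.load
    points = default_tumor_points(geo)
    ref_depth = geo.tumor_axial_mm[1]
    times = load.sample_times_s

    true_mats = _true_materials(cfg)
    fields = [displacement_field_at(geo, true_mats, load, t, cfg.grid_step_mm)
              for t in times]
    ref_fields = [
        elastic_reference_field(geo, load, t, e_pa=1.0,
                                known_materials=cfg.known_materials,
                                grid_step_mm=cfg.grid_step_mm)
        for t in times
    ]
    diag: dict = {"fields": fields, "ref_fields": ref_fields, "points": points}

    if not cfg.use_tracking:
        y = assemble_observation(fields, points, ref_depth_mm=ref_depth)
        ref_disp = assemble_observation(ref_fields, points, ref_depth_mm=ref_depth)
        obs = ObservationSet(y, ref_disp, points, times, ref_depth_mm=ref_depth)
        return obs, diag

    probe = cfg.probe
    # scatterers must cover the imaging window at every load state, so seed
    # beyond it by the largest plausible bulk probe-frame excursion
    seed_margin = 16.0
    seed_window = (max(0.0, probe.axial_window_mm[0] - seed_margin),
                   min(geo.axial_mm, probe.axial_window_mm[1] + seed_margin))
    sset = seed_scatterers(geo, cfg.scatterer_density_per_mm2, cfg.seed,
                           axial_window_mm=seed_window)
    frames = [
        synthesize_rf(displace_scatterers(sset, to_probe_frame(f)), probe,
                      time_s=f.time_s)
        for f in fields
    ]
    tcfg = (cfg.tracking if cfg.tracking is not None
            else TrackingConfig.for_frame(frames[0]))
    mm_per_sample = probe.mm_per_sample

    # the lesion is anechoic, so its interior cannot be tracked directly;
    # locate its dark band in the first frame and, per unique lateral
    # position of the observation points, place a column of speckle windows
    # just above and one just below it (clear of the band by half a window
    # plus roughly a pulse length).  All positions are coordinates *in the
    # first frame*; uniform strain inside the lesion preserves fractional
    # position, so the interface-interpolated interior displacements
    # correspond to the material observation points exactly.
    pts = np.asarray(points, dtype=float)
    lats = np.unique(pts[:, 1])
    band_top, band_bot = locate_anechoic_band(
        frames[0], probe, lateral_center_mm=float(np.mean(lats)))
    ws_mm = tcfg.window_samples * mm_per_sample
    clear = 0.5 * ws_mm + 0.8
    col = clear + 0.8 * np.arange(4)
    above_z = band_top - col
    below_z = band_bot + col
    mat_pts = np.array([(z, lat) for lat in lats for z in above_z]
                       + [(z, lat) for lat in lats for z in below_z])
    n_above = len(lats) * len(col)
    lat0 = probe.line_positions_mm[0]

    u_ax = np.zeros(len(mat_pts))          # accumulated axial shift, mm
    u_lat = np.zeros(len(mat_pts))         # accumulated lateral shift, mm
    inc_seed = np.zeros(len(mat_pts))      # previous axial increment, samples
    inc_seed_l = np.zeros(len(mat_pts))
    blocks = [np.zeros(len(pts))]          # first instant is the baseline
    estimates = []
    r_first = int(np.ceil(FIRST_PAIR_SEARCH_MM / mm_per_sample))
    r_next = int(np.ceil(INCREMENT_SEARCH_MM / mm_per_sample))
    for i in range(1, len(frames)):
        cur = np.column_stack([mat_pts[:, 0] + u_ax,
                               mat_pts[:, 1] - lat0 + u_lat])
        est = track_points(
            frames[i - 1], frames[i], cur, tcfg,
            seeds_samples=None if i == 1 else inc_seed,
            seeds_lines=None if i == 1 else inc_seed_l,
            search_radius_samples=r_first if i == 1 else r_next,
            search_radius_lines=tcfg.max_lateral_lag if i == 1 else 1,
        )
        u_ax += est.axial_shift_mm
        u_lat += est.lateral_shift_lines * probe.lateral_spacing_mm
        inc_seed = est.axial_shift_samples
        inc_seed_l = est.lateral_shift_lines
        estimates.append(est)

        # per lateral: extrapolate each column linearly to its interface,
        # then interpolate the interior points between the interfaces
        delta = {}
        for li, lat in enumerate(lats):
            ua = u_ax[li * len(col):(li + 1) * len(col)]
            ub = u_ax[n_above + li * len(col):n_above + (li + 1) * len(col)]
            u_prox = np.polyval(np.polyfit(above_z, ua, 1), band_top)
            u_dist = np.polyval(np.polyfit(below_z, ub, 1), band_bot)
            delta[lat] = u_prox - u_dist
        z_prox, z_dist = geo.tumor_axial_mm
        frac = (z_dist - pts[:, 0]) / (z_dist - z_prox)
        blocks.append(np.array([delta[lat] for lat in pts[:, 1]]) * frac)
    y = np.concatenate(blocks)
    ref_disp = assemble_observation(ref_fields, points, ref_depth_mm=ref_depth,
                                    baseline_first=True)
    diag["estimates"] = estimates
    obs = ObservationSet(y, ref_disp, points, times, ref_depth_mm=ref_depth,
                         baseline_first=True)
    return obs, diag


def run_pipeline(cfg: RunConfig) -> EstimationResult:
    """Execute one end-to-end run and (optionally) persist artifacts."""
    obs, _diag = build_observations(cfg)
    result = iterate(
        obs, cfg.geometry, cfg.known_materials, cfg.load,
        schedule=cfg.schedule, tol=cfg.tolerances, mode=cfg.mode,
        grid_step_mm=cfg.grid_step_mm,
    )
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = result.to_dict()
        payload["seed"] = cfg.seed
        (out / "result.json").write_text(json.dumps(payload, indent=2))
        rows = pd.DataFrame(payload["trace"])
        rows.to_csv(out / "iterations.csv", index=False)
    return result


def inject_displacement_noise(y: np.ndarray, level_pct: float, seed: int) -> np.ndarray:
    """Relative i.i.d. Gaussian perturbation: y_i * (1 + N(0, level/100))."""
    if level_pct < 0.0:
        raise ValueError("noise level must be non-negative")
    y = np.asarray(y, dtype=float)
    if level_pct == 0.0:
        return y.copy()
    rng = np.random.default_rng(seed)
    return y * (1.0 + rng.normal(0.0, level_pct / 100.0, size=y.shape))


@dataclass
class EvalReport:
    """Per-seed/per-level sweep results with a median summary."""

    table: pd.DataFrame

    def median_by_level(self) -> pd.DataFrame:
        cols = ["err_c10_pct", "err_c01_pct", "err_e_estt_pct", "err_y_estt_pct"]
        return self.table.groupby("noise_level_pct")[cols].median()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def noise_sweep(
    cfg: RunConfig,
    levels_pct: Sequence[float] = (2.0, 5.0, 8.0, 10.0),
    n_seeds: int = 20,
) -> EvalReport:
    """Robustness of the inversion to displacement errors.

    The clean observation vector is generated once (tracking bypassed — the
    perturbation itself models measurement error), then perturbed per
    level/seed and inverted in ``noisy`` (successive-iterate) mode; level 0
    runs in ``exact`` mode.  Errors are reported against the generating
    constants and against the run's own modulus/displacement estimates.
    """
    if n_seeds < 1:
        raise ValueError("need at least one seed")
    clean_cfg = RunConfig(**{**asdict_shallow(cfg), "use_tracking": False})
    obs, _ = build_observations(clean_cfg)
    truth = cfg.true_tumor

    rows = []
    base = np.random.SeedSequence(cfg.seed)
    child_seeds = base.generate_state(n_seeds * max(1, len(levels_pct))) % (2**31)
    idx = 0
    for level in levels_pct:
        for s in range(n_seeds):
            seed = int(child_seeds[idx]); idx += 1
            y = inject_displacement_noise(obs.y_realt, level, seed)
            noisy_obs = ObservationSet(y, obs.ref_disp, obs.points, obs.times,
                                       ref_depth_mm=obs.ref_depth_mm,
                                       baseline_first=obs.baseline_first)
            mode = "exact" if level == 0.0 else "noisy"
            sched = StrainSchedule(
                initial_strains=cfg.schedule.initial_strains.copy(),
                decay=cfg.schedule.decay,
                jitter_rel=cfg.schedule.jitter_rel,
                seed=seed,
                auto_sign=cfg.schedule.auto_sign,
            )
            res = iterate(noisy_obs, cfg.geometry, cfg.known_materials, cfg.load,
                          schedule=sched, tol=cfg.tolerances, mode=mode,
                          grid_step_mm=cfg.grid_step_mm)
            best = res.best
            y_rel_err = 100.0 * float(
                np.linalg.norm(best.y_estt - y) / np.linalg.norm(y)
            )
            rows.append({
                "noise_level_pct": level,
                "seed": seed,
                "c10_pa": best.c10,
                "c01_pa": best.c01,
                "err_c10_pct": percent_error(truth.c10, best.c10),
                "err_c01_pct": percent_error(truth.c01, best.c01),
                "e_realt_pa": res.e_realt,
                "err_e_estt_pct": percent_error(res.e_realt, best.e_estt),
                "err_y_estt_pct": y_rel_err,
                "err_e_sum_pct": percent_error(
                    youngs_from_mr(truth), 6.0 * (best.c10 + best.c01)
                ),
                "converged": res.converged,
                "iterations": res.iterations,
            })
    return EvalReport(pd.DataFrame(rows))


def asdict_shallow(cfg: RunConfig) -> dict:
    """Shallow field dict of a RunConfig (objects kept, not recursed)."""
    return {name: getattr(cfg, name) for name in cfg.__dataclass_fields__}
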