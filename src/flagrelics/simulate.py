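"""Synthetic-data generators for every input class the pipeline consumes.

The generators emulate the statistical structure the downstream analyses
assume: point placement on elliptical cell poles (random, steric hard-core,
jittered hexagonal grid, Thomas cluster), a stochastic birth–death model of
per-cell flagellation with a nutrient-depletion ejection trigger, shed
flagella with hooks at exactly one end, swim tracks with known ground-truth
speed, periplasmic distance measurements with configurable class spreads,
and cylindrically symmetric motor/relic density phantoms with n-fold subunit
modulation.  Every generator is deterministic given (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .maps import DensityMap
from .spatial import (
    PolePattern,
    SaturationError,
    _rsa_in_ellipse,
    _uniform_in_ellipse,
)

PatternKind = Literal["uniform", "hardcore", "grid", "cluster"]


@dataclass(frozen=True)
class PatternModel:
    """Parameters of one point-placement hypothesis on an elliptical pole."""

    kind: PatternKind
    n_points: int
    semi_axis_x_nm: float = 130.0
    semi_axis_y_nm: float = 130.0
    exclusion_diameter_nm: float = 45.0  # hardcore
    lattice_spacing_nm: float = 64.0  # grid
    jitter_sd_nm: float = 0.0  # grid
    n_parents: int = 2  # cluster
    offspring_sd_nm: float = 10.0  # cluster
    motor_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        for name in (
            "semi_axis_x_nm",
            "semi_axis_y_nm",
            "exclusion_diameter_nm",
            "lattice_spacing_nm",
            "offspring_sd_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.motor_fraction <= 1.0:
            raise ValueError("motor_fraction must be in [0, 1]")


def simulate_pole(
    model: PatternModel,
    seed: int | np.random.Generator = 0,
    pole_id: str = "sim",
    cring_diameter_nm: float = 45.0,
) -> PolePattern:
    """Draw one pole pattern from the given placement model.

    All points land inside the model ellipse.  Hard-core patterns respect the
    exclusion diameter (random sequential adsorption, bounded retries; raises
    :class:`~flagrelics.spatial.SaturationError` on infeasible packings).
    Grid patterns sit on a jittered hexagonal lattice clipped to the ellipse.
    """
    rng = np.random.default_rng(seed)
    a, b = model.semi_axis_x_nm, model.semi_axis_y_nm
    n = model.n_points
    if model.kind == "uniform":
        xy = _uniform_in_ellipse(n, a, b, rng)
    elif model.kind == "hardcore":
        excl_area = n * math.pi * (model.exclusion_diameter_nm / 2) ** 2
        if excl_area > 0.5 * math.pi * a * b:
            raise SaturationError(requested=n, achieved=0)
        xy = _rsa_in_ellipse(n, a, b, model.exclusion_diameter_nm, rng)
    elif model.kind == "grid":
        xy = _hex_lattice_in_ellipse(
            n, a, b, model.lattice_spacing_nm, model.jitter_sd_nm, rng
        )
    elif model.kind == "cluster":
        xy = _thomas_in_ellipse(
            n, a, b, model.n_parents, model.offspring_sd_nm, rng
        )
    else:  # pragma: no cover - guarded by the Literal type
        raise ValueError(f"unknown pattern kind {model.kind!r}")
    labels = np.where(
        rng.random(n) < model.motor_fraction, "motor", "relic"
    ).astype(object)
    return PolePattern(
        pole_id=pole_id, xy=xy, labels=labels, cring_diameter_nm=cring_diameter_nm
    )


def _hex_lattice_in_ellipse(
    n: int,
    a: float,
    b: float,
    spacing: float,
    jitter_sd: float,
    rng: np.random.Generator,
    max_jitter_tries: int = 1000,
) -> np.ndarray:
    """n points of a (jittered) hexagonal lattice, compact about the centre."""
    reach = max(a, b) + 2 * spacing
    jmax = int(math.ceil(reach / (spacing * math.sqrt(3) / 2)))
    imax = int(math.ceil(reach / spacing))
    pts = []
    for j in range(-jmax, jmax + 1):
        y = j * spacing * math.sqrt(3) / 2
        off = (spacing / 2) if (j % 2) else 0.0
        for i in range(-imax, imax + 1):
            x = i * spacing + off
            pts.append((x, y))
    pts_arr = np.array(pts)
    inside = (pts_arr[:, 0] / a) ** 2 + (pts_arr[:, 1] / b) ** 2 <= 1.0
    pts_arr = pts_arr[inside]
    if len(pts_arr) < n:
        raise ValueError(
            f"hexagonal lattice with spacing {spacing} nm fits only "
            f"{len(pts_arr)} points in the ellipse; {n} requested"
        )
    order = np.argsort(np.hypot(pts_arr[:, 0], pts_arr[:, 1]), kind="stable")
    xy = pts_arr[order[:n]].astype(float)
    if jitter_sd > 0:
        for i in range(n):
            for _ in range(max_jitter_tries):
                cand = xy[i] + rng.normal(0.0, jitter_sd, 2)
                if (cand[0] / a) ** 2 + (cand[1] / b) ** 2 <= 1.0:
                    xy[i] = cand
                    break
    return xy


def _thomas_in_ellipse(
    n: int,
    a: float,
    b: float,
    n_parents: int,
    offspring_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thomas process: uniform parents, Gaussian offspring, clipped."""
    parents = _uniform_in_ellipse(n_parents, a, b, rng)
    out = np.empty((n, 2))
    k = 0
    while k < n:
        p = parents[rng.integers(n_parents)]
        cand = p + rng.normal(0.0, offspring_sd, 2)
        if (cand[0] / a) ** 2 + (cand[1] / b) ** 2 <= 1.0:
            out[k] = cand
            k += 1
    return out


# --------------------------------------------------------------------------
# Population time courses


@dataclass(frozen=True)
class PopulationModel:
    """Birth–death model of per-cell flagellation along a growth curve.

    The culture grows logistically in OD units; CFU/ml is OD times
    ``cfu_per_ml_per_od``.  Each tracked cell assembles flagella at
    ``assembly_rate`` and divides at the logistic per-capita rate.  In
    ``polar_ejection`` mode, once the culture OD reaches ``trigger_od``
    (nutrient depletion), assembly halts and each flagellum is ejected
    independently at ``ejection_rate_post_trigger``; at division the polar
    bundle passes intact to the old-pole daughter (all-or-none inheritance).
    In ``peritrichous_dilution`` mode nothing is ever ejected and counts are
    halved binomially at division (flagella spread over the whole surface).

    The paper-style growth curve motivates the defaults: doubling every
    ~19 min early on (growth_rate ~ 2.2/h), a sharp motility collapse around
    OD 0.8 (trigger), and initial flagellation of ~5 per cell.  No
    quantitative ejection rate is published; the default is illustrative and
    flagged in the run configuration.
    """

    mode: Literal["polar_ejection", "peritrichous_dilution"] = "polar_ejection"
    growth_rate_per_h: float = 2.2
    assembly_rate_per_h: float = 5.0
    ejection_rate_post_trigger_per_h: float = 6.0
    trigger_od: float = 0.8
    carrying_od: float = 1.4
    initial_od: float = 0.05
    initial_mean_flagella: float = 5.0
    cfu_per_ml_per_od: float = 8.0e8

    def __post_init__(self) -> None:
        for name in (
            "growth_rate_per_h",
            "assembly_rate_per_h",
            "ejection_rate_post_trigger_per_h",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.trigger_od <= 0:
            raise ValueError("trigger_od must be > 0")
        if not 0 < self.initial_od < self.carrying_od:
            raise ValueError("need 0 < initial_od < carrying_od")

    def od_at(self, t_h: float | np.ndarray) -> float | np.ndarray:
        """Deterministic logistic OD600 at time t (hours)."""
        k, n0, r = self.carrying_od, self.initial_od, self.growth_rate_per_h
        return k / (1.0 + (k / n0 - 1.0) * np.exp(-r * np.asarray(t_h, float)))

    def trigger_time_h(self) -> float:
        """Time at which OD crosses the ejection trigger (inf if never)."""
        k, n0, r = self.carrying_od, self.initial_od, self.growth_rate_per_h
        if self.trigger_od <= n0:
            return 0.0
        if self.trigger_od >= k or r <= 0:
            return math.inf
        return math.log((k / n0 - 1.0) / (k / self.trigger_od - 1.0)) / r


@dataclass(frozen=True)
class PopulationTimepoint:
    t_h: float
    od600: float
    cfu_per_ml: float
    counts: np.ndarray  # per-cell flagella counts of the sampled cells


def simulate_population(
    model: PopulationModel,
    timepoints_h: Sequence[float],
    seed: int | np.random.Generator = 0,
    n_cells: int = 150,
) -> list[PopulationTimepoint]:
    """Simulate per-cell flagella counts along the growth curve.

    Each of *n_cells* tracked lineages is an independent continuous-time
    Markov chain simulated exactly (event-driven, with explicit handling of
    the deterministic trigger-crossing time); the culture-level OD/CFU are
    deterministic.  Timepoints must be increasing.
    """
    t_arr = np.asarray(list(timepoints_h), dtype=float)
    if t_arr.ndim != 1 or len(t_arr) < 1:
        raise ValueError("need at least one timepoint")
    if np.any(np.diff(t_arr) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    rng = np.random.default_rng(seed)
    t_trig = model.trigger_time_h()
    counts_now = rng.poisson(model.initial_mean_flagella, n_cells)
    out: list[PopulationTimepoint] = []
    t_now = 0.0
    for t_next in t_arr:
        for i in range(n_cells):
            counts_now[i] = _evolve_cell(
                int(counts_now[i]), t_now, t_next, t_trig, model, rng
            )
        od = float(model.od_at(t_next))
        out.append(
            PopulationTimepoint(
                t_h=float(t_next),
                od600=od,
                cfu_per_ml=od * model.cfu_per_ml_per_od,
                counts=counts_now.copy(),
            )
        )
        t_now = float(t_next)
    return out


def _evolve_cell(
    k: int,
    t0: float,
    t1: float,
    t_trig: float,
    m: PopulationModel,
    rng: np.random.Generator,
) -> int:
    """Exact stochastic simulation of one cell from t0 to t1 (hours)."""
    t = t0
    polar = m.mode == "polar_ejection"
    while True:
        post = t >= t_trig if polar else False
        # per-capita division rate from the logistic curve at time t
        div = m.growth_rate_per_h * max(0.0, 1.0 - float(m.od_at(t)) / m.carrying_od)
        asm = 0.0 if (polar and post) else m.assembly_rate_per_h
        eject = m.ejection_rate_post_trigger_per_h * k if (polar and post) else 0.0
        total = div + asm + eject
        if total <= 0.0:
            return k
        dt = rng.exponential(1.0 / total)
        # rates change discontinuously at the trigger: advance and redraw
        if polar and not post and t + dt > t_trig >= t:
            t = t_trig
            continue
        t = t + dt
        if t >= t1:
            return k
        u = rng.uniform(0.0, total)
        if u < div:
            if polar:
                # all-or-none: old-pole daughter keeps the bundle
                k = k if rng.random() < 0.5 else 0
            else:
                k = int(rng.binomial(k, 0.5)) if k > 0 else 0
        elif u < div + asm:
            k += 1
        else:
            k -= 1


# --------------------------------------------------------------------------
# Detached flagella


@dataclass(frozen=True)
class DetachedFlagellum:
    """A shed filament; the hook sits at exactly one end iff the flagellum
    was ejected at the base of its hook, and at neither end for a
    mid-filament shear."""

    flagellum_id: str
    break_mode: Literal["base_of_hook", "midfilament"]
    hook_at_end: tuple[bool, bool]

    def __post_init__(self) -> None:
        n_hooks = sum(self.hook_at_end)
        if self.break_mode == "base_of_hook" and n_hooks != 1:
            raise ValueError("base_of_hook flagella carry a hook at exactly one end")
        if self.break_mode == "midfilament" and n_hooks != 0:
            raise ValueError("midfilament fragments carry no hook")


def simulate_detached_flagella(
    n: int,
    break_mode: Literal["base_of_hook", "midfilament"],
    seed: int | np.random.Generator = 0,
) -> list[DetachedFlagellum]:
    """Simulate n shed flagella of one breakage mode."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        if break_mode == "base_of_hook":
            end = int(rng.integers(2))
            hooks = (end == 0, end == 1)
        elif break_mode == "midfilament":
            hooks = (False, False)
        else:
            raise ValueError(f"unknown break_mode {break_mode!r}")
        out.append(
            DetachedFlagellum(
                flagellum_id=f"{break_mode}_{i:04d}",
                break_mode=break_mode,
                hook_at_end=hooks,
            )
        )
    return out


# --------------------------------------------------------------------------
# Swim tracks


@dataclass(frozen=True)
class SwimTrack:
    track_id: str
    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    true_speed_um_s: float | None = None  # generator ground truth

    def __post_init__(self) -> None:
        if len(self.t_s) != len(self.x_um) or len(self.t_s) != len(self.y_um):
            raise ValueError("track arrays must share a length")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("track times must be strictly increasing")


def simulate_tracks(
    n_tracks: int,
    speed_mean_um_s: float = 40.0,
    speed_sd_um_s: float = 5.0,
    duration_s: float = 10.0,
    frame_dt_s: float = 0.1,
    heading_sd_rad: float = 0.15,
    seed: int | np.random.Generator = 0,
) -> list[SwimTrack]:
    """Straight-run swim tracks with heading noise.

    Each track has a constant ground-truth speed drawn from a normal
    distribution truncated at zero; the heading performs a Gaussian random
    walk per frame.  Because every step has length v*dt, the path-length
    speed estimator recovers the ground truth exactly at zero noise.
    """
    n_frames = int(round(duration_s / frame_dt_s)) + 1
    if n_frames < 2:
        raise ValueError("need at least 2 frames: increase duration or shrink dt")
    rng = np.random.default_rng(seed)
    tracks = []
    t = np.arange(n_frames) * frame_dt_s
    for i in range(n_tracks):
        v = max(0.0, float(rng.normal(speed_mean_um_s, speed_sd_um_s)))
        theta = float(rng.uniform(0.0, 2 * math.pi))
        x = np.empty(n_frames)
        y = np.empty(n_frames)
        x[0] = y[0] = 0.0
        for j in range(1, n_frames):
            if heading_sd_rad > 0:
                theta += float(rng.normal(0.0, heading_sd_rad))
            x[j] = x[j - 1] + v * frame_dt_s * math.cos(theta)
            y[j] = y[j - 1] + v * frame_dt_s * math.sin(theta)
        tracks.append(
            SwimTrack(
                track_id=f"track_{i:05d}",
                t_s=t,
                x_um=x,
                y_um=y,
                true_speed_um_s=v,
            )
        )
    return tracks


# --------------------------------------------------------------------------
# Periplasmic distances


def simulate_periplasm_measurements(
    class_params: Mapping[str, tuple[float, float]],
    n_per_class: int = 50,
    seed: int | np.random.Generator = 0,
    dist: Literal["uniform", "normal"] = "uniform",
) -> pd.DataFrame:
    """Simulate inner-to-outer-membrane distances per structure class.

    ``class_params`` maps a class name (``"motor"`` / ``"relic"``) to
    ``(mean, spread)`` in nm.  With ``dist="uniform"`` the spread is the full
    range (mean +/- spread/2), matching how the study reports class
    variability; with ``dist="normal"`` the spread is a standard deviation.
    All generated distances are positive (resampled if not).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for klass, (mean, spread) in class_params.items():
        if mean <= 0 or spread < 0:
            raise ValueError("class mean must be > 0 and spread >= 0")
        for i in range(n_per_class):
            while True:
                if dist == "uniform":
                    v = rng.uniform(mean - spread / 2.0, mean + spread / 2.0)
                elif dist == "normal":
                    v = rng.normal(mean, spread)
                else:
                    raise ValueError(f"unknown dist {dist!r}")
                if v > 0:
                    break
            rows.append(
                {
                    "structure_id": f"{klass}_{i:04d}",
                    "klass": klass,
                    "distance_nm": float(v),
                }
            )
    return pd.DataFrame(rows, columns=["structure_id", "klass", "distance_nm"])


# --------------------------------------------------------------------------
# Density phantoms


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic motor/relic density phantom.

    The defaults encode the measured motor geometry: a 44 nm diameter T-ring
    sitting 19 nm below the outer membrane, a 15 nm rod exit aperture in the
    membrane, and 13 azimuthal stator/T-ring subunits.  ``plug_present``
    fills the aperture with the relic's plug density.
    """

    t_ring_diameter_nm: float = 44.0
    t_ring_to_outer_membrane_nm: float = 19.0
    aperture_diameter_nm: float = 15.0
    n_subunits: int = 13
    plug_present: bool = False
    voxel_size_nm: float = 1.0
    box_size: int = 64
    membrane_sd_nm: float = 2.0
    ring_sd_nm: float = 2.0
    subunit_modulation: float = 0.5
    membrane_amplitude: float = 1.0
    ring_amplitude: float = 1.0
    plug_amplitude: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "t_ring_diameter_nm",
            "t_ring_to_outer_membrane_nm",
            "aperture_diameter_nm",
            "voxel_size_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")
        if self.box_size < 8:
            raise ValueError("box_size must be >= 8")


class PhantomSizingError(ValueError):
    """Requested phantom geometry does not fit in the voxel box."""


def build_phantom(
    spec: PhantomSpec,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> DensityMap:
    """Build a cylindrically symmetric motor/relic phantom.

    Components, all centred on the z axis through the grid centre:

    * an outer-membrane slab (Gaussian in z) with a soft-edged circular
      aperture of the specified diameter,
    * a plug density filling the aperture when ``plug_present``,
    * a T-ring annulus (Gaussian torus) of the specified diameter, offset
      below the membrane, modulated azimuthally by ``n_subunits`` density
      bumps (``n_subunits == 1`` leaves the ring rotationally smooth),
    * optional white Gaussian noise (seeded).
    """
    N = spec.box_size
    vox = spec.voxel_size_nm
    half_nm = (N - 1) / 2.0 * vox
    r_ring = spec.t_ring_diameter_nm / 2.0
    z_mem = 13.0 if half_nm > 16.0 else half_nm / 2.0
    z_ring = z_mem - spec.t_ring_to_outer_membrane_nm
    margin = 3.0 * spec.ring_sd_nm
    if r_ring + margin > half_nm or abs(z_ring) + margin > half_nm:
        raise PhantomSizingError(
            f"ring radius {r_ring} nm / axial offset {z_ring} nm do not fit "
            f"a box of half-extent {half_nm:.1f} nm"
        )
    c = (N - 1) / 2.0
    zz, yy, xx = np.meshgrid(
        (np.arange(N) - c) * vox,
        (np.arange(N) - c) * vox,
        (np.arange(N) - c) * vox,
        indexing="ij",
    )
    # z in the grid runs along axis 0; membrane at z = z_mem relative centre
    z = zz - 0.0
    r = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)

    r_ap = spec.aperture_diameter_nm / 2.0
    edge_w = max(vox, 1.0)
    hole = 0.5 * (1.0 + np.tanh((r - r_ap) / edge_w))
    membrane = (
        spec.membrane_amplitude
        * np.exp(-((z - z_mem) ** 2) / (2 * spec.membrane_sd_nm**2))
        * hole
    )
    ring = spec.ring_amplitude * np.exp(
        -(((r - r_ring) ** 2) + (z - z_ring) ** 2) / (2 * spec.ring_sd_nm**2)
    )
    if spec.n_subunits > 1:
        ring = ring * (1.0 + spec.subunit_modulation * np.cos(spec.n_subunits * theta))
    density = membrane + ring
    if spec.plug_present:
        plug = (
            spec.plug_amplitude
            * np.exp(-((z - z_mem) ** 2) / (2 * spec.membrane_sd_nm**2))
            * 0.5
            * (1.0 - np.tanh((r - r_ap) / edge_w))
        )
        density = density + plug
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        density = density + rng.normal(0.0, noise_sd, density.shape)
    return DensityMap(data=density.astype(np.float32), voxel_size_nm=vox)
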