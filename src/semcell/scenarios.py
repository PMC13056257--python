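"""Experiment protocols: nucleus phase separation, ECM construction and
spreading, displacement-controlled spherical indentation, and constricted
migration via particle turnover.

Each protocol is a plain function taking an initialized system plus a small
protocol dataclass and returning a result object holding the final
configuration, trajectory snapshots and a pandas metrics table.  All
randomness flows through an explicit seed or Generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import analysis
from .dynamics import (BrownianIntegrator, DEFAULT_KT_FRACTION, freeze_particles,
                       nuclear_bias_force, nuclear_gather_force,
                       peripheral_basal_selector)
from .model import (CYT, ECM, GLA, NUC, InvalidParameterError, ParticleKind,
                    ParticleSystem, SEMParameters)
from .potentials import indenter_force

__all__ = [
    "EcmPattern",
    "build_ecm",
    "AnnealStage",
    "default_anneal_schedule",
    "equilibrate_nucleus",
    "make_spread_cell",
    "run_spreading",
    "IndentationProtocol",
    "run_indentation",
    "MigrationProtocol",
    "run_constricted_migration",
    "ProtocolError",
]


class ProtocolError(RuntimeError):
    """A protocol was configured inconsistently."""


# ---------------------------------------------------------------------------
# ECM patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EcmPattern:
    """Planar lattice pattern of adhesive ECM sites with a glass margin.

    ``shape`` is one of circle/square/triangle/rectangle/plane; ``size`` is
    the radius (circle), side (square/triangle/plane half-extent) or
    (width, height) for rectangles, in µm.  Sites outside the shape but
    within ``margin`` of its bounding box become inert glass particles.
    """

    shape: str
    size: float | tuple[float, float]
    spacing: float
    margin: float = 0.0
    z: float = 0.0
    centered: bool = False   # sites at cell centers ((i+1/2)s) vs nodes (i s)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.shape == "circle":
            return x**2 + y**2 <= float(self.size) ** 2
        if self.shape in ("square", "plane"):
            h = float(self.size) / 2.0
            return (np.abs(x) <= h) & (np.abs(y) <= h)
        if self.shape == "rectangle":
            w, h = self.size
            return (np.abs(x) <= w / 2.0) & (np.abs(y) <= h / 2.0)
        if self.shape == "triangle":
            # equilateral, centroid at origin, one vertex up
            a = float(self.size)
            rc = a / np.sqrt(3.0)
            verts = np.array([[rc * np.cos(np.deg2rad(t)),
                               rc * np.sin(np.deg2rad(t))]
                              for t in (90, 210, 330)])
            inside = np.ones_like(x, dtype=bool)
            for k in range(3):
                p, q = verts[k], verts[(k + 1) % 3]
                cross = ((q[0] - p[0]) * (y - p[1])
                         - (q[1] - p[1]) * (x - p[0]))
                inside &= cross >= -1e-12
            return inside
        raise InvalidParameterError(f"unknown ECM shape {self.shape!r}")

    @property
    def bbox(self) -> tuple[float, float]:
        if self.shape == "circle":
            r = float(self.size)
            return r, r
        if self.shape in ("square", "plane"):
            h = float(self.size) / 2.0
            return h, h
        if self.shape == "rectangle":
            w, h = self.size
            return w / 2.0, h / 2.0
        if self.shape == "triangle":
            rc = float(self.size) / np.sqrt(3.0)
            return rc, rc
        raise InvalidParameterError(f"unknown ECM shape {self.shape!r}")


def build_ecm(pattern: EcmPattern) -> ParticleSystem:
    """Deterministic lattice placement of ECM (inside) and glass (margin).

    Lattice sites sit at integer multiples of the spacing, centered on the
    origin; no site holds two particles.
    """
    if pattern.spacing <= 0:
        raise InvalidParameterError("lattice spacing must be positive")
    bx, by = pattern.bbox
    if bx <= 0 or by <= 0:
        raise InvalidParameterError("zero-area ECM pattern")
    s = pattern.spacing
    if pattern.centered:
        nx = int(np.ceil((bx + pattern.margin) / s))
        ny = int(np.ceil((by + pattern.margin) / s))
        xs = (np.arange(-nx, nx) + 0.5) * s
        ys = (np.arange(-ny, ny) + 0.5) * s
    else:
        nx = int(np.floor((bx + pattern.margin) / s))
        ny = int(np.floor((by + pattern.margin) / s))
        xs = np.arange(-nx, nx + 1) * s
        ys = np.arange(-ny, ny + 1) * s
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    x, y = X.ravel(), Y.ravel()
    inside = pattern.contains(x, y)
    if not inside.any():
        raise InvalidParameterError("zero-area ECM pattern (no lattice sites)")
    keep = inside if pattern.margin <= 0 else np.ones_like(inside)
    x, y, inside = x[keep], y[keep], inside[keep]
    n = len(x)
    kinds = np.where(inside, ECM, GLA)
    positions = np.column_stack([x, y, np.full(n, pattern.z)])
    return ParticleSystem(
        positions=positions, kinds=kinds, mobile=np.zeros(n, dtype=bool),
        cell_id=np.full(n, -1, dtype=np.int64))


# ---------------------------------------------------------------------------
# Nucleus phase separation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnealStage:
    """One stage of the phase-separation anneal.

    The nuclear self-interaction is temporarily strengthened (u0 ×
    ``u0_mult``) and extended (cutoff × ``cutoff_mult``) while the
    effective temperature is scaled by ``kT_mult`` relative to the base
    kT_eff.  ``bias_mode`` selects the centering force: "gather" pulls each
    nuclear particle individually toward the cell center (contracts and
    merges dispersed nuclear clusters — the pair attraction alone is too
    short-ranged to do so), "bias" rigidly re-centers the formed nucleus.
    ``bias_factor`` scales the spring constant in units of u0/deq².  The
    final stage restores the nominal interaction.
    """

    u0_mult: float
    cutoff_mult: float
    kT_mult: float
    steps: int
    bias_mode: str = "bias"
    bias_factor: float = 0.1


def default_anneal_schedule() -> list[AnnealStage]:
    """Gather-then-relax anneal: contract the dispersed nuclear particles
    under a boosted, extended self-attraction at elevated noise, then relax
    to the nominal potential at working noise."""
    return [
        AnnealStage(3.0, 1.5, 3.0, 5000, bias_mode="gather", bias_factor=1.0),
        AnnealStage(3.0, 1.5, 1.0, 3000, bias_mode="gather", bias_factor=0.5),
        AnnealStage(1.5, 1.2, 1.0, 1500),
        AnnealStage(1.0, 1.0, 1.0, 1500),
    ]


def rescue_anneal_cycle() -> list[AnnealStage]:
    """Extra gather/relax cycle appended when the purity target is missed."""
    return [
        AnnealStage(3.0, 1.5, 3.0, 3000, bias_mode="gather", bias_factor=1.0),
        AnnealStage(1.5, 1.2, 1.0, 1000),
    ]


def equilibrate_nucleus(
    system: ParticleSystem,
    table,
    params: SEMParameters,
    drag: np.ndarray,
    *,
    schedule: list[AnnealStage] | None = None,
    purity_target: float = 8.0,
    kT_base: float | None = None,
    max_rescue_cycles: int = 3,
    quench_steps: int = 200,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Stage the nuclear self-interaction until the nucleus demixes.

    Runs the anneal stages in order, recording the phase-separation purity
    (percent cytoplasmic particles inside the nuclear hull) after each, and
    stops once purity ≤ ``purity_target`` (finishing with a short relax at
    the nominal potential if the stop happens at a boosted stage).  When
    the scheduled stages miss the target, up to ``max_rescue_cycles`` extra
    gather/relax cycles are appended before giving up.

    Returns (system, purity_trace, reached) where ``reached`` flags whether
    the target was met; when it is not, the best-so-far configuration is
    returned with ``reached=False`` (non-fatal).
    """
    if schedule is None:
        schedule = default_anneal_schedule()
    if kT_base is None:
        kT_base = DEFAULT_KT_FRACTION * params.u0
    if rng is None:
        rng = np.random.default_rng(seed)

    trace = [analysis.nuclear_purity(system)]
    if trace[0] <= purity_target:
        return system, trace, True
    best = (trace[0], system.copy())
    # quench the random initial overlaps before annealing
    BrownianIntegrator(system, table, drag, params.deq, kT_eff=0.0,
                       rng=rng, adaptive=True).step(quench_steps)

    def run_stage(stage):
        k = stage.bias_factor * params.u0 / params.deq**2
        if stage.bias_mode == "gather":
            ext = (lambda s: nuclear_gather_force(s, k))
        else:
            ext = (lambda s: nuclear_bias_force(s, k, plane="xyz"))
        staged_table = table.scaled(NUC, NUC, u0_mult=stage.u0_mult,
                                    cutoff_mult=stage.cutoff_mult)
        integ = BrownianIntegrator(
            system, staged_table, drag, params.deq,
            kT_eff=stage.kT_mult * kT_base, rng=rng, adaptive=True,
            externals=[ext])
        integ.step(stage.steps)
        return analysis.nuclear_purity(system)

    def final_relax():
        run_stage(AnnealStage(1.0, 1.0, 1.0, 800))

    stages = list(schedule)
    for cycle in range(max_rescue_cycles + 1):
        for stage in stages:
            purity = run_stage(stage)
            trace.append(purity)
            if purity < best[0]:
                best = (purity, system.copy())
            if purity <= purity_target:
                if stage.u0_mult != 1.0 or stage.cutoff_mult != 1.0:
                    final_relax()
                    purity = analysis.nuclear_purity(system)
                    trace.append(purity)
                    if purity < best[0]:
                        best = (purity, system.copy())
                    if purity > purity_target:
                        continue   # relaxation re-mixed; keep annealing
                return system, trace, True
        stages = rescue_anneal_cycle()
    if best[0] <= purity_target:
        return best[1], trace, True
    warnings.warn(
        f"phase-separation purity target {purity_target}% not reached; "
        f"best {best[0]:.2f}%")
    return best[1], trace, False


# ---------------------------------------------------------------------------
# Spread-cell construction (synthetic adherent configuration)
# ---------------------------------------------------------------------------

def make_spread_cell(
    params: SEMParameters,
    nuclear_fraction: float = 0.10,
    *,
    spread_factor: float = 1.4,
    z_bottom: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    cell_id: int = 0,
) -> ParticleSystem:
    """Synthetic pre-spread adherent cell: a particle pancake with the
    nucleus parked near its top surface.

    Geometric construction (no spreading simulation): cytoplasm fills a
    cylinder of radius ``spread_factor × Rcell`` whose height conserves the
    spherical cell volume; nuclear particles fill an oblate spheroid
    centered in the upper half.  Intended as the starting state for
    indentation and as a deterministic test fixture; a short relaxation run
    settles it onto the substrate.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    Np = params.Np
    n_nuc = int(round(Np * nuclear_fraction))
    r_spread = spread_factor * params.Rcell
    cell_volume = 4.0 / 3.0 * np.pi * params.Rcell**3
    height = cell_volume / (np.pi * r_spread**2)
    spacing = 0.55 * params.deq

    # oblate nuclear spheroid in the upper half, volume-conserving
    nuc_volume = cell_volume * nuclear_fraction
    c_semi = 0.30 * height
    a_semi = np.sqrt(3.0 * nuc_volume / (4.0 * np.pi * c_semi))
    z_nuc = z_bottom + 0.62 * height

    positions = np.empty((Np, 3))
    placed = 0

    def try_place(cand):
        nonlocal placed
        if placed:
            d2 = np.sum((positions[:placed] - cand) ** 2, axis=1)
            if d2.min() < spacing**2:
                return False
        positions[placed] = cand
        placed += 1
        return True

    attempts = 0
    while placed < n_nuc:
        attempts += 1
        if attempts > 200000:
            raise ProtocolError("could not pack the nuclear spheroid")
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        r = rng.random() ** (1.0 / 3.0)
        cand = np.array([z_nuc * 0 + a_semi * r * u[0], a_semi * r * u[1],
                         z_nuc + c_semi * r * u[2]])
        try_place(cand)
    attempts = 0
    while placed < Np:
        attempts += 1
        if attempts > 500000:
            raise ProtocolError("could not pack the cytoplasmic pancake")
        rr = r_spread * np.sqrt(rng.random())
        th = 2.0 * np.pi * rng.random()
        z = z_bottom + height * rng.random()
        try_place(np.array([rr * np.cos(th), rr * np.sin(th), z]))

    kinds = np.full(Np, CYT, dtype=np.int64)
    kinds[:n_nuc] = NUC
    return ParticleSystem(
        positions=positions, kinds=kinds, mobile=np.ones(Np, dtype=bool),
        cell_id=np.full(Np, cell_id, dtype=np.int64))


def place_on_substrate(cell: ParticleSystem, sigma: float,
                       clearance_factor: float = 1.05) -> ParticleSystem:
    """Shift a cell vertically so its lowest particle sits just above the
    substrate adhesion minimum (``clearance_factor × σ``).

    A freely equilibrated droplet can drift below the z = 0 plane; dropping
    it into the steep LJ core would blow up the forces, so every protocol
    that combines a pre-built cell with a substrate starts from this
    placement.
    """
    z_min = cell.positions[:, 2].min()
    cell.positions[:, 2] += clearance_factor * sigma - z_min
    return cell


# ---------------------------------------------------------------------------
# Spreading
# ---------------------------------------------------------------------------

@dataclass
class SpreadingResult:
    system: ParticleSystem
    metrics: pd.DataFrame
    frames: list[tuple[float, np.ndarray]]
    detached: bool = False


def run_spreading(
    cell: ParticleSystem,
    ecm: ParticleSystem,
    table,
    params: SEMParameters,
    drag_cell: np.ndarray,
    *,
    n_steps: int,
    output_every: int = 200,
    kT_eff: float | None = None,
    dt: float | str = "auto",
    basal_slab_deq: float = 1.5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    store_frames: bool = False,
) -> SpreadingResult:
    """Brownian dynamics of a cell adhering to and spreading on an ECM.

    Records CSI, NSI, projected basal area, ellipticity and purity at the
    output interval.  Flags the run as detached when no cell particle comes
    within the ECM cutoff of a substrate particle in some frame.
    """
    if kT_eff is None:
        kT_eff = DEFAULT_KT_FRACTION * params.u0
    system = ParticleSystem.concatenate(cell, ecm)
    drag = np.concatenate([drag_cell, np.full(ecm.n, np.inf)])
    drag[~np.isfinite(drag)] = drag_cell.max() * 1e6   # immobile anyway
    integ = BrownianIntegrator(system, table, drag, params.deq, dt=dt,
                               kT_eff=kT_eff, seed=seed, rng=rng)
    ecm_tree = cKDTree(ecm.positions[ecm.kinds == ECM]) \
        if np.any(ecm.kinds == ECM) else None
    dc = table.get(CYT, ECM).cutoff

    rows = []
    frames = []
    detached = False

    def record(intg, _step):
        nonlocal detached
        cellmask = system.cell_id >= 0
        z_slab = (system.positions[cellmask, 2].min()
                  + basal_slab_deq * params.deq)
        m = analysis.shape_metrics(system, z_slab=None)
        m["time"] = intg.state.time
        try:
            m["basal_area"] = analysis.projected_area(
                system, z_max=z_slab, cells_only=True)
        except (analysis.EmptySelectionError, analysis.DegenerateGeometryError):
            m["basal_area"] = np.nan
        if ecm_tree is not None:
            cellmask = system.cell_id >= 0
            dmin, _ = ecm_tree.query(system.positions[cellmask], k=1)
            if dmin.min() > dc:
                detached = True
        rows.append(m)
        if store_frames:
            frames.append((intg.state.time, system.positions.copy()))

    record(integ, 0)
    integ.run(n_steps, callback=record, callback_every=output_every)
    metrics = pd.DataFrame(rows)[["time", "csi", "nsi", "area",
                                  "basal_area", "ellipticity", "purity"]]
    if detached:
        warnings.warn("cell detached from the ECM during spreading")
    return SpreadingResult(system=system, metrics=metrics, frames=frames,
                           detached=detached)


# ---------------------------------------------------------------------------
# Indentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndentationProtocol:
    """Displacement-controlled spherical indentation.

    The tip approaches at ``approach_speed`` from one clearance above the
    top particle, indents to ``depth`` below the initial contact plane,
    holds for ``hold_duration`` and retracts at ``retract_speed`` back to
    the start.  Speeds default to the experimental 1 µm/s loading rate.
    """

    tip_radius: float = 5.0          # µm
    approach_speed: float = 1.0      # µm/s
    depth: float = 2.0               # µm
    hold_duration: float = 2.0       # s
    retract_speed: float = 1.0       # µm/s
    sampling_interval: float = 0.05  # s
    clearance_factor: float = 1.0    # × deq above the top particle

    def __post_init__(self):
        if self.approach_speed <= 0 or self.retract_speed <= 0:
            raise InvalidParameterError("indentation speeds must be positive")
        if self.depth < 0:
            raise InvalidParameterError("indentation depth must be >= 0")


@dataclass
class IndentationResult:
    force_curve: pd.DataFrame   # time, force, phase
    system: ParticleSystem
    frozen: np.ndarray
    tip_track: pd.DataFrame     # time, z


def run_indentation(
    spread_system: ParticleSystem,
    table,
    params: SEMParameters,
    drag: np.ndarray,
    protocol: IndentationProtocol,
    *,
    freeze_selector=None,
    tip_stiffness: float | None = None,
    kT_eff: float = 0.0,
    dt: float | str = "auto",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> IndentationResult:
    """Three-phase (load/hold/unload) indentation force–time experiment.

    Peripheral basal particles are immobilized (mimicking focal adhesions)
    so the cell does not keep spreading under the tip.  The tip exerts the
    quadratic penalty force F = K (r − R)² on penetrating particles; the
    recorded force is the vertical reaction on the tip.
    """
    system = spread_system
    cellmask = system.cell_id >= 0
    if not cellmask.any():
        raise ProtocolError("no cell particles to indent")
    if tip_stiffness is None:
        # effectively rigid: penalty stiffness far above pair stiffness
        tip_stiffness = 1e3 * params.u0 / params.deq**3
    if freeze_selector is None:
        freeze_selector = peripheral_basal_selector(
            radial_fraction=0.85,
            z_max=system.positions[cellmask, 2].min() + params.deq)
    frozen = freeze_particles(system, freeze_selector)

    z_top = system.positions[cellmask, 2].max()
    R = protocol.tip_radius
    z_start = z_top + protocol.clearance_factor * params.deq + R
    z_min = z_top + R - protocol.depth
    if z_min - R < 0.0:
        raise ProtocolError(
            f"tip bottom would reach z = {z_min - R:.3g} µm, below the "
            "ECM plane; reduce the indentation depth")
    t_load = (z_start - z_min) / protocol.approach_speed
    t_hold = t_load + protocol.hold_duration
    t_end = t_hold + (z_start - z_min) / protocol.retract_speed

    def tip_z(t):
        if t <= t_load:
            return z_start - protocol.approach_speed * t, "load"
        if t <= t_hold:
            return z_min, "hold"
        if t <= t_end:
            return z_min + protocol.retract_speed * (t - t_hold), "unload"
        return z_start, "unload"

    tip_center = np.array([*system.positions[cellmask, :2].mean(axis=0), z_start])

    def tip_force(s):
        return indenter_force(s.positions, tip_center, R, tip_stiffness,
                              shape="sphere")[0]

    integ = BrownianIntegrator(system, table, drag, params.deq, dt=dt,
                               kT_eff=kT_eff, seed=seed, rng=rng,
                               frozen=frozen, adaptive=True,
                               externals=[tip_force])
    rows, track = [], []
    next_sample = 0.0
    while integ.state.time < t_end:
        z, phase = tip_z(integ.state.time)
        tip_center[2] = z
        # the tip is displacement-controlled: bound dt so it never moves
        # more than a fraction of deq within one step
        speed = max(protocol.approach_speed, protocol.retract_speed)
        integ.state.dt = min(integ.state.dt, 0.1 * params.deq / speed)
        integ.step(1)
        if integ.state.time >= next_sample or integ.state.time >= t_end:
            _, reaction = indenter_force(system.positions, tip_center, R,
                                         tip_stiffness, shape="sphere")
            rows.append({"time": integ.state.time, "force": reaction[2],
                         "phase": phase})
            track.append({"time": integ.state.time, "z": z})
            next_sample += protocol.sampling_interval
    return IndentationResult(
        force_curve=pd.DataFrame(rows), system=system, frozen=frozen,
        tip_track=pd.DataFrame(track))


# ---------------------------------------------------------------------------
# Constricted migration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MigrationProtocol:
    """Cell translocation through a two-pillar constriction.

    Migration is driven by particle turnover: every ``period`` steps one
    cytoplasmic particle is inserted at the leading-edge surface (within a
    60° cone about ``direction``) and the trailing-most cytoplasmic
    particle is removed, conserving the particle count.  A centering
    spring pulls the nucleus toward the cytoplasmic centroid in the
    migration plane.  The pillars are rigid vertical cylinders separated
    by ``gap``.
    """

    gap: float                        # µm, clear spacing between pillars
    obstacle_radius: float            # µm
    obstacle_x: float                 # µm, pillar center x
    period: int = 200                 # steps between turnover events
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    bias_k: float | None = None
    cone_half_angle_deg: float = 30.0
    obstacle_stiffness: float | None = None
    slab_height: float | None = None  # µm; device ceiling, None = open top
    floor_z: float = 0.0              # µm; floor felt by nuclear particles


@dataclass
class MigrationResult:
    system: ParticleSystem
    metrics: pd.DataFrame      # time, nsi, ellipticity, nucleus_x, n_particles
    transited: bool


def _insert_leading_particle(system, protocol, deq, rng):
    """Lamellipodium-like growth: a new cytoplasmic particle is placed on
    the substrate just ahead of the basal leading edge, within a planar
    cone about the migration direction.

    The anchor is the foremost basal *bulk* particle (enough neighbors to
    exclude a previously inserted particle that has not yet been absorbed),
    so insertions extend the adherent front rather than growing a detached
    filament.
    """
    direction = np.asarray(protocol.direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    half = np.deg2rad(protocol.cone_half_angle_deg)

    cyt = np.flatnonzero(system.kind_mask(ParticleKind.CYTOPLASM)
                         & system.mobile)
    pos = system.positions[cyt]
    z_base = pos[:, 2].min()
    tree = cKDTree(system.positions[system.cell_id >= 0])
    n_nbrs = np.array([len(x) - 1 for x in
                       tree.query_ball_point(pos, 1.3 * deq)])
    basal = pos[:, 2] < z_base + 1.5 * deq
    bulk = (n_nbrs >= 4) & basal
    if not bulk.any():
        bulk = n_nbrs >= 4
    candidates = pos[bulk] if bulk.any() else pos
    # surface positions within the in-plane cone about the leading
    # direction, measured from the cytoplasmic centroid
    center = pos.mean(axis=0)
    radial = candidates[:, :2] - center[:2]
    rnorm = np.linalg.norm(radial, axis=1)
    rnorm[rnorm == 0] = 1.0
    cosang = (radial @ direction[:2]) / rnorm
    in_cone = cosang >= np.cos(half)
    front = candidates[in_cone] if in_cone.any() else candidates
    radial = radial[in_cone] if in_cone.any() else radial
    # outermost shell of the cone: the actual leading surface
    proj = front[:, :2] @ direction[:2]
    shell = proj >= np.quantile(proj, 0.7)
    idx = rng.choice(np.flatnonzero(shell))
    anchor = front[idx]
    outward = radial[idx] / max(np.linalg.norm(radial[idx]), 1e-12)
    return np.array([anchor[0] + deq * outward[0],
                     anchor[1] + deq * outward[1], anchor[2]])


def run_constricted_migration(
    cell: ParticleSystem,
    ecm: ParticleSystem,
    table,
    params: SEMParameters,
    drag_fn,
    protocol: MigrationProtocol,
    *,
    n_steps: int,
    output_every: int = 200,
    settle_steps: int = 0,
    kT_eff: float | None = None,
    dt: float | None = None,
    seed: int | None = None,
    transit_margin: float | None = None,
) -> MigrationResult:
    """Drive a cell through a rigid constriction by particle turnover.

    ``drag_fn(system) -> (N,) array`` supplies per-particle drags (the
    particle count changes during the run).  Returns NSI and ellipticity
    time series of the nucleus plus a transit flag (nuclear centroid past
    the pillars).
    """
    rng = np.random.default_rng(seed)
    if kT_eff is None:
        kT_eff = DEFAULT_KT_FRACTION * params.u0
    bias_k = protocol.bias_k
    if bias_k is None:
        bias_k = 0.2 * params.u0 / params.deq**2
    K_obs = protocol.obstacle_stiffness
    if K_obs is None:
        K_obs = 1e3 * params.u0 / params.deq**3
    y_off = protocol.gap / 2.0 + protocol.obstacle_radius
    centers = [np.array([protocol.obstacle_x, +y_off, 0.0]),
               np.array([protocol.obstacle_x, -y_off, 0.0])]

    def obstacles(s):
        total = np.zeros_like(s.positions)
        for c in centers:
            f, _ = indenter_force(s.positions, c, protocol.obstacle_radius,
                                  K_obs, shape="cylinder", axis="z")
            total += f
        return total

    def bias(s):
        return nuclear_bias_force(s, bias_k, plane="xy")

    def slab(s):
        # microfluidic-device vertical confinement: quadratic penalty
        # above the ceiling (all mobile particles) and below the floor
        # (nuclear particles, which have no substrate interaction)
        forces = np.zeros_like(s.positions)
        z = s.positions[:, 2]
        if protocol.slab_height is not None:
            over = z > protocol.slab_height
            forces[over, 2] = -K_obs * (z[over] - protocol.slab_height) ** 2
        under = (z < protocol.floor_z) & s.kind_mask(ParticleKind.NUCLEUS)
        forces[under, 2] = K_obs * (protocol.floor_z - z[under]) ** 2
        return forces

    system = ParticleSystem.concatenate(cell, ecm)
    n_total = system.n
    if transit_margin is None:
        transit_margin = protocol.obstacle_radius

    rows = []
    fixed_dt = dt
    done = 0
    transited = False
    time_now = 0.0
    rng_dyn = np.random.default_rng(rng.integers(2**31))

    if settle_steps:
        # relax the cell under the device confinement before turnover
        settle = BrownianIntegrator(
            system, table, drag_fn(system), params.deq,
            dt="auto" if fixed_dt is None else fixed_dt,
            kT_eff=kT_eff, rng=rng_dyn, adaptive=True,
            externals=[obstacles, bias, slab])
        settle.step(settle_steps)
        fixed_dt = settle.state.dt

    while done < n_steps:
        drag = drag_fn(system)
        integ = BrownianIntegrator(
            system, table, drag, params.deq,
            dt="auto" if fixed_dt is None else fixed_dt,
            kT_eff=kT_eff, rng=rng_dyn, adaptive=True,
            externals=[obstacles, bias, slab])
        integ.state.time = time_now
        chunk = min(protocol.period, n_steps - done)
        sub = 0
        while sub < chunk:
            inner = min(output_every, chunk - sub)
            integ.step(inner)
            sub += inner
            nucmask = system.kind_mask(ParticleKind.NUCLEUS)
            nuc = system.positions[nucmask]
            try:
                nsi, _, _ = analysis.shape_index(nuc)
            except analysis.DegenerateGeometryError:
                nsi = np.nan
            try:
                ell = analysis.ellipticity(nuc)
            except analysis.DegenerateGeometryError:
                ell = np.nan
            rows.append({"time": integ.state.time, "nsi": nsi,
                         "ellipticity": ell,
                         "nucleus_x": nuc[:, 0].mean(),
                         "nucleus_y": nuc[:, 1].mean(),
                         "nucleus_y_width": nuc[:, 1].max() - nuc[:, 1].min(),
                         "nucleus_x_width": nuc[:, 0].max() - nuc[:, 0].min(),
                         "n_particles": system.n})
            if nuc[:, 0].mean() > protocol.obstacle_x + transit_margin:
                transited = True
        time_now = integ.state.time
        fixed_dt = integ.state.dt   # carry the adapted dt across rebuilds
        done += chunk
        if done >= n_steps:
            break
        # particle turnover: add at the leading edge, remove the trailing-most
        new_pos = _insert_leading_particle(system, protocol, params.deq, rng)
        direction = np.asarray(protocol.direction, dtype=float)
        direction /= np.linalg.norm(direction)
        cyt_idx = np.where(system.kind_mask(ParticleKind.CYTOPLASM)
                           & system.mobile)[0]
        trailing = cyt_idx[np.argmin(system.positions[cyt_idx] @ direction)]
        cid = int(system.cell_id[trailing])
        keep = np.ones(system.n, dtype=bool)
        keep[trailing] = False
        system = ParticleSystem(
            positions=np.vstack([system.positions[keep], new_pos]),
            kinds=np.append(system.kinds[keep], CYT),
            mobile=np.append(system.mobile[keep], True),
            cell_id=np.append(system.cell_id[keep], cid),
        )
        assert system.n == n_total
    metrics = pd.DataFrame(rows)
    if not transited:
        warnings.warn("cell did not transit the constriction in the "
                      "allotted steps")
    return MigrationResult(system=system, metrics=metrics, transited=transited)
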