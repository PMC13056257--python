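"""Overdamped Langevin (Brownian) time integration.

Each mobile particle follows the first-order equation of motion
η ẏ = F(y) + ξ, integrated with Euler–Maruyama:

    y ← y + (dt/η) F + sqrt(2 kT_eff dt / η) N(0, 1)   per coordinate.

kT_eff is an effective thermal energy controlling the noise amplitude via
the fluctuation–dissipation relation; the default u0/50 keeps bound pairs
bound (barrier ≫ kT_eff) while still annealing phase separation.  The drag
η is per-particle and kind-dependent (cytoplasm vs nucleus).  ECM, glass
and explicitly frozen particles never move.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ParticleKind, ParticleSystem
from .potentials import (NeighborList, StabilityError,
                         build_interaction_neighbor_list, total_forces)

__all__ = [
    "IntegratorState",
    "BrownianIntegrator",
    "auto_timestep",
    "nuclear_bias_force",
    "freeze_particles",
]

#: default ratio of effective thermal energy to the cytoplasmic well depth
DEFAULT_KT_FRACTION = 1.0 / 50.0
#: target max displacement per step, in units of deq, for the auto timestep
AUTO_DT_DISPLACEMENT = 0.02
#: hard per-step displacement bound, in units of deq
MAX_STEP_DISPLACEMENT = 0.5


@dataclass
class IntegratorState:
    time: float
    dt: float
    kT_eff: float
    rng: np.random.Generator
    frozen: np.ndarray            # (N,) bool
    drag: np.ndarray              # (N,) zJ·s/µm²
    nlist: NeighborList | None = None
    rebuild_count: int = 0


def auto_timestep(system, table, drag, deq, *, nlist=None,
                  target=AUTO_DT_DISPLACEMENT, externals=()):
    """dt such that the current max drift displacement is ``target``·deq.

    Falls back to the pair-relaxation scale when forces are (near) zero.
    """
    if nlist is None:
        nlist = build_interaction_neighbor_list(system.positions,
                                                system.kinds, table,
                                                skin=0.3 * deq)
    forces = total_forces(system, table, nlist, externals=externals)
    speed = np.linalg.norm(forces, axis=1) / drag
    vmax = speed[system.mobile].max(initial=0.0)
    if vmax <= 0:
        # characteristic speed from the softest relevant force scale
        u0 = max((pi.u0 + pi.epsilon) for _, pi in table.items())
        vmax = u0 / (deq * drag.min())
    return target * deq / vmax


class BrownianIntegrator:
    """Euler–Maruyama integrator for one particle system.

    Parameters
    ----------
    system : ParticleSystem
        Integrated in place.
    table : InteractionTable
    drag : array (N,)
        Per-particle drag coefficients, zJ·s/µm².
    deq : float
        Equilibrium spacing, used for the stability bound and list skin.
    dt : float or "auto"
    kT_eff : float
        Effective thermal energy (zJ); 0 disables noise.
    seed : int, optional
        Seeds the internal Generator; pass ``rng`` to share one instead.
    frozen : bool array, optional
        Extra immobilized particles (beyond ECM/glass).
    """

    def __init__(self, system, table, drag, deq, *, dt="auto", kT_eff=0.0,
                 seed=None, rng=None, frozen=None, skin=None, externals=(),
                 adaptive=False):
        self.system = system
        self.table = table
        self.deq = float(deq)
        self.adaptive = bool(adaptive)
        self.externals = list(externals)
        drag = np.asarray(drag, dtype=float)
        if np.any(drag <= 0):
            raise ValueError("drag coefficients must be positive")
        if frozen is None:
            frozen = np.zeros(system.n, dtype=bool)
        skin = 0.3 * deq if skin is None else skin
        self._skin = skin
        nlist = build_interaction_neighbor_list(
            system.positions, system.kinds, table, skin=skin)
        if dt == "auto":
            dt = auto_timestep(system, table, drag, deq, nlist=nlist,
                               externals=self.externals)
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.state = IntegratorState(
            time=0.0, dt=float(dt), kT_eff=float(kT_eff),
            rng=rng if rng is not None else np.random.default_rng(seed),
            frozen=np.asarray(frozen, dtype=bool), drag=drag, nlist=nlist)

    # -- helpers -----------------------------------------------------------

    @property
    def movable(self) -> np.ndarray:
        return self.system.mobile & ~self.state.frozen

    def _ensure_nlist(self):
        st = self.state
        if st.nlist is None or not st.nlist.is_valid(self.system.positions):
            st.nlist = build_interaction_neighbor_list(
                self.system.positions, self.system.kinds, self.table,
                skin=self._skin)
            st.rebuild_count += 1
        return st.nlist

    def forces(self, extra_externals=()):
        nlist = self._ensure_nlist()
        return total_forces(self.system, self.table, nlist,
                            externals=list(self.externals) + list(extra_externals))

    # -- stepping ----------------------------------------------------------

    def step(self, n=1, extra_externals=()):
        """Advance n Euler–Maruyama steps; returns the system.

        With ``adaptive=True`` the timestep is retried at a smaller value
        when the drift displacement overshoots the stability target and is
        grown slowly when the dynamics are quiet; otherwise an over-large
        step raises a stability error.
        """
        st = self.state
        mob = self.movable
        drag_col = st.drag[:, None]
        sqrt_drag = np.sqrt(st.drag)[:, None]
        limit = MAX_STEP_DISPLACEMENT * self.deq
        target = AUTO_DT_DISPLACEMENT * self.deq
        done = 0
        retries = 0
        while done < n:
            forces = self.forces(extra_externals)
            drift = (st.dt / drag_col) * forces
            drift_max = np.linalg.norm(drift[mob], axis=1).max(initial=0.0)
            if self.adaptive and drift_max > 2.0 * target:
                if retries > 200:
                    raise StabilityError(
                        "adaptive timestep collapsed; configuration is "
                        "unstable")
                st.dt *= max(0.2, target / drift_max)
                retries += 1
                continue
            disp = drift
            if st.kT_eff > 0:
                noise_amp = np.sqrt(2.0 * st.kT_eff * st.dt) / sqrt_drag
                disp = disp + noise_amp * st.rng.standard_normal(
                    self.system.positions.shape)
            dmax = np.linalg.norm(disp[mob], axis=1).max(initial=0.0)
            if dmax > limit:
                raise StabilityError(
                    f"per-step displacement {dmax:.3g} µm exceeds "
                    f"{MAX_STEP_DISPLACEMENT} deq = {limit:.3g} µm at "
                    f"t = {st.time:.4g} s; reduce dt")
            self.system.positions[mob] += disp[mob]
            st.time += st.dt
            done += 1
            retries = 0
            if self.adaptive and drift_max < 0.5 * target:
                st.dt *= 1.05
        return self.system

    def run(self, n_steps, callback=None, callback_every=0):
        """Run n_steps, optionally invoking callback(integrator, step)."""
        if callback is None or callback_every <= 0:
            return self.step(n_steps)
        done = 0
        while done < n_steps:
            chunk = min(callback_every, n_steps - done)
            self.step(chunk)
            done += chunk
            callback(self, done)
        return self.system


# ---------------------------------------------------------------------------
# Special forces and constraints
# ---------------------------------------------------------------------------

_PLANE_AXES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2), "xyz": (0, 1, 2)}


def nuclear_bias_force(system, k_bias, plane="xy"):
    """Centering spring pulling the nucleus toward the cell centroid.

    Every nuclear particle receives the same force k_bias (c_cell − c_nuc)
    restricted to the given plane, where c_cell is the cytoplasmic centroid
    and c_nuc the nuclear centroid.  Keeps the nucleus embedded in the
    cytoplasmic ensemble during phase separation and migration.
    """
    forces = np.zeros_like(system.positions)
    nuc = system.kind_mask(ParticleKind.NUCLEUS)
    cyt = system.kind_mask(ParticleKind.CYTOPLASM)
    if not nuc.any():
        import warnings
        warnings.warn("nuclear bias requested but no nuclear particles")
        return forces
    if not cyt.any():
        raise ValueError("nuclear bias needs at least one cytoplasmic particle")
    delta = (system.positions[cyt].mean(axis=0)
             - system.positions[nuc].mean(axis=0))
    f = np.zeros(3)
    axes = _PLANE_AXES[plane]
    for a in axes:
        f[a] = k_bias * delta[a]
    forces[nuc] = f
    return forces


def nuclear_gather_force(system, k_gather, plane="xyz"):
    """Per-particle spring pulling each nuclear particle to the cell center.

    Unlike :func:`nuclear_bias_force` (a rigid translation of the nuclear
    ensemble), each nuclear particle is pulled individually toward the
    cytoplasmic centroid, which contracts and merges dispersed nuclear
    clusters.  Used during the phase-separation anneal, where the centering
    bias acts while the nucleus is still forming.
    """
    forces = np.zeros_like(system.positions)
    nuc = system.kind_mask(ParticleKind.NUCLEUS)
    cyt = system.kind_mask(ParticleKind.CYTOPLASM)
    if not nuc.any() or not cyt.any():
        return forces
    center = system.positions[cyt].mean(axis=0)
    delta = center[None, :] - system.positions[nuc]
    keep = np.zeros(3)
    for a in _PLANE_AXES[plane]:
        keep[a] = 1.0
    forces[nuc] = k_gather * delta * keep
    return forces


def freeze_particles(system, selector):
    """Resolve a freeze selection to a boolean mask.

    ``selector`` is either an iterable of particle indices or a predicate
    ``f(positions, kinds) -> bool array``.  Used to immobilize peripheral
    basal particles (mimicking focal adhesions) before indentation.
    """
    if callable(selector):
        mask = np.asarray(selector(system.positions, system.kinds), dtype=bool)
        if mask.shape != (system.n,):
            raise ValueError("freeze predicate must return one flag per particle")
    else:
        ids = np.asarray(list(selector), dtype=np.int64)
        mask = np.zeros(system.n, dtype=bool)
        mask[ids] = True
    return mask & system.mobile


def peripheral_basal_selector(radial_fraction=0.85, z_max=None, deq=None,
                              center=None):
    """Selector for the basal annulus of a spread cell.

    Picks cytoplasmic particles below ``z_max`` (default one deq above the
    substrate) whose in-plane radius exceeds ``radial_fraction`` of the
    current spread radius.
    """
    if z_max is None:
        if deq is None:
            raise ValueError("need z_max or deq")
        z_max = deq

    def predicate(positions, kinds):
        cyt = kinds == int(ParticleKind.CYTOPLASM)
        xy = positions[:, :2]
        c = xy[cyt].mean(axis=0) if center is None else np.asarray(center)
        r = np.linalg.norm(xy - c, axis=1)
        r_spread = r[cyt].max(initial=0.0)
        return cyt & (positions[:, 2] < z_max) & (r > radial_fraction * r_spread)

    return predicate
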