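"""Core domain types: units, particle system, pair-parameter derivation.

The simulator works in a micrometre / second / zeptojoule unit system, the
natural scales of single-cell mechanics: cell radii are ~10 µm, adhesion
well depths are ~1e4–1e5 zJ, and cell-level stiffnesses of ~1e-2 N/m map to
~1e7 zJ/µm².  All cell-level rheological inputs (stiffness in N/m, drag in
N·s/m) are converted on entry; every derived per-particle quantity is stored
in internal units.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .potentials import PairInteraction

__all__ = [
    "UnitSystem",
    "units",
    "ParticleKind",
    "ParticleSystem",
    "SEMParameters",
    "InteractionTable",
    "derive_pair_parameters",
    "build_interaction_table",
    "init_cell",
    "InvalidParameterError",
    "GeometryError",
    "DEFAULT_CONFIG",
]


class InvalidParameterError(ValueError):
    """A physically inadmissible model parameter."""


class GeometryError(RuntimeError):
    """Initial-placement geometry cannot accommodate the request."""


# ---------------------------------------------------------------------------
# Units
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitSystem:
    """Internal unit system: length µm, time s, energy zJ.

    Derived units follow: force zJ/µm, stiffness zJ/µm² (1 N/m = 1e9
    zJ/µm²), drag zJ·s/µm² (1 N·s/m = 1e9 zJ·s/µm²), mass ng.
    """

    length_um_per_m: float = 1e6
    time_s_per_s: float = 1.0
    energy_zj_per_j: float = 1e21
    mass_ng_per_kg: float = 1e12

    @property
    def stiffness_per_npm(self) -> float:
        """zJ/µm² per N/m."""
        return self.energy_zj_per_j / self.length_um_per_m**2

    @property
    def drag_per_nspm(self) -> float:
        """zJ·s/µm² per N·s/m."""
        return self.stiffness_per_npm * self.time_s_per_s

    @property
    def force_per_n(self) -> float:
        """zJ/µm per N."""
        return self.energy_zj_per_j / self.length_um_per_m

    def stiffness_from_si(self, value_n_per_m: float) -> float:
        return value_n_per_m * self.stiffness_per_npm

    def stiffness_to_si(self, value: float) -> float:
        return value / self.stiffness_per_npm

    def drag_from_si(self, value_ns_per_m: float) -> float:
        return value_ns_per_m * self.drag_per_nspm

    def drag_to_si(self, value: float) -> float:
        return value / self.drag_per_nspm


#: module-wide unit system instance
units = UnitSystem()


# ---------------------------------------------------------------------------
# Particle kinds and systems
# ---------------------------------------------------------------------------

class ParticleKind(enum.IntEnum):
    """Stable integer codes for the particle types.

    Cytoplasm (1) and nucleus (2) are mobile and equal-sized; ECM (3) and
    glass (4) are immobile substrate particles.  Indenters are virtual
    (not particles) and carry no code.
    """

    CYTOPLASM = 1
    NUCLEUS = 2
    ECM = 3
    GLASS = 4


#: kinds that never move, by construction
IMMOBILE_KINDS = (ParticleKind.ECM, ParticleKind.GLASS)


@dataclass
class ParticleSystem:
    """Positions plus per-particle bookkeeping for one simulation box.

    Positions are 3-D Cartesian in µm with the substrate plane at z = 0 and
    z pointing up.  ``mobile`` marks particles the integrator may move;
    ECM/glass particles are immobile by construction.  ``mp`` is the
    per-particle mass in ng — bookkeeping only, the dynamics are overdamped.
    """

    positions: np.ndarray          # (N, 3) float64, µm
    kinds: np.ndarray              # (N,) int
    mobile: np.ndarray             # (N,) bool
    cell_id: np.ndarray            # (N,) int; -1 for substrate particles
    mp: np.ndarray | None = None   # (N,) float, ng

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.kinds = np.asarray(self.kinds, dtype=np.int64)
        self.mobile = np.asarray(self.mobile, dtype=bool)
        self.cell_id = np.asarray(self.cell_id, dtype=np.int64)
        n = len(self.positions)
        if not (len(self.kinds) == len(self.mobile) == len(self.cell_id) == n):
            raise ValueError("per-particle arrays must share one length")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        immobile_kind = np.isin(self.kinds, [int(k) for k in IMMOBILE_KINDS])
        self.mobile = self.mobile & ~immobile_kind
        if self.mp is not None:
            self.mp = np.asarray(self.mp, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n(self) -> int:
        return len(self.positions)

    def kind_mask(self, kind: ParticleKind) -> np.ndarray:
        return self.kinds == int(kind)

    def count(self, kind: ParticleKind) -> int:
        return int(np.count_nonzero(self.kind_mask(kind)))

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            self.positions.copy(), self.kinds.copy(), self.mobile.copy(),
            self.cell_id.copy(), None if self.mp is None else self.mp.copy(),
        )

    @staticmethod
    def concatenate(*systems: "ParticleSystem") -> "ParticleSystem":
        mp_arrays = []
        for s in systems:
            mp_arrays.append(s.mp if s.mp is not None else np.zeros(s.n))
        return ParticleSystem(
            np.vstack([s.positions for s in systems]),
            np.concatenate([s.kinds for s in systems]),
            np.concatenate([s.mobile for s in systems]),
            np.concatenate([s.cell_id for s in systems]),
            np.concatenate(mp_arrays),
        )


# ---------------------------------------------------------------------------
# Pair-parameter derivation from cell-level rheology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SEMParameters:
    """Per-particle interaction parameters derived from cell rheology.

    The derivation treats the cell as Np densely packed particles connected
    by springs: the equilibrium spacing follows from close packing at the
    cell radius, the effective pair stiffness softens with Np (corrected by
    the lattice-departure tuning coefficient λ), and the Morse well depth
    follows from the pair stiffness at the well minimum.

    Inputs are stored as given; derived quantities are in internal units
    (µm, s, zJ):

    - ``deq``: equilibrium particle spacing, deq = 2 Rcell (pd/Np)^(1/3)
    - ``kappa_eff``: effective pair stiffness κ = κ0 Np^(-1/3) (1 − λ Np^(-1/3))
    - ``u0``: Morse well depth u0 = κ deq² / (8 ρ²)
    - ``eta_p``: per-particle drag η0/Np (so the ensemble's summed drag
      equals the cell-level drag)
    - ``cutoff``: interaction range, 2.5 deq
    """

    Rcell: float          # µm
    Np: int
    pd: float
    rho: float
    alpha: float
    kappa0: float         # zJ/µm²
    eta0: float           # zJ·s/µm²
    lam: float
    deq: float            # µm
    kappa_eff: float      # zJ/µm²
    u0: float             # zJ
    eta_p: float          # zJ·s/µm²
    cutoff: float         # µm

    @property
    def particle_radius(self) -> float:
        """Equal cytoplasm/nucleus particle radius, deq/2 (µm)."""
        return self.deq / 2.0


def derive_pair_parameters(
    Rcell: float,
    Np: int,
    pd: float,
    rho: float,
    alpha: float,
    kappa0_si: float,
    eta0_si: float,
    lam: float,
    *,
    drag_scaling: str = "divide",
    cutoff_factor: float = 2.5,
) -> SEMParameters:
    """Derive per-particle Morse parameters from cell-level rheology.

    Parameters
    ----------
    Rcell : float
        Cell radius in µm.
    Np : int
        Number of particles representing the cell.
    pd : float
        Sphere close-packing density (0.74 for FCC).
    rho, alpha : float
        Morse scaling and shifting factors.
    kappa0_si : float
        Cell stiffness in N/m.
    eta0_si : float
        Cell viscosity (drag) in N·s/m.
    lam : float
        Tuning coefficient correcting the cubic-lattice elastic estimate.
    drag_scaling : {"divide", "multiply"}
        How the cell drag maps to per-particle drag.  "divide" (η0/Np, the
        default) keeps the summed ensemble drag equal to the cell-level
        value and is the physically consistent reading; "multiply" is kept
        as a sensitivity switch.
    cutoff_factor : float
        Interaction cutoff in units of deq (default 2.5).
    """
    for name, v in (("Rcell", Rcell), ("Np", Np), ("pd", pd), ("rho", rho),
                    ("alpha", alpha), ("kappa0", kappa0_si),
                    ("eta0", eta0_si)):
        if v <= 0:
            raise InvalidParameterError(f"{name} must be positive, got {v}")
    if not 0 < pd <= 1:
        raise InvalidParameterError(f"pd must lie in (0, 1], got {pd}")
    if lam < 0:
        raise InvalidParameterError(f"lambda must be non-negative, got {lam}")
    softening = lam * Np ** (-1.0 / 3.0)
    if softening >= 1.0:
        raise InvalidParameterError(
            f"lambda * Np^(-1/3) = {softening:.4g} >= 1: effective pair "
            "stiffness would be non-positive")
    if drag_scaling not in ("divide", "multiply"):
        raise InvalidParameterError(f"unknown drag_scaling {drag_scaling!r}")

    kappa0 = units.stiffness_from_si(kappa0_si)
    eta0 = units.drag_from_si(eta0_si)
    deq = 2.0 * Rcell * (pd / Np) ** (1.0 / 3.0)
    kappa_eff = kappa0 * Np ** (-1.0 / 3.0) * (1.0 - softening)
    u0 = kappa_eff * deq**2 / (8.0 * rho**2)
    eta_p = eta0 / Np if drag_scaling == "divide" else eta0 * Np
    return SEMParameters(
        Rcell=Rcell, Np=int(Np), pd=pd, rho=rho, alpha=alpha,
        kappa0=kappa0, eta0=eta0, lam=lam,
        deq=deq, kappa_eff=kappa_eff, u0=u0, eta_p=eta_p,
        cutoff=cutoff_factor * deq,
    )


def well_depth_from_stiffness(kappa_si: float, params: SEMParameters) -> float:
    """Morse well depth (zJ) from a cell-level stiffness in N/m.

    Applies the same Np-softening chain used for the cytoplasm (effective
    pair stiffness, then the well-depth relation at the shared deq and ρ),
    so well-depth ratios equal cell-level stiffness ratios: a nucleus with
    κnuc = 2 κ0 has twice the cytoplasmic well depth.
    """
    if kappa_si <= 0:
        raise InvalidParameterError("stiffness must be positive")
    kappa = units.stiffness_from_si(kappa_si)
    softening = params.lam * params.Np ** (-1.0 / 3.0)
    kappa_eff = kappa * params.Np ** (-1.0 / 3.0) * (1.0 - softening)
    return kappa_eff * params.deq**2 / (8.0 * params.rho**2)


# ---------------------------------------------------------------------------
# Interaction table
# ---------------------------------------------------------------------------

CYT = int(ParticleKind.CYTOPLASM)
NUC = int(ParticleKind.NUCLEUS)
ECM = int(ParticleKind.ECM)
GLA = int(ParticleKind.GLASS)


class InteractionTable:
    """Symmetric per-kind-pair table of pair interactions.

    Lookups are order-independent: ``table[(p, q)] is table[(q, p)]``.
    Absent pairs interact with a NONE placeholder (zero energy and force).
    """

    _NONE = PairInteraction.none()

    def __init__(self) -> None:
        self._pairs: dict[tuple[int, int], PairInteraction] = {}

    @staticmethod
    def _key(p: int, q: int) -> tuple[int, int]:
        p, q = int(p), int(q)
        return (p, q) if p <= q else (q, p)

    def set(self, p: int, q: int, interaction: PairInteraction) -> None:
        self._pairs[self._key(p, q)] = interaction

    def get(self, p: int, q: int) -> PairInteraction:
        return self._pairs.get(self._key(p, q), self._NONE)

    def __getitem__(self, pq: tuple[int, int]) -> PairInteraction:
        return self.get(*pq)

    def items(self):
        return self._pairs.items()

    @property
    def max_cutoff(self) -> float:
        active = [pi.cutoff for pi in self._pairs.values() if pi.form != "none"]
        return max(active) if active else 0.0

    def scaled(self, p: int, q: int, *, u0_mult: float = 1.0,
               cutoff_mult: float = 1.0) -> "InteractionTable":
        """Return a copy with one pair's well depth / cutoff rescaled.

        Used by the phase-separation anneal, which temporarily strengthens
        and extends the nuclear self-interaction.
        """
        out = InteractionTable()
        out._pairs = dict(self._pairs)
        base = out.get(p, q)
        out.set(p, q, base.rescaled(u0_mult=u0_mult, cutoff_mult=cutoff_mult))
        return out


def build_interaction_table(
    params: SEMParameters,
    kappa_nuc_si: float,
    k12: float,
    ecm_epsilon: float,
    ecm_sigma: float,
    ecm_cutoff: float,
    *,
    glass_sigma: float | None = None,
    nucleus_ecm: dict | None = None,
    shift_morse: bool = True,
) -> InteractionTable:
    """Assemble the default pair-interaction table.

    - cytoplasm–cytoplasm: Morse with the derived u0
    - nucleus–nucleus: Morse with u0 from the nuclear stiffness κnuc
    - cytoplasm–nucleus: Morse with u0(1,2) = k12 · u0(1,1); the particles
      are equal-sized so deq(1,2) = deq(1,1)
    - cytoplasm–ECM: Lennard-Jones 12–6 (ε in zJ, σ and cutoff in µm)
    - cytoplasm–glass: the same LJ truncated at its zero crossing, i.e.
      purely repulsive volume exclusion
    - nucleus–ECM: none by default; optionally a weak generalized m–n
      attractive–repulsive coupling via ``nucleus_ecm={"epsilon":, "sigma":,
      "m": 3, "n": 2, "cutoff":}``
    - all other pairs (nucleus–glass, substrate–substrate): none
    """
    if k12 <= 0:
        raise InvalidParameterError(f"k12 must be positive, got {k12}")
    if ecm_epsilon < 0:
        raise InvalidParameterError("ECM well depth must be non-negative")
    if ecm_sigma <= 0:
        raise InvalidParameterError("ECM sigma must be positive")
    if ecm_cutoff <= ecm_sigma:
        raise InvalidParameterError("ECM cutoff must exceed sigma")

    u0_cc = params.u0
    u0_nn = well_depth_from_stiffness(kappa_nuc_si, params)
    u0_cn = k12 * u0_cc

    table = InteractionTable()
    morse = dict(rho=params.rho, alpha=params.alpha, deq=params.deq,
                 cutoff=params.cutoff, shift=shift_morse)
    table.set(CYT, CYT, PairInteraction.morse(u0=u0_cc, **morse))
    table.set(NUC, NUC, PairInteraction.morse(u0=u0_nn, **morse))
    table.set(CYT, NUC, PairInteraction.morse(u0=u0_cn, **morse))
    table.set(CYT, ECM, PairInteraction.lj126(
        epsilon=ecm_epsilon, sigma=ecm_sigma, cutoff=ecm_cutoff))
    gsig = ecm_sigma if glass_sigma is None else glass_sigma
    table.set(CYT, GLA, PairInteraction.lj_repulsive(
        epsilon=ecm_epsilon, sigma=gsig))
    if nucleus_ecm is not None:
        table.set(NUC, ECM, PairInteraction.lj_general(
            epsilon=nucleus_ecm["epsilon"], sigma=nucleus_ecm["sigma"],
            m=nucleus_ecm.get("m", 3), n=nucleus_ecm.get("n", 2),
            cutoff=nucleus_ecm["cutoff"]))
    return table


# ---------------------------------------------------------------------------
# Cell initialization
# ---------------------------------------------------------------------------

def init_cell(
    Np: int,
    nuclear_fraction: float,
    radius: float,
    height: float,
    *,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    min_spacing: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mcell: float | None = None,
    cell_id: int = 0,
    max_attempts_per_particle: int = 2000,
) -> ParticleSystem:
    """Place Np particles uniformly at random in a cylinder.

    Exactly ``round(Np * nuclear_fraction)`` particles are tagged as nuclear
    (randomly interleaved with cytoplasmic ones), matching the mixed initial
    state from which the nucleus later phase-separates.  Rejection sampling
    enforces a minimum pairwise spacing.  The same seed always reproduces
    the identical configuration.
    """
    if not 0 <= nuclear_fraction < 1:
        raise InvalidParameterError("nuclear_fraction must lie in [0, 1)")
    if radius <= 0 or height <= 0 or Np < 1:
        raise InvalidParameterError("cylinder geometry and Np must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=float)

    positions = np.empty((Np, 3))
    placed = 0
    attempts_left = max_attempts_per_particle * Np
    while placed < Np:
        if attempts_left <= 0:
            raise GeometryError(
                f"could not place {Np} particles at spacing {min_spacing} in "
                f"cylinder (r={radius}, h={height}); placed {placed}")
        m = min(256, attempts_left)
        r = radius * np.sqrt(rng.random(m))
        th = 2.0 * np.pi * rng.random(m)
        z = height * (rng.random(m) - 0.5)
        cand = np.column_stack([r * np.cos(th), r * np.sin(th), z]) + center
        for c in cand:
            attempts_left -= 1
            if placed and min_spacing > 0:
                d2 = np.sum((positions[:placed] - c) ** 2, axis=1)
                if d2.min() < min_spacing**2:
                    continue
            positions[placed] = c
            placed += 1
            if placed == Np:
                break

    n_nuc = int(round(Np * nuclear_fraction))
    kinds = np.full(Np, CYT, dtype=np.int64)
    nuclear_ids = rng.choice(Np, size=n_nuc, replace=False)
    kinds[nuclear_ids] = NUC
    mp = None
    if mcell is not None:
        mp = np.full(Np, mcell / Np)
    return ParticleSystem(
        positions=positions, kinds=kinds, mobile=np.ones(Np, dtype=bool),
        cell_id=np.full(Np, cell_id, dtype=np.int64), mp=mp)


# ---------------------------------------------------------------------------
# Default configuration (flat sections; units as reported in the field:
# stiffness N/m, drag N·s/m, ε zJ, lengths µm, mass ng)
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "cell": {"Rcell": 10.0, "Np": 1000, "nuclear_fraction": 0.10,
             "mcell": 3.1},
    "sem": {"pd": 0.74, "rho": 2.0, "alpha": 2.0, "kappa0": 1.2e-2,
            "eta0": 5.0e-2, "lambda": 0.75, "drag_scaling": "divide"},
    "nucleus": {"kappa": 4.5e-2, "eta": 2.1e-1, "k12": 1.51,
                "drag_norm": "np"},
    "ecm": {"epsilon": 60000.0, "sigma": 5.0, "cutoff": 15.0},
    "dynamics": {"dt": "auto", "kT_eff": "auto", "bias_k": 0.0},
    "rng": {"seed": 0},
    "output": {"every": 100},
}


def params_from_config(config: dict) -> SEMParameters:
    """Derive SEM pair parameters from a (nested) config mapping."""
    cell, sem = config["cell"], config["sem"]
    return derive_pair_parameters(
        Rcell=cell["Rcell"], Np=cell["Np"], pd=sem["pd"], rho=sem["rho"],
        alpha=sem["alpha"], kappa0_si=sem["kappa0"], eta0_si=sem["eta0"],
        lam=sem["lambda"], drag_scaling=sem.get("drag_scaling", "divide"))


def table_from_config(config: dict, params: SEMParameters | None = None
                      ) -> InteractionTable:
    if params is None:
        params = params_from_config(config)
    nuc, ecm = config["nucleus"], config["ecm"]
    return build_interaction_table(
        params, kappa_nuc_si=nuc["kappa"], k12=nuc["k12"],
        ecm_epsilon=ecm["epsilon"], ecm_sigma=ecm["sigma"],
        ecm_cutoff=ecm["cutoff"],
        nucleus_ecm=ecm.get("nucleus_coupling"))


def nuclear_drag(config: dict, params: SEMParameters) -> float:
    """Per-particle nuclear drag (zJ·s/µm²).

    The per-particle drag derivation fixes the particle count at the cell
    level, so the nuclear viscosity maps to per-particle drag with the same
    Np divisor as the cytoplasm ("np", default: only the viscosity
    prefactor differs between the types).  The alternative "nn" distributes
    the nuclear viscosity over the nuclear particles alone.
    """
    nuc = config["nucleus"]
    eta_nuc = units.drag_from_si(nuc["eta"])
    n_nuc = max(1, int(round(config["cell"]["Np"]
                             * config["cell"]["nuclear_fraction"])))
    norm = nuc.get("drag_norm", "np")
    if norm == "nn":
        return eta_nuc / n_nuc
    if norm == "np":
        return eta_nuc / config["cell"]["Np"]
    raise InvalidParameterError(f"unknown nuclear drag_norm {norm!r}")


def drag_array(system: ParticleSystem, params: SEMParameters,
               eta_nuc_p: float) -> np.ndarray:
    """Per-particle drag: cytoplasm uses the derived η_p, nucleus η_nuc_p."""
    eta = np.full(system.n, params.eta_p)
    eta[system.kind_mask(ParticleKind.NUCLEUS)] = eta_nuc_p
    return eta
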