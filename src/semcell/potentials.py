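"""Closed-form pair potentials, rigid-indenter forces, neighbor search.

Sign convention throughout: the returned radial force is the force on a
particle along the outward pair separation, f(d) = -dV/dd, so positive
means repulsion.  Energies and forces are truncated to exactly zero at and
beyond each interaction's cutoff; the Morse form optionally shifts the
energy so it is continuous there (the force is left untouched — the jump at
2.5 deq is ~1e-4 of the well curvature and irrelevant to the dynamics).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PairInteraction",
    "NeighborList",
    "morse_energy_force",
    "lj_energy_force",
    "generalized_lj_energy_force",
    "indenter_force",
    "build_neighbor_list",
    "pair_terms",
    "total_forces",
    "StabilityError",
]


class StabilityError(RuntimeError):
    """Non-finite force or over-large step, typically from particle overlap."""


def _check_distance(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("pair distance must be positive")
    return d


# ---------------------------------------------------------------------------
# Analytic forms
# ---------------------------------------------------------------------------

def morse_energy_force(d, u0, rho, alpha, deq, cutoff, shift=True):
    """Morse-like pair potential in the squared-distance exponent form.

    V(d) = u0 exp(2ρ(1 − d²/deq²)) − α u0 exp(ρ(1 − d²/deq²)),
    truncated at ``cutoff``.  With α = 2 the minimum sits at d = deq with
    depth −u0.  Returns (energy, radial force), force = −dV/dd.
    """
    d = _check_distance(d)
    s = 1.0 - d**2 / deq**2
    e2, e1 = np.exp(2.0 * rho * s), np.exp(rho * s)
    energy = u0 * e2 - alpha * u0 * e1
    force = (2.0 * rho * d / deq**2) * (2.0 * u0 * e2 - alpha * u0 * e1)
    if shift:
        sc = 1.0 - cutoff**2 / deq**2
        energy = energy - (u0 * np.exp(2.0 * rho * sc)
                           - alpha * u0 * np.exp(rho * sc))
    inside = d < cutoff
    return np.where(inside, energy, 0.0), np.where(inside, force, 0.0)


def lj_energy_force(d, epsilon, sigma, dc, shift=False):
    """Lennard-Jones 12–6: V(d) = 4ε[(σ/d)¹² − (σ/d)⁶], truncated at dc.

    ``dc = sigma`` gives the purely repulsive (volume-exclusion) variant,
    which is automatically continuous at the cutoff.
    """
    d = _check_distance(d)
    sr6 = (sigma / d) ** 6
    energy = 4.0 * epsilon * (sr6**2 - sr6)
    force = 24.0 * epsilon * (2.0 * sr6**2 - sr6) / d
    if shift:
        s6 = (sigma / dc) ** 6
        energy = energy - 4.0 * epsilon * (s6**2 - s6)
    inside = d < dc
    return np.where(inside, energy, 0.0), np.where(inside, force, 0.0)


def mie_prefactor(m: float, n: float) -> float:
    """Normalization C(m,n) so min_d C ε[(σ/d)^m − (σ/d)^n] = −ε."""
    if m <= n or n <= 0:
        raise ValueError(f"require m > n > 0, got m={m}, n={n}")
    return (m / (m - n)) * (m / n) ** (n / (m - n))


def generalized_lj_energy_force(d, epsilon, sigma, m, n, dc, shift=False):
    """Generalized attractive–repulsive m–n (Mie) potential.

    V(d) = C ε[(σ/d)^m − (σ/d)^n] with C chosen so the well depth is
    exactly −ε.  (m, n) = (12, 6) reduces to the standard LJ form; (3, 2)
    is the long-ranged soft coupling used for weak nucleus–ECM adhesion.
    """
    d = _check_distance(d)
    C = mie_prefactor(m, n)
    srm, srn = (sigma / d) ** m, (sigma / d) ** n
    energy = C * epsilon * (srm - srn)
    force = C * epsilon * (m * srm - n * srn) / d
    if shift:
        energy = energy - C * epsilon * ((sigma / dc) ** m - (sigma / dc) ** n)
    inside = d < dc
    return np.where(inside, energy, 0.0), np.where(inside, force, 0.0)


# ---------------------------------------------------------------------------
# Pair-interaction records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairInteraction:
    """One entry of the kind-pair interaction table."""

    form: str                       # morse | lj126 | lj_repulsive | lj_general | none
    cutoff: float = 0.0
    u0: float = 0.0
    rho: float = 0.0
    alpha: float = 0.0
    deq: float = 0.0
    epsilon: float = 0.0
    sigma: float = 0.0
    m: float = 0.0
    n: float = 0.0
    shift: bool = True

    @classmethod
    def morse(cls, u0, rho, alpha, deq, cutoff, shift=True):
        if u0 < 0:
            raise ValueError("Morse well depth must be non-negative")
        return cls(form="morse", u0=u0, rho=rho, alpha=alpha, deq=deq,
                   cutoff=cutoff, shift=shift)

    @classmethod
    def lj126(cls, epsilon, sigma, cutoff, shift=False):
        if epsilon < 0:
            raise ValueError("LJ well depth must be non-negative")
        return cls(form="lj126", epsilon=epsilon, sigma=sigma, cutoff=cutoff,
                   shift=shift)

    @classmethod
    def lj_repulsive(cls, epsilon, sigma):
        return cls(form="lj_repulsive", epsilon=epsilon, sigma=sigma,
                   cutoff=sigma, shift=False)

    @classmethod
    def lj_general(cls, epsilon, sigma, m, n, cutoff, shift=False):
        mie_prefactor(m, n)   # validates m > n > 0
        return cls(form="lj_general", epsilon=epsilon, sigma=sigma,
                   m=float(m), n=float(n), cutoff=cutoff, shift=shift)

    @classmethod
    def none(cls):
        return cls(form="none", cutoff=0.0)

    def rescaled(self, *, u0_mult: float = 1.0, cutoff_mult: float = 1.0):
        if self.form == "none":
            return self
        return replace(self, u0=self.u0 * u0_mult,
                       epsilon=self.epsilon * u0_mult,
                       cutoff=self.cutoff * cutoff_mult)

    def energy_force(self, d):
        """(V(d), −dV/dd), both zero at and beyond the cutoff."""
        if self.form == "morse":
            return morse_energy_force(d, self.u0, self.rho, self.alpha,
                                      self.deq, self.cutoff, self.shift)
        if self.form == "lj126":
            return lj_energy_force(d, self.epsilon, self.sigma, self.cutoff,
                                   self.shift)
        if self.form == "lj_repulsive":
            return lj_energy_force(d, self.epsilon, self.sigma, self.cutoff,
                                   shift=False)
        if self.form == "lj_general":
            return generalized_lj_energy_force(
                d, self.epsilon, self.sigma, self.m, self.n, self.cutoff,
                self.shift)
        d = np.asarray(d, dtype=float)
        return np.zeros_like(d), np.zeros_like(d)


# ---------------------------------------------------------------------------
# Rigid indenters
# ---------------------------------------------------------------------------

def indenter_force(positions, center, R, K, shape="sphere", axis="z"):
    """Penalty force of a rigid spherical or cylindrical indenter.

    Particles at distance r < R from the indenter center (sphere) or axis
    (cylinder) are pushed radially outward with magnitude K (r − R)²; the
    force vanishes for r ≥ R (purely repulsive, no adhesion).  A particle
    exactly at the center is pushed along +z (sphere) or the in-plane +x
    direction (cylinder), with magnitude K R².

    Returns (per-particle forces (N,3), total reaction force on the
    indenter = −Σ particle forces).
    """
    if R <= 0 or K <= 0:
        raise ValueError("indenter radius and stiffness must be positive")
    positions = np.asarray(positions, dtype=float)
    center = np.asarray(center, dtype=float)
    rvec = positions - center
    if shape == "cylinder":
        ax = {"x": 0, "y": 1, "z": 2}[axis]
        rvec = rvec.copy()
        rvec[:, ax] = 0.0
        fallback = np.zeros(3)
        fallback[(ax + 1) % 3] = 1.0
    elif shape == "sphere":
        fallback = np.array([0.0, 0.0, 1.0])
    else:
        raise ValueError(f"unknown indenter shape {shape!r}")
    r = np.linalg.norm(rvec, axis=1)
    contact = r < R
    forces = np.zeros_like(positions)
    if np.any(contact):
        mag = K * (r[contact] - R) ** 2
        rc = r[contact]
        dirs = np.where(rc[:, None] > 0, rvec[contact] / np.maximum(rc, 1e-300)[:, None],
                        fallback)
        forces[contact] = mag[:, None] * dirs
    return forces, -forces.sum(axis=0)


# ---------------------------------------------------------------------------
# Neighbor list
# ---------------------------------------------------------------------------

@dataclass
class NeighborList:
    """Verlet pair list with a skin margin.

    Contains every unordered pair closer than build_radius + skin at build
    time; remains valid until some particle has moved farther than skin/2
    from its build-time position.
    """

    pairs: np.ndarray          # (M, 2) int
    build_radius: float
    skin: float
    ref_positions: np.ndarray  # (N, 3) snapshot at build time

    def is_valid(self, positions: np.ndarray) -> bool:
        if len(positions) != len(self.ref_positions):
            return False
        disp2 = np.sum((positions - self.ref_positions) ** 2, axis=1)
        return bool(disp2.max(initial=0.0) <= (0.5 * self.skin) ** 2)

    def grouped(self, kinds: np.ndarray):
        """Pair indices grouped by unordered kind pair (cached).

        Kinds are fixed for the lifetime of a list, so the grouping is
        computed once per rebuild and reused every step.
        """
        cached = getattr(self, "_grouped", None)
        if cached is not None:
            return cached
        groups = {}
        if len(self.pairs):
            i, j = self.pairs[:, 0], self.pairs[:, 1]
            combo = (np.minimum(kinds[i], kinds[j]) * 100
                     + np.maximum(kinds[i], kinds[j]))
            order = np.argsort(combo, kind="stable")
            combo_sorted = combo[order]
            boundaries = np.flatnonzero(np.diff(combo_sorted)) + 1
            for seg, c in zip(np.split(order, boundaries),
                              combo_sorted[np.r_[0, boundaries]]
                              if len(combo_sorted) else []):
                groups[(int(c) // 100, int(c) % 100)] = self.pairs[seg]
        self._grouped = groups
        return groups


def build_neighbor_list(positions, build_radius, skin=0.0) -> NeighborList:
    """All unordered pairs with distance < build_radius + skin (kd-tree)."""
    positions = np.asarray(positions, dtype=float)
    tree = cKDTree(positions)
    pairs = tree.query_pairs(build_radius + skin, output_type="ndarray")
    # query_pairs includes distances == r; drop them to match the strict bound
    if len(pairs):
        d = np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]],
                           axis=1)
        pairs = pairs[d < build_radius + skin]
    return NeighborList(pairs=pairs.astype(np.int64),
                        build_radius=build_radius, skin=skin,
                        ref_positions=positions.copy())


def build_interaction_neighbor_list(positions, kinds, table, skin=0.0
                                    ) -> NeighborList:
    """Neighbor list with per-kind-pair build radii.

    Each active kind pair is searched at its own cutoff + skin, so a
    long-ranged substrate interaction (e.g. the 15 µm cell–ECM cutoff)
    does not inflate the short-ranged cell–cell pair list.  The grouped
    view is precomputed.
    """
    positions = np.asarray(positions, dtype=float)
    kinds = np.asarray(kinds)
    present = set(np.unique(kinds).tolist())
    idx_of = {k: np.flatnonzero(kinds == k) for k in present}
    trees = {k: cKDTree(positions[v]) for k, v in idx_of.items()
             if len(v)}
    groups: dict[tuple[int, int], np.ndarray] = {}
    all_pairs = []
    max_radius = 0.0
    for (p, q), interaction in table.items():
        if interaction.form == "none" or p not in trees or q not in trees:
            continue
        r = interaction.cutoff + skin
        max_radius = max(max_radius, r)
        if p == q:
            local = trees[p].query_pairs(r, output_type="ndarray")
            pairs = idx_of[p][local] if len(local) else np.empty((0, 2), np.int64)
        else:
            hits = trees[p].query_ball_tree(trees[q], r)
            ii, jj = [], []
            for a, nbrs in enumerate(hits):
                ii.extend([a] * len(nbrs))
                jj.extend(nbrs)
            pairs = (np.column_stack([idx_of[p][ii], idx_of[q][jj]])
                     if ii else np.empty((0, 2), np.int64))
        groups[(p, q)] = pairs.astype(np.int64)
        all_pairs.append(groups[(p, q)])
    pairs = (np.vstack(all_pairs) if all_pairs
             else np.empty((0, 2), np.int64))
    nlist = NeighborList(pairs=pairs, build_radius=max_radius - skin,
                         skin=skin, ref_positions=positions.copy())
    nlist._grouped = groups
    return nlist


# ---------------------------------------------------------------------------
# Force assembly
# ---------------------------------------------------------------------------

def pair_terms(positions, kinds, table, pairs):
    """Per-pair separations, energies and force vectors.

    Returns (rij, dist, energy, fvec) over the given (M, 2) pair index
    array, where rij = r_i − r_j and fvec is the force ON particle i FROM
    particle j (the force on j is −fvec).  Pairs whose kind combination has
    no interaction contribute zeros.
    """
    positions = np.asarray(positions, dtype=float)
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    i, j = pairs[:, 0], pairs[:, 1]
    rij = positions[i] - positions[j]
    dist = np.linalg.norm(rij, axis=1)
    energy = np.zeros(len(pairs))
    fmag = np.zeros(len(pairs))
    ki = np.minimum(kinds[i], kinds[j])
    kj = np.maximum(kinds[i], kinds[j])
    combo = ki * 100 + kj
    for c in np.unique(combo):
        interaction = table.get(int(c) // 100, int(c) % 100)
        if interaction.form == "none":
            continue
        sel = combo == c
        e, f = interaction.energy_force(dist[sel])
        energy[sel] = e
        fmag[sel] = f
    with np.errstate(invalid="ignore"):
        fvec = (fmag / dist)[:, None] * rij
    return rij, dist, energy, fvec


def total_forces(system, table, nlist, externals=(), check_finite=True):
    """Net per-particle forces: pairwise (Newton's third law) + externals.

    ``externals`` is an iterable of (N, 3) arrays or callables mapping the
    system to such an array.  Forces on immobile/frozen particles are
    included in the result (for stress bookkeeping); the integrator is
    responsible for not applying them.
    """
    positions = system.positions
    n = len(positions)
    forces = np.zeros((n, 3))
    for (p, q), pairs in nlist.grouped(system.kinds).items():
        interaction = table.get(p, q)
        if interaction.form == "none" or not len(pairs):
            continue
        i, j = pairs[:, 0], pairs[:, 1]
        rij = positions[i] - positions[j]
        dist = np.sqrt(np.einsum("ma,ma->m", rij, rij))
        _, fmag = interaction.energy_force(dist)
        if check_finite and not np.all(np.isfinite(fmag)):
            bad = int(np.flatnonzero(~np.isfinite(fmag))[0])
            raise StabilityError(
                f"non-finite pair force between particles {i[bad]} and "
                f"{j[bad]} (distance {dist[bad]:.3e} µm); likely overlap "
                "blow-up — reduce dt or increase min_spacing")
        scale = fmag / dist
        for a in range(3):
            comp = scale * rij[:, a]
            forces[:, a] += np.bincount(i, weights=comp, minlength=n)
            forces[:, a] -= np.bincount(j, weights=comp, minlength=n)
    for ext in externals:
        contrib = ext(system) if callable(ext) else np.asarray(ext)
        forces = forces + contrib
    return forces
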