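"""Coarse-grained force field and the three-term energy decomposition.

The total potential splits into intra-tail, tail-rest and intra-rest
contributions.  Nonbonded terms are a purely repulsive WCA core plus a
Debye-Hueckel screened Coulomb interaction (cut and shifted at four
Debye lengths); bonds are harmonic.  The sampler scales the tail terms
as lambda^2 * E_tail + lambda * E_tail_rest + E_rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .constants import AVOGADRO, BJERRUM_PREFACTOR, COULOMB_CONSTANT
from .model_builder import CGSystem, REST, TAIL


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field parameters (kcal/mol, angstrom, kelvin, e units)."""

    bond_k: float = 10.0
    wca_epsilon: float = 0.2
    dielectric: float = 80.0
    ionic_strength: float = 0.153
    coulomb_constant: float = COULOMB_CONSTANT
    temperature: float = 300.0
    cutoff_debye_lengths: float = 4.0
    #: optional harmonic bending stiffness (kcal/mol/rad^2) applied to
    #: consecutive tail-bead triplets around a straight rest angle; 0
    #: leaves the chain fully flexible (the default).
    angle_k: float = 0.0
    angle_theta0: float = np.pi

    def __post_init__(self) -> None:
        if self.bond_k <= 0 or self.wca_epsilon <= 0 or self.ionic_strength <= 0 \
                or self.temperature <= 0:
            raise ValueError("force-field parameters must be positive")
        if self.dielectric < 1:
            raise ValueError("dielectric must be >= 1")


@dataclass(frozen=True)
class EnergyDecomposition:
    """The three-term split of the total potential energy (kcal/mol)."""

    e_tail: float
    e_tail_rest: float
    e_rest: float

    @property
    def total(self) -> float:
        return self.e_tail + self.e_tail_rest + self.e_rest

    def scaled(self, lam: float) -> float:
        return lam * lam * self.e_tail + lam * self.e_tail_rest + self.e_rest


def debye_length(ionic_strength: float, temperature: float = 300.0,
                 dielectric: float = 80.0) -> float:
    """Debye screening length (A) of a 1:1 electrolyte.

    kappa^2 = 4 pi l_B * sum_i n_i z_i^2 with the Bjerrum length l_B and
    ion number densities n_i in A^-3.
    """
    if ionic_strength <= 0 or temperature <= 0 or dielectric <= 0:
        raise ValueError("ionic strength, temperature and dielectric must be positive")
    l_bjerrum = BJERRUM_PREFACTOR / (dielectric * temperature)
    n_per_a3 = AVOGADRO * ionic_strength * 1e-27  # mol/L -> 1/A^3
    kappa_sq = 4.0 * np.pi * l_bjerrum * 2.0 * n_per_a3
    return 1.0 / np.sqrt(kappa_sq)


class CGEnergetics:
    """Precomputed pair bookkeeping for fast energy/force evaluation.

    Exposes the protocol the sampler relies on: ``masses``, ``mobile``,
    ``decompose(pos)`` and ``forces_and_decompose(pos, lam)``.
    """

    def __init__(self, system: CGSystem, params: ForceFieldParams | None = None):
        self.system = system
        self.params = params or ForceFieldParams()
        p = self.params
        self.kappa_inv = debye_length(p.ionic_strength, p.temperature, p.dielectric)
        self.cutoff = p.cutoff_debye_lengths * self.kappa_inv
        # energy shift so the screened-Coulomb term vanishes at the cutoff
        self._shift_per_qq = (p.coulomb_constant / p.dielectric) * \
            np.exp(-self.cutoff / self.kappa_inv) / self.cutoff

        n = system.n_beads
        self.masses = np.ones(n)
        self.mobile = system.mobile.copy()
        tail = system.tail_indices
        rest = system.rest_indices
        self.tail = tail
        self.rest = rest

        ti, tj = np.triu_indices(len(tail), k=1)
        self._tt_pairs = (tail[ti], tail[tj])
        self._tr_pairs = (np.repeat(tail, len(rest)), np.tile(rest, len(tail)))
        self._rest_rigid = not np.any(system.mobile[rest]) if len(rest) else True
        if self._rest_rigid and len(rest) > 1:
            ri, rj = np.triu_indices(len(rest), k=1)
            self._e_rest_nb_const = self._pair_energy(
                system.positions, rest[ri], rest[rj])[0]
        else:
            self._e_rest_nb_const = None

        b = system.bonds
        bi = b[:, 0].astype(int)
        bj = b[:, 1].astype(int)
        cat = np.zeros(len(b), dtype=int)  # 0 tail-tail, 1 tail-rest (incl. tether), 2 rest
        for k in range(len(b)):
            regs = {system.region[bi[k]], system.region[bj[k]]}
            if regs == {TAIL}:
                cat[k] = 0
            elif regs == {REST}:
                cat[k] = 2
            else:
                cat[k] = 1
        self._bonds = (bi, bj, b[:, 2].copy(), cat)
        # excluded nonbonded pairs: directly bonded beads
        self._excluded = set(zip(bi.tolist(), bj.tolist())) | set(zip(bj.tolist(), bi.tolist()))
        self._tt_mask = ~np.array([(i, j) in self._excluded
                                   for i, j in zip(*self._tt_pairs)], dtype=bool)
        self._tr_mask = ~np.array([(i, j) in self._excluded
                                   for i, j in zip(*self._tr_pairs)], dtype=bool)

        # flattened pair arrays for the (optional) jit fast path
        self._use_numba = _kernels.HAVE_NUMBA
        self._jit = {}
        for name, (pi, pj), pmask in (("tt", self._tt_pairs, self._tt_mask),
                                      ("tr", self._tr_pairs, self._tr_mask)):
            ii = np.ascontiguousarray(pi[pmask], dtype=np.int64)
            jj = np.ascontiguousarray(pj[pmask], dtype=np.int64)
            self._jit[name] = (
                ii, jj,
                np.ascontiguousarray(system.radii[ii] + system.radii[jj]),
                np.ascontiguousarray(system.charges[ii] * system.charges[jj]),
            )
        bi, bj, r0, cat = self._bonds
        self._jit["bonds"] = (np.ascontiguousarray(bi, dtype=np.int64),
                              np.ascontiguousarray(bj, dtype=np.int64),
                              np.ascontiguousarray(r0),
                              np.ascontiguousarray(cat, dtype=np.int64))

        # consecutive tail triplets for the optional bending term
        t = tail
        self._angle_triplets = np.array(
            [(t[k], t[k + 1], t[k + 2]) for k in range(len(t) - 2)], dtype=int
        ).reshape(-1, 3) if self.params.angle_k > 0 and len(t) >= 3 else \
            np.zeros((0, 3), dtype=int)

    # -- pairwise terms ------------------------------------------------------

    def _pair_energy(self, pos: np.ndarray, ii: np.ndarray, jj: np.ndarray,
                     mask: np.ndarray | None = None):
        """WCA + screened-Coulomb energy and per-pair force magnitudes.

        Returns (energy, fvec) where fvec[k] is the force on bead ii[k]
        (bead jj[k] receives -fvec[k]).
        """
        if mask is not None:
            ii = ii[mask]
            jj = jj[mask]
        if len(ii) == 0:
            return 0.0, ii, jj, np.zeros((0, 3))
        p = self.params
        sys = self.system
        d = pos[ii] - pos[jj]
        r2 = np.einsum("ij,ij->i", d, d)
        if np.any(r2 < 1e-12):
            raise FloatingPointError("coincident beads: WCA energy diverges")
        r = np.sqrt(r2)
        sigma = sys.radii[ii] + sys.radii[jj]
        qq = sys.charges[ii] * sys.charges[jj]

        e = np.zeros_like(r)
        f_over_r = np.zeros_like(r)

        wca_cut = sigma * (2.0 ** (1.0 / 6.0))
        m = r < wca_cut
        if np.any(m):
            sr6 = (sigma[m] / r[m]) ** 6
            e[m] += 4.0 * p.wca_epsilon * (sr6 * sr6 - sr6) + p.wca_epsilon
            f_over_r[m] += 4.0 * p.wca_epsilon * (12.0 * sr6 * sr6 - 6.0 * sr6) / r2[m]

        mq = (qq != 0.0) & (r < self.cutoff)
        if np.any(mq):
            pref = (p.coulomb_constant / p.dielectric) * qq[mq]
            ex = np.exp(-r[mq] / self.kappa_inv)
            e[mq] += pref * ex / r[mq] - self._shift_per_qq * qq[mq]
            f_over_r[mq] += pref * ex * (1.0 / r[mq] + 1.0 / self.kappa_inv) / r2[mq]

        fvec = f_over_r[:, None] * d
        return float(e.sum()), ii, jj, fvec

    def _bond_terms(self, pos: np.ndarray):
        bi, bj, r0, cat = self._bonds
        if len(bi) == 0:
            return np.zeros(3), (bi, bj, np.zeros((0, 3)))
        d = pos[bi] - pos[bj]
        r = np.linalg.norm(d, axis=1)
        dr = r - r0
        e = 0.5 * self.params.bond_k * dr * dr
        e_by_cat = np.array([e[cat == c].sum() for c in (0, 1, 2)])
        fmag = -self.params.bond_k * dr / np.maximum(r, 1e-12)
        return e_by_cat, (bi, bj, fmag[:, None] * d)

    def _angle_terms(self, pos: np.ndarray):
        """Harmonic bending energy E = k/2 (theta - theta0)^2 and forces."""
        trip = self._angle_triplets
        if len(trip) == 0:
            return 0.0, None
        k = self.params.angle_k
        th0 = self.params.angle_theta0
        i, j, l = trip[:, 0], trip[:, 1], trip[:, 2]
        a = pos[i] - pos[j]
        b = pos[l] - pos[j]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        cos_t = np.clip(np.einsum("ij,ij->i", a, b) / (na * nb), -1.0, 1.0)
        theta = np.arccos(cos_t)
        e = 0.5 * k * (theta - th0) ** 2
        sin_t = np.sqrt(np.maximum(1.0 - cos_t * cos_t, 1e-12))
        pref = k * (theta - th0) / sin_t  # -dE/dtheta * dtheta/dcos
        fa = pref[:, None] * (b / nb[:, None] - cos_t[:, None] * a / na[:, None]) \
            / na[:, None]
        fb = pref[:, None] * (a / na[:, None] - cos_t[:, None] * b / nb[:, None]) \
            / nb[:, None]
        forces = np.zeros_like(pos)
        np.add.at(forces, i, fa)
        np.add.at(forces, l, fb)
        np.add.at(forces, j, -(fa + fb))
        return float(e.sum()), forces

    # -- public API ----------------------------------------------------------

    def _rest_cache_valid(self, pos: np.ndarray) -> bool:
        return self._e_rest_nb_const is not None and np.array_equal(
            pos[self.rest], self.system.positions[self.rest])

    def decompose(self, pos: np.ndarray) -> EnergyDecomposition:
        e_tt, *_ = self._pair_energy(pos, *self._tt_pairs, self._tt_mask)
        e_tr, *_ = self._pair_energy(pos, *self._tr_pairs, self._tr_mask)
        if self._rest_cache_valid(pos):
            e_rr = self._e_rest_nb_const
        elif len(self.rest) > 1:
            ri, rj = np.triu_indices(len(self.rest), k=1)
            e_rr, *_ = self._pair_energy(pos, self.rest[ri], self.rest[rj])
        else:
            e_rr = 0.0
        eb, _ = self._bond_terms(pos)
        e_ang, _ = self._angle_terms(pos)
        return EnergyDecomposition(e_tail=e_tt + eb[0] + e_ang,
                                   e_tail_rest=e_tr + eb[1],
                                   e_rest=e_rr + eb[2])

    def _forces_and_decompose_jit(self, pos: np.ndarray, lam: float):
        p = self.params
        forces = np.zeros_like(pos)
        coulomb_over_eps = p.coulomb_constant / p.dielectric
        e_tt = _kernels.pair_forces(pos, *self._jit["tt"], lam * lam,
                                    self.kappa_inv, self.cutoff, self._shift_per_qq,
                                    p.wca_epsilon, coulomb_over_eps, forces)
        e_tr = _kernels.pair_forces(pos, *self._jit["tr"], lam,
                                    self.kappa_inv, self.cutoff, self._shift_per_qq,
                                    p.wca_epsilon, coulomb_over_eps, forces)
        if np.isnan(e_tt) or np.isnan(e_tr):
            raise FloatingPointError("coincident beads: WCA energy diverges")
        bi, bj, r0, cat = self._jit["bonds"]
        bond_scale = np.where(cat == 0, lam * lam, np.where(cat == 1, lam, 1.0))
        e_by_cat = np.zeros(3)
        _kernels.bond_forces(pos, bi, bj, r0, bond_scale, p.bond_k, e_by_cat, cat,
                             forces)
        if self._rest_cache_valid(pos):
            e_rr = self._e_rest_nb_const
        elif len(self.rest) > 1:
            ri, rj = np.triu_indices(len(self.rest), k=1)
            e_rr, ii, jj, fv = self._pair_energy(pos, self.rest[ri], self.rest[rj])
            np.add.at(forces, ii, fv)
            np.add.at(forces, jj, -fv)
        else:
            e_rr = 0.0
        forces[~self.mobile] = 0.0
        decomp = EnergyDecomposition(e_tail=e_tt + e_by_cat[0],
                                     e_tail_rest=e_tr + e_by_cat[1],
                                     e_rest=e_rr + e_by_cat[2])
        return forces, decomp

    def forces_and_decompose(self, pos: np.ndarray, lam: float):
        """Forces of the lambda-scaled potential plus the (unscaled) decomposition."""
        if lam <= 0:
            raise ValueError("lambda must be positive")
        if self._use_numba and len(self._angle_triplets) == 0:
            return self._forces_and_decompose_jit(np.ascontiguousarray(pos), lam)
        forces = np.zeros_like(pos)

        e_tt, ii, jj, fv = self._pair_energy(pos, *self._tt_pairs, self._tt_mask)
        scale = lam * lam
        np.add.at(forces, ii, scale * fv)
        np.add.at(forces, jj, -scale * fv)

        e_tr, ii, jj, fv = self._pair_energy(pos, *self._tr_pairs, self._tr_mask)
        np.add.at(forces, ii, lam * fv)
        if not self._rest_rigid:
            np.add.at(forces, jj, -lam * fv)

        eb, (bi, bj, bfv) = self._bond_terms(pos)
        _, _, _, cat = self._bonds
        bond_scale = np.where(cat == 0, lam * lam, np.where(cat == 1, lam, 1.0))
        sfv = bond_scale[:, None] * bfv
        np.add.at(forces, bi, sfv)
        np.add.at(forces, bj, -sfv)

        if self._rest_cache_valid(pos):
            e_rr = self._e_rest_nb_const
        elif len(self.rest) > 1:
            ri, rj = np.triu_indices(len(self.rest), k=1)
            e_rr, ii, jj, fv = self._pair_energy(pos, self.rest[ri], self.rest[rj])
            np.add.at(forces, ii, fv)
            np.add.at(forces, jj, -fv)
        else:
            e_rr = 0.0

        e_ang, f_ang = self._angle_terms(pos)
        if f_ang is not None:
            forces += (lam * lam) * f_ang
        forces[~self.mobile] = 0.0
        decomp = EnergyDecomposition(e_tail=e_tt + eb[0] + e_ang,
                                     e_tail_rest=e_tr + eb[1],
                                     e_rest=e_rr + eb[2])
        return forces, decomp

    def forces(self, pos: np.ndarray, lam: float) -> np.ndarray:
        return self.forces_and_decompose(pos, lam)[0]

    # -- jit integration support --------------------------------------------

    def supports_jit_integration(self, pos: np.ndarray) -> bool:
        """Whole-loop jit path applies to rigid-scaffold systems only."""
        _, _, _, cat = self._bonds
        return (self._use_numba and self._rest_rigid
                and len(self._angle_triplets) == 0
                and not np.any(cat == 2)
                and (len(self.rest) <= 1 or self._rest_cache_valid(pos)))

    def jit_integration_args(self, bias) -> dict:
        bias_x, bias_c = bias.ppoly()
        p = self.params
        return {
            "tt": self._jit["tt"],
            "tr": self._jit["tr"],
            "bonds": self._jit["bonds"],
            "kappa_inv": self.kappa_inv,
            "cutoff": self.cutoff,
            "shift_per_qq": self._shift_per_qq,
            "wca_epsilon": p.wca_epsilon,
            "coulomb_over_eps": p.coulomb_constant / p.dielectric,
            "bond_k": p.bond_k,
            "e_rest": float(self._e_rest_nb_const or 0.0),
            "bias_x": bias_x,
            "bias_c": bias_c,
        }


def energy_decomposition(system: CGSystem, positions: np.ndarray,
                         params: ForceFieldParams | None = None) -> EnergyDecomposition:
    """Three-term energy decomposition at the given coordinates."""
    return CGEnergetics(system, params).decompose(np.asarray(positions, dtype=float))


def forces(system: CGSystem, positions: np.ndarray, lam: float,
           params: ForceFieldParams | None = None) -> np.ndarray:
    """Negative gradient of the lambda-scaled potential; zero on immobile beads."""
    return CGEnergetics(system, params).forces(np.asarray(positions, dtype=float), lam)


class HarmonicTailSystem:
    """Analytic test system: one mobile bead with E_tail = k/2 * x^2.

    Only the x coordinate carries energy, so the canonical weight of
    lambda is proportional to 1/lambda -- the closed form used to
    validate bias adaptation and reweighting.
    Implements the same protocol as :class:`CGEnergetics`.
    """

    def __init__(self, k: float = 1.0):
        if k <= 0:
            raise ValueError("k must be positive")
        self.k = k
        self.masses = np.ones(1)
        self.mobile = np.array([True])

    def initial_positions(self) -> np.ndarray:
        return np.zeros((1, 3))

    def decompose(self, pos: np.ndarray) -> EnergyDecomposition:
        x = float(pos[0, 0])
        return EnergyDecomposition(e_tail=0.5 * self.k * x * x, e_tail_rest=0.0, e_rest=0.0)

    def forces_and_decompose(self, pos: np.ndarray, lam: float):
        decomp = self.decompose(pos)
        f = np.zeros_like(pos)
        f[0, 0] = -lam * lam * self.k * pos[0, 0]
        return f, decomp

    def forces(self, pos: np.ndarray, lam: float) -> np.ndarray:
        return self.forces_and_decompose(pos, lam)[0]
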