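"""Desk-scale restraint-satisfaction engine.

A simplified Cartesian simulated-annealing refiner that stands in for a
full structure-calculation package inside the iterative disambiguation
loop.  The pseudo-energy is a sum of

* harmonic covalent-geometry terms (bonds, angle-equivalent 1-3 distances,
  peptide-plane and chirality dihedrals),
* flat-bottom distance-restraint terms, zero inside ``[lower, upper]`` and
  quadratic outside, with r^-6 pooling over the assignment options of an
  ambiguous restraint,
* flat-bottom torsion terms, and
* a soft-sphere repulsion.

Each model starts from torsion-seeded chain segments at independent random
poses, assembles them by rigid-body annealing against the restraints, then
runs full-coordinate perturbation/quench cycles with decreasing amplitude
and a final quench.  This is NOT a molecular-dynamics engine: no
torsion-angle dynamics, no empirical force field, no solvent.
The reference annealing parameters of the full-scale protocol are kept for
provenance and executed scaled down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np
from scipy.optimize import minimize

from . import geometry
from .structures import Model, StructureEnsemble

#: full-scale simulated-annealing parameters of the reference protocol
#: (stored for provenance; the desk engine runs them scaled down)
REFERENCE_ANNEAL = {
    "tad_high_temperature_K": 20000.0,
    "tad_time_step_factor": 9.0,
    "cartesian_high_temperature_K": 3000.0,
    "time_step_ps": 0.003,
    "cool1_final_K": 1000.0,
    "cool1_steps": 100000,
    "cool2_final_K": 50.0,
    "cool2_steps": 100000,
    "high_temperature_steps": 20000,
    "refine_steps": 8000,
}
TEMPERATURE_SCALE = 0.1
STEP_SCALE = 0.01


@dataclass
class AnnealConfig:
    """Desk-scale annealing schedule and force constants."""

    high_temperature: float = REFERENCE_ANNEAL["cartesian_high_temperature_K"] * TEMPERATURE_SCALE
    cool_steps: int = int((REFERENCE_ANNEAL["cool1_steps"]
                           + REFERENCE_ANNEAL["cool2_steps"]) * STEP_SCALE)
    refine_steps: int = int(REFERENCE_ANNEAL["refine_steps"] * 10 * STEP_SCALE)
    n_cycles: int = 4
    k_bond: float = 60.0          # kcal-like / A^2
    k_distance: float = 25.0      # restraint flat-bottom, / A^2
    k_hbond: float = 25.0
    k_torsion: float = 0.02       # / deg^2
    k_dihedral_geom: float = 0.01  # peptide plane + chirality, / deg^2
    k_repulsion: float = 20.0
    repulsion_dmin: float = 1.8   # A; below hydrogen-bond H..O contact
    n_models: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.high_temperature <= 0 or self.cool_steps <= 0 or self.refine_steps <= 0:
            raise ValueError("temperatures and step counts must be positive")

    def noise_amplitudes(self) -> np.ndarray:
        """Perturbation amplitude per annealing cycle (A), cooling
        geometrically from an amplitude set by the high temperature."""
        amp0 = 1.5 * np.sqrt(self.high_temperature / 300.0) / np.sqrt(10.0)
        return amp0 * 0.5 ** np.arange(self.n_cycles)


# --------------------------------------------------------------------------
# topology
# --------------------------------------------------------------------------

_IDEAL = geometry


def _d13(r_ab: float, r_bc: float, angle_deg: float) -> float:
    a = np.deg2rad(angle_deg)
    return float(np.sqrt(r_ab ** 2 + r_bc ** 2 - 2 * r_ab * r_bc * np.cos(a)))


class Topology:
    """Atom indexing and covalent terms for one chain (with breaks)."""

    def __init__(self, sequence: str, chain_breaks=(), resnums=None):
        self.sequence = sequence
        self.chain_breaks = set(int(b) for b in chain_breaks)
        n = len(sequence)
        self.resnums = np.arange(1, n + 1) if resnums is None else np.asarray(resnums, int)
        self.index: dict[tuple[int, str], int] = {}
        self.atom_res: list[int] = []
        self.atom_name: list[str] = []
        for i, aa in enumerate(sequence):
            resnum = int(self.resnums[i])
            atoms = ["N", "H", "CA", "CB", "C", "O"]
            if aa == "G":
                atoms.remove("CB")
            if aa == "P":
                atoms.remove("H")
            for a in atoms:
                self.index[(resnum, a)] = len(self.atom_res)
                self.atom_res.append(resnum)
                self.atom_name.append(a)
        self.n_atoms = len(self.atom_res)
        self.atom_res = np.array(self.atom_res)
        self._build_terms()

    def has_bond_to_next(self, resnum: int) -> bool:
        return (resnum not in self.chain_breaks
                and (resnum + 1, "N") in {k for k in self.index if k[1] == "N"})

    def _build_terms(self) -> None:
        g = _IDEAL
        idx = self.index
        bonds = []
        n = len(self.sequence)

        def add(a, b, d0):
            if a in idx and b in idx:
                bonds.append((idx[a], idx[b], d0))

        pair13 = []

        def add13(a, b, d0):
            if a in idx and b in idx:
                pair13.append((idx[a], idx[b], d0))

        quads = []  # (i,j,k,l, target_deg, kind) kind: 0 harmonic, used for omega/impropers

        for i in range(n):
            r = int(self.resnums[i])
            nxt = r + 1
            linked = (r not in self.chain_breaks) and i + 1 < n
            seg_start = i == 0 or (r - 1) in self.chain_breaks
            seg_end = i == n - 1 or r in self.chain_breaks
            add((r, "N"), (r, "CA"), g.BOND_N_CA)
            add((r, "CA"), (r, "C"), g.BOND_CA_C)
            add((r, "C"), (r, "O"), g.BOND_C_O)
            add((r, "N"), (r, "H"), g.BOND_N_H)
            add((r, "CA"), (r, "CB"), g.BOND_CA_CB)
            add13((r, "N"), (r, "C"), _d13(g.BOND_N_CA, g.BOND_CA_C, g.ANGLE_N_CA_C))
            if not seg_end:  # terminal O follows a different build-out rule
                # sp2 anti-bisector placement: CA-C-O = O-C-N' = (360-116.2)/2
                add13((r, "CA"), (r, "O"), _d13(g.BOND_CA_C, g.BOND_C_O, 121.9))
            add13((r, "N"), (r, "CB"), _d13(g.BOND_N_CA, g.BOND_CA_CB, g.ANGLE_N_CA_CB))
            add13((r, "C"), (r, "CB"), _d13(g.BOND_CA_C, g.BOND_CA_CB, g.ANGLE_C_CA_CB))
            if not seg_start:  # start-residue H is a synthetic build-out
                add13((r, "H"), (r, "CA"), _d13(g.BOND_N_H, g.BOND_N_CA, 119.15))
            if linked:
                add((r, "C"), (nxt, "N"), g.BOND_C_N)
                add13((r, "CA"), (nxt, "N"), _d13(g.BOND_CA_C, g.BOND_C_N, g.ANGLE_CA_C_N))
                add13((r, "O"), (nxt, "N"), _d13(g.BOND_C_O, g.BOND_C_N, 121.9))
                add13((r, "C"), (nxt, "CA"), _d13(g.BOND_C_N, g.BOND_N_CA, g.ANGLE_C_N_CA))
                add13((r, "C"), (nxt, "H"), _d13(g.BOND_C_N, g.BOND_N_H, 119.15))
                # trans peptide plane: omega and the O/H anti arrangement
                if all(k in idx for k in ((r, "CA"), (r, "C"), (nxt, "N"), (nxt, "CA"))):
                    quads.append((idx[(r, "CA")], idx[(r, "C")], idx[(nxt, "N")],
                                  idx[(nxt, "CA")], 180.0))
                if all(k in idx for k in ((r, "O"), (r, "C"), (nxt, "N"), (nxt, "H"))):
                    quads.append((idx[(r, "O")], idx[(r, "C")], idx[(nxt, "N")],
                                  idx[(nxt, "H")], 180.0))
            # CB chirality improper (L-amino acids); target measured from the
            # ideal construction
            if all(k in idx for k in ((r, "N"), (r, "C"), (r, "CA"), (r, "CB"))):
                quads.append((idx[(r, "N")], idx[(r, "C")], idx[(r, "CA")],
                              idx[(r, "CB")], _cb_improper_target()))

        self.bond_idx = np.array([(a, b) for a, b, _ in bonds + pair13], int)
        self.bond_d0 = np.array([d for _, _, d in bonds + pair13])
        self.geom_quads = np.array([q[:4] for q in quads], int) if quads else np.zeros((0, 4), int)
        self.geom_targets = np.array([q[4] for q in quads]) if quads else np.zeros(0)

        # nonbonded exclusions: same residue or sequence-adjacent residues
        res = self.atom_res
        nb_mask = np.abs(res[:, None] - res[None, :]) >= 2
        iu = np.triu(nb_mask)
        self.nb_i, self.nb_j = np.nonzero(iu)

    def phi_quad(self, resnum: int):
        idx = self.index
        keys = ((resnum - 1, "C"), (resnum, "N"), (resnum, "CA"), (resnum, "C"))
        if (resnum - 1) in self.chain_breaks or not all(k in idx for k in keys):
            return None
        return tuple(idx[k] for k in keys)

    def psi_quad(self, resnum: int):
        idx = self.index
        keys = ((resnum, "N"), (resnum, "CA"), (resnum, "C"), (resnum + 1, "N"))
        if resnum in self.chain_breaks or not all(k in idx for k in keys):
            return None
        return tuple(idx[k] for k in keys)


_CB_TARGET: float | None = None


def _cb_improper_target() -> float:
    """Improper N-C-CA-CB of an ideally built L-residue (degrees)."""
    global _CB_TARGET
    if _CB_TARGET is None:
        bb = geometry.build_backbone(np.full(2, -120.0), np.full(2, 130.0))
        CB = geometry.add_beta_carbons(bb["N"], bb["CA"], bb["C"])
        _CB_TARGET = float(geometry.dihedral(bb["N"][0], bb["C"][0], bb["CA"][0], CB[0]))
    return _CB_TARGET


# --------------------------------------------------------------------------
# vectorized dihedral with analytic gradient
# --------------------------------------------------------------------------

def _dihedrals_grad(x: np.ndarray, quads: np.ndarray):
    """Dihedral angles (degrees) and gradients d(angle)/dx (degrees/A).

    Returns (phi[M], grad[M,4,3]) for quad atom indices (M,4).
    """
    p0, p1, p2, p3 = (x[quads[:, k]] for k in range(4))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.maximum(np.linalg.norm(b2, axis=1), 1e-12)
    xcomp = np.einsum("ij,ij->i", n1, n2)
    ycomp = np.einsum("ij,ij->i", np.cross(n1, n2), b2 / b2n[:, None])
    phi = np.arctan2(ycomp, xcomp)

    n1sq = np.maximum(np.einsum("ij,ij->i", n1, n1), 1e-12)
    n2sq = np.maximum(np.einsum("ij,ij->i", n2, n2), 1e-12)
    g0 = -(b2n / n1sq)[:, None] * n1
    g3 = (b2n / n2sq)[:, None] * n2
    c1 = (np.einsum("ij,ij->i", b1, b2) / b2n ** 2)[:, None]
    c2 = (np.einsum("ij,ij->i", b3, b2) / b2n ** 2)[:, None]
    g1 = -(1.0 + c1) * g0 + c2 * g3
    g2 = -(g0 + g1 + g3)  # translation invariance
    grad = np.stack([g0, g1, g2, g3], axis=1)
    return np.rad2deg(phi), np.rad2deg(grad)


# --------------------------------------------------------------------------
# energy model
# --------------------------------------------------------------------------

def _scatter_add(grad: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """grad[idx] += vals via bincount (much faster than np.add.at)."""
    n = grad.shape[0]
    for c in range(3):
        grad[:, c] += np.bincount(idx, weights=vals[:, c], minlength=n)


def _norms(dv: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("ij,ij->i", dv, dv))


# hot per-evaluation kernels, compiled with numba

@numba.njit(cache=True, fastmath=True)
def _bond_kernel(x, grad, idx_i, idx_j, d0, k):
    e = 0.0
    for m in range(idx_i.shape[0]):
        i, j = idx_i[m], idx_j[m]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d < 1e-9:
            d = 1e-9
        dev = d - d0[m]
        e += k * dev * dev
        c = 2.0 * k * dev / d
        grad[i, 0] += c * dx
        grad[i, 1] += c * dy
        grad[i, 2] += c * dz
        grad[j, 0] -= c * dx
        grad[j, 1] -= c * dy
        grad[j, 2] -= c * dz
    return e


@numba.njit(cache=True, fastmath=True)
def _restraint_kernel(x, grad, opt_i, opt_j, seg, lower, upper, kf, n_seg):
    # r^-6 pooled flat-bottom over option groups (seg ids are sorted)
    d = np.empty(opt_i.shape[0])
    s = np.zeros(n_seg)
    for m in range(opt_i.shape[0]):
        i, j = opt_i[m], opt_j[m]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        dm = np.sqrt(dx * dx + dy * dy + dz * dz)
        if dm < 1e-6:
            dm = 1e-6
        d[m] = dm
        s[seg[m]] += dm ** -6.0
    e = 0.0
    dE = np.zeros(n_seg)
    deff = np.empty(n_seg)
    for g in range(n_seg):
        de = s[g] ** (-1.0 / 6.0)
        deff[g] = de
        viol = 0.0
        if de > upper[g]:
            viol = de - upper[g]
        elif de < lower[g]:
            viol = de - lower[g]
        e += kf[g] * viol * viol
        dE[g] = 2.0 * kf[g] * viol
    for m in range(opt_i.shape[0]):
        g = seg[m]
        if dE[g] == 0.0:
            continue
        i, j = opt_i[m], opt_j[m]
        coef = dE[g] * (deff[g] / d[m]) ** 7.0 / d[m]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        grad[i, 0] += coef * dx
        grad[i, 1] += coef * dy
        grad[i, 2] += coef * dz
        grad[j, 0] -= coef * dx
        grad[j, 1] -= coef * dy
        grad[j, 2] -= coef * dz
    return e


@numba.njit(cache=True, fastmath=True)
def _repulsion_kernel(x, grad, idx_i, idx_j, dmin, k):
    e = 0.0
    for m in range(idx_i.shape[0]):
        i, j = idx_i[m], idx_j[m]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d >= dmin:
            continue
        if d < 1e-6:
            d = 1e-6
        dev = dmin - d
        e += k * dev * dev
        c = -2.0 * k * dev / d
        grad[i, 0] += c * dx
        grad[i, 1] += c * dy
        grad[i, 2] += c * dz
        grad[j, 0] -= c * dx
        grad[j, 1] -= c * dy
        grad[j, 2] -= c * dz
    return e

class EnergyModel:
    """Pseudo-energy and gradient over flattened coordinates."""

    def __init__(self, top: Topology, distance_restraints=(), torsions=(),
                 hbonds=(), config: AnnealConfig | None = None):
        self.top = top
        self.cfg = config or AnnealConfig()
        self._nb_counter = 0
        self._nb_pairs = None
        self._setup_restraints(distance_restraints, hbonds)
        self._setup_torsions(torsions)

    def _setup_restraints(self, adrs, hbonds) -> None:
        idx = self.top.index
        oi, oj, seg, lowers, uppers, ks = [], [], [], [], [], []
        nseg = 0
        for r in adrs:
            if not getattr(r, "active", True):
                continue
            opts = [(o.atom_a, o.atom_b) for o in r.options
                    if o.atom_a in idx and o.atom_b in idx]
            if not opts:
                continue
            for a, b in opts:
                oi.append(idx[a])
                oj.append(idx[b])
                seg.append(nseg)
            lowers.append(r.lower)
            uppers.append(r.upper)
            ks.append(self.cfg.k_distance)
            nseg += 1
        for hb in hbonds:
            donor_atom = "H" if hb.kind == "H_O" else "N"
            a = (hb.donor_residue, donor_atom)
            b = (hb.acceptor_residue, "O")
            if a not in idx or b not in idx:
                continue
            oi.append(idx[a])
            oj.append(idx[b])
            seg.append(nseg)
            lowers.append(hb.lower)
            uppers.append(hb.upper)
            ks.append(self.cfg.k_hbond)
            nseg += 1
        self.opt_i = np.array(oi, int)
        self.opt_j = np.array(oj, int)
        self.opt_seg = np.array(seg, int)
        self.r_lower = np.array(lowers)
        self.r_upper = np.array(uppers)
        self.r_k = np.array(ks)
        self.n_restraints = nseg

    def _setup_torsions(self, torsions) -> None:
        quads, centers, widths = [], [], []
        for t in torsions:
            q = (self.top.phi_quad(t.residue) if t.angle == "phi"
                 else self.top.psi_quad(t.residue))
            if q is None:
                continue
            quads.append(q)
            centers.append(t.center)
            widths.append(max(t.half_width, 1.0))
        self.tor_quads = np.array(quads, int) if quads else np.zeros((0, 4), int)
        self.tor_centers = np.array(centers)
        self.tor_widths = np.array(widths)

    # individual terms -----------------------------------------------------

    def _bond_energy(self, x, grad):
        return _bond_kernel(x, grad, self.top.bond_idx[:, 0],
                            self.top.bond_idx[:, 1], self.top.bond_d0,
                            self.cfg.k_bond)

    def _geom_dihedral_energy(self, x, grad):
        # smooth periodic well, curvature-matched to k*delta^2 near the
        # minimum; no kink at the anti-target ridge
        if len(self.top.geom_quads) == 0:
            return 0.0
        phi, dphi = _dihedrals_grad(x, self.top.geom_quads)
        delta = np.deg2rad(geometry.wrap_angle(phi - self.top.geom_targets))
        k = self.cfg.k_dihedral_geom * 2.0 * np.rad2deg(1.0) ** 2
        e = k * np.sum(1.0 - np.cos(delta))
        coef = k * np.sin(delta) * (np.pi / 180.0)  # dE/d(phi_deg)
        for col in range(4):
            _scatter_add(grad, self.top.geom_quads[:, col],
                         coef[:, None] * dphi[:, col])
        return e

    def _torsion_energy(self, x, grad):
        if len(self.tor_quads) == 0:
            return 0.0
        phi, dphi = _dihedrals_grad(x, self.tor_quads)
        delta = geometry.wrap_angle(phi - self.tor_centers)
        viol = np.maximum(np.abs(delta) - self.tor_widths, 0.0) * np.sign(delta)
        k = self.cfg.k_torsion
        e = k * np.sum(viol ** 2)
        coef = 2 * k * viol
        for col in range(4):
            _scatter_add(grad, self.tor_quads[:, col], coef[:, None] * dphi[:, col])
        return e

    def restraint_energy(self, x, grad=None):
        """Flat-bottom term over r^-6-pooled effective distances."""
        if self.n_restraints == 0:
            return 0.0
        if grad is None:
            grad = np.zeros_like(x)
        return _restraint_kernel(x, grad, self.opt_i, self.opt_j,
                                 self.opt_seg, self.r_lower, self.r_upper,
                                 self.r_k, self.n_restraints)

    def refresh_neighbors(self, x: np.ndarray) -> None:
        """Rebuild the soft-sphere neighbor list (3.5 A skin).

        The list is intentionally frozen between refreshes: rebuilding it
        inside a line search would make the energy discontinuous.
        """
        i, j = self.top.nb_i, self.top.nb_j
        d = _norms(x[i] - x[j])
        keep = d < self.cfg.repulsion_dmin + 3.5
        self._nb_pairs = (i[keep], j[keep])

    def _repulsion_energy(self, x, grad):
        dmin = self.cfg.repulsion_dmin
        if self._nb_pairs is None:
            self.refresh_neighbors(x)
        i, j = self._nb_pairs
        if len(i) == 0 or self.cfg.k_repulsion == 0.0:
            return 0.0
        return _repulsion_kernel(x, grad, i, j, dmin, self.cfg.k_repulsion)

    # total ----------------------------------------------------------------

    def energy_grad(self, flat: np.ndarray):
        x = flat.reshape(-1, 3)
        grad = np.zeros_like(x)
        e = self._bond_energy(x, grad)
        e += self._geom_dihedral_energy(x, grad)
        e += self._torsion_energy(x, grad)
        e += self.restraint_energy(x, grad)
        e += self._repulsion_energy(x, grad)
        return e, grad.ravel()

    def energy(self, x: np.ndarray) -> float:
        return self.energy_grad(np.asarray(x).ravel())[0]


def minimize_energy(em: EnergyModel, x: np.ndarray, iters: int,
                    chunk: int = 400) -> tuple[np.ndarray, float]:
    """Chunked L-BFGS quench.

    The neighbor list is rebuilt between chunks only, keeping the energy
    smooth within each line search.
    """
    e = np.inf
    stalls = 0
    done = 0
    while done < iters:
        em.refresh_neighbors(x)
        res = minimize(em.energy_grad, x.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": min(chunk, iters - done),
                                "maxfun": 6 * chunk,
                                "ftol": 1e-12, "gtol": 1e-8})
        x = res.x.reshape(-1, 3)
        done += max(res.nit, chunk // 2)  # budget even when line search aborts
        # a line-search abort is not convergence: restarting the chunk
        # resets the L-BFGS memory and usually gets past the kink, so only
        # stop after repeated chunks without progress
        if e - res.fun < 1e-6 * max(abs(e), 1.0):
            stalls += 1
            if stalls >= 2:
                e = float(res.fun)
                break
        else:
            stalls = 0
        e = float(res.fun)
    em.refresh_neighbors(x)
    e = em.energy(x)
    return x, float(e)


def pseudo_energy(model: Model, distance_restraints=(), torsions=(), hbonds=(),
                  config: AnnealConfig | None = None, chain_breaks=()) -> float:
    """Total pseudo-energy of a model under the given restraints."""
    top = Topology(model.sequence, chain_breaks, model.resnums)
    em = EnergyModel(top, distance_restraints, torsions, hbonds, config)
    x = _model_to_flat(model, top)
    return em.energy(x)


def restraint_energy(model: Model, distance_restraints=(), hbonds=(),
                     config: AnnealConfig | None = None, chain_breaks=()) -> float:
    """Restraint term alone; zero iff every restraint is satisfied."""
    top = Topology(model.sequence, chain_breaks, model.resnums)
    em = EnergyModel(top, distance_restraints, (), hbonds, config)
    x = _model_to_flat(model, top)
    return em.restraint_energy(x.reshape(-1, 3))


def _model_to_flat(model: Model, top: Topology) -> np.ndarray:
    from .structures import ATOM_INDEX
    x = np.zeros((top.n_atoms, 3))
    lookup = {int(r): i for i, r in enumerate(model.resnums)}
    for (resnum, atom), k in top.index.items():
        x[k] = model.coords[lookup[resnum], ATOM_INDEX[atom]]
    return x


def _flat_to_model(x: np.ndarray, top: Topology, sequence: str,
                   energy: float | None = None) -> Model:
    from .structures import ATOM_INDEX
    n = len(sequence)
    coords = np.full((n, 6, 3), np.nan)
    lookup = {int(r): i for i, r in enumerate(top.resnums)}
    for (resnum, atom), k in top.index.items():
        coords[lookup[resnum], ATOM_INDEX[atom]] = x[k]
    return Model(coords, sequence, top.resnums, pseudo_energy=energy)


# --------------------------------------------------------------------------
# distance-geometry initialization
# --------------------------------------------------------------------------

# --------------------------------------------------------------------------
# annealing
# --------------------------------------------------------------------------

def _segments(top: Topology, extra_splits=()) -> list[list[int]]:
    """Residue numbers grouped into assembly segments.

    Segments split at chain breaks and additionally at ``extra_splits``
    (midpoints of flexible runs); covalent terms across extra splits stay
    in the energy model, so split segments remain tethered during
    assembly.
    """
    splits = top.chain_breaks | set(int(s) for s in extra_splits)
    segs: list[list[int]] = [[]]
    for i, r in enumerate(top.resnums):
        segs[-1].append(int(r))
        if int(r) in splits and i + 1 < len(top.resnums):
            segs.append([])
    return segs


def _flexible_splits(top: Topology, torsions) -> list[int]:
    """Split points at the centres of torsionally unrestrained runs."""
    restrained = {t.residue for t in torsions}
    splits = []
    run: list[int] = []
    for r in top.resnums:
        if int(r) not in restrained:
            run.append(int(r))
        else:
            if len(run) >= 2:
                splits.append(run[len(run) // 2])
            run = []
    return splits


def _segment_template(top: Topology, seg: list[int], torsions) -> np.ndarray:
    """Build one segment with restrained torsions (extended elsewhere).

    Returns (n_seg_atoms, 3) in the order of the topology's atom indices
    for that segment.
    """
    centers = {(t.residue, t.angle): t.center for t in torsions}
    phi = np.array([centers.get((r, "phi"), -135.0) for r in seg])
    psi = np.array([centers.get((r, "psi"), 135.0) for r in seg])
    bb = geometry.build_backbone(phi, psi)
    from .structures import model_from_backbone
    sub = "".join(top.sequence[np.searchsorted(top.resnums, r)] for r in seg)
    m = model_from_backbone(bb, sub, np.array(seg))
    from .structures import ATOM_INDEX
    pts = []
    for r in seg:
        for a in ("N", "H", "CA", "CB", "C", "O"):
            if (r, a) in top.index:
                pts.append(m.coords[seg.index(r), ATOM_INDEX[a]])
    return np.array(pts)


def _segment_links(em: EnergyModel, atom_slices: list[np.ndarray]
                   ) -> dict[tuple[int, int], list[tuple[int, int, float]]]:
    """Unambiguous short restraints between different segments.

    Returns (seg_a, seg_b) -> [(atom_a, atom_b, target_distance)] for the
    restraints informative enough to guide the initial assembly: single
    assignment option and an upper bound below 4 A (hydrogen bonds and the
    strong amide distance class).
    """
    seg_of = np.empty(em.top.n_atoms, int)
    for s, sl in enumerate(atom_slices):
        seg_of[sl] = s
    links: dict[tuple[int, int], list] = {}
    for seg in range(em.n_restraints):
        members = np.nonzero(em.opt_seg == seg)[0]
        if len(members) != 1 or em.r_upper[seg] > 4.0:
            continue
        k = members[0]
        i, j = int(em.opt_i[k]), int(em.opt_j[k])
        sa, sb = int(seg_of[i]), int(seg_of[j])
        if sa == sb:
            continue
        key = (min(sa, sb), max(sa, sb))
        if sa > sb:
            i, j = j, i
        links.setdefault(key, []).append(
            (i, j, 0.5 * (em.r_lower[seg] + em.r_upper[seg])))
    return links


def _guided_placement(em: EnergyModel, templates, atom_slices, rng,
                      noise: float = 1.0) -> np.ndarray | None:
    """Initial poses from the unambiguous-link graph.

    Segments are placed breadth-first: each new segment is rigidly docked
    by least squares onto the link distances to already-placed segments
    (plus the covalent tether to sequence neighbours), with seeded noise
    for ensemble diversity.  Returns None when the graph is too sparse to
    guide anything.
    """
    from scipy.optimize import least_squares

    n_seg = len(templates)
    links = _segment_links(em, atom_slices)
    degree = np.zeros(n_seg)
    for (a, b), lst in links.items():
        degree[a] += len(lst)
        degree[b] += len(lst)
    if n_seg > 1 and np.count_nonzero(degree) < 2:
        return None
    # covalent tethers between sequence-adjacent segments
    tethers: dict[tuple[int, int], list] = {}
    seg_of = np.empty(em.top.n_atoms, int)
    for s, sl in enumerate(atom_slices):
        seg_of[sl] = s
    for (i, j), d0 in zip(em.top.bond_idx, em.top.bond_d0):
        sa, sb = int(seg_of[i]), int(seg_of[j])
        if sa == sb:
            continue
        key = (min(sa, sb), max(sa, sb))
        a, b = (i, j) if sa < sb else (j, i)
        tethers.setdefault(key, []).append((int(a), int(b), float(d0)))

    x = np.zeros((em.top.n_atoms, 3))
    placed: list[int] = []
    order = [int(np.argmax(degree))]
    seen = set(order)
    while len(order) < n_seg:
        # next segment: most links into the placed set
        best, best_score = None, -1.0
        for s in range(n_seg):
            if s in seen:
                continue
            score = 0.0
            for t in order:
                key = (min(s, t), max(s, t))
                score += 2.0 * len(links.get(key, ()))
                score += len(tethers.get(key, ()))
            if score > best_score:
                best, best_score = s, score
        order.append(best)
        seen.add(best)

    for s in order:
        tpl = templates[s] - templates[s].mean(axis=0)
        if not placed:
            x[atom_slices[s]] = tpl @ _random_rotation(rng).T
            placed.append(s)
            continue
        cons = []  # (local atom row, global anchor xyz, target)
        local_index = {int(g): r for r, g in enumerate(atom_slices[s])}
        for t in placed:
            key = (min(s, t), max(s, t))
            for a, b, d0 in links.get(key, []):
                if a in local_index:
                    cons.append((local_index[a], x[b], d0))
                else:
                    cons.append((local_index[b], x[a], d0))
            for a, b, d0 in tethers.get(key, []):
                w = 3  # covalent tether counts strongly
                if a in local_index:
                    cons += [(local_index[a], x[b], d0)] * w
                else:
                    cons += [(local_index[b], x[a], d0)] * w
        if not cons:
            v = rng.normal(size=3)
            x[atom_slices[s]] = tpl @ _random_rotation(rng).T \
                + x[atom_slices[placed[-1]]].mean(axis=0) \
                + v / np.linalg.norm(v) * 12.0
            placed.append(s)
            continue
        anchors = np.array([c[1] for c in cons])
        rows = np.array([c[0] for c in cons])
        targets = np.array([c[2] for c in cons])

        def resid(p):
            R = _rotmat_from_vec(p[:3])
            pts = tpl[rows] @ R.T + p[3:]
            return np.linalg.norm(pts - anchors, axis=1) - targets

        center = anchors.mean(axis=0)
        best = None
        for trial in range(4):
            rv = rng.normal(0, np.pi / 2, 3)
            p0 = np.concatenate([rv, center + rng.normal(0, 3.0, 3)])
            try:
                res = least_squares(resid, p0, max_nfev=200)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        R = _rotmat_from_vec(best.x[:3])
        pose = tpl @ R.T + best.x[3:]
        pose += rng.normal(0, noise * 0.2, 3)  # diversity
        x[atom_slices[s]] = pose
        placed.append(s)
    return x


def _torsion_14_distance(angle_name: str, torsion_deg: float) -> float:
    """1-4 distance fixed by one backbone torsion at ideal geometry."""
    g = geometry
    if angle_name == "phi":  # C(i-1)-N-CA-C
        p0 = np.zeros(3)
        p1 = p0 + [g.BOND_C_N, 0, 0]
        p2 = g.place_atom(p0 + [0, 1, 0], p0, p1, g.BOND_N_CA, g.ANGLE_C_N_CA, 90.0)
        p3 = g.place_atom(p0, p1, p2, g.BOND_CA_C, g.ANGLE_N_CA_C, torsion_deg)
    else:  # psi: N-CA-C-N(i+1)
        p0 = np.zeros(3)
        p1 = p0 + [g.BOND_N_CA, 0, 0]
        p2 = g.place_atom(p0 + [0, 1, 0], p0, p1, g.BOND_CA_C, g.ANGLE_N_CA_C, 90.0)
        p3 = g.place_atom(p0, p1, p2, g.BOND_C_N, g.ANGLE_CA_C_N, torsion_deg)
    return float(np.linalg.norm(p3 - p0))


class _DistanceGeometry:
    """Bound-smoothed metric-matrix embedding of the restraint network.

    Exact bounds for covalent terms and torsion-derived 1-4 distances,
    restraint bounds for unambiguous restraints, triangle-inequality
    smoothing of the upper bounds; per model a random distance matrix is
    embedded (classical MDS) and refined against the sparse bounds by a
    smooth stress minimization, then mirror-corrected via the side-chain
    chirality impropers.
    """

    def __init__(self, em: EnergyModel, torsions=()):
        top = em.top
        n = top.n_atoms
        U = np.full((n, n), 999.0)
        L = np.full((n, n), 1.8)
        np.fill_diagonal(U, 0.0)
        np.fill_diagonal(L, 0.0)
        cons_i, cons_j, cons_lo, cons_hi = [], [], [], []

        def set_pair(i, j, lo, hi):
            U[i, j] = U[j, i] = min(U[i, j], hi)
            L[i, j] = L[j, i] = max(L[i, j], lo)
            cons_i.append(i)
            cons_j.append(j)
            cons_lo.append(lo)
            cons_hi.append(hi)

        for (i, j), d0 in zip(top.bond_idx, top.bond_d0):
            set_pair(i, j, d0 - 0.01, d0 + 0.01)
        for i in range(len(top.sequence) - 1):
            r = int(top.resnums[i])
            if r in top.chain_breaks:
                continue
            a, b = top.index.get((r, "CA")), top.index.get((r + 1, "CA"))
            if a is not None and b is not None:
                set_pair(a, b, 3.70, 3.90)  # trans peptide
        for t in torsions:
            q = (top.phi_quad(t.residue) if t.angle == "phi"
                 else top.psi_quad(t.residue))
            if q is None:
                continue
            d = _torsion_14_distance(t.angle, t.center)
            set_pair(q[0], q[3], d - 0.3, d + 0.3)
        for seg in range(em.n_restraints):
            members = np.nonzero(em.opt_seg == seg)[0]
            if len(members) != 1:
                continue
            k = members[0]
            set_pair(int(em.opt_i[k]), int(em.opt_j[k]),
                     max(em.r_lower[seg], 1.8), em.r_upper[seg])
        for k in range(n):  # triangle smoothing of upper bounds
            np.minimum(U, U[:, k, None] + U[None, k, :], out=U)
        self.L = np.minimum(L, U)
        self.U = U
        self.n = n
        self.cons = (np.array(cons_i), np.array(cons_j),
                     np.array(cons_lo), np.array(cons_hi))
        self.em = em

    def _stress(self, flat):
        x = flat.reshape(-1, 3)
        i, j, lo, hi = self.cons
        dv = x[i] - x[j]
        dd = np.maximum(np.linalg.norm(dv, axis=1), 1e-9)
        over = np.maximum(dd - hi, 0.0)
        under = np.minimum(dd - lo, 0.0)
        viol = over + under
        e = np.sum(viol ** 2)
        coef = 2.0 * viol / dd
        g = np.zeros_like(x)
        f = coef[:, None] * dv
        np.add.at(g, i, f)
        np.add.at(g, j, -f)
        return e, g.ravel()

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        frac = rng.uniform(0.3, 0.7, size=(self.n, self.n))
        frac = (frac + frac.T) / 2.0
        D = self.L + frac * (self.U - self.L)
        np.fill_diagonal(D, 0.0)
        D2 = D ** 2
        J = np.eye(self.n) - 1.0 / self.n
        B = -0.5 * J @ D2 @ J
        w, V = np.linalg.eigh(B)
        idx = np.argsort(w)[::-1][:3]
        x = V[:, idx] * np.sqrt(np.clip(w[idx], 0.0, None))
        res = minimize(self._stress, x.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": 500})
        x = res.x.reshape(-1, 3)
        return self._fix_chirality(x)

    def _fix_chirality(self, x: np.ndarray) -> np.ndarray:
        top = self.em.top
        quads = [q for q, t in zip(top.geom_quads, top.geom_targets)
                 if abs(abs(t) - 180.0) > 5.0]
        if not quads:
            return x
        phi, _ = _dihedrals_grad(x, np.array(quads))
        if np.median(phi) * _cb_improper_target() < 0:
            x = x.copy()
            x[:, 2] *= -1.0
        return x


def repair_dihedral_defects(em: EnergyModel, x: np.ndarray,
                            segment_bounds: list[tuple[int, int]] | None = None
                            ) -> tuple[np.ndarray, int]:
    """Fix cis-peptide and chirality defects left by an embedding.

    Gradient descent cannot flip a cis peptide or a D-centre (the path
    leads through collinear geometry), so they are repaired directly:
    a wrong-handed CB is mirrored through its N/CA/C plane, and a cis
    omega is rotated back to trans by turning everything downstream of
    the peptide bond up to the next flexible point.  Returns the repaired
    coordinates and the number of defects touched.
    """
    top = em.top
    x = x.copy()
    n_fixed = 0
    # chirality: mirror CB through the backbone plane
    target = _cb_improper_target()
    for q, t in zip(top.geom_quads, top.geom_targets):
        if abs(abs(t) - 180.0) < 5.0:
            continue  # omega-type quad
        phi = float(_dihedrals_grad(x, np.array([q]))[0][0])
        if phi * target < 0:
            nq, cq, caq, cbq = q
            u = np.cross(x[cq] - x[nq], x[caq] - x[nq])
            nu = np.linalg.norm(u)
            if nu < 1e-9:
                continue
            u /= nu
            v = x[cbq] - x[caq]
            x[cbq] = x[caq] + v - 2.0 * (v @ u) * u
            n_fixed += 1
    # cis peptides: rotate the downstream stretch about the C-N bond
    flex = set()
    if segment_bounds:
        for lo, hi in segment_bounds:
            flex.add(hi)  # segment ends are free to swing
    for q, t in zip(top.geom_quads, top.geom_targets):
        if abs(abs(t) - 180.0) >= 5.0:
            continue
        phi = float(_dihedrals_grad(x, np.array([q]))[0][0])
        delta = float(geometry.wrap_angle(180.0 - phi))
        if abs(delta) < 60.0:
            continue
        cq, nq = q[1], q[2]
        res_n = int(top.atom_res[nq])
        # rotate residues res_n .. end of this segment
        if segment_bounds:
            hi = next((h for lo, h in segment_bounds if lo <= res_n <= h),
                      int(top.resnums[-1]))
        else:
            hi = int(top.resnums[-1])
        rows = [k for k in range(top.n_atoms)
                if res_n <= top.atom_res[k] <= hi and k != nq]
        axis = x[nq] - x[cq]
        na = np.linalg.norm(axis)
        if na < 1e-9 or not rows:
            continue
        R = _rotmat(axis / na, np.deg2rad(delta))
        x[rows] = (x[rows] - x[nq]) @ R.T + x[nq]
        n_fixed += 1
    return x, n_fixed


def _rotmat_from_vec(rv: np.ndarray) -> np.ndarray:
    ang = np.linalg.norm(rv)
    if ang < 1e-12:
        return np.eye(3)
    return _rotmat(rv / ang, ang)


def _assemble_segments(em: EnergyModel, templates: list[np.ndarray],
                       atom_slices: list[np.ndarray], rng,
                       steps: int, amp: float) -> np.ndarray:
    """Rigid-body annealing of the segments against the restraint network.

    Each segment keeps its internal geometry; its pose follows a noisy
    gradient descent on the total pseudo-energy (gradient mapped to rigid
    translations and rotations about the segment centroid).
    """
    n_seg = len(templates)
    x = _guided_placement(em, templates, atom_slices, rng)
    if x is None:
        # random-walk placement keeps covalently tethered segments near
        # their neighbours while randomizing the topology
        x = np.zeros((em.top.n_atoms, 3))
        center = np.zeros(3)
        prev_ext = 0.0
        for s, tpl in enumerate(templates):
            R = _random_rotation(rng)
            ext = 0.5 * float(np.linalg.norm(tpl.max(axis=0) - tpl.min(axis=0)))
            if s > 0:
                v = rng.normal(size=3)
                center = center + v / np.linalg.norm(v) * 0.7 * (prev_ext + ext)
            x[atom_slices[s]] = (tpl - tpl.mean(axis=0)) @ R.T + center
            prev_ext = ext
    lr_t, lr_w = 0.05, 0.002
    for step in range(steps):
        frac = step / max(steps - 1, 1)
        noise = amp * (1.0 - frac)
        if step % 20 == 0:
            em.refresh_neighbors(x)
        _, g = em.energy_grad(x.ravel())
        g = g.reshape(-1, 3)
        for s in range(n_seg):
            sl = atom_slices[s]
            xs = x[sl]
            c = xs.mean(axis=0)
            gt = g[sl].sum(axis=0)
            gw = np.cross(xs - c, g[sl]).sum(axis=0)
            t_step = -lr_t * gt / len(sl) + rng.normal(0, noise, 3)
            step_norm = np.linalg.norm(t_step)
            if step_norm > 0.5:  # cap per-step motion to keep assembly stable
                t_step *= 0.5 / step_norm
            w = -lr_w * gw / len(sl) + rng.normal(0, noise * 0.05, 3)
            ang = np.linalg.norm(w)
            if ang > 1e-12:
                K = _rotmat(w / ang, min(ang, 0.3))
                xs = (xs - c) @ K.T + c
            x[sl] = xs + t_step
    return x


def _rotmat(axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    ax, ay, az = axis
    K = np.array([[0, -az, ay], [az, 0, -ax], [-ay, ax, 0]])
    return np.eye(3) + s * K + (1 - c) * K @ K


def _random_rotation(rng) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return _rotmat(v, rng.uniform(0, 2 * np.pi))


def anneal(sequence: str, distance_restraints, torsions=(), hbonds=(),
           config: AnnealConfig | None = None, chain_breaks=(),
           resnums=None) -> StructureEnsemble:
    """Compute an ensemble of models satisfying the restraints.

    Each model starts from torsion-seeded chain segments placed at an
    independent seeded random pose (segments without torsion information
    start extended), assembles them by rigid-body annealing against the
    restraint network, then relaxes all coordinates through perturbation /
    quench cycles with decreasing amplitude and a final quench.  Without
    any distance restraint the regularized start conformations are returned
    directly.  Divergence (non-finite energy) raises with the seed id.
    """
    cfg = config or AnnealConfig()
    top = Topology(sequence, chain_breaks, resnums)
    em = EnergyModel(top, distance_restraints, torsions, hbonds, cfg)
    have_restraints = em.n_restraints > 0
    segs = _segments(top, _flexible_splits(top, torsions))
    templates = [_segment_template(top, s, torsions) for s in segs]
    slices = []
    pos = 0
    for tpl in templates:
        slices.append(np.arange(pos, pos + len(tpl)))
        pos += len(tpl)
    amps = cfg.noise_amplitudes()
    cyc_iter = max(40, cfg.cool_steps // (2 * max(cfg.n_cycles, 1)))
    rigid_steps = max(100, cfg.cool_steps // 4)
    # embed from the restraint network when it carries enough unambiguous
    # information; otherwise assemble torsion-seeded segments
    n_unamb = int(np.sum(np.bincount(em.opt_seg,
                                     minlength=max(em.n_restraints, 1)) == 1)) \
        if em.n_restraints else 0
    dg = None
    # embedding needs a RELIABLE unambiguous network: hydrogen-bond
    # restraints mark the late, well-disambiguated stage of a calculation;
    # early iterations use the rigid-segment annealing path instead
    if (have_restraints and len(list(hbonds)) > 0
            and n_unamb >= max(8, len(sequence) // 4)):
        dg = _DistanceGeometry(em, torsions)
    restrained = {t.residue for t in torsions}
    core_masks = [np.array([int(top.atom_res[g]) in restrained for g in sl])
                  for sl in slices]
    seg_bounds = [(s[0], s[-1]) for s in segs]

    def _regularize(x):
        # rigid templates fitted on the torsion-restrained core of each
        # segment: keeps the embedded global fold, restores clean local
        # geometry (embedding artifacts live mostly in the flexible parts)
        out = x.copy()
        for tpl, sl, mask in zip(templates, slices, core_masks):
            msk = mask if mask.sum() >= 3 else np.ones(len(sl), bool)
            cp = tpl[msk].mean(axis=0)
            cq = x[sl][msk].mean(axis=0)
            R = geometry.kabsch_rotation(tpl[msk] - cp, x[sl][msk] - cq)
            out[sl] = (tpl - cp) @ R.T + cq
        return out

    models = []
    for k in range(cfg.n_models):
        rng = np.random.default_rng(cfg.seed * 100003 + 31 * k + 7)
        if have_restraints:
            if dg is not None:
                x = _regularize(dg.sample(rng))
                x, e = minimize_energy(em, x, cfg.cool_steps)
                x, nfix = repair_dihedral_defects(em, x, seg_bounds)
                if nfix:
                    x, e = minimize_energy(em, x, cfg.cool_steps // 2)
                x, e = minimize_energy(em, x, cfg.refine_steps)
            else:
                x = _assemble_segments(em, templates, slices, rng, rigid_steps,
                                       amp=0.05 * np.sqrt(cfg.high_temperature / 300.0))
                x, e = minimize_energy(em, x, cyc_iter)
                for amp in amps:
                    x = x + rng.normal(0.0, amp, x.shape)
                    x, e = minimize_energy(em, x, cyc_iter)
                x, e = minimize_energy(em, x, cfg.refine_steps)
        else:
            x = np.concatenate(templates, axis=0).copy()
            x, e = minimize_energy(em, x, cfg.refine_steps)
        if not np.isfinite(e):
            raise RuntimeError(f"annealing diverged for seed {cfg.seed}/{k}")
        models.append(_flat_to_model(x, top, sequence, e))
    return StructureEnsemble(sequence, top.resnums, models,
                             provenance={"seed": cfg.seed, "engine": "anneal"})


# --------------------------------------------------------------------------
# ensemble statistics
# --------------------------------------------------------------------------

_BACKBONE_FOR_RMSD = ("N", "CA", "C", "O")


def _backbone_coords(model: Model, residue_subset) -> np.ndarray:
    from .structures import ATOM_INDEX
    lookup = {int(r): i for i, r in enumerate(model.resnums)}
    pts = []
    for r in residue_subset:
        for a in _BACKBONE_FOR_RMSD:
            xyz = model.coords[lookup[int(r)], ATOM_INDEX[a]]
            if not np.any(np.isnan(xyz)):
                pts.append(xyz)
    return np.array(pts)


def backbone_rmsd(ensemble: StructureEnsemble, residue_subset=None
                  ) -> tuple[float, float]:
    """Mean and sd of pairwise backbone RMSD over a residue subset."""
    if len(ensemble) < 2:
        raise ValueError("need at least two models")
    subset = list(residue_subset) if residue_subset is not None else list(ensemble.resnums)
    if not subset:
        raise ValueError("empty residue subset")
    coords = [_backbone_coords(m, subset) for m in ensemble.models]
    vals = []
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            vals.append(geometry.superposed_rmsd(coords[i], coords[j]))
    return float(np.mean(vals)), float(np.std(vals))


def select_converged(ensemble: StructureEnsemble, residue_subset=None,
                     radius: float = 2.0, n_select: int = 5
                     ) -> StructureEnsemble:
    """The converged subset of a bundle.

    Restraint networks with residual false restraints admit a few
    competing minima; converged models agree with each other while decoys
    scatter.  The representative is the model with the most neighbours
    within ``radius`` (backbone RMSD over ``residue_subset``; energy
    breaks ties), and the ``n_select`` lowest-energy members of its
    cluster form the returned bundle.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    subset = list(residue_subset) if residue_subset is not None \
        else list(ensemble.resnums)
    coords = [_backbone_coords(m, subset) for m in ensemble.models]
    n = len(coords)
    close = np.zeros((n, n), bool)
    for i in range(n):
        for j in range(i + 1, n):
            close[i, j] = close[j, i] = \
                geometry.superposed_rmsd(coords[i], coords[j]) < radius
    energies = ensemble.pseudo_energies
    degree = close.sum(axis=1)
    rep = min(range(n), key=lambda k: (-degree[k], energies[k]))
    members = [k for k in range(n) if k == rep or close[rep, k]]
    members.sort(key=lambda k: energies[k])
    members = members[:n_select]
    return StructureEnsemble(ensemble.sequence, ensemble.resnums,
                             [ensemble.models[k] for k in members],
                             provenance=dict(ensemble.provenance,
                                             cluster_size=int(degree[rep] + 1)))


def rmsd_to_reference(ensemble: StructureEnsemble, reference: Model,
                      residue_subset=None) -> float:
    """Mean backbone RMSD of the ensemble's models to a reference model."""
    subset = list(residue_subset) if residue_subset is not None else list(ensemble.resnums)
    ref = _backbone_coords(reference, subset)
    vals = [geometry.superposed_rmsd(_backbone_coords(m, subset), ref)
            for m in ensemble.models]
    return float(np.mean(vals))
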