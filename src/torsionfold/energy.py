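"""Composite folding energy and its analytic gradient in torsion space.

The total energy is a linear combination of seven restraint-derived
terms (CB-CB and CA-CA distances, CB and CA contacts, and the three
inter-residue orientation angles), each with separate weights for
short-, medium- and long-range sequence separations, plus three generic
terms: backbone hydrogen bonding, a soft van-der-Waals clash penalty and
a statistical backbone-torsion potential -- 24 weights in total.

Every term is C1-smooth, so the gradient with respect to the backbone
dihedrals exists everywhere.  Gradients are assembled by first
accumulating the Cartesian gradient dE/dx over all sites and then
applying the rigid-rotation chain rule dx_a/dchi = e x (x_a - p) for
atoms downstream of each rotating bond.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from torsionfold import geometry as geom
from torsionfold import restraints as rst
from torsionfold.geometry import CA, CB, C, H, N, O, SC

RESTRAINT_TERMS = (
    "cb_distance",
    "ca_distance",
    "cb_contact",
    "ca_contact",
    "omega",
    "theta",
    "phi_angle",
)
GENERIC_TERMS = ("hb", "vdw", "tor")

WEIGHT_NAMES = tuple(
    f"{term}.{rng}" for term in RESTRAINT_TERMS for rng in rst.RANGE_CLASSES
) + GENERIC_TERMS

WEIGHT_MIN, WEIGHT_MAX = 0.0, 25.0

# default weights; calibrated on the package's synthetic fixture suite
DEFAULT_WEIGHTS = {
    "cb_distance.short": 2.0,
    "cb_distance.medium": 2.5,
    "cb_distance.long": 3.0,
    "ca_distance.short": 1.0,
    "ca_distance.medium": 1.25,
    "ca_distance.long": 1.5,
    "cb_contact.short": 0.25,
    "cb_contact.medium": 0.25,
    "cb_contact.long": 0.5,
    "ca_contact.short": 0.25,
    "ca_contact.medium": 0.25,
    "ca_contact.long": 0.5,
    "omega.short": 1.0,
    "omega.medium": 1.0,
    "omega.long": 1.0,
    "theta.short": 1.0,
    "theta.medium": 1.0,
    "theta.long": 1.0,
    "phi_angle.short": 0.5,
    "phi_angle.medium": 0.5,
    "phi_angle.long": 0.5,
    "hb": 0.5,
    "vdw": 1.0,
    "tor": 0.2,
}

VDW_SIGMA = 0.85  # clash radius scale factor
VDW_RADII = {N: 1.55, CA: 1.70, C: 1.70, O: 1.52, CB: 1.80, SC: 2.00}

HB_DMAX = 3.0  # A; H...O pairs beyond this contribute exactly zero


class WeightError(ValueError):
    pass


@dataclass
class WeightVector:
    """The 24 energy weights: 7 restraint terms x 3 ranges + 3 generic."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (24,):
            raise WeightError(f"expected 24 weights, got {self.values.shape}")
        if np.any(self.values < WEIGHT_MIN) or np.any(self.values > WEIGHT_MAX):
            raise WeightError(
                f"weights must lie in [{WEIGHT_MIN}, {WEIGHT_MAX}]"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "WeightVector":
        unknown = set(d) - set(WEIGHT_NAMES)
        if unknown:
            raise WeightError(f"unknown weight names: {sorted(unknown)}")
        return cls(np.array([d.get(name, 0.0) for name in WEIGHT_NAMES]))

    @classmethod
    def default(cls) -> "WeightVector":
        return cls.from_dict(DEFAULT_WEIGHTS)

    def to_dict(self) -> dict:
        return dict(zip(WEIGHT_NAMES, self.values.tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[WEIGHT_NAMES.index(name)])

    def restraint_weights(self, term: str) -> np.ndarray:
        """(3,) weights of one restraint term by range class."""
        i = RESTRAINT_TERMS.index(term) * 3
        return self.values[i : i + 3]

    def replace(self, name: str, value: float) -> "WeightVector":
        v = self.values.copy()
        v[WEIGHT_NAMES.index(name)] = value
        return WeightVector(v)


@dataclass
class EnergyBreakdown:
    """Total energy plus unweighted per-term values.

    ``restraint_terms[kind]`` is a (3,) array of unweighted sums by range
    class; ``generic_terms`` maps hb/vdw/tor to unweighted values.  The
    total equals the weighted sum of all entries.
    """

    total: float
    restraint_terms: dict = field(default_factory=dict)
    generic_terms: dict = field(default_factory=dict)

    def weighted_total(self, weights: WeightVector) -> float:
        t = 0.0
        for kind in RESTRAINT_TERMS:
            t += float(self.restraint_terms[kind] @ weights.restraint_weights(kind))
        for name in GENERIC_TERMS:
            t += weights[name] * self.generic_terms[name]
        return t


# ---------------------------------------------------------------------------
# smooth switching helpers (C1 cubic smoothstep)

def _smoothstep(t):
    """0 -> 1 over t in [0, 1], C1 at both ends; clamped outside."""
    t = np.clip(t, 0.0, 1.0)
    return 3 * t * t - 2 * t ** 3


def _smoothstep_d(t):
    inside = (t > 0.0) & (t < 1.0)
    t = np.clip(t, 0.0, 1.0)
    return np.where(inside, 6 * t - 6 * t * t, 0.0)


# ---------------------------------------------------------------------------
# statistical backbone-torsion surface

class TorsionSurface:
    """Periodic bicubic (Catmull-Rom) interpolation of a -log p grid.

    The grid is 24 x 24 cells of 15 x 15 degrees over (phi, psi); three
    tables are shipped -- general, glycine and proline -- each built from
    a smooth mixture of wrapped Gaussians over the allowed Ramachandran
    basins.
    """

    STEP = 15.0

    def __init__(self, grid: np.ndarray):
        if grid.shape != (24, 24):
            raise ValueError("torsion grid must be 24 x 24")
        self.grid = np.asarray(grid, dtype=float)

    @staticmethod
    def _weights(t):
        """Catmull-Rom weights and their derivatives for frac t."""
        t2, t3 = t * t, t * t * t
        w = np.stack(
            [
                0.5 * (-t3 + 2 * t2 - t),
                0.5 * (3 * t3 - 5 * t2 + 2),
                0.5 * (-3 * t3 + 4 * t2 + t),
                0.5 * (t3 - t2),
            ],
            axis=-1,
        )
        dw = np.stack(
            [
                0.5 * (-3 * t2 + 4 * t - 1),
                0.5 * (9 * t2 - 10 * t),
                0.5 * (-9 * t2 + 8 * t + 1),
                0.5 * (3 * t2 - 2 * t),
            ],
            axis=-1,
        )
        return w, dw

    def evaluate(self, phi_deg, psi_deg):
        """Values and (d/dphi, d/dpsi) in energy per degree."""
        phi = np.atleast_1d(np.asarray(phi_deg, dtype=float))
        psi = np.atleast_1d(np.asarray(psi_deg, dtype=float))
        # grid knots at bin centers -172.5 + 15 k
        u = (phi + 172.5) / self.STEP
        v = (psi + 172.5) / self.STEP
        iu = np.floor(u).astype(int)
        iv = np.floor(v).astype(int)
        tu = u - iu
        tv = v - iv
        wu, dwu = self._weights(tu)
        wv, dwv = self._weights(tv)
        idx_u = (iu[:, None] + np.arange(-1, 3)[None, :]) % 24
        idx_v = (iv[:, None] + np.arange(-1, 3)[None, :]) % 24
        patch = self.grid[idx_u[:, :, None], idx_v[:, None, :]]  # (n, 4, 4)
        val = np.einsum("na,nab,nb->n", wu, patch, wv)
        dphi = np.einsum("na,nab,nb->n", dwu, patch, wv) / self.STEP
        dpsi = np.einsum("na,nab,nb->n", wu, patch, dwv) / self.STEP
        return val, dphi, dpsi


def _wrapped_gaussian_grid(basins, floor=0.02):
    """-log of a wrapped-Gaussian mixture tabulated on the 24 x 24 grid."""
    centers = np.arange(-172.5, 180.0, 15.0)
    pp, ss = np.meshgrid(centers, centers, indexing="ij")
    p = np.full(pp.shape, floor)
    for (mphi, mpsi, sphi, spsi, w) in basins:
        acc = np.zeros_like(pp)
        for kx in (-360.0, 0.0, 360.0):
            for ky in (-360.0, 0.0, 360.0):
                acc += np.exp(
                    -0.5 * ((pp - mphi + kx) / sphi) ** 2
                    - 0.5 * ((ss - mpsi + ky) / spsi) ** 2
                )
        p += w * acc
    return -np.log(p)


_GENERAL_BASINS = [
    (-63.0, -43.0, 18.0, 18.0, 0.35),   # alpha helix
    (-120.0, 130.0, 25.0, 25.0, 0.35),  # beta sheet
    (-65.0, 145.0, 20.0, 20.0, 0.20),   # polyproline II
    (55.0, 40.0, 15.0, 15.0, 0.05),     # left-handed alpha
]
_GLY_BASINS = [
    (-63.0, -43.0, 22.0, 22.0, 0.22),
    (63.0, 43.0, 22.0, 22.0, 0.22),
    (-120.0, 130.0, 30.0, 30.0, 0.22),
    (120.0, -130.0, 30.0, 30.0, 0.22),
    (-65.0, 145.0, 25.0, 25.0, 0.12),
]
_PRO_BASINS = [
    (-63.0, -35.0, 10.0, 18.0, 0.45),
    (-63.0, 145.0, 10.0, 22.0, 0.55),
]

TORSION_TABLES = {
    "general": TorsionSurface(_wrapped_gaussian_grid(_GENERAL_BASINS)),
    "G": TorsionSurface(_wrapped_gaussian_grid(_GLY_BASINS)),
    "P": TorsionSurface(_wrapped_gaussian_grid(_PRO_BASINS)),
}


def torsion_table_for(aa: str) -> TorsionSurface:
    return TORSION_TABLES.get(aa, TORSION_TABLES["general"])


# ---------------------------------------------------------------------------
# angle gradients w.r.t. the defining atom positions

def dihedral_gradients(p1, p2, p3, p4):
    """Dihedral (radians) and d(angle)/d(position) for each defining atom.

    Vectorized over leading axes; the Blondel-Karplus form, consistent
    with the IUPAC sign convention of :func:`torsionfold.geometry.dihedral`.
    """
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=-1)
    sq1 = np.einsum("...k,...k->...", n1, n1)
    sq2 = np.einsum("...k,...k->...", n2, n2)
    x = np.einsum("...k,...k->...", n1, n2)
    y = np.einsum("...k,...k->...", np.cross(n1, n2), b2 / nb2[..., None])
    ang = np.arctan2(y, x)
    g1 = -(nb2 / sq1)[..., None] * n1
    g4 = (nb2 / sq2)[..., None] * n2
    c12 = (np.einsum("...k,...k->...", b1, b2) / (nb2 * nb2))[..., None]
    c32 = (np.einsum("...k,...k->...", b3, b2) / (nb2 * nb2))[..., None]
    g2 = -(1.0 + c12) * g1 + c32 * g4
    g3 = c12 * g1 - (1.0 + c32) * g4
    return ang, g1, g2, g3, g4


def planar_angle_gradients(p1, p2, p3):
    """Planar angle at p2 (radians) and its position gradients."""
    u = p1 - p2
    w = p3 - p2
    nu = np.linalg.norm(u, axis=-1)
    nw = np.linalg.norm(w, axis=-1)
    uh = u / nu[..., None]
    wh = w / nw[..., None]
    cos = np.clip(np.einsum("...k,...k->...", uh, wh), -1.0, 1.0)
    ang = np.arccos(cos)
    sin = np.sqrt(np.maximum(1.0 - cos * cos, 1e-12))
    g1 = (cos[..., None] * uh - wh) / (nu * sin)[..., None]
    g3 = (cos[..., None] * wh - uh) / (nw * sin)[..., None]
    g2 = -(g1 + g3)
    return ang, g1, g2, g3


# ---------------------------------------------------------------------------
# the compiled energy model

def _bond_exclusions():
    """(offset, slot_a, slot_b) pairs within 2 covalent bonds.

    Derived by BFS over the reduced-model bond graph of two consecutive
    residues (SC is treated as bonded to CB).
    """
    bonds = [
        (0, N, 0, H), (0, N, 0, CA), (0, CA, 0, C), (0, CA, 0, CB),
        (0, C, 0, O), (0, CB, 0, SC), (0, C, 1, N),
        (1, N, 1, H), (1, N, 1, CA), (1, CA, 1, C), (1, CA, 1, CB),
        (1, C, 1, O), (1, CB, 1, SC),
    ]
    adj = {}
    for r1, s1, r2, s2 in bonds:
        adj.setdefault((r1, s1), []).append((r2, s2))
        adj.setdefault((r2, s2), []).append((r1, s1))
    excl = set()
    for start in adj:
        frontier = {start}
        seen = {start: 0}
        for depth in (1, 2):
            nxt = set()
            for node in frontier:
                for nb in adj.get(node, []):
                    if nb not in seen:
                        seen[nb] = depth
                        nxt.add(nb)
            frontier = nxt
        for (r2, s2), depth in seen.items():
            r1, s1 = start
            excl.add((r2 - r1, s1, s2))
            excl.add((r1 - r2, s2, s1))
    # within one residue the sites N, CA, C, CB, SC are mutually rigid
    # under ideal geometry -- their distances carry no conformational
    # signal, so they are excluded as well
    rigid = (N, CA, C, CB, SC)
    for s1 in rigid:
        for s2 in rigid:
            excl.add((0, s1, s2))
    return excl

_VDW_EXCLUSIONS = _bond_exclusions()


class EnergyModel:
    """Bound evaluator: sequence + potentials + weights -> E(x), dE/dx.

    Precomputes pair tables, the vdW exclusion list and the torsion-space
    chain-rule mask so that per-step evaluation is fully vectorized.
    """

    def __init__(self, sequence: str, potentials: rst.SplinePotentialSet | None,
                 weights: WeightVector):
        self.sequence = geom.validate_sequence(sequence)
        self.L = len(sequence)
        if potentials is not None and potentials.L != self.L:
            raise WeightError(
                f"potentials built for L={potentials.L}, sequence has L={self.L}"
            )
        self.potentials = potentials
        self.weights = weights
        L = self.L
        self._mask = geom.moving_mask(L)
        gly = np.array([aa == "G" for aa in self.sequence])
        self._cb_slot = np.where(gly, CA, CB)
        # restraint channel tables (drop orientation pairs involving Gly,
        # whose CB frame is degenerate)
        self._channels = {}
        self._contacts = {}
        if potentials is not None:
            for kind, ch in potentials.channels.items():
                pairs = ch.pairs
                if kind in ("omega", "theta", "phi_angle"):
                    ok = ~(gly[pairs[:, 0]] | gly[pairs[:, 1]])
                    if not np.all(ok):
                        raise rst.SchemaError(
                            "orientation channels must not include glycine pairs"
                            " (fit splines with the sequence to drop them)"
                        )
                self._channels[kind] = ch
            self._contacts = potentials.contacts
        # vdW pair table over heavy sites (Gly CB/SC duplicates skipped)
        atoms = []
        for i in range(L):
            for slot in (N, CA, C, O, CB, SC):
                if gly[i] and slot in (CB, SC):
                    continue
                atoms.append((i, slot))
        atoms = np.array(atoms)
        ii, jj = np.triu_indices(len(atoms), k=1)
        ri, si = atoms[ii, 0], atoms[ii, 1]
        rj, sj = atoms[jj, 0], atoms[jj, 1]
        off = rj - ri
        keep = np.ones(len(ii), dtype=bool)
        for k in range(len(ii)):
            if (off[k], si[k], sj[k]) in _VDW_EXCLUSIONS:
                keep[k] = False
        slot_to_r = {s: VDW_RADII[s] for s in VDW_RADII}
        self._vdw_i = np.stack([ri[keep], si[keep]], axis=1)
        self._vdw_j = np.stack([rj[keep], sj[keep]], axis=1)
        self._vdw_flat_i = (ri[keep] * 7 + si[keep]).astype(np.intp)
        self._vdw_flat_j = (rj[keep] * 7 + sj[keep]).astype(np.intp)
        self._vdw_rclash = VDW_SIGMA * (
            np.array([slot_to_r[s] for s in si[keep]])
            + np.array([slot_to_r[s] for s in sj[keep]])
        )
        self._vdw_rclash2 = self._vdw_rclash ** 2
        # hydrogen-bond donor/acceptor table: H_i/N_i vs O_j, |i-j| > 2
        di, aj = np.meshgrid(np.arange(1, L), np.arange(L), indexing="ij")
        di, aj = di.ravel(), aj.ravel()
        sep_ok = np.abs(di - aj) > 2
        self._hb_donor = di[sep_ok]
        self._hb_accept = aj[sep_ok]
        # per-residue torsion tables for residues with both angles defined
        self._tor_res = np.arange(1, L - 1)
        self._tor_tables = {}
        for key in ("general", "G", "P"):
            sel = np.array(
                [
                    (self.sequence[i] == key)
                    or (key == "general" and self.sequence[i] not in "GP")
                    for i in self._tor_res
                ]
            )
            if np.any(sel):
                self._tor_tables[key] = self._tor_res[sel]

    # -- public API ---------------------------------------------------------

    def evaluate(self, x: np.ndarray, want_grad: bool = True):
        """Energy breakdown (and torsion gradient) at torsion vector ``x``."""
        phi, psi = geom.torsions_from_vector(np.asarray(x, dtype=float))
        model = geom.build_coordinates(self.sequence, phi, psi)
        return self.evaluate_model(model, want_grad=want_grad)

    def evaluate_model(self, model: geom.ProteinModel, want_grad: bool = True):
        L = self.L
        coords = model.coords
        G = np.zeros((L, 7, 3)) if want_grad else None
        direct = np.zeros(2 * L - 2) if want_grad else None
        breakdown = EnergyBreakdown(total=0.0)

        cb_pos = coords[np.arange(L), self._cb_slot]
        w = self.weights

        for kind in RESTRAINT_TERMS:
            breakdown.restraint_terms[kind] = np.zeros(3)

        # spline channels
        for kind, ch in self._channels.items():
            pi, pj = ch.pairs[:, 0], ch.pairs[:, 1]
            wpair = w.restraint_weights(kind)[ch.range_class]
            if kind in ("cb_distance", "ca_distance"):
                slot = self._cb_slot if kind == "cb_distance" else np.full(L, CA)
                xi = coords[pi, slot[pi]]
                xj = coords[pj, slot[pj]]
                diff = xj - xi
                d = np.linalg.norm(diff, axis=1)
                v, g = ch.bank.evaluate(d)
                self._bin_ranges(breakdown, kind, ch.range_class, v)
                if want_grad:
                    u = diff / d[:, None]
                    f = (wpair * g)[:, None] * u
                    self._scatter(G, pj, slot[pj], f)
                    self._scatter(G, pi, slot[pi], -f)
            elif kind in ("omega", "theta"):
                if kind == "omega":
                    ats = [(pi, CA), (pi, CB), (pj, CB), (pj, CA)]
                else:
                    ats = [(pi, N), (pi, CA), (pi, CB), (pj, CB)]
                ps = [coords[r, s] for r, s in ats]
                ang, *grads = dihedral_gradients(*ps)
                v, g = ch.bank.evaluate(ang)
                self._bin_ranges(breakdown, kind, ch.range_class, v)
                if want_grad:
                    for (r, s), ga in zip(ats, grads):
                        self._scatter(G, r, s, (wpair * g)[:, None] * ga)
            else:  # phi_angle
                ats = [(pi, CA), (pi, CB), (pj, CB)]
                ps = [coords[r, s] for r, s in ats]
                ang, *grads = planar_angle_gradients(*ps)
                v, g = ch.bank.evaluate(ang)
                self._bin_ranges(breakdown, kind, ch.range_class, v)
                if want_grad:
                    for (r, s), ga in zip(ats, grads):
                        self._scatter(G, r, s, (wpair * g)[:, None] * ga)

        # contact wells
        for kind, cp in self._contacts.items():
            pi, pj = cp.pairs[:, 0], cp.pairs[:, 1]
            slot = self._cb_slot if kind == "cb_contact" else np.full(self.L, CA)
            xi = coords[pi, slot[pi]]
            xj = coords[pj, slot[pj]]
            diff = xj - xi
            d = np.linalg.norm(diff, axis=1)
            v, g = cp.evaluate(d)
            self._bin_ranges(breakdown, kind, cp.range_class, v)
            if want_grad:
                wpair = w.restraint_weights(kind)[cp.range_class]
                u = diff / d[:, None]
                f = (wpair * g)[:, None] * u
                self._scatter(G, pj, slot[pj], f)
                self._scatter(G, pi, slot[pi], -f)

        # generic terms
        e_vdw = self._vdw(coords, G, w["vdw"] if want_grad else 0.0, want_grad)
        e_hb = self._hbond(coords, G, w["hb"] if want_grad else 0.0, want_grad)
        e_tor = self._torsion(model, direct, w["tor"] if want_grad else 0.0, want_grad)
        breakdown.generic_terms = {"vdw": e_vdw, "hb": e_hb, "tor": e_tor}

        breakdown.total = breakdown.weighted_total(w)
        if not want_grad:
            return breakdown, None
        grad = geom.cartesian_to_torsion_gradient(coords, G, self._mask)
        grad += direct
        return breakdown, grad

    def energy(self, x: np.ndarray) -> float:
        return self.evaluate(x, want_grad=False)[0].total

    def energy_and_grad(self, x: np.ndarray):
        bd, g = self.evaluate(x, want_grad=True)
        return bd.total, g, bd

    # -- internals ----------------------------------------------------------

    @staticmethod
    def _bin_ranges(breakdown, kind, rclass, values):
        breakdown.restraint_terms[kind] += np.bincount(
            rclass, weights=values, minlength=3
        )

    @staticmethod
    def _scatter(G, res, slot, vec):
        """Accumulate (n, 3) Cartesian gradient entries into G (L, 7, 3)."""
        flat = res * 7 + slot
        for k in range(3):
            np.add.at(G[..., k].reshape(-1), flat, vec[:, k])

    def _vdw(self, coords, G, wscale, want_grad):
        flat = coords.reshape(-1, 3)
        diff = flat[self._vdw_flat_j] - flat[self._vdw_flat_i]
        d2 = np.einsum("ij,ij->i", diff, diff)
        over = d2 < self._vdw_rclash2
        if not np.any(over):
            return 0.0
        d = np.sqrt(d2[over])
        dd = self._vdw_rclash[over] - d
        e = float(np.sum(dd * dd))
        if want_grad:
            g = -2.0 * dd  # dE/dd
            u = diff[over] / d[:, None]
            f = (wscale * g)[:, None] * u
            self._scatter(G, self._vdw_j[over, 0], self._vdw_j[over, 1], f)
            self._scatter(G, self._vdw_i[over, 0], self._vdw_i[over, 1], -f)
        return e

    def _hbond(self, coords, G, wscale, want_grad):
        di, aj = self._hb_donor, self._hb_accept
        hx = coords[di, H]
        ox = coords[aj, O]
        diff = ox - hx
        d = np.linalg.norm(diff, axis=1)
        close = d < HB_DMAX
        if not np.any(close):
            return 0.0
        di, aj = di[close], aj[close]
        hx, ox, d = hx[close], ox[close], d[close]
        nx = coords[di, N]
        # radial gate: up over [1.2, 1.5], down over [2.6, 3.0]
        t_up = (d - 1.2) / 0.3
        t_dn = (d - 2.6) / 0.4
        fd = _smoothstep(t_up) * (1.0 - _smoothstep(t_dn))
        dfd = (
            _smoothstep_d(t_up) / 0.3 * (1.0 - _smoothstep(t_dn))
            - _smoothstep(t_up) * _smoothstep_d(t_dn) / 0.4
        )
        # angular gate on the N-H...O angle: up over [120, 150] degrees
        ang, gN, gH, gO = planar_angle_gradients(nx, hx, ox)
        a0, a1 = np.deg2rad(120.0), np.deg2rad(150.0)
        t_a = (ang - a0) / (a1 - a0)
        fa = _smoothstep(t_a)
        dfa = _smoothstep_d(t_a) / (a1 - a0)
        e = float(-np.sum(fd * fa))
        if want_grad:
            u = (ox - hx) / d[:, None]
            # distance part
            f = (-wscale * dfd * fa)[:, None] * u
            self._scatter(G, aj, np.full(len(aj), O), f)
            self._scatter(G, di, np.full(len(di), H), -f)
            # angle part
            c = (-wscale * fd * dfa)[:, None]
            self._scatter(G, di, np.full(len(di), N), c * gN)
            self._scatter(G, di, np.full(len(di), H), c * gH)
            self._scatter(G, aj, np.full(len(aj), O), c * gO)
        return e

    def _torsion(self, model, direct, wscale, want_grad):
        e = 0.0
        L = self.L
        for key, residues in self._tor_tables.items():
            table = TORSION_TABLES[key]
            val, dphi, dpsi = table.evaluate(model.phi[residues], model.psi[residues])
            e += float(np.sum(val))
            if want_grad:
                # convert energy/degree to energy/radian
                conv = 180.0 / np.pi
                direct[residues - 1] += wscale * dphi * conv
                direct[L - 1 + residues] += wscale * dpsi * conv
        return e


# ---------------------------------------------------------------------------
# spec-level operations

def total_energy(model: geom.ProteinModel, potentials, weights) -> EnergyBreakdown:
    em = EnergyModel(model.sequence, potentials, weights)
    return em.evaluate_model(model, want_grad=False)[0]


def energy_gradient(model: geom.ProteinModel, potentials, weights) -> np.ndarray:
    em = EnergyModel(model.sequence, potentials, weights)
    return em.evaluate_model(model, want_grad=True)[1]


def vdw_energy(model: geom.ProteinModel) -> float:
    em = EnergyModel(model.sequence, None, WeightVector.default())
    return em._vdw(model.coords, None, 0.0, False)


def hbond_energy(model: geom.ProteinModel) -> float:
    em = EnergyModel(model.sequence, None, WeightVector.default())
    return em._hbond(model.coords, None, 0.0, False)


def torsion_energy(model: geom.ProteinModel) -> float:
    em = EnergyModel(model.sequence, None, WeightVector.default())
    return em._torsion(model, None, 0.0, False)


# ---------------------------------------------------------------------------
# coordinate-descent weight search

def optimize_weights(objective, init: WeightVector | None = None,
                     names=WEIGHT_NAMES) -> WeightVector:
    """Coordinate-wise grid search maximizing ``objective(WeightVector)``.

    Pass 1 scans each weight from a zero start over [0, 25] at step 0.25;
    three refinement passes rescan at step 0.1; a final pass perturbs
    each weight by up to +-2 at step 0.02.  A proposal is accepted only
    if the objective improves.  Deterministic for a deterministic
    objective.
    """
    if not callable(objective):
        raise WeightError("objective must be callable")
    w = init if init is not None else WeightVector(np.zeros(24))
    best = objective(w)

    def scan(w, best, name, grid):
        for value in grid:
            if abs(value - w[name]) < 1e-12:
                continue
            cand = w.replace(name, value)
            score = objective(cand)
            if score > best:
                w, best = cand, score
        return w, best

    coarse = np.arange(0.0, 25.0 + 0.125, 0.25)
    for name in names:
        w, best = scan(w, best, name, coarse)
    fine = np.arange(0.0, 25.0 + 0.05, 0.1)
    for _ in range(3):
        for name in names:
            w, best = scan(w, best, name, fine)
    for name in names:
        lo = max(WEIGHT_MIN, w[name] - 2.0)
        hi = min(WEIGHT_MAX, w[name] + 2.0)
        w, best = scan(w, best, name, np.arange(lo, hi + 0.01, 0.02))
    return w
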