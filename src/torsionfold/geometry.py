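"""Reduced backbone representation and torsion <-> Cartesian conversion.

A chain is represented by seven sites per residue -- N, amide H, CA, C,
carbonyl O, CB and the side-chain center (SC) -- with every covalent bond
length and angle fixed at ideal values, so the only conformational degrees
of freedom are the backbone dihedrals (phi, psi); the peptide bond omega is
held at 180 degrees.  Coordinates are built sequentially (NeRF-style
internal-to-Cartesian placement) in a canonical frame: N of residue 1 at
the origin, its CA on +x, its C in the xy-plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# atom slot layout of the (L, 7, 3) coordinate array
N, H, CA, C, O, CB, SC = range(7)
ATOM_NAMES = ("N", "H", "CA", "C", "O", "CB", "SC")
SLOT = {name: i for i, name in enumerate(ATOM_NAMES)}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Engh-Huber-style ideal covalent geometry (lengths in Angstrom, angles deg)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
BOND_CA_CB = 1.521

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_N_H = 119.0
ANGLE_N_CA_CB = 110.4
# improper dihedral C-N-CA-CB fixing the L-configuration at CA
DIHEDRAL_C_N_CA_CB = -122.6

OMEGA_TRANS = 180.0

#: sentinel for the undefined phi of the first and psi of the last residue
TORSION_UNDEFINED = 999.0

# distance (Angstrom) from CA to the side-chain geometric center, along the
# CA->CB axis; rough per-residue centroid offsets for the reduced model
SC_DISTANCE = {
    "A": 1.53, "C": 2.31, "D": 2.47, "E": 3.09, "F": 3.41,
    "G": 0.00, "H": 3.14, "I": 2.33, "K": 3.52, "L": 2.61,
    "M": 2.95, "N": 2.47, "P": 1.88, "Q": 3.09, "R": 4.10,
    "S": 1.90, "T": 1.93, "V": 1.97, "W": 3.86, "Y": 3.77,
}


class GeometryError(ValueError):
    """Degenerate geometry (colinear atoms defining a dihedral/frame)."""


class SequenceError(ValueError):
    """Invalid sequence (length or alphabet)."""


@dataclass
class ProteinModel:
    """One chain: sequence, backbone torsions (degrees) and coordinates.

    ``phi[0]`` and ``psi[L-1]`` are undefined and carry the sentinel value
    :data:`TORSION_UNDEFINED`.  ``coords`` has shape (L, 7, 3) with atom
    slots ordered N, H, CA, C, O, CB, SC.  Glycine rows carry CB = CA and
    SC = CA, so CB-based restraint terms fall back to CA for glycine.
    """

    sequence: str
    phi: np.ndarray
    psi: np.ndarray
    coords: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def pair_atoms(self, kind: str) -> np.ndarray:
        """Coordinates used by a restraint channel: CB (CA for Gly) or CA."""
        if kind.startswith("ca"):
            return self.coords[:, CA, :]
        return self.cb_or_ca()

    def cb_or_ca(self) -> np.ndarray:
        out = self.coords[:, CB, :].copy()
        gly = np.array([aa == "G" for aa in self.sequence])
        out[gly] = self.coords[gly, CA, :]
        return out


def validate_sequence(sequence: str) -> str:
    sequence = sequence.upper()
    for pos, aa in enumerate(sequence, start=1):
        if aa not in AMINO_ACIDS:
            raise SequenceError(
                f"non-standard residue letter {aa!r} at position {pos}"
            )
    return sequence


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-10:
        raise GeometryError("zero-length vector in frame construction")
    return v / n


def _place_scalar(a, b, c, bond, theta, tau):
    """Scalar-arithmetic NeRF placement (radians); hot path of the build."""
    from math import cos, sin, sqrt

    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    inv = 1.0 / sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx * inv, bcy * inv, bcz * inv
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = sqrt(nx * nx + ny * ny + nz * nz)
    if nn < 1e-10:
        raise GeometryError("colinear atoms A,B,C in placement frame")
    inv = 1.0 / nn
    nx, ny, nz = nx * inv, ny * inv, nz * inv
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * cos(theta)
    st = bond * sin(theta)
    d1 = st * cos(tau)
    d2 = st * sin(tau)
    return (
        c[0] + d0 * bcx + d1 * mx + d2 * nx,
        c[1] + d0 * bcy + d1 * my + d2 * ny,
        c[2] + d0 * bcz + d1 * mz + d2 * nz,
    )


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom D bonded to ``c`` given the chain A-B-C-D.

    ``bond`` = |C-D|, ``angle_deg`` = angle B-C-D, ``torsion_deg`` =
    dihedral A-B-C-D in the IUPAC convention (cis = 0).
    """
    return np.array(
        _place_scalar(
            tuple(a), tuple(b), tuple(c),
            bond, np.deg2rad(angle_deg), np.deg2rad(torsion_deg),
        )
    )


def dihedral(p0, p1, p2, p3) -> float:
    """IUPAC dihedral angle p0-p1-p2-p3 in degrees, range (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    if np.linalg.norm(np.cross(b0, b1)) < 1e-10 or np.linalg.norm(
        np.cross(b1, b2)
    ) < 1e-10:
        raise GeometryError("colinear atoms defining a dihedral")
    b1 = _unit(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def planar_angle(p0, p1, p2) -> float:
    """Angle at vertex p1 between p0 and p2, degrees in [0, 180]."""
    u = _unit(p0 - p1)
    v = _unit(p2 - p1)
    return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))


def build_coordinates(sequence: str, phi, psi) -> ProteinModel:
    """Build all-site coordinates from backbone torsions (degrees).

    The first residue is placed in the canonical frame; each subsequent
    backbone atom is appended with ideal bond lengths/angles and the given
    dihedrals, omega fixed trans.  Pseudo-atoms (H, O, CB, SC) are then
    attached with ideal geometry.
    """
    sequence = validate_sequence(sequence)
    L = len(sequence)
    if L < 2:
        raise SequenceError(f"need at least 2 residues, got {L}")
    phi = np.asarray(phi, dtype=float).copy()
    psi = np.asarray(psi, dtype=float).copy()
    if phi.shape != (L,) or psi.shape != (L,):
        raise SequenceError("phi/psi must have one entry per residue")
    phi[0] = TORSION_UNDEFINED
    psi[L - 1] = TORSION_UNDEFINED
    defined = np.concatenate([phi[1:], psi[:-1]])
    if not np.all(np.isfinite(defined)):
        raise SequenceError("defined torsions must be finite")

    coords = np.zeros((L, 7, 3))
    # canonical frame for residue 0
    ang = np.deg2rad(ANGLE_N_CA_C)
    n_prev = (0.0, 0.0, 0.0)
    ca_prev = (BOND_N_CA, 0.0, 0.0)
    c_prev = (
        BOND_N_CA - BOND_CA_C * np.cos(ang), BOND_CA_C * np.sin(ang), 0.0
    )
    coords[0, N] = n_prev
    coords[0, CA] = ca_prev
    coords[0, C] = c_prev
    deg = np.pi / 180.0
    a_can = deg * ANGLE_CA_C_N
    a_cnca = deg * ANGLE_C_N_CA
    a_ncac = deg * ANGLE_N_CA_C
    omega = deg * OMEGA_TRANS
    phi_r = deg * phi
    psi_r = deg * psi
    for i in range(1, L):
        n_i = _place_scalar(n_prev, ca_prev, c_prev, BOND_C_N, a_can, psi_r[i - 1])
        ca_i = _place_scalar(ca_prev, c_prev, n_i, BOND_N_CA, a_cnca, omega)
        c_i = _place_scalar(c_prev, n_i, ca_i, BOND_CA_C, a_ncac, phi_r[i])
        coords[i, N] = n_i
        coords[i, CA] = ca_i
        coords[i, C] = c_i
        n_prev, ca_prev, c_prev = n_i, ca_i, c_i
    model = ProteinModel(sequence=sequence, phi=phi, psi=psi, coords=coords)
    place_pseudo_atoms(model)
    return model


def place_pseudo_atoms(model: ProteinModel) -> ProteinModel:
    """Attach H, O, CB and SC to an existing N/CA/C backbone (in place)."""
    L = len(model)
    coords = model.coords
    psi = model.psi
    deg = np.pi / 180.0
    a_caco = deg * ANGLE_CA_C_O
    a_cnh = deg * ANGLE_C_N_H
    a_ncacb = deg * ANGLE_N_CA_CB
    t_cb = deg * DIHEDRAL_C_N_CA_CB
    inv_cb = 1.0 / BOND_CA_CB
    for i in range(L):
        n_i = tuple(coords[i, N])
        ca_i = tuple(coords[i, CA])
        c_i = tuple(coords[i, C])
        # carbonyl O anti to the next N (dihedral psi + 180); the chain
        # terminus has no next N, so its O is placed as if the chain
        # continued in an extended conformation (implied psi = 120)
        tau_o = deg * ((psi[i] if i < L - 1 else 120.0) + 180.0)
        coords[i, O] = _place_scalar(n_i, ca_i, c_i, BOND_C_O, a_caco, tau_o)
        # amide H in the peptide plane, anti to the carbonyl O across C-N
        if i > 0:
            coords[i, H] = _place_scalar(
                tuple(coords[i - 1, CA]), tuple(coords[i - 1, C]), n_i,
                BOND_N_H, a_cnh, 0.0,
            )
        else:
            # N-terminus: no peptide plane; fixed placement off the C frame
            coords[i, H] = _place_scalar(c_i, ca_i, n_i, BOND_N_H, a_cnh, np.pi)
        aa = model.sequence[i]
        if aa == "G":
            coords[i, CB] = ca_i
            coords[i, SC] = ca_i
        else:
            cb_i = _place_scalar(c_i, n_i, ca_i, BOND_CA_CB, a_ncacb, t_cb)
            coords[i, CB] = cb_i
            f = SC_DISTANCE[aa] * inv_cb
            coords[i, SC] = (
                ca_i[0] + f * (cb_i[0] - ca_i[0]),
                ca_i[1] + f * (cb_i[1] - ca_i[1]),
                ca_i[2] + f * (cb_i[2] - ca_i[2]),
            )
    return model


def compute_torsions(coords: np.ndarray):
    """Backbone (phi, psi) in degrees from an (L, >=4, 3) coordinate array.

    Uses the N/CA/C slots only; undefined torsions carry the sentinel.
    """
    L = coords.shape[0]
    phi = np.full(L, TORSION_UNDEFINED)
    psi = np.full(L, TORSION_UNDEFINED)
    for i in range(L):
        if i > 0:
            phi[i] = dihedral(
                coords[i - 1, C], coords[i, N], coords[i, CA], coords[i, C]
            )
        if i < L - 1:
            psi[i] = dihedral(
                coords[i, N], coords[i, CA], coords[i, C], coords[i + 1, N]
            )
    return phi, psi


# ---------------------------------------------------------------------------
# torsion-space kinematics shared by the energy gradient

def torsion_vector(model_or_phi, psi=None) -> np.ndarray:
    """Pack defined torsions into the optimization vector (radians).

    Layout: [phi_1 .. phi_{L-1}, psi_0 .. psi_{L-2}], length 2L-2.
    """
    if psi is None:
        phi, psi = model_or_phi.phi, model_or_phi.psi
    else:
        phi = model_or_phi
    return np.deg2rad(np.concatenate([phi[1:], psi[:-1]]))


def torsions_from_vector(x: np.ndarray):
    """Inverse of :func:`torsion_vector`; returns (phi, psi) in degrees."""
    L = x.size // 2 + 1
    phi = np.full(L, TORSION_UNDEFINED)
    psi = np.full(L, TORSION_UNDEFINED)
    phi[1:] = np.rad2deg(x[: L - 1])
    psi[:-1] = np.rad2deg(x[L - 1 :])
    return phi, psi


def wrap_angles(x: np.ndarray) -> np.ndarray:
    """Wrap radians into (-pi, pi]."""
    out = -np.mod(-np.asarray(x) + np.pi, 2 * np.pi) + np.pi
    return out


def torsion_axes(coords: np.ndarray):
    """Rotation axes for every optimization variable.

    Returns (pivot, axis) arrays of shape (2L-2, 3): phi_i rotates about
    N_i -> CA_i, psi_i about CA_i -> C_i.
    """
    L = coords.shape[0]
    pivots = np.empty((2 * L - 2, 3))
    axes = np.empty((2 * L - 2, 3))
    # phi_1 .. phi_{L-1}
    dn = coords[1:, CA] - coords[1:, N]
    pivots[: L - 1] = coords[1:, N]
    axes[: L - 1] = dn / np.linalg.norm(dn, axis=1, keepdims=True)
    # psi_0 .. psi_{L-2}
    dc = coords[:-1, C] - coords[:-1, CA]
    pivots[L - 1 :] = coords[:-1, CA]
    axes[L - 1 :] = dc / np.linalg.norm(dc, axis=1, keepdims=True)
    return pivots, axes


def moving_mask(L: int) -> np.ndarray:
    """Boolean (L, 7, 2L-2) mask: does atom (res, slot) move with torsion t?

    Every atom of a residue downstream of the rotating bond moves.  Within
    the bond's own residue, phi additionally rotates C, O, CB and SC, and
    psi rotates the carbonyl O (anti to the next N by construction).
    """
    T = 2 * L - 2
    res = np.arange(L)
    mask = np.zeros((L, 7, T), dtype=bool)
    # phi torsions are variables 0..L-2 for residues 1..L-1
    phi_res = np.arange(1, L)
    mask[:, :, : L - 1] = res[:, None, None] > phi_res[None, None, :]
    same = res[:, None] == phi_res[None, :]
    for slot in (C, O, CB, SC):
        mask[:, slot, : L - 1] |= same
    # psi torsions are variables L-1..2L-3 for residues 0..L-2
    psi_res = np.arange(0, L - 1)
    mask[:, :, L - 1 :] = res[:, None, None] > psi_res[None, None, :]
    mask[:, O, L - 1 :] |= res[:, None] == psi_res[None, :]
    return mask


def cartesian_to_torsion_gradient(
    coords: np.ndarray, cart_grad: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Chain rule from a Cartesian gradient (L, 7, 3) to torsion space.

    For an atom a rigidly downstream of a rotating bond with unit axis e
    through pivot p, dx_a/dchi = e x (x_a - p); the contribution of a to
    dE/dchi is therefore e . ((x_a - p) x dE/dx_a).
    """
    L = coords.shape[0]
    if mask is None:
        mask = moving_mask(L)
    pivots, axes = torsion_axes(coords)  # (T, 3)
    flat_x = coords.reshape(-1, 3)  # (L*7, 3)
    flat_g = cart_grad.reshape(-1, 3)
    flat_m = mask.reshape(-1, mask.shape[-1])  # (L*7, T)
    # r = x_a - p_t  -> (A, T, 3); contribution e_t . (r x g_a)
    r = flat_x[:, None, :] - pivots[None, :, :]
    cr = np.cross(r, flat_g[:, None, :])
    contrib = np.einsum("atk,tk->at", cr, axes)
    return np.sum(contrib * flat_m, axis=0)
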