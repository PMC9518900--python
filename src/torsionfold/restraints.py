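"""Binned inter-residue restraints and their continuous spline potentials.

Predicted restraints arrive as per-pair probability histograms: 38-bin
distance maps for CB-CB and CA-CA pairs (one bin below 2 A, 36 bins of
0.5 A width over [2, 20), one bin for >= 20 A), 15-degree-wide bins for
the three inter-residue orientation angles (dihedrals omega and theta,
planar angle phi) with an extra "no interaction" bin, and a single
contact probability per pair.  The histograms are converted to energies
by a negative log-ratio against a reference bin and fitted with cubic
splines so that the folding energy is continuously differentiable.

Orientation angle conventions (on the CA/CB frames of a residue pair):
omega is the CA_i-CB_i-CB_j-CA_j dihedral (symmetric), theta the
N_i-CA_i-CB_i-CB_j dihedral and phi the CA_i-CB_i-CB_j planar angle
(both asymmetric).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

KINDS = (
    "cb_distance",
    "ca_distance",
    "omega",
    "theta",
    "phi_angle",
    "cb_contact",
    "ca_contact",
)
BINNED_KINDS = ("cb_distance", "ca_distance", "omega", "theta", "phi_angle")
DISTANCE_KINDS = ("cb_distance", "ca_distance")
DIHEDRAL_KINDS = ("omega", "theta")
CONTACT_KINDS = ("cb_contact", "ca_contact")
SYMMETRIC_KINDS = ("cb_distance", "ca_distance", "omega", "cb_contact", "ca_contact")

#: sequence-separation classes (short, medium, long); |i-j| <= 1 is excluded
RANGE_CLASSES = ("short", "medium", "long")

EPSILON = 1e-4  # probability floor guarding log(0)

#: contact-well first-well width d_b (A); matches the 8 A contact definition
DEFAULT_CONTACT_WELL = 8.0

#: orientation terms apply only where the no-interaction probability is low
NO_INTERACTION_CUTOFF = 0.5


class SchemaError(ValueError):
    """Unknown restraint kind or malformed schema."""


class RestraintValidationError(ValueError):
    """Histogram fails normalization/symmetry/shape checks."""


@dataclass(frozen=True)
class BinSchema:
    """Bin layout of one restraint channel."""

    kind: str
    edges: np.ndarray  # ordered boundaries, length n_value_bins + 1
    has_no_interaction_bin: bool

    @property
    def n_value_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def n_bins(self) -> int:
        return self.n_value_bins + int(self.has_no_interaction_bin)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def bin_schema(kind: str) -> BinSchema:
    """Bin schema for a restraint channel.

    Distances: 38 bins -- (-inf, 2), 36 x 0.5 A over [2, 20), [20, inf);
    the open end bins are given nominal edges 1.5 and 20.5 so that every
    bin has a finite center for spline knots.  Dihedrals: 24 x 15-degree
    bins over (-180, 180] plus a no-interaction bin.  Planar angle:
    12 x 15-degree bins over [0, 180] plus a no-interaction bin.
    """
    if kind in DISTANCE_KINDS:
        edges = np.concatenate([[1.5], np.arange(2.0, 20.0 + 0.25, 0.5), [20.5]])
        return BinSchema(kind, edges, has_no_interaction_bin=False)
    if kind in DIHEDRAL_KINDS:
        edges = np.arange(-180.0, 180.0 + 7.5, 15.0)
        return BinSchema(kind, edges, has_no_interaction_bin=True)
    if kind == "phi_angle":
        edges = np.arange(0.0, 180.0 + 7.5, 15.0)
        return BinSchema(kind, edges, has_no_interaction_bin=True)
    if kind in CONTACT_KINDS:
        return BinSchema(kind, np.array([0.0, DEFAULT_CONTACT_WELL]), False)
    raise SchemaError(f"unknown restraint kind {kind!r}")


@dataclass
class RestraintSet:
    """All restraint channels for one sequence of length L.

    ``tensors[kind]`` is (L, L, n_bins) for binned kinds and (L, L) for
    contacts.  Diagonal and |i-j| = 1 entries are never consumed.  For the
    orientation channels the no-interaction bin is stored last.
    """

    L: int
    tensors: dict = field(default_factory=dict)

    def validate(self, atol: float = 1e-5) -> None:
        for kind, t in self.tensors.items():
            schema = bin_schema(kind)
            if kind in CONTACT_KINDS:
                if t.shape != (self.L, self.L):
                    raise RestraintValidationError(f"{kind}: bad shape {t.shape}")
                if np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
                    raise RestraintValidationError(f"{kind}: probabilities outside [0,1]")
                continue
            if t.shape != (self.L, self.L, schema.n_bins):
                raise RestraintValidationError(f"{kind}: bad shape {t.shape}")
            if np.any(t < -1e-12):
                raise RestraintValidationError(f"{kind}: negative probability")
            mask = offdiag_mask(self.L)
            sums = t.sum(axis=2)[mask]
            if np.any(np.abs(sums - 1.0) > atol):
                raise RestraintValidationError(
                    f"{kind}: histograms not normalized (max dev "
                    f"{np.abs(sums - 1.0).max():.2e})"
                )
            if kind in SYMMETRIC_KINDS:
                if not np.allclose(t, np.swapaxes(t, 0, 1), atol=1e-6):
                    raise RestraintValidationError(f"{kind}: symmetry violated")

    def distance_confidence(self, kind: str = "cb_distance") -> np.ndarray:
        """Per-pair confidence: total probability mass below 20 A."""
        t = self.tensors[kind]
        return t[:, :, :-1].sum(axis=2)


def offdiag_mask(L: int, min_sep: int = 2) -> np.ndarray:
    """Boolean (L, L) mask of pairs with |i-j| >= min_sep."""
    i, j = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    return np.abs(i - j) >= min_sep


def range_class_of(sep: np.ndarray) -> np.ndarray:
    """0 = short (1 < s <= 11), 1 = medium (11 < s <= 23), 2 = long (> 23).

    Separations <= 1 get class -1 (excluded everywhere).
    """
    sep = np.abs(np.asarray(sep))
    out = np.full(sep.shape, -1, dtype=int)
    out[(sep > 1) & (sep <= 11)] = 0
    out[(sep > 11) & (sep <= 23)] = 1
    out[sep > 23] = 2
    return out


def histogram_to_energy(probabilities: np.ndarray, schema: BinSchema) -> np.ndarray:
    """Per-bin energies E_b = -log((p_b + eps) / (p_ref + eps)).

    The reference bin is the last distance bin (>= 20 A) for distance
    kinds and the no-interaction bin for orientation kinds.  For
    orientation kinds the returned energies cover only the value bins
    (the no-interaction bin itself carries no potential).
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0):
        raise RestraintValidationError("negative probabilities")
    ref = p[..., -1:]
    e = -np.log((p + EPSILON) / (ref + EPSILON))
    if schema.has_no_interaction_bin:
        return e[..., :-1]
    return e


class SplineBank:
    """Cubic splines for many pairs sharing one knot grid.

    Evaluates value and derivative for every pair at a per-pair abscissa
    in a single vectorized pass.  ``periodic`` banks wrap the abscissa
    into one period; distance banks extrapolate with a repulsive
    quadratic below the first knot and a slope that smoothly flattens to
    zero above the last knot.
    """

    #: curvature of the short-range repulsive continuation (energy / A^2)
    REPULSION_CURVATURE = 50.0
    #: distance beyond the last knot at which the extrapolation flattens (A)
    FLATTEN_SPAN = 1.75

    def __init__(self, knots: np.ndarray, energies: np.ndarray, periodic: bool = False):
        """``energies``: (n_pairs, n_knots) knot energies."""
        knots = np.asarray(knots, dtype=float)
        energies = np.atleast_2d(np.asarray(energies, dtype=float))
        if knots.size < 4:
            raise SchemaError("spline fitting needs at least 4 knots")
        self.periodic = periodic
        if periodic:
            self.period = knots[-1] + (knots[1] - knots[0]) - knots[0]
            knots = np.concatenate([knots, [knots[0] + self.period]])
            energies = np.concatenate([energies, energies[:, :1]], axis=1)
            bc = "periodic"
        else:
            bc = "natural"
        self.knots = knots
        cs = CubicSpline(knots, energies.T, axis=0, bc_type=bc)
        # PPoly coefficients (4, nseg, n_pairs) for direct per-pair evaluation
        self._coef = cs.c
        self.n_pairs = energies.shape[0]
        # terminal values/slopes for distance extrapolation
        dcs = cs.derivative()
        self._y0 = energies[:, 0]
        self._s0 = np.atleast_1d(np.asarray(dcs(knots[0])))
        self._yK = energies[:, -1]
        self._sK = np.atleast_1d(np.asarray(dcs(knots[-1])))

    def _eval_poly(self, x: np.ndarray):
        """Evaluate each pair's own piecewise cubic at its abscissa."""
        seg = np.clip(np.searchsorted(self.knots, x, side="right") - 1, 0,
                      len(self.knots) - 2)
        t = x - self.knots[seg]
        ar = np.arange(self.n_pairs)
        c3, c2, c1, c0 = (self._coef[k, seg, ar] for k in range(4))
        v = ((c3 * t + c2) * t + c1) * t + c0
        d = (3 * c3 * t + 2 * c2) * t + c1
        return v, d

    def evaluate(self, x: np.ndarray):
        """Energies and derivatives at per-pair abscissae ``x`` (n_pairs,)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_pairs,):
            raise ValueError(f"expected {self.n_pairs} abscissae, got {x.shape}")
        k0, kK = self.knots[0], self.knots[-1]
        if self.periodic:
            xw = k0 + np.mod(x - k0, self.period)
            return self._eval_poly(xw)
        v, d = self._eval_poly(np.clip(x, k0, kK))
        below = x < k0
        if np.any(below):
            dx = x[below] - k0  # negative
            a = self.REPULSION_CURVATURE
            v[below] = self._y0[below] + self._s0[below] * dx + a * dx * dx
            d[below] = self._s0[below] + 2 * a * dx
        above = x > kK
        if np.any(above):
            h = self.FLATTEN_SPAN
            t = np.minimum((x[above] - kK) / h, 1.0)
            # C1 ramp: slope decays linearly from s_K to 0 over [kK, kK+h]
            v[above] = self._yK[above] + self._sK[above] * h * (t - t * t / 2.0)
            d[above] = self._sK[above] * (1.0 - t)
        return v, d


@dataclass
class ChannelPotential:
    """Selected pairs of one channel with their spline bank."""

    kind: str
    pairs: np.ndarray  # (n, 2) residue indices
    range_class: np.ndarray  # (n,) 0/1/2
    bank: SplineBank


@dataclass
class ContactPotential:
    """Smooth flat-bottom contact wells for selected pairs.

    E(d) = -p * S(d) with S = 1 for d <= d_b, a cubic switch to 0 over
    [d_b, d_b + 1]; depth proportional to the predicted contact
    probability.
    """

    kind: str
    pairs: np.ndarray
    range_class: np.ndarray
    prob: np.ndarray
    well: float = DEFAULT_CONTACT_WELL

    def evaluate(self, d: np.ndarray):
        t = np.clip((d - self.well), 0.0, 1.0)
        s = 1.0 - (3 * t * t - 2 * t ** 3)
        ds = -(6 * t - 6 * t * t)
        inside = (d > self.well) & (d < self.well + 1.0)
        ds = np.where(inside, ds, 0.0)
        return -self.prob * s, -self.prob * ds


@dataclass
class SplinePotentialSet:
    """Continuous potentials for every channel after restraint selection."""

    L: int
    channels: dict = field(default_factory=dict)  # kind -> ChannelPotential
    contacts: dict = field(default_factory=dict)  # kind -> ContactPotential


def select_restraints(restraints: RestraintSet, policy) -> dict:
    """Boolean selection masks per distance channel.

    ``policy`` is ``("prob_cutoff", c)`` -- keep pairs whose confidence
    (probability mass below 20 A) exceeds c -- or
    ``("top_nl", n, range_class)`` -- keep the floor(n*L) most confident
    pairs within one sequence-separation class ("short"/"medium"/"long"/
    "all"), ties broken by (i, j) order.  Masks are symmetric and cover
    unordered pairs with |i-j| > 1.
    """
    L = restraints.L
    name = policy[0]
    masks = {}
    for kind in DISTANCE_KINDS:
        if kind not in restraints.tensors:
            continue
        conf = restraints.distance_confidence(kind)
        valid = offdiag_mask(L)
        iu, ju = np.triu_indices(L, k=2)
        if name == "prob_cutoff":
            c = policy[1]
            mask = (conf > c) & valid
            mask &= mask.T  # symmetric channels: same confidence both ways
        elif name == "top_nl":
            n, rclass = policy[1], policy[2]
            sep = ju - iu
            rc = range_class_of(sep)
            if rclass == "all":
                in_class = rc >= 0
            else:
                in_class = rc == RANGE_CLASSES.index(rclass)
            cand_i, cand_j = iu[in_class], ju[in_class]
            cand_conf = conf[cand_i, cand_j]
            keep = int(np.floor(n * L))
            # stable sort descending by confidence, ties by (i, j) order
            order = np.argsort(-cand_conf, kind="stable")[:keep]
            mask = np.zeros((L, L), dtype=bool)
            mask[cand_i[order], cand_j[order]] = True
            mask |= mask.T
        else:
            raise SchemaError(f"unknown selection policy {name!r}")
        masks[kind] = mask
    return masks


def fit_splines(
    restraints: RestraintSet, selection: dict, sequence: str | None = None
) -> SplinePotentialSet:
    """Fit per-pair spline potentials for the selected restraints.

    Distance channels use the masks in ``selection``; orientation
    channels are evaluated for pairs whose no-interaction probability is
    below :data:`NO_INTERACTION_CUTOFF` (intersected with the CB distance
    mask when present); contact channels keep pairs with contact
    probability > 0.5.  When ``sequence`` is given, orientation pairs
    involving glycine (degenerate CB frame) are dropped.
    """
    L = restraints.L
    out = SplinePotentialSet(L=L)
    cb_mask = selection.get("cb_distance")
    gly_ok = None
    if sequence is not None:
        not_gly = np.array([aa != "G" for aa in sequence.upper()])
        gly_ok = np.outer(not_gly, not_gly)

    for kind in DISTANCE_KINDS:
        if kind not in restraints.tensors or kind not in selection:
            continue
        schema = bin_schema(kind)
        mask = np.triu(selection[kind], k=2)
        pi, pj = np.nonzero(mask)
        if pi.size == 0:
            continue
        probs = restraints.tensors[kind][pi, pj]
        energies = histogram_to_energy(probs, schema)
        bank = SplineBank(schema.centers, energies, periodic=False)
        out.channels[kind] = ChannelPotential(
            kind, np.stack([pi, pj], axis=1), range_class_of(pj - pi), bank
        )

    for kind in ("omega", "theta", "phi_angle"):
        if kind not in restraints.tensors:
            continue
        schema = bin_schema(kind)
        t = restraints.tensors[kind]
        active = t[:, :, -1] < NO_INTERACTION_CUTOFF
        if cb_mask is not None:
            active &= cb_mask
        if gly_ok is not None:
            active &= gly_ok
        if kind == "omega":  # symmetric: evaluate each unordered pair once
            active = np.triu(active, k=2)
        else:
            active &= offdiag_mask(L)
        pi, pj = np.nonzero(active)
        if pi.size == 0:
            continue
        energies = histogram_to_energy(t[pi, pj], schema)
        bank = SplineBank(
            np.deg2rad(schema.centers), energies, periodic=kind in DIHEDRAL_KINDS
        )
        out.channels[kind] = ChannelPotential(
            kind, np.stack([pi, pj], axis=1), range_class_of(np.abs(pj - pi)), bank
        )

    for kind in CONTACT_KINDS:
        if kind not in restraints.tensors:
            continue
        p = restraints.tensors[kind]
        active = np.triu(p > 0.5, k=2)
        pi, pj = np.nonzero(active)
        if pi.size == 0:
            continue
        out.contacts[kind] = ContactPotential(
            kind,
            np.stack([pi, pj], axis=1),
            range_class_of(pj - pi),
            p[pi, pj].astype(float),
        )
    return out


# ---------------------------------------------------------------------------
# DFR v1 text container

def write_dfr(restraints: RestraintSet, path) -> None:
    """Write the "DFR v1" plain-text restraint container.

    One section per channel: header ``#kind L nbins symmetric`` followed
    by sparse records ``i j b p`` (0-based residue indices, bin index,
    probability).  Symmetric channels store i < j only; bins with zero
    probability are omitted.
    """
    with open(path, "w") as fh:
        fh.write("#DFR v1\n")
        for kind in KINDS:
            if kind not in restraints.tensors:
                continue
            t = restraints.tensors[kind]
            sym = int(kind in SYMMETRIC_KINDS)
            nbins = 1 if kind in CONTACT_KINDS else t.shape[2]
            fh.write(f"#{kind} {restraints.L} {nbins} {sym}\n")
            if kind in CONTACT_KINDS:
                iu, ju = np.nonzero(np.triu(t, k=2) > 0)
                for i, j in zip(iu, ju):
                    fh.write(f"{i} {j} 0 {t[i, j]:.6g}\n")
            else:
                if sym:
                    pi, pj = np.triu_indices(restraints.L, k=2)
                else:
                    m = offdiag_mask(restraints.L)
                    pi, pj = np.nonzero(m)
                for i, j in zip(pi, pj):
                    row = t[i, j]
                    for b in np.nonzero(row > 0)[0]:
                        fh.write(f"{i} {j} {b} {row[b]:.6g}\n")


def read_dfr(path) -> RestraintSet:
    """Read a DFR v1 file; validates histogram normalization."""
    tensors = {}
    L = None
    kind = None
    sym = False
    nbins = 0
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#DFR"):
            raise RestraintValidationError(f"{path}: not a DFR restraint file")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) != 4:
                    raise RestraintValidationError(
                        f"{path}:{lineno}: malformed section header"
                    )
                kind = parts[0]
                if kind not in KINDS:
                    raise RestraintValidationError(
                        f"{path}:{lineno}: unknown channel {kind!r}"
                    )
                L = int(parts[1])
                nbins = int(parts[2])
                sym = bool(int(parts[3]))
                expected = 1 if kind in CONTACT_KINDS else bin_schema(kind).n_bins
                if nbins != expected:
                    raise RestraintValidationError(
                        f"{path}:{lineno}: {kind} expects {expected} bins, got {nbins}"
                    )
                if kind in CONTACT_KINDS:
                    tensors[kind] = np.zeros((L, L))
                else:
                    tensors[kind] = np.zeros((L, L, nbins))
                continue
            if kind is None:
                raise RestraintValidationError(f"{path}:{lineno}: record before header")
            parts = line.split()
            i, j, b = int(parts[0]), int(parts[1]), int(parts[2])
            p = float(parts[3])
            if kind in CONTACT_KINDS:
                tensors[kind][i, j] = p
                if sym:
                    tensors[kind][j, i] = p
            else:
                tensors[kind][i, j, b] = p
                if sym:
                    tensors[kind][j, i, b] = p
    if L is None:
        raise RestraintValidationError(f"{path}: no channels found")
    rs = RestraintSet(L=L, tensors=tensors)
    # unnormalized rows are only an error where some mass was recorded;
    # fully absent pairs are treated as no-interaction patterns
    for k in list(rs.tensors):
        if k in CONTACT_KINDS:
            continue
        t = rs.tensors[k]
        sums = t.sum(axis=2)
        usable = offdiag_mask(L)
        empty = (sums == 0) & usable
        bad = (~empty) & (np.abs(sums - 1.0) > 1e-5) & usable
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise RestraintValidationError(
                f"{path}: channel {k} pair ({i},{j}) sums to {sums[i, j]:.6f}"
            )
        t[empty, -1] = 1.0  # absent pairs -> all mass in the reference bin
    return rs
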