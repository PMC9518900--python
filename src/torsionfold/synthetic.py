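"""Synthetic fixtures: toy native structures and restraints derived from them.

Stands in for a trained restraint-prediction network so the folding
pipeline can be exercised end to end.  Toy natives are ideal-torsion
constructions (helices, beta hairpins, helix bundles); restraints are
per-pair probability histograms obtained by discretizing a Gaussian
centred on the true geometry, with controllable sharpness (sigma),
noise (a fraction eta of pairs replaced by uninformative uniform
histograms) and coverage (a fraction 1 - kappa of pairs blanked to the
no-interaction pattern).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from torsionfold import geometry as geom
from torsionfold import restraints as rst
from torsionfold.geometry import CA, CB, N

FOLD_TYPES = ("helix", "hairpin", "helix_bundle", "mixed")

HELIX = (-57.0, -47.0)
STRAND = (-120.0, 120.0)
#: four-residue turn joining antiparallel strands; chosen clash-free
#: with cross-strand and end-to-end contacts
TURN = [(-120.0, 120.0), (45.0, -60.0), (-150.0, 30.0), (-120.0, 120.0)]
#: four-residue loop that packs consecutive helices without overlap
LOOP = [(0.0, -90.0), (90.0, -60.0), (-180.0, -120.0), (30.0, 120.0)]
#: helix-to-strand junction of the mixed topology (clash-free)
JUNCTION = [(-120.0, 90.0), (-30.0, -120.0), (-90.0, 60.0), (-120.0, -90.0)]


@dataclass
class FixtureSpec:
    """Recipe for one synthetic fixture."""

    length: int
    fold_type: str = "helix"
    sigma_distance: float = 0.5  # A
    sigma_angle: float = 10.0  # degrees
    noise: float = 0.0  # eta: fraction of pairs replaced by uniform noise
    coverage: float = 1.0  # kappa: fraction of pairs carrying signal
    jitter: float = 0.0  # optional torsion jitter (degrees, <= 5 recommended)
    seed: int = 0

    def __post_init__(self):
        if self.fold_type not in FOLD_TYPES:
            raise ValueError(f"unknown fold type {self.fold_type!r}")
        if self.sigma_distance <= 0 or self.sigma_angle <= 0:
            raise ValueError("sharpness sigma must be positive")
        if not 0.0 <= self.noise <= 1.0 or not 0.0 <= self.coverage <= 1.0:
            raise ValueError("noise and coverage must lie in [0, 1]")


def _torsion_plan(spec: FixtureSpec):
    """Per-residue ((phi, psi), ss_label) list for a fixture recipe."""
    L = spec.length
    kind = spec.fold_type

    def tag(tors, label):
        return [(t, label) for t in tors]

    if kind == "helix":
        if L < 5:
            raise ValueError("helix fixtures need length >= 5")
        return tag([HELIX] * L, "H")
    if L < 10:
        raise ValueError(f"{kind} fixtures need length >= 10")
    if kind == "hairpin":
        n_strand = (L - 4) // 2
        return (
            tag([STRAND] * n_strand, "E")
            + tag(TURN, "C")
            + tag([STRAND] * (L - 4 - n_strand), "E")
        )
    if kind == "helix_bundle":
        n_loop = len(LOOP)
        n_helix = (L - n_loop) // 2
        return (
            tag([HELIX] * n_helix, "H")
            + tag(LOOP, "C")
            + tag([HELIX] * (L - n_loop - n_helix), "H")
        )
    # mixed: one helix joined to a strand pair; the junction torsions
    # were chosen clash-free with the strand region packing back against
    # the helix
    n_helix = max(5, L // 3)
    rest = L - n_helix - 4
    n_strand = rest // 2
    plan = (
        tag([HELIX] * n_helix, "H")
        + tag(JUNCTION, "C")
        + tag([STRAND] * n_strand, "E")
        + tag([(-70.0, 140.0)] * (rest - 2 * n_strand), "C")
        + tag([STRAND] * n_strand, "E")
    )
    return plan[:L]


def secondary_structure(spec: FixtureSpec) -> str:
    """H/E/C string of a fixture; emulates a secondary-structure
    prediction for initializing folding runs."""
    return "".join(label for _, label in _torsion_plan(spec))


# a hydrophobic-ish default sequence pattern; avoids Gly/Pro so every
# residue carries a CB frame for the orientation channels
_SEQ_PATTERN = "AVLIFAVLMEKRDQSTYWHN"


def default_sequence(length: int) -> str:
    reps = -(-length // len(_SEQ_PATTERN))
    return (_SEQ_PATTERN * reps)[:length]


def make_toy_protein(spec: FixtureSpec, sequence: str | None = None) -> geom.ProteinModel:
    """Deterministic toy native built from ideal torsions (+ optional jitter)."""
    plan = [t for t, _ in _torsion_plan(spec)]
    L = spec.length
    phi = np.array([p for p, _ in plan])
    psi = np.array([s for _, s in plan])
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        phi = phi + rng.uniform(-spec.jitter, spec.jitter, L)
        psi = psi + rng.uniform(-spec.jitter, spec.jitter, L)
    if sequence is None:
        sequence = default_sequence(L)
    return geom.build_coordinates(sequence, phi, psi)


def _gaussian_histogram(value: float, edges: np.ndarray, sigma: float,
                        open_ended: bool) -> np.ndarray:
    """Probability mass of N(value, sigma) per bin.

    ``open_ended`` distance schemas route the tail mass below/above the
    finite edge span into the first/last bin.
    """
    cdf = norm.cdf(edges, loc=value, scale=sigma)
    p = np.diff(cdf)
    if open_ended:
        p[0] += cdf[0]
        p[-1] += 1.0 - cdf[-1]
    return p


def _wrapped_gaussian_histogram(value: float, edges: np.ndarray, sigma: float):
    """Wrapped normal over periodic angle bins (degrees, period 360)."""
    p = np.zeros(len(edges) - 1)
    for k in (-360.0, 0.0, 360.0):
        cdf = norm.cdf(edges, loc=value + k, scale=sigma)
        p += np.diff(cdf)
    return p


def restraints_from_structure(native: geom.ProteinModel,
                              spec: FixtureSpec) -> rst.RestraintSet:
    """Emulated network output: binned histograms around the true geometry.

    Distance histograms are Gaussians of width ``sigma_distance``
    discretized on the 38-bin schema; orientation histograms are wrapped
    Gaussians of width ``sigma_angle`` over the 15-degree bins scaled by
    (1 - p_no_interaction); contacts are smoothed indicators.  A seeded
    fraction ``noise`` of pairs is replaced by uniform histograms and a
    fraction ``1 - coverage`` is blanked to the no-interaction pattern.
    Glycine pairs never carry orientation signal.
    """
    if spec.sigma_distance <= 0:
        raise ValueError("sigma must be positive")
    L = len(native)
    rng = np.random.default_rng(spec.seed + 1)
    cb = native.cb_or_ca()
    ca = native.coords[:, CA]
    gly = np.array([aa == "G" for aa in native.sequence])

    dist_schema = rst.bin_schema("cb_distance")
    omega_schema = rst.bin_schema("omega")
    phi_schema = rst.bin_schema("phi_angle")

    tensors = {
        "cb_distance": np.zeros((L, L, 38)),
        "ca_distance": np.zeros((L, L, 38)),
        "omega": np.zeros((L, L, 25)),
        "theta": np.zeros((L, L, 25)),
        "phi_angle": np.zeros((L, L, 13)),
        "cb_contact": np.zeros((L, L)),
        "ca_contact": np.zeros((L, L)),
    }

    iu, ju = np.triu_indices(L, k=2)
    n_pairs = len(iu)
    u = rng.random(n_pairs)
    noisy = u < spec.noise
    blanked = (~noisy) & (rng.random(n_pairs) > spec.coverage)

    def no_interaction(i, j):
        for kind in ("cb_distance", "ca_distance"):
            tensors[kind][i, j, -1] = tensors[kind][j, i, -1] = 1.0
        for kind in ("omega", "theta", "phi_angle"):
            tensors[kind][i, j, -1] = tensors[kind][j, i, -1] = 1.0

    def uniform(i, j):
        for kind in ("cb_distance", "ca_distance"):
            tensors[kind][i, j] = tensors[kind][j, i] = 1.0 / 38
        tensors["omega"][i, j] = tensors["omega"][j, i] = 1.0 / 25
        tensors["theta"][i, j] = tensors["theta"][j, i] = 1.0 / 25
        tensors["phi_angle"][i, j] = tensors["phi_angle"][j, i] = 1.0 / 13
        tensors["cb_contact"][i, j] = tensors["cb_contact"][j, i] = 0.5
        tensors["ca_contact"][i, j] = tensors["ca_contact"][j, i] = 0.5

    coords = native.coords
    for k in range(n_pairs):
        i, j = int(iu[k]), int(ju[k])
        if noisy[k]:
            uniform(i, j)
            continue
        if blanked[k]:
            no_interaction(i, j)
            continue
        d_cb = float(np.linalg.norm(cb[j] - cb[i]))
        d_ca = float(np.linalg.norm(ca[j] - ca[i]))
        h_cb = _gaussian_histogram(d_cb, dist_schema.edges, spec.sigma_distance, True)
        h_ca = _gaussian_histogram(d_ca, dist_schema.edges, spec.sigma_distance, True)
        tensors["cb_distance"][i, j] = tensors["cb_distance"][j, i] = h_cb
        tensors["ca_distance"][i, j] = tensors["ca_distance"][j, i] = h_ca
        p_cb = norm.cdf(8.0, loc=d_cb, scale=spec.sigma_distance)
        p_ca = norm.cdf(8.0, loc=d_ca, scale=spec.sigma_distance)
        tensors["cb_contact"][i, j] = tensors["cb_contact"][j, i] = p_cb
        tensors["ca_contact"][i, j] = tensors["ca_contact"][j, i] = p_ca
        # no-interaction probability from the CB-distance tail beyond 20 A
        p_noint = float(h_cb[-1])
        for kind in ("omega", "theta", "phi_angle"):
            if gly[i] or gly[j]:
                tensors[kind][i, j, -1] = tensors[kind][j, i, -1] = 1.0
        if gly[i] or gly[j]:
            continue
        omega = geom.dihedral(coords[i, CA], coords[i, CB], coords[j, CB], coords[j, CA])
        h = _wrapped_gaussian_histogram(omega, omega_schema.edges, spec.sigma_angle)
        row = np.concatenate([(1.0 - p_noint) * h / h.sum(), [p_noint]])
        tensors["omega"][i, j] = tensors["omega"][j, i] = row
        for (a, b) in ((i, j), (j, i)):
            theta = geom.dihedral(coords[a, N], coords[a, CA], coords[a, CB], coords[b, CB])
            h = _wrapped_gaussian_histogram(theta, omega_schema.edges, spec.sigma_angle)
            tensors["theta"][a, b] = np.concatenate(
                [(1.0 - p_noint) * h / h.sum(), [p_noint]]
            )
            phia = geom.planar_angle(coords[a, CA], coords[a, CB], coords[b, CB])
            h = _gaussian_histogram(phia, phi_schema.edges, spec.sigma_angle, True)
            tensors["phi_angle"][a, b] = np.concatenate(
                [(1.0 - p_noint) * h / h.sum(), [p_noint]]
            )

    out = rst.RestraintSet(L=L, tensors=tensors)
    out.validate()
    return out


def standard_suite(seed: int = 0, lengths=None, fold_types=None,
                   sigma: float = 0.5, noise: float = 0.0,
                   coverage: float = 1.0):
    """The shipped 10-fixture suite: (spec, native, restraints) triples.

    Lengths 30-60 across helix, hairpin, bundle and mixed topologies.
    """
    if lengths is None:
        lengths = [30, 34, 38, 40, 44, 48, 50, 54, 58, 60]
    if fold_types is None:
        fold_types = [
            "helix", "hairpin", "helix_bundle", "mixed", "hairpin",
            "helix_bundle", "mixed", "helix", "helix_bundle", "mixed",
        ]
    suite = []
    for k, (L, ft) in enumerate(zip(lengths, fold_types)):
        spec = FixtureSpec(
            length=L, fold_type=ft, sigma_distance=sigma, noise=noise,
            coverage=coverage, seed=seed + k,
        )
        native = make_toy_protein(spec)
        restraints = restraints_from_structure(native, spec)
        suite.append((spec, native, restraints))
    return suite
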