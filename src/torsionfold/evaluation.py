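"""Model-quality metrics: TM-score, RMSD, distance MAE, contact precision.

All superpositions are sequence-dependent (fixed residue
correspondence).  TM-score uses the standard length normalization
d0 = 1.24 (L - 15)^(1/3) - 1.8 (floored at 0.5 A) and the usual
fragment-seeded iterative search: initial superpositions on contiguous
fragments of lengths L, L/2 and L/4, each refined by repeatedly
re-superposing on the residues currently within the inclusion cutoff
until the selected set reaches a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from torsionfold import geometry as geom
from torsionfold import restraints as rst
from torsionfold.geometry import CA


class MetricError(ValueError):
    pass


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    distances: np.ndarray
    rmsd: float
    tm_score: float | None = None


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares proper rotation + translation mapping P onto Q.

    Reflections are corrected, so the rotation determinant is +1.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise MetricError(f"point sets must match: {P.shape} vs {Q.shape}")
    if len(P) < 3:
        raise MetricError("need at least 3 points for superposition")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    Hm = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(Hm)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    dists = np.linalg.norm(moved - Q, axis=1)
    rmsd = float(np.sqrt(np.mean(dists**2)))
    return SuperpositionResult(R, t, dists, rmsd)


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    return kabsch_superpose(P, Q).rmsd


def tm_d0(L: int) -> float:
    if L > 15:
        return max(1.24 * (L - 15) ** (1.0 / 3.0) - 1.8, 0.5)
    return 0.5


def _tm_from_superposition(P, Q, sup, d0):
    moved = P @ sup.rotation.T + sup.translation
    d = np.linalg.norm(moved - Q, axis=1)
    return float(np.mean(1.0 / (1.0 + (d / d0) ** 2))), d


def tm_score(model_ca: np.ndarray, native_ca: np.ndarray,
             max_iter: int = 20) -> float:
    """Sequence-dependent TM-score of a model against its native.

    Accepts (L, 3) CA coordinate arrays or :class:`ProteinModel`s.
    """
    if isinstance(model_ca, geom.ProteinModel):
        model_ca = model_ca.coords[:, CA]
    if isinstance(native_ca, geom.ProteinModel):
        native_ca = native_ca.coords[:, CA]
    P = np.asarray(model_ca, dtype=float)
    Q = np.asarray(native_ca, dtype=float)
    if P.shape != Q.shape:
        raise MetricError(f"length mismatch: {P.shape} vs {Q.shape}")
    L = len(P)
    d0 = tm_d0(L)
    best = 0.0
    # inclusion cutoff for iterative refinement (never below 4.5 A so the
    # selected set cannot collapse for poor models)
    d_cut = max(d0, 4.5)
    for frag in {L, max(L // 2, 4), max(L // 4, 4)}:
        for start in range(0, L - frag + 1, max(1, frag // 2)):
            idx = np.arange(start, start + frag)
            prev = None
            for _ in range(max_iter):
                if len(idx) < 3:
                    break
                sup = kabsch_superpose(P[idx], Q[idx])
                score, d = _tm_from_superposition(P, Q, sup, d0)
                best = max(best, score)
                sel = np.nonzero(d < d_cut)[0]
                cut = d_cut
                while len(sel) < 3:
                    cut *= 1.5
                    sel = np.nonzero(d < cut)[0]
                if prev is not None and np.array_equal(sel, prev):
                    break
                prev = idx = sel
    return best


def superpose_models(model: geom.ProteinModel, native: geom.ProteinModel):
    """Full superposition report on CA atoms: RMSD plus TM-score."""
    P = model.coords[:, CA]
    Q = native.coords[:, CA]
    sup = kabsch_superpose(P, Q)
    sup.tm_score = tm_score(P, Q)
    return sup


def predicted_distances(restraints: rst.RestraintSet, kind: str = "cb_distance"):
    """Argmax-bin-center distance map (L, L); pairs predicted beyond 20 A
    or with no signal carry NaN."""
    schema = rst.bin_schema(kind)
    t = restraints.tensors[kind]
    amax = np.argmax(t, axis=2)
    centers = schema.centers
    dmap = centers[amax]
    dmap = np.where(amax == schema.n_bins - 1, np.nan, dmap)
    return dmap


def distance_mae(restraints: rst.RestraintSet, model: geom.ProteinModel,
                 n: float, range_class: str = "long",
                 kind: str = "cb_distance") -> float:
    """MAE between predicted (argmax-bin) and model distances on the top
    n*L most confident pairs of one separation class.

    If fewer than floor(n*L) pairs are available, all pairs in the class
    are used.
    """
    if restraints.L != len(model):
        raise MetricError("restraints/model length mismatch")
    sel = rst.select_restraints(restraints, ("top_nl", n, range_class))[kind]
    iu, ju = np.nonzero(np.triu(sel, k=2))
    if iu.size == 0:
        raise MetricError(f"no pairs available in class {range_class!r}")
    dmap = predicted_distances(restraints, kind)
    pred = dmap[iu, ju]
    pos = model.pair_atoms(kind)
    act = np.linalg.norm(pos[ju] - pos[iu], axis=1)
    ok = ~np.isnan(pred)
    if not np.any(ok):
        raise MetricError("no finite predicted distances among selected pairs")
    return float(np.mean(np.abs(pred[ok] - act[ok])))


def contact_precision(restraints: rst.RestraintSet, native: geom.ProteinModel,
                      n: int, kind: str = "cb_contact",
                      contact_cutoff: float = 8.0) -> float:
    """Precision of the top-n predicted long-range contacts.

    A predicted contact counts as correct when the native CB-CB distance
    (CA for glycine) is below 8 A.
    """
    if n <= 0:
        raise MetricError("n must be positive")
    L = restraints.L
    p = restraints.tensors[kind]
    iu, ju = np.triu_indices(L, k=2)
    rc = rst.range_class_of(ju - iu)
    long_i, long_j = iu[rc == 2], ju[rc == 2]
    if long_i.size == 0:
        raise MetricError("no long-range pairs for this length")
    probs = p[long_i, long_j]
    order = np.argsort(-probs, kind="stable")[:n]
    pos = native.cb_or_ca()
    d = np.linalg.norm(pos[long_j[order]] - pos[long_i[order]], axis=1)
    return float(np.mean(d < contact_cutoff))


def clash_count(model: geom.ProteinModel, cutoff_ratio: float = 0.6) -> int:
    """Non-bonded site pairs closer than cutoff_ratio * (R_a + R_b).

    Uses the same heavy-site list and 2-covalent-bond exclusions as the
    van-der-Waals term; a lightweight steric-quality indicator.
    """
    from torsionfold.energy import EnergyModel, WeightVector

    em = EnergyModel(model.sequence, None, WeightVector.default())
    flat = model.coords.reshape(-1, 3)
    diff = flat[em._vdw_flat_j] - flat[em._vdw_flat_i]
    d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    cutoff = cutoff_ratio * em._vdw_rclash / 0.85
    return int(np.sum(d < cutoff))
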