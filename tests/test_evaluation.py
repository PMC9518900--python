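"""Model-quality metrics against brute-force oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from torsionfold import evaluation as ev
from torsionfold import geometry as geom
from torsionfold import restraints as rst
from torsionfold import synthetic as syn
from torsionfold.geometry import CA


def random_rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(1 << 30)))
    return R.as_matrix(), rng.normal(size=3) * 10


def oracle_rmsd(P, Q):
    """Brute-force superposition: coarse Euler-angle grid + refinement."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def cost(angles):
        R = Rotation.from_euler("xyz", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1)))

    best = None
    for a in np.linspace(-np.pi, np.pi, 7):
        for b in np.linspace(-np.pi / 2, np.pi / 2, 5):
            for c in np.linspace(-np.pi, np.pi, 7):
                r = minimize(cost, [a, b, c], method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-12})
                if best is None or r.fun < best:
                    best = r.fun
    return best


class TestKabsch:
    def test_identity(self):
        P = np.random.default_rng(0).normal(size=(8, 3))
        assert ev.kabsch_rmsd(P, P) < 1e-12

    def test_rigid_transform_gives_zero(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(10, 3))
        R, t = random_rigid(rng)
        assert ev.kabsch_rmsd(P, P @ R.T + t) < 1e-9

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(6, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # reflection: optimal orthogonal map is improper
        sup = ev.kabsch_superpose(P, Q)
        assert abs(np.linalg.det(sup.rotation) - 1.0) < 1e-9

    def test_matches_brute_force_oracle(self):
        P = np.array(
            [[0.0, 0.0, 0.0], [1.7, 0.2, -0.4], [0.9, 2.1, 0.3],
             [-0.8, 1.0, 1.9]]
        )
        rng = np.random.default_rng(3)
        Q = P + rng.normal(0, 0.3, P.shape)
        assert abs(ev.kabsch_rmsd(P, Q) - oracle_rmsd(P, Q)) < 1e-6

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ev.MetricError):
            ev.kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


def oracle_tm(P, Q, max_iter=40):
    """Independent TM-score search: every contiguous seed fragment of the
    three canonical lengths, iterated to a selection fixed point."""
    L = len(P)
    d0 = max(1.24 * (L - 15) ** (1 / 3) - 1.8, 0.5) if L > 15 else 0.5
    d_cut = max(d0, 4.5)
    best = 0.0
    frags = sorted({L, max(L // 2, 4), max(L // 4, 4)})
    for frag in frags:
        for start in range(0, L - frag + 1):
            sel = list(range(start, start + frag))
            seen = set()
            for _ in range(max_iter):
                sup = ev.kabsch_superpose(P[sel], Q[sel])
                moved = P @ sup.rotation.T + sup.translation
                d = np.linalg.norm(moved - Q, axis=1)
                best = max(best, float(np.mean(1 / (1 + (d / d0) ** 2))))
                cut = d_cut
                new = np.nonzero(d < cut)[0].tolist()
                while len(new) < 3:
                    cut *= 1.5
                    new = np.nonzero(d < cut)[0].tolist()
                key = tuple(new)
                if key in seen:
                    break
                seen.add(key)
                sel = new
    return best


class TestTmScore:
    def test_identical_structures_score_one(self, hairpin20):
        assert ev.tm_score(hairpin20, hairpin20) == pytest.approx(1.0, abs=1e-12)

    def test_rigid_copy_scores_one(self, hairpin20):
        rng = np.random.default_rng(4)
        R, t = random_rigid(rng)
        moved = hairpin20.coords[:, CA] @ R.T + t
        assert ev.tm_score(moved, hairpin20.coords[:, CA]) > 1.0 - 1e-6

    def test_matches_exhaustive_seed_oracle(self):
        spec = syn.FixtureSpec(length=30, fold_type="mixed", seed=5)
        native = syn.make_toy_protein(spec)
        rng = np.random.default_rng(6)
        # a genuinely partial model: same fold with one distorted half
        phi = native.phi.copy()
        psi = native.psi.copy()
        phi[15:] = phi[15:] + rng.normal(0, 40, 15)
        psi[15:] = psi[15:] + rng.normal(0, 40, 15)
        model = geom.build_coordinates(native.sequence, phi, psi)
        P = model.coords[:, CA]
        Q = native.coords[:, CA]
        mine = ev.tm_score(P, Q)
        oracle = oracle_tm(P, Q)
        assert mine == pytest.approx(oracle, abs=1e-6)

    def test_at_least_global_superposition_bound(self):
        rng = np.random.default_rng(7)
        for seed in range(3):
            spec = syn.FixtureSpec(length=25, fold_type="hairpin", seed=seed,
                                   jitter=5.0)
            native = syn.make_toy_protein(spec)
            P = native.coords[:, CA] + rng.normal(0, 2.0, (25, 3))
            Q = native.coords[:, CA]
            sup = ev.kabsch_superpose(P, Q)
            d0 = ev.tm_d0(25)
            moved = P @ sup.rotation.T + sup.translation
            d = np.linalg.norm(moved - Q, axis=1)
            bound = float(np.mean(1 / (1 + (d / d0) ** 2)))
            assert ev.tm_score(P, Q) >= bound - 1e-12

    def test_symmetry(self):
        spec = syn.FixtureSpec(length=24, fold_type="hairpin", seed=8, jitter=4.0)
        a = syn.make_toy_protein(spec)
        spec2 = syn.FixtureSpec(length=24, fold_type="hairpin", seed=9, jitter=4.0)
        b = syn.make_toy_protein(spec2)
        t1 = ev.tm_score(a.coords[:, CA], b.coords[:, CA])
        t2 = ev.tm_score(b.coords[:, CA], a.coords[:, CA])
        assert t1 == pytest.approx(t2, abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ev.MetricError):
            ev.tm_score(np.zeros((10, 3)), np.zeros((12, 3)))


class TestDistanceMae:
    def test_zero_when_model_sits_at_bin_centers(self, bundle30):
        spec, native, restraints = bundle30
        # predicted argmax centers vs the native the restraints came from:
        # sharp histograms put every argmax in the native's own bin
        sharp = syn.FixtureSpec(length=30, fold_type="helix_bundle",
                                sigma_distance=0.05, seed=3)
        R = syn.restraints_from_structure(native, sharp)
        mae = ev.distance_mae(R, native, 2.0, "long")
        assert mae < 0.25  # within half a bin width

    def test_hand_built_table(self):
        L = 30
        t = np.zeros((L, L, 38))
        t[..., -1] = 1.0
        schema = rst.bin_schema("cb_distance")
        pairs = [(0, 25), (1, 27), (2, 29), (0, 28), (3, 27)]
        bins = [10, 12, 14, 16, 18]
        for (i, j), b in zip(pairs, bins):
            t[i, j] = t[j, i] = 0.0
            t[i, j, b] = t[j, i, b] = 0.9
            t[i, j, -1] = t[j, i, -1] = 0.1
        rs = rst.RestraintSet(L=L, tensors={"cb_distance": t})
        m = geom.build_coordinates("A" * L, np.full(L, -57.0), np.full(L, -47.0))
        cb = m.cb_or_ca()
        expect = np.mean(
            [
                abs(schema.centers[b] - np.linalg.norm(cb[j] - cb[i]))
                for (i, j), b in zip(pairs, bins)
            ]
        )
        mae = ev.distance_mae(rs, m, 2.0, "long")
        assert mae == pytest.approx(expect, abs=1e-12)

    def test_clamps_to_available_pairs(self, bundle30):
        spec, native, restraints = bundle30
        a = ev.distance_mae(restraints, native, 50.0, "long")
        b = ev.distance_mae(restraints, native, 1000.0, "long")
        assert a == b

    def test_mae_grows_with_noise_fraction(self):
        """Replacing restraint histograms with uninformative noise can
        only push the argmax-center MAE up."""
        spec0 = syn.FixtureSpec(length=34, fold_type="hairpin", seed=3)
        native = syn.make_toy_protein(spec0)
        maes = []
        for eta in (0.0, 0.3, 0.7):
            spec = syn.FixtureSpec(length=34, fold_type="hairpin",
                                   noise=eta, seed=3)
            R = syn.restraints_from_structure(native, spec)
            maes.append(ev.distance_mae(R, native, 2.0, "long"))
        assert all(b >= a - 1e-9 for a, b in zip(maes, maes[1:]))
        assert maes[-1] > maes[0]


class TestContactPrecision:
    def test_noise_free_restraints_score_one(self):
        # hairpin ends give several true long-range contacts; n is kept
        # within their count so perfect restraints score exactly 1
        spec = syn.FixtureSpec(length=34, fold_type="hairpin", seed=1)
        native = syn.make_toy_protein(spec)
        restraints = syn.restraints_from_structure(native, spec)
        assert ev.contact_precision(restraints, native, 5) == 1.0

    def test_far_predictions_score_zero(self):
        L = 30
        p = np.zeros((L, L))
        m = geom.build_coordinates("A" * L, np.full(L, -120.0), np.full(L, 120.0))
        # predict contacts on pairs that are far apart in the extended chain
        p[0, 29] = p[29, 0] = 0.9
        p[1, 28] = p[28, 1] = 0.8
        rs = rst.RestraintSet(L=L, tensors={"cb_contact": p})
        assert ev.contact_precision(rs, m, 2) == 0.0

    def test_matches_exhaustive_recount(self):
        rng = np.random.default_rng(10)
        L = 30
        p = rng.random((L, L))
        p = (p + p.T) / 2
        rs = rst.RestraintSet(L=L, tensors={"cb_contact": p})
        spec = syn.FixtureSpec(length=L, fold_type="mixed", seed=11)
        native = syn.make_toy_protein(spec)
        n = 10
        mine = ev.contact_precision(rs, native, n)
        # brute force recount
        cb = native.cb_or_ca()
        cand = [
            (p[i, j], i, j)
            for i in range(L)
            for j in range(i + 2, L)
            if j - i > 23
        ]
        cand.sort(key=lambda x: (-x[0], x[1], x[2]))
        hits = sum(
            1 for _, i, j in cand[:n] if np.linalg.norm(cb[j] - cb[i]) < 8.0
        )
        assert mine == hits / n

    def test_nonpositive_n_rejected(self, bundle30):
        _, native, restraints = bundle30
        with pytest.raises(ev.MetricError):
            ev.contact_precision(restraints, native, 0)


class TestClashCount:
    def test_ideal_helix_is_clash_free(self, helix12):
        assert ev.clash_count(helix12) == 0

    def test_overlap_detected_and_matches_recount(self):
        from torsionfold.energy import EnergyModel, WeightVector

        m = geom.build_coordinates("AAAA", np.full(4, -57.0), np.full(4, -47.0))
        m.coords[3] = m.coords[1] + 0.3  # collapse residue 4 onto residue 2
        count = ev.clash_count(m)
        em = EnergyModel(m.sequence, None, WeightVector.default())
        flat = m.coords.reshape(-1, 3)
        expect = 0
        for a, b, rc in zip(em._vdw_flat_i, em._vdw_flat_j, em._vdw_rclash):
            if np.linalg.norm(flat[a] - flat[b]) < 0.6 * rc / 0.85:
                expect += 1
        assert count >= 1
        assert count == expect

    def test_rigid_motion_invariance(self, hairpin20):
        rng = np.random.default_rng(12)
        R, t = random_rigid(rng)
        moved = geom.ProteinModel(
            sequence=hairpin20.sequence, phi=hairpin20.phi, psi=hairpin20.psi,
            coords=hairpin20.coords @ R.T + t,
        )
        assert ev.clash_count(moved) == ev.clash_count(hairpin20)
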