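"""Composite energy: weights, terms, gradients, weight search."""

import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from torsionfold import energy as en
from torsionfold import geometry as geom
from torsionfold import restraints as rst
from torsionfold import synthetic as syn
from torsionfold.geometry import CA


class TestWeightVector:
    def test_has_24_entries(self):
        w = en.WeightVector.default()
        assert w.values.shape == (24,)
        assert len(en.WEIGHT_NAMES) == 24

    def test_range_and_shape_validation(self):
        with pytest.raises(en.WeightError):
            en.WeightVector(np.zeros(23))
        with pytest.raises(en.WeightError):
            en.WeightVector(np.full(24, 26.0))
        with pytest.raises(en.WeightError):
            en.WeightVector(np.full(24, -0.1))

    def test_from_dict_rejects_unknown_names(self):
        with pytest.raises(en.WeightError):
            en.WeightVector.from_dict({"bogus": 1.0})


@pytest.fixture(scope="module")
def small_system():
    spec = syn.FixtureSpec(length=12, fold_type="hairpin", seed=2)
    native = syn.make_toy_protein(spec)
    restraints = syn.restraints_from_structure(native, spec)
    sel = rst.select_restraints(restraints, ("prob_cutoff", 0.3))
    pots = rst.fit_splines(restraints, sel, sequence=native.sequence)
    return native, restraints, pots


class TestTotalEnergy:
    def test_zero_weights_zero_total_terms_still_reported(self, small_system):
        native, _, pots = small_system
        w = en.WeightVector(np.zeros(24))
        bd = en.total_energy(native, pots, w)
        assert bd.total == 0.0
        assert set(bd.restraint_terms) == set(en.RESTRAINT_TERMS)
        assert any(np.any(v != 0) for v in bd.restraint_terms.values())
        assert bd.generic_terms["tor"] != 0.0

    def test_doubling_weights_doubles_total(self, small_system):
        native, _, pots = small_system
        w1 = en.WeightVector.default()
        w2 = en.WeightVector(w1.values * 2)
        t1 = en.total_energy(native, pots, w1).total
        t2 = en.total_energy(native, pots, w2).total
        assert abs(t2 - 2 * t1) < 1e-9 * max(1.0, abs(t1))

    def test_breakdown_sums_to_total(self, small_system):
        native, _, pots = small_system
        w = en.WeightVector.default()
        bd = en.total_energy(native, pots, w)
        assert abs(bd.total - bd.weighted_total(w)) < 1e-9 * abs(bd.total)

    def test_matches_per_pair_brute_force(self, small_system):
        """Distance-channel energies recomputed pair by pair with an
        independently constructed scipy spline."""
        native, restraints, pots = small_system
        w = en.WeightVector.default()
        bd = en.total_energy(native, pots, w)
        schema = rst.bin_schema("cb_distance")
        for kind, slot_fn in (
            ("cb_distance", lambda m: m.cb_or_ca()),
            ("ca_distance", lambda m: m.coords[:, CA]),
        ):
            ch = pots.channels[kind]
            pos = slot_fn(native)
            eps = rst.EPSILON
            total = np.zeros(3)
            for (i, j), rc in zip(ch.pairs, ch.range_class):
                p = restraints.tensors[kind][i, j]
                e_bins = -np.log((p + eps) / (p[-1] + eps))
                cs = CubicSpline(schema.centers, e_bins, bc_type="natural")
                d = np.linalg.norm(pos[j] - pos[i])
                total[rc] += cs(d)
            assert np.abs(bd.restraint_terms[kind] - total).max() < 1e-9

    def test_length_mismatch_rejected(self, small_system):
        _, _, pots = small_system
        with pytest.raises(en.WeightError):
            en.EnergyModel("A" * 20, pots, en.WeightVector.default())

    def test_term_independence(self, small_system):
        """Zeroing one weight changes only that term's contribution."""
        native, _, pots = small_system
        w = en.WeightVector.default()
        bd0 = en.total_energy(native, pots, w)
        w2 = w.replace("cb_distance.short", 0.0)
        bd1 = en.total_energy(native, pots, w2)
        for kind in en.RESTRAINT_TERMS:
            assert np.allclose(
                bd0.restraint_terms[kind], bd1.restraint_terms[kind]
            )
        delta = bd0.total - bd1.total
        expect = (
            w["cb_distance.short"] * bd0.restraint_terms["cb_distance"][0]
        )
        assert abs(delta - expect) < 1e-9


class TestVdw:
    def test_zero_for_well_separated_chain(self, extended12):
        assert en.vdw_energy(extended12) == 0.0

    def test_forced_overlap_matches_closed_form(self):
        # two residues pushed together via compressed torsions is awkward;
        # instead overlap two CA pseudo-atoms directly
        m = geom.build_coordinates("AA", [0.0, -120.0], [120.0, 0.0])
        em = en.EnergyModel(m.sequence, None, en.WeightVector.default())
        coords = m.coords.copy()
        # move residue 2 rigidly so its CA sits 1.0 A from CA of residue 1
        shift = coords[0, CA] + np.array([1.0, 0.0, 0.0]) - coords[1, CA]
        coords[1] += shift
        e = em._vdw(coords, None, 0.0, False)
        # brute-force recount with the same exclusions
        flat = coords.reshape(-1, 3)
        expect = 0.0
        for a, b, rc in zip(em._vdw_flat_i, em._vdw_flat_j, em._vdw_rclash):
            d = np.linalg.norm(flat[a] - flat[b])
            if d < rc:
                expect += (rc - d) ** 2
        assert expect > 0
        assert abs(e - expect) < 1e-9

    def test_penalty_nonincreasing_with_distance(self):
        rc = en.VDW_SIGMA * 2 * en.VDW_RADII[CA]
        d = np.linspace(0.5, rc + 1.0, 100)
        pen = np.where(d < rc, (rc - d) ** 2, 0.0)
        assert np.all(np.diff(pen) <= 1e-12)


class TestHbond:
    def test_extended_chain_has_no_hbonds(self, extended12):
        assert en.hbond_energy(extended12) == 0.0

    def test_helix_hbonds_beat_extended(self, helix12, extended12):
        e_helix = en.hbond_energy(helix12)
        e_ext = en.hbond_energy(extended12)
        assert e_helix < e_ext
        assert e_helix <= -5.0  # i,i+4 ladder: most residues bonded

    def test_rigid_motion_invariance(self, helix12):
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        moved = geom.ProteinModel(
            sequence=helix12.sequence,
            phi=helix12.phi,
            psi=helix12.psi,
            coords=helix12.coords @ Q.T + rng.normal(size=3),
        )
        assert abs(en.hbond_energy(moved) - en.hbond_energy(helix12)) < 1e-9


class TestTorsionSurface:
    def test_interpolates_grid_at_knots(self):
        surf = en.TORSION_TABLES["general"]
        kmin = np.unravel_index(np.argmin(surf.grid), surf.grid.shape)
        phi = -172.5 + 15.0 * kmin[0]
        psi = -172.5 + 15.0 * kmin[1]
        val, _, _ = surf.evaluate(phi, psi)
        assert abs(val[0] - surf.grid.min()) < 1e-10

    def test_disallowed_region_scores_higher_than_helix(self):
        surf = en.TORSION_TABLES["general"]
        bad, _, _ = surf.evaluate(60.0, -60.0)
        helical, _, _ = surf.evaluate(-57.0, -47.0)
        assert bad[0] > helical[0]

    def test_flat_table_contributes_nothing(self):
        surf = en.TorsionSurface(np.zeros((24, 24)))
        rng = np.random.default_rng(6)
        v, dphi, dpsi = surf.evaluate(
            rng.uniform(-180, 180, 20), rng.uniform(-180, 180, 20)
        )
        assert np.abs(v).max() < 1e-12
        assert np.abs(dphi).max() < 1e-12

    def test_periodic_continuity(self):
        surf = en.TORSION_TABLES["general"]
        v1, _, _ = surf.evaluate(-180.0, 35.0)
        v2, _, _ = surf.evaluate(180.0, 35.0)
        assert abs(v1[0] - v2[0]) < 1e-10


class TestGradient:
    def _fd_check(self, em, x, h=1e-5, tol=1e-4):
        _, g, _ = em.energy_and_grad(x)
        fd = np.empty_like(g)
        for k in range(len(x)):
            xp = x.copy()
            xp[k] += h
            xm = x.copy()
            xm[k] -= h
            fd[k] = (em.energy(xp) - em.energy(xm)) / (2 * h)
        scale = np.maximum(np.abs(fd), 1e-3)
        return np.max(np.abs(g - fd) / scale)

    def test_all_terms_match_finite_differences(self, small_system):
        native, _, pots = small_system
        em = en.EnergyModel(native.sequence, pots, en.WeightVector.default())
        rng = np.random.default_rng(0)
        x = geom.torsion_vector(native) + rng.normal(0, 0.25, 2 * len(native) - 2)
        assert self._fd_check(em, x) < 1e-4

    def test_flat_potentials_zero_gradient(self):
        m = geom.build_coordinates("AVLIF", np.zeros(5), np.zeros(5))
        em = en.EnergyModel(m.sequence, None, en.WeightVector(np.zeros(24)))
        _, g, _ = em.energy_and_grad(geom.torsion_vector(m))
        assert np.abs(g).max() == 0.0

    def test_single_pair_gradient_localized(self):
        """A lone CB-CB distance restraint only bends torsions between
        the two residues."""
        L = 10
        seq = "A" * L
        t = np.zeros((L, L, 38))
        t[..., -1] = 1.0
        i, j = 2, 7
        schema = rst.bin_schema("cb_distance")
        # broad harmonic-like well centred at 10 A so the gradient is
        # felt at typical chain geometries
        p = np.exp(-0.5 * ((schema.centers - 10.0) / 2.0) ** 2)
        p /= p.sum()
        t[i, j] = t[j, i] = p
        rs = rst.RestraintSet(L=L, tensors={"cb_distance": t})
        sel = rst.select_restraints(rs, ("prob_cutoff", 0.5))
        pots = rst.fit_splines(rs, sel, sequence=seq)
        w = en.WeightVector(np.zeros(24))
        for r in ("short", "medium", "long"):
            w = w.replace(f"cb_distance.{r}", 1.0)
        em = en.EnergyModel(seq, pots, w)
        rng = np.random.default_rng(8)
        x = np.deg2rad(-60.0) + rng.normal(0, 0.1, 2 * L - 2)
        _, g, _ = em.energy_and_grad(x)
        # variables: phi_1..phi_9 (idx 0..8), psi_0..psi_8 (idx 9..17)
        # torsions strictly outside [i, j] leave the i-j distance fixed
        active = np.zeros(2 * L - 2, dtype=bool)
        active[i : j] = True          # phi_{i+1} .. phi_j  (indices r-1)
        active[L - 1 + i : L - 1 + j] = True  # psi_i .. psi_{j-1}
        assert np.abs(g[~active]).max() < 1e-12
        assert np.any(np.abs(g[active]) > 1e-6)

    def test_rigid_motion_invariance_of_total(self, small_system):
        """Energies depend only on internal coordinates, so the first
        residue's canonical frame carries no information."""
        native, _, pots = small_system
        w = en.WeightVector.default()
        bd = en.total_energy(native, pots, w)
        rng = np.random.default_rng(9)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        moved = geom.ProteinModel(
            sequence=native.sequence, phi=native.phi, psi=native.psi,
            coords=native.coords @ Q.T + 5.0,
        )
        em = en.EnergyModel(native.sequence, pots, w)
        bd2, _ = em.evaluate_model(moved, want_grad=False)
        assert abs(bd.total - bd2.total) < 1e-9 * max(1.0, abs(bd.total))


def test_native_beats_random_conformations(small_system):
    native, _, pots = small_system
    em = en.EnergyModel(native.sequence, pots, en.WeightVector.default())
    e_native = em.energy(geom.torsion_vector(native))
    rng = np.random.default_rng(14)
    worse = 0
    for _ in range(100):
        x = rng.uniform(-np.pi, np.pi, 2 * len(native) - 2)
        if em.energy(x) > e_native:
            worse += 1
    assert worse == 100


class TestOptimizeWeights:
    def test_single_weight_toy_objective(self):
        target = 7.3

        def objective(w):
            return -(w["hb"] - target) ** 2

        w = en.optimize_weights(objective, names=("hb",))
        assert abs(w["hb"] - target) <= 0.02 + 1e-12

    def test_two_term_separable_matches_exhaustive(self):
        t1, t2 = 3.1, 11.7

        def objective(w):
            return -(w["hb"] - t1) ** 2 - (w["vdw"] - t2) ** 2

        w = en.optimize_weights(objective, names=("hb", "vdw"))
        # exhaustive 2-D search over the final-pass resolution
        grid = np.round(np.arange(0, 25.0001, 0.02), 10)
        best = max(
            ((-(a - t1) ** 2 - (b - t2) ** 2, a, b) for a in grid for b in grid),
        )
        assert abs(w["hb"] - best[1]) <= 0.02 + 1e-12
        assert abs(w["vdw"] - best[2]) <= 0.02 + 1e-12

    def test_requires_callable(self):
        with pytest.raises(en.WeightError):
            en.optimize_weights(None)
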