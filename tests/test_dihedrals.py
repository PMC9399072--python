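import numpy as np
import pytest

from phasefit.core import DihedralTerm, EnergyOptions, MMEvaluator, measure_dihedral
from phasefit.dihedrals import (
    DihedralGroup,
    apply_fit,
    augment_multiplicities,
    fit_group,
    fit_workflow,
    scan_baseline,
)
from phasefit.errors import EmptyFitError
from phasefit.formats import ScanTable
from phasefit.phases import assignment_from_decisions, predict_phases
from phasefit.synthetic import FixtureSpec, generate_scan, make_fixture


def _assignment(fx, params=None):
    return assignment_from_decisions(
        predict_phases(fx.system, params or fx.true_params))


def _truncate(scan, keep_rows):
    angles = scan.angles[keep_rows]
    return ScanTable(scan.driven, angles, scan.energies[keep_rows],
                     np.arange(len(keep_rows)),
                     [scan.frames[scan.frame_indices[r]] for r in keep_rows],
                     step=scan.step, scan_range=scan.scan_range,
                     origin=scan.origin)


class TestScanBaseline:
    def test_empty_group_equals_full_profile(self, chain_fixture):
        fx, scans = chain_fixture
        group = DihedralGroup("none", frozenset(), 0)
        base = scan_baseline(fx.system, fx.true_params, scans[0], group)
        ev = MMEvaluator(fx.system, fx.true_params)
        full = np.array([ev.energy(scans[0].row_coordinates(r)).total
                         for r in range(len(scans[0].energies))])
        np.testing.assert_allclose(base, full - full.min(), atol=1e-10)

    def test_all_types_zeroed_no_other_terms_is_zero(self, chain_fixture, all_types_group):
        fx, scans = chain_fixture
        opts = EnergyOptions(bonds=False, angles=False, impropers=False,
                             lj=False, coulomb=False)
        base = scan_baseline(fx.system, fx.true_params, scans[0],
                             all_types_group, opts)
        np.testing.assert_allclose(base, 0.0, atol=1e-12)

    def test_matches_generator_truth(self, chain_fixture, all_types_group):
        # oracle: the generator records the exact per-row decomposition
        fx, scans = chain_fixture
        scan = scans[0]
        base = scan_baseline(fx.system, fx.true_params, scan, all_types_group)
        truth_total = np.array([bd["total"] - bd["dihedral"]
                                for bd in scan.truth["breakdowns"]])
        # chain group contains every dihedral type, so non-group energy is
        # total minus all dihedral terms
        np.testing.assert_allclose(base, truth_total - truth_total.min(), atol=1e-8)


class TestFitGroup:
    def test_noiseless_recovery(self, chain_fixture, all_types_group):
        fx, scans = chain_fixture
        res = fit_group(fx.system, fx.start_params, scans, all_types_group,
                        _assignment(fx, fx.start_params))
        for key, terms in fx.true_params.dihedrals.items():
            for t in terms:
                assert res.fitted[(key, t.n)] == pytest.approx(t.k_phi, abs=1e-6)

    def test_target_equal_to_baseline_fits_zero(self, chain_fixture, all_types_group):
        fx, scans = chain_fixture
        scan = scans[0]
        base = scan_baseline(fx.system, fx.true_params, scan, all_types_group)
        flat = ScanTable(scan.driven, scan.angles, base, scan.frame_indices,
                         scan.frames, step=scan.step, scan_range=scan.scan_range)
        res = fit_group(fx.system, fx.true_params, [flat], all_types_group,
                        _assignment(fx))
        assert all(k == pytest.approx(0.0, abs=1e-8) for k in res.fitted.values())
        assert res.rmse_after == pytest.approx(0.0, abs=1e-8)

    def test_cutoff_equivalent_to_pre_truncation(self, chain_fixture, all_types_group):
        fx, scans = chain_fixture
        scan = scans[0]
        shifted = ScanTable(scan.driven, scan.angles, scan.energies + 0.0,
                            scan.frame_indices, scan.frames, step=scan.step,
                            scan_range=scan.scan_range)
        cutoff = 1.0
        rel = shifted.relative_energies()
        keep = [r for r in range(len(rel)) if rel[r] <= cutoff]
        assert 0 < len(keep) < len(rel), "cutoff must actually exclude rows"
        res_cut = fit_group(fx.system, fx.start_params, [shifted],
                            all_types_group, _assignment(fx, fx.start_params),
                            cutoff=cutoff)
        res_pre = fit_group(fx.system, fx.start_params, [_truncate(shifted, keep)],
                            all_types_group, _assignment(fx, fx.start_params),
                            cutoff=cutoff)
        assert res_cut.fitted == res_pre.fitted
        assert res_cut.rmse_after == res_pre.rmse_after
        assert res_cut.points_used == res_pre.points_used

    def test_rmse_never_increases(self, chain_fixture, all_types_group):
        fx, scans = chain_fixture
        res = fit_group(fx.system, fx.start_params, scans, all_types_group,
                        _assignment(fx, fx.start_params))
        assert res.rmse_after <= res.rmse_before + 1e-9

    def test_matches_brute_force_k_grid(self):
        # single term, single scan: NNLS optimum must match a 0..10 step
        # 0.01 grid search over k within grid resolution
        fx = make_fixture(FixtureSpec(template="chain", seed=9,
                                      simple_terms=True))
        quad = fx.rotatable[1]
        key = fx.system.dihedral_key(*quad)
        scan = generate_scan(fx, quad, scan_range=(-90, 90), step=10,
                             mode="rigid", seed=0)
        group = DihedralGroup("one", frozenset({key}), 0)
        start = fx.true_params.copy()
        term = start.dihedrals[key][0]
        start.set_dihedral_term(key, DihedralTerm(0.0, term.n, term.delta))
        assign = {(key, term.n): term.delta}
        res = fit_group(fx.system, start, [scan], group, assign)

        base = scan_baseline(fx.system, start, scan, group)
        rel = scan.relative_energies()
        keep = rel <= 10.0
        phis = np.array([measure_dihedral(scan.row_coordinates(r), quad)
                         for r in range(len(rel))])[keep]
        col = 1 + np.cos(np.radians(term.n * phis - term.delta))
        target = (rel - base)[keep]

        def sse(k):
            resid = target - k * col
            return np.sum((resid - resid.mean()) ** 2)

        grid = np.arange(0.0, 10.0, 0.01)
        k_grid = grid[np.argmin([sse(k) for k in grid])]
        assert res.fitted[(key, term.n)] == pytest.approx(k_grid, abs=0.01)

    def test_all_rows_excluded_raises(self, chain_fixture, all_types_group):
        fx, scans = chain_fixture
        with pytest.raises(EmptyFitError):
            fit_group(fx.system, fx.start_params, scans, all_types_group,
                      _assignment(fx, fx.start_params), cutoff=-1.0)

    def test_unidentifiable_term_keeps_incoming_value(self, chain_fixture):
        fx, scans = chain_fixture
        # fit a single-type group against a scan that does not move it
        other = fx.system.dihedral_key(*scans[0].driven[0])
        victim = next(k for k in fx.start_params.dihedrals if k != other)
        group = DihedralGroup("victim", frozenset({victim}), 0)
        # rigid scan of the other torsion leaves the victim's angle frozen
        rigid = generate_scan(fx, scans[0].driven[0], scan_range=(-60, 60),
                              step=10, mode="rigid", seed=0)
        res = fit_group(fx.system, fx.start_params, [rigid], group,
                        _assignment(fx, fx.start_params))
        incoming = {(victim, t.n): t.k_phi
                    for t in fx.start_params.dihedrals[victim]}
        for key_n, k in res.fitted.items():
            assert key_n in incoming
            assert k == pytest.approx(incoming[key_n])
        assert res.unidentifiable


class TestAugmentation:
    def test_exact_base_fit_accepts_nothing(self, chain_fixture, all_types_group):
        fx, scans = chain_fixture
        params, assign, base, trials = augment_multiplicities(
            fx.system, fx.true_params, scans, all_types_group, _assignment(fx))
        assert not any(t.accepted for t in trials)

    def test_recovers_missing_n4_delta0_term(self):
        fx = make_fixture(FixtureSpec(template="chain", seed=13, simple_terms=True))
        quad = fx.rotatable[1]
        key = fx.system.dihedral_key(*quad)
        truth = fx.true_params.copy()
        truth.set_dihedral_term(key, DihedralTerm(0.9, 4, 0.0))
        fx.true_params.dihedrals.clear()
        fx.true_params.dihedrals.update(truth.dihedrals)
        scan = generate_scan(fx, quad, scan_range=(-90, 90), step=10,
                             mode="rigid", seed=0)
        # starting params miss the n=4 term entirely
        start = truth.copy()
        start.dihedrals[key] = [t for t in start.dihedrals[key] if t.n != 4]
        group = DihedralGroup("one", frozenset({key}), 0)
        assign = {(key, t.n): t.delta for t in start.dihedrals[key]}
        params, assign2, base, trials = augment_multiplicities(
            fx.system, start, [scan], group, assign, accept_threshold=0.10)
        added = [t for t in params.dihedrals[key] if t.n == 4]
        assert added and added[0].delta == 0.0
        assert added[0].k_phi == pytest.approx(0.9, abs=1e-4)

    def test_greedy_best_first(self, chain_fixture, all_types_group):
        fx, scans = chain_fixture
        params, assign, base, trials = augment_multiplicities(
            fx.system, fx.start_params, scans, all_types_group,
            _assignment(fx, fx.start_params), accept_threshold=0.05)
        accepted = [t for t in trials if t.accepted]
        # each accepted trial was the best of its round
        for t in accepted:
            assert t.rmse <= min(x.rmse for x in trials)  # final best is global
            break

    def test_augmentation_never_increases_rmse(self, chain_fixture, all_types_group):
        fx, scans = chain_fixture
        _p, _a, base, trials = augment_multiplicities(
            fx.system, fx.start_params, scans, all_types_group,
            _assignment(fx, fx.start_params))
        first = fit_group(fx.system, fx.start_params, scans, all_types_group,
                          _assignment(fx, fx.start_params))
        assert base.rmse_after <= first.rmse_after + 1e-9


class TestFitWorkflow:
    def test_fixed_point_on_noiseless_data(self, chain_fixture, all_types_group):
        fx, scans = chain_fixture
        keys = sorted({fx.system.dihedral_key(*q) for q in fx.system.dihedral_instances})
        assign = _assignment(fx, fx.start_params)
        p1, _ = fit_workflow(fx.system, fx.start_params, scans,
                             [all_types_group], assign, iterations=1)
        p2, _ = fit_workflow(fx.system, fx.start_params, scans,
                             [all_types_group], assign, iterations=2)
        for key in keys:
            for t1, t2 in zip(p1.dihedrals[key], p2.dihedrals[key]):
                assert t1.k_phi == pytest.approx(t2.k_phi, abs=1e-8)

    def test_iteration2_rmse_not_worse(self, fused45_fixture):
        fx, scans = fused45_fixture
        groups = fx.default_groups()
        assign = _assignment(fx, fx.start_params)
        _p, history = fit_workflow(fx.system, fx.start_params, scans, groups,
                                   assign, iterations=2)
        by_group: dict = {}
        for it, name, res in history:
            by_group.setdefault(name, []).append(res.rmse_after)
        for name, rmses in by_group.items():
            assert rmses[-1] <= rmses[0] + 1e-9, name

    def test_double_bond_group_fitted_first_wins_largest_k(self):
        # cephem-like check: with the double-bond group ranked first, the
        # largest ring force constant lands on the double bond
        fx = make_fixture(FixtureSpec(template="fused46", seed=3,
                                      perturb_params=True,
                                      perturb_scope="dihedral-only"))
        seen, scans = set(), []
        for q in fx.system.dihedral_instances:
            key = fx.system.dihedral_key(*q)
            if key in seen:
                continue
            seen.add(key)
            ring4 = next((r for r in fx.rings if len(r) == 4), frozenset())
            rng_, st = ((-45, 45), 5) if all(x in ring4 for x in q) else ((-60, 60), 10)
            scans.append(generate_scan(fx, q, scan_range=rng_, step=st,
                                       mode="relaxed", seed=5))
        groups = fx.default_groups()
        assert groups[0].name == "double-bond"
        assign = _assignment(fx, fx.start_params)
        final, _hist = fit_workflow(fx.system, fx.start_params, scans, groups,
                                    assign, iterations=2)
        db_keys = groups[0].members
        ring_keys = db_keys | next(g.members for g in groups if g.name == "fused")
        best_key = max(ring_keys,
                       key=lambda k: max(t.k_phi for t in final.dihedrals[k]))
        assert best_key in db_keys

    def test_groups_must_be_disjoint(self, chain_fixture):
        fx, scans = chain_fixture
        key = fx.system.dihedral_key(*fx.system.dihedral_instances[0])
        g1 = DihedralGroup("a", frozenset({key}), 0)
        g2 = DihedralGroup("b", frozenset({key}), 1)
        with pytest.raises(ValueError, match="disjoint"):
            fit_workflow(fx.system, fx.start_params, scans, [g1, g2],
                         _assignment(fx, fx.start_params))


class TestTwofoldSymmetryRule:
    def test_carboxylate_forced_to_n2(self):
        from phasefit.dihedrals import apply_twofold_symmetry_rule
        fx = make_fixture(FixtureSpec(template="fused45-carboxylate", seed=2))
        params, changed = apply_twofold_symmetry_rule(
            fx.true_params, fx.system, fx.carboxylate_terminal_type)
        target_keys = [k for k in params.dihedrals
                       if fx.carboxylate_terminal_type in (k[0], k[3])
                       and fx.system.instances_of_dihedral_type(k)]
        assert target_keys
        for key in target_keys:
            assert [t.n for t in params.dihedrals[key]] == [2]
        # idempotent, and other types untouched
        params2, changed2 = apply_twofold_symmetry_rule(
            params, fx.system, fx.carboxylate_terminal_type)
        assert changed2 == []
        for key in params.dihedrals:
            if key not in target_keys:
                assert params.dihedrals[key] == fx.true_params.dihedrals[key]


class TestRecoveryProperty:
    @pytest.mark.parametrize("seed", range(5))
    def test_noiseless_recovery_many_seeds(self, seed):
        fx = make_fixture(FixtureSpec(template="chain", seed=100 + seed,
                                      perturb_params=True,
                                      perturb_scope="dihedral-only"))
        scans = [generate_scan(fx, q, scan_range=(-90, 90), step=10,
                               mode="rigid", seed=seed) for q in fx.rotatable]
        keys = {fx.system.dihedral_key(*q) for q in fx.system.dihedral_instances}
        group = DihedralGroup("all", frozenset(keys), 0)
        res = fit_group(fx.system, fx.start_params, scans, group,
                        _assignment(fx, fx.start_params))
        for key, terms in fx.true_params.dihedrals.items():
            for t in terms:
                assert res.fitted[(key, t.n)] == pytest.approx(t.k_phi, abs=1e-4)
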