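import math

import numpy as np
import pytest

from dendrocable.fixtures import (
    make_passive_config,
    make_single_cylinder,
    make_y_tree,
)
from dendrocable.model import Model
from dendrocable.morphology import (
    build_segments,
    read_swc,
    split_to_sections,
    write_swc,
)
from dendrocable.reduction import (
    EquivalentCylinder,
    ImpedancePair,
    PassiveProps,
    _cylinder_pair,
    equivalent_cylinder,
    fit_reduced_distribution,
    map_channel_values,
    reduce_all_stems,
    reduce_subtree,
    subtree_impedances,
)

PASSIVES = PassiveProps(Rm=1e4, Cm=1.0, Ra=150.0)


def cylinder_sectree(L=500.0, d=2.0):
    return split_to_sections(read_swc(make_single_cylinder(L, d, n_points=11)))


class TestImpedances:
    def test_single_cylinder_matches_cable_closed_form(self):
        """Sealed cylinder: Z00 = R∞·coth(L/λ), Z0L = Z00/cosh(L/λ)."""
        L, d = 500.0, 2.0
        pair = subtree_impedances(cylinder_sectree(L, d), 0, PASSIVES, 0.0)
        d_cm = d * 1e-4
        lam = math.sqrt(PASSIVES.Rm * d_cm / (4 * PASSIVES.Ra))
        r_inf = (2 / math.pi) * math.sqrt(PASSIVES.Rm * PASSIVES.Ra) * d_cm**-1.5
        lhat = L * 1e-4 / lam
        z00 = r_inf / math.tanh(lhat) * 1e-6
        assert pair.Z00 == pytest.approx(z00, rel=1e-9)
        assert pair.Z0L == pytest.approx(z00 / math.cosh(lhat), rel=1e-9)

    def test_short_cable_limit_z0l_near_z00(self):
        pair = subtree_impedances(cylinder_sectree(L=1.0), 0, PASSIVES, 0.0)
        assert pair.Z0L == pytest.approx(pair.Z00, rel=1e-4)

    def test_symmetric_y_parallel_composition(self):
        """|Z00| of a symmetric Y equals the stem composed with half the
        single-branch input impedance."""
        swc = make_y_tree(stem_length=100.0, branch_length=150.0,
                          stem_diam=2.0, branch_diam=1.4)
        sectree = split_to_sections(read_swc(swc))
        stem_idx = next(
            s.idx for s in sectree.sections if s.domain == "apical" and s.children
        )
        pair = subtree_impedances(sectree, stem_idx, PASSIVES, 0.0)

        # independent oracle: closed-form branch Zin, halved, loaded stem
        def zin_sealed(L, d):
            d_cm = d * 1e-4
            lam = math.sqrt(PASSIVES.Rm * d_cm / (4 * PASSIVES.Ra))
            r_inf = (2 / math.pi) * math.sqrt(PASSIVES.Rm * PASSIVES.Ra) * d_cm**-1.5
            return r_inf / math.tanh(L * 1e-4 / lam)

        def zin_loaded(L, d, z_load):
            d_cm = d * 1e-4
            lam = math.sqrt(PASSIVES.Rm * d_cm / (4 * PASSIVES.Ra))
            r_inf = (2 / math.pi) * math.sqrt(PASSIVES.Rm * PASSIVES.Ra) * d_cm**-1.5
            lh = L * 1e-4 / lam
            th = math.tanh(lh)
            return r_inf * (z_load + r_inf * th) / (r_inf + z_load * th)

        z_branch = zin_sealed(150.0, 1.4) / 2.0
        z_total = zin_loaded(100.0, 2.0, z_branch) * 1e-6
        assert pair.Z00 == pytest.approx(z_total, rel=1e-6)

    def test_transfer_bounded_by_input(self):
        for L in (50.0, 300.0, 1500.0):
            pair = subtree_impedances(cylinder_sectree(L), 0, PASSIVES, 0.0)
            assert pair.Z0L <= pair.Z00

    def test_zero_diameter_rejected(self):
        text = "1 4 0 0 0 1 -1\n2 4 100 0 0 1 1"
        sectree = split_to_sections(read_swc(text))
        sectree.sections[0]._radii = np.array([0.0, 0.0])
        with pytest.raises(ValueError, match="diameter"):
            subtree_impedances(sectree, 0, PASSIVES, 0.0)


class TestEquivalentCylinder:
    def test_round_trip_recovery(self):
        d, L = 1.7, 640.0
        z00, z0l = _cylinder_pair(d, L, PASSIVES, 0.0)
        cyl = equivalent_cylinder(ImpedancePair(z00, z0l, 0.0), PASSIVES)
        assert cyl.diam == pytest.approx(d, rel=1e-3)
        assert cyl.length == pytest.approx(L, rel=1e-3)

    def test_round_trip_at_nonzero_frequency(self):
        d, L = 2.0, 400.0
        omega = 2 * math.pi * 100.0 / 1000.0  # 100 Hz in rad/ms
        z00, z0l = _cylinder_pair(d, L, PASSIVES, omega)
        cyl = equivalent_cylinder(ImpedancePair(z00, z0l, omega), PASSIVES)
        assert cyl.diam == pytest.approx(d, rel=1e-3)
        assert cyl.length == pytest.approx(L, rel=1e-3)

    def test_self_consistency_for_tree_pair(self):
        """The defining contract: the produced cylinder reproduces the
        subtree's impedance pair."""
        swc = make_y_tree()
        sectree = split_to_sections(read_swc(swc))
        stem = next(
            s.idx for s in sectree.sections if s.domain == "apical" and s.children
        )
        pair = subtree_impedances(sectree, stem, PASSIVES, 0.0)
        cyl = equivalent_cylinder(pair, PASSIVES)
        z00, z0l = _cylinder_pair(cyl.diam, cyl.length, PASSIVES, 0.0)
        assert z00 == pytest.approx(pair.Z00, rel=1e-6)
        assert z0l == pytest.approx(pair.Z0L, rel=1e-6)

    def test_degenerate_pair_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            equivalent_cylinder(ImpedancePair(100.0, 100.0, 0.0), PASSIVES)
        with pytest.raises(ValueError):
            ImpedancePair(100.0, 150.0, 0.0)


class TestReduceSubtree:
    @pytest.fixture()
    def y_stree(self):
        return build_segments(
            split_to_sections(read_swc(make_y_tree())), d_lambda=0.1,
            Ra=PASSIVES.Ra, cm=PASSIVES.Cm,
        )

    def test_soma_reduction_rejected(self, y_stree):
        with pytest.raises(ValueError, match="soma"):
            reduce_subtree(y_stree, 0, PASSIVES)

    def test_unbranched_identity(self):
        """Reducing a single-cylinder subtree reproduces it closely."""
        lines = ["1 1 0 0 0 10 -1", "2 4 0 0 0 1 1", "3 4 250 0 0 1 2",
                 "4 4 500 0 0 1 3"]
        stree = build_segments(
            split_to_sections(read_swc("\n".join(lines))), d_lambda=0.1,
            Ra=PASSIVES.Ra, cm=PASSIVES.Cm,
        )
        model = reduce_subtree(stree, 1, PASSIVES)
        # SWC stores radii: r=1 µm -> a 2 µm diameter, 500 µm cable
        assert model.cylinder.diam == pytest.approx(2.0, rel=0.01)
        assert model.cylinder.length == pytest.approx(500.0, rel=0.01)

    def test_idempotence(self, y_stree):
        stem = next(
            s.idx for s in y_stree.sectree.sections
            if s.domain == "apical" and s.children
        )
        first = reduce_subtree(y_stree, stem, PASSIVES)
        again = reduce_subtree(first.stree, first.reduced_section, PASSIVES)
        assert again.cylinder.diam == pytest.approx(first.cylinder.diam, rel=1e-3)
        assert again.cylinder.length == pytest.approx(first.cylinder.length, rel=1e-3)

    def test_map_covers_all_original_segments(self, y_stree):
        stem = next(
            s.idx for s in y_stree.sectree.sections
            if s.domain == "apical" and s.children
        )
        sub_secs = set()
        stack = [stem]
        while stack:
            i = stack.pop()
            sub_secs.add(i)
            stack.extend(y_stree.sectree.sections[i].children)
        n_subtree = sum(len(y_stree.section_segments[i]) for i in sub_secs)
        model = reduce_subtree(y_stree, stem, PASSIVES)
        assert len(model.rmap.coordinate) == n_subtree
        assert sum(len(b) for b in model.rmap.bins) == n_subtree
        assert all(0 <= c <= 1 for c in model.rmap.coordinate.values())

    def test_all_stems_gives_ball_and_stick(self, y_stree):
        models = reduce_all_stems(y_stree, PASSIVES)
        final = models[-1].sectree
        stems = [s for s in final.sections if s.parent == 0]
        assert all(not final.sections[c.idx].children for c in stems)
        assert len(final.sections) == 2  # soma + one cylinder

    def test_somatic_input_resistance_preserved(self, y_stree, toy_channels):
        cfg = make_passive_config(g_leak=1 / PASSIVES.Rm, e_leak=-65.0,
                                  Ra=PASSIVES.Ra)

        def rin(swc_text):
            m = Model(swc_text, cfg, channels=toy_channels, d_lambda=0.1)
            tr = m.run_step(-0.05, delay=20, duration=300, tstop=340)["v@0"]
            from dendrocable.protocols import input_resistance

            return input_resistance(tr, -0.05, 20.0, 320.0)

        r_before = rin(make_y_tree())
        models = reduce_all_stems(y_stree, PASSIVES)
        r_after = rin(write_swc(models[-1].ptree))
        assert r_after == pytest.approx(r_before, rel=0.05)


class TestChannelMapping:
    def test_uniform_stays_uniform(self):
        from dendrocable.reduction import ReductionMap

        rmap = ReductionMap(
            coordinate={i: i / 10 for i in range(10)},
            bins=[[0, 1, 2], [3, 4], [5, 6], [7, 8, 9]],
        )
        vals = map_channel_values(rmap, {i: 0.5 for i in range(10)})
        assert vals == pytest.approx(np.full(4, 0.5))

    def test_linear_gradient_bin_means(self):
        from dendrocable.reduction import ReductionMap

        original = {i: float(i) for i in range(12)}
        bins = [[0, 1, 2], [3, 4, 5], [6, 7, 8], [9, 10, 11]]
        rmap = ReductionMap(coordinate={}, bins=bins)
        vals = map_channel_values(rmap, original)
        assert vals == pytest.approx([1.0, 4.0, 7.0, 10.0])

    def test_hot_spot_preserved_and_gaps_interpolated(self):
        from dendrocable.reduction import ReductionMap

        original = {i: (10.0 if 4 <= i <= 6 else 0.0) for i in range(10)}
        bins = [[0, 1], [2, 3], [4, 5, 6], [], [7, 8, 9]]
        rmap = ReductionMap(coordinate={}, bins=bins)
        vals = map_channel_values(rmap, original)
        assert vals[2] == pytest.approx(10.0)  # hot spot at its bin
        assert vals[0] == vals[1] == 0.0
        assert 0.0 < vals[3] < 10.0  # empty bin interpolated


class TestDistributionRefit:
    def test_constant_data_selects_constant(self):
        d = np.linspace(0, 100, 20)
        fn, mse = fit_reduced_distribution(d, np.full_like(d, 3.0))
        assert fn.kind == "constant"
        assert mse == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_beats_cubic_by_complexity(self):
        d = np.linspace(0, 100, 25)
        y = 0.02 * d + 1.0
        fn, mse = fit_reduced_distribution(d, y)
        assert fn.kind == "linear"
        assert fn.coeffs["slope"] == pytest.approx(0.02)

    def test_noisy_step_recovered(self):
        rng = np.random.default_rng(11)
        d = np.linspace(0, 300, 61)
        y = np.where((d >= 100) & (d <= 200), 5.0, 1.0) + rng.normal(0, 0.05, d.size)
        fn, _mse = fit_reduced_distribution(d, y)
        assert fn.kind == "step"
        spacing = d[1] - d[0]
        assert fn.coeffs["d_start"] == pytest.approx(100.0, abs=spacing)
        assert fn.coeffs["d_end"] == pytest.approx(200.0, abs=spacing)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_reduced_distribution([1.0], [2.0])
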