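"""EHH engine: worked examples, brute-force oracle, decay properties."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import mlgscan as m
from mlgscan.ehh import EHHCurve, ExtensionPolicy
from tests.conftest import random_genotype_matrix


def brute_homozygosity(values, lo, hi, cols):
    """Independent oracle: hash the full substring per sequence."""
    strings = [values[lo : hi + 1, i].tobytes() for i in cols]
    counts = Counter(strings)
    n = len(cols)
    return sum(c * c for c in counts.values()) / (n * n)


def brute_ehh_full(values, core, extent):
    lo, hi = sorted((core, extent))
    return brute_homozygosity(values, lo, hi, range(values.shape[1]))


def brute_ehh_core(values, core, c, extent):
    lo, hi = sorted((core, extent))
    cols = np.nonzero(values[core] == c)[0]
    return brute_homozygosity(values, lo, hi, cols)


def brute_cehh_core(values, core, c, extent):
    lo, hi = sorted((core, extent))
    cols = np.nonzero(values[core] != c)[0]
    return brute_homozygosity(values, lo, hi, cols)


class TestWorkedExamples:
    def test_full_sample_at_core(self, example_genotypes):
        assert m.ehh_full(example_genotypes, 0, 0) == pytest.approx(14 / 36)

    def test_full_sample_extended(self, example_genotypes):
        assert m.ehh_full(example_genotypes, 0, 1) == pytest.approx(10 / 36)

    def test_identical_individuals_stay_at_one(self):
        gm = m.GenotypeMatrix(np.ones((5, 4), dtype=int))
        for extent in range(5):
            assert m.ehh_full(gm, 0, extent) == 1.0

    def test_core_conditioned(self, example_genotypes):
        assert m.ehh_core(example_genotypes, 0, 2, 0) == 1.0
        assert m.ehh_core(example_genotypes, 0, 2, 1) == pytest.approx(5 / 9)

    def test_single_heterozygote_core(self, example_genotypes):
        for extent in range(2):
            assert m.ehh_core(example_genotypes, 0, 1, extent) == 1.0

    def test_complement(self, example_genotypes):
        # complement of c=2 at the core splits into classes {0: 2, 1: 1}
        assert m.cehh_core(example_genotypes, 0, 2, 0) == pytest.approx(5 / 9)
        assert m.cehh_core(example_genotypes, 0, 2, 1) == pytest.approx(5 / 9)

    def test_singleton_complement(self):
        gm = m.GenotypeMatrix(np.array([[2, 2, 1], [0, 1, 2]]))
        for extent in range(2):
            assert m.cehh_core(gm, 0, 2, extent) == 1.0

    def test_empty_core_class_signals(self, example_genotypes):
        with pytest.raises(m.UndefinedCoreError):
            m.ehh_core(m.GenotypeMatrix(np.array([[0, 0, 1]])), 0, 2, 0)


class TestPartitionOracle:
    def test_matches_brute_force_on_random_instances(self, rng):
        policy = ExtensionPolicy(cutoff=0.0, trunc_ok=True, max_extend_sites=10_000)
        for _ in range(30):
            gm = random_genotype_matrix(rng)
            sites = m.make_site_table(np.sort(rng.choice(10_000, gm.n_sites, replace=False)) + 1)
            core = int(rng.integers(gm.n_sites))
            up, down = m.ehh_decay_curve(gm, core, None, policy, sites, "bp")
            for curve in (up, down):
                for k, extent in enumerate(curve.sites):
                    assert curve.ehh[k] == brute_ehh_full(gm.values, core, int(extent))
            present = [c for c in (0, 1, 2) if (gm.values[core] == c).any()]
            for c in present:
                if (gm.values[core] != c).sum() == 0:
                    continue
                up, down = m.ehh_decay_curve(gm, core, c, policy, sites, "bp")
                for curve in (up, down):
                    for k, extent in enumerate(curve.sites):
                        assert curve.ehh[k] == brute_ehh_core(gm.values, core, c, int(extent))
                        assert curve.cehh[k] == brute_cehh_core(gm.values, core, c, int(extent))

    @given(
        hnp.arrays(
            np.int8,
            shape=st.tuples(st.integers(1, 10), st.integers(2, 8)),
            elements=st.integers(0, 2),
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_homozygosity_identities_hold_on_arbitrary_matrices(self, values):
        gm = m.GenotypeMatrix(values)
        for extent in range(gm.n_sites):
            e = m.ehh_full(gm, 0, extent)
            assert e == brute_ehh_full(gm.values, 0, extent)
            assert 1.0 / gm.n <= e <= 1.0
            # full-sample homozygosity decomposes over core classes
            parts = 0.0
            for c in (0, 1, 2):
                n_c = int((gm.values[0] == c).sum())
                if n_c:
                    parts += m.ehh_core(gm, 0, c, extent) * n_c**2
            assert parts / gm.n**2 == pytest.approx(e)

    def test_all_distinct_first_extension(self):
        # every individual unique after one site: EHH_c(x1) = 1/n_c
        gm = m.GenotypeMatrix(np.array([[2, 2, 2, 0, 0, 0], [0, 1, 2, 0, 1, 2]]))
        assert m.ehh_core(gm, 0, 2, 1) == pytest.approx(1 / 3)
        assert m.ehh_core(gm, 0, 0, 1) == pytest.approx(1 / 3)


class TestDecayCurves:
    def test_monotone_and_truncated_at_zero_cutoff(self, small_fixture, rng):
        _, gm, sites = small_fixture
        policy = ExtensionPolicy(cutoff=0.0, trunc_ok=True, max_extend_bp=10**9)
        for core in rng.choice(gm.n_sites, 5, replace=False):
            up, down = m.ehh_decay_curve(gm, int(core), None, policy, sites, "bp")
            assert up.truncated and down.truncated
            assert up.sites[-1] == gm.n_sites - 1 and down.sites[-1] == 0
            for curve in (up, down):
                assert (np.diff(curve.ehh) <= 1e-12).all()

    def test_gap_stops_extension(self):
        gm = m.GenotypeMatrix(np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]]))
        sites = m.make_site_table([100, 200, 300_000])
        policy = ExtensionPolicy(cutoff=0.0, max_gap_bp=1_000, trunc_ok=True)
        up, _ = m.ehh_decay_curve(gm, 0, None, policy, sites, "bp")
        assert up.sites.tolist() == [0, 1]
        assert not up.truncated

    def test_site_budget_in_sites_mode(self, small_fixture):
        _, gm, sites = small_fixture
        policy = ExtensionPolicy(cutoff=0.0, max_extend_sites=3, trunc_ok=True)
        up, down = m.ehh_decay_curve(gm, 10, None, policy, sites, "sites")
        assert len(up) <= 4 and len(down) <= 4
        assert (up.distances[1:] == 1.0).all()

    def test_cutoff_crossing_point_is_included(self, small_fixture):
        _, gm, sites = small_fixture
        policy = ExtensionPolicy(cutoff=0.3, trunc_ok=True)
        up, _ = m.ehh_decay_curve(gm, 5, None, policy, sites, "bp")
        if not up.truncated and len(up) > 1:
            assert up.ehh[-1] < 0.3
            assert (up.ehh[:-1] >= 0.3).any() or len(up) == 2

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            ExtensionPolicy(cutoff=1.5)


def make_curve(direction, sites, distances, ehh, truncated=False):
    return EHHCurve(
        direction=direction,
        sites=np.asarray(sites),
        distances=np.asarray(distances, dtype=float),
        ehh=np.asarray(ehh, dtype=float),
        cehh=None,
        truncated=truncated,
    )


class TestIntegration:
    def test_hand_trapezoid_bp(self):
        up = make_curve("up", [5, 6, 7], [0, 100, 200], [1.0, 0.6, 0.2])
        down = make_curve("down", [5], [0], [1.0])
        assert m.integrate_ihh(up, down) == pytest.approx(160.0)

    def test_hand_trapezoid_sites(self):
        up = make_curve("up", [5, 6, 7], [0, 1, 1], [1.0, 0.6, 0.2])
        down = make_curve("down", [5], [0], [1.0])
        assert m.integrate_ihh(up, down) == pytest.approx(1.2)

    def test_flat_rectangle(self):
        up = make_curve("up", [1, 2], [0, 1000], [1.0, 1.0])
        down = make_curve("down", [1, 0], [0, 1000], [1.0, 1.0])
        assert m.integrate_ihh(up, down) == pytest.approx(2000.0)

    def test_core_only_curves_integrate_to_zero(self):
        up = make_curve("up", [0], [0], [1.0])
        down = make_curve("down", [0], [0], [1.0])
        assert m.integrate_ihh(up, down) == 0.0

    def test_truncation_skip_signal(self):
        up = make_curve("up", [0, 1], [0, 10], [1.0, 0.9], truncated=True)
        down = make_curve("down", [0], [0], [1.0])
        assert m.integrate_ihh(up, down, trunc_ok=False) is None
        assert m.integrate_ihh(up, down, trunc_ok=True) == pytest.approx(9.5)

    def test_mismatched_cores_rejected(self):
        up = make_curve("up", [1], [0], [1.0])
        down = make_curve("down", [0], [0], [1.0])
        with pytest.raises(ValueError):
            m.integrate_ihh(up, down)
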