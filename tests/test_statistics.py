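"""Score assembly: sign rules, equivalences, phase invariance."""

import numpy as np
import pandas as pd
import pytest

import mlgscan as m
from mlgscan.ehh import ExtensionPolicy
from mlgscan.statistics import ScanConfig, combine_unphased_ihs


def _policy(**kw):
    base = dict(trunc_ok=True)
    base.update(kw)
    return ExtensionPolicy(**base)


def _cfg(stat, unphased=True, **kw):
    return ScanConfig(statistic=stat, unphased=unphased, policy=_policy(**kw),
                      maf_threshold=0.0)


class TestSignRule:
    def test_symmetric_ratios_give_zero(self):
        score, num, den = combine_unphased_ihs(5.0, 5.0, 3.0, 3.0)
        assert score == 0.0

    def test_derived_branch_selected(self):
        score, num, den = combine_unphased_ihs(10.0, 1.0, 1.0, 1.0)
        assert score == pytest.approx(1.0)
        assert (num, den) == (10.0, 1.0)

    def test_ancestral_branch_negated(self):
        score, num, den = combine_unphased_ihs(1.0, 1.0, 10.0, 1.0)
        assert score == pytest.approx(-1.0)
        assert (num, den) == (10.0, 1.0)

    def test_tie_falls_to_ancestral_branch(self):
        # the two-branch rule taken literally: iHS2 > iHS0 fails on equality
        score, num, den = combine_unphased_ihs(10.0, 1.0, 20.0, 2.0)
        assert score == pytest.approx(-1.0)
        assert (num, den) == (20.0, 2.0)


def _two_pop(seed, sweep=None, L=50_000):
    params = m.SimulationParameters(
        L=L, n_hap=40, theta_like=47, rho_like=24, seed=seed, sweep=sweep
    )
    return m.simulate_two_pops(params)


class TestPhaseInvariance:
    def test_unphased_statistics_ignore_phase(self):
        """Collapsing to genotypes commutes with phase destruction, so the
        unphased statistics are bit-identical on scrambled data."""
        for seed in range(5):
            ha, hb, sites = _two_pop(seed)
            sa = m.scramble_phase(ha, 0.5, seed=seed + 100)
            sb = m.scramble_phase(hb, 0.5, seed=seed + 200)
            for stat in ("ihs", "nsl"):
                cfg = _cfg(stat)
                pd.testing.assert_frame_equal(
                    m.scan(ha, sites, cfg), m.scan(sa, sites, cfg)
                )
            for stat in ("xpehh", "xpnsl"):
                cfg = _cfg(stat)
                pd.testing.assert_frame_equal(
                    m.scan(ha, sites, cfg, data_b=hb),
                    m.scan(sa, sites, cfg, data_b=sb),
                )


class TestCrossPopulation:
    def test_identical_populations_score_zero(self, small_fixture):
        haps, gm, sites = small_fixture
        cfg = _cfg("xpnsl")
        df = m.scan(gm, sites, cfg, data_b=gm)
        assert len(df) > 0
        assert (df["score"] == 0.0).all()

    def test_antisymmetry(self):
        ha, hb, sites = _two_pop(3)
        cfg = _cfg("xpnsl")
        ab = m.scan(ha, sites, cfg, data_b=hb)
        ba = m.scan(hb, sites, cfg, data_b=ha)
        # cores are filtered on the target population; compare the overlap
        merged = ab.merge(ba, on="pos_bp", suffixes=("_ab", "_ba"))
        assert len(merged) > 0
        assert (merged["score_ab"] == -merged["score_ba"]).all()

    def test_monomorphic_target_population_scores_positive(self, rng):
        n_sites = 30
        a = m.GenotypeMatrix(np.zeros((n_sites, 10), dtype=int))
        a.values[15] = 2  # shared core, EHH stays 1 elsewhere
        b = m.GenotypeMatrix(rng.integers(0, 3, size=(n_sites, 10)))
        b.values[15] = a.values[15]
        sites = m.make_site_table(np.arange(1, n_sites + 1) * 50)
        rec = m.unphased_xp_site(a, b, sites, 15, _cfg("xpehh"))
        assert rec is not None and rec.score > 0

    def test_duplicated_haplotype_diploids_agree_in_sign(self):
        # individuals homozygous everywhere: phased and unphased XP agree
        ha, hb, sites = _two_pop(11)
        dup_a = m.HaplotypeMatrix(np.repeat(ha.values[:, ::2], 2, axis=1))
        dup_b = m.HaplotypeMatrix(np.repeat(hb.values[:, ::2], 2, axis=1))
        cfg_u, cfg_p = _cfg("xpnsl"), _cfg("xpnsl", unphased=False)
        unph = m.scan(dup_a, sites, cfg_u, data_b=dup_b)
        ph = m.scan(dup_a, sites, cfg_p, data_b=dup_b)
        merged = unph.merge(ph, on="pos_bp", suffixes=("_u", "_p"))
        assert len(merged) > 0
        nz = merged[(merged.score_u != 0) & (merged.score_p != 0)]
        assert (np.sign(nz.score_u) == np.sign(nz.score_p)).all()


class TestEquivalences:
    def test_nsl_equals_ihs_under_unit_distances(self):
        """With consecutive integer bp positions and matched extension
        limits, the bp distance measure degenerates to the site count."""
        params = m.SimulationParameters(L=50_000, n_hap=40, theta_like=47,
                                        rho_like=24, seed=5)
        haps, sites = m.simulate_neutral(params)
        gm = m.collapse_to_genotypes(haps)
        unit_sites = m.make_site_table(np.arange(1, gm.n_sites + 1))
        kw = dict(max_extend_bp=10**9, max_extend_sites=10**6, max_gap_bp=10**9)
        ihs = m.scan(gm, unit_sites, _cfg("ihs", **kw))
        nsl = m.scan(gm, unit_sites, _cfg("nsl", **kw))
        assert len(ihs) > 0
        assert ihs["score"].tolist() == nsl["score"].tolist()

    def test_core_coding_flip_negates_score(self, small_fixture, nsl_config):
        haps, gm, sites = small_fixture
        flipped = gm.values.copy()
        hits = 0
        for core in range(gm.n_sites):
            col = gm.values[core]
            if not ((col == 0).any() and (col == 2).any()):
                continue
            rec = m.unphased_nsl_site(gm, sites, core, nsl_config)
            if rec is None:
                continue
            flipped_gm = m.GenotypeMatrix(np.vstack([
                gm.values[:core], [2 - col], gm.values[core + 1:]
            ]))
            rec_f = m.unphased_nsl_site(flipped_gm, sites, core, nsl_config)
            assert rec_f is not None
            assert rec_f.score == pytest.approx(-rec.score)
            hits += 1
            if hits >= 10:
                break
        assert hits > 0


class TestPhasedBaselines:
    def test_symmetric_core_classes_score_zero(self):
        # derived and ancestral haplotype sets are mirror images
        values = np.array([
            [0, 0, 1, 1],
            [0, 1, 0, 1],
            [0, 1, 0, 1],
        ])
        sites = m.make_site_table([100, 200, 300])
        cfg = _cfg("nsl", unphased=False)
        rec = m.phased_ihs_site(m.HaplotypeMatrix(values), sites, 0, cfg)
        assert rec is not None and rec.score == 0.0

    def test_identical_populations_phased_xp_zero(self):
        ha, _, sites = _two_pop(9)
        cfg = _cfg("xpnsl", unphased=False)
        df = m.scan(ha, sites, cfg, data_b=ha)
        assert len(df) > 0 and (df["score"] == 0.0).all()


class TestScan:
    def test_empty_sites(self, nsl_config):
        gm = m.GenotypeMatrix(np.zeros((0, 4), dtype=int))
        df = m.scan(gm, m.make_site_table([]), nsl_config)
        assert len(df) == 0

    def test_maf_filter_reduces_records(self):
        values = np.array([
            [1, 1, 0, 0],
            [1, 0, 0, 0],   # freq 0.125 < 0.2 -> filtered as core
            [0, 1, 1, 0],
        ])
        gm = m.GenotypeMatrix(values)
        sites = m.make_site_table([100, 200, 300])
        cfg = ScanConfig("nsl", unphased=True, policy=_policy(), maf_threshold=0.2)
        df = m.scan(gm, sites, cfg)
        assert df.attrs["skipped"]["maf_filter"] == 1
        assert len(df) + sum(df.attrs["skipped"].values()) == 3

    def test_positions_strictly_increasing(self, small_fixture, nsl_config):
        _, gm, sites = small_fixture
        df = m.scan(gm, sites, nsl_config)
        assert (np.diff(df["pos_bp"].to_numpy()) > 0).all()

    def test_xp_requires_second_population(self):
        gm = m.GenotypeMatrix(np.zeros((1, 4), dtype=int))
        with pytest.raises(ValueError, match="second population"):
            m.scan(gm, m.make_site_table([1]), _cfg("xpehh"))

    def test_distance_mode_statistic_consistency(self):
        with pytest.raises(ValueError, match="incompatible"):
            ScanConfig(statistic="ihs", distance_mode="sites")
        with pytest.raises(ValueError, match="incompatible"):
            ScanConfig(statistic="nsl", distance_mode="bp")
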