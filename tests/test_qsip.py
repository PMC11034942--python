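"""qSIP chain: spot values, invariants, and the independent equation oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qsipx import (
    CONTROL_TREATMENT,
    DEFAULT_CONSTANTS,
    FractionTable,
    QsipDomainError,
    RunConfig,
    SimNoise,
    absolute_growth,
    estimate_growth,
    excess_atom_fraction,
    filter_window,
    gc_from_wad,
    growth_rate,
    molecular_weights,
    phylum_cumulative_growth,
    simulate_community,
    simulate_fraction_tables,
    synthetic_design,
    taxon_copies,
    unlabeled_copies,
    weighted_average_density,
)

K = DEFAULT_CONSTANTS


class TestElementaryOps:
    def test_gc_inversion(self):
        assert gc_from_wad(1.687810) == pytest.approx(0.500, abs=1e-4)
        assert gc_from_wad(K.gc_intercept) == pytest.approx(0.0, abs=1e-12)

    def test_gc_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamp"):
            assert gc_from_wad(1.60) == 0.0

    def test_molecular_weight_spot_values(self):
        m_light, m_lab, m_heavy = molecular_weights(0.5, 1.687810, 1.700000)
        assert m_light == pytest.approx(307.939, abs=1e-3)
        assert m_lab == pytest.approx(310.163, abs=1e-3)
        assert m_heavy == pytest.approx(307.939 + 12.07747, abs=1e-3)

    def test_no_shift_no_labeling(self):
        m_light, m_lab, _ = molecular_weights(0.5, 1.69, 1.69)
        assert m_lab == m_light

    def test_eaf_endpoints_and_spot_value(self):
        m_light, m_lab, m_heavy = 307.939, 310.163, 320.016
        assert excess_atom_fraction(m_light, m_light, m_heavy) == 0.0
        assert excess_atom_fraction(m_light, m_heavy, m_heavy) == pytest.approx(
            1 - K.p_nat_18o
        )
        assert excess_atom_fraction(m_light, m_lab, m_heavy) == pytest.approx(
            0.1838, abs=2e-4
        )

    def test_unlabeled_copies_linearity(self):
        m_light, m_heavy = 308.0, 320.0
        assert unlabeled_copies(1000, m_light, m_light, m_heavy) == 1000
        assert unlabeled_copies(1000, m_light, m_heavy, m_heavy) == 0
        mid = (m_light + m_heavy) / 2
        assert unlabeled_copies(1000, m_light, mid, m_heavy) == pytest.approx(500)
        with pytest.raises(QsipDomainError, match="over-labeling"):
            unlabeled_copies(1000, m_light, m_heavy + 1, m_heavy)

    def test_growth_rate_exact_inversion(self):
        assert growth_rate(1000.0, 1000.0, 2.0) == 0.0
        assert growth_rate(1000.0, 1000.0 * math.exp(-2), 2.0) == pytest.approx(1.0)
        assert growth_rate(1000.0, 1100.0, 2.0) < 0  # negative EAF noise allowed
        with pytest.raises(QsipDomainError):
            growth_rate(1000.0, 0.0, 2.0)

    def test_absolute_growth(self):
        assert absolute_growth(1000.0, 0.0, 2.0) == 0.0
        assert absolute_growth(1000.0, 1.0, 2.0) == pytest.approx(
            1000 * (1 - math.exp(-2)) / 2
        )
        # large-g limit: everything present is new
        assert absolute_growth(1000.0, 50.0, 2.0) == pytest.approx(500.0)

    def test_wad_symmetry_and_absence(self):
        assert weighted_average_density(
            [100, 200, 100], [1.70, 1.71, 1.72]
        ) == pytest.approx(1.71)
        assert weighted_average_density([0, 50, 0], [1.70, 1.715, 1.72]) == 1.715
        assert math.isnan(weighted_average_density([0, 0, 0], [1.7, 1.71, 1.72]))
        assert math.isnan(
            weighted_average_density([0, 5, 0], [1.7, 1.71, 1.72], 2)
        )

    @given(
        w_lab=st.floats(1.66, 1.76),
        delta=st.floats(1e-6, 0.01),
    )
    def test_eaf_monotone_in_labeled_wad(self, w_lab, delta):
        w_light = 1.68
        gc = gc_from_wad(w_light)
        low = excess_atom_fraction(*molecular_weights(gc, w_light, w_lab))
        high = excess_atom_fraction(*molecular_weights(gc, w_light, w_lab + delta))
        assert high > low

    @given(
        eaf=st.floats(0.0, 0.9),
        delta=st.floats(1e-6, 0.05),
    )
    def test_growth_monotone_in_eaf(self, eaf, delta):
        def g_of(e):
            n_light = 1000.0 * (1 - e / (1 - K.p_nat_18o))
            return growth_rate(1000.0, n_light, 2.0)

        assert g_of(min(eaf + delta, 0.95)) > g_of(eaf)


class TestWindowAndCopies:
    def make_table(self, densities, tube="t1"):
        n = len(densities)
        return FractionTable(
            pd.DataFrame(
                {
                    "tube_id": [tube] * n,
                    "treatment": ["T0nP"] * n,
                    "isotope": ["16O"] * n,
                    "replicate": [1] * n,
                    "fraction": range(1, n + 1),
                    "density": densities,
                    "total_copies": [1e6] * n,
                    "sp1": [0.25] * n,
                }
            )
        )

    def test_window_is_closed_interval(self):
        table = self.make_table([1.700, 1.703, 1.715, 1.727, 1.730])
        out = filter_window(table, (1.703, 1.727))
        assert len(out) == 3
        assert out.data["density"].tolist() == [1.703, 1.715, 1.727]

    def test_infinite_window_is_identity(self):
        table = self.make_table([1.68, 1.71, 1.74])
        out = filter_window(table, (0.0, np.inf))
        assert out.data.equals(table.data)

    def test_empty_tube_is_error(self):
        table = self.make_table([1.60, 1.62], tube="lonely")
        with pytest.raises(QsipDomainError, match="lonely"):
            filter_window(table, (1.703, 1.727))

    def test_taxon_copies_arithmetic(self):
        table = self.make_table([1.70])
        table.data["sp1"] = [0.25]
        table.data["total_copies"] = [4e6]
        out = taxon_copies(table)
        assert out["sp1"].iloc[0] == pytest.approx(1e6)
        table.data["sp1"] = [0.0]
        assert taxon_copies(table)["sp1"].iloc[0] == 0.0


def straight_line_chain(w_light, w_lab, n_total, t):
    """Independent transcription of the qSIP equations, scalar arithmetic only."""
    gc = (w_light - 1.646057) / 0.083506
    m_light = 0.496 * gc + 307.691
    m_heavy = m_light + 12.07747
    m_lab = m_light * (w_lab / w_light)
    eaf = (m_lab - m_light) / (m_heavy - m_light) * (1 - 0.002000429)
    n_light = n_total * (m_heavy - m_lab) / (m_heavy - m_light)
    g = math.log(n_total / n_light) / t
    dndt = n_total * (1 - math.exp(-g * t)) / t
    return eaf, g, dndt


def straight_line_wad(densities, copies):
    num = sum(d * c for d, c in zip(densities, copies))
    den = sum(copies)
    return num / den


class TestFullChainOracle:
    def test_chain_matches_straight_line_transcription(self, sim_design):
        """Noiseless 5-taxon, 7-window-fraction dataset: the packaged chain
        must agree with an independent scalar transcription of the equations
        to 1e-10 relative."""
        params = simulate_community(5, sim_design, seed=77)
        table, _ = simulate_fraction_tables(
            params, sim_design, SimNoise.zero(), seed=78
        )
        # restrict analysis to a 7-fraction window around the community
        window = (1.6901, 1.7319)  # 7 of the 20 grid fractions
        config = RunConfig(rng_seed=0, n_bootstrap=10)
        results = estimate_growth(
            table, sim_design, config, window=window
        )
        filtered = filter_window(table, window)
        assert filtered.data.groupby("tube_id").size().eq(7).all()

        checked = 0
        for tr, res in results.items():
            sub = filtered.subset(treatment=tr)
            for _, row in res.estimates.iterrows():
                taxon = row["taxon"]
                wads = {}
                totals = []
                for iso in ("16O", "18O"):
                    tube_wads = []
                    for tube in sub.subset(isotope=iso).tubes:
                        tube_df = sub.subset(tube_id=tube).data
                        copies = (
                            tube_df[taxon].to_numpy()
                            * tube_df["total_copies"].to_numpy()
                        )
                        tube_wads.append(
                            straight_line_wad(tube_df["density"].tolist(), copies)
                        )
                        if iso == "18O":
                            totals.append(sum(copies))
                    wads[iso] = sum(tube_wads) / len(tube_wads)
                n_total = sum(totals) / len(totals)
                eaf, g, dndt = straight_line_chain(
                    wads["16O"], wads["18O"], n_total, sim_design.incubation_days
                )
                assert row["eaf"] == pytest.approx(eaf, rel=1e-10, abs=1e-12)
                assert row["g"] == pytest.approx(g, rel=1e-10, abs=1e-12)
                assert row["dndt"] == pytest.approx(dndt, rel=1e-10)
                checked += 1
        assert checked == 5 * len(results)


def degenerate_table(g_true=0.5):
    """Three identical replicate tubes per isotope, one growing taxon."""
    design = synthetic_design()
    params = simulate_community(2, design, seed=13)
    table, _ = simulate_fraction_tables(params, design, SimNoise.zero(), seed=14)
    # overwrite replicates with copies of replicate 1 -> degenerate bootstrap
    df = table.data
    rep1 = df[df["replicate"] == 1]
    clones = []
    for rep in (2, 3):
        c = rep1.copy()
        c["replicate"] = rep
        c["tube_id"] = rep1["tube_id"].str.replace("_r1", f"_r{rep}")
        clones.append(c)
    return FractionTable(
        pd.concat([rep1] + clones, ignore_index=True)
    ), design, params


class TestEstimateGrowth:
    def test_identical_replicates_zero_width_ci(self, config):
        table, design, _ = degenerate_table()
        res = estimate_growth(table, design, config, CONTROL_TREATMENT)
        est = res.estimates
        np.testing.assert_allclose(est["g_ci_low"], est["g"], rtol=1e-9)
        np.testing.assert_allclose(est["g_ci_high"], est["g"], rtol=1e-9)
        # degenerate bootstrap: incorporator iff point g > 0
        assert (est["incorporator"] == (est["g"] > 0)).all()

    def test_ci_ordering_invariant(self, sim_design, config):
        params = simulate_community(10, sim_design, seed=41)
        table, _ = simulate_fraction_tables(params, sim_design, SimNoise(), seed=42)
        results = estimate_growth(table, sim_design, config)
        for res in results.values():
            est = res.estimates
            for stem in ("eaf", "g", "dndt"):
                assert (est[f"{stem}_ci_low"] <= est[stem] + 1e-12).all()
                assert (est[stem] <= est[f"{stem}_ci_high"] + 1e-12).all()

    def test_replicate_rates_have_one_row_per_labeled_tube(self, sim_design, config):
        params = simulate_community(4, sim_design, seed=51)
        table, _ = simulate_fraction_tables(params, sim_design, SimNoise(), seed=52)
        res = estimate_growth(table, sim_design, config, CONTROL_TREATMENT)
        assert len(res.replicate_dndt) == sim_design.n_replicates


class TestPhylumAggregation:
    def make_result(self, config):
        design = synthetic_design()
        params = simulate_community(6, design, seed=61)
        table, _ = simulate_fraction_tables(params, design, SimNoise(), seed=62)
        return estimate_growth(table, design, config, CONTROL_TREATMENT)

    def test_single_phylum_equals_community_sum(self, config):
        res = self.make_result(config)
        taxonomy = {t: "Actinobacteria" for t in res.estimates["taxon"]}
        agg = phylum_cumulative_growth(res, taxonomy)
        assert len(agg) == 1
        assert agg["dndt"].iloc[0] == pytest.approx(res.estimates["dndt"].sum())

    def test_partition_conserves_total(self, config):
        res = self.make_result(config)
        taxa = list(res.estimates["taxon"])
        taxonomy = {t: ("A" if i % 2 else "B") for i, t in enumerate(taxa)}
        agg = phylum_cumulative_growth(res, taxonomy)
        assert agg["dndt"].sum() == pytest.approx(res.estimates["dndt"].sum())

    def test_unmapped_taxa_pooled_as_unassigned(self, config):
        res = self.make_result(config)
        agg = phylum_cumulative_growth(res, {})
        assert set(agg["phylum"]) == {"unassigned"}
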