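"""Equilibrium consumption, flow partition, mortality split, trophic levels."""

import numpy as np
import pytest

from webstab import FunctionalGroup, WebValidationError
from webstab.energetics import (
    detritus_budget,
    mortality_partition,
    partition_flows,
    total_consumption,
    trophic_levels,
)
from webstab.synth import SynthParams, generate_synthetic_web

from conftest import make_web


class TestTotalConsumption:
    @pytest.mark.parametrize(
        "pb,b,e,expected",
        [(2.0, 10.0, 0.25, 80.0), (0.0, 10.0, 0.25, 0.0), (1.0, 7.0, 1.0, 7.0)],
    )
    def test_production_over_efficiency(self, pb, b, e, expected):
        g = FunctionalGroup("A", "consumer", b, pb=pb, efficiency=e)
        assert total_consumption(g) == pytest.approx(expected, abs=0.0)

    def test_rejects_non_consumers(self):
        with pytest.raises(WebValidationError):
            total_consumption(FunctionalGroup("P", "producer", 1.0, pb=1.0))


class TestPartitionFlows:
    def test_biomass_weighted_preferences(self):
        # F*_A = 2*10/0.25 = 80 split over prey with equal preference and
        # biomasses 10 and 30 -> shares 0.25/0.75 -> flows 20/60
        web = make_web(
            [
                FunctionalGroup("D", "detritus", 1.0),
                FunctionalGroup("P1", "producer", 10.0, pb=10.0),
                FunctionalGroup("P2", "producer", 30.0, pb=10.0),
                FunctionalGroup("A", "consumer", 10.0, pb=2.0,
                                efficiency=0.25),
            ],
            {("P1", "A"): 0.5, ("P2", "A"): 0.5},
        )
        flows = partition_flows(web)
        assert flows.totals[web.index("A")] == pytest.approx(80.0)
        assert flows.flows[web.index("P1"), web.index("A")] == pytest.approx(20.0)
        assert flows.flows[web.index("P2"), web.index("A")] == pytest.approx(60.0)

    def test_single_prey_gets_everything(self, pred_prey):
        flows = partition_flows(pred_prey)
        a = pred_prey.index("A")
        assert flows.flows[pred_prey.index("P"), a] == pytest.approx(
            flows.totals[a]
        )

    def test_fraction_mode(self):
        web = make_web(
            [
                FunctionalGroup("D", "detritus", 1.0),
                FunctionalGroup("P", "producer", 50.0, pb=10.0),
                FunctionalGroup("A", "consumer", 2.0, pb=1.0, efficiency=0.2),
            ],
            {("P", "A"): 0.3, ("D", "A"): 0.7},
            mode="fraction",
        )
        flows = partition_flows(web)  # F*_A = 10
        assert flows.flows[web.index("P"), web.index("A")] == pytest.approx(3.0)
        assert flows.flows[web.index("D"), web.index("A")] == pytest.approx(7.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_on_synthetic_webs(self, seed):
        web = generate_synthetic_web(SynthParams(seed=seed))
        flows = partition_flows(web)
        for g in web.consumers:
            j = web.index(g.name)
            np.testing.assert_allclose(
                flows.flows[:, j].sum(), flows.totals[j], rtol=1e-9
            )


class TestMortalityPartition:
    def test_top_predator_dies_only_naturally(self, toy3):
        flows = partition_flows(toy3)
        mort = mortality_partition(toy3, flows)
        a = toy3.index("A")
        assert mort.predation[a] == 0.0
        assert mort.nonpred_rate[a] == pytest.approx(toy3.group("A").pb)

    def test_partition_arithmetic(self):
        # prey P/B=2, B=10, predation flow 15 -> m = 2 - 1.5 = 0.5
        web = make_web(
            [
                FunctionalGroup("D", "detritus", 1.0),
                FunctionalGroup("P", "producer", 10.0, pb=2.0),
                FunctionalGroup("A", "consumer", 15.0, pb=0.2,
                                efficiency=0.2),
            ],
            {("P", "A"): 1.0},
        )
        flows = partition_flows(web)  # F*_A = 0.2*15/0.2 = 15
        mort = mortality_partition(web, flows)
        assert mort.nonpred_rate[web.index("P")] == pytest.approx(0.5)

    def test_unbalanced_web_raises(self):
        # predation 25 on a prey producing 20 -> m = -0.5
        web = make_web(
            [
                FunctionalGroup("D", "detritus", 1.0),
                FunctionalGroup("P", "producer", 10.0, pb=2.0),
                FunctionalGroup("A", "consumer", 25.0, pb=0.2,
                                efficiency=0.2),
            ],
            {("P", "A"): 1.0},
        )
        flows = partition_flows(web)
        with pytest.raises(WebValidationError, match="'P'"):
            mortality_partition(web, flows)

    def test_balance_identity_holds(self, omnivory):
        flows = partition_flows(omnivory)
        mort = mortality_partition(omnivory, flows)
        for g in omnivory.living:
            i = omnivory.index(g.name)
            np.testing.assert_allclose(
                g.pb * g.biomass,
                mort.predation[i] + mort.nonpred_rate[i] * g.biomass,
                rtol=1e-9,
            )


class TestDetritusBudget:
    def test_egestion_is_080_of_total_feeding(self, omnivory):
        flows = partition_flows(omnivory)
        mort = mortality_partition(omnivory, flows)
        budget = detritus_budget(omnivory, flows, mort)
        assert budget.inflow_egestion == pytest.approx(
            0.8 * flows.total_feeding
        )

    def test_no_detritivores_means_zero_outflow(self, pred_prey):
        flows = partition_flows(pred_prey)
        mort = mortality_partition(pred_prey, flows)
        budget = detritus_budget(pred_prey, flows, mort)
        assert budget.outflow_consumption == 0.0
        assert budget.implied_import < 0  # inflows with no drain

    def test_implied_import_closes_the_budget(self, toy3):
        flows = partition_flows(toy3)
        mort = mortality_partition(toy3, flows)
        b = detritus_budget(toy3, flows, mort)
        assert b.implied_import == pytest.approx(
            b.outflow_consumption - b.inflow_egestion - b.inflow_mortality
        )


class TestTrophicLevels:
    def test_basal_and_simple_chains(self, toy3):
        levels = trophic_levels(toy3)
        assert levels[toy3.index("D")] == pytest.approx(1.0)
        assert levels[toy3.index("P")] == pytest.approx(1.0)
        # A eats P (share 1/6) and D (share 5/6), both level 1 -> level 2
        assert levels[toy3.index("A")] == pytest.approx(2.0)

    def test_half_herbivore_half_carnivore(self):
        web = make_web(
            [
                FunctionalGroup("D", "detritus", 1.0),
                FunctionalGroup("P", "producer", 100.0, pb=10.0),
                FunctionalGroup("H", "consumer", 10.0, pb=2.0,
                                efficiency=0.2),
                FunctionalGroup("C", "consumer", 1.0, pb=0.5,
                                efficiency=0.25),
            ],
            {("P", "H"): 1.0, ("P", "C"): 0.5, ("H", "C"): 0.5},
            mode="fraction",
        )
        # C's diet: 50% producer, 50% herbivore
        levels = trophic_levels(web)
        assert levels[web.index("H")] == pytest.approx(2.0)
        assert levels[web.index("C")] == pytest.approx(2.5)


class TestOrderIndependence:
    def test_results_invariant_under_group_permutation(self):
        web = generate_synthetic_web(SynthParams(seed=11))
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(web.names))
        shuffled = web.reordered(perm)
        f1 = partition_flows(web)
        f2 = partition_flows(shuffled)
        for prey in web.names:
            for pred in web.names:
                a = f1.flows[web.index(prey), web.index(pred)]
                b = f2.flows[shuffled.index(prey), shuffled.index(pred)]
                assert a == pytest.approx(b, rel=1e-12)
        m1 = mortality_partition(web, f1)
        m2 = mortality_partition(shuffled, f2)
        for nm in web.names:
            a, b = m1.nonpred_rate[web.index(nm)], m2.nonpred_rate[shuffled.index(nm)]
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)
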