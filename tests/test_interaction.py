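"""Community-matrix construction: pair strengths, detritus interactions,
variants and the diagonal."""

import numpy as np
import pytest

from webstab import WebValidationError
from webstab.energetics import mortality_partition, partition_flows
from webstab.interaction import (
    build_matrix,
    detritus_effect_of_detritivore,
    detritus_effect_of_prey,
    pair_strengths,
    set_diagonal,
)
from webstab import FunctionalGroup

from conftest import make_web


def pipeline(web, **kw):
    flows = partition_flows(web)
    mort = mortality_partition(web, flows)
    return flows, mort, build_matrix(web, flows, mort, **kw)


class TestPairStrengths:
    @pytest.mark.parametrize(
        "flow,bp,bq,e,expected",
        [
            (20.0, 10.0, 10.0, 0.25, (-2.0, 0.5)),
            (0.0, 10.0, 10.0, 0.25, (0.0, 0.0)),
            (5.0, 5.0, 1.0, 1.0, (-5.0, 1.0)),
        ],
    )
    def test_topdown_and_bottomup(self, flow, bp, bq, e, expected):
        assert pair_strengths(flow, bp, bq, e) == pytest.approx(expected)

    def test_zero_biomass_rejected(self):
        with pytest.raises(WebValidationError):
            pair_strengths(1.0, 0.0, 1.0, 0.2)


class TestDetritusEffects:
    def make(self, prey_pb, pred_flow_setup):
        """Web where P is preyed on by consumers with chosen demand."""
        groups = [
            FunctionalGroup("D", "detritus", 100.0),
            FunctionalGroup("P", "producer", 10.0, pb=prey_pb),
        ]
        entries = {}
        for k, (pb, b, e) in enumerate(pred_flow_setup):
            nm = f"M{k}"
            groups.append(
                FunctionalGroup(nm, "consumer", b, pb=pb, efficiency=e)
            )
            entries[("P", nm)] = 1.0
        return make_web(groups, entries)

    def test_egestion_plus_mortality(self):
        # one predator with F* = 5 on B_P = 10, ac = 0.2, m_P = 0.3
        # -> 0.8*5/10 + 0.3 = 0.7
        web = self.make(0.8, [(1.0, 1.0, 0.2)])  # F*_M = 1*1/0.2 = 5
        flows = partition_flows(web)
        mort = mortality_partition(web, flows)
        assert mort.nonpred_rate[web.index("P")] == pytest.approx(0.3)
        assert detritus_effect_of_prey(web, flows, mort, "P") == pytest.approx(
            0.7
        )

    def test_unpreyed_producer_contributes_its_mortality(self):
        # P has no predators; a detritivore keeps the web non-trivial
        web = make_web(
            [
                FunctionalGroup("D", "detritus", 100.0),
                FunctionalGroup("P", "producer", 10.0, pb=0.4),
                FunctionalGroup("A", "consumer", 1.0, pb=0.5,
                                efficiency=0.5),
            ],
            {("D", "A"): 1.0},
        )
        flows = partition_flows(web)
        mort = mortality_partition(web, flows)
        assert detritus_effect_of_prey(web, flows, mort, "P") == pytest.approx(
            0.4
        )

    def test_two_predators_accumulate(self):
        # two predators, F* = 5 each, B_P = 10, m_P = 0 -> 0.8
        web = self.make(1.0, [(1.0, 1.0, 0.2), (1.0, 1.0, 0.2)])
        flows = partition_flows(web)
        mort = mortality_partition(web, flows)
        assert mort.nonpred_rate[web.index("P")] == pytest.approx(0.0)
        assert detritus_effect_of_prey(web, flows, mort, "P") == pytest.approx(
            0.8
        )

    def test_detritivore_aggregate(self):
        # F*_DA = 10, B_A = 5, m_A = 0.5, one predator ac = 0.2, F*_AK = 2
        # -> -10/5 + 0.5 + 0.8*2/5 = -1.18
        # A: F*_DA = pb*B/e = 0.9*5/0.45 = 10; K: F*_AK = 0.4*1/0.2 = 2;
        # m_A = 0.9 - 2/5 = 0.5
        web = make_web(
            [
                FunctionalGroup("D", "detritus", 100.0),
                FunctionalGroup("P", "producer", 50.0, pb=2.0),
                FunctionalGroup("A", "consumer", 5.0, pb=0.9,
                                efficiency=0.45),
                FunctionalGroup("K", "consumer", 1.0, pb=0.4,
                                efficiency=0.2),
            ],
            {("D", "A"): 1.0, ("A", "K"): 1.0},
        )
        flows = partition_flows(web)  # F*_DA = 0.9*5/0.45 = 10, F*_AK = 2
        mort = mortality_partition(web, flows)
        assert flows.flows[web.index("D"), web.index("A")] == pytest.approx(10)
        assert mort.nonpred_rate[web.index("A")] == pytest.approx(0.5)
        assert detritus_effect_of_detritivore(
            web, flows, mort, "A"
        ) == pytest.approx(-1.18)

    def test_reduces_to_prey_form_without_detritivory(self, omnivory):
        flows = partition_flows(omnivory)
        mort = mortality_partition(omnivory, flows)
        # O eats no detritus in this fixture
        assert detritus_effect_of_detritivore(
            omnivory, flows, mort, "O"
        ) == pytest.approx(detritus_effect_of_prey(omnivory, flows, mort, "O"))

    def test_pure_detritivore_sign(self):
        # F*_DA = 10, B_A = 5, m = 0, no predators -> -2.0
        web = make_web(
            [
                FunctionalGroup("D", "detritus", 100.0),
                FunctionalGroup("P", "producer", 50.0, pb=0.1),
                FunctionalGroup("A", "consumer", 5.0, pb=1.0,
                                efficiency=0.5),
            ],
            {("D", "A"): 1.0},
        )
        flows = partition_flows(web)
        mort = mortality_partition(web, flows)
        val = detritus_effect_of_detritivore(web, flows, mort, "A")
        # m_A = pb = 1.0 here (top predator), so -2.0 + 1.0
        assert val == pytest.approx(-10 / 5 + 1.0)


class TestBuildMatrix:
    def test_variants_differ_only_in_detritus_row(self, toy3):
        _, _, graz = pipeline(toy3, variant="grazing")
        _, _, det = pipeline(toy3, variant="detritus")
        d = toy3.index("D")
        mask = np.ones_like(graz.alpha, dtype=bool)
        mask[d, :] = False
        np.testing.assert_array_equal(graz.alpha[mask], det.alpha[mask])
        assert not np.array_equal(graz.alpha[d, :], det.alpha[d, :])

    def test_no_detritivores_gives_nonneg_detritus_row(self, pred_prey):
        _, _, det = pipeline(pred_prey, variant="detritus")
        d = pred_prey.index("D")
        assert np.all(det.alpha[:, d] == 0.0)  # nothing feels detritus
        row = np.delete(det.alpha[d, :], d)
        assert np.all(row >= 0.0)

    def test_predator_prey_sign_structure(self, omnivory):
        _, _, cm = pipeline(omnivory, variant="detritus")
        for prey, pred in omnivory.diet.entries:
            if omnivory.group(prey).role == "detritus":
                continue
            i, j = omnivory.index(prey), omnivory.index(pred)
            assert cm.alpha[i, j] < 0  # top-down
            assert cm.alpha[j, i] > 0  # bottom-up

    def test_nonzero_pattern_is_contained_in_pathways(self, omnivory):
        _, _, cm = pipeline(omnivory, variant="detritus")
        d = omnivory.index("D")
        allowed = set()
        for prey, pred in omnivory.diet.entries:
            i, j = omnivory.index(prey), omnivory.index(pred)
            allowed |= {(i, j), (j, i)}
        allowed |= {(d, omnivory.index(g.name)) for g in omnivory.living}
        nz = {tuple(ij) for ij in np.argwhere(cm.alpha != 0.0)}
        assert nz <= allowed

    def test_full_derivative_adds_own_egestion(self, toy3):
        flows, mort, cm = pipeline(toy3, variant="detritus")
        _, _, full = pipeline(toy3, variant="detritus", full_derivative=True)
        d, a = toy3.index("D"), toy3.index("A")
        extra = (1 - toy3.group("A").unassim) * flows.totals[a] / toy3.group(
            "A"
        ).biomass
        assert full.alpha[d, a] == pytest.approx(cm.alpha[d, a] + extra)


class TestSetDiagonal:
    def test_zero_strength_zero_diagonal(self, toy3):
        _, mort, cm = pipeline(toy3)
        out = set_diagonal(cm, 0.0, mort)
        assert np.all(np.diag(out.alpha) == 0.0)

    def test_scaled_by_mortality(self, toy3):
        _, mort, cm = pipeline(toy3)
        out = set_diagonal(cm, 1.0, mort)
        p, a = toy3.index("P"), toy3.index("A")
        assert out.alpha[p, p] == pytest.approx(-mort.nonpred_rate[p])
        assert out.alpha[a, a] == pytest.approx(-mort.nonpred_rate[a])
        assert out.alpha[toy3.index("D"), toy3.index("D")] == 0.0

    def test_setting_is_idempotent(self, toy3):
        _, mort, cm = pipeline(toy3)
        via2 = set_diagonal(set_diagonal(cm, 2.0, mort), 1.0, mort)
        direct = set_diagonal(cm, 1.0, mort)
        np.testing.assert_array_equal(via2.alpha, direct.alpha)

    def test_negative_s_rejected(self, toy3):
        _, mort, cm = pipeline(toy3)
        with pytest.raises(WebValidationError):
            set_diagonal(cm, -0.1, mort)

    def test_donor_policy_sets_detritus_selfterm(self, toy3):
        flows, mort, _ = pipeline(toy3)
        cm = build_matrix(toy3, flows, mort, detritus_diagonal="donor")
        out = set_diagonal(cm, 1.0, mort)
        d = toy3.index("D")
        expected = -flows.flows[d, :].sum() / toy3.group("D").biomass
        assert out.alpha[d, d] == pytest.approx(expected)
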