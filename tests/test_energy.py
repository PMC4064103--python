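import math

import pytest

from hierfold import (
    RnaSequence,
    SecondaryStructure,
    parse_structure,
)
from hierfold.energy import (
    EnergyError,
    INF,
    Loop,
    _scale,
    decompose,
    evaluate_centi,
    evaluate_structure,
    load_params,
    loop_energy,
)
from hierfold.structures import BasePair, StructureError


# Table-style constants of the pseudoknot model, hundredths of kcal/mol
EXPECTED_CONSTANTS = {
    "P_s": -138, "P_sm": 1007, "P_sp": 1500, "P_b": 246, "P_up": 6, "P_ps": 96,
    "a": 339, "b": 3, "c": 2, "a_prime": 341, "b_prime": 56, "c_prime": 12,
    "band_stack_factor": 89, "band_internal_factor": 74,
}


class TestLoader:
    def test_default_constants(self, model):
        for name, value in EXPECTED_CONSTANTS.items():
            assert getattr(model, name) == value, name

    def test_missing_table(self, tmp_path):
        path = tmp_path / "p.par"
        lines = ["[constants]"] + [
            f"{k} = {v / 100}" for k, v in EXPECTED_CONSTANTS.items()
        ]
        path.write_text("\n".join(lines))
        with pytest.raises(EnergyError, match="missing table: stack"):
            load_params(str(path))

    def test_missing_scalar(self, tmp_path):
        path = tmp_path / "p.par"
        path.write_text("[constants]\nP_s = -1.38\n")
        with pytest.raises(EnergyError, match="missing constant"):
            load_params(str(path))

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "p.par"
        lines = (
            ["[constants]"]
            + [f"{k} = {v / 100}" for k, v in EXPECTED_CONSTANTS.items()]
            + ["[hairpin_loop]", "3 5.4", "[internal_loop]", "2 1.5"]
            + ["[stack]", "AU AU not-a-number"]
        )
        path.write_text("\n".join(lines))
        with pytest.raises(EnergyError, match=r":21"):
            load_params(str(path))

    def test_stack_table_symmetry(self, model):
        # e(XY/ZW) == e(WZ/YX): the physical 180-degree rotation
        for (xy, zw), e in model.stack_table.items():
            mirror = (zw[1] + zw[0], xy[1] + xy[0])
            assert model.stack_table[mirror] == e


class TestElementaryTerms:
    def test_multiloop_linear_form(self, model):
        # 3 branch pairs and 4 unpaired bases: a + 3b + 4c = 3.56 kcal/mol
        assert model.multiloop(3, 4) == 356

    def test_band_factors_fixed_point_whole_table(self, model):
        for key, e in model.stack_table.items():
            assert _scale(e, 89) == int(
                math.copysign(math.floor(abs(e * 0.89) + 0.5), e * 0.89)
            )
        for n1 in range(0, 10):
            for n2 in range(0, 10):
                if not (n1 or n2):
                    continue
                plain = model.internal(n1, n2)
                band = model.band_internal(n1, n2)
                assert band == _scale(plain, 74)

    def test_hairpin_minimum(self, model):
        assert model.hairpin(2) >= INF
        assert model.hairpin(3) == 540

    def test_loop_energy_rejects_tiny_hairpin(self, model):
        seq = RnaSequence("GAAC")
        with pytest.raises(EnergyError):
            loop_energy(model, Loop("hairpin", closing=BasePair(1, 4)), seq)

    def test_band_ratios(self, model):
        seq = RnaSequence("GGAACC")
        closing, inner = BasePair(1, 6), BasePair(2, 5)
        plain = loop_energy(model, Loop("stack", closing=closing, inner=inner), seq)
        band = loop_energy(
            model, Loop("stack", closing=closing, inner=inner, band_spanning=True), seq
        )
        assert abs(band / plain - 0.89) < 0.005
        plain_i = loop_energy(model, Loop("internal", n1=1, n2=1), seq)
        band_i = loop_energy(model, Loop("internal", n1=1, n2=1, band_spanning=True), seq)
        assert abs(band_i / plain_i - 0.74) < 0.005


class TestDecompose:
    def test_single_helix(self, model):
        seq = RnaSequence("GGCAAAAAGCC")
        s = SecondaryStructure([(1, 11), (2, 10), (3, 9)])
        loops = decompose(s, seq).loops
        kinds = sorted(l.kind for l in loops)
        assert kinds == ["hairpin", "stack", "stack"]
        assert evaluate_centi(s, seq, model) == -330 - 340 + 570

    def test_h_type_hand_ledger(self, model):
        seq = RnaSequence("GGAAAGAACCAAACUA")
        s = SecondaryStructure([(1, 10), (2, 9), (5, 15), (6, 14)])
        loops = decompose(s, seq).loops
        pl = [l for l in loops if l.kind == "pseudoloop"]
        assert len(pl) == 1 and pl[0].context == "exterior"
        assert pl[0].n_bands == 2 and pl[0].n_unpaired == 7
        stacks = [l for l in loops if l.kind == "stack"]
        assert len(stacks) == 2 and all(l.band_spanning for l in stacks)
        # P_s + 2 P_b + 7 P_up + 0.89*(-3.30) + 0.89*(-2.10), half-away rounding
        assert evaluate_centi(s, seq, model) == -138 + 2 * 246 + 7 * 6 - 294 - 187

    def test_pseudoknot_in_multiloop_charges_psm(self, model):
        base = RnaSequence("GGAAAGAACCAAACUA")
        seq = RnaSequence("G" + base.bases + "AC")
        inner_pairs = [(i + 1, j + 1) for (i, j) in [(1, 10), (2, 9), (5, 15), (6, 14)]]
        s = SecondaryStructure([(1, 19)] + inner_pairs)
        pl = [l for l in decompose(s, seq).loops if l.kind == "pseudoloop"][0]
        assert pl.context == "multiloop"
        # only the initiation differs from the exterior placement
        exterior = [
            l for l in decompose(SecondaryStructure(
                [(i, j) for i, j in [(1, 10), (2, 9), (5, 15), (6, 14)]]
            ), base).loops if l.kind == "pseudoloop"
        ][0]
        delta = loop_energy(model, pl, seq) - loop_energy(model, exterior, base)
        assert abs(delta - 11.45) < 1e-9

    def test_additivity(self, model):
        seq = RnaSequence("GGAAAGAACCAAACUA")
        s = SecondaryStructure([(1, 10), (2, 9), (5, 15), (6, 14)])
        dec = decompose(s, seq)
        total = sum(loop_energy(model, l, seq) for l in dec.loops)
        assert abs(total - evaluate_structure(s, seq, model)) < 1e-9

    def test_extra_band_costs_exactly_pb(self, model):
        sA = RnaSequence("GAAAAAAAACAAAAAAAU")
        rA = SecondaryStructure([(1, 10), (5, 18)])
        sB = RnaSequence("GAAAAAAAACAGAAUAAAAC")
        rB = SecondaryStructure([(1, 10), (5, 15), (12, 20)])
        delta = evaluate_centi(rB, sB, model) - evaluate_centi(rA, sA, model)
        assert delta == 246

    def test_energy_depends_only_on_pair_set(self, model):
        seq = RnaSequence("GGAAAGAACCAAACUA")
        s = SecondaryStructure([(1, 10), (2, 9), (5, 15), (6, 14)])
        text = "((..[[..))...]]."
        alt = "{{..<<..}}...>>."
        assert parse_structure(text, 16) == parse_structure(alt, 16)
        assert evaluate_centi(parse_structure(alt, 16), seq, model) == evaluate_centi(
            s, seq, model
        )

    def test_rejects_non_density_two(self, model):
        seq = RnaSequence("G" * 25 + "C" * 25)
        s = SecondaryStructure([(1, 30), (10, 40), (20, 50)])
        with pytest.raises(StructureError):
            decompose(s, seq)


class TestEvaluate:
    def test_empty_structure_scores_zero(self, model):
        assert evaluate_structure(SecondaryStructure(), RnaSequence("ACGU"), model) == 0.0

    def test_lone_hairpin_is_exactly_eh(self, model):
        seq = RnaSequence("GAAAAC")
        s = SecondaryStructure([(1, 6)])
        assert evaluate_centi(s, seq, model) == model.hairpin(4)

    def test_infeasible_hairpin_scores_inf(self, model):
        seq = RnaSequence("GAAC")
        s = SecondaryStructure([(1, 4)])
        assert evaluate_structure(s, seq, model) == math.inf
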