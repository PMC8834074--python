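import itertools

import numpy as np
import pandas as pd
import pytest

from qdgame.screen import (CATEGORY5, TABLE1_CLASSES, aggregate_category,
                           classify_table1, sign_of_dependence)


class TestSignOfDependence:
    def test_positive_when_significant_and_large(self):
        assert sign_of_dependence(0.5, 1.0, True) == "+"

    def test_neutral_when_not_significant(self):
        for nd in (-5.0, 0.0, 5.0):
            assert sign_of_dependence(nd, 1.0, False) == "0"

    def test_neutral_below_relative_threshold(self):
        assert sign_of_dependence(-0.03, 1.0, True, tau=0.05) == "0"
        assert sign_of_dependence(-0.07, 1.0, True, tau=0.05) == "-"

    def test_requires_positive_range(self):
        with pytest.raises(ValueError):
            sign_of_dependence(0.5, 0.0, True)


class TestClassifyTable1:
    @pytest.mark.parametrize("s12, s21, d12, d21, expected", [
        ("+", "+", 1.0, 1.0, "symmetric_synergism"),
        ("+", "+", 1.0, 2.0, "asymmetric_synergism"),
        ("+", "0", 1.0, 0.0, "directional_synergism_toward_k"),
        ("0", "+", 0.0, 1.0, "directional_synergism_toward_kprime"),
        ("+", "-", 1.0, -1.0, "altruism_toward_k"),
        ("-", "+", -1.0, 1.0, "altruism_toward_kprime"),
        ("-", "-", -1.0, -1.0, "symmetric_antagonism"),
        ("-", "-", -1.0, -3.0, "asymmetric_antagonism"),
        ("-", "0", -1.0, 0.0, "directional_antagonism_toward_k"),
        ("0", "-", 0.0, -1.0, "directional_antagonism_toward_kprime"),
        ("0", "0", 0.0, 0.0, "coexistence"),
    ])
    def test_eleven_classes(self, s12, s21, d12, d21, expected):
        assert classify_table1(s12, s21, d12, d21) == expected

    def test_symmetry_tolerance_boundary(self):
        # within 10% relative difference counts as symmetric
        assert classify_table1("+", "+", 1.0, 1.05) == "symmetric_synergism"
        assert classify_table1("+", "+", 1.0, 1.2) == "asymmetric_synergism"

    def test_total_over_all_sign_pairs(self):
        for s12, s21 in itertools.product("+0-", repeat=2):
            d12 = {"+": 1.0, "0": 0.0, "-": -1.0}[s12]
            d21 = {"+": 2.0, "0": 0.0, "-": -2.0}[s21]
            cls = classify_table1(s12, s21, d12, d21)
            assert cls in TABLE1_CLASSES


class TestAggregateCategory:
    def test_exhaustive_six_way_map(self):
        seen = {aggregate_category(c) for c in TABLE1_CLASSES}
        assert seen == {"synergistic", "directional_synergistic", "altruistic",
                        "antagonistic", "directional_antagonistic", "none"}

    @pytest.mark.parametrize("cls, cat", [
        ("symmetric_synergism", "synergistic"),
        ("directional_antagonism_toward_kprime", "directional_antagonistic"),
        ("coexistence", "none"),
    ])
    def test_examples(self, cls, cat):
        assert aggregate_category(cls) == cat

    def test_none_iff_coexistence(self):
        for cls in TABLE1_CLASSES:
            assert (CATEGORY5[cls] == "none") == (cls == "coexistence")

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            aggregate_category("mutualism")


class TestLabelSwapEquivariance:
    def test_swapping_cell_types_mirrors_directional_classes(self):
        """Relabeling k <-> k' maps 'toward k' onto 'toward k-prime'."""
        for s12, s21 in itertools.product("+0-", repeat=2):
            d12 = {"+": 1.0, "0": 0.0, "-": -1.0}[s12]
            d21 = {"+": 2.0, "0": 0.0, "-": -2.0}[s21]
            cls = classify_table1(s12, s21, d12, d21)
            swapped = classify_table1(s21, s12, d21, d12)
            if "toward_kprime" in cls:
                assert swapped == cls.replace("toward_kprime", "toward_k")
            elif "toward_k" in cls:
                assert swapped == cls.replace("toward_k", "toward_kprime")
            else:
                assert swapped == cls


class TestScreenPipeline:
    def test_small_screen_produces_report(self):
        """End-to-end screen over a 3-gene synthetic two-group table."""
        from qdgame.data import ExpressionTable
        from qdgame.screen import calls_to_frame, screen_genes
        from qdgame.simulate import default_ar1, default_pair_spec, simulate_pairwise

        rng = np.random.default_rng(0)
        rows, units = [], [f"u{i}" for i in range(12)]
        for g, (s12, s21) in enumerate([(3.0, 3.0), (0.0, 0.0), (3.0, -1.5)]):
            spec = default_pair_spec(s12, s21)
            prof, _ = simulate_pairwise(spec, default_ar1(), n=12, seed=g,
                                        ni_mode="consistent")
            rows.append((prof.g1, prof.g2))
        cols, data = [], np.zeros((3, 24))
        for i, u in enumerate(units):
            cols += [f"{u}_t1", f"{u}_t2"]
            for g in range(3):
                data[g, 2 * i] = rows[g][0][i]
                data[g, 2 * i + 1] = rows[g][1][i]
        values = pd.DataFrame(data, index=["gA", "gB", "gC"], columns=cols)
        meta = pd.DataFrame({
            "unit_id": [c.rsplit("_", 1)[0] for c in cols],
            "group_label": ["type1", "type2"] * 12,
            "stage": "s",
        }, index=cols)
        table = ExpressionTable(values, meta)
        calls, summary = screen_genes(table, n_perm=19, seed=0)
        frame = calls_to_frame(calls)
        assert len(frame) == 3
        assert set(frame["gene_id"]) == {"gA", "gB", "gC"}
        assert sum(summary.values()) == 3
        for c in calls:
            assert c.table1_class in TABLE1_CLASSES + ("unclassified",)
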