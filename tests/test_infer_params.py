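"""Recovery of per-residue descriptor tables by least squares."""

import numpy as np
import pytest

from aexapr.descriptors import (
    DISTINCT,
    MEAN,
    SUM,
    ResidueParamTable,
    mean_parameter,
    sum_parameter,
)
from aexapr.infer_params import (
    build_design_matrix,
    infer_mean_table,
    infer_sum_table,
)
from aexapr.reference_data import CANONICAL_RESIDUES, random_peptides


class TestDesignMatrix:
    def test_counts(self):
        cm = build_design_matrix(["CQQYN"])
        row = dict(zip(cm.residues, cm.matrix[0]))
        assert row == {"C": 1, "N": 1, "Q": 2, "Y": 1}

    def test_identical_sequences_identical_rows(self):
        cm = build_design_matrix(["ALLVN", "ALLVN"])
        assert (cm.matrix[0] == cm.matrix[1]).all()

    def test_row_sums_equal_lengths(self, records):
        cm = build_design_matrix([r.sequence for r in records])
        assert cm.matrix.shape[0] == 148
        assert (cm.matrix.sum(axis=1) == [len(r.sequence) for r in records]).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_design_matrix([])


class TestSumInference:
    def test_full_fixture_rot_recovered_exactly(self, records):
        """The rounded least-squares ROT table predicts every printed
        sequence-level ROT without error: the sum rule is exactly linear
        in residue composition."""
        res = infer_sum_table(
            [r.sequence for r in records], [r.rot for r in records], "ROT"
        )
        assert res.rank == res.n_observed_residues == 20
        assert res.max_abs_residual == 0.0

    def test_gsffl_rot_from_inferred_table(self, records):
        res = infer_sum_table(
            [r.sequence for r in records], [r.rot for r in records], "ROT"
        )
        assert sum_parameter("GSFFL", res.table) == 18.0

    @pytest.mark.parametrize("desc,attr", [
        ("AM", "am"), ("AC", "ac"), ("NON", "non"),
    ])
    def test_other_integer_descriptors_recovered(self, records, desc, attr):
        res = infer_sum_table(
            [r.sequence for r in records],
            [getattr(r, attr) for r in records], desc,
        )
        assert res.max_abs_residual == 0.0

    def test_cross_validated_integer_recovery(self, records):
        """Tables fitted on 120 rows predict the held-out 28 exactly."""
        rng = np.random.default_rng(20160707)
        idx = rng.permutation(len(records))
        train = [records[i] for i in idx[:120]]
        test = [records[i] for i in idx[120:]]
        for desc, attr in (("AM", "am"), ("AC", "ac"), ("ROT", "rot"), ("NON", "non")):
            res = infer_sum_table(
                [r.sequence for r in train], [getattr(r, attr) for r in train], desc
            )
            for r in test:
                assert sum_parameter(r.sequence, res.table) == getattr(r, attr), (desc, r.id)

    def test_real_valued_descriptors_not_rounded(self, records):
        res = infer_sum_table(
            [r.sequence for r in records], [r.ip for r in records], "IP"
        )
        # printed IP is rounded to two decimals, so small residuals remain
        assert 0 < res.max_abs_residual < 0.05
        assert any(v != round(v) for v in res.table.values.values())

    def test_degenerate_repeated_sequence_reports_rank_deficiency(self):
        res = infer_sum_table(["ALLVN", "ALLVN"], [15, 15], "ROT")
        assert res.rank == 1
        assert res.rank < res.n_observed_residues == 4

    def test_prediction_invariant_to_training_order(self, records):
        seqs = [r.sequence for r in records]
        vals = [r.hba for r in records]
        fwd = infer_sum_table(seqs, vals, "HBA")
        rev = infer_sum_table(seqs[::-1], vals[::-1], "HBA")
        for pep in ("ALLVN", "GSFFL", "WSWIR"):
            assert sum_parameter(pep, fwd.table) == pytest.approx(
                sum_parameter(pep, rev.table), abs=1e-8
            )


class TestMeanInference:
    def _synthetic(self, rule_mode, n=200, seed=42):
        rng = np.random.default_rng(seed)
        truth = {ch: float(v) for ch, v in
                 zip(CANONICAL_RESIDUES, rng.normal(0, 3, size=20))}
        table = ResidueParamTable("QPCaco", MEAN, truth)
        lengths = rng.integers(5, 11, size=n)
        peps = []
        for i, L in enumerate(lengths):
            peps.extend(random_peptides(1, int(L), seed=seed * 1000 + i))
        values = [mean_parameter(p, table, rule_mode) for p in peps]
        return truth, peps, values

    def test_recovery_from_synthetic_distinct_data(self):
        truth, peps, values = self._synthetic(DISTINCT)
        res = infer_mean_table(peps, values, "QPCaco")
        assert res.denominator_mode_selected == DISTINCT
        assert res.max_abs_residual < 1e-6
        for ch, v in truth.items():
            assert res.table.values[ch] == pytest.approx(v, abs=1e-6)

    def test_recovery_from_synthetic_length_data(self):
        truth, peps, values = self._synthetic("length")
        res = infer_mean_table(peps, values, "QPlogS")
        assert res.denominator_mode_selected == "length"
        assert res.max_abs_residual < 1e-6

    def test_sum_rule_recovery_from_synthetic_data(self):
        rng = np.random.default_rng(7)
        truth = {ch: float(v) for ch, v in
                 zip(CANONICAL_RESIDUES, rng.uniform(-5, 5, size=20))}
        table = ResidueParamTable("IP", SUM, truth)
        peps = random_peptides(200, 8, seed=11)
        values = [sum_parameter(p, table) for p in peps]
        res = infer_sum_table(peps, values, "IP")
        for ch, v in truth.items():
            assert res.table.values[ch] == pytest.approx(v, abs=1e-6)

    def test_fixture_qpcaco_selects_distinct(self, inferred):
        assert inferred["QPCaco"].denominator_mode_selected == DISTINCT

    def test_fixture_qplogs_selects_distinct(self, inferred):
        assert inferred["QPlogS"].denominator_mode_selected == DISTINCT

    def test_single_sequence_underdetermined(self):
        res = infer_mean_table(["ALLVN"], [4.41], "QPCaco")
        assert res.rank == 1
        assert res.rank < res.n_observed_residues

    def test_rule_mismatch_rejected(self):
        with pytest.raises(ValueError):
            infer_mean_table(["AA"], [1.0], "ROT")
        with pytest.raises(ValueError):
            infer_sum_table(["AA"], [1.0], "QPCaco")
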