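"""Contact maps, EC tables and prediction-evaluation metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from navpd.contact_analysis import (
    ContactEvalResult,
    ECRecord,
    ECSet,
    Scope,
    canonical_pair,
    compute_contact_map,
    evaluate_predictions,
    parse_ec_table,
    predict_contacts,
    write_ec_table,
)
from navpd.errors import ConfigurationError, ECTableFormatError, MissingResidueError
from navpd.structure_model import Atom, Residue, StructureModel, residue_min_distance


def _point_residue(domain, idx, xyz):
    return Residue(domain, idx, "GLY", [Atom("CA", "C", xyz)])


def _two_residue_model(distance):
    return StructureModel("pair", [
        _point_residue("D1", 1, [0.0, 0.0, 0.0]),
        _point_residue("D1", 2, [distance, 0.0, 0.0]),
    ])


class TestComputeContactMap:
    def test_pair_below_cutoff_in_contact(self):
        cmap = compute_contact_map(_two_residue_model(7.9), Scope.intra("D1"))
        assert cmap.n_pairs == 1

    def test_boundary_is_strict(self):
        cmap = compute_contact_map(_two_residue_model(8.0), Scope.intra("D1"))
        assert cmap.n_pairs == 0

    def test_unknown_domain(self):
        with pytest.raises(MissingResidueError):
            compute_contact_map(_two_residue_model(5.0), Scope.intra("D9"))

    def test_min_seq_sep_filters_neighbours(self):
        cmap = compute_contact_map(_two_residue_model(5.0), Scope.intra("D1"),
                                   min_seq_sep=2)
        assert cmap.n_pairs == 0

    def test_matches_brute_force_on_synthetic_helix(self, rng):
        """O(n²) brute-force oracle on a 30-residue perturbed helix."""
        residues = []
        for i in range(30):
            theta = math.radians(100.0) * i
            base = np.array([2.3 * math.cos(theta), 2.3 * math.sin(theta), 1.5 * i])
            coords = base + rng.normal(0, 0.8, (3, 3))
            residues.append(Residue("D1", i + 1, "ALA",
                                    [Atom(f"C{k}", "C", c) for k, c in enumerate(coords)]))
        model = StructureModel("helix", residues)
        cmap = compute_contact_map(model, Scope.intra("D1"))
        expected = set()
        for i, ra in enumerate(residues):
            for rb in residues[i + 1:]:
                if residue_min_distance(ra, rb) < 8.0:
                    expected.add(canonical_pair(ra.key, rb.key))
        assert set(cmap.pairs) == expected

    def test_inter_scope_matches_brute_force(self, bundle):
        cmap = compute_contact_map(bundle.model, Scope.inter("D1", "D2"))
        doms = bundle.model.domains()
        expected = {
            canonical_pair(ra.key, rb.key)
            for ra in doms["D1"] for rb in doms["D2"]
            if residue_min_distance(ra, rb) < 8.0
        }
        assert set(cmap.pairs) == expected


class TestECTable:
    def _ec(self):
        return ECSet([
            ECRecord(("D1", 1), ("D1", 5), 0.25),
            ECRecord(("D1", 2), ("D1", 6), 0.2),
            ECRecord(("D1", 3), ("D1", 7), 0.15),
        ], Scope.intra("D1"))

    def test_parse_three_rows(self, tmp_path):
        path = tmp_path / "ec.tsv"
        write_ec_table(self._ec(), path)
        back = parse_ec_table(path, Scope.intra("D1"))
        assert len(back) == 3

    def test_duplicates_keep_max_score(self):
        ec = ECSet([
            ECRecord(("D1", 1), ("D1", 5), 0.1),
            ECRecord(("D1", 5), ("D1", 1), 0.3),
        ], Scope.intra("D1"))
        assert len(ec) == 1
        assert ec.scores()[(("D1", 1), ("D1", 5))] == 0.3

    def test_roundtrip_equal_sets(self, tmp_path):
        path = tmp_path / "ec.tsv"
        ec = self._ec()
        write_ec_table(ec, path)
        back = parse_ec_table(path, Scope.intra("D1"))
        assert back.scores() == ec.scores()

    def test_malformed_row_reports_row_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("domain_i\tindex_i\tdomain_j\tindex_j\tscore\n"
                        "D1\t1\tD1\t5\t0.4\n"
                        "D1\toops\tD1\t6\t0.2\n")
        with pytest.raises(ECTableFormatError, match="row 3"):
            parse_ec_table(path, Scope.intra("D1"))

    def test_missing_columns(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("a\tb\n1\t2\n")
        with pytest.raises(ECTableFormatError, match="missing columns"):
            parse_ec_table(path, Scope.intra("D1"))


class TestPredictContacts:
    def test_strict_threshold(self):
        ec = ECSet([
            ECRecord(("D1", 1), ("D1", 5), 0.25),
            ECRecord(("D1", 2), ("D1", 6), 0.2),
            ECRecord(("D1", 3), ("D1", 7), 0.15),
        ], Scope.intra("D1"))
        assert len(predict_contacts(ec, 0.2)) == 1

    def test_empty_set(self):
        assert predict_contacts(ECSet([], Scope.intra("D1"))) == frozenset()

    def test_count_matches_brute_force_filter(self, rng):
        records = [ECRecord(("D1", i + 1), ("D1", i + 40), float(s))
                   for i, s in enumerate(rng.uniform(0, 1, 100))]
        ec = ECSet(records, Scope.intra("D1"))
        predicted = predict_contacts(ec, 0.2)
        assert len(predicted) == sum(1 for r in ec.records if r.score > 0.2)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(threshold=st.floats(-1.0, 1.2), seed=st.integers(0, 1000))
    def test_threshold_monotonicity(self, threshold, seed):
        """Raising the threshold never increases the predicted count."""
        r = np.random.default_rng(seed)
        records = [ECRecord(("D1", i + 1), ("D1", i + 30), float(s))
                   for i, s in enumerate(r.uniform(0, 1, 50))]
        ec = ECSet(records, Scope.intra("D1"))
        lower = predict_contacts(ec, threshold)
        higher = predict_contacts(ec, threshold + 0.1)
        assert higher <= lower


class TestEvaluatePredictions:
    def test_printed_count_arithmetic(self):
        """Precision recomputed from tabulated counts: 32 of 52 predicted → 61.538 %."""
        row = ContactEvalResult.from_counts(539, 52, 32, 8)
        assert row.precision_pct == pytest.approx(61.538, abs=5e-4)

    def test_disjoint_prediction_gives_zero_precision(self, bundle):
        cmap = bundle.intra_maps["D1"]
        non_contacts = [
            (("D1", i), ("D1", j))
            for i in range(1, 31) for j in range(i + 1, 31)
            if (("D1", i), ("D1", j)) not in cmap.pairs
        ][:10]
        ec = ECSet([ECRecord(a, b, 0.9) for a, b in non_contacts], Scope.intra("D1"))
        res = evaluate_predictions(ec, cmap)
        assert res.n_coin == 0
        assert res.precision_pct == 0.0

    def test_perfect_ec_set_gives_full_precision(self, bundle):
        """True pairs scored 1.0, others 0.0 → precision 100 %, n_t10 = min(10, CA_Str)."""
        cmap = bundle.intra_maps["D1"]
        records = [ECRecord(a, b, 1.0) for a, b in cmap.pairs]
        records += [ECRecord(("D1", 1), ("D1", 30), 0.0)]
        ec = ECSet(records, Scope.intra("D1"))
        res = evaluate_predictions(ec, cmap)
        assert res.precision_pct == pytest.approx(100.0)
        assert res.n_t10 == min(10, cmap.n_pairs)
        assert res.ca_str == cmap.n_pairs

    def test_low_threshold_predicts_everything(self, bundle):
        cmap = bundle.intra_maps["D1"]
        ec = ECSet([ECRecord(a, b, 0.5) for a, b in list(cmap.pairs)[:20]],
                   Scope.intra("D1"))
        res = evaluate_predictions(ec, cmap, threshold=-math.inf)
        assert res.ca_dca == len(ec)

    def test_zero_predictions_warns_nan(self, bundle):
        cmap = bundle.intra_maps["D1"]
        ec = ECSet([ECRecord(("D1", 1), ("D1", 20), 0.05)], Scope.intra("D1"))
        with pytest.warns(UserWarning):
            res = evaluate_predictions(ec, cmap, threshold=0.2)
        assert math.isnan(res.precision_pct)

    def test_scope_mismatch_rejected(self, bundle):
        ec = ECSet([ECRecord(("D2", 1), ("D2", 5), 0.5)], Scope.intra("D2"))
        with pytest.raises(ConfigurationError):
            evaluate_predictions(ec, bundle.intra_maps["D1"])

    def test_monotone_counts_in_threshold(self, bundle, default_spec):
        from navpd.synthetic import gen_ec
        ec = gen_ec(bundle.intra_maps["D1"], default_spec)
        prev_dca, prev_coin = math.inf, math.inf
        for thr in (0.1, 0.2, 0.3, 0.5):
            res = evaluate_predictions(ec, bundle.intra_maps["D1"], threshold=thr)
            assert res.ca_dca <= prev_dca
            assert res.n_coin <= prev_coin
            prev_dca, prev_coin = res.ca_dca, res.n_coin
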