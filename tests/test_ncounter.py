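"""Count-table I/O and the normalization chain."""

import numpy as np
import pandas as pd
import pytest

from nanosig import ncounter
from nanosig.ncounter import (
    NCounterError,
    QCThresholds,
    background_correct,
    positive_control_scale,
    qc_filter,
    read_counts,
    reference_normalize,
    write_counts,
)

from conftest import make_count_matrix


class TestReadCounts:
    def test_round_trip_identity(self, tmp_path):
        cm = make_count_matrix(
            endogenous={"G1": [10, 20], "G2": [5, 8]},
            negative={"NEG_A": [1, 2]},
            positive={"POS_A": [100, 110]},
        )
        path = tmp_path / "counts.tsv"
        write_counts(cm, path)
        back = read_counts(path)
        pd.testing.assert_frame_equal(back.counts, cm.counts)
        pd.testing.assert_frame_equal(back.probes, cm.probes)

    def test_negative_count_rejected_with_cell(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "probe_id\tgene_symbol\tprobe_class\tS1\nG1\tG1\tendogenous\t-3\n"
        )
        with pytest.raises(NCounterError, match="G1.*S1"):
            read_counts(path)

    def test_non_integer_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "probe_id\tgene_symbol\tprobe_class\tS1\nG1\tG1\tendogenous\t2.5\n"
        )
        with pytest.raises(NCounterError, match="non-integer"):
            read_counts(path)

    def test_duplicate_probe_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "probe_id\tgene_symbol\tprobe_class\tS1\n"
            "G1\tG1\tendogenous\t1\nG1\tG1\tendogenous\t2\n"
        )
        with pytest.raises(NCounterError, match="duplicate"):
            read_counts(path)

    def test_unknown_probe_class_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("probe_id\tgene_symbol\tprobe_class\tS1\nG1\tG1\tweird\t1\n")
        with pytest.raises(NCounterError, match="weird"):
            read_counts(path)


class TestBackgroundCorrect:
    def test_zero_background_leaves_counts(self):
        cm = make_count_matrix(
            endogenous={"G1": [10.0]}, negative={"NEG_A": [0.0], "NEG_B": [0.0]}
        )
        out = background_correct(cm)
        assert out.counts.loc["G1", "S1"] == 10.0

    def test_floor_applies_when_background_exceeds_count(self):
        cm = make_count_matrix(
            endogenous={"G1": [10.0]}, negative={"NEG_A": [10.0], "NEG_B": [10.0]}
        )
        assert background_correct(cm).counts.loc["G1", "S1"] == 1.0

    def test_mean_background_subtracted(self):
        # mean(4, 6) = 5; 100 - 5 = 95
        cm = make_count_matrix(
            endogenous={"G1": [100.0]}, negative={"NEG_A": [4.0], "NEG_B": [6.0]}
        )
        assert background_correct(cm).counts.loc["G1", "S1"] == 95.0

    def test_no_negative_controls_is_error(self):
        cm = make_count_matrix(endogenous={"G1": [10.0]})
        with pytest.raises(NCounterError, match="background"):
            background_correct(cm)

    def test_negative_controls_retained(self):
        cm = make_count_matrix(
            endogenous={"G1": [100.0]}, negative={"NEG_A": [4.0], "NEG_B": [6.0]}
        )
        out = background_correct(cm)
        assert out.counts.loc["NEG_A", "S1"] == 4.0

    def test_idempotent_once_negatives_zeroed(self):
        cm = make_count_matrix(
            endogenous={"G1": [100.0], "G2": [37.0]},
            negative={"NEG_A": [4.0], "NEG_B": [6.0]},
        )
        once = background_correct(cm)
        zeroed = once.counts.copy()
        zeroed.loc[["NEG_A", "NEG_B"]] = 0.0
        twice = background_correct(
            ncounter.CountMatrix(once.probes, zeroed)
        )
        pd.testing.assert_series_equal(
            twice.counts.loc["G1"], once.counts.loc["G1"]
        )


class TestPositiveControlScale:
    def test_identical_positives_leave_matrix_unchanged(self):
        cm = make_count_matrix(
            endogenous={"G1": [10.0, 20.0]},
            positive={"POS_A": [100.0, 100.0], "POS_B": [400.0, 400.0]},
        )
        out = positive_control_scale(cm)
        pd.testing.assert_frame_equal(out.counts, cm.counts)

    def test_scale_factors_from_geometric_means(self):
        # sample geomeans 8 and 2, grand geomean 4 -> factors 0.5 and 2
        cm = make_count_matrix(
            endogenous={"G1": [10.0, 10.0]},
            positive={"POS_A": [4.0, 1.0], "POS_B": [16.0, 4.0]},
        )
        out = positive_control_scale(cm)
        assert out.counts.loc["G1", "S1"] == pytest.approx(5.0)
        assert out.counts.loc["G1", "S2"] == pytest.approx(20.0)

    def test_all_zero_positives_flagged(self):
        cm = make_count_matrix(
            endogenous={"G1": [10.0, 10.0]},
            positive={"POS_A": [4.0, 0.0], "POS_B": [16.0, 0.0]},
        )
        with pytest.raises(NCounterError, match="S2"):
            positive_control_scale(cm)


class TestReferenceNormalize:
    def test_reference_genes_average_zero_per_sample(self):
        cm = make_count_matrix(
            endogenous={"G1": [100.0, 50.0]},
            reference={"R1": [10.0, 30.0], "R2": [40.0, 70.0]},
        )
        expr = reference_normalize(cm, ["R1", "R2"])
        assert np.allclose(expr.values.loc[["R1", "R2"]].mean(axis=0), 0.0)

    def test_invariant_to_per_sample_scaling(self):
        cm = make_count_matrix(
            endogenous={"G1": [100.0, 50.0]},
            reference={"R1": [10.0, 30.0], "R2": [40.0, 70.0]},
        )
        doubled = cm.counts.copy()
        doubled["S1"] *= 2
        expr_a = reference_normalize(cm, ["R1", "R2"])
        expr_b = reference_normalize(ncounter.CountMatrix(cm.probes, doubled),
                                     ["R1", "R2"])
        pd.testing.assert_frame_equal(expr_a.values, expr_b.values)

    def test_hand_value(self):
        # gene 8 vs reference geometric mean 2 -> log2(8) - log2(2) = 2
        cm = make_count_matrix(
            endogenous={"G1": [8.0]}, reference={"R1": [1.0], "R2": [4.0]}
        )
        expr = reference_normalize(cm, ["R1", "R2"])
        assert expr.values.loc["G1", "S1"] == pytest.approx(2.0)

    def test_missing_reference_gene_listed(self):
        cm = make_count_matrix(endogenous={"G1": [8.0]}, reference={"R1": [2.0]})
        with pytest.raises(NCounterError, match="R9"):
            reference_normalize(cm, ["R1", "R9"])

    def test_provenance_records_reference_set(self):
        cm = make_count_matrix(
            endogenous={"G1": [8.0]}, reference={"R1": [2.0], "R2": [2.0]}
        )
        expr = reference_normalize(cm, ["R2", "R1"])
        assert expr.reference_genes == ("R1", "R2")


class TestQCFilter:
    def test_zero_thresholds_exclude_nothing(self):
        cm = make_count_matrix(
            endogenous={"G1": [5.0, 0.0]}, negative={"NEG_A": [1.0, 1.0]}
        )
        kept, report = qc_filter(cm, QCThresholds(0, 0))
        assert report.excluded == []
        assert kept.samples == ["S1", "S2"]

    def test_all_zero_sample_excluded_for_total_counts(self):
        cm = make_count_matrix(
            endogenous={"G1": [5000.0, 0.0], "G2": [5000.0, 0.0]},
            negative={"NEG_A": [1.0, 1.0]},
        )
        kept, report = qc_filter(cm)
        assert report.excluded == ["S2"]
        assert report.reasons["S2"] == "total counts"

    def test_empty_cohort_is_error(self):
        cm = make_count_matrix(
            endogenous={"G1": [5.0]}, negative={"NEG_A": [1.0]}
        )
        with pytest.raises(NCounterError, match="empty cohort"):
            qc_filter(cm, QCThresholds(min_total_counts=1e9))

    def test_generator_degraded_samples_excluded(self):
        from nanosig.simulate import GeneratorConfig, generate_cohort

        cfg = GeneratorConfig(
            group_sizes={"control": 8},
            subtype_mixture={"control": {s: 0.2 for s in
                                         ("normal", "lumA", "lumB", "Her2", "basal")}},
            group_shifts={}, n_pairs={}, n_degraded=2, seed=5,
        )
        cm, _, truth = generate_cohort(cfg)
        kept, report = qc_filter(cm)
        assert set(report.excluded) == set(truth.index[truth["degraded"]])


def test_full_chain_invariant_to_sample_scaling():
    """Positive-control + reference normalization cancels a per-sample
    multiplicative factor applied to the raw counts."""
    cm = make_count_matrix(
        endogenous={"G1": [100, 200], "G2": [50, 75]},
        reference={"R1": [20, 30], "R2": [80, 90]},
        negative={"NEG_A": [0, 0], "NEG_B": [0, 0]},
        positive={"POS_A": [100, 120], "POS_B": [400, 390]},
    )
    scaled_counts = cm.counts.copy()
    scaled_counts["S2"] *= 3.7
    scaled_counts.loc[["NEG_A", "NEG_B"]] = 0.0
    cm_scaled = ncounter.CountMatrix(cm.probes, scaled_counts)
    a = ncounter.normalize(cm, ["R1", "R2"])
    b = ncounter.normalize(cm_scaled, ["R1", "R2"])
    assert np.allclose(a.values, b.values, atol=1e-12)


def test_full_chain_recovers_generator_fold_changes():
    """Normalized output recovers the generator's between-subtype log-fold
    differences for a strongly separated gene, within noise."""
    from nanosig.simulate import low_noise_config, generate_cohort
    from nanosig.signatures import load_packaged_centroids

    cfg = low_noise_config(n=200, seed=11)
    cm, _, truth = generate_cohort(cfg)
    cent = load_packaged_centroids()
    kept, _ = qc_filter(cm)
    expr = ncounter.normalize(kept, list(load_packaged_centroids().reference_genes))
    basal = truth.index[truth["true_subtype"] == "basal"]
    luma = truth.index[truth["true_subtype"] == "lumA"]
    for gene in ("KRT5", "ESR1"):
        observed = (
            expr.values.loc[gene, basal].mean() - expr.values.loc[gene, luma].mean()
        )
        expected = cent.centroids.loc[gene, "basal"] - cent.centroids.loc[gene, "lumA"]
        assert observed == pytest.approx(expected, abs=0.35)
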