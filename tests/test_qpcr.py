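import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from refstab.qpcr import (
    CqDataset,
    DilutionSeries,
    QpcrError,
    UnresolvableReplicatesError,
    average_tech_reps,
    collapse_tech_reps,
    fit_efficiency,
    percent_efficiency,
    qc_3p5p,
    qpcr_cv,
    relative_expression,
)


def make_rel(records):
    """Long rel_expr frame from (gene, tissue, bio_rep, rel_expr) tuples."""
    return pd.DataFrame(
        records, columns=["gene", "tissue", "bio_rep", "rel_expr"]
    ).assign(species="mim")


class TestTechReps:
    def test_within_one_cq_plain_mean(self):
        mean, dropped = average_tech_reps([20.0, 20.1, 20.2])
        assert mean == pytest.approx(20.1)
        assert dropped is None

    def test_outlier_dropped_and_remaining_averaged(self):
        mean, dropped = average_tech_reps([20.0, 20.1, 23.0])
        assert dropped == 2
        assert mean == pytest.approx(20.05)

    def test_outlier_below_also_detected(self):
        mean, dropped = average_tech_reps([17.0, 20.1, 20.0])
        assert dropped == 0
        assert mean == pytest.approx(20.05)

    def test_singleton_passthrough(self):
        assert average_tech_reps([20.0]) == (20.0, None)

    def test_two_discordant_reps_unresolvable(self):
        with pytest.raises(UnresolvableReplicatesError):
            average_tech_reps([20.0, 21.5])

    def test_collapse_excludes_unresolvable_groups(self):
        rec = pd.DataFrame(
            {
                "gene": ["A"] * 2 + ["B"] * 3,
                "species": "mim",
                "tissue": "leaf",
                "bio_rep": 1,
                "tech_rep": [1, 2, 1, 2, 3],
                "cq": [20.0, 22.0, 25.0, 25.1, 24.9],
            }
        )
        collapsed, log = collapse_tech_reps(rec)
        assert list(collapsed["gene"]) == ["B"]
        assert collapsed["cq"].iloc[0] == pytest.approx(25.0)
        assert (log["event"] == "excluded_unresolvable").sum() == 1


class TestEfficiency:
    def test_perfect_doubling_assay(self):
        s = DilutionSeries([1, 0.25, 0.0625], [20.0, 22.0, 24.0])
        assert fit_efficiency(s) == pytest.approx(2.0, abs=1e-12)
        assert s.slope == pytest.approx(-math.log2(10), abs=1e-12)  # -3.3219

    def test_slope_minus_3_59_gives_1_90(self):
        # synthesize exact points on a slope -3.59 line
        dil = [1, 0.25, 0.0625, 0.015625]
        cq = [18.0 - 3.59 * math.log10(d) for d in dil]
        s = DilutionSeries(dil, cq)
        assert fit_efficiency(s) == pytest.approx(10 ** (1 / 3.59), abs=1e-9)
        assert fit_efficiency(s) == pytest.approx(1.90, abs=0.005)
        assert percent_efficiency(s.efficiency) == pytest.approx(90.0, abs=0.5)

    def test_two_points_insufficient(self):
        with pytest.raises(QpcrError, match="at least 3"):
            fit_efficiency(DilutionSeries([1, 0.25], [20.0, 22.0]))

    def test_positive_slope_is_assay_failure(self):
        with pytest.raises(QpcrError, match="slope"):
            fit_efficiency(DilutionSeries([1, 0.25, 0.0625], [20.0, 19.0, 18.0]))

    @given(st.floats(1.5001, 2.1))
    def test_exact_recovery_on_noiseless_series(self, e):
        dil = [0.25**k for k in range(5)]
        cq = [20.0 - math.log(d, e) for d in dil]
        s = DilutionSeries(dil, cq)
        assert fit_efficiency(s) == pytest.approx(e, rel=1e-9)


def make_dataset(rows, efficiencies, calibrator=("A", ("mim", "leaf", 1))):
    rec = pd.DataFrame(rows, columns=["gene", "tissue", "bio_rep", "cq"])
    rec["species"] = "mim"
    return CqDataset(rec, efficiencies, calibrator)


class TestRelativeExpression:
    def test_delta_cq_zero_gives_one(self):
        ds = make_dataset([("A", "leaf", 1, 20.0)], {"A": 2.0})
        rel = relative_expression(ds)
        assert rel["rel_expr"].iloc[0] == pytest.approx(1.0)

    def test_one_cycle_earlier_doubles(self):
        ds = make_dataset(
            [("A", "leaf", 1, 20.0), ("A", "stem", 1, 19.0)], {"A": 2.0}
        )
        rel = relative_expression(ds).set_index("tissue")
        assert rel.loc["stem", "rel_expr"] == pytest.approx(2.0)

    def test_fractional_efficiency_hand_value(self):
        ds = make_dataset(
            [("A", "leaf", 1, 22.4), ("A", "stem", 1, 24.1)], {"A": 1.9}
        )
        rel = relative_expression(ds).set_index("tissue")
        assert rel.loc["stem", "rel_expr"] == pytest.approx(1.9 ** -1.7, abs=1e-9)
        assert rel.loc["stem", "rel_expr"] == pytest.approx(0.336, abs=0.001)

    def test_missing_calibrator_errors_with_count(self):
        ds = make_dataset([("A", "stem", 1, 20.0)], {"A": 2.0})
        with pytest.raises(QpcrError, match="1 records"):
            relative_expression(ds)

    def test_calibrator_resolved_per_run(self):
        rec = pd.DataFrame(
            {
                "gene": ["A", "B", "A", "B"],
                "species": "mim",
                "tissue": ["leaf", "stem", "leaf", "stem"],
                "bio_rep": 1,
                "cq": [20.0, 19.0, 21.0, 20.0],
                "run_id": ["r1", "r1", "r2", "r2"],
            }
        )
        ds = CqDataset(rec, {"A": 2.0, "B": 2.0}, ("A", ("mim", "leaf", 1)))
        rel = relative_expression(ds)
        # in each run, B sits one cycle below that run's calibrator
        assert rel.loc[rel["gene"] == "B", "rel_expr"].tolist() == pytest.approx(
            [2.0, 2.0]
        )

    def test_run_without_calibrator_errors(self):
        rec = pd.DataFrame(
            {
                "gene": ["A", "B"],
                "species": "mim",
                "tissue": ["leaf", "stem"],
                "bio_rep": 1,
                "cq": [20.0, 19.0],
                "run_id": ["r1", "r2"],
            }
        )
        ds = CqDataset(rec, {"A": 2.0, "B": 2.0}, ("A", ("mim", "leaf", 1)))
        with pytest.raises(QpcrError, match="r2"):
            relative_expression(ds)

    def test_monotone_decreasing_in_sample_cq(self):
        cqs = [18.0, 20.0, 25.0, 30.0]
        ds = make_dataset(
            [("A", "leaf", 1, 20.0)]
            + [("A", "stem", i + 1, c) for i, c in enumerate(cqs)],
            {"A": 1.9},
        )
        rel = relative_expression(ds)
        stem = rel[rel["tissue"] == "stem"].sort_values("bio_rep")["rel_expr"]
        assert (np.diff(stem) < 0).all()

    def test_cq_ceiling_enforced(self):
        with pytest.raises(QpcrError, match="Cq values"):
            make_dataset([("A", "leaf", 1, 41.0)], {"A": 2.0})

    def test_missing_efficiency_rejected(self):
        with pytest.raises(QpcrError, match="efficiency"):
            make_dataset([("A", "leaf", 1, 20.0)], {})


class TestQpcrCV:
    def test_equal_tissue_means_give_zero(self):
        rel = make_rel(
            [("A", t, r, 5.0) for t in ("leaf", "stem") for r in (1, 2)]
        )
        assert qpcr_cv(rel).loc["A", "cv"] == 0.0

    def test_hand_computed_tissue_mean_cv(self):
        rel = make_rel(
            [("A", t, 1, v) for t, v in zip(("leaf", "stem", "petal", "calyx"), (1, 2, 3, 4))]
        )
        out = qpcr_cv(rel)
        assert out.loc["A", "mean"] == pytest.approx(2.5)
        assert out.loc["A", "sd"] == pytest.approx(math.sqrt(5 / 3), abs=1e-6)
        assert out.loc["A", "cv"] == pytest.approx(0.5163978, abs=1e-6)

    def test_bio_reps_averaged_before_cv(self):
        rel = make_rel(
            [("A", "leaf", 1, 1.0), ("A", "leaf", 2, 3.0), ("A", "stem", 1, 2.0)]
        )
        out = qpcr_cv(rel)
        assert out.loc["A", "cv"] == 0.0  # leaf mean 2.0 equals stem mean

    def test_tissue_exclusion(self):
        rel = make_rel(
            [("A", "leaf", 1, 1.0), ("A", "stem", 1, 1.0), ("A", "petal", 1, 9.0)]
        )
        assert qpcr_cv(rel, exclude_tissues={"petal"}).loc["A", "cv"] == 0.0
        assert qpcr_cv(rel).loc["A", "cv"] > 0.5

    def test_fewer_than_two_tissues_errors(self):
        rel = make_rel([("A", "leaf", 1, 1.0), ("A", "stem", 1, 2.0)])
        with pytest.raises(QpcrError, match="at least 2 tissues"):
            qpcr_cv(rel, exclude_tissues={"stem"})

    @given(st.floats(0.01, 100.0))
    def test_invariant_to_calibrator_rescaling(self, c):
        rel = make_rel(
            [("A", t, r, v) for (t, r), v in zip(
                [(t, r) for t in ("leaf", "stem", "petal") for r in (1, 2)],
                (1.0, 1.5, 4.0, 3.0, 0.5, 0.8),
            )]
        )
        base = qpcr_cv(rel).loc["A", "cv"]
        scaled = rel.assign(rel_expr=rel["rel_expr"] * c)
        assert qpcr_cv(scaled).loc["A", "cv"] == pytest.approx(base, rel=1e-9)


class TestThreePrimeFivePrime:
    def test_equal_ends_ratio_one(self):
        qc = qc_3p5p(20.0, 20.0, efficiency=2.0)
        assert qc.ratio_3p_5p == pytest.approx(1.0)
        assert qc.pass_

    def test_three_cycle_gap_fails(self):
        qc = qc_3p5p(20.0, 23.0, efficiency=2.0)
        assert qc.ratio_3p_5p == pytest.approx(8.0)
        assert not qc.pass_

    def test_reverse_gap_within_bounds(self):
        qc = qc_3p5p(22.0, 20.0, efficiency=2.0)
        assert qc.ratio_3p_5p == pytest.approx(0.25)
        assert qc.pass_

    @pytest.mark.parametrize("ratio,ok", [(0.2, True), (5.0, True), (0.19, False), (5.01, False)])
    def test_bounds_are_inclusive(self, ratio, ok):
        # a one-cycle gap at base `ratio` reproduces the ratio exactly
        qc = qc_3p5p(20.0, 21.0, efficiency=ratio)
        assert qc.ratio_3p_5p == ratio
        assert qc.pass_ is ok
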