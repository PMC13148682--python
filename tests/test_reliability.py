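"""ICC(3,1) against an explicit sums-of-squares oracle, bands, table building."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import netretest as nt
from netretest.reliability import records_to_frame
from netretest.metrics import ScanMetricRecord
from oracles import anova_icc31


class TestIcc31:
    def test_perfect_reliability(self):
        rec, dec = nt.icc_3_1(np.array([[1, 1], [2, 2], [3, 3]], float))
        assert rec.icc == pytest.approx(1.0)
        assert dec.ms_error == pytest.approx(0.0)

    def test_constant_session_offset_still_perfect(self):
        # consistency ICC: the session main effect is absorbed
        X = np.array([[1, 3], [2, 4], [3, 5]], float)
        rec, _ = nt.icc_3_1(X)
        assert rec.icc == pytest.approx(1.0)
        oracle, *_ = anova_icc31(X)
        assert rec.icc_raw == pytest.approx(oracle, abs=1e-12)

    def test_matches_hand_oracle(self):
        X = np.array([[1, 2], [2, 3], [4, 6], [5, 8]], float)
        rec, dec = nt.icc_3_1(X)
        icc, msp, mss, mse = anova_icc31(X)
        assert rec.icc_raw == pytest.approx(icc, abs=1e-12)
        assert dec.ms_subjects == pytest.approx(msp, abs=1e-12)
        assert dec.ms_sessions == pytest.approx(mss, abs=1e-12)
        assert dec.ms_error == pytest.approx(mse, abs=1e-12)
        assert dec.df_subjects == 3 and dec.df_sessions == 1 and dec.df_error == 3

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(200):
            n = rng.integers(3, 10)
            d = rng.integers(2, 5)
            X = rng.normal(0, 1, (n, d))
            rec, _ = nt.icc_3_1(X)
            assert rec.icc_raw == pytest.approx(anova_icc31(X)[0], abs=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(10):
            X = rng.normal(0, 1, (8, 3))
            rec, _ = nt.icc_3_1(X)
            df = pd.DataFrame({
                "subject": np.repeat(np.arange(8), 3),
                "session": np.tile(np.arange(3), 8),
                "score": X.ravel(),
            })
            out = pg.intraclass_corr(df, targets="subject", raters="session",
                                     ratings="score")
            # ICC(C,1): consistency, single rater == ICC(3,1)
            ref = float(out.loc[out["Type"] == "ICC(C,1)", "ICC"].iloc[0])
            assert rec.icc_raw == pytest.approx(ref, abs=1e-9)

    def test_negative_raw_icc_clamped_and_preserved(self, rng):
        # anti-correlated sessions give a negative raw ICC
        x = rng.normal(0, 1, 20)
        X = np.column_stack([x, -x])
        rec, _ = nt.icc_3_1(X)
        assert rec.icc_raw < 0
        assert rec.icc == 0.0
        assert rec.category == "poor"

    def test_listwise_deletion_of_incomplete_subjects(self):
        X = np.array([[1, 2], [2, 3], [4, 6], [np.nan, 8], [5, 7]], float)
        rec, _ = nt.icc_3_1(X)
        assert rec.n_subjects == 4
        ref, *_ = anova_icc31(np.array([[1, 2], [2, 3], [4, 6], [5, 7]], float))
        assert rec.icc_raw == pytest.approx(ref, abs=1e-12)

    def test_too_few_subjects_error(self):
        with pytest.raises(nt.ValidationError):
            nt.icc_3_1(np.array([[1, 2], [2, 3]], float))

    def test_zero_variance_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="zero total variance"):
            rec, _ = nt.icc_3_1(np.full((4, 2), 3.0))
        assert rec.icc_raw == 0.0

    @given(arrays(np.float64, (6, 2),
                  elements=st.floats(-10, 10, allow_nan=False)),
           st.floats(0.1, 5), st.floats(-3, 3))
    def test_affine_invariance(self, X, a, b):
        if np.ptp(X) < 1e-6:  # degenerate: variance lost to rounding
            return
        r1, _ = nt.icc_3_1(X)
        r2, _ = nt.icc_3_1(a * X + b)
        assert r1.icc_raw == pytest.approx(r2.icc_raw, abs=1e-10)


class TestCategorize:
    @pytest.mark.parametrize("icc, label", [
        (0.0, "poor"), (0.19, "poor"), (0.2, "fair"), (0.39, "fair"),
        (0.4, "moderate"), (0.59, "moderate"), (0.6, "good"), (0.79, "good"),
        (0.8, "excellent"), (0.85, "excellent"), (1.0, "excellent"),
    ])
    def test_bands(self, icc, label):
        assert nt.categorize_icc(icc) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(nt.ValidationError):
            nt.categorize_icc(-0.1)
        with pytest.raises(nt.ValidationError):
            nt.categorize_icc(1.2)


def make_records(values, networks=("A",), conditions=("RS",),
                 subjects=4, sessions=("ses1", "ses2")):
    """ScanMetricRecords with every metric set to the given per-scan value."""
    recs = []
    for network in networks:
        for condition in conditions:
            for i in range(subjects):
                for j, session in enumerate(sessions):
                    v = values(network, condition, i, j)
                    recs.append(ScanMetricRecord(
                        subject=f"s{i}", session=session, condition=condition,
                        network=network, degree_centrality=v,
                        clustering_coefficient=v + 1, betweenness_centrality=v + 2,
                        global_efficiency=v + 3, mean_shortest_path_length=v + 4,
                    ))
    return recs


class TestReliabilityTable:
    def test_cartesian_row_count(self, rng):
        recs = make_records(
            lambda *a: float(rng.normal()),
            networks=("A", "B", "C"), conditions=("RS", "NV"),
        )
        table = nt.reliability_table(recs)
        assert len(table) == 3 * 2 * 5

    def test_duplicated_sessions_are_perfectly_reliable(self, rng):
        draws = {}

        def val(network, condition, i, j):
            return draws.setdefault((network, condition, i), float(rng.normal()))

        table = nt.reliability_table(make_records(val))
        assert all(r.icc == pytest.approx(1.0) for r in table)

    def test_independent_sessions_have_near_zero_icc(self, rng):
        recs = make_records(lambda *a: float(rng.normal()), subjects=200)
        table = nt.reliability_table(recs)
        mean_icc = np.mean([r.icc for r in table])
        assert mean_icc == pytest.approx(0.0, abs=0.1)

    def test_unbalanced_sessions_rejected_with_offenders(self, rng):
        recs = make_records(lambda *a: float(rng.normal()))
        dropped = recs[1:]  # s0 loses one session
        with pytest.raises(nt.ValidationError, match="s0"):
            nt.reliability_table(dropped)

    def test_accepts_long_frame_input(self, rng):
        recs = make_records(lambda *a: float(rng.normal()))
        from_objects = nt.reliability_to_frame(nt.reliability_table(recs))
        from_frame = nt.reliability_to_frame(
            nt.reliability_table(records_to_frame(recs)))
        pd.testing.assert_frame_equal(from_objects, from_frame)
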