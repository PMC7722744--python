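"""Sign test of quantiles: comparison vector, exact binomial p-value,
two-period assessment, multi-period trend test and population analysis."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from callrhythm.cdr_io import Mode
from callrhythm.persistence import (
    analyze_population,
    assess_pair,
    assess_sequence,
    comparison_vector,
    format_pvalue,
    sign_test_pvalue,
)
from callrhythm.synthetic_data import SimulationConfig, generate_dataset, partition_for
from conftest import rhythm_from_counts


class TestComparisonVector:
    def test_direct_indicator_evaluation(self):
        z = comparison_vector(0.3, [0.2, 0.4], [0.1, 0.5])
        assert z.tolist() == [1, 0, 1, 0] and z.sum() == 2

    def test_y_smaller_than_every_x_gives_all_zero(self):
        assert comparison_vector(0.05, [0.2, 0.4], [0.1, 0.5]).sum() == 0

    def test_ties_count_as_failures(self):
        assert comparison_vector(0.3, [0.3], [0.3]).tolist() == [0, 0]

    def test_empty_vectors_rejected(self):
        with pytest.raises(ValueError):
            comparison_vector(0.3, [], [])

    @given(
        y=st.integers(0, 1024),
        x=st.lists(st.integers(0, 1024), min_size=1, max_size=20),
    )
    def test_monotone_transform_invariance(self, y, x):
        """Any strictly increasing transform of all dissimilarities leaves z
        unchanged (values on a 1/1024 grid so the transform stays strictly
        increasing in floating point)."""
        y = y / 1024.0
        x = np.array(x) / 1024.0
        transform = lambda v: np.exp(3.0 * np.asarray(v)) + np.asarray(v)
        z_raw = comparison_vector(y, x, x)
        z_tr = comparison_vector(float(transform(y)), transform(x), transform(x))
        assert np.array_equal(z_raw, z_tr)


class TestSignTest:
    def test_zero_successes_of_fifty(self):
        assert sign_test_pvalue(0, 50, 0.5) == pytest.approx(0.5**50, rel=1e-14)

    def test_one_success_of_fifty(self):
        assert sign_test_pvalue(1, 50, 0.5) == pytest.approx(51 * 0.5**50, rel=1e-14)

    def test_full_support_gives_one(self):
        assert sign_test_pvalue(50, 50, 0.5) == 1.0
        assert sign_test_pvalue(7, 7, 0.25) == 1.0

    def test_three_significant_figure_rendering(self):
        assert format_pvalue(sign_test_pvalue(0, 50, 0.5)) == "8.88E-16"
        assert format_pvalue(sign_test_pvalue(14, 50, 0.5)) == "1.30E-03"
        assert format_pvalue(1.0) == "1.00E+00"

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            sign_test_pvalue(5, 4, 0.5)
        with pytest.raises(ValueError):
            sign_test_pvalue(-1, 4, 0.5)
        with pytest.raises(ValueError):
            sign_test_pvalue(2, 4, 1.0)

    @given(n_comp=st.integers(1, 64), q=st.sampled_from([0.25, 0.5, 0.75]))
    def test_nondecreasing_in_n_plus(self, n_comp, q):
        ps = [sign_test_pvalue(k, n_comp, q) for k in range(n_comp + 1)]
        assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))
        assert ps[-1] == 1.0


def two_period_population(stable_owner="A"):
    """Population where the focal owner's two rhythms are identical and
    every other individual occupies different, mutually distinct hours."""
    rhythms = {}
    hours = {"A": (9, 9), "B": (7, 18), "C": (11, 22), "D": (13, 2)}
    for owner, (h1, h2) in hours.items():
        for period, h in zip(("T1", "T2"), (h1, h2)):
            counts = np.zeros(24)
            counts[h] = 10
            counts[(h + 1) % 24] = 5
            rhythms[(owner, period)] = rhythm_from_counts(counts, owner=owner, period=period)
    return rhythms


class TestAssessPair:
    def test_stable_focal_beats_all(self):
        res = assess_pair("A", "T1", "T2", two_period_population())
        assert res.y == 0.0
        assert res.n_plus == 0 and res.n_comp == 6
        assert res.p_value == pytest.approx(0.5**6)
        assert res.persistent

    def test_log_base_invariance_end_to_end(self):
        pop = two_period_population()
        res2 = assess_pair("B", "T1", "T2", pop, log_base=2.0)
        rese = assess_pair("B", "T1", "T2", pop, log_base=math.e)
        assert res2.n_plus == rese.n_plus
        assert res2.p_value == rese.p_value
        assert np.array_equal(res2.z, rese.z)

    def test_n_comp_is_two_n_minus_two(self):
        cfg = SimulationConfig(seed=3)
        records, _ = generate_dataset(cfg)
        analysis = analyze_population(records, partition_for(cfg), modes=[Mode.TOTAL])
        assert (analysis.table.n_comp == 50).all()


def multi_period_population(n_periods, stable=("A",)):
    """Rhythms over n_periods periods: stable owners repeat one profile,
    others hop to a fresh pair of hours each period."""
    rhythms = {}
    owners = ["A", "B", "C", "D"]
    for idx, owner in enumerate(owners):
        for k in range(n_periods):
            counts = np.zeros(24)
            if owner in stable:
                h = 8 + idx
            else:
                h = (3 * idx + 5 * k) % 24
            counts[h] = 10
            counts[(h + 2) % 24] = 4
            label = f"T{k + 1}"
            rhythms[(owner, label)] = rhythm_from_counts(counts, owner=owner, period=label)
    return rhythms


class TestAssessSequence:
    def test_requires_three_periods(self):
        with pytest.raises(ValueError, match="assess_pair"):
            assess_sequence("A", ["T1", "T2"], two_period_population())

    def test_all_persistent_pairs_give_half_power_nt_minus_one(self):
        """v all ones -> p = 0.5^(N_T - 1); with N_T = 4 this is 0.125,
        documenting the low power of short sequences."""
        rhythms = multi_period_population(4)
        seq = assess_sequence("A", ["T1", "T2", "T3", "T4"], rhythms)
        assert seq.v.tolist() == [1, 1, 1]
        assert seq.p_value == pytest.approx(0.125)
        assert not seq.trend_persistent  # 0.125 > 0.05

    def test_eight_periods_reach_significance(self):
        rhythms = multi_period_population(8)
        seq = assess_sequence("A", [f"T{k}" for k in range(1, 9)], rhythms)
        assert seq.v.tolist() == [1] * 7
        assert seq.p_value == pytest.approx(0.5**7)
        assert seq.trend_persistent

    def test_no_persistence_events_give_p_one(self):
        """A focal individual who changes drastically while the comparison
        population stays mutually similar fails every pairwise test, so
        v is all zeros and the trend p-value is 1."""

        def profile(h, main, shared):
            counts = np.zeros(24)
            counts[h], counts[12] = main, shared
            return counts

        rhythms = {}
        for k in range(4):
            label = f"T{k + 1}"
            # B hops to a fresh hour each period with little shared mass
            rhythms[("B", label)] = rhythm_from_counts(
                profile((5 * k + 1) % 24, 10, 2), owner="B", period=label
            )
            for owner, h in (("A", 8), ("C", 10), ("D", 11)):
                rhythms[(owner, label)] = rhythm_from_counts(
                    profile(h, 5, 10), owner=owner, period=label
                )
        seq = assess_sequence("B", ["T1", "T2", "T3", "T4"], rhythms)
        assert seq.v.sum() == 0 and seq.p_value == 1.0 and not seq.trend_persistent

    def test_v_mirrors_pairwise_verdicts(self):
        rhythms = multi_period_population(5)
        seq = assess_sequence("A", [f"T{k}" for k in range(1, 6)], rhythms)
        assert len(seq.v) == 4
        assert seq.v.tolist() == [int(r.p_value < r.alpha) for r in seq.per_pair_results]


@pytest.fixture(scope="module")
def dataset():
    cfg = SimulationConfig(seed=11)
    records, truth = generate_dataset(cfg)
    return cfg, records, truth


class TestAnalyzePopulation:
    def test_row_count_and_shape(self, dataset):
        cfg, records, _ = dataset
        analysis = analyze_population(records, partition_for(cfg))
        assert len(analysis.table) == 78  # 26 individuals x 3 modes
        assert set(analysis.table["mode"]) == {"outgoing", "incoming", "total"}
        assert (analysis.table.n_comp == 50).all()

    def test_deterministic_output(self, dataset, tmp_path):
        cfg, records, _ = dataset
        paths = []
        for name in ("a.csv", "b.csv"):
            analysis = analyze_population(records, partition_for(cfg))
            p = tmp_path / name
            analysis.table.to_csv(p, index=False)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_empty_period_individual_excluded_and_ncomp_shrinks(self, dataset):
        cfg, records, _ = dataset
        # remove every T2 call of individual A so their total-mode rhythm is undefined
        t2_start = partition_for(cfg).starts[1]
        pruned = [r for r in records if not (r.owner_id == "A" and r.timestamp >= t2_start)]
        analysis = analyze_population(pruned, partition_for(cfg), modes=[Mode.TOTAL])
        assert "A" not in set(analysis.table["individual"])
        assert (analysis.table.n_comp == 2 * 25 - 2).all()
        assert any(e["owner_id"] == "A" for e in analysis.exclusions)

    def test_bh_column_optional(self, dataset):
        cfg, records, _ = dataset
        plain = analyze_population(records, partition_for(cfg), modes=[Mode.TOTAL])
        adjusted = analyze_population(records, partition_for(cfg), modes=[Mode.TOTAL], bh_correct=True)
        assert "p_value_bh" not in plain.table.columns
        assert (adjusted.table.p_value_bh >= adjusted.table.p_value - 1e-15).all()

    def test_sequence_rows_for_four_periods(self):
        cfg = SimulationConfig(seed=5, n_periods=4, period_days=91)
        records, _ = generate_dataset(cfg)
        analysis = analyze_population(records, partition_for(cfg), modes=[Mode.TOTAL])
        assert len(analysis.sequence_results) == len(analysis.table) == 26
        assert all(len(s.v) == 3 for s in analysis.sequence_results)
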