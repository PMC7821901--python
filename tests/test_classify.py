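"""Class assignment, Freeman–Halton exact test, composition and pairing."""

import itertools
import math
import shutil
import subprocess
from fractions import Fraction
from functools import lru_cache

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher_2x2

from stoptrace import (
    InputError,
    classify_cell,
    composition_test,
    cross_context_compare,
    fisher_exact_rxc,
    start_stop_pairing,
)
from stoptrace.events import ResamplingResult


def _result(excited, inhibited, max_pct=99.0, min_pct=99.0, z_max=5.0, z_min=5.0):
    return ResamplingResult(
        observed_max=1.0,
        observed_min=-1.0,
        shuffled_max=np.zeros(1000),
        shuffled_min=np.zeros(1000),
        excited=excited,
        inhibited=inhibited,
        n_events=60,
        n_shuffles=1000,
        alpha=0.05,
        low_n=False,
        max_percentile=max_pct,
        min_percentile=min_pct,
        z_max=z_max,
        z_min=z_min,
    )


class TestClassifyCell:
    @pytest.mark.parametrize(
        "excited,inhibited,expected",
        [(True, False, "excited"), (False, True, "inhibited"), (False, False, "uncorrelated")],
    )
    def test_single_flag_maps_directly(self, excited, inhibited, expected):
        assert classify_cell(_result(excited, inhibited)) == expected

    def test_dual_flags_resolved_by_percentile_extremity(self):
        res = _result(True, True, max_pct=99.9, min_pct=96.0)
        assert classify_cell(res) == "excited"
        res = _result(True, True, max_pct=96.0, min_pct=99.9)
        assert classify_cell(res) == "inhibited"

    def test_saturated_percentiles_resolved_by_null_sd_margin(self):
        res = _result(True, True, max_pct=100.0, min_pct=100.0, z_max=3.0, z_min=9.0)
        assert classify_cell(res) == "inhibited"


# ---------------------------------------------------------------------------
# independent exact-Fraction enumeration oracle for the Freeman–Halton test

@lru_cache(maxsize=None)
def _margin_distribution(row_sums, col_sums):
    """All 2×c tables with the given margins and their exact probabilities."""
    r1, r2 = row_sums
    n = r1 + r2
    denom = Fraction(math.factorial(n))
    margin_num = Fraction(
        math.prod(math.factorial(v) for v in row_sums)
        * math.prod(math.factorial(v) for v in col_sums)
    )
    tables = []
    c = len(col_sums)

    def rec(j, left, row):
        if j == c - 1:
            if left <= col_sums[j]:
                full = row + (left,)
                bottom = tuple(col_sums[k] - full[k] for k in range(c))
                if all(v >= 0 for v in bottom):
                    cells = full + bottom
                    prob = margin_num / (
                        denom * math.prod(math.factorial(v) for v in cells)
                    )
                    tables.append((cells, prob))
            return
        for v in range(min(left, col_sums[j]) + 1):
            rec(j + 1, left - v, row + (v,))

    rec(0, r1, ())
    return tables


def oracle_freeman_halton(table):
    table = np.asarray(table, dtype=int)
    row_sums = tuple(int(v) for v in table.sum(axis=1))
    col_sums = tuple(int(v) for v in table.sum(axis=0))
    dist = _margin_distribution(row_sums, col_sums)
    obs = tuple(int(v) for v in table.ravel())
    p_obs = dict(dist)[obs]
    return float(sum(p for _, p in dist if p <= p_obs))


class TestFisherExactRxc:
    def test_2x2_closed_form_example(self):
        # hypergeometric enumeration: P([[3,1],[1,3]]) = 34/70
        assert fisher_exact_rxc([[3, 1], [1, 3]]) == pytest.approx(34 / 70, abs=1e-12)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact_rxc([[2, 2, 2], [2, 2, 2]]) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_row_swap_and_column_permutation(self):
        t = np.array([[5, 1, 3], [2, 6, 1]])
        p = fisher_exact_rxc(t)
        assert fisher_exact_rxc(t[::-1]) == pytest.approx(p, abs=1e-12)
        for perm in itertools.permutations(range(3)):
            assert fisher_exact_rxc(t[:, perm]) == pytest.approx(p, abs=1e-12)

    def test_matches_scipy_on_2x2_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = rng.integers(0, 12, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            _, p_ref = scipy_fisher_2x2(t, alternative="two-sided")
            assert fisher_exact_rxc(t) == pytest.approx(p_ref, abs=1e-10)

    def test_matches_fraction_oracle_on_small_2x3_tables(self):
        # every 2×3 table with total ≤ 8
        for total in range(1, 9):
            for cells in itertools.product(range(total + 1), repeat=6):
                if sum(cells) != total:
                    continue
                t = np.array(cells).reshape(2, 3)
                if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
                    continue
                assert fisher_exact_rxc(t) == pytest.approx(
                    oracle_freeman_halton(t), abs=1e-12
                ), t

    def test_matches_r_fisher_test(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        tables = [[[5, 1, 3], [2, 6, 1]], [[10, 0, 0], [0, 10, 0]], [[4, 4], [4, 4]]]
        script = tmp_path / "fisher.R"
        script.write_text(
            "\n".join(
                f"cat(fisher.test(matrix(c({','.join(str(v) for row in t for v in row)}),"
                f"nrow=2,byrow=TRUE))$p.value, '\\n')"
                for t in tables
            )
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, check=True
        )
        r_ps = [float(x) for x in out.stdout.split()]
        for t, p_ref in zip(tables, r_ps):
            # Rscript prints ~7 significant digits
            assert fisher_exact_rxc(t) == pytest.approx(p_ref, rel=1e-6)

    def test_invalid_tables_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_rxc([[1.5, 2.0], [1.0, 3.0]])
        with pytest.raises(InputError):
            fisher_exact_rxc([[-1, 2], [3, 4]])
        with pytest.raises(InputError):
            fisher_exact_rxc(np.full((2, 3), 100))  # total beyond enumeration bound


def _cells(classes, locations):
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(classes))],
            "location": locations,
            "cell_class": classes,
        }
    )


class TestCompositionTest:
    def test_disjoint_groups_highly_significant(self):
        classes = ["excited"] * 10 + ["inhibited"] * 10
        locations = ["medial"] * 10 + ["lateral"] * 10
        table, p = composition_test(_cells(classes, locations))
        assert p < 1e-3
        assert table.loc["medial", "excited"] == 10

    def test_matched_groups_rarely_significant(self):
        rng = np.random.default_rng(1)
        n_sig = 0
        for _ in range(20):
            classes = list(rng.choice(["excited", "inhibited", "uncorrelated"],
                                      size=200, p=[0.5, 0.25, 0.25]))
            locations = ["medial", "lateral"] * 100
            _, p = composition_test(_cells(classes, locations))
            n_sig += p < 0.05
        assert n_sig <= 2  # ≥ 90% of null populations above 0.05

    def test_single_group_rejected(self):
        with pytest.raises(InputError):
            composition_test(_cells(["excited", "inhibited"], ["medial", "medial"]))

    def test_empty_cell_set_rejected(self):
        with pytest.raises(InputError):
            composition_test(_cells([], []))

    def test_class_fractions_sum_to_one_per_group(self):
        rng = np.random.default_rng(2)
        classes = list(rng.choice(["excited", "inhibited", "uncorrelated"], size=60))
        locations = list(rng.choice(["medial", "lateral"], size=60))
        table, _ = composition_test(_cells(classes, locations))
        frac = table.div(table.sum(axis=1), axis=0)
        assert np.allclose(frac.sum(axis=1), 1.0)


def _results(classes, peaks=None):
    n = len(classes)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "cell_class": classes,
            "peak": peaks if peaks is not None else np.linspace(0.2, 1.0, n),
        }
    )


class TestPairedComparisons:
    def test_identical_result_sets_fully_consistent(self):
        res = _results(["excited", "inhibited", "uncorrelated", "excited"])
        cmp = cross_context_compare(res, res)
        assert cmp.counts["n_included"] == 3  # uncorrelated-in-both excluded
        assert cmp.counts["consistent_both"] == 3
        assert cmp.counts["excited_both"] == 2

    def test_cells_significant_in_neither_context_excluded(self):
        a = _results(["uncorrelated", "excited"])
        b = _results(["uncorrelated", "uncorrelated"])
        cmp = cross_context_compare(a, b)
        assert cmp.counts["n_included"] == 1
        assert set(cmp.table.cell_id) == {"c1"}

    def test_no_shared_ids_rejected(self):
        a = _results(["excited"])
        b = _results(["excited"])
        b["cell_id"] = ["other"]
        with pytest.raises(InputError):
            cross_context_compare(a, b)

    def test_opposite_sign_pairs_counted(self):
        stop = _results(["excited", "inhibited", "excited"])
        start = _results(["inhibited", "excited", "excited"])
        pairing = start_stop_pairing(stop, start)
        assert pairing.counts["n_both_significant"] == 3
        assert pairing.counts["opposite_sign"] == 2
        assert pairing.counts["same_sign"] == 1

    def test_no_start_modulation_gives_zero_both_significant(self):
        stop = _results(["excited", "inhibited"])
        start = _results(["uncorrelated", "uncorrelated"])
        pairing = start_stop_pairing(stop, start)
        assert pairing.counts["n_both_significant"] == 0
        assert pairing.counts["n_included"] == 2
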