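"""Normalisation, Yanai tissue-specificity, high-expression rule and
tissue enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avirescue import expression as ex


def _matrix(counts, genes=None, tissues=None):
    counts = np.asarray(counts, dtype=float)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    tissues = tissues or [f"t{j}" for j in range(counts.shape[1])]
    return pd.DataFrame(counts, index=genes, columns=tissues)


class TestRpkm:
    def test_worked_example(self):
        m = _matrix([[10.0]])
        out = ex.rpkm(m, pd.Series({"g0": 1000}), pd.Series({"t0": 1_000_000}))
        assert out.iloc[0, 0] == pytest.approx(10.0)

    def test_zero_count(self):
        out = ex.rpkm(_matrix([[0.0]]), pd.Series({"g0": 500}), pd.Series({"t0": 1e6}))
        assert out.iloc[0, 0] == 0.0

    def test_halves_when_library_doubles(self):
        m = _matrix([[10.0]])
        lens = pd.Series({"g0": 1000})
        a = ex.rpkm(m, lens, pd.Series({"t0": 1e6}))
        b = ex.rpkm(m, lens, pd.Series({"t0": 2e6}))
        assert a.iloc[0, 0] == pytest.approx(2 * b.iloc[0, 0])

    def test_zero_length_error(self):
        with pytest.raises(ValueError):
            ex.rpkm(_matrix([[1.0]]), pd.Series({"g0": 0}))


class TestTpm:
    def test_symmetry(self):
        out = ex.tpm(_matrix([[5.0], [5.0]]), pd.Series({"g0": 100, "g1": 100}))
        assert out["t0"].tolist() == pytest.approx([500000.0, 500000.0])

    def test_length_weighting(self):
        out = ex.tpm(_matrix([[6.0], [6.0]]), pd.Series({"g0": 1000, "g1": 2000}))
        assert out["t0"].tolist() == pytest.approx([666666.67, 333333.33], rel=1e-6)

    def test_columns_sum_to_million(self, rng):
        m = _matrix(rng.integers(0, 1000, (20, 5)).astype(float))
        lens = pd.Series(rng.integers(200, 3000, 20), index=m.index)
        out = ex.tpm(m, lens)
        assert out.sum(axis=0).tolist() == pytest.approx([1e6] * 5, rel=1e-9)

    def test_all_zero_column_warns(self):
        m = _matrix([[0.0, 1.0], [0.0, 3.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            out = ex.tpm(m, pd.Series({"g0": 100, "g1": 100}))
        assert out["t0"].tolist() == [0.0, 0.0]


class TestTsi:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 1, 1, 1], 0.0), ([0, 0, 0, 5], 1.0), ([2, 4], 0.5)],
    )
    def test_examples(self, values, expected):
        r = ex.tsi(pd.Series(values, dtype=float), warn_few_tissues=False)
        assert r.tsi == pytest.approx(expected)

    def test_all_zero_is_missing(self):
        r = ex.tsi(pd.Series([0.0, 0.0, 0.0]), warn_few_tissues=False)
        assert np.isnan(r.tsi)

    def test_guard_warns_for_few_tissues(self):
        with pytest.warns(UserWarning, match="tissues"):
            ex.tsi(pd.Series([1.0, 2.0, 3.0]))

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.floats(0.0, 100.0, allow_subnormal=False), min_size=3, max_size=15
        ).filter(lambda v: max(v) > 1e-6),
        st.floats(0.01, 50.0, allow_subnormal=False),
    )
    def test_scale_invariance(self, values, c):
        a = ex.tsi(pd.Series(values), warn_few_tissues=False).tsi
        b = ex.tsi(pd.Series([c * v for v in values]), warn_few_tissues=False).tsi
        assert a == pytest.approx(b, abs=1e-9)

    def test_monotone_under_concentration(self, rng):
        for _ in range(20):
            v = rng.uniform(0.1, 10, 8)
            i_max = int(np.argmax(v))
            donors = [i for i in range(8) if i != i_max and v[i] > 0]
            j = int(rng.choice(donors))
            moved = v.copy()
            delta = moved[j] * 0.5
            moved[j] -= delta
            moved[i_max] += delta
            t0 = ex.tsi(pd.Series(v), warn_few_tissues=False).tsi
            t1 = ex.tsi(pd.Series(moved), warn_few_tissues=False).tsi
            assert t1 >= t0 - 1e-12

    def test_too_few_tissues_error(self):
        with pytest.raises(ValueError):
            ex.tsi(pd.Series([1.0]), warn_few_tissues=False)


class TestHighlyExpressed:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([9, 1, 1, 1], ["t0"]),  # mean 3, threshold 9, boundary inclusive
            ([1, 1, 1, 1], []),
            ([30, 1, 1, 1, 1, 1], ["t0"]),  # mean 5.83; only t0 reaches 3x
            ([0, 0, 0], []),
        ],
    )
    def test_rule(self, values, expected):
        v = pd.Series(values, index=[f"t{i}" for i in range(len(values))], dtype=float)
        assert ex.highly_expressed(v) == expected


class TestTissueEnrichment:
    def test_single_top_tissue(self):
        m = _matrix([[9, 1, 1], [8, 2, 1], [5, 0, 0]])
        out = ex.tissue_enrichment(m, ["g0", "g1"], ["g2"])
        assert out.loc["t0", "top_fraction_A"] == pytest.approx(1.0)
        assert out["top_fraction_A"].sum() == pytest.approx(1.0)
        assert out["top_fraction_B"].sum() == pytest.approx(1.0)

    def test_matches_argmax_tally_oracle(self, rng):
        m = _matrix(rng.uniform(0, 10, (12, 4)))
        genes_a = list(m.index[:6])
        genes_b = list(m.index[6:])
        out = ex.tissue_enrichment(m, genes_a, genes_b)
        tally = {t: 0.0 for t in m.columns}
        for g in genes_a:
            tally[m.loc[g].idxmax()] += 1  # no ties in continuous draws
        for t in m.columns:
            assert out.loc[t, "top_fraction_A"] == pytest.approx(tally[t] / len(genes_a))

    def test_tie_splitting(self):
        m = _matrix([[5, 5, 0]])
        out = ex.tissue_enrichment(m, ["g0"], ["g0"])
        assert out["top_fraction_A"].tolist() == pytest.approx([0.5, 0.5, 0.0])

    def test_empty_set_error(self):
        m = _matrix([[1.0, 2.0]])
        with pytest.raises(ValueError):
            ex.tissue_enrichment(m, [], ["g0"])
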