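import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from endoclone import (
    LineageTree,
    clone_stats,
    ks_two_sample,
    median_cell,
    mrca_table,
    stem_fraction,
    tumor_cdfs,
)
from endoclone.analytics import tumor_median_distribution
from endoclone.analytics import CdfTable


def snapshot(d, k, alpha):
    return pd.DataFrame({"d": d, "k": k, "alpha": alpha})


class TestCloneStats:
    def test_single_peak(self):
        class R:
            peak, lifespan_days = 1024, 150.0
        out = clone_stats([R()])
        assert out.loc["peak_cells", "median"] == 1024
        assert out.loc["peak_cells", "sd"] == 0.0

    def test_odd_sample_median(self):
        class R:
            def __init__(self, p):
                self.peak, self.lifespan_days = p, 100.0
        out = clone_stats([R(1024), R(1030), R(1040)])
        assert out.loc["peak_cells", "median"] == 1030

    def test_even_sample_midpoint_convention(self):
        class R:
            def __init__(self, p):
                self.peak, self.lifespan_days = p, 100.0
        out = clone_stats([R(1024), R(1043)])
        assert out.loc["peak_cells", "median"] == 1033.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            clone_stats([])


class TestTumorCdfs:
    def test_degenerate_snapshot(self):
        s = snapshot([44] * 5, [0.3] * 5, [10.0] * 5)
        cdfs = tumor_cdfs(s)
        probs = cdfs["d"].probabilities
        assert set(np.unique(probs)) <= {0.0, 1.0}
        assert cdfs["d"].median == 44

    def test_hand_counted_fractions(self):
        d = [28, 30, 30, 35, 41, 41, 44, 45, 46, 47]
        s = snapshot(d, np.linspace(0, 0.9, 10), np.linspace(1, 10, 10))
        tab = tumor_cdfs(s)["d"]
        by_bp = dict(zip(tab.breakpoints, tab.probabilities))
        assert by_bp[28] == 0.1
        assert by_bp[30] == 0.3
        assert by_bp[40] == 0.4
        assert by_bp[47] == 1.0

    def test_cdf_ends_at_one_and_median_consistent(self, rng):
        d = rng.integers(30, 47, 500)
        k = rng.uniform(0, 1.6, 500)
        a = rng.uniform(-5.0, 17.5, 500)  # within the tabulated alpha range
        cdfs = tumor_cdfs(snapshot(d, k, a))
        for var, col in (("d", d), ("k", k), ("alpha", a)):
            assert cdfs[var].probabilities[-1] == 1.0
            assert cdfs[var].median == np.median(col)

    def test_invalid_cdf_rejected(self):
        with pytest.raises(ValueError):
            CdfTable("d", [1.0, 1.0], [0.5, 1.0], median=1, n=2)
        with pytest.raises(ValueError):
            CdfTable("d", [1.0, 2.0], [0.8, 0.5], median=1, n=2)

    def test_empty_snapshot_rejected(self):
        with pytest.raises(ValueError):
            tumor_cdfs(snapshot([], [], []))


class TestStemFraction:
    def test_no_stem_cells(self):
        assert stem_fraction(snapshot([1], [0.4], [1.0])) == 0.0

    def test_two_of_ten(self):
        k = [0.0, 0.0] + [0.5] * 8
        assert stem_fraction(snapshot([1] * 10, k, [1.0] * 10)) == 0.2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stem_fraction(snapshot([], [], []))


class TestMrcaTable:
    def _toy_tumor(self, rng):
        codes = ["1"]
        leaves = ["1"]
        while len(leaves) < 64:
            parent = leaves.pop(rng.integers(len(leaves)))
            codes += [parent + "1", parent + "2"]
            leaves += [parent + "1", parent + "2"]
        k_birth = {c: float(rng.uniform(0, 2)) for c in codes}
        alpha_birth = {c: float(rng.uniform(1, 8)) for c in codes}
        return LineageTree.from_codes(codes, alive=leaves,
                                      k_birth=k_birth, alpha_birth=alpha_birth)

    def test_full_mass_row_is_root(self, rng):
        trees = [self._toy_tumor(rng) for _ in range(5)]
        table = mrca_table(trees)
        row = table.loc[("d", 1.0)]
        assert row["median"] == 1 and row["sd"] == 0.0
        assert row["min"] == 1 and row["max"] == 1

    def test_single_tumor_degenerate_stats(self, rng):
        table = mrca_table([self._toy_tumor(rng)])
        assert (table["median"] == table["min"]).all()
        assert (table["median"] == table["max"]).all()
        assert (table["sd"] == 0.0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mrca_table([])


class TestMedianCell:
    def test_single_cell_snapshot(self):
        s = pd.DataFrame({"d": [44], "g": [45], "k": [0.3], "alpha": [10.3]})
        mcc = median_cell(s)
        assert mcc["k"] == 0.3 and mcc["alpha"] == 10.3
        assert mcc["d"] == 44 and mcc["g"] == 45
        assert mcc["phenotype"].g == 45

    def test_componentwise_medians(self):
        s = pd.DataFrame({"d": [40, 44, 50], "g": [41, 45, 51],
                          "k": [0.0, 0.3, 0.6], "alpha": [8.0, 10.0, 14.0]})
        assert median_cell(s)["k"] == 0.3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_cell(pd.DataFrame({"d": [], "g": [], "k": [], "alpha": []}))


class TestTumorMedianDistribution:
    def test_moment_conventions(self, rng):
        # symmetric data: skewness ~ 0 and RAW kurtosis ~ 3 (not excess)
        det = pd.DataFrame({
            "median_k": rng.normal(0.3, 0.05, 4000),
            "median_alpha": rng.normal(10.3, 0.2, 4000),
            "median_d": rng.normal(45.0, 1.9, 4000),
        })
        out = tumor_median_distribution(det)
        assert out.loc["alpha", "kurtosis"] == pytest.approx(3.0, abs=0.3)
        assert out.loc["alpha", "skewness"] == pytest.approx(0.0, abs=0.15)
        assert out.loc["d", "mean"] == pytest.approx(45.0, abs=0.2)

    def test_requires_two_tumors(self):
        with pytest.raises(ValueError):
            tumor_median_distribution(pd.DataFrame(
                {"median_k": [0.3], "median_alpha": [10.0], "median_d": [44]}))


class TestKsTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_known_quartet(self):
        d, _ = ks_two_sample([1, 2, 3, 4], [3, 4, 5, 6])
        assert d == 0.5

    def test_undersized_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([1], [1, 2])

    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.normal(size=rng.integers(10, 300))
            b = rng.normal(rng.uniform(-1, 1), size=rng.integers(10, 300))
            d, _ = ks_two_sample(a, b)
            ref = scipy.stats.ks_2samp(a, b)
            assert abs(d - ref.statistic) < 1e-6


def test_ks_pvalue_matches_R_reference(tmp_path):
    """The asymptotic p-value agrees with R's classical two-sample
    Kolmogorov-Smirnov test (ks.test, exact = FALSE) to 1e-3 relative."""
    rng = np.random.default_rng(42)
    lines = ["results <- c()"]
    ours = []
    for _ in range(20):
        a = rng.normal(size=int(rng.integers(30, 150)))
        b = rng.normal(rng.uniform(-0.8, 0.8), size=int(rng.integers(30, 150)))
        _, p = ks_two_sample(a, b)
        ours.append(p)
        va = ",".join(repr(float(v)) for v in a)
        vb = ",".join(repr(float(v)) for v in b)
        lines.append(
            f"results <- c(results, ks.test(c({va}), c({vb}), exact=FALSE)$p.value)")
    lines.append('cat(sprintf("%.12g\\n", results))')
    script = tmp_path / "ks_reference.R"
    script.write_text("\n".join(lines))
    proc = subprocess.run(["Rscript", str(script)],
                          capture_output=True, text=True, timeout=300)
    assert proc.returncode == 0, proc.stderr
    ref = []
    for tok in proc.stdout.split():
        try:
            ref.append(float(tok))
        except ValueError:
            continue
    assert len(ref) == len(ours)
    for p_ours, p_ref in zip(ours, ref):
        assert p_ours == pytest.approx(p_ref, rel=1e-3, abs=1e-12)
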