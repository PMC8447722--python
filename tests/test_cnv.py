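"""Window-merging CNV caller against an independent brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popcnv import (DetectorParams, WindowCoverageMatrix, classify_b_contigs,
                    cnv_summary, detect_cnvs, normalize_coverage, tile_windows,
                    window_sd)
from conftest import copy_vector_matrix, scaled_config, W


# ---------------------------------------------------------------------------
# brute-force oracle: a literal, single-contig re-statement of the five
# merge criteria using scipy.stats.pearsonr directly (plain Pearson mode)

def oracle_runs(values, sd_threshold=0.7, alpha=0.05, min_windows=3):
    """Return the list of window-index lists a direct reading of the merge
    criteria produces for a single-contig matrix (rows = windows)."""
    n, _ = values.shape
    sd = values.std(axis=1, ddof=1)
    seeds = {i for i in range(n) if sd[i] > sd_threshold}

    def correlated(i, j):
        if values[i].std() == 0 or values[j].std() == 0:
            return False
        r, p = stats.pearsonr(values[i], values[j])
        return p < alpha

    # criteria 1+2: group adjacent correlated seed windows
    assigned = {}
    groups = []
    for i in sorted(seeds):
        if i - 1 in assigned and correlated(i - 1, i):
            grp = assigned[i - 1]
        else:
            grp = []
            groups.append(grp)
        grp.append(i)
        assigned[i] = grp

    # criterion 3: contig-end windows join an adjacent CNV
    def try_edge(edge, neighbor):
        grp = assigned.get(neighbor)
        if grp is None:
            return
        if edge in assigned:
            egrp = assigned[edge]
            if egrp is grp:
                return
            if len(egrp) > 1:
                return           # edge already in its own multi-window CNV
            groups.remove(egrp)
        grp.append(edge)
        grp.sort()
        assigned[edge] = grp

    if n >= 2:
        try_edge(0, 1)
        try_edge(n - 1, n - 2)

    # criterion 4: bridge exactly-one-window gaps, repeat until stable
    changed = True
    while changed:
        changed = False
        groups.sort(key=lambda g: g[0])
        for a, b in zip(groups, groups[1:]):
            gap = b[0] - a[-1] - 1
            if gap == 1 and correlated(a[-1], b[0]):
                merged = a + [a[-1] + 1] + b
                groups.remove(a)
                groups.remove(b)
                groups.append(sorted(merged))
                for i in merged:
                    assigned[i] = merged
                changed = True
                break

    # criterion 5: minimum length last
    groups.sort(key=lambda g: g[0])
    return [g for g in groups if len(g) >= min_windows]


def one_contig_matrix(values, contig="ctg"):
    values = np.asarray(values, dtype=float)
    ws = tile_windows({contig: values.shape[0] * W}, W)
    libs = [f"L{i}" for i in range(values.shape[1])]
    return WindowCoverageMatrix(ws, pd.DataFrame(values, columns=libs),
                                normalized=True)


def random_fixture(rng, n_windows, n_libs=10):
    """A random single-contig matrix mixing diploid background, correlated
    copy-number segments and uncorrelated high-variance windows."""
    vals = 2.0 + rng.normal(0, 0.1, size=(n_windows, n_libs))
    pos = 0
    while pos < n_windows - 1:
        seg = int(rng.integers(1, 8))
        kind = rng.random()
        if kind < 0.35:                       # correlated CNV segment
            copies = rng.integers(0, 7, size=n_libs).astype(float)
            vals[pos:pos + seg] = copies[None, :] + \
                rng.normal(0, 0.2, size=(min(seg, n_windows - pos), n_libs))
        elif kind < 0.5:                      # independent noisy windows
            vals[pos:pos + seg] = rng.normal(2.0, 1.5,
                                             size=(min(seg, n_windows - pos), n_libs))
        pos += seg + int(rng.integers(1, 5))
    return np.clip(vals, 0, None)


PEARSON = DetectorParams(correlation="pearson")


class TestDetectorOracleEquivalence:
    def test_all_diploid_matrix_yields_nothing(self):
        m = one_contig_matrix(np.full((20, 8), 2.0))
        assert detect_cnvs(m, PEARSON) == []

    def test_ten_window_copy_segment_is_one_cnv(self):
        m = copy_vector_matrix([0, 0, 2, 3, 4, 6], n_var=10, n_diploid_flank=5)
        cnvs = detect_cnvs(m, PEARSON)
        assert len(cnvs) == 1
        assert list(cnvs[0].window_indices) == list(range(5, 15))

    @pytest.mark.parametrize("n_var,expected", [(1, 0), (2, 0), (3, 1)])
    def test_minimum_length_filter(self, n_var, expected):
        m = copy_vector_matrix([0, 0, 2, 3, 4, 6], n_var=n_var,
                               n_diploid_flank=5)
        assert len(detect_cnvs(m, PEARSON)) == expected

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 51))
        vals = random_fixture(rng, n)
        m = one_contig_matrix(vals)
        got = [list(c.window_indices) for c in detect_cnvs(m, PEARSON)]
        expected = oracle_runs(vals)
        assert got == expected

    def test_maximality_no_adjacent_window_extends(self):
        rng = np.random.default_rng(99)
        vals = random_fixture(rng, 40)
        m = one_contig_matrix(vals)
        sd = window_sd(m)
        for c in detect_cnvs(m, PEARSON):
            idx = list(c.window_indices)
            for nb in (idx[0] - 1, idx[-1] + 1):
                if 0 <= nb < 40:
                    # the excluded neighbor fails seed or correlation or the
                    # contig-edge rule would have captured it
                    inner = idx[0] if nb < idx[0] else idx[-1]
                    r, p = stats.pearsonr(vals[nb], vals[inner])
                    assert (sd[nb] <= 0.7) or (p >= 0.05)


class TestDetectorBehavior:
    def test_unnormalized_matrix_rejected(self):
        m = one_contig_matrix(np.full((10, 4), 2.0))
        m.normalized = False
        with pytest.raises(ValueError):
            detect_cnvs(m, PEARSON)

    def test_short_contig_skipped_with_warning(self):
        ws = tile_windows({"tiny": 2 * W, "big": 20 * W}, W)
        vals = np.full((22, 6), 2.0)
        m = WindowCoverageMatrix(ws, pd.DataFrame(
            vals, columns=[f"L{i}" for i in range(6)]), normalized=True)
        with pytest.warns(UserWarning, match="tiny"):
            detect_cnvs(m, PEARSON)

    def test_determinism(self):
        rng = np.random.default_rng(3)
        m = one_contig_matrix(random_fixture(rng, 45))
        a = [list(c.window_indices) for c in detect_cnvs(m, PEARSON)]
        b = [list(c.window_indices) for c in detect_cnvs(m, PEARSON)]
        assert a == b

    def test_sd_threshold_monotonicity(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            m = one_contig_matrix(random_fixture(rng, 50))
            totals = []
            for thr in (0.4, 0.7, 1.2, 2.0):
                cnvs = detect_cnvs(m, DetectorParams(sd_threshold=thr,
                                                     correlation="pearson"))
                totals.append(sum(c.length_bp for c in cnvs))
            assert totals == sorted(totals, reverse=True)

    def test_partial_correlation_mode_uses_batches(self, small_sim):
        cnvs = detect_cnvs(small_sim["norm"], DetectorParams(),
                           library_meta=small_sim["meta"])
        assert len(cnvs) == 4


class TestRecoveryOnSimulation:
    def test_perfect_recovery_of_implanted_elements(self, small_sim):
        cfg = small_sim["config"]
        cnvs = detect_cnvs(small_sim["norm"], DetectorParams(),
                           library_meta=small_sim["meta"])
        truth = sorted(
            (s, e) for el in cfg.elements for (s, e) in el.host_windows)
        got = sorted((int(c.window_indices[0]), int(c.window_indices[-1]) + 1)
                     for c in cnvs)
        assert len(got) == len(truth)         # precision = recall = 1
        for (gs, ge), (ts, te) in zip(got, truth):
            assert abs(gs - ts) <= 1 and abs(ge - te) <= 1


class TestPlacementAndBContigs:
    def test_placement_classes(self, small_sim):
        cnvs = detect_cnvs(small_sim["norm"], DetectorParams(),
                           library_meta=small_sim["meta"])
        by_contig = {}
        for c in cnvs:
            by_contig.setdefault(c.contig, []).append(c)
        assert by_contig["c0"][0].placement == "whole-contig"
        assert by_contig["c2"][0].placement == "whole-contig"
        assert all(c.placement == "internal" for c in by_contig["c1"])

    @pytest.mark.parametrize("frac,b90,b95", [
        (1.00, True, True), (0.50, False, False), (0.92, True, False),
    ])
    def test_b_contig_thresholds(self, frac, b90, b95):
        n = 100
        ws = tile_windows({"ctg": n * W}, W)
        vals = np.full((n, 6), 2.0)
        k = int(round(frac * n))
        copies = np.array([0, 1, 2, 4, 5, 6], dtype=float)
        vals[:k] = copies[None, :]
        m = WindowCoverageMatrix(ws, pd.DataFrame(
            vals, columns=[f"L{i}" for i in range(6)]), normalized=True)
        cnvs = detect_cnvs(m, PEARSON)
        call = classify_b_contigs(cnvs, ws)[0]
        assert call.cnv_fraction == pytest.approx(frac, abs=0.011)
        assert call.is_b90 is b90 and call.is_b95 is b95


class TestSummary:
    def test_single_cnv(self):
        m = copy_vector_matrix([0, 1, 2, 4, 5, 6], n_var=2, n_diploid_flank=0,
                               noise_sd=0.01)
        cnvs = detect_cnvs(m, DetectorParams(min_windows=1,
                                             correlation="pearson"))
        s = cnv_summary(cnvs, assembly_bp=2 * W)
        assert s["count"] == 1 and s["n50_bp"] == 2 * W

    def test_n50_cumulative_rule(self):
        # lengths 4,3,2,1 windows: N50 = 3 windows (4+3 >= 10/2)
        class Fake:
            def __init__(self, bp):
                self.length_bp = bp
        s = cnv_summary([Fake(4), Fake(3), Fake(2), Fake(1)], assembly_bp=100)
        assert s["n50_bp"] == 3

    def test_assembly_fraction(self):
        class Fake:
            def __init__(self, bp):
                self.length_bp = bp
        s = cnv_summary([Fake(21), Fake(10)], assembly_bp=100)
        assert s["assembly_fraction"] == pytest.approx(0.31)

    def test_empty_list_gives_zeros(self):
        s = cnv_summary([], assembly_bp=100)
        assert s == {"count": 0, "total_bp": 0, "assembly_fraction": 0.0,
                     "n50_bp": 0}
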