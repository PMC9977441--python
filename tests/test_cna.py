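"""Normalization, segmentation and locus-summarization checks against
independent arithmetic/interval oracles."""
import numpy as np
import pandas as pd
import pytest

import methylcna as m
from conftest import make_track


def _bins(values, chrom="chr1", bin_size=1000):
    n = len(values)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * bin_size,
            "end": (np.arange(n) + 1) * bin_size,
            "value": values,
        }
    )


class TestNormalize:
    def test_identity(self):
        ref = _bins(np.full(100, 3.0))
        tum = ref.assign(sample_id="t1")
        out = m.normalize_to_reference(tum, ref)
        assert np.allclose(out["log2_ratio"], 0.0)

    def test_doubled_arm(self):
        ref = _bins(np.full(100, 2.0))
        vals = np.full(100, 2.0)
        vals[:20] = 4.0  # one "arm" doubled
        tum = _bins(vals).assign(sample_id="t1")
        out = m.normalize_to_reference(tum, ref)
        assert np.allclose(out["log2_ratio"][:20], 1.0)
        assert np.allclose(out["log2_ratio"][20:], 0.0)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(0)
        ref = _bins(rng.uniform(0.5, 4.0, 200))
        tum = _bins(rng.uniform(0.5, 4.0, 200)).assign(sample_id="t1")
        out = m.normalize_to_reference(tum, ref)
        expected = np.log2(tum["value"].values / ref["value"].values)
        expected -= np.median(expected)
        assert np.allclose(out["log2_ratio"], expected)

    def test_rejects_mismatched_grid(self):
        ref = _bins(np.full(10, 1.0))
        tum = _bins(np.full(12, 1.0)).assign(sample_id="t1")
        with pytest.raises(ValueError, match="grid"):
            m.normalize_to_reference(tum, ref)

    def test_rejects_nonpositive_reference(self):
        ref = _bins(np.array([1.0, 0.0, 1.0, 1.0]))
        tum = _bins(np.ones(4)).assign(sample_id="t1")
        with pytest.raises(ValueError):
            m.normalize_to_reference(tum, ref)


def _exhaustive_split(x, min_bins, alpha):
    """Oracle: exhaustive single-split maximizer applied recursively."""
    out = []

    def rec(lo, hi):
        seg = x[lo:hi]
        n = len(seg)
        if n < 2 * min_bins:
            return
        best_k, best_t = None, 0.0
        d = np.diff(seg)
        sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
        atol = 1e-10 * (np.abs(seg).max() + 1.0)
        for k in range(min_bins, n - min_bins + 1):
            m1, m2 = seg[:k].mean(), seg[k:].mean()
            if abs(m2 - m1) <= atol:
                continue
            t = abs(m2 - m1) * np.sqrt(k * (n - k) / n) / max(sigma, atol)
            if t > best_t:
                best_k, best_t = k, t
        if best_k is None:
            return
        from scipy import stats
        p = 2.0 * stats.norm.sf(best_t)
        p_adj = 1.0 - (1.0 - min(p, 1.0)) ** (n - 2 * min_bins + 1)
        if p_adj < alpha:
            out.append(lo + best_k)
            rec(lo, lo + best_k)
            rec(lo + best_k, hi)

    rec(0, len(x))
    return sorted(out)


class TestSegmentation:
    def test_constant_track_single_segment(self):
        seg = m.segment_bins(make_track(np.full(80, 0.3)))
        assert len(seg) == 1
        assert seg["seg_mean"].iloc[0] == pytest.approx(0.3)
        assert seg["n_bins"].iloc[0] == 80

    def test_clean_step(self):
        seg = m.segment_bins(make_track(np.r_[np.zeros(50), np.ones(50)]))
        assert len(seg) == 2
        assert seg["end"].iloc[0] == 50_000
        assert np.allclose(seg["seg_mean"], [0.0, 1.0])

    def test_short_chromosome_is_single_segment(self):
        seg = m.segment_bins(make_track(np.array([0.0, 5.0, 0.0])), min_bins=5)
        assert len(seg) == 1

    def test_matches_exhaustive_oracle(self):
        for s in range(20):
            rng = np.random.default_rng(s)
            x = np.concatenate(
                [rng.normal(0, 0.1, 100), rng.normal(0.8, 0.1, 100), rng.normal(0, 0.1, 100)]
            )
            seg = m.segment_bins(make_track(x))
            got = sorted(seg["start"].values[1:] // 1000)
            assert list(got) == _exhaustive_split(x, 5, 0.01)

    def test_breakpoint_recovery_rate(self):
        hits = 0
        n_rep = 100
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            x = np.concatenate(
                [rng.normal(0, 0.1, 100), rng.normal(0.8, 0.1, 100), rng.normal(0, 0.1, 100)]
            )
            bps = sorted(m.segment_bins(make_track(x))["start"].values[1:] // 1000)
            if len(bps) == 2 and abs(bps[0] - 100) <= 2 and abs(bps[1] - 200) <= 2:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_conservation_of_mean(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 0.1, 60), rng.normal(0.7, 0.1, 60)])
        seg = m.segment_bins(make_track(x))
        pooled = np.average(seg["seg_mean"], weights=seg["n_bins"])
        assert pooled == pytest.approx(x.mean(), abs=1e-12)


def _brute_force_locus_value(segments, chrom, start, end):
    total_w, total = 0.0, 0.0
    for _, row in segments.iterrows():
        if row["chrom"] != chrom:
            continue
        w = min(row["end"], end) - max(row["start"], start)
        if w > 0:
            total += w * row["seg_mean"]
            total_w += w
    return total / total_w if total_w else np.nan


class TestSummarizeLoci:
    def _segments(self):
        return pd.DataFrame(
            {
                "sample_id": "s1",
                "chrom": "chr1",
                "start": [0, 1000, 3000],
                "end": [1000, 3000, 5000],
                "n_bins": [10, 20, 20],
                "seg_mean": [0.4, 0.0, 1.0],
            }
        )

    def test_contained_locus(self):
        ann = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [900],
                            "locus_id": ["l1"]})
        out = m.summarize_loci(self._segments(), ann)
        assert out.loc["l1", "s1"] == pytest.approx(0.4)

    def test_straddling_locus_weighted_mean(self):
        ann = pd.DataFrame({"chrom": ["chr1"], "start": [2000], "end": [4000],
                            "locus_id": ["l1"]})
        out = m.summarize_loci(self._segments(), ann)
        assert out.loc["l1", "s1"] == pytest.approx(0.5)

    def test_matches_brute_force_on_random_layout(self):
        rng = np.random.default_rng(1)
        starts = np.sort(rng.choice(np.arange(1, 100), size=9, replace=False)) * 100
        bounds = np.r_[0, starts, 10_000]
        segs = pd.DataFrame(
            {
                "sample_id": "s1",
                "chrom": "chr1",
                "start": bounds[:-1],
                "end": bounds[1:],
                "n_bins": 1,
                "seg_mean": rng.normal(size=len(bounds) - 1),
            }
        )
        l_start = rng.integers(0, 9_800, size=200)
        l_len = rng.integers(50, 2_000, size=200)
        ann = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": l_start,
                "end": np.minimum(l_start + l_len, 10_000),
                "locus_id": [f"L{i:03d}" for i in range(200)],
            }
        )
        out = m.summarize_loci(segs, ann)
        for _, row in ann.iterrows():
            expect = _brute_force_locus_value(segs, "chr1", row["start"], row["end"])
            assert out.loc[row["locus_id"], "s1"] == pytest.approx(expect)

    def test_invariant_to_splitting_a_segment(self):
        segs = self._segments()
        split = pd.concat(
            [
                segs.iloc[:2],
                pd.DataFrame(
                    {
                        "sample_id": ["s1", "s1"],
                        "chrom": ["chr1", "chr1"],
                        "start": [3000, 4000],
                        "end": [4000, 5000],
                        "n_bins": [10, 10],
                        "seg_mean": [1.0, 1.0],
                    }
                ),
            ],
            ignore_index=True,
        )
        ann = pd.DataFrame({"chrom": ["chr1"], "start": [2500], "end": [4500],
                            "locus_id": ["l1"]})
        a = m.summarize_loci(segs, ann)
        b = m.summarize_loci(split, ann)
        assert a.loc["l1", "s1"] == pytest.approx(b.loc["l1", "s1"])

    def test_unknown_chromosome_rejected(self):
        ann = pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [10],
                            "locus_id": ["l1"]})
        with pytest.raises(ValueError, match="chrX"):
            m.summarize_loci(self._segments(), ann)


def test_prepare_matrix_drops_and_imputes():
    mat = pd.DataFrame(
        {
            "s1": [0.1, np.nan, np.nan],
            "s2": [0.2, 0.4, np.nan],
            "s3": [0.3, 0.5, np.nan],
            "s4": [0.4, 0.6, 0.1],
            "s5": [0.5, 0.7, 0.2],
            "s6": [0.6, 0.8, 0.3],
            "s7": [0.7, 0.9, 0.4],
            "s8": [0.8, 1.0, 0.5],
            "s9": [0.9, 1.1, 0.6],
            "s10": [1.0, 1.2, 0.7],
        },
        index=["a", "b", "c"],
    )
    out = m.prepare_matrix(mat, max_missing_frac=0.10)
    assert list(out.index) == ["a", "b"]  # c is 20% missing
    assert out.loc["b", "s1"] == pytest.approx(mat.loc["b"].mean())
    assert not out.isna().any().any()
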