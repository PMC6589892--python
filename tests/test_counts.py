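"""Site filtering, count orientation and unit aggregation."""

import numpy as np
import pandas as pd
import pytest

from imprintseq.counts import ParentalCountMatrix, aggregate_by_unit, filter_sites, orient_counts


def mk_sites(positions, chrom="1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions})


class TestFilterSites:
    def test_empty_masks_retain_all(self):
        snvs = mk_sites([10, 20, 30])
        retained, removed = filter_sites(snvs, {})
        assert len(retained) == 3 and len(removed) == 0

    def test_masked_site_removed_with_reason(self):
        snvs = mk_sites([10, 200])
        masks = {"simple_repeat": pd.DataFrame({"chrom": ["1"], "start": [5], "end": [15]})}
        retained, removed = filter_sites(snvs, masks)
        assert list(retained["pos"]) == [200]
        assert removed.iloc[0]["masks"] == "simple_repeat"

    def test_random_sites_match_bruteforce(self, rng):
        pos = rng.integers(1, 10_000, 1000)
        snvs = mk_sites(pos)
        masks = {}
        for name in ("mappability", "cnv", "segdup"):
            s = rng.integers(0, 10_000, 30)
            masks[name] = pd.DataFrame({"chrom": "1", "start": s, "end": s + rng.integers(1, 300, 30)})
        retained, _ = filter_sites(snvs, masks)

        def hit(p):
            return any(
                ((bed["start"] <= p - 1) & (p - 1 < bed["end"])).any() for bed in masks.values()
            )

        expected = [p for p in pos if not hit(p)]
        assert sorted(retained["pos"]) == sorted(expected)


class TestOrientCounts:
    def _calls(self):
        return pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "pos": [100, 200],
                "sample": ["s1", "s1"],
                "paternal_allele": ["G", "."],
                "maternal_allele": ["A", "."],
                "status": ["mendelian", "missing"],
            }
        )

    def test_paternal_alt_swaps_counts(self):
        counts = pd.DataFrame(
            {
                "chrom": ["1"],
                "pos": [100],
                "sample": ["s1"],
                "ref_count": [7],
                "alt_count": [3],
                "ref_base": ["A"],
            }
        )
        out = orient_counts(counts, self._calls())
        assert out.loc[0, "pat_count"] == 3 and out.loc[0, "mat_count"] == 7

    def test_missing_pofo_keeps_refalt_only(self):
        counts = pd.DataFrame(
            {
                "chrom": ["1"],
                "pos": [200],
                "sample": ["s1"],
                "ref_count": [5],
                "alt_count": [2],
                "ref_base": ["C"],
            }
        )
        out = orient_counts(counts, self._calls())
        assert np.isnan(out.loc[0, "pat_count"])
        assert out.loc[0, "ref_count"] == 5

    def test_inconsistent_alleles_flagged_and_dropped(self):
        counts = pd.DataFrame(
            {
                "chrom": ["1"],
                "pos": [100],
                "sample": ["s1"],
                "ref_count": [4],
                "alt_count": [4],
                "ref_base": ["T"],  # neither call allele matches the site ref
            }
        )
        out = orient_counts(counts, self._calls())
        assert bool(out.loc[0, "inconsistent"])
        assert np.isnan(out.loc[0, "pat_count"])


class TestAggregateByUnit:
    def _oriented(self, rows):
        return pd.DataFrame(
            rows,
            columns=["chrom", "pos", "sample", "ref_count", "alt_count", "pat_count", "mat_count"],
        )

    def test_simple_sum_and_ratio(self):
        oriented = self._oriented(
            [
                ("1", 1, "s1", 6, 0, 5.0, 1.0),
                ("1", 2, "s1", 2, 0, 2.0, 0.0),
                ("1", 3, "s1", 0, 2, 0.0, 2.0),
            ]
        )
        units = pd.Series(["u1", "u1", "u1"])
        pcm, summary = aggregate_by_unit(oriented, units, ["s1"])
        assert pcm.pat[0, 0] == 7 and pcm.mat[0, 0] == 3
        assert summary.loc[0, "mean_pat_ratio"] == pytest.approx(0.7)

    def test_informative_threshold_is_inclusive(self):
        rows = [("1", 1, f"s{i}", 1, 0, 1.0, 0.0) for i in range(9)]
        oriented = self._oriented(rows)
        samples = [f"s{i}" for i in range(100)]
        pcm, summary = aggregate_by_unit(oriented, pd.Series(["u1"] * 9), samples)
        assert not summary.loc[0, "tested"]  # 9 < 10% of 100
        rows.append(("1", 2, "s9", 1, 0, 1.0, 0.0))
        pcm, summary = aggregate_by_unit(self._oriented(rows), pd.Series(["u1"] * 10), samples)
        assert summary.loc[0, "tested"]  # exactly 10% is tested (inclusive rule)

    def test_count_conservation_random_cohort(self, rng):
        n = 400
        oriented = self._oriented(
            [
                (
                    "1",
                    int(rng.integers(1, 50)),
                    f"s{rng.integers(0, 5)}",
                    int(rng.integers(0, 10)),
                    int(rng.integers(0, 10)),
                    float(rng.integers(0, 10)),
                    float(rng.integers(0, 10)),
                )
                for _ in range(n)
            ]
        )
        units = pd.Series(rng.choice(["u1", "u2", "u3"], n))
        samples = [f"s{i}" for i in range(5)]
        pcm, summary = aggregate_by_unit(oriented, units, samples)
        assert pcm.pat.sum() == oriented["pat_count"].sum()
        assert pcm.mat.sum() == oriented["mat_count"].sum()
        assert pcm.ref.sum() == oriented["ref_count"].sum()
        # mean ratio equals independent recomputation
        for ui, u in enumerate(pcm.unit_ids):
            sub = oriented[units.values == u]
            g = sub.groupby("sample")[["pat_count", "mat_count"]].sum()
            g = g[(g.pat_count + g.mat_count) > 0]
            expected = (g.pat_count / (g.pat_count + g.mat_count)).mean()
            got = summary.loc[summary.unit_id == u, "mean_pat_ratio"].iloc[0]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)

    def test_pat_ratio_bounds(self, small_cohort):
        from imprintseq.pipeline import oriented_site_counts
        from imprintseq.annotation import assign_snvs_to_ugfs, build_ugfs

        co = small_cohort
        oriented = oriented_site_counts(co.trio, co.counts)
        ugfs = build_ugfs(co.genes)
        units = assign_snvs_to_ugfs(oriented[["chrom", "pos"]], ugfs)
        samples = sorted(co.counts["sample"].unique())
        pcm, summary = aggregate_by_unit(oriented, units, samples)
        r = summary["mean_pat_ratio"].dropna()
        assert ((r >= 0) & (r <= 1)).all()
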