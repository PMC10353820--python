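import numpy as np
import pandas as pd
import pytest
from scipy import stats

from txvar._stats import bh_adjust, spearman_pvalue
from txvar.crossstudy import SDMatrix
from txvar.features import (
    GeneRegion,
    chromatin_state_proportions,
    compare_groups_states,
    partial_spearman,
    partial_spearman_table,
    weighted_connectivity,
    windows_to_genes,
)
from txvar.preprocess import ExpressionMatrix
from txvar.ranking import compute_rank


def _expr(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values=pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(values.shape[0])],
            columns=[f"smp{j}" for j in range(values.shape[1])],
        ),
        provenance="residual",
    )


def _brute_force_connectivity(values, fdr=0.01, signed=True):
    """Independent recomputation: pairwise scipy.spearmanr + BH."""
    n_genes, n_samples = values.shape
    pairs, rhos, pvals = [], [], []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            rho = stats.spearmanr(values[i], values[j]).statistic
            pairs.append((i, j))
            rhos.append(rho)
            pvals.append(spearman_pvalue(rho, n_samples))
    adj = bh_adjust(np.array(pvals))
    conn = np.zeros(n_genes)
    for (i, j), rho, a in zip(pairs, rhos, adj):
        if a <= fdr:
            w = rho if signed else abs(rho)
            conn[i] += w
            conn[j] += w
    return conn


class TestConnectivity:
    def test_hand_fixture_duplicate_genes(self):
        rng = np.random.default_rng(0)
        g2 = rng.normal(size=100)
        vals = np.vstack([rng.normal(size=100), g2, g2.copy()])
        conn = weighted_connectivity([_expr(vals)])
        rho12 = stats.spearmanr(vals[0], vals[1]).statistic
        sig = spearman_pvalue(rho12, 100)  # raw p; with 3 edges BH keeps rho=1 edge
        expected_g1 = 1.0 + (2 * rho12 if False else 0.0)
        assert conn["g1"] == pytest.approx(
            _brute_force_connectivity(vals)[1], abs=1e-12
        )
        assert conn["g1"] >= 1.0 - 1e-12  # the perfect edge always survives

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=60)
        vals = base + rng.normal(0, 1.0, size=(12, 60))
        conn = weighted_connectivity([_expr(vals)], fdr=0.05)
        np.testing.assert_allclose(
            conn.to_numpy(), _brute_force_connectivity(vals, fdr=0.05), atol=1e-10
        )

    def test_duplicated_study_mean_unchanged(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(6, 40)) + rng.normal(size=40)
        one = weighted_connectivity([_expr(vals)])
        two = weighted_connectivity([_expr(vals), _expr(vals)])
        np.testing.assert_allclose(one.to_numpy(), two.to_numpy(), atol=1e-12)

    def test_fdr_zero_no_edges(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(8, 30))  # independent noise, no p == 0 edges
        conn = weighted_connectivity([_expr(vals)], fdr=0.0)
        np.testing.assert_array_equal(conn.to_numpy(), 0.0)

    def test_unsigned_mode(self):
        rng = np.random.default_rng(4)
        g = rng.normal(size=80)
        vals = np.vstack([g, -g, rng.normal(size=80)])
        signed = weighted_connectivity([_expr(vals)], signed=True)
        unsigned = weighted_connectivity([_expr(vals)], signed=False)
        assert signed["g0"] == pytest.approx(-1.0, abs=0.2)
        assert unsigned["g0"] >= 1.0 - 1e-12

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="5 samples"):
            weighted_connectivity([_expr(np.zeros((3, 4)))])


def _per_base_window_oracle(track, region):
    """Naive per-base scan: mean of window values over overlapped windows."""
    hit = []
    for row in track.itertuples(index=False):
        if row.chrom != region.chrom:
            continue
        positions = set(range(row.start, row.end)) & set(range(region.start, region.end))
        if positions:
            hit.append(row.value)
    return float(np.mean(hit)) if hit else np.nan


class TestWindowsToGenes:
    def test_two_windows_mean(self):
        track = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [0, 100], "end": [100, 200], "value": [0.1, 0.3]}
        )
        out = windows_to_genes(track, [GeneRegion("g", "c", 50, 150)])
        assert out["g"] == pytest.approx(0.2)

    def test_gene_inside_single_window(self):
        track = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1000], "value": [0.7]})
        out = windows_to_genes(track, [GeneRegion("g", "c", 10, 20)])
        assert out["g"] == pytest.approx(0.7)

    def test_absent_chromosome_missing(self):
        track = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [100], "value": [1.0]})
        out = windows_to_genes(track, [GeneRegion("g", "c2", 0, 50)])
        assert np.isnan(out["g"])

    def test_half_open_boundary(self):
        track = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [0, 100], "end": [100, 200], "value": [0.0, 1.0]}
        )
        # gene ends exactly where window 2 starts: no overlap with window 2
        out = windows_to_genes(track, [GeneRegion("g", "c", 50, 100)])
        assert out["g"] == pytest.approx(0.0)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(5)
        starts = np.arange(0, 5000, 250)
        track = pd.DataFrame(
            {"chrom": "c", "start": starts, "end": starts + 250, "value": rng.uniform(size=len(starts))}
        )
        regions = [
            GeneRegion(f"g{i}", "c", int(s), int(s + ln))
            for i, (s, ln) in enumerate(zip(rng.integers(0, 4500, 30), rng.integers(50, 600, 30)))
        ]
        out = windows_to_genes(track, regions)
        for region in regions:
            oracle = _per_base_window_oracle(track, region)
            assert out[region.gene] == pytest.approx(oracle, abs=1e-12)

    def test_malformed_interval_rejected(self):
        track = pd.DataFrame({"chrom": ["c"], "start": [10], "end": [10], "value": [1.0]})
        with pytest.raises(ValueError, match="malformed"):
            windows_to_genes(track, [GeneRegion("g", "c", 0, 5)])


def _per_base_state_oracle(seg, region, flank, chrom_len):
    lo = max(region.start - flank, 0)
    hi = min(region.end + flank, chrom_len)
    per_base = {}
    for row in seg.itertuples(index=False):
        for pos in range(max(row.start, lo), min(row.end, hi)):
            per_base[pos] = row.state
    states = sorted(seg["state"].unique())
    length = hi - lo
    return {s: sum(1 for v in per_base.values() if v == s) / length for s in states}


class TestChromatinProportions:
    def test_region_inside_one_state(self):
        seg = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [0, 1000], "end": [1000, 2000], "state": ["A", "B"]}
        )
        out = chromatin_state_proportions(seg, [GeneRegion("g", "c", 100, 200)], flank=0)
        assert out.loc["g", "A"] == pytest.approx(1.0)
        assert out.loc["g", "B"] == pytest.approx(0.0)

    def test_even_split(self):
        seg = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [0, 500], "end": [500, 1000], "state": ["A", "B"]}
        )
        out = chromatin_state_proportions(seg, [GeneRegion("g", "c", 400, 600)], flank=0)
        assert out.loc["g", "A"] == pytest.approx(0.5)
        assert out.loc["g", "B"] == pytest.approx(0.5)

    def test_partition_sums_to_one(self):
        rng = np.random.default_rng(6)
        cuts = np.sort(rng.choice(np.arange(1, 10_000), size=30, replace=False))
        bounds = np.concatenate([[0], cuts, [10_000]])
        seg = pd.DataFrame(
            {
                "chrom": "c",
                "start": bounds[:-1],
                "end": bounds[1:],
                "state": rng.choice(list("ABC"), size=len(bounds) - 1),
            }
        )
        regions = [GeneRegion(f"g{i}", "c", int(s), int(s + 200)) for i, s in enumerate(range(100, 9000, 700))]
        out = chromatin_state_proportions(
            seg, regions, flank=10_000, chrom_lengths={"c": 10_000}
        )
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(7)
        bounds = np.concatenate([[0], np.sort(rng.choice(np.arange(1, 3000), 10, replace=False)), [3000]])
        seg = pd.DataFrame(
            {"chrom": "c", "start": bounds[:-1], "end": bounds[1:],
             "state": rng.choice(list("AB"), size=len(bounds) - 1)}
        )
        for region in [GeneRegion("g1", "c", 200, 400), GeneRegion("g2", "c", 2500, 2900)]:
            out = chromatin_state_proportions(
                seg, [region], flank=300, chrom_lengths={"c": 3000}
            )
            oracle = _per_base_state_oracle(seg, region, 300, 3000)
            for state, val in oracle.items():
                assert out.loc[region.gene, state] == pytest.approx(val, abs=1e-12)

    def test_missing_state_labels_rejected(self):
        seg = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10], "state": [None]})
        with pytest.raises(ValueError, match="state labels"):
            chromatin_state_proportions(seg, [GeneRegion("g", "c", 0, 5)])


class TestCompareGroupsStates:
    def _props(self, n=40, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.beta(2, 5, size=(2 * n, 3))
        a[:n, 0] += shift
        a = np.clip(a, 0, 1)
        props = pd.DataFrame(a, columns=["A", "B", "C"], index=[f"g{i}" for i in range(2 * n)])
        return props, {f"g{i}" for i in range(n)}, {f"g{i}" for i in range(n, 2 * n)}

    def test_identical_groups_null(self):
        props, high, low = self._props(shift=0.0, seed=1)
        # make groups literally identical
        props.iloc[40:] = props.iloc[:40].to_numpy()
        res = compare_groups_states(props, high, low)
        assert (res["p_adjusted"] > 0.9).all()

    def test_shifted_state_detected(self):
        hits = 0
        others_clean = 0
        for rep in range(20):
            props, high, low = self._props(shift=0.3, seed=100 + rep)
            res = compare_groups_states(props, high, low).set_index("state")
            hits += res.loc["A", "p_adjusted"] < 0.05
            others_clean += (res.loc[["B", "C"], "p_adjusted"] > 0.05).all()
        assert hits >= 18
        assert others_clean >= 18

    def test_minimum_group_size(self):
        props, high, low = self._props()
        with pytest.raises(ValueError, match="group size"):
            compare_groups_states(props, {"g0"}, {"g40"})

    def test_disjoint_groups_required(self):
        props, high, low = self._props()
        with pytest.raises(ValueError, match="disjoint"):
            compare_groups_states(props, high, high)

    def test_medians_and_sem_reported(self):
        props, high, low = self._props(seed=3)
        res = compare_groups_states(props, high, low)
        assert {"median_high", "median_low", "sem_high", "sem_low"} <= set(res.columns)


def _rank_pair(n=200, seed=0, rho=0.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = rho * x + np.sqrt(max(1 - rho**2, 0)) * rng.normal(size=n)

    def _vr(values, kind):
        from txvar.ranking import VarianceRank

        genes = pd.Index([f"g{i}" for i in range(n)])
        score = pd.Series(values, index=genes)
        return VarianceRank(
            genes=genes,
            pc1_score=score,
            rank=score.rank(method="first").astype(int),
            presence_fraction=pd.Series(1.0, index=genes),
            kind=kind,
            scope="across-study",
            pc_variance_explained=np.array([1.0]),
        )

    return _vr(x, "variance"), _vr(y, "mean")


class TestPartialSpearman:
    def test_perfect_control_kills_correlation(self):
        # feature identical to the control variable: nothing left after
        # partialling it out, whatever the rank argument is
        vr, mr = _rank_pair(seed=1, rho=0.3)
        feature = pd.Series(mr.rank.to_numpy(dtype=float), index=mr.rank.index)
        rho, p = partial_spearman(feature, vr, mr)
        assert abs(rho) < 1e-8
        assert p == pytest.approx(1.0)

    def test_self_correlation_is_one(self):
        vr, mr = _rank_pair(seed=2)
        feature = pd.Series(vr.rank.to_numpy(dtype=float), index=vr.rank.index)
        rho, p = partial_spearman(feature, vr, mr)
        assert rho == pytest.approx(1.0, abs=1e-10)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_independent_control_matches_plain_spearman(self):
        rng = np.random.default_rng(3)
        n = 5000
        vr, _ = _rank_pair(n=n, seed=3)
        _, control = _rank_pair(n=n, seed=4)  # independent of both
        feature = pd.Series(
            vr.pc1_score.to_numpy() + rng.normal(0, 1.0, size=n), index=vr.rank.index
        )
        partial, _ = partial_spearman(feature, vr, control)
        plain = stats.spearmanr(feature, vr.rank).statistic
        assert partial == pytest.approx(plain, abs=0.02)

    def test_matches_recursive_formula(self):
        vr, mr = _rank_pair(n=300, seed=5, rho=0.4)
        rng = np.random.default_rng(6)
        feature = pd.Series(
            vr.pc1_score.to_numpy() + rng.normal(size=300), index=vr.rank.index
        )
        rho, _ = partial_spearman(feature, vr, mr)
        r_xy = stats.spearmanr(feature, vr.rank).statistic
        r_xz = stats.spearmanr(feature, mr.rank).statistic
        r_yz = stats.spearmanr(vr.rank, mr.rank).statistic
        expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert rho == pytest.approx(expected, abs=1e-8)

    def test_too_few_genes(self):
        vr, mr = _rank_pair(n=200)
        feature = pd.Series(np.nan, index=vr.rank.index)
        feature.iloc[:5] = 1.0
        with pytest.raises(ValueError, match="10 genes"):
            partial_spearman(feature, vr, mr)

    def test_batch_table_bh(self):
        vr, mr = _rank_pair(n=100, seed=7)
        rng = np.random.default_rng(8)
        feats = pd.DataFrame(
            rng.normal(size=(100, 4)), index=vr.rank.index, columns=list("wxyz")
        )
        table = partial_spearman_table(feats, vr, mr)
        assert (table["p_adjusted"] >= table["p"] - 1e-15).all()
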