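"""Group statistics: ANOVA, FDR, Ward clustering, correlation screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import sleepmet as sm
from sleepmet.stats import (
    StatsError,
    bh_fdr,
    correlation_screen,
    one_way_anova,
    ratios_to_control,
    two_factor_anova,
    two_factor_contrasts,
    ward_cluster,
)


class TestRatios:
    def test_control_group_is_unity(self, small_cohort):
        table, design, _ = small_cohort
        r = ratios_to_control(table, design)
        assert np.allclose(r["SHAM-CT"], 1.0)

    def test_arithmetic(self):
        # two groups with means 2 and 4 -> ratio 2.0
        from sleepmet.panel import PanelManifest, SampleTable, StudyDesign, VALID

        man = PanelManifest(
            pd.DataFrame(
                {"class": ["amino_acid"], "lod": [0.01], "lloq": [0.1], "uloq": [100]},
                index=pd.Index(["M"], name="metabolite_id"),
            )
        )
        ids = ["a1", "a2", "b1", "b2"]
        conc = pd.DataFrame({"M": [2.0, 2.0, 4.0, 4.0]}, index=ids)
        status = pd.DataFrame(VALID, index=ids, columns=["M"])
        t = SampleTable(conc, status, pd.Series("study", index=ids))
        d = StudyDesign(
            pd.DataFrame(
                [
                    {"sample_id": "a1", "treatment": "SHAM", "procedure": "CT"},
                    {"sample_id": "a2", "treatment": "SHAM", "procedure": "CT"},
                    {"sample_id": "b1", "treatment": "SHAM", "procedure": "SR"},
                    {"sample_id": "b2", "treatment": "SHAM", "procedure": "SR"},
                ]
            ).set_index("sample_id")
        )
        r = ratios_to_control(t, d)
        assert r.at["M", "SHAM-SR"] == pytest.approx(2.0)


class TestOneWayAnova:
    def test_hand_computed_f8(self):
        # groups (1,2) and (3,4): SSB=4, SSW=1, df=(1,2) -> F=8, p~0.106
        p = one_way_anova([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert p == pytest.approx(sps.f.sf(8, 1, 2), abs=1e-12)
        assert p == pytest.approx(0.1056, abs=2e-4)

    def test_identical_groups_p_one(self):
        assert one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3) == pytest.approx(1.0)

    def test_matches_scipy_oracle_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            y = rng.standard_normal(18)
            g = np.repeat(["a", "b", "c"], 6)
            _, p_oracle = sps.f_oneway(y[:6], y[6:12], y[12:])
            assert one_way_anova(y, g) == pytest.approx(p_oracle, abs=1e-10)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(1000):
            y = rng.standard_normal(30)
            ps.append(one_way_anova(y, np.repeat(list("abcdef"), 5)))
        d, _ = sps.kstest(ps, "uniform")
        assert d < 0.08

    def test_degenerate_grouping_rejected(self):
        with pytest.raises(StatsError):
            one_way_anova([1, 2, 3], ["a", "a", "b"])


class TestTwoFactorAnova:
    def _design(self, n_per_cell=4):
        t = np.repeat(["SHAM", "ROT"], 3 * n_per_cell)
        p = np.tile(np.repeat(["CT", "SR", "REB"], n_per_cell), 2)
        return t, p

    def test_planted_treatment_effect(self):
        rng = np.random.default_rng(21)
        t, p = self._design()
        y = rng.standard_normal(len(t)) + 2.0 * (t == "ROT")
        pt, pp, pi = two_factor_anova(y, t, p)
        assert pt < 0.01 and pp > 0.1

    def test_constant_values_p_one(self):
        t, p = self._design()
        assert two_factor_anova(np.ones(len(t)), t, p) == (1.0, 1.0, 1.0)

    def test_balanced_design_all_ss_types_agree(self):
        # in a balanced design Type I/II/III decompositions coincide; check
        # against a direct Type-I (sequential) matrix-algebra oracle
        rng = np.random.default_rng(3)
        t, p = self._design()
        y = rng.standard_normal(len(t))
        pt, pp, pi = two_factor_anova(y, t, p)

        def rss(cols):
            X = np.column_stack(cols)
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            return ((y - X @ b) ** 2).sum()

        one = np.ones(len(t))
        dt = (t == "ROT").astype(float)
        dsr, dreb = (p == "SR").astype(float), (p == "REB").astype(float)
        inter = [dt * dsr, dt * dreb]
        rss_full = rss([one, dt, dsr, dreb, *inter])
        df_res = len(t) - 6
        mse = rss_full / df_res
        f_t = (rss([one]) - rss([one, dt])) / 1 / mse  # sequential: t first
        f_p = (rss([one, dt]) - rss([one, dt, dsr, dreb])) / 2 / mse
        f_i = (rss([one, dt, dsr, dreb]) - rss_full) / 2 / mse
        assert pt == pytest.approx(sps.f.sf(f_t, 1, df_res), abs=1e-10)
        assert pp == pytest.approx(sps.f.sf(f_p, 2, df_res), abs=1e-10)
        assert pi == pytest.approx(sps.f.sf(f_i, 2, df_res), abs=1e-10)

    def test_batch_path_equals_per_metabolite_oracle(self, small_cohort):
        table, design, _ = small_cohort
        res = sm.compute_group_stats(table, design)
        conc = table.study_concentrations()
        tr = design.table["treatment"]
        pr = design.table["procedure"]
        for mid in ["Ile", "Kynurenine", "PC ae C38:3", "C9"]:
            y = np.log(conc[mid])
            pt, pp, pi = two_factor_anova(y, tr, pr)
            ct = two_factor_contrasts(y, tr, pr)
            p1 = one_way_anova(y, design.table["group"])
            row = res.tests.loc[mid]
            got = row[["p_treatment", "p_procedure", "p_interaction", "p_rot", "p_sr", "p_reb", "p_oneway"]]
            assert np.allclose(
                got.astype(float), [pt, pp, pi, ct["rotenone"], ct["sr"], ct["reb"], p1], atol=1e-10
            )


class TestBhFdr:
    @pytest.mark.parametrize(
        "p,q",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.03], [0.03]),
            ([0.005, 0.05], [0.01, 0.05]),
        ],
    )
    def test_step_up_hand_computation(self, p, q):
        assert np.allclose(bh_fdr(p), q)

    def test_matches_explicit_step_up_oracle(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=37)
        m = len(p)
        order = np.argsort(p)
        q_oracle = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            q_oracle[i] = prev
        assert np.allclose(bh_fdr(p), q_oracle, atol=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_properties(self, p):
        q = bh_fdr(p)
        p_arr = np.asarray(p)
        assert (q >= p_arr - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        # q ranks follow p ranks (step-up is monotone)
        order = np.argsort(p_arr, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(bh_fdr(p_arr[perm]), q[perm])  # order-equivariant


def _brute_force_ward(X):
    """Exhaustive greedy Ward: recompute objective over all merge sequences.

    Uses the Ward objective directly (increase in within-cluster SS); returns
    the sequence of merge heights produced by always taking the cheapest pair.
    """
    clusters = {i: [i] for i in range(len(X))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            pa, pb = X[clusters[a]], X[clusters[b]]
            na, nb = len(pa), len(pb)
            d2 = ((pa.mean(axis=0) - pb.mean(axis=0)) ** 2).sum()
            cost = np.sqrt(2 * na * nb / (na + nb) * d2)
            if best is None or cost < best[0]:
                best = (cost, a, b)
        cost, a, b = best
        heights.append(cost)
        new_key = max(clusters) + 1
        clusters[new_key] = clusters.pop(a) + clusters.pop(b)
    return heights


class TestWard:
    def test_first_merge_is_nearest_pair(self):
        d = ward_cluster(np.array([[0.0], [1.0], [10.0]]))
        a, b, h = d.merges[0]
        assert {a, b} == {0, 1}

    def test_identical_rows_zero_heights(self):
        d = ward_cluster(np.ones((4, 3)))
        assert all(h == pytest.approx(0.0, abs=1e-12) for _, _, h in d.merges)

    def test_heights_match_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            X = rng.standard_normal((6, 3))
            d = ward_cluster(X)
            oracle = _brute_force_ward(X)
            assert np.allclose(sorted(h for _, _, h in d.merges), sorted(oracle), atol=1e-8)

    def test_leaf_order_is_permutation(self):
        X = np.random.default_rng(6).standard_normal((9, 4))
        d = ward_cluster(X)
        assert sorted(d.leaf_order) == list(range(9))

    def test_bcaa_co_cluster_on_synthetic_cohorts(self, manifest):
        # LEU/ILE/VAL are generated with r >= 0.89 and should sit on adjacent
        # leaves of the metabolite dendrogram in nearly every cohort
        from sleepmet.simulate import SimConfig, simulate_cohort

        good = 0
        n_seeds = 40
        for seed in range(n_seeds):
            table, design, _ = simulate_cohort(SimConfig(manifest=manifest, n_per_group=11, seed=seed))
            conc = np.log(table.study_concentrations())
            z = (conc - conc.mean()) / conc.std()
            d = ward_cluster(z.T.to_numpy(), labels=list(conc.columns))
            order = d.ordered_labels
            pos = sorted(order.index(m) for m in ("Leu", "Ile", "Val"))
            good += pos[2] - pos[0] == 2
        assert good / n_seeds >= 0.95


class TestCorrelationScreen:
    def test_duplicated_covariate_reported_as_identity(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(30)
        df = pd.DataFrame({"m1": x, "m2": rng.standard_normal(30)})
        cov = pd.DataFrame({"c": x}, index=df.index)
        hits = correlation_screen(df, cov, r_cutoff=0.4)
        pairs = {(h.entity_a, h.entity_b): h.pearson_r for h in hits}
        assert pairs[("m1", "c")] == pytest.approx(1.0)

    def test_activity_sleep_hit_on_default_cohort(self, large_cohort):
        table, _, covs = large_cohort
        conc = table.study_concentrations()[["Ile", "Met"]]
        hits = correlation_screen(conc, covs, r_cutoff=0.4)
        match = [h for h in hits if {h.entity_a, h.entity_b} == {"total_activity", "sleep_condition"}]
        assert match and match[0].pearson_r == pytest.approx(-0.57, abs=0.03)

    def test_null_rate_below_ten_percent(self):
        # independent Gaussian columns at n=44: |r|>0.4 for a given pair is rare
        reported = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            df = pd.DataFrame({"a": rng.standard_normal(44), "b": rng.standard_normal(44)})
            hits = correlation_screen(df, None, r_cutoff=0.4)
            reported += bool(hits)
        assert reported / reps < 0.10
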