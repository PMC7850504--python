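"""Map-window thinning, pseudo-haploids, admixture EM and delta-K."""

import numpy as np
import pandas as pd
import pytest

from poolkin import (
    FrequencyMatrix,
    LikelihoodTable,
    MarkerPanel,
    admixture_em,
    assign_groups,
    best_k,
    evanno_deltak,
    simulate_haploids,
    structure_scan,
    thin_by_windows,
)


def _panel(positions, chrom="chr1"):
    return MarkerPanel(pd.DataFrame({
        "locus_id": [f"s{i}" for i in range(len(positions))],
        "chromosome": chrom,
        "position_cM": positions}))


def _fm(rows):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return FrequencyMatrix([f"L{i}" for i in range(rows.shape[0])],
                           [f"s{j}" for j in range(rows.shape[1])], rows)


class TestThinByWindows:
    def test_one_snp_per_window_keeps_all(self):
        panel = _panel(np.arange(2500, dtype=float))
        kept = thin_by_windows(panel, 2500, seed=0)
        assert len(kept) == 2500

    def test_two_snps_per_window_keeps_half(self):
        panel = _panel(np.arange(5000, dtype=float) / 2.0)
        kept = thin_by_windows(panel, 2500, seed=0)
        assert len(kept) == 2500

    def test_clustered_snps_only_occupied_windows(self):
        # 100 SNPs piled into 10 tight clusters on a long map
        positions = np.concatenate(
            [c * 100.0 + np.linspace(0, 0.001, 10) for c in range(10)])
        panel = _panel(positions)
        kept = thin_by_windows(panel, 2500, seed=0)
        assert len(kept) == 10

    def test_output_in_map_order(self):
        panel = _panel(np.linspace(0, 100, 50))
        kept = thin_by_windows(panel, 10, seed=1)
        order = {lid: i for i, lid in enumerate(panel.locus_ids)}
        ranks = [order[k] for k in kept]
        assert ranks == sorted(ranks)

    def test_multichromosome_allocation_proportional(self):
        t = pd.concat([
            _panel(np.linspace(0, 300, 600)).table.assign(chromosome="chr1"),
            _panel(np.linspace(0, 100, 600)).table.assign(chromosome="chr2"),
        ], ignore_index=True)
        t["locus_id"] = [f"m{i}" for i in range(len(t))]
        kept = thin_by_windows(MarkerPanel(t), 100, seed=2)
        panel = MarkerPanel(t)
        chrom_of = dict(zip(panel.table["locus_id"], panel.table["chromosome"]))
        n1 = sum(chrom_of[k] == "chr1" for k in kept)
        n2 = len(kept) - n1
        assert n1 == 75 and n2 == 25  # 300 vs 100 cM -> 3:1 windows

    def test_invalid_window_count_rejected(self):
        with pytest.raises(ValueError):
            thin_by_windows(_panel([0.0, 1.0]), 0)


class TestSimulateHaploids:
    def test_fixed_frequencies_deterministic_alleles(self):
        fm = _fm([[1.0, 0.0]])
        hp = simulate_haploids(fm, n_rep=5, seed=0)
        assert (hp.genotypes[:, 0] == 1).all()
        assert (hp.genotypes[:, 1] == 0).all()
        assert len(hp.sample_ids) == 5

    def test_intermediate_frequency_binomial_bound(self):
        fm = _fm([np.full(10000, 0.5)])
        hp = simulate_haploids(fm, n_rep=5, seed=1)
        means = hp.genotypes.mean(axis=1)
        assert np.all(means > 0.485) and np.all(means < 0.515)

    def test_seed_reproducibility(self, two_group_panel):
        fm, _, _ = two_group_panel
        a = simulate_haploids(fm, 3, seed=9)
        b = simulate_haploids(fm, 3, seed=9)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)


class TestAdmixtureEm:
    def test_k1_closed_form(self, rng):
        g = (rng.random((8, 50)) < 0.4).astype(int)
        fm = _fm(rng.random((4, 50)))
        hp = simulate_haploids(fm, 2, seed=0)
        res = admixture_em(hp, K=1)
        np.testing.assert_allclose(res.P[0], hp.genotypes.mean(axis=0))
        p = np.clip(hp.genotypes.mean(axis=0), 1e-300, None)
        with np.errstate(divide="ignore"):
            expect = np.where(hp.genotypes == 1, np.log(p),
                              np.log(np.clip(1 - p, 1e-300, None))).sum()
        assert res.loglik == pytest.approx(expect)

    def test_loglik_monotone_nondecreasing(self, rng):
        fm = _fm(rng.random((6, 80)))
        hp = simulate_haploids(fm, 3, seed=1)
        res = admixture_em(hp, K=3, seed=2, max_iter=150)
        assert np.all(np.diff(res.loglik_trace) >= -1e-7 * np.abs(res.loglik))

    def test_q_rows_sum_to_one(self, rng):
        fm = _fm(rng.random((5, 60)))
        hp = simulate_haploids(fm, 2, seed=3)
        res = admixture_em(hp, K=2, seed=4, max_iter=100)
        np.testing.assert_allclose(res.Q.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(res.Q_landrace.sum(axis=1), 1.0, atol=1e-8)

    def test_seed_determinism_bit_for_bit(self, two_group_panel):
        fm, _, _ = two_group_panel
        hp = simulate_haploids(fm, 2, seed=5)
        a = admixture_em(hp, K=2, seed=6, max_iter=60)
        b = admixture_em(hp, K=2, seed=6, max_iter=60)
        np.testing.assert_array_equal(a.Q, b.Q)
        np.testing.assert_array_equal(a.P, b.P)
        assert a.loglik == b.loglik

    def test_k_exceeding_samples_rejected(self, rng):
        fm = _fm(rng.random((2, 10)))
        hp = simulate_haploids(fm, 1, seed=0)
        with pytest.raises(ValueError):
            admixture_em(hp, K=3)

    def test_two_group_assignment_recovery(self, two_group_panel):
        """>=95% of landraces recover their true cluster at Fst ~ 0.2."""
        fm, pp, _ = two_group_panel
        hp = simulate_haploids(fm, 5, seed=7)
        best = None
        for s in (10, 11, 12):
            res = admixture_em(hp, K=2, seed=s, max_iter=300)
            if best is None or res.loglik > best.loglik:
                best = res
        pred = assign_groups(best)["cluster"].to_numpy()
        truth = np.array([0] * 15 + [1] * 15)
        acc = max((pred == truth).mean(), (pred == 1 - truth).mean())
        assert acc >= 0.95

    def test_pure_cluster_q_converges_to_indicator(self, rng):
        # landraces drawn from one of two very distinct frequency profiles
        pa = rng.uniform(0.02, 0.2, 5000)
        pb = rng.uniform(0.8, 0.98, 5000)
        fm = FrequencyMatrix([f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)],
                             [f"s{j}" for j in range(5000)],
                             np.vstack([np.tile(pa, (4, 1)), np.tile(pb, (4, 1))]))
        hp = simulate_haploids(fm, 2, seed=8)
        res = admixture_em(hp, K=2, seed=9, max_iter=200)
        top = res.Q_landrace.max(axis=1)
        assert np.all(top >= 0.95)


class TestEvannoDeltaK:
    @staticmethod
    def _table(means, spread):
        rows = []
        for k, m in means.items():
            for rep, delta in enumerate((-spread, spread)):
                rows.append({"K": k, "replicate": rep, "loglik": m + delta,
                             "seed": rep})
        return LikelihoodTable(pd.DataFrame(rows))

    def test_hand_worked_second_difference(self):
        # means (-1000, -900, -890); replicate sd 5 at every K
        spread = 5 / np.sqrt(2)  # sd of {m-d, m+d} with ddof=1 is d*sqrt(2)
        lt = self._table({1: -1000.0, 2: -900.0, 3: -890.0}, spread)
        dk = evanno_deltak(lt)
        row = dk[dk["K"] == 2].iloc[0]
        assert row["delta_k"] == pytest.approx(18.0)

    def test_linear_loglik_gives_zero(self):
        lt = self._table({1: -100.0, 2: -90.0, 3: -80.0, 4: -70.0}, 1.0)
        dk = evanno_deltak(lt)
        np.testing.assert_allclose(dk["delta_k"], 0.0, atol=1e-12)

    def test_zero_sd_flagged_nan(self):
        lt = self._table({1: -10.0, 2: -5.0, 3: -4.0}, 0.0)
        with pytest.warns(UserWarning):
            dk = evanno_deltak(lt)
        assert np.isnan(dk.loc[dk["K"] == 2, "delta_k"]).all()

    def test_noncontiguous_k_rejected(self):
        lt = self._table({1: -10.0, 3: -5.0, 5: -4.0}, 1.0)
        with pytest.raises(ValueError):
            evanno_deltak(lt)

    def test_two_group_data_selects_k2(self, two_group_panel):
        fm, _, _ = two_group_panel
        hp = simulate_haploids(fm, 5, seed=20)
        _, lt = structure_scan(hp, range(1, 5), n_replicates=3, seed=21,
                               max_iter=300)
        assert best_k(evanno_deltak(lt)) == 2


class TestAssignGroups:
    @staticmethod
    def _result(q_rows):
        from poolkin.structure import AncestryResult
        q = np.asarray(q_rows, dtype=float)
        return AncestryResult(
            K=q.shape[1], sample_ids=[], Q=q, P=np.zeros((q.shape[1], 1)),
            loglik=0.0, n_iter=0, converged=True, seed=None,
            landrace_ids=[f"L{i}" for i in range(q.shape[0])], Q_landrace=q)

    def test_pure_and_admixed_cutoff(self):
        out = assign_groups(self._result([[0.8, 0.2], [0.6, 0.4]]))
        assert out["cluster"].tolist() == [0, 0]
        assert out["is_pure"].tolist() == [True, False]

    def test_tie_goes_to_lowest_cluster_with_warning(self):
        with pytest.warns(UserWarning):
            out = assign_groups(self._result([[0.5, 0.5]]))
        assert out.loc[0, "cluster"] == 0
        assert not out.loc[0, "is_pure"]
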