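"""Wavelength-selector tests: SIMPLS engine, UVE, CARS, SPA oracles and properties."""

import itertools

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from teadtc._pls import cross_val_pls, kfold_splits, loo_splits, pls_fit, simpls_paths
from teadtc.select import CARSSelector, CVConfig, SPASelector, UVESelector
from teadtc.synth import ExperimentDesign, generate_experiment, informative_bands


class TestSimpls:
    def test_matches_sklearn_pls_for_single_response(self, rng):
        X = rng.normal(size=(30, 8))
        y = X @ rng.normal(size=8) + 0.1 * rng.normal(size=30)
        for a in (1, 2, 3, 5):
            B, b0 = simpls_paths(X, y, a)
            sk = PLSRegression(n_components=a, scale=False).fit(X, y)
            pred_ours = X @ B[:, a - 1] + b0[a - 1]
            pred_sk = sk.predict(X).ravel()
            assert np.allclose(pred_ours, pred_sk, atol=1e-8)
            assert np.allclose(B[:, a - 1], sk.coef_.ravel(), atol=1e-8)

    def test_full_rank_path_reaches_ols(self, rng):
        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(size=20) * 0.01
        b, b0 = pls_fit(X, y, 3)
        A = np.column_stack([np.ones(20), X])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.allclose(b, beta[1:], atol=1e-8)
        assert b0 == pytest.approx(beta[0], abs=1e-8)

    def test_cross_val_rmse_identifies_signal_rank(self, rng):
        X = rng.normal(size=(40, 10))
        y = X[:, 0] + 2 * X[:, 1]
        rmse, coefs = cross_val_pls(X, y, 5, loo_splits(40), collect_coefs=True)
        assert rmse[1] < rmse[0]  # 2 latent variables beat 1
        assert coefs.shape == (40, 10, 5)

    def test_kfold_split_partition(self, rng):
        splits = kfold_splits(23, 5, rng)
        tested = np.sort(np.concatenate([te for _, te in splits]))
        assert np.array_equal(tested, np.arange(23))
        for tr, te in splits:
            assert np.intersect1d(tr, te).size == 0


class TestUVE:
    def test_keeps_planted_informative_column(self, rng):
        X = rng.normal(size=(40, 21))
        y = X[:, 7].copy()
        sel = UVESelector(random_state=1).fit(X, y)
        assert sel.support_[7]

    def test_noise_survival_rate_bounded(self):
        kept = total = 0
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            X = rng.normal(size=(40, 30))
            y = rng.normal(size=40)
            total += 30
            try:
                kept += int(UVESelector(cutoff_factor=1.0, random_state=s).fit(X, y)
                            .support_.sum())
            except ValueError:
                pass  # everything eliminated counts as zero survivors
        assert kept / total <= 0.05

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(30, 15))
        y = X[:, 3] + 0.1 * rng.normal(size=30)
        a = UVESelector(random_state=9).fit(X, y)
        b = UVESelector(random_state=9).fit(X, y)
        assert np.array_equal(a.support_, b.support_)
        assert np.array_equal(a.stability_, b.stability_)
        assert a.cutoff_ == b.cutoff_

    def test_cutoff_monotonicity(self, rng):
        X = rng.normal(size=(40, 20))
        y = X[:, 2] + X[:, 11] + 0.3 * rng.normal(size=40)
        sizes = []
        for factor in (0.5, 1.0, 2.0, 4.0):
            try:
                sizes.append(int(UVESelector(cutoff_factor=factor, random_state=4)
                                 .fit(X, y).support_.sum()))
            except ValueError:
                sizes.append(0)
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_all_eliminated_raises_helpfully(self, rng):
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        with pytest.raises(ValueError, match="cutoff_factor"):
            UVESelector(cutoff_factor=50.0, random_state=0).fit(X, y)


class TestCARS:
    def test_retained_counts_nonincreasing_to_two(self, rng):
        X = rng.normal(size=(60, 50))
        y = rng.normal(size=60)
        sel = CARSSelector(n_runs=50, random_state=0).fit(X, y)
        counts = sel.result_.diagnostics["retained_counts"]
        assert np.all(np.diff(counts) <= 0)
        assert counts[-1] == 2

    def test_recovers_planted_linear_band(self, rng):
        X = rng.normal(size=(60, 30))
        y = 3.0 * X[:, 7] + rng.normal(scale=0.01, size=60)
        sel = CARSSelector(random_state=2).fit(X, y)
        assert sel.support_[7]
        d = sel.result_.diagnostics
        assert d["rmsecv"][d["best_iteration"]] < d["rmsecv"][0]

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(40, 25))
        y = X[:, 5] + 0.2 * rng.normal(size=40)
        a = CARSSelector(random_state=11).fit(X, y)
        b = CARSSelector(random_state=11).fit(X, y)
        assert np.array_equal(a.support_, b.support_)
        assert np.array_equal(a.result_.diagnostics["rmsecv"],
                              b.result_.diagnostics["rmsecv"])

    def test_minimum_sample_guard(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            CARSSelector().fit(rng.normal(size=(5, 10)), rng.normal(size=5))


class TestSPA:
    def test_duplicate_columns_never_co_selected(self, rng):
        X = rng.normal(size=(30, 8))
        X[:, 5] = X[:, 2]  # exact duplicate
        y = X[:, 2] + X[:, 7] + 0.05 * rng.normal(size=30)
        sel = SPASelector(max_vars=4, random_state=0).fit(X, y)
        chosen = set(sel.result_.selected.tolist())
        assert not {2, 5} <= chosen

    def test_orthogonal_columns_selected_by_norm(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(20, 5)))
        X = Q * np.array([3.0, 2.0, 1.0, 0.5, 0.4])
        y = X[:, 0] + X[:, 1]
        # chain from the norm-3 start: projection leaves orthogonal norms
        # unchanged, so the norm-2 column is appended next
        sel = SPASelector(max_vars=2, starts=[0], random_state=3).fit(X, y)
        assert sel.result_.selected.tolist() == [0, 1]
        # with all starts allowed the winning subset is still {0, 1}
        sel_all = SPASelector(max_vars=2, random_state=3).fit(X, y)
        assert set(sel_all.result_.selected.tolist()) == {0, 1}

    def test_matches_exhaustive_two_subset_search(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(24, 5)))
        X = Q * np.array([5.0, 4.0, 1.0, 0.9, 0.8])
        y = X[:, 0] + X[:, 1] + 0.01 * rng.normal(size=24)
        sel = SPASelector(max_vars=2, val_fraction=0.25, random_state=1).fit(X, y)
        # independent brute force over all 2-subsets with the same split + OLS scorer
        perm = np.random.default_rng(1).permutation(24)
        n_val = int(round(0.25 * 24))
        val, tr = perm[:n_val], perm[n_val:]

        def rmse_of(cols):
            A = np.column_stack([np.ones(tr.size), X[np.ix_(tr, cols)]])
            beta = np.linalg.lstsq(A, y[tr], rcond=None)[0]
            pred = np.column_stack([np.ones(val.size), X[np.ix_(val, cols)]]) @ beta
            return np.sqrt(np.mean((pred - y[val]) ** 2))

        best = min(itertools.combinations(range(5), 2), key=lambda c: rmse_of(list(c)))
        assert set(sel.result_.selected.tolist()) == set(best)

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(30, 12))
        y = X[:, 4] + 0.1 * rng.normal(size=30)
        a = SPASelector(max_vars=5, random_state=7).fit(X, y)
        b = SPASelector(max_vars=5, random_state=7).fit(X, y)
        assert np.array_equal(a.result_.selected, b.result_.selected)


class TestOnSyntheticSpectra:
    def test_selectors_hit_true_informative_windows(self):
        """Each method's picks, dilated +/-3 bands, overlap the generator's truth."""
        design = ExperimentDesign(
            varieties=("QN36", "QN1", "QN21"), replicates_per_cell=3,
            n_bands=120, wavelength_step=5.0,
        )
        truth_idx = set()
        for b in informative_bands(design.wavelengths):
            truth_idx.update(range(b - 3, b + 4))
        hits = {"uve": 0, "cars": 0, "spa": 0}
        n_seeds = 10
        for seed in range(n_seeds):
            spectra, physio, truth = generate_experiment(
                ExperimentDesign(varieties=design.varieties,
                                 replicates_per_cell=3, n_bands=120,
                                 wavelength_step=5.0, seed=seed)
            )
            y = 1.0 - truth.true_dtc  # stress-oriented response
            X = spectra.values
            selectors = {
                "uve": UVESelector(random_state=seed),
                "cars": CARSSelector(n_runs=30, random_state=seed),
                "spa": SPASelector(max_vars=10, random_state=seed),
            }
            for name, sel in selectors.items():
                try:
                    sel.fit(X, y)
                except ValueError:
                    continue  # a fully-eliminated run counts as a miss
                if truth_idx & set(np.flatnonzero(sel.support_).tolist()):
                    hits[name] += 1
        for name, count in hits.items():
            assert count > 0, f"{name} never hit the informative windows"

    def test_selected_indices_within_range(self, rng):
        X = rng.normal(size=(40, 20))
        y = X[:, 3] + 0.1 * rng.normal(size=40)
        for sel in (UVESelector(random_state=0), CARSSelector(random_state=0, n_runs=20),
                    SPASelector(max_vars=5, random_state=0)):
            sel.fit(X, y)
            chosen = np.flatnonzero(sel.support_)
            assert chosen.size >= 1
            assert np.unique(chosen).size == chosen.size
            assert chosen.min() >= 0 and chosen.max() < 20
            assert sel.transform(X).shape == (40, chosen.size)
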