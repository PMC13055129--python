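import itertools

import numpy as np
import pandas as pd
import pytest

from clonotrace.cnv import (CNVCaller, HMMParams, center_cells,
                            estimate_hmm_params, filter_genes_by_mean,
                            reference_residuals, smooth_chromosome,
                            smoothing_matrix, states_to_segments,
                            subclone_mean_profile, viterbi_states,
                            viterbi_states_matrix)


class TestGeneFilter:
    def test_boundary_inclusive(self):
        # one cell, means equal the values
        norm = np.array([[0.099, 0.1, 0.5]])
        kept = filter_genes_by_mean(norm, np.array([0]), min_mean=0.1)
        assert kept.tolist() == [1, 2]

    def test_zero_cutoff_is_identity(self):
        norm = np.random.default_rng(0).random((5, 8))
        kept = filter_genes_by_mean(norm, np.array([0, 1]), min_mean=0.0)
        assert kept.tolist() == list(range(8))

    def test_hand_fixture_survivors(self):
        means = [0.0, 0.05, 0.1, 0.2, 0.09, 1.0, 0.11, 0.099, 0.5, 0.1]
        norm = np.array(means)[None, :]
        kept = filter_genes_by_mean(norm, np.array([0]), min_mean=0.1)
        assert kept.tolist() == [2, 3, 5, 6, 8, 9]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            filter_genes_by_mean(np.ones((2, 2)), np.array([], dtype=int))


class TestResiduals:
    def test_self_reference_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(1.0, 0.3, size=(150, 20))
        res = reference_residuals(X, np.ones(150, dtype=bool))
        assert np.abs(res.mean(axis=0)).max() < 0.05

    def test_clipping_exact(self):
        X = np.zeros((3, 1))
        X[2, 0] = 100.0
        res = reference_residuals(X, np.array([True, True, False]), clip=3.0)
        assert res[2, 0] == 3.0

    def test_planted_gain_gives_positive_residual(self, small_experiment, small_norm):
        exp = small_experiment
        mal = exp.cells["malignant"].to_numpy()
        q = (exp.cells["population"] == "Q").to_numpy()
        res = reference_residuals(np.asarray(small_norm.todense()), ~mal)
        seg = exp.truth_segments["Q"]
        amp = seg[seg["copy_number"] == 4].iloc[0]
        spanned = ((exp.genes["chromosome"] == amp["chromosome"])
                   & (exp.genes["start"] >= amp["start"])
                   & (exp.genes["end"] <= amp["end"])).to_numpy()
        assert res[np.ix_(q, spanned)].mean() > 0.05


class TestSmoothing:
    def test_window_one_identity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 30))
        chroms = np.array(["chr1"] * 30)
        np.testing.assert_allclose(smooth_chromosome(X, chroms, window=1), X)

    def test_constant_conserved(self):
        X = np.full((3, 50), 0.7)
        chroms = np.array(["chr1"] * 25 + ["chr2"] * 25)
        out = smooth_chromosome(X, chroms, window=7)
        # weights sum to exactly 1 per row; only rounding of the products remains
        np.testing.assert_allclose(out, X, atol=1e-12)

    def test_matches_brute_force_everywhere(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(2, 40))
        chroms = np.array(["chr1"] * 23 + ["chr2"] * 17)
        window, h = 5, 2
        out = smooth_chromosome(X, chroms, window=window)
        for cell in range(2):
            for chrom in ("chr1", "chr2"):
                cols = np.flatnonzero(chroms == chrom)
                vals = X[cell, cols]
                for i in range(len(cols)):
                    num = den = 0.0
                    for j in range(max(0, i - h), min(len(cols), i + h + 1)):
                        w = h + 1 - abs(j - i)
                        num += w * vals[j]
                        den += w
                    assert out[cell, cols[i]] == pytest.approx(num / den, abs=1e-10)

    def test_never_mixes_chromosomes(self):
        X = np.zeros((1, 20))
        X[0, 9] = 100.0  # last gene of chr1
        chroms = np.array(["chr1"] * 10 + ["chr2"] * 10)
        out = smooth_chromosome(X, chroms, window=9)
        assert (out[0, 10:] == 0).all()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smoothing_matrix(10, 4)

    def test_invariant_to_cell_order(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 15))
        chroms = np.array(["chr1"] * 15)
        perm = rng.permutation(6)
        a = smooth_chromosome(X, chroms, window=5)[perm]
        b = smooth_chromosome(X[perm], chroms, window=5)
        np.testing.assert_allclose(a, b)


class TestCenterCells:
    def test_median_exactly_zero(self):
        rng = np.random.default_rng(5)
        X = rng.normal(2.0, 1.0, size=(7, 21))
        out = center_cells(X)
        np.testing.assert_allclose(np.median(out, axis=1), 0.0, atol=1e-14)

    def test_shift_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(3, 11))
        shifted = X.copy()
        shifted[1] += 0.7
        np.testing.assert_allclose(center_cells(shifted)[1], center_cells(X)[1])


def _random_params(rng):
    means = np.sort(rng.normal(0, 1, 6))
    while np.any(np.diff(means) <= 1e-3):
        means = np.sort(rng.normal(0, 1, 6))
    initial = rng.dirichlet(np.ones(6))
    return HMMParams(means=means, sigma=float(rng.uniform(0.1, 1.0)),
                     transition=float(rng.uniform(1e-4, 0.15)),
                     initial=initial)


def brute_force_viterbi(obs, params):
    """Independent exhaustive MAP path: score every one of 6^L paths."""
    L = len(obs)
    paths = np.array(list(itertools.product(range(6), repeat=L)), dtype=np.int8)
    logT = params.log_transition_matrix
    ll = (-0.5 * np.log(2 * np.pi * params.sigma**2)
          - (obs[None, :] - params.means[paths]) ** 2 / (2 * params.sigma**2))
    score = np.log(params.initial)[paths[:, 0]] + ll.sum(axis=1)
    for t in range(1, L):
        score += logT[paths[:, t - 1], paths[:, t]]
    best = score.argmax()
    return paths[best], score[best]


class TestViterbi:
    def test_observations_at_diploid_mean_give_diploid_path(self):
        params = estimate_hmm_params(np.zeros(10), kappa=0.5)
        obs = np.full(20, params.means[2])
        assert (viterbi_states(obs, params) == 2).all()

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            L = int(rng.integers(2, 7))
            params = _random_params(rng)
            obs = rng.normal(0, 1.5, size=L)
            path = viterbi_states(obs, params)
            brute_path, brute_score = brute_force_viterbi(obs, params)
            assert path.tolist() == brute_path.tolist()

    def test_planted_run_recovered_with_tight_breakpoints(self):
        params = estimate_hmm_params(np.zeros(10), kappa=1.0, transition=1e-6,
                                     sigma_floor=0.05)
        rng = np.random.default_rng(8)
        truth = np.array([2] * 40 + [4] * 30 + [2] * 40)
        obs = params.means[truth] + rng.normal(0, params.sigma, size=truth.size)
        path = viterbi_states(obs, params)
        changes = np.flatnonzero(np.diff(path))
        assert set(path.tolist()) == {2, 4}
        assert abs(changes[0] - 39) <= 1 and abs(changes[-1] - 69) <= 1

    def test_matrix_version_consistent_with_single(self):
        rng = np.random.default_rng(9)
        params = _random_params(rng)
        obs = rng.normal(size=(5, 12))
        batch = viterbi_states_matrix(obs, params)
        for i in range(5):
            assert batch[i].tolist() == viterbi_states(obs[i], params).tolist()

    def test_empty_segment_rejected(self):
        params = estimate_hmm_params(np.zeros(5), kappa=0.5)
        with pytest.raises(ValueError):
            viterbi_states(np.array([]), params)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            HMMParams(means=np.array([0, 1, 2, 3, 4, 4]), sigma=1.0)  # not increasing
        with pytest.raises(ValueError):
            HMMParams(means=np.arange(6.0), sigma=-1.0)
        with pytest.raises(ValueError):
            HMMParams(means=np.arange(6.0), sigma=1.0, transition=0.5)


class TestSegments:
    COORDS = pd.DataFrame({
        "chromosome": ["chr1"] * 6 + ["chr2"] * 4,
        "start": [1, 100, 200, 300, 400, 500, 1, 100, 200, 300],
        "end": [50, 150, 250, 350, 450, 550, 50, 150, 250, 350],
    })

    def test_all_diploid_gives_no_events(self):
        states = np.full((4, 10), 2)
        out = states_to_segments(states, self.COORDS, np.zeros(4), events_only=True)
        assert out.empty

    def test_adjacent_runs_split_at_state_change(self):
        states = np.tile([3, 3, 3, 1, 1, 1, 2, 2, 2, 2], (3, 1))
        out = states_to_segments(states, self.COORDS, np.zeros(3))
        chr1 = out[out["chromosome"] == "chr1"]
        assert chr1[["start", "end", "copy_number"]].values.tolist() == [
            [1, 250, 3], [300, 550, 1]]

    def test_majority_vote_across_cells(self):
        states = np.full((5, 10), 2)
        states[:3, 0:2] = 1  # majority deletion on first two genes
        out = states_to_segments(states, self.COORDS, np.zeros(5), events_only=True)
        assert out.iloc[0][["start", "end", "copy_number"]].tolist() == [1, 150, 1]

    def test_runs_never_cross_chromosomes(self):
        states = np.full((2, 10), 3)
        out = states_to_segments(states, self.COORDS, np.zeros(2))
        assert len(out) == 2 and set(out["chromosome"]) == {"chr1", "chr2"}

    def test_mismatched_labels_rejected(self):
        with pytest.raises(ValueError):
            states_to_segments(np.full((4, 10), 2), self.COORDS, np.zeros(3))


class TestSubcloneMeanProfile:
    def test_single_cell_subclone_is_its_row(self):
        X = np.arange(12.0).reshape(3, 4)
        out = subclone_mean_profile(X, ["a", "b", "a"])
        np.testing.assert_allclose(out.loc["b"], X[1])

    def test_identical_cells_mean_equals_either(self):
        X = np.vstack([np.ones(4), np.ones(4)])
        out = subclone_mean_profile(X, ["a", "a"])
        np.testing.assert_allclose(out.loc["a"], 1.0)


@pytest.fixture(scope="module")
def clean_cnv_setup():
    """Low-noise fixture for per-cell state-call properties.

    Deep libraries and mild NB overdispersion isolate the inference from
    count-sampling noise; realistic-noise behavior is covered by the
    subclone-level tests below and the pipeline tests.
    """
    import math

    from clonotrace.preprocess import log_normalize
    from clonotrace.simulate import (CNVEvent, SampleSpec, SimulationConfig,
                                     build_genome, plant_clonal_architecture,
                                     simulate_counts)

    g = build_genome(6, 120, seed=0)
    genes = g.genes
    chr2 = genes[genes["chromosome"] == "chr2"]
    chr3 = genes[genes["chromosome"] == "chr3"]
    subs = plant_clonal_architecture(g, [
        ("P", None, [CNVEvent("chr2", int(chr2.iloc[10]["start"]),
                              int(chr2.iloc[80]["end"]), 1)], {"S": 0.5}),
        ("Q", "P", [CNVEvent("chr3", int(chr3.iloc[20]["start"]),
                             int(chr3.iloc[90]["end"]), 4)], {"S": 0.5}),
    ])
    cfg = SimulationConfig(
        samples={"S": SampleSpec("diagnosis", {"B": 150, "malignant": 400})},
        libsize_meanlog=math.log(20_000.0), dispersion=20.0,
        s_fraction=0.0, g2m_fraction=0.0, seed=5)
    exp = simulate_counts(g, subs, cfg)
    norm = log_normalize(exp.counts)
    mal = exp.cells["malignant"].to_numpy()
    caller = CNVCaller(gene_chromosomes=exp.genes["chromosome"].to_numpy(),
                       window=31).fit(norm, ~mal)
    return exp, norm, caller


class TestCNVCallerEndToEnd:
    def test_reference_cells_called_diploid(self, clean_cnv_setup):
        exp, norm, caller = clean_cnv_setup
        mal = exp.cells["malignant"].to_numpy()
        states = caller.predict(norm[np.flatnonzero(~mal)])
        assert (states == 2).mean() >= 0.99

    def test_planted_events_recovered_in_direction(self, clean_cnv_setup):
        exp, norm, caller = clean_cnv_setup
        q_idx = np.flatnonzero((exp.cells["population"] == "Q").to_numpy())
        states = caller.predict(norm[q_idx])
        kept = exp.genes.iloc[caller.kept_genes_]
        seg = exp.truth_segments["Q"]
        for _, ev in seg.iterrows():
            spanned = ((kept["chromosome"] == ev["chromosome"])
                       & (kept["start"] >= ev["start"])
                       & (kept["end"] <= ev["end"])).to_numpy()
            direction = np.sign(ev["copy_number"] - 2)
            acc = (np.sign(states[:, spanned] - 2) == direction).mean()
            assert acc >= 0.9

        # subclone mean state over the 4-copy region exceeds 2.5
        amp = seg[seg["copy_number"] == 4].iloc[0]
        spanned = ((kept["chromosome"] == amp["chromosome"])
                   & (kept["start"] >= amp["start"])
                   & (kept["end"] <= amp["end"])).to_numpy()
        prof = subclone_mean_profile(states.astype(float), ["Q"] * len(q_idx))
        assert prof.loc["Q"].to_numpy()[spanned].mean() > 2.5

    def test_majority_recovery_under_realistic_noise(self, small_experiment, small_norm):
        # shallow overdispersed counts: per-cell calls are noisy, but the
        # majority state across a subclone's cells recovers event directions
        exp = small_experiment
        mal = exp.cells["malignant"].to_numpy()
        caller = CNVCaller(gene_chromosomes=exp.genes["chromosome"].to_numpy(),
                           window=31).fit(small_norm, ~mal)
        q_idx = np.flatnonzero((exp.cells["population"] == "Q").to_numpy())
        states = caller.predict(small_norm[q_idx])
        kept = exp.genes.iloc[caller.kept_genes_]
        for _, ev in exp.truth_segments["Q"].iterrows():
            spanned = ((kept["chromosome"] == ev["chromosome"])
                       & (kept["start"] >= ev["start"])
                       & (kept["end"] <= ev["end"])).to_numpy()
            direction = np.sign(ev["copy_number"] - 2)
            majority = np.median(states[:, spanned], axis=0)
            assert (np.sign(majority - 2) == direction).mean() >= 0.9
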