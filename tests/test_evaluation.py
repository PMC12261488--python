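import numpy as np
import pytest

from tcrdiff.evaluation import (
    LatentEmbedding,
    classification_metrics,
    knn_purity,
    latent_map,
    mean_cosine,
    pfm_export,
    positionwise_pearson,
)


class TestPositionwisePearson:
    def test_identical_sets_give_unit_correlation(self):
        seqs = ["ATGTGC", "ATGGCA", "TTGGCA", "ATCGCA"]
        r, defined = positionwise_pearson(seqs, seqs)
        assert np.allclose(r[defined], 1.0)

    def test_zero_variance_flagged_undefined(self):
        r, defined = positionwise_pearson(["AAA", "AAA"], ["AAA", "AAT"])
        # every position of set_a is all-A with uniform frequency column? no:
        # column frequencies are [1,0,0,0] (nonzero variance); build a truly
        # flat column instead
        r2, defined2 = positionwise_pearson(["A", "T", "G", "C"], ["A", "A", "A", "A"])
        assert not defined2[0]
        assert np.isnan(r2[0])

    def test_matches_textbook_covariance_formula(self):
        a = ["ATGT", "ATCC", "GTGA", "ATGG"]
        b = ["TTGT", "ATCA", "GGGA", "CTGG"]
        r, defined = positionwise_pearson(a, b)
        for i in range(4):
            fa = np.array([[s[i] == c for s in a].count(True) / 4 for c in "ATGC"])
            fb = np.array([[s[i] == c for s in b].count(True) / 4 for c in "ATGC"])
            if np.ptp(fa) == 0 or np.ptp(fb) == 0:
                assert not defined[i]
                continue
            expected = np.corrcoef(fa, fb)[0, 1]
            assert r[i] == pytest.approx(expected, abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            positionwise_pearson([], ["ATG"])


class TestMeanCosine:
    def test_identical_sequences(self):
        mean, sim = mean_cosine(["ATG"], ["ATG"])
        assert mean == pytest.approx(1.0)

    def test_half_overlap(self):
        mean, _ = mean_cosine(["AA"], ["AT"])
        assert mean == pytest.approx(0.5)

    def test_mean_equals_average_of_pairwise(self):
        a = ["ATG", "GTC", "TTA"]
        b = ["ATC", "GGC", "TAA"]
        mean, sim = mean_cosine(a, b)
        brute = []
        for sa in a:
            for sb in b:
                va = np.zeros((3, 4))
                vb = np.zeros((3, 4))
                for i, c in enumerate(sa):
                    va[i, "ATGC".index(c)] = 1
                for i, c in enumerate(sb):
                    vb[i, "ATGC".index(c)] = 1
                brute.append(va.ravel() @ vb.ravel() / (np.linalg.norm(va) * np.linalg.norm(vb)))
        assert mean == pytest.approx(np.mean(brute), abs=1e-12)
        assert sim.shape == (3, 3)

    def test_symmetry_and_bounds(self):
        a = ["ATGTGC", "TTGGCA"]
        b = ["ATGGCA", "ATCGCA", "GGGGGG"]
        m_ab, sim = mean_cosine(a, b)
        m_ba, _ = mean_cosine(b, a)
        assert m_ab == pytest.approx(m_ba)
        assert np.all(sim >= 0.0) and np.all(sim <= 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_cosine([], ["ATG"])


def _cluster_latents(rng, centers, n_per, spread=0.05):
    latents, labels = [], []
    for ci, c in enumerate(centers):
        for i in range(n_per):
            v = c + spread * rng.standard_normal(c.size)
            latents.append(LatentEmbedding(vector=v, tcr_id=f"c{ci}_{i}", epitope=str(ci)))
            labels.append(str(ci))
    return latents, labels


class TestKnnPurity:
    def test_single_class_is_pure(self):
        rng = np.random.default_rng(0)
        latents, labels = _cluster_latents(rng, [np.zeros(16)], 10)
        assert knn_purity(latents, labels, k=3) == 1.0

    def test_well_separated_clusters(self):
        rng = np.random.default_rng(1)
        centers = [np.zeros(16), np.full(16, 100.0)]
        latents, labels = _cluster_latents(rng, centers, 20)
        assert knn_purity(latents, labels, k=5) == 1.0

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(2)
        latents, labels = _cluster_latents(rng, [np.zeros(4)], 5)
        with pytest.raises(ValueError):
            knn_purity(latents, labels, k=5)


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        m = classification_metrics([0, 1, 1, 0], [0.1, 0.9, 0.8, 0.2])
        assert m["accuracy"] == 1.0 and m["f1"] == 1.0
        assert (m["tp"], m["tn"], m["fp"], m["fn"]) == (2, 2, 0, 0)

    def test_all_positive_on_balanced_set(self):
        labels = [0] * 5 + [1] * 5
        m = classification_metrics(labels, [0.9] * 10)
        assert m["accuracy"] == pytest.approx(0.5)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([0, 1], [0.5])


class TestPfmExport:
    def test_single_sequence_gives_basis_columns(self):
        pfm = pfm_export(["ATG"], "nt")
        assert pfm.matrix.tolist() == [
            [1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0],
        ]

    def test_columns_sum_to_one(self):
        pfm = pfm_export(["ATGC", "TTGA", "ATCC"], "nt")
        assert np.allclose(pfm.matrix.sum(axis=1), 1.0)

    def test_hand_counted_frequencies(self):
        pfm = pfm_export(["AT", "AG", "TG", "AG"], "nt")
        assert pfm.matrix[0].tolist() == [0.75, 0.25, 0.0, 0.0]
        assert pfm.matrix[1].tolist() == [0.0, 0.25, 0.75, 0.0]

    def test_variable_lengths_normalized_by_coverage(self):
        pfm = pfm_export(["AT", "A"], "nt")
        assert pfm.counts_total.tolist() == [2, 1]
        assert pfm.matrix[1].tolist() == [0, 1, 0, 0]

    def test_amino_acid_alphabet(self):
        pfm = pfm_export(["CASSF", "CASRF"], "aa")
        assert np.allclose(pfm.matrix.sum(axis=1), 1.0)

    def test_wrong_alphabet_rejected(self):
        with pytest.raises(ValueError):
            pfm_export(["CASSF"], "nt")  # S, F outside the nucleotide alphabet
        with pytest.raises(ValueError):
            pfm_export(["ABXZ"], "aa")  # B, X, Z are not standard residues
        with pytest.raises(ValueError):
            pfm_export([], "nt")

    def test_tsv_export(self, tmp_path):
        pfm = pfm_export(["ATG", "ATC"], "nt")
        path = tmp_path / "pfm.tsv"
        pfm.to_tsv(str(path))
        lines = path.read_text().strip().splitlines()
        assert lines[0].split("\t") == ["position", "A", "T", "G", "C", "n"]
        assert len(lines) == 4


class TestLatentMap:
    def test_two_dimensional_seeded_output(self):
        rng = np.random.default_rng(3)
        centers = [np.zeros(24), np.full(24, 50.0)]
        latents, _ = _cluster_latents(rng, centers, 16)
        coords = latent_map(latents, seed=0)
        assert coords.shape == (32, 2)
        coords2 = latent_map(latents, seed=0)
        assert np.allclose(coords, coords2)

    def test_too_few_points_rejected(self):
        rng = np.random.default_rng(4)
        latents, _ = _cluster_latents(rng, [np.zeros(8)], 10)
        with pytest.raises(ValueError):
            latent_map(latents)

    def test_pca_variances_non_increasing(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(5)
        x = rng.standard_normal((40, 20)) * np.linspace(5, 0.1, 20)
        pca = PCA(n_components=10).fit(x)
        assert np.all(np.diff(pca.explained_variance_) <= 1e-12)
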