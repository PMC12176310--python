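"""Vocabulary, alignment windows, rollup, binarization and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wardfusion import cui_param as cp
from wardfusion.synthetic_cohort import EncounterRecord


def enc(notes, eid="E1", obs=None):
    return EncounterRecord(
        encounter_id=eid, admission_time=0.0, sex="female", race="White",
        ethnicity="Not Hispanic or Latino", age_years=40,
        structured_obs=obs or [(1.0, 0, 1.0)],
        note_events=[(t, frozenset(c)) for t, c in notes],
    )


def vocab_of(cuis, **kw):
    return cp.CuiVocabulary.from_metadata(cuis=list(cuis), **kw)


class TestBuildVocabulary:
    def test_min_admission_threshold_inclusive(self):
        cohort = (
            [enc([(1.0, {"CA"})], eid=f"A{i}") for i in range(5)]
            + [enc([(1.0, {"CB"})], eid=f"B{i}") for i in range(4)]
        )
        v = cp.build_vocabulary(cohort, min_admissions=5)
        assert "CA" in v and "CB" not in v
        assert v.admission_df["CA"] == 5

    def test_df_counts_admissions_not_mentions(self):
        # ten mentions within a single admission -> df 1 -> excluded
        cohort = [enc([(float(t), {"CX"}) for t in range(10)])]
        v = cp.build_vocabulary(cohort, min_admissions=5)
        assert "CX" not in v

    def test_token_order_by_df_then_string(self):
        cohort = (
            [enc([(1.0, {"CB", "CC"})], eid=f"X{i}") for i in range(6)]
            + [enc([(1.0, {"CA"})], eid=f"Y{i}") for i in range(5)]
        )
        v = cp.build_vocabulary(cohort, min_admissions=5)
        # CB/CC df=6 (tie broken by string), CA df=5
        assert v.cui_to_token == {"CB": 2, "CC": 3, "CA": 4}

    def test_empty_note_stream_gives_empty_vocabulary(self, caplog):
        v = cp.build_vocabulary([enc([])])
        assert len(v) == 0

    def test_reserved_tokens_never_assigned(self):
        v = vocab_of(["C1", "C2"])
        assert min(v.cui_to_token.values()) >= cp.FIRST_CUI_TOKEN


class TestHarmonize:
    def test_intersection_and_identity(self):
        dev = vocab_of(["CA"])
        external = [enc([(1.0, {"CA", "CB"}), (2.0, {"CB"})])]
        out = cp.harmonize(dev, external)
        assert out[0].note_events[0][1] == frozenset({"CA"})
        assert out[0].note_events[1][1] == frozenset()
        # harmonizing a cohort against its own vocabulary changes nothing
        again = cp.harmonize(dev, out)
        assert [e.note_events for e in again] == [e.note_events for e in out]

    def test_external_vocab_nests_in_dev_vocab(self):
        dev = vocab_of(["CA", "CB"])
        external = [enc([(1.0, {"CA", "CZ"})], eid=f"E{i}") for i in range(6)]
        harmonized = cp.harmonize(dev, external)
        ext_vocab = cp.build_vocabulary(harmonized, min_admissions=5)
        assert set(ext_vocab.cui_to_token) <= set(dev.cui_to_token)


class TestAlignment:
    def test_padding_and_unique_count(self):
        v = vocab_of(["CA", "CB", "CC"])
        e = enc([(1.0, {"CA", "CB", "CC"})])
        win = cp.align_cuis_to_timesteps(e, v, timesteps=[2.0], window=10)
        assert win.shape == (1, 10)
        assert (win[0] != cp.PAD_TOKEN).sum() == 3
        assert (win[0, 3:] == cp.PAD_TOKEN).all()

    def test_window_cap_keeps_most_recent(self):
        cuis = [f"C{i:03d}" for i in range(8)]
        v = vocab_of(cuis)
        notes = [(float(i), {c}) for i, c in enumerate(cuis)]
        win = cp.align_cuis_to_timesteps(enc(notes), v, timesteps=[10.0],
                                         window=3)
        kept = {v.token_to_cui[t] for t in win[0]}
        assert kept == set(cuis[-3:])  # latest three occurrence times

    def test_duplicate_cui_ranked_by_latest_occurrence(self):
        v = vocab_of(["CA", "CB"])
        notes = [(2.0, {"CA"}), (5.0, {"CB"}), (9.0, {"CA"})]
        win = cp.align_cuis_to_timesteps(enc(notes), v, timesteps=[10.0],
                                         window=5)
        toks = [t for t in win[0] if t != cp.PAD_TOKEN]
        # CA appears once, ranked first by its 9h occurrence
        assert toks == [v.cui_to_token["CA"], v.cui_to_token["CB"]]

    def test_note_at_timestep_included_future_excluded(self):
        v = vocab_of(["CA", "CB"])
        notes = [(5.0, {"CA"}), (6.0, {"CB"})]
        win = cp.align_cuis_to_timesteps(enc(notes), v, timesteps=[5.0],
                                         window=4)
        toks = {t for t in win[0] if t != cp.PAD_TOKEN}
        assert toks == {v.cui_to_token["CA"]}

    def test_causality_adding_later_notes_never_changes_earlier_windows(self):
        v = vocab_of(["CA", "CB", "CC"])
        base = [(1.0, {"CA"}), (3.0, {"CB"})]
        later = base + [(7.0, {"CC"})]
        w1 = cp.align_cuis_to_timesteps(enc(base), v, timesteps=[2.0, 4.0],
                                        window=5)
        w2 = cp.align_cuis_to_timesteps(enc(later), v, timesteps=[2.0, 4.0],
                                        window=5)
        np.testing.assert_array_equal(w1, w2)


class TestTokenize:
    def test_mapping_oov_and_empty(self):
        v = vocab_of(["C1", "C2"])
        t1 = v.cui_to_token["C1"]
        t2 = v.cui_to_token["C2"]
        assert cp.tokenize(["C2", "C1"], v) == [t2, t1]
        assert cp.tokenize(["C?"], v) == [cp.OOV_TOKEN]
        assert cp.tokenize([], v) == []


class TestIcdRollup:
    def vocab(self):
        return vocab_of(
            ["C1", "C2", "C3", "C4", "C5"],
            icd_code={"C1": "I50.9", "C2": "I50.1", "C3": "J18.9", "C5": "A1"},
        )

    def test_shared_prefix_same_group_distinct_prefix_different(self):
        r = cp.build_icd_rollup(self.vocab())
        v = self.vocab()
        g = {c: r[v.cui_to_token[c]] for c in v.cui_to_token}
        assert g["C1"] == g["C2"]          # I50 shared
        assert g["C1"] != g["C3"]          # I50 vs J18
        assert g["C4"] == 0                 # code-less group
        assert g["C5"] not in (g["C1"], g["C3"], 0)  # short code, own key

    def test_partition_total_and_group_count(self):
        v = self.vocab()
        r = cp.build_icd_rollup(v)
        assert set(r.token_to_group) == set(v.cui_to_token.values())
        assert r.n_groups == 4  # {codeless, A1, I50, J18}
        sizes = {}
        for g in r.token_to_group.values():
            sizes[g] = sizes.get(g, 0) + 1
        assert sum(sizes.values()) == len(v)

    def test_no_codes_means_single_bucket(self):
        v = vocab_of(["C1", "C2"])
        r = cp.build_icd_rollup(v)
        assert r.n_groups == 1
        assert set(r.token_to_group.values()) == {0}


class TestBinarize:
    def test_positions_duplicates_empty(self):
        np.testing.assert_array_equal(
            cp.binarize([2, 5], 8),
            [0, 0, 1, 0, 0, 1, 0, 0])
        np.testing.assert_array_equal(cp.binarize([2, 2], 8)[2], 1.0)
        assert cp.binarize([2, 2], 8).sum() == 1.0
        assert cp.binarize([], 8).sum() == 0.0

    def test_out_of_range_token_rejected(self):
        with pytest.raises(ValueError):
            cp.binarize([9], 8)

    @given(st.lists(st.integers(2, 15), max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_order_and_multiplicity_invariance(self, toks):
        a = cp.binarize(toks, 16)
        b = cp.binarize(sorted(toks, reverse=True) + toks, 16)
        np.testing.assert_array_equal(a, b)


class TestEmbedLookup:
    def test_rows_and_padding(self):
        M = np.arange(12.0).reshape(4, 3)
        M[0] = 0.0
        out = cp.embed_lookup([0, 2], M)
        np.testing.assert_array_equal(out[0], [0, 0, 0])
        np.testing.assert_array_equal(out[1], M[2])

    def test_permutation_permutes_rows(self):
        M = np.arange(12.0).reshape(4, 3)
        a = cp.embed_lookup([1, 2, 3], M)
        b = cp.embed_lookup([3, 1, 2], M)
        np.testing.assert_array_equal(a[[2, 0, 1]], b)

    def test_missing_row_is_error(self):
        with pytest.raises(ValueError):
            cp.embed_lookup([5], np.zeros((4, 3)))


class TestClustering:
    def blobs_vocab(self, n=60, sep=25.0, dim=12, seed=0):
        rng = np.random.default_rng(seed)
        centers = rng.normal(size=(2, dim))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        centers *= sep
        cuis, emb, truth = [], {}, {}
        for i in range(n):
            c = f"C{i:04d}"
            cuis.append(c)
            truth[c] = i % 2
            emb[c] = centers[i % 2] + rng.normal(size=dim)
        return vocab_of(cuis, embedding=emb), truth

    def test_identical_embeddings_single_cluster(self):
        v = vocab_of(["C1", "C2", "C3"],
                     embedding={c: np.ones(4) for c in ["C1", "C2", "C3"]})
        cm = cp.cluster_embeddings(v, pca_dim=2, distance_threshold=0.5)
        assert cm.n_clusters == 1

    def test_zero_threshold_all_singletons(self):
        v, _ = self.blobs_vocab(n=20)
        cm = cp.cluster_embeddings(v, pca_dim=5, distance_threshold=0.0)
        assert cm.n_clusters == 20

    def test_two_blobs_recovered_exactly(self):
        v, truth = self.blobs_vocab()
        cm = cp.cluster_embeddings(v, pca_dim=5, distance_threshold=0.5)
        assert cm.n_clusters == 2
        from sklearn.metrics import adjusted_rand_score

        pred = [cm[v.cui_to_token[c]] for c in v.cuis]
        true = [truth[c] for c in v.cuis]
        assert adjusted_rand_score(true, pred) == 1.0

    def test_cluster_count_monotone_in_threshold(self):
        v, _ = self.blobs_vocab(n=40)
        counts = [
            cp.cluster_embeddings(v, pca_dim=5, distance_threshold=t).n_clusters
            for t in (0.01, 0.1, 0.5, 1.0, 2.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_partition_covers_all_tokens(self):
        v, _ = self.blobs_vocab(n=30)
        cm = cp.cluster_embeddings(v, pca_dim=5, distance_threshold=0.5)
        assert set(cm.token_to_cluster) == set(v.cui_to_token.values())
        assert set(cm.token_to_cluster.values()) == set(range(cm.n_clusters))

    def test_agreement_with_scipy_reference_at_many_cut_levels(self):
        """Flat clusters match scipy average-linkage cut-for-cut."""
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(3)
        n, dim = 120, 8
        cuis = [f"C{i:04d}" for i in range(n)]
        emb = {c: rng.normal(size=dim) for c in cuis}
        v = vocab_of(cuis, embedding=emb)
        tokens, Z = cp._reduced_embeddings(v, pca_dim=dim)
        D = cp._cosine_distance_matrix(Z)
        link = linkage(squareform(D, checks=False), method="average")
        heights = np.unique(link[:, 2])
        mids = (heights[:-1] + heights[1:]) / 2
        for t in mids[:: max(1, len(mids) // 12)]:
            ours = cp.cluster_embeddings(v, pca_dim=dim, distance_threshold=t)
            ref = fcluster(link, t=t, criterion="distance")
            pred = [ours[tok] for tok in tokens]
            assert adjusted_rand_score(ref, pred) == 1.0

    def test_threshold_search_hits_target_count(self):
        v, _ = self.blobs_vocab(n=50)
        for target in (2, 7, 25):
            thr = cp.threshold_for_cluster_count(v, target, pca_dim=5)
            cm = cp.cluster_embeddings(v, pca_dim=5, distance_threshold=thr)
            assert cm.n_clusters == target


class TestClusterBinarize:
    def test_same_cluster_single_bit_empty_all(self):
        cm = cp.ClusterMap(token_to_cluster={2: 0, 3: 0, 4: 1}, n_clusters=2,
                           pca_dim=2, distance_threshold=0.5, linkage="average")
        np.testing.assert_array_equal(cp.cluster_binarize([2, 3], cm), [1, 0])
        np.testing.assert_array_equal(cp.cluster_binarize([], cm), [0, 0])
        np.testing.assert_array_equal(cp.cluster_binarize([2, 4], cm), [1, 1])

    def test_unmapped_token_is_error(self):
        cm = cp.ClusterMap(token_to_cluster={2: 0}, n_clusters=1, pca_dim=2,
                           distance_threshold=0.5, linkage="average")
        with pytest.raises(ValueError):
            cp.cluster_binarize([7], cm)


class TestVocabularySerialization:
    def test_json_round_trip_with_hash(self, tmp_path):
        v = vocab_of(["C1", "C2"], icd_code={"C1": "I50.9"},
                     embedding={"C1": np.ones(3), "C2": np.zeros(3)},
                     admission_df={"C1": 7, "C2": 5})
        path = tmp_path / "vocab.json"
        v.to_json(path)
        v2 = cp.CuiVocabulary.from_json(path)
        assert v2.cui_to_token == v.cui_to_token
        assert v2.content_hash() == v.content_hash()
        np.testing.assert_array_equal(v2.embedding["C1"], v.embedding["C1"])
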