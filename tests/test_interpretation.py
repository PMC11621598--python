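"""Integrated gradients, segment extraction, clustering, PWM/MEME export,
masking mechanics, and class correlation."""

import numpy as np
import pytest

from dnamod.network import MethylationClassifier, ModelConfig
from dnamod.records import LABELS, SITE_INDEX, TOKEN_LENGTH, tokenize
from dnamod.simulate import SyntheticSpec, generate_dataset
from dnamod import interpretation as I
from conftest import make_record

RNG = np.random.default_rng(0)


def small_model(seed=5):
    return MethylationClassifier(ModelConfig(
        embed_dim=16, n_resnet_blocks=1, n_attention_blocks=1, n_heads=4,
        dropout=0.0, seed=seed,
    ))


class LinearSurrogate:
    """A model whose target logit is linear in the embedding:
    F(e) = Σ_{t,d} w[t,d]·e[t,d].  Its integrated gradients have the
    closed form attribution_t = Σ_d w[t,d]·e[t,d] for any step count."""

    def __init__(self, weights, table):
        self.weights = weights  # (42, dim)
        self.table = table      # (5, dim) embedding table

    def embed_tokens(self, ids):
        return self.table[np.asarray(ids)]

    def logit_grads(self, emb, target_class):
        logits = (emb * self.weights).sum(axis=(1, 2))
        grads = np.broadcast_to(self.weights, emb.shape).copy()
        return logits, grads


class TestIntegratedGradients:
    def test_linear_model_matches_closed_form_for_any_steps(self):
        weights = RNG.normal(size=(TOKEN_LENGTH, 8))
        table = RNG.normal(size=(5, 8))
        surrogate = LinearSurrogate(weights, table)
        ids = RNG.integers(0, 5, size=TOKEN_LENGTH)
        emb = surrogate.embed_tokens(ids)
        expect = (weights * emb).sum(axis=1)
        for steps in (1, 3, 50):
            track = I.integrated_gradients(surrogate, ids, 0, steps=steps)
            assert np.allclose(track.token_attributions, expect, atol=1e-8)
            assert abs(track.completeness_residual) <= 1e-8

    def test_constant_logit_gives_zero_attributions(self):
        model = small_model()
        model.kmer_conv.weight.data[:] = 0.0  # severs input from the head
        rec = make_record()
        track = I.integrated_gradients(model, tokenize(rec), rec.label)
        assert np.allclose(track.token_attributions, 0.0, atol=1e-12)

    def test_completeness_residual_shrinks_with_steps(self, trained_model,
                                                      default_dataset):
        model, _ = trained_model
        for label in ("6mA", "5mC"):
            rec = next(r for r in default_dataset if r.label == label)
            coarse = I.integrated_gradients(model, tokenize(rec), label, steps=50)
            fine = I.integrated_gradients(model, tokenize(rec), label, steps=500)
            emb = model.embed_tokens(np.array(tokenize(rec).token_ids))
            logits, _ = model.logit_grads(np.stack([emb, np.zeros_like(emb)]),
                                          LABELS.index(label))
            scale = abs(logits[0] - logits[1])
            assert abs(fine.completeness_residual) <= \
                abs(coarse.completeness_residual) + 0.01 * scale

    def test_attribution_sum_approximates_logit_difference(self, trained_model,
                                                           default_dataset):
        # completeness at fine discretization: residual within 2% of the gap
        model, _ = trained_model
        rec = next(r for r in default_dataset if r.label == "6mA")
        track = I.integrated_gradients(model, tokenize(rec), rec.label, steps=500)
        emb = model.embed_tokens(np.array(tokenize(rec).token_ids))
        logits, _ = model.logit_grads(np.stack([emb, np.zeros_like(emb)]),
                                      LABELS.index("6mA"))
        diff = logits[0] - logits[1]
        assert track.token_attributions.sum() == pytest.approx(
            diff, abs=0.02 * abs(diff)
        )

    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError, match="steps"):
            I.integrated_gradients(small_model(), tokenize(make_record()), 0, steps=0)


class _FixedProbModel:
    def __init__(self, probs):
        self.probs = np.asarray(probs)

    def predict_proba(self, tokens):
        return self.probs


class TestSelectSamples:
    def test_threshold_is_strict(self):
        records = [
            make_record(label="6mA", rec_id="above"),
            make_record(label="6mA", rec_id="at"),
        ]
        class_id = LABELS.index("6mA")
        probs = np.full((2, 5), 0.1)
        probs[0, class_id] = 0.31
        probs[1, class_id] = 0.30
        kept = I.select_samples(_FixedProbModel(probs), records)
        assert [r.id for r in kept] == ["above"]

    def test_uniform_model_selects_nothing(self):
        records = [make_record(rec_id=f"r{i}") for i in range(4)]
        probs = np.full((4, 5), 0.2)
        assert I.select_samples(_FixedProbModel(probs), records) == []


class TestExtractSegment:
    def track_with(self, attributions):
        return I.AttributionTrack(
            token_attributions=np.asarray(attributions, dtype=float),
            target_class="6mA", predicted_probability=1.0,
            completeness_residual=0.0,
        )

    def test_flank_five_gives_11_bases_10_flanking(self):
        rec = make_record("A" * 41, label="6mA")
        seg = I.extract_segment(self.track_with(np.arange(42)), rec, flank=5)
        assert seg.bases == "A" * 11
        assert len(seg.bases) - 1 == 10
        # token indices 16..26 align to sequence positions 15..25
        assert np.array_equal(seg.attributions, np.arange(16, 27))

    def test_flank_zero_single_site_base(self):
        rec = make_record(label="5mC")
        seg = I.extract_segment(self.track_with(np.zeros(42)), rec, flank=0)
        assert seg.bases == rec.sequence[SITE_INDEX]

    def test_segment_slices_expected_window(self):
        seq = "ACGTACGTACGTACGTACGTCACGTACGTACGTACGTACGT"
        rec = make_record(seq, label="5mC")
        seg = I.extract_segment(self.track_with(np.zeros(42)), rec, flank=5)
        assert seg.bases == rec.sequence[15:26]

    def test_flank_outside_window_rejected(self):
        rec = make_record()
        with pytest.raises(ValueError, match="outside"):
            I.extract_segment(self.track_with(np.zeros(42)), rec, flank=21)


def make_segments(bases_list, attr_value=1.0):
    return [
        I.AttributionSegment(bases=b, attributions=np.full(len(b), attr_value),
                             record_id=f"s{i}")
        for i, b in enumerate(bases_list)
    ]


class TestBuildPwm:
    def test_identical_members_zero_pseudocount_one_hot(self):
        pwm = I.build_pwm(make_segments(["ACGTA", "ACGTA"]), pseudocount=0.0)
        assert np.allclose(pwm.max(axis=1), 1.0)
        assert np.allclose(pwm.sum(axis=1), 1.0)

    def test_even_split_counts(self):
        pwm = I.build_pwm(make_segments(["A", "T"]), pseudocount=0.0)
        assert np.allclose(pwm[0], [0.5, 0.0, 0.0, 0.5])

    def test_pseudocount_arithmetic(self):
        pwm = I.build_pwm(make_segments(["A", "A", "C"]), pseudocount=0.01)
        assert np.allclose(pwm[0], np.array([2.01, 1.01, 0.01, 0.01]) / 3.04)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            I.build_pwm([])


class TestClusterSegments:
    def test_two_planted_motifs_give_two_pure_clusters(self):
        rng = np.random.default_rng(1)
        bases = []
        for motif in ("AAAAA", "CCCCC"):
            for _ in range(60):
                flank1 = "".join(rng.choice(list("ACGT"), 3))
                flank2 = "".join(rng.choice(list("ACGT"), 3))
                bases.append(flank1 + motif + flank2)
        segments = make_segments(bases)
        clusters = I.cluster_segments(segments, I.ClusterParams(seed=3))
        assert len(clusters) == 2
        for cluster in clusters:
            cores = {seg.bases[3:8] for seg in cluster.segments}
            assert len(cores) == 1  # pure

    def test_all_identical_segments_single_cluster(self):
        segments = make_segments(["ACGTACGTACG"] * 30)
        clusters = I.cluster_segments(segments, I.ClusterParams())
        assert len(clusters) == 1
        assert clusters[0].size == 30

    def test_fixed_seed_deterministic(self):
        rng = np.random.default_rng(2)
        bases = ["".join(rng.choice(list("ACGT"), 11)) for _ in range(80)]
        segments = make_segments(bases)
        params = I.ClusterParams(seed=7)
        first = I.cluster_segments(segments, params)
        second = I.cluster_segments(segments, params)
        assert [sorted(s.record_id for s in c.segments) for c in first] == \
               [sorted(s.record_id for s in c.segments) for c in second]

    def test_too_few_segments_warn_and_empty(self):
        with pytest.warns(UserWarning, match="fewer"):
            out = I.cluster_segments(make_segments(["ACGTACGTACG"] * 3),
                                     I.ClusterParams(min_cluster_size=10))
        assert out == []

    def test_mean_attribution_is_member_mean(self):
        segments = make_segments(["AAAAA"] * 10, attr_value=2.0) + \
            make_segments(["AAAAA"] * 10, attr_value=4.0)
        clusters = I.cluster_segments(segments, I.ClusterParams())
        assert len(clusters) == 1
        assert np.allclose(clusters[0].mean_attribution, 3.0)


class TestMemeExport:
    def test_zero_clusters_header_only(self, tmp_path):
        path = tmp_path / "empty.meme"
        I.export_meme([], path)
        text = path.read_text()
        assert text.startswith("MEME version 4")
        assert "MOTIF" not in text

    def test_one_hot_rows(self, tmp_path):
        segments = make_segments(["ACGTACGTACG"] * 5)
        cluster = I.cluster_segments(segments, I.ClusterParams(min_cluster_size=5))[0]
        cluster.pwm = I.build_pwm(cluster.segments, pseudocount=0.0)
        path = tmp_path / "onehot.meme"
        I.export_meme([cluster], path)
        for line in path.read_text().splitlines():
            if line.startswith(" "):
                assert line.split().count("1.000000") == 1

    def test_round_trip_random_pwms(self, tmp_path):
        rng = np.random.default_rng(4)
        clusters = []
        for i in range(3):
            segs = make_segments(["ACGTACGTACG"] * 4)
            cluster = I.MotifCluster(
                cluster_id=i, segments=segs,
                mean_attribution=np.zeros(11),
                pwm=rng.dirichlet(np.ones(4), size=11),
            )
            clusters.append(cluster)
        path = tmp_path / "motifs.meme"
        I.export_meme(clusters, path)
        back = I.read_meme(path)
        assert len(back) == 3
        for cluster in clusters:
            got = back[f"cluster_{cluster.cluster_id}"]
            assert np.abs(got - cluster.pwm).max() <= 1e-6

    def test_biopython_parses_export(self, tmp_path):
        # independent reader: the minimal-format parser from Bio.motifs
        from Bio import motifs as bio_motifs

        segs = make_segments(["ACGTACGTACG"] * 6)
        cluster = I.cluster_segments(segs, I.ClusterParams(min_cluster_size=5))[0]
        path = tmp_path / "bio.meme"
        I.export_meme([cluster], path)
        with open(path) as handle:
            parsed = bio_motifs.parse(handle, "minimal")
        assert len(parsed) == 1
        assert parsed[0].length == 11


class TestMaskingMechanics:
    def records_and_span(self):
        spec = SyntheticSpec(
            counts={"6mA": 30, "4mC": 0, "5hmC": 0, "5mC": 0, "6mA-neg": 0},
            seed=6,
        )
        return generate_dataset(spec), (22, 28)

    def test_zero_positions_equals_unmasked(self):
        records, span = self.records_and_span()
        model = small_model()
        mean_in, std_in = I.masked_recall(model, records, span, "inside", 0)
        from dnamod.records import encode_dataset
        tokens, labels = encode_dataset(records)
        unmasked = (model.predict(tokens) == labels).mean()
        assert mean_in == pytest.approx(unmasked)
        assert std_in == 0.0

    def test_constant_model_inside_equals_outside(self):
        records, span = self.records_and_span()
        model = small_model()
        model.kmer_conv.weight.data[:] = 0.0  # output independent of input
        result = I.masking_experiment(model, records, span, n_positions=2, seed=1)
        assert result.mean_recall_inside == pytest.approx(result.mean_recall_outside)

    def test_site_never_eligible_inside(self):
        eligible = I._eligible_positions((18, 24), "inside")
        from dnamod.records import SITE_TOKEN_INDEX
        assert SITE_TOKEN_INDEX not in eligible

    def test_cls_never_eligible_outside(self):
        eligible = I._eligible_positions((22, 28), "outside")
        assert 0 not in eligible

    def test_excessive_positions_rejected(self):
        records, span = self.records_and_span()
        with pytest.raises(ValueError, match="eligible"):
            I.masked_recall(small_model(), records, span, "inside", 10)

    def test_minimum_repetitions_enforced(self):
        records, span = self.records_and_span()
        with pytest.raises(ValueError, match="repetitions"):
            I.masked_recall(small_model(), records, span, "inside", 1, n_reps=5)


class TestClassCorrelation:
    def small_mixed_dataset(self):
        counts = {label: 10 for label in LABELS}
        return generate_dataset(SyntheticSpec(counts=counts, seed=12))

    def test_symmetric_unit_diagonal_bounded(self):
        matrix = I.class_correlation(small_model(), self.small_mixed_dataset())
        assert matrix.shape == (5, 5)
        assert np.allclose(matrix, matrix.T, atol=1e-12)
        assert np.allclose(np.diag(matrix), 1.0)
        assert (np.abs(matrix) <= 1.0 + 1e-12).all()

    def test_identical_record_sets_correlate_perfectly(self):
        rng = np.random.default_rng(14)
        data = []
        # 4mC and 5mC get byte-identical sequences (central C for both)
        for i in range(6):
            seq = "".join(rng.choice(list("ACGT"), 41))
            seq = seq[:20] + "C" + seq[21:]
            data.append(make_record(seq, label="4mC", rec_id=f"a{i}"))
            data.append(make_record(seq, label="5mC", rec_id=f"b{i}"))
        for label in ("5hmC", "6mA", "6mA-neg"):
            for i in range(3):
                seq = "".join(rng.choice(list("ACGT"), 41))
                data.append(make_record(seq, label=label, rec_id=f"{label}{i}"))
        matrix = I.class_correlation(small_model(), data)
        i, j = LABELS.index("4mC"), LABELS.index("5mC")
        assert matrix[i, j] == pytest.approx(1.0)

    def test_missing_class_rejected(self):
        data = [r for r in self.small_mixed_dataset() if r.label != "5hmC"]
        with pytest.raises(ValueError, match="missing"):
            I.class_correlation(small_model(), data)
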