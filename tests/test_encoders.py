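import numpy as np
import pytest
import scipy.sparse as sp

from epimodal.encoders import (
    KmerRegionEmbedder,
    MultimodalModel,
    SequenceEncoderConfig,
    StructureEncoderConfig,
    build_sequence_encoder,
    build_structure_encoder,
    kmer_region_embedder,
    load_checkpoint,
    load_sequence_encoder_weights,
    save_checkpoint,
)
from epimodal.genome_io import GenomeAssembly
from epimodal.hic_io import BinGrid, InteractionMatrix
from epimodal.nn import Tensor


def toy_matrix(n_bins=6, seed=0, chrom_len=600, res=100):
    asm = GenomeAssembly(["c1"], {"c1": "A" * chrom_len})
    grid = BinGrid.from_assembly(asm, resolution=res)
    rng = np.random.default_rng(seed)
    raw = rng.poisson(2.0, (n_bins, n_bins)).astype(float)
    raw = np.maximum(raw, raw.T)
    return InteractionMatrix(grid, sp.csr_matrix(raw))


class TestSequenceEncoderConfigs:
    def test_default_constants_are_published_layout(self):
        cfg = SequenceEncoderConfig()
        assert cfg.conv_channels == (320, 480, 960)
        assert cfg.kernel_size == 8 and cfg.pool_sizes == (4, 4)
        cfg2 = SequenceEncoderConfig(variant="cnn_rnn")
        assert cfg2.rnn_channels == 320 and cfg2.rnn_kernel_size == 26
        assert cfg2.rnn_pool_size == 13 and cfg2.lstm_hidden == 320

    def test_sei_variant_reserved(self):
        with pytest.raises(NotImplementedError):
            SequenceEncoderConfig(variant="sei")

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            SequenceEncoderConfig(variant="transformer")

    def test_pool_layout_validation(self):
        with pytest.raises(ValueError, match="pool_sizes"):
            SequenceEncoderConfig(conv_channels=(8, 8), pool_sizes=(4, 4))


class TestSequenceEncoders:
    @pytest.mark.parametrize("variant", ["cnn", "cnn_rnn"])
    def test_miniature_embedding_dims(self, variant):
        cfg = SequenceEncoderConfig.miniature(variant, window_length=400, embed_dim=32)
        enc = build_sequence_encoder(cfg, seed=0)
        out = enc(Tensor(np.zeros((2, 4, 400))))
        assert out.shape == (2, 32)

    def test_all_n_window_gives_finite_embedding(self):
        cfg = SequenceEncoderConfig.miniature("cnn", window_length=400)
        enc = build_sequence_encoder(cfg, seed=0)
        out = enc(Tensor(np.zeros((1, 4, 400))))
        assert np.isfinite(out.data).all()

    def test_wrong_shape_names_expected_dims(self):
        cfg = SequenceEncoderConfig.miniature("cnn", window_length=400)
        enc = build_sequence_encoder(cfg, seed=0)
        with pytest.raises(ValueError, match=r"\(N, 4, 400\)"):
            enc(Tensor(np.zeros((1, 4, 100))))

    def test_first_layer_kernel_geometry(self):
        cnn = build_sequence_encoder(SequenceEncoderConfig.miniature("cnn"), seed=0)
        assert cnn.first_layer_kernels().shape == (32, 4, 8)
        rnn = build_sequence_encoder(
            SequenceEncoderConfig.miniature("cnn_rnn", window_length=400), seed=0)
        assert rnn.first_layer_kernels().shape[2] == 26

    def test_eval_forward_deterministic(self):
        cfg = SequenceEncoderConfig.miniature("cnn", window_length=400)
        enc = build_sequence_encoder(cfg, seed=0)
        enc.eval()
        rng = np.random.default_rng(0)
        x = Tensor((rng.random((3, 4, 400)) < 0.25).astype(float))
        np.testing.assert_array_equal(enc(x).data, enc(x).data)


class TestStructureEncoders:
    def test_gcn_topo_initial_features_are_all_ones(self):
        m = toy_matrix()
        enc = build_structure_encoder(
            StructureEncoderConfig.miniature("gcn_topo"), m, seed=0)
        assert (enc.h0 == 1).all()
        assert enc.h0.shape == (6, 16)

    def test_gcn_default_node_feature_width_768(self):
        m = toy_matrix()
        enc = build_structure_encoder(StructureEncoderConfig(variant="gcn_topo"), m)
        assert enc.h0.shape == (6, 768)

    def test_gcn_permutation_equivariance(self):
        m = toy_matrix(seed=3)
        perm = np.array([3, 1, 5, 0, 2, 4])
        dense = m.dense
        permuted = InteractionMatrix(m.grid, sp.csr_matrix(dense[np.ix_(perm, perm)]))
        enc = build_structure_encoder(
            StructureEncoderConfig.miniature("gcn_topo"), m, seed=0)
        enc_p = build_structure_encoder(
            StructureEncoderConfig.miniature("gcn_topo"), permuted, seed=0)
        out = enc(np.arange(6)).data
        out_p = enc_p(np.arange(6)).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-10)

    def test_mlp_zero_rows_share_one_embedding(self):
        asm = GenomeAssembly(["c1"], {"c1": "A" * 600})
        grid = BinGrid.from_assembly(asm, resolution=100)
        arr = np.zeros((6, 6))
        arr[0, 1] = arr[1, 0] = 3.0
        m = InteractionMatrix(grid, sp.csr_matrix(arr))
        enc = build_structure_encoder(StructureEncoderConfig.miniature("mlp"), m, seed=0)
        out = enc(np.array([2, 3, 4])).data
        np.testing.assert_allclose(out[0], out[1])
        np.testing.assert_allclose(out[0], out[2])

    def test_bin_index_out_of_range(self):
        enc = build_structure_encoder(
            StructureEncoderConfig.miniature("mlp"), toy_matrix(), seed=0)
        with pytest.raises(IndexError):
            enc(np.array([99]))

    def test_gcn_seq_requires_embedder(self):
        with pytest.raises(ValueError, match="region embedder"):
            build_structure_encoder(
                StructureEncoderConfig.miniature("gcn_seq"), toy_matrix())


class TestKmerRegionEmbedder:
    def test_deterministic_and_dim(self):
        emb = kmer_region_embedder(k=4, out_dim=768, seed=5)
        v1 = emb.embed("ACGT" * 300)
        v2 = emb.embed("ACGT" * 300)
        assert v1.shape == (768,)
        np.testing.assert_array_equal(v1, v2)

    def test_polya_and_polyt_differ(self):
        emb = kmer_region_embedder(k=3, out_dim=32, seed=0)
        assert not np.allclose(emb.embed("A" * 500), emb.embed("T" * 500))

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            KmerRegionEmbedder(k=0)


class TestMultimodalModel:
    def test_probabilities_strictly_inside_unit_interval(self, tiny_model, small_fixture):
        probs = tiny_model.predict(small_fixture.onehot[:4],
                                   small_fixture.sample_hic_bins[:4])
        assert probs.shape == (4, 6)
        assert (probs > 0).all() and (probs < 1).all()

    def test_head_width_equals_concat_dim(self, tiny_model):
        assert tiny_model.head_in == 16 + 8

    def test_zeroed_head_outputs_sigmoid_bias(self, tiny_model, small_fixture):
        import copy

        m = copy.deepcopy(tiny_model)
        head = m._children["head"]
        head.w.data[:] = 0.0
        head.b.data[:] = 0.3
        probs = m.predict(small_fixture.onehot[:2], small_fixture.sample_hic_bins[:2])
        expected = 1 / (1 + np.exp(-0.3))
        np.testing.assert_allclose(probs, expected, atol=1e-12)

    def test_accessibility_channel_widens_head(self, small_fixture):
        from epimodal.hic_io import accessibility

        seq = build_sequence_encoder(
            SequenceEncoderConfig.miniature("cnn", window_length=1000, embed_dim=16),
            seed=0)
        model = MultimodalModel(seq, None, n_events=6,
                                rng=np.random.default_rng(0),
                                accessibility=accessibility(small_fixture.matrix),
                                accessibility_dim=4)
        assert model.head_in == 16 + 4
        probs = model.predict(small_fixture.onehot[:2],
                              small_fixture.sample_hic_bins[:2])
        assert probs.shape == (2, 6)


class TestCheckpoints:
    def test_save_load_round_trip(self, tiny_model, small_fixture, tmp_path):
        save_checkpoint(tiny_model, tmp_path / "ckpt")
        seq = build_sequence_encoder(tiny_model.seq.config, seed=42)
        struct = build_structure_encoder(tiny_model.struct.config,
                                         small_fixture.matrix, seed=43)
        other = MultimodalModel(seq, struct, n_events=6,
                                rng=np.random.default_rng(44))
        load_checkpoint(other, tmp_path / "ckpt")
        x = small_fixture.onehot[:3]
        b = small_fixture.sample_hic_bins[:3]
        np.testing.assert_array_equal(tiny_model.predict(x, b), other.predict(x, b))

    def test_manifest_mismatch_fails_loudly(self, tiny_model, small_fixture, tmp_path):
        save_checkpoint(tiny_model, tmp_path / "ckpt")
        seq = build_sequence_encoder(
            SequenceEncoderConfig.miniature("cnn", window_length=1000, embed_dim=24),
            seed=0)
        other = MultimodalModel(seq, None, n_events=6, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="manifest mismatch"):
            load_checkpoint(other, tmp_path / "ckpt")

    def test_warm_start_rejects_mismatched_window_length(self, tiny_model, tmp_path):
        save_checkpoint(tiny_model, tmp_path / "ckpt")
        seq = build_sequence_encoder(
            SequenceEncoderConfig.miniature("cnn", window_length=400, embed_dim=16),
            seed=0)
        other = MultimodalModel(seq, None, n_events=6, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="does not match"):
            load_sequence_encoder_weights(other, tmp_path / "ckpt")
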