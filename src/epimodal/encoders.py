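"""Sequence encoders, structure encoders and the multimodal head.

The model family pairs a local-sequence encoder over a 1-kb one-hot window
with a global-structure encoder over the whole-genome Hi-C graph, and feeds
the concatenated embeddings to one fully connected sigmoid layer that emits
the probability of each epigenetic event.

Sequence encoders
-----------------
``cnn``      three 1D convolutions (320/480/960 kernels of size 8) with two
             interspersed max-pool(4) layers, the DeepSEA layout;
``cnn_rnn``  one convolution (320 kernels of size 26), max-pool(13), then a
             bidirectional LSTM (320 units per direction), the DanQ layout.
Both end in an affine map to a 925-dimensional embedding.

Structure encoders
------------------
``mlp``       a bin's row of the row-normalised interaction matrix through
              two hidden ReLU layers;
``gcn_topo``  a 3-layer graph convolution over the symmetrically normalised
              contact graph with all-ones node features of width 768;
``gcn_seq``   the same graph convolution with node features supplied by a
              regional sequence embedder (a k-mer embedder by default,
              standing behind the same mean-pooled-regional-embedding
              contract as a pretrained DNA language model).

All layer constants are config-overridable so miniature models can be
trained at desk scale; the defaults reproduce the published architecture.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .genome_io import BASES, GenomeAssembly
from .hic_io import InteractionMatrix, normalize
from .nn import Tensor
from .nn import autograd as ag

SEI_VARIANT = "sei"  # reserved: residual-CNN/B-spline encoder, not implemented


@dataclass(frozen=True)
class SequenceEncoderConfig:
    variant: str = "cnn"
    window_length: int = 1000
    embed_dim: int = 925
    # cnn constants; the defaults are the published 3-conv layout.  Miniature
    # configs may use fewer convolution layers (pool_sizes lists one pool per
    # non-final layer).
    conv_channels: tuple[int, ...] = (320, 480, 960)
    kernel_size: int = 8
    pool_sizes: tuple[int, ...] = (4, 4)
    dropouts: tuple[float, float, float] = (0.2, 0.2, 0.5)
    # optional max-pool after the last convolution, before flattening.
    # 1 = no extra pooling (the published layout); 0 = global (pool over the
    # whole remaining length), which concentrates gradient credit on the
    # best-matching position and makes desk-scale miniatures learn motifs
    # from a few thousand windows.
    final_pool: int = 1
    # cnn_rnn constants (DanQ layout)
    rnn_channels: int = 320
    rnn_kernel_size: int = 26
    rnn_pool_size: int = 13
    lstm_hidden: int = 320
    rnn_dropout: float = 0.2

    def __post_init__(self):
        if self.variant == SEI_VARIANT:
            raise NotImplementedError("the residual-CNN/B-spline variant is reserved")
        if self.variant not in ("cnn", "cnn_rnn"):
            raise ValueError(f"unknown sequence encoder variant {self.variant!r}")
        if self.variant == "cnn":
            if not (1 <= len(self.conv_channels) <= 3):
                raise ValueError("conv_channels must list 1 to 3 layers")
            if len(self.pool_sizes) != len(self.conv_channels) - 1:
                raise ValueError("pool_sizes must list one pool per non-final conv")

    @classmethod
    def miniature(cls, variant: str = "cnn", window_length: int = 400,
                  embed_dim: int = 32) -> "SequenceEncoderConfig":
        """A small configuration for desk-scale training and tests.

        The cnn miniature is a single 32-kernel convolution followed by a
        global max pool: with a few thousand training windows this shallow
        layout learns planted motifs where the deep full-size stack (built
        for millions of windows) would only memorise.
        """
        if variant == "cnn":
            return cls(
                variant="cnn", window_length=window_length, embed_dim=embed_dim,
                conv_channels=(32,), pool_sizes=(), final_pool=0,
                dropouts=(0.0, 0.0, 0.0),
            )
        return cls(
            variant=variant, window_length=window_length, embed_dim=embed_dim,
            rnn_channels=8, rnn_pool_size=13, lstm_hidden=8, rnn_dropout=0.0,
        )


@dataclass(frozen=True)
class StructureEncoderConfig:
    variant: str = "mlp"
    node_feature_dim: int = 768
    gcn_layers: int = 3
    gcn_hidden: tuple[int, ...] = (256, 256)
    struct_embed_dim: int = 128
    mlp_hidden: tuple[int, ...] = (256, 256)

    def __post_init__(self):
        if self.variant not in ("mlp", "gcn_topo", "gcn_seq"):
            raise ValueError(f"unknown structure encoder variant {self.variant!r}")
        if len(self.gcn_hidden) != self.gcn_layers - 1:
            raise ValueError("gcn_hidden must list one width per non-final layer")

    @classmethod
    def miniature(cls, variant: str = "mlp", struct_embed_dim: int = 16) -> "StructureEncoderConfig":
        return cls(variant=variant, node_feature_dim=16, gcn_hidden=(16, 16),
                   struct_embed_dim=struct_embed_dim, mlp_hidden=(32, 32))


class SequenceEncoder(nn.Module):
    """One-hot (N, 4, L) window -> (N, embed_dim) embedding."""

    def __init__(self, config: SequenceEncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self._rng = rng
        L = config.window_length
        if config.variant == "cnn":
            k = config.kernel_size
            length = L
            in_ch = 4
            for i, out_ch in enumerate(config.conv_channels, start=1):
                self.add_child(f"conv{i}", nn.Conv1d(in_ch, out_ch, k, rng))
                length = length - k + 1
                if length < 1:
                    raise ValueError(f"window length {L} too short for the cnn layout")
                if i - 1 < len(config.pool_sizes):
                    length //= config.pool_sizes[i - 1]
                in_ch = out_ch
            self._final_pool = length if config.final_pool == 0 else config.final_pool
            self.flat_dim = in_ch * (length // self._final_pool)
            if self.flat_dim < 1:
                raise ValueError(f"window length {L} too short for the cnn layout")
        else:  # cnn_rnn
            c = config.rnn_channels
            self.add_child("conv1", nn.Conv1d(4, c, config.rnn_kernel_size, rng))
            T = (L - config.rnn_kernel_size + 1) // config.rnn_pool_size
            if T < 1:
                raise ValueError(f"window length {L} too short for the cnn_rnn layout")
            self.add_child("lstm", nn.BiLSTM(c, config.lstm_hidden, rng))
            self.flat_dim = T * 2 * config.lstm_hidden
        self.add_child("embed", nn.Linear(self.flat_dim, config.embed_dim, rng))

    def first_layer_kernels(self) -> np.ndarray:
        """The first convolutional layer's kernels, shape (F, 4, K)."""
        return self._children["conv1"].w.data.copy()

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.config
        if x.data.ndim != 3 or x.data.shape[1:] != (4, cfg.window_length):
            raise ValueError(
                f"expected one-hot input of shape (N, 4, {cfg.window_length}), "
                f"got {x.data.shape}"
            )
        N = x.data.shape[0]
        if cfg.variant == "cnn":
            h = x
            n_convs = len(cfg.conv_channels)
            for i in range(1, n_convs + 1):
                h = ag.relu(self._children[f"conv{i}"](h))
                if i - 1 < len(cfg.pool_sizes):
                    h = ag.maxpool1d(h, cfg.pool_sizes[i - 1])
                    h = ag.dropout(h, cfg.dropouts[i - 1], self._rng, self.training)
            if self._final_pool > 1:
                h = ag.maxpool1d(h, self._final_pool)
            h = ag.dropout(h, cfg.dropouts[-1], self._rng, self.training)
            h = ag.reshape(h, (N, self.flat_dim))
        else:
            h = ag.relu(self._children["conv1"](x))
            h = ag.maxpool1d(h, cfg.rnn_pool_size)
            h = ag.dropout(h, cfg.rnn_dropout, self._rng, self.training)
            h = ag.transpose(h, (0, 2, 1))  # (N, T, C)
            h = self._children["lstm"](h)
            h = ag.reshape(h, (N, self.flat_dim))
        return ag.relu(self._children["embed"](h))


class RegionEmbedder:
    """Contract: map a bin-length DNA sequence to a fixed-dim vector by
    mean-pooling embeddings of its sub-windows.  Deterministic per instance."""

    out_dim: int

    def embed(self, sequence: str) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class KmerRegionEmbedder(RegionEmbedder):
    """k-mer composition embedder: per 1-kb sub-window k-mer count vectors,
    mean-pooled over sub-windows, projected by a fixed seeded random matrix."""

    def __init__(self, k: int = 4, out_dim: int = 768, seed: int = 0,
                 subwindow: int = 1000):
        if not (1 <= k <= 8):
            raise ValueError("k must be in [1, 8]")
        self.k, self.out_dim, self.seed, self.subwindow = k, out_dim, seed, subwindow
        rng = np.random.default_rng(seed)
        self._proj = rng.standard_normal((4**k, out_dim)) / np.sqrt(4**k)
        self._base = {b: i for i, b in enumerate(BASES)}

    def _counts(self, seq: str) -> np.ndarray:
        v = np.zeros(4**self.k)
        code = 0
        valid = 0
        for ch in seq:
            b = self._base.get(ch)
            if b is None:
                code, valid = 0, 0
                continue
            code = (code * 4 + b) % (4**self.k)
            valid += 1
            if valid >= self.k:
                v[code] += 1
        return v

    def embed(self, sequence: str) -> np.ndarray:
        sub = self.subwindow
        chunks = [sequence[i : i + sub] for i in range(0, len(sequence), sub)] or [""]
        counts = np.stack([self._counts(c) for c in chunks]).mean(axis=0)
        return counts @ self._proj


class StructureEncoder(nn.Module):
    """Global bin index -> (N, struct_embed_dim) embedding.

    The interaction matrix is a model constant; for the GCN variants the
    full-graph forward is run per call (desk-scale graphs are small) and the
    requested bins' rows are gathered, so gradients stay exact.
    """

    def __init__(self, config: StructureEncoderConfig, matrix: InteractionMatrix,
                 rng: np.random.Generator, region_embedder: RegionEmbedder | None = None,
                 region_sequences: Sequence[str] | None = None):
        super().__init__()
        self.config = config
        self.n_bins = matrix.grid.n_bins
        if config.variant == "mlp":
            self._rows = normalize(matrix, "row").values
            dims = [self.n_bins, *config.mlp_hidden, config.struct_embed_dim]
            self.add_child("mlp", nn.MLP(dims, rng))
        else:
            self._adj = normalize(matrix, "sym_loop").values
            if config.variant == "gcn_seq":
                if region_embedder is None or region_sequences is None:
                    raise ValueError(
                        "gcn_seq requires a region embedder and per-bin sequences"
                    )
                if len(region_sequences) != self.n_bins:
                    raise ValueError("one region sequence per bin required")
                h0 = np.stack([region_embedder.embed(s) for s in region_sequences])
                in_dim = region_embedder.out_dim
            else:
                in_dim = config.node_feature_dim
                h0 = np.ones((self.n_bins, in_dim))
            self.h0 = h0
            widths = [in_dim, *config.gcn_hidden, config.struct_embed_dim]
            for i, (d_in, d_out) in enumerate(zip(widths[:-1], widths[1:])):
                self.add_child(f"gcn{i}", nn.Linear(d_in, d_out, rng))

    def __call__(self, bin_indices: np.ndarray) -> Tensor:
        bin_indices = np.asarray(bin_indices, dtype=np.intp)
        if bin_indices.size and (bin_indices.min() < 0 or bin_indices.max() >= self.n_bins):
            raise IndexError(
                f"bin index out of range [0, {self.n_bins}): {bin_indices}"
            )
        if self.config.variant == "mlp":
            rows = np.asarray(self._rows[bin_indices].todense())
            return self._children["mlp"](Tensor(rows))
        h = Tensor(self.h0)
        for i in range(self.config.gcn_layers):
            h = ag.relu(self._children[f"gcn{i}"](ag.spmm(self._adj, h)))
        return ag.gather_rows(h, bin_indices)


class MultimodalModel(nn.Module):
    """Concatenates sequence and structure embeddings into an E-event
    sigmoid head.  ``structure_encoder=None`` gives the sequence-only
    baseline; an optional accessibility channel appends an affine embedding
    of the bin's Hi-C row sum (an ablation input, off by default)."""

    def __init__(self, sequence_encoder: SequenceEncoder,
                 structure_encoder: StructureEncoder | None,
                 n_events: int = 919, rng: np.random.Generator | None = None,
                 accessibility: np.ndarray | None = None,
                 accessibility_dim: int = 8):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_events = n_events
        self.seq = self.add_child("seq", sequence_encoder)
        self.struct = structure_encoder
        head_in = sequence_encoder.config.embed_dim
        if structure_encoder is not None:
            self.add_child("struct", structure_encoder)
            head_in += structure_encoder.config.struct_embed_dim
        self.accessibility = None
        if accessibility is not None:
            self.accessibility = np.log1p(np.asarray(accessibility, dtype=float))
            self.add_child("acc", nn.Linear(1, accessibility_dim, rng))
            head_in += accessibility_dim
        self.head_in = head_in
        self.add_child("head", nn.Linear(head_in, n_events, rng))

    def embeddings(self, onehot: np.ndarray, bin_indices: np.ndarray) -> Tensor:
        parts = [self.seq(Tensor(np.asarray(onehot)))]
        if self.struct is not None:
            parts.append(self.struct(bin_indices))
        if self.accessibility is not None:
            acc = self.accessibility[np.asarray(bin_indices, dtype=np.intp)][:, None]
            parts.append(ag.relu(self._children["acc"](Tensor(acc))))
        joint = ag.concat(parts, axis=1) if len(parts) > 1 else parts[0]
        assert joint.data.shape[1] == self.head_in
        return joint

    def __call__(self, onehot: np.ndarray, bin_indices: np.ndarray) -> Tensor:
        return ag.sigmoid(self._children["head"](self.embeddings(onehot, bin_indices)))

    def predict(self, onehot: np.ndarray, bin_indices: np.ndarray,
                batch_size: int = 64) -> np.ndarray:
        """Deterministic evaluation-mode probabilities, batched."""
        self.eval()
        out = []
        onehot = np.asarray(onehot)
        bin_indices = np.asarray(bin_indices, dtype=np.intp)
        for lo in range(0, onehot.shape[0], batch_size):
            out.append(self(onehot[lo : lo + batch_size],
                            bin_indices[lo : lo + batch_size]).data)
        return np.concatenate(out, axis=0)


def build_sequence_encoder(config: SequenceEncoderConfig, seed: int = 0) -> SequenceEncoder:
    return SequenceEncoder(config, np.random.default_rng(seed))


def build_structure_encoder(config: StructureEncoderConfig, matrix: InteractionMatrix,
                            seed: int = 0, region_embedder: RegionEmbedder | None = None,
                            region_sequences: Sequence[str] | None = None) -> StructureEncoder:
    return StructureEncoder(config, matrix, np.random.default_rng(seed),
                            region_embedder=region_embedder,
                            region_sequences=region_sequences)


def kmer_region_embedder(k: int = 4, out_dim: int = 768, seed: int = 0,
                         subwindow: int = 1000) -> KmerRegionEmbedder:
    return KmerRegionEmbedder(k=k, out_dim=out_dim, seed=seed, subwindow=subwindow)


def region_sequences(assembly: GenomeAssembly, grid) -> list[str]:
    """Per-bin DNA sequences (resolution-length, shorter at chromosome ends)."""
    out = []
    for chrom in grid.chrom_names:
        seq = assembly.chrom_seqs[chrom]
        for b in range(grid.bins_per_chrom[chrom]):
            out.append(seq[b * grid.resolution : (b + 1) * grid.resolution])
    return out


# --- checkpointing ----------------------------------------------------------

def save_checkpoint(model: MultimodalModel, path) -> None:
    """Write a checkpoint directory: manifest.json + params.npz."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_events": model.n_events,
        "sequence": dataclasses.asdict(model.seq.config),
        "structure": dataclasses.asdict(model.struct.config) if model.struct else None,
        "has_accessibility": model.accessibility is not None,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    np.savez(path / "params.npz", **model.state_dict())


def load_manifest(path) -> dict:
    return json.loads((Path(path) / "manifest.json").read_text())


def load_checkpoint(model: MultimodalModel, path) -> MultimodalModel:
    """Load parameters into an already-built model; the manifest must match."""
    manifest = load_manifest(path)
    want = {
        "n_events": model.n_events,
        "sequence": dataclasses.asdict(model.seq.config),
        "structure": dataclasses.asdict(model.struct.config) if model.struct else None,
        "has_accessibility": model.accessibility is not None,
    }
    for key, val in want.items():
        if manifest.get(key) != (list(val) if isinstance(val, tuple) else _jsonable(val)):
            raise ValueError(
                f"checkpoint manifest mismatch on {key!r}: "
                f"checkpoint={manifest.get(key)!r}, model={val!r}"
            )
    with np.load(Path(path) / "params.npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def load_sequence_encoder_weights(model: MultimodalModel, path) -> None:
    """Warm start: copy only the sequence-encoder parameters from a
    checkpoint (e.g. a pretrained sequence-only model)."""
    manifest = load_manifest(path)
    if manifest["sequence"] != _jsonable(dataclasses.asdict(model.seq.config)):
        raise ValueError(
            "warm-start checkpoint's sequence-encoder config does not match: "
            f"{manifest['sequence']!r} vs "
            f"{dataclasses.asdict(model.seq.config)!r}"
        )
    with np.load(Path(path) / "params.npz") as data:
        state = {k: data[k] for k in data.files if k.startswith("seq.")}
        sub = {k[len("seq.") :]: v for k, v in state.items()}
        model.seq.load_state_dict(sub)


def _jsonable(obj):
    """Mirror json round-tripping (tuples -> lists) for manifest comparison."""
    return json.loads(json.dumps(obj))
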