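"""The sequence classifier: embedding, k-mer aggregation, residual
convolution stack, multi-head self-attention stack, softmax head.

Architecture summary (sequence axis is length 42 — [CLS] + 41 nt — at
every stage):

* each token id is embedded into an ``embed_dim``-dimensional vector
  (256 by default);
* a kernel-3, stride-1, same-padded 1-D convolution aggregates each
  position with its immediate neighbours (k-mer aggregation);
* a stack of residual blocks ``y = F(x) + x`` where ``F`` is two
  (conv → layer-norm → ReLU) stages, all length-preserving; a 1-window
  projection shortcut ``W_s x`` is used when channel counts differ;
* a stack of multi-head self-attention blocks,
  ``softmax(Q Kᵀ / √d_k) V`` per head, heads concatenated and
  projected by ``W^O``;
* the [CLS]-position row is pooled and mapped by a fully connected
  layer with softmax over the five modification classes.

No positional encoding is added: position-local structure enters
through the convolutions, and classification is content-based.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import tensor as T
from .records import TOKEN_LENGTH, VOCABULARY
from .tensor import Tensor

LAYER_TAGS = ("embedding", "post_kmer", "post_resnet", "post_attention", "last_hidden")


@dataclass
class ModelConfig:
    embed_dim: int = 256
    kmer_window: int = 3
    n_resnet_blocks: int = 5
    n_attention_blocks: int = 2
    n_heads: int = 8
    n_classes: int = 5
    dropout: float = 0.1
    pool: str = "cls"  # "cls" or "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.n_resnet_blocks < 1 or self.n_attention_blocks < 1:
            raise ValueError("need at least one residual and one attention block")
        if self.pool not in ("cls", "mean"):
            raise ValueError("pool must be 'cls' or 'mean'")

    @property
    def d_k(self) -> int:
        return self.embed_dim // self.n_heads


class Conv1d:
    """Same-padded 1-D convolution layer (stride 1, channels preserved or mapped)."""

    def __init__(self, kernel: int, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.weight = Tensor(rng.normal(0.0, scale, (kernel, c_in, c_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return T.conv1d(x, self.weight, self.bias)

    def parameters(self):
        return [self.weight, self.bias]


class LayerNorm:
    def __init__(self, dim: int):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return T.layer_norm(x, self.gain, self.bias)

    def parameters(self):
        return [self.gain, self.bias]


class ResNetBlock:
    """y = F(x) + shortcut(x); F = 2 × (conv → norm → ReLU), length-preserving."""

    def __init__(self, kernel: int, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv1d(kernel, c_in, c_out, rng)
        self.norm1 = LayerNorm(c_out)
        self.conv2 = Conv1d(kernel, c_out, c_out, rng)
        self.norm2 = LayerNorm(c_out)
        # projection shortcut only when channel counts differ
        self.projection = Conv1d(1, c_in, c_out, rng) if c_in != c_out else None

    def residual_function(self, x: Tensor) -> Tensor:
        h = T.relu(self.norm1(self.conv1(x)))
        return T.relu(self.norm2(self.conv2(h)))

    def __call__(self, x: Tensor) -> Tensor:
        shortcut = self.projection(x) if self.projection is not None else x
        return self.residual_function(x) + shortcut

    def parameters(self):
        params = (self.conv1.parameters() + self.norm1.parameters()
                  + self.conv2.parameters() + self.norm2.parameters())
        if self.projection is not None:
            params += self.projection.parameters()
        return params


class MultiHeadSelfAttention:
    """softmax(Q Kᵀ/√d_k) V per head; Concat(head_1..head_h) W^O."""

    def __init__(self, embed_dim: int, n_heads: int, rng: np.random.Generator):
        if embed_dim % n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_k = embed_dim // n_heads
        scale = np.sqrt(1.0 / embed_dim)
        self.w_q = Tensor(rng.normal(0.0, scale, (embed_dim, embed_dim)), requires_grad=True)
        self.w_k = Tensor(rng.normal(0.0, scale, (embed_dim, embed_dim)), requires_grad=True)
        self.w_v = Tensor(rng.normal(0.0, scale, (embed_dim, embed_dim)), requires_grad=True)
        self.w_o = Tensor(rng.normal(0.0, scale, (embed_dim, embed_dim)), requires_grad=True)

    def _split_heads(self, x: Tensor, batch: int, length: int) -> Tensor:
        x = T.reshape(x, (batch, length, self.n_heads, self.d_k))
        return T.transpose(x, (0, 2, 1, 3))  # (batch, heads, L, d_k)

    def attention(self, x: Tensor) -> tuple[Tensor, np.ndarray]:
        """Return the block output and the (batch, heads, L, L) weight array."""
        batch, length, dim = x.shape
        q = self._split_heads(T.matmul(x, self.w_q), batch, length)
        k = self._split_heads(T.matmul(x, self.w_k), batch, length)
        v = self._split_heads(T.matmul(x, self.w_v), batch, length)
        scores = T.mul(T.matmul(q, T.transpose(k, (0, 1, 3, 2))),
                       1.0 / np.sqrt(self.d_k))
        weights = T.softmax(scores)
        context = T.matmul(weights, v)  # (batch, heads, L, d_k)
        context = T.transpose(context, (0, 2, 1, 3))
        concat = T.reshape(context, (batch, length, dim))
        return T.matmul(concat, self.w_o), weights.data

    def __call__(self, x: Tensor) -> Tensor:
        out, _ = self.attention(x)
        return out

    def parameters(self):
        return [self.w_q, self.w_k, self.w_v, self.w_o]


class MethylationClassifier:
    """The full forward model over [CLS]+41-nt token sequences."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(self.config.seed)
        dim = self.config.embed_dim
        self.embedding = Tensor(rng.normal(0.0, 0.1, (len(VOCABULARY), dim)),
                                requires_grad=True)
        self.kmer_conv = Conv1d(self.config.kmer_window, dim, dim, rng)
        self.resnet_blocks = [
            ResNetBlock(self.config.kmer_window, dim, dim, rng)
            for _ in range(self.config.n_resnet_blocks)
        ]
        self.attention_blocks = [
            MultiHeadSelfAttention(dim, self.config.n_heads, rng)
            for _ in range(self.config.n_attention_blocks)
        ]
        scale = np.sqrt(1.0 / dim)
        self.fc_weight = Tensor(rng.normal(0.0, scale, (dim, self.config.n_classes)),
                                requires_grad=True)
        self.fc_bias = Tensor(np.zeros(self.config.n_classes), requires_grad=True)

    # -- parameters --------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params = [self.embedding] + self.kmer_conv.parameters()
        for block in self.resnet_blocks:
            params += block.parameters()
        for block in self.attention_blocks:
            params += block.parameters()
        params += [self.fc_weight, self.fc_bias]
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- forward -----------------------------------------------------
    def embed_tokens(self, token_ids: np.ndarray) -> np.ndarray:
        """Raw embedded input, shape (batch, 42, embed_dim)."""
        token_ids = np.asarray(token_ids)
        if token_ids.max() >= self.embedding.shape[0] or token_ids.min() < 0:
            raise ValueError("token id outside the vocabulary")
        return self.embedding.data[token_ids]

    def forward_from_embedding(
        self,
        emb: Tensor,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> dict:
        """Run the model from an embedded input; returns tagged stages."""
        if emb.shape[1] != TOKEN_LENGTH:
            raise ValueError(f"sequence axis must have length {TOKEN_LENGTH}")
        stages: dict[str, Tensor] = {"embedding": emb}
        x = self.kmer_conv(emb)
        stages["post_kmer"] = x
        for block in self.resnet_blocks:
            x = block(x)
        stages["post_resnet"] = x
        for block in self.attention_blocks:
            x = block(x)
            if train and self.config.dropout > 0:
                if rng is None:
                    raise ValueError("training-mode forward needs an rng for dropout")
                keep = 1.0 - self.config.dropout
                mask = (rng.random(x.shape) < keep) / keep
                x = T.mul(x, mask)
        stages["post_attention"] = x
        stages["last_hidden"] = T.mul(x, 1.0)  # head input, tagged separately
        if self.config.pool == "cls":
            pooled = T.take_position(stages["last_hidden"], 0)
        else:
            pooled = T.reduce_mean(stages["last_hidden"], axis=1)
        logits = T.matmul(pooled, self.fc_weight) + self.fc_bias
        stages["logits"] = logits
        stages["probabilities"] = T.softmax(logits)
        return stages

    def forward(self, token_ids: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> dict:
        token_ids = np.asarray(token_ids)
        if token_ids.ndim == 1:
            token_ids = token_ids[None, :]
        if token_ids.max() >= self.embedding.shape[0] or token_ids.min() < 0:
            raise ValueError("token id outside the vocabulary")
        emb = T.embedding(self.embedding, token_ids)
        return self.forward_from_embedding(emb, train=train, rng=rng)

    def predict_proba(self, token_ids: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Class probabilities in evaluation mode, shape (n, n_classes)."""
        token_ids = np.asarray(token_ids)
        if token_ids.ndim == 1:
            token_ids = token_ids[None, :]
        chunks = [
            self.forward(token_ids[i:i + batch_size])["probabilities"].data
            for i in range(0, len(token_ids), batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    def predict(self, token_ids: np.ndarray, batch_size: int = 512) -> np.ndarray:
        return self.predict_proba(token_ids, batch_size).argmax(axis=1)

    def layer_outputs(self, token_ids: np.ndarray) -> dict[str, np.ndarray]:
        """Evaluation-mode intermediate representations for every tag."""
        stages = self.forward(token_ids)
        return {tag: stages[tag].data for tag in LAYER_TAGS}

    def logit_grads(self, emb: np.ndarray, target_class: int) -> tuple[np.ndarray, np.ndarray]:
        """Target-class logits and their gradients w.r.t. an embedded batch.

        ``emb`` has shape (batch, 42, embed_dim); returns (logits (batch,),
        gradients with the same shape as ``emb``).
        """
        emb_t = Tensor(emb, requires_grad=True)
        stages = self.forward_from_embedding(emb_t)
        target_logits = T.pick(stages["logits"], np.full(emb_t.shape[0], target_class))
        T.reduce_sum(target_logits).backward()
        return target_logits.data.copy(), emb_t.grad.copy()

    # -- checkpointing -----------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for i, p in enumerate(params):
            value = state[f"param_{i}"]
            if value.shape != p.data.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = value.astype(np.float64).copy()

    def save(self, path: str | Path) -> None:
        arrays = self.state_dict()
        arrays["config_yaml"] = np.array(yaml.safe_dump(asdict(self.config)))
        np.savez(path if str(path).endswith(".npz") else f"{path}", **arrays)

    @classmethod
    def load(cls, path: str | Path, config: ModelConfig | None = None) -> "MethylationClassifier":
        with np.load(path, allow_pickle=False) as archive:
            stored = ModelConfig(**yaml.safe_load(str(archive["config_yaml"][()])))
            if config is not None and asdict(config) != asdict(stored):
                raise ValueError(
                    "checkpoint was written with a different model configuration"
                )
            model = cls(stored)
            model.load_state({k: archive[k] for k in archive.files
                              if k != "config_yaml"})
        return model
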