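"""Event-triplet sequence encoder with masked-modality self-supervision.

Each event contributes one token: a per-modality linear projection of its
standardized value, plus a learned modality embedding, plus a sinusoidal
positional encoding evaluated at *continuous* time (hours since induction,
not sequence index). A learned summary token prepended at
t = min(timestamps) − 1 s pools the sequence; its final-layer state is the
context vector ``z_obs``.

Pre-training masks whole events (the value contribution is replaced by a
learned mask embedding; time and modality are kept) and reconstructs the
standardized values of the masked events with a linear readout — the model
must impute from cross-modal temporal context. Full-scale defaults mirror a
4-layer, 8-head, d=256 encoder with dropout 0.15 and 30% masking; tests and
the bundled smoke profile run at d=32.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Parameter, Tensor, stack
from .event_schema import Episode, ModalityVocabulary, Standardizer

__all__ = ["EncoderConfig", "time_positional_encoding", "EventEncoder"]


@dataclass(frozen=True)
class EncoderConfig:
    layers: int = 4
    heads: int = 8
    d_model: int = 256
    dropout: float = 0.15
    mask_rate: float = 0.30
    pretrain_epochs: int = 50
    finetune_epochs: int = 50
    learning_rate: float = 1e-4
    max_events: int = 512           # longest sequences are truncated (oldest
                                    # events dropped) to bound attention cost

    def __post_init__(self):
        if self.d_model % self.heads != 0:
            raise ValueError("model width must be divisible by head count")

    def smoke(self) -> "EncoderConfig":
        return dataclasses.replace(self, layers=2, heads=4, d_model=32,
                                   pretrain_epochs=3, finetune_epochs=5)


def time_positional_encoding(timestamps_sec, width: int) -> np.ndarray:
    """Sinusoid pairs evaluated at continuous time (hours since induction).

    Row i holds ``sin(t_i * ω_k), cos(t_i * ω_k)`` with geometrically spaced
    ω_k — so rows at t and t+Δ are related by a fixed per-frequency rotation.
    """
    if width % 2 != 0:
        raise ValueError("encoding width must be even (sin/cos pairs)")
    t_h = np.asarray(timestamps_sec, dtype=float).reshape(-1, 1) / 3600.0
    half = width // 2
    freqs = 1.0 / (1000.0 ** (np.arange(half) / max(half - 1, 1)))
    ang = t_h * freqs
    pe = np.empty((t_h.shape[0], width))
    pe[:, 0::2] = np.sin(ang)
    pe[:, 1::2] = np.cos(ang)
    return pe


def _layer_norm(x: Tensor, gain: Parameter, bias: Parameter) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + 1e-6) ** 0.5 * gain + bias


class EventEncoder:
    """Self-attention encoder over event triplets (numpy autodiff core)."""

    def __init__(self, config: EncoderConfig, vocab: ModalityVocabulary,
                 seed: int = 0):
        self.cfg = config
        self.vocab = vocab
        rng = np.random.default_rng(seed)
        d = config.d_model
        nm = len(vocab)

        def lin(fan_in, fan_out):
            return Parameter(rng.normal(0, (2.0 / (fan_in + fan_out)) ** 0.5,
                                        (fan_in, fan_out)))

        self.w = {
            "mod_embed": Parameter(rng.normal(0, 0.5, (nm, d))),
            "val_proj": Parameter(rng.normal(0, 0.5, (nm, d))),
            "val_bias": Parameter(np.zeros((nm, d))),
            "mask_embed": Parameter(rng.normal(0, 0.5, d)),
            "cls": Parameter(rng.normal(0, 0.5, d)),
            "readout_w": lin(d, 1),
            "readout_b": Parameter(np.zeros(1)),
        }
        for li in range(config.layers):
            for name in ("wq", "wk", "wv", "wo"):
                self.w[f"L{li}.{name}"] = lin(d, d)
            self.w[f"L{li}.ff1"] = lin(d, 4 * d)
            self.w[f"L{li}.ff1b"] = Parameter(np.zeros(4 * d))
            self.w[f"L{li}.ff2"] = lin(4 * d, d)
            self.w[f"L{li}.ff2b"] = Parameter(np.zeros(d))
            for ln in ("ln1g", "ln2g"):
                self.w[f"L{li}.{ln}"] = Parameter(np.ones(d))
            for ln in ("ln1b", "ln2b"):
                self.w[f"L{li}.{ln}"] = Parameter(np.zeros(d))
        self.w["lnfg"] = Parameter(np.ones(d))
        self.w["lnfb"] = Parameter(np.zeros(d))

    def parameters(self) -> list[Parameter]:
        return list(self.w.values())

    def checksum(self) -> float:
        return float(sum(np.abs(p.data).sum() for p in self.parameters()))

    # ------------------------------------------------------------------
    def embed_events(self, episode: Episode, standardizer: Standardizer,
                     mask_idx: np.ndarray | None = None,
                     value_tensors: list[Tensor] | None = None) -> Tensor:
        """Token matrix for an episode, summary token prepended.

        ``mask_idx`` marks events whose value contribution is replaced by the
        mask embedding (pre-training). ``value_tensors`` optionally supplies
        the standardized values as autodiff leaves (attribution paths).
        """
        events = episode.events[-self.cfg.max_events:]
        if not events:
            raise ValueError(
                "cannot encode an empty event sequence; use the static-only "
                "fallback for episodes without events")
        codes = np.array([self.vocab.code(e.modality) for e in events])
        times = np.array([e.t_sec for e in events])
        pe_t = np.concatenate([[times.min() - 1.0], times])
        pe = Tensor(time_positional_encoding(pe_t, self.cfg.d_model))
        masked = np.zeros(len(events), bool)
        if mask_idx is not None:
            masked[mask_idx] = True

        rows = []
        for i, e in enumerate(events):
            c = codes[i]
            mod = self.w["mod_embed"][c]
            if masked[i]:
                rows.append(mod + self.w["mask_embed"])
                continue
            if value_tensors is not None:
                v = value_tensors[i]
            else:
                v = Tensor(standardizer.transform_value(e.modality, e.value))
            rows.append(mod + self.w["val_proj"][c] * v + self.w["val_bias"][c])
        tokens = stack([self.w["cls"]] + rows, axis=0)
        return tokens + pe

    # ------------------------------------------------------------------
    def _attention(self, x: Tensor, li: int) -> Tensor:
        d, h = self.cfg.d_model, self.cfg.heads
        dh = d // h
        n = x.shape[0]
        q = (x @ self.w[f"L{li}.wq"]).reshape(n, h, dh).transpose(1, 0, 2)
        k = (x @ self.w[f"L{li}.wk"]).reshape(n, h, dh).transpose(1, 0, 2)
        v = (x @ self.w[f"L{li}.wv"]).reshape(n, h, dh).transpose(1, 0, 2)
        att = (q @ k.transpose(0, 2, 1)) * (1.0 / dh ** 0.5)
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(1, 0, 2).reshape(n, d)
        return out @ self.w[f"L{li}.wo"]

    def _dropout(self, x: Tensor, rng) -> Tensor:
        p = self.cfg.dropout
        if rng is None or p <= 0:
            return x
        keep = (rng.uniform(size=x.shape) >= p) / (1.0 - p)
        return x * Tensor(keep)

    def forward_tokens(self, tokens: Tensor, rng=None) -> Tensor:
        x = tokens
        for li in range(self.cfg.layers):
            h = _layer_norm(x, self.w[f"L{li}.ln1g"], self.w[f"L{li}.ln1b"])
            x = x + self._dropout(self._attention(h, li), rng)
            h = _layer_norm(x, self.w[f"L{li}.ln2g"], self.w[f"L{li}.ln2b"])
            ff = ((h @ self.w[f"L{li}.ff1"] + self.w[f"L{li}.ff1b"]).gelu()
                  @ self.w[f"L{li}.ff2"] + self.w[f"L{li}.ff2b"])
            x = x + self._dropout(ff, rng)
        return _layer_norm(x, self.w["lnfg"], self.w["lnfb"])

    def encode(self, episode: Episode, standardizer: Standardizer,
               rng=None, value_tensors=None) -> Tensor:
        """Context vector z_obs = final state of the summary token."""
        tokens = self.embed_events(episode, standardizer,
                                   value_tensors=value_tensors)
        return self.forward_tokens(tokens, rng)[0]

    # ------------------------------------------------------------------
    def pretrain_masked(self, episodes, standardizer: Standardizer,
                        epochs: int | None = None, seed: int = 0,
                        lr: float | None = None) -> list[float]:
        """Masked-event reconstruction; returns per-epoch mean losses."""
        if self.cfg.mask_rate <= 0:
            raise ValueError("mask rate 0 leaves no reconstruction targets")
        epochs = epochs if epochs is not None else self.cfg.pretrain_epochs
        rng = np.random.default_rng(seed)
        opt = Adam(self.parameters(), lr=lr or self.cfg.learning_rate,
                   total_steps=epochs * len(episodes))
        losses = []
        for _ in range(epochs):
            order = rng.permutation(len(episodes))
            tot, cnt = 0.0, 0
            for j in order:
                ep = episodes[j]
                events = ep.events[-self.cfg.max_events:]
                n = len(events)
                if n < 4:
                    continue
                k = max(1, int(round(self.cfg.mask_rate * n)))
                midx = rng.choice(n, size=k, replace=False)
                tokens = self.embed_events(ep, standardizer, mask_idx=midx)
                hidden = self.forward_tokens(tokens, rng=rng)
                preds = hidden[midx + 1] @ self.w["readout_w"] \
                    + self.w["readout_b"]
                target = np.array([[standardizer.transform_value(
                    events[i].modality, events[i].value)] for i in midx])
                err = preds - Tensor(target)
                loss = (err * err).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                tot += loss.item()
                cnt += 1
            losses.append(tot / max(cnt, 1))
        return losses
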