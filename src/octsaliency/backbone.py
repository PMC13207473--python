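"""Hierarchical windowed-attention classifier with a gradient-capture contract.

The model mirrors the structure every saliency method here relies on: patch
embedding, stages of window-attention blocks (alternating unshifted and
cyclically shifted windows, with attention masked across the wrap-around
seam), patch merging between stages, a final layer norm, global average
pooling and a small MLP head.  A forward pass can record, at addressable
blocks, the post-softmax attention probabilities, the norm1/norm2 token
descriptors and the final-norm tokens — together with the gradient of a
target-class logit with respect to each captured array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor

__all__ = [
    "BackboneSpec",
    "BlockAddress",
    "CaptureSpec",
    "WindowedAttentionCapture",
    "TokenCapture",
    "ActivationCapture",
    "CaptureBundle",
    "ClassifierModel",
    "build_model",
    "forward_with_capture",
]


@dataclass(frozen=True)
class BackboneSpec:
    """Architecture hyperparameters.

    The production-scale configuration (input 256, patch 4, four stages)
    is expressible, but the test fixture uses a miniature: two stages of
    depth two, window 4, input 32, patch 4.
    """

    stage_depths: tuple[int, ...] = (2, 2)
    embed_dims: tuple[int, ...] = (16, 32)
    num_heads: tuple[int, ...] = (2, 4)
    window_size: int = 4
    input_side: int = 32
    patch_size: int = 4
    mlp_ratio: float = 4.0
    head_hidden: int = 512
    head_dropout: float = 0.5

    def __post_init__(self):
        if not (len(self.stage_depths) == len(self.embed_dims) == len(self.num_heads)):
            raise ValueError("stage_depths, embed_dims and num_heads must align")
        for s in range(len(self.stage_depths)):
            side = self.grid_side(s)
            if side % self.window_size != 0:
                raise ValueError(
                    f"window size {self.window_size} does not divide the "
                    f"stage-{s} grid side {side}"
                )

    def grid_side(self, stage: int) -> int:
        return self.input_side // self.patch_size // (2**stage)

    @property
    def n_stages(self) -> int:
        return len(self.stage_depths)

    @property
    def total_blocks(self) -> int:
        return int(sum(self.stage_depths))


@dataclass(frozen=True)
class BlockAddress:
    """Stage-local and flattened (global) index of one transformer block."""

    stage_index: int
    block_index_in_stage: int
    global_index: int

    @staticmethod
    def from_global(spec: BackboneSpec, global_index: int) -> "BlockAddress":
        g = global_index
        for s, d in enumerate(spec.stage_depths):
            if g < d:
                return BlockAddress(s, g, global_index)
            g -= d
        raise ValueError(f"global block index {global_index} out of range")


@dataclass
class CaptureSpec:
    """Which arrays to record during a forward pass."""

    attention_at: tuple[int, ...] = ()  # global block indices
    norm_tokens_at: tuple[int, ...] = ()  # global block indices, norm2 preferred
    final_norm: bool = False
    target_activation: bool = False  # final-norm tokens as a C x H x W activation
    want_gradients: bool = True


@dataclass
class WindowedAttentionCapture:
    probs: np.ndarray  # (num_windows, heads, N, N)
    grad: np.ndarray | None
    window_size: int
    shift_size: int
    grid: tuple[int, int]
    address: BlockAddress


@dataclass
class TokenCapture:
    tokens: np.ndarray  # (N_tokens, C)
    grad: np.ndarray | None
    grid: tuple[int, int]
    address: BlockAddress | None
    source: str  # "norm2", "norm1" or "final_norm"


@dataclass
class ActivationCapture:
    activation: np.ndarray  # (C, H, W)
    grad: np.ndarray | None
    grid: tuple[int, int]


@dataclass
class CaptureBundle:
    logits: np.ndarray
    target_class: int
    attention: dict[int, WindowedAttentionCapture] = field(default_factory=dict)
    tokens: dict[int, TokenCapture] = field(default_factory=dict)
    final_norm: TokenCapture | None = None
    activation: ActivationCapture | None = None


def _trunc_normal(rng: np.random.Generator, shape, std=0.02):
    vals = rng.normal(0.0, std, size=shape)
    return np.clip(vals, -2 * std, 2 * std)


def _attention_mask(H: int, W: int, w: int, s: int) -> np.ndarray | None:
    """Swin-style mask blocking attention across the cyclic-shift seam.

    Returns (num_windows, N, N) additive mask (0 or -1e4), or None if s == 0.
    """
    if s == 0:
        return None
    img_mask = np.zeros((H, W))
    cnt = 0
    for hs in (slice(0, -w), slice(-w, -s), slice(-s, None)):
        for ws in (slice(0, -w), slice(-w, -s), slice(-s, None)):
            img_mask[hs, ws] = cnt
            cnt += 1
    rolled = np.roll(img_mask, (-s, -s), axis=(0, 1))
    wins = (
        rolled.reshape(H // w, w, W // w, w)
        .transpose(0, 2, 1, 3)
        .reshape(-1, w * w)
    )
    diff = wins[:, :, None] - wins[:, None, :]
    return np.where(diff == 0, 0.0, -1e4)


class ClassifierModel:
    """Windowed-attention backbone + MLP head, parameters as autodiff tensors."""

    def __init__(self, spec: BackboneSpec, n_classes: int = 6, seed: int = 0):
        self.spec = spec
        self.n_classes = n_classes
        self.seed = seed
        self.params: dict[str, Tensor] = {}
        self._masks: dict[int, np.ndarray | None] = {}
        self._init_params(np.random.default_rng(seed))

    # ------------------------------------------------------------------ init
    def _add(self, name: str, arr: np.ndarray) -> None:
        self.params[name] = Tensor(arr, requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        sp = self.spec
        ps, in_ch = sp.patch_size, 3
        self._add("patch_embed.weight", _trunc_normal(rng, (in_ch * ps * ps, sp.embed_dims[0])))
        self._add("patch_embed.bias", np.zeros(sp.embed_dims[0]))
        self._add("patch_embed.norm.gamma", np.ones(sp.embed_dims[0]))
        self._add("patch_embed.norm.beta", np.zeros(sp.embed_dims[0]))
        w = sp.window_size
        N = w * w
        for s, depth in enumerate(sp.stage_depths):
            C = sp.embed_dims[s]
            heads = sp.num_heads[s]
            hidden = int(C * sp.mlp_ratio)
            for b in range(depth):
                pre = f"stage{s}.block{b}"
                for nm in ("norm1", "norm2"):
                    self._add(f"{pre}.{nm}.gamma", np.ones(C))
                    self._add(f"{pre}.{nm}.beta", np.zeros(C))
                for nm in ("q", "k", "v", "proj"):
                    self._add(f"{pre}.attn.{nm}.weight", _trunc_normal(rng, (C, C)))
                    self._add(f"{pre}.attn.{nm}.bias", np.zeros(C))
                self._add(f"{pre}.attn.rel_bias", np.zeros((heads, N, N)))
                self._add(f"{pre}.mlp.fc1.weight", _trunc_normal(rng, (C, hidden)))
                self._add(f"{pre}.mlp.fc1.bias", np.zeros(hidden))
                self._add(f"{pre}.mlp.fc2.weight", _trunc_normal(rng, (hidden, C)))
                self._add(f"{pre}.mlp.fc2.bias", np.zeros(C))
            if s < sp.n_stages - 1:
                C_next = sp.embed_dims[s + 1]
                self._add(f"merge{s}.norm.gamma", np.ones(4 * C))
                self._add(f"merge{s}.norm.beta", np.zeros(4 * C))
                self._add(f"merge{s}.reduction.weight", _trunc_normal(rng, (4 * C, C_next)))
                self._add(f"merge{s}.reduction.bias", np.zeros(C_next))
        C_last = sp.embed_dims[-1]
        self._add("final_norm.gamma", np.ones(C_last))
        self._add("final_norm.beta", np.zeros(C_last))
        # head: Linear(C_last, hidden) -> ReLU -> Dropout -> Linear(hidden, K)
        self._add("head.fc1.weight", _trunc_normal(rng, (C_last, sp.head_hidden)))
        self._add("head.fc1.bias", np.zeros(sp.head_hidden))
        self._add("head.fc2.weight", _trunc_normal(rng, (sp.head_hidden, self.n_classes)))
        self._add("head.fc2.bias", np.zeros(self.n_classes))

    # -------------------------------------------------------------- policies
    def head_param_names(self) -> list[str]:
        return [n for n in self.params if n.startswith("head.")]

    def backbone_param_names(self) -> list[str]:
        return [n for n in self.params if not n.startswith("head.")]

    def trainable_names(self, freeze_backbone: bool, unfreeze_last_n_blocks: int) -> set[str]:
        """Head always trains; under a frozen backbone the deepest
        `unfreeze_last_n_blocks` blocks (capped at the total) and the final
        normalisation layer stay trainable."""
        names = set(self.head_param_names())
        if not freeze_backbone:
            return set(self.params)
        n = min(unfreeze_last_n_blocks, self.spec.total_blocks)
        unfrozen = set(range(self.spec.total_blocks - n, self.spec.total_blocks))
        for g in unfrozen:
            addr = BlockAddress.from_global(self.spec, g)
            prefix = f"stage{addr.stage_index}.block{addr.block_index_in_stage}."
            names.update(p for p in self.params if p.startswith(prefix))
        names.update(p for p in self.params if p.startswith("final_norm."))
        return names

    def shift_size(self, block_in_stage: int) -> int:
        return 0 if block_in_stage % 2 == 0 else self.spec.window_size // 2

    # -------------------------------------------------------------- forward
    def _mask_for(self, grid_side: int, shift: int) -> np.ndarray | None:
        key = (grid_side, shift)
        if key not in self._masks:
            self._masks[key] = _attention_mask(
                grid_side, grid_side, self.spec.window_size, shift
            )
        return self._masks[key]

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        capture: CaptureSpec | None = None,
        perturb: dict | None = None,
    ) -> tuple[Tensor, dict]:
        """Run the network on a (B, 3, S, S) batch.

        Returns the logits tensor and a dict of captured interior tensors
        (still attached to the graph, so a later backward pass fills their
        gradients).  `perturb` maps capture keys — ("attn", g), ("norm1", g),
        ("norm2", g) or ("final_norm", None) — to additive arrays injected at
        that point, enabling finite-difference checks of interior gradients.
        """

        def _inject(t: Tensor, key) -> Tensor:
            if perturb and key in perturb:
                return t + Tensor(np.asarray(perturb[key], dtype=np.float64).reshape(t.shape))
            return t
        sp = self.spec
        P = self.params
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        B = x.shape[0]
        S, ps = sp.input_side, sp.patch_size
        Hp = S // ps
        caches: dict = {}

        t = Tensor(x)
        # patch embedding: (B,3,S,S) -> (B,Hp,Wp, 3*ps*ps) -> linear
        t = (
            t.reshape(B, 3, Hp, ps, Hp, ps)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(B, Hp, Hp, 3 * ps * ps)
        )
        t = t @ P["patch_embed.weight"] + P["patch_embed.bias"]
        t = t.layer_norm(P["patch_embed.norm.gamma"], P["patch_embed.norm.beta"])

        w = sp.window_size
        N = w * w
        g = 0  # global block index
        for s, depth in enumerate(sp.stage_depths):
            C = sp.embed_dims[s]
            heads = sp.num_heads[s]
            hd = C // heads
            side = sp.grid_side(s)
            nW = (side // w) ** 2
            for b in range(depth):
                pre = f"stage{s}.block{b}"
                shift = self.shift_size(b)
                shortcut = t
                h = _inject(t.layer_norm(P[f"{pre}.norm1.gamma"], P[f"{pre}.norm1.beta"]),
                            ("norm1", g))
                if capture and g in capture.norm_tokens_at:
                    caches[("norm1", g)] = (h, (side, side))
                if shift:
                    h = h.roll((-shift, -shift), axis=(1, 2))
                h = (
                    h.reshape(B, side // w, w, side // w, w, C)
                    .transpose(0, 1, 3, 2, 4, 5)
                    .reshape(B * nW, N, C)
                )
                q = (h @ P[f"{pre}.attn.q.weight"] + P[f"{pre}.attn.q.bias"])
                k = (h @ P[f"{pre}.attn.k.weight"] + P[f"{pre}.attn.k.bias"])
                v = (h @ P[f"{pre}.attn.v.weight"] + P[f"{pre}.attn.v.bias"])
                q = q.reshape(B * nW, N, heads, hd).transpose(0, 2, 1, 3)
                k = k.reshape(B * nW, N, heads, hd).transpose(0, 2, 1, 3)
                v = v.reshape(B * nW, N, heads, hd).transpose(0, 2, 1, 3)
                attn = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
                attn = attn + P[f"{pre}.attn.rel_bias"]
                mask = self._mask_for(side, shift)
                if mask is not None:
                    attn = attn.reshape(B, nW, heads, N, N) + Tensor(mask[:, None, :, :])
                    attn = attn.reshape(B * nW, heads, N, N)
                probs = _inject(attn.softmax(axis=-1), ("attn", g))  # the attn-drop input
                if capture and g in capture.attention_at:
                    caches[("attn", g)] = (probs, w, shift, (side, side), nW, heads)
                out = probs @ v  # (B*nW, heads, N, hd)
                out = out.transpose(0, 2, 1, 3).reshape(B * nW, N, C)
                out = out @ P[f"{pre}.attn.proj.weight"] + P[f"{pre}.attn.proj.bias"]
                out = (
                    out.reshape(B, side // w, side // w, w, w, C)
                    .transpose(0, 1, 3, 2, 4, 5)
                    .reshape(B, side, side, C)
                )
                if shift:
                    out = out.roll((shift, shift), axis=(1, 2))
                t = shortcut + out
                h2 = _inject(t.layer_norm(P[f"{pre}.norm2.gamma"], P[f"{pre}.norm2.beta"]),
                             ("norm2", g))
                if capture and g in capture.norm_tokens_at:
                    caches[("norm2", g)] = (h2, (side, side))
                m = (h2 @ P[f"{pre}.mlp.fc1.weight"] + P[f"{pre}.mlp.fc1.bias"]).gelu()
                m = m @ P[f"{pre}.mlp.fc2.weight"] + P[f"{pre}.mlp.fc2.bias"]
                t = t + m
                g += 1
            if s < sp.n_stages - 1:
                # 2x2 patch merging: (B,H,W,C) -> (B,H/2,W/2,4C) -> linear
                t = (
                    t.reshape(B, side // 2, 2, side // 2, 2, C)
                    .transpose(0, 1, 3, 2, 4, 5)
                    .reshape(B, side // 2, side // 2, 4 * C)
                )
                t = t.layer_norm(P[f"merge{s}.norm.gamma"], P[f"merge{s}.norm.beta"])
                t = t @ P[f"merge{s}.reduction.weight"] + P[f"merge{s}.reduction.bias"]

        side_last = sp.grid_side(sp.n_stages - 1)
        t = _inject(t.layer_norm(P["final_norm.gamma"], P["final_norm.beta"]),
                    ("final_norm", None))
        if capture and (capture.final_norm or capture.target_activation):
            caches[("final_norm", None)] = (t, (side_last, side_last))
        pooled = t.reshape(B, side_last * side_last, sp.embed_dims[-1]).mean(axis=1)
        h1 = (pooled @ P["head.fc1.weight"] + P["head.fc1.bias"]).relu()
        if training and self.spec.head_dropout > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            keep = 1.0 - self.spec.head_dropout
            drop = (rng.random(h1.shape) < keep).astype(np.float64) / keep
            h1 = h1 * Tensor(drop)
        logits = h1 @ P["head.fc2.weight"] + P["head.fc2.bias"]
        return logits, caches

    # ------------------------------------------------------------- inference
    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(x)
        return logits.data

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.predict_logits(x)
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_logits(x).argmax(axis=-1)

    # ---------------------------------------------------------- persistence
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float64)


def build_model(spec: BackboneSpec, n_classes: int = 6, seed: int = 0) -> ClassifierModel:
    """Construct the classifier; head (and backbone) init is seed-deterministic."""
    return ClassifierModel(spec, n_classes=n_classes, seed=seed)


def save_checkpoint(model: ClassifierModel, path) -> None:
    """Single-file parameter map (.npz) with a JSON architecture sidecar."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    np.savez(path, **model.state_dict())
    meta = {"spec": asdict(model.spec), "n_classes": model.n_classes, "seed": model.seed}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path) -> ClassifierModel:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec_kw = dict(meta["spec"])
    for key in ("stage_depths", "embed_dims", "num_heads"):
        spec_kw[key] = tuple(spec_kw[key])
    model = ClassifierModel(BackboneSpec(**spec_kw), meta["n_classes"], meta["seed"])
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model


def forward_with_capture(
    model: ClassifierModel,
    x: np.ndarray,
    spec: CaptureSpec,
    target_class: int | str = "predicted",
) -> CaptureBundle:
    """One forward pass recording the requested arrays, plus one backward pass
    of the target-class pre-softmax logit populating their gradients.

    `target_class="predicted"` resolves to the argmax of the logits, so the
    explanation refers to the decision the model actually made.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    if x.shape[0] != 1:
        raise ValueError("capture operates on a single image")
    total = model.spec.total_blocks
    for g in tuple(spec.attention_at) + tuple(spec.norm_tokens_at):
        if not 0 <= g < total:
            raise ValueError(f"no capture point at block address {g} (model has {total} blocks)")

    logits_t, caches = model.forward(x, capture=spec)
    logits = logits_t.data[0]
    tgt = int(np.argmax(logits)) if target_class == "predicted" else int(target_class)
    if not 0 <= tgt < model.n_classes:
        raise ValueError(f"target class {tgt} out of range")

    if spec.want_gradients:
        seed = np.zeros_like(logits_t.data)
        seed[0, tgt] = 1.0
        logits_t.backward(seed)

    bundle = CaptureBundle(logits=logits, target_class=tgt)
    for (kind, g), payload in caches.items():
        if kind == "attn":
            probs, w, shift, grid, nW, heads = payload
            N = w * w
            arr = probs.data.reshape(nW, heads, N, N)
            grad = probs.grad.reshape(nW, heads, N, N) if probs.grad is not None else None
            bundle.attention[g] = WindowedAttentionCapture(
                probs=arr,
                grad=grad,
                window_size=w,
                shift_size=shift,
                grid=grid,
                address=BlockAddress.from_global(model.spec, g),
            )
        elif kind in ("norm1", "norm2"):
            tokens, grid = payload
            # norm2 preferred: do not overwrite an existing norm2 capture
            if g in bundle.tokens and bundle.tokens[g].source == "norm2":
                continue
            C = tokens.data.shape[-1]
            bundle.tokens[g] = TokenCapture(
                tokens=tokens.data.reshape(-1, C),
                grad=tokens.grad.reshape(-1, C) if tokens.grad is not None else None,
                grid=grid,
                address=BlockAddress.from_global(model.spec, g),
                source=kind,
            )
        elif kind == "final_norm":
            tokens, grid = payload
            C = tokens.data.shape[-1]
            cap = TokenCapture(
                tokens=tokens.data.reshape(-1, C),
                grad=tokens.grad.reshape(-1, C) if tokens.grad is not None else None,
                grid=grid,
                address=None,
                source="final_norm",
            )
            bundle.final_norm = cap
            if spec.target_activation:
                H, W = grid
                act = cap.tokens.reshape(H, W, C).transpose(2, 0, 1)
                gr = (
                    cap.grad.reshape(H, W, C).transpose(2, 0, 1)
                    if cap.grad is not None
                    else None
                )
                bundle.activation = ActivationCapture(activation=act, grad=gr, grid=grid)
    return bundle
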