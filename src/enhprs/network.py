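"""Hybrid convolutional / bidirectional-GRU enhancer classifier.

Architecture (in forward order):

    one-hot input (L x 4)
      -> 1-D convolution, valid, stride 1 (filter bank M, F filters of
         length m over 4 channels) -> ReLU
      -> non-overlapping max pooling of width p (remainder truncated)
      -> dropout (training only)
      -> bidirectional GRU over the pooled position axis; the final hidden
         states of both directions are concatenated
      -> dense layer of 32 units (weight matrix WM) with ReLU
      -> scalar projection -> sigmoid score in (0, 1)

The convolution filters act as position-weight-matrix-like motif
detectors; the bidirectional recurrence models how detected motifs combine
along either strand orientation.  The pooled length is
floor((L - m + 1) / p) and the GRU runs over exactly that many steps.

Everything here is plain numpy, including the backward pass
(:func:`backward`), which returns gradients for every parameter and is
verified against finite differences in the test suite.

Parameter groups for the L1 penalties:

* ``M``  — the convolution filter bank;
* ``WU`` — the GRU gate weight matrices.  Each direction has an input
  projection and a recurrent projection for its three gates (update,
  reset, candidate memory); they are stored as two stacked matrices per
  direction (gate order: update, reset, candidate);
* ``WM`` — the dense-layer weight matrix.

Biases and the final scalar projection are excluded from all three groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .encoding import EncodedBatch

__all__ = [
    "NetworkConfig",
    "NetworkParameters",
    "build_network",
    "forward",
    "backward",
    "l1_norms",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_FORMAT_VERSION",
]

CHECKPOINT_FORMAT_VERSION = 1

GRID_FILTER_NUMBERS = (32, 64, 128, 256)
GRID_FILTER_LENGTHS = tuple(range(5, 26, 2))
GRID_POOL_SIZES = (3, 5, 8, 11, 14, 17)

#: parameter-group membership for the three L1 penalties
GROUP_M = ("conv_W",)
GROUP_WU = ("gru_fw_W", "gru_fw_U", "gru_bw_W", "gru_bw_U")
GROUP_WM = ("dense_W",)


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the network.

    Defaults follow the grid-search optimum for 1 kb enhancer windows:
    64 filters of length 23 with pooling width 8, a 32-unit dense layer,
    and dropout 0.2 after pooling.
    """

    filter_number: int = 64
    filter_length: int = 23
    pool_size: int = 8
    gru_units_per_direction: int = 32
    dense_units: int = 32
    dropout_rate: float = 0.2
    input_length: int = 1000

    def __post_init__(self) -> None:
        for name in ("filter_number", "filter_length", "pool_size",
                     "gru_units_per_direction", "dense_units", "input_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.filter_length > self.input_length:
            raise ValueError(
                f"filter_length {self.filter_length} exceeds input_length {self.input_length}"
            )
        if self.pooled_length < 1:
            raise ValueError(
                f"pool_size {self.pool_size} larger than convolution output "
                f"({self.conv_length} positions)"
            )

    @property
    def conv_length(self) -> int:
        return self.input_length - self.filter_length + 1

    @property
    def pooled_length(self) -> int:
        return self.conv_length // self.pool_size

    def validate_for_grid(self) -> None:
        """Enforce the grid-search domain for filter length and pool size."""
        if self.filter_length % 2 == 0 or not (5 <= self.filter_length <= 25):
            raise ValueError("grid-search filter_length must be odd and in [5, 25]")
        if self.pool_size not in GRID_POOL_SIZES:
            raise ValueError(f"grid-search pool_size must be one of {GRID_POOL_SIZES}")

    def to_dict(self) -> dict:
        return {
            "filter_number": self.filter_number,
            "filter_length": self.filter_length,
            "pool_size": self.pool_size,
            "gru_units_per_direction": self.gru_units_per_direction,
            "dense_units": self.dense_units,
            "dropout_rate": self.dropout_rate,
            "input_length": self.input_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass
class NetworkParameters:
    """All learnable weights; shapes are fully determined by a config.

    Keys (F filters, length m, H GRU units per direction, D dense units):

    ==============  ==================  =========================
    key             shape               L1 group
    ==============  ==================  =========================
    conv_W          (F, m, 4)           M
    conv_b          (F,)                —
    gru_{fw,bw}_W   (F, 3H)             WU (input projections)
    gru_{fw,bw}_U   (H, 3H)             WU (recurrent projections)
    gru_{fw,bw}_b   (3H,)               —
    dense_W         (2H, D)             WM
    dense_b         (D,)                —
    out_w           (D,)                — (final projection)
    out_b           ()                  —
    ==============  ==================  =========================
    """

    arrays: dict[str, np.ndarray]

    def copy(self) -> "NetworkParameters":
        return NetworkParameters({k: v.copy() for k, v in self.arrays.items()})

    def __getitem__(self, key: str) -> np.ndarray:
        return self.arrays[key]

    def __setitem__(self, key: str, value: np.ndarray) -> None:
        self.arrays[key] = value

    def keys(self):
        return self.arrays.keys()

    def allclose(self, other: "NetworkParameters", **kw) -> bool:
        return set(self.arrays) == set(other.arrays) and all(
            np.allclose(self.arrays[k], other.arrays[k], **kw) for k in self.arrays
        )

    def check_finite(self) -> None:
        for k, v in self.arrays.items():
            if not np.all(np.isfinite(v)):
                raise FloatingPointError(f"non-finite values in parameter {k}")


def expected_shapes(cfg: NetworkConfig) -> dict[str, tuple[int, ...]]:
    F, m = cfg.filter_number, cfg.filter_length
    H, D = cfg.gru_units_per_direction, cfg.dense_units
    shapes: dict[str, tuple[int, ...]] = {
        "conv_W": (F, m, 4),
        "conv_b": (F,),
        "dense_W": (2 * H, D),
        "dense_b": (D,),
        "out_w": (D,),
        "out_b": (),
    }
    for d in ("fw", "bw"):
        shapes[f"gru_{d}_W"] = (F, 3 * H)
        shapes[f"gru_{d}_U"] = (H, 3 * H)
        shapes[f"gru_{d}_b"] = (3 * H,)
    return shapes


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def build_network(cfg: NetworkConfig, seed: int) -> NetworkParameters:
    """Initialize parameters (Glorot-uniform weights, zero biases).

    Deterministic for a fixed seed: the same seed yields bitwise-identical
    parameters.
    """
    rng = np.random.default_rng(seed)
    F, m = cfg.filter_number, cfg.filter_length
    H, D = cfg.gru_units_per_direction, cfg.dense_units
    arrays: dict[str, np.ndarray] = {}
    arrays["conv_W"] = _glorot(rng, (F, m, 4), fan_in=m * 4, fan_out=F)
    arrays["conv_b"] = np.zeros(F)
    for d in ("fw", "bw"):
        arrays[f"gru_{d}_W"] = _glorot(rng, (F, 3 * H), fan_in=F, fan_out=H)
        arrays[f"gru_{d}_U"] = _glorot(rng, (H, 3 * H), fan_in=H, fan_out=H)
        arrays[f"gru_{d}_b"] = np.zeros(3 * H)
    arrays["dense_W"] = _glorot(rng, (2 * H, D), fan_in=2 * H, fan_out=D)
    arrays["dense_b"] = np.zeros(D)
    arrays["out_w"] = _glorot(rng, (D,), fan_in=D, fan_out=1)
    arrays["out_b"] = np.zeros(())
    return NetworkParameters(arrays)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _gru_direction(
    h_in: np.ndarray, W: np.ndarray, U: np.ndarray, b: np.ndarray, want_cache: bool
):
    """Run one GRU direction over (N, T, F) inputs; returns final state.

    Gate order in the stacked matrices is (update z, reset r, candidate).
    State update: h_t = (1 - z_t) * h_{t-1} + z_t * hcand_t.
    """
    N, T, F = h_in.shape
    H = U.shape[0]
    A = h_in.reshape(N * T, F) @ W + b  # input projections, all steps at once
    A = A.reshape(N, T, 3 * H)
    h = np.zeros((N, H))
    cache = [] if want_cache else None
    Uz, Ur, Uh = U[:, :H], U[:, H:2 * H], U[:, 2 * H:]
    for t in range(T):
        At = A[:, t]
        z = _sigmoid(At[:, :H] + h @ Uz)
        r = _sigmoid(At[:, H:2 * H] + h @ Ur)
        rh = r * h
        hcand = np.tanh(At[:, 2 * H:] + rh @ Uh)
        h_new = (1.0 - z) * h + z * hcand
        if want_cache:
            cache.append((h, z, r, rh, hcand))
        h = h_new
    return h, A, cache


def forward(
    params: NetworkParameters,
    cfg: NetworkConfig,
    batch: EncodedBatch,
    train_mode: bool = False,
    dropout_rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Compute sigmoid scores for a batch; optionally keep a backward cache.

    With ``train_mode`` off the output is a pure deterministic function of
    (params, batch).  With it on, inverted dropout is applied after pooling
    using ``dropout_rng``.  Raises ``FloatingPointError`` on non-finite
    activations (divergence).
    """
    X = batch.sequences
    if X.ndim != 3 or X.shape[1] != cfg.input_length or X.shape[2] != 4:
        raise ValueError(
            f"batch shape {X.shape} incompatible with input_length {cfg.input_length}"
        )
    N = X.shape[0]
    F, m, p = cfg.filter_number, cfg.filter_length, cfg.pool_size
    Lc, T = cfg.conv_length, cfg.pooled_length

    # convolution via im2col, one large GEMM
    windows = np.lib.stride_tricks.sliding_window_view(X, (m, 4), axis=(1, 2))
    windows = np.ascontiguousarray(windows.reshape(N * Lc, m * 4))
    Wf = params["conv_W"].reshape(F, m * 4).T
    conv = (windows @ Wf).reshape(N, Lc, F) + params["conv_b"]
    relu = np.maximum(conv, 0.0)

    # non-overlapping max pooling, remainder truncated; argmax over a
    # contiguous last axis (the (N, T, F, p) layout) is much faster
    blocks = np.ascontiguousarray(
        relu[:, :T * p].reshape(N, T, p, F).transpose(0, 1, 3, 2)
    )
    pool_arg = blocks.argmax(axis=3)             # (N, T, F)
    pooled = np.take_along_axis(blocks, pool_arg[:, :, :, None], axis=3)[:, :, :, 0]

    if train_mode and cfg.dropout_rate > 0:
        if dropout_rng is None:
            raise ValueError("train_mode with dropout requires dropout_rng")
        keep = 1.0 - cfg.dropout_rate
        drop_mask = (dropout_rng.random(pooled.shape) < keep) / keep
    else:
        drop_mask = None
    h_gru_in = pooled if drop_mask is None else pooled * drop_mask

    h_fw, A_fw, cache_fw = _gru_direction(
        h_gru_in, params["gru_fw_W"], params["gru_fw_U"], params["gru_fw_b"], return_cache
    )
    h_bw, A_bw, cache_bw = _gru_direction(
        h_gru_in[:, ::-1], params["gru_bw_W"], params["gru_bw_U"], params["gru_bw_b"],
        return_cache,
    )
    hcat = np.concatenate([h_fw, h_bw], axis=1)  # (N, 2H)

    dense_pre = hcat @ params["dense_W"] + params["dense_b"]
    dense = np.maximum(dense_pre, 0.0)
    logit = dense @ params["out_w"] + params["out_b"]
    if not np.all(np.isfinite(logit)):
        raise FloatingPointError("non-finite activation in forward pass (divergence)")
    eps = 1e-12
    scores = np.clip(_sigmoid(logit), eps, 1.0 - eps)

    if not return_cache:
        return scores
    cache = {
        "windows": windows, "conv": conv, "relu": relu, "pool_arg": pool_arg,
        "drop_mask": drop_mask, "h_gru_in": h_gru_in,
        "A_fw": A_fw, "cache_fw": cache_fw, "h_fw": h_fw,
        "A_bw": A_bw, "cache_bw": cache_bw, "h_bw": h_bw,
        "hcat": hcat, "dense_pre": dense_pre, "dense": dense, "logit": logit,
    }
    return scores, cache


def _gru_backward(
    dh_last: np.ndarray,
    h_in: np.ndarray,
    U: np.ndarray,
    cache: list,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backprop through one GRU direction given gradient on the final state.

    Returns (dA, dU, dx) where dA is the gradient on the stacked input
    projections (N, T, 3H) and dx the gradient on the direction's inputs.
    """
    N, T, F = h_in.shape
    H = U.shape[0]
    Uz, Ur, Uh = U[:, :H], U[:, H:2 * H], U[:, 2 * H:]
    dA = np.zeros((N, T, 3 * H))
    dU = np.zeros_like(U)
    dh = dh_last
    for t in range(T - 1, -1, -1):
        h_prev, z, r, rh, hcand = cache[t]
        dz = dh * (hcand - h_prev)
        dhcand = dh * z
        dh_prev = dh * (1.0 - z)

        dact_h = dhcand * (1.0 - hcand * hcand)
        dA[:, t, 2 * H:] = dact_h
        dU[:, 2 * H:] += rh.T @ dact_h
        drh = dact_h @ Uh.T
        dr = drh * h_prev
        dh_prev = dh_prev + drh * r

        dact_z = dz * z * (1.0 - z)
        dact_r = dr * r * (1.0 - r)
        dA[:, t, :H] = dact_z
        dA[:, t, H:2 * H] = dact_r
        dU[:, :H] += h_prev.T @ dact_z
        dU[:, H:2 * H] += h_prev.T @ dact_r
        dh_prev = dh_prev + dact_z @ Uz.T + dact_r @ Ur.T
        dh = dh_prev
    return dA, dU, None


def backward(
    params: NetworkParameters,
    cfg: NetworkConfig,
    batch: EncodedBatch,
    scores: np.ndarray,
    cache: dict,
    dlogit: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss with respect to every parameter.

    ``dlogit`` is dLoss/dlogit per record (for mean binary cross-entropy on
    sigmoid outputs this is (scores - labels) / N).
    """
    N = len(batch)
    F, m, p = cfg.filter_number, cfg.filter_length, cfg.pool_size
    Lc, T = cfg.conv_length, cfg.pooled_length
    H = cfg.gru_units_per_direction
    grads: dict[str, np.ndarray] = {}

    dense, dense_pre, hcat = cache["dense"], cache["dense_pre"], cache["hcat"]
    grads["out_w"] = dense.T @ dlogit
    grads["out_b"] = np.sum(dlogit)
    ddense = np.outer(dlogit, params["out_w"]) * (dense_pre > 0)
    grads["dense_W"] = hcat.T @ ddense
    grads["dense_b"] = ddense.sum(axis=0)
    dhcat = ddense @ params["dense_W"].T

    h_gru_in = cache["h_gru_in"]
    dA_fw, dU_fw, _ = _gru_backward(
        dhcat[:, :H], h_gru_in, params["gru_fw_U"], cache["cache_fw"]
    )
    rev_in = h_gru_in[:, ::-1]
    dA_bw, dU_bw, _ = _gru_backward(
        dhcat[:, H:], rev_in, params["gru_bw_U"], cache["cache_bw"]
    )
    for d, dA, dU, x_in in (("fw", dA_fw, dU_fw, h_gru_in), ("bw", dA_bw, dU_bw, rev_in)):
        flat = dA.reshape(N * T, 3 * H)
        grads[f"gru_{d}_W"] = x_in.reshape(N * T, F).T @ flat
        grads[f"gru_{d}_U"] = dU
        grads[f"gru_{d}_b"] = flat.sum(axis=0)
    dx = dA_fw.reshape(N * T, 3 * H) @ params["gru_fw_W"].T
    dx = dx.reshape(N, T, F)
    dx_bw = dA_bw.reshape(N * T, 3 * H) @ params["gru_bw_W"].T
    dx = dx + dx_bw.reshape(N, T, F)[:, ::-1]

    if cache["drop_mask"] is not None:
        dx = dx * cache["drop_mask"]

    # unpool: scatter gradients to the argmax positions ((N, T, F, p) layout)
    drelu_blocks = np.zeros((N, T, F, p))
    np.put_along_axis(drelu_blocks, cache["pool_arg"][:, :, :, None], dx[:, :, :, None], axis=3)
    drelu = np.zeros((N, Lc, F))
    drelu[:, :T * p] = drelu_blocks.transpose(0, 1, 3, 2).reshape(N, T * p, F)
    dconv = drelu * (cache["conv"] > 0)

    flat = dconv.reshape(N * Lc, F)
    grads["conv_W"] = (cache["windows"].T @ flat).T.reshape(F, m, 4)
    grads["conv_b"] = flat.sum(axis=0)
    return grads


def l1_norms(params: NetworkParameters) -> tuple[float, float, float]:
    """(‖M‖₁, ‖WU‖₁, ‖WM‖₁): element-wise absolute sums of the convolution
    filters, the GRU gate matrices, and the dense weights.  Biases and the
    final projection are excluded from every group."""
    norm = lambda keys: float(sum(np.abs(params[k]).sum() for k in keys))
    return norm(GROUP_M), norm(GROUP_WU), norm(GROUP_WM)


# ---------------------------------------------------------------------------
# Checkpoint I/O
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: NetworkParameters, cfg: NetworkConfig,
                    meta: dict | None = None) -> None:
    """Serialize config + parameters (npz container with a version field)."""
    header = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": cfg.to_dict(),
        "meta": meta or {},
    }
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **params.arrays)


def load_checkpoint(path) -> tuple[NetworkParameters, NetworkConfig, dict]:
    """Load a checkpoint; fails loudly on version or shape mismatch."""
    with np.load(path) as npz:
        if "__header__" not in npz:
            raise ValueError(f"{path}: not a checkpoint (missing header)")
        header = json.loads(bytes(npz["__header__"].tobytes()).decode())
        if header.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"{path}: unsupported checkpoint format version "
                f"{header.get('format_version')}"
            )
        cfg = NetworkConfig.from_dict(header["config"])
        arrays = {k: npz[k] for k in npz.files if k != "__header__"}
    shapes = expected_shapes(cfg)
    if set(arrays) != set(shapes):
        raise ValueError(
            f"{path}: parameter keys {sorted(arrays)} do not match config "
            f"expectation {sorted(shapes)}"
        )
    for k, shp in shapes.items():
        if arrays[k].shape != shp:
            raise ValueError(f"{path}: {k} has shape {arrays[k].shape}, expected {shp}")
    return NetworkParameters(arrays), cfg, header.get("meta", {})
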