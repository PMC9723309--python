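"""Minimal 3D convolutional classifier for spectral topographic volumes.

The architecture is deliberately tiny (about a thousand trainable weights):

    Input (20, 20, 50, 1)
    -> Conv3D(2, 3x3x3, same, sigmoid) -> AvgPool(2, ceil)
    -> Conv3D(3, 3x3x3, same, sigmoid) -> AvgPool(2, ceil)
    -> Conv3D(3, 3x3x3, same, sigmoid) -> AvgPool(2, ceil)
    -> BatchNorm -> Flatten(189) -> Dropout(0.5) -> ReLU
    -> Dense(3) -> softmax

Average pooling halves each spatial/frequency extent with ceiling rounding
(20 -> 10 -> 5 -> 3 and 50 -> 25 -> 13 -> 7), so the flattened feature
vector has 3 x 3 x 7 x 3 = 189 entries. There is intentionally no hidden
layer in the classifier head: the last convolutional feature maps connect
(after normalization, dropout and a ReLU) directly to the softmax, which is
what makes the Grad-CAM readout of that layer directly interpretable.

Everything — forward pass, backprop, L1/L2 penalties — is implemented
explicitly on numpy arrays, which keeps the full computation graph
accessible for the gradient-based saliency analysis and for finite-
difference verification.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

INPUT_SHAPE = (20, 20, 50)


@dataclass(frozen=True)
class ModelSpec:
    conv_filters: tuple = (2, 3, 3)
    kernel: int = 3
    stride: int = 1
    conv_activation: str = "sigmoid"
    pool: int = 2                  # average pooling window/stride, ceil rounding
    use_relu_head: bool = True
    dropout_rate: float = 0.5
    n_classes: int = 3
    l1: float = 1e-4
    l2: float = 1e-2
    input_shape: tuple = INPUT_SHAPE
    bn_momentum: float = 0.99
    bn_eps: float = 1e-3
    dtype: str = "float64"

    def __post_init__(self):
        if any(f < 1 for f in self.conv_filters):
            raise ValueError("filter counts must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("regularizers must be >= 0")
        if self.stride != 1 or self.kernel != 3:
            raise ValueError("only 3x3x3 kernels with stride 1 are supported")


def _ceil_half(n: int) -> int:
    return -(-n // 2)


def shape_chain(spec: ModelSpec) -> list:
    """Output shapes of the conv/pool chain, mirroring a layer summary."""
    x, y, f = spec.input_shape
    chain = [("Input", (x, y, f, 1))]
    c_in = 1
    for li, c_out in enumerate(spec.conv_filters, start=1):
        chain.append((f"Conv_{li}", (x, y, f, c_out)))
        x, y, f = _ceil_half(x), _ceil_half(y), _ceil_half(f)
        chain.append((f"AvgPool_{li}", (x, y, f, c_out)))
        c_in = c_out
    chain.append(("Batch_Norm", (x, y, f, c_in)))
    chain.append(("Flatten", (x * y * f * c_in,)))
    return chain


def flatten_length(spec: ModelSpec) -> int:
    return shape_chain(spec)[-1][1][0]


def count_parameters(spec: ModelSpec, include_batchnorm: bool = False) -> dict:
    """Per-layer and total trainable parameter counts from the spec shapes.

    The headline total excludes the batch-norm scale/offset pair per feature
    by default; both conventions are available via ``include_batchnorm``.
    """
    k3 = spec.kernel**3
    counts = {}
    c_in = 1
    for li, c_out in enumerate(spec.conv_filters, start=1):
        counts[f"Conv_{li}"] = c_out * (k3 * c_in + 1)
        c_in = c_out
    counts["Batch_Norm"] = 2 * c_in
    counts["Dense"] = flatten_length(spec) * spec.n_classes + spec.n_classes
    total_with_bn = sum(counts.values())
    total = total_with_bn if include_batchnorm else total_with_bn - counts["Batch_Norm"]
    counts["total"] = total
    counts["total_with_batchnorm"] = total_with_bn
    return counts


# ---------------------------------------------------------------------------
# primitive ops (forward + backward)
# ---------------------------------------------------------------------------

def _conv3d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3D correlation via the ndimage stencil kernel.

    x: (B, X, Y, F, Ci); W: (3,3,3,Ci,Co).
    """
    from scipy import ndimage

    Ci, Co = W.shape[3], W.shape[4]
    out = np.empty(x.shape[:4] + (Co,), dtype=x.dtype)
    for co in range(Co):
        acc = None
        for ci in range(Ci):
            r = ndimage.correlate(x[..., ci], W[None, :, :, :, ci, co],
                                  mode="constant", cval=0.0, output=x.dtype)
            acc = r if acc is None else acc + r
        acc += b[co]
        out[..., co] = acc
    return out


def _conv3d_backward(x: np.ndarray, W: np.ndarray, g: np.ndarray,
                     need_dx: bool = True):
    """Gradients of a same-padded conv. Returns (dW, db, dx or None)."""
    from scipy import ndimage

    B, X, Y, F, Ci = x.shape
    Co = W.shape[4]
    db = g.sum(axis=(0, 1, 2, 3))
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
    dW = np.empty_like(W)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                xs = xp[:, i : i + X, j : j + Y, k : k + F, :]
                dW[i, j, k] = np.tensordot(xs, g, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
    dx = None
    if need_dx:
        Wf = W[::-1, ::-1, ::-1]  # backward through a correlation is a convolution
        dx = np.zeros_like(x)
        for ci in range(Ci):
            acc = None
            for co in range(Co):
                r = ndimage.correlate(g[..., co], Wf[None, :, :, :, ci, co],
                                      mode="constant", cval=0.0, output=g.dtype)
                acc = r if acc is None else acc + r
            dx[..., ci] = acc
    return dW, db, dx


def _pool_axis_forward(x: np.ndarray, axis: int):
    n = x.shape[axis]
    pairs = n // 2
    main = np.moveaxis(x, axis, 0)[: 2 * pairs]
    main = 0.5 * (main[0::2] + main[1::2])
    if n % 2:
        last = np.moveaxis(x, axis, 0)[-1:]
        out = np.concatenate([main, last], axis=0)
    else:
        out = main
    return np.moveaxis(out, 0, axis)


def _pool_axis_backward(g: np.ndarray, axis: int, n_in: int):
    gm = np.moveaxis(g, axis, 0)
    pairs = n_in // 2
    parts = [np.repeat(0.5 * gm[:pairs], 2, axis=0)]
    if n_in % 2:
        parts.append(gm[-1:])
    out = np.concatenate(parts, axis=0)
    return np.moveaxis(out, 0, axis)


def avg_pool3d(x: np.ndarray) -> np.ndarray:
    """Window-2, stride-2 average pooling with ceiling rounding on the three
    leading feature axes (batch and channel axes untouched). Edge windows
    average only the elements actually present."""
    for ax in (1, 2, 3):
        x = _pool_axis_forward(x, ax)
    return x


def avg_pool3d_backward(g: np.ndarray, in_shape: tuple) -> np.ndarray:
    for ax in (3, 2, 1):
        g = _pool_axis_backward(g, ax, in_shape[ax])
    return g


def _sigmoid(z):
    from scipy.special import expit

    return expit(z)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class Model3DCNN:
    """The spectral-volume classifier with explicit forward/backward passes."""

    PENALIZED = ("W",)  # weight (not bias/batch-norm) arrays carry L1+L2

    def __init__(self, spec: ModelSpec, rng: np.random.Generator | None = None):
        self.spec = spec
        self.dtype = np.dtype(spec.dtype)
        if rng is None:
            rng = np.random.default_rng(0)
        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for li, c_out in enumerate(spec.conv_filters, start=1):
            fan_in = 27 * c_in
            fan_out = 27 * c_out
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            if spec.conv_activation == "sigmoid":
                # gain-4 Glorot: compensates sigmoid's 1/4 derivative so
                # activation variance survives a stack of sigmoid layers
                limit *= 4.0
            self.params[f"conv{li}_W"] = rng.uniform(
                -limit, limit, size=(3, 3, 3, c_in, c_out)
            ).astype(self.dtype)
            self.params[f"conv{li}_b"] = np.zeros(c_out, dtype=self.dtype)
            c_in = c_out
        n_flat = flatten_length(spec)
        limit = np.sqrt(6.0 / (n_flat + spec.n_classes))
        self.params["bn_gamma"] = np.ones(c_in, dtype=self.dtype)
        self.params["bn_beta"] = np.zeros(c_in, dtype=self.dtype)
        self.params["dense_W"] = rng.uniform(
            -limit, limit, size=(n_flat, spec.n_classes)
        ).astype(self.dtype)
        self.params["dense_b"] = np.zeros(spec.n_classes, dtype=self.dtype)
        self.bn_mean = np.zeros(c_in, dtype=self.dtype)
        self.bn_var = np.ones(c_in, dtype=self.dtype)

    # -- helpers ----------------------------------------------------------
    @property
    def n_conv(self) -> int:
        return len(self.spec.conv_filters)

    def _prepare(self, volumes: np.ndarray) -> np.ndarray:
        v = np.asarray(volumes, dtype=self.dtype)
        if v.ndim == 3:
            v = v[None]
        if v.shape[1:4] != tuple(self.spec.input_shape):
            raise ValueError(
                f"expected volumes shaped {self.spec.input_shape}, got {v.shape[1:4]}"
            )
        if v.ndim == 4:
            v = v[..., None]
        return v

    # -- forward ----------------------------------------------------------
    def forward(self, volumes: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None, return_cache: bool = False,
                update_bn: bool = True):
        """Class probabilities for a batch of volumes.

        Dropout is active only with ``training=True``; batch statistics are
        used for normalization during training and running moments
        otherwise. ``update_bn=False`` freezes the normalization layer (it
        then uses its running moments even in training mode), as during
        softmax-only fine-tuning.
        """
        x = self._prepare(volumes)
        cache: dict = {"conv_in": [], "conv_pre": [], "conv_act": [],
                       "pool_in_shapes": []}
        spec = self.spec
        for li in range(1, self.n_conv + 1):
            cache["conv_in"].append(x)
            # the stencil kernel silently skips non-finite weights, so bad
            # parameters must be rejected up front
            if not (np.all(np.isfinite(self.params[f"conv{li}_W"]))
                    and np.all(np.isfinite(self.params[f"conv{li}_b"]))):
                raise FloatingPointError(f"non-finite parameters in Conv_{li}")
            z = _conv3d_forward(x, self.params[f"conv{li}_W"], self.params[f"conv{li}_b"])
            if not np.all(np.isfinite(z)):
                raise FloatingPointError(f"non-finite activations in Conv_{li}")
            a = _sigmoid(z) if spec.conv_activation == "sigmoid" else np.maximum(z, 0.0)
            cache["conv_pre"].append(z)
            cache["conv_act"].append(a)
            cache["pool_in_shapes"].append(a.shape)
            x = avg_pool3d(a)
        # batch norm over features
        bn_batch_stats = training and update_bn
        if bn_batch_stats:
            mu = x.mean(axis=(0, 1, 2, 3))
            var = x.var(axis=(0, 1, 2, 3))
            m = spec.bn_momentum
            self.bn_mean = m * self.bn_mean + (1 - m) * mu
            self.bn_var = m * self.bn_var + (1 - m) * var
        else:
            mu, var = self.bn_mean, self.bn_var
        inv_sd = 1.0 / np.sqrt(var + spec.bn_eps)
        xhat = (x - mu) * inv_sd
        bn_out = self.params["bn_gamma"] * xhat + self.params["bn_beta"]
        cache.update(bn_in=x, bn_xhat=xhat, bn_inv_sd=inv_sd, bn_training=bn_batch_stats)
        flat = bn_out.reshape(bn_out.shape[0], -1)
        # dropout (training only)
        if training and spec.dropout_rate > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            mask = (rng.random(flat.shape) >= spec.dropout_rate) / (1.0 - spec.dropout_rate)
        else:
            mask = None
        dropped = flat * mask if mask is not None else flat
        head_in = np.maximum(dropped, 0.0) if spec.use_relu_head else dropped
        logits = head_in @ self.params["dense_W"] + self.params["dense_b"]
        probs = softmax(logits)
        cache.update(flat=flat, mask=mask, dropped=dropped, head_in=head_in,
                     logits=logits, probs=probs)
        if return_cache:
            return probs, cache
        return probs

    def predict_proba(self, volumes: np.ndarray, batch_size: int = 100) -> np.ndarray:
        v = self._prepare(volumes)
        out = [self.forward(v[i : i + batch_size]) for i in range(0, len(v), batch_size)]
        return np.concatenate(out, axis=0)

    def feature_maps(self, volumes: np.ndarray, layer_index: int) -> np.ndarray:
        """Post-activation (pre-pool) feature maps of a convolutional layer."""
        if layer_index not in range(1, self.n_conv + 1):
            raise ValueError(f"layer_index must be in 1..{self.n_conv}")
        x = self._prepare(volumes)
        for li in range(1, layer_index + 1):
            z = _conv3d_forward(x, self.params[f"conv{li}_W"], self.params[f"conv{li}_b"])
            a = _sigmoid(z) if self.spec.conv_activation == "sigmoid" else np.maximum(z, 0.0)
            if li == layer_index:
                return a
            x = avg_pool3d(a)
        raise AssertionError  # pragma: no cover

    def forward_from_activation(self, activation: np.ndarray, layer_index: int) -> np.ndarray:
        """Continue the (inference-mode) forward pass from a given conv
        layer's post-activation feature maps; returns the logits.

        Useful for perturbation analyses of the saliency computation: the
        rest of the network is evaluated exactly as in :meth:`forward`.
        """
        x = np.asarray(activation, dtype=self.dtype)
        x = avg_pool3d(x)
        for li in range(layer_index + 1, self.n_conv + 1):
            z = _conv3d_forward(x, self.params[f"conv{li}_W"], self.params[f"conv{li}_b"])
            a = _sigmoid(z) if self.spec.conv_activation == "sigmoid" else np.maximum(z, 0.0)
            x = avg_pool3d(a)
        inv_sd = 1.0 / np.sqrt(self.bn_var + self.spec.bn_eps)
        bn_out = self.params["bn_gamma"] * (x - self.bn_mean) * inv_sd + self.params["bn_beta"]
        flat = bn_out.reshape(bn_out.shape[0], -1)
        head_in = np.maximum(flat, 0.0) if self.spec.use_relu_head else flat
        return head_in @ self.params["dense_W"] + self.params["dense_b"]

    # -- loss and gradients -----------------------------------------------
    def penalty(self) -> float:
        """L1 + L2 penalty over the convolutional and dense weight matrices."""
        p = 0.0
        for name, w in self.params.items():
            if name.endswith("_W"):
                p += self.spec.l1 * np.abs(w).sum() + self.spec.l2 * (w**2).sum()
        return float(p)

    def loss_and_grads(self, volumes, labels, class_weights=None,
                       training: bool = True, rng=None, update_bn: bool = True):
        """Class-weighted cross-entropy + penalties, with full backprop.

        Returns ``(loss, grads)`` where grads maps parameter names to
        arrays of matching shape.
        """
        labels = np.asarray(labels)
        probs, cache = self.forward(volumes, training=training, rng=rng,
                                    return_cache=True, update_bn=update_bn)
        B = probs.shape[0]
        if class_weights is None:
            w = np.ones(self.spec.n_classes, dtype=self.dtype)
        else:
            w = np.asarray(class_weights, dtype=self.dtype)
        wi = w[labels]
        eps = np.finfo(self.dtype).tiny
        data_loss = float(-(wi * np.log(probs[np.arange(B), labels] + eps)).sum() / B)
        loss = data_loss + self.penalty()

        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits *= wi[:, None] / B
        grads = self._backward(cache, dlogits)
        for name in list(grads):
            if name.endswith("_W"):
                wmat = self.params[name]
                grads[name] = grads[name] + self.spec.l1 * np.sign(wmat) + 2.0 * self.spec.l2 * wmat
        return loss, grads

    def _backward(self, cache: dict, dlogits: np.ndarray,
                  stop_at_conv: int | None = None):
        """Backprop from logits. If ``stop_at_conv`` is given, returns the
        gradient w.r.t. that conv layer's post-activation feature map
        instead of the parameter gradients."""
        spec = self.spec
        grads: dict[str, np.ndarray] = {}
        grads["dense_W"] = cache["head_in"].T @ dlogits
        grads["dense_b"] = dlogits.sum(axis=0)
        d_head_in = dlogits @ self.params["dense_W"].T
        if spec.use_relu_head:
            d_dropped = d_head_in * (cache["dropped"] > 0)
        else:
            d_dropped = d_head_in
        d_flat = d_dropped * cache["mask"] if cache["mask"] is not None else d_dropped
        d_bn_out = d_flat.reshape(cache["bn_in"].shape)
        xhat, inv_sd = cache["bn_xhat"], cache["bn_inv_sd"]
        grads["bn_gamma"] = (d_bn_out * xhat).sum(axis=(0, 1, 2, 3))
        grads["bn_beta"] = d_bn_out.sum(axis=(0, 1, 2, 3))
        d_xhat = d_bn_out * self.params["bn_gamma"]
        if cache["bn_training"]:
            n = float(np.prod(xhat.shape[:4]))
            d_x = (inv_sd / n) * (
                n * d_xhat
                - d_xhat.sum(axis=(0, 1, 2, 3))
                - xhat * (d_xhat * xhat).sum(axis=(0, 1, 2, 3))
            )
        else:
            d_x = d_xhat * inv_sd
        g = d_x
        for li in range(self.n_conv, 0, -1):
            a = cache["conv_act"][li - 1]
            g = avg_pool3d_backward(g, cache["pool_in_shapes"][li - 1])
            if stop_at_conv is not None and li == stop_at_conv:
                return g
            if spec.conv_activation == "sigmoid":
                g = g * a * (1.0 - a)
            else:
                g = g * (cache["conv_pre"][li - 1] > 0)
            x_in = cache["conv_in"][li - 1]
            dW, db, dx = _conv3d_backward(x_in, self.params[f"conv{li}_W"], g,
                                          need_dx=(li > 1 or stop_at_conv is not None))
            grads[f"conv{li}_W"] = dW
            grads[f"conv{li}_b"] = db
            g = dx
        if stop_at_conv is not None:
            raise ValueError("stop_at_conv beyond the first layer's activation")
        return grads

    def activation_gradient(self, volumes, target_class: int, layer_index: int,
                            scalar: str = "class_score",
                            class_weights=None) -> tuple:
        """Gradient of a scalar network output w.r.t. a conv layer's
        post-activation feature maps, for Grad-CAM.

        ``scalar`` is either the target class's pre-softmax score (standard
        Grad-CAM) or the cross-entropy ``loss`` at the target label.
        Returns ``(activation, gradient)``, both (B, x, y, f, filters).
        """
        if layer_index not in range(1, self.n_conv + 1):
            raise ValueError(f"layer_index must be in 1..{self.n_conv}")
        probs, cache = self.forward(volumes, training=False, return_cache=True)
        B = probs.shape[0]
        if scalar == "class_score":
            dlogits = np.zeros_like(cache["logits"])
            dlogits[:, target_class] = 1.0
        elif scalar == "loss":
            labels = np.full(B, target_class)
            w = (np.ones(self.spec.n_classes) if class_weights is None
                 else np.asarray(class_weights))
            dlogits = probs.copy()
            dlogits[np.arange(B), labels] -= 1.0
            dlogits *= w[labels][:, None] / B
        else:
            raise ValueError("scalar must be 'class_score' or 'loss'")
        g = self._backward(cache, dlogits, stop_at_conv=layer_index)
        return cache["conv_act"][layer_index - 1], g

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict:
        d = {k: v.copy() for k, v in self.params.items()}
        d["bn_mean"] = self.bn_mean.copy()
        d["bn_var"] = self.bn_var.copy()
        return d

    def load_state_dict(self, state: dict):
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=self.dtype).copy()
        self.bn_mean = np.asarray(state["bn_mean"], dtype=self.dtype).copy()
        self.bn_var = np.asarray(state["bn_var"], dtype=self.dtype).copy()

    def save(self, path):
        """Weights as an .npz container plus a JSON manifest (spec, shapes, hash)."""
        path = Path(path)
        state = self.state_dict()
        np.savez(path.with_suffix(".npz"), **state)
        h = hashlib.sha256()
        for k in sorted(state):
            h.update(k.encode())
            h.update(np.ascontiguousarray(state[k]).tobytes())
        manifest = {
            "spec": asdict(self.spec),
            "shapes": {k: list(v.shape) for k, v in state.items()},
            "sha256": h.hexdigest(),
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path) -> "Model3DCNN":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        spec_d = manifest["spec"]
        for key in ("conv_filters", "input_shape"):
            spec_d[key] = tuple(spec_d[key])
        model = cls(ModelSpec(**spec_d))
        with np.load(path.with_suffix(".npz")) as npz:
            model.load_state_dict(dict(npz))
        return model


def build_model(spec: ModelSpec = ModelSpec(), seed: int = 0) -> Model3DCNN:
    """Build and initialize the network (Glorot-uniform weights)."""
    model = Model3DCNN(spec, np.random.default_rng(seed))
    chain = shape_chain(spec)
    if chain[-1][1][0] != model.params["dense_W"].shape[0]:  # pragma: no cover
        raise AssertionError("flatten length inconsistent with dense layer")
    return model
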