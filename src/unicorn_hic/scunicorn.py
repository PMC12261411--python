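"""Blind super-resolution of single-cell Hi-C contact maps.

The observed low-depth map ``L`` is modelled as a learnable degradation
of the underlying high-depth map ``H``:

    L = T(H) + E,        J(H, T) = ||L - T(H)||^2 + beta * P(H)

where ``T`` is a small convolution kernel with a positive scalar scale
(read-depth degradation preserves matrix dimensions), ``E`` is
unmodelled noise absorbed by the data term, and ``P`` a sparsity or
smoothness prior.  Enhancement is performed by an unrolled alternating
network: a degradation head extracts features of ``L``; an Estimator
refines a low-dimensional representation of the degradation from
``(L, current H)``; a Restorer rebuilds ``H`` from ``L`` conditioned on
that representation (FiLM-style); the loop runs ``N`` times (default 5)
before a final image tail.  Estimator and Restorer are trained jointly
with one optimizer — the alternation is architectural (an unrolled
loop), not an outer optimization.

All tensors are small (patches of ~40x40), so the network runs on the
numpy autodiff engine in :mod:`unicorn_hic.autograd`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from unicorn_hic.autograd import Tensor, concat_channels, conv2d, dense
from unicorn_hic.hic_io import ContactMap, Patch, extract_patches, reassemble, symmetrize
from unicorn_hic.simulate import TrainingPair

__all__ = [
    "DegradationModel",
    "AlternatingNetwork",
    "TrainConfig",
    "apply_degradation",
    "degradation_objective",
    "estimator_step",
    "restorer_step",
    "alternate_forward",
    "train",
    "enhance",
    "implied_scale",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``beta`` weights the prior ``P(H)`` (``l1_sparsity``: mean |H|;
    ``total_variation``: mean absolute neighbour difference).
    ``loss_weights`` are ``(w_restore, w_kernel)`` for the restoration
    L1 term and the degradation-consistency L1 term.  The squared-norm
    objective ``J`` is kept by :func:`degradation_objective`; the
    network training loss uses L1 data terms, which are robust to count
    outliers.
    """

    beta: float = 1e-4
    prior: str = "l1_sparsity"  # {"l1_sparsity", "total_variation"}
    steps: int = 500
    batch: int = 4
    learning_rate: float = 2e-3
    patch_side: int = 40
    seed: int = 0
    loss_weights: tuple[float, float] = (1.0, 0.1)
    channels: int = 8
    rep_dim: int = 8
    n_alternations: int = 5
    kernel_side: int = 5

    def __post_init__(self) -> None:
        if self.beta < 0 or self.steps < 1 or self.patch_side < 8:
            raise ValueError("need beta >= 0, steps >= 1, patch_side >= 8")
        if self.prior not in ("l1_sparsity", "total_variation"):
            raise ValueError(f"unknown prior {self.prior!r}")
        if self.n_alternations < 1:
            raise ValueError("n_alternations must be >= 1")
        if self.kernel_side % 2 != 1:
            raise ValueError("kernel_side must be odd")
        self.loss_weights = tuple(self.loss_weights)  # type: ignore[assignment]


class DegradationModel:
    """The learnable degradation operator ``T``: same-shape convolution
    with an odd kernel plus a positive scalar scale, output clamped at
    zero.  The kernel starts as the identity (centre 1) and the scale
    at 1, so an untrained model satisfies ``T(H) = H`` exactly.
    """

    def __init__(self, kernel_side: int = 5):
        if kernel_side % 2 != 1:
            raise ValueError("kernel_side must be odd")
        k = np.zeros((kernel_side, kernel_side))
        k[kernel_side // 2, kernel_side // 2] = 1.0
        self.kernel = Tensor(k, requires_grad=True)
        self.log_scale = Tensor(0.0, requires_grad=True)

    @property
    def kernel_side(self) -> int:
        return self.kernel.shape[0]

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale.data))

    def set_scale(self, scale: float) -> None:
        if scale <= 0:
            raise ValueError("scale must be positive")
        self.log_scale.data = np.asarray(np.log(scale), dtype=float)

    def parameters(self) -> list[Tensor]:
        return [self.kernel, self.log_scale]

    def apply_t(self, h: Tensor) -> Tensor:
        """``T(H)`` on a (1, n, n) tensor, differentiable."""
        k = self.kernel.shape[0]
        w = self.kernel.reshape(1, 1, k, k)
        out = conv2d(h, w, Tensor(np.zeros(1)))
        return (out * self.log_scale.exp()).relu()


def apply_degradation(dm: DegradationModel, h: np.ndarray) -> np.ndarray:
    """``T(H)`` for a plain square matrix."""
    h = np.asarray(h, dtype=float)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ValueError(f"expected a square matrix, got {h.shape}")
    return dm.apply_t(Tensor(h[None])).data[0]


def _prior_value(h: np.ndarray, prior: str) -> float:
    if prior == "l1_sparsity":
        return float(np.mean(np.abs(h)))
    dx = np.abs(np.diff(h, axis=0)).sum()
    dy = np.abs(np.diff(h, axis=1)).sum()
    return float((dx + dy) / h.size)


def _prior_tensor(h: Tensor, prior: str) -> Tensor:
    if prior == "l1_sparsity":
        return h.abs().mean()
    raise NotImplementedError(
        "total_variation prior is available for the objective J only")


def degradation_objective(dm: DegradationModel, h: np.ndarray,
                          l_observed: np.ndarray, cfg: TrainConfig) -> float:
    """``J(H, T) = mean((L - T(H))^2) + beta * P(H)`` (mean-squared form)."""
    h = np.asarray(h, dtype=float)
    l_observed = np.asarray(l_observed, dtype=float)
    if h.shape != l_observed.shape:
        raise ValueError("H and L shapes differ")
    resid = l_observed - apply_degradation(dm, h)
    return float(np.mean(resid ** 2)) + cfg.beta * _prior_value(h, cfg.prior)


def _he(rng: np.random.Generator, shape, fan_in: float, gain: float = 1.0) -> np.ndarray:
    return rng.normal(0.0, gain * np.sqrt(2.0 / fan_in), size=shape)


def _split_vec(v: Tensor, nc: int) -> tuple[Tensor, Tensor]:
    """Split a (2*nc,) vector tensor into two (nc,) halves."""

    def back_first(g):
        out = np.zeros(2 * nc)
        out[:nc] = g
        return (out,)

    def back_second(g):
        out = np.zeros(2 * nc)
        out[nc:] = g
        return (out,)

    first = Tensor(v.data[:nc], _parents=(v,), _backward=back_first)
    second = Tensor(v.data[nc:], _parents=(v,), _backward=back_second)
    return first, second


class AlternatingNetwork:
    """Unrolled Estimator/Restorer stack.

    Inputs are divided by ``input_scale`` (set from the training data)
    so the convolutions see O(1) values; outputs are scaled back.
    ``trained`` is set by :func:`train`; :func:`enhance` refuses an
    untrained network.
    """

    def __init__(self, channels: int = 8, rep_dim: int = 8,
                 n_alternations: int = 5, seed: int = 0):
        if n_alternations < 1:
            raise ValueError("n_alternations must be >= 1")
        rng = np.random.default_rng(seed)
        nc, rd = channels, rep_dim
        self.channels, self.rep_dim = nc, rd
        self.n_alternations = n_alternations
        self.input_scale = 1.0
        self.trained = False
        p = {}
        # degradation head: feature extractor on L
        p["head_w"] = _he(rng, (nc, 1, 3, 3), 9)
        p["head_b"] = np.zeros(nc)
        # estimator: conv on [features(L), H] -> pool -> 2-layer MLP -> rep
        p["est_w"] = _he(rng, (nc, nc + 1, 3, 3), 9 * (nc + 1))
        p["est_b"] = np.zeros(nc)
        p["est_fc1_w"] = _he(rng, (nc, nc), nc)
        p["est_fc1_b"] = np.zeros(nc)
        p["est_fc2_w"] = _he(rng, (rd, nc), nc)
        p["est_fc2_b"] = np.zeros(rd)
        # restorer: FiLM conditioning of L-features by the kernel rep
        p["film_w"] = _he(rng, (2 * nc, rd), rd, gain=0.1)
        p["film_b"] = np.zeros(2 * nc)
        p["r1_w"] = _he(rng, (nc, 1, 3, 3), 9)
        p["r1_b"] = np.zeros(nc)
        p["r2_w"] = _he(rng, (1, nc, 3, 3), 9 * nc, gain=0.1)
        p["r2_b"] = np.zeros(1)
        # image tail: final residual refinement
        p["t1_w"] = _he(rng, (nc, 1, 3, 3), 9)
        p["t1_b"] = np.zeros(nc)
        p["t2_w"] = _he(rng, (1, nc, 3, 3), 9 * nc, gain=0.1)
        p["t2_b"] = np.zeros(1)
        self.params = {k: Tensor(v, requires_grad=True) for k, v in p.items()}

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- components (tensor space, inputs already scaled) -----------------

    def head(self, l: Tensor) -> Tensor:
        p = self.params
        return conv2d(l, p["head_w"], p["head_b"]).relu()

    def estimator(self, l_features: Tensor, h_current: Tensor) -> Tensor:
        p = self.params
        z = conv2d(concat_channels([l_features, h_current]),
                   p["est_w"], p["est_b"]).relu()
        v = dense(z.mean_spatial(), p["est_fc1_w"], p["est_fc1_b"]).relu()
        return dense(v, p["est_fc2_w"], p["est_fc2_b"])

    def restorer(self, l: Tensor, kernel_rep: Tensor) -> Tensor:
        p = self.params
        nc = self.channels
        film = dense(kernel_rep, p["film_w"], p["film_b"])
        gamma_raw, beta = _split_vec(film, nc)
        gamma = gamma_raw + 1.0  # identity-centred scaling
        g = conv2d(l, p["r1_w"], p["r1_b"]).relu()
        g = (gamma.reshape(nc, 1, 1) * g + beta.reshape(nc, 1, 1)).relu()
        return (l + conv2d(g, p["r2_w"], p["r2_b"])).relu()

    def image_tail(self, h: Tensor) -> Tensor:
        p = self.params
        z = conv2d(h, p["t1_w"], p["t1_b"]).relu()
        return (h + conv2d(z, p["t2_w"], p["t2_b"])).relu()

    def forward(self, l: Tensor) -> tuple[Tensor, Tensor]:
        """Head -> N x (Estimator, Restorer) -> image tail.

        ``l`` is a (1, n, n) tensor in network units (already divided
        by ``input_scale``).  Returns the restored map and the final
        kernel representation, both as tensors.
        """
        f = self.head(l)
        h = l
        rep = None
        for _ in range(self.n_alternations):
            rep = self.estimator(f, h)
            h = self.restorer(l, rep)
        return self.image_tail(h), rep

    def enhance_matrix(self, matrix: np.ndarray) -> np.ndarray:
        """Run the forward pass on a plain matrix (no gradients)."""
        x = np.asarray(matrix, dtype=float)[None] / self.input_scale
        h, _ = self.forward(Tensor(x))
        return h.data[0] * self.input_scale


def estimator_step(net: AlternatingNetwork, l_observed: np.ndarray,
                   h_current: np.ndarray) -> np.ndarray:
    """One Estimator evaluation: the kernel representation implied by
    the observed low-depth map and the current restored estimate."""
    _check_finite(l_observed, h_current)
    s = net.input_scale
    f = net.head(Tensor(np.asarray(l_observed, dtype=float)[None] / s))
    rep = net.estimator(f, Tensor(np.asarray(h_current, dtype=float)[None] / s))
    return rep.data.copy()


def restorer_step(net: AlternatingNetwork, l_observed: np.ndarray,
                  kernel_rep: np.ndarray) -> np.ndarray:
    """One Restorer evaluation: restored map given the representation."""
    _check_finite(l_observed)
    s = net.input_scale
    h = net.restorer(Tensor(np.asarray(l_observed, dtype=float)[None] / s),
                     Tensor(np.asarray(kernel_rep, dtype=float)))
    return h.data[0] * s


def alternate_forward(net: AlternatingNetwork,
                      l_observed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full unrolled pass on one matrix; returns (H_hat, kernel rep)."""
    l_observed = np.asarray(l_observed, dtype=float)
    if l_observed.ndim != 2 or l_observed.shape[0] != l_observed.shape[1]:
        raise ValueError(f"expected a square matrix, got {l_observed.shape}")
    _check_finite(l_observed)
    h, rep = net.forward(Tensor(l_observed[None] / net.input_scale))
    return h.data[0] * net.input_scale, rep.data.copy()


def _check_finite(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.all(np.isfinite(np.asarray(a, dtype=float))):
            raise ValueError("non-finite values in network input")


class _Adam:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.grad = None


def train(pairs: Sequence[TrainingPair | tuple],
          cfg: TrainConfig) -> tuple[AlternatingNetwork, DegradationModel, np.ndarray]:
    """Jointly train the alternating network and the degradation kernel.

    Per-step loss over a random batch of (HR, LR) patch pairs:

        w_restore * mean|H_hat - H_GT|
      + w_kernel  * mean|T(H_GT) - L_GT|
      + beta * P(H_hat)

    with all terms computed in network units (counts divided by
    ``input_scale``).  Fully seeded: the returned loss trace is
    bit-identical across runs with the same config and data.
    """
    if not pairs:
        raise ValueError("no training pairs")
    hrs = [np.asarray(p.hr.values if isinstance(p, TrainingPair) else p[0], dtype=float)
           for p in pairs]
    lrs = [np.asarray(p.lr.values if isinstance(p, TrainingPair) else p[1], dtype=float)
           for p in pairs]
    sides = {h.shape for h in hrs} | {l.shape for l in lrs}
    if len(sides) != 1:
        raise ValueError(f"inconsistent patch shapes: {sides}")

    rng = np.random.default_rng(cfg.seed)
    net = AlternatingNetwork(channels=cfg.channels, rep_dim=cfg.rep_dim,
                             n_alternations=cfg.n_alternations,
                             seed=int(rng.integers(0, 2 ** 31 - 1)))
    dm = DegradationModel(kernel_side=cfg.kernel_side)
    scale = float(np.mean([h.mean() for h in hrs]))
    net.input_scale = max(scale, 1e-8)

    opt = _Adam(net.parameters() + dm.parameters(), cfg.learning_rate)
    w_restore, w_kernel = cfg.loss_weights
    trace = np.empty(cfg.steps)
    s = net.input_scale
    for step in range(cfg.steps):
        idx = rng.integers(0, len(pairs), size=min(cfg.batch, len(pairs)))
        loss: Tensor | None = None
        for b in idx:
            hr = Tensor(hrs[b][None] / s)
            lr = Tensor(lrs[b][None] / s)
            h_hat, _ = net.forward(lr)
            term = (h_hat - hr).abs().mean() * w_restore
            if w_kernel != 0:
                term = term + (dm.apply_t(hr) - lr).abs().mean() * w_kernel
            if cfg.beta != 0:
                term = term + _prior_tensor(h_hat, cfg.prior) * cfg.beta
            loss = term if loss is None else loss + term
        loss = loss * (1.0 / len(idx))
        if not np.isfinite(loss.data):
            raise RuntimeError(f"non-finite training loss at step {step}")
        loss.backward()
        opt.step()
        trace[step] = float(loss.data)
    net.trained = True
    return net, dm, trace


def enhance(net: AlternatingNetwork, cm: ContactMap,
            patch_side: int = 40) -> ContactMap:
    """Enhance a full contact map with a trained network.

    The map is tiled into ``patch_side`` patches (edge patches overlap),
    each patch is restored by the unrolled forward pass, overlaps are
    averaged on reassembly, and the result is symmetrized and clamped
    at zero.  Metadata is copied from the input.
    """
    if not net.trained:
        raise RuntimeError("refusing to enhance with an untrained network")
    side = min(patch_side, cm.n_bins)
    patches = extract_patches(cm, side, side)
    out = [Patch(net.enhance_matrix(p.values), p.origin) for p in patches]
    m = reassemble(out, cm.n_bins)
    return cm.with_matrix(np.maximum(symmetrize(m), 0.0))


def implied_scale(net: AlternatingNetwork, l_observed: np.ndarray) -> float:
    """Implied degradation scale of an observed map: the ratio of its
    total reads to the total of its restoration.  For a well-trained
    model this tracks the read-retention fraction of the degradation."""
    h_hat, _ = alternate_forward(net, l_observed)
    total = float(np.sum(h_hat))
    if total <= 0:
        return np.nan
    return float(np.sum(l_observed)) / total


# -- checkpointing ---------------------------------------------------------


def save_checkpoint(net: AlternatingNetwork, dm: DegradationModel,
                    cfg: TrainConfig, path: str | Path) -> None:
    """Single-file ``.npz`` checkpoint: weights, config echo, version."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(cfg),
        "channels": net.channels,
        "rep_dim": net.rep_dim,
        "n_alternations": net.n_alternations,
        "input_scale": net.input_scale,
        "trained": net.trained,
        "kernel_side": dm.kernel_side,
    }
    arrays = {f"net_{k}": t.data for k, t in net.params.items()}
    arrays["dm_kernel"] = dm.kernel.data
    arrays["dm_log_scale"] = np.asarray(dm.log_scale.data)
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> tuple[AlternatingNetwork, DegradationModel, TrainConfig]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        net = AlternatingNetwork(channels=meta["channels"], rep_dim=meta["rep_dim"],
                                 n_alternations=meta["n_alternations"])
        for k in net.params:
            net.params[k].data = data[f"net_{k}"]
        net.input_scale = float(meta["input_scale"])
        net.trained = bool(meta["trained"])
        dm = DegradationModel(kernel_side=meta["kernel_side"])
        dm.kernel.data = data["dm_kernel"]
        dm.log_scale.data = data["dm_log_scale"]
        cfg_d = meta["config"]
        cfg_d["loss_weights"] = tuple(cfg_d["loss_weights"])
        cfg = TrainConfig(**cfg_d)
    return net, dm, cfg
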