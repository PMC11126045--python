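"""Bi-LSTM sequence regression for AIF saturation correction.

The model maps a stack of per-time-step channels -- the dictionary-
inverted (saturated) AIF, optionally followed by N tissue curves in
ascending-ktrans order -- to the 120-point true AIF.  Four stacked
bidirectional LSTM layers (32 hidden units per direction) feed a linear
layer that maps the 64 concatenated features at each time step to one
output sample.  Training uses Adam with L1-type losses:

* ``aif_only``            -- mean absolute error on the AIF.
* ``aif_plus_param``      -- adds an L1 penalty between an auxiliary
  parameter head (4 values per tissue curve, from the final hidden
  states) and the generating compartment-model parameters.
* ``aif_plus_model_tissue`` -- adds an L1 penalty between the measured
  tissue curves and the compartment model forward-simulated from the
  *predicted* AIF and *predicted* parameters (fully differentiable,
  sharing the generator's convolution; the arrival delay is applied at
  nearest-sample granularity and treated as constant in the backward
  pass).

The network is implemented directly on NumPy arrays with hand-written
reverse-mode gradients; the sequential recurrences run as numba kernels
(:mod:`aifcorr._recurrent`).  Given a seed, initialisation, batching and
training are bit-reproducible on a fixed BLAS configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._recurrent import lstm_core_forward, lstm_core_backward
from .grid import ConcentrationCurve, TimeGrid
from .data_factory import Dataset

__all__ = [
    "NetworkConfig",
    "LossConfig",
    "TrainedModel",
    "BiLSTM",
    "build_model",
    "lstm_parameter_count",
    "compute_loss",
    "train",
    "correct_aif",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and optimisation hyperparameters."""

    input_channels: int = 11
    n_layers: int = 4
    hidden_size: int = 32
    output_length: int = 120
    batch_size: int = 16
    epochs: int = 100
    learning_rate: float = 3e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_channels < 1:
            raise ValueError("need at least the saturated-AIF input channel")
        if self.n_layers < 1 or self.hidden_size < 1:
            raise ValueError("invalid architecture")


@dataclass(frozen=True)
class LossConfig:
    """Loss selection and weights.

    ``alpha`` weighs the AIF term; ``beta`` the parameter term
    (``aif_plus_param`` only); ``delta`` the model-tissue term
    (``aif_plus_model_tissue`` only); ``n_tissue`` is N in the summed
    terms (0 means: use every tissue curve available in the dataset).
    """

    kind: str = "aif_only"
    alpha: float = 1.0
    beta: float = 0.0
    delta: float = 0.0
    n_tissue: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("aif_only", "aif_plus_param", "aif_plus_model_tissue"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def needs_param_head(self) -> bool:
        return self.kind in ("aif_plus_param", "aif_plus_model_tissue")


def lstm_parameter_count(n_layers: int, hidden: int, input_channels: int) -> int:
    """Learnable parameters of the bidirectional recurrent stack alone."""
    total = 0
    c = input_channels
    for _ in range(n_layers):
        per_direction = 4 * hidden * (c + hidden) + 4 * hidden
        total += 2 * per_direction
        c = 2 * hidden
    return total


class BiLSTM:
    """Stacked bidirectional LSTM with a per-time-step linear output head."""

    def __init__(self, cfg: NetworkConfig, n_param_outputs: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        self.n_param_outputs = n_param_outputs
        self.params: dict[str, np.ndarray] = {}
        self._init_params()

    # -- initialisation -------------------------------------------------
    def _init_params(self) -> None:
        rng = np.random.default_rng(self.cfg.seed)
        H = self.cfg.hidden_size
        c = self.cfg.input_channels

        def he(shape):
            fan_in = shape[0]
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(self.dtype)

        for layer in range(self.cfg.n_layers):
            for d in ("f", "b"):
                self.params[f"l{layer}_{d}_Wx"] = he((c, 4 * H))
                self.params[f"l{layer}_{d}_Wh"] = he((H, 4 * H))
                self.params[f"l{layer}_{d}_b"] = np.zeros(4 * H, dtype=self.dtype)
            c = 2 * H
        self.params["head_W"] = he((2 * H, 1))
        self.params["head_b"] = np.zeros(1, dtype=self.dtype)
        if self.n_param_outputs:
            self.params["phead_W"] = he((2 * H, self.n_param_outputs))
            self.params["phead_b"] = np.zeros(self.n_param_outputs, dtype=self.dtype)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward --------------------------------------------------------
    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Forward pass.

        x : (B, T, C) input batch.  Returns (pred_aif, pred_params, cache)
        with pred_aif (B, T) and pred_params (B, n_param_outputs) or None.
        """
        B, T, C = x.shape
        if C != self.cfg.input_channels:
            raise ValueError(
                f"model expects {self.cfg.input_channels} input channels, got {C}"
            )
        H = self.cfg.hidden_size
        xt = np.ascontiguousarray(x.transpose(1, 0, 2), dtype=self.dtype)  # (T,B,C)
        cache = {"x": []} if want_cache else None
        cur = xt
        last_states = None
        for layer in range(self.cfg.n_layers):
            cin = cur.shape[2]
            x2d = cur.reshape(T * B, cin)
            # forward direction
            pf = self.params
            one = np.dtype(self.dtype).type(1.0)
            xp_f = (x2d @ pf[f"l{layer}_f_Wx"] + pf[f"l{layer}_f_b"]).reshape(T, B, 4 * H)
            hs_f, cs_f, gates_f = lstm_core_forward(
                np.ascontiguousarray(xp_f), pf[f"l{layer}_f_Wh"], one
            )
            # backward direction: run on the time-reversed sequence
            cur_rev = np.ascontiguousarray(cur[::-1])
            xr2d = cur_rev.reshape(T * B, cin)
            xp_b = (xr2d @ pf[f"l{layer}_b_Wx"] + pf[f"l{layer}_b_b"]).reshape(T, B, 4 * H)
            hs_b, cs_b, gates_b = lstm_core_forward(
                np.ascontiguousarray(xp_b), pf[f"l{layer}_b_Wh"], one
            )
            out = np.empty((T, B, 2 * H), dtype=self.dtype)
            out[:, :, :H] = hs_f[1:]
            out[:, :, H:] = hs_b[1:][::-1]
            if want_cache:
                cache["x"].append((cur, cur_rev, hs_f, cs_f, gates_f, hs_b, cs_b, gates_b))
            last_states = (hs_f[T], hs_b[T])
            cur = out
        out2d = cur.reshape(T * B, 2 * H)
        y = (out2d @ self.params["head_W"] + self.params["head_b"]).reshape(T, B)
        pred_aif = np.ascontiguousarray(y.T)
        pred_params = None
        if self.n_param_outputs:
            z = np.concatenate(last_states, axis=1)  # (B, 2H)
            pred_params = z @ self.params["phead_W"] + self.params["phead_b"]
        if want_cache:
            cache["top_out"] = cur
            cache["z"] = np.concatenate(last_states, axis=1) if self.n_param_outputs else None
            cache["shape"] = (B, T)
        return pred_aif, pred_params, cache

    # -- backward -------------------------------------------------------
    def backward(self, cache, d_pred_aif: np.ndarray, d_pred_params: np.ndarray | None = None):
        """Backpropagate output gradients; returns dict of parameter grads."""
        B, T = cache["shape"]
        H = self.cfg.hidden_size
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dY = np.ascontiguousarray(d_pred_aif.T, dtype=self.dtype).reshape(T * B, 1)
        out2d = cache["top_out"].reshape(T * B, 2 * H)
        grads["head_W"] += out2d.T @ dY
        grads["head_b"] += dY.sum(axis=0)
        dout = (dY @ self.params["head_W"].T).reshape(T, B, 2 * H)

        dz = None
        if self.n_param_outputs and d_pred_params is not None:
            dP = np.asarray(d_pred_params, dtype=self.dtype)
            grads["phead_W"] += cache["z"].T @ dP
            grads["phead_b"] += dP.sum(axis=0)
            dz = dP @ self.params["phead_W"].T  # (B, 2H)

        for layer in range(self.cfg.n_layers - 1, -1, -1):
            cur, cur_rev, hs_f, cs_f, gates_f, hs_b, cs_b, gates_b = cache["x"][layer]
            cin = cur.shape[2]
            dh_f = np.ascontiguousarray(dout[:, :, :H])
            dh_b_rev = np.ascontiguousarray(dout[:, :, H:][::-1])
            if dz is not None and layer == self.cfg.n_layers - 1:
                dh_f = dh_f.copy()
                dh_b_rev = dh_b_rev.copy()
                dh_f[T - 1] += dz[:, :H]
                dh_b_rev[T - 1] += dz[:, H:]
            p = self.params
            WhT_f = np.ascontiguousarray(p[f"l{layer}_f_Wh"].T)
            WhT_b = np.ascontiguousarray(p[f"l{layer}_b_Wh"].T)
            dxp_f = lstm_core_backward(dh_f, hs_f, cs_f, gates_f, WhT_f)
            dxp_b = lstm_core_backward(dh_b_rev, hs_b, cs_b, gates_b, WhT_b)
            dxp_f2d = dxp_f.reshape(T * B, 4 * H)
            dxp_b2d = dxp_b.reshape(T * B, 4 * H)
            x2d = cur.reshape(T * B, cin)
            xr2d = cur_rev.reshape(T * B, cin)
            grads[f"l{layer}_f_Wx"] += x2d.T @ dxp_f2d
            grads[f"l{layer}_b_Wx"] += xr2d.T @ dxp_b2d
            grads[f"l{layer}_f_Wh"] += hs_f[:T].reshape(T * B, H).T @ dxp_f2d
            grads[f"l{layer}_b_Wh"] += hs_b[:T].reshape(T * B, H).T @ dxp_b2d
            grads[f"l{layer}_f_b"] += dxp_f2d.sum(axis=0)
            grads[f"l{layer}_b_b"] += dxp_b2d.sum(axis=0)
            dx_f = (dxp_f2d @ p[f"l{layer}_f_Wx"].T).reshape(T, B, cin)
            dx_b = (dxp_b2d @ p[f"l{layer}_b_Wx"].T).reshape(T, B, cin)[::-1]
            dout = dx_f + dx_b
        return grads


def build_model(cfg: NetworkConfig, loss_cfg: LossConfig | None = None, dtype=np.float32) -> BiLSTM:
    """Construct a seeded model; adds the parameter head when the loss needs it."""
    n_param_outputs = 0
    if loss_cfg is not None and loss_cfg.needs_param_head:
        if loss_cfg.n_tissue < 1:
            raise ValueError("parameter/tissue losses need n_tissue >= 1")
        n_param_outputs = 4 * loss_cfg.n_tissue
    return BiLSTM(cfg, n_param_outputs=n_param_outputs, dtype=dtype)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

#: clamp ranges applied to predicted parameters inside the model-tissue loss
_PARAM_CLIP = np.array([[0.0, 5.0], [0.0, 20.0], [0.0, 0.2], [0.0, 0.1]])


def _aif_term(pred, true):
    diff = pred - true
    loss = float(np.abs(diff).mean())
    grad = np.sign(diff) / diff.size
    return loss, grad


def _param_term(pred_params, true_params):
    # pred/true: (B, N, 4); elementwise mean absolute deviation (the
    # standard deep-learning L1 reduction), so the alpha:beta ratio
    # compares quantities normalised the same way as the AIF term
    diff = pred_params - true_params
    loss = float(np.abs(diff).mean())
    grad = np.sign(diff) / diff.size
    return loss, grad


def _tissue_model_term(pred_aif, pred_params, tissue, grid: TimeGrid):
    """Differentiable compartment-model tissue term.

    pred_aif (B,T), pred_params (B,N,4), tissue (B,N,T).  Returns
    (loss, d_pred_aif, d_pred_params).  Parameter clamps use a
    straight-through gradient so out-of-range predictions keep learning;
    the arrival delay is rounded to the nearest sample and treated as
    constant in the backward pass.
    """
    pred_aif = np.asarray(pred_aif, dtype=np.float64)
    pred_params = np.asarray(pred_params, dtype=np.float64)
    B, N, T = tissue.shape
    t = grid.values
    dt = grid.dt
    loss = 0.0
    dA = np.zeros_like(pred_aif)
    dP = np.zeros_like(pred_params)
    norm = B * N * T
    for b in range(B):
        A = pred_aif[b]
        for n in range(N):
            kt, kep, vp, dtau = np.clip(pred_params[b, n], _PARAM_CLIP[:, 0], _PARAM_CLIP[:, 1])
            s = int(round(dtau / dt))
            sh = np.zeros(T)
            sh[s:] = A[: T - s] if s > 0 else A
            kern = kt * np.exp(-kep * t)
            conv = np.convolve(sh, kern)[:T]
            y = dt * (conv - 0.5 * (sh * kern[0] + sh[0] * kern)) + vp * sh
            r = y - tissue[b, n]
            loss += np.abs(r).sum()
            rs = np.sign(r) / norm
            # gradient w.r.t. the kernel samples
            dk = dt * np.convolve(rs, sh[::-1])[T - 1 : 2 * T - 1]
            dk[0] -= 0.5 * dt * float(rs @ sh)
            dk -= 0.5 * dt * rs * sh[0]
            ek = np.exp(-kep * t)
            dP[b, n, 0] += float(dk @ ek)
            dP[b, n, 1] += float(dk @ (-t * kt * ek))
            dP[b, n, 2] += float(rs @ sh)
            # gradient w.r.t. the shifted AIF, then unshift
            dsh = dt * np.convolve(rs[::-1], kern)[:T][::-1]
            dsh -= 0.5 * dt * rs * kern[0]
            dsh[0] -= 0.5 * dt * float(rs @ kern)
            dsh += vp * rs
            if s > 0:
                dA[b, : T - s] += dsh[s:]
            else:
                dA[b] += dsh
    return loss / norm, dA, dP


def _loss_and_grads(
    cfg: LossConfig,
    pred_aif,
    true_aif,
    pred_params=None,
    true_params=None,
    tissue_curves=None,
    grid: TimeGrid | None = None,
):
    """Scalar loss plus gradients w.r.t. the network outputs."""
    l_aif, g_aif = _aif_term(np.asarray(pred_aif, float), np.asarray(true_aif, float))
    loss = cfg.alpha * l_aif
    d_pred = cfg.alpha * g_aif
    d_params = None
    if cfg.kind == "aif_only":
        return loss, d_pred, None
    if pred_params is None:
        raise ValueError(f"loss kind {cfg.kind!r} requires the parameter head outputs")
    B = np.shape(pred_aif)[0]
    n = cfg.n_tissue
    pp = np.asarray(pred_params, float).reshape(B, n, 4)
    if cfg.kind == "aif_plus_param":
        if true_params is None:
            raise ValueError("aif_plus_param requires the generating parameters")
        l_par, g_par = _param_term(pp, np.asarray(true_params, float)[:, :n, :])
        loss += cfg.beta * l_par
        d_params = (cfg.beta * g_par).reshape(B, 4 * n)
    else:  # aif_plus_model_tissue
        if tissue_curves is None or grid is None:
            raise ValueError("aif_plus_model_tissue requires tissue curves and a grid")
        l_tis, dA, dP = _tissue_model_term(pred_aif, pp, np.asarray(tissue_curves, float)[:, :n, :], grid)
        loss += cfg.delta * l_tis
        d_pred = d_pred + cfg.delta * dA
        d_params = (cfg.delta * dP).reshape(B, 4 * n)
    return loss, d_pred, d_params


def compute_loss(
    cfg: LossConfig,
    pred_aif,
    true_aif,
    pred_params=None,
    true_params=None,
    tissue_curves=None,
    grid: TimeGrid | None = None,
) -> float:
    """Evaluate the configured training loss on a batch of outputs."""
    loss, _, _ = _loss_and_grads(
        cfg, pred_aif, true_aif, pred_params, true_params, tissue_curves, grid
    )
    return loss


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A trained network plus its configuration and training history."""

    net_cfg: NetworkConfig
    loss_cfg: LossConfig
    params: dict[str, np.ndarray]
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    n_param_outputs: int = 0

    def model(self) -> BiLSTM:
        m = BiLSTM(self.net_cfg, n_param_outputs=self.n_param_outputs)
        for k in m.params:
            m.params[k] = self.params[k].astype(m.dtype)
        return m

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass on (B, T, C) inputs; output clipped at 0 from below."""
        pred, _, _ = self.model().forward(np.asarray(x))
        return np.clip(pred, 0.0, None)

    def save(self, path_prefix: str) -> None:
        np.savez(f"{path_prefix}.npz", **self.params)
        side = {
            "net_cfg": asdict(self.net_cfg),
            "loss_cfg": asdict(self.loss_cfg),
            "best_epoch": self.best_epoch,
            "n_param_outputs": self.n_param_outputs,
            "history": self.history,
        }
        with open(f"{path_prefix}.json", "w") as f:
            json.dump(side, f, indent=1)

    @classmethod
    def load(cls, path_prefix: str) -> "TrainedModel":
        with open(f"{path_prefix}.json") as f:
            side = json.load(f)
        with np.load(f"{path_prefix}.npz") as z:
            params = {k: z[k] for k in z.files}
        return cls(
            net_cfg=NetworkConfig(**side["net_cfg"]),
            loss_cfg=LossConfig(**side["loss_cfg"]),
            params=params,
            history=side["history"],
            best_epoch=side["best_epoch"],
            n_param_outputs=side["n_param_outputs"],
        )


def _dataset_inputs(ds: Dataset, n_input_tissue: int) -> np.ndarray:
    """Stack saturated AIF + tissue channels as (n, T, C), float32."""
    if n_input_tissue > ds.n_tissue:
        raise ValueError(
            f"model wants {n_input_tissue} tissue input curves but the dataset has {ds.n_tissue}"
        )
    parts = [ds.sat_aif[:, None, :]]
    if n_input_tissue:
        parts.append(ds.tissue[:, :n_input_tissue, :])
    return np.ascontiguousarray(
        np.concatenate(parts, axis=1).transpose(0, 2, 1), dtype=np.float32
    )


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k in sorted(params):
            g = grads[k].astype(params[k].dtype)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _validation_aif_l1(model: BiLSTM, x: np.ndarray, y: np.ndarray, chunk: int = 256) -> float:
    total = 0.0
    for start in range(0, x.shape[0], chunk):
        pred, _, _ = model.forward(x[start : start + chunk])
        total += float(np.abs(pred - y[start : start + chunk]).sum())
    return total / y.size


def train(
    splits: dict[str, Dataset],
    net_cfg: NetworkConfig,
    loss_cfg: LossConfig | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Mini-batch training with per-epoch validation on the AIF L1 metric.

    The model with the lowest validation AIF L1 loss is retained
    ("highest validation accuracy").  Raises if the loss diverges.
    """
    loss_cfg = loss_cfg or LossConfig()
    train_ds, val_ds = splits["train"], splits["val"]
    n_input_tissue = net_cfg.input_channels - 1
    x_train = _dataset_inputs(train_ds, n_input_tissue)
    y_train = train_ds.true_aif.astype(np.float32)
    x_val = _dataset_inputs(val_ds, n_input_tissue)
    y_val = val_ds.true_aif.astype(np.float32)

    n_loss_tissue = loss_cfg.n_tissue
    if loss_cfg.needs_param_head and n_loss_tissue < 1:
        raise ValueError("parameter/tissue losses need n_tissue >= 1")
    model = build_model(net_cfg, loss_cfg)
    opt = _Adam(model.params, net_cfg.learning_rate)
    rng = np.random.default_rng(net_cfg.seed + 1)
    grid = train_ds.grid

    n = x_train.shape[0]
    history: list[dict] = []
    best_val = np.inf
    best_epoch = -1
    best_params = {k: v.copy() for k, v in model.params.items()}
    for epoch in range(net_cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, net_cfg.batch_size):
            idx = order[start : start + net_cfg.batch_size]
            xb = x_train[idx]
            yb = y_train[idx]
            pred, pred_params, cache = model.forward(xb, want_cache=True)
            loss, d_pred, d_params = _loss_and_grads(
                loss_cfg,
                pred,
                yb,
                pred_params,
                train_ds.pk[idx] if loss_cfg.kind == "aif_plus_param" else None,
                train_ds.tissue[idx] if loss_cfg.kind == "aif_plus_model_tissue" else None,
                grid,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, batch {n_batches}: loss={loss}"
                )
            grads = model.backward(cache, d_pred, d_params)
            opt.step(model.params, grads)
            epoch_loss += loss
            n_batches += 1
        val_loss = _validation_aif_l1(model, x_val, y_val)
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / n_batches, "val_loss": val_loss}
        )
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_params = {k: v.copy() for k, v in model.params.items()}
        if verbose:
            print(f"epoch {epoch:3d}  train {epoch_loss / n_batches:.5f}  val {val_loss:.5f}")
    return TrainedModel(
        net_cfg=net_cfg,
        loss_cfg=loss_cfg,
        params=best_params,
        history=history,
        best_epoch=best_epoch,
        n_param_outputs=model.n_param_outputs,
    )


def correct_aif(
    model: TrainedModel,
    saturated_aif: ConcentrationCurve,
    tissue_curves: list[ConcentrationCurve] | None = None,
) -> ConcentrationCurve:
    """Correct one saturated AIF; output is clipped at zero concentration."""
    tissue_curves = tissue_curves or []
    expected = model.net_cfg.input_channels
    if 1 + len(tissue_curves) != expected:
        raise ValueError(
            f"model expects {expected} input channels, got 1 AIF + {len(tissue_curves)} tissue curves"
        )
    channels = [saturated_aif.values] + [c.values for c in tissue_curves]
    x = np.ascontiguousarray(np.stack(channels, axis=1)[None, :, :], dtype=np.float32)
    pred = model.predict(x)  # (1, T, C) in, (1, T) out
    return ConcentrationCurve(saturated_aif.grid, pred[0].astype(float))
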