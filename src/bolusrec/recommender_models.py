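"""Neural recommendation models: the two-LSTM chain and the residual stack.

The chain model runs one recurrent encoder over the 72-step history of
(glucose, carbs, bolus, basal), initializes a second encoder from a linear
projection of the first encoder's final state, runs it over the sparse event
channels of the prediction window, and feeds the concatenation
``[s1, s2, target BG, tau, ToD average (, planned carbs)]`` through a ReLU
fully connected head with a linear output: the estimated carbs or dose.

The residual stack reuses that chain as a repeating block: each block emits a
72-step *backcast* of its glucose input and a scalar *forecast*; the backcast
is subtracted from the block's glucose input to form the next block's input,
and the forecasts are summed into the final estimate.  With the (default)
joint head, a single linear layer of width 73 emits backcast and forecast
together.  Per-block backcast/forecast loss terms add supervision.

Everything operates on scaled quantities; inference is deterministic
(dropout is train-time only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field, replace
from typing import NamedTuple, Optional

import numpy as np

from .autodiff import Tensor, concat, glorot, lstm_seq, mse, parameter
from .example_builder import HISTORY_STEPS, RecommendationExample
from .preprocessing import Scaler

#: horizon feature mapped linearly from [30, 90] min to [0, 1]
TAU_LO, TAU_HI = 30.0, 90.0


@dataclass
class LSTMChainConfig:
    state_size: int = 32
    fc_layers: int = 3
    fc_width: int = 64
    dropout: float = 0.0
    history_channels: int = 4     # bg, carbs, bolus, basal
    window_channels: int = 3      # carbs, bolus, basal (no bg in the future)
    extra_features: int = 3       # target bg, tau, ToD average (+ planned carbs)

    def __post_init__(self):
        if self.state_size <= 0 or self.fc_width <= 0:
            raise ValueError("state_size and fc_width must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0,1)")


@dataclass
class ResidualStackConfig:
    blocks: int = 5
    block: LSTMChainConfig = field(default_factory=LSTMChainConfig)
    backcast_length: int = HISTORY_STEPS
    joint_head: bool = True
    share_weights: bool = False

    def __post_init__(self):
        if self.blocks < 1:
            raise ValueError("a residual stack needs at least one block")


#: tuned (fc_layers, dropout) for the chain model, per scenario and class
CHAIN_DEFAULTS = {
    ("carbs_pm_b", "inertial"): (3, 0.1), ("carbs_pm_b", "unrestricted"): (3, 0.1),
    ("carbs_m_b", "inertial"): (3, 0.1), ("carbs_m_b", "unrestricted"): (3, 0.1),
    ("bolus_pm_c", "inertial"): (3, 0.0), ("bolus_pm_c", "unrestricted"): (2, 0.3),
    ("bolus_p_c", "inertial"): (2, 0.2), ("bolus_p_c", "unrestricted"): (2, 0.5),
}

#: tuned (blocks, fc_layers, dropout) for the residual stack
STACK_DEFAULTS = {
    ("carbs_pm_b", "inertial"): (5, 2, 0.3), ("carbs_pm_b", "unrestricted"): (3, 3, 0.3),
    ("carbs_m_b", "inertial"): (5, 2, 0.3), ("carbs_m_b", "unrestricted"): (3, 3, 0.3),
    ("bolus_pm_c", "inertial"): (5, 4, 0.2), ("bolus_pm_c", "unrestricted"): (4, 4, 0.2),
    ("bolus_p_c", "inertial"): (5, 4, 0.5), ("bolus_p_c", "unrestricted"): (3, 5, 0.2),
}


def default_chain_config(scenario: str, example_class: str) -> LSTMChainConfig:
    fc_layers, dropout = CHAIN_DEFAULTS[(scenario, example_class)]
    cfg = LSTMChainConfig(fc_layers=fc_layers, dropout=dropout,
                          extra_features=4 if scenario == "bolus_p_c" else 3)
    if scenario == "carbs_m_b":   # halved widths for the small-data scenario
        cfg = replace(cfg, state_size=16, fc_width=32)
    return cfg


def default_stack_config(scenario: str, example_class: str) -> ResidualStackConfig:
    blocks, fc_layers, dropout = STACK_DEFAULTS[(scenario, example_class)]
    block = LSTMChainConfig(fc_layers=fc_layers, dropout=dropout,
                            extra_features=4 if scenario == "bolus_p_c" else 3)
    if scenario == "carbs_m_b":
        block = replace(block, state_size=16, fc_width=32)
    return ResidualStackConfig(blocks=blocks, block=block)


# ---------------------------------------------------------------------------
# Parameter initialization
# ---------------------------------------------------------------------------

def _init_chain(cfg: LSTMChainConfig, rng: np.random.Generator,
                out_width: int, prefix: str = "") -> dict:
    H = cfg.state_size
    p = {}
    p[prefix + "lstm1.W"] = parameter(glorot(rng, cfg.history_channels + H, 4 * H))
    b1 = np.zeros(4 * H)
    b1[H:2 * H] = 1.0           # forget-gate bias
    p[prefix + "lstm1.b"] = parameter(b1)
    p[prefix + "proj.W"] = parameter(glorot(rng, H, 2 * H))
    p[prefix + "proj.b"] = parameter(np.zeros(2 * H))
    p[prefix + "lstm2.W"] = parameter(glorot(rng, cfg.window_channels + H, 4 * H))
    b2 = np.zeros(4 * H)
    b2[H:2 * H] = 1.0
    p[prefix + "lstm2.b"] = parameter(b2)
    width_in = 2 * H + cfg.extra_features
    for i in range(cfg.fc_layers):
        p[prefix + f"fc{i}.W"] = parameter(glorot(rng, width_in, cfg.fc_width))
        p[prefix + f"fc{i}.b"] = parameter(np.zeros(cfg.fc_width))
        width_in = cfg.fc_width
    p[prefix + "out.W"] = parameter(glorot(rng, width_in, out_width))
    p[prefix + "out.b"] = parameter(np.zeros(out_width))
    return p


# ---------------------------------------------------------------------------
# Forward passes
# ---------------------------------------------------------------------------

def _chain_hidden(params: dict, prefix: str, cfg: LSTMChainConfig,
                  bg: Tensor, hist_rest: np.ndarray, win: np.ndarray,
                  extras: np.ndarray, train: bool, drop_rng):
    """Shared trunk: two chained encoders plus the FC hidden layers.

    ``bg`` is a (B, 72) tensor (differentiable inside a residual stack);
    the other inputs are constants.  Returns (last hidden, s1, s2).
    """
    H = cfg.state_size
    s1 = lstm_seq(hist_rest, params[prefix + "lstm1.W"],
                  params[prefix + "lstm1.b"], bg=bg)
    hc = s1 @ params[prefix + "proj.W"] + params[prefix + "proj.b"]
    h0, c0 = hc.cols(0, H), hc.cols(H, 2 * H)
    s2 = lstm_seq(win, params[prefix + "lstm2.W"], params[prefix + "lstm2.b"],
                  h0=h0, c0=c0)
    x = concat([s1, s2, Tensor(extras)])
    for i in range(cfg.fc_layers):
        x = (x @ params[prefix + f"fc{i}.W"] + params[prefix + f"fc{i}.b"]).relu()
        if train and cfg.dropout > 0:
            mask = (drop_rng.random(x.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            x = x * Tensor(mask)
    return x, s1, s2


@dataclass
class BlockOutput:
    backcast: Tensor      # (B, 72) scaled glucose reconstruction
    forecast: Tensor      # (B, 1) scaled label contribution
    s1: Tensor
    s2: Tensor
    bg_input: Tensor      # the glucose input this block received


class LSTMChain:
    """Plain two-LSTM chain recommender."""

    kind = "lstm"

    def __init__(self, config: LSTMChainConfig, seed: int = 0,
                 params: Optional[dict] = None):
        self.config = config
        self.params = params if params is not None else _init_chain(
            config, np.random.default_rng(seed), out_width=1)

    def forward(self, hist: np.ndarray, win: np.ndarray, extras: np.ndarray,
                train: bool = False, drop_rng=None) -> Tensor:
        cfg = self.config
        bg = Tensor(hist[:, :, 0])
        x, _, _ = _chain_hidden(self.params, "", cfg, bg, hist[:, :, 1:],
                                win, extras, train, drop_rng)
        return x @ self.params["out.W"] + self.params["out.b"]


class ResidualStack:
    """Deep residual stack of two-LSTM-chain blocks (backcast/forecast)."""

    kind = "nbeats"

    def __init__(self, config: ResidualStackConfig, seed: int = 0,
                 params: Optional[dict] = None):
        self.config = config
        if params is not None:
            self.params = params
        else:
            rng = np.random.default_rng(seed)
            L = config.backcast_length
            out_w = L + 1 if config.joint_head else None
            self.params = {}
            n_param_blocks = 1 if config.share_weights else config.blocks
            for b in range(n_param_blocks):
                if config.joint_head:
                    self.params.update(_init_chain(config.block, rng, out_w,
                                                   prefix=f"block{b}."))
                else:
                    p = _init_chain(config.block, rng, L, prefix=f"block{b}.")
                    # separate forecast head
                    w_in = config.block.fc_width if config.block.fc_layers else \
                        2 * config.block.state_size + config.block.extra_features
                    p[f"block{b}.fore.W"] = parameter(glorot(rng, w_in, 1))
                    p[f"block{b}.fore.b"] = parameter(np.zeros(1))
                    self.params.update(p)

    def _prefix(self, b: int) -> str:
        return "block0." if self.config.share_weights else f"block{b}."

    def forward(self, hist: np.ndarray, win: np.ndarray, extras: np.ndarray,
                train: bool = False, drop_rng=None):
        cfg = self.config
        L = cfg.backcast_length
        bg = Tensor(hist[:, :, 0])
        blocks: list[BlockOutput] = []
        estimate = None
        for b in range(cfg.blocks):
            pre = self._prefix(b)
            x, s1, s2 = _chain_hidden(self.params, pre, cfg.block, bg,
                                      hist[:, :, 1:], win, extras, train, drop_rng)
            if cfg.joint_head:
                y = x @ self.params[pre + "out.W"] + self.params[pre + "out.b"]
                backcast, forecast = y.cols(0, L), y.cols(L, L + 1)
            else:
                backcast = x @ self.params[pre + "out.W"] + self.params[pre + "out.b"]
                forecast = x @ self.params[pre + "fore.W"] + self.params[pre + "fore.b"]
            blocks.append(BlockOutput(backcast=backcast, forecast=forecast,
                                      s1=s1, s2=s2, bg_input=bg))
            estimate = forecast if estimate is None else estimate + forecast
            bg = bg - backcast
        return estimate, blocks


# ---------------------------------------------------------------------------
# Loss and bookkeeping
# ---------------------------------------------------------------------------

def training_loss(estimate: Tensor, blocks, label: np.ndarray,
                  alpha: float = 1.0, beta: float = 1.0) -> Tensor:
    """MSE to the recorded label, plus (for stacks) per-block terms: the
    cumulative forecast through block b against the label, and each block's
    backcast against its glucose input, both averaged over blocks."""
    y = Tensor(np.asarray(label, dtype=float).reshape(-1, 1))
    loss = mse(estimate, y)
    if blocks:
        nb = len(blocks)
        cum = None
        for blk in blocks:
            cum = blk.forecast if cum is None else cum + blk.forecast
            if alpha:
                loss = loss + Tensor(alpha / nb) * mse(cum, y)
            if beta:
                loss = loss + Tensor(beta / nb) * mse(blk.backcast, blk.bg_input)
    return loss


def count_parameters(obj) -> int:
    """Exact number of trainable scalars in a model or config."""
    if hasattr(obj, "params"):
        return sum(p.data.size for p in obj.params.values())
    if isinstance(obj, LSTMChainConfig):
        return count_parameters(LSTMChain(obj))
    if isinstance(obj, ResidualStackConfig):
        return count_parameters(ResidualStack(obj))
    raise TypeError(f"cannot count parameters of {type(obj)!r}")


# ---------------------------------------------------------------------------
# Example encoding (physical units -> scaled model inputs)
# ---------------------------------------------------------------------------

class EncodedExample(NamedTuple):
    history: np.ndarray    # (72, 4) scaled
    window: np.ndarray     # (T, 3) scaled
    extras: np.ndarray     # (E,) scaled
    label: float           # scaled


def encode_example(ex: RecommendationExample, scaler: Scaler) -> EncodedExample:
    hist = np.column_stack([
        scaler.scale(ex.history[:, 0], "bg"),
        scaler.scale(ex.history[:, 1], "carbs"),
        scaler.scale(ex.history[:, 2], "bolus"),
        scaler.scale(ex.history[:, 3], "basal"),
    ])
    win = np.column_stack([
        scaler.scale(ex.window_events[:, 0], "carbs"),
        scaler.scale(ex.window_events[:, 1], "bolus"),
        scaler.scale(ex.window_events[:, 2], "basal"),
    ])
    extras = [float(scaler.scale(ex.target_bg, "bg")),
              (ex.tau - TAU_LO) / (TAU_HI - TAU_LO),
              float(scaler.scale(ex.tod_avg, "label"))]
    if ex.planned_carbs is not None:
        extras.append(float(scaler.scale(ex.planned_carbs, "carbs")))
    return EncodedExample(history=hist, window=win,
                          extras=np.array(extras), label=float(scaler.scale(ex.label, "label")))


def lstm_chain_forward(example: EncodedExample, model: LSTMChain) -> float:
    """Scalar estimate (scaled units) for one encoded example."""
    out = model.forward(example.history[None], example.window[None],
                        example.extras[None])
    return float(out.data[0, 0])


def residual_stack_forward(example: EncodedExample, model: ResidualStack):
    """(estimate, per-block outputs) for one encoded example."""
    est, blocks = model.forward(example.history[None], example.window[None],
                                example.extras[None])
    return float(est.data[0, 0]), blocks


# ---------------------------------------------------------------------------
# Checkpoints: binary weights + JSON sidecar
# ---------------------------------------------------------------------------

def save_checkpoint(model, path, scaler: Optional[Scaler] = None,
                    seed: Optional[int] = None, meta: Optional[dict] = None) -> None:
    path = str(path)
    np.savez_compressed(path if path.endswith(".npz") else path + ".npz",
                        **{k: p.data for k, p in model.params.items()})
    side = {"kind": model.kind, "seed": seed, "meta": meta or {}}
    if model.kind == "lstm":
        side["config"] = asdict(model.config)
    else:
        side["config"] = asdict(model.config)
    if scaler is not None:
        side["scaler"] = {"mins": scaler.mins, "maxs": scaler.maxs}
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as fh:
        json.dump(side, fh, indent=1)


def load_checkpoint(path):
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        side = json.load(fh)
    z = np.load(base + ".npz")
    params = {k: parameter(z[k]) for k in z.files}
    if side["kind"] == "lstm":
        model = LSTMChain(LSTMChainConfig(**side["config"]), params=params)
    else:
        cfg = side["config"]
        cfg["block"] = LSTMChainConfig(**cfg["block"])
        model = ResidualStack(ResidualStackConfig(**cfg), params=params)
    scaler = None
    if "scaler" in side:
        scaler = Scaler(mins=side["scaler"]["mins"], maxs=side["scaler"]["maxs"])
    return model, scaler, side
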