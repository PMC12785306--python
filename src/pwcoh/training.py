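"""Unsupervised training and validation loop for the I/Q enhancer.

Each optimization step draws one acquisition (uniformly), one reference
frame (uniformly among non-center frames with a non-empty decorrelated
target set), crops one shared 256×256 window from the reference and its
targets, runs the enhancer on the reference patch, and minimizes the
selection-gated coherence loss (or the all-pairs / MSE baselines) with
AdamW under a cosine learning-rate cycle between 1e−4 and 1e−7 every
20,000 steps (batch size 1, 40,000 steps by default — desk-scale runs use
far smaller values of all three).

Validation holds out the center (0°) frame: it is zero-padded to the
configured canvas (never resized), enhanced, un-padded, and scored with
the same data-source-specific N_excl against the center reference's
target frames; the loss is averaged over all validation acquisitions.
The best-validation parameters are checkpointed in memory. Every source
of randomness flows from the single configured seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .acquisition import FrameSet, random_crop, unpad, zero_pad
from .das import coherent_compound
from .loss import (
    coherence_loss,
    coherence_loss_grad,
    mse_loss,
    mse_loss_grad,
)
from .network import (
    NetworkSpec,
    UNet,
    build_enhancer,
    channels_to_complex,
    complex_to_channels,
)
from .selection import FrameSelection

__all__ = ["TrainConfig", "TrainState", "AdamW", "lr_at", "make_training_example", "train", "validate"]

LOSS_MODES = ("optimized", "fixed_dcl", "mse")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults are the full-scale recipe)."""

    lr_high: float = 1e-4
    lr_low: float = 1e-7
    cycle_steps: int = 20_000
    total_steps: int = 40_000
    batch_size: int = 1
    patch: int = 256
    seed: int = 0
    loss_mode: str = "optimized"
    schedule: str = "cosine"  # or 'triangular'
    val_every: int = 500
    val_pad: int = 1024
    weight_decay: float = 1e-2
    network: NetworkSpec = field(default_factory=NetworkSpec)

    def __post_init__(self) -> None:
        if not self.lr_high > self.lr_low > 0:
            raise ValueError("need lr_high > lr_low > 0")
        if self.total_steps < 1 or self.cycle_steps < 2:
            raise ValueError("total_steps >= 1 and cycle_steps >= 2 required")
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"loss_mode must be one of {LOSS_MODES}")
        if self.schedule not in ("cosine", "triangular"):
            raise ValueError("schedule must be 'cosine' or 'triangular'")


@dataclass
class TrainState:
    """Per-step training history and the best-validation checkpoint."""

    step: int = 0
    lr: float = 0.0
    train_loss: list[float] = field(default_factory=list)
    lr_history: list[float] = field(default_factory=list)
    val_steps: list[int] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_cnr: list[float] = field(default_factory=list)
    best_val: float = np.inf
    best_state: dict | None = None
    pair_log: list[tuple[int, int, tuple[int, ...]]] = field(default_factory=list)


def lr_at(step: int, cfg: TrainConfig) -> float:
    """Learning rate at ``step``: a restarting cycle from lr_high to lr_low.

    Cosine (default): ``lr_low + (lr_high−lr_low)·(1+cos(π·p/(C−1)))/2``
    with ``p = step mod C``; starts each cycle at lr_high and reaches
    lr_low on its last step. The triangular variant descends linearly.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    p = step % cfg.cycle_steps
    frac = p / (cfg.cycle_steps - 1)
    if cfg.schedule == "cosine":
        w = 0.5 * (1.0 + np.cos(np.pi * frac))
    else:
        w = 1.0 - frac
    return cfg.lr_low + (cfg.lr_high - cfg.lr_low) * float(w)


class AdamW:
    """Adam with decoupled weight decay, operating on a UNet's parameters."""

    def __init__(self, net: UNet, weight_decay: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.net = net
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {name: np.zeros_like(getattr(layer, attr))
                  for name, layer, attr in net.parameters()}
        self.v = {name: np.zeros_like(getattr(layer, attr))
                  for name, layer, attr in net.parameters()}

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for name, layer, attr in self.net.parameters():
            p = getattr(layer, attr)
            g = layer.dW if attr == "W" else layer.db
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            # decoupled decay: applied to the parameter, not the gradient
            p -= lr * self.weight_decay * p
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def make_training_example(
    frame_set: FrameSet,
    selection: FrameSelection,
    rng: np.random.Generator,
    patch: int = 256,
):
    """Draw (reference patch, target patches, reference index) for one step.

    The reference is drawn uniformly from the non-center frames; its
    targets come from the precomputed selection; one shared crop window is
    applied to reference and targets alike. Returns ``None`` (with a
    warning) when the drawn reference has no valid targets.
    """
    candidates = sorted(selection.valid_targets.keys())
    i = int(candidates[rng.integers(0, len(candidates))])
    targets = selection.valid_targets[i]
    if not targets:
        warnings.warn(f"reference {i} has no valid targets; example skipped", stacklevel=2)
        return None
    cropped = random_crop(frame_set, size=(patch, patch), rng=rng)
    top = int(round((cropped.grid.z0 - frame_set.grid.z0) / frame_set.grid.dz))
    left = int(round((cropped.grid.x0 - frame_set.grid.x0) / frame_set.grid.dx))
    ref = cropped.frames[i]
    tgt = [cropped.frames[j] for j in sorted(targets)]
    return ref, tgt, i, (top, left)


def _forward_complex(net: UNet, frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    out_ch = net.forward(complex_to_channels(frame))
    return out_ch, channels_to_complex(out_ch)


def _backward_complex(net: UNet, grad_complex: np.ndarray) -> None:
    dy = np.stack([grad_complex.real, grad_complex.imag]).astype(net.spec.dtype)
    net.backward(dy)


def validate(
    net: UNet,
    frame_set: FrameSet,
    selection: FrameSelection,
    pad_target: int = 1024,
) -> tuple[float, np.ndarray]:
    """Validation loss on the held-out 0° frame, plus the enhanced frame.

    The center frame is zero-padded to ``pad_target``², enhanced,
    un-padded, and scored with the selection-gated coherence loss against
    the center reference's targets (full frames, original indexing).
    """
    center = frame_set.center_index
    padded, placement = zero_pad(frame_set.frames[center], (pad_target, pad_target))
    _, out = _forward_complex(net, padded)
    enhanced = unpad(out, placement)
    targets = [frame_set.frames[j] for j in sorted(selection.validation_targets)]
    report = coherence_loss(enhanced, targets)
    return report.value, enhanced


def train(
    datasets: list[FrameSet],
    selections: list[FrameSelection],
    cfg: TrainConfig,
    val_datasets: list[FrameSet] | None = None,
    val_selections: list[FrameSelection] | None = None,
) -> tuple[UNet, TrainState]:
    """Run the seeded optimization loop; returns the network and its history.

    ``loss_mode='optimized'`` uses each acquisition's decorrelation-gated
    target sets; ``'fixed_dcl'`` uses all non-reference frames (the
    all-pairs ablation, i.e. the selection with N_excl forced to 1);
    ``'mse'`` regresses onto the coherently compounded frame (the
    supervised baseline wiring). Non-finite losses abort with a state dump
    in the raised error.
    """
    if len(datasets) != len(selections):
        raise ValueError("one FrameSelection per dataset required")
    if val_datasets is None:
        val_datasets, val_selections = datasets, selections

    if cfg.loss_mode == "fixed_dcl":
        from .selection import FrameSelection as FS, select_target_frames

        selections = [
            FS(
                z_fov=s.z_fov,
                theta_dec=s.theta_dec,
                n_excl=1,
                valid_targets={
                    i: select_target_frames(i, 1, len(d), frozenset({s.center_index}))
                    for i in range(len(d))
                    if i != s.center_index
                },
                validation_targets=select_target_frames(s.center_index, 1, len(d)),
                n_pulse_cycles=s.n_pulse_cycles,
                center_index=s.center_index,
            )
            for d, s in zip(datasets, selections)
        ]

    rng = np.random.default_rng(cfg.seed)
    net = build_enhancer(cfg.network, seed=int(rng.integers(0, 2**31 - 1)))
    opt = AdamW(net, weight_decay=cfg.weight_decay)
    state = TrainState()
    compounds = [coherent_compound(d) for d in datasets] if cfg.loss_mode == "mse" else None

    for step in range(cfg.total_steps):
        d_idx = int(rng.integers(0, len(datasets)))
        fs = datasets[d_idx]
        sel = selections[d_idx]
        example = make_training_example(fs, sel, rng, patch=cfg.patch)
        if example is None:
            continue
        ref, targets, ref_idx, (top, left) = example
        net.zero_grad()
        _, pred = _forward_complex(net, ref)
        if cfg.loss_mode == "mse":
            gt = compounds[d_idx][top : top + cfg.patch, left : left + cfg.patch]
            loss_value = mse_loss(pred, gt)
            grad = mse_loss_grad(pred, gt)
        else:
            report = coherence_loss(pred, targets)
            loss_value = report.value
            grad = coherence_loss_grad(pred, targets)
        if not np.isfinite(loss_value):
            raise FloatingPointError(
                f"non-finite training loss at step {step}: {loss_value!r}; state: {state!r}"
            )
        _backward_complex(net, grad)
        lr = lr_at(step, cfg)
        opt.step(lr)
        state.step = step + 1
        state.lr = lr
        state.lr_history.append(float(lr))
        state.train_loss.append(float(loss_value))
        state.pair_log.append((d_idx, ref_idx, tuple(sorted(sel.valid_targets[ref_idx]))))

        if (step + 1) % cfg.val_every == 0 or step + 1 == cfg.total_steps:
            vals = [
                validate(net, vd, vs, pad_target=cfg.val_pad)[0]
                for vd, vs in zip(val_datasets, val_selections)
            ]
            v = float(np.mean(vals))
            state.val_steps.append(step + 1)
            state.val_loss.append(v)
            if v < state.best_val:
                state.best_val = v
                state.best_state = net.state_dict()

    if state.best_state is not None:
        net.load_state_dict(state.best_state)
    return net, state
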