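"""Model/Results interface over the unsupervised enhancer.

:class:`PlaneWaveEnhancer` is built from data (beamformed frame sets, or
raw acquisitions via :meth:`PlaneWaveEnhancer.from_acquisitions`); its
:meth:`~PlaneWaveEnhancer.fit` runs the seeded coherence-loss training
loop and returns a :class:`PlaneWaveEnhancerResults` carrying the trained
network, the loss histories, the per-dataset frame selections, and a
``summary()`` table. Enhancement of new frames and history plotting hang
off the results object.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .acquisition import FrameSet, maxabs_normalize, unpad, zero_pad
from .das import BeamformConfig, beamform_all
from .loss import coherence_loss
from .metrics import ROIPair, cnr, envelope, gcnr
from .network import UNet, enhance
from .selection import FrameSelection, selection_for_acquisition
from .training import TrainConfig, TrainState, train, validate

__all__ = ["PlaneWaveEnhancer", "PlaneWaveEnhancerResults"]


class PlaneWaveEnhancer:
    """Unsupervised clutter-suppressing enhancer for single plane-wave frames.

    Parameters
    ----------
    frame_sets : list of FrameSet
        Per-angle complex I/Q images (training corpus). Normalized
        internally with one global max-abs scale per set.
    probes : list of ProbeConfig
        One probe description per frame set (drives the physics-based
        frame selection).
    config : TrainConfig, optional
        Optimization hyperparameters; defaults are the full-scale recipe.
    n_pulse_cycles : float
        Pulse-length multiplier of the decorrelation condition (default
        2: a 50% fractional-bandwidth pulse spans about two cycles).
    """

    def __init__(self, frame_sets, probes, config: TrainConfig | None = None,
                 n_pulse_cycles: float = 2.0):
        if len(frame_sets) != len(probes):
            raise ValueError("one ProbeConfig per FrameSet required")
        self.frame_sets = [maxabs_normalize(fs) for fs in frame_sets]
        self.probes = list(probes)
        self.config = config or TrainConfig()
        self.selections: list[FrameSelection] = [
            selection_for_acquisition(p, fs.angles, n_pulse_cycles)
            for p, fs in zip(self.probes, self.frame_sets)
        ]

    @classmethod
    def from_acquisitions(cls, acquisitions, beamform_cfgs, config: TrainConfig | None = None,
                          n_pulse_cycles: float = 2.0) -> "PlaneWaveEnhancer":
        """Beamform raw acquisitions (DAS, dynamic focusing) and build the model."""
        if not isinstance(beamform_cfgs, (list, tuple)):
            beamform_cfgs = [beamform_cfgs] * len(acquisitions)
        frame_sets = [beamform_all(a, c) for a, c in zip(acquisitions, beamform_cfgs)]
        return cls(frame_sets, [a.probe for a in acquisitions], config, n_pulse_cycles)

    def fit(self, seed: int | None = None) -> "PlaneWaveEnhancerResults":
        """Train the enhancer; fully reproducible given the seed."""
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        net, state = train(self.frame_sets, self.selections, cfg)
        return PlaneWaveEnhancerResults(self, net, state, cfg)


class PlaneWaveEnhancerResults:
    """Fitted enhancer: network, training history, and evaluation helpers."""

    def __init__(self, model: PlaneWaveEnhancer, network: UNet, state: TrainState,
                 config: TrainConfig):
        self.model = model
        self.network = network
        self.state = state
        self.config = config

    @property
    def loss_history(self) -> pd.DataFrame:
        """Per-step train loss and the validation checkpoints."""
        df = pd.DataFrame(
            {"step": np.arange(1, len(self.state.train_loss) + 1),
             "lr": self.state.lr_history,
             "train_loss": self.state.train_loss}
        )
        val = pd.DataFrame({"step": self.state.val_steps, "val_loss": self.state.val_loss})
        return df.merge(val, on="step", how="left")

    def enhance_frame(self, frame: np.ndarray, pad: bool = True) -> np.ndarray:
        """Enhance one complex I/Q frame (zero-padding to the validation canvas)."""
        if not pad:
            return enhance(self.network, frame)
        padded, placement = zero_pad(frame, (self.config.val_pad, self.config.val_pad))
        return unpad(enhance(self.network, padded), placement)

    def enhance_center(self, frame_set: FrameSet) -> np.ndarray:
        """Enhance the held-out 0° frame of a (normalized) frame set."""
        fs = maxabs_normalize(frame_set) if frame_set.normalization_scale == 1.0 else frame_set
        return self.enhance_frame(fs.frames[fs.center_index])

    def evaluate(self, frame_set: FrameSet, rois: ROIPair, probe=None) -> pd.Series:
        """CNR/gCNR of the enhanced 0° frame versus its single-PW input."""
        fs = maxabs_normalize(frame_set) if frame_set.normalization_scale == 1.0 else frame_set
        single = envelope(fs.frames[fs.center_index])
        enhanced = envelope(self.enhance_center(fs))
        return pd.Series(
            {
                "cnr_das_1pw": cnr(single, rois),
                "gcnr_das_1pw": gcnr(single, rois),
                "cnr_enhanced": cnr(enhanced, rois),
                "gcnr_enhanced": gcnr(enhanced, rois),
            }
        )

    def summary(self) -> str:
        s = self.state
        lines = [
            "Plane-wave coherence enhancer — fit summary",
            "=" * 47,
            f"loss mode:          {self.config.loss_mode}",
            f"steps run:          {s.step}",
            f"network parameters: {self.network.n_parameters}",
            f"final train loss:   {s.train_loss[-1]: .4f}" if s.train_loss else "",
            f"best val loss:      {s.best_val: .4f}" if np.isfinite(s.best_val) else "",
            "",
            "per-dataset frame selection:",
        ]
        for i, sel in enumerate(self.model.selections):
            lines.append(
                f"  dataset {i}: z_FOV = {sel.z_fov * 1e3:7.2f} mm, "
                f"theta_dec = {sel.theta_dec:6.3f} deg, N_excl = {sel.n_excl}"
            )
        return "\n".join(line for line in lines if line != "")

    def plot_history(self, ax=None):
        """Train/validation loss curves (matplotlib axes returned)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.loss_history
        ax.plot(df["step"], df["train_loss"], label="train", lw=0.8)
        ax.plot(self.state.val_steps, self.state.val_loss, "o-", label="validation")
        ax.set_xlabel("step")
        ax.set_ylabel("coherence loss")
        ax.legend()
        return ax
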