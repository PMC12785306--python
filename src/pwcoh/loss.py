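"""Coherence loss, its selection-gated variant, and the MSE baseline.

The coherence loss between a network prediction f(P_i) and a set of target
frames P_t is the negative mean normalized cross-correlation

    L = −(1/|T|) Σ_t  Re⟨f(P_i), P_t*⟩ / sqrt(⟨f, f*⟩ · ⟨P_t, P_t*⟩)

computed on complex I/Q patches. Maximizing correlation with the selected
(decorrelated-clutter) targets preserves angle-coherent tissue while
suppressing angle-incoherent clutter, so minimizing L does the enhancement.

The complex inner product is reduced to a real scalar via its real part
(``mode='real'``): a sign-flipped frame then scores −1, preserving
phase-opposition information; the magnitude reduction is available as
``mode='magnitude'`` for ablations.

Because the package trains its network with hand-derived backpropagation,
each loss also exposes its analytic gradient with respect to the
prediction (as a complex array ``g`` such that a real perturbation ``δ``
changes the loss by ``Re Σ conj(g)·δ``); the gradients are validated
against finite differences in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import FrameSet
from .selection import FrameSelection

__all__ = [
    "LossReport",
    "normalized_xcorr",
    "coherence_loss",
    "coherence_loss_grad",
    "optimized_coherence_loss",
    "mse_loss",
    "mse_loss_grad",
]

EPS = 1e-12


@dataclass(frozen=True)
class LossReport:
    """Scalar loss plus its per-target decomposition."""

    value: float
    per_target_terms: tuple[float, ...]
    n_pairs: int

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


def _energy(a: np.ndarray) -> float:
    return float(np.sum(a.real**2 + a.imag**2))


def normalized_xcorr(a: np.ndarray, b: np.ndarray, mode: str = "real") -> float:
    """Normalized cross-correlation of two complex images, in [−1, 1].

    ``Re⟨a, b*⟩ / sqrt(⟨a, a*⟩·⟨b, b*⟩)`` with ⟨·,·⟩ summing elementwise
    products over all pixels. Invariant to positive scaling of either
    argument. A zero-energy argument gets an ε-stabilized denominator and
    a warning (both zero → 0).
    """
    a = np.asarray(a, dtype=np.complex128)
    b = np.asarray(b, dtype=np.complex128)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    inner = np.sum(a * np.conj(b))
    num = float(np.real(inner)) if mode == "real" else float(np.abs(inner))
    if mode not in ("real", "magnitude"):
        raise ValueError("mode must be 'real' or 'magnitude'")
    den = np.sqrt(_energy(a) * _energy(b))
    if den < EPS:
        warnings.warn("zero-energy argument in normalized_xcorr; returning stabilized value",
                      stacklevel=2)
        den += EPS
    return num / den


def coherence_loss(
    prediction: np.ndarray, targets: list[np.ndarray] | tuple[np.ndarray, ...], mode: str = "real"
) -> LossReport:
    """Negative mean normalized cross-correlation against the target frames."""
    if len(targets) == 0:
        raise ValueError(
            "coherence loss needs at least one target frame "
            "(an empty set signals an over-aggressive N_excl)"
        )
    terms = tuple(normalized_xcorr(prediction, t, mode=mode) for t in targets)
    return LossReport(value=-float(np.mean(terms)), per_target_terms=terms, n_pairs=len(terms))


def coherence_loss_grad(
    prediction: np.ndarray, targets: list[np.ndarray] | tuple[np.ndarray, ...]
) -> np.ndarray:
    """Analytic gradient of :func:`coherence_loss` w.r.t. the prediction.

    For one target t with D = sqrt(E_p E_t) and c = Re⟨p, t*⟩ / D the
    gradient of c in the (real, imag) parametrization of p is
    ``(t − (Re⟨p, t*⟩ / E_p) · p) / D``; the loss gradient is the negative
    mean over targets. Only the ``'real'`` reduction is differentiated
    (it is the training default).
    """
    p = np.asarray(prediction, dtype=np.complex128)
    grad = np.zeros_like(p)
    ep = _energy(p)
    for t in targets:
        t = np.asarray(t, dtype=np.complex128)
        et = _energy(t)
        den = np.sqrt(ep * et)
        if den < EPS:
            den += EPS
        re_inner = float(np.real(np.sum(p * np.conj(t))))
        grad += (t - (re_inner / max(ep, EPS)) * p) / den
    return -grad / len(targets)


def optimized_coherence_loss(
    prediction: np.ndarray,
    frame_set: FrameSet,
    reference_index: int,
    selection: FrameSelection,
    mode: str = "real",
) -> LossReport:
    """Coherence loss restricted to the selection's valid targets.

    With ``N_excl = 1`` every non-reference frame is a target and the loss
    degenerates exactly to the all-pairs (fixed) variant, the ablation
    baseline.
    """
    if reference_index == selection.center_index:
        indices = selection.validation_targets
    else:
        indices = selection.valid_targets.get(reference_index, set())
    if not indices:
        raise ValueError(
            f"no valid target frames for reference {reference_index} at "
            f"N_excl = {selection.n_excl}; reduce N_excl or widen the angle span"
        )
    targets = [frame_set.frames[j] for j in sorted(indices)]
    return coherence_loss(prediction, targets, mode=mode)


def mse_loss(prediction: np.ndarray, reference: np.ndarray) -> float:
    """Mean squared modulus of the difference (supervised baseline loss)."""
    prediction = np.asarray(prediction)
    reference = np.asarray(reference)
    if prediction.shape != reference.shape:
        raise ValueError(f"shape mismatch: {prediction.shape} vs {reference.shape}")
    d = prediction - reference
    return float(np.mean(d.real**2 + d.imag**2))


def mse_loss_grad(prediction: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Gradient of :func:`mse_loss` w.r.t. the prediction (complex array)."""
    d = np.asarray(prediction) - np.asarray(reference)
    return 2.0 * d / d.size
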