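"""Per-voxel signal conditioning: phase handling, filtering, and the GLM.

The pipeline mirrors standard high-resolution BOLD processing: temporal
phase unwrapping, then phase regression (ordinary least squares of the
magnitude time series on the unwrapped phase, keeping the residual) to
suppress macrovascular signal — large veins impose phase fluctuations
while microvascular/tissue signal is phase-neutral — then zero-phase
Butterworth filtering (band-pass 0.01-0.1 Hz for rest, high-pass 0.01 Hz
for task), and finally a GLM with the canonical double-gamma HRF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

__all__ = [
    "GLMDesign",
    "ActivationEstimate",
    "unwrap_phase",
    "phase_regress",
    "bandpass",
    "highpass",
    "double_gamma_hrf",
    "make_task_design",
    "glm_fit",
]


def unwrap_phase(ts: np.ndarray, axis: int = -1) -> np.ndarray:
    """Temporally unwrap a phase time series (radians).

    Successive differences are forced into (-pi, pi] by adding integer
    multiples of 2*pi; wrapping the output back mod 2*pi recovers the input.
    """
    return np.unwrap(np.asarray(ts, dtype=float), axis=axis)


def phase_regress(magnitude: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """Remove the phase-correlated (macrovascular) part of a magnitude series.

    Ordinary least squares of magnitude on [1, phase]; the residual plus the
    voxel mean is returned, so the output has zero sample correlation with
    the phase regressor but keeps the baseline level.  Applied per voxel,
    early in the pipeline (before temporal filtering).

    Both inputs are 1-D of equal length, or (sites x time) arrays regressed
    row-wise.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    phase = np.asarray(phase, dtype=float)
    if magnitude.shape != phase.shape:
        raise ValueError(f"shape mismatch: {magnitude.shape} vs {phase.shape}")
    if magnitude.ndim == 2:
        return np.vstack([phase_regress(m, p) for m, p in zip(magnitude, phase)])
    if magnitude.ndim != 1:
        raise ValueError("expected 1-D or 2-D input")

    p_centered = phase - phase.mean()
    denom = p_centered @ p_centered
    if denom < 1e-30 * max(1.0, float(np.abs(phase).max()) ** 2 * phase.size):
        warnings.warn(
            "phase regressor is constant; returning magnitude unchanged",
            RuntimeWarning,
            stacklevel=2,
        )
        return magnitude.copy()
    slope = (p_centered @ (magnitude - magnitude.mean())) / denom
    return magnitude - slope * p_centered


def _sos_filter(ts, sos, axis):
    return signal.sosfiltfilt(sos, np.asarray(ts, dtype=float), axis=axis)


def bandpass(
    ts: np.ndarray,
    TR_s: float,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    order: int = 4,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (default 0.01-0.1 Hz)."""
    fs = 1.0 / TR_s
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(
            f"high cutoff {high_hz} Hz is not below the Nyquist frequency "
            f"{nyq} Hz at TR={TR_s} s"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return _sos_filter(ts, sos, axis)


def highpass(
    ts: np.ndarray,
    TR_s: float,
    cutoff_hz: float = 0.01,
    order: int = 4,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth high-pass (default 0.01 Hz)."""
    fs = 1.0 / TR_s
    nyq = fs / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz) at TR={TR_s} s"
        )
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=fs, output="sos")
    return _sos_filter(ts, sos, axis)


def double_gamma_hrf(TR_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, sampled at TR.

    Difference of two gamma densities (delays 6 and 16 s, unit dispersions,
    undershoot ratio 1/6), peak normalised to 1.  The positive lobe peaks
    near 5 s, the undershoot near 15 s.
    """
    if TR_s <= 0:
        raise ValueError("TR must be > 0")
    # dense evaluation so the peak normalisation is stable for coarse TR
    t = np.arange(0, duration_s + 1e-9, TR_s)
    peak = stats.gamma.pdf(t, a=6.0, scale=1.0)
    undershoot = stats.gamma.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    dense = np.arange(0, duration_s, 0.01)
    hmax = np.max(stats.gamma.pdf(dense, a=6.0) - stats.gamma.pdf(dense, a=16.0) / 6.0)
    return h / hmax


@dataclass
class GLMDesign:
    """Design matrix plus column names; first column is the intercept."""

    matrix: np.ndarray  # (time x k)
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("design matrix / names mismatch")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                corr = np.corrcoef(self.matrix.T)
            bad = [
                (self.names[i], self.names[j])
                for i in range(len(self.names))
                for j in range(i + 1, len(self.names))
                if not np.isfinite(corr[i, j]) or abs(corr[i, j]) > 0.999
            ]
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    @property
    def n_time(self) -> int:
        return self.matrix.shape[0]

    @property
    def dof(self) -> int:
        return self.matrix.shape[0] - self.matrix.shape[1]


def make_task_design(paradigm, TR_s: float | None = None) -> GLMDesign:
    """Intercept + HRF-convolved task boxcar for a block paradigm.

    ``paradigm`` is a :class:`layervn.cortex.BlockParadigm`; the regressor is
    the ON/OFF boxcar convolved with the double-gamma HRF.
    """
    TR = paradigm.TR_s if TR_s is None else TR_s
    box = paradigm.boxcar()
    hrf = double_gamma_hrf(TR)
    reg = np.convolve(box, hrf)[: box.size]
    n = box.size
    return GLMDesign(np.column_stack([np.ones(n), reg]), ["intercept", "task"])


def make_seed_design(seed_ts: np.ndarray) -> GLMDesign:
    """Intercept + seed time course, for seed-based FC via the GLM."""
    seed_ts = np.asarray(seed_ts, dtype=float)
    if np.ptp(seed_ts) == 0:
        raise ValueError("seed time course has zero variance")
    return GLMDesign(np.column_stack([np.ones(seed_ts.size), seed_ts]), ["intercept", "seed"])


@dataclass
class ActivationEstimate:
    """OLS effect estimate for one regressor at one site."""

    beta: float
    percent_signal_change: float
    t_stat: float
    z_stat: float
    dof: int
    se: float
    baseline: float


_T_CAP = 1e8  # representation for a perfect, noise-free fit


def glm_fit(ts: np.ndarray, design: GLMDesign, regressor: str | int = 1) -> ActivationEstimate:
    """Fit one time series with OLS and report the named regressor's effect.

    t = beta / SE with the OLS standard error; z is the standard-normal
    quantile of the Student-t CDF at t; percent signal change references
    the regressor's peak-to-peak excursion to the voxel baseline (the
    intercept estimate).
    """
    y = np.asarray(ts, dtype=float)
    X = design.matrix
    if y.shape != (X.shape[0],):
        raise ValueError(f"time series length {y.shape} does not match design {X.shape}")
    k = design.names.index(regressor) if isinstance(regressor, str) else regressor

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = design.dof
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[k, k]))
    if se == 0.0:
        t = np.sign(beta[k]) * _T_CAP if beta[k] != 0 else 0.0
    else:
        t = float(beta[k] / se)
    # tail-probability-preserving conversion, via the survival function so
    # large t values stay monotone instead of saturating the CDF
    if abs(t) >= _T_CAP:
        z = np.sign(t) * _T_CAP
    else:
        tail = stats.t.sf(abs(t), dof)
        z = float(np.sign(t) * stats.norm.isf(tail)) if tail > 0 else float(np.sign(t)) * 40.0
    baseline = float(beta[0]) if design.names[0] == "intercept" else float(y.mean())
    ptp = float(np.ptp(X[:, k]))
    psc = 100.0 * beta[k] * ptp / baseline if baseline != 0 else np.nan
    return ActivationEstimate(
        beta=float(beta[k]),
        percent_signal_change=psc,
        t_stat=t,
        z_stat=z,
        dof=dof,
        se=se,
        baseline=baseline,
    )
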