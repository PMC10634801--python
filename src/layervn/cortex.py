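"""Synthetic cortical-column generator for velocity-nulled layer fMRI.

Ground-truth forward model of the depth-resolved, complex-valued BOLD
signal in a cortical column:

* laminar neural sources drive a tissue/capillary signal at their own depth;
* intracortical penetrating veins drain deeper-layer signal toward the pial
  surface (the "leakage" mechanism), with vein blood volume increasing
  linearly toward the surface;
* a large pial vein adds an extravascular perturbation ("blooming") to both
  magnitude and phase, falling off with the square of distance from the
  vessel surface — the phase part is what phase regression exploits;
* a velocity-nulling gradient attenuates each intravascular pool by
  exp(-b D*) with the pool's pseudo-diffusion coefficient (the pial
  blooming term is extravascular and is not attenuated);
* independent complex Gaussian noise.

Task runs use 30 s ON / 30 s OFF blocks at TR = 4 s; resting runs use
band-limited (0.01-0.1 Hz) Gaussian sources with a prescribed cross-region,
cross-layer correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg

from .preprocess import bandpass, double_gamma_hrf
from .vascular import (
    CAPILLARY,
    CORTICAL_ARTERY,
    PENETRATING_VEIN,
    VNGradientSpec,
    vn_attenuation,
)

__all__ = [
    "DEPTH_LO",
    "DEPTH_HI",
    "LAYER_WINDOWS",
    "BlockParadigm",
    "CorticalColumnSpec",
    "LaminarNetworkSpec",
    "ComplexTimeSeries",
    "n_volumes",
    "leakage_operator",
    "pial_extravascular_term",
    "double_peak_profile",
    "simulate_task",
    "simulate_rest",
    "make_subject_cohort",
    "default_network",
    "Subject",
]

#: Depth convention: 0 = GM/WM boundary, 1 = CSF/GM boundary; the sampling
#: grid deliberately extends slightly beyond the ribbon on both sides.
DEPTH_LO = -0.125
DEPTH_HI = 1.0625

#: Canonical cortical-depth sampling windows (projection fractions).
LAYER_WINDOWS = {
    "superficial": (0.85, 0.90),
    "middle": (0.45, 0.50),
    "deep": (0.10, 0.15),
    "overall": (0.10, 0.90),
}


@dataclass(frozen=True)
class BlockParadigm:
    """Block design: ON/OFF durations, block count, and sampling interval."""

    on_s: float = 30.0
    off_s: float = 30.0
    n_blocks: int = 18
    TR_s: float = 4.0
    press_rate_hz: float = 2.0  # annotation only

    def __post_init__(self) -> None:
        total = self.n_blocks * (self.on_s + self.off_s)
        if abs(total / self.TR_s - round(total / self.TR_s)) > 1e-9:
            raise ValueError(
                f"block length {self.on_s}+{self.off_s} s over {self.n_blocks} blocks "
                f"is not an integer number of TR={self.TR_s} s volumes"
            )

    @property
    def n_volumes(self) -> int:
        return int(round(self.n_blocks * (self.on_s + self.off_s) / self.TR_s))

    def boxcar(self) -> np.ndarray:
        """0/1 stimulus timing sampled at TR, ON first."""
        t = np.arange(self.n_volumes) * self.TR_s
        return ((t % (self.on_s + self.off_s)) < self.on_s).astype(float)


def n_volumes(paradigm: BlockParadigm) -> int:
    """Number of volumes in a block run: n_blocks * (on+off) / TR."""
    return paradigm.n_volumes


@dataclass(frozen=True)
class CorticalColumnSpec:
    """Geometry and compartment weights of one synthetic cortical column.

    Signal units are per cent of a baseline of 100 a.u., so an amplitude of
    2.0 is a 2% BOLD response.
    """

    n_depths: int = 20
    depth_lo: float = DEPTH_LO
    depth_hi: float = DEPTH_HI
    drain_fraction: float = 0.4  # fraction of vein signal carried up per depth step
    vein_gain: float = 0.6  # vein CBV weight at the pial surface
    arterial_gain: float = 0.1
    pial_diameter_mm: float = 0.3
    cortical_thickness_mm: float = 2.0
    pial_mag_gain: float = 1.0  # magnitude blooming strength at the surface voxel
    phase_rad_per_unit: float = 0.02  # phase per unit macrovascular magnitude
    baseline: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drain_fraction <= 1.0:
            raise ValueError(f"drain_fraction must be in [0, 1], got {self.drain_fraction}")
        if self.n_depths < 1:
            raise ValueError("need at least one depth")
        if min(self.vein_gain, self.arterial_gain, self.pial_mag_gain) < 0:
            raise ValueError("compartment weights must be >= 0")

    @property
    def depths(self) -> np.ndarray:
        """Bin-centre depth fractions, strictly increasing WM -> CSF."""
        w = (self.depth_hi - self.depth_lo) / self.n_depths
        return self.depth_lo + w * (np.arange(self.n_depths) + 0.5)

    def tissue_weight(self, d: np.ndarray) -> np.ndarray:
        """Tissue/capillary weight: 1 inside the ribbon, tapering outside."""
        d = np.asarray(d, dtype=float)
        below = np.clip((d - self.depth_lo) / (0.0 - self.depth_lo), 0.0, 1.0)
        above = np.clip((self.depth_hi - d) / (self.depth_hi - 1.0), 0.0, 1.0)
        return np.where(d < 0.0, below, np.where(d > 1.0, above, 1.0))

    def vein_weight(self, d: np.ndarray) -> np.ndarray:
        """Penetrating-vein CBV weight, increasing linearly toward the surface."""
        d = np.asarray(d, dtype=float)
        return self.vein_gain * np.clip(
            (d - self.depth_lo) / (1.0 - self.depth_lo), 0.0, None
        )

    def pial_distance(self, d: np.ndarray) -> np.ndarray:
        """Distance (mm) from the pial vessel surface to depth ``d``."""
        d = np.asarray(d, dtype=float)
        radius = self.pial_diameter_mm / 2.0
        return radius + np.clip(1.0 - d, 0.0, None) * self.cortical_thickness_mm


@dataclass(frozen=True)
class ComplexTimeSeries:
    """Magnitude + phase over (site x time) with site metadata.

    ``sites`` is a DataFrame with at least columns ``roi`` and ``depth``.
    Phase is stored wrapped to (-pi, pi].
    """

    magnitude: np.ndarray
    phase: np.ndarray
    TR_s: float
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase must be congruent")
        if self.magnitude.ndim != 2 or len(self.sites) != self.magnitude.shape[0]:
            raise ValueError("site table does not match array shape")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be >= 0")

    @property
    def n_sites(self) -> int:
        return self.magnitude.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.magnitude.shape[1]

    @property
    def depths(self) -> np.ndarray:
        return self.sites["depth"].to_numpy()


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase to (-pi, pi]."""
    return -np.mod(-np.asarray(phi, dtype=float) + np.pi, 2 * np.pi) + np.pi


def leakage_operator(
    laminar_signal: np.ndarray, drain_fraction: float, vein_weight: np.ndarray
) -> np.ndarray:
    """Vein-compartment signal from cumulative upward drainage.

    Depth index 0 is the deepest (GM/WM) position.  The vein signal at depth
    k is ``vein_weight[k] * sum_{j<=k} drain_fraction**(k-j) * laminar[j]``:
    deep activity is carried toward the surface, never downward, so the
    mixing is linear, causal in depth, and upper-triangular toward the pial
    surface.
    """
    if not 0.0 <= drain_fraction <= 1.0:
        raise ValueError(f"drain_fraction must be in [0, 1], got {drain_fraction}")
    lam = np.atleast_2d(np.asarray(laminar_signal, dtype=float))
    vw = np.asarray(vein_weight, dtype=float)
    if vw.shape[0] != lam.shape[0]:
        raise ValueError("vein_weight length must match the depth axis")
    out = np.empty_like(lam)
    running = np.zeros(lam.shape[1])
    for k in range(lam.shape[0]):
        running = lam[k] + drain_fraction * running
        out[k] = vw[k] * running
    return out


def pial_extravascular_term(
    column: CorticalColumnSpec, pial_signal: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude and phase perturbations of the pial vein's blooming field.

    Both scale as (radius / distance-to-vessel-surface)^2 times the pial
    signal; the phase part is the handle phase regression uses.
    """
    pial_signal = np.asarray(pial_signal, dtype=float)
    radius = column.pial_diameter_mm / 2.0
    factor = (radius / column.pial_distance(column.depths)) ** 2
    mag = column.pial_mag_gain * factor[:, None] * pial_signal[None, :]
    phase = column.phase_rad_per_unit * mag
    return mag, phase


def double_peak_profile(depths: np.ndarray, peaks=(0.15, 0.85), width: float = 0.10) -> np.ndarray:
    """Double-peaked laminar activation profile (deep + superficial), max 1.

    The hallmark motor-cortex pattern for a button-press task: input arrives
    in superficial layers, output is generated in deep layers, middle layers
    stay comparatively quiet.
    """
    d = np.asarray(depths, dtype=float)
    prof = np.zeros_like(d)
    for p in peaks:
        prof += np.exp(-0.5 * ((d - p) / width) ** 2)
    return prof / prof.max()


def _as_b_value(vn) -> float:
    if vn is None:
        return 0.0
    if isinstance(vn, VNGradientSpec):
        return vn.b_value
    return float(vn)


def _forward(
    column: CorticalColumnSpec,
    lam: np.ndarray,
    b: float,
    noise_sd: float,
    rng: np.random.Generator | None,
    TR_s: float,
    roi: str,
) -> ComplexTimeSeries:
    """Shared forward path: compartments -> VN attenuation -> noise -> wrap."""
    depths = column.depths
    att_cap = vn_attenuation(b, CAPILLARY)
    att_vein = vn_attenuation(b, PENETRATING_VEIN)
    att_art = vn_attenuation(b, CORTICAL_ARTERY)

    tissue = att_cap * column.tissue_weight(depths)[:, None] * lam
    vein = att_vein * leakage_operator(lam, column.drain_fraction, column.vein_weight(depths))
    artery = att_art * column.arterial_gain * column.tissue_weight(depths)[:, None] * lam
    pial_mag, pial_phase = pial_extravascular_term(column, lam.mean(axis=0))

    # Voxel phase tracks the coherent field of the large pial vessel only:
    # penetrating veins are sub-voxel and quasi-randomly oriented, so their
    # net phase contribution averages out.
    magnitude = column.baseline + tissue + vein + artery + pial_mag
    phase = pial_phase
    if noise_sd > 0:
        magnitude = magnitude + noise_sd * rng.standard_normal(magnitude.shape)
        phase = phase + (noise_sd / column.baseline) * rng.standard_normal(phase.shape)
    sites = pd.DataFrame({"roi": roi, "depth": depths})
    return ComplexTimeSeries(
        magnitude=np.clip(magnitude, 0.0, None),
        phase=wrap_phase(phase),
        TR_s=TR_s,
        sites=sites,
    )


def simulate_task(
    column: CorticalColumnSpec,
    paradigm: BlockParadigm,
    activation_profile: np.ndarray | None = None,
    vn: VNGradientSpec | float | None = None,
    noise_sd: float = 1.0,
    seed: int | None = None,
    amplitude: float = 2.0,
    roi: str = "M1",
) -> ComplexTimeSeries:
    """Simulate one task run for a single column.

    The laminar neural signal is ``activation_profile`` (default
    double-peaked, deep + superficial) times the HRF-convolved boxcar,
    scaled so the profile peak is ``amplitude`` per cent of baseline; it is
    then forwarded through tissue, drained-vein, arterial, and pial terms
    with VN attenuation, and complex Gaussian noise is added.
    """
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")
    rng = np.random.default_rng(seed)
    depths = column.depths
    if activation_profile is None:
        activation_profile = double_peak_profile(depths)
    activation_profile = np.asarray(activation_profile, dtype=float)
    if activation_profile.shape != depths.shape:
        raise ValueError("activation_profile length must equal n_depths")

    box = paradigm.boxcar()
    hrf = double_gamma_hrf(paradigm.TR_s)
    resp = np.convolve(box, hrf)[: box.size]
    lam = amplitude * activation_profile[:, None] * resp[None, :]
    b = _as_b_value(vn)
    return _forward(column, lam, b, noise_sd, rng, paradigm.TR_s, roi)


# --------------------------------------------------------------------------
# resting state


@dataclass(frozen=True)
class LaminarNetworkSpec:
    """Ground-truth laminar network: ROIs and cross-layer correlated edges.

    ``edges`` are (roi_a, layer_a, roi_b, layer_b, r) tuples with layer in
    {superficial, middle, deep}.  One band-limited Gaussian source exists
    per (roi, layer); the edge list fixes the source correlation matrix.
    """

    rois: tuple = ("M1", "S1")
    edges: tuple = ()
    band_hz: tuple = (0.01, 0.1)
    layer_depths: dict = field(
        default_factory=lambda: {
            name: (lo + hi) / 2.0
            for name, (lo, hi) in LAYER_WINDOWS.items()
            if name != "overall"
        }
    )

    def __post_init__(self) -> None:
        for e in self.edges:
            ra, la, rb, lb, r = e
            if ra not in self.rois or rb not in self.rois:
                raise ValueError(f"edge {e} names an unknown ROI")
            if la not in self.layer_depths or lb not in self.layer_depths:
                raise ValueError(f"edge {e} names an unknown layer")
            if not abs(r) < 1:
                raise ValueError(f"edge {e} needs |r| < 1")

    @property
    def layers(self) -> list[str]:
        return list(self.layer_depths)

    @property
    def source_labels(self) -> list[tuple[str, str]]:
        return [(roi, layer) for roi in self.rois for layer in self.layers]

    def source_index(self, roi: str, layer: str) -> int:
        return self.source_labels.index((roi, layer))

    def correlation_matrix(self) -> np.ndarray:
        m = len(self.source_labels)
        C = np.eye(m)
        for ra, la, rb, lb, r in self.edges:
            i, j = self.source_index(ra, la), self.source_index(rb, lb)
            C[i, j] = C[j, i] = r
        return C

    def validate_psd(self) -> np.ndarray:
        C = self.correlation_matrix()
        if np.min(np.linalg.eigvalsh(C)) < -1e-10:
            raise ValueError(
                "edge correlations do not form a positive semi-definite "
                f"matrix; offending edges: {list(self.edges)}"
            )
        return C


def default_network() -> LaminarNetworkSpec:
    """Two-region sensorimotor-style network with layer-specific edges."""
    return LaminarNetworkSpec(
        rois=("M1", "S1"),
        edges=(
            ("M1", "superficial", "S1", "superficial", 0.5),
            ("M1", "deep", "S1", "deep", 0.3),
        ),
    )


def _band_limited_sources(
    network: LaminarNetworkSpec, n_volumes: int, TR_s: float, rng: np.random.Generator
) -> np.ndarray:
    """(n_sources x time) band-limited unit-variance sources with the
    network's correlation structure."""
    C = network.validate_psd()
    m = C.shape[0]
    white = rng.standard_normal((m, n_volumes))
    filt = bandpass(white, TR_s, *network.band_hz, axis=-1)
    filt /= filt.std(axis=1, keepdims=True)
    L = linalg.cholesky(C + 1e-10 * np.eye(m), lower=True)
    return L @ filt


def _layer_kernels(network: LaminarNetworkSpec, depths: np.ndarray, width: float = 0.12):
    """Gaussian depth deposition kernel for each layer source, peak 1."""
    return {
        layer: np.exp(-0.5 * ((depths - d0) / width) ** 2)
        for layer, d0 in network.layer_depths.items()
    }


def simulate_rest(
    network: LaminarNetworkSpec,
    columns: dict | None = None,
    vn: VNGradientSpec | float | None = None,
    noise_sd: float = 1.0,
    n_volumes: int = 300,
    TR_s: float = 4.0,
    seed: int | None = None,
    amplitude: float = 1.0,
    sources: np.ndarray | None = None,
) -> dict:
    """Simulate one resting run; returns {roi: ComplexTimeSeries}.

    Laminar sources are band-limited (0.01-0.1 Hz) unit-variance Gaussian
    processes with the network's cross-ROI/cross-layer correlations,
    deposited over depth with Gaussian kernels and forwarded through the
    same leakage/pial/VN/noise path as task runs.  Pass ``sources`` (from a
    previous call's generator) to reuse identical neural activity across
    acquisition conditions.
    """
    if seed is None and (noise_sd > 0 or sources is None):
        raise ValueError("a seed is required for stochastic runs (noise or source draws)")
    rng = np.random.default_rng(seed)
    if columns is None:
        columns = {roi: CorticalColumnSpec() for roi in network.rois}
    if sources is None:
        sources = _band_limited_sources(network, n_volumes, TR_s, rng)
    b = _as_b_value(vn)

    out = {}
    for roi in network.rois:
        col = columns[roi]
        kernels = _layer_kernels(network, col.depths)
        lam = np.zeros((col.n_depths, n_volumes))
        for layer in network.layers:
            src = sources[network.source_index(roi, layer)]
            lam += amplitude * kernels[layer][:, None] * src[None, :]
        out[roi] = _forward(col, lam, b, noise_sd, rng, TR_s, roi)
    return out


@dataclass
class Subject:
    """One synthetic participant: jittered columns + paired condition runs."""

    subject_id: int
    columns: dict
    runs: dict  # b value -> {roi: ComplexTimeSeries}


def make_subject_cohort(
    n_subjects: int = 14,
    between_subject_sd: float = 0.1,
    seed: int | None = None,
    network: LaminarNetworkSpec | None = None,
    b_values=(0.0, 7.0),
    noise_sd: float = 1.0,
    n_volumes: int = 300,
    TR_s: float = 4.0,
) -> list[Subject]:
    """Paired-condition resting cohort (default N=14, b = 0 and 7 s/mm^2).

    Per-subject physiology (drain fraction, vein gain, fluctuation
    amplitude) is jittered once per subject; both conditions share the
    subject's neural sources so paired contrasts are meaningful.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if seed is None:
        raise ValueError("a seed is required (cohort generation is stochastic)")
    if network is None:
        network = default_network()
    master = np.random.default_rng(seed)

    subjects = []
    for sid in range(n_subjects):
        jit = master.normal(0.0, between_subject_sd, size=3)
        base = CorticalColumnSpec()
        cols = {
            roi: replace(
                base,
                drain_fraction=float(np.clip(base.drain_fraction * (1 + jit[0]), 0.0, 1.0)),
                vein_gain=float(max(base.vein_gain * (1 + jit[1]), 0.0)),
            )
            for roi in network.rois
        }
        amp = float(max(1.0 * (1 + jit[2]), 0.1))
        src_rng = np.random.default_rng(master.integers(2**31))
        sources = _band_limited_sources(network, n_volumes, TR_s, src_rng)
        runs = {}
        for b in b_values:
            runs[b] = simulate_rest(
                network,
                columns=cols,
                vn=b,
                noise_sd=noise_sd,
                n_volumes=n_volumes,
                TR_s=TR_s,
                seed=int(master.integers(2**31)),
                amplitude=amp,
                sources=sources,
            )
        subjects.append(Subject(subject_id=sid, columns=cols, runs=runs))
    return subjects
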