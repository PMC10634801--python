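"""Layer-specific functional connectivity and group statistics.

Three analysis surfaces, mirroring common laminar-FC practice:

* seed-based FC maps — a layer-sampled seed time course regressed (GLM)
  against every target, or plain Pearson/Fisher-z;
* intra-cortical depth x depth FC matrices — pairwise Pearson correlation
  between layer time series of one column, Fisher-z transformed, averaged
  over columns; the off-diagonal structure indexes inter-layer signal
  dependency (draining-vein leakage inflates it);
* depth-dependent laminar connectomes — (layers_a x layers_b) z-matrices
  per ROI pair with one-sample group t-tests.

Group inference is element-wise paired or one-sample t on Fisher-z values
with Benjamini-Hochberg FDR over unmasked cells; diagonal/self cells are
excluded from statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import make_seed_design, glm_fit

__all__ = [
    "fisher_z",
    "seed_fc_map",
    "depth_fc_matrix",
    "condition_contrast",
    "cross_layer_difference",
    "laminar_connectome",
    "DepthFCMatrix",
    "GroupStatResult",
]


def fisher_z(r):
    """Fisher z transform atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


@dataclass
class DepthFCMatrix:
    """Depth x depth Fisher-z connectivity matrix for one subject/condition."""

    z: np.ndarray
    condition: str = ""
    subject_id: int | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("depth-FC matrix must be square")

    @property
    def n_depths(self) -> int:
        return self.z.shape[0]

    def offdiag_mask(self) -> np.ndarray:
        """True where a cell enters statistics (off-diagonal, finite)."""
        return ~np.eye(self.n_depths, dtype=bool) & np.isfinite(self.z)


@dataclass
class GroupStatResult:
    """Element-wise group test with BH-FDR correction."""

    t: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray  # boolean, q < alpha on unmasked cells
    dof: int
    mean_effect: np.ndarray
    alpha: float = 0.05


def seed_fc_map(
    seed_ts: np.ndarray,
    target_ts: np.ndarray,
    method: str = "glm",
) -> np.ndarray:
    """Seed-based FC statistic per target time series.

    ``method='glm'``: the seed time course is a GLM regressor for each
    target; the seed t statistic is converted to a z score via the normal
    quantile of the Student-t CDF.  ``method='pearson'``: Fisher z of the
    Pearson correlation.  Both are monotone in the underlying correlation.
    """
    seed_ts = np.asarray(seed_ts, dtype=float)
    targets = np.atleast_2d(np.asarray(target_ts, dtype=float))
    if np.ptp(seed_ts) == 0:
        raise ValueError("seed time course has zero variance")
    if method == "glm":
        design = make_seed_design(seed_ts)
        return np.array([glm_fit(y, design, regressor="seed").z_stat for y in targets])
    if method == "pearson":
        zs = []
        for y in targets:
            r = float(np.corrcoef(seed_ts, y)[0, 1])
            zs.append(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)))
        return np.array(zs)
    raise ValueError(f"unknown method {method!r}; use 'glm' or 'pearson'")


def depth_fc_matrix(
    layer_ts,
    condition: str = "",
    subject_id: int | None = None,
) -> DepthFCMatrix:
    """Intra-cortical depth x depth Fisher-z matrix.

    ``layer_ts`` is one (depth x time) array or a sequence of them (one per
    column/vertex); matrices are computed per column and averaged.
    Constant rows give masked (NaN) entries with a warning.  The diagonal
    is NaN: self-correlation carries no information.
    """
    if isinstance(layer_ts, np.ndarray) and layer_ts.ndim == 2:
        layer_ts = [layer_ts]
    mats = []
    for ts in layer_ts:
        ts = np.asarray(ts, dtype=float)
        if ts.shape[0] < 2:
            raise ValueError("need at least 2 depths")
        sd = ts.std(axis=1)
        if np.any(sd == 0):
            warnings.warn(
                f"constant time series at depth row(s) {np.flatnonzero(sd == 0).tolist()}; "
                "entries masked",
                RuntimeWarning,
                stacklevel=2,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = np.corrcoef(ts)
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        z = np.arctanh(r)
        np.fill_diagonal(z, np.nan)
        mats.append(z)
    if len(mats) > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN diagonal
            z = np.nanmean(np.stack(mats), axis=0)
    else:
        z = mats[0]
    return DepthFCMatrix(z=z, condition=condition, subject_id=subject_id)


def _fdr_result(t, p, mask, dof, mean_effect, alpha):
    p_fdr = np.full_like(p, np.nan)
    sig = np.zeros_like(mask)
    if mask.any():
        rej, padj, _, _ = multipletests(p[mask], alpha=alpha, method="fdr_bh")
        p_fdr[mask] = padj
        sig[mask] = rej
    return GroupStatResult(
        t=t, p_raw=p, p_fdr=p_fdr, significant=sig, dof=dof,
        mean_effect=mean_effect, alpha=alpha,
    )


def condition_contrast(
    matrices_a,
    matrices_b,
    paired: bool = True,
    alpha: float = 0.05,
) -> GroupStatResult:
    """Element-wise contrast of two sets of Fisher-z matrices (A minus B).

    Paired t-test across subjects per cell, BH FDR over unmasked cells at
    ``alpha``.  For the draining-vein question, A = b0 and B = VN matrices:
    positive significant cells mark inter-layer dependency removed by the
    velocity-nulling gradient.
    """
    za = np.stack([m.z if isinstance(m, DepthFCMatrix) else np.asarray(m) for m in matrices_a])
    zb = np.stack([m.z if isinstance(m, DepthFCMatrix) else np.asarray(m) for m in matrices_b])
    if za.shape != zb.shape:
        raise ValueError("condition sets differ in shape")
    n = za.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if not paired:
        raise NotImplementedError("only the paired design is implemented")

    diff = za - zb
    mask = np.all(np.isfinite(diff), axis=0)
    if diff.ndim == 3:
        np.fill_diagonal(mask, False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN masked cells
        mean = np.where(mask, np.nanmean(diff, axis=0), np.nan)
        sd = np.where(mask, np.nanstd(diff, axis=0, ddof=1), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    p = 2 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(mask, p, np.nan)
    return _fdr_result(t, p, mask, n - 1, mean, alpha)


def cross_layer_difference(fc_maps: dict, alpha: float = 0.05) -> dict:
    """Pairwise differences of layer-specific FC maps with group stats.

    ``fc_maps`` maps layer name -> (subjects x targets) Fisher-z array.
    Returns {(layer_a, layer_b): GroupStatResult} for each ordered pair of
    distinct layers (paired differences a - b); diff(A,B) = -diff(B,A).
    """
    layers = list(fc_maps)
    arrays = {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in fc_maps.items()}
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise ValueError("layer maps are not aligned over subjects/targets")
    out = {}
    for i, la in enumerate(layers):
        for lb in layers[i + 1:]:
            res = condition_contrast(arrays[la], arrays[lb], paired=True, alpha=alpha)
            out[(la, lb)] = res
    return out


def laminar_connectome(
    roi_layer_ts: list,
    roi_pairs: list,
    alpha: float = 0.05,
) -> dict:
    """Depth-dependent connectome for ROI pairs with one-sample group stats.

    ``roi_layer_ts`` is a list over subjects of {roi: {layer: time series}}.
    For each (roi_a, roi_b) pair, each subject contributes a
    (layers_a x layers_b) Fisher-z matrix; a one-sample t-test across
    subjects is run per cell with BH FDR over the pair's cells.

    Returns {(roi_a, roi_b): {"z": subjects x la x lb, "layers_a": [...],
    "layers_b": [...], "stats": GroupStatResult}}.
    """
    if len(roi_layer_ts) < 2:
        raise ValueError("need at least 2 subjects")
    out = {}
    for roi_a, roi_b in roi_pairs:
        zs = []
        for si, subj in enumerate(roi_layer_ts):
            for roi in (roi_a, roi_b):
                if roi not in subj:
                    raise ValueError(f"subject {si} is missing ROI {roi!r}")
            layers_a = list(subj[roi_a])
            layers_b = list(subj[roi_b])
            z = np.empty((len(layers_a), len(layers_b)))
            for i, la in enumerate(layers_a):
                for j, lb in enumerate(layers_b):
                    x, y = subj[roi_a][la], subj[roi_b][lb]
                    if x is None or y is None:
                        raise ValueError(f"subject {si} is missing ts for {roi_a}/{la} or {roi_b}/{lb}")
                    r = float(np.corrcoef(x, y)[0, 1])
                    z[i, j] = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
            zs.append(z)
        zarr = np.stack(zs)
        n = zarr.shape[0]
        t, p = stats.ttest_1samp(zarr, 0.0, axis=0)
        mask = np.isfinite(p)
        res = _fdr_result(t, np.where(mask, p, np.nan), mask, n - 1, zarr.mean(axis=0), alpha)
        out[(roi_a, roi_b)] = {
            "z": zarr,
            "layers_a": layers_a,
            "layers_b": layers_b,
            "stats": res,
        }
    return out
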