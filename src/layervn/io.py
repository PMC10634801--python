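"""NIfTI and tabular I/O for complex-valued depth-resolved time series.

Synthetic data use a depth-as-spatial-axis convention: a run is stored as
a pair of 4-D NIfTI volumes (sites x 1 x 1 x time) holding magnitude and
phase, so standard viewers and tools can open the files, plus a TSV site
table (roi, depth) and an optional JSON ground-truth sidecar.  TR is
carried in the NIfTI header (4th pixdim).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cortex import ComplexTimeSeries, wrap_phase

__all__ = [
    "write_complex_pair",
    "read_complex_pair",
    "write_tsv",
    "write_json",
]


def write_complex_pair(
    cts: ComplexTimeSeries,
    mag_path,
    phase_path,
    sites_path=None,
) -> None:
    """Write a run as a magnitude/phase NIfTI pair (+ optional TSV site table).

    Phase is re-wrapped to (-pi, pi] on write; data are float32, so a
    write -> read round trip is lossless at float32 precision.
    """
    for arr, path in (
        (cts.magnitude, mag_path),
        (wrap_phase(cts.phase), phase_path),
    ):
        data = np.asarray(arr, dtype=np.float32)[:, None, None, :]
        img = nib.Nifti1Image(data, affine=np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, float(cts.TR_s)))
        img.header.set_xyzt_units(xyz="mm", t="sec")
        nib.save(img, str(path))
    if sites_path is not None:
        cts.sites.to_csv(sites_path, sep="\t", index=False)


def read_complex_pair(mag_path, phase_path, sites_path=None) -> ComplexTimeSeries:
    """Read a magnitude/phase NIfTI pair back into a ComplexTimeSeries.

    Accepts 4-D volumes with singleton spatial axes (the depth-as-axis
    convention) or any 4-D volume, which is flattened over space.
    """
    mag_img = nib.load(str(mag_path))
    phase_img = nib.load(str(phase_path))
    if mag_img.shape != phase_img.shape:
        raise ValueError(
            f"magnitude shape {mag_img.shape} != phase shape {phase_img.shape}"
        )
    tr_m = float(mag_img.header.get_zooms()[3]) if len(mag_img.shape) == 4 else 0.0
    tr_p = float(phase_img.header.get_zooms()[3]) if len(phase_img.shape) == 4 else 0.0
    if tr_m <= 0 or tr_p <= 0:
        raise ValueError(
            "TR missing from NIfTI header (4th pixdim is 0); set it with "
            "header.set_zooms((1, 1, 1, TR)) when writing"
        )
    if abs(tr_m - tr_p) > 1e-6:
        raise ValueError(f"TR mismatch between magnitude ({tr_m}) and phase ({tr_p})")

    mag = np.asarray(mag_img.get_fdata(), dtype=float)
    phase = np.asarray(phase_img.get_fdata(), dtype=float)
    n_t = mag.shape[-1]
    mag = mag.reshape(-1, n_t)
    phase = phase.reshape(-1, n_t)
    if sites_path is not None:
        sites = pd.read_csv(sites_path, sep="\t")
    else:
        sites = pd.DataFrame({"roi": "unknown", "depth": np.full(mag.shape[0], np.nan)})
    return ComplexTimeSeries(
        magnitude=mag, phase=wrap_phase(phase), TR_s=tr_m, sites=sites
    )


def write_tsv(df: pd.DataFrame, path, comment: str | None = None) -> None:
    """TSV with an optional leading header comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
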