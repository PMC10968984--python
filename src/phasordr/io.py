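"""File formats for the phasor-FLIM drug-response pipeline.

The native decay-cube container is HDF5: dataset ``/counts`` (unsigned
32-bit, dims y x t) plus scalar attributes ``bin_width_ps``, ``rep_rate_hz``,
``sample_id``, ``treatment``, ``condition``, ``fov_index``.  A 16-bit TIFF
time-stack with a JSON metadata sidecar is accepted as a fallback.  Sample
sheets are plain CSV; curves are CSV with '#' comment headers; drug-response
results are JSON.

All writers are deterministic (same object, byte-identical file) and all
readers validate rather than guess: malformed input raises
:class:`FormatError` naming the offending field.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING

import h5py
import numpy as np
import pandas as pd
import tifffile

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, types only
    from .fractions import MeanCurve
    from .scoring import DRResult

logger = logging.getLogger(__name__)

#: Treatment tokens accepted in sample sheets and cube metadata.
TREATMENTS = ("CONTROL", "TMZ", "REGO", "CALIBRATION")
CONDITIONS = ("control", "treated", "calibration")

SHEET_COLUMNS = ("file_path", "sample_id", "treatment", "condition", "fov_index")

_CUBE_ATTRS = ("bin_width_ps", "rep_rate_hz", "sample_id", "treatment",
               "condition", "fov_index")


class FormatError(ValueError):
    """Raised when a file does not conform to the expected layout."""


def _sig9(x: float) -> str:
    """Format a float at 9 significant digits (deterministic output)."""
    return format(float(x), ".9g")


# ---------------------------------------------------------------------------
# DecayCube
# ---------------------------------------------------------------------------

@dataclass
class DecayCube:
    """Per-FOV 3D photon histogram with acquisition metadata.

    ``counts`` is indexed (row, col, time_bin); ``bin_width`` and the laser
    repetition rate ``rep_rate`` are in SI units (seconds, Hz).  Time bin k
    spans [k*bin_width, (k+1)*bin_width); bin centers sit at
    (k + 0.5)*bin_width with t = 0 at the laser sync.
    """

    counts: np.ndarray
    bin_width: float
    rep_rate: float
    sample_id: str = ""
    treatment: str = "CONTROL"
    condition: str = "control"
    fov_index: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise FormatError("counts must be 3-D (row, col, time_bin)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise FormatError("counts must be an integer array")
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")
        if self.bin_width <= 0 or self.rep_rate <= 0:
            raise FormatError("bin_width and rep_rate must be positive")
        window = self.n_time_bins * self.bin_width
        if window > self.period * (1 + 1e-9):
            raise FormatError(
                f"time window {window:.3e}s exceeds repetition period "
                f"{self.period:.3e}s")
        if self.treatment not in TREATMENTS:
            raise FormatError(f"unknown treatment {self.treatment!r}")

    @property
    def n_time_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def period(self) -> float:
        """Laser repetition period in seconds."""
        return 1.0 / self.rep_rate

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_time_bins) + 0.5) * self.bin_width

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DecayCube):
            return NotImplemented
        return (np.array_equal(self.counts, other.counts)
                and self.bin_width == other.bin_width
                and self.rep_rate == other.rep_rate
                and self.sample_id == other.sample_id
                and self.treatment == other.treatment
                and self.condition == other.condition
                and self.fov_index == other.fov_index)


def write_decay_cube(cube: DecayCube, path: str | Path) -> Path:
    """Write a cube; HDF5 for '.h5'/'.hdf5', TIFF+JSON sidecar for '.tif(f)'."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _write_cube_tiff(cube, path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("counts", data=cube.counts.astype(np.uint32),
                              track_times=False)
        ds.attrs["dims"] = "y x t"
        f.attrs["bin_width_ps"] = cube.bin_width * 1e12
        f.attrs["rep_rate_hz"] = cube.rep_rate
        f.attrs["sample_id"] = cube.sample_id
        f.attrs["treatment"] = cube.treatment
        f.attrs["condition"] = cube.condition
        f.attrs["fov_index"] = int(cube.fov_index)
    return path


def _write_cube_tiff(cube: DecayCube, path: Path) -> Path:
    if cube.counts.max(initial=0) > np.iinfo(np.uint16).max:
        raise FormatError("TIFF fallback is 16-bit; counts exceed 65535")
    # time axis first so each page is one time bin
    stack = np.moveaxis(cube.counts.astype(np.uint16), 2, 0)
    tifffile.imwrite(path, stack)
    meta = {
        "bin_width_ps": cube.bin_width * 1e12,
        "rep_rate_hz": cube.rep_rate,
        "sample_id": cube.sample_id,
        "treatment": cube.treatment,
        "condition": cube.condition,
        "fov_index": int(cube.fov_index),
    }
    path.with_suffix(".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_decay_cube(path: str | Path) -> DecayCube:
    """Read a cube written by :func:`write_decay_cube` (HDF5 or TIFF+JSON)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_cube_tiff(path)
    with h5py.File(path, "r") as f:
        if "counts" not in f:
            raise FormatError(f"{path}: missing dataset 'counts'")
        for attr in _CUBE_ATTRS:
            if attr not in f.attrs:
                raise FormatError(f"{path}: missing attribute {attr!r}")
        counts = f["counts"][()]
        if not np.issubdtype(counts.dtype, np.integer):
            raise FormatError(f"{path}: counts dataset is not integer-typed")
        return DecayCube(
            counts=counts,
            bin_width=float(f.attrs["bin_width_ps"]) * 1e-12,
            rep_rate=float(f.attrs["rep_rate_hz"]),
            sample_id=str(f.attrs["sample_id"]),
            treatment=str(f.attrs["treatment"]),
            condition=str(f.attrs["condition"]),
            fov_index=int(f.attrs["fov_index"]),
        )


def _read_cube_tiff(path: Path) -> DecayCube:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"{path}: missing JSON metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for attr in _CUBE_ATTRS:
        if attr not in meta:
            raise FormatError(f"{sidecar}: missing field {attr!r}")
    stack = tifffile.imread(path)
    if stack.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D time stack")
    counts = np.moveaxis(stack, 0, 2)
    return DecayCube(
        counts=counts.astype(np.uint32),
        bin_width=float(meta["bin_width_ps"]) * 1e-12,
        rep_rate=float(meta["rep_rate_hz"]),
        sample_id=str(meta["sample_id"]),
        treatment=str(meta["treatment"]),
        condition=str(meta["condition"]),
        fov_index=int(meta["fov_index"]),
    )


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Validated mapping of files to (sample, treatment, condition, FOV)."""

    frame: pd.DataFrame

    @property
    def calibration_row(self) -> pd.Series:
        cal = self.frame[self.frame["treatment"] == "CALIBRATION"]
        if len(cal) == 0:
            raise FormatError("sample sheet has no calibration entry")
        return cal.iloc[0]

    def sample_treatments(self) -> list[tuple[str, str]]:
        """Distinct (sample_id, treatment) pairs excluding the calibration."""
        f = self.frame[self.frame["treatment"] != "CALIBRATION"]
        return sorted(set(zip(f["sample_id"], f["treatment"])))

    def rows(self, sample_id: str, treatment: str, condition: str) -> pd.DataFrame:
        f = self.frame
        return f[(f["sample_id"] == sample_id) & (f["treatment"] == treatment)
                 & (f["condition"] == condition)]


def read_sample_sheet(path: str | Path, *,
                      require_calibration: bool = True) -> SampleSheet:
    """Read and validate a sample-sheet CSV.

    Rejects unknown treatment/condition tokens, duplicate
    (sample, treatment, condition, fov) rows, groups lacking a control arm
    or having fewer than 2 FOVs per condition, and (by default) sheets
    without exactly one calibration acquisition.
    """
    frame = pd.read_csv(path, dtype={"file_path": str, "sample_id": str,
                                     "treatment": str, "condition": str})
    missing = [c for c in SHEET_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"sample sheet missing column(s) {missing}")
    frame = frame.loc[:, list(SHEET_COLUMNS)]
    bad_t = sorted(set(frame["treatment"]) - set(TREATMENTS))
    if bad_t:
        raise FormatError(f"unknown treatment token(s) {bad_t}")
    bad_c = sorted(set(frame["condition"]) - set(CONDITIONS))
    if bad_c:
        raise FormatError(f"unknown condition token(s) {bad_c}")

    key = ["sample_id", "treatment", "condition", "fov_index"]
    dup = frame[frame.duplicated(subset=key, keep=False)]
    if len(dup):
        raise FormatError(
            "duplicated (sample, treatment, condition, fov) rows: "
            f"{dup.index.tolist()}")

    science = frame[frame["treatment"] != "CALIBRATION"]
    for (sid, trt), grp in science.groupby(["sample_id", "treatment"]):
        conds = set(grp["condition"])
        if "control" not in conds:
            raise FormatError(f"({sid}, {trt}): no control arm")
        if "treated" not in conds:
            raise FormatError(f"({sid}, {trt}): no treated arm")
        for cond, sub in grp.groupby("condition"):
            if len(sub) < 2:
                raise FormatError(
                    f"({sid}, {trt}, {cond}): fewer than 2 FOVs")

    n_cal = int((frame["treatment"] == "CALIBRATION").sum())
    if require_calibration and n_cal != 1:
        raise FormatError(
            f"expected exactly one calibration entry, found {n_cal}")
    return SampleSheet(frame=frame.reset_index(drop=True))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> Path:
    path = Path(path)
    sheet.frame.to_csv(path, index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# Curves (CSV) and results (JSON)
# ---------------------------------------------------------------------------

def write_distribution_csv(curve: "MeanCurve", path: str | Path) -> Path:
    """Write a mean fractional-distribution curve.

    Data columns are (bin_center, mean_density, sd, n_fov); the per-FOV mean
    bound fractions and the bin width are preserved in '#' comment headers so
    the curve round-trips losslessly.
    """
    path = Path(path)
    lines = ["# phasordr mean fractional-distribution curve"]
    lines.append(f"# bin_width: {_sig9(curve.bin_width)}")
    if curve.fov_means is not None:
        vals = ",".join(_sig9(v) for v in curve.fov_means)
        lines.append(f"# fov_means: {vals}")
    lines.append("bin_center,mean_density,sd,n_fov")
    for c, m, sd in zip(curve.bin_centers, curve.mean_density, curve.sd_density):
        lines.append(f"{_sig9(c)},{_sig9(m)},{_sig9(sd)},{curve.n_fov}")
    Path(path).write_text("\n".join(lines) + "\n")
    return path


def read_distribution_csv(path: str | Path) -> "MeanCurve":
    from .fractions import MeanCurve  # deferred: avoids an import cycle

    path = Path(path)
    bin_width = None
    fov_means = None
    for line in path.read_text().splitlines():
        if line.startswith("# bin_width:"):
            bin_width = float(line.split(":", 1)[1])
        elif line.startswith("# fov_means:"):
            fov_means = np.array(
                [float(v) for v in line.split(":", 1)[1].split(",")])
    frame = pd.read_csv(path, comment="#")
    for col in ("bin_center", "mean_density", "sd", "n_fov"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing curve column {col!r}")
    centers = frame["bin_center"].to_numpy(float)
    if bin_width is None:
        if len(centers) < 2:
            raise FormatError(f"{path}: cannot infer bin width")
        bin_width = float(centers[1] - centers[0])
    edges = np.concatenate([centers - bin_width / 2,
                            [centers[-1] + bin_width / 2]])
    return MeanCurve(
        bin_edges=edges,
        mean_density=frame["mean_density"].to_numpy(float),
        sd_density=frame["sd"].to_numpy(float),
        n_fov=int(frame["n_fov"].iloc[0]),
        fov_means=fov_means,
    )


def _result_to_dict(result: "DRResult") -> dict:
    return {
        "percent_dr": float(_sig9(result.percent_dr)),
        "label": result.label,
        "alpha": float(_sig9(result.alpha)),
        "threshold": float(_sig9(result.threshold)),
        "shift_direction_p": float(_sig9(result.shift_direction_p)),
        "per_bin_p": [float(_sig9(p)) for p in result.per_bin_p],
        "significant_bins": [bool(b) for b in result.significant_bins],
    }


def write_results(results, path: str | Path) -> Path:
    """Serialize one DRResult, or a {name: DRResult} mapping, as JSON."""
    path = Path(path)
    if isinstance(results, dict):
        payload = {k: _result_to_dict(v) for k, v in sorted(results.items())}
    else:
        payload = _result_to_dict(results)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_results(path: str | Path):
    from .scoring import DRResult  # deferred: avoids an import cycle

    def build(d: dict) -> DRResult:
        for key in ("percent_dr", "label", "alpha", "threshold",
                    "shift_direction_p", "per_bin_p", "significant_bins"):
            if key not in d:
                raise FormatError(f"{path}: missing result field {key!r}")
        return DRResult(
            percent_dr=float(d["percent_dr"]),
            label=str(d["label"]),
            alpha=float(d["alpha"]),
            threshold=float(d["threshold"]),
            shift_direction_p=float(d["shift_direction_p"]),
            per_bin_p=np.array(d["per_bin_p"], float),
            significant_bins=np.array(d["significant_bins"], bool),
        )

    payload = json.loads(Path(path).read_text())
    if "percent_dr" in payload:
        return build(payload)
    return {k: build(v) for k, v in payload.items()}
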