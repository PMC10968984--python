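"""Cohort-level stratification and cross-treatment concordance.

Aggregates per-sample %DR results into a table sorted from lowest to
highest %DR within each treatment, with per-treatment responder counts, and
cross-tabulates NR/Resp labels between two treatment arms over the shared
samples (e.g. whether every non-responder to one drug is also a
non-responder to the other).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .fractions import (bound_fraction_map, component_endpoints,
                        fov_distribution, mean_curve)
from .io import DecayCube, SampleSheet, read_decay_cube, _sig9
from .phasor import (apply_calibration, compute_phasor, derive_calibration,
                     smooth_phasor)
from .scoring import DRResult, classify, percent_dr

logger = logging.getLogger(__name__)


@dataclass
class ScoredSample:
    """One sample x treatment drug-response result."""

    sample_id: str
    treatment: str
    result: DRResult


@dataclass
class CohortTable:
    """Sorted per-sample stratification plus per-treatment summary counts."""

    table: pd.DataFrame      # sample_id, treatment, percent_dr, label
    summary: pd.DataFrame    # treatment, n, n_resp, n_nr, pct_resp, pct_nr
    threshold: float

    def treatments(self) -> list[str]:
        return sorted(self.table["treatment"].unique())


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_cohort_table(results: list[ScoredSample],
                       threshold: float | None = None) -> CohortTable:
    """Build the stratification table, lowest %DR first within treatment."""
    if not results:
        raise ValueError("need at least one scored sample")
    thresholds = {r.result.threshold for r in results}
    if threshold is None:
        if len(thresholds) > 1:
            raise ValueError(f"mixed %DR thresholds in results: {thresholds}")
        threshold = thresholds.pop()

    rows = []
    seen = set()
    for r in results:
        key = (r.sample_id, r.treatment)
        if key in seen:
            raise ValueError(f"duplicate (sample, treatment) entry {key}")
        seen.add(key)
        expected = classify(r.result.percent_dr, threshold)
        if r.result.label != expected:
            raise ValueError(
                f"{key}: label {r.result.label!r} inconsistent with "
                f"%DR {r.result.percent_dr:g} at threshold {threshold:g}")
        rows.append({"sample_id": r.sample_id, "treatment": r.treatment,
                     "percent_dr": r.result.percent_dr,
                     "label": r.result.label})
    table = (pd.DataFrame(rows)
             .sort_values(["treatment", "percent_dr", "sample_id"],
                          kind="mergesort")
             .reset_index(drop=True))

    summary_rows = []
    for trt, grp in table.groupby("treatment"):
        n = len(grp)
        if n == 0:  # pragma: no cover - groupby never yields empty groups
            logger.warning("treatment arm %s is empty; omitted", trt)
            continue
        n_resp = int((grp["label"] == "Resp").sum())
        summary_rows.append({
            "treatment": trt, "n": n, "n_resp": n_resp, "n_nr": n - n_resp,
            "pct_resp": _round_half_up(100.0 * n_resp / n),
            "pct_nr": _round_half_up(100.0 * (n - n_resp) / n)})
    summary = pd.DataFrame(summary_rows)
    return CohortTable(table=table, summary=summary, threshold=threshold)


def concordance(table_a: CohortTable, table_b: CohortTable) -> dict:
    """Cross-tabulate NR/Resp labels of two treatment arms on shared samples.

    Returns the 2x2 counts, whether arm-B non-responders are a subset of
    arm-A non-responders, and the list of discordant samples.
    """
    trts_a, trts_b = table_a.treatments(), table_b.treatments()
    if len(trts_a) != 1 or len(trts_b) != 1:
        raise ValueError("each table must hold exactly one treatment")
    trt_a, trt_b = trts_a[0], trts_b[0]
    if trt_a == trt_b:
        raise ValueError("treatments must be distinct")

    a = table_a.table.set_index("sample_id")["label"]
    b = table_b.table.set_index("sample_id")["label"]
    shared = sorted(set(a.index) & set(b.index))
    if not shared:
        raise ValueError("no shared samples between the two arms")

    cross = {f"{la}_{lb}": 0 for la in ("NR", "Resp") for lb in ("NR", "Resp")}
    discordant = []
    for sid in shared:
        cross[f"{a[sid]}_{b[sid]}"] += 1
        if a[sid] != b[sid]:
            discordant.append(
                {"sample_id": sid, trt_a: a[sid], trt_b: b[sid]})
    nr_b = {sid for sid in shared if b[sid] == "NR"}
    nr_a = {sid for sid in shared if a[sid] == "NR"}
    return {
        "treatment_a": trt_a,
        "treatment_b": trt_b,
        "n_shared": len(shared),
        "crosstab": cross,            # keys are <label_a>_<label_b>
        "nr_b_subset_of_nr_a": nr_b <= nr_a,
        "discordant": discordant,
    }


def _score_one(cubes_control: list[DecayCube], cubes_treated: list[DecayCube],
               calibration_cube: DecayCube,
               config: AnalysisConfig) -> DRResult:
    """Run phasor -> referencing -> unmixing -> curves -> %DR."""
    cal_field = compute_phasor(calibration_cube, config.harmonic,
                               config.intensity_threshold)
    cal = derive_calibration(cal_field, config.tau_ref)
    pair = component_endpoints(config.tau_free, config.tau_bound, cal.omega)

    def distributions(cubes: list[DecayCube]):
        out = []
        for cube in cubes:
            f = compute_phasor(cube, config.harmonic,
                               config.intensity_threshold)
            f = apply_calibration(f, cal)
            f = smooth_phasor(f, config.smooth_passes)
            fmap = bound_fraction_map(f, pair)
            out.append(fov_distribution(fmap, f.valid_mask, config.n_bins,
                                        cube.fov_index))
        return out

    ctrl_curve = mean_curve(distributions(cubes_control))
    trt_curve = mean_curve(distributions(cubes_treated))
    return percent_dr(ctrl_curve, trt_curve, config.alpha,
                      config.dr_threshold)


def score_cubes(control_cubes: list[DecayCube],
                treated_cubes: list[DecayCube],
                calibration_cube: DecayCube,
                config: AnalysisConfig | None = None) -> DRResult:
    """Score one in-memory experiment (convenience entry point)."""
    config = config or AnalysisConfig()
    return _score_one(control_cubes, treated_cubes, calibration_cube, config)


def score_sample(sheet: SampleSheet, config: AnalysisConfig | None = None,
                 data_dir: str | Path = ".") -> list[ScoredSample]:
    """Score every (sample, treatment) pair in a sample sheet.

    Reads the cubes named by the sheet (paths relative to ``data_dir``),
    derives the referencing correction from the sheet's calibration
    acquisition, and returns one DRResult per pair.  Deterministic given
    identical inputs.
    """
    config = config or AnalysisConfig()
    config.log_parameters()
    data_dir = Path(data_dir)
    cal_cube = read_decay_cube(data_dir / sheet.calibration_row["file_path"])

    results = []
    for sample_id, treatment in sheet.sample_treatments():
        def load(condition: str) -> list[DecayCube]:
            rows = sheet.rows(sample_id, treatment, condition)
            return [read_decay_cube(data_dir / p)
                    for p in rows["file_path"]]
        try:
            result = _score_one(load("control"), load("treated"), cal_cube,
                                config)
        except Exception as exc:
            raise RuntimeError(
                f"scoring failed for sample {sample_id!r}, "
                f"treatment {treatment!r}: {exc}") from exc
        logger.info("scored %s/%s: %%DR = %.3f (%s)", sample_id, treatment,
                    result.percent_dr, result.label)
        results.append(ScoredSample(sample_id=sample_id, treatment=treatment,
                                    result=result))
    return results


# ---------------------------------------------------------------------------
# Cohort output files
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: CohortTable, path: str | Path) -> Path:
    """Rows as CSV; the summary block follows as '#' comment lines."""
    path = Path(path)
    lines = ["sample_id,treatment,percent_dr,label"]
    for _, r in cohort.table.iterrows():
        lines.append(f"{r.sample_id},{r.treatment},"
                     f"{_sig9(r.percent_dr)},{r.label}")
    lines.append(f"# dr_threshold: {_sig9(cohort.threshold)}")
    for _, r in cohort.summary.iterrows():
        lines.append(f"# {r.treatment}: n={r.n} Resp={r.n_resp} NR={r.n_nr} "
                     f"pct_resp={r.pct_resp} pct_nr={r.pct_nr}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read back the row block of a cohort CSV."""
    return pd.read_csv(path, comment="#",
                       dtype={"sample_id": str, "treatment": str,
                              "label": str})


def write_concordance_json(conc: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(conc, indent=2, sort_keys=True) + "\n")
    return path


def format_report(cohort: CohortTable, conc: dict | None = None) -> str:
    """Plain-text cohort report."""
    lines = [f"Drug-response stratification (threshold {cohort.threshold:g}%DR)",
             ""]
    for _, r in cohort.summary.iterrows():
        lines.append(f"{r.treatment}: {r.n_resp}/{r.n} responders "
                     f"({r.pct_resp}%), {r.n_nr}/{r.n} non-responders "
                     f"({r.pct_nr}%)")
    lines.append("")
    for _, r in cohort.table.iterrows():
        lines.append(f"  {r.sample_id:<16s} {r.treatment:<6s} "
                     f"{r.percent_dr:7.2f}%DR  {r.label}")
    if conc is not None:
        lines += ["",
                  f"Concordance {conc['treatment_a']} vs "
                  f"{conc['treatment_b']} ({conc['n_shared']} shared samples):"]
        for key, n in conc["crosstab"].items():
            la, lb = key.split("_")
            lines.append(f"  {conc['treatment_a']}-{la} & "
                         f"{conc['treatment_b']}-{lb}: {n}")
        subset = ("are" if conc["nr_b_subset_of_nr_a"] else "are not")
        lines.append(f"  {conc['treatment_b']}-NRs {subset} a subset of "
                     f"{conc['treatment_a']}-NRs")
    return "\n".join(lines) + "\n"
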