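"""Group-level quantification and significance testing.

Per-section liver metrics (mean speed of sound, background-removed lipid
signal, cross-sectional area, body weight) are aggregated per study group
and compared pairwise with unpaired t-tests, reproducing the structure of
the study's group-comparison figures.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ReconImage

__all__ = [
    "REQUIRED_COLUMNS",
    "validate_cohort_table",
    "liver_mean_sos",
    "group_summary",
    "unpaired_ttest",
    "significance_stars",
    "percent_difference",
    "build_report",
]

REQUIRED_COLUMNS = (
    "section_id",
    "group",
    "mouse_id",
    "liver_mean_sos",
    "lipid_metric",
    "area",
    "weight",
)
METRICS = ("liver_mean_sos", "lipid_metric", "area", "weight")


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort table contract and drop QC-excluded rows."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if table["section_id"].duplicated().any():
        dupes = table.loc[table["section_id"].duplicated(), "section_id"].tolist()
        raise ValueError(f"duplicate section_ids: {dupes}")
    if "qc_excluded" in table.columns:
        table = table.loc[~table["qc_excluded"].astype(bool)].copy()
    return table


def liver_mean_sos(sos_image: ReconImage, liver_mask: np.ndarray) -> float:
    """Arithmetic mean of the speed-of-sound map within the liver mask (m/s)."""
    mask = np.asarray(liver_mask, dtype=bool)
    if mask.shape != sos_image.pixels.shape:
        raise ValueError("liver mask grid mismatch")
    if not mask.any():
        raise ValueError("empty liver mask")
    return float(sos_image.pixels[mask].mean())


def group_summary(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-group sample mean, sample STD (n-1 denominator) and count."""
    table = validate_cohort_table(table)
    if metric not in table.columns:
        raise ValueError(f"unknown metric {metric!r}")
    rows = []
    for group, sub in table.groupby("group", sort=True):
        if len(sub) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 usable sections")
        vals = sub[metric].to_numpy(dtype=float)
        rows.append(
            {"group": group, "mean": vals.mean(), "std": vals.std(ddof=1), "n": len(vals)}
        )
    return pd.DataFrame(rows)


def unpaired_ttest(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Two-sample t-test (pooled-variance Student by default).

    Returns ``(t, p_two_tailed)``.  When both groups have zero variance and
    equal means the comparison is uninformative and ``(0, 1)`` is returned
    by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    """Star notation: * p<=0.05, ** <=0.01, *** <=0.001, **** <=0.0001."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def percent_difference(mean_a: float, mean_b: float) -> float:
    """Percent difference of ``mean_a`` relative to reference ``mean_b``."""
    if mean_b == 0:
        raise ValueError("reference mean must be non-zero")
    return 100.0 * (mean_a - mean_b) / mean_b


def build_report(
    table: pd.DataFrame,
    out_dir,
    manifest: dict | None = None,
    welch: bool = False,
) -> dict[str, Path]:
    """Write group summaries, pairwise tests and a long-format table.

    Produces ``summary.csv`` (per group x metric), ``pairwise.csv`` (all
    group pairs per metric with t, p, stars and percent difference),
    ``long.csv`` (boxplot-ready) and ``manifest.json`` (seeds/config and the
    rows excluded by QC).  Outputs are deterministic for identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    full = table.copy()
    kept = validate_cohort_table(table)

    summaries = []
    pairwise = []
    groups = sorted(kept["group"].unique())
    for metric in METRICS:
        summ = group_summary(kept, metric)
        summ.insert(0, "metric", metric)
        summaries.append(summ)
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                va = kept.loc[kept["group"] == ga, metric].to_numpy(dtype=float)
                vb = kept.loc[kept["group"] == gb, metric].to_numpy(dtype=float)
                t, p = unpaired_ttest(va, vb, welch=welch)
                pairwise.append(
                    {
                        "metric": metric,
                        "group_a": ga,
                        "group_b": gb,
                        "t": t,
                        "p": p,
                        "stars": significance_stars(p),
                        "percent_difference": percent_difference(va.mean(), vb.mean()),
                    }
                )
    paths = {
        "summary": out_dir / "summary.csv",
        "pairwise": out_dir / "pairwise.csv",
        "long": out_dir / "long.csv",
        "manifest": out_dir / "manifest.json",
    }
    pd.concat(summaries, ignore_index=True).to_csv(paths["summary"], index=False)
    pd.DataFrame(pairwise).to_csv(paths["pairwise"], index=False)
    long = kept.melt(
        id_vars=["section_id", "group", "mouse_id"],
        value_vars=list(METRICS),
        var_name="metric",
        value_name="value",
    )
    long.to_csv(paths["long"], index=False)
    excluded = []
    if "qc_excluded" in full.columns:
        excluded = full.loc[full["qc_excluded"].astype(bool), "section_id"].tolist()
    doc = {"n_sections": int(len(kept)), "groups": groups, "qc_excluded": excluded}
    if manifest:
        doc.update(manifest)
    with open(paths["manifest"], "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
    return paths
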