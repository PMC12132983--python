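"""Pattern matrix and supervision figures.

The pattern matrix is the one-page view a district supervisor would
scan: facilities as rows, signs and z-indicators as columns, each cell
listing the detected pattern types with an ordinal severity marker
(``+`` mild, ``++`` moderate, ``+++`` severe, e.g. ``Skipper+++ -
Mono+``), plus a final column marking the facilities shortlisted for
in-person observation.

Figures: per-sign missing/not-feasible bars by facility, per-facility
boxplots with the pooled distribution alongside, density plots, and
z-score histograms.  Output is deterministic SVG (fixed hash salt, no
embedded date), so re-rendering identical inputs yields identical files.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from matplotlib.figure import Figure

from cdsaqc.classify import PatternFlag
from cdsaqc.signs import MEASURED, NOT_APPLICABLE, SIGN_ORDER, SIGNS, Z_INDICATORS

#: column order of the pattern matrix (basic signs, z-indicators, vitals)
MATRIX_COLUMNS = (
    "temperature", "muac", "weight", "height",
    "muac_for_age", "weight_for_age", "weight_for_height",
    "heart_rate", "spo2", "resp_rate",
)

_TYPE_LABEL = {
    "skipper": "Skipper",
    "mono_repeater": "Mono",
    "multi_repeater": "Multi",
    "wrongly_evaluated": "WE",
}
_SEVERITY_MARK = {"mild": "+", "moderate": "++", "severe": "+++"}
_TYPE_ORDER = {t: i for i, t in enumerate(_TYPE_LABEL)}

EMPTY_CELL = "-"


def build_pattern_matrix(
    flags: list[PatternFlag],
    selection: set[str],
    facilities: list[str] | None = None,
) -> pd.DataFrame:
    """Facility x sign matrix of flagged patterns with a selection column.

    ``facilities`` fixes the row order (defaults to the sorted set of
    facilities appearing in ``flags`` or ``selection``).  Cells with
    several flags are joined ``"Type - Type"``.
    """
    if facilities is None:
        facilities = sorted({f.hc_id for f in flags} | set(selection))
    cells: dict[tuple[str, str], list[PatternFlag]] = {}
    for flag in flags:
        cells.setdefault((flag.hc_id, flag.sign), []).append(flag)

    rows = []
    for hc_id in facilities:
        row: dict[str, str] = {"hc_id": hc_id}
        for sign in MATRIX_COLUMNS:
            here = sorted(
                cells.get((hc_id, sign), []), key=lambda f: _TYPE_ORDER[f.pattern_type]
            )
            row[sign] = (
                " - ".join(f"{_TYPE_LABEL[f.pattern_type]}{_SEVERITY_MARK[f.severity]}" for f in here)
                or EMPTY_CELL
            )
        row["selected_for_observation"] = "Yes" if hc_id in selection else "No"
        rows.append(row)
    return pd.DataFrame(rows).set_index("hc_id")


def matrix_markdown(matrix: pd.DataFrame) -> str:
    """Render the pattern matrix as a GitHub-style Markdown table."""
    header = ["Health center", *matrix.columns]
    lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
    for hc_id, row in matrix.iterrows():
        lines.append("| " + " | ".join([str(hc_id), *map(str, row)]) + " |")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# figures

def _measured(df: pd.DataFrame, sign: str) -> pd.Series:
    vals = pd.to_numeric(df[f"{sign}_value"], errors="coerce")
    return vals[(df[f"{sign}_status"] == MEASURED) & vals.notna()]


def _savefig(fig: Figure, path: Path) -> None:
    with matplotlib.rc_context({"svg.hashsalt": "cdsaqc"}):
        fig.savefig(path, format="svg", metadata={"Date": None})


def render_figures(records: pd.DataFrame, out_dir: str | Path) -> dict[str, dict]:
    """Write the four figure families; returns per-figure metadata
    (e.g. the medians drawn in the boxplots, for cross-checking against
    the summaries table).  Empty input is a warning no-op."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(records) == 0:
        import warnings

        warnings.warn("no records; no figures rendered")
        return {}
    facilities = sorted(records["hc_id"].unique())
    meta: dict[str, dict] = {}

    # 1. missing/not-feasible fractions per facility, one panel per sign
    fig = Figure(figsize=(12, 8))
    axes = fig.subplots(2, 4).ravel()
    for ax, sign in zip(axes, SIGN_ORDER):
        fracs = []
        for hc in facilities:
            sub = records[records["hc_id"] == hc]
            eligible = sub[f"{sign}_status"] != NOT_APPLICABLE
            n_eligible = int(eligible.sum())
            measured = (sub[f"{sign}_status"] == MEASURED).sum()
            fracs.append(1 - measured / n_eligible if n_eligible else np.nan)
        ax.bar(range(len(facilities)), fracs, color="#4878a8")
        ax.set_title(sign)
        ax.set_xticks(range(len(facilities)))
        ax.set_xticklabels(facilities, rotation=90, fontsize=6)
        ax.set_ylabel("missing fraction")
    axes[-1].axis("off")
    fig.tight_layout()
    _savefig(fig, out_dir / "missing_by_facility.svg")
    meta["missing_by_facility.svg"] = {"signs": list(SIGN_ORDER)}

    # 2. boxplots per facility with the pooled distribution alongside
    fig = Figure(figsize=(12, 8))
    axes = fig.subplots(2, 4).ravel()
    medians: dict[str, dict[str, float]] = {}
    for ax, sign in zip(axes, SIGN_ORDER):
        data, labels = [], []
        for hc in facilities:
            vals = _measured(records[records["hc_id"] == hc], sign)
            if len(vals):
                data.append(vals.to_numpy())
                labels.append(hc)
        pooled = _measured(records, sign)
        if len(pooled):
            data.append(pooled.to_numpy())
            labels.append("ALL")
        if not data:
            ax.axis("off")
            continue
        ax.boxplot(data, tick_labels=labels, showfliers=False)
        ax.set_title(f"{sign} ({SIGNS[sign].unit})")
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        medians[sign] = {l: float(np.median(d)) for l, d in zip(labels, data)}
    axes[-1].axis("off")
    fig.tight_layout()
    _savefig(fig, out_dir / "boxplots_by_facility.svg")
    meta["boxplots_by_facility.svg"] = {"medians": medians}

    # 3. density plots (per facility, pooled overlaid)
    from scipy.stats import gaussian_kde

    fig = Figure(figsize=(12, 8))
    axes = fig.subplots(2, 4).ravel()
    for ax, sign in zip(axes, SIGN_ORDER):
        pooled = _measured(records, sign).to_numpy()
        if len(pooled) < 3 or np.ptp(pooled) == 0:
            ax.axis("off")
            continue
        grid = np.linspace(pooled.min(), pooled.max(), 200)
        for hc in facilities:
            vals = _measured(records[records["hc_id"] == hc], sign).to_numpy()
            if len(vals) > 2 and np.ptp(vals) > 0:
                ax.plot(grid, gaussian_kde(vals)(grid), lw=0.7, alpha=0.6)
        ax.plot(grid, gaussian_kde(pooled)(grid), color="black", lw=1.8, label="ALL")
        ax.set_title(sign)
        ax.legend(fontsize=6)
    axes[-1].axis("off")
    fig.tight_layout()
    _savefig(fig, out_dir / "density_by_facility.svg")
    meta["density_by_facility.svg"] = {"signs": list(SIGN_ORDER)}

    # 4. z-score histograms (clamped integer grid), if z columns present
    have_z = all(f"{ind}_zraw" in records.columns for ind in Z_INDICATORS)
    fig = Figure(figsize=(10, 4))
    axes = fig.subplots(1, len(Z_INDICATORS))
    for ax, ind in zip(np.atleast_1d(axes), Z_INDICATORS):
        if have_z:
            z = pd.to_numeric(records[f"{ind}_zraw"], errors="coerce").dropna()
            ax.hist(z, bins=np.arange(-5, 5.25, 0.25), color="#4878a8")
            ax.axvline(-2, color="red", lw=0.8)
            ax.axvline(2, color="red", lw=0.8)
        ax.set_title(ind)
    fig.tight_layout()
    _savefig(fig, out_dir / "zscore_distributions.svg")
    meta["zscore_distributions.svg"] = {"indicators": list(Z_INDICATORS)}
    return meta
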