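"""Correlation report between network variables and flow parameters.

Associations are quantified with the two-tailed Pearson test (significance
level 0.05), complete-case per variable pair, with correlation strength
categorized by |r|: [0, 0.30) negligible, [0.30, 0.50) low, [0.50, 0.70)
moderate, [0.70, 0.90) high, [0.90, 1] very high. A sensitivity re-analysis
drops high junction-exponent outliers (JE above a threshold, default 4)
before re-correlating the collecting-junction exponent with velocity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, InsufficientDataError, UndefinedCorrelationError

NETWORK_VARIABLES = (
    "feeder_distance_um",
    "depth_um",
    "branch_order",
    "je_upstream",
    "je_downstream",
)
FLOW_VARIABLES = ("v_ave", "v_min", "v_max", "pulsatility")

STRENGTH_BINS = (
    (0.30, "negligible"),
    (0.50, "low"),
    (0.70, "moderate"),
    (0.90, "high"),
    (np.inf, "very_high"),
)


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    n: int
    r: float
    p: float
    strength: str


def pearson(x, y) -> tuple:
    """Complete-case Pearson correlation: returns (r, p, n).

    The p-value is the two-tailed probability of t = r*sqrt((n-2)/(1-r^2))
    on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("x and y must be paired (same length)")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), int(n)


def strength_category(r: float) -> str:
    """Correlation strength label by |r| (left-closed bins; 0.30 -> low)."""
    a = abs(float(r))
    if a > 1:
        raise InputError(f"|r| = {a} > 1")
    for upper, label in STRENGTH_BINS:
        if a < upper:
            return label
    return "very_high"


def correlate(records: pd.DataFrame, x_name: str, y_name: str) -> CorrelationResult:
    r, p, n = pearson(records[x_name], records[y_name])
    return CorrelationResult(x_name, y_name, n, r, p, strength_category(r))


def network_flow_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-vessel records -> distribution + correlation report.

    One row per network variable (feeder distance, depth, branch order,
    upstream and downstream junction exponents): number of vessels with the
    variable, its mean (median for branch order) and range, and Pearson r
    against each flow parameter with p<0.05 / p<0.01 flags. Cells with fewer
    than 3 complete pairs or a constant variable are NA.
    """
    rows = []
    for var in NETWORK_VARIABLES:
        if var in records.columns:
            vals = pd.to_numeric(records[var], errors="coerce").to_numpy(dtype=float)
        else:
            vals = np.full(len(records), np.nan)
        ok = np.isfinite(vals)
        row = {
            "variable": var,
            "n": int(ok.sum()),
            "average": np.nan,
            "min": np.nan,
            "max": np.nan,
        }
        if ok.any():
            center = np.median(vals[ok]) if var == "branch_order" else np.mean(vals[ok])
            row.update(average=float(center), min=float(vals[ok].min()), max=float(vals[ok].max()))
        for flow in FLOW_VARIABLES:
            r = p = np.nan
            n_pair = 0
            if flow in records.columns:
                try:
                    r, p, n_pair = pearson(vals, pd.to_numeric(records[flow], errors="coerce"))
                except (InsufficientDataError, UndefinedCorrelationError):
                    pass
            row[f"r_{flow}"] = r
            row[f"p_{flow}"] = p
            row[f"n_{flow}"] = n_pair
            row[f"sig05_{flow}"] = bool(np.isfinite(p) and p < 0.05)
            row[f"sig01_{flow}"] = bool(np.isfinite(p) and p < 0.01)
        rows.append(row)
    return pd.DataFrame(rows)


def outlier_rerun(records: pd.DataFrame, je_threshold: float = 4.0) -> dict:
    """Sensitivity re-analysis: drop vessels with je_downstream above the
    threshold and re-correlate the collecting-junction exponent with v_ave
    and v_min. Returns the two results and the number of vessels removed."""
    je = pd.to_numeric(records["je_downstream"], errors="coerce")
    have = je.notna()
    keep = have & (je <= je_threshold)
    n_removed = int((have & ~keep).sum())
    subset = records.loc[keep]
    out = {"je_threshold": je_threshold, "n_removed": n_removed}
    for flow in ("v_ave", "v_min"):
        r, p, n = pearson(subset["je_downstream"], subset[flow])
        out[flow] = CorrelationResult("je_downstream", flow, n, r, p, strength_category(r))
    return out


def format_report(table: pd.DataFrame, rerun: Optional[dict] = None) -> str:
    """Human-readable text rendering of the correlation report."""
    lines = [
        f"{'variable':<20}{'n':>4}{'average':>10}{'range':>16}"
        + "".join(f"{('r_' + f):>14}" for f in FLOW_VARIABLES)
    ]
    for _, row in table.iterrows():
        rng = (
            f"{row['min']:.3g}-{row['max']:.3g}" if np.isfinite(row["min"]) else "NA"
        )
        cells = ""
        for f in FLOW_VARIABLES:
            r = row[f"r_{f}"]
            if not np.isfinite(r):
                cells += f"{'NA':>14}"
            else:
                star = "**" if row[f"sig01_{f}"] else ("*" if row[f"sig05_{f}"] else "")
                cells += f"{f'{r:.2f}{star}':>14}"
        avg = f"{row['average']:.2f}" if np.isfinite(row["average"]) else "NA"
        lines.append(f"{row['variable']:<20}{row['n']:>4}{avg:>10}{rng:>16}" + cells)
    lines.append("*: p<0.05, **: p<0.01 (two-tailed Pearson)")
    if rerun is not None:
        lines.append(
            f"outlier rerun (je_downstream <= {rerun['je_threshold']}, "
            f"{rerun['n_removed']} removed): "
            + ", ".join(
                f"r({f}) = {rerun[f].r:.2f} (p = {rerun[f].p:.3f}, n = {rerun[f].n})"
                for f in ("v_ave", "v_min")
            )
        )
    return "\n".join(lines)
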