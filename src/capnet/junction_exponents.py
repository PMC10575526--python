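"""Junction exponent fitting (generalized Murray's law).

At a three-way vascular junction the major (widest) vessel radius relates to
the two minor radii through an exponent x:

    R_major ** x = R_minor1 ** x + R_minor2 ** x

Murray's law (minimum-energy branching under Poiseuille flow) predicts
x = 3; retinal microvessels typically fit lower exponents. The exponent is
estimated by brute force: for every candidate x on a grid the parent radius
predicted from the daughters, (r1**x + r2**x)**(1/x), is compared with the
measured parent radius and the candidate minimizing the squared error wins.

A junction is only fittable when all three radii are available and the
classical parent (upstream vessel at a bifurcation, collector at a
confluence) is in fact the widest: the power-mean form cannot produce a
parent narrower than the widest daughter.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InputError
from .network_model import JunctionKind, VascularNetwork

#: default brute-force grid: x = 0.01 ... 10.00 in steps of 0.01
#: (x = 0 is excluded: the 1/x root is undefined there)
DEFAULT_GRID = np.arange(1, 1001) / 100.0

#: measured radii agreeing within this margin (um) count as "not widest"
WIDEST_ATOL_UM = 0.01


class FitSide(str, Enum):
    UPSTREAM = "UPSTREAM"      # supplying (arteriolar) junction of the vessel of interest
    DOWNSTREAM = "DOWNSTREAM"  # collecting (venular) junction


class FitStatus(str, Enum):
    FIT = "FIT"
    NONFIT_MISSING_RADIUS = "NONFIT_MISSING_RADIUS"
    NONFIT_PARENT_NOT_WIDEST = "NONFIT_PARENT_NOT_WIDEST"


@dataclass
class JunctionExponentFit:
    junction_id: Optional[str]
    side: Optional[FitSide]
    status: FitStatus
    exponent: Optional[float] = None   # grid value in (0, 10]
    sse: Optional[float] = None        # um^2
    r_parent: Optional[float] = None   # um
    r_daughter1: Optional[float] = None
    r_daughter2: Optional[float] = None


def check_fittable(r_parent, r_d1, r_d2, widest_atol: float = WIDEST_ATOL_UM) -> FitStatus:
    """Admissibility of a junction for exponent fitting.

    Returns ``NONFIT_MISSING_RADIUS`` when any radius is absent,
    ``NONFIT_PARENT_NOT_WIDEST`` when the parent does not exceed both
    daughters by more than *widest_atol* um, else ``FIT``.
    """
    radii = (r_parent, r_d1, r_d2)
    for r in radii:
        if r is not None and not np.isnan(r) and r <= 0:
            raise InputError(f"non-positive radius {r}")
    if any(r is None or np.isnan(r) for r in radii):
        return FitStatus.NONFIT_MISSING_RADIUS
    if r_parent <= max(r_d1, r_d2) + widest_atol:
        return FitStatus.NONFIT_PARENT_NOT_WIDEST
    return FitStatus.FIT


def predict_parent_radius(r_d1, r_d2, x):
    """Power-mean parent radius (r_d1**x + r_d2**x) ** (1/x); um.

    Vectorized over *x*. Strictly decreasing in x for unequal daughters and
    tending to max(r_d1, r_d2) as x grows.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise InputError("exponent x must be > 0")
    if r_d1 <= 0 or r_d2 <= 0:
        raise InputError("daughter radii must be > 0")
    # factor out the larger radius for numerical stability at large x
    rmax, rmin = max(r_d1, r_d2), min(r_d1, r_d2)
    out = rmax * (1.0 + (rmin / rmax) ** x) ** (1.0 / x)
    return float(out) if out.ndim == 0 else out


def fit_junction_exponent(
    r_parent,
    r_d1,
    r_d2,
    grid: np.ndarray = DEFAULT_GRID,
    junction_id: Optional[str] = None,
    side: Optional[FitSide] = None,
) -> JunctionExponentFit:
    """Brute-force SSE grid search for the junction exponent.

    For each candidate x on *grid* the squared error
    (r_parent - predicted_parent(x))**2 is evaluated; the minimizing x is
    returned (ties -> the smallest x). Ineligible inputs yield a NONFIT
    record carrying no exponent.
    """
    status = check_fittable(r_parent, r_d1, r_d2)
    fit = JunctionExponentFit(
        junction_id=junction_id,
        side=side,
        status=status,
        r_parent=r_parent,
        r_daughter1=r_d1,
        r_daughter2=r_d2,
    )
    if status is not FitStatus.FIT:
        return fit
    pred = predict_parent_radius(r_d1, r_d2, grid)
    sq_err = (r_parent - pred) ** 2
    i = int(np.argmin(sq_err))  # argmin takes the first minimum -> smallest x on ties
    fit.exponent = float(grid[i])
    fit.sse = float(sq_err[i])
    return fit


def fit_all(
    net: VascularNetwork,
    voi_ids=None,
    grid: np.ndarray = DEFAULT_GRID,
) -> pd.DataFrame:
    """Fit the supplying and collecting junction exponents of each vessel.

    For every vessel of interest, an UPSTREAM record is produced when its
    supplying junction exists and is a bifurcation, and a DOWNSTREAM record
    when its collecting junction exists and is a confluence (upstream and
    downstream ends correspond to arteriolar and venular junctions
    respectively). Radii are half the measured lumen diameters.
    """
    if voi_ids is None:
        voi_ids = sorted(net.segments)
    rows = []
    for vid in voi_ids:
        net._check_id(vid)
        for side, junction in (
            (FitSide.UPSTREAM, net.upstream_junction(vid)),
            (FitSide.DOWNSTREAM, net.downstream_junction(vid)),
        ):
            if junction is None:
                continue
            if side is FitSide.UPSTREAM and junction.kind is not JunctionKind.BIFURCATION:
                continue
            if side is FitSide.DOWNSTREAM and junction.kind is not JunctionKind.CONFLUENCE:
                continue
            r_parent = net.segments[junction.major_id].radius
            r_d1 = net.segments[junction.minor_ids[0]].radius
            r_d2 = net.segments[junction.minor_ids[1]].radius
            fit = fit_junction_exponent(
                r_parent, r_d1, r_d2, grid=grid, junction_id=junction.id, side=side
            )
            rows.append(
                {
                    "voi_id": vid,
                    "junction_id": junction.id,
                    "side": side.value,
                    "status": fit.status.value,
                    "exponent": fit.exponent,
                    "sse_um2": fit.sse,
                    "r_parent_um": r_parent,
                    "r_daughter1_um": r_d1,
                    "r_daughter2_um": r_d2,
                }
            )
    cols = [
        "voi_id", "junction_id", "side", "status", "exponent", "sse_um2",
        "r_parent_um", "r_daughter1_um", "r_daughter2_um",
    ]
    return pd.DataFrame(rows, columns=cols)


def fit_summary(fits: pd.DataFrame) -> pd.Series:
    """Counts of FIT vs NONFIT records by reason."""
    return fits["status"].value_counts().reindex(
        [s.value for s in FitStatus], fill_value=0
    )
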