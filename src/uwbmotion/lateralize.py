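"""Left/right movement attribution and asymmetry percentages.

Combines the two radars' per-second movement series into side totals and
the asymmetry indices Lt/Total (%) and Rt/Total (%) — the fraction of all
quantified movement attributed to each side of the body.  A second enters
the totals only if it is non-missing on *both* sides, so caregiver
exclusions cannot bias the ratio toward whichever radar kept recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import MovementSeries

__all__ = ["AsymmetryResult", "compute_asymmetry", "asymmetry_timeline"]

logger = logging.getLogger(__name__)


@dataclass
class AsymmetryResult:
    """Side-attributed movement totals and percentages for one session.

    When ``total_left + total_right == 0`` the percentages are undefined and
    reported as NaN with ``defined=False``.
    """

    total_left: float
    total_right: float
    lt_over_total_pct: float
    rt_over_total_pct: float
    n_seconds_used: int
    session_id: str = ""
    defined: bool = True


def _median_nonzero(values: np.ndarray) -> float:
    nz = values[values > 0]
    return float(np.median(nz)) if nz.size else 1.0


def compute_asymmetry(
    left: MovementSeries,
    right: MovementSeries,
    normalize_gains: bool = False,
    session_id: str = "",
) -> AsymmetryResult:
    """Compute Lt/Total and Rt/Total over jointly valid seconds.

    ``normalize_gains=True`` divides each side's per-second series by its
    session-median nonzero value before totaling, compensating for the two
    radars sitting at slightly different distances (different antenna
    gains).  Off by default: raw amplitude-difference totals.
    """
    if left.per_second is None or right.per_second is None:
        raise ValueError("both series must be aggregated per second first")
    n = min(left.per_second.shape[0], right.per_second.shape[0])
    ls, rs = left.per_second[:n], right.per_second[:n]
    valid = ~np.isnan(ls) & ~np.isnan(rs)
    if not valid.any():
        raise ValueError("no jointly valid (non-missing) seconds")
    ls, rs = ls[valid], rs[valid]
    if normalize_gains:
        ls = ls / _median_nonzero(ls)
        rs = rs / _median_nonzero(rs)
    total_left = float(ls.sum())
    total_right = float(rs.sum())
    total = total_left + total_right
    if total > 0:
        lt_pct = 100.0 * total_left / total
        rt_pct = 100.0 * total_right / total
        defined = True
    else:
        lt_pct = rt_pct = float("nan")
        defined = False
    return AsymmetryResult(
        total_left=total_left,
        total_right=total_right,
        lt_over_total_pct=lt_pct,
        rt_over_total_pct=rt_pct,
        n_seconds_used=int(valid.sum()),
        session_id=session_id,
        defined=defined,
    )


def asymmetry_timeline(sessions: list[AsymmetryResult]) -> pd.DataFrame:
    """Chronologically ordered per-session asymmetry table for trend display."""
    if not sessions:
        logger.warning("asymmetry_timeline called with no sessions")
    rows = [
        {
            "session_id": s.session_id,
            "lt_over_total_pct": s.lt_over_total_pct,
            "rt_over_total_pct": s.rt_over_total_pct,
            "n_seconds_used": s.n_seconds_used,
            "defined": s.defined,
        }
        for s in sessions
    ]
    return pd.DataFrame(
        rows,
        columns=["session_id", "lt_over_total_pct", "rt_over_total_pct",
                 "n_seconds_used", "defined"],
    )
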