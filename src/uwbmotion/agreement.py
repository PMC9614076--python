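"""Cross-modal agreement: Lin's concordance correlation coefficient.

Radar, actigraphy and video tracking all measure the same underlying limb
movement, but in incommensurate units (summed amplitude differences,
accelerometer counts, pixels).  Agreement between any two aligned 1 Hz
series is quantified with Lin's concordance correlation coefficient (CCC),

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)

with population (1/n) moments, which penalizes both imprecision (scatter
about the best-fit line) and inaccuracy (location/scale shifts from the
identity line).  Confidence intervals are built on the Fisher
z-transformation z = atanh(rho_c):

* ``fisher_simple`` — z +/- z_{1-a/2} / sqrt(n-3), back-transformed;
* ``lin_variance``  — same transform with Lin's asymptotic variance of z;
* ``bootstrap``     — seeded percentile bootstrap.

Because the units differ across modalities, series are z-scored by default
before the CCC (recorded in every output row); ``normalization="none"``
reproduces raw-unit behavior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import MovementSeries, aggregate_per_second

__all__ = ["AlignedPair", "AgreementResult", "align_pair", "ccc", "ccc_ci",
           "agreement_table"]

NORMALIZATIONS = ("none", "zscore", "unit_median")
CI_METHODS = ("fisher_simple", "lin_variance", "bootstrap")


@dataclass
class AlignedPair:
    """Two equal-length 1 Hz series with missing seconds removed pairwise."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, str, str] = ("a", "b", "")  # (modality, modality, side)
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")
        if self.n < 4:
            raise ValueError(f"need at least 4 jointly valid seconds, got {self.n}")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValueError("aligned pair must not contain missing values")

    @property
    def n(self) -> int:
        return self.x.shape[0]


@dataclass
class AgreementResult:
    """CCC point estimate with its 95% (or 1-alpha) confidence interval."""

    rho_z: float
    ci_low: float
    ci_high: float
    ci_method: str
    n: int
    labels: tuple[str, str, str] = ("a", "b", "")
    normalization: str = "none"


def _to_1hz(series) -> np.ndarray:
    if isinstance(series, MovementSeries):
        if series.per_second is None:
            series = aggregate_per_second(series)
        return series.per_second
    return np.asarray(series, dtype=float)


def _normalize(v: np.ndarray, how: str) -> np.ndarray:
    if how == "none":
        return v
    if how == "zscore":
        sd = v.std()
        if sd == 0:
            raise ValueError("cannot z-score a constant series")
        return (v - v.mean()) / sd
    if how == "unit_median":
        nz = v[v > 0]
        med = np.median(nz) if nz.size else 1.0
        return v / med if med > 0 else v
    raise ValueError(f"unknown normalization {how!r}; choose from {NORMALIZATIONS}")


def align_pair(a, b, normalization: str = "zscore",
               labels: tuple[str, str, str] = ("a", "b", "")) -> AlignedPair:
    """Align two 1 Hz series on the session clock and drop missing seconds.

    Accepts :class:`MovementSeries` (aggregated to 1 Hz if needed) or plain
    arrays.  A second missing in either series is dropped from both; each
    surviving series is then normalized per ``normalization``.
    """
    x, y = _to_1hz(a), _to_1hz(b)
    n = min(x.shape[0], y.shape[0])
    x, y = x[:n], y[:n]
    valid = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[valid], y[valid]
    if x.shape[0] < 4:
        raise ValueError(
            f"only {x.shape[0]} jointly valid seconds; need at least 4"
        )
    return AlignedPair(
        x=_normalize(x, normalization),
        y=_normalize(y, normalization),
        labels=labels,
        normalization=normalization,
    )


def ccc(pair_or_x, y=None, ddof: int = 0) -> float:
    """Lin's concordance correlation coefficient.

    ``ddof=0`` (population 1/n moments) is Lin's original definition;
    ``ddof=1`` matches software that uses sample (1/(n-1)) moments — with
    the squared mean difference unscaled, the two differ slightly.
    """
    if isinstance(pair_or_x, AlignedPair):
        x, yy = pair_or_x.x, pair_or_x.y
    else:
        x = np.asarray(pair_or_x, dtype=float)
        yy = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    mx, my = x.mean(), yy.mean()
    vx = x.var(ddof=ddof)
    vy = yy.var(ddof=ddof)
    sxy = ((x - mx) * (yy - my)).sum() / (n - ddof)
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: both series constant and equal")
    return float(2.0 * sxy / denom)


def _lin_z_variance(x: np.ndarray, y: np.ndarray, rho_c: float) -> float:
    """Lin's asymptotic variance of z = atanh(rho_c)."""
    n = x.shape[0]
    r = float(np.corrcoef(x, y)[0, 1])
    sx, sy = x.std(), y.std()
    u = (x.mean() - y.mean()) / np.sqrt(sx * sy)
    c2 = rho_c ** 2
    one_m = 1.0 - c2
    var_z = (
        (1.0 - r ** 2) * c2 / (one_m * r ** 2)
        + 2.0 * rho_c ** 3 * (1.0 - rho_c) * u ** 2 / (r * one_m ** 2)
        - rho_c ** 4 * u ** 4 / (2.0 * r ** 2 * one_m ** 2)
    ) / (n - 2)
    return var_z


def ccc_ci(
    pair: AlignedPair,
    method: str = "fisher_simple",
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int | None = None,
) -> AgreementResult:
    """Confidence interval for the CCC via the chosen method."""
    if method not in CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}; choose from {CI_METHODS}")
    n = pair.n
    if method in ("fisher_simple", "lin_variance") and n < 8:
        raise ValueError(f"asymptotic CI needs n >= 8, got {n}")
    point = ccc(pair)

    if abs(point) >= 1.0 - 1e-12:
        warnings.warn(
            "|CCC| = 1: returning a degenerate point-mass interval",
            RuntimeWarning,
        )
        return AgreementResult(point, point, point, method, n,
                               pair.labels, pair.normalization)

    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    if method == "fisher_simple":
        z = np.arctanh(point)
        hw = zcrit / np.sqrt(n - 3)
        lo, hi = np.tanh(z - hw), np.tanh(z + hw)
    elif method == "lin_variance":
        z = np.arctanh(point)
        se = np.sqrt(_lin_z_variance(pair.x, pair.y, point))
        lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    else:  # bootstrap
        if n < 20:
            raise ValueError(f"bootstrap CI needs n >= 20, got {n}")
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            reps[b] = ccc(pair.x[idx], pair.y[idx])
        lo = float(np.quantile(reps, alpha / 2.0))
        hi = float(np.quantile(reps, 1.0 - alpha / 2.0))
    lo, hi = min(float(lo), point), max(float(hi), point)
    return AgreementResult(point, lo, hi, method, n,
                           pair.labels, pair.normalization)


def agreement_table(
    pairs: list[AlignedPair],
    method: str = "fisher_simple",
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """One agreement row per (device pair, side), deterministically ordered.

    Pairs whose CI computation fails are kept as flagged rows (NaN
    estimates plus the error message) rather than silently dropped.
    """
    if not pairs:
        raise ValueError("need at least one aligned pair")
    rows = []
    for pair in pairs:
        device = f"{pair.labels[0]} vs {pair.labels[1]}"
        side = pair.labels[2]
        try:
            res = ccc_ci(pair, method=method, alpha=alpha, seed=seed)
            rows.append({
                "Device": device, "Side": side, "rho_z": res.rho_z,
                "ci_low": res.ci_low, "ci_high": res.ci_high, "n": res.n,
                "ci_method": res.ci_method,
                "normalization": pair.normalization, "error": "",
            })
        except ValueError as exc:
            rows.append({
                "Device": device, "Side": side, "rho_z": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "n": pair.n,
                "ci_method": method, "normalization": pair.normalization,
                "error": str(exc),
            })
    df = pd.DataFrame(rows)
    return df.sort_values(["Device", "Side"], kind="stable").reset_index(drop=True)
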