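"""Min–max normalization and pairwise Granger-causality connectivity.

Normalization maps a signal affinely onto [−1, 1]:

    X = 2 · (E − E_min) / (E_max − E_min) − 1

Granger causality between a driver x and a response y is tested by
comparing two ordinary-least-squares autoregressions of y on the common
sample (the first p points dropped):

    restricted:    y(t) = c + Σ_{i=1..p} a_i · y(t−i) + e(t)
    unrestricted:  y(t) = c + Σ_{i=1..p} a_i · y(t−i)
                            + Σ_{j=1..p} b_j · x(t−j) + ẽ(t)

and forming the F-statistic

    F = ((RSS_r − RSS_u) / p) / (RSS_u / (n_eff − 2p − 1))

with n_eff = n − p observations in both fits.  A large F means x's past
improves the prediction of y beyond y's own past — x "Granger-causes" y.
The classical binary verdict (variance of ẽ smaller than variance of e at
the α = 0.05 critical value) is exposed as a convenience on the result,
but the pipeline's quantifier works on the raw F values.

The lag order p is either fixed or selected per pair by minimizing the
Bayesian information criterion of the unrestricted model over 1..max_lag.

Connectivity matrices are oriented row = target, column = source: entry
(i, j) holds the F-statistic for "signal j Granger-causes signal i".  The
diagonal is undefined and stored as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CollinearityError",
    "ConnectivityMatrix",
    "GCResult",
    "NormalizedSignal",
    "ZeroDynamicRangeError",
    "connectivity_matrix",
    "granger_f",
    "normalize",
]

LagPolicy = int | Literal["bic"]
DEFAULT_MAX_LAG = 20


class ZeroDynamicRangeError(ValueError):
    """Raised when normalizing a constant signal (E_max == E_min)."""


class CollinearityError(ValueError):
    """Raised when a regression design matrix is rank-deficient."""


@dataclass(frozen=True)
class NormalizedSignal:
    """A signal mapped onto [−1, 1] with its source extrema retained."""

    values: np.ndarray
    e_min: float
    e_max: float


def normalize(signal: np.ndarray | Sequence[float]) -> NormalizedSignal:
    """Affinely map a signal onto [−1, 1] (E_min → −1, E_max → +1).

    Raises
    ------
    ZeroDynamicRangeError
        For a constant signal, where the map is undefined.
    """
    values = np.asarray(signal, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError(f"expected a 1-D signal of length >= 2, got {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("signal contains non-finite values")
    e_min = float(values.min())
    e_max = float(values.max())
    if e_max == e_min:
        raise ZeroDynamicRangeError(
            f"zero dynamic range: constant signal at {e_min}"
        )
    scaled = 2.0 * (values - e_min) / (e_max - e_min) - 1.0
    return NormalizedSignal(values=scaled, e_min=e_min, e_max=e_max)


@dataclass(frozen=True)
class GCResult:
    """One directed Granger-causality test."""

    f_stat: float
    p_lags: int
    n_effective: int
    rss_restricted: float
    rss_unrestricted: float

    @property
    def df_denom(self) -> int:
        return self.n_effective - 2 * self.p_lags - 1

    def critical_value(self, alpha: float = 0.05) -> float:
        return float(stats.f.ppf(1.0 - alpha, self.p_lags, self.df_denom))

    @property
    def causal(self) -> bool:
        """Binary Granger verdict: F beyond the α = 0.05 critical value."""
        return self.f_stat > self.critical_value()


def _lag_matrix(signal: np.ndarray, p: int, n_eff: int) -> np.ndarray:
    """Columns [s(t−1), ..., s(t−p)] aligned with the last n_eff samples."""
    n = len(signal)
    return np.column_stack([signal[n - n_eff - k : n - k] for k in range(1, p + 1)])


def _ols_rss(design: np.ndarray, response: np.ndarray) -> float:
    coefs, residual, rank, _ = np.linalg.lstsq(design, response, rcond=None)
    if rank < design.shape[1]:
        raise CollinearityError(
            f"rank-deficient design matrix (rank {rank} < {design.shape[1]} "
            "columns); regressors are collinear"
        )
    fitted = design @ coefs
    return float(np.sum((response - fitted) ** 2))


def _fit_pair(x: np.ndarray, y: np.ndarray, p: int) -> GCResult:
    n = len(y)
    n_eff = n - p
    response = y[p:]
    ones = np.ones((n_eff, 1))
    y_lags = _lag_matrix(y, p, n_eff)
    x_lags = _lag_matrix(x, p, n_eff)
    rss_r = _ols_rss(np.hstack([ones, y_lags]), response)
    rss_u = _ols_rss(np.hstack([ones, y_lags, x_lags]), response)
    rss_u = min(rss_u, rss_r)  # guard float jitter; adding regressors cannot raise RSS
    df_denom = n_eff - 2 * p - 1
    if rss_u <= 0:
        f = np.inf
    else:
        f = ((rss_r - rss_u) / p) / (rss_u / df_denom)
    return GCResult(
        f_stat=float(max(f, 0.0)),
        p_lags=p,
        n_effective=n_eff,
        rss_restricted=rss_r,
        rss_unrestricted=rss_u,
    )


def _bic_lag(x: np.ndarray, y: np.ndarray, max_lag: int) -> int:
    best_p, best_bic = 1, np.inf
    for p in range(1, max_lag + 1):
        n_eff = len(y) - p
        if n_eff <= 2 * p + 1:
            break
        response = y[p:]
        design = np.hstack(
            [np.ones((n_eff, 1)), _lag_matrix(y, p, n_eff), _lag_matrix(x, p, n_eff)]
        )
        try:
            rss = _ols_rss(design, response)
        except CollinearityError:
            continue
        if rss <= 0:
            return p
        bic = n_eff * np.log(rss / n_eff) + (2 * p + 1) * np.log(n_eff)
        if bic < best_bic:
            best_p, best_bic = p, bic
    return best_p


def granger_f(
    x: np.ndarray | Sequence[float],
    y: np.ndarray | Sequence[float],
    lags: LagPolicy = "bic",
    max_lag: int = DEFAULT_MAX_LAG,
) -> GCResult:
    """Test whether ``x`` Granger-causes ``y``.

    Parameters
    ----------
    lags:
        Either a fixed positive lag order, or ``"bic"`` to select the order
        in 1..``max_lag`` minimizing the unrestricted model's BIC.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-D, got {x.shape}, {y.shape}")
    if lags == "bic":
        p = _bic_lag(x, y, max_lag)
    else:
        p = int(lags)
        if p < 1:
            raise ValueError(f"lag order must be >= 1, got {p}")
    if len(y) <= 3 * p + 2:
        raise ValueError(
            f"need more than {3 * p + 2} samples for lag order {p}, got {len(y)}"
        )
    return _fit_pair(x, y, p)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Directed F-statistic matrix; row = target, column = source."""

    values: np.ndarray
    labels: tuple[str, ...]
    lag_orders: np.ndarray
    n_failed: int = 0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def plot_heatmap(self, ax=None, cmap: str = "hot"):
        """Basic matrix heat map (targets on rows, sources on columns)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.values, cmap=cmap)
        ax.set_xticks(range(self.n), self.labels, rotation=90)
        ax.set_yticks(range(self.n), self.labels)
        ax.set_xlabel("source")
        ax.set_ylabel("target")
        ax.figure.colorbar(im, ax=ax, label="F-statistic")
        return ax


def connectivity_matrix(
    signals: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    lags: LagPolicy = 1,
    max_lag: int = DEFAULT_MAX_LAG,
    pre_normalize: bool = True,
) -> ConnectivityMatrix:
    """All-pairs directed Granger F-statistics.

    Each signal is min–max normalized before fitting (the F-statistic is
    invariant to affine rescaling, so this is belt-and-braces consistency
    with the pipeline definition, not a numerical necessity).  A failing
    cell — constant signal, collinear pair — yields F = 0 with a logged
    warning instead of aborting the whole matrix.
    """
    n = len(signals)
    if n < 2:
        raise ValueError(f"need at least 2 signals, got {n}")
    lengths = {len(s) for s in signals}
    if len(lengths) != 1:
        raise ValueError(f"signals differ in length: {sorted(lengths)}")
    names = tuple(labels) if labels is not None else tuple(
        f"s{i + 1}" for i in range(n)
    )
    prepared: list[np.ndarray | None] = []
    for name, sig in zip(names, signals):
        if not pre_normalize:
            prepared.append(np.asarray(sig, dtype=float))
            continue
        try:
            prepared.append(normalize(sig).values)
        except ZeroDynamicRangeError as exc:
            logger.warning("signal %s cannot be normalized (%s); its cells set to 0",
                           name, exc)
            prepared.append(None)

    values = np.zeros((n, n))
    lag_orders = np.zeros((n, n), dtype=int)
    n_failed = 0
    for i in range(n):  # target
        for j in range(n):  # source
            if i == j:
                continue
            if prepared[i] is None or prepared[j] is None:
                n_failed += 1
                continue
            try:
                res = granger_f(prepared[j], prepared[i], lags=lags, max_lag=max_lag)
            except (CollinearityError, ValueError) as exc:
                logger.warning(
                    "GC cell (target=%s, source=%s) failed: %s; F set to 0",
                    names[i], names[j], exc,
                )
                n_failed += 1
                continue
            values[i, j] = res.f_stat
            lag_orders[i, j] = res.p_lags
    return ConnectivityMatrix(
        values=values, labels=names, lag_orders=lag_orders, n_failed=n_failed
    )
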