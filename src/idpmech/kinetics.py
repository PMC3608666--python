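"""First-order kinetics fits of native-contact decay.

Unfolding/unbinding at high temperature is well described by single
exponential decay of the native-contact fraction, q(t) = exp(-k t).  The fit
is performed as linear least squares of ln q versus t, which matches the
log-scale presentation of Q traces and gives closed-form standard errors.
The half-time is t_1/2 = ln 2 / k with its standard error propagated from
the slope covariance, se(t_1/2) = ln 2 * se(k) / k^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contacts import QSeries

__all__ = ["KineticsFit", "fit_first_order", "averaged_fit"]

LN2 = float(np.log(2.0))


@dataclass
class KineticsFit:
    """Result of a first-order (single-exponential) decay fit."""

    rate: float  # k, ps^-1
    half_time: float  # ln2 / k, ps (inf when non-decaying)
    se_rate: float  # ps^-1
    se_half_time: float  # ps
    fit_window: tuple[float, float]  # [t_start, t_end], ps
    r_squared: float
    n_points: int
    decaying: bool  # False when the fitted slope is non-negative

    def __post_init__(self) -> None:
        if self.decaying and self.rate > 0:
            assert abs(self.half_time * self.rate - LN2) < 1e-9


def _window_mask(times: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        # default: first 80% of the series (kinetic phase before the
        # unfolded-equilibrium tail)
        t_end = times[0] + 0.8 * (times[-1] - times[0])
        window = (float(times[0]), float(t_end))
    t0, t1 = window
    return (times >= t0) & (times <= t1)


def fit_first_order(
    series: QSeries,
    channel: str = "qf",
    window: tuple[float, float] | None = None,
) -> KineticsFit:
    """Fit ln q = -k t + c over a time window by linear least squares.

    Parameters
    ----------
    series:
        Native-contact fraction series; ``channel`` selects ``qf`` or ``qb``.
    window:
        ``(t_start, t_end)`` in ps; default is the first 80% of the series.

    Raises
    ------
    ValueError
        If fewer than 5 frames fall in the window, or any q in the window is
        non-positive (the caller should truncate the window to the decaying,
        positive part of the trace).
    """
    q = np.asarray(series.channel(channel), dtype=float)
    t = np.asarray(series.times, dtype=float)
    mask = _window_mask(t, window)
    t = t[mask]
    q = q[mask]
    if t.size < 5:
        raise ValueError(f"need >= 5 frames in the fit window, got {t.size}")
    if np.any(q <= 0):
        raise ValueError(
            "non-positive q in the fit window; truncate the window to the "
            "region where q > 0 before fitting in log space"
        )
    res = stats.linregress(t, np.log(q))
    k = -float(res.slope)
    se_k = float(res.stderr)
    r2 = float(res.rvalue) ** 2
    decaying = k > 0
    if decaying:
        half = LN2 / k
        se_half = LN2 * se_k / k**2
    else:
        half = float("inf")
        se_half = float("inf")
    return KineticsFit(
        rate=k,
        half_time=half,
        se_rate=se_k,
        se_half_time=se_half,
        fit_window=(float(t[0]), float(t[-1])),
        r_squared=r2,
        n_points=int(t.size),
        decaying=decaying,
    )


def averaged_fit(
    replicas: list[QSeries],
    channel: str = "qf",
    window: tuple[float, float] | None = None,
) -> KineticsFit:
    """Average q over replica trajectories per timestamp, then fit.

    All replicas must share the same time grid (independent runs of one
    protocol).  Averaging before fitting suppresses per-replica shot noise
    the way pooling independent trajectories of one system does.
    """
    if not replicas:
        raise ValueError("no series given")
    t0 = np.asarray(replicas[0].times, dtype=float)
    for s in replicas[1:]:
        if not np.array_equal(np.asarray(s.times, dtype=float), t0):
            raise ValueError("replica series must share identical time grids")
    mean_q = np.mean([s.channel(channel) for s in replicas], axis=0)
    pooled = QSeries(
        times=t0,
        qf=mean_q if channel == "qf" else None,
        qb=mean_q if channel == "qb" else None,
        n_native_tertiary=replicas[0].n_native_tertiary,
        n_native_binding=replicas[0].n_native_binding,
    )
    return fit_first_order(pooled, channel=channel, window=window)
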