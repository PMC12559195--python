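"""Log-spaced raised-cosine temporal basis.

A compact basis for 1 s cue histories: a handful of overlapping cosine
bumps whose peak lags are spaced logarithmically, so recent history is
represented at fine resolution and the distant past coarsely.  Filters
fitted in basis space are recovered on the lag grid by back-projection.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RaisedCosineBasis"]


class RaisedCosineBasis:
    """Raised-cosine bumps on a log-warped lag axis.

    Each basis function is ``b_j(t) = 0.5 * (1 + cos(pi/2 * (phi(t) - phi_j) / dphi))``
    for ``|phi(t) - phi_j| <= 2 * dphi`` and zero elsewhere, with the warp
    ``phi(t) = log(t + c)``.  Peak positions ``phi_j`` are equally spaced in
    warped time, so the peak lags are log-spaced and successive bumps widen
    toward longer lags.  Columns peak at 1 by construction.

    Parameters
    ----------
    n_basis : int
        Number of bumps (default 4).
    window_s : float
        Length of the history window in seconds (default 1.0).  The lag
        grid covers ``(0, window_s]`` at ``rate_hz``, strictly preceding
        the predicted frame.
    rate_hz : float
        Sampling rate of the lag grid.
    first_peak_s, last_peak_s : float
        Lags of the first and last peaks.  Defaults put the first peak
        near 40 ms and the last at 85% of the window, keeping every peak
        strictly inside the window.
    log_offset_s : float
        Warp offset ``c`` in ``log(t + c)``; controls how strongly early
        lags are magnified.
    """

    def __init__(
        self,
        n_basis: int = 4,
        window_s: float = 1.0,
        rate_hz: float = 50.0,
        first_peak_s: float = 0.04,
        last_peak_s: float | None = None,
        log_offset_s: float = 0.01,
    ):
        if n_basis < 1:
            raise ValueError("n_basis must be >= 1")
        if window_s <= 0 or rate_hz <= 0:
            raise ValueError("window_s and rate_hz must be positive")
        n_lags = int(round(window_s * rate_hz))
        if n_lags < 2:
            raise ValueError(
                f"window of {window_s} s at {rate_hz} Hz yields {n_lags} lag "
                "samples; need at least 2"
            )
        if last_peak_s is None:
            last_peak_s = 0.85 * window_s
        if not (0 < first_peak_s <= last_peak_s < window_s):
            raise ValueError("need 0 < first_peak_s <= last_peak_s < window_s")

        self.n_basis = int(n_basis)
        self.window_s = float(window_s)
        self.rate_hz = float(rate_hz)
        self.first_peak_s = float(first_peak_s)
        self.last_peak_s = float(last_peak_s)
        self.log_offset_s = float(log_offset_s)

        c = self.log_offset_s
        # lag grid tau = 1/rate .. window (strictly preceding the frame)
        self.lags_s = np.arange(1, n_lags + 1) / self.rate_hz
        phi = np.log(self.lags_s + c)
        phi_peaks = np.linspace(
            np.log(first_peak_s + c), np.log(last_peak_s + c), self.n_basis
        )
        if self.n_basis > 1:
            dphi = phi_peaks[1] - phi_peaks[0]
        else:
            dphi = np.log(window_s + c) - np.log(first_peak_s + c)
        arg = (phi[:, None] - phi_peaks[None, :]) * (np.pi / (2.0 * dphi))
        B = 0.5 * (1.0 + np.cos(np.clip(arg, -np.pi, np.pi)))
        # normalize to unit peak (the analytic peak may fall between grid lags)
        B = B / B.max(axis=0, keepdims=True)
        self.B = B
        self.phi_peaks = phi_peaks
        self.peak_lags_s = np.exp(phi_peaks) - c

    @property
    def n_lags(self) -> int:
        return self.B.shape[0]

    def project(self, filters: np.ndarray) -> np.ndarray:
        """Least-squares coefficients of temporal filters in the basis.

        ``filters`` has lags on its last axis; returns the same shape with
        the lag axis replaced by ``n_basis``.
        """
        filters = np.asarray(filters, dtype=float)
        flat = filters.reshape(-1, self.n_lags).T
        coef, *_ = np.linalg.lstsq(self.B, flat, rcond=None)
        return coef.T.reshape(filters.shape[:-1] + (self.n_basis,))

    def back_project(self, weights: np.ndarray) -> np.ndarray:
        """Temporal filters on the lag grid from basis-space weights."""
        weights = np.asarray(weights, dtype=float)
        flat = weights.reshape(-1, self.n_basis).T
        return (self.B @ flat).T.reshape(weights.shape[:-1] + (self.n_lags,))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"RaisedCosineBasis(n_basis={self.n_basis}, window_s={self.window_s}, "
            f"rate_hz={self.rate_hz})"
        )
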