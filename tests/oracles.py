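"""Independent brute-force oracles used to cross-check the fitted estimators.

These deliberately avoid the square-root transform: the induction oracle
grid-searches the first-appearance time on the *raw* signal, solving the
amplitude in closed form at each candidate, so it shares no code path with
the Schleif-plot fit it validates.
"""

from __future__ import annotations

import numpy as np


def grid_search_t_first(
    times_s: np.ndarray,
    signal: np.ndarray,
    baseline_window: int = 4,
    step_s: float = 1.0,
) -> float:
    """Least-squares first-appearance time on the raw quadratic signal.

    For each candidate T on a dense grid, the best amplitude for the hinge
    basis ``max(0, t - T)^2`` has a closed form; the T minimising the raw
    sum of squared errors is returned.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(signal, dtype=float) - signal[:baseline_window].mean()
    best_sse, best_t = np.inf, float(t[0])
    for tf in np.arange(t[0], t[-1], step_s):
        basis = np.clip(t - tf, 0.0, None) ** 2
        denom = float(basis @ basis)
        if denom == 0.0:
            continue
        amp = max(float(basis @ y) / denom, 0.0)
        sse = float(((y - amp * basis) ** 2).sum())
        if sse < best_sse:
            best_sse, best_t = sse, float(tf)
    return best_t


def exponential_rate_closed_form(od0: float, od1: float, dt_min: float) -> float:
    """Per-hour rate from two OD readings, ln(od1/od0)/dt."""
    return float(np.log(od1 / od0) / (dt_min / 60.0))
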