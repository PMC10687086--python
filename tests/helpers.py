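"""Independent numerical oracles used across the test suite.

These deliberately avoid the package's solver path: the progress-curve
oracle is a fixed-step explicit Euler march on the closed-form rate law.
"""

from __future__ import annotations

import numpy as np


def euler_progress(params, S0: float, E0: float, times, dt: float = 1e-3) -> np.ndarray:
    """Explicit-Euler integration of dP/dt = v_QSSA(S0-P, P), step dt."""
    out = np.empty(len(times))
    P, t = 0.0, 0.0
    k_cat, K_m, K_p, K_s = params.k_cat, params.K_m, params.K_p, params.K_s
    for i, tt in enumerate(times):
        n = int(round((tt - t) / dt))
        for _ in range(n):
            S = S0 - P
            if S <= 0:
                break
            P += dt * k_cat * E0 * S / (K_m * (1 + P / K_p) + S * (1 + S / K_s))
        P = min(P, S0)
        t = tt
        out[i] = P
    return out
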