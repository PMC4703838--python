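"""Independent oracles used to validate the analytic implementations.

These deliberately avoid the code paths they check: the photochemistry
oracle integrates the two-state ODE numerically (adaptive RK), and the
Welch oracle evaluates the t statistic and Welch–Satterthwaite degrees of
freedom from their textbook formulas.
"""

import math

import numpy as np
from scipy import stats
from scipy.integrate import solve_ivp


def ode_fractions(k_u: float, k_b: float, k_a: float, dose: float, retain_alcohol: bool):
    """Numerically integrate dc/dD = -(k_u+k_b)c, da/dD = k_u c - k_a a."""
    if dose == 0:
        return 1.0, 0.0, 0.0

    def rhs(_t, y):
        return [-(k_u + k_b) * y[0], k_u * y[0] - k_a * y[1]]

    sol = solve_ivp(rhs, [0.0, dose], [1.0, 0.0], rtol=1e-11, atol=1e-13)
    caged, alcohol = sol.y[:, -1]
    if not retain_alcohol:
        alcohol = 0.0
    return float(caged), float(alcohol), float(1.0 - caged - alcohol)


def welch_from_formulas(x, y):
    """Welch t, Welch–Satterthwaite df and two-sided p from first principles."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p
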