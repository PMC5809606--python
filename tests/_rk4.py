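"""Independent fixed-step RK4 oracle for the two AML models.

The right-hand side is coded here from scratch (not imported from the
package) so trajectory comparisons are a genuine dual-route check.
"""

import numpy as np


def rk4_simulate(params, y0, t_grid, stimulated=False):
    """Classic RK4 at the resolution of ``t_grid`` sub-steps.

    params: cytoaml ModelParams (only its numbers are read).
    y0: length-4 array (c1, c2, l1, l2).  Returns array (len(t_grid), 4).
    """
    a_c, p_c, d_c = params.healthy.a, params.healthy.p, params.healthy.d
    a_l, p_l, d_l = params.leukemic.a, params.leukemic.p, params.leukemic.d
    k, dbar = params.k, params.dbar
    model1 = params.variant.value == "model1"

    def f(y):
        c1, c2, l1, l2 = y
        consumers = c2 + l2 if model1 else c2
        s = 1.0 if stimulated else 1.0 / (1.0 + k * consumers)
        sig = s if model1 else 1.0
        crowd = dbar * (c1 + l1)
        return np.array(
            [
                (2.0 * a_c * s - 1.0) * p_c * c1 - crowd * c1,
                2.0 * (1.0 - a_c * s) * p_c * c1 - d_c * c2,
                (2.0 * a_l * sig - 1.0) * p_l * l1 - crowd * l1,
                2.0 * (1.0 - a_l * sig) * p_l * l1 - d_l * l2,
            ]
        )

    out = np.empty((len(t_grid), 4))
    out[0] = y = np.asarray(y0, dtype=float).copy()
    for i in range(1, len(t_grid)):
        h = t_grid[i] - t_grid[i - 1]
        k1 = f(y)
        k2 = f(y + 0.5 * h * k1)
        k3 = f(y + 0.5 * h * k2)
        k4 = f(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i] = y
    return out
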