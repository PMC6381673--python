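"""Independent line-by-line transcription of the cascade rate equations.

Deliberately written as one literal expression per species, with no
shared sub-expressions and no reuse of package internals, so it can
serve as an independent oracle for the packaged right-hand side.
"""

import numpy as np


def rhs_transcription(x, params, pools, light_on=True):
    """d(x1..x8)/dt, each equation transcribed verbatim."""
    x1, x2, x3, x4, x5, x6, x7, x8 = [float(v) for v in x]
    p = params
    R0, G0, E0, cG0, Ca0 = pools.R0, pools.G0, pools.E0, pools.cG0, pools.Ca0
    n = p.n_cG
    k1u = p.k1u if light_on else 0.0

    dx1 = (k1u * (R0 - x1 - x3)
           - p.k2 * x1 * (G0 - x3 - x2 - x4 - x5 - x7)
           + p.k3 * x3 + p.k4 * x3
           - p.k13 * (Ca0 - x8) * x1
           - p.k16 * x1)
    dx2 = p.k4 * x3 - p.k5 * x2 * (E0 - x4 - x5)
    dx3 = (p.k2 * x1 * (G0 - x3 - x2 - x4 - x5 - x7)
           - p.k3 * x3 - p.k4 * x3)
    dx4 = (p.k5 * x2 * (E0 - x4 - x5)
           - p.k6 * x4 * x6
           + p.k7 * x5 + p.k8 * x5
           - p.k9 * x4)
    dx5 = p.k6 * x4 * x6 - p.k7 * x5 - p.k8 * x5
    dx6 = (-p.k6 * x4 * x6
           + p.k7 * x5
           + p.k14 * (Ca0 - x8) * (cG0 - x6)
           + p.k15 * (cG0 - x6))
    dx7 = p.k9 * x4 - p.k10 * x7
    dx8 = -p.k11 * (cG0 ** n - x6 ** n) + p.k12 * (Ca0 - x8)

    return np.array([dx1, dx2, dx3, dx4, dx5, dx6, dx7, dx8])
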