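"""Compiled per-reaction rate evaluation.

The hot loop of every simulation.  Compiled with numba when available;
falls back to the identical pure-Python implementation otherwise.
Negative solver excursions are clamped to zero inside the rate law so the
dynamics remain well defined near the axes.
"""

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def reaction_rates(y, k_eff, km, km_idx, driver_idx, n_reac, reac_idx,
                   reac_st):
    n_rx = k_eff.shape[0]
    rates = np.empty(n_rx)
    for j in range(n_rx):
        if driver_idx[j] >= 0:
            x = y[driver_idx[j]]
            if x < 0.0:
                x = 0.0
            if km_idx[j] >= 0:
                denom = km[j] + x
                rates[j] = k_eff[j] * x / denom if denom > 0.0 else 0.0
            else:
                rates[j] = k_eff[j] * x
        else:
            r = k_eff[j]
            for i in range(n_reac[j]):
                c = y[reac_idx[j, i]]
                if c < 0.0:
                    c = 0.0
                for _ in range(reac_st[j, i]):
                    r *= c
            rates[j] = r
    return rates


@njit(cache=False)
def rhs_flat(y, k_eff, km, km_idx, driver_idx, n_reac, reac_idx, reac_st,
             stoich):
    rates = reaction_rates(y, k_eff, km, km_idx, driver_idx, n_reac,
                           reac_idx, reac_st)
    return stoich @ rates
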