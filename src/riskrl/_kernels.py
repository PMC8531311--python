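"""Compiled inner loops for likelihood evaluation.

The hierarchical fitter and the Monte-Carlo marginal likelihood both hammer
the per-subject choice likelihood (hundreds of thousands of 420-trial
replays), so the replay is a numba kernel over a flat 8-entry parameter
layout: [alpha_p(gain), alpha_p(loss), alpha_n(gain), alpha_n(loss),
beta(gain), beta(loss), kappa_gain, kappa_loss].  Models that do not split a
parameter simply repeat it across both domain entries; models without a
utility parameter carry 1.0.
"""

import numpy as np
from numba import njit

N_OPTIONS = 5


@njit(cache=True)
def loglik_one(chosen, other, outcome, domain, block_start, p8):
    """Log likelihood of one choice sequence under one parameter vector.

    Values are indexed by option within the current block and reset to zero
    whenever ``block_start`` flags a new block.  Only the chosen option's
    value is updated; the learning rate is routed by the sign of the
    prediction error and the trial's domain.  A zero prediction error leaves
    the value untouched.
    """
    q = np.zeros(N_OPTIONS)
    ll = 0.0
    for t in range(chosen.shape[0]):
        if block_start[t]:
            for j in range(N_OPTIONS):
                q[j] = 0.0
        d = domain[t]
        qc = q[chosen[t]]
        qo = q[other[t]]
        x = p8[4 + d] * qc
        y = p8[4 + d] * qo
        m = x if x > y else y
        ll += x - m - np.log(np.exp(x - m) + np.exp(y - m))
        r = outcome[t]
        if r == 2:
            u = 2.0 * p8[6]
        elif r == -2:
            u = -2.0 * p8[7]
        else:
            u = float(r)
        pe = u - qc
        if pe > 0.0:
            q[chosen[t]] = qc + p8[0 + d] * pe
        elif pe < 0.0:
            q[chosen[t]] = qc + p8[2 + d] * pe
    return ll


@njit(cache=True)
def loglik_batch(chosen, other, outcome, domain, block_start, p8_matrix):
    """Log likelihood of one choice sequence under many parameter vectors."""
    n = p8_matrix.shape[0]
    out = np.empty(n)
    for s in range(n):
        out[s] = loglik_one(
            chosen, other, outcome, domain, block_start, p8_matrix[s]
        )
    return out
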