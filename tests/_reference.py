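"""Independent, loop-based reference implementations used as test oracles.

Everything here is written deliberately straightforwardly (explicit Python
loops, direct formulas) and shares no code path with the package internals
it is used to check.
"""

import math

import numpy as np


def ref_conditional_probs(params, prefix, y, k):
    """P(a_k | a_<k, y) for every symbol, by direct energy summation."""
    q = params.q
    probs = []
    for a in range(q):
        energy = params.h[k][a]
        for alpha in range(params.d):
            energy += y[alpha] * params.G[k][a, alpha]
        for i in range(k):
            energy += params.J[k][i][a, prefix[i]]
        probs.append(math.exp(energy))
    total = sum(probs)
    return [p / total for p in probs]


def ref_log_prob(params, seq, y):
    """log P(a | y) by multiplying per-rank conditionals one at a time."""
    ranked = [seq[c] for c in params.ordering]
    logp = 0.0
    for k in range(params.L):
        probs = ref_conditional_probs(params, ranked[:k], y, k)
        logp += math.log(probs[ranked[k]])
    return logp


def ref_gaussian_logpdf(mean, cov, y):
    """Multivariate normal log-density from the explicit closed form."""
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    y = np.asarray(y, dtype=float)
    d = mean.shape[0]
    diff = y - mean
    quad = float(diff @ np.linalg.solve(cov, diff))
    _, logdet = np.linalg.slogdet(cov)
    return -0.5 * (d * math.log(2 * math.pi) + logdet + quad)


def ref_delta_e_unconditioned(params, wt, column, mut_index):
    """Delta_E of a substitution under a d = 0 model, summed rank by rank.

    Only ranks at or after the mutated rank contribute, because earlier
    conditionals do not see the mutated column.
    """
    assert params.d == 0
    wt = list(wt)
    mutant = list(wt)
    mutant[column] = mut_index
    y = np.zeros(0)
    ranked_wt = [wt[c] for c in params.ordering]
    ranked_mut = [mutant[c] for c in params.ordering]
    mut_rank = list(params.ordering).index(column)
    delta = 0.0
    for k in range(mut_rank, params.L):
        p_wt = ref_conditional_probs(params, ranked_wt[:k], y, k)
        p_mut = ref_conditional_probs(params, ranked_mut[:k], y, k)
        delta -= math.log(p_mut[ranked_mut[k]]) - math.log(p_wt[ranked_wt[k]])
    return delta


def ref_brute_force_probs(params, y):
    """Exact P(a | y) over all q^L sequences via ref_log_prob."""
    import itertools

    probs = []
    for seq in itertools.product(range(params.q), repeat=params.L):
        probs.append(math.exp(ref_log_prob(params, list(seq), y)))
    return np.array(probs)
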