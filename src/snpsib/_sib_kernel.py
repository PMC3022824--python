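"""Numba kernel for the sequential information-bottleneck sweep.

The sequential step draws one sample at a time out of its cluster and
re-inserts it into the cluster that minimizes the information-bottleneck
functional L = I(C;X) - beta*I(C;Y).  With hard assignments and a uniform
prior over the n training samples, I(C;X) = H(C) and I(C;Y) is computed
from the induced joint p(c,y) = sum_{x in c} p(x) p(y|x).

Two exact optimizations keep the tens of thousands of sIB fits of the
cross-validated subset searches affordable:

* every sample profile puts mass 1/s on each of its s tokens, so cluster
  token masses are integer multiples of 1/s and cluster sizes are
  integers; the kernel keeps integer sufficient statistics and reads the
  x*log2(x)-type terms from precomputed tables;
* the insertion/removal evaluations depend on a sample only through its
  genotype pattern, so they are memoized per (pattern, cluster) and
  invalidated only when a cluster actually changes — a converged sweep
  costs lookups only.

Both are algebraically transparent: the sweep's decisions are identical
to the direct computation.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _build_tables(n, s, n_tokens, tokens):
    """Lookup tables for the objective terms.

    xl[k]     = (k/s) * log2(k/s)            (token-mass term)
    hterm[k]  = -(k/n) * log2(k/n)           (cluster entropy term)
    nl[k]     = k * log2(k)                  (cluster-size term)
    lpy[t]    = log2 p(y=t)                  (fixed token marginal)
    """
    inv_s = 1.0 / s
    xl = np.zeros(n * s + 2)
    for k in range(1, n * s + 2):
        v = k * inv_s
        xl[k] = v * np.log2(v)
    hterm = np.zeros(n + 2)
    nl = np.zeros(n + 2)
    for k in range(1, n + 1):
        p = k / n
        hterm[k] = -p * np.log2(p)
        nl[k] = k * np.log2(k)
    py = np.zeros(n_tokens)
    for i in range(n):
        for j in range(s):
            py[tokens[i, j]] += inv_s
    py /= n
    lpy = np.zeros(n_tokens)
    for t in range(n_tokens):
        if py[t] > 0.0:
            lpy[t] = np.log2(py[t])
    return xl, hterm, nl, lpy


@njit(cache=True, inline="always")
def _cluster_f(k, a, b, bn, hterm, nl):
    """One cluster's contribution to L; k = cluster size (int)."""
    if k <= 0:
        return 0.0
    return hterm[k] - bn * (a - nl[k] - b)


def _pattern_index(tokens):
    """Map each sample to a dense genotype-pattern id (same tokens = same id)."""
    n, s = tokens.shape
    n_tok = 3 * s
    if n_tok ** s < 2**62:  # encode the token tuple as one integer key
        keys = (tokens.astype(np.int64) * (n_tok ** np.arange(s, dtype=np.int64))).sum(axis=1)
        ukeys, first, pat = np.unique(keys, return_index=True, return_inverse=True)
        reps = tokens[first]
    else:
        reps, pat = np.unique(tokens, axis=0, return_inverse=True)
    return pat.astype(np.int64).ravel(), np.ascontiguousarray(reps), reps.shape[0]


def sib_sweeps(tokens, n_tokens, K, beta, n_restarts, max_sweeps, seed, record):
    """Run the full restart schedule; return the best hard partition.

    Parameters
    ----------
    tokens : (n, s) int32 token index per sample and subset position.
    record : when True, the incrementally maintained objective after every
        draw-and-reinsert step is returned with its restart id (for
        monotonicity audits); otherwise the trace arrays have length 0.

    Returns
    -------
    best_assign (n,), best_L, trace_L, trace_restart
    """
    pat, preps, n_pat = _pattern_index(tokens)
    return _sib_sweeps_jit(
        tokens, n_tokens, K, beta, n_restarts, max_sweeps, seed, record,
        pat, preps, n_pat,
    )


@njit(cache=True)
def _sib_sweeps_jit(tokens, n_tokens, K, beta, n_restarts, max_sweeps, seed, record,
                    pat, preps, n_pat):
    n, s = tokens.shape
    inv_s = 1.0 / s
    bn = beta / n
    xl, hterm, nl, lpy = _build_tables(n, s, n_tokens, tokens)

    cap = n_restarts * max_sweeps * n if record else 0
    trace_L = np.empty(cap)
    trace_restart = np.empty(cap, dtype=np.int32)
    n_steps = 0

    best_L = np.inf
    best_assign = np.zeros(n, dtype=np.int32)

    # per-(pattern, cluster) memo of insertion / removal evaluations
    cache_ins = np.zeros((K, n_pat))
    cache_rem = np.zeros((K, n_pat))
    valid_ins = np.zeros((K, n_pat), dtype=np.uint8)
    valid_rem = np.zeros((K, n_pat), dtype=np.uint8)

    for r in range(n_restarts):
        np.random.seed(seed + r)
        assign = np.random.randint(0, K, n).astype(np.int32)

        ncl = np.zeros(K, dtype=np.int64)
        S = np.zeros((K, n_tokens), dtype=np.int64)  # token counts, units of 1/s
        for i in range(n):
            c = assign[i]
            ncl[c] += 1
            for j in range(s):
                S[c, tokens[i, j]] += 1
        A = np.zeros(K)
        B = np.zeros(K)
        for c in range(K):
            for t in range(n_tokens):
                A[c] += xl[S[c, t]]
                B[c] += S[c, t] * inv_s * lpy[t]
        fvals = np.zeros(K)
        L = 0.0
        for c in range(K):
            fvals[c] = _cluster_f(ncl[c], A[c], B[c], bn, hterm, nl)
            L += fvals[c]
        valid_ins[:] = 0
        valid_rem[:] = 0

        for _sweep in range(max_sweeps):
            order = np.random.permutation(n)
            changed = False
            for oi in range(n):
                i = order[oi]
                c0 = assign[i]
                p = pat[i]

                # f of cluster c0 with the sample drawn out
                if valid_rem[c0, p]:
                    f_c0_removed = cache_rem[c0, p]
                else:
                    dA = 0.0
                    dB = 0.0
                    for j in range(s):
                        t = preps[p, j]
                        k = S[c0, t]
                        dA += xl[k - 1] - xl[k]
                        dB -= inv_s * lpy[t]
                    f_c0_removed = _cluster_f(
                        ncl[c0] - 1, A[c0] + dA, B[c0] + dB, bn, hterm, nl
                    )
                    cache_rem[c0, p] = f_c0_removed
                    valid_rem[c0, p] = 1

                # evaluate re-insertion into every cluster (incl. the old one)
                best_c = 0
                best_d = np.inf
                for c in range(K):
                    if c == c0:
                        # re-insertion restores the original cluster exactly
                        d = fvals[c0] - f_c0_removed
                    else:
                        if valid_ins[c, p]:
                            f_ins = cache_ins[c, p]
                        else:
                            dA = 0.0
                            dB = 0.0
                            for j in range(s):
                                t = preps[p, j]
                                k = S[c, t]
                                dA += xl[k + 1] - xl[k]
                                dB += inv_s * lpy[t]
                            f_ins = _cluster_f(
                                ncl[c] + 1, A[c] + dA, B[c] + dB, bn, hterm, nl
                            )
                            cache_ins[c, p] = f_ins
                            valid_ins[c, p] = 1
                        d = f_ins - fvals[c]
                    if d < best_d:  # strict: ties keep the lowest index
                        best_d = d
                        best_c = c

                if best_c != c0:
                    f_ins_best = cache_ins[best_c, p]
                    for j in range(s):
                        t = preps[p, j]
                        S[c0, t] -= 1
                        A[c0] += xl[S[c0, t]] - xl[S[c0, t] + 1]
                        B[c0] -= inv_s * lpy[t]
                        S[best_c, t] += 1
                        A[best_c] += xl[S[best_c, t]] - xl[S[best_c, t] - 1]
                        B[best_c] += inv_s * lpy[t]
                    ncl[c0] -= 1
                    ncl[best_c] += 1
                    L += f_c0_removed - fvals[c0] + f_ins_best - fvals[best_c]
                    fvals[c0] = f_c0_removed
                    fvals[best_c] = f_ins_best
                    assign[i] = best_c
                    changed = True
                    for q in range(n_pat):
                        valid_ins[c0, q] = 0
                        valid_rem[c0, q] = 0
                        valid_ins[best_c, q] = 0
                        valid_rem[best_c, q] = 0
                if record:
                    trace_L[n_steps] = L
                    trace_restart[n_steps] = r
                    n_steps += 1
            if not changed:
                break

        # recompute the final objective from the exact integer statistics
        L_final = _partition_objective(tokens, assign, n_tokens, K, bn, xl, hterm, nl, lpy)
        if L_final < best_L:
            best_L = L_final
            best_assign = assign.copy()

    return best_assign, best_L, trace_L[:n_steps], trace_restart[:n_steps]


@njit(cache=True)
def _partition_objective(tokens, assign, n_tokens, K, bn, xl, hterm, nl, lpy):
    n, s = tokens.shape
    inv_s = 1.0 / s
    ncl = np.zeros(K, dtype=np.int64)
    S = np.zeros((K, n_tokens), dtype=np.int64)
    for i in range(n):
        c = assign[i]
        ncl[c] += 1
        for j in range(s):
            S[c, tokens[i, j]] += 1
    L = 0.0
    for c in range(K):
        a = 0.0
        b = 0.0
        for t in range(n_tokens):
            a += xl[S[c, t]]
            b += S[c, t] * inv_s * lpy[t]
        L += _cluster_f(ncl[c], a, b, bn, hterm, nl)
    return L
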