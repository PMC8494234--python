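"""Numba kernels for collapsed Gibbs sampling.

All kernels use numba's own seeded RNG so that single-worker runs are
bit-reproducible given a seed. Hyperparameters arrive as per-component
values (``a`` = alpha/K, ``b_v`` = beta/V) plus the total beta mass for the
denominator.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=False)
def gibbs_train(
    doc_ids, word_ids, z, n_dk, n_wk, n_k,
    a, b_v, b_total,
    n_iter, burn_in, stride, seed,
    sum_ndk, sum_nwk, freq, track_freq,
):
    """Run collapsed Gibbs sweeps in place; accumulate post-burn-in samples.

    The conditional for token i in document d with word w is
    ``p(z_i = k) ∝ (n_dk + a) (n_wk + b_v) / (n_k + b_total)``
    with token i's current assignment removed from the counts.
    Returns the number of samples accumulated into ``sum_ndk``/``sum_nwk``.
    """
    np.random.seed(seed)
    n_tokens = doc_ids.shape[0]
    n_topics = n_dk.shape[1]
    p = np.empty(n_topics)
    n_samples = 0
    for sweep in range(n_iter):
        for i in range(n_tokens):
            d = doc_ids[i]
            w = word_ids[i]
            k = z[i]
            n_dk[d, k] -= 1
            n_wk[w, k] -= 1
            n_k[k] -= 1
            total = 0.0
            for kk in range(n_topics):
                pk = (n_dk[d, kk] + a) * (n_wk[w, kk] + b_v) / (n_k[kk] + b_total)
                p[kk] = pk
                total += pk
            u = np.random.random() * total
            acc = 0.0
            k = n_topics - 1
            for kk in range(n_topics):
                acc += p[kk]
                if u < acc:
                    k = kk
                    break
            z[i] = k
            n_dk[d, k] += 1
            n_wk[w, k] += 1
            n_k[k] += 1
        if sweep >= burn_in and (sweep - burn_in) % stride == 0:
            n_samples += 1
            for d in range(n_dk.shape[0]):
                for kk in range(n_topics):
                    sum_ndk[d, kk] += n_dk[d, kk]
            for w in range(n_wk.shape[0]):
                for kk in range(n_topics):
                    sum_nwk[w, kk] += n_wk[w, kk]
            if track_freq:
                for i in range(n_tokens):
                    freq[i, z[i]] += 1
    return n_samples


@njit(cache=False)
def gibbs_predict_doc(word_ids, phi, a, alpha_total, n_iter, burn_in, stride, seed):
    """Infer a topic-mixture row for one document with phi held fixed.

    Returns the prior-smoothed posterior-mean theta row, averaged over
    post-burn-in samples taken every ``stride`` sweeps.
    """
    np.random.seed(seed)
    n = word_ids.shape[0]
    n_topics = phi.shape[0]
    n_k = np.zeros(n_topics)
    z = np.empty(n, dtype=np.int64)
    for i in range(n):
        k = int(np.random.random() * n_topics)
        if k == n_topics:
            k = n_topics - 1
        z[i] = k
        n_k[k] += 1
    p = np.empty(n_topics)
    theta = np.zeros(n_topics)
    n_samples = 0
    for sweep in range(n_iter):
        for i in range(n):
            w = word_ids[i]
            k = z[i]
            n_k[k] -= 1
            total = 0.0
            for kk in range(n_topics):
                pk = (n_k[kk] + a) * phi[kk, w]
                p[kk] = pk
                total += pk
            u = np.random.random() * total
            acc = 0.0
            k = n_topics - 1
            for kk in range(n_topics):
                acc += p[kk]
                if u < acc:
                    k = kk
                    break
            z[i] = k
            n_k[k] += 1
        if sweep >= burn_in and (sweep - burn_in) % stride == 0:
            n_samples += 1
            for kk in range(n_topics):
                theta[kk] += (n_k[kk] + a) / (n + alpha_total)
    for kk in range(n_topics):
        theta[kk] /= n_samples
    return theta


@njit(cache=False)
def _log_joint(z, word_ids, log_phi, a, alpha_total):
    """log p(w, z | phi, alpha) for one document (theta integrated out)."""
    n = word_ids.shape[0]
    n_topics = log_phi.shape[0]
    n_k = np.zeros(n_topics)
    lj = math.lgamma(alpha_total) - math.lgamma(alpha_total + n)
    for i in range(n):
        lj += log_phi[z[i], word_ids[i]]
        n_k[z[i]] += 1
    for kk in range(n_topics):
        lj += math.lgamma(a + n_k[kk]) - math.lgamma(a)
    return lj


@njit(cache=False)
def _log_transition(z_from, z_star, word_ids, phi, a):
    """log T(z* | z) for one systematic-scan Gibbs sweep with phi fixed."""
    n = word_ids.shape[0]
    n_topics = phi.shape[0]
    n_k = np.zeros(n_topics)
    for i in range(n):
        n_k[z_from[i]] += 1
    logt = 0.0
    for i in range(n):
        w = word_ids[i]
        n_k[z_from[i]] -= 1
        total = 0.0
        pstar = 0.0
        for kk in range(n_topics):
            pk = (n_k[kk] + a) * phi[kk, w]
            total += pk
            if kk == z_star[i]:
                pstar = pk
        logt += math.log(pstar / total)
        n_k[z_star[i]] += 1
    return logt


@njit(cache=False)
def chib_chain(word_ids, phi, a, alpha_total, n_iter, burn_in, stride, seed):
    """One Gibbs chain over a held-out document's assignments with phi fixed.

    The chain has three phases: burn-in, pivot selection (tracking the
    highest-joint-probability state visited), and state collection. Returns
    ``(best_lj, z_star, states)`` where ``best_lj = log p(w, z*)``. Keeping
    the selection phase disjoint from the collection phase avoids the upward
    coupling bias of evaluating the transition kernel at states that
    co-determined the pivot.
    """
    np.random.seed(seed)
    n = word_ids.shape[0]
    n_topics = phi.shape[0]
    log_phi = np.log(phi)
    n_k = np.zeros(n_topics)
    z = np.empty(n, dtype=np.int64)
    for i in range(n):
        k = int(np.random.random() * n_topics)
        if k == n_topics:
            k = n_topics - 1
        z[i] = k
        n_k[k] += 1

    select_end = burn_in + (n_iter - burn_in) // 3
    max_samples = (n_iter - select_end + stride - 1) // stride + 1
    states = np.empty((max_samples, n), dtype=np.int64)
    n_states = 0
    z_star = z.copy()
    best_lj = -1e300
    p = np.empty(n_topics)

    for sweep in range(n_iter):
        for i in range(n):
            w = word_ids[i]
            k = z[i]
            n_k[k] -= 1
            total = 0.0
            for kk in range(n_topics):
                pk = (n_k[kk] + a) * phi[kk, w]
                p[kk] = pk
                total += pk
            u = np.random.random() * total
            acc = 0.0
            k = n_topics - 1
            for kk in range(n_topics):
                acc += p[kk]
                if u < acc:
                    k = kk
                    break
            z[i] = k
            n_k[k] += 1
        if burn_in <= sweep < select_end:
            lj = _log_joint(z, word_ids, log_phi, a, alpha_total)
            if lj > best_lj:
                best_lj = lj
                z_star = z.copy()
        elif sweep >= select_end and (sweep - select_end) % stride == 0:
            states[n_states] = z
            n_states += 1
    return best_lj, z_star, states[:n_states]


@njit(cache=False)
def kernel_log_transitions(states, z_star, word_ids, phi, a):
    """log T(z* | z_s) for every collected state (systematic-scan kernel)."""
    out = np.empty(states.shape[0])
    for s in range(states.shape[0]):
        out[s] = _log_transition(states[s], z_star, word_ids, phi, a)
    return out


def chib_loglik_doc(
    word_ids, phi, a, alpha_total, n_iter, burn_in, stride, seed, n_chains=4
):
    """Chib-style marginal log-likelihood of one held-out document.

    Pools ``n_chains`` independent chains: the pivot z* is the best state
    found in any chain's selection phase, and ``p̂(z* | w)`` averages the
    one-sweep transition kernel over all chains' collected states, so
    ``log p(w) = log p(w, z*) - log p̂(z* | w)``.
    """
    best_lj = -np.inf
    z_star = None
    all_states = []
    for c in range(n_chains):
        lj, zs, states = chib_chain(
            word_ids, phi, a, alpha_total, n_iter, burn_in, stride,
            (seed + 7919 * c) & 0x7FFFFFFF,
        )
        if lj > best_lj:
            best_lj = lj
            z_star = zs
        all_states.append(states)
    states = np.concatenate(all_states)
    logts = kernel_log_transitions(states, z_star, word_ids, phi, a)
    m = logts.max()
    log_phat = m + math.log(np.mean(np.exp(logts - m)))
    return best_lj - log_phat
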