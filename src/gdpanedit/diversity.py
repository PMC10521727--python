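"""Effective library size: expected number of distinct variants in a pool.

A mutagenized pool of P cells drawn over variant classes (k mutated
positions out of E editable ones, 3 alternative bases each) occupies

    E[distinct] = sum over variants v of 1 - (1 - p_v)^P

With within-class uniformity p_v = w_k / N_k where N_k = C(E, k) * 3^k, the
sum collapses to one term per mutation count and is evaluated in the log
domain (N_k overflows floats long before E reaches nanobody scale). Real
editors are not uniform within a class — a cytidine deaminase concentrates
mass on few positions — so the uniform estimate is an upper bound on
occupancy evenness; an optional weighted path (exact for single-mutation
variants, second-order collision correction above) uses the generator's own
position/alternative weights when they are known.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, exp, expm1, log, log1p

import numpy as np
from scipy.special import gammaln, logsumexp


@dataclass(frozen=True)
class DiversityEstimate:
    pool_size: int
    mean_mutations_per_seq: float
    editable_positions: int
    alt_bases_per_position: int
    expected_distinct: float
    theoretical_space: float  # log10 of the variant-space size

    def __post_init__(self):
        if self.expected_distinct > self.pool_size * (1 + 1e-9):
            raise ValueError("expected_distinct cannot exceed pool_size")


def _normalize_dist(dist) -> dict[int, float]:
    if isinstance(dist, dict):
        items = dist.items()
    else:
        items = enumerate(dist)
    out = {int(k): float(w) for k, w in items if w > 0}
    total = sum(out.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"mutation_count_dist sums to {total}, expected 1")
    return {k: w / total for k, w in out.items()}


def poisson_count_dist(mean: float, kmax: int | None = None) -> dict[int, float]:
    """Poisson(mean) over mutation counts, truncated and renormalized."""
    if kmax is None:
        kmax = max(20, int(mean + 12 * mean ** 0.5 + 12))
    k = np.arange(kmax + 1)
    logw = k * log(mean) - mean - gammaln(k + 1) if mean > 0 else \
        np.where(k == 0, 0.0, -np.inf)
    w = np.exp(logw - logsumexp(logw))
    return {int(i): float(x) for i, x in zip(k, w) if x > 0}


def estimate_diversity(pool_size: int, mutation_count_dist,
                       editable_positions: int,
                       alt_bases_per_position: int = 3) -> DiversityEstimate:
    """Analytic occupancy estimate of distinct variants in the pool.

    ``mutation_count_dist`` maps mutation count k to its probability (dict
    or sequence). Variants within a class are treated as equiprobable.
    """
    if pool_size < 1:
        raise ValueError("pool_size >= 1")
    dist = _normalize_dist(mutation_count_dist)
    E, A = editable_positions, alt_bases_per_position
    if E == 0 and any(k > 0 for k in dist):
        raise ValueError("editable_positions = 0 with nonzero mutation mass")
    total = 0.0
    log_space = []
    for k, w in dist.items():
        if k > E:
            raise ValueError(f"mutation count {k} exceeds {E} editable positions")
        logN = (gammaln(E + 1) - gammaln(k + 1) - gammaln(E - k + 1)
                + k * log(A))
        log_space.append(logN)
        log_p = log(w) - logN  # per-variant hit probability
        if log_p < -700:  # p underflows doubles: draws are collision-free
            total += pool_size * w
        elif log_p >= 0.0:  # w >= N: every variant of the class is hit
            total += exp(logN)
        else:
            p = exp(log_p)
            # log-domain: N may overflow while the term itself is <= pool
            total += exp(logN + log(-expm1(pool_size * log1p(-p))))
    total = min(total, float(pool_size))
    mean_k = sum(k * w for k, w in dist.items())
    return DiversityEstimate(pool_size, mean_k, E, A, total,
                             float(logsumexp(log_space) / log(10)))


def estimate_distinct_weighted(counts_by_k: dict[int, int],
                               position_weights: np.ndarray,
                               alt_weights: np.ndarray
                               ) -> tuple[float, float]:
    """Occupancy estimate honoring known per-position/per-alt biases.

    ``counts_by_k[k]`` is the number of pool sequences carrying k mutations;
    ``position_weights`` (length E) the relative chance each editable
    position mutates; ``alt_weights`` (E x 3) the alternative-base
    distribution per position. Classes with k <= 2 are enumerated and
    evaluated exactly (they hold all the collision mass at desk scale); for
    k >= 3 a second-order birthday-collision correction with product-form
    variant probabilities (elementary symmetric polynomial sums) suffices.
    Returns (estimate, approximate standard error).
    """
    u = np.asarray(position_weights, dtype=float)
    if u.sum() <= 0:
        raise ValueError("position weights must have positive mass")
    u = u / u.sum()
    a = np.asarray(alt_weights, dtype=float)
    a = a / a.sum(axis=1, keepdims=True)
    total = 0.0
    var = 0.0
    E = len(u)
    for k, n_k in sorted(counts_by_k.items()):
        if n_k <= 0:
            continue
        if k == 0:
            total += 1.0
        elif k == 1:
            pi = (u[:, None] * a).ravel()
            surv = (1.0 - pi) ** n_k
            total += float((1.0 - surv).sum())
            var += float((surv * (1.0 - surv)).sum())
        elif k == 2 and E <= 400:
            # enumerate all C(E,2) x 9 double-mutant variants
            pw = np.triu(u[:, None] * u[None, :], 1)
            pw = pw / pw.sum()
            iu, ju = np.nonzero(pw)
            alt_pair = (a[iu][:, :, None] * a[ju][:, None, :]).reshape(-1, 9)
            pi = (pw[iu, ju][:, None] * alt_pair).ravel()
            surv = (1.0 - pi) ** n_k
            total += float((1.0 - surv).sum())
            var += float((surv * (1.0 - surv)).sum())
        else:
            # E[duplicates] ~= C(n_k,2) * sum_v pi_v^2 with
            # pi_v = k! prod(u_i a_i,alt) / Z_k (Poissonized subset law)
            v2 = u ** 2 * (a ** 2).sum(axis=1)
            z1 = _esp(u, k)
            z2 = _esp(v2, k)
            fact = np.exp(gammaln(k + 1))
            sum_pi2 = (fact ** 2 * z2) / (fact * z1) ** 2
            dup = comb(n_k, 2) * sum_pi2
            dup = min(dup, n_k - 1.0)
            total += n_k - dup
            var += dup  # duplicates are roughly Poisson
    return total, var ** 0.5


def _esp(x: np.ndarray, k: int) -> float:
    """Elementary symmetric polynomial e_k(x) by the standard DP."""
    e = np.zeros(k + 1)
    e[0] = 1.0
    for xi in x:
        e[1:] = e[1:] + xi * e[:-1]
    return float(e[k])


def empirical_distinct(pool) -> int:
    """Unique sequences (exact string identity, case-normalized)."""
    seqs = set()
    for rec in pool:
        seq = rec if isinstance(rec, str) else rec.seq
        seqs.add(seq.upper())
    return len(seqs)


def mutation_count_distribution(net_ledger, pool_size: int) -> dict[int, int]:
    """Counts of sequences by number of mutated positions, from a net ledger."""
    if len(net_ledger) == 0:
        return {0: pool_size}
    per_cell = net_ledger.groupby("cell_id").size()
    counts: dict[int, int] = {}
    for k in per_cell:
        counts[int(k)] = counts.get(int(k), 0) + 1
    counts[0] = counts.get(0, 0) + pool_size - len(per_cell)
    return counts
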