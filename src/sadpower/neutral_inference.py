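"""Exact likelihood and sampling for the standard neutral model (SNM).

The probability of observing an abundance data set ``D = (n_1 .. n_S)`` with
``J = sum n_i`` individuals under Hubbell's spatially implicit neutral model
with biodiversity number ``theta`` and immigration parameter ``m`` is given
by the Etienne sampling formula.  With ``I = m (J-1) / (1-m)``:

    P(D | theta, m, J) = J! / (prod_i n_i * prod_j Phi_j!)
                         * theta^S / (I)_J
                         * sum_{A=S}^{J} K(D, A) I^A / (theta)_A

where ``(x)_N`` is the rising factorial, ``Phi_j`` the number of species
with abundance ``j``, and

    K(D, A) = sum_{a_1+..+a_S = A, 1 <= a_i <= n_i}
              prod_i  s(n_i, a_i) s(a_i, 1) / s(n_i, 1)

with ``s`` the unsigned Stirling numbers of the first kind (so
``s(a, 1) = (a-1)!``).  ``K(D, .)`` depends only on the abundance multiset;
it is assembled once per data set by convolving the per-species coefficient
arrays ``k_i(a) = s(n_i, a) (a-1)! / (n_i - 1)!`` and cached on the sample.
All arithmetic is in log space: individual terms span hundreds of orders of
magnitude at realistic ``J``, but every quantity is a sum of positive terms,
so log-sum-exp keeps the computation exact to double precision.

The ``m = 1`` endpoint is the Ewens sampling formula (a pure metacommunity
sample); it is handled as that limit rather than through ``I``.

Sampling from the same law uses the sequential urn scheme: individual ``j``
(1-based) is a new immigrant ancestor with probability ``I / (I + j - 1)``,
otherwise it copies the species of a uniformly chosen earlier individual;
the ``a``-th ancestor founds a new species with probability
``theta / (theta + a - 1)``, otherwise it takes the species of a uniformly
chosen earlier ancestor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from numba import njit
from scipy.special import gammaln, logsumexp

__all__ = [
    "AbundanceSample",
    "NeutralFit",
    "etienne_log_likelihood",
    "maximize_likelihood",
    "urn_sample",
]


# --------------------------------------------------------------------------
# Abundance samples
# --------------------------------------------------------------------------

@dataclass
class AbundanceSample:
    """One observed or simulated species abundance data set.

    ``counts`` are per-species abundances, stored sorted in descending
    order; the likelihood depends only on this multiset.
    """

    counts: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)
    _logK: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64).ravel()
        if c.size == 0:
            raise ValueError("abundance sample must contain at least one species")
        if np.any(c <= 0):
            raise ValueError("all species abundances must be positive integers")
        self.counts = np.sort(c)[::-1].copy()

    @property
    def J(self) -> int:
        return int(self.counts.sum())

    @property
    def S(self) -> int:
        return int(self.counts.size)

    @property
    def phi(self) -> np.ndarray:
        """Abundance histogram: ``phi[j]`` species have abundance ``j``."""
        return np.bincount(self.counts, minlength=self.J + 1)

    def log_prefactor(self) -> float:
        """log of ``J! / (prod_i n_i * prod_j Phi_j!)``."""
        phi = self.phi
        return float(
            gammaln(self.J + 1)
            - np.log(self.counts).sum()
            - gammaln(phi[phi > 0] + 1.0).sum()
        )

    def log_K(self) -> np.ndarray:
        """``log K(D, A)`` for ``A = S .. J`` (computed once, cached)."""
        if self._logK is None:
            self._logK = _log_K(self.counts)
        return self._logK

    @classmethod
    def from_counts(cls, counts: Sequence[int], **metadata: Any) -> "AbundanceSample":
        return cls(np.asarray(counts), metadata=dict(metadata))


# --------------------------------------------------------------------------
# Stirling-number coefficient arrays
# --------------------------------------------------------------------------

class _StirlingRatioCache:
    """Rows ``log k_n(a) = log[s(n,a) (a-1)!/(n-1)!]``, ``a = 1..n``.

    The log unsigned-Stirling frontier row is extended upward by the
    recurrence ``s(n+1, a) = n s(n, a) + s(n, a-1)``; only rows for
    abundance values actually requested are retained.
    """

    _CHECKPOINT = 64    # keep every 64th raw Stirling row to bound rebuilds
    _CACHE_MAX_N = 8192  # ratio rows above this are rebuilt on demand

    def __init__(self) -> None:
        self._checkpoints: dict[int, np.ndarray] = {1: np.zeros(1)}
        self._rows: dict[int, np.ndarray] = {}

    @staticmethod
    def _advance(logS: np.ndarray, k: int) -> np.ndarray:
        """One step of ``s(k+1, a) = k s(k, a) + s(k, a-1)`` in log space."""
        nxt = np.empty(k + 1)
        nxt[0] = math.log(k) + logS[0]  # s(k+1, 1) = k!
        nxt[k] = 0.0                    # s(k+1, k+1) = 1
        if k > 1:
            nxt[1:k] = np.logaddexp(math.log(k) + logS[1:], logS[:-1])
        return nxt

    def row(self, n: int) -> np.ndarray:
        cached = self._rows.get(n)
        if cached is not None:
            return cached
        base = max(k for k in self._checkpoints if k <= n)
        logS, k = self._checkpoints[base], base
        while k < n:
            logS = self._advance(logS, k)
            k += 1
            if k % self._CHECKPOINT == 0 and k not in self._checkpoints:
                self._checkpoints[k] = logS
        a = np.arange(1, n + 1)
        row = logS + gammaln(a) - gammaln(n)
        if n <= self._CACHE_MAX_N:
            self._rows[n] = row
        return row


_STIRLING = _StirlingRatioCache()


@njit(cache=True)
def _range_segments(x, max_range):  # pragma: no cover
    """Partition indices of ``x`` so each chunk spans <= ``max_range`` nats."""
    n = x.size
    bounds = np.empty(n + 1, np.int64)
    bounds[0] = 0
    nb = 1
    lo = x[0]
    hi = x[0]
    for i in range(1, n):
        v = x[i]
        if v < lo:
            lo = v
        if v > hi:
            hi = v
        if hi - lo > max_range:
            bounds[nb] = i
            nb += 1
            lo = v
            hi = v
    bounds[nb] = n
    return bounds[: nb + 1]


_NAIVE_OPS = 4096     # below this, plain log-space convolution is fastest
_SEG_RANGE = 340.0    # chunk scales keep all products within double range


def _log_conv_naive(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.full(a.size + b.size - 1, -np.inf)
    for j in range(b.size):
        seg = out[j : j + a.size]
        np.logaddexp(seg, a + b[j], out=seg)
    return out


def _log_conv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Log-space polynomial product of two positive coefficient arrays.

    Long products are evaluated chunk-wise in linear space: each chunk is
    rescaled by its maximum so every product stays inside double range, and
    because all coefficients are positive the relative error of each output
    coefficient is at machine-precision level regardless of the hundreds of
    orders of magnitude the arrays span.
    """
    if b.size > a.size:
        a, b = b, a
    if b.size == 1:
        return a + b[0]
    if a.size * b.size <= _NAIVE_OPS:
        return _log_conv_naive(a, b)
    out = np.full(a.size + b.size - 1, -np.inf)
    ab = _range_segments(a, _SEG_RANGE)
    bb = _range_segments(b, _SEG_RANGE)
    for ia in range(ab.size - 1):
        a0, a1 = ab[ia], ab[ia + 1]
        ma = a[a0:a1].max()
        ea = np.exp(a[a0:a1] - ma)
        for ib in range(bb.size - 1):
            b0, b1 = bb[ib], bb[ib + 1]
            mb = b[b0:b1].max()
            lin = np.convolve(ea, np.exp(b[b0:b1] - mb))
            lg = np.full(lin.size, -np.inf)
            np.log(lin, out=lg, where=lin > 0)
            lg += ma + mb
            seg = out[a0 + b0 : a0 + b0 + lg.size]
            np.logaddexp(seg, lg, out=seg)
    return out


def _log_K(counts: np.ndarray) -> np.ndarray:
    """``log K(D, A)`` for ``A = S..J`` by convolving per-species arrays."""
    rows = [_STIRLING.row(int(n)) for n in sorted(counts.tolist())]
    out = rows[0]
    for r in rows[1:]:
        out = _log_conv(out, r)
    return out


# --------------------------------------------------------------------------
# Likelihood
# --------------------------------------------------------------------------

def _validate_theta_m(theta: float, m: float) -> None:
    if not theta > 0:
        raise ValueError(f"theta must be positive, got {theta}")
    if not 0.0 < m <= 1.0:
        raise ValueError(f"m must be in (0, 1], got {m}")


def etienne_log_likelihood(D: AbundanceSample, theta: float, m: float) -> float:
    """Natural-log probability of ``D`` under the SNM at ``(theta, m)``.

    Finite for all valid inputs; the ``A``-sum is evaluated by
    log-sum-exp over the cached ``K(D, .)`` coefficients.
    """
    _validate_theta_m(theta, m)
    J, S = D.J, D.S
    if J == 1:
        return 0.0  # a single individual is always exactly one species
    pre = D.log_prefactor()
    if m == 1.0:  # Ewens limit: pure metacommunity sample
        return pre + S * math.log(theta) - (gammaln(theta + J) - gammaln(theta))
    I = m * (J - 1) / (1.0 - m)
    A = np.arange(S, J + 1)
    terms = D.log_K() + A * math.log(I) - (gammaln(theta + A) - gammaln(theta))
    return float(
        pre + S * math.log(theta) - (gammaln(I + J) - gammaln(I)) + logsumexp(terms)
    )


# terms dropped below max - 46 nats contribute < J * exp(-46) ~ 1e-16
_TERM_CUT = 46.0
_TERM_STRIDE = 64


@njit(cache=True)
def _nb_log_sum_terms(logK, S, logI, theta):  # pragma: no cover
    """Log-sum-exp of ``logK(A) + A logI - log (theta)_A`` over ``A``.

    The summand is strictly log-concave in ``A`` (a verified property of
    the Stirling coefficient arrays), so for long sums a coarse scan
    brackets the peak and only the window within ``_TERM_CUT`` nats of it
    is evaluated exactly.
    """
    n = logK.size
    lgt = math.lgamma(theta)
    lo, hi = 0, n - 1
    if n > 4 * _TERM_STRIDE:
        cmax = -1e300
        for i in range(0, n, _TERM_STRIDE):
            A = S + i
            t = logK[i] + A * logI - (math.lgamma(theta + A) - lgt)
            if t > cmax:
                cmax = t
        thresh = cmax - _TERM_CUT
        i = 0
        while True:
            A = S + i
            if logK[i] + A * logI - (math.lgamma(theta + A) - lgt) >= thresh:
                break
            i += _TERM_STRIDE
        lo = max(i - _TERM_STRIDE, 0)
        i = ((n - 1) // _TERM_STRIDE) * _TERM_STRIDE
        while True:
            A = S + i
            if logK[i] + A * logI - (math.lgamma(theta + A) - lgt) >= thresh:
                break
            i -= _TERM_STRIDE
        hi = min(i + _TERM_STRIDE, n - 1)
    # exact streaming log-sum-exp over the window, with the rising
    # factorial log (theta)_A advanced incrementally
    lg = math.lgamma(theta + S + lo) - lgt
    run_max = -1e300
    run_sum = 0.0
    for i in range(lo, hi + 1):
        A = S + i
        t = logK[i] + A * logI - lg
        if t > run_max:
            run_sum = run_sum * math.exp(run_max - t) + 1.0
            run_max = t
        else:
            run_sum += math.exp(t - run_max)
        lg += math.log(theta + A)
    return run_max + math.log(run_sum)


class _LikelihoodEvaluator:
    """Fast repeated evaluation of the log-likelihood for one sample."""

    def __init__(self, D: AbundanceSample) -> None:
        self.J, self.S = D.J, D.S
        self.pre = D.log_prefactor()
        self.logK = D.log_K()

    def __call__(self, theta: float, m: float) -> float:
        J, S = self.J, self.S
        if J == 1:
            return 0.0
        if m >= 1.0:
            return self.pre + S * math.log(theta) - (
                gammaln(theta + J) - gammaln(theta)
            )
        I = m * (J - 1) / (1.0 - m)
        return (
            self.pre + S * math.log(theta)
            - (math.lgamma(I + J) - math.lgamma(I))
            + _nb_log_sum_terms(self.logK, S, math.log(I), theta)
        )


# --------------------------------------------------------------------------
# Maximum likelihood fit
# --------------------------------------------------------------------------

@dataclass
class NeutralFit:
    """Maximum-likelihood SNM fit of one abundance sample."""

    m_hat: float
    theta_hat: float
    logL_max: float
    converged: bool
    n_starts: int
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def at_boundary(self) -> bool:
        return bool(self.metadata.get("at_boundary", False))


# optimization box in transformed coordinates (log theta, logit m); the
# likelihood is flat beyond these in any case of practical interest
_LOGTH_LO, _LOGTH_HI = math.log(1e-4), math.log(1e7)
_LOGITM_LO, _LOGITM_HI = -25.0, 16.0


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x)) if x < 35 else 1.0


def _nelder_mead_2d(f, x0, fatol: float, xatol: float, maxfev: int):
    """Minimal scalar 2-D Nelder-Mead (the optimizer runs ~10^5 times per
    power calculation, so per-iteration overhead matters more than
    generality)."""
    v = [
        (f((x0[0], x0[1])), x0[0], x0[1]),
        (f((x0[0] + 0.25, x0[1])), x0[0] + 0.25, x0[1]),
        (f((x0[0], x0[1] + 0.25)), x0[0], x0[1] + 0.25),
    ]
    nfev = 3
    while nfev < maxfev:
        v.sort()
        (f0, a0, b0), (f1, a1, b1), (f2, a2, b2) = v
        if (f2 - f0 < fatol
                and max(abs(a1 - a0), abs(b1 - b0),
                        abs(a2 - a0), abs(b2 - b0)) < xatol):
            return np.array([a0, b0]), f0, nfev, True
        ca, cb = 0.5 * (a0 + a1), 0.5 * (b0 + b1)
        ra, rb = 2.0 * ca - a2, 2.0 * cb - b2
        fr = f((ra, rb)); nfev += 1
        if fr < f0:
            ea, eb = 3.0 * ca - 2.0 * a2, 3.0 * cb - 2.0 * b2
            fe = f((ea, eb)); nfev += 1
            v[2] = (fe, ea, eb) if fe < fr else (fr, ra, rb)
        elif fr < f1:
            v[2] = (fr, ra, rb)
        else:
            if fr < f2:
                xa, xb_ = 0.5 * (ca + ra), 0.5 * (cb + rb)
            else:
                xa, xb_ = 0.5 * (ca + a2), 0.5 * (cb + b2)
            fc = f((xa, xb_)); nfev += 1
            if fc < min(fr, f2):
                v[2] = (fc, xa, xb_)
            else:  # shrink toward the best vertex
                sa1, sb1 = 0.5 * (a0 + a1), 0.5 * (b0 + b1)
                sa2, sb2 = 0.5 * (a0 + a2), 0.5 * (b0 + b2)
                v[1] = (f((sa1, sb1)), sa1, sb1)
                v[2] = (f((sa2, sb2)), sa2, sb2)
                nfev += 2
    v.sort()
    return np.array([v[0][1], v[0][2]]), v[0][0], nfev, False


def maximize_likelihood(
    D: AbundanceSample,
    *,
    grid_theta: int = 5,
    grid_m: int = 5,
    n_refine: int = 2,
    fatol: float = 1e-6,
) -> NeutralFit:
    """Maximize the SNM log-likelihood of ``D`` over ``(theta, m)``.

    A coarse log-spaced grid of starts (``theta`` in ``[1, J]``, ``m`` in
    ``[1e-4, 0.99]``) is scored, then Nelder-Mead refines the best start and
    — because the surface can be bimodal — the best start far from it.
    """
    ev = _LikelihoodEvaluator(D)
    J = ev.J
    if J == 1:
        return NeutralFit(0.5, 1.0, 0.0, True, 0, {"degenerate": "J=1"})

    def negll(x: np.ndarray) -> float:
        lx = min(max(x[0], _LOGTH_LO), _LOGTH_HI)
        lm = min(max(x[1], _LOGITM_LO), _LOGITM_HI)
        val = ev(math.exp(lx), _expit(lm))
        return -val if math.isfinite(val) else math.inf

    thetas = np.geomspace(1.0, max(J, 2), grid_theta)
    ms = np.geomspace(1e-4, 0.99, grid_m)
    starts = []
    for th in thetas:
        for m in ms:
            x = np.array([math.log(th), math.log(m / (1 - m))])
            starts.append((negll(x), x))
    starts.sort(key=lambda s: s[0])

    # refine from the best start, plus the best start in a distant basin
    # when that basin is remotely competitive (bimodal surfaces carry two
    # near-equal optima; a basin hundreds of nats down never wins)
    chosen = [starts[0]]
    for f, x in starts[1:]:
        if len(chosen) >= n_refine:
            break
        if f - starts[0][0] < 100.0 and all(
            np.max(np.abs(x - xc)) > 1.5 for _, xc in chosen
        ):
            chosen.append((f, x))

    best, results = None, []
    for f0, x0 in chosen:
        xb, fb, nfev, ok = _nelder_mead_2d(negll, x0, fatol, 3e-3, 300)
        results.append((float(-fb), xb.copy(), ok))
        if best is None or -fb > best[0]:
            best = (float(-fb), xb, ok)

    logL, x, ok = best
    lx = min(max(x[0], _LOGTH_LO), _LOGTH_HI)
    lm = min(max(x[1], _LOGITM_LO), _LOGITM_HI)
    at_boundary = (
        lx <= _LOGTH_LO or lx >= _LOGTH_HI or lm <= _LOGITM_LO or lm >= _LOGITM_HI
    )
    if not ok and not results:
        raise RuntimeError("all optimizer starts failed")
    return NeutralFit(
        m_hat=_expit(lm),
        theta_hat=math.exp(lx),
        logL_max=logL,
        converged=ok or at_boundary,
        n_starts=len(starts),
        metadata={
            "at_boundary": at_boundary,
            "starts": [(f, tuple(xx), s) for f, xx, s in results],
            "grid_best_logL": -starts[0][0],
        },
    )


# --------------------------------------------------------------------------
# Urn sampler
# --------------------------------------------------------------------------

@njit(cache=True)
def _urn_kernel(theta, I, J, u_new, u_spec, u_copy):  # pragma: no cover
    ind = np.empty(J, np.int64)
    anc = np.empty(J, np.int64)
    n_anc = 0
    n_sp = 0
    infinite_I = not np.isfinite(I)
    for j in range(J):
        if j == 0 or infinite_I or u_new[j] * (I + j) < I:
            a = n_anc
            if a == 0 or u_spec[j] * (theta + a) < theta:
                s = n_sp
                n_sp += 1
            else:
                s = anc[int(u_copy[j] * a)]
            anc[n_anc] = s
            n_anc += 1
            ind[j] = s
        else:
            ind[j] = ind[int(u_copy[j] * j)]
    counts = np.zeros(n_sp, np.int64)
    for j in range(J):
        counts[ind[j]] += 1
    return counts


def urn_sample(
    theta: float, m: float, J: int, rng: np.random.Generator
) -> AbundanceSample:
    """Draw one SNM abundance sample of size ``J`` at ``(theta, m)``.

    The marginal law of the returned multiset matches
    :func:`etienne_log_likelihood` (the scheme is exchangeable and
    consistent in ``J`` at fixed ``I``).
    """
    _validate_theta_m(theta, m)
    J = int(J)
    if J < 1:
        raise ValueError(f"J must be >= 1, got {J}")
    I = math.inf if m == 1.0 else m * (J - 1) / (1.0 - m)
    u = rng.random((3, J))
    counts = _urn_kernel(float(theta), float(I), J, u[0], u[1], u[2])
    return AbundanceSample(
        counts, metadata={"source": "urn", "theta": theta, "m": m, "J": J}
    )
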