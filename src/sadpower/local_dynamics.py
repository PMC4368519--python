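"""Non-neutral local community simulators (models HL, PC, IF).

All three models keep the local community at exactly ``J`` individuals
(strict zero-sum dynamics) and receive a fraction ``m`` of recruits as
immigrants drawn from a metacommunity with fixed relative abundances
``P_i``.  Each model has one parameter controlling the strength of the
non-neutral process, and each reduces to neutral local dynamics when that
parameter is zero:

* **HL** — sequential (Moran-type) stochastic Lotka-Volterra competition.
  The next death is of species ``i`` with probability proportional to
  ``[(1-gamma) + gamma n_i/J] * n_i/J`` (Eq. weights); the recruit is of
  species ``i`` with probability ``(1-m) n_i/J + m P_i`` evaluated on the
  post-death abundances.  ``gamma`` in [0, 1] is the excess of intra- over
  inter-specific mortality; ``gamma=0`` is neutral, ``gamma=1`` independent
  stochastic logistic niches.  One time step is ``J`` elemental updates.
* **PC** — synchronous (Wright-Fisher-type) Ricker dynamics on fecundity:
  local propagule fractions ``L_i = n_i e^{-c n_i/J} / sum_k n_k e^{-c n_k/J}``,
  recruit probabilities ``R_i = m P_i + (1-m) L_i``, new configuration
  ``multinomial(J, R)``.  ``c = J(a-b) >= 0`` measures intra- minus
  inter-specific density dependence.
* **IF** — synchronous dynamics with intrinsic fitness differences:
  ``L_i = f_i n_i / sum_k f_k n_k`` with species fitnesses ``f_i`` drawn
  once per realisation from a Gamma distribution with shape ``1/k`` and
  mean 1 (``sqrt(k)`` is the fitness coefficient of variation).

The large-``J`` deterministic limit of the PC model (vanishing ``m``) is
the mean map ``r_i(t+1) = r_i e^{-c r_i} / sum_k r_k e^{-c r_k}``.
Linearizing at the uniform fixed point ``r* = 1/S_T`` gives eigenvalue
``1 - c r*`` on the zero-sum subspace, so the fixed point loses stability
through a flip bifurcation where the scaled competition strength
``c r* = c/S_T`` reaches 2 (the classic Ricker period-doubling threshold);
beyond it the community shows limit cycles or chaos.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numba import njit

from .metacommunity import MetacommunityAbundances
from .neutral_inference import AbundanceSample

__all__ = [
    "LocalCommunityState",
    "HLParams",
    "PCParams",
    "IFParams",
    "BurnInPolicy",
    "ConvergenceError",
    "hl_mortality_weights",
    "hl_step",
    "hl_params_from_rates",
    "pc_propagule_fractions",
    "pc_step",
    "if_assign_fitnesses",
    "if_propagule_fractions",
    "if_step",
    "if_kinf_even_probs",
    "if_kinf_even_sample",
    "pc_mean_map",
    "pc_perturbation_growth_rate",
    "pc_uniform_fixed_point_stable",
    "pc_critical_scaled_c",
    "run_to_equilibrium",
]


class ConvergenceError(RuntimeError):
    """Raised when the burn-in detector fails within its step cap."""

    def __init__(self, message: str, diagnostics: dict[str, Any] | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


# --------------------------------------------------------------------------
# States and parameter records
# --------------------------------------------------------------------------

@dataclass
class LocalCommunityState:
    """Integer abundance configuration of a local community of size ``J``.

    ``counts`` maps species label -> abundance; zero-abundance species are
    never stored.  ``time`` counts elemental steps / ``J`` for HL (i.e.
    time steps) and generations for PC/IF.
    """

    counts: dict[int, int]
    J: int
    time: int = 0

    def __post_init__(self) -> None:
        self.counts = {int(s): int(n) for s, n in self.counts.items() if n != 0}
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("negative abundance in community state")
        if sum(self.counts.values()) != self.J:
            raise ValueError(
                f"abundances sum to {sum(self.counts.values())}, expected J={self.J}"
            )

    @property
    def S(self) -> int:
        return len(self.counts)

    def to_sample(self, **metadata: Any) -> AbundanceSample:
        return AbundanceSample(np.array(list(self.counts.values())), metadata=metadata)


@dataclass(frozen=True)
class HLParams:
    gamma: float
    m: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if not 0.0 < self.m <= 1.0:
            raise ValueError(f"m must be in (0, 1], got {self.m}")


@dataclass(frozen=True)
class PCParams:
    c: float
    m: float

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"c must be non-negative, got {self.c}")
        if not 0.0 < self.m <= 1.0:
            raise ValueError(f"m must be in (0, 1], got {self.m}")

    def check_stability(self, S_T: float) -> None:
        """Warn when the deterministic uniform fixed point is unstable."""
        if math.isfinite(S_T) and self.c / S_T >= 2.0:
            warnings.warn(
                f"c/S_T = {self.c / S_T:.3g} >= 2: the uniform fixed point of "
                "the deterministic PC mean map is unstable (limit cycles or "
                "chaos); proceeding anyway",
                stacklevel=2,
            )


@dataclass
class IFParams:
    k: float
    m: float
    fitnesses: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"k must be non-negative, got {self.k}")
        if not 0.0 < self.m <= 1.0:
            raise ValueError(f"m must be in (0, 1], got {self.m}")
        if self.fitnesses is not None:
            if any(f < 0 for f in self.fitnesses.values()):
                raise ValueError("fitnesses must be non-negative")


# --------------------------------------------------------------------------
# Model HL (sequential death-birth)
# --------------------------------------------------------------------------

def hl_mortality_weights(state: LocalCommunityState, gamma: float) -> dict[int, float]:
    """Probability that the next death is of each species.

    ``w_i \\propto [(1-gamma) + gamma n_i/J] (n_i/J)``, normalized to 1.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    J = state.J
    w = {
        s: ((1.0 - gamma) + gamma * n / J) * (n / J)
        for s, n in state.counts.items()
    }
    tot = sum(w.values())
    return {s: v / tot for s, v in w.items()}


def _hl_immigrant_prob(m: float, J: int) -> float:
    # Eq. recruit weights use post-death abundances (sum J-1), so the
    # normalized probability of an immigrant recruit is:
    return m / (m + (1.0 - m) * (J - 1) / J)


@njit(cache=True)
def _hl_kernel(sp_id, sp_n, n_active, pos, J, gamma, p_imm, meta_cum,
               infinite, next_label, n_steps, seed):  # pragma: no cover
    np.random.seed(seed)
    for _ in range(n_steps * J):
        # death: weights ((1-gamma) + gamma n/J) * n  (common 1/J dropped)
        tot = 0.0
        for i in range(n_active):
            n = sp_n[i]
            tot += ((1.0 - gamma) + gamma * n / J) * n
        u = np.random.random() * tot
        di = n_active - 1
        acc = 0.0
        for i in range(n_active):
            n = sp_n[i]
            acc += ((1.0 - gamma) + gamma * n / J) * n
            if u < acc:
                di = i
                break
        sp_n[di] -= 1
        if sp_n[di] == 0:
            last = n_active - 1
            if not infinite:
                pos[sp_id[di]] = -1
            if di != last:
                sp_id[di] = sp_id[last]
                sp_n[di] = sp_n[last]
                if not infinite:
                    pos[sp_id[di]] = di
            n_active = last
        # recruitment (dying individual excluded from the copy pool)
        if np.random.random() < p_imm:
            if infinite:
                sp_id[n_active] = next_label
                sp_n[n_active] = 1
                n_active += 1
                next_label += 1
            else:
                r = np.random.random()
                s = np.searchsorted(meta_cum, r, side="right")
                if s >= meta_cum.size:
                    s = meta_cum.size - 1
                j = pos[s]
                if j >= 0:
                    sp_n[j] += 1
                else:
                    sp_id[n_active] = s
                    sp_n[n_active] = 1
                    pos[s] = n_active
                    n_active += 1
        else:
            r = int(np.random.random() * (J - 1))
            ci = n_active - 1
            acc2 = 0
            for i in range(n_active):
                acc2 += sp_n[i]
                if r < acc2:
                    ci = i
                    break
            sp_n[ci] += 1
    return n_active, next_label


class _HLSim:
    """Array-backed HL community advanced in blocks by the numba kernel."""

    def __init__(self, state: LocalCommunityState, params: HLParams,
                 meta: MetacommunityAbundances, next_label: int | None = None):
        self.J = state.J
        self.params = params
        self.meta = meta
        self.infinite = meta.is_infinite
        cap = self.J + 1
        self.sp_id = np.zeros(cap, dtype=np.int64)
        self.sp_n = np.zeros(cap, dtype=np.int64)
        self.n_active = 0
        if self.infinite:
            self.pos = np.zeros(1, dtype=np.int64)
            self.meta_cum = np.zeros(1)
            used = [s for s in state.counts]
            self.next_label = (max(used) + 1 if used else 1) \
                if next_label is None else next_label
        else:
            self.pos = np.full(meta.S_T, -1, dtype=np.int64)
            self.meta_cum = meta.cumulative()
            self.next_label = 0
        for s, n in state.counts.items():
            i = self.n_active
            sid = s if self.infinite else s - 1  # finite labels are 1-based
            self.sp_id[i] = sid
            self.sp_n[i] = n
            if not self.infinite:
                self.pos[sid] = i
            self.n_active += 1
        self.time = state.time

    def run(self, n_steps: int, rng: np.random.Generator) -> None:
        seed = int(rng.integers(2**31 - 1))
        p_imm = _hl_immigrant_prob(self.params.m, self.J)
        self.n_active, self.next_label = _hl_kernel(
            self.sp_id, self.sp_n, self.n_active, self.pos, self.J,
            float(self.params.gamma), float(p_imm), self.meta_cum,
            self.infinite, self.next_label, int(n_steps), seed,
        )
        self.time += int(n_steps)

    def counts_array(self) -> np.ndarray:
        return self.sp_n[: self.n_active].copy()

    def to_state(self) -> LocalCommunityState:
        counts = {}
        for i in range(self.n_active):
            sid = int(self.sp_id[i])
            counts[sid if self.infinite else sid + 1] = int(self.sp_n[i])
        return LocalCommunityState(counts=counts, J=self.J, time=self.time)


def hl_step(
    state: LocalCommunityState,
    params: HLParams,
    meta: MetacommunityAbundances,
    rng: np.random.Generator,
) -> LocalCommunityState:
    """One HL time step (``J`` elemental death-recruitment updates)."""
    sim = _HLSim(state, params, meta)
    sim.run(1, rng)
    return sim.to_state()


def hl_params_from_rates(
    r_plus: float, r_minus: float, K_prime: float, alpha: float,
    mu: float, J: int, S_T: int,
) -> HLParams:
    """Map stochastic Lotka-Volterra rates onto ``(gamma, m)``.

    The rate parametrization with density-independent birth/death rates
    ``r_plus``/``r_minus``, carrying capacity ``K_prime``, niche-overlap
    parameter ``alpha`` (neutral at 1) and immigration rate ``mu`` is
    equivalent to the HL update with

        gamma = 1 / (1 + [r_- K' + (r_+ - r_-) J alpha]
                         / [(r_+ - r_-) J (1 - alpha)])
        m     = 1 / (1 + r_+ J / (mu S_T))

    valid for ``r_+ > r_-`` and ``-r_- K' / ((r_+ - r_-) J) <= alpha <= 1``
    (strongly mutualistic interactions are excluded).
    """
    if r_plus <= r_minus:
        raise ValueError("r_plus must exceed r_minus for a non-trivial equilibrium")
    alpha_min = -r_minus * K_prime / ((r_plus - r_minus) * J)
    if not alpha_min <= alpha <= 1.0:
        raise ValueError(
            f"alpha={alpha} outside admissible range [{alpha_min}, 1]"
        )
    if alpha == 1.0:
        gamma = 0.0  # neutral interactions
    else:
        bracket = (r_minus * K_prime + (r_plus - r_minus) * J * alpha) / (
            (r_plus - r_minus) * J * (1.0 - alpha)
        )
        gamma = 1.0 / (1.0 + bracket)
    m = 1.0 / (1.0 + r_plus * J / (mu * S_T))
    params = HLParams(gamma=gamma, m=m)
    return params


# --------------------------------------------------------------------------
# Model PC (synchronous Ricker fecundity)
# --------------------------------------------------------------------------

def pc_propagule_fractions(state: LocalCommunityState, c: float) -> dict[int, float]:
    """Local propagule fractions ``L_i = n_i e^{-c n_i/J} / sum_k (...)``."""
    if c < 0:
        raise ValueError(f"c must be non-negative, got {c}")
    J = state.J
    w = {s: n * math.exp(-c * n / J) for s, n in state.counts.items()}
    tot = sum(w.values())
    return {s: v / tot for s, v in w.items()}


def _synchronous_gen_finite(
    n_dense: np.ndarray, local_w: np.ndarray, P: np.ndarray,
    m: float, J: int, rng: np.random.Generator,
) -> np.ndarray:
    tot = local_w.sum()
    if tot > 0:
        R = m * P + (1.0 - m) * local_w / tot
    else:  # no viable local propagules: all recruits are immigrants
        R = P
    return rng.multinomial(J, R / R.sum())


def pc_step(
    state: LocalCommunityState,
    params: PCParams,
    meta: MetacommunityAbundances,
    rng: np.random.Generator,
) -> LocalCommunityState:
    """One synchronous PC generation: ``{n_i} ~ multinomial(J, {R_i})``."""
    J = state.J
    if meta.is_infinite:
        labels = np.array(sorted(state.counts), dtype=np.int64)
        n = np.array([state.counts[int(s)] for s in labels], dtype=np.int64)
        w = n * np.exp(-params.c * n / J)
        new, fresh = _infinite_even_gen(n, w, params.m, J, rng)
        next_label = int(labels.max()) + 1 if labels.size else 1
        counts = {int(s): int(v) for s, v in zip(labels, new) if v > 0}
        for i in range(fresh):
            counts[next_label + i] = counts.get(next_label + i, 0) + 1
        return LocalCommunityState(counts=counts, J=J, time=state.time + 1)
    n_dense = _dense_counts(state, meta.S_T)
    w = n_dense * np.exp(-params.c * n_dense / J)
    new = _synchronous_gen_finite(n_dense, w, meta.rel_abundance, params.m, J, rng)
    return _state_from_dense(new, J, state.time + 1)


def _infinite_even_gen(
    n: np.ndarray, local_w: np.ndarray, m: float, J: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """One synchronous generation under immigration-as-speciation.

    Returns (new counts over existing species, number of fresh singleton
    species).  Each immigrant founds a species never seen before.
    """
    tot = local_w.sum()
    n_imm = int(rng.binomial(J, m)) if tot > 0 else J
    n_local = J - n_imm
    if n_local > 0:
        new = rng.multinomial(n_local, local_w / tot)
    else:
        new = np.zeros_like(n)
    return new, n_imm


# --------------------------------------------------------------------------
# Model IF (intrinsic fitness differences)
# --------------------------------------------------------------------------

def if_assign_fitnesses(
    species: int | list[int], k: float, rng: np.random.Generator
) -> dict[int, float]:
    """Draw i.i.d. species fitnesses for one realisation.

    Gamma with shape ``1/k`` and scale ``k`` (mean 1, CV ``sqrt(k)``);
    ``k = 0`` gives identical fitnesses, ``k = inf`` a single dominant
    species with all the fitness mass.
    """
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    labels = list(range(1, species + 1)) if isinstance(species, int) else list(species)
    if k == 0:
        return {s: 1.0 for s in labels}
    if math.isinf(k):
        f = {s: 0.0 for s in labels}
        f[labels[int(rng.integers(len(labels)))]] = 1.0
        return f
    # Gamma(1/k) via the boost identity G_a = G_{a+1} U^{1/a}: drawing the
    # log directly keeps extreme-k draws from underflowing to zero, and the
    # result is rescaled to mean 1 (the propagule fractions are scale-free)
    a = 1.0 / k
    n = len(labels)
    logf = np.log(rng.gamma(shape=a + 1.0, size=n)) + np.log(rng.random(n)) / a
    logf -= logf.max()
    f = np.exp(logf)
    mean = f.mean()
    if mean > 0:
        f = f / mean
    return {s: float(v) for s, v in zip(labels, f)}


def if_propagule_fractions(
    state: LocalCommunityState, fitnesses: dict[int, float]
) -> dict[int, float]:
    """Local propagule fractions ``L_i = f_i n_i / sum_k f_k n_k``.

    A pure ratio: rescaling all fitnesses by a common factor leaves the
    fractions unchanged.
    """
    w = {s: fitnesses[s] * n for s, n in state.counts.items()}
    tot = sum(w.values())
    if tot == 0:
        raise ValueError("total local fitness is zero; no local propagules")
    return {s: v / tot for s, v in w.items()}


def if_step(
    state: LocalCommunityState,
    params: IFParams,
    meta: MetacommunityAbundances,
    rng: np.random.Generator,
) -> LocalCommunityState:
    """One synchronous IF generation with ``L_i = f_i n_i / sum f_k n_k``."""
    if params.fitnesses is None:
        raise ValueError("IFParams.fitnesses must be assigned before stepping")
    J = state.J
    missing = [s for s in state.counts if s not in params.fitnesses]
    if missing:
        raise RuntimeError(f"species without assigned fitness: {missing[:5]}")
    if meta.is_infinite:
        labels = np.array(sorted(state.counts), dtype=np.int64)
        n = np.array([state.counts[int(s)] for s in labels], dtype=np.int64)
        f = np.array([params.fitnesses[int(s)] for s in labels])
        new, fresh = _infinite_even_gen(n, f * n, params.m, J, rng)
        next_label = max(params.fitnesses, default=0) + 1
        counts = {int(s): int(v) for s, v in zip(labels, new) if v > 0}
        for i in range(fresh):
            lab = next_label + i
            counts[lab] = 1
            params.fitnesses[lab] = _fresh_fitness(params.k, rng)
        return LocalCommunityState(counts=counts, J=J, time=state.time + 1)
    n_dense = _dense_counts(state, meta.S_T)
    f = np.array([params.fitnesses.get(s + 1, 0.0) for s in range(meta.S_T)])
    new = _synchronous_gen_finite(
        n_dense, f * n_dense, meta.rel_abundance, params.m, J, rng
    )
    return _state_from_dense(new, J, state.time + 1)


def _fresh_fitness(k: float, rng: np.random.Generator) -> float:
    if k == 0:
        return 1.0
    if math.isinf(k):
        return 0.0  # a fresh arrival never out-competes the dominant
    return float(rng.gamma(shape=1.0 / k, scale=k))


def if_kinf_even_probs(m: float, S_T: int) -> np.ndarray:
    """Stationary composition law of IF/EVEN in the ``k -> inf`` limit.

    Each individual is the single dominant species with probability
    ``1 - m (1 - 1/S_T)`` and each other species with probability
    ``m / S_T``; species 0 is the dominant.
    """
    p = np.full(S_T, m / S_T)
    p[0] = 1.0 - m * (1.0 - 1.0 / S_T)
    return p


def if_kinf_even_sample(
    m: float, S_T: int, J: int, rng: np.random.Generator
) -> AbundanceSample:
    """Exact equilibrium sample of IF/EVEN at ``k = inf`` (closed form)."""
    counts = rng.multinomial(J, if_kinf_even_probs(m, S_T))
    return AbundanceSample(
        counts[counts > 0],
        metadata={"source": "if_kinf_even", "m": m, "S_T": S_T, "J": J},
    )


# --------------------------------------------------------------------------
# Deterministic PC mean map and its stability
# --------------------------------------------------------------------------

def pc_mean_map(r: np.ndarray, c: float) -> np.ndarray:
    """Large-``J`` deterministic PC update on relative abundances."""
    g = r * np.exp(-c * r)
    return g / g.sum()


def pc_perturbation_growth_rate(
    c: float, S_T: int, n_iter: int = 4000, eps: float = 1e-8,
    seed: int = 0,
) -> float:
    """Per-step growth factor of a perturbation of the uniform fixed point.

    Power iteration on the map: a zero-sum perturbation of size ``eps`` is
    renormalized each step; the geometric mean growth factor estimates the
    dominant eigenvalue magnitude of the linearized map (< 1: stable).
    """
    rng = np.random.default_rng(seed)
    u = np.full(S_T, 1.0 / S_T)
    d = rng.normal(size=S_T)
    d -= d.mean()
    d /= np.linalg.norm(d)
    log_growth = 0.0
    n_meas = 0
    for t in range(n_iter):
        r = u + eps * d
        r_new = pc_mean_map(r, c)
        d_new = r_new - u
        nrm = np.linalg.norm(d_new)
        if nrm == 0:
            return 0.0
        if t >= n_iter // 10:  # discard transient onto dominant eigenvector
            log_growth += math.log(nrm / eps)
            n_meas += 1
        d = d_new / nrm
    return math.exp(log_growth / max(n_meas, 1))


def pc_uniform_fixed_point_stable(c: float, S_T: int, **kw: Any) -> bool:
    """Whether the uniform fixed point ``r* = 1/S_T`` is linearly stable."""
    return pc_perturbation_growth_rate(c, S_T, **kw) < 1.0


def pc_critical_scaled_c(
    S_T: int, tol: float = 1e-4, lo: float = 1.0, hi: float = 3.0,
) -> float:
    """Numerically locate the stability boundary of the uniform fixed point.

    Bisects on the scaled competition strength ``x = c r* = c / S_T``
    between a stable and an unstable value; returns the critical ``x``
    (analytically 2, the Ricker flip-bifurcation threshold).
    """
    f_lo = pc_perturbation_growth_rate(lo * S_T, S_T) - 1.0
    f_hi = pc_perturbation_growth_rate(hi * S_T, S_T) - 1.0
    if f_lo >= 0 or f_hi <= 0:
        raise ValueError("bracket does not straddle the stability boundary")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if pc_perturbation_growth_rate(mid * S_T, S_T) < 1.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# Equilibration driver
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BurnInPolicy:
    """Automatic burn-in detection for the community simulators.

    Richness and Shannon index are recorded on a geometric checkpoint
    schedule; once a trailing window of ``window`` checkpoints shows no
    significant shift in either series (Welch test between the window
    halves at level ``alpha``), that time ``T`` is taken as the
    equilibration estimate and the run is extended to
    ``safety_factor * T`` total steps.
    """

    # growth^(window-1) bounds the time-span ratio of the trailing window,
    # hence how far past the end of the transient detection can lag
    window: int = 12
    alpha: float = 0.05
    safety_factor: int = 10
    growth: float = 1.08
    max_steps: int = 200_000


def _dense_counts(state: LocalCommunityState, S_T: int) -> np.ndarray:
    n = np.zeros(S_T, dtype=np.int64)
    for s, v in state.counts.items():
        if not 1 <= s <= S_T:
            raise ValueError(f"species label {s} outside 1..{S_T}")
        n[s - 1] = v
    return n


def _state_from_dense(n: np.ndarray, J: int, time: int) -> LocalCommunityState:
    idx = np.nonzero(n)[0]
    return LocalCommunityState(
        counts={int(i) + 1: int(n[i]) for i in idx}, J=J, time=time
    )


def _sh(counts: np.ndarray, J: int) -> tuple[int, float]:
    p = counts[counts > 0] / J
    return int(p.size), float(-(p * np.log(p)).sum())


def _no_trend(times: list[int], vals: list[float], alpha: float) -> bool:
    # Welch test for a mean shift between the two window halves.  A rank
    # slope test is badly fooled by sparse discrete series (richness at
    # tiny m is mostly constant with rare spikes, which rank statistics
    # read as a strong trend); the half-window mean comparison treats a
    # lone spike as variance instead.
    from scipy.stats import ttest_ind

    arr = np.asarray(vals, dtype=float)
    scale = max(1.0, float(np.abs(arr).max()))
    if np.ptp(arr) <= 1e-9 * scale:
        return True
    h = arr.size // 2
    a, b = arr[:h], arr[arr.size - h:]
    if a.var() == 0 and b.var() == 0:
        return bool(a.mean() == b.mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = ttest_ind(a, b, equal_var=False)
    return bool(np.isnan(p) or p > alpha)


def _initial_state(
    meta: MetacommunityAbundances, J: int, rng: np.random.Generator
) -> LocalCommunityState:
    # i.i.d. draws from the metacommunity: unbiased w.r.t. local dynamics
    # and exact in the m=1 limit
    if meta.is_infinite:
        return LocalCommunityState(counts={i + 1: 1 for i in range(J)}, J=J)
    n = rng.multinomial(J, meta.rel_abundance)
    return _state_from_dense(n, J, 0)


def run_to_equilibrium(
    model: str,
    params: HLParams | PCParams | IFParams,
    meta: MetacommunityAbundances,
    J: int,
    rng: np.random.Generator,
    burn_in_policy: BurnInPolicy | None = None,
) -> AbundanceSample:
    """Simulate one model realisation to equilibrium; return its SAD.

    The community is initialized with ``J`` i.i.d. metacommunity draws,
    run until the burn-in detector sees no trend in richness or Shannon
    index, then extended by the policy's safety factor.  Time is counted
    in time steps (HL) or generations (PC/IF).
    """
    model = model.upper()
    policy = burn_in_policy or BurnInPolicy()
    state = _initial_state(meta, J, rng)

    if model == "IF" and params.fitnesses is None:
        if meta.is_infinite:
            fit = {s: _fresh_fitness(params.k, rng) for s in state.counts}
        else:
            fit = if_assign_fitnesses(int(meta.S_T), params.k, rng)
        params = IFParams(k=params.k, m=params.m, fitnesses=fit)
    if model == "PC":
        params.check_stability(meta.S_T)

    if model not in ("HL", "PC", "IF"):
        raise ValueError(f"unknown model {model!r}")
    hl_sim = _HLSim(state, params, meta) if model == "HL" else None
    dense = model in ("PC", "IF") and not meta.is_infinite
    if dense:
        n_dense = _dense_counts(state, meta.S_T)
        P = meta.rel_abundance
        if model == "IF":
            f_dense = np.array(
                [params.fitnesses.get(s + 1, 0.0) for s in range(meta.S_T)]
            )

    def advance(cur, n):
        nonlocal n_dense
        if model == "HL":
            hl_sim.run(n, rng)
            return None
        if dense:
            for _ in range(n):
                if model == "PC":
                    w = n_dense * np.exp(-params.c * n_dense / J)
                else:
                    w = f_dense * n_dense
                n_dense = _synchronous_gen_finite(n_dense, w, P, params.m, J, rng)
            return None
        for _ in range(n):
            cur = (pc_step if model == "PC" else if_step)(cur, params, meta, rng)
        return cur

    def current_counts(cur) -> np.ndarray:
        if model == "HL":
            return hl_sim.counts_array()
        if dense:
            return n_dense[n_dense > 0]
        return np.fromiter(cur.counts.values(), dtype=np.int64)

    def measure(cur) -> tuple[int, float]:
        return _sh(current_counts(cur), J)

    cur = None if (model == "HL" or dense) else state
    t = 0
    times: list[int] = []
    Ss: list[float] = []
    Hs: list[float] = []
    T_detect = None
    detect_cap = policy.max_steps // policy.safety_factor
    step = 1
    while t < detect_cap:
        cur = advance(cur, step)
        t += step
        S, H = measure(cur)
        times.append(t)
        Ss.append(S)
        Hs.append(H)
        w = policy.window
        if len(times) >= w and _no_trend(times[-w:], Ss[-w:], policy.alpha) \
                and _no_trend(times[-w:], Hs[-w:], policy.alpha):
            T_detect = t
            break
        step = max(step + 1, int(step * policy.growth))
    if T_detect is None:
        raise ConvergenceError(
            f"no equilibrium detected within {detect_cap} steps",
            diagnostics={"times": times, "richness": Ss, "shannon": Hs,
                         "model": model, "J": J},
        )
    cur = advance(cur, (policy.safety_factor - 1) * T_detect)
    total = policy.safety_factor * T_detect
    return AbundanceSample(
        current_counts(cur),
        metadata={
            "source": "simulation", "model": model, "meta": meta.kind,
            "J": J, "m": params.m, "params": params, "steps_run": total,
            "burn_in_detected": T_detect, "meta_S_T": meta.S_T,
            "meta_theta": meta.theta,
        },
    )
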