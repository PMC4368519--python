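"""Static metacommunity relative-abundance models.

The local community receives immigrants from a large, effectively static
species pool ("metacommunity") with fixed relative abundances ``P_i``.
Two concrete pools are provided:

* **LOGS** — relative abundances follow the continuum Fisher log-series
  (Ewens) frequency spectrum ``f_M(x) dx = theta x^{-1} (1-x)^{theta-1} dx``,
  the metacommunity of Hubbell's standard neutral model.  It is sampled by
  stick-breaking from the GEM(theta) size-biased representation, truncated
  at ``S_T`` species and renormalized; the truncation leaves expected mass
  ``(theta/(theta+1))^{S_T}``, negligible at the default ``S_T = 2000``.
* **EVEN** — ``S_T`` species with equal relative abundance ``1/S_T``, the
  maximally even (extremely non-neutral) contrast to the log-series.
* **infinite EVEN** — the ``S_T -> infinity`` limit of EVEN, in which every
  immigration event introduces a species never seen before locally, so
  immigration acts effectively as a speciation process.  Represented
  symbolically; simulators allocate fresh integer labels on arrival.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetacommunityAbundances",
    "sample_logseries_metacommunity",
    "even_metacommunity",
    "infinite_even_metacommunity",
    "write_metacommunity_table",
    "read_metacommunity_table",
]

LOGS = "LOGS"
EVEN = "EVEN"
INFINITE_EVEN = "INFINITE_EVEN"

_NORM_TOL = 1e-12


@dataclass
class MetacommunityAbundances:
    """Fixed relative species frequencies driving the immigration process.

    Parameters
    ----------
    rel_abundance
        Relative frequencies ``P_i`` (length ``S_T``); ``None`` for the
        symbolic infinite-EVEN pool.
    kind
        One of ``"LOGS"``, ``"EVEN"``, ``"INFINITE_EVEN"``.
    theta
        Fundamental biodiversity number (LOGS only).
    S_T
        Number of species in the pool, or ``math.inf``.
    """

    rel_abundance: np.ndarray | None
    kind: str
    theta: float | None = None
    S_T: float | int = 0
    seed: int | None = None
    _cum: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in (LOGS, EVEN, INFINITE_EVEN):
            raise ValueError(f"unknown metacommunity kind {self.kind!r}")
        if self.kind == INFINITE_EVEN:
            if self.rel_abundance is not None:
                raise ValueError("infinite-EVEN pool carries no frequency vector")
            self.S_T = math.inf
            return
        p = np.asarray(self.rel_abundance, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("rel_abundance must be a non-empty 1-D sequence")
        if np.any(p <= 0):
            raise ValueError("all relative abundances must be strictly positive")
        if abs(p.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"relative abundances sum to {p.sum()!r}, not 1")
        if self.kind == EVEN and not np.all(p == p[0]):
            raise ValueError("EVEN pool must have exactly equal frequencies")
        self.rel_abundance = p
        self.S_T = int(p.size)

    @property
    def is_infinite(self) -> bool:
        return self.kind == INFINITE_EVEN

    def cumulative(self) -> np.ndarray:
        """Cumulative frequencies, cached, for inverse-CDF immigrant draws."""
        if self._cum is None:
            c = np.cumsum(self.rel_abundance)
            c[-1] = 1.0
            self._cum = c
        return self._cum

    def shannon(self) -> float:
        if self.is_infinite:
            return math.inf
        p = self.rel_abundance
        return float(-np.sum(p * np.log(p)))


def sample_logseries_metacommunity(
    theta: float, S_T: int, seed: int | np.random.Generator
) -> MetacommunityAbundances:
    """Draw a LOGS metacommunity of ``S_T`` species at diversity ``theta``.

    Stick-breaking: residual fractions ``V_j ~ Beta(1, theta)`` give sizes
    ``P_j = V_j * prod_{l<j} (1 - V_l)``; the species-frequency density of
    this process is exactly ``theta x^{-1} (1-x)^{theta-1}``.  Truncated at
    ``S_T`` and renormalized.  Deterministic given ``seed``.
    """
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    S_T = int(S_T)
    if S_T < 1:
        raise ValueError(f"S_T must be >= 1, got {S_T}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = rng.beta(1.0, theta, size=S_T)
    v = np.clip(v, None, 1.0 - 1e-16)  # tiny theta can round the break to 1
    # log-space cumulative product of (1 - V) to stay stable at large S_T
    log_rem = np.concatenate(([0.0], np.cumsum(np.log1p(-v))[:-1]))
    p = np.exp(np.log(v) + log_rem)
    p = np.clip(p, np.finfo(float).tiny, None)
    p /= p.sum()
    return MetacommunityAbundances(
        rel_abundance=p, kind=LOGS, theta=float(theta),
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


def even_metacommunity(S_T: int) -> MetacommunityAbundances:
    """EVEN pool: ``S_T`` species, each with relative abundance ``1/S_T``."""
    S_T = int(S_T)
    if S_T < 1:
        raise ValueError(f"S_T must be >= 1, got {S_T}")
    return MetacommunityAbundances(rel_abundance=np.full(S_T, 1.0 / S_T), kind=EVEN)


def infinite_even_metacommunity() -> MetacommunityAbundances:
    """The EVEN pool in the ``S_T -> infinity`` limit (symbolic).

    Every immigrant belongs to a species never seen before in the local
    community; simulators allocate fresh labels from a counter.
    """
    return MetacommunityAbundances(rel_abundance=None, kind=INFINITE_EVEN)


def ewens_density(x: np.ndarray | float, theta: float) -> np.ndarray | float:
    """Expected number of species per unit relative abundance at ``x``."""
    x = np.asarray(x, dtype=float)
    return theta * (1.0 - x) ** (theta - 1.0) / x


def write_metacommunity_table(meta: MetacommunityAbundances, path) -> None:
    """Two-column TSV (species_id, rel_abundance) with a '#' header line."""
    if meta.is_infinite:
        raise ValueError("infinite-EVEN pool has no finite frequency table")
    with open(path, "w") as fh:
        fh.write(f"# kind={meta.kind} S_T={meta.S_T}"
                 + (f" theta={meta.theta}" if meta.theta is not None else "") + "\n")
        fh.write("# species_id\trel_abundance\n")
        for i, p in enumerate(meta.rel_abundance, start=1):
            fh.write(f"{i}\t{p:.17g}\n")


def read_metacommunity_table(path) -> MetacommunityAbundances:
    kind, theta = EVEN, None
    freqs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("kind="):
                        kind = tok[5:]
                    elif tok.startswith("theta="):
                        theta = float(tok[6:])
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            freqs.append(float(parts[1]))
    if not freqs:
        raise ValueError(f"{path}: empty metacommunity table")
    p = np.asarray(freqs)
    p /= p.sum()  # guard against round-tripped rounding
    if kind == EVEN and not np.allclose(p, p[0]):
        kind = LOGS
    return MetacommunityAbundances(rel_abundance=p, kind=kind, theta=theta)
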