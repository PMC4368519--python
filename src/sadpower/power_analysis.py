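"""Statistical power of the neutrality test for non-neutral generators.

The power of the test against a given community model is the probability
of rejecting the neutral null hypothesis when data are generated by that
model: many equilibrium data sets are simulated from the alternative,
each is tested by the parametric bootstrap, and the rejection fraction is
reported with a 95% Jeffreys binomial interval (equal-tailed
``Beta(x + 1/2, n - x + 1/2)`` quantiles).

A declarative sweep driver iterates a model x parameter x ``J`` grid,
writing one TSV row per cell and checkpointing so interrupted sweeps can
resume — a nod to how expensive these calculations are at realistic
scales.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
from scipy.stats import beta as beta_dist

from .local_dynamics import (
    BurnInPolicy,
    ConvergenceError,
    HLParams,
    IFParams,
    PCParams,
    if_kinf_even_sample,
    run_to_equilibrium,
)
from .metacommunity import (
    MetacommunityAbundances,
    even_metacommunity,
    infinite_even_metacommunity,
    sample_logseries_metacommunity,
)
from .neutral_inference import AbundanceSample, urn_sample
from .neutrality_test import bootstrap_test

__all__ = [
    "PowerEstimate",
    "ModelSpec",
    "jeffreys_interval",
    "estimate_power",
    "run_sweep",
    "FAST_PROFILE",
    "FULL_PROFILE",
]

# full-scale experiment profile (n_datasets, u) and a reduced fast profile
FULL_PROFILE = {"n_datasets": 400, "u": 1000}
FAST_PROFILE = {"n_datasets": 100, "u": 200}


def jeffreys_interval(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed Jeffreys interval for a binomial proportion.

    Endpoints are ``Beta(x+1/2, n-x+1/2)`` quantiles, with the standard
    conventions ``low = 0`` when ``x = 0`` and ``high = 1`` when ``x = n``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    tail = (1.0 - level) / 2.0
    a, b = x + 0.5, n - x + 0.5
    low = 0.0 if x == 0 else float(beta_dist.ppf(tail, a, b))
    high = 1.0 if x == n else float(beta_dist.ppf(1.0 - tail, a, b))
    return low, high


@dataclass(frozen=True)
class ModelSpec:
    """A fully specified generating model for one power calculation.

    ``model`` is one of ``"hl"``, ``"pc"``, ``"if"`` (simulated to
    equilibrium), ``"if-kinf"`` (the exact closed-form ``k -> inf``
    IF/EVEN generator) or ``"snm"`` (the neutral urn itself, for type-I
    calibration).  ``meta`` is ``"logs"``, ``"even"`` or
    ``"infinite-even"``; by default a fresh LOGS metacommunity is drawn
    for every replicate data set (set ``share_metacommunity`` to reuse
    one draw).
    """

    model: str
    J: int
    m: float
    meta: str = "logs"
    strength: float = 0.0           # gamma (hl), c (pc) or k (if)
    theta: float | None = None      # LOGS diversity
    S_T: int | None = None          # EVEN diversity
    share_metacommunity: bool = False
    burn_in: BurnInPolicy = field(default_factory=BurnInPolicy)

    def __post_init__(self) -> None:
        if self.model not in ("hl", "pc", "if", "if-kinf", "snm"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.meta not in ("logs", "even", "infinite-even"):
            raise ValueError(f"unknown metacommunity {self.meta!r}")
        if self.meta == "logs" and self.theta is None and self.model != "snm":
            raise ValueError("LOGS metacommunity requires theta")
        if self.meta == "even" and self.S_T is None:
            raise ValueError("EVEN metacommunity requires S_T")
        self.params()  # validate parameter ranges up front

    def params(self) -> HLParams | PCParams | IFParams | None:
        if self.model == "hl":
            return HLParams(gamma=self.strength, m=self.m)
        if self.model == "pc":
            return PCParams(c=self.strength, m=self.m)
        if self.model == "if":
            return IFParams(k=self.strength, m=self.m)
        return None

    def make_meta(self, rng: np.random.Generator) -> MetacommunityAbundances | None:
        if self.model in ("snm", "if-kinf"):
            return None
        if self.meta == "logs":
            return sample_logseries_metacommunity(self.theta, 2000, rng)
        if self.meta == "even":
            return even_metacommunity(self.S_T)
        return infinite_even_metacommunity()

    def sample(
        self, rng: np.random.Generator,
        meta: MetacommunityAbundances | None = None,
    ) -> AbundanceSample:
        """Draw one equilibrium data set from the generating model."""
        if self.model == "snm":
            if self.theta is None:
                raise ValueError("snm generator requires theta")
            return urn_sample(self.theta, self.m, self.J, rng)
        if self.model == "if-kinf":
            if self.S_T is None:
                raise ValueError("if-kinf generator requires S_T")
            return if_kinf_even_sample(self.m, self.S_T, self.J, rng)
        if meta is None:
            meta = self.make_meta(rng)
        return run_to_equilibrium(
            self.model, self.params(), meta, self.J, rng,
            burn_in_policy=self.burn_in,
        )


@dataclass
class PowerEstimate:
    """Rejection count, power, and Jeffreys CI for one parameter set."""

    n_datasets: int
    n_rejected: int
    power: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    generating_model: dict[str, Any] = field(default_factory=dict)
    n_failed: int = 0
    p_values: np.ndarray | None = None


def estimate_power(
    model_spec: ModelSpec,
    n_datasets: int = 400,
    u: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    level: float = 0.95,
    keep_p_values: bool = True,
) -> PowerEstimate:
    """Estimate the power of the neutrality test against ``model_spec``.

    Simulates ``n_datasets`` equilibrium data sets, bootstrap-tests each
    with ``u`` null replicates, and returns the rejection fraction with a
    Jeffreys ``level`` interval.  Data sets whose simulation fails to
    equilibrate are excluded and counted in ``n_failed``.
    """
    if n_datasets < 1:
        raise ValueError(f"n_datasets must be >= 1, got {n_datasets}")
    rng = rng if rng is not None else np.random.default_rng()
    shared_meta = None
    if model_spec.share_metacommunity:
        shared_meta = model_spec.make_meta(rng)
    p_values = []
    n_failed = 0
    for sub in rng.spawn(n_datasets):
        try:
            D = model_spec.sample(sub, meta=shared_meta)
        except ConvergenceError:
            n_failed += 1
            continue
        res = bootstrap_test(D, u=u, alpha=alpha, rng=sub)
        p_values.append(res.p_value)
    p_values = np.asarray(p_values)
    n_ok = p_values.size
    if n_ok == 0:
        raise RuntimeError("every data set failed to equilibrate")
    x = int(np.count_nonzero(p_values < alpha))
    lo, hi = jeffreys_interval(x, n_ok, level)
    return PowerEstimate(
        n_datasets=n_ok,
        n_rejected=x,
        power=x / n_ok,
        ci_low=lo,
        ci_high=hi,
        level=level,
        generating_model=dataclasses.asdict(model_spec),
        n_failed=n_failed,
        p_values=p_values if keep_p_values else None,
    )


# --------------------------------------------------------------------------
# Sweep driver
# --------------------------------------------------------------------------

_SWEEP_COLUMNS = [
    "model", "meta", "J", "m", "diversity", "strength",
    "n", "x", "power", "ci_low", "ci_high", "u", "alpha", "seed",
]


def _sweep_cells(config: dict[str, Any]) -> Iterable[dict[str, Any]]:
    """Expand a sweep config into per-cell parameter dictionaries."""
    def aslist(v: Any) -> list:
        return list(v) if isinstance(v, (list, tuple)) else [v]

    for J in aslist(config["J"]):
        for m in aslist(config["m"]):
            for strength in aslist(config.get("strength", 0.0)):
                for div in aslist(config.get("theta") or config.get("S_T") or [None]):
                    yield {
                        "model": config["model"], "meta": config.get("meta", "logs"),
                        "J": int(J), "m": float(m), "strength": float(strength),
                        "diversity": div,
                    }


def run_sweep(
    config: dict[str, Any],
    out_path: str,
    seed: int,
    n_datasets: int | None = None,
    u: int | None = None,
    alpha: float = 0.05,
) -> None:
    """Run a power sweep, appending one TSV row per completed cell.

    Cells already present in ``out_path`` are skipped, so an interrupted
    sweep resumes where it left off.  Every cell derives its RNG from
    ``seed`` and its own parameters, independent of execution order.
    """
    import os

    profile = FAST_PROFILE if config.get("profile") == "fast" else FULL_PROFILE
    n_datasets = n_datasets or config.get("n_datasets") or profile["n_datasets"]
    u = u or config.get("u") or profile["u"]
    alpha = config.get("alpha", alpha)

    done: set[tuple] = set()
    if os.path.exists(out_path):
        with open(out_path) as fh:
            for line in fh.read().splitlines()[1:]:
                parts = line.split("\t")
                if len(parts) == len(_SWEEP_COLUMNS):
                    done.add(tuple(parts[:6]))
    else:
        with open(out_path, "w") as fh:
            fh.write("\t".join(_SWEEP_COLUMNS) + "\n")

    for cell in _sweep_cells(config):
        key = tuple(
            str(cell[c]) for c in ("model", "meta", "J", "m", "diversity", "strength")
        )
        if key in done:
            continue
        div = cell["diversity"]
        is_logs = cell["meta"] == "logs"
        spec = ModelSpec(
            model=cell["model"], J=cell["J"], m=cell["m"], meta=cell["meta"],
            strength=cell["strength"],
            theta=float(div) if is_logs and div is not None else None,
            S_T=int(div) if not is_logs and div is not None else None,
        )
        import zlib

        cell_seed = zlib.crc32(repr((seed,) + key).encode()) % (2**31)
        est = estimate_power(
            spec, n_datasets=n_datasets, u=u, alpha=alpha,
            rng=np.random.default_rng(cell_seed), keep_p_values=False,
        )
        row = [
            cell["model"], cell["meta"], cell["J"], cell["m"], div,
            cell["strength"], est.n_datasets, est.n_rejected,
            f"{est.power:.6g}", f"{est.ci_low:.6g}", f"{est.ci_high:.6g}",
            u, alpha, cell_seed,
        ]
        with open(out_path, "a") as fh:
            fh.write("\t".join(str(v) for v in row) + "\n")
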