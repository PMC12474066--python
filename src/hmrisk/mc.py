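"""Monte Carlo wrapper over the deterministic health-risk model.

Uncertain inputs (concentrations, exposure parameters) are described by
:class:`ParameterDistribution` objects; ``run_mc`` draws n joint samples
from a single seeded stream (draw order: sorted parameter names), pushes
them through the vectorised TEHI/TCRI computation, and summarises each
output with percentiles, a CI for the mean, and threshold-exceedance
probabilities.  Sensitivity is contribution-to-variance: signed squared
Spearman rank correlation between each input and the output, normalised so
absolute contributions sum to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConfigurationError, ReferenceStandards, ValidationError
from .health import DEFAULT_CARCINOGENS, PATHWAYS, ExposureParameters, tehi_tcri_vector

__all__ = [
    "ParameterDistribution",
    "McResult",
    "McRun",
    "run_mc",
    "convergence_check",
    "sensitivity",
]

_TRUNC_RETRIES = 1000


@dataclass(frozen=True)
class ParameterDistribution:
    """One uncertain model input.

    law: "point" (value), "normal" (mean, sd), "lognormal" (arithmetic mean,
    sd), "uniform" (low, high), or "triangular" (left, mode, right); optional
    truncation bounds are enforced by rejection resampling.
    """

    name: str
    law: str
    params: tuple[float, ...]
    bounds: tuple[float | None, float | None] = (None, None)

    def __post_init__(self) -> None:
        n_needed = {"point": 1, "normal": 2, "lognormal": 2, "uniform": 2, "triangular": 3}
        if self.law not in n_needed:
            raise ConfigurationError(f"{self.name}: unknown law {self.law!r}")
        if len(self.params) != n_needed[self.law]:
            raise ConfigurationError(
                f"{self.name}: law {self.law!r} needs {n_needed[self.law]} parameter(s)"
            )
        if self.law in ("normal", "lognormal") and self.params[1] < 0:
            raise ConfigurationError(f"{self.name}: sd must be >= 0")
        if self.law == "uniform" and self.params[0] > self.params[1]:
            raise ConfigurationError(f"{self.name}: uniform low > high")
        if self.law == "triangular" and not (
            self.params[0] <= self.params[1] <= self.params[2]
        ):
            raise ConfigurationError(f"{self.name}: triangular needs left <= mode <= right")
        lo, hi = self.bounds
        if lo is not None and hi is not None and lo > hi:
            raise ConfigurationError(f"{self.name}: truncation bounds out of order")

    def _draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.law == "point":
            return np.full(n, float(self.params[0]))
        if self.law == "normal":
            return rng.normal(self.params[0], self.params[1], n)
        if self.law == "lognormal":
            mean, sd = self.params
            if sd == 0:
                return np.full(n, float(mean))
            if mean <= 0:
                raise ConfigurationError(f"{self.name}: lognormal mean must be > 0")
            sigma2 = np.log1p((sd / mean) ** 2)
            return rng.lognormal(np.log(mean) - sigma2 / 2, np.sqrt(sigma2), n)
        if self.law == "uniform":
            return rng.uniform(self.params[0], self.params[1], n)
        return rng.triangular(self.params[0], self.params[1], self.params[2], n)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        x = self._draw(rng, n)
        lo, hi = self.bounds
        if lo is not None or hi is not None:
            lo_ = -np.inf if lo is None else lo
            hi_ = np.inf if hi is None else hi
            for _ in range(_TRUNC_RETRIES):
                bad = (x < lo_) | (x > hi_)
                if not bad.any():
                    break
                x[bad] = self._draw(rng, int(bad.sum()))
            else:
                raise ValidationError(
                    f"{self.name}: truncation to [{lo_}, {hi_}] failed after "
                    f"{_TRUNC_RETRIES} passes"
                )
        return x


@dataclass
class McResult:
    """Summaries of one Monte Carlo output (TEHI or TCRI for a receptor)."""

    name: str
    samples: np.ndarray
    mean: float
    percentiles: dict[float, float]
    ci95_mean: tuple[float, float]
    exceedance: dict[float, float]
    n: int
    seed: int

    @classmethod
    def from_samples(
        cls, name: str, samples: np.ndarray, thresholds: Sequence[float], seed: int
    ) -> "McResult":
        s = np.asarray(samples, dtype=float)
        pcts = {q: float(np.percentile(s, q)) for q in (5.0, 50.0, 95.0)}
        se = s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0
        mean = float(s.mean())
        return cls(
            name=name,
            samples=s,
            mean=mean,
            percentiles=pcts,
            ci95_mean=(mean - 1.96 * se, mean + 1.96 * se),
            exceedance={float(t): float((s > t).mean()) for t in thresholds},
            n=len(s),
            seed=seed,
        )


@dataclass
class McRun:
    """A full Monte Carlo run: per-output results plus the input draws."""

    results: dict[str, McResult]
    input_draws: dict[str, np.ndarray]
    n: int
    seed: int
    provenance: dict = field(default_factory=dict)


def run_mc(
    standards: ReferenceStandards,
    exposure: ExposureParameters,
    dists: Mapping[str, ParameterDistribution],
    n: int = 10_000,
    seed: int = 0,
    pathways: Sequence[str] = PATHWAYS,
    carcinogens: Sequence[str] = DEFAULT_CARCINOGENS,
    tehi_threshold: float = 1.0,
    tcri_thresholds: Sequence[float] = (1e-6, 1e-4),
) -> McRun:
    """Sample uncertain inputs and propagate them through TEHI/TCRI.

    ``dists`` keys are either ``"C:<metal>"`` (a concentration, mg/kg) or an
    exposure field name (e.g. ``"BW"``); parameters without a distribution
    stay at their deterministic value from ``exposure``.  Identical seeds
    reproduce the run exactly (single stream, draws in sorted-key order).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws: dict[str, np.ndarray] = {}
    for key in sorted(dists):
        d = dists[key]
        x = d.sample(rng, n)
        if key.startswith("C:") or key in ("BW", "IR_ing", "IR_inh", "EF", "ED"):
            if np.any(x < 0) or (key == "BW" and np.any(x == 0)):
                raise ValidationError(f"distribution for {key} produced invalid draws")
        draws[key] = x

    conc = {key[2:]: x for key, x in draws.items() if key.startswith("C:")}
    if not conc:
        raise ConfigurationError("no concentration distribution (key 'C:<metal>') given")
    params: dict[str, np.ndarray | float] = exposure.as_dict()
    for key, x in draws.items():
        if not key.startswith("C:"):
            if key not in params and key not in ("AT_nc",):
                raise ConfigurationError(f"{key} does not map to a model input")
            params[key] = x

    tehi, tcri = tehi_tcri_vector(conc, params, standards, pathways, carcinogens)
    tehi = np.broadcast_to(tehi, (n,)).astype(float)
    tcri = np.broadcast_to(tcri, (n,)).astype(float)
    results = {
        f"TEHI:{exposure.receptor}": McResult.from_samples(
            f"TEHI:{exposure.receptor}", tehi, [tehi_threshold], seed
        ),
        f"TCRI:{exposure.receptor}": McResult.from_samples(
            f"TCRI:{exposure.receptor}", tcri, tcri_thresholds, seed
        ),
    }
    return McRun(
        results=results,
        input_draws=draws,
        n=n,
        seed=seed,
        provenance={
            "receptor": exposure.receptor,
            "pathways": list(pathways),
            "carcinogens": list(carcinogens),
        },
    )


def convergence_check(
    samples: np.ndarray, batch: int, tol: float = 0.01
) -> dict:
    """Batch-wise stability of the running mean and 95th percentile.

    Splits the sample into consecutive batches, tracks the cumulative mean
    and P95 after each, and flags convergence when the relative change of
    the P95 between the last two batches falls below ``tol`` (1% default).
    """
    s = np.asarray(samples, dtype=float)
    if batch < 1 or len(s) < 2 * batch:
        raise ValidationError("need at least two batches")
    edges = np.arange(batch, len(s) + 1, batch)
    running_mean = np.array([s[:e].mean() for e in edges])
    running_p95 = np.array([np.percentile(s[:e], 95.0) for e in edges])
    prev, last = running_p95[-2], running_p95[-1]
    rel_change = abs(last - prev) / abs(prev) if prev != 0 else abs(last - prev)
    return {
        "batch_edges": edges,
        "running_mean": running_mean,
        "running_p95": running_p95,
        "p95_rel_change": float(rel_change),
        "converged": bool(rel_change < tol),
        "tol": tol,
    }


def sensitivity(
    input_draws: Mapping[str, np.ndarray], output: np.ndarray
) -> pd.DataFrame:
    """Signed contribution-to-variance per input.

    Spearman rank correlation rho between each input and the output;
    contribution = 100 * rho^2 / sum(rho^2), carrying rho's sign.  Rank
    basis makes the measure invariant to monotone rescaling of inputs.
    Zero-variance inputs get contribution 0 and a flag.
    """
    out = np.asarray(output, dtype=float)
    rows = {}
    for name, x in input_draws.items():
        x = np.asarray(x, dtype=float)
        if len(x) != len(out):
            raise ValidationError(f"{name}: draw length mismatch")
        if x.std() == 0 or out.std() == 0:
            rows[name] = {"rho": 0.0, "flag": "zero-variance"}
            continue
        rho = float(stats.spearmanr(x, out).statistic)
        rows[name] = {"rho": rho, "flag": ""}
    df = pd.DataFrame.from_dict(rows, orient="index")
    total = float((df["rho"] ** 2).sum())
    if total > 0:
        df["contribution"] = 100.0 * np.sign(df["rho"]) * df["rho"] ** 2 / total
    else:
        df["contribution"] = 0.0
    return df.sort_values("contribution", key=np.abs, ascending=False)
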