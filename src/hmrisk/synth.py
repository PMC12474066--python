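"""Seeded synthetic site-table generator.

The field survey this package analyses published only summary statistics
(per-metal mean/SD/min/max over 33 water and 31 sediment sites) and mean BCR
fraction profiles, not per-site data.  This module generates site-level
tables whose summary statistics emulate those targets, so every downstream
index is testable end to end.

Concentrations are lognormal (non-negative, right-skewed, the conventional
law for environmental trace-metal data).  By default the draws are
*moment-calibrated*: the underlying normal deviates are standardised and a
two-parameter log-affine transform is solved (Brent's method) so the sample
arithmetic mean and SD equal the targets exactly.  This keeps small site
sets faithful to the published table; plain i.i.d. sampling is available
with ``calibrate=False``.

BCR fractions are Dirichlet about the target mean profile, so each site's
four fractions close to 100% by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .core import ConcentrationTable, Medium, ValidationError, data_path, logger
from .speciation import SpeciationTable

__all__ = [
    "MetalTarget",
    "GeneratorSpec",
    "GenerationError",
    "load_generator_spec",
    "default_spec_path",
    "generate_concentrations",
    "generate_speciation",
    "apply_hotspot",
]

#: passes of rejection resampling before truncated generation gives up
MAX_TRUNCATION_RETRIES = 1000

FRACTION_COLS = ("F1", "F2", "F3", "F4")


class GenerationError(RuntimeError):
    """Raised when a generator target is infeasible."""


@dataclass(frozen=True)
class MetalTarget:
    """Target arithmetic mean/SD (and optional truncation bounds) for one metal."""

    mean: float
    sd: float
    vmin: float | None = None
    vmax: float | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("target SD must be >= 0")
        if self.sd > 0 and self.mean <= 0:
            raise ValidationError("target mean must be > 0 when SD > 0")


@dataclass
class GeneratorSpec:
    """Full generator configuration: per-medium concentration targets,
    BCR fraction targets, site counts, Dirichlet precision, and the seed."""

    concentrations: dict[Medium, dict[str, MetalTarget]]
    n_sites: dict[Medium, int]
    fractions: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    speciation_n_sites: int = 31
    concentration_param: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for medium, n in self.n_sites.items():
            if n < 2:
                raise ValidationError(f"n_sites[{medium}] must be >= 2")
        for metal, fr in self.fractions.items():
            fr = tuple(float(x) for x in fr)
            if len(fr) != 4:
                raise ValidationError(f"{metal}: need four BCR fractions")
            if abs(sum(fr) - 100.0) > 0.01:
                raise ValidationError(f"{metal}: fraction targets sum to {sum(fr)}, not 100")
            self.fractions[metal] = fr


def default_spec_path() -> Path:
    return data_path("dongping_targets.yaml")


def load_generator_spec(path: str | Path | None = None, seed: int = 0) -> GeneratorSpec:
    """Load a generator spec from YAML (shipped survey targets when path is None)."""
    path = default_spec_path() if path is None else Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    conc: dict[Medium, dict[str, MetalTarget]] = {}
    n_sites: dict[Medium, int] = {}
    for medium in (Medium.WATER, Medium.SEDIMENT):
        block = raw.get(medium.value)
        if block is None:
            continue
        n_sites[medium] = int(block["n_sites"])
        conc[medium] = {
            metal: MetalTarget(
                mean=float(t["mean"]),
                sd=float(t["sd"]),
                vmin=float(t["min"]) if "min" in t else None,
                vmax=float(t["max"]) if "max" in t else None,
            )
            for metal, t in block["metals"].items()
        }
    spec_block = raw.get("speciation", {})
    fractions = {m: tuple(map(float, v)) for m, v in spec_block.get("fractions", {}).items()}
    return GeneratorSpec(
        concentrations=conc,
        n_sites=n_sites,
        fractions=fractions,
        speciation_n_sites=int(spec_block.get("n_sites", 31)),
        concentration_param=float(spec_block.get("concentration", 100.0)),
        seed=seed,
    )


def _calibrated_lognormal(rng: np.random.Generator, n: int, target: MetalTarget) -> np.ndarray:
    """Lognormal sample whose sample mean and SD (ddof=1) equal the target exactly."""
    z = rng.standard_normal(n)
    s = z.std(ddof=0)
    if s == 0:  # pragma: no cover - probability zero for n >= 2
        z = np.linspace(-1.0, 1.0, n)
        s = z.std(ddof=0)
    z = (z - z.mean()) / s
    cv = target.sd / target.mean
    if cv == 0:
        return np.full(n, target.mean)

    def gap(beta: float) -> float:
        w = np.exp(beta * z)
        return w.std(ddof=1) / w.mean() - cv

    beta = brentq(gap, 0.0, 50.0, xtol=1e-14)
    w = np.exp(beta * z)
    return w * (target.mean / w.mean())


def _iid_lognormal(rng: np.random.Generator, n: int, target: MetalTarget) -> np.ndarray:
    if target.sd == 0:
        return np.full(n, target.mean)
    cv2 = (target.sd / target.mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(target.mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), n)


def _truncated_lognormal(rng: np.random.Generator, n: int, target: MetalTarget) -> np.ndarray:
    lo = -np.inf if target.vmin is None else target.vmin
    hi = np.inf if target.vmax is None else target.vmax
    if not (lo <= target.mean <= hi):
        raise GenerationError(
            f"infeasible truncation: mean {target.mean} outside [{lo}, {hi}]"
        )
    x = _iid_lognormal(rng, n, target)
    for _ in range(MAX_TRUNCATION_RETRIES):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            return x
        x[bad] = _iid_lognormal(rng, int(bad.sum()), target)
    raise GenerationError(
        f"truncation to [{lo}, {hi}] did not converge in {MAX_TRUNCATION_RETRIES} passes"
    )


def generate_concentrations(
    spec: GeneratorSpec,
    medium: Medium | str,
    seed: int | None = None,
    calibrate: bool = True,
    truncate: bool = False,
) -> ConcentrationTable:
    """Generate a sites x metals table for one medium from the spec targets.

    Same spec and seed produce a byte-identical table.  ``truncate=True``
    resamples values outside each metal's [min, max] (plain i.i.d. draws:
    truncation and exact moment calibration are incompatible).
    """
    medium = Medium(medium)
    targets = spec.concentrations[medium]
    n = spec.n_sites[medium]
    base = spec.seed if seed is None else seed
    rng = np.random.default_rng([base, 0 if medium is Medium.WATER else 1])
    cols = {}
    for metal, target in targets.items():
        if truncate:
            cols[metal] = _truncated_lognormal(rng, n, target)
        elif calibrate:
            cols[metal] = _calibrated_lognormal(rng, n, target)
        else:
            cols[metal] = _iid_lognormal(rng, n, target)
    prefix = "W" if medium is Medium.WATER else "S"
    df = pd.DataFrame(cols, index=[f"{prefix}{i + 1:02d}" for i in range(n)])
    return ConcentrationTable(df, medium)


def generate_speciation(
    spec: GeneratorSpec, seed: int | None = None, noise: bool = True
) -> SpeciationTable:
    """Generate per-site BCR fraction profiles (percent mode).

    Per-site fraction quadruples are Dirichlet with mean equal to the target
    profile and precision ``spec.concentration_param``; ``noise=False`` is
    the infinite-precision limit where every site equals the targets.
    """
    if not spec.fractions:
        raise ValidationError("spec has no fraction targets")
    n = spec.speciation_n_sites
    base = spec.seed if seed is None else seed
    rng = np.random.default_rng([base, 2])
    blocks = {}
    for metal in spec.fractions:
        p = np.asarray(spec.fractions[metal], dtype=float) / 100.0
        if noise:
            alpha = spec.concentration_param * p
            draws = rng.dirichlet(alpha, size=n) * 100.0
        else:
            draws = np.tile(p * 100.0, (n, 1))
        blocks[metal] = draws
    sites = [f"S{i + 1:02d}" for i in range(n)]
    data = pd.concat(
        {m: pd.DataFrame(v, index=sites, columns=list(FRACTION_COLS)) for m, v in blocks.items()},
        axis=1,
    )
    return SpeciationTable(data, mode="percent")


def apply_hotspot(
    table: ConcentrationTable,
    sites: Sequence[str],
    metal: str,
    factor: float,
) -> ConcentrationTable:
    """Multiply the named metal by ``factor`` at the listed sites (point-source
    enrichment, e.g. the survey's Cd hotspots near the river inlet)."""
    if not np.isfinite(factor):
        raise ValidationError("hotspot factor must be finite")
    if len(sites) == 0:
        warnings.warn("apply_hotspot: empty site subset, returning table unchanged")
        return table.copy()
    missing = [s for s in sites if s not in table.values.index]
    if missing:
        raise ValidationError(f"hotspot sites not in table: {missing}")
    if metal not in table.values.columns:
        raise ValidationError(f"hotspot metal not in table: {metal}")
    out = table.values.copy()
    out.loc[list(sites), metal] *= factor
    logger.info("hotspot: %s x%g at %d sites", metal, factor, len(sites))
    return ConcentrationTable(out, table.medium)
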