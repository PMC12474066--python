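"""Heavy Metal Pollution Index (HPI) for surface water.

HPI is the Si-weighted mean of per-metal quality subindices:

    Wi = k / Si          unit weight (k cancels in the quotient)
    Qi = 100 * rho_i / Si
    HPI = sum(Qi * Wi) / sum(Wi)

with Si the maximum allowable concentration (GB 3838-2002 Class III here)
and rho_i the monitored concentration, both in ug/L.  HPI = 100 is the
conventional critical value.  HPI is linear in the concentration vector, so
the mean of per-site HPI equals the HPI of mean concentrations exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    HPI_METALS,
    SCALES,
    ConcentrationTable,
    Medium,
    ReferenceStandards,
    RiskResult,
    ValidationError,
)

__all__ = ["HpiBreakdown", "unit_weight", "quality_subindex", "hpi", "hpi_by_site"]


@dataclass
class HpiBreakdown:
    """HPI with its per-metal weights and subindices retained for audit."""

    wi: pd.Series
    qi: pd.Series
    hpi: float
    n: int


def unit_weight(si: float, k: float = 1.0) -> float:
    """Wi = k/Si; Si is the maximum allowable concentration (ug/L)."""
    if si <= 0:
        raise ValidationError(f"Si must be > 0, got {si}")
    return k / si


def quality_subindex(rho: float, si: float) -> float:
    """Qi = 100*rho/Si; 100 marks a concentration at its allowable limit."""
    if si <= 0:
        raise ValidationError(f"Si must be > 0, got {si}")
    if rho < 0:
        raise ValidationError(f"concentration must be >= 0, got {rho}")
    return 100.0 * rho / si


def hpi(
    concentrations: Mapping[str, float] | pd.Series,
    standards: ReferenceStandards,
    metals: Sequence[str] | None = None,
) -> HpiBreakdown:
    """Weighted HPI over a metal set (default: the ten prioritized water metals)."""
    conc = pd.Series(dict(concentrations), dtype=float)
    metals = list(HPI_METALS) if metals is None else list(metals)
    if not metals:
        raise ValidationError("empty metal set for HPI")
    missing = [m for m in metals if m not in conc.index]
    if missing:
        raise ValidationError(f"missing concentration for metal(s): {missing}")
    si = pd.Series(standards.require("water_limit", metals))
    wi = si.rdiv(standards.k)
    qi = pd.Series({m: quality_subindex(conc[m], si[m]) for m in metals})
    value = float((qi * wi).sum() / wi.sum())
    return HpiBreakdown(wi=wi, qi=qi, hpi=value, n=len(metals))


def hpi_by_site(
    table: ConcentrationTable,
    standards: ReferenceStandards,
    metals: Sequence[str] | None = None,
    low_threshold: float = 10.0,
) -> RiskResult:
    """Per-site HPI plus summary statistics for a water table."""
    if table.medium is not Medium.WATER:
        raise ValidationError("HPI is defined for water tables only")
    per_site = pd.Series(
        {site: hpi(table.values.loc[site], standards, metals).hpi for site in table.site_ids},
        name="HPI",
    )
    labels = pd.Series(
        SCALES["hpi"].classify_array(per_site.to_numpy()),
        index=per_site.index,
        name="class",
    )
    summary = {
        "mean": float(per_site.mean()),
        "min": float(per_site.min()),
        "max": float(per_site.max()),
        f"fraction_below_{low_threshold:g}": float((per_site < low_threshold).mean()),
    }
    return RiskResult(
        index_name="HPI",
        values=per_site,
        labels=labels,
        summary=summary,
        provenance={
            "metals": list(HPI_METALS) if metals is None else list(metals),
            "standards": standards.source,
            "n_sites": table.n_sites,
        },
    )
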