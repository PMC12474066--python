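"""Deterministic EPA-style multi-pathway exposure and risk computation.

For each metal and receptor, the average daily dose (ADD, mg kg-1 day-1)
through sediment ingestion, dermal contact, and particulate inhalation is

    ADD_ing  = C * IR_ing * EF * ED * CF / (BW * AT)
    ADD_derm = C * SA * AF * ABS * EF * ED * CF / (BW * AT)
    ADD_inh  = C * IR_inh * EF * ED / (PEF * BW * AT)

with C in mg/kg, CF = 1e-6 kg/mg, and AT the non-carcinogenic averaging
time ED*365 days or the 70-year lifetime for carcinogens.  Non-carcinogenic
hazard quotients are HQ = ADD/RfD, summed into the total exposure hazard
index TEHI (threshold 1); carcinogenic risks are CR = ADD*SF, summed into
TCRI (conventional acceptability band 1e-6 to 1e-4).

All functions accept scalars or aligned numpy arrays for every parameter,
which is what the Monte Carlo wrapper exploits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import SCALES, ConfigurationError, ReferenceStandards, ValidationError, data_path

__all__ = [
    "ExposureParameters",
    "HealthRiskResult",
    "load_exposure_parameters",
    "add_ingestion",
    "add_dermal",
    "add_inhalation",
    "total_add",
    "hazard",
    "cancer",
    "assess",
    "PATHWAYS",
    "DEFAULT_CARCINOGENS",
]

PATHWAYS = ("ingestion", "dermal", "inhalation")

# The survey's results name Cr > Ni > Cd as the assessed carcinogens.
DEFAULT_CARCINOGENS = ("Cr", "Ni", "Cd")


@dataclass
class ExposureParameters:
    """Receptor exposure parameters (see data/exposure_defaults.yaml for units)."""

    receptor: str
    IR_ing: float
    EF: float
    ED: float
    BW: float
    CF: float = 1e-6
    IR_inh: float | None = None
    SA: float | None = None
    AF: float | None = None
    ABS: float | None = None
    PEF: float | None = None
    AT_ca: float = 25550.0
    AT_nc: float | None = None  # defaults to ED*365

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ConfigurationError(f"{f.name} must be non-negative, got {v}")
        if self.ABS is not None and not (0.0 <= self.ABS <= 1.0):
            raise ConfigurationError("ABS must lie in [0, 1]")

    def averaging_time(self, carcinogenic: bool) -> float:
        if carcinogenic:
            return self.AT_ca
        return self.ED * 365.0 if self.AT_nc is None else self.AT_nc

    def as_dict(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in dc_fields(self)
            if f.name != "receptor" and getattr(self, f.name) is not None
        }


def load_exposure_parameters(path: str | Path | None = None) -> dict[str, ExposureParameters]:
    """Load receptor parameter sets (shipped child/adult defaults when None)."""
    path = data_path("exposure_defaults.yaml") if path is None else Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        receptor: ExposureParameters(receptor=receptor, **{k: float(v) for k, v in block.items()})
        for receptor, block in raw.items()
    }


def _param(p, name, default=None):
    v = p.get(name, default) if isinstance(p, Mapping) else getattr(p, name, default)
    return v


def _at(p, carcinogenic: bool):
    if isinstance(p, Mapping):
        if carcinogenic:
            return p["AT_ca"]
        return p.get("AT_nc", np.asarray(p["ED"], dtype=float) * 365.0)
    return p.averaging_time(carcinogenic)


def _dose(numerator, p, carcinogenic: bool):
    bw = np.asarray(_param(p, "BW"), dtype=float)
    at = np.asarray(_at(p, carcinogenic), dtype=float)
    denom = bw * at
    if np.any(denom == 0):
        raise ValidationError("BW*AT must be non-zero")
    out = numerator / denom
    return float(out) if np.ndim(out) == 0 else out


def add_ingestion(c, p, carcinogenic: bool = False):
    """ADD via incidental sediment ingestion."""
    num = (
        np.asarray(c, dtype=float)
        * np.asarray(_param(p, "IR_ing"), dtype=float)
        * np.asarray(_param(p, "EF"), dtype=float)
        * np.asarray(_param(p, "ED"), dtype=float)
        * np.asarray(_param(p, "CF", 1e-6), dtype=float)
    )
    return _dose(num, p, carcinogenic)


def add_dermal(c, p, carcinogenic: bool = False):
    """ADD via dermal contact with sediment (needs SA, AF, ABS)."""
    sa, af, absf = (_param(p, n) for n in ("SA", "AF", "ABS"))
    if sa is None or af is None or absf is None:
        raise ConfigurationError("dermal pathway needs SA, AF and ABS")
    num = (
        np.asarray(c, dtype=float)
        * np.asarray(sa, dtype=float)
        * np.asarray(af, dtype=float)
        * np.asarray(absf, dtype=float)
        * np.asarray(_param(p, "EF"), dtype=float)
        * np.asarray(_param(p, "ED"), dtype=float)
        * np.asarray(_param(p, "CF", 1e-6), dtype=float)
    )
    return _dose(num, p, carcinogenic)


def add_inhalation(c, p, carcinogenic: bool = False):
    """ADD via inhalation of resuspended particulates (needs IR_inh, PEF)."""
    ir, pef = _param(p, "IR_inh"), _param(p, "PEF")
    if ir is None or pef is None:
        raise ConfigurationError("inhalation pathway needs IR_inh and PEF")
    num = (
        np.asarray(c, dtype=float)
        * np.asarray(ir, dtype=float)
        * np.asarray(_param(p, "EF"), dtype=float)
        * np.asarray(_param(p, "ED"), dtype=float)
    ) / np.asarray(pef, dtype=float)
    return _dose(num, p, carcinogenic)


_PATHWAY_FUN = {
    "ingestion": add_ingestion,
    "dermal": add_dermal,
    "inhalation": add_inhalation,
}
_PATHWAY_NEEDS = {
    "ingestion": ("IR_ing",),
    "dermal": ("SA", "AF", "ABS"),
    "inhalation": ("IR_inh", "PEF"),
}


def total_add(c, p, carcinogenic: bool = False, pathways: Sequence[str] = PATHWAYS):
    """Sum of pathway ADDs; pathways missing their parameters are skipped
    with a warning (the survey notes dermal exposure is minor)."""
    total = None
    for pw in pathways:
        if any(_param(p, need) is None for need in _PATHWAY_NEEDS[pw]):
            warnings.warn(f"pathway {pw!r} skipped: missing parameter(s)")
            continue
        val = _PATHWAY_FUN[pw](c, p, carcinogenic)
        total = val if total is None else total + val
    if total is None:
        raise ConfigurationError("no pathway could be evaluated")
    return total


def hazard(
    adds: Mapping[str, float] | pd.Series, standards: ReferenceStandards
) -> tuple[pd.Series, float]:
    """Per-metal HQ = ADD/RfD and their sum TEHI.

    ``adds`` are non-carcinogenic total ADDs per metal (already summed over
    pathways).  Metals without an RfD are excluded with a warning.
    """
    adds = pd.Series(dict(adds), dtype=float)
    have = [m for m in adds.index if m in standards.rfd]
    dropped = [m for m in adds.index if m not in standards.rfd]
    if dropped:
        warnings.warn(f"no RfD for: {dropped}; excluded from TEHI")
    hq = pd.Series({m: adds[m] / standards.rfd[m] for m in have})
    return hq, float(hq.sum())


def cancer(
    adds: Mapping[str, float] | pd.Series,
    standards: ReferenceStandards,
    carcinogens: Sequence[str] = DEFAULT_CARCINOGENS,
) -> tuple[pd.Series, float, str]:
    """Per-carcinogen CR = ADD*SF, TCRI = sum(CR), and the TCRI band label."""
    adds = pd.Series(dict(adds), dtype=float)
    missing = [m for m in carcinogens if m not in standards.sf]
    if missing:
        raise ConfigurationError(f"no slope factor for carcinogen(s): {missing}")
    cr = pd.Series({m: adds[m] * standards.sf[m] for m in carcinogens})
    tcri = float(cr.sum())
    return cr, tcri, SCALES["tcri"].classify(tcri)


@dataclass
class HealthRiskResult:
    """Per-metal ADD/HQ/CR with TEHI and TCRI for one receptor."""

    receptor: str
    add_nc: pd.DataFrame
    add_ca: pd.DataFrame
    hq: pd.Series
    tehi: float
    cr: pd.Series
    tcri: float
    tcri_label: str
    tehi_label: str = ""
    provenance: dict = field(default_factory=dict)


def assess(
    concentrations: Mapping[str, float] | pd.Series,
    standards: ReferenceStandards,
    params: ExposureParameters,
    pathways: Sequence[str] = PATHWAYS,
    carcinogens: Sequence[str] = DEFAULT_CARCINOGENS,
) -> HealthRiskResult:
    """Full deterministic assessment of one concentration vector for one receptor."""
    conc = pd.Series(dict(concentrations), dtype=float)
    usable = [
        pw for pw in pathways if all(_param(params, n) is not None for n in _PATHWAY_NEEDS[pw])
    ]
    skipped = [pw for pw in pathways if pw not in usable]
    if skipped:
        warnings.warn(f"pathway(s) {skipped} skipped: missing parameter(s)")
    if not usable:
        raise ConfigurationError("no usable exposure pathway")
    add_nc = pd.DataFrame(
        {pw: {m: _PATHWAY_FUN[pw](conc[m], params, False) for m in conc.index} for pw in usable}
    )
    add_ca = pd.DataFrame(
        {pw: {m: _PATHWAY_FUN[pw](conc[m], params, True) for m in conc.index} for pw in usable}
    )
    hq, tehi = hazard(add_nc.sum(axis=1), standards)
    crs, tcri, tcri_label = cancer(
        add_ca.sum(axis=1)[list(carcinogens)], standards, carcinogens
    )
    return HealthRiskResult(
        receptor=params.receptor,
        add_nc=add_nc,
        add_ca=add_ca,
        hq=hq,
        tehi=tehi,
        cr=crs,
        tcri=tcri,
        tcri_label=tcri_label,
        tehi_label="negligible" if tehi < 1.0 else "potential concern",
        provenance={
            "pathways": usable,
            "carcinogens": list(carcinogens),
            "standards": standards.source,
        },
    )


def tehi_tcri_vector(
    conc: Mapping[str, np.ndarray],
    params: Mapping[str, np.ndarray],
    standards: ReferenceStandards,
    pathways: Sequence[str] = PATHWAYS,
    carcinogens: Sequence[str] = DEFAULT_CARCINOGENS,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised TEHI and TCRI over aligned parameter arrays (Monte Carlo core).

    ``conc`` maps metal -> concentration array; ``params`` maps exposure
    field -> array (or scalar).  Metals without an RfD contribute nothing to
    TEHI; carcinogens must all carry slope factors.
    """
    usable = [
        pw
        for pw in pathways
        if all(params.get(n) is not None for n in _PATHWAY_NEEDS[pw])
    ]
    if not usable:
        raise ConfigurationError("no usable exposure pathway")
    tehi = 0.0
    tcri = 0.0
    for metal, c in conc.items():
        if metal in standards.rfd:
            add_nc = sum(_PATHWAY_FUN[pw](c, params, False) for pw in usable)
            tehi = tehi + add_nc / standards.rfd[metal]
        if metal in carcinogens:
            if metal not in standards.sf:
                raise ConfigurationError(f"no slope factor for carcinogen {metal}")
            add_ca = sum(_PATHWAY_FUN[pw](c, params, True) for pw in usable)
            tcri = tcri + add_ca * standards.sf[metal]
    return np.asarray(tehi, dtype=float), np.asarray(tcri, dtype=float)
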