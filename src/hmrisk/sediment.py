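"""Sediment contamination and ecological-risk indices, Igeo, and TEL/PEL screening.

Hakanson's scheme: contamination factor Cf = C/Bn (measured over geochemical
background), per-metal potential ecological risk Er = Tr*Cf weighted by the
toxic-response coefficient, and the multi-metal risk index RI = sum(Er).
Because Er is linear in concentration, the mean of per-site Er equals the Er
of mean concentrations exactly, which is how the lake-level worked values
are reproduced from the published means.

The Muller geo-accumulation index Igeo = log2(C / (K*Bn)) with K = 1.5
(background-fluctuation correction) is nonlinear, so lake means only
approximate the mean of per-site Igeo (Jensen gap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    SCALES,
    ConcentrationTable,
    Medium,
    ReferenceStandards,
    RiskResult,
    ValidationError,
)

__all__ = [
    "EcologicalRiskBreakdown",
    "contamination_factor",
    "potential_risk",
    "risk_index",
    "ecological_risk",
    "er_by_site",
    "igeo",
    "igeo_table",
    "sqg_screen",
    "background_ratio_table",
]


def contamination_factor(c0, cn):
    """Cf = C0/Cn: measured content over the background (both mg/kg)."""
    cn_arr = np.asarray(cn, dtype=float)
    if np.any(cn_arr <= 0):
        raise ValidationError("background Cn must be > 0")
    c0_arr = np.asarray(c0, dtype=float)
    if np.any(c0_arr < 0):
        raise ValidationError("measured content must be >= 0")
    out = c0_arr / cn_arr
    return float(out) if out.ndim == 0 else out


def potential_risk(cf, tr):
    """Er = Tr*Cf, the per-metal potential ecological risk coefficient."""
    tr_arr = np.asarray(tr, dtype=float)
    if np.any(tr_arr < 0):
        raise ValidationError("toxicity coefficient Tr must be >= 0")
    out = tr_arr * np.asarray(cf, dtype=float)
    return float(out) if out.ndim == 0 else out


def risk_index(er_values: Mapping[str, float] | pd.Series) -> float:
    """RI = sum of Er over the assessed metal set (order-invariant)."""
    er = pd.Series(dict(er_values), dtype=float)
    if er.empty:
        raise ValidationError("RI of an empty metal set is undefined")
    return float(er.sum())


@dataclass
class EcologicalRiskBreakdown:
    """Cf/Er per metal and their sum RI, with the background set recorded."""

    cf: pd.Series
    er: pd.Series
    ri: float
    background_source: str = ""
    labels: pd.Series = field(default_factory=pd.Series)
    ri_label: str = ""


def ecological_risk(
    concentrations: Mapping[str, float] | pd.Series,
    standards: ReferenceStandards,
    metals: Sequence[str] | None = None,
) -> EcologicalRiskBreakdown:
    """Hakanson breakdown for one concentration vector (e.g. lake means)."""
    conc = pd.Series(dict(concentrations), dtype=float)
    metals = list(conc.index) if metals is None else list(metals)
    bn = pd.Series(standards.require("background", metals))
    tr = pd.Series(standards.require("toxicity", metals))
    cf = pd.Series({m: contamination_factor(conc[m], bn[m]) for m in metals})
    er = pd.Series({m: potential_risk(cf[m], tr[m]) for m in metals})
    ri = risk_index(er)
    labels = pd.Series(SCALES["er"].classify_array(er.to_numpy()), index=er.index)
    return EcologicalRiskBreakdown(
        cf=cf,
        er=er,
        ri=ri,
        background_source=standards.source,
        labels=labels,
        ri_label=SCALES["ri"].classify(ri),
    )


def er_by_site(table: ConcentrationTable, standards: ReferenceStandards) -> RiskResult:
    """Per-site Cf and Er matrices plus per-site RI."""
    if table.medium is not Medium.SEDIMENT:
        raise ValidationError("ecological risk is defined for sediment tables")
    metals = table.metals
    bn = pd.Series(standards.require("background", metals))
    tr = pd.Series(standards.require("toxicity", metals))
    er = table.values.div(bn, axis=1).mul(tr, axis=1)
    labels = er.apply(lambda col: SCALES["er"].classify_array(col.to_numpy()))
    ri = er.sum(axis=1)
    return RiskResult(
        index_name="Er",
        values=er,
        labels=labels,
        summary={
            "RI_per_site_mean": float(ri.mean()),
            "RI_of_means": float(er.mean(axis=0).sum()),
            "Er_means": er.mean(axis=0).to_dict(),
        },
        provenance={"standards": standards.source, "n_sites": table.n_sites},
    )


def igeo(c, bn, k: float = 1.5):
    """Muller geo-accumulation index log2(C/(K*Bn)).

    C = 0 (non-detect) maps to -inf rather than being dropped; callers that
    aggregate must handle the sentinel explicitly (silent exclusion would
    bias means).
    """
    bn_arr = np.asarray(bn, dtype=float)
    if np.any(bn_arr <= 0) or k <= 0:
        raise ValidationError("Igeo needs Bn > 0 and K > 0")
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValidationError("Igeo needs C >= 0")
    with np.errstate(divide="ignore"):
        out = np.log2(c_arr / (k * bn_arr))
    return float(out) if out.ndim == 0 else out


def igeo_table(
    table: ConcentrationTable, standards: ReferenceStandards, k: float = 1.5
) -> RiskResult:
    """Per-site Igeo matrix with class labels; -inf sentinels flagged."""
    bn = pd.Series(standards.require("background", table.metals))
    vals = table.values.apply(lambda col: igeo(col.to_numpy(), bn[col.name], k))
    nondetect = [
        (site, metal)
        for metal in vals.columns
        for site in vals.index[np.isneginf(vals[metal])]
    ]
    finite = vals.replace(-np.inf, np.nan)
    labels = vals.apply(
        lambda col: np.where(
            np.isneginf(col),
            "unpolluted",
            SCALES["igeo"].classify_array(np.where(np.isneginf(col), 0.0, col)),
        )
    )
    return RiskResult(
        index_name="Igeo",
        values=vals,
        labels=labels,
        summary={"means": finite.mean(axis=0).to_dict(), "K": k},
        provenance={
            "standards": standards.source,
            "nondetect_sentinels": nondetect,
            "n_sites": table.n_sites,
        },
    )


def sqg_screen(table: ConcentrationTable, standards: ReferenceStandards) -> RiskResult:
    """Fractions of sites above TEL and above PEL per metal.

    TEL marks the concentration below which adverse biological effects are
    not expected; PEL the level above which they occur frequently.  Metals
    lacking both thresholds are skipped with a warning.
    """
    if table.medium is not Medium.SEDIMENT:
        raise ValidationError("SQG screening is defined for sediment tables")
    rows, above_tel, above_pel, skipped = {}, {}, {}, []
    for metal in table.metals:
        tel = standards.tel.get(metal)
        pel = standards.pel.get(metal)
        if tel is None and pel is None:
            skipped.append(metal)
            continue
        col = table.values[metal]
        rec = {}
        if tel is not None:
            above_tel[metal] = col > tel
            rec["frac_above_tel"] = float((col > tel).mean())
        if pel is not None:
            above_pel[metal] = col > pel
            rec["frac_above_pel"] = float((col > pel).mean())
        rows[metal] = rec
    if skipped:
        warnings.warn(f"no TEL/PEL thresholds for: {skipped}; skipped")
    values = pd.DataFrame.from_dict(rows, orient="index")
    return RiskResult(
        index_name="SQG",
        values=values,
        labels=None,
        summary={
            "above_tel": pd.DataFrame(above_tel),
            "above_pel": pd.DataFrame(above_pel),
            "skipped": skipped,
        },
        provenance={"standards": standards.source, "n_sites": table.n_sites},
    )


def background_ratio_table(
    concentrations: Mapping[str, float] | pd.Series | ConcentrationTable,
    standards: ReferenceStandards,
) -> pd.Series:
    """Mean-concentration / background ratio per metal, descending."""
    if isinstance(concentrations, ConcentrationTable):
        conc = concentrations.mean()
    else:
        conc = pd.Series(dict(concentrations), dtype=float)
    bn = pd.Series(standards.require("background", list(conc.index)))
    return (conc / bn).sort_values(ascending=False).rename("ratio_to_background")
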