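"""BCR sequential-extraction speciation summaries and the Risk Assessment Code.

The BCR scheme partitions each metal into four operational fractions:
F1 weak-acid-soluble/exchangeable, F2 reducible (Fe/Mn oxide bound),
F3 oxidizable (organic/sulfide bound), F4 residual (lattice bound).
RAC is the F1 share of the total, a standard mobility/bioavailability proxy:
the higher the exchangeable share, the more readily the metal remobilises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SCALES, ClassificationScale, RiskResult, ValidationError

__all__ = ["SpeciationTable", "rac", "fraction_profile", "rac_by_site"]

FRACTION_COLS = ("F1", "F2", "F3", "F4")


@dataclass
class SpeciationTable:
    """Sites x (metal, fraction) table of BCR fractions.

    ``data`` has a two-level column index (metal, F1..F4).  ``mode`` is
    "percent" (each site's quadruple sums to 100 within ``closure_tol``) or
    "absolute" (mg/kg contents).  Analytical BCR data rarely closes exactly,
    so closure violations warn rather than fail.
    """

    data: pd.DataFrame
    mode: str = "percent"
    closure_tol: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("percent", "absolute"):
            raise ValidationError(f"unknown speciation mode {self.mode!r}")
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise ValidationError("speciation data needs (metal, fraction) columns")
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise ValidationError("negative fraction content")
        if self.mode == "percent":
            bad = self.closure_violations()
            if bad:
                warnings.warn(f"speciation closure beyond tolerance at: {bad}")

    @property
    def metals(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    def metal_frame(self, metal: str) -> pd.DataFrame:
        return self.data[metal]

    def closure_violations(self) -> list[tuple]:
        """(site, metal) pairs whose percent quadruple misses 100 by > closure_tol."""
        out = []
        for metal in self.metals:
            sums = self.data[metal].sum(axis=1)
            for site in sums.index[(sums - 100.0).abs() > self.closure_tol]:
                out.append((site, metal))
        return out

    def to_percent(self) -> "SpeciationTable":
        """Normalise each site quadruple to percentages (identity in percent mode
        up to closure error)."""
        blocks = {}
        for metal in self.metals:
            f = self.data[metal]
            total = f.sum(axis=1)
            if (total <= 0).any():
                raise ValidationError(f"all-zero fraction quadruple for {metal}")
            blocks[metal] = f.div(total, axis=0) * 100.0
        return SpeciationTable(pd.concat(blocks, axis=1), mode="percent")

    def to_long_csv(self, path: str | Path) -> None:
        rows = []
        for metal in self.metals:
            f = self.data[metal]
            for site in f.index:
                rows.append([site, metal, *f.loc[site, list(FRACTION_COLS)]])
        pd.DataFrame(rows, columns=["site", "metal", *FRACTION_COLS]).to_csv(path, index=False)

    @classmethod
    def from_long_csv(cls, path: str | Path, mode: str = "percent") -> "SpeciationTable":
        long = pd.read_csv(path, float_precision="round_trip")
        blocks = {
            metal: grp.set_index("site").rename_axis(None)[list(FRACTION_COLS)].astype(float)
            for metal, grp in long.groupby("metal", sort=False)
        }
        return cls(pd.concat(blocks, axis=1), mode=mode)


def rac(f1, f2, f3, f4):
    """Risk Assessment Code: 100*F1/(F1+F2+F3+F4), in percent.

    Scale-invariant, so absolute contents and percentages give the same
    value.  An all-zero quadruple is undefined and raises.
    """
    f1, f2, f3, f4 = (np.asarray(f, dtype=float) for f in (f1, f2, f3, f4))
    total = f1 + f2 + f3 + f4
    if np.any(total <= 0):
        raise ValidationError("RAC undefined: fraction quadruple sums to zero")
    out = 100.0 * f1 / total
    return float(out) if out.ndim == 0 else out


def fraction_profile(table: SpeciationTable, pooled: bool = False) -> pd.DataFrame:
    """Per-metal mean fraction percentages plus the 'available' share (F1+F2+F3).

    Default is the mean of per-site percentages; ``pooled=True`` instead
    computes percentages of the summed contents (the two agree for
    closed percent-mode data with equal site totals).
    """
    pct = table if table.mode == "percent" else table.to_percent()
    rows = {}
    for metal in pct.metals:
        if pooled:
            sums = table.metal_frame(metal).sum(axis=0)
            vec = (sums / sums.sum() * 100.0).to_numpy()
        else:
            vec = pct.metal_frame(metal).mean(axis=0).to_numpy()
        rows[metal] = vec
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(FRACTION_COLS))
    out["available"] = out[["F1", "F2", "F3"]].sum(axis=1)
    return out


def rac_by_site(
    table: SpeciationTable, scale: ClassificationScale | None = None
) -> RiskResult:
    """Per-site, per-metal RAC with class labels and per-metal summaries."""
    scale = SCALES["rac"] if scale is None else scale
    values = {}
    for metal in table.metals:
        f = table.metal_frame(metal)
        values[metal] = rac(f["F1"], f["F2"], f["F3"], f["F4"])
    vals = pd.DataFrame(values, index=table.site_ids)
    labels = vals.apply(lambda col: scale.classify_array(col.to_numpy()))
    summary = {
        metal: {
            "mean": float(vals[metal].mean()),
            "max": float(vals[metal].max()),
            "class_counts": labels[metal].value_counts().to_dict(),
        }
        for metal in vals.columns
    }
    return RiskResult(
        index_name="RAC",
        values=vals,
        labels=labels,
        summary=summary,
        provenance={"scale": scale.name, "mode": table.mode, "n_sites": len(vals)},
    )
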