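"""Shared domain types: concentration tables, reference standards, classification scales.

Concentrations are carried as a pandas DataFrame (sites x metals) wrapped in
:class:`ConcentrationTable`, which pins down the medium (water in ug/L,
sediment in mg/kg dry weight) and enforces non-negativity.  Reference values
(regulatory limits, geochemical backgrounds, toxicity coefficients, TEL/PEL,
RfD, SF) live in :class:`ReferenceStandards`, loaded from a YAML config; the
shipped defaults transcribe the study-area values (GB 3838-2002 Class III
water limits, Yellow River sediment backgrounds) plus reconstructed appendix
tables, each flagged as such in the file.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("hmrisk")

__all__ = [
    "Medium",
    "ConcentrationTable",
    "ReferenceStandards",
    "ClassificationScale",
    "RiskResult",
    "ValidationError",
    "ConfigurationError",
    "SCALES",
    "load_concentration_table",
    "load_reference_standards",
    "classify",
    "default_reference_path",
    "data_path",
]


class ValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


class ConfigurationError(ValueError):
    """Raised when a reference/exposure config is incomplete or inconsistent."""


class Medium(str, enum.Enum):
    WATER = "water"
    SEDIMENT = "sediment"

    @property
    def units(self) -> str:
        return "ug/L" if self is Medium.WATER else "mg/kg"


# Known element symbols for the two media in this study.
WATER_METALS = ["Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "As", "Cd", "Pb"]
SEDIMENT_METALS = ["Cr", "Mn", "Ni", "Cu", "Zn", "V", "Cd", "Pb", "Co"]

# Ten water metals retained for HPI (high detection rate in the study area).
HPI_METALS = ["Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "As"]


@dataclass
class ConcentrationTable:
    """Sites x metals concentration matrix with an attached medium.

    ``values`` is a DataFrame indexed by site label with element-symbol
    columns.  Missing observations stay as NaN and are reported through
    :meth:`missing_mask`; they are never silently treated as zero.
    """

    values: pd.DataFrame
    medium: Medium

    def __post_init__(self) -> None:
        self.medium = Medium(self.medium)
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicated site ids: {dupes}")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=np.inf) < 0:
            raise ValidationError("negative concentration in table")

    @property
    def site_ids(self) -> list:
        return list(self.values.index)

    @property
    def metals(self) -> list[str]:
        return list(self.values.columns)

    @property
    def units(self) -> str:
        return self.medium.units

    @property
    def n_sites(self) -> int:
        return len(self.values)

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def mean(self) -> pd.Series:
        return self.values.mean(axis=0)

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="site")

    def copy(self) -> "ConcentrationTable":
        return ConcentrationTable(self.values.copy(), self.medium)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConcentrationTable):
            return NotImplemented
        return self.medium == other.medium and self.values.equals(other.values)


def load_concentration_table(
    path: str | Path,
    medium: Medium | str,
    known_metals: Sequence[str] | None = None,
) -> ConcentrationTable:
    """Read a delimited site table (header row of element symbols, one row per site).

    Raises :class:`ValidationError` for negative values or, when
    ``known_metals`` is given, for unrecognised element symbols.
    """
    medium = Medium(medium)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0].lower() in ("site", "site_id", "id"):
        df = df.set_index(df.columns[0]).rename_axis(None)
    else:
        df.index = [f"S{i + 1}" for i in range(len(df))]
    if known_metals is None:
        known_metals = WATER_METALS if medium is Medium.WATER else SEDIMENT_METALS
    unknown = [m for m in df.columns if m not in known_metals]
    if unknown:
        raise ValidationError(f"unknown metal symbol(s): {unknown}")
    return ConcentrationTable(df.astype(float), medium)


@dataclass
class ReferenceStandards:
    """Per-metal reference values used by all assessment stages.

    water_limit
        Si, maximum allowable water concentration (ug/L; GB 3838-2002 Class III).
    background
        Bn, sediment geochemical background (mg/kg; Yellow River sediments).
    toxicity
        Tr, Hakanson toxic-response coefficient (dimensionless).
    tel / pel
        Threshold / probable effect level sediment quality guidelines (mg/kg).
    rfd
        Oral reference dose (mg kg-1 day-1).
    sf
        Carcinogenic slope factor ((mg kg-1 day-1)-1).
    k
        Proportionality constant for HPI unit weights (cancels; default 1).
    """

    water_limit: dict[str, float] = field(default_factory=dict)
    background: dict[str, float] = field(default_factory=dict)
    toxicity: dict[str, float] = field(default_factory=dict)
    tel: dict[str, float] = field(default_factory=dict)
    pel: dict[str, float] = field(default_factory=dict)
    rfd: dict[str, float] = field(default_factory=dict)
    sf: dict[str, float] = field(default_factory=dict)
    k: float = 1.0
    source: str = ""

    def __post_init__(self) -> None:
        for name, d, cond in (
            ("water_limit", self.water_limit, lambda v: v > 0),
            ("background", self.background, lambda v: v > 0),
            ("toxicity", self.toxicity, lambda v: v >= 0),
            ("rfd", self.rfd, lambda v: v > 0),
            ("sf", self.sf, lambda v: v >= 0),
        ):
            for metal, v in d.items():
                if not cond(float(v)):
                    raise ConfigurationError(f"{name}[{metal}] = {v} violates positivity")
        for metal in set(self.tel) & set(self.pel):
            if self.tel[metal] > self.pel[metal]:
                raise ConfigurationError(f"TEL > PEL for {metal}")

    def require(self, field_name: str, metals: Iterable[str]) -> dict[str, float]:
        """Return the named table restricted to ``metals``; error if any is absent."""
        table: Mapping[str, float] = getattr(self, field_name)
        missing = [m for m in metals if m not in table]
        if missing:
            raise ConfigurationError(f"missing {field_name} for metal(s): {missing}")
        return {m: float(table[m]) for m in metals}


def data_path(name: str) -> Path:
    """Path to a shipped data file inside the installed package."""
    return Path(resources.files("hmrisk.data").joinpath(name))  # type: ignore[arg-type]


def default_reference_path() -> Path:
    return data_path("reference_standards.yaml")


def load_reference_standards(path: str | Path | None = None) -> ReferenceStandards:
    """Load a ReferenceStandards YAML config (shipped defaults when ``path`` is None)."""
    path = default_reference_path() if path is None else Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ReferenceStandards(
        water_limit={k: float(v) for k, v in raw.get("water_limit", {}).items()},
        background={k: float(v) for k, v in raw.get("background", {}).items()},
        toxicity={k: float(v) for k, v in raw.get("toxicity", {}).items()},
        tel={k: float(v) for k, v in raw.get("tel", {}).items()},
        pel={k: float(v) for k, v in raw.get("pel", {}).items()},
        rfd={k: float(v) for k, v in raw.get("rfd", {}).items()},
        sf={k: float(v) for k, v in raw.get("sf", {}).items()},
        k=float(raw.get("k", 1.0)),
        source=str(raw.get("source", path)),
    )


@dataclass(frozen=True)
class ClassificationScale:
    """Ordered banding of a risk index into qualitative labels.

    ``bounds`` are the k interior cut points and ``labels`` the k+1 band
    names; every interval is lower-inclusive / upper-exclusive, so a value
    exactly on a cut point takes the upper band's label.
    """

    name: str
    bounds: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.bounds) + 1:
            raise ConfigurationError(f"scale {self.name}: need len(bounds)+1 labels")
        if any(b2 <= b1 for b1, b2 in zip(self.bounds, self.bounds[1:])):
            raise ConfigurationError(f"scale {self.name}: bounds not strictly increasing")
        if len(set(self.labels)) != len(self.labels):
            raise ConfigurationError(f"scale {self.name}: duplicate labels")

    def classify(self, value: float) -> str:
        if not np.isfinite(value):
            raise ValidationError(f"cannot classify non-finite value {value!r}")
        idx = int(np.searchsorted(self.bounds, value, side="right"))
        return self.labels[idx]

    def classify_array(self, values) -> np.ndarray:
        arr = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("cannot classify non-finite values")
        idx = np.searchsorted(self.bounds, arr, side="right")
        return np.asarray(self.labels, dtype=object)[idx]


def classify(value: float, scale: ClassificationScale) -> str:
    """Map a value to its band label under the scale's lower-inclusive convention."""
    return scale.classify(value)


# Literature banding scales.  The study's appendix tables are not published;
# these are the standard scales (Hakanson 1980 for Er/RI, Muller for Igeo,
# the conventional RAC bands), shipped here as the editable defaults.
SCALES: dict[str, ClassificationScale] = {
    "hpi": ClassificationScale(
        "hpi", (100.0,), ("acceptable", "exceeds acceptable")
    ),
    "er": ClassificationScale(
        "er",
        (40.0, 80.0, 160.0, 320.0),
        ("low", "moderate", "considerable", "high", "very high"),
    ),
    "ri": ClassificationScale(
        "ri", (150.0, 300.0, 600.0), ("low", "moderate", "considerable", "high")
    ),
    "igeo": ClassificationScale(
        "igeo",
        (0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
        (
            "unpolluted",
            "unpolluted to moderate",
            "moderate",
            "moderate to heavy",
            "heavy",
            "heavy to extreme",
            "extreme",
        ),
    ),
    "rac": ClassificationScale(
        "rac",
        (1.0, 10.0, 30.0, 50.0),
        ("none", "low", "medium", "high", "very high"),
    ),
    "tcri": ClassificationScale(
        "tcri", (1e-6, 1e-4), ("negligible", "acceptable", "unacceptable")
    ),
    # Ad-hoc cut points quoted in the study's narrative ("less than 5",
    # "range of 5-10", "range of 80-160"); kept as a named alternative.
    "er_narrative": ClassificationScale(
        "er_narrative",
        (5.0, 10.0, 80.0, 160.0),
        ("no hazard", "slight", "enriched", "high", "severe"),
    ),
}


@dataclass
class RiskResult:
    """Per-site / per-metal index values with class labels and provenance."""

    index_name: str
    values: pd.DataFrame | pd.Series
    labels: pd.DataFrame | pd.Series | None = None
    summary: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValidationError("RiskResult.provenance must be populated")
        if self.labels is not None and np.shape(self.labels) != np.shape(self.values):
            raise ValidationError("value and label matrices must share shape")
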