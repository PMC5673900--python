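"""Station-table ingest: validation, blank correction, volume normalization.

Particulate trace-element samples arrive as per-filter leachate amounts
(nmol per filter) together with the volume of water drawn through each
filter. This module turns those bottle records into depth-ordered
:class:`StationProfile` objects holding concentrations in nM with 2SD
uncertainties, applying the max-of-blanks correction before volume
normalization. All tabular output is plain comma-separated text and
round-trips losslessly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("pelagicbarite")

#: Elements quantified in filter leachates.
ELEMENTS = ("Al", "Ba", "Ca", "Cd", "Fe", "Mn", "P", "Sr", "Ti", "V", "Y")

#: Default analytical relative standard deviations (1 RSD, fraction).
#: Midpoints of the typical 2-4% (most elements) and 7-10% (Cd, Ti, V)
#: ICP-MS reproducibility ranges; override per run via the schema.
DEFAULT_ANALYTIC_RSD = {
    el: (0.085 if el in ("Cd", "Ti", "V") else 0.03) for el in ELEMENTS
}

#: Acceptable filtered-volume window in liters (configurable via schema).
DEFAULT_VOLUME_WINDOW = (0.5, 3.0)


class SchemaError(ValueError):
    """A station table does not match the expected column layout."""


class ValidationError(ValueError):
    """A record violates a physical invariant (e.g. negative volume)."""


@dataclass(frozen=True)
class IsotopeDelta:
    """A δ138/134Ba value in per mil vs NIST SRM 3104a.

    ``kind`` labels the uncertainty ("2SD", "2SE", or "range"); ``n`` is
    the number of measurements behind the value where applicable.
    """

    value: float
    uncertainty: float
    kind: str = "2SD"
    n: int | None = None

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValidationError("isotope uncertainty must be >= 0")
        if not self.kind:
            raise ValidationError("uncertainty kind label is required")


@dataclass
class RawBottleRecord:
    """One filter's worth of leachate data, in internal units (m, L, nmol)."""

    station: str
    depth_m: float
    volume_L: float
    amounts: dict[str, float]  # nmol per filter
    rsd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ANALYTIC_RSD))
    delta138Ba: float | None = None
    delta138Ba_2sd: float | None = None
    dissolved_Ba_nM: float | None = None
    dissolved_delta138Ba: float | None = None
    nepheloid: bool = False
    pool_top_m: float | None = None
    pool_bottom_m: float | None = None

    def __post_init__(self) -> None:
        if self.depth_m <= 0:
            raise ValidationError(f"depth must be > 0 m, got {self.depth_m}")
        if self.volume_L <= 0:
            raise ValidationError(f"filtered volume must be > 0 L, got {self.volume_L}")
        for el, amt in self.amounts.items():
            if amt < 0:
                raise ValidationError(f"negative leachate amount for {el}: {amt}")


@dataclass
class BlankSet:
    """Dipped blank plus exactly two process blanks, in nmol per filter."""

    dipped: dict[str, float]
    process: tuple[dict[str, float], dict[str, float]]
    rsd: float = 0.12  # 1 RSD of blank measurement, median reported value

    def __post_init__(self) -> None:
        if len(self.process) != 2:
            raise ValidationError("exactly two process blanks are required")
        for blanks in (self.dipped, *self.process):
            for el, v in blanks.items():
                if v < 0:
                    raise ValidationError(f"negative blank for {el}: {v}")

    @classmethod
    def zero(cls) -> "BlankSet":
        z = {el: 0.0 for el in ELEMENTS}
        return cls(dipped=dict(z), process=(dict(z), dict(z)), rsd=0.12)


@dataclass
class TableSchema:
    """Column vocabulary + unit scales for delimited station tables.

    Element columns hold leachate amounts per filter; ``amount_scale``
    converts them to nmol (1.0 when the table is already in nmol).
    Foreign tables (e.g. repository exports with their own headers) are
    read by overriding the column names here, never by editing the table.
    """

    station_col: str = "station"
    depth_col: str = "depth_m"
    volume_col: str = "volume_L"
    element_cols: dict[str, str] = field(
        default_factory=lambda: {el: el for el in ELEMENTS}
    )
    delta_col: str = "delta138Ba"
    delta_sd_col: str = "delta138Ba_2sd"
    dissolved_ba_col: str = "dissolved_Ba_nM"
    dissolved_delta_col: str = "dissolved_delta138Ba"
    nepheloid_col: str = "nepheloid"
    pool_top_col: str = "pool_top_m"
    pool_bottom_col: str = "pool_bottom_m"
    depth_scale: float = 1.0  # multiply to get meters
    volume_scale: float = 1.0  # multiply to get liters
    amount_scale: float = 1.0  # multiply to get nmol
    rsd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ANALYTIC_RSD))
    volume_window: tuple[float, float] = DEFAULT_VOLUME_WINDOW


def read_station_table(path, schema: TableSchema | None = None) -> list[RawBottleRecord]:
    """Read a delimited station table into raw bottle records.

    Required columns are the station id, depth, filtered volume, and at
    least one element column. Missing required columns raise
    :class:`SchemaError` naming the column; a nonpositive volume raises
    :class:`ValidationError`.
    """
    schema = schema or TableSchema()
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"unreadable or empty station table {path}: {exc}") from exc
    for col in (schema.station_col, schema.depth_col, schema.volume_col):
        if col not in table.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    present = {
        el: col for el, col in schema.element_cols.items() if col in table.columns
    }
    if not present:
        raise SchemaError(f"no element columns found in {path}")

    records = []
    for _, row in table.iterrows():
        volume = float(row[schema.volume_col]) * schema.volume_scale
        if volume <= 0:
            raise ValidationError(
                f"nonpositive filtered volume {volume} L at depth {row[schema.depth_col]}"
            )
        lo, hi = schema.volume_window
        if not (lo <= volume <= hi):
            log.warning("filtered volume %.2f L outside window [%g, %g] L", volume, lo, hi)
        amounts = {
            el: float(row[col]) * schema.amount_scale
            for el, col in present.items()
            if pd.notna(row[col])
        }

        def opt(col):
            return float(row[col]) if col in table.columns and pd.notna(row[col]) else None

        records.append(
            RawBottleRecord(
                station=str(row[schema.station_col]),
                depth_m=float(row[schema.depth_col]) * schema.depth_scale,
                volume_L=volume,
                amounts=amounts,
                rsd=dict(schema.rsd),
                delta138Ba=opt(schema.delta_col),
                delta138Ba_2sd=opt(schema.delta_sd_col),
                dissolved_Ba_nM=opt(schema.dissolved_ba_col),
                dissolved_delta138Ba=opt(schema.dissolved_delta_col),
                nepheloid=bool(row[schema.nepheloid_col])
                if schema.nepheloid_col in table.columns and pd.notna(row[schema.nepheloid_col])
                else False,
                pool_top_m=opt(schema.pool_top_col),
                pool_bottom_m=opt(schema.pool_bottom_col),
            )
        )
    return records


def blank_correct(
    raw: RawBottleRecord, blanks: BlankSet, element: str
) -> tuple[float, float, bool]:
    """Blank-correct one element of one record.

    Subtracts the larger of the dipped blank or the mean of the two
    process blanks. Blank measurement uncertainty is propagated scaled by
    the magnitude of the correction actually applied. Returns
    ``(corrected_nmol, two_sd_nmol, negative_flag)``; negative corrected
    values are retained and flagged, never clipped.
    """
    if element not in raw.amounts:
        raise KeyError(f"element {element!r} not present in record")
    amount = raw.amounts[element]
    dipped = blanks.dipped.get(element, 0.0)
    proc = 0.5 * (blanks.process[0].get(element, 0.0) + blanks.process[1].get(element, 0.0))
    correction = max(dipped, proc)
    corrected = amount - correction
    sd_analytic = raw.rsd.get(element, 0.03) * amount
    sd_blank = blanks.rsd * correction
    two_sd = 2.0 * math.hypot(sd_analytic, sd_blank)
    negative = corrected < 0
    if negative:
        log.warning(
            "blank-corrected %s below zero (%.3g - %.3g nmol) at %.1f m; flagged",
            element, amount, correction, raw.depth_m,
        )
    elif correction > 0:
        log.debug("blank correction for %s: -%.3g nmol (%.1f%%)",
                  element, correction, 100 * correction / amount if amount else float("inf"))
    return corrected, two_sd, negative


def to_concentration(
    amount_nmol: float,
    two_sd_nmol: float,
    volume_L: float,
    volume_two_sd_L: float = 0.0,
) -> tuple[float, float]:
    """Volume-normalize a corrected amount to nM, combining relative
    uncertainties in quadrature."""
    if volume_L <= 0:
        raise ValidationError(f"volume must be > 0 L, got {volume_L}")
    conc = amount_nmol / volume_L
    rel_v = volume_two_sd_L / volume_L
    if amount_nmol != 0:
        rel_a = two_sd_nmol / abs(amount_nmol)
        two_sd = abs(conc) * math.hypot(rel_a, rel_v)
    else:
        # zero amount: only the (absolute) blank-derived term survives
        two_sd = two_sd_nmol / volume_L
    return conc, two_sd


@dataclass
class StationProfile:
    """Depth-ordered particulate/dissolved measurements for one station.

    ``data`` holds one row per depth with columns ``depth_m``,
    ``p_<el>`` / ``p_<el>_2sd`` (nM), optional ``delta138Ba`` /
    ``delta138Ba_2sd`` (per mil), dissolved Ba columns, and boolean flags
    (``nepheloid``, per-element ``<el>_neg_blank``). Depths are strictly
    increasing.
    """

    station: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        depths = self.data["depth_m"].to_numpy(float)
        if not np.all(np.diff(depths) > 0):
            raise ValidationError("profile depths must be strictly increasing")
        for col in self.data.columns:
            if col.startswith("p_") and not col.endswith(("_2sd", "_neg_blank")):
                if f"{col}_2sd" not in self.data.columns:
                    raise ValidationError(f"missing uncertainty column {col}_2sd")
        self._check_pools()

    def _check_pools(self) -> None:
        if "pool_top_m" not in self.data.columns:
            return
        pools = self.data.dropna(subset=["pool_top_m", "pool_bottom_m"])
        spans = sorted(zip(pools["pool_top_m"], pools["pool_bottom_m"]))
        for (t0, b0), (t1, _) in zip(spans, spans[1:]):
            if t1 < b0:
                raise ValidationError("pooled-depth ranges overlap")

    @property
    def depths(self) -> np.ndarray:
        return self.data["depth_m"].to_numpy(float)

    def element(self, el: str) -> tuple[np.ndarray, np.ndarray]:
        """Concentration and 2SD arrays (nM) for one element."""
        return (
            self.data[f"p_{el}"].to_numpy(float),
            self.data[f"p_{el}_2sd"].to_numpy(float),
        )

    @property
    def elements(self) -> list[str]:
        return [
            c[2:]
            for c in self.data.columns
            if c.startswith("p_") and not c.endswith(("_2sd", "_neg_blank"))
        ]


def build_profile(
    records: list[RawBottleRecord], blanks: BlankSet | None = None
) -> StationProfile:
    """Blank-correct and volume-normalize bottle records into a profile.

    Records are sorted by depth (positive downward). With ``blanks=None``
    a zero blank set is used, i.e. pure volume normalization.
    """
    if not records:
        raise ValidationError("no records to build a profile from")
    blanks = blanks or BlankSet.zero()
    stations = {r.station for r in records}
    if len(stations) > 1:
        raise ValidationError(f"records span multiple stations: {sorted(stations)}")
    rows = []
    for rec in sorted(records, key=lambda r: r.depth_m):
        row: dict[str, object] = {"depth_m": rec.depth_m}
        for el in rec.amounts:
            corrected, two_sd, neg = blank_correct(rec, blanks, el)
            conc, conc_sd = to_concentration(corrected, two_sd, rec.volume_L)
            row[f"p_{el}"] = conc
            row[f"p_{el}_2sd"] = conc_sd
            row[f"p_{el}_neg_blank"] = neg
        row["delta138Ba"] = rec.delta138Ba
        row["delta138Ba_2sd"] = rec.delta138Ba_2sd
        row["dissolved_Ba_nM"] = rec.dissolved_Ba_nM
        row["dissolved_delta138Ba"] = rec.dissolved_delta138Ba
        row["nepheloid"] = rec.nepheloid
        row["pool_top_m"] = rec.pool_top_m
        row["pool_bottom_m"] = rec.pool_bottom_m
        rows.append(row)
    return StationProfile(station=records[0].station, data=pd.DataFrame(rows))


def write_profile(profile: StationProfile, path) -> None:
    """Write a profile as CSV with full float precision (round-trip safe)."""
    out = profile.data.copy()
    out.insert(0, "station", profile.station)
    out.to_csv(path, index=False, float_format="%.17g")


def read_profile(path) -> StationProfile:
    data = pd.read_csv(path, float_precision="round_trip")
    if "station" not in data.columns:
        raise SchemaError(f"profile table {path} lacks a 'station' column")
    station = str(data["station"].iloc[0])
    for col in data.columns:
        if col.endswith("_neg_blank") or col == "nepheloid":
            data[col] = data[col].astype(bool)
    return StationProfile(station=station, data=data.drop(columns="station"))
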