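"""Decomposition of particulate Ba into lithogenic, biogenic, and excess
phases, plus profile diagnostics.

The operational definition of excess particulate barium subtracts a
lithogenic contribution (Fe-normalized) and an organic-matter contribution
(P-normalized) from measured particulate Ba:

    pBa_XS = p[Ba] - p[Fe] * (Ba/Fe)_litho - p[P] * (Ba/P)_bio

with all concentrations in nM and the normalizing ratios in mol/mol.
pBa_XS is the water-column proxy for pelagic barite. Diagnostics here
(depth-integrated excess fraction, Ba:Sr, the p[P] gradient, and the
power-law attenuation exponent b) characterize where in the water column
organic matter is remineralized and where the excess appears.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles_io import StationProfile, ValidationError

log = logging.getLogger("pelagicbarite")


@dataclass
class EndmemberRatios:
    """Normalizing molar ratios, in mM:M (i.e. 1e-3 mol/mol), with 2SD.

    Defaults are the lithogenic Ba:Fe and organic-matter Ba:P of dilute
    lake particulates; the 2SDs are configuration, not measured truth
    (10% relative by default).
    """

    ba_fe_mM_M: float = 2.87
    ba_fe_2sd: float = 0.287
    ba_p_mM_M: float = 0.44
    ba_p_2sd: float = 0.044

    def __post_init__(self) -> None:
        if self.ba_fe_mM_M <= 0 or self.ba_p_mM_M <= 0:
            raise ValidationError("endmember ratios must be > 0")

    @property
    def ba_fe(self) -> float:
        """Ba:Fe in mol/mol."""
        return self.ba_fe_mM_M * 1e-3

    @property
    def ba_p(self) -> float:
        """Ba:P in mol/mol."""
        return self.ba_p_mM_M * 1e-3


@dataclass
class PartitionResult:
    """Per-depth decomposition of measured particulate Ba.

    ``table`` columns: depth_m, pBa_meas, pBa_litho, pBa_bio, pBa_xs,
    pBa_xs_2sd, f_litho, f_bio, f_xs, negative_xs. The three components
    sum to the measured value exactly at every depth (closure).
    """

    station: str
    ratios: EndmemberRatios
    table: pd.DataFrame


def partition_excess(
    profile: StationProfile, ratios: EndmemberRatios | None = None
) -> PartitionResult:
    """Partition particulate Ba into lithogenic/biogenic/excess at each depth.

    Depths missing any of Ba, Fe, P are omitted with a warning. Negative
    excess is retained and flagged. The quoted 2SD on pBa_XS is Gaussian
    quadrature over the five inputs; the full joint treatment lives in
    :mod:`pelagicbarite.isotope_massbalance`.
    """
    ratios = ratios or EndmemberRatios()
    for el in ("Ba", "Fe", "P"):
        if el not in profile.elements:
            raise ValidationError(f"profile lacks p[{el}]")
    ba, ba_sd = profile.element("Ba")
    fe, fe_sd = profile.element("Fe")
    p, p_sd = profile.element("P")
    depths = profile.depths

    ok = np.isfinite(ba) & np.isfinite(fe) & np.isfinite(p)
    if not ok.all():
        log.warning(
            "omitting %d depth(s) with missing Ba/Fe/P: %s",
            int((~ok).sum()), depths[~ok],
        )
    litho = fe * ratios.ba_fe
    bio = p * ratios.ba_p
    xs = ba - litho - bio
    # quadrature over p[Ba], p[Fe], p[P], and both ratios (2SDs throughout)
    xs_sd = np.sqrt(
        ba_sd**2
        + (ratios.ba_fe * fe_sd) ** 2
        + (fe * ratios.ba_fe_2sd * 1e-3) ** 2
        + (ratios.ba_p * p_sd) ** 2
        + (p * ratios.ba_p_2sd * 1e-3) ** 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        f_litho = np.where(ba != 0, litho / ba, np.nan)
        f_bio = np.where(ba != 0, bio / ba, np.nan)
        f_xs = np.where(ba != 0, xs / ba, np.nan)
    table = pd.DataFrame(
        {
            "depth_m": depths[ok],
            "pBa_meas": ba[ok],
            "pBa_litho": litho[ok],
            "pBa_bio": bio[ok],
            "pBa_xs": xs[ok],
            "pBa_xs_2sd": xs_sd[ok],
            "f_litho": f_litho[ok],
            "f_bio": f_bio[ok],
            "f_xs": f_xs[ok],
            "negative_xs": xs[ok] < 0,
        }
    )
    n_neg = int(table["negative_xs"].sum())
    if n_neg:
        log.info("%d depth(s) with negative pBa_XS retained and flagged", n_neg)
    return PartitionResult(station=profile.station, ratios=ratios, table=table)


def integrate_excess_fraction(
    result: PartitionResult, window: tuple[float, float]
) -> float:
    """Fraction of depth-integrated particulate Ba that is excess.

    Trapezoidal integrals of pBa_XS and measured pBa over the depths
    falling inside ``window`` (meters, inclusive), on the native grid.
    """
    z0, z1 = window
    sub = result.table[(result.table["depth_m"] >= z0) & (result.table["depth_m"] <= z1)]
    if len(sub) < 2:
        raise ValidationError(
            f"depth window [{z0}, {z1}] m contains {len(sub)} profile depth(s); need >= 2"
        )
    z = sub["depth_m"].to_numpy(float)
    total = np.trapezoid(sub["pBa_meas"].to_numpy(float), z)
    excess = np.trapezoid(sub["pBa_xs"].to_numpy(float), z)
    if total == 0:
        raise ValidationError("integrated pBa is zero over the window")
    return float(excess / total)


@dataclass
class AttenuationFit:
    """Power-law attenuation fit p[P](z) = p[P]_ref * (z/z_ref)^b."""

    b: float
    r_squared: float
    z_ref_m: float
    p_ref_nM: float
    depths_used: np.ndarray = field(repr=False)
    excluded_depths: np.ndarray = field(repr=False)


def fit_attenuation(
    profile: StationProfile, exclude_nepheloid: bool = True,
    exclude_depths: tuple[float, ...] = (),
) -> AttenuationFit:
    """Fit the power-law attenuation exponent b to the p[P] profile.

    The reference depth is the depth of maximum p[P] (shallower depth on
    ties); the fit uses depths at or below it, by ordinary least squares
    on log-transformed values with a free intercept. Flagged nepheloid
    samples and any explicitly excluded depths are dropped first;
    nonpositive p[P] values in the fit window are dropped with a warning.
    """
    p, _ = profile.element("P")
    z = profile.depths
    excluded = np.zeros_like(z, dtype=bool)
    if exclude_nepheloid and "nepheloid" in profile.data.columns:
        excluded |= profile.data["nepheloid"].fillna(False).to_numpy(bool)
    for d in exclude_depths:
        excluded |= np.isclose(z, d)

    cand = ~excluded & np.isfinite(p)
    if not cand.any():
        raise ValidationError("no usable p[P] values for attenuation fit")
    i_ref = np.flatnonzero(cand)[np.argmax(p[cand])]  # argmax -> shallowest tie
    z_ref, p_ref = z[i_ref], p[i_ref]
    window = cand & (z >= z_ref)
    bad = window & (p <= 0)
    if bad.any():
        log.warning("dropping %d nonpositive p[P] value(s) from fit window", int(bad.sum()))
        window &= p > 0
    if window.sum() < 3:
        raise ValidationError(
            f"attenuation fit needs >= 3 depths at/below z_ref={z_ref} m, have {int(window.sum())}"
        )
    x = np.log(z[window] / z_ref)
    y = np.log(p[window] / p_ref)
    b, intercept = np.polyfit(x, y, 1)
    yhat = b * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot
    return AttenuationFit(
        b=float(b),
        r_squared=r2,
        z_ref_m=float(z_ref),
        p_ref_nM=float(p_ref),
        depths_used=z[window],
        excluded_depths=z[excluded],
    )


def p_gradient(profile: StationProfile) -> np.ndarray:
    """dp[P]/dz in nM per m on the native grid.

    Centered finite differences at interior depths, one-sided at the
    ends (``numpy.gradient`` on the nonuniform grid). Negative values
    mean attenuation with depth.
    """
    p, _ = profile.element("P")
    z = profile.depths
    if len(z) < 2:
        raise ValidationError("gradient needs >= 2 depths")
    return np.gradient(p, z)


def ba_sr_ratio(profile: StationProfile) -> pd.DataFrame:
    """Molar p[Ba]:p[Sr] per depth with quadrature uncertainty.

    Depths with p[Sr] = 0 yield NaN and are flagged ``undefined``.
    """
    ba, ba_sd = profile.element("Ba")
    sr, sr_sd = profile.element("Sr")
    undefined = sr == 0
    if undefined.any():
        log.warning("p[Sr] = 0 at %d depth(s); Ba:Sr undefined there", int(undefined.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(undefined, np.nan, ba / sr)
        rel = np.sqrt(
            np.where(ba != 0, (ba_sd / ba) ** 2, 0.0)
            + np.where(undefined, np.nan, (sr_sd / np.where(undefined, np.nan, sr)) ** 2)
        )
    return pd.DataFrame(
        {
            "depth_m": profile.depths,
            "ba_sr": ratio,
            "ba_sr_2sd": np.abs(ratio) * rel,
            "undefined": undefined,
        }
    )
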