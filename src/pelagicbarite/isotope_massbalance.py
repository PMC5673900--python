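"""Ba-isotope mass balance for the excess particulate phase.

δ138/134Ba is the per-mil deviation of a sample's 138Ba/134Ba from the
NIST SRM 3104a standard. Measured particulate δ is modeled as a
two-component mixture of "supported" Ba (lithogenic + organic-matter
endmembers, combined abundance-weighted) and the excess phase, whose
composition follows from unmixing:

    δ_XS = (δ_meas - f_supp * δ_supp) / f_XS ,   f_supp + f_XS = 1

Uncertainty on the unmixed δ_XS is propagated by joint Monte Carlo over
every input of both the concentration partitioning and the isotope
balance. Gaussian perturbations use SD = half the quoted 2SD; the
organic-matter endmember, quoted as mean ± range, is drawn uniformly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .partitioning import EndmemberRatios
from .profiles_io import IsotopeDelta, StationProfile, ValidationError

log = logging.getLogger("pelagicbarite")


@dataclass
class EndmemberDeltas:
    """Isotopic endmembers (per mil vs NIST SRM 3104a)."""

    litho: IsotopeDelta = IsotopeDelta(+0.02, 0.05, "2SD")
    bio: IsotopeDelta = IsotopeDelta(-0.02, 0.08, "range")
    dissolved: IsotopeDelta = IsotopeDelta(+0.23, 0.02, "2SD")


@dataclass
class MCSettings:
    """Monte Carlo configuration. The seed is mandatory and is recorded
    in every output."""

    n_draws: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1000:
            raise ValidationError("need >= 1000 draws for a reported 2SD")


def delta_from_ratios(sample_ratio: float, standard_ratio: float) -> float:
    """δ (per mil) from a sample and standard 138Ba/134Ba ratio."""
    if sample_ratio <= 0 or standard_ratio <= 0:
        raise ValidationError("isotope ratios must be > 0")
    return (sample_ratio / standard_ratio - 1.0) * 1000.0


def supported_delta(f_bio, f_litho, endmembers: EndmemberDeltas | None = None):
    """Abundance-weighted δ of the supported (litho + bio) pool.

    Weights are renormalized over the supported pool, so only the
    bio:litho proportion matters.
    """
    endmembers = endmembers or EndmemberDeltas()
    f_bio = np.asarray(f_bio, float)
    f_litho = np.asarray(f_litho, float)
    tot = f_bio + f_litho
    if np.any(tot <= 0):
        raise ValidationError("supported fractions sum to zero")
    out = (endmembers.bio.value * f_bio + endmembers.litho.value * f_litho) / tot
    return float(out) if out.ndim == 0 else out


def excess_delta(delta_meas, f_supp, delta_supp, f_xs, atol: float = 1e-9):
    """Unmix the excess-phase δ from the measured particulate δ."""
    delta_meas = np.asarray(delta_meas, float)
    f_supp = np.asarray(f_supp, float)
    f_xs = np.asarray(f_xs, float)
    if np.any(np.abs(f_supp + f_xs - 1.0) > max(atol, 1e-9)):
        raise ValidationError("f_supp + f_XS must equal 1")
    if np.any(f_xs <= 0):
        raise ValidationError("delta_XS undefined for f_XS <= 0")
    out = (delta_meas - f_supp * np.asarray(delta_supp, float)) / f_xs
    return float(out) if out.ndim == 0 else out


@dataclass
class ExcessDeltaResult:
    """Per-depth Monte Carlo unmixing output.

    ``table`` columns: depth_m, f_xs (deterministic), pBa_xs,
    pBa_xs_median, pBa_xs_2sd, delta_xs (deterministic point value),
    delta_xs_median, delta_xs_2sd, valid_fraction (share of draws with
    f_XS > 0), unreliable (valid fraction < 0.5), passes_filter
    (f_xs > threshold with a finite δ). Rows exist only where a measured
    particulate δ is available.
    """

    station: str
    table: pd.DataFrame
    settings: MCSettings
    f_threshold: float


def monte_carlo_excess(
    profile: StationProfile,
    ratios: EndmemberRatios | None = None,
    endmembers: EndmemberDeltas | None = None,
    settings: MCSettings | None = None,
    f_threshold: float = 0.2,
) -> ExcessDeltaResult:
    """Jointly propagate partitioning and unmixing uncertainties.

    Per draw, the two normalizing ratios and the two endmember δs are
    perturbed globally (one draw shared by all depths), while measured
    concentrations and δ are perturbed per depth. Draws with f_XS <= 0 at
    a depth are excluded from that depth's δ distribution but counted,
    so the validity rate is auditable; depths where more than half the
    draws are invalid are flagged unreliable. Central values are medians
    of the draw distributions; spreads are 2SD of the draws.
    """
    ratios = ratios or EndmemberRatios()
    endmembers = endmembers or EndmemberDeltas()
    settings = settings or MCSettings()
    rng = np.random.default_rng(settings.seed)
    n = settings.n_draws

    if "delta138Ba" not in profile.data.columns:
        raise ValidationError("profile has no particulate delta138Ba column")
    has_delta = np.isfinite(profile.data["delta138Ba"].to_numpy(float))
    if not has_delta.any():
        raise ValidationError("profile has no particulate delta138Ba measurements")
    sub = profile.data[has_delta]
    depths = sub["depth_m"].to_numpy(float)
    ba = sub["p_Ba"].to_numpy(float)
    ba_sd = sub["p_Ba_2sd"].to_numpy(float) / 2
    fe = sub["p_Fe"].to_numpy(float)
    fe_sd = sub["p_Fe_2sd"].to_numpy(float) / 2
    p = sub["p_P"].to_numpy(float)
    p_sd = sub["p_P_2sd"].to_numpy(float) / 2
    d_meas = sub["delta138Ba"].to_numpy(float)
    d_meas_sd = np.nan_to_num(sub["delta138Ba_2sd"].to_numpy(float)) / 2

    # global per-draw parameter perturbations
    r_fe = rng.normal(ratios.ba_fe, ratios.ba_fe_2sd * 1e-3 / 2, size=n)
    r_p = rng.normal(ratios.ba_p, ratios.ba_p_2sd * 1e-3 / 2, size=n)
    d_litho = rng.normal(endmembers.litho.value, endmembers.litho.uncertainty / 2, size=n)
    d_bio = rng.uniform(
        endmembers.bio.value - endmembers.bio.uncertainty,
        endmembers.bio.value + endmembers.bio.uncertainty,
        size=n,
    )

    rows = []
    for i, z in enumerate(depths):
        ba_i = rng.normal(ba[i], ba_sd[i], size=n)
        fe_i = rng.normal(fe[i], fe_sd[i], size=n)
        p_i = rng.normal(p[i], p_sd[i], size=n)
        dm_i = rng.normal(d_meas[i], d_meas_sd[i], size=n)
        litho_i = fe_i * r_fe
        bio_i = p_i * r_p
        xs_i = ba_i - litho_i - bio_i
        with np.errstate(divide="ignore", invalid="ignore"):
            f_xs_i = xs_i / ba_i
            supp_pool = litho_i + bio_i
            d_supp_i = np.where(
                supp_pool > 0, (d_bio * bio_i + d_litho * litho_i) / supp_pool, np.nan
            )
            d_xs_i = (dm_i - (1.0 - f_xs_i) * d_supp_i) / f_xs_i
        valid = (f_xs_i > 0) & np.isfinite(d_xs_i)
        valid_fraction = float(valid.mean())

        # deterministic point evaluation at central parameter values
        xs_det = ba[i] - fe[i] * ratios.ba_fe - p[i] * ratios.ba_p
        f_xs_det = xs_det / ba[i] if ba[i] != 0 else np.nan
        if np.isfinite(f_xs_det) and f_xs_det > 0:
            d_supp_det = supported_delta(
                p[i] * ratios.ba_p, fe[i] * ratios.ba_fe, endmembers
            )
            d_xs_det = excess_delta(d_meas[i], 1 - f_xs_det, d_supp_det, f_xs_det)
        else:
            d_xs_det = np.nan

        d_valid = d_xs_i[valid]
        rows.append(
            {
                "depth_m": z,
                "f_xs": f_xs_det,
                "pBa_xs": xs_det,
                "pBa_xs_median": float(np.median(xs_i)),
                "pBa_xs_2sd": float(2 * np.std(xs_i)),
                "delta_xs": d_xs_det,
                "delta_xs_median": float(np.median(d_valid)) if d_valid.size else np.nan,
                "delta_xs_2sd": float(2 * np.std(d_valid)) if d_valid.size else np.nan,
                "valid_fraction": valid_fraction,
                "unreliable": valid_fraction < 0.5,
            }
        )
        if valid_fraction < 0.5:
            log.warning(
                "depth %.1f m: %.0f%% of draws invalid (f_XS <= 0); flagged unreliable",
                z, 100 * (1 - valid_fraction),
            )
    table = pd.DataFrame(rows)
    table["passes_filter"] = (
        (table["f_xs"] > f_threshold)
        & np.isfinite(table["delta_xs_median"])
        & ~table["unreliable"]
    )
    return ExcessDeltaResult(
        station=profile.station, table=table, settings=settings, f_threshold=f_threshold
    )


@dataclass
class OffsetResult:
    """Mean excess-minus-dissolved isotopic offset across stations."""

    offset: float  # per mil
    se2: float  # 2 SE of the mean
    n: int
    mean_delta_xs: float


def mean_offset(
    results: list[ExcessDeltaResult] | ExcessDeltaResult,
    dissolved: IsotopeDelta | float,
    f_threshold: float = 0.2,
) -> OffsetResult:
    """Unweighted mean δ_XS of qualifying samples minus dissolved δ.

    Qualifying samples are those with f_XS above the threshold; the
    result is invariant to depth ordering and station concatenation
    order. Uncertainty is 2 SE = 2 * SD / sqrt(n) of the qualifying
    sample values.
    """
    if isinstance(results, ExcessDeltaResult):
        results = [results]
    d_diss = dissolved.value if isinstance(dissolved, IsotopeDelta) else float(dissolved)
    values = []
    for res in results:
        t = res.table
        q = (t["f_xs"] > f_threshold) & np.isfinite(t["delta_xs_median"]) & ~t["unreliable"]
        values.extend(t.loc[q, "delta_xs_median"].tolist())
    if len(values) < 2:
        raise ValidationError(
            f"need >= 2 qualifying samples with f_XS > {f_threshold}, have {len(values)}"
        )
    arr = np.asarray(values, float)
    mean = float(arr.mean())
    se2 = float(2 * arr.std(ddof=1) / math.sqrt(arr.size))
    return OffsetResult(offset=mean - d_diss, se2=se2, n=arr.size, mean_delta_xs=mean)


def group_compare(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Two-tailed unpaired t-test between two sets of δ values.

    Equal-variance (Student) by default; ``welch=True`` for unequal
    variances. The degenerate zero-variance, equal-mean case returns
    (0, 1) by convention.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
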