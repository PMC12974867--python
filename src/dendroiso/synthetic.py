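"""Ground-truth-known synthetic inputs for the whole pipeline.

The generator emulates the statistical structure of a semi-arid
dendro-isotope study: a regional rainfall history with a slow drying
trend, centennial wet/dry cycles and red (AR(1)) interannual noise; a
negative linear rainfall → ring-δ13C response with sub-0.2‰ measurement
noise; several slow-growing cores sampled at constant radial increments,
one with a multi-century growth hiatus; a wiggly radiocarbon calibration
curve with an optional non-monotone post-1950 bomb segment; and the
post-industrial atmospheric δ13C decline and CO2 rise that the correction
stages must remove.

Everything regenerates bit-identically from (seed, parameters), and the
true values (rainfall, signal, per-sample ages, tie points) are returned
alongside the observables so that parameter-recovery tests can score every
stage of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .correction import PinParameters, _discrimination, _invert_discrimination
from .agemodel import TiePoint
from .types import (
    AnnualRecord,
    CalibrationCurve,
    IsotopeSeries,
    RadiocarbonDate,
    ValidationError,
    ce_to_bp,
)

__all__ = [
    "generate_rainfall",
    "rainfall_to_d13c",
    "simulate_tree",
    "synth_calibration_curve",
    "simulate_radiocarbon_dates",
    "simulate_atm_records",
    "generate_forcing_index",
    "TreeConfig",
    "SyntheticWorld",
    "generate_world",
]

DEFAULT_SPAN = (1300, 2015)


def generate_rainfall(span: Tuple[int, int] = DEFAULT_SPAN,
                      mean_mm: float = 450.0,
                      trend_mm_per_century: float = -15.0,
                      ar1_phi: float = 0.6,
                      centennial_amp_mm: float = 60.0,
                      centennial_period_yr: float = 200.0,
                      noise_sd_mm: float = 40.0,
                      seed: int = 0) -> AnnualRecord:
    """Annual rainfall: linear trend + centennial cycle + AR(1) anomalies.

    The trend is centred mid-span so the series mean stays near
    ``mean_mm``.  Values are clipped at zero (arid-margin realism); the
    AR(1) innovation scale is ``noise_sd_mm·√(1 − φ²)`` so the stationary
    anomaly standard deviation is ``noise_sd_mm``.
    """
    y0, y1 = span
    if y1 - y0 < 100:
        raise ValidationError("rainfall span must cover >= 100 years")
    if abs(ar1_phi) >= 1:
        raise ValidationError(f"|ar1_phi| must be < 1, got {ar1_phi}")
    rng = np.random.default_rng(seed)
    years = np.arange(y0, y1 + 1)
    t = years - years.mean()
    cycle = centennial_amp_mm * np.sin(2 * np.pi * (years - y0)
                                       / centennial_period_yr)
    cycle -= cycle.mean()  # truncated cycles must not bias the series mean
    base = mean_mm + trend_mm_per_century * t / 100.0 + cycle
    innov = rng.normal(0.0, noise_sd_mm * np.sqrt(1 - ar1_phi ** 2),
                       size=years.size)
    anom = np.empty_like(innov)
    acc = 0.0
    for i, e in enumerate(innov):
        acc = ar1_phi * acc + e
        anom[i] = acc
    vals = np.clip(base + anom, 0.0, None)
    return AnnualRecord(years=years, values=vals, kind="rainfall")


def rainfall_to_d13c(rain: AnnualRecord,
                     baseline_permil: float = -25.3,
                     sensitivity_permil_per_100mm: float = -0.35,
                     noise_sd_permil: float = 0.15,
                     seed: int = 0) -> AnnualRecord:
    """True ring-δ13C signal from rainfall: linear response plus noise.

    δ(t) = baseline + sensitivity·(rain(t) − mean)/100 + ε.  The
    sensitivity must be negative — wetter years give more-negative δ13C.
    Returned as an annual record (kind ``forcing_index`` is reused as the
    generic unitless tag; values are ‰).
    """
    if not sensitivity_permil_per_100mm < 0:
        raise ValidationError(
            "rainfall→δ13C sensitivity must be negative (drier = enriched)"
        )
    rng = np.random.default_rng(seed)
    anom = rain.values - rain.values.mean()
    vals = (baseline_permil + sensitivity_permil_per_100mm * anom / 100.0
            + rng.normal(0.0, noise_sd_permil, size=rain.values.size))
    return AnnualRecord(years=rain.years.copy(), values=vals,
                        kind="forcing_index")


def _industrial_forward(delta_pin, years, atm: AnnualRecord,
                        co2: AnnualRecord, params: PinParameters):
    """Embed Suess and CO2/water-use-efficiency effects into a clean signal.

    Exact forward model of the correction pipeline under the
    constant-ci-offset plant response: suess_correct then pin_correct
    (same parameters) recover the input to floating-point accuracy.
    """
    delta_atm_ref = float(atm.at(params.ref_year_ce))
    ca_ref = float(co2.at(params.ref_year_ce))
    a, b = params.a_diffusion, params.b_carboxylation
    out = np.array(delta_pin, dtype=float)
    post = np.asarray(years) > params.ref_year_ce
    if post.any():
        ca = co2.at(np.asarray(years)[post])
        cap_pin = _discrimination(out[post], delta_atm_ref)
        ci_ref = ca_ref * (cap_pin - a) / (b - a)
        ci = ci_ref + (ca - ca_ref)
        cap = a + (b - a) * ci / ca
        out[post] = _invert_discrimination(cap, delta_atm_ref)
    out += atm.at(years) - delta_atm_ref
    return out


@dataclass(frozen=True)
class TreeConfig:
    """Growth configuration for one synthetic core."""

    tree_id: str
    growth_rate: float  # samples per year
    hiatus: Optional[Tuple[float, float]] = None  # (stop_CE, resume_CE)
    measurement_noise_sd: float = 0.1
    n_dates: int = 13


def simulate_tree(signal: AnnualRecord, growth_rate: float,
                  hiatus: Optional[Tuple[float, float]] = None,
                  measurement_noise_sd: float = 0.1,
                  seed: int = 0, tree_id: str = "SYN",
                  atm: Optional[AnnualRecord] = None,
                  co2: Optional[AnnualRecord] = None,
                  pin_params: PinParameters = PinParameters(),
                  ) -> Tuple[IsotopeSeries, np.ndarray]:
    """Sample a core from the true δ13C signal at constant radial growth.

    Sample 1 sits at the bark (youngest year of the signal span); each
    deeper sample is 1/``growth_rate`` years older.  A ``hiatus``
    ``(stop_CE, resume_CE)`` removes that calendar window: no sample is
    dated inside it, and the age sequence jumps by its duration.  When
    ``atm``/``co2`` records are given, the post-industrial atmospheric
    decline and the constant-ci-offset CO2 response are embedded so the
    observable series carries the contamination the correction stages
    exist to remove.

    Returns the observable :class:`IsotopeSeries` and the true age (year
    CE, possibly fractional) of every sample.
    """
    if growth_rate <= 0:
        raise ValidationError("growth rate must be positive")
    y0, y1 = signal.span
    if hiatus is not None:
        h0, h1 = hiatus
        if not (y0 < h0 < h1 < y1):
            raise ValidationError(
                f"hiatus {hiatus} must lie strictly inside the span "
                f"({y0}, {y1})"
            )
        if h1 - h0 >= y1 - y0:
            raise ValidationError("hiatus covers the whole span")
    rng = np.random.default_rng(seed)
    dt = 1.0 / growth_rate
    grow_span = (y1 - y0) - ((h1 - h0) if hiatus else 0.0)
    if grow_span < 2.0 * dt:
        raise ValidationError(
            "hiatus covers essentially the whole span: fewer than two "
            "samples of growth remain"
        )
    n = int(np.floor(grow_span / dt)) + 1
    growth_time = np.arange(n) * dt
    ages = y1 - growth_time
    if hiatus is not None:
        # growth stopped at h0 and restarted at h1: ages that would fall
        # at or below the restart year shift down by the gap duration
        ages = np.where(ages >= h1, ages, ages - (h1 - h0))
    vals = signal.at(ages)
    if atm is not None and co2 is not None:
        vals = _industrial_forward(vals, ages, atm, co2, pin_params)
    if measurement_noise_sd > 0:
        vals = vals + rng.normal(0.0, measurement_noise_sd, size=n)
    series = IsotopeSeries(
        tree_id=tree_id,
        sample_numbers=np.arange(1, n + 1),
        delta13c=vals,
        metadata={"growth_rate_samples_per_year": growth_rate,
                  "hiatus": list(hiatus) if hiatus else None},
    )
    return series, ages


def true_tie_points(tree_id: str, ages: np.ndarray,
                    hiatus: Optional[Tuple[float, float]] = None,
                    n_interior: int = 1) -> List[TiePoint]:
    """Exact tie points reproducing a constant-growth-rate chronology.

    For a hiatus tree the duplicated ring carries the two true ages
    bracketing the gap, so the fitted model reproduces every sample age
    exactly.
    """
    n = ages.size
    pts = [TiePoint(tree_id, 1, float(ages[0])),
           TiePoint(tree_id, n, float(ages[-1]))]
    if hiatus is not None:
        h0, h1 = hiatus
        # first sample on the old side of the gap carries both ages: the
        # model maps the hiatus ring itself to the older (growth-arrest)
        # year, so the pair sits there for exact recovery
        k = int(np.flatnonzero(ages < h1)[0]) + 1
        gap = h1 - h0
        pts.append(TiePoint(tree_id, k, float(ages[k - 1]) + gap))
        pts.append(TiePoint(tree_id, k, float(ages[k - 1])))
    else:
        for q in np.linspace(0, 1, n_interior + 2)[1:-1]:
            k = int(round(1 + q * (n - 1)))
            pts.append(TiePoint(tree_id, k, float(ages[k - 1])))
    return sorted(pts, key=lambda p: (p.sample_number, -p.year_ce))


def synth_calibration_curve(span: Tuple[int, int] = DEFAULT_SPAN,
                            slope: float = 1.0,
                            wiggle_amp_14cyr: float = 20.0,
                            wiggle_period_yr: float = 150.0,
                            curve_sigma: float = 10.0,
                            bomb: bool = False,
                            margin_yr: float = 200.0,
                            seed: int = 0) -> CalibrationCurve:
    """A wiggly synthetic calibration curve covering ``span`` (years CE).

    14C age = slope·calBP + smooth sinusoidal wiggle (random phase from
    ``seed``).  With ``bomb=True`` a non-monotone F14C segment for
    1950–2020 (sharp rise to a mid-1960s peak, slow decline) is attached
    as ``curve.bomb_segment``; its non-monotonicity makes some F14C values
    calibrate to two disjoint intervals, as with the real bomb curve.
    """
    if slope <= 0:
        raise ValidationError("curve slope must be positive")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    bp_lo = ce_to_bp(span[1]) - margin_yr
    bp_hi = ce_to_bp(span[0]) + margin_yr
    cal_bp = np.arange(float(np.floor(bp_lo)), float(np.ceil(bp_hi)) + 1.0)
    c14 = slope * cal_bp + wiggle_amp_14cyr * np.sin(
        2 * np.pi * cal_bp / wiggle_period_yr + phase)
    curve = CalibrationCurve(
        cal_bp=cal_bp,
        c14_value=c14,
        curve_sigma=np.full_like(cal_bp, float(curve_sigma)),
        era="pre_bomb",
        name="synthetic",
    )
    if bomb:
        # F14C knots (year CE, F14C): pre-bomb baseline, sharp rise,
        # 1965 peak, monotone decline — Southern-Hemisphere-like shape
        knots_ce = np.array([1945, 1950, 1955, 1958, 1962, 1965, 1970,
                             1980, 1990, 2000, 2010, 2020], dtype=float)
        knots_f = np.array([0.98, 0.985, 1.00, 1.08, 1.45, 1.62, 1.55,
                            1.30, 1.18, 1.10, 1.06, 1.03])
        from scipy.interpolate import PchipInterpolator
        years = np.arange(1945.0, 2020.5, 0.5)
        f = PchipInterpolator(knots_ce, knots_f)(years)
        bp = ce_to_bp(years)
        order = np.argsort(bp)
        curve.bomb_segment = CalibrationCurve(
            cal_bp=bp[order],
            c14_value=f[order],
            curve_sigma=np.full(bp.size, 0.004),
            era="post_bomb_F14C",
            name="synthetic-bomb",
        )
    return curve


def simulate_radiocarbon_dates(true_ages: np.ndarray,
                               curve: CalibrationCurve,
                               n_dates: int = 13,
                               lab_sigma: float = 25.0,
                               lab_sigma_f14c: float = 0.005,
                               outlier_rate: float = 0.0,
                               seed: int = 0,
                               tree_id: str = "SYN",
                               ) -> List[RadiocarbonDate]:
    """Draw AMS dates for a core: evenly spread samples, Gaussian lab error.

    Dated sample numbers span the core including both ends.  True ages
    after 1950 are measured as F14C on ``curve.bomb_segment`` when one is
    attached, otherwise as conventional ages on the main curve.  With
    probability ``outlier_rate`` one pair of dated samples swaps ages — a
    labelling blunder that stratigraphic inversion screening should catch.
    """
    n_samples = true_ages.size
    if n_dates < 2:
        raise ValidationError("need at least 2 dates")
    if n_dates > n_samples:
        raise ValidationError(
            f"{n_dates} dates requested but core has {n_samples} samples"
        )
    rng = np.random.default_rng(seed)
    idx = np.unique(np.round(np.linspace(0, n_samples - 1, n_dates))
                    .astype(int))
    ages = true_ages[idx].copy()
    if outlier_rate > 0 and rng.random() < outlier_rate:
        # swap the ages of two well-separated dated samples
        i, j = 1, len(idx) - 2
        if i < j:
            ages[i], ages[j] = ages[j], ages[i]
    bomb = getattr(curve, "bomb_segment", None)
    dates = []
    for k, a in zip(idx, ages):
        if bomb is not None and a > 1950.0:
            val = float(bomb.mu(ce_to_bp(a)) + rng.normal(0, lab_sigma_f14c))
            dates.append(RadiocarbonDate(
                tree_id=tree_id, sample_number=int(k + 1),
                measurement_type="F14C", value=max(val, 1e-6),
                sigma=lab_sigma_f14c))
        else:
            val = float(curve.mu(ce_to_bp(a)) + rng.normal(0, lab_sigma))
            dates.append(RadiocarbonDate(
                tree_id=tree_id, sample_number=int(k + 1),
                measurement_type="conventional_BP", value=val,
                sigma=lab_sigma))
    return dates


def simulate_atm_records(span: Tuple[int, int] = DEFAULT_SPAN,
                         preindustrial_d13c: float = -6.3,
                         suess_decline_permil: float = -2.0,
                         co2_pre_ppm: float = 280.0,
                         co2_modern_ppm: float = 400.0,
                         onset_year: int = 1850,
                         ) -> Tuple[AnnualRecord, AnnualRecord]:
    """Atmospheric δ13C and CO2 histories: flat, then smooth ramps.

    Both records are constant at their pre-industrial values before
    ``onset_year`` and follow a quadratic (accelerating) ramp to the
    modern endpoint, mimicking the fossil-fuel era.  The span must contain
    the correction reference year 1748.
    """
    y0, y1 = span
    if not (y0 <= 1748 <= y1):
        raise ValidationError("atmospheric span must include 1748")
    years = np.arange(y0, y1 + 1)
    u = np.clip((years - onset_year) / max(y1 - onset_year, 1), 0.0, None)
    ramp = u ** 2
    atm = AnnualRecord(years=years,
                       values=preindustrial_d13c + suess_decline_permil * ramp,
                       kind="d13c_atm")
    co2 = AnnualRecord(years=years,
                       values=co2_pre_ppm + (co2_modern_ppm - co2_pre_ppm) * ramp,
                       kind="co2")
    return atm, co2


def generate_forcing_index(span: Tuple[int, int] = DEFAULT_SPAN,
                           ar1_phi: float = 0.7,
                           coupled_to: Optional[AnnualRecord] = None,
                           coupling: float = 0.0,
                           seed: int = 0,
                           ) -> AnnualRecord:
    """A standardized annual climate index, optionally rainfall-coupled.

    index = coupling·z(source) + √(1 − coupling²)·AR1(φ), so ``coupling``
    is the population correlation with the source record.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(span[0], span[1] + 1)
    innov = rng.normal(0.0, np.sqrt(1 - ar1_phi ** 2), size=years.size)
    z = np.empty_like(innov)
    acc = 0.0
    for i, e in enumerate(innov):
        acc = ar1_phi * acc + e
        z[i] = acc
    if coupled_to is not None and coupling != 0.0:
        src = coupled_to.at(years)
        src = (src - src.mean()) / src.std()
        z = coupling * src + np.sqrt(1 - coupling ** 2) * z
    return AnnualRecord(years=years, values=z, kind="forcing_index")


DEFAULT_TREES = (
    TreeConfig("DFL", growth_rate=0.61, n_dates=12),
    TreeConfig("DFS", growth_rate=0.62, n_dates=12),
    TreeConfig("GTR", growth_rate=0.87, hiatus=(1500.0, 1700.0), n_dates=13),
    TreeConfig("TSP", growth_rate=0.99, n_dates=15),
)


@dataclass
class SyntheticWorld:
    """A complete synthetic study: observables plus the hidden truth."""

    seed: int
    span: Tuple[int, int]
    rainfall: AnnualRecord
    signal: AnnualRecord
    atm: AnnualRecord
    co2: AnnualRecord
    curve: CalibrationCurve
    trees: Dict[str, IsotopeSeries]
    true_ages: Dict[str, np.ndarray]
    tie_points: Dict[str, List[TiePoint]]
    dates: Dict[str, List[RadiocarbonDate]]
    forcings: Dict[str, AnnualRecord] = field(default_factory=dict)
    tree_configs: Dict[str, TreeConfig] = field(default_factory=dict)


def generate_world(seed: int = 0,
                   span: Tuple[int, int] = DEFAULT_SPAN,
                   trees: Tuple[TreeConfig, ...] = DEFAULT_TREES,
                   lab_sigma: float = 25.0,
                   outlier_rate: float = 0.0,
                   bomb: bool = True,
                   embed_industrial: bool = True,
                   **rain_kwargs) -> SyntheticWorld:
    """Generate the default four-tree study.

    Child seeds for every stochastic component are spawned from ``seed``
    deterministically, so the whole world regenerates bit-identically and
    two worlds with different seeds share structure but not noise.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(3 + 3 * len(trees) + 2) % (2 ** 31)
    rainfall = generate_rainfall(span=span, seed=int(child[0]), **rain_kwargs)
    signal = rainfall_to_d13c(rainfall, seed=int(child[1]))
    atm, co2 = simulate_atm_records(span=span)
    curve = synth_calibration_curve(span=span, bomb=bomb, seed=int(child[2]))
    world = SyntheticWorld(
        seed=seed, span=span, rainfall=rainfall, signal=signal,
        atm=atm, co2=co2, curve=curve, trees={}, true_ages={},
        tie_points={}, dates={},
        tree_configs={t.tree_id: t for t in trees},
    )
    for i, cfg in enumerate(trees):
        series, ages = simulate_tree(
            signal, cfg.growth_rate, hiatus=cfg.hiatus,
            measurement_noise_sd=cfg.measurement_noise_sd,
            seed=int(child[3 + 3 * i]), tree_id=cfg.tree_id,
            atm=atm if embed_industrial else None,
            co2=co2 if embed_industrial else None,
        )
        world.trees[cfg.tree_id] = series
        world.true_ages[cfg.tree_id] = ages
        world.tie_points[cfg.tree_id] = true_tie_points(
            cfg.tree_id, ages, hiatus=cfg.hiatus)
        world.dates[cfg.tree_id] = simulate_radiocarbon_dates(
            ages, curve, n_dates=cfg.n_dates, lab_sigma=lab_sigma,
            outlier_rate=outlier_rate, seed=int(child[4 + 3 * i]),
            tree_id=cfg.tree_id)
    world.forcings["SST"] = generate_forcing_index(
        span, coupled_to=rainfall, coupling=0.5, seed=int(child[-2]))
    world.forcings["SAM"] = generate_forcing_index(
        span, seed=int(child[-1]))
    return world
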