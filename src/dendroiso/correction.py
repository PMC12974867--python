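"""Atmospheric and physiological corrections of tree-ring δ13C.

Two effects unrelated to local climate contaminate ring δ13C after the
industrial revolution and must be removed before interpreting the series
as a water-stress (rainfall) proxy:

1. **Suess effect** — fossil-fuel CO2 has depleted atmospheric δ13C by
   ~2‰ since ~1850.  :func:`suess_correct` normalises the measured series
   to the pre-industrial atmosphere by subtracting the atmospheric δ13C
   anomaly relative to a reference year (default 1748, the inflection
   between pre- and post-industrial atmospheric change).

2. **Rising CO2 / water-use efficiency** — the plant's photosynthetic
   discrimination Δ depends on the ratio of leaf-internal to ambient CO2
   (c_i/c_a).  Rising c_a changes Δ even under constant climate.  The
   "pre-industrial" (pin) correction maps each year's inferred leaf state
   back to pre-industrial c_a, bracketing the unknown plant response
   between two classic scenarios: constant c_i − c_a offset (active
   response) and constant c_i/c_a ratio (passive response).

The discrimination model is the standard two-endpoint C3 form
Δ = a + (b − a)·c_i/c_a with a = 4.4‰ (diffusion) and b = 27‰
(carboxylation); these constants are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import AnnualRecord, DatedSeries, ValidationError

__all__ = ["PinParameters", "delta_from_ratio", "suess_correct", "pin_correct"]


@dataclass(frozen=True)
class PinParameters:
    """Constants for the pre-industrial (pin) CO2 correction.

    ``response_mode``:

    * ``"constant_ci_offset"`` (default) — the plant holds c_a − c_i
      constant: the active-response endpoint, yielding the largest
      defensible CO2 correction.
    * ``"constant_ci_ca"`` — the plant holds c_i/c_a constant, which
      leaves Δ (and hence δ13C) unchanged: the identity endpoint.
    """

    ref_year_ce: int = 1748
    a_diffusion: float = 4.4
    b_carboxylation: float = 27.0
    response_mode: str = "constant_ci_offset"

    def __post_init__(self):
        if not self.b_carboxylation > self.a_diffusion:
            raise ValidationError(
                f"b ({self.b_carboxylation}) must exceed a ({self.a_diffusion})"
            )
        if self.response_mode not in ("constant_ci_offset", "constant_ci_ca"):
            raise ValidationError(
                f"unknown response_mode {self.response_mode!r}"
            )


def delta_from_ratio(r_sample, r_standard):
    """δ13C (‰ VPDB) from isotope-ratio measurements.

    δ13C = (R_sample / R_standard − 1) · 1000.
    """
    r_sample = np.asarray(r_sample, dtype=float)
    r_standard = np.asarray(r_standard, dtype=float)
    if (r_sample <= 0).any() or (r_standard <= 0).any():
        raise ValidationError("isotope ratios must be positive")
    out = (r_sample / r_standard - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


def _discrimination(delta_plant, delta_atm):
    """Photosynthetic discrimination Δ from plant and air δ13C (both ‰)."""
    return (delta_atm - delta_plant) / (1.0 + delta_plant / 1000.0)


def _invert_discrimination(delta_cap, delta_atm):
    """Plant δ13C from discrimination Δ at atmospheric δ13C ``delta_atm``."""
    return (delta_atm - delta_cap) / (1.0 + delta_cap / 1000.0)


def suess_correct(series: DatedSeries, atm: AnnualRecord,
                  ref_year_ce: int = 1748) -> DatedSeries:
    """Remove the atmospheric δ13C (Suess) anomaly from a dated series.

    δ_corr(t) = δ_meas(t) − (δ_atm(t) − δ_atm(ref)).  Years at or before
    the reference are untouched whenever the atmospheric record is flat
    before it.  Fractional sample years interpolate the annual record.
    """
    if atm.kind != "d13c_atm":
        raise ValidationError(f"expected a d13c_atm record, got {atm.kind!r}")
    anomaly = atm.at(series.years) - atm.at(ref_year_ce)
    return DatedSeries(tree_id=series.tree_id, years=series.years.copy(),
                       values=series.values - anomaly)


def pin_correct(series: DatedSeries, atm: AnnualRecord, co2: AnnualRecord,
                params: PinParameters = PinParameters()) -> DatedSeries:
    """Pre-industrial (pin) correction for the plant response to rising CO2.

    Expects a series already Suess-corrected (normalised to the reference
    atmosphere).  For each sample year t after the reference year:

    1. Δ(t) = (δ_atm(ref) − δ(t)) / (1 + δ(t)/1000) — discrimination
       implied by the corrected ring value under the reference atmosphere;
    2. c_i(t) = c_a(t) · (Δ(t) − a) / (b − a);
    3. project the leaf state to pre-industrial c_a:
       constant_ci_offset: c_i_pin = c_i(t) − (c_a(t) − c_a(ref)) — the
       active-response endpoint, the largest defensible correction;
       constant_ci_ca: c_i_pin = c_i(t)·c_a(ref)/c_a(t) — the passive
       endpoint, an identity in δ by construction.  The truth lies
       between the two modes, so run both to bracket sensitivity;
    4. Δ_pin = a + (b − a)·c_i_pin/c_a(ref) and δ_pin inverts the
       discrimination formula at δ_atm(ref).

    Years at or before the reference pass through bit-identically.
    """
    if co2.kind != "co2":
        raise ValidationError(f"expected a co2 record, got {co2.kind!r}")
    a, b = params.a_diffusion, params.b_carboxylation
    delta_atm_ref = float(atm.at(params.ref_year_ce))
    ca_ref = float(co2.at(params.ref_year_ce))

    years = series.years
    out = series.values.copy()
    post = years > params.ref_year_ce
    # only years whose c_a actually departs from the reference are touched,
    # so a flat CO2 record leaves the series bit-identical
    post[post] = co2.at(years[post]) != ca_ref
    if not post.any():
        return DatedSeries(series.tree_id, years.copy(), out)

    d = out[post]
    ca = co2.at(years[post])
    cap = _discrimination(d, delta_atm_ref)
    ci = ca * (cap - a) / (b - a)
    if params.response_mode == "constant_ci_ca":
        ci_pin = ci * ca_ref / ca
    else:
        ci_pin = ci - (ca - ca_ref)
    if (ci_pin <= 0).any():
        bad = int(np.flatnonzero(ci_pin <= 0)[0])
        raise ValidationError(
            f"{series.tree_id}: non-positive pre-industrial c_i at year "
            f"{years[post][bad]:.1f} — implausible δ13C/CO2 inputs"
        )
    cap_pin = a + (b - a) * ci_pin / ca_ref
    out[post] = _invert_discrimination(cap_pin, delta_atm_ref)
    return DatedSeries(series.tree_id, years.copy(), out)
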