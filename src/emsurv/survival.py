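"""Expected annual survivors of out-of-hospital cardiac arrest (OHCA).

The model chains three quantities for a region and a resource set j:

1. eligible patients per year, ``R = I * (1 - P_A)`` — annual OHCA incidence
   with resuscitation attempted, minus the fraction that occurred after
   ambulance arrival (those cases cannot benefit from a faster dispatch);
2. survival probability, ``S = sum_t (b_t / POP) * vf_t * surv_t`` — the
   population-share reached at each total time-to-defibrillation bin t,
   weighted by the probability of still being in a defibrillatable rhythm
   (VF) at t and of surviving given defibrillation at t;
3. expected survivors per year, ``beta = R * S``.

Total time to defibrillation composes static alarm-process intervals that do
not depend on geography (incident-to-call, emergency call handling, on-scene
preparation; defaults 2 + 1.5 + 1.5 minutes) with the simulated station
reaction + drive time.  With the default statics and the 1.5-minute minimum
reaction time, no patient can be treated in under 6.5 minutes.

Scenario analysis of *static* changes (e.g. trimming call handling by a
minute) is an integer shift of the reach curve along the time axis — the
geography is untouched, every home is simply treated that much earlier or
later.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import HazardCurves, lookup, N_BINS
from .drivetime import ReachCurve, ResponseTimeField, build_reach_curve, response_time_field
from .region import RegionScenario

TAIL_31PLUS = "31plus"
TAIL_ZERO = "zero"


@dataclass(frozen=True)
class StaticIntervals:
    """Geography-independent components of time to defibrillation, minutes."""

    call_delay: float = 2.0       # incident to first call to the call centre
    call_handling: float = 1.5    # operator handling until services alerted
    preparation: float = 1.5      # arrival on scene to defibrillator attached

    def __post_init__(self) -> None:
        for name in ("call_delay", "call_handling", "preparation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def static_overhead(self) -> float:
        return self.call_delay + self.call_handling + self.preparation


@dataclass(frozen=True)
class IncidenceModel:
    """Annual OHCA incidence with resuscitation attempted, and the probability
    the arrest occurred after ambulance arrival (default study values:
    I = 816/year, P_A = 0.15)."""

    incidence: float = 816.0
    p_after_arrival: float = 0.15

    def __post_init__(self) -> None:
        if self.incidence < 0:
            raise ValueError("incidence must be >= 0")
        if not 0 <= self.p_after_arrival <= 1:
            raise ValueError("p_after_arrival must lie in [0, 1]")


def eligible_patients(inc: IncidenceModel) -> float:
    """R = I * (1 - P_A): annual arrests that dispatch can still save."""
    return inc.incidence * (1.0 - inc.p_after_arrival)


def compose_total_time(drive_plus_reaction: float, statics: StaticIntervals) -> float:
    """Total minutes from collapse to defibrillation."""
    if drive_plus_reaction < 0:
        raise ValueError("drive_plus_reaction must be >= 0")
    return statics.static_overhead + drive_plus_reaction


def shift_reach_curve(curve: ReachCurve, shift: int) -> ReachCurve:
    """Translate the curve ``shift`` whole minutes along the time axis.

    Mass pushed below bin 1 piles up in bin 1; mass pushed past the last bin
    piles up in the last bin.  Population is conserved."""
    shift = int(shift)
    if shift == 0:
        return curve
    n = curve.n_bins
    b = np.zeros(n, dtype=np.int64)
    for t, mass in enumerate(curve.b, start=1):
        b[min(max(t + shift, 1), n) - 1] += mass
    return ReachCurve(b=tuple(int(v) for v in b), pop=curve.pop, unreached=curve.unreached)


def survival_rate(curve: ReachCurve, curves: HazardCurves,
                  tail: str = TAIL_31PLUS) -> tuple[float, np.ndarray]:
    """S and its per-bin contributions for a reach curve already on the
    total time-to-defibrillation axis.

    ``tail`` controls bins beyond 31: ``"31plus"`` applies the terminal 31+
    curve values (the curves' own convention), ``"zero"`` grants no survival
    past 31 minutes (sensitivity option).  Unreached population contributes
    zero either way but stays in the POP denominator."""
    if curve.pop <= 0:
        raise ValueError("reach curve has POP = 0")
    if tail not in (TAIL_31PLUS, TAIL_ZERO):
        raise ValueError(f"unknown tail mode {tail!r}")
    per_bin = np.zeros(curve.n_bins)
    for t, mass in enumerate(curve.b, start=1):
        if mass == 0:
            continue
        if t > N_BINS and tail == TAIL_ZERO:
            continue
        per_bin[t - 1] = (mass / curve.pop) * lookup(curves, t, "vf") * lookup(curves, t, "surv")
    return float(per_bin.sum()), per_bin


def expected_survivors(r: float, s: float) -> float:
    """beta = R * S: expected annual survivors attributable to the resource."""
    if r < 0:
        raise ValueError("R must be >= 0")
    if not 0 <= s <= 1:
        raise ValueError("S must lie in [0, 1]")
    return r * s


@dataclass(frozen=True)
class SurvivalResult:
    """One scenario's outcome, with a per-bin audit trail (sum(per_bin) = S)."""

    scenario: str
    kinds: frozenset[str]
    r: float
    s: float
    beta: float
    incidence: float
    per_bin: tuple[float, ...]
    reach: ReachCurve = field(repr=False)

    @property
    def survival_pct(self) -> float:
        """S among eligible patients, as a percentage."""
        return 100.0 * self.s

    @property
    def beta_over_incidence_pct(self) -> float:
        """beta as a share of raw annual incidence (beta / I), as a
        percentage.  Survivor rates can be quoted against either the eligible
        denominator (S) or all arrests with resuscitation attempted; both are
        reported and neither is privileged."""
        return 100.0 * self.beta / self.incidence if self.incidence > 0 else 0.0


def run_scenario(region: RegionScenario, curves: HazardCurves,
                 statics: StaticIntervals, inc: IncidenceModel,
                 kinds: set[str] | frozenset[str], *,
                 label: str | None = None,
                 tail: str = TAIL_31PLUS,
                 field_cache: dict[frozenset[str], ResponseTimeField] | None = None,
                 ) -> SurvivalResult:
    """Full pipeline for one resource set: response-time field -> compose with
    static intervals -> reach curve on the treatment-time axis -> S -> beta."""
    kinds = frozenset(kinds)
    if field_cache is not None and kinds in field_cache:
        rt_field = field_cache[kinds]
    else:
        rt_field = response_time_field(region, kinds)
        if field_cache is not None:
            field_cache[kinds] = rt_field
    n_bins = N_BINS + 1 if tail == TAIL_ZERO else N_BINS
    reach = build_reach_curve(rt_field, region, n_bins=n_bins,
                              offset_minutes=statics.static_overhead)
    s, per_bin = survival_rate(reach, curves, tail=tail)
    r = eligible_patients(inc)
    beta = expected_survivors(r, s)
    return SurvivalResult(
        scenario=label or "+".join(sorted(kinds)),
        kinds=kinds,
        r=r, s=s, beta=beta,
        incidence=inc.incidence,
        per_bin=tuple(float(v) for v in per_bin),
        reach=reach,
    )


def marginal_effects(region: RegionScenario, curves: HazardCurves,
                     statics: StaticIntervals, inc: IncidenceModel,
                     kind_sets: list[set[str] | frozenset[str]],
                     shifts: list[int], *, tail: str = TAIL_31PLUS) -> pd.DataFrame:
    """Survivors under integer-minute shifts of the static intervals.

    One row per (shift, resource set); the shift-0 row reproduces the
    unshifted scenario exactly.  Columns: shift_minutes, resource_set, r, s,
    beta, delta_beta (vs the same resource set's shift-0 baseline)."""
    shifts = [int(v) for v in shifts]
    if 0 not in shifts:
        raise ValueError("shifts must include 0 (the baseline)")
    cache: dict[frozenset[str], ResponseTimeField] = {}
    rows = []
    for kinds in kind_sets:
        base = run_scenario(region, curves, statics, inc, kinds,
                            tail=tail, field_cache=cache)
        for shift in sorted(shifts):
            if shift == 0:
                s, beta = base.s, base.beta
            else:
                shifted = shift_reach_curve(base.reach, shift)
                s, _ = survival_rate(shifted, curves, tail=tail)
                beta = expected_survivors(base.r, s)
            rows.append({
                "shift_minutes": shift,
                "resource_set": "+".join(sorted(frozenset(kinds))),
                "r": base.r,
                "s": s,
                "beta": beta,
                "delta_beta": beta - base.beta,
            })
    return pd.DataFrame(rows)
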