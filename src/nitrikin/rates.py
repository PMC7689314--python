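"""Nitrification rates from paired slurry concentration measurements, and
their partition into total / AOA / AOB components.

The assay measures NO2- + NO3- (NOx) and NH4+ at two time points (2 h and
24 h by default).  The nitrification rate is the NOx accumulation over that
window, scaled to mg N per kg dry soil per day.  Activity in the bottle that
received 1-octyne (which blocks the bacterial ammonia monooxygenase) is
attributed to archaea (AOA); bacterial activity (AOB) is total minus AOA.
The substrate concentration assigned to each rate is the mean of the two
measured NH4+ concentrations, which folds in any NH4+ produced by net
mineralization during the incubation.

The nitrification *potential* assay is this same computation applied at a
single, saturating NH4+ level (10 mM); there is no separate code path.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "IncubationRecord",
    "RateObservation",
    "compute_rate",
    "mean_substrate",
    "partition_taxa",
    "partition_records",
]


@dataclass(frozen=True)
class IncubationRecord:
    """One bottle: measured concentrations at two time points plus slurry
    metadata.  NOx in mg N L-1, NH4+ in mM, times in hours.

    Negative measured concentrations are retained (they are legitimate noisy
    readings near zero); downstream code flags rather than clamps them.
    """

    ecosystem_id: str
    replicate_id: str
    octyne: bool
    nh4_target: float  # mM
    nox_t1: float
    nox_t2: float
    nh4_t1: float
    nh4_t2: float
    fresh_mass: float  # g
    moisture_fraction: float
    slurry_volume: float  # L
    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not self.t2 > self.t1:
            raise ValueError(f"t2 must exceed t1 (got t1={self.t1}, t2={self.t2})")
        if not self.fresh_mass > 0:
            raise ValueError("fresh_mass must be positive")
        if not (0 <= self.moisture_fraction <= 1):
            raise ValueError("moisture_fraction must be in [0, 1]")
        if not self.slurry_volume > 0:
            raise ValueError("slurry_volume must be positive")

    @property
    def pair_key(self):
        return (self.ecosystem_id, self.replicate_id, self.nh4_target)


@dataclass(frozen=True)
class RateObservation:
    """One (ecosystem, replicate, taxon, S, V) point feeding the kinetic fits.

    ``substrate_s`` in mM NH4+, ``rate_v`` in mg N kg-1 dry soil day-1.
    ``below_detection`` marks rates whose NOx accumulation fell under the
    configured detection limit; ``negative`` marks negative rates (possible
    for AOB, a difference of two noisy rates).
    """

    ecosystem_id: str
    replicate_id: str
    taxon: str  # "total", "AOA" or "AOB"
    substrate_s: float
    rate_v: float
    nh4_target: float
    below_detection: bool = False
    negative: bool = False


def compute_rate(record: IncubationRecord) -> float:
    """NOx accumulation rate in mg N kg-1 dry soil day-1.

    rate = (nox_t2 - nox_t1) * slurry_volume / dry_mass_kg * 24 / (t2 - t1)
    with dry_mass_kg = fresh_mass * (1 - moisture_fraction) / 1000.
    """
    dry_kg = record.fresh_mass * (1.0 - record.moisture_fraction) / 1000.0
    if dry_kg <= 0:
        raise ValueError("dry soil mass is zero (moisture_fraction == 1?)")
    dnox = record.nox_t2 - record.nox_t1
    return dnox * record.slurry_volume / dry_kg * 24.0 / (record.t2 - record.t1)


def mean_substrate(record: IncubationRecord) -> float:
    """Arithmetic mean of the two measured NH4+ concentrations (mM)."""
    for v in (record.nh4_t1, record.nh4_t2):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError("missing NH4+ measurement")
    s = 0.5 * (record.nh4_t1 + record.nh4_t2)
    if record.nh4_t1 == 0 and record.nh4_t2 == 0:
        warnings.warn(
            f"degenerate substrate: both NH4+ measurements are zero for "
            f"{record.pair_key}",
            UserWarning,
            stacklevel=2,
        )
    return s


def partition_taxa(
    no_octyne: IncubationRecord,
    octyne: IncubationRecord,
    *,
    detection_limit: float = 0.0,
) -> dict[str, RateObservation]:
    """Partition a matched bottle pair into total / AOA / AOB rates.

    total = rate of the uninhibited bottle; AOA = rate of the +octyne bottle;
    AOB = total - AOA (exact by construction).  The substrate assigned to the
    total and AOB observations comes from the uninhibited bottle, AOA's from
    the +octyne bottle.  ``detection_limit`` is a NOx accumulation floor
    (mg N L-1): bottles below it get ``below_detection=True``.
    """
    if octyne.pair_key != no_octyne.pair_key:
        raise ValueError(
            f"unmatched pair: {no_octyne.pair_key} vs {octyne.pair_key}"
        )
    if no_octyne.octyne or not octyne.octyne:
        raise ValueError("arguments must be (no-octyne, octyne) in that order")

    v_total = compute_rate(no_octyne)
    v_aoa = compute_rate(octyne)
    v_aob = v_total - v_aoa
    s_total = mean_substrate(no_octyne)
    s_aoa = mean_substrate(octyne)

    bd_total = (no_octyne.nox_t2 - no_octyne.nox_t1) < detection_limit
    bd_aoa = (octyne.nox_t2 - octyne.nox_t1) < detection_limit

    common = dict(
        ecosystem_id=no_octyne.ecosystem_id,
        replicate_id=no_octyne.replicate_id,
        nh4_target=no_octyne.nh4_target,
    )
    total = RateObservation(
        taxon="total", substrate_s=s_total, rate_v=v_total,
        below_detection=bd_total, negative=v_total < 0, **common,
    )
    aoa = RateObservation(
        taxon="AOA", substrate_s=s_aoa, rate_v=v_aoa,
        below_detection=bd_aoa, negative=v_aoa < 0, **common,
    )
    aob = RateObservation(
        taxon="AOB", substrate_s=s_total, rate_v=v_aob,
        below_detection=bd_total or bd_aoa, negative=v_aob < 0, **common,
    )
    return {"total": total, "AOA": aoa, "AOB": aob}


def partition_records(
    records: list[IncubationRecord],
    *,
    detection_limit: float = 0.0,
) -> list[RateObservation]:
    """Pair up a full table of bottles on (ecosystem, replicate, NH4+ target)
    and partition every pair.  Raises on orphaned bottles, naming the key."""
    pairs: dict[tuple, dict[bool, IncubationRecord]] = {}
    for rec in records:
        slot = pairs.setdefault(rec.pair_key, {})
        if rec.octyne in slot:
            raise ValueError(f"duplicate bottle for key {rec.pair_key} octyne={rec.octyne}")
        slot[rec.octyne] = rec
    orphans = [k for k, slot in pairs.items() if len(slot) != 2]
    if orphans:
        raise ValueError(f"unmatched +/-octyne bottles for keys: {sorted(orphans)}")
    out: list[RateObservation] = []
    for key in pairs:
        slot = pairs[key]
        parts = partition_taxa(slot[False], slot[True], detection_limit=detection_limit)
        out.extend([parts["total"], parts["AOA"], parts["AOB"]])
    return out
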