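"""Synthetic soil-slurry incubation data with the structure of a shaken-slurry
nitrification kinetics assay.

The emulated design: 5 g fresh soil shaken in 50 mL at eight ammonium addition
levels (0.01-15 mM), with a paired bottle receiving 1-octyne (a selective
inhibitor of the bacterial ammonia monooxygenase) at each level, and 3-4 field
replicates per ecosystem.  NO2- + NO3- and NH4+ are "sampled" at 2 h and 24 h.
Ground-truth kinetic parameters default to the published estimates for the
management-intensity gradient encoded in :data:`KINETICS_REFERENCE`.

True NOx accumulation is obtained by forward integration of the kinetic rate
law at the drifting substrate concentration (fixed 0.1 h Euler steps), so the
2 h / 24 h ammonium pair reflects both consumption by nitrification and any
net mineralization.  Measurement error is multiplicative Gaussian on each
measured concentration, mimicking instrument-style error on a flow-injection
analyzer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rates import IncubationRecord

__all__ = [
    "EcosystemTruth",
    "IncubationDesign",
    "NoiseModel",
    "KINETICS_REFERENCE",
    "default_truths",
    "simulate_incubation",
]

#: mg of nitrogen per mmol (one N per NH4+ / NO2- / NO3-).
N_MG_PER_MMOL = 14.0067

#: Fixed Euler step for substrate-drift integration, hours.
INTEGRATION_STEP_H = 0.1


@dataclass(frozen=True)
class EcosystemTruth:
    """Generating kinetic parameters for one (ecosystem, taxon) population.

    Units: ``vmax_true`` mg N kg-1 dry soil day-1; ``km_true`` and ``ki_true``
    mM NH4+.  ``ki_true`` is only meaningful for the Haldane model.
    """

    ecosystem_id: str
    taxon: str  # "AOA" or "AOB"
    model: str  # "MM" or "Haldane"
    vmax_true: float
    km_true: float
    ki_true: float | None = None

    def __post_init__(self) -> None:
        if self.taxon not in ("AOA", "AOB"):
            raise ValueError(f"taxon must be AOA or AOB, got {self.taxon!r}")
        if self.model not in ("MM", "Haldane"):
            raise ValueError(f"model must be MM or Haldane, got {self.model!r}")
        if not self.vmax_true > 0:
            raise ValueError("vmax_true must be positive")
        if not self.km_true > 0:
            raise ValueError("km_true must be positive")
        if self.model == "Haldane":
            if self.ki_true is None or not self.ki_true > 0:
                raise ValueError("Haldane truth requires ki_true > 0")

    def rate(self, s):
        """True rate at substrate concentration ``s`` (mM), vectorized."""
        s = np.asarray(s, dtype=float)
        if self.model == "MM":
            return self.vmax_true * s / (self.km_true + s)
        return self.vmax_true * s / (self.km_true + s + s * s / self.ki_true)


@dataclass(frozen=True)
class IncubationDesign:
    """Physical layout of the slurry assay.

    Defaults follow the emulated protocol: 5 g fresh soil in a final liquid
    volume of 50 mL, sampled at 2 h and 24 h, eight NH4+ addition levels, four
    field replicates, 4 uM aqueous octyne in the inhibited bottle (metadata
    only -- inhibition efficacy lives in :class:`NoiseModel`).
    """

    nh4_levels: tuple = (0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0, 15.0)
    replicates: int = 4
    soil_fresh_mass: float = 5.0  # g
    moisture_fraction: float = 0.20  # g water / g fresh soil
    slurry_volume: float = 0.050  # L
    t_first: float = 2.0  # h
    t_last: float = 24.0  # h
    octyne_caq: float = 4.0  # uM, metadata

    def __post_init__(self) -> None:
        levels = tuple(float(x) for x in self.nh4_levels)
        object.__setattr__(self, "nh4_levels", levels)
        if not (self.t_last > self.t_first >= 0):
            raise ValueError("require t_last > t_first >= 0")
        if not (0 <= self.moisture_fraction < 1):
            raise ValueError("moisture_fraction must be in [0, 1)")
        if not self.slurry_volume > 0:
            raise ValueError("slurry_volume must be positive")
        if not self.soil_fresh_mass > 0:
            raise ValueError("soil_fresh_mass must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(l <= 0 for l in levels):
            raise ValueError("nh4_levels must be strictly positive")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("nh4_levels must be strictly increasing")

    @property
    def dry_mass_kg(self) -> float:
        return self.soil_fresh_mass * (1.0 - self.moisture_fraction) / 1000.0


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic elements of the simulated assay.

    ``conc_cv``: relative SD of every measured concentration (multiplicative
    Gaussian).  ``mineralization_rate``: net NH4+ production, mM day-1 in the
    slurry.  ``octyne_efficacy``: fraction of AOB activity suppressed in the
    +octyne bottle (1.0 = complete inhibition).
    """

    conc_cv: float = 0.05
    mineralization_rate: float = 0.0
    octyne_efficacy: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conc_cv < 0:
            raise ValueError("conc_cv must be >= 0")
        if self.mineralization_rate < 0:
            raise ValueError("mineralization_rate must be >= 0")
        if not (0 <= self.octyne_efficacy <= 1):
            raise ValueError("octyne_efficacy must be in [0, 1]")


# Published kinetic parameter estimates (mean, SE) along the long-term
# management-intensity gradient: two annual cropping systems, a hybrid poplar
# stand, successional grassland/old-field systems (with long-term fertilized
# "+N" subplots), and late-successional deciduous forest.  Km in uM, Ki in mM,
# Vmax in mg N kg-1 dry soil day-1.  "model" is the law selected for that
# population by AIC + nested F-test; Haldane rows carry a Ki.
KINETICS_REFERENCE = [
    # ecosystem, taxon, model, vmax, se_vmax, km_uM, se_km_uM, ki_mM, se_ki_mM
    ("Conventional", "AOA", "MM", 1.44, 0.09, 5.67, 4.34, None, None),
    ("Conventional", "AOB", "MM", 4.80, 0.29, 22.8, 9.6, None, None),
    ("Biologically-based", "AOA", "MM", 2.82, 0.11, 2.84, 1.64, None, None),
    ("Biologically-based", "AOB", "Haldane", 5.29, 0.36, 9.18, 3.46, 52.2, 32.1),
    ("Poplar", "AOA", "MM", 0.78, 0.06, 2.26, 3.51, None, None),
    ("Poplar", "AOB", "Haldane", 1.90, 0.27, 6.91, 6.79, 14.8, 9.5),
    ("Early successional", "AOA", "MM", 0.89, 0.08, 0.02, 1.86, None, None),
    ("Early successional", "AOB", "MM", 1.30, 0.14, 4.32, 4.26, None, None),
    ("Early successional+N", "AOA", "MM", 2.11, 0.21, 9.14, 6.82, None, None),
    ("Early successional+N", "AOB", "Haldane", 3.15, 0.45, 21.5, 12.4, 23.6, 18.2),
    ("Grassland", "AOA", "MM", 0.86, 0.07, 0.44, 0.37, None, None),
    ("Grassland", "AOB", "MM", 0.38, 0.05, 0.60, 0.56, None, None),
    ("Deciduous forest", "AOA", "Haldane", 0.67, 0.04, 0.14, 1.46, 12.5, 3.3),
    ("Deciduous forest", "AOB", "Haldane", 0.57, 0.05, 1.18, 2.42, 24.5, 12.0),
    ("Deciduous forest+N", "AOA", "MM", 0.61, 0.08, 0.49, 0.44, None, None),
    ("Deciduous forest+N", "AOB", "Haldane", 0.87, 0.35, 33.6, 37.3, 2.01, 2.38),
]


def default_truths() -> list[EcosystemTruth]:
    """One :class:`EcosystemTruth` per (ecosystem, taxon) in the reference
    table, with Km converted uM -> mM."""
    out = []
    for eco, taxon, model, vmax, _, km_um, _, ki_mm, _ in KINETICS_REFERENCE:
        out.append(
            EcosystemTruth(
                ecosystem_id=eco,
                taxon=taxon,
                model=model,
                vmax_true=vmax,
                km_true=km_um / 1000.0,
                ki_true=ki_mm,
            )
        )
    return out


def _integrate_bottles(
    aoa: EcosystemTruth,
    aob: EcosystemTruth,
    s0: np.ndarray,
    aob_factor: np.ndarray,
    design: IncubationDesign,
    mineralization_rate: float,
):
    """Euler-integrate substrate (mM) and NOx accumulation (mg N L-1) for a
    batch of bottles; returns (s_t1, s_t2, nox_t1, nox_t2)."""
    # rate (mg N kg-1 day-1) -> slurry NOx production (mg N L-1 h-1)
    to_slurry = design.dry_mass_kg / design.slurry_volume / 24.0
    mineral_per_h = mineralization_rate / 24.0  # mM h-1

    dt = INTEGRATION_STEP_H
    n_steps = int(round(design.t_last / dt))
    s = np.array(s0, dtype=float)
    nox = np.zeros_like(s)
    s_t1 = np.empty_like(s)
    nox_t1 = np.empty_like(s)
    i_first = int(round(design.t_first / dt))
    for i in range(n_steps):
        if i == i_first:
            s_t1[:] = s
            nox_t1[:] = nox
        v = aoa.rate(s) + aob_factor * aob.rate(s)  # mg N kg-1 day-1
        dnox = v * to_slurry * dt  # mg N L-1
        nox += dnox
        s += (mineral_per_h - v * to_slurry / N_MG_PER_MMOL) * dt
        np.clip(s, 0.0, None, out=s)
    if i_first == n_steps:  # t_first == t_last is rejected upstream
        s_t1[:] = s
        nox_t1[:] = nox
    return s_t1, s, nox_t1, nox


def simulate_incubation(
    truths: list[EcosystemTruth],
    design: IncubationDesign,
    noise: NoiseModel,
) -> list[IncubationRecord]:
    """Simulate one full incubation experiment.

    For every ecosystem x field replicate x NH4+ level, a matched pair of
    bottles (without / with octyne) is produced.  The +octyne bottle carries
    the AOA rate plus ``(1 - octyne_efficacy)`` of the AOB rate.  Output order
    and noise draws are fully determined by ``noise.seed``.
    """
    by_eco: dict[str, dict[str, EcosystemTruth]] = {}
    for t in truths:
        by_eco.setdefault(t.ecosystem_id, {})[t.taxon] = t
    for eco, d in by_eco.items():
        if "AOA" not in d or "AOB" not in d:
            raise ValueError(f"ecosystem {eco!r} needs both AOA and AOB truths")
    if not by_eco:
        raise ValueError("no truths supplied")

    rng = np.random.default_rng(noise.seed)
    levels = np.asarray(design.nh4_levels, dtype=float)
    records: list[IncubationRecord] = []

    for eco in by_eco:
        aoa, aob = by_eco[eco]["AOA"], by_eco[eco]["AOB"]
        # bottle batch: replicates x levels x (no-octyne, octyne)
        n_pairs = design.replicates * len(levels)
        s0 = np.tile(np.repeat(levels, 2), design.replicates)
        factor = np.tile([1.0, 1.0 - noise.octyne_efficacy], n_pairs)
        s_t1, s_t2, nox_t1, nox_t2 = _integrate_bottles(
            aoa, aob, s0, factor, design, noise.mineralization_rate
        )
        truth_vals = np.column_stack([nox_t1, nox_t2, s_t1, s_t2])
        if noise.conc_cv > 0:
            meas = truth_vals * (1.0 + rng.normal(0.0, noise.conc_cv, truth_vals.shape))
        else:
            meas = truth_vals
        idx = 0
        for rep in range(design.replicates):
            for lvl in levels:
                for octyne in (False, True):
                    m = meas[idx]
                    records.append(
                        IncubationRecord(
                            ecosystem_id=eco,
                            replicate_id=f"R{rep + 1}",
                            octyne=octyne,
                            nh4_target=float(lvl),
                            nox_t1=float(m[0]),
                            nox_t2=float(m[1]),
                            nh4_t1=float(m[2]),
                            nh4_t2=float(m[3]),
                            fresh_mass=design.soil_fresh_mass,
                            moisture_fraction=design.moisture_fraction,
                            slurry_volume=design.slurry_volume,
                            t1=design.t_first,
                            t2=design.t_last,
                        )
                    )
                    idx += 1
    return records
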