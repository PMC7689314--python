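"""CSV schemas for every pipeline table.

Each file starts with a versioned comment line (``# nitrikin <table> v1``);
readers skip comment lines.  Column names and float formatting are fixed so
that identical inputs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .kinetics import KineticFit
from .model_select import ModelComparison
from .rates import IncubationRecord, RateObservation
from .synthetic import EcosystemTruth

FLOAT_FMT = "%.10g"

INCUBATION_COLUMNS = [
    "ecosystem", "replicate", "octyne", "nh4_target_mM",
    "nox_t1_mgN_L", "nox_t2_mgN_L", "nh4_t1_mM", "nh4_t2_mM",
    "fresh_mass_g", "moisture_fraction", "slurry_volume_L", "t1_h", "t2_h",
]

RATE_COLUMNS = [
    "ecosystem", "replicate", "taxon", "substrate_mM",
    "rate_mgN_kg_day", "nh4_target_mM", "below_detection", "negative",
]

FIT_COLUMNS = [
    "ecosystem", "taxon", "model", "vmax", "se_vmax", "km_uM", "se_km_uM",
    "ki_mM", "se_ki_mM", "rss", "aic", "n_obs", "n_params",
    "converged", "km_constrained",
]

COMPARISON_COLUMNS = [
    "ecosystem", "taxon", "aic_mm", "aic_haldane", "f_stat", "p_value",
    "selected", "haldane_failed",
]


def _write(df: pd.DataFrame, path, schema: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# nitrikin {schema} v1\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def _read(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path, comment="#")


def write_incubation_csv(records: list[IncubationRecord], path) -> None:
    rows = [
        (r.ecosystem_id, r.replicate_id, r.octyne, r.nh4_target,
         r.nox_t1, r.nox_t2, r.nh4_t1, r.nh4_t2,
         r.fresh_mass, r.moisture_fraction, r.slurry_volume, r.t1, r.t2)
        for r in records
    ]
    _write(pd.DataFrame(rows, columns=INCUBATION_COLUMNS), path, "incubation")


def read_incubation_csv(path) -> list[IncubationRecord]:
    df = _read(path)
    return [
        IncubationRecord(
            ecosystem_id=str(r.ecosystem),
            replicate_id=str(r.replicate),
            octyne=bool(r.octyne),
            nh4_target=float(r.nh4_target_mM),
            nox_t1=float(r.nox_t1_mgN_L),
            nox_t2=float(r.nox_t2_mgN_L),
            nh4_t1=float(r.nh4_t1_mM),
            nh4_t2=float(r.nh4_t2_mM),
            fresh_mass=float(r.fresh_mass_g),
            moisture_fraction=float(r.moisture_fraction),
            slurry_volume=float(r.slurry_volume_L),
            t1=float(r.t1_h),
            t2=float(r.t2_h),
        )
        for r in df.itertuples()
    ]


def write_rates_csv(obs: list[RateObservation], path) -> None:
    rows = [
        (o.ecosystem_id, o.replicate_id, o.taxon, o.substrate_s, o.rate_v,
         o.nh4_target, o.below_detection, o.negative)
        for o in obs
    ]
    _write(pd.DataFrame(rows, columns=RATE_COLUMNS), path, "rates")


def read_rates_csv(path) -> list[RateObservation]:
    df = _read(path)
    return [
        RateObservation(
            ecosystem_id=str(r.ecosystem),
            replicate_id=str(r.replicate),
            taxon=str(r.taxon),
            substrate_s=float(r.substrate_mM),
            rate_v=float(r.rate_mgN_kg_day),
            nh4_target=float(r.nh4_target_mM),
            below_detection=bool(r.below_detection),
            negative=bool(r.negative),
        )
        for r in df.itertuples()
    ]


def fits_to_frame(fits: dict[tuple[str, str, str], KineticFit]) -> pd.DataFrame:
    """Rows keyed by (ecosystem, taxon, model); Km reported in uM, Ki in mM."""
    rows = []
    for (eco, taxon, model), f in fits.items():
        rows.append(
            (eco, taxon, model, f.vmax, f.se_vmax,
             f.km * 1000.0, f.se_km * 1000.0,
             f.ki if f.ki is not None else float("nan"),
             f.se_ki if f.se_ki is not None else float("nan"),
             f.rss, f.aic, f.n_obs, f.n_params, f.converged, f.km_constrained)
        )
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def write_fits_csv(fits, path) -> None:
    _write(fits_to_frame(fits), path, "fits")


def read_fits_csv(path) -> pd.DataFrame:
    return _read(path)


def comparisons_to_frame(comps: list[ModelComparison]) -> pd.DataFrame:
    rows = [
        (c.ecosystem_id, c.taxon, c.aic_mm, c.aic_haldane, c.f_stat,
         c.p_value, c.selected, c.haldane_failed)
        for c in comps
    ]
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)


def write_comparisons_csv(comps: list[ModelComparison], path) -> None:
    _write(comparisons_to_frame(comps), path, "model_selection")


def read_truths_csv(path) -> list[EcosystemTruth]:
    """Truth table: columns ecosystem, taxon, model, vmax, km_mM, ki_mM."""
    df = _read(path)
    out = []
    for r in df.itertuples():
        ki = getattr(r, "ki_mM", None)
        ki = None if ki is None or pd.isna(ki) else float(ki)
        out.append(
            EcosystemTruth(
                ecosystem_id=str(r.ecosystem),
                taxon=str(r.taxon),
                model=str(r.model),
                vmax_true=float(r.vmax),
                km_true=float(r.km_mM),
                ki_true=ki,
            )
        )
    return out
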