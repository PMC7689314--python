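"""End-to-end orchestration: simulate -> rates -> fit -> select -> Bayesian
contrasts (-> covariate regressions), with a YAML/JSON config, a plain-text
log, and deterministic artifacts for a given (config, seed)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .bayes import ChainConfig, GroupPrior, bayes_f_test, bayes_t_test, sample_posterior
from .kinetics import fit_kinetics
from .model_select import select_model
from .rates import partition_records
from .regression import covariate_regression
from .synthetic import IncubationDesign, NoiseModel, default_truths, simulate_incubation

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs.  ``seed`` drives every stochastic
    stage (simulation, bootstrap, MCMC) through fixed offsets."""

    seed: int = 1
    outdir: str = "results/run"
    alpha: float = 0.1
    detection_limit: float = 0.0
    truths: str = "default"  # "default" or a truths CSV path
    design: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    chains: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=lambda: {"enabled": False, "n_boot": 1000})
    covariates: str | None = None  # optional CSV: ecosystem + covariate columns

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise PipelineError(f"stage config: unknown keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise PipelineError(f"stage config: file not found: {path}")
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrapped
    return deco


@_stage("simulate")
def _simulate(config: PipelineConfig):
    if config.truths == "default":
        truths = default_truths()
    else:
        truths = nio.read_truths_csv(config.truths)
    design = IncubationDesign(**config.design)
    noise_kwargs = dict(config.noise)
    noise_kwargs.setdefault("seed", config.seed)
    noise = NoiseModel(**noise_kwargs)
    return truths, simulate_incubation(truths, design, noise)


@_stage("rates")
def _rates(records, detection_limit):
    return partition_records(records, detection_limit=detection_limit)


@_stage("fit")
def _fit(obs):
    fits = {}
    keys = sorted({(o.ecosystem_id, o.taxon) for o in obs if o.taxon != "total"})
    for eco, taxon in keys:
        group = [o for o in obs if o.ecosystem_id == eco and o.taxon == taxon]
        fits[(eco, taxon, "MM")] = fit_kinetics(group, "MM")
        try:
            fits[(eco, taxon, "Haldane")] = fit_kinetics(group, "Haldane")
        except (ValueError, np.linalg.LinAlgError):
            fits[(eco, taxon, "Haldane")] = None
    return fits


@_stage("select")
def _select(fits, alpha):
    comps = []
    pairs = sorted({(eco, taxon) for (eco, taxon, _m) in fits})
    for eco, taxon in pairs:
        comps.append(
            select_model(
                eco, taxon, fits[(eco, taxon, "MM")],
                fits.get((eco, taxon, "Haldane")), alpha=alpha,
            )
        )
    return comps


@_stage("bayes")
def _bayes(fits, comps, config: PipelineConfig):
    """Vmax contrasts across ecosystems, per taxon, plugin mode."""
    chain_kwargs = dict(config.chains)
    selected = {(c.ecosystem_id, c.taxon): c.selected for c in comps}
    rows, letter_rows = [], []
    seed_base = config.seed + 1000
    for t_idx, taxon in enumerate(("AOA", "AOB")):
        draws = []
        ecos = sorted({eco for (eco, tx, _m) in fits if tx == taxon})
        for e_idx, eco in enumerate(ecos):
            fit = fits.get((eco, taxon, selected.get((eco, taxon), "MM")))
            if fit is None or not fit.converged or not np.isfinite(fit.se_vmax):
                continue
            cfg = ChainConfig(
                **{**chain_kwargs, "seed": seed_base + 100 * t_idx + e_idx}
            )
            prior = GroupPrior(eco, fit.vmax, fit.se_vmax, "Vmax")
            draws.append(sample_posterior(prior, cfg, "plugin"))
        if len(draws) < 2:
            continue
        if len(draws) == 2:
            contrasts = [bayes_t_test(draws[0], draws[1])]
            letters = None
        else:
            contrasts, letters = bayes_f_test(draws)
        for c in contrasts:
            rows.append(
                (taxon, "Vmax", c.group_a, c.group_b, c.prob_a_gt_b,
                 c.diff_ci[0], c.diff_ci[1], c.significant)
            )
        if letters:
            means = {d.group_id: float(np.mean(d.samples)) for d in draws}
            for gid in sorted(letters):
                letter_rows.append((taxon, "Vmax", gid, letters[gid], means[gid]))
    contrasts_df = pd.DataFrame(
        rows,
        columns=["taxon", "parameter", "group_a", "group_b", "prob_a_gt_b",
                 "diff_lo", "diff_hi", "significant"],
    )
    letters_df = pd.DataFrame(
        letter_rows,
        columns=["taxon", "parameter", "ecosystem", "letter", "posterior_mean"],
    )
    return contrasts_df, letters_df


@_stage("regress")
def _regress(fits, comps, covariates_path):
    cov = nio._read(covariates_path)
    if "ecosystem" not in cov.columns:
        raise ValueError("covariates CSV needs an 'ecosystem' column")
    cov = cov.set_index("ecosystem")
    selected = {(c.ecosystem_id, c.taxon): c.selected for c in comps}
    rows = []
    for taxon in ("AOA", "AOB"):
        for col in cov.columns:
            pts = []
            for eco in cov.index:
                fit = fits.get((eco, taxon, selected.get((eco, taxon), "MM")))
                if fit is None or not np.isfinite(cov.loc[eco, col]):
                    continue
                pts.append((float(cov.loc[eco, col]), fit.vmax))
            if len(pts) < 3:
                continue
            r = covariate_regression(pts, response="Vmax", covariate=str(col))
            rows.append(
                (taxon, r.covariate, r.slope, r.intercept, r.r_squared,
                 r.p_value, r.n)
            )
    return pd.DataFrame(
        rows,
        columns=["taxon", "covariate", "slope", "intercept", "r_squared",
                 "p_value", "n"],
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write artifacts under ``config.outdir``.

    Identical config + seed produce byte-identical artifacts.  Returns the
    run directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"run seed={config.seed}"]

    truths, records = _simulate(config)
    nio.write_incubation_csv(records, outdir / "incubation.csv")
    log.append(
        f"simulate: {len(truths)} truths, {len(records)} bottles, "
        f"seed={dict(config.noise).get('seed', config.seed)}"
    )

    obs = _rates(records, config.detection_limit)
    nio.write_rates_csv(obs, outdir / "rates.csv")
    log.append(
        f"rates: {len(obs)} observations (pairs x 3 taxa), "
        f"detection_limit={config.detection_limit}"
    )

    fits = _fit(obs)
    fits_ok = {k: f for k, f in fits.items() if f is not None}
    nio.write_fits_csv(fits_ok, outdir / "fits.csv")
    log.append(f"fit: {len(fits_ok)} fits ({len(fits) - len(fits_ok)} failed)")

    comps = _select(fits, config.alpha)
    nio.write_comparisons_csv(comps, outdir / "model_selection.csv")
    n_h = sum(c.selected == "Haldane" for c in comps)
    log.append(f"select: {len(comps)} comparisons, Haldane chosen {n_h}x, alpha={config.alpha}")

    contrasts_df, letters_df = _bayes(fits, comps, config)
    nio._write(contrasts_df, outdir / "contrasts.csv", "contrasts")
    nio._write(letters_df, outdir / "letters.csv", "letters")
    log.append(
        f"bayes: {len(contrasts_df)} contrasts, {len(letters_df)} letter rows, "
        f"seed_base={config.seed + 1000}"
    )

    if config.covariates:
        reg_df = _regress(fits, comps, config.covariates)
        nio._write(reg_df, outdir / "regression.csv", "regression")
        log.append(f"regress: {len(reg_df)} regressions from {config.covariates}")

    config.to_yaml(outdir / "config_snapshot.yaml")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return outdir
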