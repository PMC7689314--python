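"""Compare fitted Vmax across ecosystems with plugin-mode posterior contrasts.

Two comparisons, mirroring the two-stage design of the study system:
  * managed systems (Conventional, Biologically-based, Poplar, Grassland):
    all pairwise contrasts plus a compact letter display per taxon;
  * fertilization pairs (Early successional and Deciduous forest, 0N vs +N):
    two-group contrasts per taxon.

Priors are the (estimate, SE) pairs from this run's own fits table
(results/analysis/fits.csv), restricted to each population's selected model;
13,002 draws per group (3 x 15,000, burn-in 2,000, thin 3).

Writes results/analysis/contrasts.csv and letters.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nitrikin import ChainConfig, GroupPrior, bayes_f_test, bayes_t_test, sample_posterior

OUT = Path("results/analysis")
SEED = 1
MANAGED = ["Conventional", "Biologically-based", "Poplar", "Grassland"]
FERT_PAIRS = [("Early successional", "Early successional+N"),
              ("Deciduous forest", "Deciduous forest+N")]


def selected_vmax_priors() -> dict[tuple[str, str], tuple[float, float]]:
    fits = pd.read_csv(OUT / "fits.csv", comment="#")
    sel = pd.read_csv(OUT / "model_selection.csv", comment="#")
    chosen = {(r.ecosystem, r.taxon): r.selected for r in sel.itertuples()}
    out = {}
    for r in fits.itertuples():
        if chosen.get((r.ecosystem, r.taxon)) == r.model and np.isfinite(r.se_vmax):
            out[(r.ecosystem, r.taxon)] = (float(r.vmax), float(r.se_vmax))
    return out


def draws_for(priors, eco, taxon, seed):
    m, s = priors[(eco, taxon)]
    cfg = ChainConfig(seed=seed)
    return sample_posterior(GroupPrior(eco, m, s, "Vmax"), cfg, "plugin")


def main() -> None:
    priors = selected_vmax_priors()
    rows, letter_rows = [], []

    for t_idx, taxon in enumerate(("AOA", "AOB")):
        groups = [draws_for(priors, e, taxon, SEED + 100 * t_idx + i)
                  for i, e in enumerate(MANAGED)]
        contrasts, letters = bayes_f_test(groups)
        print(f"{taxon} Vmax letter groups over managed systems "
              f"(same letter = not significantly different):")
        for eco in MANAGED:
            m, s = priors[(eco, taxon)]
            print(f"  {eco:20s} {m:5.2f} +- {s:4.2f}  {letters[eco]}")
        for c in contrasts:
            rows.append((taxon, "managed", c.group_a, c.group_b,
                         c.prob_a_gt_b, *c.diff_ci, c.significant))
        for eco in MANAGED:
            letter_rows.append((taxon, eco, letters[eco]))

    for t_idx, taxon in enumerate(("AOA", "AOB")):
        for p_idx, (ctrl_id, fert_id) in enumerate(FERT_PAIRS):
            ctrl = draws_for(priors, ctrl_id, taxon, SEED + 500 + 10 * t_idx + p_idx)
            fert = draws_for(priors, fert_id, taxon, SEED + 600 + 10 * t_idx + p_idx)
            c = bayes_t_test(fert, ctrl)
            verdict = "significant" if c.significant else "not significant"
            print(f"{taxon} {ctrl_id}: +N effect on Vmax "
                  f"P(+N > 0N) = {c.prob_a_gt_b:.4f} ({verdict})")
            rows.append((taxon, "fertilization", c.group_a, c.group_b,
                         c.prob_a_gt_b, *c.diff_ci, c.significant))

    pd.DataFrame(
        rows, columns=["taxon", "comparison", "group_a", "group_b",
                       "prob_a_gt_b", "diff_lo", "diff_hi", "significant"],
    ).to_csv(OUT / "contrasts.csv", index=False)
    pd.DataFrame(letter_rows, columns=["taxon", "ecosystem", "letter"]).to_csv(
        OUT / "letters.csv", index=False
    )
    print(f"wrote {OUT / 'contrasts.csv'} and {OUT / 'letters.csv'}")


if __name__ == "__main__":
    main()
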