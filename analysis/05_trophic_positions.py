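"""Trophic positions of residents and natives on the shared baseline scale.

Point estimates (lambda + mean standardized d15N / 3.4) and Bayesian
posteriors (TDF-uncertain one-baseline model) per species, using the
macrophyte baseline at trophic level 2.  Writes results/trophic/tp.csv.
"""

import pathlib

import pandas as pd

from isoniche.io import read_isotope_table
from isoniche.standardization import standardize_community, superimpose
from isoniche.trophic import MCMCConfig, bayesian_trophic_position, point_trophic_position

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"
SEED = 23


def main() -> None:
    data = ROOT / "data"
    out = ROOT / "trophic"
    out.mkdir(parents=True, exist_ok=True)
    community = standardize_community(read_isotope_table(data / "arreo.csv"))
    for stem, sp in (
        ("donor_T", "T. tinca"),
        ("donor_A", "A. anguilla"),
        ("donor_Gyrinus", "Gyrinus sp."),
    ):
        donor = standardize_community(read_isotope_table(data / f"{stem}.csv"))
        community = superimpose(community, donor, sp)

    rows = []
    for i, (sp, g) in enumerate(community.groups.items()):
        if sp == community.baseline_species:
            continue
        res = bayesian_trophic_position(
            g, community.baseline, mcmc=MCMCConfig(seed=SEED + i)
        )
        rows.append(
            {
                "species": sp,
                "point_tp": point_trophic_position(float(g.d15N.mean())),
                "median_tp": res.median,
                "ci95_lo": res.ci95[0],
                "ci95_hi": res.ci95[1],
                "rhat": res.rhat,
            }
        )
        print(
            f"{sp:<13} TP point {rows[-1]['point_tp']:5.2f}  "
            f"median {res.median:5.2f}  95% CI "
            f"[{res.ci95[0]:5.2f}, {res.ci95[1]:5.2f}]  Rhat {res.rhat:.3f}"
        )
    pd.DataFrame(rows).round(3).to_csv(out / "tp.csv", index=False)
    print(f"wrote {out / 'tp.csv'}")


if __name__ == "__main__":
    main()
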