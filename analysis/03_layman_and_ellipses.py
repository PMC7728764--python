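"""Layman metrics and ellipse niche areas, with and without each native.

Runs four scenarios — residents only, plus one superimposed native at a
time — and emits the species-by-metrics table (NR, CR, TA, CD, NND, SDNND,
SEAc, SEAb) for each, mirroring the "community with and without them"
design.  Tables land in results/niche/.
"""

import pathlib

import pandas as pd

from isoniche.pipeline import ScenarioConfig, run_scenario

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"
SEED = 7


def main() -> None:
    data = ROOT / "data"
    out = ROOT / "niche"
    out.mkdir(parents=True, exist_ok=True)
    donors = {
        "T. tinca": str(data / "donor_T.csv"),
        "A. anguilla": str(data / "donor_A.csv"),
        "Gyrinus sp.": str(data / "donor_Gyrinus.csv"),
    }
    frames = []
    for native in (None, "T. tinca", "Gyrinus sp.", "A. anguilla"):
        res = run_scenario(
            ScenarioConfig(
                target=str(data / "arreo.csv"),
                donors=donors,
                species_to_superimpose=native,
                analyses=("metrics", "ellipses"),
                seed=SEED,
            )
        )
        m = res["metrics"].merge(
            res["ellipse_areas"][["species", "SEAc", "SEAb"]],
            on="species", how="left",
        )
        m.insert(0, "scenario", res["manifest"]["community"])
        frames.append(m)
        label = native or "residents only"
        comm = m.iloc[0]
        print(
            f"{label:<16} community: CR={comm.CR:5.2f}  TA={comm.TA:6.2f}  "
            f"CD={comm.CD:4.2f}  NND={comm.NND:4.2f}"
        )
    table = pd.concat(frames, ignore_index=True).round(2)
    # each scenario repeats the residents; keep one copy of each species row
    species_rows = (
        table[~table.species.str.startswith("Community")]
        .drop_duplicates("species", keep="last")
    )
    community_rows = table[table.species.str.startswith("Community")]
    pd.concat([community_rows, species_rows]).to_csv(
        out / "layman_ellipses.csv", index=False
    )
    print(f"wrote {out / 'layman_ellipses.csv'}")


if __name__ == "__main__":
    main()
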