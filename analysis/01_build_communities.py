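"""Generate the study communities and write them as tidy CSVs.

Builds the target lake community (four non-native consumers over a
macrophyte baseline) and one donor ecosystem per extirpated native species
(tench, European eel, whirligig beetle), each at its published standardized
means/ranges and sample sizes but on a shifted raw baseline, then writes
them under results/data/.
"""

import pathlib

from isoniche.io import write_community
from isoniche.synthetic import arreo_fixture

SEED = 20_000
OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    target, donors = arreo_fixture(seed=SEED)
    write_community(target, OUT / "arreo.csv")
    print(f"target community ({target.ecosystem}):")
    for g in target:
        print(f"  {g.species:<14} n={g.n:<3} role={g.role}")
    for sp, ds in donors.items():
        path = OUT / f"donor_{sp.split()[0].strip('.')}.csv"
        write_community(ds, path)
        print(f"donor {sp} from {ds.ecosystem}: n={ds.group(sp).n} -> {path.name}")


if __name__ == "__main__":
    main()
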