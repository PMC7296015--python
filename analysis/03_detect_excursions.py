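#!/usr/bin/env python
"""Detect extra-territorial excursions and assemble monthly assessments.

Scores every fix against its home territory polygon, keeps the farthest
fix per badger-night, calls a night an excursion when that fix is more
than 15 m beyond the boundary, and reduces to one record per badger-month
with the excursion frequency fETE. Also validates detection against the
simulator's ground truth.
"""

from pathlib import Path

import pandas as pd

from foray.detection import (
    assemble_monthly,
    assign_nights,
    count_active_nights,
    detect_etes,
)
from foray.io import read_animals, read_fixes, read_territories, write_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data = ROOT / "results" / "data"
    fixes = read_fixes(data / "fixes.csv")
    animals = read_animals(data / "animals.csv")
    maps = read_territories(data / "territories.geojson")

    nf = assign_nights(fixes)
    etes = detect_etes(nf, maps)
    monthly = assemble_monthly(etes, count_active_nights(nf), animals)
    write_table(etes, ROOT / "results" / "ete_events.csv")
    write_table(monthly, ROOT / "results" / "monthly_assessments.csv")

    truth = pd.read_csv(data / "truth.csv")
    truth["night_date"] = pd.to_datetime(truth["night_date"]).dt.date
    det = etes[["animal_id", "night_date"]].assign(det=True)
    m = truth.merge(det, on=["animal_id", "night_date"], how="left")
    m["det"] = m["det"].notna()
    sens = m.loc[m["is_excursion_night"], "det"].mean()
    fpr = m.loc[~m["is_excursion_night"], "det"].mean()

    print(f"{len(etes)} excursion nights among {len(monthly)} badger-months")
    print(f"  fETE: mean {monthly['fete'].mean():.3f}, "
          f"zero months {(monthly['ete_count'] == 0).mean():.2%}")
    print(f"  vs ground truth: sensitivity {sens:.3f}, "
          f"false-positive rate {fpr:.5f} per night")
    print(f"  excursion distance: median {etes['distance_m'].median():.0f} m, "
          f"mean {etes['distance_m'].mean():.0f} m")


if __name__ == "__main__":
    main()
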