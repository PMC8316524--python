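#!/usr/bin/env python
"""Population-uniqueness estimates from the verification EER.

For the best verification method, converts the EER into special-uniqueness
(one probe sample is unique within a population) and general-uniqueness
(every member of the population is unique) probabilities across a range of
population sizes.
"""
from pathlib import Path

import pandas as pd

from gaituniq.verification import uniqueness_estimates

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    summary = pd.read_csv(RESULTS / "verification_summary.csv")
    best = summary.loc[summary.eer.idxmin()]
    eer = float(best.eer)
    print(f"best method {best.method}: EER {eer:.4f}")

    rows = []
    for population in (2, 5, 10, 20, 50, 100):
        if eer * population > 1.0:
            print(f"population {population}: union bound degenerates "
                  f"(EER x population > 1)")
            continue
        bound, special, general = uniqueness_estimates(eer, population)
        rows.append({"population": population, "error_bound": bound,
                     "special_uniqueness": special,
                     "general_uniqueness": general})
        print(f"population {population:3d}: misattribution bound {bound:.4f}, "
              f"special uniqueness {special:.4f}, general uniqueness {general:.4f}")

    pd.DataFrame(rows).to_csv(RESULTS / "uniqueness.csv", index=False)
    print(f"wrote {RESULTS / 'uniqueness.csv'}")


if __name__ == "__main__":
    main()
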