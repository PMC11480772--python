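#!/usr/bin/env python
"""Salt dependence of the binding free energy.

Ordinary least squares of dG_b against ln[NaCl] for both water models
and both simulation routes (restraint-route contribution totals and
unrestrained-separation totals), plus the inverse interpolation of the
TIP4P-D line at the experimentally measured affinity of -12.2 kcal/mol.

Writes results/salt_dependence.csv.
"""

from pathlib import Path

import pandas as pd

from bindfe.io import salt_series_from_table
from bindfe.transitions import (interpolate_concentration,
                                salt_dependence_regression)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for water in ("TIP3P", "TIP4P-D"):
        for source in ("contributions", "separation"):
            series = salt_series_from_table(water, source=source)
            slope, stderr = salt_dependence_regression(series, log_base="natural")
            rows.append(dict(water_model=water, route=source,
                             slope_kcal_per_ln=round(slope, 3),
                             slope_stderr=round(stderr, 3)))
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "salt_dependence.csv", index=False)
    print(df.to_string(index=False))

    series = salt_series_from_table("TIP4P-D", source="contributions")
    conc = interpolate_concentration(series, -12.2, log_base="natural")
    print(f"\nTIP4P-D restraint-route regression inverted at -12.2 kcal/mol: "
          f"{conc:.0f} mM")
    print("Experimental context: the homologous lambda-phage complex binds at")
    print("-12.2 kcal/mol near 120 mM salt; the regression places it at the")
    print(f"concentration above.")


if __name__ == "__main__":
    main()
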