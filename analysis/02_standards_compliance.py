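#!/usr/bin/env python
"""Grade the recomputed fuel properties of the 11 cultures against the
EN 14214, ASTM and IS 15607 biodiesel standards.

Writes one pass/fail matrix per (standard, season) under results/.
"""

from pathlib import Path

from famefuel.datasets import load_table1_profiles
from famefuel.fuel_properties import properties_table
from famefuel.standards import compliance_matrix, load_standards

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = properties_table(load_table1_profiles(), use_reported_totals=True)
    for name, spec in load_standards().items():
        seasonal = any(l.seasonal for l in spec.limits.values())
        for season in (("summer", "winter") if seasonal else (None,)):
            matrix = compliance_matrix(table, spec, season)
            tag = f"{name}_{season}" if season else name
            matrix.to_csv(OUT / f"compliance_{tag}.csv", index=False)
            fails = matrix[matrix.overall == "fail"]
            label = f"{name} ({season})" if season else name
            if len(fails):
                detail = "; ".join(
                    f"{r.sample_id}: " + ",".join(
                        p for p in spec.limits if r._asdict().get(p) == "fail"
                    )
                    for r in fails.itertuples()
                )
                print(f"{label}: {len(fails)}/11 cultures fail ({detail})")
            else:
                print(f"{label}: all 11 cultures pass")
    print(f"\nWrote matrices under {OUT}")


if __name__ == "__main__":
    main()
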