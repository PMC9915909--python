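"""Getis-Ord Gi* cold/hot-spot analysis of the CEI and LE fields.

Computes per-region Gi* z-scores (binary queen weights, self-inclusive)
for every variable-year and the tiered 90/95/99% hot/cold labels,
writing results/hotspots/hotspots.csv.
"""

import sys
from collections import Counter
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import ecolag as e

ROOT = Path(__file__).resolve().parents[1]
SRC = ROOT / "results" / "synthetic"
OUT = ROOT / "results" / "hotspots"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    w = e.read_gal(SRC / "weights.gal")
    cei = e.read_panel_csv(ROOT / "results" / "cei" / "cei.csv", "CEI")
    le = e.read_panel_csv(SRC / "le.csv", "LE")
    rows = []
    for panel in (cei, le):
        for t in panel.timepoints:
            res = e.gi_star(panel.column(t), w)
            rows.extend({"variable": panel.variable, "timepoint": t,
                         "region_id": rid, "z": z, "category": cat}
                        for rid, z, cat in zip(res.ids, res.z, res.category))
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "hotspots.csv", index=False)
    for (var, t), g in df.groupby(["variable", "timepoint"]):
        counts = Counter(g.category)
        hot = sum(v for k, v in counts.items() if k.startswith("hot"))
        cold = sum(v for k, v in counts.items() if k.startswith("cold"))
        print(f"{var} {t}: {hot} hot, {cold} cold, "
              f"{counts['not_significant']} not significant "
              f"(max |z| {g.z.abs().max():.2f})")


if __name__ == "__main__":
    main()
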