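"""Spatiotemporal-lag spatial cross-correlation: the headline analysis.

For every (x_time <= y_time) design over the three census years, computes
the aspatial Pearson r and the lagged bivariate Moran's I of LE on the
CEI with permutation significance and LISA cluster labels, then pools
same-lag designs and ranks candidate lags by pooled |I|.  On this
synthetic study the planted 5-year lag should come out on top.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import ecolag as e

ROOT = Path(__file__).resolve().parents[1]
SRC = ROOT / "results" / "synthetic"
OUT = ROOT / "results" / "crosscorr"
SEED = 20230125


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    w = e.row_standardize(e.read_gal(SRC / "weights.gal"))
    cei = e.read_panel_csv(ROOT / "results" / "cei" / "cei.csv", "CEI")
    le = e.read_panel_csv(SRC / "le.csv", "LE")
    rng = np.random.default_rng(SEED)

    rows, local_rows = [], []
    for x_t in le.timepoints:
        for y_t in le.timepoints:
            if x_t > y_t:
                continue
            pair = e.LagPair("LE", y_t, "CEI", x_t)
            r = e.pearson_lag_matrix({"CEI": cei}, le, [pair])[0]
            res = e.cross_moran(le.column(y_t), cei.column(x_t), w,
                                n_perm=999, seed=int(rng.integers(2 ** 31)))
            rows.append({"x_time": x_t, "y_time": y_t, "m": pair.m,
                         "pearson_r": r["pearson_r"],
                         "moran_I": res.global_I, "p_value": res.p_value})
            local_rows.extend(
                {"x_time": x_t, "y_time": y_t, "region_id": rid,
                 "local_I": li, "local_p": lp, "cluster": cl}
                for rid, li, lp, cl in zip(res.ids, res.local_I,
                                           res.local_p, res.cluster))
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "global.csv", index=False)
    pd.DataFrame(local_rows).to_csv(OUT / "local.csv", index=False)

    print("design table (CEI at x_time vs LE at y_time):")
    for r in rows:
        print(f"  CEI {r['x_time']} -> LE {r['y_time']} (m={r['m']:>2}): "
              f"r={r['pearson_r']:+.3f}  I={r['moran_I']:+.3f} "
              f"(p={r['p_value']:.3f})")
    pooled = df.groupby("m").moran_I.mean()
    ranking = pooled.abs().sort_values(ascending=False)
    print("pooled |I| by lag:", {int(m): round(v, 3)
                                 for m, v in ranking.items()})
    print(f"best-supported lag in this single draw: {int(ranking.index[0])} "
          f"years (planted: 5 years)")

    # a single 16-region draw is noisy; the replicated experiment is the
    # meaningful readout of lag recovery
    wins = 0
    n_rep = 200
    for s in range(n_rep):
        study = e.generate_study(e.SyntheticConfig(seed=s))
        le_r, cei_r = study["le"], study["cei"]
        I = lambda yt, xt: e.global_cross_moran(le_r.column(yt),
                                                cei_r.column(xt), w)
        m5 = np.mean([I(2015, 2010), I(2020, 2015)])
        m0 = np.mean([I(2010, 2010), I(2015, 2015), I(2020, 2020)])
        wins += abs(m5) > abs(m0)
    print(f"replicated recovery: true 5-year lag beats lag 0 in "
          f"{wins}/{n_rep} replicates ({wins / n_rep:.0%})")

    sig = [r for r in local_rows if r["local_p"] <= 0.05
           and r["x_time"] == 2015 and r["y_time"] == 2020]
    print(f"LISA (CEI 2015 -> LE 2020): {len(sig)} significant regions: "
          + ", ".join(f"{r['region_id']}={r['cluster']}" for r in sig))


if __name__ == "__main__":
    main()
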