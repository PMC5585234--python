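"""Calibrate both transfer-function branches on the modern world and validate.

Pairs the modern assemblage matrix with the SST climatology, fits the
factor-analysis transfer function (k = 4) and the ANN ensemble (5 hidden
units, 100 replicates, median aggregation), and reports internal
(resubstitution) and leave-one-out deviations for mean SST.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from coralclim.ann import AnnConfig, internal_validation, train_ensemble
from coralclim.assemblage import AssemblageMatrix
from coralclim.climatology import ClimatologyField, pair_cells
from coralclim.evaluate import cross_validation
from coralclim.ikfa import fit_ikfa

ANN_KW = dict(max_iterations=200, gradient_tol=1e-5)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--k", type=int, default=4)
    ap.add_argument("--replicates", type=int, default=100)
    args = ap.parse_args()

    field = ClimatologyField.from_long_csv(args.out / "modern_sst_climatology.csv")
    wide = pd.read_csv(args.out / "assemblage_modern_species.csv")
    matrix = AssemblageMatrix.from_wide_frame(wide, rank="species")
    calib, env = pair_cells(matrix, field)

    fa = fit_ikfa(calib, env[["mean_sst", "stv"]], k=args.k)
    fa.to_json(args.out / "ikfa_model.json")
    print(f"IKFA (k={args.k}) calibration RMSE: "
          f"{fa.calibration_stats['rmse']['mean_sst']:.3f} C (mean SST), "
          f"{fa.calibration_stats['rmse']['stv']:.3f} C (STV)")

    cfg = AnnConfig(n_replicates=args.replicates, base_seed=args.seed, **ANN_KW)
    ens = train_ensemble(calib, env["mean_sst"], cfg)
    ens.to_json(args.out / "ann_ensemble_mean_sst.json")
    dev = internal_validation(calib, env["mean_sst"], cfg, latitudes=env["lat"])
    dev.to_csv(args.out / "ann_internal_validation.csv")
    print(f"ANN internal validation: median deviation "
          f"{dev['deviation'].median():+.3f} C over {len(dev)} cells")

    loo_fa = cross_validation(calib, env["mean_sst"], method="ikfa",
                              mode="leave_one_out", k=args.k)
    print(f"IKFA leave-one-out RMSE: "
          f"{float(np.sqrt((loo_fa.deviation ** 2).mean())):.3f} C")
    loo_fa.to_csv(args.out / "ikfa_loo_deviations.csv")


if __name__ == "__main__":
    main()
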