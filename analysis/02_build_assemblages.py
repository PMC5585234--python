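"""Filter occurrence records and build harmonized assemblage matrices.

Reads the occurrence tables written by 01_simulate_world.py, applies the
depth (<= 60 m) and zooxanthellate filters, grids records into 1-degree
proportional assemblages, drops single-genus cells, and restricts modern and
fossil matrices to their shared taxon pool.
"""

import argparse
from pathlib import Path

import pandas as pd

from coralclim.assemblage import (
    apply_cell_filters,
    build_matrix,
    filter_records,
    harmonize_taxa,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--rank", choices=["species", "genus"], default="species")
    ap.add_argument("--min-genera", type=int, default=2)
    args = ap.parse_args()

    matrices = {}
    for epoch, fname in [("modern", "occurrences_modern.csv"),
                         ("lig", "occurrences_lig.csv")]:
        records = pd.read_csv(args.out / fname)
        kept = filter_records(records)
        m = apply_cell_filters(build_matrix(kept, rank=args.rank),
                               min_genera=args.min_genera)
        matrices[epoch] = m
        print(f"{epoch}: {len(records)} records -> {len(kept)} after filters -> "
              f"{m.props.shape[0]} cells x {m.props.shape[1]} taxa")

    modern, fossil = harmonize_taxa(matrices["modern"], matrices["lig"],
                                    min_genera=args.min_genera)
    print(f"harmonized shared pool: {len(modern.taxa)} taxa; "
          f"{len(modern.props)} modern and {len(fossil.props)} fossil cells")

    modern.to_csv(args.out / f"assemblage_modern_{args.rank}.csv")
    fossil.to_csv(args.out / f"assemblage_lig_{args.rank}.csv")


if __name__ == "__main__":
    main()
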