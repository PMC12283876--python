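#!/usr/bin/env python
"""Pairwise weighted-Jaccard trajectory distances.

Reads the clustering-period status matrix and computes, for every pair of
men, the comparability-weighted sum over indicators of (1 - Jaccard) between
their active-month sets. Writes the square labeled matrix to
results/distance_matrix.csv.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from behavclust.distance import pairwise_distance
from behavclust.trajectories import StatusMatrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    meta = json.loads((args.outdir / "dense_period.json").read_text())
    matrix = StatusMatrix.from_long_frame(
        pd.read_csv(args.outdir / "clustering_matrix.csv"), meta["start"]
    )
    dist = pairwise_distance(matrix)
    dist.to_frame().to_csv(args.outdir / "distance_matrix.csv")

    off = dist.values[np.triu_indices(dist.n, k=1)]
    print(f"distance matrix: {dist.n} men, {len(matrix.indicators)} indicators")
    print(f"pairwise distances: mean {off.mean():.2f}, "
          f"range {off.min():.2f}..{off.max():.2f} "
          f"(bound {len(matrix.indicators)})")


if __name__ == "__main__":
    main()
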