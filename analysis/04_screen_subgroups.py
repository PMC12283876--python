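#!/usr/bin/env python
"""Hierarchical clustering and heuristic subgroup screening.

Clusters the distance matrix (average linkage), scans the top six hierarchy
levels (ten candidate clusters), evaluates the reach/hegemonic/rising
criteria on each candidate's denominator-filtered frequency series, prunes
descendants whose criterion-2 modes repeat their ancestor's, and writes the
dendrogram (Newick) and the screening report (JSON).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from behavclust import subgroups
from behavclust.distance import DistanceMatrix
from behavclust.trajectories import StatusMatrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--linkage", default="average")
    args = ap.parse_args()

    meta = json.loads((args.outdir / "dense_period.json").read_text())
    matrix = StatusMatrix.from_long_frame(
        pd.read_csv(args.outdir / "clustering_matrix.csv"), meta["start"]
    )
    df = pd.read_csv(args.outdir / "distance_matrix.csv", index_col=0)
    dist = DistanceMatrix(list(df.index), df.to_numpy())

    tree = subgroups.cluster_hierarchical(dist, args.linkage)
    directions = {s["name"]: s["exposure_direction"] for s in meta["indicators"]}
    report = subgroups.screen_subgroups(tree, matrix, directions)

    (args.outdir / "dendrogram.nwk").write_text(subgroups.to_newick(tree) + "\n")
    (args.outdir / "subgroups.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")

    print(f"{len(report['candidates'])} candidate clusters in the top "
          f"{report['criteria']['levels_scanned']} levels")
    for c in report["candidates"]:
        status = c["label"] or ("pruned" if c["pruned_reason"] else "out")
        modes = ", ".join(f"{i}:{m}" for i, m in c["modes"]) or "-"
        print(f"  level {c['level']} size {c['size']:4d} -> {status:7s} [{modes}]")
    print(f"final subgroups: {sorted(report['subgroups'])}")


if __name__ == "__main__":
    main()
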