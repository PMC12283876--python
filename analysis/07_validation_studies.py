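#!/usr/bin/env python
"""Planted-truth validation studies.

Runs the package's simulation studies — planted hegemonic/rising/flat
detection rates, three-profile recovery (adjusted Rand index under average
and complete linkage), and first-visit classifier recovery with a null-signal
control — and writes the summary to results/validation.json.
"""

import argparse
import json
from pathlib import Path

from behavclust import experiments


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    seeds20 = [args.seed * 1000 + i for i in range(20)]
    seeds10 = seeds20[:10]

    detect = experiments.criteria_detection_rates(seeds20)
    rec_avg = experiments.planted_recovery_ari(seeds20, "average")
    rec_com = experiments.planted_recovery_ari(seeds20, "complete")
    clf = experiments.classifier_recovery(seeds10)
    null = experiments.classifier_null_check(args.seed)

    out = {
        "criteria_detection": detect,
        "recovery_average": rec_avg,
        "recovery_complete": rec_com,
        "classifier_recovery": clf,
        "classifier_null": null,
    }
    args.outdir.mkdir(parents=True, exist_ok=True)
    (args.outdir / "validation.json").write_text(
        json.dumps(out, indent=2, sort_keys=True) + "\n")

    print(f"hegemonic detected in {detect['hegemonic_rate']:.0%} of seeds, "
          f"rising in {detect['rising_rate']:.0%}, "
          f"flat-low falsely flagged in {detect['false_flag_rate']:.0%}")
    print(f"3-profile recovery: median ARI {rec_avg['median_ari']:.2f} "
          f"(average linkage), {rec_com['median_ari']:.2f} (complete)")
    print(f"classifier: median accuracy {clf['median_accuracy']:.2f}, "
          f"informative feature top-1 in {clf['top1_informative_rate']:.0%} "
          f"of seeds; null gap {null['gap_in_se']:+.1f} SE")


if __name__ == "__main__":
    main()
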