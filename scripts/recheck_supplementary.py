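#!/usr/bin/env python
"""One-command re-check of published differential counts from a Score table.

Point this at a per-condition protein Score table (the shape journal
supplementary material usually takes: a first accession column followed by
one replicate-averaged Score column per condition/sample; TSV, CSV or
xlsx).  It rebuilds the condition profiles, reruns the DAve/DCI comparison
for each requested column pair at the published thresholds (DAve 0.4, DCI
400 by default) and prints differential counts, up/down and exclusive
breakdowns, and strict/relaxed overlap between comparisons as YAML.

Example:

    python scripts/recheck_supplementary.py scores.xlsx \\
        --compare ATX3_16h:Ctrl_16h --compare ATX3_48h:Ctrl_48h \\
        --overlap ATX3_16h_vs_Ctrl_16h:ATX3_48h_vs_Ctrl_48h
"""

from __future__ import annotations

import argparse
import sys

import yaml

from mapdiff.differential import DiffThresholds
from mapdiff.recheck import load_score_table, recheck_comparisons


def main() -> None:
    parser = argparse.ArgumentParser(
        description=__doc__, formatter_class=argparse.RawDescriptionHelpFormatter
    )
    parser.add_argument("score_table", help="accession x sample Score table")
    parser.add_argument(
        "--compare", action="append", required=True, metavar="X:Y",
        help="sample column pair to compare (repeatable)",
    )
    parser.add_argument(
        "--overlap", action="append", default=[], metavar="X_vs_Y:A_vs_B",
        help="comparison-name pair whose differential lists to intersect (repeatable)",
    )
    parser.add_argument("--dave-min", type=float, default=0.4)
    parser.add_argument("--dci-min", type=float, default=400.0)
    args = parser.parse_args()

    profiles = load_score_table(args.score_table)
    report = recheck_comparisons(
        profiles,
        [tuple(p.split(":", 1)) for p in args.compare],
        [tuple(p.split(":", 1)) for p in args.overlap],
        DiffThresholds(dave_min=args.dave_min, dci_min=args.dci_min),
    )
    yaml.safe_dump(report, sys.stdout, sort_keys=False)


if __name__ == "__main__":
    main()
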