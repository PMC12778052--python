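#!/usr/bin/env python
"""Classify every growth curve with mouse-adapted mRECIST (mCR/mPR/mSD/mPD
via BestResponse and BestAvgResponse at/after day 10) and code binary
responder labels (mPD = 0, stable disease or better = 1).

Reads results/cohort/growth.csv, writes results/mrecist.csv, and prints
label counts per arm plus agreement with the generative labels.
"""

from pathlib import Path

import pandas as pd

from petpd.mrecist import classify_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    growth = pd.read_csv(ROOT / "cohort" / "growth.csv")
    truth = pd.read_csv(ROOT / "cohort" / "truth.csv")

    labels = classify_table(growth)
    labels.to_csv(ROOT / "mrecist.csv", index=False)
    print(f"wrote {ROOT / 'mrecist.csv'} ({len(labels)} animals)")

    joined = labels.merge(truth[["animal_id", "group", "responder_true"]], on="animal_id")
    print(joined.groupby(["group", "label"]).size().unstack(fill_value=0).to_string())
    agree = (joined["responder"].astype(int) == joined["responder_true"]).mean()
    print(f"mRECIST labels agree with generative responder status for {agree:.0%} of animals")


if __name__ == "__main__":
    main()
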