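#!/usr/bin/env python
"""Filter, segment, and featurize the cohort.

For each moving-average width w in {3, 5}: denoise every recording,
cut it into 128-sample windows stepped by 64 (a 300-sample minute gives
3 segments even after filter shrinkage), and compute the 114-feature
descriptor per segment.  Writes one feature matrix per w.
"""
from pathlib import Path

import emogait as eg

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    recordings = eg.read_recordings(RESULTS / "data" / "recordings.csv")
    print(f"read {len(recordings)} recordings")
    for w in (3, 5):
        table = eg.build_feature_table(recordings, eg.FilterConfig(w))
        out = RESULTS / f"features_w{w}.csv"
        table.to_csv(out, index=False)
        print(f"w={w}: {len(table)} segments x {len(eg.FEATURE_NAMES)} features -> {out}")


if __name__ == "__main__":
    main()
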