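#!/usr/bin/env python
"""PCA feature selection and loading-matrix interpretation.

For each (filter width, wear site): z-score the 114 features, fit PCA,
retain the smallest component prefix explaining >= 95% of variance, and
list the original features whose factor loading on a retained component
reaches 0.71 — i.e. the features the leading components are made of.
Reports which feature families (temporal / frequency / temporal-
frequency) dominate those high loadings.
"""
import json
from collections import Counter
from pathlib import Path

import pandas as pd

import emogait as eg

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    report = {}
    for w in (3, 5):
        table = pd.read_csv(RESULTS / f"features_w{w}.csv")
        for site in eg.SITES:
            sub = table[table["site"] == site]
            model = eg.fit_select(sub[list(eg.FEATURE_NAMES)], threshold=0.95)
            loadings = eg.loading_report(model, cutoff=0.71)
            families = Counter(
                e["family"] for entries in loadings.values() for e in entries
            )
            report[f"w{w}_{site}"] = {
                "n_retained": model.n_retained,
                "cumulative_share": round(model.cumulative_share, 4),
                "high_loading_families": dict(families),
                "loadings": {str(k): v for k, v in loadings.items()},
            }
            print(
                f"w={w} site={site}: {model.n_retained} components reach "
                f"{100 * model.cumulative_share:.1f}% of variance; "
                f"|loading| >= 0.71 features by family: {dict(families)}"
            )
    out = RESULTS / "selection_report.json"
    out.write_text(json.dumps(report, indent=2) + "\n")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
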