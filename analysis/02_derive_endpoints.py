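"""Derive case/control/excluded labels for every endpoint and tabulate.

Reads the simulated cohort from 01, applies each endpoint definition
(threshold, baseline policy, exclusion flags) and writes a per-endpoint
summary of cohort sizes and toxicity rates to results/cohort_summary.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from toxsae import ENDPOINT_SPECS, derive_labels, format_prevalence
from toxsae.endpoints import read_phenotypes


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/cohort_summary.tsv"))
    args = ap.parse_args()

    rows = []
    for endpoint, spec in sorted(ENDPOINT_SPECS.items()):
        records = read_phenotypes(args.cohort / f"phenotypes_{endpoint}.tsv")
        labels = derive_labels(records, spec)
        reasons = labels.exclusion_reason.value_counts().to_dict()
        rows.append(
            {
                "endpoint": endpoint,
                "grade_threshold": spec.grade_threshold,
                "cases": labels.n_cases,
                "controls": labels.n_controls,
                "excluded": labels.n_excluded,
                "prevalence": format_prevalence(labels),
                "exclusion_reasons": "; ".join(
                    f"{k}={v}" for k, v in sorted(reasons.items())
                ),
            }
        )
        print(f"{endpoint}: {labels.n_cases} cases / "
              f"{labels.n_cases + labels.n_controls} available "
              f"({format_prevalence(labels)}), {labels.n_excluded} excluded")
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, sep="\t", index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
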