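"""Final report: identification matrices and the two arms side by side.

Combines the selection tiers (03) and the univariate scans (04) into one
per-endpoint table — Identified / Not validated per percentile tier, with
the univariate p-value and the planted truth — and summarises how often
each arm caught the planted SNPs.  Writes results/report_<endpoint>.tsv
and results/arms_summary.tsv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from toxsae import ENDPOINT_SPECS


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    truth = json.loads((args.results / "cohort" / "truth.json").read_text())
    summary = []
    for endpoint in sorted(ENDPOINT_SPECS):
        sel = pd.read_csv(
            args.results / "selection" / f"selection_{endpoint}.tsv", sep="\t"
        ).set_index("rsid")
        uni = pd.read_csv(
            args.results / "univariate" / f"association_{endpoint}.tsv", sep="\t"
        ).set_index("rsid")
        planted = set(truth[endpoint]["planted_rsids"])

        table = sel[["delta", "tier", "effect_label"]].copy()
        for p in (70, 80, 90, 95):
            table[f"{p}th"] = sel[f"p{p}"].map(
                {True: "Identified", False: "Not validated"}
            )
        table["univariate_p"] = uni["p"]
        table["planted"] = [r in planted for r in table.index]
        table.reset_index().to_csv(
            args.results / f"report_{endpoint}.tsv", sep="\t", index=False,
            float_format="%.4g",
        )

        dsae_hits = int((sel.loc[sorted(planted), "p80"]).sum())
        bonf_hits = int(uni.loc[sorted(planted), "bonferroni"].sum())
        nominal_hits = int(uni.loc[sorted(planted), "nominal"].sum())
        summary.append(
            {
                "endpoint": endpoint,
                "planted": len(planted),
                "dsae_p80_hits": dsae_hits,
                "univariate_nominal_hits": nominal_hits,
                "univariate_bonferroni_hits": bonf_hits,
            }
        )
        print(f"{endpoint}: DSAE p80 {dsae_hits}/5, univariate nominal "
              f"{nominal_hits}/5, Bonferroni {bonf_hits}/5")
    df = pd.DataFrame(summary)
    df.to_csv(args.results / "arms_summary.tsv", sep="\t", index=False)
    print(f"wrote {args.results}/arms_summary.tsv")


if __name__ == "__main__":
    main()
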