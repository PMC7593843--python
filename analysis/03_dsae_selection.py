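"""Autoencoder selection arm: replicate training and Delta tiers per endpoint.

For each endpoint: derive labels, run B split/train/test replicates of the
sparse autoencoder on the healthy-only training sets, average the
per-class per-SNP reconstruction errors, and keep SNPs above the
70/80/90/95th percentiles of the Delta distribution.  Writes per-endpoint
selection TSVs and two-panel figures under results/selection/, and prints
how many planted SNPs each tier caught.
"""

import argparse
import json
from pathlib import Path

from toxsae import ENDPOINT_SPECS, derive_labels, load_panel
from toxsae.dsae import NetworkSpec
from toxsae.endpoints import read_phenotypes
from toxsae.pipeline import align_genotypes
from toxsae.plots import render_selection_figure
from toxsae.selection import delta_profile, run_replicates, tier_select
from toxsae.simulate import read_genotypes


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results/selection"))
    ap.add_argument("--b", type=int, default=20,
                    help="replicates per endpoint (50 at full scale)")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    panel = load_panel()
    gm = read_genotypes(args.cohort / "genotypes.tsv")
    truth = json.loads((args.cohort / "truth.json").read_text())
    net = NetworkSpec(input_width=gm.j)

    for endpoint, spec in sorted(ENDPOINT_SPECS.items()):
        records = read_phenotypes(args.cohort / f"phenotypes_{endpoint}.tsv")
        labels = derive_labels(records, spec)
        X, y = align_genotypes(gm, labels)
        reps = run_replicates(X, y, net, b=args.b, master_seed=args.seed)
        prof = delta_profile(reps, gm.rsids)
        report = tier_select(prof, panel=panel, endpoint=endpoint)
        report.to_tsv(args.outdir / f"selection_{endpoint}.tsv")
        render_selection_figure(
            prof, report, endpoint, args.outdir / f"selection_{endpoint}.png"
        )
        planted = set(truth[endpoint]["planted_rsids"])
        for p in (70, 80, 90, 95):
            members = set(report.tier_members(p))
            print(f"{endpoint} p{p}: {len(members)} selected, "
                  f"{len(members & planted)}/5 planted")
    print(f"wrote selection tables and figures to {args.outdir}")


if __name__ == "__main__":
    main()
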