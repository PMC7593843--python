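"""Simulate the study cohort: shared panel genotypes, five endpoint outcomes.

One genotype matrix for the 43-SNP literature panel (HWE, one correlated
six-SNP block) is shared across endpoints, as in a real cohort; for each
of the five toxicity endpoints an additive-logistic outcome with five
planted SNPs (OR 2.5-3.5) is drawn at a 10% case rate, and grade
trajectories realising those outcomes are written alongside, with
realistic exclusion-feature rates (hemorrhoids, TURB, anti-muscarinics,
collagen vascular disease and baseline-prevalent symptoms).

Writes results/cohort/: genotypes.tsv, genotypes.vcf,
phenotypes_<endpoint>.tsv and truth.json.
"""

import argparse
import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from toxsae import ENDPOINT_SPECS, load_panel
from toxsae.endpoints import write_phenotypes
from toxsae.simulate import (
    ExclusionRates,
    simulate_genotypes,
    simulate_longitudinal,
    simulate_outcome,
    solve_intercept,
    write_genotypes,
    write_vcf,
)

RATES = ExclusionRates(
    hemorrhoids=0.10, turb=0.03, antimuscarinic=0.01, cvd=0.035,
    baseline_prevalent=0.05,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n", type=int, default=1400)
    ap.add_argument("--outdir", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    panel = load_panel()
    gm, base_truth = simulate_genotypes(args.n, panel, seed=args.seed)
    write_genotypes(gm, args.outdir / "genotypes.tsv")
    write_vcf(gm, args.outdir / "genotypes.vcf")

    candidates = [k for k, e in enumerate(panel) if not e.ld_group]
    truth_out = {}
    for k, endpoint in enumerate(sorted(ENDPOINT_SPECS)):
        rng = np.random.default_rng(args.seed + 10 * (k + 1))
        planted = rng.choice(candidates, size=5, replace=False)
        betas = np.zeros(gm.j)
        betas[planted] = rng.uniform(np.log(2.5), np.log(3.5), 5)
        truth = replace(
            base_truth,
            planted_effects=betas,
            target_prevalence=0.10,
            intercept=solve_intercept(betas, gm, 0.10),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        y = simulate_outcome(gm, truth)
        records = simulate_longitudinal(
            y, ENDPOINT_SPECS[endpoint], rates=RATES,
            seed=args.seed + 10 * (k + 1) + 1, patient_ids=gm.patient_ids,
        )
        write_phenotypes(records, args.outdir / f"phenotypes_{endpoint}.tsv")
        truth_out[endpoint] = {
            "planted_rsids": truth.planted_rsids(gm.rsids),
            "intercept": truth.intercept,
            "case_fraction": float(y.mean()),
        }
        print(f"{endpoint}: {int(y.sum())}/{args.n} cases, "
              f"planted {truth_out[endpoint]['planted_rsids']}")
    (args.outdir / "truth.json").write_text(json.dumps(truth_out, indent=2))
    print(f"wrote cohort to {args.outdir}")


if __name__ == "__main__":
    main()
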