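"""Synthetic radiogenomic cohort generator.

Emulates the data structure the selection method assumes: a panel-sized
additive genotype matrix under Hardy-Weinberg equilibrium with one
linkage-disequilibrium block (generated by copying latent haplotypes with a
flip probability calibrated to the target r^2), binary late-toxicity
outcomes from an additive logistic model with planted odds ratios, and
longitudinal CTCAE-style grade trajectories consistent with those outcomes
so the endpoint-derivation rules can be exercised end to end.

Everything is a pure function of its parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .endpoints import EndpointSpec, ToxicityRecord
from .panel import SNPPanelEntry

__all__ = [
    "GenotypeMatrix",
    "SimulationTruth",
    "ExclusionRates",
    "simulate_genotypes",
    "solve_intercept",
    "simulate_outcome",
    "simulate_longitudinal",
    "planted_scenario",
    "write_genotypes",
    "read_genotypes",
    "write_vcf",
    "read_vcf_dosages",
]


@dataclass
class GenotypeMatrix:
    """N x J additive dosage matrix with aligned rsID / patient labels."""

    dosages: np.ndarray
    rsids: list[str]
    patient_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D")
        n, j = self.dosages.shape
        if j != len(self.rsids) or n != len(self.patient_ids):
            raise ValueError("label lengths inconsistent with dosage shape")
        if np.isnan(self.dosages).any():
            raise ValueError("missing dosages not allowed")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def j(self) -> int:
        return self.dosages.shape[1]


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort."""

    planted_effects: np.ndarray  # per-SNP log-OR, 0 for null SNPs
    intercept: float
    target_prevalence: float
    mafs: np.ndarray
    ld_r2: float
    seed: int

    def planted_rsids(self, rsids: Sequence[str]) -> list[str]:
        return [r for r, b in zip(rsids, self.planted_effects) if b != 0.0]


def _ld_resample_probability(ld_r2: float) -> float:
    # Haplotype alleles copy a shared latent haplotype and are redrawn from
    # Bernoulli(maf) with probability eps (preserving the marginal maf);
    # the correlation between two such copies is (1-eps)^2, so
    # r^2 = (1-eps)^4.
    return 1.0 - float(ld_r2) ** 0.25


def simulate_genotypes(
    n: int,
    panel: Sequence[SNPPanelEntry],
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_r2: float = 0.9,
    seed: int = 0,
    integer_dosages: bool = True,
    dosage_noise_sd: float = 0.05,
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Draw HWE genotypes for the panel, correlating each declared LD group.

    Ungrouped SNPs are independent Binomial(2, maf) columns.  SNPs sharing
    an ``ld_group`` are noisy copies of a latent two-haplotype genotype and
    share the group's allele frequency; their pairwise r^2 approximates
    ``ld_r2``.  With ``integer_dosages=False``, truncated Gaussian noise is
    added to mimic imputed dosages.
    """
    if not panel:
        raise ValueError("panel is empty")
    if n < 2:
        raise ValueError("need at least two individuals")
    if not 0.0 <= ld_r2 <= 1.0:
        raise ValueError("ld_r2 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    j = len(panel)
    lo, hi = maf_range
    mafs = rng.uniform(lo, hi, size=j)

    groups: dict[str, list[int]] = {}
    for k, entry in enumerate(panel):
        if entry.ld_group:
            groups.setdefault(entry.ld_group, []).append(k)
    # one shared frequency per LD group (a single association signal)
    for idx in groups.values():
        mafs[idx] = mafs[idx[0]]

    X = np.empty((n, j))
    grouped = {k for idx in groups.values() for k in idx}
    for k in range(j):
        if k not in grouped:
            X[:, k] = rng.binomial(2, mafs[k], size=n)
    eps = _ld_resample_probability(ld_r2)
    for idx in groups.values():
        latent = rng.random((n, 2)) < mafs[idx[0]]  # two latent haplotypes
        for k in idx:
            redraw = rng.random((n, 2)) < eps
            fresh = rng.random((n, 2)) < mafs[idx[0]]
            X[:, k] = np.where(redraw, fresh, latent).sum(axis=1)
    if not integer_dosages:
        X = np.clip(X + rng.normal(0.0, dosage_noise_sd, size=X.shape), 0.0, 2.0)

    gm = GenotypeMatrix(
        dosages=X,
        rsids=[e.rsid for e in panel],
        patient_ids=[f"P{i:05d}" for i in range(n)],
    )
    truth = SimulationTruth(
        planted_effects=np.zeros(j),
        intercept=0.0,
        target_prevalence=0.5,
        mafs=mafs,
        ld_r2=ld_r2,
        seed=seed,
    )
    return gm, truth


def solve_intercept(
    effects: np.ndarray, genotypes: GenotypeMatrix, target_prevalence: float
) -> float:
    """Intercept making the cohort-average logistic risk hit the target.

    The mean of expit(b0 + X @ effects) is strictly increasing in b0, so a
    bracketing root search converges to machine precision.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must lie in (0, 1)")
    effects = np.asarray(effects, dtype=float)
    if not np.all(np.isfinite(effects)):
        raise ValueError("effects must be finite")
    score = genotypes.dosages @ effects

    def gap(b0: float) -> float:
        return float(expit(b0 + score).mean() - target_prevalence)

    return float(brentq(gap, -60.0, 60.0, xtol=1e-10))


def simulate_outcome(genotypes: GenotypeMatrix, truth: SimulationTruth) -> np.ndarray:
    """Independent Bernoulli outcomes under the planted logistic model."""
    p = expit(truth.intercept + genotypes.dosages @ truth.planted_effects)
    rng = np.random.default_rng(truth.seed + 1)
    return (rng.random(genotypes.n) < p).astype(int)


@dataclass(frozen=True)
class ExclusionRates:
    """Rates at which exclusion-triggering features are planted on top of
    the outcome-consistent trajectories.  All default to zero so that label
    derivation round-trips the simulated outcomes exactly."""

    hemorrhoids: float = 0.0
    turb: float = 0.0
    antimuscarinic: float = 0.0
    cvd: float = 0.0
    baseline_prevalent: float = 0.0  # controls recoded/excluded per policy

    def __post_init__(self) -> None:
        for name in ("hemorrhoids", "turb", "antimuscarinic", "cvd", "baseline_prevalent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} rate must lie in [0, 1]")


def simulate_longitudinal(
    labels: np.ndarray,
    spec: EndpointSpec,
    rates: ExclusionRates = ExclusionRates(),
    seed: int = 0,
    patient_ids: Sequence[str] | None = None,
) -> list[ToxicityRecord]:
    """Grade trajectories realising the given binary outcomes for ``spec``.

    Cases get at least one follow-up grade at or above the threshold; plain
    controls stay below it at every visit.  A ``baseline_prevalent``
    fraction of controls start at the threshold and do not worsen (these
    are excluded or recoded depending on the endpoint's baseline policy).
    Exclusion flags are drawn independently at the configured rates.
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    T = spec.grade_threshold
    top = min(T + 2, 4)
    if patient_ids is None:
        patient_ids = [f"P{i:05d}" for i in range(len(labels))]

    records = []
    for pid, y in zip(patient_ids, labels):
        if y:
            base = 0
            m12 = int(rng.integers(T, top + 1))
            m24 = int(rng.integers(0, top + 1))  # second visit unconstrained
            if rng.random() < 0.5:
                m12, m24 = m24, m12
            if max(m12, m24) < T:  # guarantee the defining visit
                m12 = T
        elif rng.random() < rates.baseline_prevalent:
            base = T
            m12 = int(rng.integers(0, T + 1))
            m24 = int(rng.integers(0, T + 1))
        else:
            base = 0
            m12 = int(rng.integers(0, T))
            m24 = int(rng.integers(0, T))
        records.append(
            ToxicityRecord(
                patient_id=str(pid),
                grades={spec.name: (base, m12, m24)},
                hemorrhoids_baseline=bool(rng.random() < rates.hemorrhoids),
                turb=bool(rng.random() < rates.turb),
                antimuscarinic=bool(rng.random() < rates.antimuscarinic),
                collagen_vascular_disease=bool(rng.random() < rates.cvd),
            )
        )
    return records


def planted_scenario(
    panel: Sequence[SNPPanelEntry],
    n: int = 1400,
    prevalence: float = 0.10,
    n_planted: int = 5,
    or_range: tuple[float, float] = (2.5, 3.5),
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_r2: float = 0.9,
    seed: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray, SimulationTruth]:
    """Cohort with a handful of planted risk SNPs at literature-sized ORs.

    Planted SNPs are drawn from outside the LD block (so each carries an
    independent signal) with log-ORs uniform on the log of ``or_range``.
    """
    gm, truth = simulate_genotypes(
        n, panel, maf_range=maf_range, ld_r2=ld_r2, seed=seed
    )
    rng = np.random.default_rng(seed + 2)
    candidates = [k for k, e in enumerate(panel) if not e.ld_group]
    planted = rng.choice(candidates, size=n_planted, replace=False)
    betas = np.zeros(len(panel))
    betas[planted] = rng.uniform(np.log(or_range[0]), np.log(or_range[1]), n_planted)
    truth = replace(truth, planted_effects=betas, target_prevalence=prevalence)
    truth = replace(truth, intercept=solve_intercept(betas, gm, prevalence))
    y = simulate_outcome(gm, truth)
    return gm, y, truth


# --- genotype I/O --------------------------------------------------------

def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """TSV with patient_id rows and rsID columns."""
    df = pd.DataFrame(gm.dosages, columns=gm.rsids)
    df.insert(0, "patient_id", gm.patient_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%g")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    ids = df.pop("patient_id").tolist()
    return GenotypeMatrix(df.to_numpy(float), list(df.columns), ids)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCFv4.2 with a DS (dosage) FORMAT field, one pseudo-locus
    per panel SNP on a synthetic contig (positions are placeholders)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=panel,length=1000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Additive dosage">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.patient_ids)
            + "\n"
        )
        for k, rsid in enumerate(gm.rsids):
            calls = []
            for d in gm.dosages[:, k]:
                gt = "0/0" if d < 0.5 else ("0/1" if d < 1.5 else "1/1")
                calls.append(f"{gt}:{d:g}")
            fh.write(
                f"panel\t{1000 * (k + 1)}\t{rsid}\tA\tG\t.\tPASS\t.\tGT:DS\t"
                + "\t".join(calls)
                + "\n"
            )


def read_vcf_dosages(path: str | Path) -> GenotypeMatrix:
    """Read additive dosages from the DS field of a VCF (requires cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rsids, cols = [], []
    for variant in vcf:
        rsids.append(variant.ID)
        cols.append(np.asarray(variant.format("DS"), dtype=float).ravel())
    vcf.close()
    return GenotypeMatrix(np.column_stack(cols), rsids, ids)
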