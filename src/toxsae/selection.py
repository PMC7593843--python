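"""Minority-class SNP selection by autoencoder reconstruction error.

The procedure treats patients with toxicity ("unhealthy") as outliers
against the representation of patients without toxicity ("healthy"):

1. *sampling* — draw S healthy patients without replacement, where S is the
   number of unhealthy patients; they join all unhealthy patients in the
   test set, and the remaining healthy patients form the training set;
2. *training* — fit a fresh sparse autoencoder on the healthy-only
   training set;
3. *testing* — compute the per-patient, per-SNP squared reconstruction
   errors R (a 2S x J matrix) on the mixed test set;
4. repeat steps 1-3 for B replicates (default 50) to damp the sampling
   bias, keeping for each replicate the per-class per-SNP mean errors;
5. *identification* — average the class-mean vectors over replicates,
   form the per-SNP difference Delta = mean(unhealthy) - mean(healthy),
   and keep SNPs whose Delta lies strictly above the 70th / 80th / 90th /
   95th percentile of the J Delta values (top 30/20/10/5%).  Tier
   membership maps to a reported effect-size label: small (70th),
   moderate (80th), large (90th/95th).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dsae import (
    NetworkSpec,
    TrainedModel,
    build_network,
    reconstruction_error_matrix,
    scale_dosages,
    train_dsae,
)
from .panel import SNPPanelEntry

__all__ = [
    "ReplicateErrors",
    "DeltaProfile",
    "SelectionReport",
    "resample_split",
    "run_replicates",
    "delta_profile",
    "tier_select",
]

PERCENTILES = (70, 80, 90, 95)
EFFECT_LABELS = {70: "small", 80: "moderate", 90: "large", 95: "large"}


@dataclass
class ReplicateErrors:
    """Per-replicate class-mean reconstruction errors (B x 2 x J)."""

    unhealthy_means: np.ndarray  # B x J
    healthy_means: np.ndarray  # B x J
    replicate_seeds: list[int]
    minority_count: int

    def __post_init__(self) -> None:
        self.unhealthy_means = np.atleast_2d(np.asarray(self.unhealthy_means, float))
        self.healthy_means = np.atleast_2d(np.asarray(self.healthy_means, float))
        if self.unhealthy_means.shape != self.healthy_means.shape:
            raise ValueError("class-mean arrays must have matching shapes")
        if self.unhealthy_means.shape[0] < 1:
            raise ValueError("need at least one replicate")
        if (self.unhealthy_means < 0).any() or (self.healthy_means < 0).any():
            raise ValueError("mean reconstruction errors must be nonnegative")

    @property
    def b(self) -> int:
        return self.unhealthy_means.shape[0]


@dataclass
class DeltaProfile:
    """Replicate-averaged class means and their per-SNP difference."""

    delta: np.ndarray
    unhealthy_mean: np.ndarray
    healthy_mean: np.ndarray
    rsids: list[str]


@dataclass
class SelectionReport:
    """Per-SNP tier assignment with literature cross-reference."""

    table: pd.DataFrame  # index rsid
    thresholds: dict[int, float]  # percentile -> Delta cut

    def tier_members(self, percentile: int) -> list[str]:
        col = f"p{percentile}"
        return list(self.table.index[self.table[col]])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.reset_index()
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def resample_split(
    labels: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """One replicate's train/test split.

    Returns (train, test) index arrays: the training set is healthy-only;
    the test set is every unhealthy patient plus S healthy sampled without
    replacement, S = number of unhealthy patients.
    """
    labels = np.asarray(labels, dtype=int)
    healthy = np.flatnonzero(labels == 0)
    unhealthy = np.flatnonzero(labels == 1)
    if len(unhealthy) < 1:
        raise ValueError("no unhealthy patients")
    if len(unhealthy) >= len(healthy):
        raise ValueError(
            "method presumes class imbalance: need more healthy than "
            f"unhealthy patients (got {len(healthy)} vs {len(unhealthy)})"
        )
    rng = np.random.default_rng(seed)
    sampled = rng.choice(healthy, size=len(unhealthy), replace=False)
    train = np.setdiff1d(healthy, sampled)
    test = np.concatenate([unhealthy, np.sort(sampled)])
    return train, test


def _replicate_seed(master_seed: int, b: int) -> int:
    # counter-based derivation: independent, reproducible streams per replicate
    return int(np.random.SeedSequence([master_seed, b]).generate_state(1)[0] % (2**31))


def _default_trainer(spec: NetworkSpec, X_train: np.ndarray, seed: int) -> TrainedModel:
    model = build_network(spec, seed=seed)
    return train_dsae(model, X_train, seed=seed, record_trace=False)


def run_replicates(
    X: np.ndarray,
    labels: np.ndarray,
    network_spec: NetworkSpec,
    b: int = 50,
    master_seed: int = 0,
    trainer: Callable[[NetworkSpec, np.ndarray, int], TrainedModel] | None = None,
) -> ReplicateErrors:
    """Steps 1-4: B independent split/train/test replicates.

    ``X`` holds raw additive dosages; scaling to the network input
    convention happens here.  ``trainer`` may be replaced (e.g. by a stub
    returning a fixed model) to test the reduction independently of
    training.
    """
    if b < 1:
        raise ValueError("need at least one replicate")
    X = scale_dosages(X)
    labels = np.asarray(labels, dtype=int)
    if X.shape[0] != len(labels):
        raise ValueError("X rows and labels length differ")
    train_fn = trainer or _default_trainer
    s = int((labels == 1).sum())
    un_means, he_means, seeds = [], [], []
    for rep in range(b):
        seed = _replicate_seed(master_seed, rep)
        train_idx, test_idx = resample_split(labels, seed=seed)
        model = train_fn(network_spec, X[train_idx], seed)
        R = reconstruction_error_matrix(model, X[test_idx])
        test_labels = labels[test_idx]
        un_means.append(R[test_labels == 1].mean(axis=0))
        he_means.append(R[test_labels == 0].mean(axis=0))
        seeds.append(seed)
    return ReplicateErrors(
        unhealthy_means=np.array(un_means),
        healthy_means=np.array(he_means),
        replicate_seeds=seeds,
        minority_count=s,
    )


def delta_profile(rep: ReplicateErrors, rsids: Sequence[str]) -> DeltaProfile:
    """Average class means over replicates (equal weight) and difference."""
    un = rep.unhealthy_means.mean(axis=0)
    he = rep.healthy_means.mean(axis=0)
    if len(rsids) != un.shape[0]:
        raise ValueError("rsids length does not match the number of features")
    return DeltaProfile(delta=un - he, unhealthy_mean=un, healthy_mean=he, rsids=list(rsids))


def tier_select(
    profile: DeltaProfile,
    panel: Sequence[SNPPanelEntry] | None = None,
    endpoint: str | None = None,
    percentiles: Sequence[int] = PERCENTILES,
) -> SelectionReport:
    """Step 5: strict percentile thresholds on the Delta distribution.

    Thresholds use linear interpolation between order statistics; a SNP
    enters a tier when its Delta is strictly above the threshold, so tiers
    are nested by construction and a degenerate (constant) Delta selects
    nothing.
    """
    delta = np.asarray(profile.delta, dtype=float)
    if not np.all(np.isfinite(delta)):
        raise ValueError("Delta contains non-finite values")
    thresholds = {int(p): float(np.percentile(delta, p)) for p in percentiles}
    if np.ptp(delta) == 0:
        warnings.warn("constant Delta: all selection tiers are empty", stacklevel=2)

    table = pd.DataFrame(
        {"delta": delta}, index=pd.Index(profile.rsids, name="rsid")
    )
    for p, cut in thresholds.items():
        table[f"p{p}"] = delta > cut

    tier = np.full(len(delta), "none", dtype=object)
    label = np.full(len(delta), "none", dtype=object)
    for p in sorted(thresholds):  # ascending: highest tier wins
        hit = table[f"p{p}"].to_numpy()
        tier[hit] = f"p{p}"
        label[hit] = EFFECT_LABELS.get(p, "large")
    table["tier"] = tier
    table["effect_label"] = label

    if panel is not None:
        by_rsid = {e.rsid: e for e in panel}
        table["literature_endpoint"] = [
            by_rsid[r].endpoint if r in by_rsid else "" for r in table.index
        ]
        table["literature_OR"] = [
            by_rsid[r].literature_effect if r in by_rsid else np.nan
            for r in table.index
        ]
        table["identified"] = table["tier"] != "none"
        if endpoint is not None:
            table["identified_for_this_endpoint"] = table["identified"] & (
                table["literature_endpoint"] == endpoint
            )
    return SelectionReport(table=table, thresholds=thresholds)
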