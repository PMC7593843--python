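"""End-to-end pipeline: simulate/load -> label -> select -> compare.

A run is fully described by a YAML-serialisable :class:`PipelineConfig`;
all randomness derives from its single master seed, and a JSON manifest
(config + hash + seeds + versions) is written next to the outputs so any
run is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dsae import NetworkSpec
from .endpoints import (
    ENDPOINT_SPECS,
    EndpointLabels,
    derive_labels,
    format_prevalence,
    read_phenotypes,
    write_phenotypes,
)
from .panel import load_panel, panel_rsids
from .selection import (
    DeltaProfile,
    SelectionReport,
    delta_profile,
    run_replicates,
    tier_select,
)
from .simulate import (
    ExclusionRates,
    GenotypeMatrix,
    planted_scenario,
    read_genotypes,
    simulate_longitudinal,
    write_genotypes,
)
from .univariate import association_table, fit_panel


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class DataError(ValueError):
    """Inconsistent or missing input data."""


@dataclass
class SimulationBlock:
    n: int = 1400
    prevalence: float = 0.10
    n_planted: int = 5
    or_range: tuple[float, float] = (2.5, 3.5)
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_r2: float = 0.9
    exclusion_rates: dict[str, float] = field(default_factory=dict)


@dataclass
class PipelineConfig:
    endpoint: str = "rectal_bleeding"
    baseline_policy: str = "exclude"
    master_seed: int = 0
    b: int = 50
    percentiles: tuple[int, ...] = (70, 80, 90, 95)
    output_dir: str = "results"
    genotypes: str | None = None
    phenotypes: str | None = None
    panel: str | None = None
    network: dict[str, Any] = field(default_factory=dict)
    simulation: SimulationBlock | None = None
    figures: bool = True

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINT_SPECS:
            raise ConfigError(f"unknown endpoint {self.endpoint!r}")
        if self.simulation is None and (self.genotypes is None or self.phenotypes is None):
            raise ConfigError(
                "provide genotype and phenotype paths, or a simulation block"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim is not None:
            for key in ("or_range", "maf_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimulationBlock(**sim)
        if "percentiles" in raw:
            raw["percentiles"] = tuple(raw["percentiles"])
        try:
            return cls(simulation=sim, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["percentiles"] = list(self.percentiles)
        if self.simulation is not None:
            d["simulation"]["or_range"] = list(self.simulation.or_range)
            d["simulation"]["maf_range"] = list(self.simulation.maf_range)
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    labels: EndpointLabels
    profile: DeltaProfile
    selection: SelectionReport
    association: pd.DataFrame
    manifest: dict[str, Any]
    output_dir: Path


def _network_spec(j: int, overrides: dict[str, Any]) -> NetworkSpec:
    for key in ("encoder_widths", "decoder_widths", "encoder_activations",
                "decoder_activations"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    try:
        return NetworkSpec(input_width=j, **overrides)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid network settings: {exc}") from None


def align_genotypes(gm: GenotypeMatrix, labels: EndpointLabels) -> tuple[np.ndarray, np.ndarray]:
    """Rows of X for non-excluded patients, in label order."""
    binary = labels.binary()
    pos = {pid: i for i, pid in enumerate(gm.patient_ids)}
    missing = [pid for pid in binary.index if pid not in pos]
    if missing:
        raise DataError(
            "phenotype patients absent from genotype matrix: "
            + ", ".join(map(str, missing[:10]))
            + ("..." if len(missing) > 10 else "")
        )
    rows = [pos[pid] for pid in binary.index]
    return gm.dosages[rows], binary.to_numpy()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write TSVs, figures and the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = load_panel(config.panel)
    spec = ENDPOINT_SPECS[config.endpoint].with_policy(config.baseline_policy)

    if config.simulation is not None:
        sim = config.simulation
        gm, y, truth = planted_scenario(
            panel,
            n=sim.n,
            prevalence=sim.prevalence,
            n_planted=sim.n_planted,
            or_range=sim.or_range,
            maf_range=sim.maf_range,
            ld_r2=sim.ld_r2,
            seed=config.master_seed,
        )
        records = simulate_longitudinal(
            y,
            spec,
            rates=ExclusionRates(**sim.exclusion_rates),
            seed=config.master_seed + 1,
            patient_ids=gm.patient_ids,
        )
        write_genotypes(gm, outdir / "genotypes.tsv")
        write_phenotypes(records, outdir / "phenotypes.tsv")
        truth_info = {
            "planted_rsids": truth.planted_rsids(gm.rsids),
            "planted_log_or": [
                float(v) for v in truth.planted_effects[truth.planted_effects != 0]
            ],
            "intercept": truth.intercept,
        }
    else:
        for path in (config.genotypes, config.phenotypes):
            if not Path(path).exists():
                raise DataError(f"input file not found: {path}")
        gm = read_genotypes(config.genotypes)
        records = read_phenotypes(config.phenotypes)
        truth_info = None

    labels = derive_labels(records, spec)
    X, y_bin = align_genotypes(gm, labels)

    net = _network_spec(gm.j, dict(config.network))
    reps = run_replicates(X, y_bin, net, b=config.b, master_seed=config.master_seed)
    profile = delta_profile(reps, gm.rsids)
    selection = tier_select(
        profile, panel=panel, endpoint=config.endpoint,
        percentiles=config.percentiles,
    )
    assoc = association_table(fit_panel(X, y_bin, gm.rsids))

    selection.to_tsv(outdir / f"selection_{config.endpoint}.tsv")
    assoc.reset_index().to_csv(
        outdir / f"association_{config.endpoint}.tsv",
        sep="\t", index=False, float_format="%.6g",
    )
    pd.DataFrame(
        {"status": labels.status, "exclusion_reason": labels.exclusion_reason}
    ).reset_index().to_csv(outdir / f"labels_{config.endpoint}.tsv", sep="\t", index=False)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "endpoint": config.endpoint,
        "n_cases": labels.n_cases,
        "n_controls": labels.n_controls,
        "n_excluded": labels.n_excluded,
        "prevalence": format_prevalence(labels),
        "network_parameters": net.n_parameters,
        "replicate_seeds": reps.replicate_seeds,
        "simulation_truth": truth_info,
        "versions": {
            "toxsae": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / f"manifest_{config.endpoint}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )

    if config.figures:
        from .plots import render_selection_figure

        render_selection_figure(
            profile, selection, config.endpoint,
            outdir / f"selection_{config.endpoint}.png",
        )

    return PipelineResult(
        labels=labels,
        profile=profile,
        selection=selection,
        association=assoc,
        manifest=manifest,
        output_dir=outdir,
    )
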