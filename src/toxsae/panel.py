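"""Literature SNP panel for late radiotherapy-toxicity endpoints.

The packaged panel lists 43 SNPs previously associated with late rectal or
urinary toxicity after prostate radiotherapy (or with a composite
overall-toxicity score), each with the endpoint it was reported for and the
published effect size (odds ratio, or hazard ratio for a few survival-model
findings).  Six of the overall-toxicity SNPs are highly correlated in
European populations and are flagged as one linkage-disequilibrium group:
they represent a single association signal.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

ENDPOINT_NAMES = (
    "rectal_bleeding",
    "urinary_frequency",
    "decreased_stream",
    "haematuria",
    "nocturia",
    "overall_STAT",
)

PANEL_SIZE = 43


@dataclass(frozen=True)
class SNPPanelEntry:
    """One literature SNP: rsID, reported endpoint and published effect."""

    rsid: str
    endpoint: str
    literature_effect: float
    effect_is_hazard_ratio: bool = False
    literature_p: float | None = None
    ld_group: str | None = None
    reference_id: str = ""

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINT_NAMES:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if not (self.literature_effect > 0 and math.isfinite(self.literature_effect)):
            raise ValueError(
                f"{self.rsid}: literature effect must be a positive finite "
                f"number, got {self.literature_effect!r}"
            )


def _default_panel_path() -> Path:
    return Path(importlib.resources.files("toxsae").joinpath("data/snp_panel.tsv"))


def load_panel(source: str | Path | None = None) -> list[SNPPanelEntry]:
    """Load the SNP panel from a TSV file (packaged fixture by default).

    Expected columns: ``rsid, endpoint, effect, effect_type, p, ld_group,
    ref``; missing p-values and ungrouped SNPs are marked ``.``.

    Raises
    ------
    ValueError
        On duplicate rsIDs or a non-positive / unparseable effect.
    """
    path = _default_panel_path() if source is None else Path(source)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    dup = df["rsid"][df["rsid"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate rsid(s) in panel: {sorted(set(dup))}")
    entries = []
    for row in df.itertuples(index=False):
        try:
            effect = float(row.effect)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{row.rsid}: malformed effect {row.effect!r}") from exc
        entries.append(
            SNPPanelEntry(
                rsid=row.rsid,
                endpoint=row.endpoint,
                literature_effect=effect,
                effect_is_hazard_ratio=(row.effect_type == "HR"),
                literature_p=None if pd.isna(row.p) else float(row.p),
                ld_group=None if pd.isna(row.ld_group) else row.ld_group,
                reference_id=row.ref,
            )
        )
    return entries


def panel_rsids(panel: list[SNPPanelEntry]) -> list[str]:
    return [e.rsid for e in panel]


def panel_frame(panel: list[SNPPanelEntry]) -> pd.DataFrame:
    """Panel as a DataFrame indexed by rsid (reporting convenience)."""
    return pd.DataFrame(
        {
            "endpoint": [e.endpoint for e in panel],
            "effect": [e.literature_effect for e in panel],
            "effect_type": ["HR" if e.effect_is_hazard_ratio else "OR" for e in panel],
            "p": [e.literature_p for e in panel],
            "ld_group": [e.ld_group for e in panel],
            "ref": [e.reference_id for e in panel],
        },
        index=pd.Index(panel_rsids(panel), name="rsid"),
    )
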