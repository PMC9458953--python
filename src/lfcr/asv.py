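"""Synthetic ASV count tables with temperature-structured composition.

Each taxon carries a per-community baseline log-abundance and a
temperature sensitivity; sample proportions follow a softmax of
``baseline + sensitivity * (T - 30)``, so a positive sensitivity means the
taxon loses ground as the reactor cools.  Counts are drawn
Dirichlet-multinomial around those proportions, which reproduces the
overdispersion of real amplicon libraries; a single concentration scalar
controls how far replicate communities scatter from their expectation.

The default design sketches the four microenvironments of a sulphate
reducing channel reactor - carbon-fibre biofilm (CF), planktonic bulk
volume (PV), planktonic surface (PS) and the floating sulphur biofilm
(FSB) - with sulphate reducers declining and cold-tolerant sulphide
oxidisers/biofilm formers expanding as temperature drops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reactor import ConfigError

COMMUNITIES = ("CF", "PV", "PS", "FSB")


@dataclass(frozen=True)
class Taxon:
    """One amplicon sequence variant with its community response profile."""

    taxon_id: str
    taxonomy: str
    baseline: dict            # community -> baseline logit
    sensitivity: float = 0.0  # logit change per degC above 30


@dataclass(frozen=True)
class AsvDesign:
    taxa: tuple
    communities: tuple = COMMUNITIES
    read_depth: int = 35_000
    overdispersion: float = 200.0

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ConfigError("design needs at least one taxon")
        if self.read_depth <= 0:
            raise ConfigError("read_depth must be positive")
        if self.overdispersion <= 0:
            raise ConfigError("overdispersion must be positive")
        for taxon in self.taxa:
            missing = [c for c in self.communities if c not in taxon.baseline]
            if missing:
                raise ConfigError(f"taxon {taxon.taxon_id} lacks baselines for {missing}")


def _tax(genus: str, lineage: str) -> str:
    return f"Bacteria;{lineage};{genus}"


def default_design() -> AsvDesign:
    """A 16-taxon design emulating the reactor's four microenvironments.

    Sensitivities are balanced so each community's abundance-weighted mean
    is near zero: declines of sulphate reducers and fermenters are mirrored
    by gains of cold-adapted biofilm formers.
    """
    d = "Proteobacteria;Deltaproteobacteria;Desulfovibrionales;Desulfovibrionaceae"
    g = "Proteobacteria;Gammaproteobacteria"
    taxa = (
        Taxon("asv01", _tax("Desulfovibrio", d), dict(CF=3.6, PV=3.4, PS=2.6, FSB=0.8), 0.10),
        Taxon("asv02", _tax("Desulfomicrobium", d), dict(CF=2.9, PV=2.8, PS=2.0, FSB=0.6), 0.09),
        Taxon("asv03", _tax("Desulfarculus", "Proteobacteria;Deltaproteobacteria;Desulfarculales;Desulfarculaceae"),
              dict(CF=2.2, PV=1.2, PS=0.2, FSB=-1.0), 0.15),
        Taxon("asv04", _tax("Desulfocurvus", "Proteobacteria;Deltaproteobacteria;Desulfovibrionales;Desulfovibrionaceae"),
              dict(CF=2.0, PV=1.0, PS=0.1, FSB=-1.0), 0.15),
        Taxon("asv05", _tax("Desulfobacter", "Proteobacteria;Deltaproteobacteria;Desulfobacterales;Desulfobacteraceae"),
              dict(CF=0.4, PV=0.2, PS=-0.5, FSB=-1.5), -0.05),
        Taxon("asv06", _tax("Veillonella", "Firmicutes;Negativicutes;Veillonellales;Veillonellaceae"),
              dict(CF=2.6, PV=2.8, PS=1.8, FSB=0.0), 0.11),
        Taxon("asv07", _tax("Ruminococcaceae_uc", "Firmicutes;Clostridia;Oscillospirales;Ruminococcaceae"),
              dict(CF=1.4, PV=1.6, PS=0.8, FSB=-0.5), 0.05),
        Taxon("asv08", _tax("Synergistaceae_uc", "Synergistetes;Synergistia;Synergistales;Synergistaceae"),
              dict(CF=2.2, PV=2.4, PS=1.4, FSB=-0.2), 0.12),
        Taxon("asv09", _tax("Pseudomonas", f"{g};Pseudomonadales;Pseudomonadaceae"),
              dict(CF=0.2, PV=0.4, PS=1.2, FSB=2.0), -0.06),
        Taxon("asv10", _tax("Klebsiella", f"{g};Enterobacterales;Enterobacteriaceae"),
              dict(CF=0.0, PV=0.3, PS=0.3, FSB=0.2), -0.07),
        Taxon("asv11", _tax("Aeromonas", f"{g};Aeromonadales;Aeromonadaceae"),
              dict(CF=-0.2, PV=0.1, PS=0.2, FSB=0.2), -0.06),
        Taxon("asv12", _tax("Arcobacter", "Epsilonbacteraeota;Campylobacteria;Campylobacterales;Arcobacteraceae"),
              dict(CF=-0.5, PV=0.0, PS=1.0, FSB=1.8), -0.05),
        Taxon("asv13", _tax("Myroides", "Bacteroidetes;Flavobacteriia;Flavobacteriales;Flavobacteriaceae"),
              dict(CF=-1.0, PV=-0.5, PS=0.5, FSB=1.0), -0.08),
        Taxon("asv14", _tax("Paracoccus", "Proteobacteria;Alphaproteobacteria;Rhodobacterales;Rhodobacteraceae"),
              dict(CF=0.0, PV=0.2, PS=0.8, FSB=1.6), 0.02),
        Taxon("asv15", _tax("Rhizobium", "Proteobacteria;Alphaproteobacteria;Rhizobiales;Rhizobiaceae"),
              dict(CF=0.2, PV=0.1, PS=0.6, FSB=1.4), 0.02),
        Taxon("asv16", _tax("Pannonibacter", "Proteobacteria;Alphaproteobacteria;Rhizobiales;Stappiaceae"),
              dict(CF=-0.3, PV=-0.2, PS=0.4, FSB=1.2), 0.0),
    )
    return AsvDesign(taxa=taxa)


def expected_proportions(design: AsvDesign, community: str, temperature_c: float) -> np.ndarray:
    """Softmax expectation of taxon proportions for one community/temperature."""
    if community not in design.communities:
        raise ConfigError(f"unknown community {community!r}")
    logits = np.array([t.baseline[community] + t.sensitivity * (temperature_c - 30.0)
                       for t in design.taxa])
    logits -= logits.max()
    w = np.exp(logits)
    return w / w.sum()


def generate_asv_table(design: AsvDesign, temperatures, seed: int = 0) -> pd.DataFrame:
    """Dirichlet-multinomial ASV counts for every (community, temperature).

    Returns a DataFrame indexed by taxon id with a ``taxonomy`` column and
    one count column per sample named ``<community>_<temp>C``; column sums
    equal the read depth exactly.  Reproducible under the seed.
    """
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for community in design.communities:
        for temp in temperatures:
            p = expected_proportions(design, community, temp)
            if len(p) == 1:
                counts = np.array([design.read_depth])
            else:
                theta = rng.dirichlet(design.overdispersion * p)
                counts = rng.multinomial(design.read_depth, theta)
            data[f"{community}_{temp:g}C"] = counts
    table = pd.DataFrame(data, index=[t.taxon_id for t in design.taxa])
    table.insert(0, "taxonomy", [t.taxonomy for t in design.taxa])
    table.index.name = "asv_id"
    return table
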