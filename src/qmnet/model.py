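"""Domain types: compound records, target maps, gene-set collections, config.

These are plain dataclasses with validation in ``__post_init__``; heavier
machinery (graphs, screening results) lives in the modules that produce it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path

import yaml

from .errors import ConfigError, QmnetError
from .symbols import GeneSymbol

HERB_CODES = ("AR", "RR", "RRER", "CF", "PS", "OR", "DR", "PR")
"""Source-herb codes: Astragali Radix, Rehmanniae Radix, Rhei Radix et
Rhizoma, Carthami Flos, Persicae Semen, Ophiopogonis Radix, Dioscoreae
Rhizoma, Pseudostellariae Radix."""

COMPOUND_CLASSES = (
    "Glycosides",
    "Organic acid",
    "Flavonoids",
    "Saponins",
    "Anthraquinones",
)


class IonMode(str, Enum):
    """ESI adduct monitored in selected-ion-monitoring (SIM) acquisition."""

    M_PLUS_H = "M_PLUS_H"  # [M + H]+
    M_MINUS_H = "M_MINUS_H"  # [M - H]-
    M_PLUS_FORMATE = "M_PLUS_FORMATE"  # [M + HCOO]-


@dataclass(frozen=True)
class CompoundRecord:
    """One quantified component of the formulation.

    ``mz_monitored`` is the SIM monitoring ion's m/z as configured on the
    instrument (low-resolution), not an exact mass.
    """

    compound_id: str
    name: str
    rt_min: float
    ion_mode: IonMode
    mz_monitored: float
    herb_codes: tuple[str, ...]
    compound_class: str

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise QmnetError("compound_id must be non-empty")
        if self.rt_min <= 0:
            raise QmnetError(f"{self.compound_id}: rt_min must be > 0")
        if self.mz_monitored <= 0:
            raise QmnetError(f"{self.compound_id}: mz_monitored must be > 0")
        if not self.herb_codes:
            raise QmnetError(f"{self.compound_id}: herb_codes must be non-empty")
        if self.compound_class not in COMPOUND_CLASSES:
            raise QmnetError(
                f"{self.compound_id}: unknown compound class {self.compound_class!r}"
            )


@dataclass
class CompoundTargetMap:
    """Per-compound sets of target genes.

    ``entries`` preserves insertion order (meaningful for reporting);
    membership is set-semantic. ``recorded_degrees`` holds a degree column
    transcribed from the source table, kept only for cross-checking — all
    degrees used in computation are recomputed from the gene sets.
    """

    entries: dict[str, set[GeneSymbol]]
    provenance: str = "fixture"
    recorded_degrees: dict[str, int] = field(default_factory=dict)

    def union(self) -> set[GeneSymbol]:
        """Union of all per-compound gene sets."""
        out: set[GeneSymbol] = set()
        for genes in self.entries.values():
            out |= genes
        return out

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathway or GO-style annotation) with an optional
    explicit universe.

    ``sets`` maps set_id -> (display name, member genes). When ``universe``
    is None, enrichment uses the union of all member genes as the universe.
    """

    sets: dict[str, tuple[str, set[GeneSymbol]]]
    universe: set[GeneSymbol] | None = None

    def union(self) -> set[GeneSymbol]:
        out: set[GeneSymbol] = set()
        for _, genes in self.sets.values():
            out |= genes
        return out

    def restricted_to(self, genes: set[GeneSymbol]) -> "GeneSetCollection":
        """Collection with every set intersected with ``genes``; empty sets kept."""
        return GeneSetCollection(
            sets={
                sid: (name, members & genes)
                for sid, (name, members) in self.sets.items()
            },
            universe=self.universe,
        )

    def top_n(self, n: int) -> "GeneSetCollection":
        """First ``n`` sets in insertion order."""
        kept = dict(list(self.sets.items())[:n])
        return GeneSetCollection(sets=kept, universe=self.universe)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class PipelineConfig:
    """Run-level knobs for the pipeline.

    tanimoto_threshold
        Fingerprint-similarity cutoff for transferring targets from reference
        ligands; comparison is strict (similarity must exceed the threshold).
    degree_threshold_mode
        ``"computed_mean"`` uses the full network's mean degree 2E/N;
        ``"fixed"`` uses ``fixed_degree_threshold``.
    ppi_confidence
        STRING-style interaction-confidence cutoff; recorded as provenance
        metadata in outputs, never applied to score-free edge lists.
    """

    tanimoto_threshold: float = 0.80
    degree_threshold_mode: str = "computed_mean"
    fixed_degree_threshold: float = 0.0
    ppi_confidence: float = 0.9
    top_n_pathways: int = 20
    top_k_genes: int = 30
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tanimoto_threshold <= 1.0:
            raise ConfigError("tanimoto_threshold must be in [0, 1]")
        if self.degree_threshold_mode not in ("computed_mean", "fixed"):
            raise ConfigError(
                "degree_threshold_mode must be 'computed_mean' or 'fixed'"
            )
        if self.fixed_degree_threshold < 0:
            raise ConfigError("fixed_degree_threshold must be non-negative")
        if not 0.0 <= self.ppi_confidence <= 1.0:
            raise ConfigError("ppi_confidence must be in [0, 1]")
        if self.top_n_pathways <= 0:
            raise ConfigError("top_n_pathways must be positive")
        if self.top_k_genes <= 0:
            raise ConfigError("top_k_genes must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a flat YAML or JSON key-value document.

        Unknown keys are rejected so typos fail loudly.
        """
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
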