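"""Ligand-based target prediction and disease-gene intersection.

The screening stage emulates how structure-based platforms transfer targets:
a query compound inherits the annotated targets of every reference ligand
whose binary-fingerprint Tanimoto similarity strictly exceeds a threshold
(default 0.80). Predicted targets are then intersected per compound with a
disease gene set; compounds with at least one common gene are "active
components", the rest are excluded from downstream network analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .symbols import GeneSymbol


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary molecular fingerprint."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("fingerprint must be a non-empty 1-D bit vector")
        if not np.all((arr == 0) | (arr == 1)):
            raise ValueError("fingerprint entries must be 0 or 1")
        object.__setattr__(self, "bits", arr)

    @property
    def n_bits(self) -> int:
        return int(self.bits.size)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class ReferenceLigand:
    """A known ligand: fingerprint plus annotated target genes."""

    ligand_id: str
    fingerprint: Fingerprint
    targets: frozenset[GeneSymbol]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"ligand {self.ligand_id!r} has no annotated targets")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity |a AND b| / |a OR b| of two fingerprints.

    Symmetric, bounded in [0, 1], and 1.0 iff the fingerprints are identical
    (given at least one set bit). Undefined — and an error — when both
    fingerprints are all-zero.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        raise ValueError("Tanimoto similarity undefined for two all-zero fingerprints")
    return inter / union


def predict_targets(
    query: Fingerprint,
    library: list[ReferenceLigand],
    threshold: float = 0.80,
) -> set[GeneSymbol]:
    """Union of target sets over library ligands with similarity > threshold.

    The comparison is strictly greater-than; a ligand sitting exactly at the
    threshold contributes nothing.
    """
    if not library:
        raise ValueError("reference library is empty")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    out: set[GeneSymbol] = set()
    for ligand in library:
        if tanimoto(query, ligand.fingerprint) > threshold:
            out |= ligand.targets
    return out


@dataclass
class VennCounts:
    """Sizes of the compound-target set, the disease set, and their overlap."""

    n_compound_targets: int
    n_disease_genes: int
    n_common: int


@dataclass
class ScreenResult:
    """Outcome of intersecting per-compound targets with a disease gene set.

    ``active_compounds`` keeps the input order of the target map;
    ``common_targets`` holds the per-compound intersections (only for active
    compounds by definition of membership, though excluded compounds appear
    with empty sets for auditability).
    """

    compound_targets: "CompoundTargetMap"
    common_targets: "CompoundTargetMap"
    disease_genes: set[GeneSymbol]
    venn: VennCounts
    active_compounds: list[str] = field(default_factory=list)
    excluded_compounds: list[str] = field(default_factory=list)

    def common_union(self) -> set[GeneSymbol]:
        return self.common_targets.union()


def intersect_with_disease(
    targets: "CompoundTargetMap", disease: set[GeneSymbol]
) -> ScreenResult:
    """Per-compound intersection of predicted targets with a disease gene set.

    Compounds whose intersection is empty are excluded (they are not active
    components for this disease); the Venn ``n_common`` is the size of the
    union of per-compound common sets.
    """
    from .model import CompoundTargetMap  # local import avoids a cycle

    if not disease:
        warnings.warn(
            "empty disease gene set: every compound will be excluded", stacklevel=2
        )
    common: dict[str, set[GeneSymbol]] = {}
    active: list[str] = []
    excluded: list[str] = []
    for cid, genes in targets.entries.items():
        inter = genes & disease
        common[cid] = inter
        (active if inter else excluded).append(cid)
    common_map = CompoundTargetMap(entries=common, provenance=targets.provenance)
    return ScreenResult(
        compound_targets=targets,
        common_targets=common_map,
        disease_genes=set(disease),
        venn=VennCounts(
            n_compound_targets=len(targets.union()),
            n_disease_genes=len(disease),
            n_common=len(common_map.union()),
        ),
        active_compounds=active,
        excluded_compounds=excluded,
    )
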