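"""End-to-end drivers chaining the pipeline stages.

``run_reference_analysis`` executes the full offline reproduction of the
HXJTY/T2DM study: bundled component and target tables, synthetic disease
padding and pathway memberships, intersection, network assembly, and
fixed-threshold degree screening (the published network-average degree, 12,
is the default threshold in this profile).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import CompoundTargetMap, GeneSetCollection
from .network import (
    HeteroNetwork,
    MarkerSelection,
    build_network,
    compound_degrees,
    select_markers,
)
from .screening import Fingerprint, ReferenceLigand, ScreenResult, intersect_with_disease, predict_targets
from .synthetic import ReferenceProfile, generate_reference_profile


def screen_compounds(
    query_fingerprints: dict[str, Fingerprint],
    library: list[ReferenceLigand],
    threshold: float = 0.80,
) -> CompoundTargetMap:
    """Predict targets for every query compound by fingerprint screening."""
    entries = {
        cid: predict_targets(fp, library, threshold)
        for cid, fp in query_fingerprints.items()
    }
    return CompoundTargetMap(entries=entries, provenance="predicted")


@dataclass
class ReferenceAnalysis:
    """Everything the reference reproduction computes, in one place."""

    profile: ReferenceProfile
    screen: ScreenResult
    network: HeteroNetwork
    degrees: dict[str, int]
    selection: MarkerSelection

    def summary(self) -> dict:
        names = {c.compound_id: c.name for c in self.profile.compounds}
        herbs = {c.compound_id: list(c.herb_codes) for c in self.profile.compounds}
        return {
            "prescription": self.profile.prescription_name,
            "disease": self.profile.disease_name,
            "n_compounds": len(self.profile.compounds),
            "n_active_compounds": len(self.screen.active_compounds),
            "excluded_compounds": list(self.screen.excluded_compounds),
            "n_common_genes": self.screen.venn.n_common,
            "n_disease_genes": self.screen.venn.n_disease_genes,
            "n_network_nodes": self.network.n_nodes,
            "n_network_edges": self.network.n_edges,
            "node_type_counts": self.network.node_type_counts(),
            "degree_threshold": self.selection.threshold_used,
            "threshold_mode": self.selection.mode,
            "n_markers": len(self.selection.selected),
            "markers": [
                {
                    "compound_id": cid,
                    "name": names.get(cid, cid),
                    "degree": self.selection.per_compound_degree[cid],
                    "herbs": herbs.get(cid, []),
                }
                for cid in self.selection.selected
            ],
        }


def run_reference_analysis(
    seed: int = 0,
    degree_threshold_mode: str = "fixed",
    fixed_degree_threshold: float = 12,
    top_n_pathways: int = 20,
) -> ReferenceAnalysis:
    """Full offline reproduction run over the bundled study tables."""
    profile = generate_reference_profile(seed=seed)
    screen = intersect_with_disease(profile.predicted_targets, profile.disease_genes)
    pathways = profile.pathways.top_n(top_n_pathways)
    net = build_network(
        screen,
        pathways,
        prescription_name=profile.prescription_name,
        disease_name=profile.disease_name,
    )
    degrees = compound_degrees(net)
    selection = select_markers(
        degrees,
        threshold_mode=degree_threshold_mode,
        fixed_value=fixed_degree_threshold,
        net=net,
    )
    return ReferenceAnalysis(
        profile=profile,
        screen=screen,
        network=net,
        degrees=degrees,
        selection=selection,
    )


def run_analysis(
    predicted: CompoundTargetMap,
    disease_genes: set,
    pathways: GeneSetCollection,
    prescription_name: str = "prescription",
    disease_name: str = "disease",
    degree_threshold_mode: str = "computed_mean",
    fixed_degree_threshold: float | None = None,
    top_n_pathways: int = 20,
) -> tuple[ScreenResult, HeteroNetwork, dict, MarkerSelection]:
    """Generic chain: intersect -> network -> degrees -> marker screen.

    Pathway sets are restricted to the common gene set and truncated to the
    top-N before network assembly.
    """
    screen = intersect_with_disease(predicted, disease_genes)
    restricted = pathways.restricted_to(screen.common_union()).top_n(top_n_pathways)
    # drop pathway sets emptied by the restriction: they carry no edges
    restricted = GeneSetCollection(
        sets={sid: nm for sid, nm in restricted.sets.items() if nm[1]},
        universe=restricted.universe,
    )
    net = build_network(
        screen,
        restricted,
        prescription_name=prescription_name,
        disease_name=disease_name,
    )
    degrees = compound_degrees(net)
    selection = select_markers(
        degrees,
        threshold_mode=degree_threshold_mode,
        fixed_value=fixed_degree_threshold,
        net=net,
    )
    return screen, net, degrees, selection
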