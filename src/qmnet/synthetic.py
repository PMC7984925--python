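"""Synthetic study generator with planted, recoverable structure.

Every pipeline stage can be exercised offline: the generator emits a
compound table with internally consistent monitoring ions, a reference
ligand library engineered so that fingerprint screening at the default
threshold reconstructs each compound's intended target set, a disease gene
set with controlled per-compound overlap, and pathway annotations in which a
known subset of sets oversamples the common genes. The planted ground truth
(which compounds must be selected as markers, which sets are enriched, the
exact Venn counts) is returned alongside and recorded in ``truth.json``.

Default condition: 22 compounds of which 12 are planted markers (mirroring
the shape of the reference study), a 2000-gene universe, a 900-gene disease
set, markers carrying 30 disease-overlapping targets versus 3 for
non-markers, and 20 pathway sets of 20–60 genes with 2 planted enriched sets
at 3x the baseline overlap.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import GenerationError
from .model import (
    COMPOUND_CLASSES,
    HERB_CODES,
    CompoundRecord,
    CompoundTargetMap,
    GeneSetCollection,
    IonMode,
)
from .adducts import adduct_mz
from .screening import Fingerprint, ReferenceLigand, VennCounts, tanimoto
from .symbols import GeneSymbol


@dataclass
class StudyParams:
    """Knobs of the synthetic study (defaults are the standard condition)."""

    n_compounds: int = 22
    n_genes_universe: int = 2000
    n_disease_genes: int = 900
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (20, 60)
    marker_fraction: float = 12 / 22
    marker_target_count: int = 30
    nonmarker_target_count: int = 3
    decoy_target_count: int = 5
    n_planted_enriched: int = 2
    enrichment_effect: float = 3.0
    fingerprint_bits: int = 1024
    fingerprint_density: float = 0.3
    decoys_per_compound: int = 2
    seed: int = 1

    def validate(self) -> None:
        if min(self.n_compounds, self.n_genes_universe, self.n_disease_genes,
               self.n_pathways, self.fingerprint_bits) <= 0:
            raise GenerationError("all counts must be positive")
        if not 0.0 <= self.marker_fraction <= 1.0:
            raise GenerationError("marker_fraction must be in [0, 1]")
        if self.marker_target_count <= self.nonmarker_target_count:
            raise GenerationError(
                "marker_target_count must exceed nonmarker_target_count"
            )
        if self.marker_target_count > self.n_disease_genes:
            raise GenerationError("marker_target_count exceeds the disease set")
        if self.n_disease_genes > self.n_genes_universe:
            raise GenerationError("disease set larger than the universe")
        if self.decoy_target_count > self.n_genes_universe - self.n_disease_genes:
            raise GenerationError("not enough non-disease genes for decoy targets")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi <= self.n_genes_universe):
            raise GenerationError("invalid pathway_size_range")
        if self.n_planted_enriched > self.n_pathways:
            raise GenerationError("more planted enriched sets than pathways")
        if not 0.0 < self.fingerprint_density < 1.0:
            raise GenerationError("fingerprint_density must be in (0, 1)")


@dataclass
class SyntheticTruth:
    """Planted ground truth the pipeline must recover."""

    planted_markers: set[str]
    planted_enriched_sets: set[str]
    expected_venn: VennCounts
    expected_common: dict[str, set[GeneSymbol]]
    rng_seed: int
    generation_params: dict


@dataclass
class SyntheticStudy:
    """All generated inputs plus the ground truth."""

    params: StudyParams
    truth: SyntheticTruth
    compounds: list[CompoundRecord]
    neutral_masses: dict[str, float]
    predicted_targets: CompoundTargetMap
    disease_genes: set[GeneSymbol]
    query_fingerprints: dict[str, Fingerprint]
    library: list[ReferenceLigand] = field(default_factory=list)
    pathways: GeneSetCollection = field(default_factory=lambda: GeneSetCollection(sets={}))

    def write(self, out_dir: str | Path) -> None:
        """Emit every fixture in the formats the IO module reads.

        Identical params + seed produce byte-identical files.
        """
        from . import io as qio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        qio.write_compound_table(self.compounds, out / "compounds.tsv")
        with (out / "masses.tsv").open("w") as fh:
            fh.write("compound_id\tneutral_mass\n")
            for cid, m in self.neutral_masses.items():
                fh.write(f"{cid}\t{m:.4f}\n")
        qio.write_target_map(self.predicted_targets, out / "targets_predicted.tsv")
        qio.write_gene_list(self.disease_genes, out / "disease_genes.txt")
        qio.write_fingerprints(self.query_fingerprints, out / "fingerprints.tsv")
        qio.write_ligand_library(self.library, out / "ligand_library.tsv")
        qio.write_gmt(self.pathways, out / "pathways.gmt")
        truth = {
            "planted_markers": sorted(self.truth.planted_markers),
            "planted_enriched_sets": sorted(self.truth.planted_enriched_sets),
            "expected_venn": asdict(self.truth.expected_venn),
            "expected_common": {
                cid: sorted(genes)
                for cid, genes in sorted(self.truth.expected_common.items())
            },
            "rng_seed": self.truth.rng_seed,
            "generation_params": self.truth.generation_params,
        }
        qio.write_json(truth, out / "truth.json")


def _rng(seed: int, offset: int) -> np.random.Generator:
    # one deterministic stream per fixture family, derived by fixed offsets
    return np.random.default_rng(np.random.SeedSequence([seed, offset]))


def _sample(rng: np.random.Generator, pool: list, size: int) -> list:
    idx = rng.choice(len(pool), size=size, replace=False)
    return [pool[i] for i in sorted(idx)]


def _random_fp(rng: np.random.Generator, n_bits: int, density: float) -> Fingerprint:
    bits = (rng.random(n_bits) < density).astype(np.uint8)
    if bits.sum() == 0:
        bits[int(rng.integers(n_bits))] = 1
    return Fingerprint(bits)


def _perturb_above(
    rng: np.random.Generator, fp: Fingerprint, threshold: float
) -> Fingerprint:
    """Copy of ``fp`` with a few bits flipped, similarity kept > threshold."""
    flips = 2
    while True:
        bits = fp.bits.copy()
        pos = rng.choice(fp.n_bits, size=flips, replace=False)
        bits[pos] ^= 1
        cand = Fingerprint(bits)
        if tanimoto(fp, cand) > threshold:
            return cand
        flips = max(1, flips - 1)


def _perturb_below(
    rng: np.random.Generator, fp: Fingerprint, threshold: float
) -> Fingerprint:
    """Copy of ``fp`` with enough bit-flip noise to fall at or below the
    threshold — a near-miss decoy exercising the strict comparison."""
    n_flips = max(1, int(0.25 * fp.n_bits))
    while True:
        bits = fp.bits.copy()
        pos = rng.choice(fp.n_bits, size=n_flips, replace=False)
        bits[pos] ^= 1
        cand = Fingerprint(bits)
        if int(np.sum(bits)) > 0 and tanimoto(fp, cand) <= threshold:
            return cand
        n_flips = min(fp.n_bits, n_flips + 8)


def generate_study(params: StudyParams | None = None, *, seed: int | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study with planted structure."""
    params = params or StudyParams()
    if seed is not None:
        params = StudyParams(**{**asdict(params), "seed": seed})
    if isinstance(params.pathway_size_range, list):
        params.pathway_size_range = tuple(params.pathway_size_range)
    params.validate()
    seed = params.seed

    universe = [f"G{i:06d}" for i in range(1, params.n_genes_universe + 1)]
    rng_dis = _rng(seed, 1)
    disease = set(_sample(rng_dis, universe, params.n_disease_genes))
    non_disease = [g for g in universe if g not in disease]

    compound_ids = [f"C{i:02d}" for i in range(1, params.n_compounds + 1)]
    n_markers = round(params.marker_fraction * params.n_compounds)
    rng_mark = _rng(seed, 2)
    planted_markers = set(_sample(rng_mark, compound_ids, n_markers))

    # per-compound targets: disease-overlapping core + off-disease decoys
    rng_tgt = _rng(seed, 3)
    disease_sorted = sorted(disease)
    predicted: dict[str, set[str]] = {}
    expected_common: dict[str, set[str]] = {}
    for cid in compound_ids:
        n_core = (
            params.marker_target_count
            if cid in planted_markers
            else params.nonmarker_target_count
        )
        core = set(_sample(rng_tgt, disease_sorted, n_core))
        decoys = set(_sample(rng_tgt, non_disease, params.decoy_target_count))
        predicted[cid] = core | decoys
        expected_common[cid] = core

    # monitoring-ion table with self-consistent adduct arithmetic
    rng_ms = _rng(seed, 4)
    modes = list(IonMode)
    compounds: list[CompoundRecord] = []
    masses: dict[str, float] = {}
    for i, cid in enumerate(compound_ids):
        mode = modes[int(rng_ms.integers(len(modes)))]
        mass = round(float(rng_ms.uniform(150.0, 950.0)), 4)
        compounds.append(
            CompoundRecord(
                compound_id=cid,
                name=cid,
                rt_min=round(5.0 + 1.7 * i + float(rng_ms.uniform(0, 0.5)), 2),
                ion_mode=mode,
                mz_monitored=round(adduct_mz(mass, mode), 2),
                herb_codes=(HERB_CODES[int(rng_ms.integers(len(HERB_CODES)))],),
                compound_class=COMPOUND_CLASSES[int(rng_ms.integers(len(COMPOUND_CLASSES)))],
            )
        )
        masses[cid] = mass

    # fingerprints + reference library; screening at the default threshold
    # must reconstruct each compound's intended predicted set exactly
    threshold = 0.80
    rng_fp = _rng(seed, 5)
    query_fps: dict[str, Fingerprint] = {}
    for cid in compound_ids:
        while True:
            fp = _random_fp(rng_fp, params.fingerprint_bits, params.fingerprint_density)
            if all(tanimoto(fp, other) <= threshold for other in query_fps.values()):
                break
        query_fps[cid] = fp

    rng_lib = _rng(seed, 6)
    library: list[ReferenceLigand] = []
    for cid in compound_ids:
        targets = sorted(predicted[cid])
        half = max(1, len(targets) // 2)
        part_a, part_b = targets[:half], targets[half:] or targets[:1]
        library.append(
            ReferenceLigand(
                ligand_id=f"{cid}_ref_a",
                fingerprint=query_fps[cid],
                targets=frozenset(part_a),
            )
        )
        library.append(
            ReferenceLigand(
                ligand_id=f"{cid}_ref_b",
                fingerprint=_perturb_above(rng_lib, query_fps[cid], threshold),
                targets=frozenset(part_b),
            )
        )
        for d in range(params.decoys_per_compound):
            junk = frozenset(_sample(rng_lib, universe, 3))
            library.append(
                ReferenceLigand(
                    ligand_id=f"{cid}_decoy_{d}",
                    fingerprint=_perturb_below(rng_lib, query_fps[cid], threshold),
                    targets=junk,
                )
            )
    # guard: a ligand may only pass the threshold against its own compound
    for cid, fp in query_fps.items():
        for lig in library:
            own = lig.ligand_id.startswith(f"{cid}_ref")
            sim = tanimoto(fp, lig.fingerprint)
            if own and sim <= threshold:
                raise GenerationError("reference ligand fell below the threshold")
            if not own and not lig.ligand_id.startswith(f"{cid}_"):
                if sim > threshold:
                    raise GenerationError(
                        f"cross-compound ligand {lig.ligand_id} too similar to {cid}"
                    )

    # pathway annotation with planted enrichment
    rng_pw = _rng(seed, 7)
    common_pool = sorted(set().union(*expected_common.values()))
    set_ids = [f"P{i:02d}" for i in range(1, params.n_pathways + 1)]
    planted_sets = set(_sample(rng_pw, set_ids, params.n_planted_enriched))
    lo, hi = params.pathway_size_range
    sets: dict[str, tuple[str, set[str]]] = {}
    for sid in set_ids:
        size = int(rng_pw.integers(lo, hi + 1))
        if sid in planted_sets:
            baseline = size * len(common_pool) / params.n_genes_universe
            k_planted = int(
                min(size, len(common_pool), round(params.enrichment_effect * baseline))
            )
            members = set(_sample(rng_pw, common_pool, k_planted))
            rest_pool = [g for g in universe if g not in members]
            members |= set(_sample(rng_pw, rest_pool, size - k_planted))
        else:
            members = set(_sample(rng_pw, universe, size))
        sets[sid] = (f"synthetic pathway {sid}", members)
    pathways = GeneSetCollection(sets=sets)

    predicted_map = CompoundTargetMap(
        entries={cid: predicted[cid] for cid in compound_ids}, provenance="synthetic"
    )
    all_predicted = predicted_map.union()
    common_union = set().union(*expected_common.values())
    truth = SyntheticTruth(
        planted_markers=planted_markers,
        planted_enriched_sets=planted_sets,
        expected_venn=VennCounts(
            n_compound_targets=len(all_predicted),
            n_disease_genes=len(disease),
            n_common=len(common_union),
        ),
        expected_common=expected_common,
        rng_seed=seed,
        generation_params={
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(params).items()
            }
        },
    )
    return SyntheticStudy(
        params=params,
        truth=truth,
        compounds=compounds,
        neutral_masses=masses,
        predicted_targets=predicted_map,
        disease_genes=disease,
        query_fingerprints=query_fps,
        library=library,
        pathways=pathways,
    )


# ---------------------------------------------------------------------------
# reference-study profile

@dataclass
class ReferenceProfile:
    """The bundled study tables wired into runnable pipeline inputs.

    The component table and the 21 common target sets are transcriptions;
    the disease list and pathway memberships are synthetic stand-ins built
    to the published shape (969 disease genes; 20 pathway sets over the 125
    common genes with the published per-pathway gene counts), so the full
    analysis is executable offline. Acteoside — the one component with no
    disease-common target — carries synthetic off-disease predicted targets
    so the intersection stage excludes it, as in the original screen.
    """

    compounds: list
    predicted_targets: CompoundTargetMap
    disease_genes: set[GeneSymbol]
    pathways: GeneSetCollection
    prescription_name: str
    disease_name: str


def generate_reference_profile(seed: int = 0) -> ReferenceProfile:
    """Build the offline reference-reproduction inputs."""
    from . import reference

    compounds = reference.compound_records()
    common21 = reference.target_map()
    common_union = common21.union()

    # predicted map in component-table order; acteoside gets synthetic
    # targets disjoint from the disease list (its published common set is empty)
    acteoside_targets = {f"SYNT{i:03d}" for i in range(1, 9)}
    entries: dict[str, set[str]] = {}
    for rec in compounds:
        if rec.compound_id == "acteoside":
            entries[rec.compound_id] = set(acteoside_targets)
        else:
            entries[rec.compound_id] = set(common21.entries[rec.compound_id])
    predicted = CompoundTargetMap(
        entries=entries,
        provenance="fixture",
        recorded_degrees=dict(common21.recorded_degrees),
    )

    # synthetic disease list at the published size (969), containing the
    # 125 common genes and padded with synthetic tokens
    n_disease = 969
    padding = {f"D{i:04d}" for i in range(1, n_disease - len(common_union) + 1)}
    disease = common_union | padding

    # 20 pathway sets over the common genes at the published per-pathway counts
    pool = sorted(common_union)
    sets: dict[str, tuple[str, set[str]]] = {}
    from . import reference as ref

    for i, (pid, name, _p, count) in enumerate(ref.pathway_table()):
        rng = _rng(seed, 100 + i)
        sets[pid] = (name, set(_sample(rng, pool, count)))
    pathways = GeneSetCollection(sets=sets, universe=set(common_union))

    return ReferenceProfile(
        compounds=compounds,
        predicted_targets=predicted,
        disease_genes=disease,
        pathways=pathways,
        prescription_name=reference.PRESCRIPTION_NAME,
        disease_name=reference.DISEASE_NAME,
    )
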