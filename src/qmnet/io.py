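"""Readers and writers for every on-disk format the pipeline touches.

All tabular inputs are tab-separated text with a header row. Gene sets use
the standard GMT layout (set id, description, then member genes, one set per
line). Networks are exported as SIF (``source<TAB>relation<TAB>target``),
GraphML, or a typed edge TSV; GraphML round-trips node types and degrees.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import ParseError
from .model import CompoundRecord, CompoundTargetMap, GeneSetCollection, IonMode
from .network import HeteroNetwork
from .screening import Fingerprint
from .symbols import GeneSymbol, normalize_symbol, split_gene_field

# ---------------------------------------------------------------------------
# ion-mode dialect handling

#: Canonical spellings after stripping spaces, superscript markers and
#: unifying hyphen/minus glyphs.
_ION_MODE_CANON = {
    "[M+H]+": IonMode.M_PLUS_H,
    "[M-H]-": IonMode.M_MINUS_H,
    "[M+HCOO]-": IonMode.M_PLUS_FORMATE,
    "M_PLUS_H": IonMode.M_PLUS_H,
    "M_MINUS_H": IonMode.M_MINUS_H,
    "M_PLUS_FORMATE": IonMode.M_PLUS_FORMATE,
}

_DASH_VARIANTS = "−–—‐‑"  # minus sign, en/em dash, hyphens


def parse_ion_mode(token: str) -> IonMode:
    """Map an adduct label to :class:`IonMode`, tolerating typography.

    Published tables are not machine-stable: spacing inside the brackets,
    ASCII hyphen versus the Unicode minus sign, and superscript charge
    markers (``[M + HCOO]^-^``) all vary. Everything is normalized before
    lookup.
    """
    t = token.strip().replace("^", "")
    for dash in _DASH_VARIANTS:
        t = t.replace(dash, "-")
    t = re.sub(r"\s+", "", t).upper()
    try:
        return _ION_MODE_CANON[t]
    except KeyError:
        raise ParseError(f"unknown ion-mode token {token!r}") from None


_ION_MODE_LABEL = {
    IonMode.M_PLUS_H: "[M + H]+",
    IonMode.M_MINUS_H: "[M - H]-",
    IonMode.M_PLUS_FORMATE: "[M + HCOO]-",
}

# ---------------------------------------------------------------------------
# compound table

COMPOUND_TABLE_COLUMNS = (
    "compound_id",
    "name",
    "rt_min",
    "ion_mode",
    "mz",
    "herbs",
    "compound_class",
)


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a monitoring-ion compound table (TSV).

    Expected header columns: ``compound_id  name  rt_min  ion_mode  mz
    herbs  compound_class``; ``herbs`` is a comma-separated list of
    source-herb codes. Returns one record per data row.
    """
    path = Path(path)
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or set(COMPOUND_TABLE_COLUMNS) - set(
            reader.fieldnames
        ):
            raise ParseError(
                f"header must contain columns {COMPOUND_TABLE_COLUMNS}", str(path), 1
            )
        for lineno, row in enumerate(reader, start=2):
            cid = (row["compound_id"] or "").strip()
            if not cid:
                raise ParseError("empty compound_id", str(path), lineno)
            if cid in seen:
                raise ParseError(f"duplicate compound_id {cid!r}", str(path), lineno)
            seen.add(cid)
            try:
                rt = float(row["rt_min"])
                mz = float(row["mz"])
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric rt_min/mz for {cid!r}", str(path), lineno
                ) from None
            try:
                mode = parse_ion_mode(row["ion_mode"])
            except ParseError as exc:
                raise ParseError(str(exc), str(path), lineno) from None
            herbs = tuple(
                h.strip().upper() for h in row["herbs"].split(",") if h.strip()
            )
            records.append(
                CompoundRecord(
                    compound_id=cid,
                    name=row["name"].strip(),
                    rt_min=rt,
                    ion_mode=mode,
                    mz_monitored=mz,
                    herb_codes=herbs,
                    compound_class=row["compound_class"].strip(),
                )
            )
    return records


def write_compound_table(records: list[CompoundRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COMPOUND_TABLE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.compound_id,
                    r.name,
                    f"{r.rt_min:g}",
                    _ION_MODE_LABEL[r.ion_mode],
                    f"{r.mz_monitored:g}",
                    ", ".join(r.herb_codes),
                    r.compound_class,
                ]
            )


# ---------------------------------------------------------------------------
# compound -> target map

def read_target_map(path: str | Path, *, provenance: str = "fixture") -> CompoundTargetMap:
    """Read a per-compound target-gene table (TSV).

    Columns: ``compound_id``, optional ``degree``, and ``targets`` (a gene
    list delimited by ASCII or fullwidth commas). The degree column, when
    present, is retained as metadata and cross-checked against the
    recomputed set size — a mismatch warns (possible transcription error)
    but never fails. An empty gene list is accepted as an empty set, with a
    warning.
    """
    path = Path(path)
    entries: dict[str, set[GeneSymbol]] = {}
    recorded: dict[str, int] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "compound_id" not in reader.fieldnames or (
            "targets" not in reader.fieldnames
        ):
            raise ParseError(
                "header must contain 'compound_id' and 'targets'", str(path), 1
            )
        has_degree = "degree" in reader.fieldnames
        for lineno, row in enumerate(reader, start=2):
            cid = (row["compound_id"] or "").strip()
            if not cid:
                raise ParseError("empty compound_id", str(path), lineno)
            if cid in entries:
                raise ParseError(f"duplicate compound_id {cid!r}", str(path), lineno)
            field = row["targets"] or ""
            genes = set(split_gene_field(field, context=f"{path}:{lineno}"))
            if not genes:
                warnings.warn(
                    f"{path}:{lineno}: compound {cid!r} has an empty target list",
                    stacklevel=2,
                )
            entries[cid] = genes
            if has_degree and (row["degree"] or "").strip():
                try:
                    deg = int(row["degree"])
                except ValueError:
                    raise ParseError(
                        f"non-integer degree for {cid!r}", str(path), lineno
                    ) from None
                recorded[cid] = deg
                if deg != len(genes):
                    warnings.warn(
                        f"{path}:{lineno}: recorded degree {deg} for {cid!r} "
                        f"differs from recomputed set size {len(genes)}",
                        stacklevel=2,
                    )
    return CompoundTargetMap(entries=entries, provenance=provenance, recorded_degrees=recorded)


def write_target_map(tmap: CompoundTargetMap, path: str | Path) -> None:
    """Write a target map as TSV (genes sorted for determinism)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["compound_id", "degree", "targets"])
        for cid, genes in tmap.entries.items():
            writer.writerow([cid, len(genes), ", ".join(sorted(genes))])


# ---------------------------------------------------------------------------
# gene lists and GMT

def read_gene_list(path: str | Path) -> set[GeneSymbol]:
    """Read a plain-text gene list, one symbol per line; blank lines and
    ``#`` comments ignored."""
    out: set[GeneSymbol] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        out.add(normalize_symbol(token, context=f"{path}:{lineno}"))
    return out


def write_gene_list(genes: set[GeneSymbol], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format: ``set_id TAB description TAB gene...``."""
    sets: dict[str, tuple[str, set[GeneSymbol]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(
                "GMT line needs set_id, description and >=1 gene", str(path), lineno
            )
        sid, desc = parts[0].strip(), parts[1].strip()
        if sid in sets:
            raise ParseError(f"duplicate set_id {sid!r}", str(path), lineno)
        genes = {
            normalize_symbol(g, context=f"{path}:{lineno}")
            for g in parts[2:]
            if g.strip()
        }
        sets[sid] = (desc, genes)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([sid, name, *sorted(genes)])
        for sid, (name, genes) in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# fingerprints

def read_fingerprints(path: str | Path) -> dict[str, Fingerprint]:
    """Read a fingerprint TSV: ``compound_id TAB bitstring`` (0/1 characters)."""
    out: dict[str, Fingerprint] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ParseError("expected 'id<TAB>bitstring'", str(path), lineno)
            cid, bits = row[0].strip(), row[1].strip()
            if not set(bits) <= {"0", "1"}:
                raise ParseError(
                    f"bitstring for {cid!r} contains non-binary characters",
                    str(path),
                    lineno,
                )
            out[cid] = Fingerprint(np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0"))
    return out


def write_fingerprints(fps: dict[str, Fingerprint], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        for cid, fp in fps.items():
            fh.write(f"{cid}\t{''.join(map(str, fp.bits.tolist()))}\n")


def read_ligand_library(path: str | Path) -> list:
    """Read a reference-ligand library TSV: ``ligand_id TAB bitstring TAB
    comma-separated target genes``."""
    from .screening import ReferenceLigand

    library = []
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise ParseError(
                    "expected 'ligand_id<TAB>bitstring<TAB>targets'", str(path), lineno
                )
            lid, bits, targets = row[0].strip(), row[1].strip(), row[2]
            if not set(bits) <= {"0", "1"}:
                raise ParseError(
                    f"bitstring for {lid!r} contains non-binary characters",
                    str(path),
                    lineno,
                )
            fp = Fingerprint(np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0"))
            library.append(
                ReferenceLigand(
                    ligand_id=lid,
                    fingerprint=fp,
                    targets=frozenset(
                        split_gene_field(targets, context=f"{path}:{lineno}")
                    ),
                )
            )
    return library


def write_ligand_library(library: list, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        for lig in library:
            bits = "".join(map(str, lig.fingerprint.bits.tolist()))
            fh.write(f"{lig.ligand_id}\t{bits}\t{', '.join(sorted(lig.targets))}\n")


# ---------------------------------------------------------------------------
# PPI edge lists

def read_ppi_edges(path: str | Path) -> list[tuple[GeneSymbol, GeneSymbol]]:
    """Read a two- or three-column PPI edge TSV (third column, typically a
    confidence score, is ignored). Symbols are normalized; no deduplication
    happens here (see :func:`qmnet.network.ppi_summary`)."""
    edges: list[tuple[GeneSymbol, GeneSymbol]] = []
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].strip().lower() in ("protein1", "source", "gene1", "node1"):
                continue  # header row
            if len(row) < 2:
                raise ParseError("edge row needs two columns", str(path), lineno)
            ctx = f"{path}:{lineno}"
            edges.append(
                (
                    normalize_symbol(row[0], context=ctx),
                    normalize_symbol(row[1], context=ctx),
                )
            )
    return edges


# ---------------------------------------------------------------------------
# network export / import

def write_network(net: HeteroNetwork, path: str | Path, fmt: str = "graphml") -> None:
    """Export a heterogeneous network.

    ``sif``
        One edge per line: ``source<TAB>relation<TAB>target`` where relation
        is the edge type (e.g. ``compound-gene``).
    ``graphml``
        Full attribute round-trip: ``ntype`` on nodes, ``etype`` on edges,
        plus each node's degree.
    ``tsv``
        Same triple layout as SIF with a header row.
    """
    path = Path(path)
    if fmt == "sif" or fmt == "tsv":
        with path.open("w", newline="") as fh:
            if fmt == "tsv":
                fh.write("source\trelation\ttarget\n")
            for u, v, etype in sorted(net.edges()):
                # source carries the type named first in the relation
                if net.graph.nodes[u]["ntype"] != etype.split("-", 1)[0]:
                    u, v = v, u
                fh.write(f"{u}\t{etype}\t{v}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        for node, ntype in sorted(net.nodes()):
            g.add_node(node, ntype=ntype, degree=net.degree(node))
        for u, v, etype in sorted(net.edges()):
            g.add_edge(u, v, etype=etype)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str | Path, fmt: str = "graphml") -> HeteroNetwork:
    """Read a network written by :func:`write_network` (graphml or sif/tsv).

    SIF/TSV carry no explicit node-type declarations, so node types are
    inferred from the typed relations; GraphML restores them exactly.
    """
    path = Path(path)
    net = HeteroNetwork()
    if fmt == "graphml":
        g = nx.read_graphml(path)
        for node, data in g.nodes(data=True):
            net.add_node(str(node), data["ntype"])
        for u, v, data in g.edges(data=True):
            net.add_edge(str(u), str(v), data["etype"])
    elif fmt in ("sif", "tsv"):
        lines = Path(path).read_text().splitlines()
        if fmt == "tsv":
            lines = lines[1:]
        triples = []
        for lineno, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError("expected source<TAB>relation<TAB>target", str(path), lineno)
            triples.append((parts[0], parts[1], parts[2]))
        for u, etype, v in triples:
            src_t, dst_t = etype.split("-", 1)
            if not net.has_node(u):
                net.add_node(u, src_t)
            if not net.has_node(v):
                net.add_node(v, dst_t)
        for u, etype, v in triples:
            net.add_edge(u, v, etype)
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    return net


# ---------------------------------------------------------------------------
# JSON summaries

def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
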