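"""Circular fingerprints, Tanimoto similarity, and similarity networks.

Compounds are fingerprinted with extended-connectivity (Morgan) circular
substructures of radius 2 bonds — diameter 4, the ECFP_4 equivalent — kept
as sparse sets of hashed feature identifiers rather than folded bit vectors,
so Tanimoto similarity is computed on sets. Stereochemistry is ignored by
default. A folded 2048-bit mode is available for interoperability with
bit-vector tooling.

The similarity network connects two compounds when their Tanimoto similarity
strictly exceeds the cutoff (default 0.5 on a 0-1 scale, 1.0 meaning
identical fingerprints). Phenotype attributes map onto node colour
(white = fitness only / no acute activity, red = photosynthesis, blue =
motility/phototaxis, green = both acute phenotypes) and shape (circle =
fitness hit, diamond = not), matching the convention used for Cytoscape
visualisation of screen data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .acute import PhenotypeCall
from .fitness import FitnessResult

DEFAULT_RADIUS = 2
DEFAULT_CUTOFF = 0.5
FOLDED_SIZE = 2048

COLOR_WHITE = "white"
COLOR_RED = "red"
COLOR_BLUE = "blue"
COLOR_GREEN = "green"
SHAPE_CIRCLE = "circle"
SHAPE_DIAMOND = "diamond"


class ChemWarning(UserWarning):
    pass


@dataclass(frozen=True)
class Fingerprint:
    """Sparse circular fingerprint: the set of hashed substructure feature
    identifiers present in one compound."""

    compound_id: str
    features: frozenset[int]

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError(f"{self.compound_id}: fingerprint has no features")

    def __len__(self) -> int:
        return len(self.features)


def _generator(radius: int, folded: bool, use_chirality: bool):
    return rdFingerprintGenerator.GetMorganGenerator(
        radius=radius,
        includeChirality=use_chirality,
        fpSize=FOLDED_SIZE if folded else 2048,
    )


def compute_fingerprint(
    smiles: str,
    compound_id: str = "",
    radius: int = DEFAULT_RADIUS,
    folded: bool = False,
    use_chirality: bool = False,
) -> Fingerprint:
    """Circular fingerprint of one SMILES.

    Features are hashed identifiers of all atom environments of radius 0 to
    ``radius`` bonds using the standard connectivity invariants (element,
    degree, charge, H count, ring membership). ``folded=True`` folds the
    identifiers into 2048 bit positions. Raises ``ValueError``, naming the
    record, on unparseable SMILES.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(
            f"unparseable SMILES for {compound_id or 'compound'}: {smiles!r}"
        )
    gen = _generator(radius, folded, use_chirality)
    if folded:
        feats = frozenset(gen.GetFingerprint(mol).GetOnBits())
    else:
        feats = frozenset(gen.GetSparseCountFingerprint(mol).GetNonzeroElements())
    return Fingerprint(compound_id=compound_id or smiles, features=feats)


def fingerprint_library(
    records: Iterable, radius: int = DEFAULT_RADIUS, folded: bool = False
) -> list[Fingerprint]:
    """Fingerprint a list of CompoundRecord (or any objects with
    ``compound_id`` and ``smiles``)."""
    return [
        compute_fingerprint(r.smiles, r.compound_id, radius=radius, folded=folded)
        for r in records
    ]


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| between two feature sets; 1.0 means
    identical fingerprints."""
    if not a.features or not b.features:
        raise ValueError("tanimoto undefined for empty fingerprints")
    inter = len(a.features & b.features)
    union = len(a.features) + len(b.features) - inter
    return inter / union


def build_network(
    fps: Sequence[Fingerprint], cutoff: float = DEFAULT_CUTOFF
) -> nx.Graph:
    """Threshold similarity network: an edge joins two compounds iff their
    Tanimoto similarity is strictly greater than ``cutoff``.

    All compounds appear as nodes; isolated nodes (no neighbour above the
    cutoff) are retained and flagged with ``singleton=True`` — network views
    typically display only the connected subset.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    if len(fps) == 0:
        raise ValueError("need at least one fingerprint")
    ids = [fp.compound_id for fp in fps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids among fingerprints")
    g = nx.Graph()
    g.add_nodes_from(ids)
    for a, b in combinations(fps, 2):
        s = tanimoto(a, b)
        if s > cutoff:
            g.add_edge(a.compound_id, b.compound_id, similarity=s)
    for node in g.nodes:
        g.nodes[node]["singleton"] = g.degree[node] == 0
    return g


def phenotype_color(
    photosynthesis_active: bool, motility_active: bool
) -> str:
    if photosynthesis_active and motility_active:
        return COLOR_GREEN
    if photosynthesis_active:
        return COLOR_RED
    if motility_active:
        return COLOR_BLUE
    return COLOR_WHITE


def annotate_network(
    net: nx.Graph,
    fitness: Sequence[FitnessResult] = (),
    acute: Sequence[PhenotypeCall] = (),
) -> nx.Graph:
    """Attach phenotype attributes to every node, in place.

    Colour encodes acute activity (green both, red photosynthesis, blue
    motility/phototaxis, white neither); shape encodes fitness (circle = hit,
    diamond = not). Nodes absent from both attribute tables get missing
    attributes and a warning.
    """
    fit = {f.compound_id: f for f in fitness}
    ac = {c.compound_id: c for c in acute}
    unannotated = []
    for node in net.nodes:
        f = fit.get(node)
        c = ac.get(node)
        if f is None and c is None:
            unannotated.append(node)
            net.nodes[node]["color"] = ""
            net.nodes[node]["shape"] = ""
            net.nodes[node]["fitness_hit"] = ""
            continue
        is_hit = bool(f.is_hit) if f is not None else False
        photo = bool(c.photosynthesis_hit) if c is not None else False
        motil = c.motility_active if c is not None else False
        net.nodes[node]["fitness_hit"] = is_hit
        net.nodes[node]["shape"] = SHAPE_CIRCLE if is_hit else SHAPE_DIAMOND
        net.nodes[node]["color"] = phenotype_color(photo, motil)
        net.nodes[node]["photosynthesis_active"] = photo
        net.nodes[node]["motility_active"] = motil
    if unannotated:
        warnings.warn(
            f"{len(unannotated)} network node(s) missing from both attribute "
            f"tables: {', '.join(sorted(unannotated)[:10])}",
            ChemWarning,
            stacklevel=2,
        )
    return net


def cluster_summary(net: nx.Graph) -> pd.DataFrame:
    """Per connected component: size and percentage of nodes in each
    phenotype class (fitness, photosynthesis, motility). Classes overlap, so
    percentages need not sum to 100.
    """
    rows = []
    comps = sorted(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    for i, comp in enumerate(comps):
        nodes = [net.nodes[n] for n in comp]
        size = len(comp)

        def pct(key: str) -> float:
            return round(100.0 * sum(bool(n.get(key)) for n in nodes) / size, 1)

        rows.append(
            {
                "component": i,
                "size": size,
                "members": ";".join(sorted(comp)),
                "pct_fitness": pct("fitness_hit"),
                "pct_photosynthesis": pct("photosynthesis_active"),
                "pct_motility": pct("motility_active"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "component",
            "size",
            "members",
            "pct_fitness",
            "pct_photosynthesis",
            "pct_motility",
        ],
    )


def write_sif(net: nx.Graph, path: str | Path) -> None:
    """Simple interaction format: one ``idA pp idB`` line per edge plus bare
    lines for isolated nodes, loadable by graph visualisation tools."""
    lines = [f"{a}\tpp\t{b}" for a, b in sorted(map(sorted, net.edges()))]
    connected = {n for e in net.edges() for n in e}
    lines += [str(n) for n in sorted(set(net.nodes) - connected)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_node_attributes(net: nx.Graph, path: str | Path) -> None:
    rows = [
        {
            "compound_id": n,
            "color": d.get("color", ""),
            "shape": d.get("shape", ""),
            "fitness_hit": d.get("fitness_hit", ""),
            "singleton": d.get("singleton", ""),
        }
        for n, d in sorted(net.nodes(data=True))
    ]
    pd.DataFrame(
        rows, columns=["compound_id", "color", "shape", "fitness_hit", "singleton"]
    ).to_csv(path, index=False)


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    """GraphML export with attributes embedded (bools coerced to int: GraphML
    writers reject Python bools inconsistently across tools)."""
    g = net.copy()
    for _, d in g.nodes(data=True):
        for k, v in list(d.items()):
            if isinstance(v, bool):
                d[k] = int(v)
    nx.write_graphml(g, path)
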