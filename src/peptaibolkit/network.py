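"""GNPS-style molecular networking: modified cosine, graph, delta annotation.

Spectra of related peptides share fragments either directly or offset by the
precursor mass difference (one residue substitution shifts every fragment
above the substitution site by the same delta). The *modified cosine*
captures both: peaks may pair at equal m/z or at m/z offset by the precursor
delta, a greedy one-to-one matching maximizes the summed intensity products
of sqrt-transformed, L2-normalized intensities, and pairs of spectra whose
score and matched-peak count clear the thresholds become network edges.

Edge mass deltas are annotated against residue-mass arithmetic (e.g.
14.0157 = Ala<->Aib = Vxx<->Lxx, one CH2), which is how analog annotations
propagate from a seeded identification across a component.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .chem import Alphabet
from .spectra import Spectrum

__all__ = [
    "NetworkParams",
    "NetworkEdge",
    "MolecularNetwork",
    "modified_cosine",
    "build_network",
    "annotate_deltas",
    "components",
    "to_graphml",
    "edge_table",
]


@dataclass(frozen=True)
class NetworkParams:
    """Networking thresholds (defaults follow common GNPS practice for QTOF data)."""

    precursor_tol: float = 0.05
    fragment_tol: float = 0.5
    min_matched_peaks: int = 4
    min_cosine: float = 0.65
    sqrt_transform: bool = True

    def __post_init__(self):
        if self.precursor_tol <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 <= self.min_cosine <= 1:
            raise ValueError("min_cosine must be in [0, 1]")


def _weights(intensity: np.ndarray, sqrt_transform: bool) -> np.ndarray:
    w = np.sqrt(intensity) if sqrt_transform else intensity.astype(float)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    fragment_tol: float = 0.5,
    *,
    sqrt_transform: bool = True,
) -> tuple[float, int]:
    """Modified cosine similarity and matched-peak count between two spectra.

    Candidate pairs are peaks matching directly within ``fragment_tol`` or
    after shifting spectrum ``b``'s peaks by the precursor difference.
    A greedy one-to-one matching (pairs sorted by intensity product, ties by
    m/z) accumulates the score; each peak is used at most once. Returns a
    score in [0, 1]; empty spectra score 0.
    """
    if len(a) == 0 or len(b) == 0:
        return 0.0, 0
    wa = _weights(a.intensity, sqrt_transform)
    wb = _weights(b.intensity, sqrt_transform)
    shift = a.precursor_mz - b.precursor_mz

    pairs: list[tuple[float, float, float, int, int]] = []
    seen: set[tuple[int, int]] = set()
    for offset in (0.0, shift):
        for i, mza in enumerate(a.mz):
            for j, mzb in enumerate(b.mz):
                if (i, j) not in seen and abs(mza - (mzb + offset)) <= fragment_tol:
                    seen.add((i, j))
                    pairs.append((wa[i] * wb[j], float(mza), float(mzb), i, j))
    # Greedy maximal matching: best products first, deterministic tie-break.
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    matched = 0
    for product, _, _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += product
        matched += 1
    return min(float(score), 1.0), matched


@dataclass(frozen=True)
class NetworkEdge:
    id_a: str
    id_b: str
    cosine: float
    matched_peaks: int
    delta_mz: float
    delta_annotation: str = ""


@dataclass(frozen=True)
class MolecularNetwork:
    """Nodes (spectrum id, precursor m/z) and thresholded scored edges."""

    nodes: tuple[tuple[str, float], ...]
    edges: tuple[NetworkEdge, ...]
    params: NetworkParams = field(default_factory=NetworkParams)


def build_network(spectra: list[Spectrum], p: NetworkParams = NetworkParams()) -> MolecularNetwork:
    """Score all spectrum pairs and keep edges clearing both thresholds.

    Node and edge order is deterministic (sorted by spectrum id), so the
    result is invariant to input order. Spectrum ids must be unique.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    ordered = sorted(spectra, key=lambda s: s.id)
    ids = [s.id for s in ordered]
    if len(set(ids)) != len(ids):
        raise ValueError("spectrum ids must be unique for networking")
    nodes = tuple((s.id, float(s.precursor_mz)) for s in ordered)
    edges: list[NetworkEdge] = []
    for sa, sb in itertools.combinations(ordered, 2):
        cosine, matched = modified_cosine(
            sa, sb, p.fragment_tol, sqrt_transform=p.sqrt_transform
        )
        if cosine >= p.min_cosine and matched >= p.min_matched_peaks:
            edges.append(
                NetworkEdge(
                    id_a=sa.id,
                    id_b=sb.id,
                    cosine=round(cosine, 6),
                    matched_peaks=matched,
                    delta_mz=abs(sa.precursor_mz - sb.precursor_mz),
                )
            )
    return MolecularNetwork(nodes=nodes, edges=tuple(edges), params=p)


def _delta_table(alphabet: Alphabet) -> list[tuple[float, str]]:
    """All pairwise residue and amino-alcohol mass differences, labeled."""
    out: list[tuple[float, str]] = []
    residues = sorted(alphabet.residues.items())
    for (ca, ra), (cb, rb) in itertools.combinations(residues, 2):
        out.append((abs(ra.monoisotopic_mass - rb.monoisotopic_mass), f"{ca}↔{cb}"))
    alcohols = sorted(alphabet.amino_alcohols.items())
    for (ca, aa), (cb, ab) in itertools.combinations(alcohols, 2):
        out.append((abs(aa.neutral_loss_mass - ab.neutral_loss_mass), f"{ca}↔{cb}"))
    return out


def annotate_deltas(
    net: MolecularNetwork, alphabet: Alphabet | None = None, tol: float | None = None
) -> MolecularNetwork:
    """Label edge precursor deltas that match residue-substitution masses.

    A delta matching several substitutions (CH2 fits both Ala<->Aib and
    Vxx<->Lxx) lists all of them joined by ' or '; anything unexplained is
    labeled 'unassigned'.
    """
    alphabet = alphabet or Alphabet.default()
    tol = net.params.precursor_tol if tol is None else tol
    table = _delta_table(alphabet)
    new_edges = []
    for edge in net.edges:
        labels = sorted(label for mass, label in table if abs(edge.delta_mz - mass) <= tol)
        annotation = " or ".join(labels) if labels else "unassigned"
        new_edges.append(replace(edge, delta_annotation=annotation))
    return MolecularNetwork(nodes=net.nodes, edges=tuple(new_edges), params=net.params)


def _graph(net: MolecularNetwork) -> nx.Graph:
    g = nx.Graph()
    for node_id, precursor in net.nodes:
        g.add_node(node_id, precursor_mz=precursor)
    for e in net.edges:
        g.add_edge(
            e.id_a,
            e.id_b,
            cosine=e.cosine,
            matched_peaks=e.matched_peaks,
            delta_mz=e.delta_mz,
            delta_annotation=e.delta_annotation,
        )
    return g


def components(net: MolecularNetwork) -> list[set[str]]:
    """Connected components, largest first, ties by smallest member id."""
    if not net.nodes:
        return []
    comps = list(nx.connected_components(_graph(net)))
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def to_graphml(net: MolecularNetwork, path) -> None:
    nx.write_graphml(_graph(net), str(path))


def edge_table(net: MolecularNetwork) -> list[dict]:
    """Edge list as records for TSV export."""
    return [
        {
            "id_a": e.id_a,
            "id_b": e.id_b,
            "cosine": e.cosine,
            "matched_peaks": e.matched_peaks,
            "delta_mz": round(e.delta_mz, 4),
            "delta_annotation": e.delta_annotation,
        }
        for e in net.edges
    ]
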