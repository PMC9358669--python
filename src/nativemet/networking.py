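"""Molecular networking: modified-cosine MS/MS similarity plus typed
binding edges.

The modified cosine allows a fragment in spectrum A to match a fragment in
B either at (nearly) equal m/z or offset by the precursor mass difference,
so structural analogs differing by one residue still score highly.
Intensities are square-root transformed and L2-normalized before scoring
(the usual molecular-networking convention), fragments are paired
one-to-one greedily by decreasing intensity product, and the score is the
sum of paired normalized-intensity products -- 1.0 for identical spectra.

The network itself holds metabolite features as nodes joined by ``msms``
edges above a score threshold (capped at each node's top-k partners) and
one protein node per target joined to its binders by ``binding`` edges
from the matching stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from nativemet.features import Feature
from nativemet.io import Spectrum
from nativemet.matching import ComplexMatch

__all__ = ["MolecularNetwork", "modified_cosine", "build_network"]

DEFAULT_FRAG_TOL = 0.02  # Da
DEFAULT_SCORE_THRESHOLD = 0.7
DEFAULT_MIN_MATCHED = 6
DEFAULT_TOP_K = 10


def _normalize(intensity: np.ndarray) -> np.ndarray:
    w = np.sqrt(np.clip(intensity, 0, None))
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def _canonical_order(a: Spectrum, b: Spectrum) -> tuple[Spectrum, Spectrum]:
    """Deterministic argument order so the score is exactly symmetric."""
    ka = (a.precursor[0] if a.precursor else 0.0, a.n_peaks, tuple(a.mz))
    kb = (b.precursor[0] if b.precursor else 0.0, b.n_peaks, tuple(b.mz))
    return (a, b) if ka <= kb else (b, a)


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    frag_tol: float = DEFAULT_FRAG_TOL,
    min_matched: int = DEFAULT_MIN_MATCHED,
    exact: bool = False,
) -> tuple[float, int]:
    """Modified-cosine similarity of two MS2 spectra.

    Returns ``(score in [0, 1], n_matched)``; the score is reported as 0
    when fewer than ``min_matched`` fragment pairs align.  ``exact=True``
    replaces the greedy one-to-one pairing with an optimal assignment
    (small spectra only; the greedy score is a documented lower bound).
    """
    a, b = _canonical_order(a, b)
    if a.n_peaks == 0 or b.n_peaks == 0:
        return 0.0, 0
    wa = _normalize(a.intensity)
    wb = _normalize(b.intensity)
    shift = 0.0
    if a.precursor is not None and b.precursor is not None:
        shift = a.precursor[0] - b.precursor[0]

    pairs = []  # (product, i, j)
    for i in range(a.n_peaks):
        for j in range(b.n_peaks):
            d = a.mz[i] - b.mz[j]
            if abs(d) <= frag_tol or abs(d - shift) <= frag_tol:
                prod = wa[i] * wb[j]
                if prod > 0:
                    pairs.append((prod, i, j))
    if not pairs:
        return 0.0, 0

    if exact:
        from scipy.optimize import linear_sum_assignment

        cost = np.zeros((a.n_peaks, b.n_peaks))
        for prod, i, j in pairs:
            cost[i, j] = -prod
        rows, cols = linear_sum_assignment(cost)
        chosen = [(-cost[i, j], i, j) for i, j in zip(rows, cols) if cost[i, j] < 0]
    else:
        pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        chosen = []
        for prod, i, j in pairs:
            if i in used_a or j in used_b:
                continue
            chosen.append((prod, i, j))
            used_a.add(i)
            used_b.add(j)

    n_matched = len(chosen)
    score = float(min(sum(p for p, _, _ in chosen), 1.0))
    if n_matched < min_matched:
        return 0.0, n_matched
    return score, n_matched


@dataclass
class MolecularNetwork:
    """Typed molecular network over metabolite features and protein nodes."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def edges_of_type(self, edge_type: str) -> list[tuple]:
        return [
            (u, v, d)
            for u, v, d in self.graph.edges(data=True)
            if d.get("type") == edge_type
        ]

    def components(self) -> list[set]:
        """Connected components over msms edges only (ligand families)."""
        sub = nx.Graph()
        sub.add_nodes_from(
            n for n, d in self.graph.nodes(data=True) if d.get("kind") == "metabolite"
        )
        for u, v, d in self.edges_of_type("msms"):
            sub.add_edge(u, v)
        return [set(c) for c in nx.connected_components(sub)]


def _representative_spectrum(
    feature: Feature, spectra: dict[str, Spectrum]
) -> Spectrum | None:
    """Highest-TIC MS2 spectrum linked to a feature."""
    best = None
    for sid in feature.msms_scan_ids:
        s = spectra.get(sid)
        if s is not None and (best is None or s.tic > best.tic):
            best = s
    return best


def build_network(
    features: list[Feature],
    spectra: dict[str, Spectrum],
    matches: list[ComplexMatch] | None = None,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    min_matched: int = DEFAULT_MIN_MATCHED,
    top_k: int = DEFAULT_TOP_K,
    frag_tol: float = DEFAULT_FRAG_TOL,
    protein_node: str = "protein",
    apo_mass: float | None = None,
) -> MolecularNetwork:
    """Assemble the combined similarity / binding network.

    msms edges require score >= ``score_threshold`` and at least
    ``min_matched`` aligned fragments, and survive only if ranked within
    both endpoints' ``top_k`` highest-scoring partners (ties broken by
    lower node id).  Every ComplexMatch adds one binding edge between the
    protein node and the matched metabolite feature.
    """
    net = MolecularNetwork()
    g = net.graph
    for f in features:
        if f.kind != "metabolite":
            continue
        g.add_node(
            f.id,
            kind="metabolite",
            mz=float(f.mass_value),
            rt=float(f.rt_apex),
            area=float(f.area),
        )

    met = sorted((f for f in features if f.kind == "metabolite"), key=lambda f: f.id)
    reps = {f.id: _representative_spectrum(f, spectra) for f in met}
    scored = []
    for i in range(len(met)):
        for j in range(i + 1, len(met)):
            sa, sb = reps[met[i].id], reps[met[j].id]
            if sa is None or sb is None:
                continue
            score, n = modified_cosine(sa, sb, frag_tol=frag_tol, min_matched=min_matched)
            if score >= score_threshold and n >= min_matched:
                scored.append((met[i].id, met[j].id, score, n))

    # top-k mutual filter with deterministic tie-break by partner id.
    ranked: dict[str, list[tuple[float, str]]] = {}
    for u, v, score, _ in scored:
        ranked.setdefault(u, []).append((score, v))
        ranked.setdefault(v, []).append((score, u))
    keep: dict[str, set[str]] = {}
    for node, partners in ranked.items():
        partners.sort(key=lambda p: (-p[0], p[1]))
        keep[node] = {v for _, v in partners[:top_k]}
    for u, v, score, n in scored:
        if v in keep.get(u, set()) and u in keep.get(v, set()):
            g.add_edge(u, v, type="msms", score=float(score), n_matched=int(n))

    if matches:
        g.add_node(
            protein_node,
            kind="protein",
            mass=float(apo_mass) if apo_mass is not None else 0.0,
        )
        for m in matches:
            if m.metabolite_feature_id not in g:
                continue
            existing = g.get_edge_data(protein_node, m.metabolite_feature_id)
            if existing is not None and abs(existing["mass_error"]) <= abs(m.mass_error):
                continue
            g.add_edge(
                protein_node,
                m.metabolite_feature_id,
                type="binding",
                score=float(m.coelution),
                delta_mass=float(m.delta_mass),
                mass_error=float(m.mass_error),
                stoichiometry=int(m.stoichiometry),
            )
    return net
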