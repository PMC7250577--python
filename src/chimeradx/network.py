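"""Per-domain sequence similarity networks.

Nodes are sequences; an undirected edge joins two sequences whose pairwise
percent identity (on a global alignment) reaches the threshold, 30% by
default — the classic cut at which protein domains of common ancestry
still connect while unrelated families fall apart.  The raw alignment
score is stored on every edge so score-based thresholds remain possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .seqcore import TaxLabeledSequence, global_align, percent_identity


@dataclass
class SimilarityNetwork:
    graph: nx.Graph
    threshold: float

    @property
    def nodes(self):
        return dict(self.graph.nodes(data=True))

    @property
    def edges(self):
        return [
            (u, v, d["percent_identity"], d["score"])
            for u, v, d in sorted(self.graph.edges(data=True))
        ]

    def write_edge_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("id1\tid2\tpct_id\tscore\n")
            for u, v, pid, score in self.edges:
                fh.write(f"{u}\t{v}\t{pid:.4f}\t{score:.1f}\n")

    def write_graphml(self, path):
        nx.write_graphml(self.graph, path)


def build_network(seqs: list[TaxLabeledSequence],
                  identity_threshold: float = 0.30,
                  local: bool = False,
                  gap_open: float = 40.0,
                  gap_extend: float = 4.0) -> SimilarityNetwork:
    """All-vs-all identity network at the given threshold.

    Node and edge order are canonical (sorted ids) so the network is
    invariant to input order.  Gap penalties are deliberately stiff: domain
    families compared here are indel-poor, and permissive gaps let the
    aligner cherry-pick matching columns between *unrelated* sequences of
    unequal length, inflating their apparent identity well above chance.
    ``local=True`` computes identity on the best local segment pair
    instead of the global alignment.
    """
    seqs = sorted(seqs, key=lambda r: r.id)
    ids = [r.id for r in seqs]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids")
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    graph = nx.Graph()
    for rec in seqs:
        graph.add_node(rec.id, domain_of_life=rec.domain_of_life,
                       category=rec.category)
    for i, a in enumerate(seqs):
        for b in seqs[i + 1:]:
            if local:
                pid, score = _local_identity(a.residues, b.residues)
            else:
                pair, score = global_align(a.residues, b.residues,
                                           gap_open=gap_open,
                                           gap_extend=gap_extend)
                pid = percent_identity(pair)
            if pid >= identity_threshold:
                graph.add_edge(a.id, b.id, percent_identity=float(pid),
                               score=float(score))
    return SimilarityNetwork(graph, identity_threshold)


def _local_identity(a: str, b: str):
    from .profile_search import score_profile_local
    from .seqcore import Alignment
    from .profile_search import build_profile

    prof = build_profile(Alignment([("q", a)]), pseudocount_weight=1e-3)
    score, env = score_profile_local(prof, b)
    if env.empty:
        return 0.0, 0.0
    seg_a = a[env.profile_start - 1:env.profile_end]
    seg_b = b[env.target_start - 1:env.target_end]
    pair, _ = global_align(seg_a, seg_b)
    return percent_identity(pair), score


def connected_components(net: SimilarityNetwork) -> list[set]:
    """Components ordered by decreasing size, then lexicographic min id."""
    comps = [set(c) for c in nx.connected_components(net.graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def cross_taxon_affinity(net: SimilarityNetwork, focal_ids) -> dict:
    """Taxonomic affinity of a focal node set via its outgoing edges.

    Over edges with exactly one focal endpoint, returns the fraction per
    non-focal endpoint's domain of life (fractions sum to 1), or
    ``{"isolated": True}`` when the focal set has no outgoing edges.
    """
    focal = set(focal_ids)
    missing = focal - set(net.graph.nodes)
    if missing:
        raise ValueError(f"focal ids not in network: {sorted(missing)}")
    counts: dict[str, int] = {}
    for u, v in net.graph.edges:
        if (u in focal) == (v in focal):
            continue
        other = v if u in focal else u
        dom = net.graph.nodes[other]["domain_of_life"]
        counts[dom] = counts.get(dom, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {"isolated": True}
    return {dom: c / total for dom, c in sorted(counts.items())}
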