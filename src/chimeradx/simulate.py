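"""Seeded, ground-truthed synthetic scenarios for chimeric-gene diagnosis.

The generator emulates the inputs of a two-domain HGT study at desk scale:

* a eukaryote-restricted family for the N-terminal domain (domain A), with
  a small bacterial outgroup clade (the handful of prokaryotic relatives
  such a family typically has);
* a bacteria-dominated family for the C-terminal domain (domain B), with a
  small archaeal outgroup clade and a small eukaryotic subclade (the
  "distant eukaryotic relatives" that make eukaryote-monophyly constraints
  meaningful);
* a clade of fusion genes carrying domain A, a fast-evolving linker and
  domain B on one protein;
* unrelated background proteins drawn i.i.d. from the model's equilibrium
  frequencies.

In a ``chimera`` scenario the fusion clade's domain B descends from an
ancestor drawn *inside* the bacterial family tree (nested placement, the
HGT signature); in a ``null_vertical`` scenario it descends from the
eukaryote side (sister to the eukaryotic subclade), the vertical
alternative.  Domain A always evolves inside the eukaryote family.

Branch lengths are in expected substitutions per site.  Family trees are
Yule trees rescaled to fixed root-to-tip heights, chosen so that within a
family sequences stay well above the 30% network-identity threshold while
different families are unalignable (< 15% identity), and so that 60-residue
windows detect only same-clade relatives while whole-domain profiles also
reach the distant outgroup clades.

One global integer seed is split hierarchically; every stochastic step
documents its draw order via the named child seeds in ``_child_seeds``.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .seqcore import (
    Alignment,
    SequenceDatabase,
    TaxLabeledSequence,
    build_nr_database,
    longest_orf,
    progressive_msa,
    six_frame_translate,
    write_fasta,
    write_alignment_fasta,
    write_taxonomy_tsv,
)
from .substitution import AMINO_ACIDS, SubstitutionModel, lg_model

FUSION_ROOT_LABEL = "__fusion_root__"


# ---------------------------------------------------------------------------
# tree simulation


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0,
                       prefix: str = "T") -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_tips`` labelled extant tips.

    The tree is rooted and binary with ``n_tips - 1`` internal nodes and
    strictly positive branch lengths; identical arguments give identical
    Newick strings.
    """
    if n_tips < 2:
        raise ValueError("a Yule tree needs at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=float(birth_rate), death_rate=0.0,
        num_extant_tips=int(n_tips), rng=rng,
    )
    width = max(2, len(str(n_tips)))
    for k, leaf in enumerate(sorted(tree.leaf_node_iter(),
                                    key=lambda l: l.taxon.label), start=1):
        leaf.taxon.label = f"{prefix}{k:0{width}d}"
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length <= 0:
            edge.length = 1e-6
    return tree


def _tree_height(tree: dendropy.Tree) -> float:
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def scale_tree_height(tree: dendropy.Tree, height: float) -> dendropy.Tree:
    cur = _tree_height(tree)
    if cur <= 0:
        raise ValueError("tree has zero height")
    factor = height / cur
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree


def _single_tip_tree(label: str) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace([label])
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node.taxon = tns.get_taxon(label)
    return tree


def _join(subtrees_with_stems) -> dendropy.Tree:
    """New rooted tree whose root children are the given (tree, stem) pairs."""
    labels = []
    for sub, _ in subtrees_with_stems:
        labels.extend(l.taxon.label for l in sub.leaf_node_iter())
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    for sub, stem in subtrees_with_stems:
        sub = sub.clone(depth=1)
        child = sub.seed_node
        tree.seed_node.add_child(child)
        child.edge.length = stem
    tree.migrate_taxon_namespace(tns)
    return tree


def _graft(host: dendropy.Tree, guest: dendropy.Tree, stem: float,
           rng: np.random.Generator, internal_only: bool = False,
           attach_label: str | None = None) -> dendropy.Tree:
    """Attach ``guest`` onto a random edge of ``host`` with the given stem.

    With ``internal_only`` the attachment edge is drawn uniformly among
    edges leading to internal nodes, excluding the root's own child edges:
    the guest clade ends up properly nested within the host — with host
    subtrees both above and below it — never sister to (almost) all of it.
    """
    host = host.clone(depth=1)
    edges = [e for e in host.preorder_edge_iter()
             if e.head_node.parent_node is not None]
    if internal_only:
        internal = [e for e in edges if not e.head_node.is_leaf()
                    and e.tail_node.parent_node is not None]
        if not internal:
            internal = [e for e in edges if not e.head_node.is_leaf()]
        edges = internal or edges
    edge = edges[int(rng.integers(len(edges)))]
    frac = 0.25 + 0.5 * rng.random()
    head, tail = edge.head_node, edge.tail_node
    attach = dendropy.Node()
    if attach_label:
        attach.label = attach_label
    tail.remove_child(head)
    tail.add_child(attach)
    attach.edge.length = edge.length * frac
    attach.add_child(head)
    head.edge.length = edge.length * (1 - frac)
    guest = guest.clone(depth=1)
    attach.add_child(guest.seed_node)
    guest.seed_node.edge.length = stem
    labels = [l.taxon.label for l in host.leaf_node_iter()]
    host.migrate_taxon_namespace(dendropy.TaxonNamespace(labels))
    return host


# ---------------------------------------------------------------------------
# sequence evolution


def evolve_alignment(tree: dendropy.Tree, root_length: int,
                     model: SubstitutionModel, seed: int = 0,
                     rate_multiplier: float = 1.0,
                     return_internal: bool = False):
    """Evolve a gap-free alignment of length ``root_length`` down the tree.

    Sites are independent; each site draws one discrete-gamma rate category
    for the whole tree (the usual site-rate model).  With
    ``return_internal`` the sequences of *labelled* internal nodes are also
    returned (used to record ground-truth ancestral segments).
    """
    if root_length < 1:
        raise ValueError("root_length must be >= 1")
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise ValueError("tree is missing branch lengths")
    rng = np.random.default_rng(seed)
    pi = model.equilibrium_freqs
    cats = model.category_rates
    site_cat = rng.integers(len(cats), size=root_length)
    states = {id(tree.seed_node): rng.choice(20, size=root_length, p=pi)}
    internal = {}
    if tree.seed_node.label:
        internal[tree.seed_node.label] = states[id(tree.seed_node)]
    tips = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_states = states[id(node.parent_node)]
        t = max(node.edge.length, 0.0) * rate_multiplier
        child = np.empty(root_length, dtype=np.int64)
        for c, rate in enumerate(cats):
            sel = site_cat == c
            if not sel.any():
                continue
            p = model.transition_matrix(t * rate)
            cum = np.cumsum(p / p.sum(axis=1, keepdims=True), axis=1)
            u = rng.random(int(sel.sum()))
            drawn = (u[:, None] > cum[parent_states[sel]]).sum(axis=1)
            child[sel] = np.minimum(drawn, 19)
        states[id(node)] = child
        if node.is_leaf():
            tips[node.taxon.label] = child
        elif node.label:
            internal[node.label] = child
    rows = [(lab, "".join(AMINO_ACIDS[s] for s in tips[lab]))
            for lab in sorted(tips)]
    aln = Alignment(rows)
    if return_internal:
        named = {lab: "".join(AMINO_ACIDS[s] for s in seq)
                 for lab, seq in internal.items()}
        return aln, named
    return aln


# ---------------------------------------------------------------------------
# scenario configuration


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario."""

    n_eukaryote_taxa: int = 8
    n_bacteria_taxa: int = 8
    n_archaea_taxa: int = 2
    n_bacterial_familyA: int = 3
    n_eukaryote_familyB: int = 4
    domainA_length: int = 100
    domainB_length: int = 190
    linker_length_range: tuple = (30, 80)
    linker_rate_multiplier: float = 3.0
    fusion_clade_size: int = 4
    background_count: int = 12
    scenario_kind: str = "chimera"
    seed: int = 0
    # evolutionary depths (expected substitutions per site, root to tip);
    # stems are chosen so whole-domain profiles reach the outgroup clades
    # while 60-residue windows only see same-clade relatives
    family_tree_height: float = 0.4
    fusion_tree_height: float = 0.12
    outgroup_clade_height: float = 0.25
    euk_side_stem: float = 0.15
    prok_side_stem: float = 0.45
    familyA_outgroup_stem: float = 0.6
    archaea_stem: float = 0.45
    fusion_stem: float = 0.08
    # in the vertical (null) scenario the fusion domain B diverged from the
    # other eukaryotic members at the root of the family, hence a long stem
    null_fusion_stem: float = 2.8

    def __post_init__(self):
        counts = [self.n_eukaryote_taxa, self.n_bacteria_taxa,
                  self.n_archaea_taxa, self.n_bacterial_familyA,
                  self.n_eukaryote_familyB, self.fusion_clade_size,
                  self.background_count]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.scenario_kind not in ("chimera", "null_vertical"):
            raise ValueError(f"unknown scenario_kind {self.scenario_kind!r}")
        if self.fusion_clade_size < 2:
            raise ValueError("need a fusion clade of >= 2")
        if self.scenario_kind == "chimera":
            if self.n_bacteria_taxa < 2:
                raise ValueError("chimera scenario needs >= 2 bacterial taxa")
            if self.fusion_clade_size < 3:
                raise ValueError("chimera scenario needs a fusion clade of >= 3")
        if self.n_eukaryote_taxa < 2:
            raise ValueError("need >= 2 eukaryote taxa for the domain A family")
        lo, hi = self.linker_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid linker_length_range")
        if self.linker_rate_multiplier <= 0:
            raise ValueError("linker_rate_multiplier must be positive")
        if self.domainA_length < 1 or self.domainB_length < 1:
            raise ValueError("domain lengths must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must rediscover."""

    fusion_member_ids: list
    donor_taxon_domain: str
    true_trees: dict       # family name -> newick string
    taxonomy: dict         # id -> (domain_of_life, category)
    domain_spans: dict     # focal id -> {"domainA": (s, e), "linker": ..., "domainB": ...}
    fusion_root_segments: dict  # {"domainA": seq, "linker": seq, "domainB": seq}
    scenario_kind: str
    seed: int
    # pre-deletion (full-length) linker per fusion member, aligned 1:1 to the
    # root linker — lets per-column linker divergence be measured exactly
    full_linkers: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        d["taxonomy"] = {k: list(v) for k, v in self.taxonomy.items()}
        d["domain_spans"] = {
            k: {dk: list(dv) for dk, dv in v.items()}
            for k, v in self.domain_spans.items()
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["taxonomy"] = {k: tuple(v) for k, v in d["taxonomy"].items()}
        d["domain_spans"] = {
            k: {dk: tuple(dv) for dk, dv in v.items()}
            for k, v in d["domain_spans"].items()
        }
        return cls(**d)


@dataclass
class Scenario:
    """A generated scenario: database, transcripts, seeds and ground truth."""

    database: SequenceDatabase
    taxonomy: dict
    transcripts: list            # [(id, nucleotide sequence)]
    seed_alignment_A: Alignment
    seed_alignment_B: Alignment
    ground_truth: GroundTruth
    config: ScenarioConfig

    def write_to_dir(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "proteins.fasta",
                    [(r.id, r.residues) for r in self.database])
        write_taxonomy_tsv(outdir / "taxonomy.tsv", self.taxonomy)
        write_fasta(outdir / "transcripts.fasta", self.transcripts)
        write_alignment_fasta(outdir / "seed_domainA.afa", self.seed_alignment_A)
        write_alignment_fasta(outdir / "seed_domainB.afa", self.seed_alignment_B)
        (outdir / "ground_truth.json").write_text(self.ground_truth.to_json())
        for name, newick in self.ground_truth.true_trees.items():
            (outdir / f"true_tree_{name}.nwk").write_text(newick + "\n")


# ---------------------------------------------------------------------------
# scenario generation


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic hierarchical seed split (one master draw per stage)."""
    master = np.random.default_rng(int(seed))
    return [int(s) for s in master.integers(2 ** 31, size=n)]


_CODONS = {}


def _codon_table():
    if not _CODONS:
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[1]
        for codon, aa in table.forward_table.items():
            _CODONS.setdefault(aa, []).append(codon)
        for aa in _CODONS:
            _CODONS[aa].sort()
        _CODONS["*"] = sorted(table.stop_codons)
    return _CODONS


def _random_protein(rng, length, pi):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=pi))


def _flanked(rng, segment, pi, lo=5, hi=20):
    n1 = int(rng.integers(lo, hi + 1))
    n2 = int(rng.integers(lo, hi + 1))
    return (_random_protein(rng, n1, pi) + segment + _random_protein(rng, n2, pi),
            n1 + 1, n1 + len(segment))


def _coding_sequence(rng, protein):
    table = _codon_table()
    codons = [table[aa][int(rng.integers(len(table[aa])))] for aa in protein]
    codons.append(table["*"][int(rng.integers(3))])
    return "".join(codons)


def _transcript_for(rng, protein, max_tries=50):
    """Embed the CDS in random UTRs on a random strand; the longest ORF of
    the six-frame translation must recover the protein exactly."""
    for _ in range(max_tries):
        cds = _coding_sequence(rng, protein)
        utr5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(15, 61))))
        utr3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(15, 61))))
        nt = utr5 + cds + utr3
        if rng.random() < 0.5:
            from Bio.Seq import Seq

            nt = str(Seq(nt).reverse_complement())
        orf = longest_orf(six_frame_translate(nt))
        if orf.found and orf.sequence == protein:
            return nt
    raise RuntimeError("could not embed coding sequence without a longer ORF")


def generate_scenario(config: ScenarioConfig,
                      model: SubstitutionModel | None = None) -> Scenario:
    """Generate a full scenario under the given configuration.

    Returns the protein database (non-redundant), taxonomy, fusion-gene
    transcripts, seed alignments for both domains (built from the first
    two fusion members' true domain segments, playing the role of the
    initially known orthologs), and the ground truth.
    """
    cfg = config
    # milder site-rate heterogeneity than the inference default: with
    # strongly conserved (slow) sites, profile search reaches arbitrarily
    # distant homologs through short cores and family boundaries blur at
    # desk scale; shape 4 keeps the detection cliffs sharp while retaining
    # rate variation
    model = model or lg_model(gamma_shape=4.0)
    pi = model.equilibrium_freqs
    seeds = _child_seeds(cfg.seed, 16)
    (s_treeA, s_treeF, s_treeB, s_treeArc, s_treeEkb, s_treeBca,
     s_graftA, s_graftB, s_evolveA, s_evolveB, s_linker, s_lenlink,
     s_background, s_flanks, s_transcripts, s_misc) = seeds

    # --- taxon trees -------------------------------------------------------
    euk = scale_tree_height(
        simulate_yule_tree(cfg.n_eukaryote_taxa, 1.0, s_treeA, "EUK"),
        cfg.family_tree_height)
    fusion = scale_tree_height(
        simulate_yule_tree(max(cfg.fusion_clade_size, 2), 1.0, s_treeF, "FUS"),
        cfg.fusion_tree_height)
    fusion.seed_node.label = FUSION_ROOT_LABEL
    bact = scale_tree_height(
        simulate_yule_tree(max(cfg.n_bacteria_taxa, 2), 1.0, s_treeB, "BAC"),
        cfg.family_tree_height)

    def _clade(n, seed, prefix):
        if n == 0:
            return None
        if n == 1:
            return _single_tip_tree(f"{prefix}01")
        return scale_tree_height(simulate_yule_tree(n, 1.0, seed, prefix),
                                 cfg.outgroup_clade_height)

    archaea = _clade(cfg.n_archaea_taxa, s_treeArc, "ARC")
    eukB = _clade(cfg.n_eukaryote_familyB, s_treeEkb, "EKB")
    bactA = _clade(cfg.n_bacterial_familyA, s_treeBca, "BCA")

    rngA = np.random.default_rng(s_graftA)
    rngB = np.random.default_rng(s_graftB)

    # domain A: fusion clade nested inside the eukaryote family, bacterial
    # outgroup clade across a long stem
    eukA = _graft(euk, fusion, cfg.fusion_stem, rngA)
    partsA = [(eukA, 0.3)]
    if bactA is not None:
        partsA.insert(0, (bactA, cfg.familyA_outgroup_stem))
    treeA = _join(partsA) if len(partsA) > 1 else eukA

    # domain B: chimera nests the fusion clade inside bacteria; the null
    # scenario descends it from the eukaryote side (sister to eukB).  The
    # archaeal clade branches as a prokaryote outgroup next to bacteria at
    # moderate depth so it anchors the root without saturating.
    if cfg.scenario_kind == "chimera":
        bactB = _graft(bact, fusion, cfg.fusion_stem, rngB, internal_only=True)
        euk_side = eukB
        donor = "Bacteria"
    else:
        bactB = bact
        if eukB is not None:
            euk_side = _join([(eukB, 0.15), (fusion, cfg.null_fusion_stem)])
        else:
            euk_side = fusion
        donor = "Eukaryota"
    if archaea is not None:
        prok_side = _join([(archaea, cfg.archaea_stem), (bactB, 0.2)])
    else:
        prok_side = bactB
    partsB = [(euk_side, cfg.euk_side_stem), (prok_side, cfg.prok_side_stem)]
    treeB = _join([p for p in partsB if p[0] is not None])

    # --- evolve segments ---------------------------------------------------
    alnA, internalsA = evolve_alignment(treeA, cfg.domainA_length, model,
                                        seed=s_evolveA, return_internal=True)
    alnB, internalsB = evolve_alignment(treeB, cfg.domainB_length, model,
                                        seed=s_evolveB, return_internal=True)
    segA = dict(alnA.rows)
    segB = dict(alnB.rows)

    lo, hi = cfg.linker_length_range
    linker_aln, linker_internal = evolve_alignment(
        fusion, hi, model, seed=s_linker,
        rate_multiplier=cfg.linker_rate_multiplier, return_internal=True)
    linker_full = dict(linker_aln.rows)
    rng_len = np.random.default_rng(s_lenlink)
    fusion_ids = sorted(linker_full)[: cfg.fusion_clade_size]
    linkers = {}
    for fid in fusion_ids:
        target = int(rng_len.integers(lo, hi + 1))
        drop = sorted(rng_len.choice(hi, size=hi - target, replace=False))
        keep = [j for j in range(hi) if j not in set(drop)]
        linkers[fid] = "".join(linker_full[fid][j] for j in keep)

    # --- assemble protein records -----------------------------------------
    rng_flank = np.random.default_rng(s_flanks)
    records = []
    taxonomy = {}
    domain_spans = {}

    def add(rec_id, residues, domain, category):
        records.append(TaxLabeledSequence(rec_id, residues, domain, category))
        taxonomy[rec_id] = (domain, category)

    for fid in fusion_ids:
        protein = "M" + segA[fid] + linkers[fid] + segB[fid]
        a_start = 2
        a_end = a_start + cfg.domainA_length - 1
        l_end = a_end + len(linkers[fid])
        b_end = l_end + cfg.domainB_length
        domain_spans[fid] = {
            "domainA": (a_start, a_end),
            "linker": (a_end + 1, l_end) if l_end > a_end else (0, 0),
            "domainB": (l_end + 1, b_end),
        }
        add(fid, protein, "Eukaryota", "focal")

    for tip, seg in segA.items():
        if tip in set(fusion_ids):
            continue
        flanked, _, _ = _flanked(rng_flank, seg, pi)
        domain = "Bacteria" if tip.startswith("BCA") else "Eukaryota"
        add(tip + "_A", flanked, domain, "familyA")
    for tip, seg in segB.items():
        if tip in set(fusion_ids):
            continue
        flanked, _, _ = _flanked(rng_flank, seg, pi)
        if tip.startswith("ARC"):
            domain = "Archaea"
        elif tip.startswith("EKB"):
            domain = "Eukaryota"
        else:
            domain = "Bacteria"
        add(tip + "_B", flanked, domain, "familyB")

    rng_bg = np.random.default_rng(s_background)
    bg_domains = ["Eukaryota", "Bacteria", "Archaea", "Virus"]
    for k in range(cfg.background_count):
        length = int(rng_bg.integers(80, 251))
        add(f"BG{k + 1:03d}", _random_protein(rng_bg, length, pi),
            bg_domains[int(rng_bg.integers(4))], "background")

    database = build_nr_database(records)

    # --- transcripts for the fusion genes ---------------------------------
    rng_tx = np.random.default_rng(s_transcripts)
    transcripts = [(fid, _transcript_for(rng_tx, database[fid].residues))
                   for fid in fusion_ids]

    # --- seed alignments (first two fusion members = known orthologs) -----
    n_seed = min(3, len(fusion_ids)) if len(fusion_ids) >= 3 else len(fusion_ids)
    seed_ids = fusion_ids[:max(2, n_seed)]
    seed_A = progressive_msa([segA[f] for f in seed_ids], ids=seed_ids)
    seed_B = progressive_msa([segB[f] for f in seed_ids], ids=seed_ids)

    truth = GroundTruth(
        fusion_member_ids=list(fusion_ids),
        donor_taxon_domain=donor,
        true_trees={
            "domainA": treeA.as_string(schema="newick").strip(),
            "domainB": treeB.as_string(schema="newick").strip(),
            "fusion": fusion.as_string(schema="newick").strip(),
        },
        taxonomy=dict(taxonomy),
        domain_spans=domain_spans,
        fusion_root_segments={
            "domainA": internalsA.get(FUSION_ROOT_LABEL, ""),
            "linker": linker_internal.get(FUSION_ROOT_LABEL, ""),
            "domainB": internalsB.get(FUSION_ROOT_LABEL, ""),
        },
        scenario_kind=cfg.scenario_kind,
        seed=cfg.seed,
        full_linkers={fid: linker_full[fid] for fid in fusion_ids},
    )
    return Scenario(database, taxonomy, transcripts, seed_A, seed_B, truth, cfg)
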