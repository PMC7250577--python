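"""Maximum-likelihood phylogenetics: pruning likelihood, tree search,
bootstrap, constrained search, the SOWH topology test and tree comparison.

Likelihoods are computed by Felsenstein pruning with a discrete-gamma rate
mixture; gaps and ``X`` are missing data (all-ones partials) and numerical
underflow is handled by per-node rescaling with accumulated log factors.
Branch lengths are optimized one edge at a time using the standard
edge-decomposition trick: with the eigensystem of the rate matrix, the
site likelihood along one edge is a short exponential sum in the branch
length, so each univariate optimization is nearly free once the partials
on both sides of the edge are in hand.

Tree search is hill-climbing over nearest-neighbour interchanges (NNI)
from a stepwise-addition start; constrained search rejects moves that stop
displaying any bipartition of the constraint.  Public functions exchange
trees as :class:`dendropy.Tree` objects whose leaf labels match alignment
row ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .seqcore import Alignment, CHAR_INDEX, GAP
from .substitution import SubstitutionModel

MIN_BLEN = 1e-8
MAX_BLEN = 20.0
NNI_TOL = 1e-4
MISSING = 20  # residue code for gap/X


# ---------------------------------------------------------------------------
# unrooted tree structure


class UTree:
    """Unrooted binary tree over tips 0..n-1 stored as an adjacency map."""

    def __init__(self, labels, adj):
        self.labels = list(labels)
        self.adj = {u: dict(nb) for u, nb in adj.items()}

    @property
    def n_tips(self):
        return len(self.labels)

    def copy(self) -> "UTree":
        return UTree(self.labels, self.adj)

    def internal_nodes(self):
        return [u for u, nb in self.adj.items() if len(nb) > 1]

    def edges(self):
        out = []
        for u, nb in self.adj.items():
            for v in nb:
                if u < v:
                    out.append((u, v))
        return out

    def internal_edges(self):
        return [(u, v) for u, v in self.edges()
                if len(self.adj[u]) > 1 and len(self.adj[v]) > 1]

    def set_length(self, u, v, t):
        self.adj[u][v] = self.adj[v][u] = t

    def length(self, u, v):
        return self.adj[u][v]

    # -- bipartitions ------------------------------------------------------

    def bipartitions(self) -> set[int]:
        """Non-trivial bipartitions as canonical tip bitmasks.

        Masks are canonicalized against the tips actually present in the
        adjacency (the tree may be partial during stepwise addition): the
        canonical side contains the lowest present tip.
        """
        order, parent = self._dfs_order()
        present = 0
        for u in order:
            if u < self.n_tips:
                present |= 1 << u
        low = present & -present
        masks = {}
        for u in reversed(order):
            m = 1 << u if u < self.n_tips else 0
            for v in self.adj[u]:
                if v != parent.get(u) and v in masks:
                    m |= masks[v]
            masks[u] = m
        out = set()
        for u, m in masks.items():
            if parent.get(u) is None:
                continue
            canon = m if (m & low) else (present ^ m)
            if _nontrivial(canon, present):
                out.add(canon)
        return out

    def _dfs_order(self, root=None):
        if root is None:
            root = max(self.adj, key=lambda u: (len(self.adj[u]), u))
        order, parent, stack = [], {root: None}, [root]
        while stack:
            u = stack.pop()
            order.append(u)
            for v in self.adj[u]:
                if v not in parent:
                    parent[v] = u
                    stack.append(v)
        return order, parent

    # -- NNI ---------------------------------------------------------------

    def nni_moves(self):
        """All (edge, swap) NNI moves: swap subtree a (neighbour of u) with
        subtree b (neighbour of v) across internal edge (u, v)."""
        moves = []
        for u, v in self.internal_edges():
            us = [w for w in self.adj[u] if w != v]
            vs = [w for w in self.adj[v] if w != u]
            # two distinct topologies: swap us[0] with each neighbour of v
            for b in vs:
                moves.append((u, v, us[0], b))
        return moves

    def apply_nni(self, u, v, a, b) -> "UTree":
        """Return a copy with subtrees a (at u) and b (at v) exchanged."""
        t = self.copy()
        ta = t.adj[u].pop(a)
        tb = t.adj[v].pop(b)
        t.adj[a].pop(u)
        t.adj[b].pop(v)
        t.adj[u][b] = tb
        t.adj[b][u] = tb
        t.adj[v][a] = ta
        t.adj[a][v] = ta
        return t

    # -- conversions -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, require_blens=True) -> "UTree":
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        seed = tree.seed_node
        if len(seed.child_nodes()) == 2 and len(tree.leaf_nodes()) > 2:
            tree.deroot()
        leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
        labels = [l.taxon.label for l in leaves]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        node_id = {}
        for i, leaf in enumerate(leaves):
            node_id[leaf] = i
        next_id = len(labels)
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            node_id[nd] = next_id
            next_id += 1
        adj: dict[int, dict[int, float]] = {i: {} for i in node_id.values()}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            t = nd.edge.length
            if t is None:
                if require_blens:
                    raise ValueError("tree is missing branch lengths")
                t = 0.1
            u, v = node_id[nd.parent_node], node_id[nd]
            t = max(float(t), 0.0)
            adj[u][v] = t
            adj[v][u] = t
        return cls(labels, adj)

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace(self.labels)
        tree = dendropy.Tree(taxon_namespace=tns)
        root = max(self.adj, key=lambda u: (len(self.adj[u]), u))
        nodes = {root: tree.seed_node}
        order, parent = self._dfs_order(root)
        for u in order:
            if u == root:
                continue
            nd = dendropy.Node()
            nodes[parent[u]].add_child(nd)
            nd.edge.length = self.adj[parent[u]][u]
            nodes[u] = nd
        for u, nd in nodes.items():
            if u < self.n_tips:
                nd.taxon = tns.get_taxon(self.labels[u]) or tns.new_taxon(self.labels[u])
        tree.is_rooted = False
        return tree


# ---------------------------------------------------------------------------
# likelihood engine


def _encode_alignment(alignment: Alignment, labels):
    rows = dict(alignment.rows)
    if set(rows) != set(labels):
        raise ValueError("tree tips and alignment rows do not match")
    n_cols = alignment.n_columns
    mat = np.empty((len(labels), n_cols), dtype=np.int64)
    for i, lab in enumerate(labels):
        for j, c in enumerate(rows[lab]):
            if c == GAP or c == "X":
                mat[i, j] = MISSING
            else:
                idx = CHAR_INDEX.get(c, MISSING)
                mat[i, j] = idx if idx < 20 else MISSING
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    return patterns, weights.astype(float)


class _Engine:
    """Pruning likelihood and branch-length optimization on fixed data."""

    def __init__(self, model: SubstitutionModel, alignment: Alignment, labels):
        self.model = model
        self.labels = list(labels)
        self.patterns, self.weights = _encode_alignment(alignment, self.labels)
        self.n_pat = self.patterns.shape[1]
        self.pi = model.equilibrium_freqs
        self.eigval, self.left, self.right = model._eigensystem
        self.rates = model.category_rates
        self.n_cat = len(self.rates)
        self._site_count = int(self.weights.sum())
        # cached tip codes: safe indices plus missing-data masks
        self._tip_miss = self.patterns >= 20
        self._tip_safe = np.where(self._tip_miss, 0, self.patterns)

    def _pmats(self, t):
        """(n_cat, 20, 20) transition matrices for branch length t."""
        out = np.empty((self.n_cat, 20, 20))
        for c in range(self.n_cat):
            e = np.exp(self.eigval * (self.rates[c] * t))
            np.matmul(self.left * e, self.right, out=out[c])
        np.clip(out, 0.0, None, out=out)
        return out

    def _tip_ltil(self, tip, pmats):
        """L-tilde for a tip: (n_cat, n_pat, 20)."""
        safe = self._tip_safe[tip]
        miss = self._tip_miss[tip]
        any_miss = bool(miss.any())
        out = np.empty((self.n_cat, self.n_pat, 20))
        for c in range(self.n_cat):
            out[c] = pmats[c].T[safe]
            if any_miss:
                out[c][miss] = 1.0
        return out

    def _postorder(self, tree: UTree, root):
        order, parent = tree._dfs_order(root)
        ltil = {}      # node -> (C, P, 20) message toward parent
        lower = {}     # internal node -> (C, P, 20) partial at node
        scale = {}     # node -> (P,) accumulated log scale of its subtree
        for u in reversed(order):
            if parent[u] is None:
                continue
            t = tree.adj[parent[u]][u]
            pmats = self._pmats(t)
            if u < tree.n_tips:
                ltil[u] = self._tip_ltil(u, pmats)
                scale[u] = np.zeros(self.n_pat)
                lower[u] = None
            else:
                part = np.ones((self.n_cat, self.n_pat, 20))
                sc = np.zeros(self.n_pat)
                for w in tree.adj[u]:
                    if w == parent[u]:
                        continue
                    part = part * ltil[w]
                    sc = sc + scale[w]
                mx = part.max(axis=(0, 2))
                mx = np.where(mx > 0, mx, 1.0)
                part = part / mx[None, :, None]
                sc = sc + np.log(mx)
                lower[u] = part
                scale[u] = sc
                lt = np.empty_like(part)
                for c in range(self.n_cat):
                    np.matmul(part[c], pmats[c].T, out=lt[c])
                ltil[u] = lt
        return order, parent, ltil, lower, scale

    def _root_lnl(self, tree, root, ltil, scale):
        part = np.ones((self.n_cat, self.n_pat, 20))
        sc = np.zeros(self.n_pat)
        for w in tree.adj[root]:
            part = part * ltil[w]
            sc = sc + scale[w]
        site = np.einsum("cpj,j->p", part, self.pi) / self.n_cat
        site = np.maximum(site, 1e-300)
        return float(np.dot(self.weights, np.log(site) + sc))

    def lnl(self, tree: UTree) -> float:
        root = max(tree.adj, key=lambda u: (len(tree.adj[u]), u))
        order, parent, ltil, lower, scale = self._postorder(tree, root)
        return self._root_lnl(tree, root, ltil, scale)

    def _lower_partial(self, tree, u, parent, ltil, lower):
        """Lower partial of node u (one-hot expansion for tips)."""
        if u >= tree.n_tips:
            return lower[u]
        codes = self.patterns[u]
        out = np.zeros((self.n_pat, 20))
        ok = codes < 20
        out[np.arange(self.n_pat)[ok], codes[ok]] = 1.0
        out[~ok] = 1.0
        return np.broadcast_to(out, (self.n_cat, self.n_pat, 20))

    def _edge_coeffs(self, tree, v, upper_v, uscale_v, lower_v, lscale_v):
        """Exponential-sum coefficients for the edge above v.

        Returns (A, mu, const) with site likelihood
        ``sum_K A[p, K] * exp(mu[K] * t) / n_cat`` and per-pattern log
        offset ``const``.
        """
        A = np.empty((self.n_pat, self.n_cat * 20))
        mu = np.empty(self.n_cat * 20)
        for c in range(self.n_cat):
            x = (upper_v[c] * self.pi[None, :]) @ self.left     # (P, 20)
            y = lower_v[c] @ self.right.T                       # (P, 20)
            A[:, c * 20:(c + 1) * 20] = x * y
            mu[c * 20:(c + 1) * 20] = self.eigval * self.rates[c]
        return A, mu, uscale_v + lscale_v

    def _edge_lnl_fn(self, A, mu, const):
        w = self.weights

        def fn(t):
            site = A @ np.exp(mu * t) / self.n_cat
            site = np.maximum(site, 1e-300)
            return float(np.dot(w, np.log(site) + const))

        return fn

    def _optimize_edge(self, fn, t0, A=None, mu=None):
        """Maximize the single-edge likelihood in the branch length.

        Newton-Raphson on the exponential-sum representation (3-6 cheap
        iterations); falls back to bounded Brent when curvature is
        unhelpful.  Never returns a worse value than the current length.
        """
        if A is not None:
            t_new = self._newton_edge(A, mu, t0)
            if t_new is not None:
                f_new, f_old = fn(t_new), fn(t0)
                return (t_new, f_new) if f_new >= f_old else (t0, f_old)
        res = minimize_scalar(lambda t: -fn(t), bounds=(MIN_BLEN, MAX_BLEN),
                              method="bounded", options={"xatol": 1e-7})
        t_new = float(res.x)
        f_new, f_old = fn(t_new), fn(t0)
        return (t_new, f_new) if f_new >= f_old else (t0, f_old)

    def _newton_edge(self, A, mu, t0, max_iter=6):
        w = self.weights
        t = min(max(t0, 1e-4), 2.0)
        A1 = A * mu
        A2 = A1 * mu
        for _ in range(max_iter):
            e = np.exp(mu * t)
            s = A @ e                    # (P,)
            s1 = A1 @ e
            s2 = A2 @ e
            s = np.where(np.abs(s) < 1e-300, 1e-300, s)
            r1 = s1 / s
            g = float(np.dot(w, r1))
            h = float(np.dot(w, s2 / s - r1 * r1))
            if not np.isfinite(g) or not np.isfinite(h) or h >= -1e-12:
                return None
            step = -g / h
            t_next = t + step
            if t_next <= MIN_BLEN:
                t_next = (t + MIN_BLEN) / 2 if t > MIN_BLEN * 2 else MIN_BLEN
            elif t_next > MAX_BLEN:
                t_next = MAX_BLEN
            if abs(t_next - t) < 1e-6:
                return t_next
            t = t_next
        return t

    def _upper_messages(self, tree, root, order, parent, ltil, scale):
        """Upper message N_v and its log scale for every non-root node v."""
        upper = {}
        uscale = {}
        for u in order:  # preorder
            if parent[u] is None:
                kids = list(tree.adj[u])
                for v in kids:
                    part = np.ones((self.n_cat, self.n_pat, 20))
                    sc = np.zeros(self.n_pat)
                    for w in kids:
                        if w != v:
                            part = part * ltil[w]
                            sc = sc + scale[w]
                    upper[v], uscale[v] = self._rescale(part, sc)
            elif u >= tree.n_tips:
                pmats = self._pmats(tree.adj[parent[u]][u])
                down = np.empty_like(upper[u])
                for c in range(self.n_cat):
                    np.matmul(upper[u][c], pmats[c].T, out=down[c])
                for v in tree.adj[u]:
                    if v == parent[u]:
                        continue
                    part = down.copy()
                    sc = uscale[u].copy()
                    for w in tree.adj[u]:
                        if w != parent[u] and w != v:
                            part = part * ltil[w]
                            sc = sc + scale[w]
                    upper[v], uscale[v] = self._rescale(part, sc)
        return upper, uscale

    @staticmethod
    def _rescale(part, sc):
        mx = part.max(axis=(0, 2))
        mx = np.where(mx > 0, mx, 1.0)
        return part / mx[None, :, None], sc + np.log(mx)

    def optimize_branches(self, tree: UTree, n_sweeps: int = 3,
                          tol: float = 1e-3) -> float:
        """Iteratively optimize every branch length in place; returns lnL.

        Each sweep recomputes partials once and optimizes each edge against
        them; a final guard keeps the best-scoring length vector seen, so
        the reported likelihood never decreases.
        """
        root = max(tree.adj, key=lambda u: (len(tree.adj[u]), u))
        best_lnl = self.lnl(tree)
        best_lengths = {e: tree.length(*e) for e in tree.edges()}
        for _ in range(n_sweeps):
            order, parent, ltil, lower, scale = self._postorder(tree, root)
            upper, uscale = self._upper_messages(tree, root, order, parent, ltil, scale)
            for u in order:
                if parent[u] is None:
                    continue
                lv = self._lower_partial(tree, u, parent, ltil, lower)
                A, mu, const = self._edge_coeffs(tree, u, upper[u], uscale[u],
                                                lv, scale[u])
                fn = self._edge_lnl_fn(A, mu, const)
                t_new, _ = self._optimize_edge(fn, tree.adj[parent[u]][u], A, mu)
                tree.set_length(parent[u], u, t_new)
            cur = self.lnl(tree)
            if cur >= best_lnl:
                improved = cur - best_lnl
                best_lnl = cur
                best_lengths = {e: tree.length(*e) for e in tree.edges()}
                if improved < tol:
                    break
            else:
                # simultaneous updates overshot: revert and fall back to the
                # slower, strictly monotone one-edge-at-a-time pass
                for (a, b), t in best_lengths.items():
                    tree.set_length(a, b, t)
                best_lnl = self._optimize_edges_sequential(tree)
                best_lengths = {e: tree.length(*e) for e in tree.edges()}
                break
        for (a, b), t in best_lengths.items():
            tree.set_length(a, b, t)
        return best_lnl

    def _optimize_edges_sequential(self, tree: UTree) -> float:
        """One-edge-at-a-time optimization with fresh partials per edge."""
        lnl = self.lnl(tree)
        for (a, b) in tree.edges():
            u, v = (a, b) if len(tree.adj[a]) > 1 else (b, a)
            lnl = self.nni_candidate_lnl(tree, u, v)
        return lnl

    def nni_candidate_lnl(self, tree: UTree, u, v) -> float:
        """lnL after optimizing only the (u, v) edge, partials rooted at u."""
        order, parent, ltil, lower, scale = self._postorder(tree, u)
        # v is a child of root u: upper message = product of other children
        part = np.ones((self.n_cat, self.n_pat, 20))
        sc = np.zeros(self.n_pat)
        for w in tree.adj[u]:
            if w != v:
                part = part * ltil[w]
                sc = sc + scale[w]
        upper_v, uscale_v = self._rescale(part, sc)
        lv = self._lower_partial(tree, v, parent, ltil, lower)
        A, mu, const = self._edge_coeffs(tree, v, upper_v, uscale_v, lv, scale[v])
        fn = self._edge_lnl_fn(A, mu, const)
        t_new, lnl = self._optimize_edge(fn, tree.adj[u][v], A, mu)
        tree.set_length(u, v, t_new)
        return lnl


# ---------------------------------------------------------------------------
# constraints


class ConstraintTree:
    """Topological constraint: bipartitions that any compliant tree must display.

    Built from a (possibly multifurcating) tree whose tip set may be a
    subset of the analysis tips; compliance of a candidate tree is checked
    on the candidate restricted to the constraint's tips.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tip_labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        index = {lab: i for i, lab in enumerate(self.tip_labels)}
        n = len(self.tip_labels)
        full = (1 << n) - 1
        work = tree.clone(depth=1)
        work.suppress_unifurcations()
        if len(work.seed_node.child_nodes()) == 2 and n > 2:
            work.deroot()
        bips = set()
        for nd in work.postorder_node_iter():
            if nd.parent_node is None:
                continue
            m = 0
            for leaf in nd.leaf_iter():
                m |= 1 << index[leaf.taxon.label]
            canon = m if (m & 1) else (full ^ m)
            if bin(canon).count("1") >= 2 and bin(full ^ canon).count("1") >= 2:
                bips.add(canon)
        self.bipartitions = bips
        self._full = full
        for a in bips:
            for b in bips:
                if a < b and not _masks_compatible(a, b, full):
                    raise ValueError("constraint contains contradictory bipartitions")

    def is_vacuous(self):
        return not self.bipartitions

    def satisfied_by(self, tree: UTree, placed_labels=None) -> bool:
        """Does the tree display every constraint bipartition?

        The check restricts the tree's bipartitions to the constraint tips
        it actually contains (the *universe*), so it also works on partial
        trees during stepwise addition: constraint bipartitions that stay
        non-trivial within the universe must already be displayed.
        """
        cindex = {lab: i for i, lab in enumerate(self.tip_labels)}
        universe = 0
        tipbit = {}
        for i, lab in enumerate(tree.labels):
            if i not in tree.adj:
                continue  # tip not yet placed (partial tree)
            ci = cindex.get(lab)
            if ci is not None:
                universe |= 1 << ci
                tipbit[i] = ci
        if bin(universe).count("1") < 4:
            return True  # too few constraint tips for any non-trivial split
        tree_masks = set()
        for mask in tree.bipartitions():
            m = 0
            for i, ci in tipbit.items():
                if mask >> i & 1:
                    m |= 1 << ci
            if _nontrivial(m, universe):
                tree_masks.add(_canon(m, universe))
        for b in self.bipartitions:
            rb = b & universe
            if _nontrivial(rb, universe) and _canon(rb, universe) not in tree_masks:
                return False
        return True


def _canon(m, full):
    if full == 0:
        return 0
    low = full & -full
    return m if (m & low) else (full ^ m)


def _nontrivial(m, universe):
    return bin(m).count("1") >= 2 and bin(universe ^ m).count("1") >= 2


def _masks_compatible(a, b, full):
    return (a & b == a) or (a & b == b) or (a & b == 0) or (a | b == full)


def star_constraint(labels) -> ConstraintTree:
    """A vacuous constraint (no internal structure)."""
    tns = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(lab)
        tree.seed_node.add_child(nd)
    return ConstraintTree(tree)


def monophyly_constraint(groups: dict, all_labels) -> ConstraintTree:
    """Constraint tree forcing each listed group to be monophyletic.

    ``groups`` maps group name -> iterable of tip labels; tips not listed
    float freely.
    """
    tns = dendropy.TaxonNamespace(list(all_labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    grouped = set()
    for labels in groups.values():
        node = dendropy.Node()
        tree.seed_node.add_child(node)
        for lab in labels:
            child = dendropy.Node()
            child.taxon = tns.get_taxon(lab)
            if child.taxon is None:
                raise ValueError(f"unknown tip {lab!r}")
            node.add_child(child)
            grouped.add(lab)
    for lab in all_labels:
        if lab not in grouped:
            child = dendropy.Node()
            child.taxon = tns.get_taxon(lab)
            tree.seed_node.add_child(child)
    return ConstraintTree(tree)


# ---------------------------------------------------------------------------
# public likelihood / search API


def log_likelihood(tree: dendropy.Tree, alignment: Alignment,
                   model: SubstitutionModel) -> float:
    """Exact pruning log-likelihood of the alignment on the tree."""
    ut = UTree.from_dendropy(tree)
    engine = _Engine(model, alignment, ut.labels)
    return engine.lnl(ut)


def _stepwise_start(engine: _Engine, labels, rng, constraint=None) -> UTree:
    n = len(labels)
    order = list(rng.permutation(n))
    adj = {n: {}}
    first3 = order[:3]
    for tip in first3:
        adj[n][tip] = 0.1
        adj[tip] = {n: 0.1}
    tree = UTree(labels, adj)
    placed = [labels[i] for i in first3]
    next_internal = n + 1
    for tip in order[3:]:
        best = None
        for (a, b) in tree.edges():
            cand = tree.copy()
            t_ab = cand.adj[a].pop(b)
            cand.adj[b].pop(a)
            w = next_internal
            cand.adj[w] = {a: t_ab / 2, b: t_ab / 2, tip: 0.1}
            cand.adj[a][w] = t_ab / 2
            cand.adj[b][w] = t_ab / 2
            cand.adj[tip] = {w: 0.1}
            if constraint is not None and not constraint.satisfied_by(
                    cand, placed + [labels[tip]]):
                continue
            lnl = engine.nni_candidate_lnl(cand, w, tip)
            if best is None or lnl > best[0]:
                best = (lnl, cand)
        if best is None:
            raise ValueError("constraint is incompatible with the tip set")
        tree = best[1]
        placed.append(labels[tip])
        next_internal += 1
    return tree


def _nni_search(engine: _Engine, tree: UTree, constraint=None,
                max_rounds: int = 50,
                start_lnl: float | None = None) -> tuple[UTree, float]:
    cur_lnl = engine.optimize_branches(tree) if start_lnl is None else start_lnl
    for _ in range(max_rounds):
        best = None
        for (u, v, a, b) in tree.nni_moves():
            cand = tree.apply_nni(u, v, a, b)
            if constraint is not None and not constraint.satisfied_by(cand):
                continue
            lnl = engine.nni_candidate_lnl(cand, u, v)
            if lnl > cur_lnl + NNI_TOL and (best is None or lnl > best[0]):
                best = (lnl, cand)
        if best is None:
            break
        tree = best[1]
        cur_lnl = engine.optimize_branches(tree)
    return tree, cur_lnl


def ml_tree_search(alignment: Alignment, model: SubstitutionModel,
                   seed: int = 0, start_tree: dendropy.Tree | None = None,
                   constraint: ConstraintTree | None = None) -> dendropy.Tree:
    """NNI hill-climbing ML tree search from a stepwise-addition start.

    Returns an unrooted dendropy tree with optimized branch lengths and a
    ``log_likelihood`` attribute.  The search stops when no NNI move
    improves the log-likelihood by more than 1e-4.
    """
    if alignment.n_rows < 3:
        raise ValueError("tree search needs at least 3 sequences")
    labels = sorted(alignment.ids)
    engine = _Engine(model, alignment, labels)
    rng = np.random.default_rng(seed)
    if constraint is not None and constraint.is_vacuous():
        constraint = None
    if start_tree is not None:
        ut = UTree.from_dendropy(start_tree, require_blens=False)
        if sorted(ut.labels) != labels:
            raise ValueError("start tree tips do not match the alignment")
        if constraint is not None and not constraint.satisfied_by(ut):
            ut = _stepwise_start(engine, labels, rng, constraint)
    else:
        ut = _stepwise_start(engine, labels, rng, constraint)
    ut, lnl = _nni_search(engine, ut, constraint)
    out = ut.to_dendropy()
    out.log_likelihood = lnl
    return out


def constrained_ml_search(alignment: Alignment, model: SubstitutionModel,
                          constraint: ConstraintTree, seed: int = 0,
                          start_tree: dendropy.Tree | None = None) -> dendropy.Tree:
    """Best tree among topologies displaying all constraint bipartitions."""
    return ml_tree_search(alignment, model, seed=seed, start_tree=start_tree,
                          constraint=constraint)


def optimize_gamma_shape(alignment: Alignment, model: SubstitutionModel,
                         tree: dendropy.Tree,
                         bounds=(0.1, 10.0)) -> SubstitutionModel:
    """Golden-section fit of the discrete-gamma shape on a fixed tree."""
    ut = UTree.from_dendropy(tree)

    def neg(shape):
        m = model.with_gamma(float(shape))
        return -_Engine(m, alignment, ut.labels).lnl(ut)

    res = minimize_scalar(neg, bounds=bounds, method="bounded",
                          options={"xatol": 1e-2})
    return model.with_gamma(float(res.x))


def bootstrap_support(alignment: Alignment, model: SubstitutionModel,
                      n_reps: int = 1000, seed: int = 0,
                      best_tree: dendropy.Tree | None = None) -> dendropy.Tree:
    """Site-resampling bootstrap; support = % of replicates displaying each
    bipartition of the best tree (stored as internal node labels)."""
    if n_reps < 1:
        raise ValueError("need at least one bootstrap replicate")
    if best_tree is None:
        best_tree = ml_tree_search(alignment, model, seed=seed)
    ut_best = UTree.from_dendropy(best_tree)
    target_bips = ut_best.bipartitions()
    counts = {b: 0 for b in target_bips}
    rng = np.random.default_rng(seed)
    n_cols = alignment.n_columns
    rows = alignment.rows
    for _ in range(n_reps):
        idx = rng.integers(0, n_cols, size=n_cols)
        boot = Alignment([(rid, "".join(row[j] for j in idx)) for rid, row in rows])
        rep = ml_tree_search(boot, model, seed=int(rng.integers(2 ** 31)),
                             start_tree=best_tree)
        rep_bips = UTree.from_dendropy(rep).bipartitions()
        for b in target_bips:
            if b in rep_bips:
                counts[b] += 1
    support = {b: 100.0 * c / n_reps for b, c in counts.items()}
    out = ut_best.to_dendropy()
    _annotate_support(out, ut_best.labels, support)
    out.log_likelihood = getattr(best_tree, "log_likelihood", None)
    return out


def _annotate_support(tree: dendropy.Tree, labels, support):
    index = {lab: i for i, lab in enumerate(labels)}
    full = (1 << len(labels)) - 1
    for nd in tree.postorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        m = 0
        for leaf in nd.leaf_iter():
            m |= 1 << index[leaf.taxon.label]
        canon = m if (m & 1) else (full ^ m)
        if canon in support:
            nd.label = f"{support[canon]:.0f}"


# ---------------------------------------------------------------------------
# SOWH test


@dataclass
class SOWHResult:
    """Parametric-bootstrap comparison of free vs constraint-compliant ML."""

    observed_delta_lnl: float
    null_deltas: list
    p_value: float
    n_sims: int
    converged_sims: int
    observed_tree: dendropy.Tree | None = None
    constrained_tree: dendropy.Tree | None = None

    def to_json_dict(self):
        nd = np.asarray(self.null_deltas)
        return {
            "observed_delta_lnl": self.observed_delta_lnl,
            "p_value": self.p_value,
            "n_sims": self.n_sims,
            "null_delta_quantiles": {
                "q50": float(np.quantile(nd, 0.5)) if nd.size else None,
                "q95": float(np.quantile(nd, 0.95)) if nd.size else None,
                "max": float(nd.max()) if nd.size else None,
            },
        }


def sowh_test(alignment: Alignment, model: SubstitutionModel,
              constraint: ConstraintTree, n_sims: int = 100, seed: int = 0,
              observed_tree: dendropy.Tree | None = None) -> SOWHResult:
    """SOWH parametric-bootstrap topology test.

    The statistic is ``delta = lnL(unconstrained ML) - lnL(constrained
    ML)``.  The null distribution comes from alignments simulated on the
    constrained ML tree under the given model; the p-value uses the
    (1 + exceedances) / (1 + n_sims) estimator.

    The observed delta and every null delta are computed with the same
    search protocol (both searches warm-started from the constrained ML
    topology, sharing one initial branch-length fit), so the statistic is
    exchangeable between the observed data and the null replicates — the
    property the type-I error of the test rests on.  When a more
    thoroughly searched ``observed_tree`` is supplied, the better of its
    likelihood and the warm-started search's is used for the free side.
    """
    from .simulate import evolve_alignment

    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    con_tree = constrained_ml_search(alignment, model, constraint, seed=seed)
    con_ut = UTree.from_dendropy(con_tree)
    use_constraint = None if constraint.is_vacuous() else constraint

    engine = _Engine(model, alignment, con_ut.labels)
    base = con_ut.copy()
    base_lnl = engine.optimize_branches(base)
    free_ut, free_lnl = _nni_search(engine, base.copy(), start_lnl=base_lnl)
    _, con_lnl = _nni_search(engine, base.copy(), use_constraint,
                             start_lnl=base_lnl)
    if observed_tree is not None:
        if getattr(observed_tree, "log_likelihood", None) is None:
            observed_tree.log_likelihood = log_likelihood(
                observed_tree, alignment, model)
        free_lnl = max(free_lnl, observed_tree.log_likelihood)
    else:
        observed_tree = free_ut.to_dendropy()
        observed_tree.log_likelihood = free_lnl
    obs_delta = max(0.0, free_lnl - con_lnl)
    n_cols = alignment.n_columns
    null_deltas = []
    for _ in range(n_sims):
        sim_seed = int(rng.integers(2 ** 31))
        sim = evolve_alignment(con_tree, n_cols, model, seed=sim_seed)
        engine = _Engine(model, sim, con_ut.labels)
        # warm-start both searches from the constrained ML topology; the
        # initial branch-length fit on that shared topology is done once
        base = con_ut.copy()
        base_lnl = engine.optimize_branches(base)
        _, free_lnl = _nni_search(engine, base.copy(), start_lnl=base_lnl)
        _, con_lnl = _nni_search(engine, base.copy(), use_constraint,
                                 start_lnl=base_lnl)
        null_deltas.append(max(0.0, free_lnl - con_lnl))
    exceed = sum(1 for d in null_deltas if d >= obs_delta - 1e-9)
    p = (1 + exceed) / (1 + n_sims)
    return SOWHResult(obs_delta, null_deltas, p, n_sims, n_sims,
                      observed_tree, con_tree)


# ---------------------------------------------------------------------------
# tree comparison and rooting


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds symmetric difference of non-trivial bipartitions."""
    u1, u2 = UTree.from_dendropy(t1, False), UTree.from_dendropy(t2, False)
    if u1.labels != u2.labels:
        raise ValueError("trees have different tip sets")
    b1, b2 = u1.bipartitions(), u2.bipartitions()
    return len(b1 ^ b2)


def jaccard_tree_similarity(t1: dendropy.Tree, t2: dendropy.Tree) -> dict:
    """Per-clade best-match Jaccard scores of t1 against t2.

    For every internal node of (rooted) t1, the score is the maximum over
    internal nodes of t2 of |A n B| / |A u B| on descendant-tip sets.
    Returns a dict mapping frozenset(tip labels) -> score.
    """
    clades1 = _clades(t1)
    clades2 = _clades(t2)
    tips1 = frozenset().union(*clades1) if clades1 else frozenset()
    tips2 = frozenset().union(*clades2) if clades2 else frozenset()
    if not (tips1 & tips2):
        raise ValueError("trees share no tips")
    out = {}
    for a in clades1:
        out[a] = max((len(a & b) / len(a | b) for b in clades2), default=0.0)
    return out


def _clades(tree: dendropy.Tree):
    out = []
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            continue
        out.append(frozenset(l.taxon.label for l in nd.leaf_iter()))
    return out


def root_with_outgroup(tree: dendropy.Tree, outgroup_labels) -> dendropy.Tree:
    """Root on the branch separating the outgroup from everything else."""
    tree = tree.clone(depth=1)
    tree.is_rooted = True  # treat the seed node as root for MRCA queries
    outgroup = set(outgroup_labels)
    taxa = [l.taxon for l in tree.leaf_node_iter() if l.taxon.label in outgroup]
    if not taxa:
        raise ValueError("no outgroup tips found in tree")
    if len(taxa) == 1:
        node = tree.find_node_with_taxon_label(taxa[0].label)
    else:
        node = tree.mrca(taxa=taxa)
        if node is tree.seed_node:
            # outgroup spans the root; root on the complement instead
            comp = [l.taxon for l in tree.leaf_node_iter()
                    if l.taxon.label not in outgroup]
            node = tree.mrca(taxa=comp)
    edge = node.edge
    if edge.length is None:
        edge.length = 0.0
    tree.reroot_at_edge(edge, length1=edge.length / 2, length2=edge.length / 2,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree
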