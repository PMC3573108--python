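"""Maximum-likelihood gene trees under GTR+G.

The engine computes Felsenstein pruning likelihoods over compressed
site patterns, optimises branch lengths one edge at a time (the
likelihood as a function of a single branch length needs only the two
directional partials flanking that edge), searches topologies by
nearest-neighbour-interchange hill climbing, and measures clade support
by nonparametric bootstrap (column resampling, implemented as
multinomial reweighting of site patterns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .alignment import GeneAlignment, compress_patterns
from .model import GTRGammaParams, GTRModel
from .treeutil import UnrootedTree, jc_distance_matrix, nj_tree

MIN_BRANCH = 1e-8
MAX_BRANCH = 10.0
DEFAULT_TOL = 1e-4


@dataclass
class SiteLikelihoods:
    """Per-site log-likelihoods of one tree under one model."""

    site_loglik: np.ndarray          # length n_sites, in original column order
    pattern_loglik: np.ndarray       # length n_patterns
    pattern_weights: np.ndarray

    @property
    def total(self) -> float:
        return float(self.pattern_weights @ self.pattern_loglik)


@dataclass
class SupportTree:
    """An unrooted ML tree with bootstrap supports on internal edges."""

    tree: UnrootedTree
    supports: dict[frozenset, int] = field(default_factory=dict)
    log_likelihood: float = float("nan")
    params: GTRGammaParams | None = None

    @property
    def taxa(self) -> set[str]:
        return self.tree.taxa

    def newick(self) -> str:
        return self.tree.newick(self.supports or None)

    def support_of(self, taxa: set[str]) -> int | None:
        """Support of the clade containing exactly ``taxa``, if present."""
        ref = min(self.tree.taxa)
        key = frozenset(taxa if ref not in taxa else self.tree.taxa - set(taxa))
        return self.supports.get(key)


class TreeLikelihood:
    """Pruning likelihood machine bound to one alignment and model."""

    def __init__(self, align: GeneAlignment, model: GTRModel,
                 taxa: list[str] | None = None):
        self.model = model
        self.taxa = list(taxa) if taxa is not None else list(align.rows)
        missing = [t for t in self.taxa if t not in align.rows]
        if missing:
            raise ValueError(f"taxa in tree but not in alignment: {missing}")
        patterns, weights, inverse = compress_patterns(align.subset_taxa(self.taxa),
                                                       self.taxa)
        self.patterns = patterns
        self.weights = weights
        self.inverse = inverse
        self.n_sites = int(weights.sum())
        # leaf conditional likelihoods, shape (4, n_patterns)
        self.leaf_clv: dict[str, np.ndarray] = {}
        for i, taxon in enumerate(self.taxa):
            codes = patterns[i]
            if np.all(codes >= 4):
                raise ValueError(f"row {taxon!r} contains no unambiguous sites")
            clv = np.zeros((4, patterns.shape[1]))
            for s in range(4):
                clv[s, codes == s] = 1.0
            clv[:, codes >= 4] = 1.0
            self.leaf_clv[taxon] = clv

    # -- weights (bootstrap) ------------------------------------------
    def set_weights(self, weights: np.ndarray) -> None:
        self.weights = np.asarray(weights, dtype=float)

    def resampled_weights(self, rng: np.random.Generator) -> np.ndarray:
        """Multinomial pattern weights equivalent to resampling columns."""
        p = self.weights / self.weights.sum()
        return rng.multinomial(self.n_sites, p).astype(float)

    def masked_view(self, weights: np.ndarray) -> "TreeLikelihood":
        """A shallow engine restricted to patterns with positive weight
        (bootstrap replicates drop ~1/e of the patterns)."""
        mask = weights > 0
        clone = object.__new__(TreeLikelihood)
        clone.model = self.model
        clone.taxa = self.taxa
        clone.weights = weights[mask]
        clone.patterns = None
        clone.inverse = None
        clone.n_sites = int(weights.sum())
        clone.leaf_clv = {t: clv[:, mask] for t, clv in self.leaf_clv.items()}
        return clone

    # -- partials -----------------------------------------------------
    def _message(self, tree: UnrootedTree, child: int, parent: int, memo) -> np.ndarray:
        """P(t) applied to the partial of ``child``'s subtree, seen at parent."""
        P = self.model.pmats(tree.nbrs[parent][child])
        if tree.is_leaf(child):
            return np.matmul(P, self.leaf_clv[tree.leaf_name[child]])
        return np.matmul(P, self._partial(tree, child, parent, memo))

    def _partial(self, tree: UnrootedTree, node: int, away: int, memo) -> np.ndarray:
        """Conditional likelihoods at ``node`` for the subtree not containing
        ``away``; iterative postorder with memoisation per call scope."""
        key = (node, away)
        if key in memo:
            return memo[key]
        stack = [(node, away, False)]
        while stack:
            a, b, expanded = stack.pop()
            if (a, b) in memo:
                continue
            children = [c for c in tree.nbrs[a] if c != b]
            if not expanded:
                stack.append((a, b, True))
                for c in children:
                    if not tree.is_leaf(c) and (c, a) not in memo:
                        stack.append((c, a, False))
            else:
                out = None
                for c in children:
                    msg = self._message(tree, c, a, memo)
                    out = msg if out is None else out * msg
                memo[(a, b)] = out
        return memo[key]

    def _edge_arrays(self, tree: UnrootedTree, u: int, v: int, memo):
        """Directional partials A (at u, away from v) and B (at v, away
        from u); leaves contribute their indicator likelihoods."""
        k = self.model.n_cat
        if tree.is_leaf(u):
            clv = self.leaf_clv[tree.leaf_name[u]]
            A = np.broadcast_to(clv, (k,) + clv.shape)
        else:
            A = self._partial(tree, u, v, memo)
        if tree.is_leaf(v):
            clv = self.leaf_clv[tree.leaf_name[v]]
            B = np.broadcast_to(clv, (k,) + clv.shape)
        else:
            B = self._partial(tree, v, u, memo)
        return A, B

    def _edge_pattern_loglik(self, A, B, t) -> np.ndarray:
        P = self.model.pmats(t)
        PB = np.matmul(P, B)
        piA = A * self.model.pi[None, :, None]
        site = np.einsum("kxp,kxp->p", piA, PB) / self.model.n_cat
        return np.log(np.maximum(site, 1e-300))

    def _edge_loglik(self, A, B, t) -> float:
        return float(self.weights @ self._edge_pattern_loglik(A, B, t))

    # -- public API ---------------------------------------------------
    def loglik(self, tree: UnrootedTree) -> float:
        u, v = next(iter(tree.edges()))
        A, B = self._edge_arrays(tree, u, v, {})
        return self._edge_loglik(A, B, tree.nbrs[u][v])

    def site_logliks(self, tree: UnrootedTree) -> SiteLikelihoods:
        u, v = next(iter(tree.edges()))
        A, B = self._edge_arrays(tree, u, v, {})
        per_pattern = self._edge_pattern_loglik(A, B, tree.nbrs[u][v])
        return SiteLikelihoods(per_pattern[self.inverse], per_pattern, self.weights)

    def optimize_branch_lengths(self, tree: UnrootedTree, sweeps: int = 2) -> float:
        """Brent-optimise each branch in turn; returns final log-likelihood."""
        best = None
        for _ in range(sweeps):
            for u, v in list(tree.edges()):
                A, B = self._edge_arrays(tree, u, v, {})
                best, t_opt = self._brent(A, B)
                tree.set_length(u, v, t_opt)
        return best if best is not None else self.loglik(tree)

    def _brent(self, A, B):
        """Optimise one branch length given the two flanking partials."""
        n_pat = A.shape[-1]
        piA = (A * self.model.pi[None, :, None]).reshape(-1, n_pat)
        w = self.weights
        inv_k = 1.0 / self.model.n_cat
        pmats = self.model.pmats

        def neg(t):
            PB = np.matmul(pmats(t), B).reshape(piA.shape)
            site = np.einsum("ip,ip->p", piA, PB) * inv_k
            return -float(w @ np.log(np.maximum(site, 1e-300)))

        res = minimize_scalar(neg, bounds=(MIN_BRANCH, MAX_BRANCH),
                              method="bounded", options={"xatol": 1e-5})
        return -res.fun, float(res.x)

    def _local5(self, raw, lengths, x1, x2, y1, y2, t_uv):
        """Score an NNI arrangement by coordinate descent on the focal
        branch and the four adjacent branches.

        ``raw`` holds the bare subtree partials (no transition matrix
        applied); ``lengths`` the starting branch lengths each subtree
        carries.  Returns (score, focal length).  Scoring candidates
        with their local neighbourhood refitted removes the bias of
        comparing them against the current topology's tuned lengths.
        """
        t = dict(lengths)

        def msg(x):
            return np.matmul(self.model.pmats(t[x]), raw[x])

        M = {x: msg(x) for x in (x1, x2, y1, y2)}
        A = M[x1] * M[x2]
        B = M[y1] * M[y2]
        _, t_uv = self._brent(A, B)
        # adjacent branches on the u side, then the v side
        P_uv = self.model.pmats(t_uv)
        PB = np.matmul(P_uv, B)
        for x, other in ((x1, x2), (x2, x1)):
            _, t[x] = self._brent(M[other] * PB, raw[x])
            M[x] = msg(x)
        A = M[x1] * M[x2]
        PA = np.matmul(P_uv.transpose(0, 2, 1), A)
        for y, other in ((y1, y2), (y2, y1)):
            _, t[y] = self._brent(M[other] * PA, raw[y])
            M[y] = msg(y)
        B = M[y1] * M[y2]
        score, t_uv = self._brent(A, B)
        return score, t_uv, t

    def nni_round(self, tree: UnrootedTree, tol: float = DEFAULT_TOL,
                  constraint: set[str] | None = None) -> bool:
        """One pass of NNI over all internal edges; greedy acceptance.

        The two interchange candidates are scored with their local
        5-branch neighbourhood re-optimised; the current arrangement is
        scored by re-optimising the focal branch (its neighbourhood is
        already fitted).  Returns True if any move was accepted.
        """
        improved = False
        for u, v in list(tree.internal_edges()):
            if v not in tree.nbrs.get(u, {}):
                continue  # edge vanished in an earlier accepted move
            memo: dict = {}
            a1, a2 = [x for x in tree.nbrs[u] if x != v]
            b1, b2 = [x for x in tree.nbrs[v] if x != u]
            k_cat = self.model.n_cat
            raw, lengths = {}, {}
            for node, anchor in ((a1, u), (a2, u), (b1, v), (b2, v)):
                if tree.is_leaf(node):
                    clv = self.leaf_clv[tree.leaf_name[node]]
                    raw[node] = np.broadcast_to(clv, (k_cat,) + clv.shape)
                else:
                    raw[node] = self._partial(tree, node, anchor, memo)
                lengths[node] = tree.nbrs[anchor][node]

            def msg(x):
                return np.matmul(self.model.pmats(lengths[x]), raw[x])

            M = {x: msg(x) for x in (a1, a2, b1, b2)}
            # current arrangement: focal branch only (its neighbourhood is
            # already fitted by the preceding sweep)
            cur_score, cur_t = self._brent(M[a1] * M[a2], M[b1] * M[b2])
            screened = []
            for x2, y1 in ((b1, a2), (b2, a2)):
                x1, y2 = a1, (b2 if x2 is b1 else b1)
                # cheap screen: focal-branch-only score with the current
                # peripheral lengths; the 5-branch refit can recover only
                # a bounded amount, so hopeless candidates are skipped
                screen, _ = self._brent(M[x1] * M[x2], M[y1] * M[y2])
                if screen >= cur_score - 10.0:
                    screened.append((screen, (x1, x2, y1, y2)))
            screened.sort(key=lambda c: -c[0])
            for _, (x1, x2, y1, y2) in screened:
                score, t_uv, t_local = self._local5(raw, lengths, x1, x2, y1, y2,
                                                    tree.nbrs[u][v])
                if score <= cur_score + tol:
                    continue
                swap_in = x2
                swap_out = a2
                t_in = tree.nbrs[v][swap_in]
                t_out = tree.nbrs[u][swap_out]
                tree.remove_edge(u, swap_out)
                tree.remove_edge(v, swap_in)
                tree.add_edge(u, swap_in, t_in)
                tree.add_edge(v, swap_out, t_out)
                if constraint is not None and not tree.has_clade(constraint):
                    # revert: the move breaks the required clade
                    tree.remove_edge(u, swap_in)
                    tree.remove_edge(v, swap_out)
                    tree.add_edge(u, swap_out, t_out)
                    tree.add_edge(v, swap_in, t_in)
                    tree.set_length(u, v, cur_t)
                    continue
                # install the refitted local branch lengths
                tree.set_length(u, v, t_uv)
                for x, t_x in t_local.items():
                    if x in tree.nbrs[u]:
                        tree.set_length(u, x, t_x)
                    elif x in tree.nbrs[v]:
                        tree.set_length(v, x, t_x)
                improved = True
                break
            else:
                tree.set_length(u, v, cur_t)
        return improved


# ---------------------------------------------------------------------------


def gtr_gamma_loglik(align: GeneAlignment, tree: UnrootedTree | SupportTree,
                     params: GTRGammaParams) -> SiteLikelihoods:
    """Per-site log-likelihoods of ``tree`` under GTR+G."""
    if isinstance(tree, SupportTree):
        tree = tree.tree
    engine = TreeLikelihood(align, GTRModel(params), taxa=sorted(tree.taxa))
    return engine.site_logliks(tree)


def estimate_parameters(align: GeneAlignment, tree: UnrootedTree,
                        engine_taxa: list[str] | None = None,
                        n_categories: int = 4) -> GTRGammaParams:
    """Estimate GTR exchangeabilities and gamma shape on a fixed tree.

    Base frequencies are empirical; the five free exchangeability
    ratios (relative to GT) and alpha are optimised numerically with
    branch lengths held fixed.  This is the standard economical scheme:
    model parameters estimated once on a starting tree, then fixed
    during topology search.
    """
    freqs = tuple(align.empirical_freqs())
    taxa = engine_taxa or sorted(tree.taxa)

    def build(theta) -> GTRGammaParams:
        ex = np.exp(np.clip(theta[:5], -7, 7))
        alpha = float(np.exp(np.clip(theta[5], np.log(0.02), np.log(50.0))))
        return GTRGammaParams(tuple(ex) + (1.0,), freqs, alpha, n_categories)

    engine = TreeLikelihood(align, GTRModel(GTRGammaParams(base_freqs=freqs)),
                            taxa=taxa)

    def objective(theta):
        # swap the model in place: site patterns and leaf partials are
        # model-independent, so recompression is unnecessary
        engine.model = GTRModel(build(theta))
        return -engine.loglik(tree)

    x0 = np.array([0.0, np.log(2.0), 0.0, 0.0, np.log(2.0), np.log(0.5)])
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxiter": 300, "xatol": 1e-3, "fatol": 1e-3})
    return build(res.x)


def _start_tree(align: GeneAlignment, taxa: list[str]) -> UnrootedTree:
    patterns, weights, _ = compress_patterns(align.subset_taxa(taxa), taxa)
    D = jc_distance_matrix(patterns, weights)
    return nj_tree(taxa, D)


def _constrained_start(align: GeneAlignment, taxa: list[str],
                       constraint: set[str]) -> UnrootedTree:
    """A starting tree in which the constraint set is monophyletic."""
    tree = _start_tree(align, taxa)
    if tree.has_clade(constraint):
        return tree
    others = [t for t in taxa if t not in constraint]
    inner = [t for t in taxa if t in constraint]
    patterns, weights, _ = compress_patterns(align.subset_taxa(taxa), taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    D = jc_distance_matrix(patterns, weights)
    # NJ on the non-constraint taxa plus one placeholder for the clade
    names = others + ["__clade__"]
    n = len(names)
    D2 = np.zeros((n, n))
    for i, ti in enumerate(others):
        for j, tj in enumerate(others):
            D2[i, j] = D[idx[ti], idx[tj]]
        D2[i, -1] = D2[-1, i] = max(np.mean([D[idx[ti], idx[c]] for c in inner]), 1e-6)
    skeleton = nj_tree(names, D2)
    hub = None
    placeholder = skeleton.node_by_name["__clade__"]
    attach, length = next(iter(skeleton.nbrs[placeholder].items()))
    skeleton.remove_edge(placeholder, attach)
    del skeleton.nbrs[placeholder]
    del skeleton.leaf_name[placeholder]
    if len(inner) == 1:
        leaf = skeleton.new_node(inner[0])
        skeleton.add_edge(attach, leaf, length)
        return skeleton
    # unrooted NJ subtree of the constraint taxa, rooted by subdividing
    # an arbitrary edge
    Din = np.array([[D[idx[a], idx[b]] for b in inner] for a in inner])
    if len(inner) == 2:
        hub = skeleton.new_node()
        skeleton.add_edge(attach, hub, length)
        for t in inner:
            skeleton.add_edge(hub, skeleton.new_node(t), max(Din[0, 1] / 2, 1e-6))
        return skeleton
    sub = nj_tree(inner, Din)
    u, v = next(iter(sub.edges()))
    half = sub.nbrs[u][v] / 2
    # graft sub into skeleton with fresh node ids
    remap: dict[int, int] = {}
    for nid in sub.nbrs:
        remap[nid] = skeleton.new_node(sub.leaf_name.get(nid))
    for a, b in sub.edges():
        if (a, b) == (min(u, v), max(u, v)):
            continue
        skeleton.add_edge(remap[a], remap[b], sub.nbrs[a][b])
    hub = skeleton.new_node()
    skeleton.add_edge(hub, remap[u], max(half, 1e-6))
    skeleton.add_edge(hub, remap[v], max(half, 1e-6))
    skeleton.add_edge(attach, hub, length)
    return skeleton


def optimize_tree(align: GeneAlignment, params: GTRGammaParams | None = None,
                  start_tree: UnrootedTree | None = None,
                  constraint: set[str] | None = None,
                  tol: float = DEFAULT_TOL, max_rounds: int = 10,
                  estimate_model: bool | None = None) -> SupportTree:
    """ML tree search: NJ start, alternating branch-length optimisation
    and NNI hill climbing until no interchange improves the score."""
    taxa = sorted(align.rows)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    if constraint is not None:
        constraint = set(constraint)
        if not constraint <= set(taxa):
            raise ValueError("constraint taxa missing from alignment")
        if len(constraint) >= len(taxa):
            raise ValueError("constraint must be a proper subset of the taxa")
        if len(constraint) < 2:
            raise ValueError("constraint needs at least 2 taxa")
    if start_tree is not None:
        tree = start_tree.copy()
        if tree.taxa != set(taxa):
            raise ValueError("start tree taxa do not match alignment")
    elif constraint is not None:
        tree = _constrained_start(align, taxa, constraint)
    else:
        tree = _start_tree(align, taxa)
    if estimate_model is None:
        estimate_model = params is None
    if params is None:
        params = GTRGammaParams(base_freqs=tuple(align.empirical_freqs()))
    if estimate_model:
        params = estimate_parameters(align, tree, engine_taxa=taxa,
                                     n_categories=params.n_categories)
    engine = TreeLikelihood(align, GTRModel(params), taxa=taxa)
    score = engine.optimize_branch_lengths(tree, sweeps=2)
    if len(taxa) >= 4:
        for _ in range(max_rounds):
            improved = engine.nni_round(tree, tol=tol, constraint=constraint)
            score = engine.optimize_branch_lengths(tree, sweeps=1)
            if not improved:
                break
    return SupportTree(tree, {}, score, params)


def bootstrap_support(align: GeneAlignment, params: GTRGammaParams | None = None,
                      reps: int = 500, seed: int = 0,
                      best: SupportTree | None = None,
                      constraint: set[str] | None = None,
                      full_search: bool = False) -> SupportTree:
    """Nonparametric bootstrap clade support for the ML tree.

    Columns are resampled with replacement (as multinomial pattern
    weights); each replicate re-optimises branch lengths and performs a
    single NNI pass from the full-data ML tree (a full search per
    replicate is available via ``full_search``).  Supports are the
    percentage of replicates containing each internal bipartition of
    the ML tree.
    """
    if reps < 1:
        raise ValueError("need at least one bootstrap replicate")
    if best is None:
        best = optimize_tree(align, params=params, constraint=constraint)
    params = best.params
    taxa = sorted(best.taxa)
    engine = TreeLikelihood(align, GTRModel(params), taxa=taxa)
    rng = np.random.default_rng(seed)
    ref = min(best.tree.taxa)
    target = set(best.tree.bipartitions().keys())
    counts = {key: 0 for key in target}
    base_weights = engine.weights.copy()
    for _ in range(reps):
        rep_engine = engine.masked_view(
            engine_weights_resample(engine, base_weights, rng))
        rep_tree = best.tree.copy()
        rep_engine.optimize_branch_lengths(rep_tree, sweeps=1)
        if len(taxa) >= 4:
            max_rounds = 10 if full_search else 2
            for _ in range(max_rounds):
                if not rep_engine.nni_round(rep_tree, constraint=constraint):
                    break
                rep_engine.optimize_branch_lengths(rep_tree, sweeps=1)
        found = rep_tree.bipartitions().keys()
        for key in target & set(found):
            counts[key] += 1
    supports = {key: int(round(100.0 * c / reps)) for key, c in counts.items()}
    return SupportTree(best.tree, supports, best.log_likelihood, params)


def engine_weights_resample(engine: TreeLikelihood, base_weights: np.ndarray,
                            rng: np.random.Generator) -> np.ndarray:
    p = base_weights / base_weights.sum()
    return rng.multinomial(int(base_weights.sum()), p).astype(float)


def constrained_ml(align: GeneAlignment, params: GTRGammaParams | None,
                   constraint: set[str], **kwargs) -> SupportTree:
    """Best tree in which ``constraint`` is forced monophyletic."""
    return optimize_tree(align, params=params, constraint=set(constraint), **kwargs)
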