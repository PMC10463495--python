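"""Felsenstein pruning, ML branch-length/alpha fitting, ancestral states.

The engine keeps, for every node, "inside" conditional likelihoods
(probability of the data below the node given the node's state) per
discrete-gamma category, with per-site log scaling factors to avoid
underflow.  "Outside" quantities (probability of everything except the
node's subtree) are computed by a root-to-tips pass and combined with
the inside quantities for marginal empirical-Bayes ancestral posteriors,
mixing rate categories by their per-site posterior weights.

Branch-length optimisation exploits the standard edge decomposition of
the likelihood: with the inside partials of the child and the outside
partials of the parent held fixed, the log-likelihood is a cheap
function of the single branch length being optimised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from . import alphabet
from .io import AminoAlignment, ValidationError, check_leaf_match
from .model import RateMatrix, SubstitutionModel, build_rate_matrix
from .tree import Phylogeny

logger = logging.getLogger(__name__)

BRANCH_BOUNDS = (1e-8, 50.0)
ALPHA_BOUNDS = (0.02, 99.0)


class PruningEngine:
    """Vectorised pruning over all sites of one alignment."""

    def __init__(self, tree: Phylogeny, model: SubstitutionModel,
                 aln: AminoAlignment) -> None:
        check_leaf_match(aln, set(tree.leaf_names))
        self.tree = tree
        self.model = model
        self.n_sites = aln.n_sites
        self.K = model.n_categories
        self.rates = model.category_rates
        self.freqs = model.freqs
        self.rate_matrix: RateMatrix = build_rate_matrix(model)
        self.lengths = tree.length.copy()

        n = tree.n_nodes
        self._codes: dict[int, np.ndarray] = {}
        for leaf in tree.leaves:
            self._codes[leaf] = aln.row(tree.name[leaf]).astype(np.intp)

        self._postorder = tree.postorder()
        self._P: list[np.ndarray | None] = [None] * n      # (K, 20, 20)
        self._I: list[np.ndarray | None] = [None] * n      # (K, n_sites, 20)
        self._M: list[np.ndarray | None] = [None] * n      # lifted child partials
        self._ls: list[np.ndarray | None] = [None] * n     # (K, n_sites) log scale
        self._refresh_transition_matrices()
        self._full_inside()

    # -- transition matrices --------------------------------------------

    def _edge_P(self, node: int) -> np.ndarray:
        t = self.lengths[node]
        return np.stack([self.rate_matrix.expm(t * r) for r in self.rates])

    def _refresh_transition_matrices(self) -> None:
        for u in range(self.tree.n_nodes):
            if u != self.tree.root:
                self._P[u] = self._edge_P(u)

    # -- inside pass -----------------------------------------------------

    def _leaf_partial(self, leaf: int) -> np.ndarray:
        codes = self._codes[leaf]
        part = np.zeros((self.n_sites, alphabet.N_STATES))
        missing = codes >= alphabet.N_STATES
        part[missing] = 1.0
        obs = ~missing
        part[np.flatnonzero(obs), codes[obs]] = 1.0
        return part

    def _compute_node(self, u: int) -> None:
        """Recompute I (and M if u is not the root) from the children."""
        kids = self.tree.children[u]
        if not kids:
            leaf = self._leaf_partial(u)
            self._I[u] = np.broadcast_to(leaf, (self.K, self.n_sites, 20)).copy()
            self._ls[u] = np.zeros((self.K, self.n_sites))
        else:
            I = None
            ls = np.zeros((self.K, self.n_sites))
            for c in kids:
                I = self._M[c] if I is None else I * self._M[c]
                ls += self._ls[c]
            scale = I.max(axis=2)
            bad = scale <= 0
            if np.any(bad):  # numerically impossible data; keep partials finite
                scale = np.where(bad, 1.0, scale)
            I /= scale[:, :, None]
            self._I[u] = I
            self._ls[u] = ls + np.log(scale)
        if u != self.tree.root:
            # M[u]_a = sum_b P_ab I_b  (per category); BLAS via matmul
            self._M[u] = self._I[u] @ self._P[u].transpose(0, 2, 1)

    def _full_inside(self) -> None:
        for u in self._postorder:
            self._compute_node(u)

    # -- likelihood -------------------------------------------------------

    def site_log_likelihoods(self) -> np.ndarray:
        r = self.tree.root
        per_cat = (self._I[r] @ self.freqs)  # (K, n_sites)
        with np.errstate(divide="ignore"):
            ll = np.log(per_cat) + self._ls[r]
        return logsumexp(ll, axis=0) - np.log(self.K)

    def log_likelihood(self) -> float:
        return float(self.site_log_likelihoods().sum())

    # -- parameter updates -------------------------------------------------

    def set_branch_length(self, node: int, t: float) -> None:
        if node == self.tree.root:
            raise ValidationError("the root has no branch")
        self.lengths[node] = t
        self._P[node] = self._edge_P(node)
        self._M[node] = self._I[node] @ self._P[node].transpose(0, 2, 1)
        for a in self.tree.path_to_root(node)[1:]:
            self._compute_node(a)

    def set_alpha(self, alpha: float) -> None:
        self.model = self.model.with_(alpha=alpha)
        self.rates = self.model.category_rates
        self._refresh_transition_matrices()
        self._full_inside()

    # -- outside pass -------------------------------------------------------

    def _category_log_weights(self) -> np.ndarray:
        """log posterior weight of each rate category per site (K, n_sites)."""
        r = self.tree.root
        with np.errstate(divide="ignore"):
            ll = np.log(self._I[r] @ self.freqs) + self._ls[r]
        return ll - logsumexp(ll, axis=0, keepdims=True)

    def node_posteriors(self, nodes: list[int]) -> dict[int, np.ndarray]:
        """Marginal state posteriors (n_sites, 20) for the given nodes.

        Scaling factors cancel inside each category's normalisation, so
        only the category weights need the full log accounting.
        """
        w = np.exp(self._category_log_weights())
        out: dict[int, np.ndarray] = {}
        for u in nodes:
            O, _ = self._outside_at(u)
            T = O * self._I[u]  # (K, n_sites, 20)
            norm = T.sum(axis=2, keepdims=True)
            norm = np.where(norm <= 0, 1.0, norm)
            out[u] = (w[:, :, None] * (T / norm)).sum(axis=0)
        return out

    # -- edge-local likelihood ----------------------------------------------

    def _outside_at(self, u: int) -> tuple[np.ndarray, np.ndarray]:
        """Outside partials at one node via a walk down from the root."""
        path = self.tree.path_to_root(u)[::-1]  # root ... u
        O = np.broadcast_to(self.freqs, (self.K, self.n_sites, 20)).copy()
        ls = np.zeros((self.K, self.n_sites))
        for parent, child in zip(path[:-1], path[1:]):
            T = O
            s = ls
            for c in self.tree.children[parent]:
                if c != child:
                    T = T * self._M[c]
                    s = s + self._ls[c]
            scale = T.max(axis=2)
            scale = np.where(scale <= 0, 1.0, scale)
            T = T / scale[:, :, None]
            O = T @ self._P[child]
            ls = s + np.log(scale)
        return O, ls

    def edge_log_likelihood(self, child: int):
        """Closure t -> total log-likelihood with only this edge varying."""
        u = int(self.tree.parent[child])
        O, Ols = self._outside_at(u)
        A = O
        Als = Ols
        for c in self.tree.children[u]:
            if c != child:
                A = A * self._M[c]
                Als = Als + self._ls[c]
        scale = A.max(axis=2)
        scale = np.where(scale <= 0, 1.0, scale)
        A = A / scale[:, :, None]
        Als = Als + np.log(scale)
        I, Ils = self._I[child], self._ls[child]
        logK = np.log(self.K)

        def loglik(t: float) -> float:
            P = np.stack([self.rate_matrix.expm(t * r) for r in self.rates])
            per_cat = ((A @ P) * I).sum(axis=2)
            with np.errstate(divide="ignore"):
                ll = np.log(per_cat) + Als + Ils
            return float((logsumexp(ll, axis=0) - logK).sum())

        return loglik


# -- public operations ---------------------------------------------------


def log_likelihood(tree: Phylogeny, model: SubstitutionModel,
                   aln: AminoAlignment) -> tuple[float, np.ndarray]:
    """Total and per-site log-likelihood of an alignment on a tree."""
    eng = PruningEngine(tree, model, aln)
    per_site = eng.site_log_likelihoods()
    return float(per_site.sum()), per_site


def site_log_likelihood(tree: Phylogeny, model: SubstitutionModel,
                        column: dict[str, str]) -> float:
    """Log-likelihood of a single alignment column (taxon -> residue)."""
    aln = AminoAlignment.from_sequences({t: c for t, c in column.items()})
    total, _ = log_likelihood(tree, model, aln)
    return total


@dataclass
class FitResult:
    """ML branch lengths and gamma shape on a fixed topology."""

    tree: Phylogeny
    branch_lengths: dict[str, float]
    alpha: float
    freqs: np.ndarray
    log_likelihood: float
    n_cycles: int
    final_improvement: float
    n_categories: int = 4
    trace: list[float] = None  # log-likelihood after each cycle

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_categories": self.n_categories,
            "freqs": list(map(float, self.freqs)),
            "branch_lengths": {k: float(v) for k, v in self.branch_lengths.items()},
            "log_likelihood": self.log_likelihood,
            "n_cycles": self.n_cycles,
            "final_improvement": self.final_improvement,
        }


def fit_parameters(
    aln: AminoAlignment,
    topology: Phylogeny,
    model: SubstitutionModel,
    *,
    freqs: str | np.ndarray = "empirical",
    optimize_alpha: bool = True,
    tol: float = 1e-6,
    max_cycles: int = 100,
) -> FitResult:
    """Coordinate-wise ML estimation of branch lengths (and alpha).

    Cycles over every branch (bounded scalar optimisation on each, with
    the rest of the tree's partials cached) and then the gamma shape,
    until the relative log-likelihood improvement drops below ``tol``.
    Deterministic given its inputs; the log-likelihood never decreases.
    """
    if len(topology.leaves) < 3:
        raise ValidationError("need at least 3 taxa to fit parameters")
    if isinstance(freqs, str) and freqs == "empirical":
        pi = aln.empirical_frequencies(pseudocount=0.5)
    elif isinstance(freqs, str) and freqs == "model":
        pi = model.freqs
    else:
        pi = np.asarray(freqs, dtype=float)
    work_model = model.with_(freqs=pi)

    eng = PruningEngine(topology, work_model, aln)
    per_site = eng.site_log_likelihoods()
    if not np.all(np.isfinite(per_site)):
        bad = int(np.flatnonzero(~np.isfinite(per_site))[0])
        raise ValidationError(
            f"non-finite likelihood at start (first offending site {bad})"
        )
    cur = float(per_site.sum())

    edges = [u for u in eng._postorder if u != topology.root]
    lo, hi = BRANCH_BOUNDS
    improvement = np.inf
    cycle = 0
    trace: list[float] = []
    for cycle in range(1, max_cycles + 1):
        before = cur
        for child in edges:
            f = eng.edge_log_likelihood(child)
            res = minimize_scalar(
                lambda t: -f(t), bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-7},
            )
            if -res.fun > cur:
                eng.set_branch_length(child, float(res.x))
                cur = -res.fun
        if optimize_alpha:
            alpha0 = eng.model.alpha

            def g(a: float) -> float:
                eng.set_alpha(a)
                return -eng.log_likelihood()

            res = minimize_scalar(
                g, bounds=ALPHA_BOUNDS, method="bounded", options={"xatol": 1e-3},
            )
            if -res.fun > cur:
                eng.set_alpha(float(res.x))
                cur = -res.fun
            else:
                eng.set_alpha(alpha0)
        improvement = cur - before
        trace.append(cur)
        if improvement < tol * abs(cur):
            break

    fitted = topology.with_lengths(
        {topology.name[u]: float(eng.lengths[u]) for u in edges}
    )
    return FitResult(
        tree=fitted,
        branch_lengths={topology.name[u]: float(eng.lengths[u]) for u in edges},
        alpha=float(eng.model.alpha),
        freqs=pi,
        log_likelihood=cur,
        n_cycles=cycle,
        final_improvement=float(improvement),
        n_categories=model.n_categories,
        trace=trace,
    )


@dataclass
class AncestralStates:
    """Marginal posteriors and MAP residues per internal node and site."""

    node_names: list[str]
    n_sites: int
    posterior: dict[str, np.ndarray]   # node name -> (n_sites, 20)
    map_codes: dict[str, np.ndarray]   # node name -> (n_sites,) int8

    def map_residue(self, node: str, site: int) -> str:
        return alphabet.AMINO_ACIDS[int(self.map_codes[node][site])]


def _map_with_alphabetical_ties(post: np.ndarray) -> np.ndarray:
    """Argmax over residues, exact ties resolved to the alphabetically
    first residue letter."""
    perm = alphabet.ALPHABETICAL_ORDER
    idx = np.argmax(post[:, perm], axis=1)
    return perm[idx].astype(np.int8)


def marginal_ancestral_states(
    tree: Phylogeny,
    model: SubstitutionModel,
    aln: AminoAlignment,
    nodes: list[str] | None = None,
    chunk_size: int = 5000,
) -> AncestralStates:
    """Empirical-Bayes marginal ancestral reconstruction.

    Posteriors are mixed over rate categories using each site's category
    posterior; ``nodes`` restricts the computation to a subset of
    internal nodes (all of them by default).  Sites are processed in
    chunks to bound memory on long alignments.
    """
    nonroot = set(np.flatnonzero(tree.parent >= 0))
    if np.any(~np.isfinite(tree.length[list(nonroot)])):
        raise ValidationError("tree has missing branch lengths")
    if nodes is None:
        node_ids = tree.internal_nodes
    else:
        node_ids = [tree.node(nm) for nm in nodes]
        for u in node_ids:
            if not tree.children[u]:
                raise ValidationError(f"{tree.name[u]!r} is a leaf, not ancestral")
    names = [tree.name[u] for u in node_ids]

    posts = {nm: np.empty((aln.n_sites, alphabet.N_STATES)) for nm in names}
    for start in range(0, aln.n_sites, chunk_size):
        stop = min(start + chunk_size, aln.n_sites)
        sub = AminoAlignment(aln.orthogroup_id, aln.taxa,
                             aln.matrix[:, start:stop])
        eng = PruningEngine(tree, model, sub)
        chunk_posts = eng.node_posteriors(node_ids)
        for u, nm in zip(node_ids, names):
            posts[nm][start:stop] = chunk_posts[u]
    maps = {nm: _map_with_alphabetical_ties(posts[nm]) for nm in names}
    return AncestralStates(node_names=names, n_sites=aln.n_sites,
                           posterior=posts, map_codes=maps)
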