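"""Null-alignment simulation and planting of known convergent sites.

``simulate_null`` evolves amino-acid sites independently down the tree
under the substitution model: each site draws a rate category uniformly
and a root residue from the stationary distribution, then states
propagate branch by branch from the matching transition-probability
rows.  No indels are produced.  ``plant_convergence`` overwrites chosen
sites with a strict parallel pattern (one residue in every foreground
taxon, a different residue in every background taxon) so a scan can be
scored against exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alphabet
from .io import AminoAlignment, TraitMap, ValidationError, write_alignment
from .model import SubstitutionModel, build_rate_matrix
from .tree import Phylogeny


@dataclass
class SimulationConfig:
    n_sites: int
    seed: int
    model: SubstitutionModel
    tree: Phylogeny

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValidationError("n_sites must be at least 1")


def _propagate(parent_states: np.ndarray, cats: np.ndarray,
               P_by_cat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample child states from the parent states' transition rows."""
    child = np.empty_like(parent_states)
    for k in range(P_by_cat.shape[0]):
        idx = np.flatnonzero(cats == k)
        if idx.size == 0:
            continue
        cum = np.cumsum(P_by_cat[k], axis=1)
        u = rng.random(idx.size)
        rows = cum[parent_states[idx]]
        child[idx] = (u[:, None] > rows).sum(axis=1)
    return np.minimum(child, alphabet.N_STATES - 1)


def simulate_null(config: SimulationConfig,
                  rng: np.random.Generator | None = None,
                  return_internal: bool = False):
    """Simulate one gap-free null alignment (no convergent evolution).

    Deterministic for a given seed; pass an explicit generator to use an
    externally managed stream (e.g. per-gene substreams).  With
    ``return_internal`` the true states at the internal nodes are
    returned as well (keyed by node name), for reconstruction audits.
    """
    tree, model = config.tree, config.model
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_sites
    K = model.n_categories
    rates = model.category_rates
    rm = build_rate_matrix(model)

    cats = rng.integers(0, K, size=n)
    states = {tree.root: rng.choice(alphabet.N_STATES, size=n, p=model.freqs)}
    for u in tree.preorder():
        if u == tree.root:
            continue
        P = np.stack([rm.expm(tree.length[u] * r) for r in rates])
        states[u] = _propagate(states[int(tree.parent[u])], cats, P, rng)

    taxa = tree.leaf_names
    matrix = np.stack([states[tree.node(t)] for t in taxa]).astype(np.int8)
    aln = AminoAlignment(orthogroup_id=f"sim_seed{config.seed}",
                         taxa=taxa, matrix=matrix)
    if return_internal:
        internal = {tree.name[u]: states[u].astype(np.int8)
                    for u in tree.internal_nodes}
        return aln, internal
    return aln


@dataclass
class PlantSpec:
    """Sites to overwrite with a strict parallel pattern.

    Each entry is (site, a, b): residue ``a`` is written into every
    foreground taxon and residue ``b`` (``b != a``) into every background
    taxon at that 0-based site.
    """

    entries: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        sites = [s for s, _, _ in self.entries]
        if len(set(sites)) != len(sites):
            raise ValidationError("planted sites must be disjoint")
        for s, a, b in self.entries:
            if a == b:
                raise ValidationError(
                    f"site {s}: foreground and background residues must differ"
                )
            for r in (a, b):
                if r not in alphabet.AMINO_ACIDS:
                    raise ValidationError(f"site {s}: {r!r} is not a residue")


def plant_convergence(
    aln: AminoAlignment, traits: TraitMap, spec: PlantSpec
) -> tuple[AminoAlignment, pd.DataFrame]:
    """Overwrite sites per the spec; returns the new alignment and the
    truth table (columns: site [1-based in output files], a, b)."""
    for s, _, _ in spec.entries:
        if not 0 <= s < aln.n_sites:
            raise ValidationError(f"planted site {s} out of range")
    if set(aln.taxa) != traits.all_taxa:
        raise ValidationError("trait map taxa do not match the alignment")
    matrix = aln.matrix.copy()
    fg = [aln.taxa.index(t) for t in sorted(traits.foreground)]
    bg = [aln.taxa.index(t) for t in sorted(traits.background)]
    rows = []
    for s, a, b in spec.entries:
        matrix[fg, s] = alphabet.AMINO_ACIDS.index(a)
        matrix[bg, s] = alphabet.AMINO_ACIDS.index(b)
        rows.append({"site": s, "a": a, "b": b})
    truth = pd.DataFrame(rows, columns=["site", "a", "b"])
    out = AminoAlignment(aln.orthogroup_id, list(aln.taxa), matrix)
    return out, truth


def generate_orthogroup_set(
    n_genes: int,
    sites_per_gene: int,
    planted_fraction: float,
    seed: int,
    *,
    tree: Phylogeny,
    traits: TraitMap,
    model: SubstitutionModel,
    out_dir: str | Path | None = None,
    planted_sites_per_gene: int = 2,
) -> tuple[dict[str, AminoAlignment], pd.DataFrame, dict]:
    """Simulate a set of per-gene alignments, planting strict parallel
    substitutions into a fraction of the genes.

    Per-gene RNG substreams are spawned from the master seed, so each
    gene's alignment is independent of how many other genes are drawn.
    Returns (alignments by gene id, truth table, manifest); if
    ``out_dir`` is given, also writes one FASTA per gene, ``truth.tsv``
    and ``manifest.json``.
    """
    if n_genes < 1 or sites_per_gene < 1:
        raise ValidationError("gene and site counts must be at least 1")
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValidationError("planted_fraction must lie in [0, 1]")
    n_planted = round(n_genes * planted_fraction)
    master = np.random.SeedSequence(seed)
    gene_seqs = master.spawn(n_genes)

    alignments: dict[str, AminoAlignment] = {}
    truth_rows = []
    for g in range(n_genes):
        gene_id = f"OG{g + 1:07d}"
        rng = np.random.default_rng(gene_seqs[g])
        cfg = SimulationConfig(n_sites=sites_per_gene, seed=seed,
                               model=model, tree=tree)
        aln = simulate_null(cfg, rng=rng)
        aln.orthogroup_id = gene_id
        if g < n_planted:
            sites = rng.choice(sites_per_gene,
                               size=min(planted_sites_per_gene, sites_per_gene),
                               replace=False)
            entries = []
            for s in sorted(int(x) for x in sites):
                a, b = rng.choice(alphabet.N_STATES, size=2, replace=False)
                entries.append((s, alphabet.AMINO_ACIDS[a],
                                alphabet.AMINO_ACIDS[b]))
            aln, truth = plant_convergence(aln, traits, PlantSpec(entries))
            aln.orthogroup_id = gene_id
            for _, row in truth.iterrows():
                truth_rows.append({"gene": gene_id, "site": int(row["site"]) + 1,
                                   "a": row["a"], "b": row["b"]})
        alignments[gene_id] = aln

    truth = pd.DataFrame(truth_rows, columns=["gene", "site", "a", "b"])
    manifest = {
        "seed": seed,
        "n_genes": n_genes,
        "sites_per_gene": sites_per_gene,
        "planted_fraction": planted_fraction,
        "planted_sites_per_gene": planted_sites_per_gene,
        "n_planted_genes": n_planted,
        "model": {"name": model.name, "alpha": model.alpha,
                  "n_categories": model.n_categories},
        "tree": tree.to_newick(),
        "taxa": tree.leaf_names,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for gene_id, aln in alignments.items():
            write_alignment(aln, out / f"{gene_id}.fasta")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return alignments, truth, manifest
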