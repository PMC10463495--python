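"""Convergence detection at conservative sites (CCS) and noise estimation.

Site rules, for a foreground set (cleaners) and background set
(non-cleaners) with minimum foreground share m:

* relaxed convergence — some residue ``a`` is carried by >= m foreground
  taxa and differs from the residue of every background taxon;
* CCS convergence — additionally, all background taxa share one
  identical residue ``b`` (the site is conservative);
* strict parallel (CEG-qualifying) — every foreground taxon carries
  ``a`` and every background taxon carries ``b != a``.

Noise classification on null simulations compares the reconstructed
residue at the ancestor of the background clade (minus the outgroup)
with the outgroup's observed residue: a detection is a *false*
convergence when they disagree (the detection rests on a
misreconstructed ancestral state) and a *random* convergence otherwise
(chance parallel substitutions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import alphabet
from .engine import AncestralStates, marginal_ancestral_states
from .io import AminoAlignment, TraitMap, ValidationError
from .model import SubstitutionModel
from .tree import Phylogeny

logger = logging.getLogger(__name__)

GAP_POLICIES = ("exclude_site", "treat_as_mismatch")

CLASS_NONE = "none"
CLASS_RELAXED = "relaxed_convergence"
CLASS_CCS = "ccs_convergence"

NOISE_NA = "not_applicable"
NOISE_RANDOM = "random"
NOISE_FALSE = "false"


@dataclass(frozen=True)
class ScanConfig:
    min_foreground_share: int = 3
    require_all_foreground_for_ceg: bool = True
    gap_policy: str = "exclude_site"

    def __post_init__(self) -> None:
        if self.min_foreground_share < 1:
            raise ValidationError("min_foreground_share must be >= 1")
        if self.gap_policy not in GAP_POLICIES:
            raise ValidationError(f"unknown gap policy {self.gap_policy!r}")


@dataclass(frozen=True)
class SiteCall:
    """One detected convergence (site x convergent residue)."""

    site: int                       # 0-based; written reports are 1-based
    klass: str
    residue_a: str
    residue_b: str | None           # background residue when conservative
    carriers: tuple[str, ...]       # foreground taxa carrying residue_a
    strict_parallel: bool
    outgroup_residue: str | None
    n_foreground_matching_background: int
    noise_class: str = NOISE_NA

    @property
    def site_1based(self) -> int:
        return self.site + 1

    @property
    def many_foreground_match_background(self) -> bool:
        """Diagnostic flag for the '>2 foreground taxa share a residue
        with the background' pattern; recorded, not used as the primary
        noise classifier."""
        return self.n_foreground_matching_background > 2


@dataclass(frozen=True)
class CegCall:
    """A convergently evolving gene: >= 1 strict parallel site."""

    orthogroup_id: str
    sites: tuple[int, ...]                 # 1-based
    residues: tuple[tuple[str, str], ...]  # (a, b) per site


@dataclass
class SiteMasks:
    """Vectorised per-site classification of one alignment."""

    excluded: np.ndarray       # gap-policy exclusions
    relaxed: np.ndarray
    ccs: np.ndarray
    strict: np.ndarray
    calls: list[SiteCall]


def _classify_matrix(aln: AminoAlignment, traits: TraitMap,
                     config: ScanConfig) -> SiteMasks:
    if set(aln.taxa) != traits.all_taxa:
        raise ValidationError("trait map taxa do not match the alignment")
    X = aln.matrix
    n = aln.n_sites
    fg_taxa = sorted(traits.foreground)
    bg_taxa = sorted(traits.background)
    fg = X[[aln.taxa.index(t) for t in fg_taxa]]
    bg = X[[aln.taxa.index(t) for t in bg_taxa]]
    F = fg.shape[0]
    m = config.min_foreground_share
    if m > F:
        raise ValidationError(
            f"min_foreground_share {m} exceeds foreground size {F}"
        )

    missing_fg = fg >= alphabet.N_STATES
    missing_bg = bg >= alphabet.N_STATES
    if config.gap_policy == "exclude_site":
        excluded = missing_fg.any(axis=0) | missing_bg.any(axis=0)
    else:  # treat_as_mismatch: missing cells simply never match anything
        excluded = np.zeros(n, dtype=bool)

    counts_fg = np.stack([(fg == r).sum(axis=0)
                          for r in range(alphabet.N_STATES)])
    bg_present = np.stack([(bg == r).any(axis=0)
                           for r in range(alphabet.N_STATES)])
    bg_complete = ~missing_bg.any(axis=0)
    bg_unanimous = bg_complete & (bg == bg[0]).all(axis=0)

    qual = (counts_fg >= m) & ~bg_present & ~excluded[None, :]
    relaxed = qual.any(axis=0)
    ccs = relaxed & bg_unanimous
    strict_res = qual & (counts_fg == F) & bg_unanimous[None, :]
    strict = strict_res.any(axis=0)

    out_idx = bg_taxa.index(traits.outgroup)
    calls: list[SiteCall] = []
    for s in np.flatnonzero(relaxed):
        b = alphabet.AMINO_ACIDS[bg[0, s]] if bg_unanimous[s] else None
        og_code = bg[out_idx, s]
        og = (alphabet.AMINO_ACIDS[og_code]
              if og_code < alphabet.N_STATES else None)
        # foreground taxa whose residue occurs anywhere in the background
        n_match = int(sum(bool(bg_present[fg[i, s], s])
                          for i in range(F) if fg[i, s] < alphabet.N_STATES))
        for r in np.flatnonzero(qual[:, s]):
            a = alphabet.AMINO_ACIDS[r]
            carriers = tuple(fg_taxa[i] for i in range(F) if fg[i, s] == r)
            calls.append(SiteCall(
                site=int(s),
                klass=CLASS_CCS if ccs[s] else CLASS_RELAXED,
                residue_a=a,
                residue_b=b,
                carriers=carriers,
                strict_parallel=bool(strict_res[r, s]),
                outgroup_residue=og,
                n_foreground_matching_background=n_match,
            ))
    return SiteMasks(excluded=excluded, relaxed=relaxed, ccs=ccs,
                     strict=strict, calls=calls)


def classify_site(column: dict[str, str], traits: TraitMap,
                  config: ScanConfig | None = None) -> list[SiteCall]:
    """Classify a single alignment column (taxon -> residue character).

    Returns one call per qualifying convergent residue (usually zero or
    one; two residues can each reach the foreground-share threshold at
    the same site and are then reported separately).
    """
    config = config or ScanConfig()
    aln = AminoAlignment.from_sequences({t: r for t, r in column.items()})
    return _classify_matrix(aln, traits, config).calls


def background_ancestor_node(tree: Phylogeny, traits: TraitMap) -> str:
    """Name of the MRCA of the background taxa minus the outgroup.

    The background may be paraphyletic, so this node can subtend
    foreground taxa as well; it is the reference ancestor whose
    reconstruction is audited against the outgroup's observed residue.
    """
    return tree.name[tree.mrca(sorted(traits.background_no_outgroup))]


def classify_noise(call: SiteCall, asr: AncestralStates, traits: TraitMap,
                   tree: Phylogeny) -> SiteCall:
    """Attach a noise class (random / false) to a detected convergence.

    False when the MAP residue reconstructed at the background ancestor
    (outgroup excluded) differs from the outgroup's observed residue at
    the site; random otherwise.
    """
    if call.klass == CLASS_NONE:
        raise ValidationError("cannot noise-classify a non-detection")
    if call.outgroup_residue is None:
        logger.warning("site %d: outgroup residue missing; skipped",
                       call.site_1based)
        return call
    node = background_ancestor_node(tree, traits)
    anc = asr.map_residue(node, call.site)
    noise = NOISE_FALSE if anc != call.outgroup_residue else NOISE_RANDOM
    return replace(call, noise_class=noise)


def scan_orthogroups(
    alignments: dict[str, AminoAlignment] | list[AminoAlignment],
    tree: Phylogeny,
    traits: TraitMap,
    config: ScanConfig | None = None,
) -> tuple[list[CegCall], pd.DataFrame, dict[str, str]]:
    """Scan per-gene alignments for convergently evolving genes.

    A gene is a CEG iff it has >= 1 strict parallel site.  Returns the
    CEG calls, a per-site table of every detected convergence (1-based
    coordinates), and a dict of per-gene errors (the scan continues past
    genes whose taxa do not match the tree).
    """
    config = config or ScanConfig()
    if isinstance(alignments, dict):
        items = sorted(alignments.items())
    else:
        items = sorted((a.orthogroup_id, a) for a in alignments)
    tree_leaves = set(tree.leaf_names)

    cegs: list[CegCall] = []
    rows: list[dict] = []
    errors: dict[str, str] = {}
    for gene_id, aln in items:
        if set(aln.taxa) != tree_leaves:
            errors[gene_id] = "alignment taxa do not match the tree leaves"
            logger.error("%s: %s", gene_id, errors[gene_id])
            continue
        masks = _classify_matrix(aln, traits, config)
        strict_sites: list[int] = []
        strict_res: list[tuple[str, str]] = []
        for call in masks.calls:
            rows.append({
                "gene": gene_id,
                "site": call.site_1based,
                "class": call.klass,
                "strict_parallel": call.strict_parallel,
                "a": call.residue_a,
                "b": call.residue_b if call.residue_b is not None else "",
                "carriers": ",".join(call.carriers),
            })
            if call.strict_parallel:
                strict_sites.append(call.site_1based)
                strict_res.append((call.residue_a, call.residue_b))
        qualifies = masks.strict.any() if not config.require_all_foreground_for_ceg \
            else bool(strict_sites)
        if qualifies and strict_sites:
            cegs.append(CegCall(orthogroup_id=gene_id,
                                sites=tuple(strict_sites),
                                residues=tuple(strict_res)))
    sites = pd.DataFrame(
        rows, columns=["gene", "site", "class", "strict_parallel",
                       "a", "b", "carriers"],
    )
    return cegs, sites, errors


@dataclass
class NoiseReport:
    """Detected-convergence counts on a null simulation, before and
    after the conservative-site restriction, split by noise class."""

    n_sites: int
    relaxed: dict[str, int]
    ccs: dict[str, int]
    reduction_percent: dict[str, float | None]
    ancestral_accuracy: float
    seed: int | None
    config: dict

    @property
    def n_relaxed(self) -> int:
        return sum(self.relaxed.values())

    @property
    def n_ccs(self) -> int:
        return sum(self.ccs.values())

    def to_dict(self) -> dict:
        red = {k: ("n/a" if v is None else v)
               for k, v in self.reduction_percent.items()}
        return {
            "n_sites": self.n_sites,
            "relaxed": dict(self.relaxed),
            "ccs_restricted": dict(self.ccs),
            "reduction_percent": red,
            "ancestral_accuracy": self.ancestral_accuracy,
            "seed": self.seed,
            "config": self.config,
        }


def _reduction(before: int, after: int) -> float | None:
    if before == 0:
        return None
    return 100.0 * (1.0 - after / before)


def noise_report(
    null_aln: AminoAlignment,
    tree: Phylogeny,
    traits: TraitMap,
    model: SubstitutionModel,
    config: ScanConfig | None = None,
    seed: int | None = None,
    chunk_size: int = 5000,
) -> tuple[NoiseReport, list[SiteCall]]:
    """Run the full noise-estimation audit on a null alignment.

    Detects convergences, reconstructs the background-ancestor state at
    every site, noise-classifies each detected site and reports counts
    at the relaxed stage and after the CCS restriction, with percent
    reductions (100 * (1 - after/before); undefined when before is 0).
    Also reports overall ancestral reconstruction accuracy, i.e. the
    fraction of sites where the background-ancestor MAP residue matches
    the outgroup's observed residue.
    """
    config = config or ScanConfig()
    masks = _classify_matrix(null_aln, traits, config)
    node = background_ancestor_node(tree, traits)
    asr = marginal_ancestral_states(tree, model, null_aln, nodes=[node],
                                    chunk_size=chunk_size)

    out_row = null_aln.row(traits.outgroup)
    observed = out_row < alphabet.N_STATES
    agree = (asr.map_codes[node] == out_row) & observed
    accuracy = float(agree.sum() / max(observed.sum(), 1))

    classified = [classify_noise(c, asr, traits, tree) for c in masks.calls]

    # noise class is a per-site property; count each detected site once
    site_noise: dict[int, tuple[str, str]] = {}
    for c in classified:
        site_noise[c.site] = (c.klass, c.noise_class)
    relaxed_counts = {NOISE_RANDOM: 0, NOISE_FALSE: 0}
    ccs_counts = {NOISE_RANDOM: 0, NOISE_FALSE: 0}
    for _, (klass, noise) in site_noise.items():
        if noise == NOISE_NA:
            continue
        relaxed_counts[noise] += 1
        if klass == CLASS_CCS:
            ccs_counts[noise] += 1

    report = NoiseReport(
        n_sites=null_aln.n_sites,
        relaxed=relaxed_counts,
        ccs=ccs_counts,
        reduction_percent={
            NOISE_RANDOM: _reduction(relaxed_counts[NOISE_RANDOM],
                                     ccs_counts[NOISE_RANDOM]),
            NOISE_FALSE: _reduction(relaxed_counts[NOISE_FALSE],
                                    ccs_counts[NOISE_FALSE]),
        },
        ancestral_accuracy=accuracy,
        seed=seed,
        config={
            "min_foreground_share": config.min_foreground_share,
            "gap_policy": config.gap_policy,
            "alpha": model.alpha,
            "n_categories": model.n_categories,
            "model": model.name,
        },
    )
    return report, classified
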