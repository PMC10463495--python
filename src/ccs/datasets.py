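"""Built-in study system: a 14-taxon cleaner-fish phylogeny.

Six cleaner wrasses (one dedicated, five facultative) form the
foreground; two non-cleaner wrasses and six reference teleosts form the
background, with the spotted gar as the designated outgroup.  The
topology follows accepted relationships among these lineages; branch
lengths are plausible amino-acid distances (substitutions per site) for
a clade spanning roughly 300 My of divergence, chosen once as the
default conditions for null simulations and parameter-recovery tests.
"""

from __future__ import annotations

from .io import TraitMap
from .tree import Phylogeny

#: cleaner (foreground) species
CLEANERS = (
    "Labroides_dimidiatus",
    "Thalassoma_bifasciatum",
    "Symphodus_melops",
    "Labrus_bergylta",
    "Semicossyphus_pulcher",
    "Tautogolabrus_adspersus",
)

#: non-cleaner (background) species; the spotted gar is the outgroup
NON_CLEANERS = (
    "Notolabrus_celidotus",
    "Cheilinus_undulatus",
    "Danio_rerio",
    "Oryzias_latipes",
    "Xiphophorus_maculatus",
    "Takifugu_rubripes",
    "Gasterosteus_aculeatus",
    "Lepisosteus_oculatus",
)

OUTGROUP = "Lepisosteus_oculatus"

CLEANER_FISH_NEWICK = (
    "(Lepisosteus_oculatus:0.35,"
    "(Danio_rerio:0.30,"
    "((Oryzias_latipes:0.22,Xiphophorus_maculatus:0.20):0.06,"
    "((Takifugu_rubripes:0.25,Gasterosteus_aculeatus:0.20):0.05,"
    "(Cheilinus_undulatus:0.12,"
    "((Labroides_dimidiatus:0.10,"
    "(Thalassoma_bifasciatum:0.09,Notolabrus_celidotus:0.08):0.015):0.02,"
    "((Symphodus_melops:0.07,Labrus_bergylta:0.06):0.015,"
    "(Semicossyphus_pulcher:0.07,Tautogolabrus_adspersus:0.08):0.015):0.02"
    "):0.02):0.05):0.03):0.04):0.05);"
)


def cleaner_fish_tree() -> Phylogeny:
    """The default 14-taxon rooted tree with branch lengths."""
    return Phylogeny.from_newick(CLEANER_FISH_NEWICK)


def cleaner_fish_traits() -> TraitMap:
    """Foreground = six cleaners, background = eight non-cleaners,
    outgroup = spotted gar."""
    return TraitMap.create(CLEANERS, NON_CLEANERS, OUTGROUP)
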