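"""Shared data model and readers/writers for the standard file formats.

The pipeline touches FASTA (aligned amino-acid sequences per orthogroup),
Newick (rooted species tree, handled in :mod:`ccs.tree`), and TSV (trait
map and per-gene statistics tables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import alphabet

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Sequences do not form a valid alignment."""


class FormatError(ValueError):
    """A file violates its declared format."""


class ValidationError(ValueError):
    """An object violates a pipeline invariant."""


@dataclass
class AminoAlignment:
    """A taxa x sites matrix of encoded amino-acid residues.

    ``matrix`` holds one int8 code per cell (see :mod:`ccs.alphabet`);
    rows follow the order of ``taxa``.
    """

    orthogroup_id: str
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise AlignmentError("matrix must be 2-D (taxa x sites)")
        if len(self.taxa) != self.matrix.shape[0]:
            raise AlignmentError(
                f"{len(self.taxa)} taxa but {self.matrix.shape[0]} matrix rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise FormatError("duplicate taxon names in alignment")
        if self.matrix.size and (
            self.matrix.min() < 0 or self.matrix.max() > alphabet.UNKNOWN
        ):
            raise AlignmentError("matrix contains codes outside the alphabet")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def column(self, site: int) -> np.ndarray:
        return self.matrix[:, site]

    def sequence(self, taxon: str) -> str:
        return alphabet.decode(self.row(taxon))

    def empirical_frequencies(self, pseudocount: float = 0.0) -> np.ndarray:
        """Observed (+F) residue frequencies over non-missing cells."""
        counts = np.bincount(
            self.matrix[self.matrix < alphabet.N_STATES].ravel(),
            minlength=alphabet.N_STATES,
        ).astype(float)
        counts += pseudocount
        total = counts.sum()
        if total == 0:
            raise ValidationError("alignment has no non-missing residues")
        return counts / total

    @classmethod
    def from_sequences(
        cls, seqs: dict[str, str], orthogroup_id: str = ""
    ) -> "AminoAlignment":
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        n = lengths.pop() if lengths else 0
        matrix = np.empty((len(taxa), n), dtype=np.int8)
        for i, t in enumerate(taxa):
            codes, bad = alphabet.encode_sequence(seqs[t])
            if bad:
                logger.warning(
                    "%s: %d unrecognised character(s) in %s mapped to UNKNOWN (%s)",
                    orthogroup_id or "<alignment>", len(bad), t,
                    ",".join(sorted(set(bad))),
                )
            matrix[i] = codes
        return cls(orthogroup_id=orthogroup_id, taxa=taxa, matrix=matrix)


def read_alignment(path: str | Path, format: str = "fasta") -> AminoAlignment:
    """Read an aligned amino-acid FASTA file into an :class:`AminoAlignment`.

    Sequences must all have the same length; duplicate taxon names are an
    error.  Characters outside the 20-residue alphabet are mapped to
    UNKNOWN with a logged warning.
    """
    if format != "fasta":
        raise FormatError(f"unsupported alignment format: {format!r}")
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate taxon {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    return AminoAlignment.from_sequences(seqs, orthogroup_id=path.stem)


def write_alignment(aln: AminoAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(aln.sequence(t)), id=t, description="") for t in aln.taxa
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class TraitMap:
    """Partition of the taxa into foreground (cleaners) and background.

    The outgroup is the single most basal background taxon; its observed
    residue anchors the ancestral-accuracy audit.
    """

    foreground: frozenset[str]
    background: frozenset[str]
    outgroup: str

    def __post_init__(self) -> None:
        if not self.foreground:
            raise ValidationError("foreground taxon set is empty")
        if not self.background:
            raise ValidationError("background taxon set is empty")
        overlap = self.foreground & self.background
        if overlap:
            raise ValidationError(f"taxa labelled both ways: {sorted(overlap)}")
        if self.outgroup not in self.background:
            raise ValidationError(
                f"outgroup {self.outgroup!r} must be a background taxon"
            )

    @property
    def all_taxa(self) -> frozenset[str]:
        return self.foreground | self.background

    @property
    def background_no_outgroup(self) -> frozenset[str]:
        return self.background - {self.outgroup}

    @classmethod
    def create(
        cls, foreground, background, outgroup: str
    ) -> "TraitMap":
        return cls(frozenset(foreground), frozenset(background), outgroup)


_FOREGROUND_LABELS = {"foreground", "cleaner", "fg", "1"}
_BACKGROUND_LABELS = {"background", "non-cleaner", "noncleaner", "bg", "0"}
_OUTGROUP_LABELS = {"outgroup"}


def read_traits(path: str | Path) -> TraitMap:
    """Read a two-column TSV trait map (taxon <tab> label).

    Labels: ``foreground``/``cleaner`` vs ``background``/``non-cleaner``;
    exactly one taxon carries the label ``outgroup`` and is placed in the
    background set.
    """
    fg: set[str] = set()
    bg: set[str] = set()
    outgroup: str | None = None
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
        taxon, label = parts[0].strip(), parts[1].strip().lower()
        if taxon in seen:
            raise FormatError(f"{path}:{lineno}: taxon {taxon!r} listed twice")
        seen.add(taxon)
        if label in _FOREGROUND_LABELS:
            fg.add(taxon)
        elif label in _BACKGROUND_LABELS:
            bg.add(taxon)
        elif label in _OUTGROUP_LABELS:
            if outgroup is not None:
                raise FormatError(f"{path}:{lineno}: second outgroup {taxon!r}")
            outgroup = taxon
            bg.add(taxon)
        else:
            raise FormatError(f"{path}:{lineno}: unknown label {label!r}")
    if outgroup is None:
        raise FormatError(f"{path}: no taxon labelled 'outgroup'")
    return TraitMap(frozenset(fg), frozenset(bg), outgroup)


def write_traits(traits: TraitMap, path: str | Path) -> None:
    lines = []
    for t in sorted(traits.foreground):
        lines.append(f"{t}\tforeground")
    for t in sorted(traits.background):
        if t == traits.outgroup:
            lines.append(f"{t}\toutgroup")
        else:
            lines.append(f"{t}\tbackground")
    Path(path).write_text("\n".join(lines) + "\n")


def read_result_table(
    path: str | Path, required_columns: list[str] | None = None
) -> pd.DataFrame:
    """Read a per-gene TSV result table, checking required columns."""
    df = pd.read_csv(path, sep="\t")
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise FormatError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
    return df


def check_leaf_match(aln: AminoAlignment, leaf_names: set[str], what: str = "tree") -> None:
    """Require alignment taxa == tree leaves (never silently subset)."""
    a, t = set(aln.taxa), set(leaf_names)
    if a != t:
        only_a = sorted(a - t)
        only_t = sorted(t - a)
        raise ValidationError(
            f"alignment/{what} leaf mismatch: "
            f"only in alignment {only_a}; only in {what} {only_t}"
        )
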