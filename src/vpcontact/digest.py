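"""In-silico restriction digestion: genome-wide site and fragment maps.

A restriction enzyme's recognition motif partitions each chromosome into
restriction fragments. Viewpoint assays (4C, Capture-C) operate on the
identity of these sites/fragments rather than on base-level alignments, so
the map built here — the reduced "library" of genome-wide sites — is the
coordinate system for everything downstream.

Conventions (recorded in every output header):

* coordinates are 0-based, half-open (BED-compatible);
* the cut is modeled at the motif start (blunt simplification — the enzyme's
  sticky-end offset is irrelevant for site/fragment identity);
* windows containing ``N`` never match a motif (conservative gap handling).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io import write_bed

#: Built-in enzyme motifs. Not exhaustive — arbitrary motifs are accepted
#: everywhere an enzyme is accepted.
ENZYMES: dict[str, str] = {
    "HindIII": "AAGCTT",
    "DpnII": "GATC",
    "MboI": "GATC",
    "EcoRI": "GAATTC",
    "NlaIII": "CATG",
}

_CANONICAL = frozenset("ACGT")


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: a name and its recognition motif."""

    name: str
    motif: str

    def __post_init__(self):
        if not self.motif:
            raise ValueError("enzyme motif must be non-empty")
        if len(self.motif) < 4:
            raise ValueError(f"enzyme motif must be >= 4 bp, got {self.motif!r}")
        bad = set(self.motif) - _CANONICAL
        if bad:
            raise ValueError(f"enzyme motif contains non-canonical bases: {sorted(bad)}")


def resolve_enzyme(name_or_motif: str) -> EnzymeSpec:
    """Turn an enzyme name (built-in table) or a raw motif into an EnzymeSpec."""
    if name_or_motif in ENZYMES:
        return EnzymeSpec(name_or_motif, ENZYMES[name_or_motif])
    return EnzymeSpec(name_or_motif.upper(), name_or_motif.upper())


def find_sites(sequence: str, motif: str) -> list[int]:
    """All 0-based start positions of ``motif`` in ``sequence``.

    Overlapping occurrences are reported. Exact matching only, so any window
    containing ``N`` (or other non-ACGT characters) is never a match.

    Raises
    ------
    ValueError
        If the motif is empty.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    out: list[int] = []
    i = sequence.find(motif)
    while i != -1:
        out.append(i)
        i = sequence.find(motif, i + 1)
    return out


@dataclass
class RestrictionMap:
    """Genome-wide ordered restriction sites and the fragments they delimit.

    ``boundaries[chrom]`` holds the fragment boundaries: position 0, every
    site position, and the chromosome length (deduplicated, increasing).
    Fragment ``i`` on a chromosome is ``[boundaries[i], boundaries[i + 1])``;
    fragments tile the chromosome exactly.
    """

    enzyme: EnzymeSpec
    chrom_lengths: dict[str, int]
    sites: dict[str, np.ndarray]
    boundaries: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, pos in self.sites.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.sites[chrom] = pos
            if chrom not in self.boundaries:
                L = self.chrom_lengths[chrom]
                self.boundaries[chrom] = np.unique(
                    np.concatenate(([0], pos, [L])).astype(np.int64)
                )

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def n_sites(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.sites[chrom])
        return sum(len(s) for s in self.sites.values())

    def n_fragments(self, chrom: str) -> int:
        return len(self.boundaries[chrom]) - 1

    def fragment(self, chrom: str, i: int) -> tuple[int, int]:
        b = self.boundaries[chrom]
        return int(b[i]), int(b[i + 1])

    def fragments(self, chrom: str) -> list[tuple[int, int]]:
        b = self.boundaries[chrom]
        return list(zip(b[:-1].tolist(), b[1:].tolist()))

    def fragment_of_site(self, chrom: str, k: int) -> tuple[int, int]:
        """The fragment whose start coincides with site ``k`` of ``chrom``."""
        pos = int(self.sites[chrom][k])
        b = self.boundaries[chrom]
        j = int(np.searchsorted(b, pos))
        return int(b[j]), int(b[j + 1])


def digest(genome: Mapping[str, str], enzyme: EnzymeSpec | str) -> RestrictionMap:
    """Digest a genome in silico, returning its :class:`RestrictionMap`.

    A chromosome with no motif occurrence yields a single fragment covering
    it entirely. Concatenating fragment sequences in order reconstructs each
    chromosome (tiling identity).
    """
    if not genome:
        raise ValueError("genome must contain at least one sequence")
    if isinstance(enzyme, str):
        enzyme = resolve_enzyme(enzyme)
    sites = {
        chrom: np.asarray(find_sites(seq, enzyme.motif), dtype=np.int64)
        for chrom, seq in genome.items()
    }
    lengths = {chrom: len(seq) for chrom, seq in genome.items()}
    return RestrictionMap(enzyme=enzyme, chrom_lengths=lengths, sites=sites)


def locate_fragment(rmap: RestrictionMap, chrom: str, pos: int) -> tuple[int, int]:
    """The unique fragment containing ``pos`` under half-open semantics.

    Raises
    ------
    KeyError
        Unknown chromosome.
    IndexError
        Position outside ``[0, chromosome length)``.
    """
    if chrom not in rmap.boundaries:
        raise KeyError(f"unknown chromosome {chrom!r}")
    L = rmap.chrom_lengths[chrom]
    if not 0 <= pos < L:
        raise IndexError(f"position {pos} outside [0, {L}) on {chrom}")
    b = rmap.boundaries[chrom]
    j = int(np.searchsorted(b, pos, side="right")) - 1
    return int(b[j]), int(b[j + 1])


def _metadata_header(rmap: RestrictionMap) -> list[str]:
    return [
        f"# enzyme={rmap.enzyme.name} motif={rmap.enzyme.motif}",
        "# coordinates=0-based,half-open cut=motif-start",
    ]


def write_sites_bed(rmap: RestrictionMap, path) -> None:
    """Sites as BED3+name (name = ``chrom_siteIndex``) with a metadata header."""
    rows = []
    for chrom in rmap.chroms:
        m = len(rmap.enzyme.motif)
        for k, pos in enumerate(rmap.sites[chrom].tolist()):
            rows.append((chrom, pos, pos + m, f"{chrom}_{k}"))
    write_bed(rows, path, header=_metadata_header(rmap))


def write_fragments_bed(rmap: RestrictionMap, path) -> None:
    """Fragments as BED4 (name = ``chrom_fragmentIndex``) with a metadata header."""
    rows = []
    for chrom in rmap.chroms:
        for i, (s, e) in enumerate(rmap.fragments(chrom)):
            rows.append((chrom, s, e, f"{chrom}_{i}"))
    write_bed(rows, path, header=_metadata_header(rmap))
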