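"""Genome-wide lookup tables of candidate insertion sites and their sequence tags.

Restriction enzyme-mediated integration (REMI) inserts a resistance cassette at
DpnII (``GATC``) or NlaIII (``CATG``) loci.  Each insertion is identified by
short stretches of genomic sequence ("tags", 19 or 20 bp) flanking the
insertion point, read out by sequencing.  This module enumerates every
candidate site in a genome, emits the upstream and downstream tag for each
site, and classifies every tag by mappability:

``unique``
    the tag sequence (or its reverse complement) occurs at exactly one genomic
    locus;
``inverted_repeat``
    the tag is multi-mapping, but every occurrence lies inside intervals the
    caller has declared equivalent (a large duplicated region of the genome);
``non_unique``
    multi-mapping and not explained by any declared interval.

Coordinates are 1-based inclusive throughout.

Tag convention
--------------
The recognition sequence occupies positions ``[p, p+3]``.  The *upstream* tag
is the ``L``-mer ending at ``p+3`` and the *downstream* tag the ``L``-mer
starting at ``p``; both therefore contain the recognition sequence at one end,
mirroring the junction fragments released in a real library prep.  Tags are
stored forward-strand; :meth:`TagTable.lookup` also matches reverse
complements and reports hits on the insertion locus.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Recognition sequences per supported enzyme.  Both are their own reverse
#: complements, so site enumeration is strand-symmetric.
RECOGNITION_SEQUENCES: dict[str, str] = {"DpnII": "GATC", "NlaIII": "CATG"}

#: Default tag length per enzyme (19 for DpnII-side fragments, 20 for
#: NlaIII-side ones); both lengths are always indexed for lookup.
DEFAULT_TAG_LENGTHS: dict[str, int] = {"DpnII": 19, "NlaIII": 20}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigurationError(ValueError):
    """Raised for invalid enzyme ids or malformed configuration."""


@dataclass(frozen=True)
class RestrictionSite:
    """A single occurrence of a recognition sequence.

    ``position`` is the 1-based coordinate of the first base of the
    recognition sequence on the chromosome.
    """

    chromosome: str
    position: int
    enzyme: str


@dataclass(frozen=True)
class Tag:
    """One flanking tag of one candidate insertion site."""

    sequence: str
    site: RestrictionSite
    side: str  # "upstream" | "downstream"
    uniqueness: str  # "unique" | "non_unique" | "inverted_repeat"


@dataclass(frozen=True)
class RepeatIntervalPair:
    """Two genomic intervals declared sequence-equivalent (1-based inclusive)."""

    chromosome: str
    first: tuple[int, int]
    second: tuple[int, int]

    def contains(self, chromosome: str, start: int, end: int) -> bool:
        if chromosome != self.chromosome:
            return False
        for lo, hi in (self.first, self.second):
            if lo <= start and end <= hi:
                return True
        return False


@dataclass
class TagTable:
    """Lookup table from tag sequences to insertion loci."""

    entries: list[Tag]
    genome_id: str = ""
    inverted_repeat_intervals: tuple[RepeatIntervalPair, ...] = ()
    _index: dict[str, list[Tag]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for tag in self.entries:
            self._index.setdefault(tag.sequence, []).append(tag)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, sequence: str) -> tuple[list[Tag], str | None]:
        """Match ``sequence`` against forward and reverse-complement entries.

        Returns the matching entries (reported on the insertion locus) and the
        strand of the match (``"+"``, ``"-"`` or ``None`` if unmapped).
        """
        hits = self._index.get(sequence)
        if hits:
            return hits, "+"
        hits = self._index.get(reverse_complement(sequence))
        if hits:
            return hits, "-"
        return [], None

    def uniqueness_counts(self) -> dict[str, int]:
        counts = {"unique": 0, "non_unique": 0, "inverted_repeat": 0}
        for tag in self.entries:
            counts[tag.uniqueness] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tag": [t.sequence for t in self.entries],
                "chrom": [t.site.chromosome for t in self.entries],
                "pos": [t.site.position for t in self.entries],
                "enzyme": [t.site.enzyme for t in self.entries],
                "side": [t.side for t in self.entries],
                "uniqueness": [t.uniqueness for t in self.entries],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, genome_id: str = "") -> "TagTable":
        df = pd.read_csv(path, sep="\t", dtype={"tag": str})
        entries = [
            Tag(
                sequence=row.tag,
                site=RestrictionSite(row.chrom, int(row.pos), row.enzyme),
                side=row.side,
                uniqueness=row.uniqueness,
            )
            for row in df.itertuples()
        ]
        return cls(entries=entries, genome_id=genome_id)

    def summary(self) -> dict:
        counts = self.uniqueness_counts()
        return {
            "genome_id": self.genome_id,
            "n_tags": len(self.entries),
            "n_sites": len({(t.site.chromosome, t.site.position) for t in self.entries}),
            **counts,
        }

    def write_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-record) FASTA into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def enumerate_restriction_sites(
    genome: Mapping[str, str], enzyme: str
) -> list[RestrictionSite]:
    """Find every occurrence of an enzyme's recognition sequence.

    Overlapping occurrences are all reported; windows containing ``N`` are
    excluded as unmappable.  Positions are 1-based and strictly increasing
    within each chromosome.
    """
    try:
        motif = RECOGNITION_SEQUENCES[enzyme]
    except KeyError:
        raise ConfigurationError(
            f"unknown enzyme {enzyme!r}; expected one of {sorted(RECOGNITION_SEQUENCES)}"
        ) from None
    sites: list[RestrictionSite] = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        start = seq.find(motif)
        while start != -1:
            sites.append(RestrictionSite(chrom, start + 1, enzyme))
            start = seq.find(motif, start + 1)
    return sites


def _census(
    genome: Mapping[str, str], tag_sequences: set[str], lengths: Iterable[int]
) -> dict[str, list[tuple[str, int]]]:
    """Count genomic occurrences (either strand) of each tag sequence.

    Returns, for each tag sequence, the list of (chromosome, 1-based start)
    loci where the sequence or its reverse complement occurs.
    """
    occurrences: dict[str, list[tuple[str, int]]] = {s: [] for s in tag_sequences}
    lengths = sorted(set(lengths))
    for chrom, seq in genome.items():
        seq = seq.upper()
        n = len(seq)
        for L in lengths:
            for i in range(n - L + 1):
                window = seq[i : i + L]
                if window in occurrences:
                    occurrences[window].append((chrom, i + 1))
                rc = reverse_complement(window)
                if rc != window and rc in occurrences:
                    occurrences[rc].append((chrom, i + 1))
    return occurrences


def build_tag_table(
    genome: Mapping[str, str],
    enzymes: Sequence[str] = ("DpnII", "NlaIII"),
    tag_length_map: Mapping[str, int] | None = None,
    inverted_repeat_intervals: Sequence[RepeatIntervalPair] = (),
    genome_id: str = "",
) -> TagTable:
    """Build the lookup table of flanking tags for every candidate site.

    For every restriction site both flanking tags are emitted (a side is
    omitted, with a log message, when the tag would extend beyond the
    chromosome end).  Tags containing ``N`` are excluded.  Uniqueness is
    assigned from a genome-wide occurrence census: multi-locus tags whose
    occurrences all lie within the declared equivalent intervals are classed
    ``inverted_repeat``, other multi-locus tags ``non_unique``.
    """
    tag_length_map = dict(tag_length_map or DEFAULT_TAG_LENGTHS)
    for enzyme in enzymes:
        if enzyme not in RECOGNITION_SEQUENCES:
            raise ConfigurationError(f"unknown enzyme {enzyme!r}")
        length = tag_length_map.get(enzyme, DEFAULT_TAG_LENGTHS[enzyme])
        if length not in (19, 20):
            raise ConfigurationError(
                f"tag length for {enzyme} must be 19 or 20, got {length}"
            )
        tag_length_map[enzyme] = length

    intervals = tuple(inverted_repeat_intervals)
    raw: list[tuple[str, RestrictionSite, str]] = []  # (sequence, site, side)
    for enzyme in enzymes:
        L = tag_length_map[enzyme]
        motif_len = len(RECOGNITION_SEQUENCES[enzyme])
        for site in enumerate_restriction_sites(genome, enzyme):
            seq = genome[site.chromosome].upper()
            p0 = site.position - 1  # 0-based start of recognition sequence
            # upstream tag: L-mer ending at the last base of the motif
            up_start = p0 + motif_len - L
            if up_start >= 0:
                tag_seq = seq[up_start : p0 + motif_len]
                if "N" not in tag_seq:
                    raw.append((tag_seq, site, "upstream"))
            else:
                logger.info(
                    "omitting upstream tag at %s:%d (%s): extends beyond chromosome start",
                    site.chromosome, site.position, enzyme,
                )
            # downstream tag: L-mer starting at the first base of the motif
            if p0 + L <= len(seq):
                tag_seq = seq[p0 : p0 + L]
                if "N" not in tag_seq:
                    raw.append((tag_seq, site, "downstream"))
            else:
                logger.info(
                    "omitting downstream tag at %s:%d (%s): extends beyond chromosome end",
                    site.chromosome, site.position, enzyme,
                )

    occurrences = _census(genome, {s for s, _, _ in raw}, tag_length_map.values())

    entries: list[Tag] = []
    for tag_seq, site, side in raw:
        loci = occurrences[tag_seq]
        if len(loci) <= 1:
            uniqueness = "unique"
        elif all(
            any(p.contains(chrom, pos, pos + len(tag_seq) - 1) for p in intervals)
            for chrom, pos in loci
        ) and intervals:
            uniqueness = "inverted_repeat"
        else:
            uniqueness = "non_unique"
        entries.append(Tag(tag_seq, site, side, uniqueness))

    return TagTable(
        entries=entries,
        genome_id=genome_id,
        inverted_repeat_intervals=intervals,
    )


def parse_interval_spec(spec: str) -> RepeatIntervalPair:
    """Parse ``chrom:start-end:start2-end2`` into a :class:`RepeatIntervalPair`."""
    try:
        chrom, first, second = spec.split(":")
        s1, e1 = (int(x) for x in first.split("-"))
        s2, e2 = (int(x) for x in second.split("-"))
    except ValueError as exc:
        raise ConfigurationError(f"cannot parse interval spec {spec!r}") from exc
    return RepeatIntervalPair(chrom, (s1, e1), (s2, e2))
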