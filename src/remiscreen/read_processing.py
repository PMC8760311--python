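"""FASTQ reads → per-insertion, per-sample count tables.

A library-prep read has the layout ``adapter5 + vector + index + tag
(+ adapter3)``: a short stretch of vector sequence proves the read spans a
real insertion junction, a vector-specific index distinguishes the two
junction sides, and the terminal 19/20-bp tag is the genomic sequence used to
identify the insertion point via a :class:`~remiscreen.tag_reference.TagTable`.

Processing steps: adapter trimming and vector check (:func:`extract_tag`),
exact-match tag lookup and counting (:func:`count_tags`), PCR-artefact
filtering on per-index support (:func:`filter_artefacts`), and depth
normalisation (:func:`normalise`).  Upstream and downstream tag counts are
summed per insertion point before any analysis.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .tag_reference import TagTable

#: Default read layout used by the simulator and the extraction examples.
DEFAULT_ADAPTERS = ("AGATGTGTATAAGAGACAG", "CTGTCTCTTATACACATCT")
DEFAULT_VECTOR = "GGTACCTTTAAATCGATA"


@dataclass(frozen=True)
class ReadLayout:
    """Positions of the functional parts of a junction read.

    ``index_length`` bases follow the vector sequence; the tag occupies the
    next ``tag_length_max`` bases (19-bp tags are matched as the 19-mer prefix
    of the extracted window).  Matching is exact by default; per-part mismatch
    tolerances are configurable.
    """

    adapter_sequences: tuple[str, str] = DEFAULT_ADAPTERS
    vector_sequence: str = DEFAULT_VECTOR
    index_length: int = 4
    tag_length_max: int = 20
    tag_length_min: int = 19
    adapter_mismatch_tolerance: int = 0
    vector_mismatch_tolerance: int = 0

    def min_read_length(self) -> int:
        return (
            len(self.adapter_sequences[0])
            + len(self.vector_sequence)
            + self.index_length
            + self.tag_length_min
        )


@dataclass(frozen=True)
class Rejection:
    reason: str  # "no_adapter" | "no_vector" | "bad_length"


@dataclass(frozen=True)
class ExtractedTag:
    tag: str
    index: str


class FastqParseError(ValueError):
    """Malformed FASTQ record; carries the 1-based record number."""

    def __init__(self, record_number: int, message: str):
        self.record_number = record_number
        super().__init__(f"record {record_number}: {message}")


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_tag(sequence: str, layout: ReadLayout) -> ExtractedTag | Rejection:
    """Trim adapters, check the vector, and pull out the tag and index.

    Returns an :class:`ExtractedTag` for reads passing all checks, otherwise a
    :class:`Rejection` with reason ``no_adapter``, ``no_vector`` or
    ``bad_length``.
    """
    sequence = sequence.upper()
    a5, a3 = layout.adapter_sequences
    if len(sequence) < len(a5) or _mismatches(
        sequence[: len(a5)], a5
    ) > layout.adapter_mismatch_tolerance:
        return Rejection("no_adapter")
    trimmed = sequence[len(a5):]
    if a3:
        cut = trimmed.find(a3)
        if cut != -1:
            trimmed = trimmed[:cut]

    v = layout.vector_sequence
    if len(trimmed) < len(v) or _mismatches(
        trimmed[: len(v)], v
    ) > layout.vector_mismatch_tolerance:
        return Rejection("no_vector")
    rest = trimmed[len(v):]

    index = rest[: layout.index_length]
    tag = rest[layout.index_length : layout.index_length + layout.tag_length_max]
    if len(index) < layout.index_length or len(tag) < layout.tag_length_min:
        return Rejection("bad_length")
    return ExtractedTag(tag=tag, index=index)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(read id, sequence)`` from a FASTQ file (optionally gzipped).

    Raises :class:`FastqParseError` naming the offending record on malformed
    input.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        record = 0
        while True:
            header = handle.readline()
            if not header:
                return
            record += 1
            seq = handle.readline().rstrip("\n")
            plus = handle.readline()
            qual = handle.readline().rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(record, "header does not start with '@'")
            if not plus.startswith("+"):
                raise FastqParseError(record, "separator line does not start with '+'")
            if not qual or len(qual) != len(seq):
                raise FastqParseError(record, "quality length differs from sequence length")
            yield header[1:].split()[0], seq


@dataclass
class CountTable:
    """Insertion-mutant × sample read counts with sample metadata.

    ``raw`` holds non-negative integer counts (rows: insertion ids, columns:
    samples).  ``samples`` carries per-sample metadata (prey, replicate,
    round).  ``norm`` is filled by :func:`normalise`; ``index_counts`` is a
    long-format frame (insertion, sample, index, count) of per-index subtotals
    used by :func:`filter_artefacts`.
    """

    raw: pd.DataFrame
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    norm: pd.DataFrame | None = None
    normalisation_constant: float | None = None
    index_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.raw.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")

    @property
    def insertions(self) -> pd.Index:
        return self.raw.index

    @property
    def sample_names(self) -> pd.Index:
        return self.raw.columns

    def samples_for(self, **criteria) -> list[str]:
        """Sample names whose metadata match all ``criteria``."""
        mask = pd.Series(True, index=self.samples.index)
        for key, value in criteria.items():
            mask &= self.samples[key] == value
        return list(self.samples.index[mask])

    def to_long(self, layer: str = "raw") -> pd.DataFrame:
        frame = getattr(self, layer)
        if frame is None:
            raise ValueError(f"layer {layer!r} not present")
        long = frame.stack().rename("count").reset_index()
        long.columns = ["insertion", "sample", "count"]
        return long

    def write_tsv(self, path: str | Path, layer: str = "raw") -> None:
        frame = getattr(self, layer)
        if frame is None:
            raise ValueError(f"layer {layer!r} not present")
        frame.to_csv(path, sep="\t", index_label="insertion")

    @classmethod
    def read_tsv(
        cls, path: str | Path, samples: pd.DataFrame | None = None
    ) -> "CountTable":
        raw = pd.read_csv(path, sep="\t", index_col="insertion")
        return cls(raw=raw, samples=samples if samples is not None else pd.DataFrame())


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV (sample, file, prey, replicate, round)."""
    sheet = pd.read_csv(path, sep="\t")
    return sheet.set_index("sample")


def count_sample(
    tag_stream: Iterable[tuple[str, str]],
    table: TagTable,
    include_inverted_repeat: bool = False,
) -> tuple[Counter, Counter, dict[str, int]]:
    """Count one sample's (tag, index) pairs against a lookup table.

    Only unique tags (and, optionally, inverted-repeat tags resolved to their
    first-listed locus) contribute counts; non-unique and unmapped tags are
    tallied in the summary.  Returns (per-insertion counts, per-(insertion,
    index) counts, mapping summary).
    """
    counts: Counter = Counter()
    index_counts: Counter = Counter()
    summary = {
        "total": 0,
        "mappable": 0,
        "unique": 0,
        "inverted_repeat": 0,
        "non_unique": 0,
        "unmapped": 0,
    }
    for tag, index in tag_stream:
        summary["total"] += 1
        hits, strand = table.lookup(tag)
        if not hits and len(tag) > 19:
            hits, strand = table.lookup(tag[:19])
        if not hits:
            summary["unmapped"] += 1
            continue
        summary["mappable"] += 1
        uniqueness = hits[0].uniqueness
        summary[uniqueness] += 1
        if uniqueness == "non_unique":
            continue
        if uniqueness == "inverted_repeat" and not include_inverted_repeat:
            continue
        site = hits[0].site
        insertion = f"{site.chromosome}:{site.position}"
        counts[insertion] += 1
        index_counts[(insertion, index)] += 1
    return counts, index_counts, summary


def count_tags(
    streams: Mapping[str, Iterable[tuple[str, str]]],
    table: TagTable,
    samples: pd.DataFrame | None = None,
    include_inverted_repeat: bool = False,
) -> tuple[CountTable, dict[str, dict[str, int]]]:
    """Count tag streams for several samples into one raw :class:`CountTable`."""
    per_sample: dict[str, Counter] = {}
    index_rows: list[tuple[str, str, str, int]] = []
    summaries: dict[str, dict[str, int]] = {}
    for sample, stream in streams.items():
        counts, index_counts, summary = count_sample(
            stream, table, include_inverted_repeat=include_inverted_repeat
        )
        per_sample[sample] = counts
        summaries[sample] = summary
        for (insertion, index), n in sorted(index_counts.items()):
            index_rows.append((insertion, sample, index, n))

    raw = pd.DataFrame(per_sample).fillna(0).astype(int)
    raw = raw.sort_index()
    if samples is not None:
        raw = raw[[s for s in samples.index if s in raw.columns]]
    index_frame = pd.DataFrame(
        index_rows, columns=["insertion", "sample", "index", "count"]
    )
    return (
        CountTable(
            raw=raw,
            samples=samples if samples is not None else pd.DataFrame(),
            index_counts=index_frame,
        ),
        summaries,
    )


def filter_artefacts(counts: CountTable, min_index_support: int = 2) -> CountTable:
    """Drop insertion points with suspect PCR-artefact support.

    An insertion point is removed when its reads arrive from only one vector
    index and that index carries fewer than ``min_index_support`` reads in
    total.  A threshold of 0 is the identity filter.  Requires per-index
    subtotals on the table.
    """
    if min_index_support <= 0:
        return counts
    if counts.index_counts is None or counts.index_counts.empty:
        raise ValueError("count table carries no per-index subtotals")
    support = (
        counts.index_counts.groupby(["insertion", "index"])["count"].sum().reset_index()
    )
    flagged: list[str] = []
    for insertion, group in support.groupby("insertion"):
        present = group[group["count"] > 0]
        if len(present) == 1 and present["count"].iloc[0] < min_index_support:
            flagged.append(insertion)
    keep = [i for i in counts.raw.index if i not in set(flagged)]
    return CountTable(
        raw=counts.raw.loc[keep],
        samples=counts.samples,
        index_counts=counts.index_counts[
            counts.index_counts["insertion"].isin(keep)
        ].reset_index(drop=True),
    )


def normalise(counts: CountTable, scale: float | None = None) -> CountTable:
    """Scale each sample to a common total read count.

    ``norm[s] = raw[s] × scale / total_raw[s]``; the default scale is the mean
    raw total across samples, so normalised counts stay on an absolute-read
    scale and read-count thresholds (e.g. ">100 normalised reads") remain
    meaningful.
    """
    totals = counts.raw.sum(axis=0).astype(float)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total reads: {list(zero.index)}")
    if scale is None:
        scale = float(totals.mean())
    if scale <= 0:
        raise ValueError("scale must be positive")
    norm = counts.raw.astype(float) * (scale / totals)
    return replace(counts, norm=norm, normalisation_constant=float(scale))
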