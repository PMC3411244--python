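"""Shustring computation: sequence pools, profiles, histograms and peaks.

A *shustring* (shortest unique substring) at query position *i* is the
shortest substring starting at *i* that occurs nowhere in the subject.  Its
length equals the matching statistic at *i* (longest prefix of the query
suffix found anywhere in the subject) plus one, capped by the distance to
the query end; capped positions are flagged because no unique extension
exists there.

Contigs are concatenated without separator characters, so shustrings may
span contig borders; this replicates the behaviour of suffix-array based
diversity scanners and is the documented source of a small upward bias in
highly fragmented assemblies.  By default both strands of each sequence are
used: the reverse complement is appended to the forward concatenation, so a
pool of single-strand length ``l`` holds ``2*l`` characters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._matcher import build_automaton, matching_statistics_from_automaton

__all__ = [
    "SequencePool",
    "ShustringProfile",
    "ShustringHistogram",
    "SubjectIndex",
    "load_pool",
    "shustring_lengths",
    "histogram",
    "count_peaks",
    "count_new_shustrings",
    "encode",
    "decode",
    "revcomp_codes",
]

logger = logging.getLogger(__name__)

# A,C,G,T -> 0,1,2,3; everything else -> 255 (dropped on load).
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate(b"ACGT"):
    _ENC[_ch] = _i
    _ENC[_ch + 32] = _i  # lowercase
_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes, dropping non-ACGT symbols."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENC[raw]
    return codes[codes < 4]


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space (A<->T, C<->G is ``3 - code``)."""
    return (3 - codes[::-1]).astype(np.uint8)


@dataclass
class SequencePool:
    """Concatenated contigs of one role (query or subject).

    ``codes`` holds the full working sequence (forward concatenation,
    followed by its reverse complement when ``strand_doubled``);
    ``half_length`` is the single-strand length, so ``len(codes)`` is
    ``2 * half_length`` for a doubled pool.
    """

    codes: np.ndarray
    contig_bounds: list[tuple[int, int]] = field(default_factory=list)
    strand_doubled: bool = True
    half_length: int = 0

    def __post_init__(self) -> None:
        if self.half_length == 0:
            self.half_length = (
                len(self.codes) // 2 if self.strand_doubled else len(self.codes)
            )

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def sequence(self) -> str:
        return decode(self.codes)

    @property
    def forward_codes(self) -> np.ndarray:
        return self.codes[: self.half_length]

    @property
    def gc_content(self) -> float:
        fwd = self.forward_codes
        return float(np.mean((fwd == 1) | (fwd == 2)))


def load_pool(records, strand_double: bool = True) -> SequencePool:
    """Build a :class:`SequencePool` from FASTA records or raw sequences.

    ``records`` may be Biopython ``SeqRecord`` objects, ``(id, sequence)``
    pairs, or plain strings.  Lowercase is accepted; ``N`` and all other
    IUPAC ambiguity codes are removed (with a logged count).  Contigs are
    concatenated in input order without separators.  Records whose ACGT
    content is empty are skipped with a warning; an input with no usable
    sequence raises ``ValueError``.
    """
    parts: list[np.ndarray] = []
    bounds: list[tuple[int, int]] = []
    offset = 0
    n_removed = 0
    n_records = 0
    for rec in records:
        n_records += 1
        if isinstance(rec, str):
            name, seq = f"contig{n_records}", rec
        elif isinstance(rec, tuple):
            name, seq = rec
        else:  # SeqRecord
            name, seq = rec.id, str(rec.seq)
        codes = encode(seq)
        n_removed += len(seq) - len(codes)
        if len(codes) == 0:
            logger.warning("record %r has no ACGT content; skipped", name)
            continue
        parts.append(codes)
        bounds.append((offset, offset + len(codes)))
        offset += len(codes)
    if not parts:
        raise ValueError("no usable sequence in input")
    if n_removed:
        logger.info("removed %d non-ACGT symbols", n_removed)
    forward = np.concatenate(parts)
    if strand_double:
        codes = np.concatenate([forward, revcomp_codes(forward)])
    else:
        codes = forward
    return SequencePool(
        codes=codes,
        contig_bounds=bounds,
        strand_doubled=strand_double,
        half_length=len(forward),
    )


@dataclass
class ShustringProfile:
    """Per-position shustring lengths of a query against a subject."""

    lengths: np.ndarray  # int64, one per query position
    capped: np.ndarray  # bool, True where the +1 extension was impossible

    def __len__(self) -> int:
        return len(self.lengths)

    @property
    def mean_length(self) -> float:
        return float(np.mean(self.lengths))


@dataclass
class ShustringHistogram:
    """Counts of shustring lengths: ``counts[x]`` positions of length x."""

    counts: np.ndarray  # counts[0] == 0
    xi: int  # longest observed shustring
    total: int  # number of profiled positions
    n_capped: int = 0  # positions where the suffix ran out before uniqueness

    @property
    def f(self) -> dict[int, int]:
        xs = np.nonzero(self.counts)[0]
        return {int(x): int(self.counts[x]) for x in xs}


class SubjectIndex:
    """Reusable matching-statistics index over one subject pool.

    Builds the suffix automaton of the reversed subject once, so that many
    query windows can be profiled against the same subject cheaply.
    """

    def __init__(self, subject: SequencePool):
        if len(subject) == 0:
            raise ValueError("subject pool is empty")
        self.subject = subject
        self._automaton = build_automaton(subject.codes[::-1])

    def matching_statistics(self, query_codes: np.ndarray) -> np.ndarray:
        """Longest prefix of each query suffix occurring in the subject."""
        per_end = matching_statistics_from_automaton(
            self._automaton, query_codes[::-1]
        )
        return per_end[::-1].copy()

    def profile(self, query_codes: np.ndarray) -> ShustringProfile:
        if len(query_codes) == 0:
            raise ValueError("query is empty")
        ms = self.matching_statistics(query_codes)
        remaining = np.arange(len(query_codes), 0, -1, dtype=np.int64)
        capped = ms >= remaining
        lengths = np.minimum(ms + 1, remaining)
        return ShustringProfile(lengths=lengths, capped=capped)


def shustring_lengths(query: SequencePool, subject) -> ShustringProfile:
    """Shustring length at every position of ``query`` against ``subject``.

    ``subject`` may be a :class:`SequencePool` or a prebuilt
    :class:`SubjectIndex`.
    """
    index = subject if isinstance(subject, SubjectIndex) else SubjectIndex(subject)
    return index.profile(query.codes)


def histogram(profile: ShustringProfile, include_capped: bool = True) -> ShustringHistogram:
    """Tally shustring lengths into an absolute-count histogram.

    Capped lengths (positions where the suffix was exhausted before
    uniqueness) are included at their capped value by default.
    """
    lengths = profile.lengths if include_capped else profile.lengths[~profile.capped]
    if len(lengths) == 0:
        raise ValueError("profile has no positions to tally")
    counts = np.bincount(lengths)
    n_capped = int(profile.capped.sum()) if include_capped else 0
    return ShustringHistogram(
        counts=counts,
        xi=int(lengths.max()),
        total=int(len(lengths)),
        n_capped=n_capped,
    )


def count_peaks(profile) -> int:
    """Number of shustring peaks in a profile.

    A peak occurs at position ``i`` (from the second position on) when the
    shustring length does not decrease from ``i - 1`` to ``i``, signalling
    that a different polymorphism is being tracked.  Used by the
    missing-data heuristic of the window scanner.
    """
    lengths = profile.lengths if isinstance(profile, ShustringProfile) else np.asarray(profile)
    if len(lengths) < 1:
        raise ValueError("profile must contain at least one position")
    return int(np.count_nonzero(lengths[1:] >= lengths[:-1]))


def count_new_shustrings(profile) -> int:
    """Number of strict rises in the shustring-length profile.

    A strict rise marks the start of a newly tracked shustring run.  This
    is the robust variant of :func:`count_peaks` used by the window
    scanner's missing-data heuristic: the non-strict count also fires on
    every equal-length jitter step at the random-match noise floor
    (roughly ``log4`` of the doubled subject length), which inflates it to
    about six times the polymorphism density and would trip the
    documented per-window threshold even for well-matched windows of
    ordinary diversity.  Strict rises stay proportional to the apparent
    polymorphism density while remaining an order of magnitude higher for
    windows without a homolog.
    """
    lengths = profile.lengths if isinstance(profile, ShustringProfile) else np.asarray(profile)
    if len(lengths) < 1:
        raise ValueError("profile must contain at least one position")
    return int(np.count_nonzero(lengths[1:] > lengths[:-1]))
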