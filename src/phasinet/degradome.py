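"""Degradome-supported sRNA target search and weighted cleavage scoring.

An sRNA is aligned, ungapped, against every window of a transcript; the
penalty (Allen convention) counts 1.0 per mismatch and 0.5 per G:U wobble,
doubled over sRNA positions 2-13 (5'->3').  The slice site sits between
the target nucleotides paired to sRNA positions 10 and 11; the
``slice_position`` reported is the transcript nucleotide 5' of the cut,
and the degradome 5'-tag peak of a true cleavage lies at
``slice_position + 1``.

Per degradome library the tag count at the peak is categorised against
the transcript-wide tag profile (CleaveLand-style categories 0-4); the
categories are weighted 5 / 4 / 0.5 / 0 / 0 and summed across libraries
into the deg_score used both for trigger assignment and for genome-wide
target validation (where an ECDF-derived threshold selects the reliable
tail).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import DegradomeLibrary, normalize_u

DEFAULT_WEIGHTS: dict[int, float] = {0: 5.0, 1: 4.0, 2: 0.5, 3: 0.0, 4: 0.0}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# penalty matrix: rows = sRNA base, cols = target base
_PEN = np.ones((5, 5), dtype=float)
for _s, _t in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
    _PEN[_CODE[_s], _CODE[_t]] = 0.0
for _s, _t in (("G", "T"), ("T", "G")):
    _PEN[_CODE[_s], _CODE[_t]] = 0.5


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        normalize_u(seq).encode().translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
        dtype=np.uint8,
    )


def allen_score(srna: str, site: str) -> float:
    """Penalty of an ungapped sRNA:target-site duplex (both 5'->3').

    sRNA position i pairs target position L-i+1.  Mismatch 1.0, G:U 0.5,
    doubled for sRNA positions 2-13; a perfect pair costs 0.
    """
    if len(srna) != len(site):
        raise ValueError(f"length mismatch: {len(srna)} vs {len(site)}")
    s = normalize_u(srna)
    t = normalize_u(site)
    total = 0.0
    L = len(s)
    for i in range(1, L + 1):
        pen = _PEN[_CODE.get(s[i - 1], 4), _CODE.get(t[L - i], 4)]
        total += pen * (2.0 if 2 <= i <= 13 else 1.0)
    return total


@dataclass(frozen=True)
class TargetAlignment:
    """One candidate ungapped sRNA:transcript duplex."""

    srna_sequence: str
    transcript_id: str
    window_start: int  # 1-based transcript coordinates, inclusive
    window_end: int
    allen_score: float
    slice_position: int  # transcript nt 5' of the cut (= window_end - 10)

    @property
    def peak_position(self) -> int:
        """Where the degradome 5'-tag of a true cleavage accumulates."""
        return self.slice_position + 1


def find_target_alignments(
    srna: str,
    transcript_id: str,
    transcript_seq: str,
    max_allen: float = 7.0,
) -> list[TargetAlignment]:
    """All transcript windows with penalty <= max_allen for one sRNA.

    Vectorised over windows; equivalent to calling :func:`allen_score` on
    every window (property-tested against it).
    """
    L = len(srna)
    if len(transcript_seq) < L:
        return []
    rs = _encode(srna)[::-1]  # rs[j] pairs window position j
    weights = np.where((L - np.arange(L) >= 2) & (L - np.arange(L) <= 13), 2.0, 1.0)
    tcodes = _encode(transcript_seq)
    windows = np.lib.stride_tricks.sliding_window_view(tcodes, L)
    penalties = (_PEN[rs[None, :], windows] * weights[None, :]).sum(axis=1)
    hits = np.flatnonzero(penalties <= max_allen + 1e-9)
    return [
        TargetAlignment(
            srna_sequence=srna,
            transcript_id=transcript_id,
            window_start=int(j) + 1,
            window_end=int(j) + L,
            allen_score=float(round(penalties[j], 6)),
            slice_position=int(j) + L - 10,
        )
        for j in hits
    ]


@dataclass
class DegradomeProfile:
    """Per-position raw 5'-tag counts on one transcript (1-based)."""

    transcript_id: str
    counts: np.ndarray

    @classmethod
    def build(
        cls,
        transcript_id: str,
        transcript_seq: str,
        library: DegradomeLibrary,
        prefix_length: int = 20,
    ) -> "DegradomeProfile":
        """Match each tag's first ``prefix_length`` nt exactly into the
        transcript; duplicated placements accumulate counts."""
        seq = normalize_u(transcript_seq)
        counts = np.zeros(len(seq) + 1, dtype=float)  # index 0 unused
        index: dict[str, list[int]] = {}
        for i in range(0, max(0, len(seq) - prefix_length + 1)):
            index.setdefault(seq[i : i + prefix_length], []).append(i + 1)
        for tag in library:
            key = normalize_u(tag.sequence)[:prefix_length]
            for pos in index.get(key, ()):
                counts[pos] += tag.count
        return cls(transcript_id, counts)

    @property
    def max_count(self) -> float:
        return float(self.counts.max()) if self.counts.size else 0.0

    @property
    def n_max_positions(self) -> int:
        m = self.max_count
        return int((self.counts == m).sum()) if m > 0 else 0

    @property
    def median_occupied(self) -> float:
        occ = self.counts[self.counts >= 1]
        return float(np.median(occ)) if occ.size else 0.0

    def count_at(self, position: int) -> float:
        if position < 1 or position >= len(self.counts):
            return 0.0
        return float(self.counts[position])


def categorize_cleavage(profile: DegradomeProfile, position: int) -> int | None:
    """CleaveLand-style category of the tag signal at one position.

    none: no tag; 4: single tag; 0: unique transcript-wide maximum;
    1: shared maximum; 2: above the median of occupied positions; 3: rest.
    """
    c = profile.count_at(position)
    if c == 0:
        return None
    if c == 1:
        return 4
    if c == profile.max_count:
        return 0 if profile.n_max_positions == 1 else 1
    if c > profile.median_occupied:
        return 2
    return 3


@dataclass(frozen=True)
class CleavageEvent:
    alignment: TargetAlignment
    library_id: str
    category: int
    tag_count: float


@dataclass
class WeightedEventScore:
    """deg_score / target_deg_score: summed category weights across libraries."""

    alignment: TargetAlignment
    score: float
    contributing: list[tuple[str, int]] = field(default_factory=list)


def weighted_score(
    events: Sequence[CleavageEvent],
    weights: Mapping[int, float] = DEFAULT_WEIGHTS,
) -> WeightedEventScore:
    """Sum category weights over libraries for one shared alignment."""
    if not events:
        raise ValueError("no events")
    aln = events[0].alignment
    for e in events:
        if e.alignment != aln:
            raise ValueError("events must share one alignment")
    contributing = [(e.library_id, e.category) for e in events]
    return WeightedEventScore(
        aln, sum(weights.get(e.category, 0.0) for e in events), contributing
    )


def score_alignment(
    alignment: TargetAlignment,
    profiles: Mapping[str, DegradomeProfile],
    weights: Mapping[int, float] = DEFAULT_WEIGHTS,
) -> WeightedEventScore:
    """Categorise one alignment's peak in every library and sum the weights."""
    events = []
    for library_id in sorted(profiles):
        cat = categorize_cleavage(profiles[library_id], alignment.peak_position)
        if cat is not None:
            events.append(
                CleavageEvent(
                    alignment, library_id, cat,
                    profiles[library_id].count_at(alignment.peak_position),
                )
            )
    if not events:
        return WeightedEventScore(alignment, 0.0, [])
    return weighted_score(events, weights)


def ecdf_threshold(scores: Iterable[float], quantile: float = 0.99) -> float:
    """Smallest observed score whose left-ECDF reaches ``quantile``.

    Returns the smallest score s with (#scores < s)/n >= quantile; when no
    score qualifies (e.g. all values tied), the largest score is returned.
    """
    values = sorted(scores)
    if not values:
        raise ValueError("no scores")
    n = len(values)
    below = 0
    i = 0
    while i < n:
        j = i
        while j < n and values[j] == values[i]:
            j += 1
        if below / n >= quantile:
            return values[i]
        below = j
        i = j
    return values[-1]
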