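"""The event-based distance between two gene blocks.

Three pairwise event types distinguish orthologous gene blocks in different
taxa: *deletions* (a family present in exactly one block), *duplications*
(copy-number differences for families present in both), and *splits*
(differences in the number of sub-blocks after restricting each block to the
families shared by the pair).  The distance is the minimized total count of
these events.

:func:`event_distance` evaluates the closed-form minimized counts;
:func:`oracle_distance` re-derives them by exhaustive uniform-cost search over
sequences of atomic edits and exists purely to validate the closed form on
small instances.
"""

from __future__ import annotations

import heapq
import itertools
from collections import Counter
from dataclasses import dataclass

from .blocks import GeneBlock

__all__ = ["EventCount", "event_distance", "oracle_distance", "OracleSizeError"]


class OracleSizeError(ValueError):
    """Instance too large for the exhaustive oracle."""


@dataclass(frozen=True)
class EventCount:
    deletions: int
    duplications: int
    splits: int

    @property
    def total(self) -> int:
        return self.deletions + self.duplications + self.splits

    def __add__(self, other: "EventCount") -> "EventCount":
        return EventCount(
            self.deletions + other.deletions,
            self.duplications + other.duplications,
            self.splits + other.splits,
        )

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.deletions, self.duplications, self.splits)


def _segments_of(block, include_pseudo: bool) -> list[tuple[str, ...]]:
    """Normalize input to a list of label tuples (one per sub-block)."""
    if isinstance(block, GeneBlock):
        segs = []
        for seg in block.segments:
            labels = tuple(
                g.label for g in seg if include_pseudo or g.status == "full"
            )
            if labels:
                segs.append(labels)
        return segs
    if isinstance(block, str):
        return [tuple(part) for part in block.split("|") if part]
    return [tuple(seg) for seg in block if seg]


def _counts(segments: list[tuple[str, ...]]) -> Counter:
    return Counter(lbl for seg in segments for lbl in seg)


def _restricted_segment_count(
    segments: list[tuple[str, ...]], families: set[str]
) -> int:
    """Number of sub-blocks still containing a gene after restriction."""
    return sum(1 for seg in segments if any(lbl in families for lbl in seg))


def event_distance(a, b, include_pseudo: bool = False) -> EventCount:
    """Minimized (deletions, duplications, splits) between two blocks.

    ``a`` and ``b`` may be :class:`~gablocks.blocks.GeneBlock` objects, block
    strings (``"bcdefghi|j"``) or raw segment lists.  Pseudogenes are excluded
    by default (a cyp115 fragment is not a functional gene copy).

    deletions     |families present in exactly one block|
    duplications  sum over shared families of |copy difference|
    splits        |difference in sub-block counts after restricting both
                  blocks to the shared families|
    """
    sa = _segments_of(a, include_pseudo)
    sb = _segments_of(b, include_pseudo)
    ca, cb = _counts(sa), _counts(sb)
    shared = set(ca) & set(cb)
    deletions = len(set(ca) ^ set(cb))
    duplications = sum(abs(ca[f] - cb[f]) for f in shared)
    splits = abs(
        _restricted_segment_count(sa, shared) - _restricted_segment_count(sb, shared)
    )
    return EventCount(deletions, duplications, splits)


# --- exhaustive oracle -----------------------------------------------------

def oracle_distance(a, b, include_pseudo: bool = False) -> EventCount:
    """Exhaustive minimized edit count between two blocks.

    In the event model a presence change is a single whole-family event
    regardless of copy number or placement, and the split and duplication
    characters are counted on the blocks restricted to the families the two
    blocks share.  The search therefore charges one deletion per family in
    the symmetric difference (forced: no other edit changes presence) and
    then minimizes, by uniform-cost search over the restricted character
    state, the remaining atomic edits: add or remove one copy of a shared
    family (a family never drops out of presence and no sub-block is left
    empty) and split/join sub-blocks.  The goal is reached when copy numbers
    and the restricted sub-block count both agree — the distance's own
    identity criterion.

    Limits: at most 6 families and 3 copies per family.
    """
    sa = _segments_of(a, include_pseudo)
    sb = _segments_of(b, include_pseudo)
    ca, cb = _counts(sa), _counts(sb)
    families = set(ca) | set(cb)
    if len(families) > 6:
        raise OracleSizeError(f"{len(families)} families exceeds oracle limit of 6")
    if any(c > 3 for c in (*ca.values(), *cb.values())):
        raise OracleSizeError("more than 3 copies of a family exceeds oracle limit")

    shared = sorted(set(ca) & set(cb))
    deletions = len(set(ca) ^ set(cb))
    if not shared:
        return EventCount(deletions, 0, 0)

    # Restricted character state: (copy-number vector over shared families,
    # restricted sub-block count).  Every nonempty sub-block holds >=1 gene,
    # so 1 <= nseg <= total copies is the only structural invariant the
    # characters impose; within-sub-block arrangement carries no information
    # for the distance and is not part of the state.
    start = (
        tuple(ca[f] for f in shared),
        _restricted_segment_count(sa, set(shared)),
    )
    goal = (
        tuple(cb[f] for f in shared),
        _restricted_segment_count(sb, set(shared)),
    )
    cap = max(sum(start[0]), sum(goal[0])) + 1  # wasteful growth is never optimal

    def moves(state):
        counts, nseg = state
        total = sum(counts)
        for i in range(len(counts)):
            if total + 1 <= cap:  # duplication: one copy in
                yield (counts[:i] + (counts[i] + 1,) + counts[i + 1 :], nseg), 1, 0
            # duplication: one copy out; the family stays present and every
            # sub-block keeps at least one gene
            if counts[i] > 1 and total - 1 >= nseg:
                yield (counts[:i] + (counts[i] - 1,) + counts[i + 1 :], nseg), 1, 0
        if nseg + 1 <= total:  # split
            yield (counts, nseg + 1), 0, 1
        if nseg > 1:  # join
            yield (counts, nseg - 1), 0, 1

    # uniform-cost search; dup and split components are each changed only by
    # their own move type, so the triple at the first goal pop is unique.
    best: dict = {start: 0}
    tiebreak = itertools.count()
    heap = [(0, next(tiebreak), start, (0, 0))]
    while heap:
        cost, _, state, (dups, splits) = heapq.heappop(heap)
        if cost > best.get(state, float("inf")):
            continue
        if state == goal:
            return EventCount(deletions, dups, splits)
        for new_state, p, s in moves(state):
            new_cost = cost + p + s
            if new_cost < best.get(new_state, float("inf")):
                best[new_state] = new_cost
                heapq.heappush(
                    heap,
                    (new_cost, next(tiebreak), new_state, (dups + p, splits + s)),
                )

    raise RuntimeError("oracle search exhausted without reaching the target")
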