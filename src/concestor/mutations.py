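"""Derived-mutation calling, collapsing and labeling between ancestor and alleles.

Events are called column-by-column in the alignment frame.  A maximal run of
columns where exactly one of the two rows is gapped collapses to a single
insertion or deletion event; a column where both rows carry (different)
bases is a substitution.  A run of gap columns flanked by substitutions
yields separate events — kinds are never merged.  Applying the called events
back to the ancestor row reproduces the allele exactly (checked at call
time), so the catalogue is a lossless edit script.

Core-region events receive letter labels (A, B, C, ... in column order) and
flank events numeric labels (1, 2, ...), mirroring the convention of
annotating a regulatory element's central binding-site-rich core separately
from its flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal

import pandas as pd

from .seq_io import GAP, CoordinateMap, GappedAlignment

Kind = Literal["substitution", "insertion", "deletion"]


class MutationCallError(ValueError):
    """Raised for unequal rows or catalogues that violate event invariants."""


@dataclass(frozen=True)
class MutationEvent:
    """One derived change in alignment-column coordinates (half-open span).

    ``ancestral``/``derived`` hold the non-gap characters of the two rows
    within the span: a substitution has one of each, a deletion an empty
    ``derived``, an insertion an empty ``ancestral``.
    """

    kind: Kind
    col_start: int
    col_end: int
    ancestral: str
    derived: str
    label: str | None = None
    region: Literal["core", "flank"] | None = None

    def __post_init__(self) -> None:
        if self.col_start >= self.col_end:
            raise MutationCallError("event span must be non-empty (col_start < col_end)")
        if self.kind == "substitution" and not (len(self.ancestral) == len(self.derived) == 1):
            raise MutationCallError("substitution must have 1-bp ancestral and derived")
        if self.kind == "deletion" and (self.derived or not self.ancestral):
            raise MutationCallError("deletion must have empty derived, non-empty ancestral")
        if self.kind == "insertion" and (self.ancestral or not self.derived):
            raise MutationCallError("insertion must have empty ancestral, non-empty derived")

    @property
    def span(self) -> tuple[int, int]:
        return (self.col_start, self.col_end)

    def __len__(self) -> int:
        return self.col_end - self.col_start


@dataclass(frozen=True)
class CoreAnnotation:
    """Half-open alignment-column interval of the element's core region."""

    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if self.col_start >= self.col_end or self.col_start < 0:
            raise ValueError("core interval must be a non-empty 0-based half-open interval")

    def overlaps(self, col_start: int, col_end: int) -> bool:
        return max(self.col_start, col_start) < min(self.col_end, col_end)


def call_mutations(ancestor_row: str, allele_row: str) -> list[MutationEvent]:
    """Call derived events of ``allele_row`` relative to ``ancestor_row``.

    Both rows must be equal-length gapped strings in the same alignment
    frame.  Events are returned sorted by ``col_start``.
    """
    if len(ancestor_row) != len(allele_row):
        raise MutationCallError(
            f"row lengths differ: {len(ancestor_row)} vs {len(allele_row)}"
        )
    n = len(ancestor_row)
    events: list[MutationEvent] = []
    i = 0
    while i < n:
        a, d = ancestor_row[i], allele_row[i]
        if a == d:
            i += 1
        elif a != GAP and d != GAP:
            events.append(
                MutationEvent("substitution", i, i + 1, ancestral=a, derived=d)
            )
            i += 1
        elif a != GAP and d == GAP:
            j = i
            while j < n and ancestor_row[j] != GAP and allele_row[j] == GAP:
                j += 1
            events.append(
                MutationEvent("deletion", i, j, ancestral=ancestor_row[i:j], derived="")
            )
            i = j
        else:  # ancestor gapped, allele not: insertion
            j = i
            while j < n and ancestor_row[j] == GAP and allele_row[j] != GAP:
                j += 1
            events.append(
                MutationEvent("insertion", i, j, ancestral="", derived=allele_row[i:j])
            )
            i = j
    # Round-trip guarantee: the catalogue re-applied to the ancestor must
    # reproduce the allele row exactly.
    assert reconstruct_row(ancestor_row, events) == allele_row
    return events


def reconstruct_row(ancestor_row: str, events: Iterable[MutationEvent]) -> str:
    """Apply events to the ancestor row, in the alignment frame."""
    row = list(ancestor_row)
    for ev in events:
        if ev.kind == "substitution":
            row[ev.col_start] = ev.derived
        elif ev.kind == "deletion":
            for c in range(ev.col_start, ev.col_end):
                row[c] = GAP
        else:  # insertion
            if len(ev.derived) != ev.col_end - ev.col_start:
                raise MutationCallError(
                    f"insertion span {ev.span} does not fit derived {ev.derived!r}"
                )
            for c, ch in zip(range(ev.col_start, ev.col_end), ev.derived):
                row[c] = ch
    return "".join(row)


def _letter_label(k: int) -> str:
    # 0 -> A ... 25 -> Z, 26 -> AA (spreadsheet style)
    label = ""
    k += 1
    while k > 0:
        k, rem = divmod(k - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def assign_labels(
    events: list[MutationEvent], core: CoreAnnotation
) -> list[MutationEvent]:
    """Label events: core events lettered, flank events numbered, in column order.

    Events must be sorted by position and non-overlapping.  An event is a
    core event iff its span intersects the core interval (a deletion
    straddling the core boundary counts as core).
    """
    prev_end = -1
    for ev in sorted(events, key=lambda e: e.col_start):
        if ev.col_start < prev_end:
            raise MutationCallError(f"overlapping events at columns {ev.span}")
        prev_end = ev.col_end
    labeled = []
    n_core = n_flank = 0
    for ev in sorted(events, key=lambda e: e.col_start):
        if core.overlaps(ev.col_start, ev.col_end):
            labeled.append(replace(ev, label=_letter_label(n_core), region="core"))
            n_core += 1
        else:
            n_flank += 1
            labeled.append(replace(ev, label=str(n_flank), region="flank"))
    return labeled


def count_mutations(events: Iterable[MutationEvent]) -> dict[str, int]:
    """Counts with each indel event counted once regardless of length."""
    subs = indels = 0
    for ev in events:
        if ev.kind == "substitution":
            subs += 1
        else:
            indels += 1
    return {"substitutions": subs, "indels": indels, "total": subs + indels}


def catalogue_table(
    allele_id: str,
    events: Iterable[MutationEvent],
    allele_map: CoordinateMap,
) -> pd.DataFrame:
    """Mutation catalogue as a tidy table (one row per event).

    ``position`` is the event's 0-based start on the allele's ungapped
    sequence (for deletions, the position where the deleted run would sit).
    """
    rows = []
    for ev in events:
        pos = allele_map.positions_before(ev.col_start)
        rows.append(
            {
                "allele_id": allele_id,
                "label": ev.label,
                "kind": ev.kind,
                "col_start": ev.col_start,
                "col_end": ev.col_end,
                "position": pos,
                "ancestral": ev.ancestral,
                "derived": ev.derived,
                "region": ev.region,
            }
        )
    cols = [
        "allele_id", "label", "kind", "col_start", "col_end",
        "position", "ancestral", "derived", "region",
    ]
    return pd.DataFrame(rows, columns=cols)


def catalogue_for_alignment(
    aln: GappedAlignment,
    ancestor_row: str,
    allele_ids: Iterable[str],
    core: CoreAnnotation | None = None,
) -> pd.DataFrame:
    """Call (and optionally label) events for each allele against one ancestor row."""
    frames = []
    for rid in allele_ids:
        events = call_mutations(ancestor_row, aln.row(rid))
        if core is not None:
            events = assign_labels(events, core)
        frames.append(catalogue_table(rid, events, aln.coordinate_map(rid)))
    if not frames:
        return catalogue_table("", [], CoordinateMap("", (), 1)).iloc[0:0]
    return pd.concat(frames, ignore_index=True)
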