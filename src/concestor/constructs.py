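"""In-silico construct design: chimeras, single-mutation substitutions, scrambles.

Constructs are built the way the corresponding molecules would be cloned:

* :func:`swap_region` joins a donor allele's sequence into a backbone over
  alignment-column intervals (core/flank and half swaps);
* :func:`apply_event` substitutes one derived mutation into an ungapped
  sequence (or refuses, if the sequence does not carry the ancestral state);
* :func:`scramble_transversions` degrades a window with non-complementary
  transversions (A<->C, G<->T) at selected positions;
* :func:`subdeletion` slices a parent deletion event into a smaller deletion
  (e.g. deleting only the first eight, or only the last, of nine deleted
  base pairs) so partial-deletion variants are expressed as ordinary events.

Every construct records its recipe in the FASTA description as ``key=value``
pairs, so a design is identifiable from its output alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .mutations import MutationEvent
from .seq_io import GAP, CoordinateMap, GappedAlignment, SequenceRecord

#: Non-complementary transversion map: never the original, never its complement.
NONCOMPLEMENTARY_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


class DesignError(ValueError):
    """Raised for out-of-bounds intervals or ancestral-state mismatches."""


@dataclass(frozen=True)
class ChimeraSpec:
    """Backbone/donor swap recipe over disjoint alignment-column intervals."""

    backbone_id: str
    donor_id: str
    swap_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        spans = sorted(self.swap_intervals)
        for start, end in spans:
            if start >= end or start < 0:
                raise DesignError(f"invalid interval [{start},{end})")
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise DesignError("swap intervals must be disjoint")


def swap_region(aln: GappedAlignment, spec: ChimeraSpec) -> SequenceRecord:
    """Build the ungapped chimera: donor row inside the swap intervals, backbone outside."""
    backbone = aln.row(spec.backbone_id)
    donor = aln.row(spec.donor_id)
    for start, end in spec.swap_intervals:
        if end > aln.n_cols:
            raise DesignError(f"interval [{start},{end}) exceeds {aln.n_cols} columns")
    in_swap = [False] * aln.n_cols
    for start, end in spec.swap_intervals:
        for c in range(start, end):
            in_swap[c] = True
    chars = [d if s else b for b, d, s in zip(backbone, donor, in_swap)]
    residues = "".join(chars).replace(GAP, "")
    intervals = ",".join(f"{s}-{e}" for s, e in spec.swap_intervals) or "none"
    return SequenceRecord(
        id=f"{spec.backbone_id}+{spec.donor_id}_chimera",
        residues=residues,
        description=f"backbone={spec.backbone_id} donor={spec.donor_id} cols={intervals}",
    )


def apply_event(
    seq: SequenceRecord, event: MutationEvent, cmap: CoordinateMap
) -> SequenceRecord:
    """Apply one mutation event to an ungapped sequence.

    The event's columns are mapped through ``cmap`` (the coordinate map of
    the frame ``seq`` lives in).  The ancestral string must match the
    sequence at the mapped span, otherwise the edit refuses to apply.
    The output length changes by ``len(derived) - len(ancestral)``.
    """
    p_start, p_end = cmap.span_to_positions(event.col_start, event.col_end)
    found = seq.residues[p_start:p_end]
    if found != event.ancestral:
        raise DesignError(
            f"ancestral-state mismatch at [{p_start},{p_end}): "
            f"event expects {event.ancestral!r}, sequence has {found!r}"
        )
    residues = seq.residues[:p_start] + event.derived + seq.residues[p_end:]
    tag = event.label or f"{event.kind}@{event.col_start}"
    desc = (seq.description + " " if seq.description else "") + f"applied={tag}"
    return SequenceRecord(id=f"{seq.id}+{tag}", residues=residues, description=desc)


def scramble_transversions(
    seq: SequenceRecord, interval: tuple[int, int], positions: Sequence[int]
) -> SequenceRecord:
    """Non-complementary transversions at selected offsets within a window.

    ``positions`` are 0-based offsets relative to ``interval[0]`` (so the
    classic every-second-base scramble of an 8-bp window is
    ``positions=(1, 3, 5, 7)``).  All other bases are untouched.
    """
    start, end = interval
    if not 0 <= start < end <= len(seq.residues):
        raise DesignError(f"interval [{start},{end}) out of range")
    chars = list(seq.residues)
    for off in positions:
        pos = start + off
        if not start <= pos < end:
            raise DesignError(f"position offset {off} outside interval [{start},{end})")
        chars[pos] = NONCOMPLEMENTARY_TRANSVERSION[chars[pos]]
    pos_tag = ",".join(str(p) for p in positions)
    desc = (seq.description + " " if seq.description else "") + (
        f"scramble={start}-{end}:{pos_tag}"
    )
    return SequenceRecord(id=f"{seq.id}_scramble", residues="".join(chars), description=desc)


def subdeletion(event: MutationEvent, offset: int, length: int) -> MutationEvent:
    """A smaller deletion sliced out of a parent deletion event.

    ``offset``/``length`` select which of the parent's deleted columns remain
    deleted; e.g. ``subdeletion(e, 0, 8)`` deletes only the first eight base
    pairs of a 9-bp deletion, ``subdeletion(e, 8, 1)`` only the ninth.
    """
    if event.kind != "deletion":
        raise DesignError("subdeletion requires a deletion event")
    span = event.col_end - event.col_start
    if not (0 <= offset and length >= 1 and offset + length <= span):
        raise DesignError(f"slice [{offset},{offset + length}) outside deletion of {span} columns")
    return replace(
        event,
        col_start=event.col_start + offset,
        col_end=event.col_start + offset + length,
        ancestral=event.ancestral[offset : offset + length],
        label=None,
        region=event.region,
    )
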