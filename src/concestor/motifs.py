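"""IUPAC consensus motif scanning and binding-site gain/loss calling.

A binding site here is a consensus match — no position-weight scoring.  The
two motifs of interest by default are the Hox factor ABD-B (``TTTAY``) and
the sex-determination factor DSX (``RNNACWAWGTNNY``); both are scanned on
both strands, since site polarity varies between elements.

Gain/loss between an ancestral sequence and a derived allele is called by
mapping each ancestral site through the alignment to the allele: ``lost``
means the allele's mapped window no longer satisfies the consensus,
``conserved`` that it still does (a reduced-affinity variant that still
matches the consensus is conserved; see :func:`evaluate_site_after_edit` for
the finer-grained check), and matches present only in the allele are
``gained``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Literal

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .mutations import MutationEvent
from .seq_io import CoordinateMap, GappedAlignment, SequenceRecord

IUPAC_CODES = frozenset(ambiguous_dna_values)  # ACGT + RYSWKMBDHVN (+X not used)

#: Default consensus motifs (empirically derived in vitro).
ABDB_MOTIF_CONSENSUS = "TTTAY"
DSX_MOTIF_CONSENSUS = "RNNACWAWGTNNY"


class MotifError(ValueError):
    """Raised for invalid IUPAC consensus strings."""


def _iupac_regex(consensus: str) -> re.Pattern[str]:
    parts = []
    for code in consensus:
        bases = ambiguous_dna_values.get(code)
        if bases is None or code == "X":
            raise MotifError(f"invalid IUPAC code {code!r} in {consensus!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping windows are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def reverse_complement_iupac(consensus: str) -> str:
    """Reverse complement honouring IUPAC degeneracy (e.g. TTTAY -> RTAAA)."""
    return str(Seq(consensus).reverse_complement())


@dataclass(frozen=True)
class Motif:
    """A named IUPAC consensus, e.g. ``Motif('ABD-B', 'TTTAY')``."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise MotifError("consensus must be non-empty")
        bad = set(self.consensus) - IUPAC_CODES | (set(self.consensus) & {"X"})
        if bad:
            raise MotifError(f"invalid IUPAC codes {sorted(bad)!r} in {self.consensus!r}")

    def __len__(self) -> int:
        return len(self.consensus)

    def matches(self, window: str, strand: str = "+") -> bool:
        """Does the forward-strand ``window`` satisfy the consensus on ``strand``?"""
        if len(window) != len(self.consensus):
            return False
        probe = window if strand == "+" else str(Seq(window).reverse_complement())
        return re.fullmatch(_iupac_regex_body(self.consensus), probe) is not None


def _iupac_regex_body(consensus: str) -> str:
    parts = []
    for code in consensus:
        bases = ambiguous_dna_values[code]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


DEFAULT_MOTIFS = (
    Motif("ABD-B", ABDB_MOTIF_CONSENSUS),
    Motif("DSX", DSX_MOTIF_CONSENSUS),
)


@dataclass(frozen=True)
class MotifSite:
    """A consensus match on an ungapped sequence, forward-strand coordinates."""

    seq_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    matched: str
    motif_name: str

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class SiteDiff:
    """Status of one site between ancestor and allele.

    For ``conserved``/``lost`` the embedded site is in the ancestor frame;
    for ``gained`` it is in the allele frame (the window has no ancestral
    counterpart).
    """

    site: MotifSite
    status: Literal["conserved", "lost", "gained"]
    allele_id: str


@dataclass(frozen=True)
class OverlapRecord:
    """A (mutation event, site) pair with a non-empty interval intersection."""

    event: MutationEvent
    site: MotifSite
    overlap_bp: int


def scan_motif(
    seq: SequenceRecord, motif: Motif, strands: Literal["both", "forward"] = "both"
) -> list[MotifSite]:
    """All consensus matches in ``seq``; minus-strand hits in forward coordinates.

    Overlapping matches are reported; an interval is reported once per strand.
    """
    pattern = _iupac_regex(motif.consensus)
    n = len(seq.residues)
    L = len(motif)
    sites: list[MotifSite] = []
    for m in pattern.finditer(seq.residues):
        start = m.start()
        sites.append(
            MotifSite(seq.id, start, start + L, "+", seq.residues[start : start + L], motif.name)
        )
    if strands == "both":
        rc = str(Seq(seq.residues).reverse_complement())
        for m in pattern.finditer(rc):
            start = n - m.start() - L
            sites.append(
                MotifSite(seq.id, start, start + L, "-", seq.residues[start : start + L], motif.name)
            )
    # dedupe identical (interval, strand) and order by position
    unique = {(s.start, s.end, s.strand): s for s in sites}
    return sorted(unique.values(), key=lambda s: (s.start, s.strand, s.motif_name))


def diff_sites(
    ancestor_row: str,
    aln: GappedAlignment,
    allele_id: str,
    motifs: Iterable[Motif] = DEFAULT_MOTIFS,
    strands: Literal["both", "forward"] = "both",
    ancestor_id: str = "Concestor",
) -> list[SiteDiff]:
    """Call conserved/lost/gained sites between an ancestor row and one allele.

    ``ancestor_row`` is a gapped row in the alignment frame (typically the
    reconstruction consensus).  Each ancestral site's window is mapped through
    alignment columns to the allele's ungapped sequence and re-tested against
    the consensus; allele-only matches are reported as gained.
    """
    if len(ancestor_row) != aln.n_cols:
        raise ValueError("ancestor row length does not match alignment columns")
    allele = aln.ungapped(allele_id)
    allele_map = aln.coordinate_map(allele_id)
    anc_seq = SequenceRecord(ancestor_id, ancestor_row.replace("-", ""))
    anc_map = CoordinateMap.from_row(ancestor_id, ancestor_row)

    diffs: list[SiteDiff] = []
    conserved_windows: set[tuple[int, int, str, str]] = set()
    for motif in motifs:
        for site in scan_motif(anc_seq, motif, strands=strands):
            col_start = anc_map.position_to_column(site.start)
            col_end = anc_map.position_to_column(site.end - 1) + 1
            p_start, p_end = allele_map.span_to_positions(col_start, col_end)
            window = allele.residues[p_start:p_end]
            if motif.matches(window, site.strand):
                status = "conserved"
                conserved_windows.add((p_start, p_end, site.strand, motif.name))
            else:
                status = "lost"
            diffs.append(SiteDiff(site=site, status=status, allele_id=allele_id))
        for site in scan_motif(allele, motif, strands=strands):
            key = (site.start, site.end, site.strand, motif.name)
            if key not in conserved_windows:
                diffs.append(SiteDiff(site=site, status="gained", allele_id=allele_id))
    return diffs


def overlap_events_sites(
    events: Iterable[MutationEvent],
    sites: Iterable[MotifSite],
    cmap: CoordinateMap,
) -> list[OverlapRecord]:
    """Intersect mutation events (alignment frame) with sites (ungapped frame).

    ``cmap`` must be the coordinate map of the sequence the sites were
    scanned on, so events are projected into that same frame.  Only pairs
    with a non-empty intersection are returned, with the intersection length
    in bp.
    """
    records = []
    site_list = list(sites)
    for ev in events:
        p_start, p_end = cmap.span_to_positions(ev.col_start, ev.col_end)
        for site in site_list:
            lo = max(p_start, site.start)
            hi = min(p_end, site.end)
            if hi > lo:
                records.append(OverlapRecord(event=ev, site=site, overlap_bp=hi - lo))
    return records


def evaluate_site_after_edit(
    seq: SequenceRecord,
    event: MutationEvent,
    site: MotifSite,
    motif: Motif,
    cmap: CoordinateMap,
) -> bool:
    """Does the site still match its consensus after applying one event?

    The event (alignment frame, mapped through ``cmap``) is applied to the
    ungapped sequence, and a consensus-length window anchored at the site's
    shifted end coordinate is re-tested.  Anchoring at the end means that a
    deletion removing the first base(s) of a site pulls upstream sequence
    into the window — exactly the situation where a deletion ending one base
    into a site can leave a window that still satisfies the consensus.
    """
    p_start, p_end = cmap.span_to_positions(event.col_start, event.col_end)
    if seq.residues[p_start:p_end] != event.ancestral:
        raise ValueError(
            f"event ancestral {event.ancestral!r} does not match sequence "
            f"{seq.residues[p_start:p_end]!r} at [{p_start},{p_end})"
        )
    edited = seq.residues[:p_start] + event.derived + seq.residues[p_end:]
    delta = len(event.derived) - len(event.ancestral)
    if site.end <= p_start:
        new_end = site.end
    elif site.end >= p_end:
        new_end = site.end + delta
    else:  # site end falls inside the edited span
        new_end = p_start + len(event.derived)
    new_start = new_end - len(motif)
    if new_start < 0 or new_end > len(edited):
        return False
    return motif.matches(edited[new_start:new_end], site.strand)


def sites_to_bed(sites: Iterable[MotifSite]) -> list[tuple[str, int, int, str, int, str]]:
    """BED6 tuples (chrom=seq_id, name=motif, score=0) for write_bed."""
    return [(s.seq_id, s.start, s.end, s.motif_name, 0, s.strand) for s in sites]
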