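"""In-silico restriction digestion, RFLP marker discovery and segregation testing.

A restriction enzyme is modelled as an IUPAC recognition pattern plus the
0-based offset of the top-strand cut inside it; only the gel-visible
fragment lengths matter, so sticky-end overhangs beyond the single cut
coordinate are not modelled.  The workhorse marker of this analysis is
BstXI (``CCANNNNN^NTGG``), whose recognition pattern is its own reverse
complement.

Genotypes are called from fragment-length multisets: an individual matching
one parental digest pattern exactly is homozygous, the union multiset of
both parental patterns is heterozygous, anything else is a no-call.
Mendelian segregation of F2 classes is tested with a plain Pearson
chi-square goodness-of-fit (no continuity correction).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .motifs import Motif, reverse_complement_iupac, _iupac_regex
from .seq_io import SequenceRecord

HOMOZYGOUS_A = "homozygous_a"
HOMOZYGOUS_B = "homozygous_b"
HETEROZYGOUS = "heterozygous"
NO_CALL = "no_call"


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Name, IUPAC recognition pattern, and top-strand cut offset."""

    name: str
    recognition: str
    cut_offset_top: int

    def __post_init__(self) -> None:
        Motif(self.name, self.recognition)  # validates IUPAC codes
        if not 0 <= self.cut_offset_top <= len(self.recognition):
            raise ValueError(
                f"{self.name}: cut offset {self.cut_offset_top} outside recognition site"
            )

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement_iupac(self.recognition) == self.recognition


#: BstXI: CCANNNNN^NTGG — cuts after the 8th base of its 12-bp site.
BSTXI = RestrictionEnzyme("BstXI", "CCANNNNNNTGG", 8)


@dataclass(frozen=True)
class DigestResult:
    """Ordered 5'→3' fragments of a digest; lengths sum to the input length."""

    fragments: tuple[str, ...]

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(f) for f in self.fragments)

    @property
    def length_multiset(self) -> tuple[int, ...]:
        """Sorted lengths — the gel-visible banding pattern."""
        return tuple(sorted(self.lengths))


@dataclass(frozen=True)
class RFLPMarker:
    """A restriction-site polymorphism distinguishing two alleles.

    ``pattern_a``/``pattern_b`` are the sorted fragment-length multisets of
    the two parental amplicons.
    """

    enzyme: RestrictionEnzyme
    interval: tuple[int, int]
    allele_a: str
    allele_b: str
    pattern_a: tuple[int, ...]
    pattern_b: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.pattern_a == self.pattern_b:
            raise ValueError("marker patterns must differ between alleles")

    @property
    def heterozygous_pattern(self) -> tuple[int, ...]:
        return tuple(sorted(self.pattern_a + self.pattern_b))


@dataclass(frozen=True)
class SegregationResult:
    """Pearson chi-square goodness-of-fit of observed class counts to a ratio."""

    observed: tuple[int, ...]
    expected_ratio: tuple[int, ...]
    chi_square: float
    df: int
    p_value: float


def _sites_with_strand(seq: str, enzyme: RestrictionEnzyme) -> list[tuple[int, str]]:
    sites = [(m.start(), "+") for m in _iupac_regex(enzyme.recognition).finditer(seq)]
    if not enzyme.is_palindromic:
        rc_pattern = _iupac_regex(reverse_complement_iupac(enzyme.recognition))
        sites += [(m.start(), "-") for m in rc_pattern.finditer(seq)]
    return sorted(set(sites))


def find_enzyme_sites(seq: SequenceRecord | str, enzyme: RestrictionEnzyme) -> list[int]:
    """0-based start positions of recognition sites on the forward sequence.

    Patterns that are not their own reverse complement are also matched in
    minus-strand orientation (i.e. the pattern's reverse complement on the
    forward strand), mapped to forward coordinates.
    """
    residues = seq if isinstance(seq, str) else seq.residues
    return sorted({pos for pos, _ in _sites_with_strand(residues, enzyme)})


def digest(seq: SequenceRecord | str, enzyme: RestrictionEnzyme) -> DigestResult:
    """Cut at every recognition site; zero sites yields the whole input.

    The cut coordinate is ``site_start + cut_offset_top`` for plus-strand
    sites and ``site_start + (len(site) - cut_offset_top)`` for minus-strand
    sites; each distinct coordinate is cut once (overlapping sites resolve
    left-to-right as a consequence).
    """
    residues = seq if isinstance(seq, str) else seq.residues
    L = len(enzyme.recognition)
    cuts = set()
    for pos, strand in _sites_with_strand(residues, enzyme):
        cut = pos + enzyme.cut_offset_top if strand == "+" else pos + (L - enzyme.cut_offset_top)
        if 0 < cut < len(residues):
            cuts.add(cut)
    bounds = [0, *sorted(cuts), len(residues)]
    frags = tuple(residues[a:b] for a, b in zip(bounds, bounds[1:]))
    return DigestResult(fragments=frags)


def rflp_discover(
    allele_a: SequenceRecord,
    allele_b: SequenceRecord,
    enzymes: Iterable[RestrictionEnzyme],
    amplicon_interval: tuple[int, int] | None = None,
) -> list[RFLPMarker]:
    """Markers (one per enzyme) whose digest patterns differ between two alleles.

    ``amplicon_interval`` is a half-open interval on each allele's ungapped
    sequence (both alleles must cover it); ``None`` digests the full sequences.
    """
    if amplicon_interval is None:
        a_amp, b_amp = allele_a.residues, allele_b.residues
        interval = (0, max(len(allele_a), len(allele_b)))
    else:
        start, end = amplicon_interval
        if not (0 <= start < end <= len(allele_a) and end <= len(allele_b)):
            raise ValueError(f"amplicon interval {amplicon_interval} out of range")
        a_amp, b_amp = allele_a.residues[start:end], allele_b.residues[start:end]
        interval = amplicon_interval
    markers = []
    for enzyme in enzymes:
        pat_a = digest(a_amp, enzyme).length_multiset
        pat_b = digest(b_amp, enzyme).length_multiset
        if pat_a != pat_b:
            markers.append(
                RFLPMarker(
                    enzyme=enzyme,
                    interval=interval,
                    allele_a=allele_a.id,
                    allele_b=allele_b.id,
                    pattern_a=pat_a,
                    pattern_b=pat_b,
                )
            )
    return markers


def call_genotype(observed_fragments: Sequence[int], marker: RFLPMarker) -> str:
    """Exact-match genotype call from an observed fragment-length multiset."""
    obs = Counter(observed_fragments)
    if obs == Counter(marker.pattern_a):
        return HOMOZYGOUS_A
    if obs == Counter(marker.pattern_b):
        return HOMOZYGOUS_B
    if obs == Counter(marker.heterozygous_pattern):
        return HETEROZYGOUS
    return NO_CALL


def segregation_test(
    counts: Sequence[int], ratio: Sequence[int]
) -> SegregationResult:
    """Pearson chi-square goodness-of-fit of class counts against an integer ratio.

    Expected counts are ``total * ratio_i / sum(ratio)``; the p-value is the
    upper tail of the chi-square distribution with ``classes - 1`` degrees of
    freedom.  No continuity correction is applied.
    """
    counts = tuple(int(c) for c in counts)
    ratio = tuple(int(r) for r in ratio)
    if len(counts) != len(ratio):
        raise ValueError("counts and ratio must have the same number of classes")
    if len(counts) < 2:
        raise ValueError("need at least two classes")
    total = sum(counts)
    if total <= 0:
        raise ValueError("total count must be positive")
    if any(r <= 0 for r in ratio):
        raise ValueError("expected ratio classes must be positive")
    expected = [total * r / sum(ratio) for r in ratio]
    chi2, p = stats.chisquare(f_obs=counts, f_exp=expected)
    return SegregationResult(
        observed=counts,
        expected_ratio=ratio,
        chi_square=float(chi2),
        df=len(counts) - 1,
        p_value=float(p),
    )
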