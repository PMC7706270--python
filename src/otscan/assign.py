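"""Assigning guide RNAs to called cleavage peaks.

For each peak the reference sequence is extracted in a +/-40 bp window
around the cut.  Windows containing N or truncated by a contig edge are
dropped.  Every guide (spacer + PAM by default) is globally aligned
against both strands of the window with free end gaps, and alignments
scoring strictly above the threshold (default 55) are kept.  Passing
alignments are decomposed into substitution / insertion / deletion
mismatches over the spacer, the observed PAM is checked against the
guide's IUPAC pattern (with a +1-shifted rescue triplet when it fails),
and the blunt-cut position is predicted ``cut_offset`` bp 5' of the PAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .align import DEFAULT_SCORING, ScoringScheme, global_align, reverse_complement
from .io import ReferenceGenome
from .peaks import CleavagePeak

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

MISMATCH_CLASSES = ("exact", "snv_1_3", "snv_ge4", "indel_mismatch", "unassigned")


@dataclass(frozen=True)
class GuideRNA:
    """A guide: 20-nt spacer, 3-nt PAM pattern, blunt cut 3 bp 5' of the PAM."""

    name: str
    spacer: str
    pam: str = "NGG"
    cut_offset: int = 3

    def __post_init__(self):
        if not 17 <= len(self.spacer) <= 23:
            raise ValueError(f"spacer length {len(self.spacer)} outside 17-23")
        if set(self.spacer) - set("ACGT"):
            raise ValueError(f"spacer must be ACGT-only: {self.spacer}")
        if len(self.pam) != 3 or set(self.pam) - set(IUPAC):
            raise ValueError(f"PAM must be a 3-nt IUPAC pattern: {self.pam}")

    def query(self, mode: str = "spacer+pam") -> str:
        if mode == "spacer":
            return self.spacer
        if mode == "spacer+pam":
            # non-ACGT IUPAC symbols become the N wildcard for alignment
            pam = "".join(c if c in "ACGT" else "N" for c in self.pam)
            return self.spacer + pam
        raise ValueError(f"unknown query mode {mode!r}")


@dataclass(frozen=True)
class WindowSeq:
    contig: str
    start: int
    end: int
    sequence: str


@dataclass(frozen=True)
class FilteredWindow:
    """A peak whose window was dropped, with the reason (contains_N / edge)."""

    contig: str
    position: int
    reason: str


@dataclass
class GrnaAlignment:
    guide: GuideRNA
    window: WindowSeq
    strand: str
    score: float
    aligned_query: str
    aligned_target: str
    n_subs: int = 0
    n_ins: int = 0
    n_del: int = 0
    target_span: tuple[int, int] = (0, 0)   # genomic, half-open
    pam_observed: str = ""
    pam_canonical: bool = False
    pam_rescue: bool = False
    predicted_cut: int = -1


@dataclass
class OTSSite:
    peak: CleavagePeak
    best: Optional[GrnaAlignment]
    all_passing: list[GrnaAlignment] = field(default_factory=list)
    mismatch_class: str = "unassigned"


def iupac_match(observed: str, pattern: str) -> bool:
    if len(observed) != len(pattern):
        return False
    return all(o in IUPAC.get(p, "") for o, p in zip(observed, pattern))


def extract_window(ref: ReferenceGenome, peak: CleavagePeak,
                   flank: int = 40) -> Union[WindowSeq, FilteredWindow]:
    """Extract ``[position - flank, position + flank + 1)`` around the cut.

    Windows truncated by a contig edge are dropped with reason ``edge``;
    windows containing any N with reason ``contains_N`` (only high-quality,
    gap-free regions are searched for guide similarity).
    """
    if peak.contig not in ref:
        raise KeyError(f"unknown contig {peak.contig!r}")
    length = ref.length(peak.contig)
    if not 0 <= peak.position < length:
        raise ValueError(f"peak position {peak.position} outside contig")
    start, end = peak.position - flank, peak.position + flank + 1
    if start < 0 or end > length:
        return FilteredWindow(peak.contig, peak.position, "edge")
    seq = ref.fetch(peak.contig, start, end)
    if "N" in seq:
        return FilteredWindow(peak.contig, peak.position, "contains_N")
    return WindowSeq(contig=peak.contig, start=start, end=end, sequence=seq)


def _annotate(alignment: GrnaAlignment, query_mode: str) -> None:
    """Fill mismatch decomposition, PAM status and predicted cut in place.

    Counts are taken over spacer columns only.  ``n_ins`` counts columns
    where the reference lacks a base present in the guide (gap in target);
    ``n_del`` counts reference bases absent from the guide (gap in query)
    internal to the spacer.
    """
    guide = alignment.guide
    spacer_len = len(guide.spacer)
    aq, at = alignment.aligned_query, alignment.aligned_target
    n_subs = n_ins = n_del = 0
    consumed = 0          # query residues consumed so far
    t_index = 0           # target residues consumed so far (oriented coords)
    q_t_start = q_t_end = None    # oriented target span of the query
    pam_t_start = None
    pam_chars = []
    for q, t in zip(aq, at):
        if q != "-" and consumed == spacer_len and pam_t_start is None:
            pam_t_start = t_index
        if q != "-" and t != "-":
            if q_t_start is None:
                q_t_start = t_index
            q_t_end = t_index + 1
            if consumed < spacer_len:
                if q != "N" and q != t:
                    n_subs += 1
            else:
                pam_chars.append(t)
            consumed += 1
            t_index += 1
        elif q != "-":   # gap in target: genome is missing this guide base
            if consumed < spacer_len:
                n_ins += 1
            else:
                pam_chars.append("-")
            consumed += 1
        else:            # gap in query
            if 0 < consumed < spacer_len:
                n_del += 1
            t_index += 1
    alignment.n_subs, alignment.n_ins, alignment.n_del = n_subs, n_ins, n_del

    window = alignment.window
    oriented_len = window.end - window.start

    def to_genomic_boundary(b: int) -> int:
        return window.start + b if alignment.strand == "+" else window.end - b

    if q_t_start is not None:
        if alignment.strand == "+":
            alignment.target_span = (window.start + q_t_start,
                                     window.start + q_t_end)
        else:
            alignment.target_span = (window.end - q_t_end,
                                     window.end - q_t_start)

    if query_mode == "spacer+pam" and pam_t_start is not None:
        alignment.pam_observed = "".join(pam_chars)
        alignment.pam_canonical = iupac_match(alignment.pam_observed, guide.pam)
        if not alignment.pam_canonical:
            oriented = (window.sequence if alignment.strand == "+"
                        else reverse_complement(window.sequence))
            shifted = oriented[pam_t_start + 1: pam_t_start + 4]
            alignment.pam_rescue = iupac_match(shifted, guide.pam)
        cut_b = pam_t_start - guide.cut_offset
        alignment.predicted_cut = to_genomic_boundary(cut_b)
    elif q_t_end is not None:
        # spacer-only query: the PAM sits just 3' of the aligned spacer
        oriented = (window.sequence if alignment.strand == "+"
                    else reverse_complement(window.sequence))
        pam_seq = oriented[q_t_end: q_t_end + 3]
        alignment.pam_observed = pam_seq
        alignment.pam_canonical = iupac_match(pam_seq, guide.pam)
        if not alignment.pam_canonical:
            shifted = oriented[q_t_end + 1: q_t_end + 4]
            alignment.pam_rescue = iupac_match(shifted, guide.pam)
        cut_b = q_t_end - guide.cut_offset
        alignment.predicted_cut = to_genomic_boundary(cut_b)


def classify_site(alignment: GrnaAlignment) -> str:
    """Mismatch class of an annotated alignment."""
    if alignment.n_ins + alignment.n_del >= 1:
        return "indel_mismatch"
    if alignment.n_subs == 0:
        return "exact"
    if alignment.n_subs >= 4:
        return "snv_ge4"
    return "snv_1_3"


def assign_guides(peak: CleavagePeak, window: WindowSeq,
                  guides: Sequence[GuideRNA], threshold: float = 55.0,
                  query_mode: str = "spacer+pam",
                  scoring: ScoringScheme = DEFAULT_SCORING) -> OTSSite:
    """Align every guide against both strands of the window and keep
    alignments scoring strictly above ``threshold``.

    The best alignment is the maximal score; ties break by guide order,
    then the + strand.  A site with no passing alignment is marked
    ``unassigned``.
    """
    if not guides:
        raise ValueError("empty guide list")
    passing: list[GrnaAlignment] = []
    for guide in guides:
        query = guide.query(query_mode)
        for strand, target in (("+", window.sequence),
                               ("-", reverse_complement(window.sequence))):
            score, aq, at = global_align(query, target, scoring)
            if score > threshold:
                aln = GrnaAlignment(guide=guide, window=window, strand=strand,
                                    score=score, aligned_query=aq,
                                    aligned_target=at)
                _annotate(aln, query_mode)
                passing.append(aln)
    if not passing:
        return OTSSite(peak=peak, best=None, all_passing=[],
                       mismatch_class="unassigned")
    guide_order = {g.name: i for i, g in enumerate(guides)}
    best = min(passing, key=lambda a: (-a.score, guide_order[a.guide.name],
                                       0 if a.strand == "+" else 1))
    return OTSSite(peak=peak, best=best, all_passing=passing,
                   mismatch_class=classify_site(best))


def assign_sites(ref: ReferenceGenome, peaks: Sequence[CleavagePeak],
                 guides: Sequence[GuideRNA], threshold: float = 55.0,
                 flank: int = 40, query_mode: str = "spacer+pam",
                 scoring: ScoringScheme = DEFAULT_SCORING
                 ) -> tuple[list[OTSSite], list[FilteredWindow]]:
    """Window extraction + guide assignment for a list of peaks."""
    sites: list[OTSSite] = []
    filtered: list[FilteredWindow] = []
    for peak in peaks:
        window = extract_window(ref, peak, flank=flank)
        if isinstance(window, FilteredWindow):
            filtered.append(window)
            continue
        sites.append(assign_guides(peak, window, guides, threshold=threshold,
                                   query_mode=query_mode, scoring=scoring))
    return sites, filtered
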