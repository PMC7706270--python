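"""Quantifying editing outcomes from long-amplicon alignments.

NHEJ repair of a Cas9 cut leaves small indels clustered at the cut
position.  Editing is quantified per site as per-position percentages of
reads with an indel *starting* at each position in a +/-2 kb window,
background-subtracted against the unedited (wild-type) sample, plus a
read-wise editing-efficiency estimate, read-level large-indel (>50 bp)
clustering, and an exact binomial test for allele-specific cleavage.

Indel anchors follow pileup semantics: an insertion is anchored to the
reference base immediately left of the inserted sequence, a deletion to
its leftmost deleted base; a multi-base deletion contributes only at its
start position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import binomtest, false_discovery_control

from .io import AlignedRead, SiteRecord

logger = logging.getLogger("otscan")


@dataclass
class IndelProfile:
    """Per-position indel-start percentages around a cut site.

    Arrays cover ``[site.position - half_window, site.position + half_window)``.
    Positions with zero coverage are NaN, never interpolated.
    """

    site: SiteRecord
    start: int
    end: int
    pct_ins: np.ndarray
    pct_del: np.ndarray
    coverage: np.ndarray


@dataclass
class DeltaProfile:
    site: SiteRecord
    start: int
    end: int
    d_ins: np.ndarray
    d_del: np.ndarray

    def summary(self, core: int = 20) -> float:
        """Max absolute difference within +-core bp of the cut."""
        cut = self.site.position
        lo = max(self.start, cut - core) - self.start
        hi = min(self.end, cut + core + 1) - self.start
        window = np.concatenate([self.d_ins[lo:hi], self.d_del[lo:hi]])
        finite = window[np.isfinite(window)]
        return float(np.max(np.abs(finite))) if finite.size else float("nan")


@dataclass(frozen=True)
class LargeIndelEvent:
    read_id: str
    kind: str
    ref_position: int
    length: int


@dataclass
class LargeIndelCluster:
    kind: str
    ref_position: int          # representative (first event's) position
    length: int                # representative length
    events: list[LargeIndelEvent] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.events)


@dataclass
class AlleleBiasResult:
    site: Optional[SiteRecord]
    alt_reads: int
    total_reads: int
    genomic_alt_fraction: float
    observed_fraction: float
    p_value: float
    biased: bool


def indel_start_profile(reads: Iterable[AlignedRead], site: SiteRecord,
                        half_window: int = 2000) -> IndelProfile:
    """Per-position percentage of covering reads with an indel starting
    there, in ``[position - half_window, position + half_window)``."""
    start = site.position - half_window
    end = site.position + half_window
    width = end - start
    coverage = np.zeros(width, dtype=np.int64)
    ins_counts = np.zeros(width, dtype=np.int64)
    del_counts = np.zeros(width, dtype=np.int64)
    n_reads = 0
    for read in reads:
        if read.contig != site.contig:
            continue
        lo = max(read.ref_start, start)
        hi = min(read.ref_end, end)
        if lo >= hi:
            continue
        n_reads += 1
        coverage[lo - start:hi - start] += 1
        for pos, kind, length in read.cigar_indels:
            if start <= pos < end and read.ref_start <= pos < read.ref_end:
                (ins_counts if kind == "ins" else del_counts)[pos - start] += 1
    if n_reads == 0:
        logger.warning("no reads overlap window of %s:%d",
                       site.contig, site.position)
        nan = np.full(width, np.nan)
        return IndelProfile(site=site, start=start, end=end,
                            pct_ins=nan.copy(), pct_del=nan.copy(),
                            coverage=coverage)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_ins = np.where(coverage > 0, 100.0 * ins_counts / coverage, np.nan)
        pct_del = np.where(coverage > 0, 100.0 * del_counts / coverage, np.nan)
    return IndelProfile(site=site, start=start, end=end,
                        pct_ins=pct_ins, pct_del=pct_del, coverage=coverage)


def subtract_background(edited: IndelProfile,
                        wildtype: IndelProfile) -> DeltaProfile:
    """Elementwise edited-minus-wild-type percentages; NaN propagates."""
    if (edited.start, edited.end) != (wildtype.start, wildtype.end) or \
            edited.site.contig != wildtype.site.contig:
        raise ValueError("profiles cover different windows")
    return DeltaProfile(site=edited.site, start=edited.start, end=edited.end,
                        d_ins=edited.pct_ins - wildtype.pct_ins,
                        d_del=edited.pct_del - wildtype.pct_del)


def _cut_proximal_fraction(reads: Sequence[AlignedRead], site: SiteRecord,
                           core: int) -> tuple[float, int]:
    cut = site.position
    spanning = [r for r in reads
                if r.contig == site.contig
                and r.ref_start <= cut - core and r.ref_end >= cut + core]
    if not spanning:
        raise ValueError(f"zero coverage spanning {site.contig}:{cut}+-{core}")
    with_indel = sum(
        1 for r in spanning
        if any(cut - core <= pos <= cut + core for pos, _, _ in r.cigar_indels))
    return with_indel / len(spanning), len(spanning)


def editing_efficiency(edited_reads: Sequence[AlignedRead],
                       wildtype_reads: Sequence[AlignedRead],
                       site: SiteRecord, core: int = 20) -> dict:
    """Read-wise editing-efficiency estimate with wild-type subtraction.

    The estimate is the fraction of edited-sample reads carrying at least
    one indel starting within +-core bp of the cut, minus the same
    fraction in the wild-type sample.  Only reads spanning the full
    +-core window count (avoids edge-truncation bias).
    """
    f_edit, n_edit = _cut_proximal_fraction(edited_reads, site, core)
    f_wt, n_wt = _cut_proximal_fraction(wildtype_reads, site, core)
    return {
        "efficiency": f_edit - f_wt,
        "edited_fraction": f_edit,
        "wildtype_fraction": f_wt,
        "n_edited_reads": n_edit,
        "n_wildtype_reads": n_wt,
    }


def detect_large_indels(reads: Iterable[AlignedRead], site: SiteRecord,
                        min_len: int = 50, half_window: int = 2000,
                        pos_tol: int = 10, len_tol: float = 0.10
                        ) -> list[LargeIndelCluster]:
    """Read-level indels of length >= ``min_len`` inside the window,
    clustered by (kind, position +-pos_tol, length +-len_tol fraction).

    ``min_len`` uses >= semantics; set 51 for a strict "longer than 50 bp"
    rule.
    """
    start = site.position - half_window
    end = site.position + half_window
    events: list[LargeIndelEvent] = []
    for read in reads:
        if read.contig != site.contig:
            continue
        for pos, kind, length in read.cigar_indels:
            if length >= min_len and start <= pos < end:
                events.append(LargeIndelEvent(read_id=read.read_id, kind=kind,
                                              ref_position=pos, length=length))
    events.sort(key=lambda e: (e.kind, e.ref_position, e.length, e.read_id))
    clusters: list[LargeIndelCluster] = []
    for ev in events:
        placed = False
        for cl in clusters:
            if (cl.kind == ev.kind
                    and abs(ev.ref_position - cl.ref_position) <= pos_tol
                    and abs(ev.length - cl.length) <= len_tol * cl.length):
                cl.events.append(ev)
                placed = True
                break
        if not placed:
            clusters.append(LargeIndelCluster(kind=ev.kind,
                                              ref_position=ev.ref_position,
                                              length=ev.length, events=[ev]))
    clusters.sort(key=lambda c: (-c.support, c.ref_position))
    return clusters


def allele_bias_test(alt_reads: int, total_reads: int,
                     genomic_alt_fraction: float, alpha: float = 0.01,
                     site: Optional[SiteRecord] = None) -> AlleleBiasResult:
    """Two-sided exact binomial test (minimum-likelihood definition) of
    the observed alt-read fraction against the genomic expectation."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not 0 <= alt_reads <= total_reads:
        raise ValueError("alt_reads outside [0, total_reads]")
    if not 0.0 < genomic_alt_fraction < 1.0:
        raise ValueError("genomic_alt_fraction must be in (0, 1)")
    p = binomtest(alt_reads, total_reads, genomic_alt_fraction,
                  alternative="two-sided").pvalue
    return AlleleBiasResult(site=site, alt_reads=alt_reads,
                            total_reads=total_reads,
                            genomic_alt_fraction=genomic_alt_fraction,
                            observed_fraction=alt_reads / total_reads,
                            p_value=float(p), biased=p < alpha)


def allele_bias_tests(cases: Sequence[tuple[int, int, float]],
                      alpha: float = 0.01) -> list[AlleleBiasResult]:
    """Run allele_bias_test per site with Benjamini-Hochberg correction
    across sites; ``biased`` flags BH-adjusted p < alpha."""
    results = [allele_bias_test(k, n, f, alpha=alpha) for k, n, f in cases]
    if len(results) > 1:
        adjusted = false_discovery_control([r.p_value for r in results],
                                           method="bh")
        for r, q in zip(results, adjusted):
            r.biased = bool(q < alpha)
    return results
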