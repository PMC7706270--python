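"""Tolerance-aware comparison of cleavage-site catalogues.

Cut positions from different platforms disagree by up to ~20 bp (nanopore
calls are fuzzy), so two sites are considered the same when they lie on
the same contig within a configurable tolerance (default 30 bp).
Matching is greedy by ascending distance and strictly one-to-one.  When
both catalogues carry guide labels, a match additionally requires label
agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io import SiteRecord

logger = logging.getLogger("otscan")


@dataclass
class SiteSet:
    label: str
    sites: list[SiteRecord] = field(default_factory=list)

    def deduplicate(self, tolerance: int = 0) -> "SiteSet":
        """Collapse sites on the same contig within ``tolerance`` of each
        other (keeps the first of each run, sites sorted by position)."""
        out: list[SiteRecord] = []
        for site in sorted(self.sites, key=lambda s: (s.contig, s.position)):
            if out and out[-1].contig == site.contig and \
                    site.position - out[-1].position <= tolerance:
                continue
            out.append(site)
        return SiteSet(label=self.label, sites=out)


@dataclass
class OverlapReport:
    pairs: list[tuple[SiteRecord, SiteRecord, int]]
    only_a: list[SiteRecord]
    only_b: list[SiteRecord]

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.pairs), len(self.only_a), len(self.only_b)


def _labels_informative(a: SiteSet, b: SiteSet) -> bool:
    return (any(s.label not in (".", "") for s in a.sites)
            and any(s.label not in (".", "") for s in b.sites))


def match_site_sets(a: SiteSet, b: SiteSet, tolerance: int = 30,
                    require_label_agreement: Optional[bool] = None
                    ) -> OverlapReport:
    """One-to-one greedy matching of two site catalogues.

    Candidate pairs are same-contig sites within ``tolerance`` bp; pairs
    are accepted in order of ascending distance (ties by (contig,
    position) of the A site, then of the B site).  By default guide-label
    agreement is required exactly when both sets carry labels.
    """
    if require_label_agreement is None:
        require_label_agreement = _labels_informative(a, b)
    contigs_a = {s.contig for s in a.sites}
    contigs_b = {s.contig for s in b.sites}
    if a.sites and b.sites and not (contigs_a & contigs_b):
        logger.warning(
            "site sets %s and %s share no contig names; "
            "mixed coordinate systems?", a.label, b.label)
    candidates = []
    for i, sa in enumerate(a.sites):
        for j, sb in enumerate(b.sites):
            if sa.contig != sb.contig:
                continue
            if require_label_agreement and sa.label != sb.label:
                continue
            d = abs(sa.position - sb.position)
            if d <= tolerance:
                candidates.append(
                    (d, sa.contig, sa.position, sb.position, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for d, _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((a.sites[i], b.sites[j], d))
    only_a = [s for i, s in enumerate(a.sites) if i not in used_a]
    only_b = [s for j, s in enumerate(b.sites) if j not in used_b]
    return OverlapReport(pairs=pairs, only_a=only_a, only_b=only_b)


def compare_to_predictions(ots: SiteSet, predicted: SiteSet,
                           tolerance: int = 30) -> dict:
    """Partition detected sites against an external predicted catalogue.

    Returns the three disjoint lists plus percentages with explicit
    numerators/denominators.
    """
    report = match_site_sets(ots, predicted, tolerance=tolerance,
                             require_label_agreement=False)
    n_both = len(report.pairs)
    result = {
        "predicted_and_detected": report.pairs,
        "detected_only": report.only_a,
        "predicted_only": report.only_b,
        "pct_predicted_detected": (100.0 * n_both / len(predicted.sites)
                                   if predicted.sites else 0.0),
        "pct_detected_predicted": (100.0 * n_both / len(ots.sites)
                                   if ots.sites else 0.0),
        "n_detected": len(ots.sites),
        "n_predicted": len(predicted.sites),
    }
    return result


def combined_height(matched: OverlapReport) -> list[tuple[SiteRecord, float]]:
    """Per-site combined read count: the sum of the two peak heights for a
    matched pair, the single height otherwise.  Sorted descending."""
    def height(site: SiteRecord) -> float:
        if site.score is None:
            logger.warning("site %s:%d has no peak height; treated as 0",
                           site.contig, site.position)
            return 0.0
        return site.score

    rows: list[tuple[SiteRecord, float]] = []
    for sa, sb, _ in matched.pairs:
        rows.append((sa, height(sa) + height(sb)))
    for s in matched.only_a + matched.only_b:
        rows.append((s, height(s)))
    rows.sort(key=lambda r: (-r[1], r[0].contig, r[0].position))
    return rows


def tabulate_mismatch_classes(sites) -> dict[str, int]:
    """Counts of assigned sites per mismatch class."""
    counts = {"exact": 0, "snv_1_3": 0, "snv_ge4": 0, "indel_mismatch": 0}
    for site in sites:
        if site.mismatch_class == "unassigned":
            continue
        if site.mismatch_class not in counts:
            raise ValueError(f"unclassified site: {site.mismatch_class!r}")
        counts[site.mismatch_class] += 1
    return counts
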