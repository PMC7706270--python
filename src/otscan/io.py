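"""Readers and writers for the formats the tool touches.

FASTA references, SAM/BAM alignments (reduced to :class:`AlignedRead`),
BED site lists, guide definitions and the tabular site report.  All
internal coordinates are 0-based, half-open (BED convention); SAM's
1-based positions are converted at parse time.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import pysam
from Bio import SeqIO

logger = logging.getLogger("otscan")

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class AlignedRead:
    """A minimal alignment record.

    ``cigar_indels`` holds ``(ref_position, kind, length)`` triples where an
    insertion is anchored to the reference base immediately left of the
    inserted sequence and a deletion to its leftmost deleted base.
    """

    read_id: str
    contig: str
    ref_start: int  # 0-based inclusive
    ref_end: int    # 0-based exclusive
    strand: str = "+"
    mapq: int = 60
    is_primary: bool = True
    cigar_indels: tuple = ()

    def __post_init__(self):
        if self.ref_start >= self.ref_end:
            raise ValueError(
                f"ref_start must be < ref_end ({self.ref_start} >= {self.ref_end})")
        for pos, kind, length in self.cigar_indels:
            if kind not in ("ins", "del"):
                raise ValueError(f"unknown indel kind {kind!r}")
            if length < 1:
                raise ValueError("indel length must be >= 1")


@dataclass
class SiteRecord:
    """A called cleavage site: a point position plus its merged interval."""

    contig: str
    position: int           # 0-based cut boundary coordinate
    start: int              # half-open interval
    end: int
    label: str = "."
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self):
        if not (self.start <= self.position < self.end):
            raise ValueError(
                f"site position {self.position} outside [{self.start},{self.end})")


class ReferenceGenome:
    """An in-memory reference: ordered contig name -> uppercase ACGTN string."""

    def __init__(self, contigs: dict[str, str]):
        for name, seq in contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} has empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"contig {name!r} contains {sorted(bad)}")
        self.contigs = dict(contigs)

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    def fetch(self, name: str, start: int, end: int) -> str:
        if name not in self.contigs:
            raise KeyError(f"unknown contig {name!r}")
        return self.contigs[name][start:end]


def _normalize_sequence(seq: str, name: str) -> str:
    seq = seq.upper().replace("U", "T")
    if set(seq) - VALID_BASES:
        n_bad = sum(1 for c in seq if c not in VALID_BASES)
        logger.warning(
            "contig %s: %d non-ACGTN characters mapped to N", name, n_bad)
        seq = "".join(c if c in VALID_BASES else "N" for c in seq)
    return seq


def load_reference(path: str | os.PathLike) -> ReferenceGenome:
    """Load a FASTA reference, uppercasing and mapping U->T, other->N."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r}")
        contigs[rec.id] = _normalize_sequence(str(rec.seq), rec.id)
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferenceGenome(contigs)


def write_reference(ref: ReferenceGenome, path: str | os.PathLike,
                    width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _indels_from_cigar(cigartuples, ref_start: int) -> tuple:
    """Extract (anchor, kind, length) indel events from pysam cigartuples."""
    events = []
    pos = ref_start
    for op, length in cigartuples:
        if op in (0, 7, 8):        # M, =, X
            pos += length
        elif op == 1:              # I: anchor = base left of insertion point
            events.append((pos - 1, "ins", length))
        elif op == 2:              # D: anchor = leftmost deleted base
            events.append((pos, "del", length))
            pos += length
        elif op == 3:              # N (ref skip)
            pos += length
        # 4 (S), 5 (H), 6 (P): no reference advance
    return tuple(events)


def load_alignments(path: str | os.PathLike, min_mapq: int = 10,
                    contig: Optional[str] = None) -> Iterator[AlignedRead]:
    """Stream primary alignments from a SAM/BAM file as :class:`AlignedRead`.

    Secondary and supplementary records and records below ``min_mapq`` are
    excluded.  Exact duplicates under ``(read_id, ref_start, ref_end)`` are
    dropped.  Output order follows file order (coordinate order for a sorted
    file) and is deterministic.
    """
    save = pysam.set_verbosity(0)
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    finally:
        pysam.set_verbosity(save)
    seen: set[tuple] = set()
    with af:
        if contig is not None and contig not in af.references:
            raise ValueError(f"unknown contig {contig!r} in {path}")
        if contig is not None and af.has_index():
            it = af.fetch(contig)
        else:
            it = af.fetch(until_eof=True)
        for rec in it:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if contig is not None and rec.reference_name != contig:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            key = (rec.query_name, rec.reference_start, rec.reference_end)
            if key in seen:
                continue
            seen.add(key)
            yield AlignedRead(
                read_id=rec.query_name,
                contig=rec.reference_name,
                ref_start=rec.reference_start,
                ref_end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality,
                is_primary=True,
                cigar_indels=_indels_from_cigar(rec.cigartuples or (),
                                                rec.reference_start),
            )


def write_sites_bed(sites: Sequence[SiteRecord], path: str | os.PathLike) -> None:
    """Write sites as BED6.  Score is integer-truncated and capped at 1000
    for BED validity; the full value is preserved in the tabular report."""
    prev = None
    for s in sites:
        key = (s.contig, s.start)
        if prev is not None and key < prev:
            raise ValueError("sites must be sorted by (contig, start)")
        prev = key
    with open(path, "w") as fh:
        for s in sites:
            score = 0 if s.score is None else min(int(s.score), 1000)
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.label}\t"
                     f"{score}\t{s.strand}\n")


def load_sites_bed(path: str | os.PathLike) -> list[SiteRecord]:
    """Read a BED3-6 file into SiteRecords (position = interval midpoint
    unless the interval has width 1)."""
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] not in (".", "") else None
            strand = parts[5] if len(parts) > 5 else "."
            pos = start if end - start == 1 else (start + end) // 2
            sites.append(SiteRecord(contig=contig, position=pos, start=start,
                                    end=end, label=label, score=score,
                                    strand=strand))
    return sites


def load_guides(path: str | os.PathLike):
    """Load guides from 2/3-column TSV (``name<TAB>SPACER[+PAM][<TAB>PAM]``)
    or FASTA.  A 23-nt second column is split into a 20-nt spacer + 3-nt PAM;
    any other length is taken as a bare spacer with the default NGG PAM.
    """
    from .assign import GuideRNA

    guides = []
    with open(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == ">":
            for rec in SeqIO.parse(fh, "fasta"):
                guides.append(_guide_from_seq(GuideRNA, rec.id, str(rec.seq)))
        else:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"malformed guide line: {line!r}")
                if len(parts) >= 3 and parts[2]:
                    guides.append(GuideRNA(name=parts[0],
                                           spacer=parts[1].upper().replace("U", "T"),
                                           pam=parts[2].upper()))
                else:
                    guides.append(_guide_from_seq(GuideRNA, parts[0], parts[1]))
    if not guides:
        raise ValueError(f"no guides found in {path}")
    names = [g.name for g in guides]
    if len(set(names)) != len(names):
        raise ValueError("duplicate guide names")
    return guides


def _guide_from_seq(GuideRNA, name: str, seq: str):
    seq = seq.upper().replace("U", "T")
    if len(seq) == 23:
        return GuideRNA(name=name, spacer=seq[:20], pam=seq[20:])
    return GuideRNA(name=name, spacer=seq)


REPORT_COLUMNS = [
    "contig", "cut_position", "guide", "score", "alignment",
    "n_subs", "n_ins", "n_del", "pam", "pam_status",
    "peak_height", "strand_balance",
]


def write_report(sites, path: str | os.PathLike,
                 keep_unassigned: bool = False) -> None:
    """Write the tab-separated site report (one row per OTSSite).

    The pairwise alignment is collapsed to a single field:
    ``query|markers|target`` where markers are ``|`` for a match, ``.`` for a
    substitution and a space at gap columns.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for site in sites:
            if site.best is None and not keep_unassigned:
                continue
            fh.write("\t".join(_report_row(site)) + "\n")


def _report_row(site) -> list[str]:
    peak = site.peak
    if site.best is None:
        return [peak.contig, str(peak.position), ".", "NA", ".",
                "NA", "NA", "NA", ".", ".",
                str(peak.peak_height), f"{peak.strand_balance:.3f}"]
    a = site.best
    markers = "".join(
        "|" if q == t else (" " if q == "-" or t == "-" else
                            ("|" if q == "N" else "."))
        for q, t in zip(a.aligned_query, a.aligned_target))
    pretty = f"{a.aligned_query}/{markers}/{a.aligned_target}"
    if a.pam_canonical:
        pam_status = "canonical"
    elif a.pam_rescue:
        pam_status = "rescued"
    else:
        pam_status = "noncanonical"
    return [peak.contig, str(a.predicted_cut), a.guide.name,
            f"{a.score:g}", pretty,
            str(a.n_subs), str(a.n_ins), str(a.n_del),
            a.pam_observed, pam_status,
            str(peak.peak_height), f"{peak.strand_balance:.3f}"]


def write_run_summary(path: str | os.PathLike, **fields) -> None:
    """Write a deterministic JSON run summary (parameters, counts, seed)."""
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True)
        fh.write("\n")
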