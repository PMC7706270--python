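"""Synthetic-data generator for the off-target sequencing workflow.

Emulates, at desk scale, what an amplification-free Cas9 enrichment run
produces: a reference with planted (mis)matched protospacers, randomly
sheared fragments, Cas9 cleavage of fragments overlapping a planted cut
(allele-aware when a heterozygous SNV modulates binding), capture
enrichment that retains cleaved molecules and leaks a small fraction of
background, per-read CIGAR-level sequencing errors, and edited/wild-type
amplicon reads with NHEJ-style cut-anchored indels.  Reads are emitted
as coordinate-true SAM records, so peak calling, guide assignment and
editing analysis are all testable against exact ground truth.

Fragment lengths are lognormal around the shearing target (8 kb
SMRT-like, 20 kb Nano-like presets) with uniform start positions; each
fragment is an independently sampled molecule, not a partition of the
genome (a partition would plant a coincident start/end pair at every
shear breakpoint, which single-molecule loading does not do).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pysam

from .assign import GuideRNA, IUPAC, WindowSeq, assign_guides
from .align import reverse_complement
from .io import AlignedRead, ReferenceGenome
from .peaks import CleavagePeak


@dataclass(frozen=True)
class AlleleSpec:
    """A heterozygous SNV inside a protospacer that modulates cleavage."""

    snv_offset: int             # bp relative to the cut boundary
    alt_fraction: float = 0.5   # genomic fraction of the alt allele
    efficiency_ref: float = 0.1
    efficiency_alt: float = 0.9


@dataclass(frozen=True)
class PlantSpec:
    """Request to plant one (mis)matched protospacer."""

    guide: str
    position: int               # intended blunt-cut boundary
    strand: str = "+"
    n_subs: int = 0
    n_ins: int = 0              # bases the genome lacks vs the guide
    n_del: int = 0              # extra bases in the genome vs the guide
    cleavage_efficiency: float = 1.0
    allele_spec: Optional[AlleleSpec] = None


@dataclass
class PlantedSite:
    """Ground truth for one planted site."""

    contig: str
    position: int
    guide: str
    strand: str
    n_subs: int
    n_ins: int
    n_del: int
    cleavage_efficiency: float
    locus_start: int
    locus_end: int
    planted_seq: str            # protospacer+PAM in guide orientation
    allele_spec: Optional[AlleleSpec] = None


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for read simulation.

    Defaults follow the SMRT-like assay: 8 kb shearing target, 30x
    coverage, a 5% capture leak for uncleaved background, and a 0.8
    retention bias toward the 3' side of the cut (adapter ligation is
    less efficient where the enzyme stays bound).  Error rates are
    CIGAR-level per-bp event rates.
    """

    genome_length: int = 300_000
    gc_fraction: float = 0.41
    n_background_targets: int = 0
    mean_fragment_length: float = 8000.0
    fragment_length_sigma: float = 0.35   # sd of log fragment length
    min_fragment_length: int = 200
    coverage: float = 30.0
    p_background_retained: float = 0.05
    side_bias: float = 0.8
    err_ins: float = 0.001
    err_del: float = 0.001
    contig: str = "sim1"

    def __post_init__(self):
        for name in ("gc_fraction", "p_background_retained", "side_bias",
                     "err_ins", "err_del"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


SMRT_PRESET = SimConfig()
NANO_PRESET = replace(SMRT_PRESET, mean_fragment_length=20000.0,
                      err_ins=0.01, err_del=0.02)


def _random_genome(rng: np.random.Generator, length: int,
                   gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=length, p=p))


def _mutate_protospacer(rng: np.random.Generator, guide: GuideRNA,
                        n_subs: int, n_ins: int, n_del: int) -> str:
    """Build the genomic protospacer carrying the requested mismatches.

    Substitutions change spacer bases; ``n_ins`` removes spacer bases from
    the genome copy (the genome must gain them to match the guide);
    ``n_del`` inserts extra bases (the genome must lose them).

    Mismatches go to spaced interior spacer positions (substitutions at
    odd offsets >= 3, removals at even offsets) so the declared counts
    are identifiable: a substitution at the spacer's 5' edge, or several
    clustered there, would be absorbed into a free terminal gap by the
    optimal alignment and the planted truth would be ill-defined.
    """
    spacer = list(guide.spacer)
    k = len(spacer)
    sub_candidates = list(range(3, k, 2))
    del_candidates = [p for p in range(4, k - 3) if p % 2 == 0]
    if n_subs > len(sub_candidates) or n_ins > len(del_candidates):
        raise ValueError("too many planted mismatches for the spacer length")
    sub_pos = (rng.choice(sub_candidates, size=n_subs, replace=False)
               if n_subs else [])
    for p in sub_pos:
        spacer[p] = str(rng.choice([b for b in "ACGT" if b != spacer[p]]))
    if n_ins:
        for p in sorted(rng.choice(del_candidates, size=n_ins,
                                   replace=False), reverse=True):
            del spacer[p]
    if n_del:
        for _ in range(n_del):
            p = int(rng.integers(2, len(spacer) - 1))
            spacer.insert(p, str(rng.choice(list("ACGT"))))
    pam = "".join(c if c in "ACGT" else str(rng.choice(list(IUPAC[c])))
                  for c in guide.pam)
    return "".join(spacer) + pam


def simulate_genome_with_targets(
    config: SimConfig, guides: Sequence[GuideRNA],
    planted: Sequence[PlantSpec], seed: int,
) -> tuple[ReferenceGenome, list[PlantedSite]]:
    """Random background genome with planted protospacers at exact loci.

    Planted loci must be non-overlapping and >= 500 bp from contig edges.
    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    genome = _random_genome(rng, config.genome_length, config.gc_fraction)
    by_name = {g.name: g for g in guides}
    sites: list[PlantedSite] = []
    occupied: list[tuple[int, int]] = []
    for spec in planted:
        guide = by_name[spec.guide]
        # redraw mutation positions until the planted counts are what the
        # optimal alignment against the real genomic context reports: some
        # draws are unidentifiable (e.g. a mismatch that an alternative
        # gap placement explains more cheaply near a repeat or G-run)
        for attempt in range(50):
            seq = _mutate_protospacer(rng, guide, spec.n_subs, spec.n_ins,
                                      spec.n_del)
            n = len(seq)            # mutated spacer + PAM
            if spec.strand == "+":
                start = spec.position + guide.cut_offset - (n - 3)
                end = start + n
                genomic = seq
            else:
                end = spec.position + (n - 3) - guide.cut_offset
                start = end - n
                genomic = reverse_complement(seq)
            if start < 500 or end > config.genome_length - 500:
                raise ValueError(f"planted site at {spec.position} too close "
                                 "to a contig edge (need >= 500 bp)")
            for a, b in occupied:
                if start < b and a < end:
                    raise ValueError("overlapping planted protospacers")
            ws = spec.position - 40
            window = genome[ws:spec.position + 41]
            window[start - ws:end - ws] = list(genomic)
            if _plant_identifiable("".join(window), ws, spec, guide,
                                   config.contig):
                break
        else:
            raise ValueError(
                f"could not plant an identifiable site for {spec.guide} "
                f"at {spec.position} with {spec.n_subs} subs, "
                f"{spec.n_ins} ins, {spec.n_del} del")
        occupied.append((start, end))
        genome[start:end] = list(genomic)
        sites.append(PlantedSite(
            contig=config.contig, position=spec.position, guide=spec.guide,
            strand=spec.strand, n_subs=spec.n_subs, n_ins=spec.n_ins,
            n_del=spec.n_del, cleavage_efficiency=spec.cleavage_efficiency,
            locus_start=start, locus_end=end, planted_seq=seq,
            allele_spec=spec.allele_spec))
    for _ in range(config.n_background_targets):
        # sequence decoys: shuffled spacer + PAM, never cleaved
        guide = by_name[list(by_name)[int(rng.integers(len(by_name)))]]
        decoy = "".join(rng.permutation(list(guide.spacer))) + "TGG"
        for _attempt in range(100):
            start = int(rng.integers(500, config.genome_length - 500 - len(decoy)))
            end = start + len(decoy)
            if all(not (start < b and a < end) for a, b in occupied):
                occupied.append((start, end))
                genome[start:end] = list(decoy)
                break
    ref = ReferenceGenome({config.contig: "".join(genome)})
    return ref, sites


def _plant_identifiable(window_seq: str, window_start: int, spec: PlantSpec,
                        guide: GuideRNA, contig: str) -> bool:
    """True iff re-aligning the guide against the planted window reports
    exactly the declared mismatch decomposition on the declared strand."""
    window = WindowSeq(contig=contig, start=window_start,
                       end=window_start + len(window_seq),
                       sequence=window_seq)
    dummy = CleavagePeak(contig=contig, position=spec.position,
                         start=spec.position, end=spec.position + 1,
                         peak_height=0, background_rate=0.0, p_value=1.0)
    site = assign_guides(dummy, window, [guide], threshold=float("-inf"))
    best = site.best
    return (best is not None and best.strand == spec.strand
            and best.n_subs == spec.n_subs and best.n_ins == spec.n_ins
            and best.n_del == spec.n_del)


def _error_indels(rng: np.random.Generator, start: int, end: int,
                  err_ins: float, err_del: float) -> list[tuple[int, str, int]]:
    """Sequencing-error indel events inside [start, end), CIGAR-level."""
    length = end - start
    events: list[tuple[int, str, int]] = []
    if length < 20:
        return events
    n_ins = rng.poisson(err_ins * length)
    n_del = rng.poisson(err_del * length)
    for _ in range(n_ins):
        pos = int(rng.integers(start, end - 2))
        events.append((pos, "ins", int(rng.geometric(0.5))))
    for _ in range(n_del):
        size = int(rng.geometric(0.5))
        pos = int(rng.integers(start + 1, max(start + 2, end - 1 - size)))
        if pos + size <= end - 1:
            events.append((pos, "del", size))
    return _sanitize_events(events)


def _sanitize_events(events):
    """Sort events and drop any anchored at or inside a previous event's
    reference span (overlapping indels cannot be expressed in one CIGAR)."""
    out: list[tuple[int, str, int]] = []
    prev_end = -1
    for pos, kind, size in sorted(events):
        if pos <= prev_end:
            continue
        out.append((pos, kind, size))
        prev_end = pos + size - 1 if kind == "del" else pos
    return out


def simulate_ots_reads(
    ref: ReferenceGenome, planted: Sequence[PlantedSite], config: SimConfig,
    seed: int,
) -> tuple[list[AlignedRead], list[dict]]:
    """Simulate one enrichment run: shear, cleave, capture, emit reads.

    Returns coordinate-true reads plus a per-read truth table
    (``read_id, origin, end_at_cut, allele``).  Cleaved pieces are always
    candidates for retention with the 3'-side bias; uncleaved fragments
    leak through capture with ``p_background_retained``.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    contig = config.contig
    length = ref.length(contig)
    n_frags = int(round(config.coverage * length / config.mean_fragment_length))
    mu = np.log(config.mean_fragment_length) - config.fragment_length_sigma ** 2 / 2
    cut_positions = sorted((s.position, s) for s in planted)
    reads: list[AlignedRead] = []
    truth: list[dict] = []
    for i in range(n_frags):
        flen = int(np.clip(rng.lognormal(mu, config.fragment_length_sigma),
                           config.min_fragment_length, length))
        start = int(rng.integers(0, length - flen + 1))
        end = start + flen
        cuts: list[tuple[int, PlantedSite, str]] = []
        for pos, site in cut_positions:
            if not (start + 1 <= pos <= end - 1):
                continue
            if site.allele_spec is not None:
                is_alt = rng.random() < site.allele_spec.alt_fraction
                eff = (site.allele_spec.efficiency_alt if is_alt
                       else site.allele_spec.efficiency_ref)
                allele = "alt" if is_alt else "ref"
            else:
                eff = site.cleavage_efficiency
                allele = "."
            if rng.random() < eff:
                cuts.append((pos, site, allele))
        if not cuts:
            if rng.random() < config.p_background_retained:
                _emit(rng, reads, truth, config, contig, start, end,
                      origin="background", end_at_cut="none", allele=".")
            continue
        boundaries = [start] + [c[0] for c in cuts] + [end]
        for k in range(len(boundaries) - 1):
            a, b = boundaries[k], boundaries[k + 1]
            left_cut = cuts[k - 1] if k > 0 else None
            right_cut = cuts[k] if k < len(cuts) else None
            if left_cut is not None and right_cut is not None:
                keep, tag = True, left_cut
            elif right_cut is not None:
                # piece 5' of the cut; bias depends on guide strand
                site = right_cut[1]
                p_keep = (1 - config.side_bias if site.strand == "+"
                          else config.side_bias)
                keep, tag = rng.random() < p_keep, right_cut
            else:
                site = left_cut[1]
                p_keep = (config.side_bias if site.strand == "+"
                          else 1 - config.side_bias)
                keep, tag = rng.random() < p_keep, left_cut
            if not keep:
                continue
            pos, site, allele = tag
            end_at = "start" if a == pos else ("end" if b == pos else "none")
            _emit(rng, reads, truth, config, contig, a, b,
                  origin=f"{site.guide}@{site.position}",
                  end_at_cut=end_at, allele=allele)
    return reads, truth


def _emit(rng, reads, truth, config, contig, start, end, origin,
          end_at_cut, allele):
    if end - start < 50:
        return
    indels = tuple(_error_indels(rng, start, end, config.err_ins,
                                 config.err_del))
    read_id = f"r{len(reads):07d}"
    reads.append(AlignedRead(
        read_id=read_id, contig=contig, ref_start=start, ref_end=end,
        strand="+" if rng.random() < 0.5 else "-", mapq=60,
        cigar_indels=indels))
    truth.append({"read_id": read_id, "origin": origin,
                  "end_at_cut": end_at_cut, "allele": allele,
                  "ref_start": start, "ref_end": end})


def simulate_amplicons(
    ref: ReferenceGenome, cut_position: int, edit_rate: float,
    n_reads: int, seed: int, contig: Optional[str] = None,
    indel_length_mean: float = 5.0,
    large_insert: Optional[tuple[int, float]] = None,
    amplicon_half: int = 2500, cut_jitter: int = 3,
    err_ins: float = 0.0003, err_del: float = 0.0007,
) -> tuple[list[AlignedRead], list[AlignedRead], list[dict]]:
    """Edited and wild-type amplicon reads over one cut site.

    Edited reads carry a cut-anchored NHEJ indel with probability
    ``edit_rate`` (geometric length, anchor jittered +-``cut_jitter`` bp)
    and, when ``large_insert=(length, rate)`` is given, a large
    vector-like insertion at the cut with probability ``rate``.
    Wild-type reads carry only sequencing-error indels (HiFi CCS-like
    defaults).  Returns ``(edited, wildtype, truth)``.
    """
    if not 0.0 <= edit_rate <= 1.0:
        raise ValueError("edit_rate outside [0, 1]")
    rng = np.random.default_rng(seed)
    if contig is None:
        contig = next(iter(ref.contigs))
    length = ref.length(contig)
    amp_start = max(0, cut_position - amplicon_half)
    amp_end = min(length, cut_position + amplicon_half)
    edited: list[AlignedRead] = []
    wildtype: list[AlignedRead] = []
    truth: list[dict] = []
    p_geom = min(1.0, 1.0 / indel_length_mean)
    for sample, out in (("edited", edited), ("wildtype", wildtype)):
        for i in range(n_reads):
            start = amp_start + int(rng.integers(0, 50))
            end = amp_end - int(rng.integers(0, 50))
            events = list(_error_indels(rng, start, end, err_ins, err_del))
            is_edited = False
            has_large = False
            if sample == "edited":
                # one repair outcome per molecule: a vector-like large
                # insertion pre-empts a small NHEJ indel at the same cut
                if large_insert is not None and rng.random() < large_insert[1]:
                    has_large = True
                    events.append((cut_position, "ins", int(large_insert[0])))
                elif rng.random() < edit_rate:
                    is_edited = True
                    anchor = cut_position + int(
                        rng.integers(-cut_jitter, cut_jitter + 1))
                    kind = "ins" if rng.random() < 0.5 else "del"
                    size = int(rng.geometric(p_geom))
                    if kind == "del":
                        size = min(size, end - anchor - 1)
                    if size >= 1:
                        events.append((anchor, kind, size))
            dedup = _sanitize_events(events)
            read_id = f"{sample[0]}{i:06d}"
            out.append(AlignedRead(
                read_id=read_id, contig=contig, ref_start=start, ref_end=end,
                strand="+" if rng.random() < 0.5 else "-", mapq=60,
                cigar_indels=tuple(dedup)))
            truth.append({"read_id": read_id, "sample": sample,
                          "edited": is_edited, "large_insert": has_large})
    return edited, wildtype, truth


def cigar_string(read: AlignedRead) -> str:
    """Reconstruct the CIGAR of a simulated read from its indel events."""
    parts = []
    cur = read.ref_start
    for pos, kind, size in sorted(read.cigar_indels):
        if kind == "ins":
            m = pos + 1 - cur
            if m > 0:
                parts.append(f"{m}M")
            parts.append(f"{size}I")
            cur = pos + 1
        else:
            m = pos - cur
            if m > 0:
                parts.append(f"{m}M")
            parts.append(f"{size}D")
            cur = pos + size
    tail = read.ref_end - cur
    if tail > 0:
        parts.append(f"{tail}M")
    return "".join(parts)


def write_sam(reads: Sequence[AlignedRead], ref: ReferenceGenome,
              path: str) -> None:
    """Write simulated reads as a coordinate-sorted SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)}
               for name, seq in ref.contigs.items()],
    }
    order = {name: i for i, name in enumerate(ref.contigs)}
    reads = sorted(reads, key=lambda r: (order[r.contig], r.ref_start,
                                         r.read_id))
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.read_id
            rec.reference_id = order[read.contig]
            rec.reference_start = read.ref_start
            rec.mapping_quality = read.mapq
            rec.flag = 16 if read.strand == "-" else 0
            rec.cigarstring = cigar_string(read)
            out.write(rec)


def write_truth(truth: Sequence[dict], path: str) -> None:
    """Write a truth table as TSV (deterministic column order)."""
    if not truth:
        with open(path, "w") as fh:
            fh.write("")
        return
    cols = list(truth[0].keys())
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in truth:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
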