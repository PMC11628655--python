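"""Merging of raw synteny blocks into resolution-limited syntenic fragments
(SFs), coverage accounting, and extraction of evolutionary breakpoint
regions (EBRs) between adjacent SFs.

An EBR is emitted wherever two reference-adjacent SFs are not adjacent in
the target genome: different target chromosome, orientation change, or a
target-order discontinuity larger than the merging resolution.  Breaks of
synteny wider than 300 kb are treated as assembly gaps and excluded from
downstream EBR statistics; breaks at reference chromosome ends are
undetectable by construction and never emitted.
"""

from __future__ import annotations

from dataclasses import replace
from itertools import groupby

from .model import (EBRInterval, GenomeAssembly, SynFragment, SyntenyBlock,
                    classify_width)


def _target_gap(left, right) -> int:
    """Signed target gap between two reference-consecutive pieces.

    Positive when the target order continues in the direction implied by the
    orientation; negative on overlap or order reversal.
    """
    if left.orientation > 0:
        return right.tgt_start - left.tgt_end
    return left.tgt_start - right.tgt_end


def _mergeable(left, right, resolution: int) -> bool:
    if left.tgt_chrom != right.tgt_chrom or left.orientation != right.orientation:
        return False
    ref_gap = right.ref_start - left.ref_end
    if ref_gap < 0 or ref_gap > resolution:
        return False
    tgap = _target_gap(left, right)
    return 0 <= tgap <= resolution


def merge_blocks(blocks, resolution: int, sf_prefix: str = "SF") -> list:
    """Merge collinear same-orientation blocks into SFs at a resolution.

    Consecutive reference blocks are merged when they share target
    chromosome and orientation, the target order is consistent (increasing
    for +, decreasing for -), and both the reference gap and the target gap
    are at most ``resolution``.  Merged fragments shorter than the
    resolution are discarded.  Input must be sorted by reference position.
    """
    blocks = list(blocks)
    for a, b in zip(blocks, blocks[1:]):
        if (a.ref_chrom, a.ref_start) > (b.ref_chrom, b.ref_start):
            raise ValueError("blocks must be sorted by (ref_chrom, ref_start)")
    sfs = []
    for _, chrom_blocks in groupby(blocks, key=lambda b: b.ref_chrom):
        run = []
        for blk in chrom_blocks:
            if run and _mergeable(run[-1], blk, resolution):
                run.append(blk)
            else:
                if run:
                    sfs.append(_close_run(run, resolution))
                run = [blk]
        if run:
            sfs.append(_close_run(run, resolution))
    sfs = [sf for sf in sfs if sf.ref_length >= resolution]
    return [replace(sf, sf_id=f"{sf_prefix}{i+1}") for i, sf in enumerate(sfs)]


def _close_run(run, resolution: int) -> SynFragment:
    first, last = run[0], run[-1]
    tgt_start = min(b.tgt_start for b in run)
    tgt_end = max(b.tgt_end for b in run)
    n_blocks = sum(getattr(b, "n_blocks", 1) for b in run)
    return SynFragment(sf_id="", ref_chrom=first.ref_chrom,
                       ref_start=first.ref_start, ref_end=last.ref_end,
                       tgt_genome=first.tgt_genome, tgt_chrom=first.tgt_chrom,
                       tgt_start=tgt_start, tgt_end=tgt_end,
                       orientation=first.orientation, resolution=resolution,
                       n_blocks=n_blocks)


def sfs_as_blocks(sfs) -> list:
    """View SFs as synteny blocks (for idempotent re-merging)."""
    return [SyntenyBlock(sf.ref_chrom, sf.ref_start, sf.ref_end, sf.tgt_genome,
                         sf.tgt_chrom, sf.tgt_start, sf.tgt_end, sf.orientation)
            for sf in sfs]


def compute_coverage(sfs, assembly: GenomeAssembly) -> float:
    """Fraction of the reference assembly covered by SFs, in [0, 1].

    SFs must be non-overlapping on the reference (they are by
    construction); overlap indicates an upstream bug and raises.
    """
    by_chrom: dict = {}
    for sf in sfs:
        by_chrom.setdefault(sf.ref_chrom, []).append((sf.ref_start, sf.ref_end))
    covered = 0
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping SFs on {chrom}: "
                                 f"[{s1},{e1}) and [{s2},{e2})")
        covered += sum(e - s for s, e in ivs)
    return covered / assembly.total_size


def classify_ebr_size(width: int) -> str:
    """Size class of a break of synteny: well_defined (<= 50 kb),
    not_defined (50-300 kb, inclusive upper bound) or gap_discarded."""
    return classify_width(width)


def call_ebrs(sfs, resolution: int | None = None,
              keep_gaps: bool = False) -> list:
    """Candidate EBRs between reference-adjacent SFs of one genome.

    An EBR is called where the target adjacency is broken; the interval is
    the raw inter-SF gap [left.ref_end, right.ref_start).  Breaks wider
    than 300 kb get size class ``gap_discarded`` and are dropped unless
    ``keep_gaps``.  No EBR is emitted across reference chromosome ends.
    """
    sfs = sorted(sfs, key=lambda s: (s.ref_chrom, s.ref_start))
    ebrs = []
    for _, group in groupby(sfs, key=lambda s: s.ref_chrom):
        group = list(group)
        for left, right in zip(group, group[1:]):
            res = resolution if resolution is not None else left.resolution
            if left.tgt_chrom != right.tgt_chrom:
                breakage = "chrom"
            elif left.orientation != right.orientation:
                breakage = "orientation"
            else:
                tgap = _target_gap(left, right)
                if 0 <= tgap <= res:
                    continue  # target-adjacent and collinear: no break
                breakage = "order"
            width = right.ref_start - left.ref_end
            ebrs.append(EBRInterval(left.ref_chrom, left.ref_end,
                                    right.ref_start, classify_width(width),
                                    left.sf_id, right.sf_id, breakage))
    if not keep_gaps:
        ebrs = [e for e in ebrs if e.size_class != "gap_discarded"]
    return ebrs


def span_accounting(sfs, ebrs_all, assembly: GenomeAssembly) -> dict:
    """Base partition of the genome: SF + EBR + discarded gaps + uncovered."""
    sf_bases = sum(sf.ref_length for sf in sfs)
    ebr_bases = sum(e.width for e in ebrs_all if e.size_class != "gap_discarded")
    gap_bases = sum(e.width for e in ebrs_all if e.size_class == "gap_discarded")
    return {"sf": sf_bases, "ebr": ebr_bases, "gap_discarded": gap_bases,
            "other": assembly.total_size - sf_bases - ebr_bases - gap_bases}
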