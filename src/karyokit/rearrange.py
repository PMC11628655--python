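"""Detection, typing and phylogenetic dating of chromosome rearrangements.

Two karyotypes expressed as signed fragments in the same reference frame are
compared after splitting to a common refinement of their fragment
boundaries.  Interchromosomal events come from the bipartite
content-sharing map (an ancestor chromosome whose content lands on k
descendant chromosomes implies k-1 fissions and vice versa for fusions);
intrachromosomal events come from a run decomposition: a maximal block of
segments whose ancestral order is intact but whose orientation is uniformly
flipped relative to an anchored flank is one inversion, and any residual
order disturbance becomes one complex event per maximal disturbed region
with a lower bound on the number of simple events it contains.

Orientation is treated as gauge freedom at the whole-chromosome level: a
reversed block with no same-chromosome flanking context (an entire
chromosome, an entire fission product, or a wholly flipped fusion operand)
is not an inversion, because a free chromosome has no intrinsic
orientation.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import pandas as pd

from .model import (GenomeAssembly, Karyotype, RearrangementEvent,
                    SignedFragment, label_from_types)

__all__ = [
    "BranchAssignment", "karyotype_from_sfs", "reference_self_karyotype",
    "compare_karyotypes", "assign_event_branches", "classify_ebr_lineage",
    "classify_ebr_type", "classify_sf_history", "rearrangement_rates",
]


@dataclass
class BranchAssignment:
    """Phylogenetic origin of an event or EBR."""

    subject: str
    branch: tuple                # (parent node, child node)
    confidence: str              # clean | reuse_flagged
    origin_label: str            # "<node>_specific" | "reference_specific"


def karyotype_from_sfs(sfs, genome_name: str) -> Karyotype:
    """Rebuild a genome's karyotype (reference-anchored signed fragments)
    from its syntenic fragments, ordered along target chromosomes."""
    by_chrom: dict = {}
    for sf in sfs:
        by_chrom.setdefault(sf.tgt_chrom, []).append(sf)
    chroms = {}
    for chrom in sorted(by_chrom):
        frags = sorted(by_chrom[chrom], key=lambda s: s.tgt_start)
        chroms[chrom] = [SignedFragment(sf.ref_chrom, sf.ref_start, sf.ref_end,
                                        sf.orientation) for sf in frags]
    return Karyotype(genome_name, chroms)


def reference_self_karyotype(assembly: GenomeAssembly) -> Karyotype:
    """The reference genome as its own karyotype: one + fragment per chromosome."""
    return Karyotype(assembly.name, {
        c: [SignedFragment(c, 0, n, 1)] for c, n in assembly.chromosomes})


def restrict_karyotype(k: Karyotype, intervals) -> Karyotype:
    """Keep only the parts of each fragment covered by reference intervals
    (used to co-restrict a full reference karyotype to SF-covered bases)."""
    keep: dict = {}
    for c, s, e in intervals:
        keep.setdefault(c, []).append((int(s), int(e)))
    for v in keep.values():
        v.sort()
    chroms = {}
    for chrom, frags in k.chromosomes.items():
        new = []
        for f in frags:
            pieces = []
            for s, e in keep.get(f.ref_chrom, ()):
                lo, hi = max(s, f.ref_start), min(e, f.ref_end)
                if lo < hi:
                    pieces.append((lo, hi))
            if f.sign < 0:
                pieces.reverse()
            new.extend(SignedFragment(f.ref_chrom, lo, hi, f.sign)
                       for lo, hi in pieces)
        if new:
            chroms[chrom] = new
    return Karyotype(k.name, chroms)


def coverage_intervals(k: Karyotype) -> list:
    """Merged reference intervals covered by a karyotype's fragments."""
    by_chrom: dict = {}
    for _, f in k.fragments():
        by_chrom.setdefault(f.ref_chrom, []).append((f.ref_start, f.ref_end))
    out = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cs, ce = ivs[0]
        for s, e in ivs[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                out.append((chrom, cs, ce))
                cs, ce = s, e
        out.append((chrom, cs, ce))
    return out


def _intersect(a: list, b: list) -> list:
    """Intersection of two (chrom, start, end) interval lists (each merged)."""
    by_chrom: dict = {}
    for c, s, e in b:
        by_chrom.setdefault(c, []).append((s, e))
    out = []
    for c, s, e in a:
        for s2, e2 in by_chrom.get(c, ()):
            lo, hi = max(s, s2), min(e, e2)
            if lo < hi:
                out.append((c, lo, hi))
    return out


def co_restrict(A: Karyotype, B: Karyotype):
    """Restrict both karyotypes to their common reference coverage (needed
    when alignment gaps leave each genome covering slightly different bases)."""
    common = _intersect(coverage_intervals(A), coverage_intervals(B))
    return restrict_karyotype(A, common), restrict_karyotype(B, common)


# ---------------------------------------------------------------------------
# Karyotype comparison
# ---------------------------------------------------------------------------

def _cutset(*karyotypes) -> dict:
    cuts: dict = {}
    for k in karyotypes:
        for _, f in k.fragments():
            cuts.setdefault(f.ref_chrom, set()).update((f.ref_start, f.ref_end))
    return {c: sorted(v) for c, v in cuts.items()}


def _refined(k: Karyotype, cuts: dict) -> dict:
    out = {}
    for chrom, frags in k.chromosomes.items():
        new = []
        for f in frags:
            cc = cuts[f.ref_chrom]
            i = bisect_right(cc, f.ref_start)
            j = bisect_left(cc, f.ref_end)
            bounds = [f.ref_start] + cc[i:j] + [f.ref_end]
            pieces = list(zip(bounds, bounds[1:]))
            if f.sign < 0:
                pieces.reverse()
            new.extend(SignedFragment(f.ref_chrom, a, b, f.sign)
                       for a, b in pieces)
        out[chrom] = new
    return out


def _edge(frag: SignedFragment, leading: bool):
    """Ref-frame coordinate of a fragment's leading/trailing edge in frame order."""
    if (frag.sign > 0) == leading:
        return (frag.ref_chrom, frag.ref_start)
    return (frag.ref_chrom, frag.ref_end)


@dataclass
class _Run:
    a_chrom: str
    lo: int
    hi: int
    rel: int
    b_first: SignedFragment
    b_last: SignedFragment
    segs: list


def _runs_of(b_frags, seg_index) -> list:
    runs = []
    for f in b_frags:
        key = (f.ref_chrom, f.ref_start, f.ref_end)
        a_chrom, a_idx, a_sign = seg_index[key]
        rel = a_sign * f.sign
        if runs:
            r = runs[-1]
            if (r.a_chrom == a_chrom and r.rel == rel
                    and a_idx == (r.hi + 1 if rel > 0 else r.lo - 1)):
                r.lo, r.hi = min(r.lo, a_idx), max(r.hi, a_idx)
                r.b_last = f
                r.segs.append(key)
                continue
        runs.append(_Run(a_chrom, a_idx, a_idx, rel, f, f, [key]))
    return runs


def compare_karyotypes(A: Karyotype, B: Karyotype,
                       restrict: bool = False) -> list:
    """Events turning karyotype A into karyotype B (same reference frame).

    Returns RearrangementEvents carrying induced reference-frame breakpoint
    coordinates and the reference intervals each event acted on (the split
    chromosome's content for fissions, the fused chromosome's content for
    fusions, the flipped block for inversions).  With ``restrict=True`` both
    karyotypes are first cut down to their common reference coverage, which
    real (gapped) synteny maps require; otherwise differing content raises.
    """
    if restrict:
        A, B = co_restrict(A, B)
    cuts = _cutset(A, B)
    a_chroms = _refined(A, cuts)
    b_chroms = _refined(B, cuts)
    seg_index, a_content = {}, {}
    for chrom, frags in a_chroms.items():
        for idx, f in enumerate(frags):
            seg_index[(f.ref_chrom, f.ref_start, f.ref_end)] = (chrom, idx, f.sign)
        a_content[chrom] = tuple((f.ref_chrom, f.ref_start, f.ref_end)
                                 for f in sorted(frags, key=lambda g:
                                                 (g.ref_chrom, g.ref_start)))
    b_keys = {(f.ref_chrom, f.ref_start, f.ref_end)
              for frags in b_chroms.values() for f in frags}
    if b_keys != set(seg_index):
        raise ValueError("karyotypes carry different total reference content")

    b_of_seg = {}
    b_content = {}
    for chrom, frags in b_chroms.items():
        for f in frags:
            b_of_seg[(f.ref_chrom, f.ref_start, f.ref_end)] = chrom
        b_content[chrom] = tuple((f.ref_chrom, f.ref_start, f.ref_end)
                                 for f in sorted(frags, key=lambda g:
                                                 (g.ref_chrom, g.ref_start)))

    events: list = []

    # fissions: A chromosome content spread over k > 1 B chromosomes
    for chrom, frags in a_chroms.items():
        targets = []
        for f in frags:
            t = b_of_seg[(f.ref_chrom, f.ref_start, f.ref_end)]
            if not targets or targets[-1][0] != t:
                targets.append((t, f))
        deg = len({t for t, _ in targets})
        junctions = []
        for (t1, f1), (t2, f2) in zip(targets, targets[1:]):
            junctions.append((_edge(f1, leading=False), _edge(f2, leading=True)))
        for i in range(deg - 1):
            bps = junctions[i] if i < len(junctions) else ()
            if i == deg - 2 and len(junctions) > deg - 1:
                bps = tuple(p for j in junctions[i:] for p in j)
            events.append(RearrangementEvent(
                "fission", chroms=(chrom,), breakpoints=tuple(bps),
                affected=a_content[chrom]))

    # fusions: B chromosome holds content of k > 1 A chromosomes
    for chrom, frags in b_chroms.items():
        sources = []
        for f in frags:
            a = seg_index[(f.ref_chrom, f.ref_start, f.ref_end)][0]
            if not sources or sources[-1][0] != a:
                sources.append((a, f))
        deg = len({a for a, _ in sources})
        junctions = []
        prev = frags[0]
        for f in frags[1:]:
            if (seg_index[(prev.ref_chrom, prev.ref_start, prev.ref_end)][0]
                    != seg_index[(f.ref_chrom, f.ref_start, f.ref_end)][0]):
                junctions.append((_edge(prev, leading=False), _edge(f, leading=True)))
            prev = f
        for i in range(deg - 1):
            bps = junctions[i] if i < len(junctions) else ()
            if i == deg - 2 and len(junctions) > deg - 1:
                bps = tuple(p for j in junctions[i:] for p in j)
            events.append(RearrangementEvent(
                "fusion", chroms=tuple(sorted({a for a, _ in sources})),
                breakpoints=tuple(bps), affected=b_content[chrom]))

    # intrachromosomal: run decomposition per B chromosome.  Runs are
    # grouped into maximal same-A-chromosome stretches; each stretch is
    # read in its own canonical orientation (majority order of the run
    # ranges), so a wholly flipped fusion operand does not masquerade as a
    # disturbance.  A stretch of a single run carries no same-chromosome
    # flanking context and is never an inversion (orientation gauge).
    for chrom, frags in b_chroms.items():
        if not frags:
            continue
        runs = _runs_of(frags, seg_index)
        start = 0
        for end in range(len(runs) + 1):
            if end < len(runs) and runs[end].a_chrom == runs[start].a_chrom:
                continue
            events.extend(_stretch_events(runs, start, end, chrom))
            start = end
    return events


def _stretch_events(runs, start, end, chrom) -> list:
    """Inversions and complex regions within runs[start:end] (one A chrom)."""
    sruns = runs[start:end]
    if len(sruns) < 2:
        return []
    asc = sum(1 for r, s in zip(sruns, sruns[1:]) if s.lo > r.hi)
    desc = sum(1 for r, s in zip(sruns, sruns[1:]) if s.hi < r.lo)
    o = 1 if asc >= desc else -1
    kinds = []
    for r, s in zip(sruns, sruns[1:]):
        contiguous = (s.lo == r.hi + 1) if o > 0 else (s.hi == r.lo - 1)
        kinds.append("good" if contiguous else "bad")
    left_kind = ["edge"] + kinds
    right_kind = kinds + ["edge"]
    events = []
    for i, r in enumerate(sruns):
        lk, rk = left_kind[i], right_kind[i]
        if r.rel == -o and "bad" not in (lk, rk) and "good" in (lk, rk):
            gi = start + i
            bps = []
            if lk == "good":
                bps.append(_edge(runs[gi - 1].b_last, leading=False))
            bps.append(_edge(r.b_first, leading=True))
            bps.append(_edge(r.b_last, leading=False))
            if rk == "good":
                bps.append(_edge(runs[gi + 1].b_first, leading=True))
            events.append(RearrangementEvent(
                "inversion", chroms=(chrom,), breakpoints=tuple(bps),
                affected=_merge_keys(r.segs)))
    # maximal disturbed regions: consecutive runs that each touch a bad
    # boundary form one complex event (good boundaries between two such
    # runs do not split the region)
    disturbed = [("bad" in (left_kind[i], right_kind[i]))
                 for i in range(len(sruns))]
    i = 0
    while i < len(sruns):
        if not disturbed[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(sruns) and disturbed[j + 1]:
            j += 1
        region = sruns[i:j + 1]
        n_bad = sum(1 for b in range(i, j) if kinds[b] == "bad")
        bps = []
        for b in range(i, j):
            if kinds[b] == "bad":
                bps.append(_edge(sruns[b].b_last, leading=False))
                bps.append(_edge(sruns[b + 1].b_first, leading=True))
        events.append(RearrangementEvent(
            "complex", chroms=(chrom,), breakpoints=tuple(bps),
            affected=_merge_keys([k for r in region for k in r.segs]),
            lower_bound=max(1, -(-n_bad // 2))))
        i = j + 1
    return events


def _merge_keys(keys) -> tuple:
    """Collapse segment keys into maximal reference intervals."""
    keys = sorted(keys)
    out = []
    for c, s, e in keys:
        if out and out[-1][0] == c and out[-1][2] == s:
            out[-1] = (c, out[-1][1], e)
        else:
            out.append((c, s, e))
    return tuple(out)


def event_counts(events) -> dict:
    out = {"inversion": 0, "fission": 0, "fusion": 0, "complex": 0}
    for e in events:
        out[e.event_type] += 1
    return out


# ---------------------------------------------------------------------------
# Branch assignment and EBR classification
# ---------------------------------------------------------------------------

def assign_event_branches(series, restrict: bool = True) -> list:
    """Compare consecutive karyotypes of a lineage series (oldest first) and
    attribute the events of each comparison to that branch."""
    series = list(series)
    if len(series) < 2:
        raise ValueError("a lineage series needs at least two karyotypes")
    events = []
    for (pn, pk), (cn, ck) in zip(series, series[1:]):
        for ev in compare_karyotypes(pk, ck, restrict=restrict):
            ev.branch = (pn, cn)
            events.append(ev)
    return events


def branch_counts(events) -> dict:
    out: dict = {}
    for ev in events:
        out.setdefault(ev.branch, {}).setdefault(ev.event_type, 0)
        out[ev.branch][ev.event_type] += 1
    return out


def _locate_base(k: Karyotype, ref_chrom: str, ref_pos: int):
    """(chrom, frame position, sign) of one reference base in a karyotype."""
    for chrom, frags in k.chromosomes.items():
        off = 0
        for f in frags:
            if (f.ref_chrom == ref_chrom
                    and f.ref_start <= ref_pos < f.ref_end):
                if f.sign > 0:
                    return chrom, off + (ref_pos - f.ref_start), f.sign
                return chrom, off + (f.ref_end - 1 - ref_pos), f.sign
            off += len(f)
    return None


def _adjacency_intact(k: Karyotype, ref_chrom: str, left_base: int,
                      right_base: int):
    """Is the reference stretch [left_base, right_base] contiguous (possibly
    wholly reversed) in this karyotype?  None when unresolvable."""
    la = _locate_base(k, ref_chrom, left_base)
    rb = _locate_base(k, ref_chrom, right_base)
    if la is None or rb is None:
        return None
    span = right_base - left_base
    return (la[0] == rb[0] and la[2] == rb[2]
            and rb[1] - la[1] == la[2] * span)


def classify_ebr_lineage(ebr, series, ebr_id: str = "") -> BranchAssignment:
    """Date an EBR by testing its flanking reference adjacency in each node.

    The adjacency flanked by the EBR exists in the reference and in every
    node younger than the rearrangement that created it; nodes older than
    the event lack it.  With a nested (prefix) broken pattern the origin is
    the branch below the youngest broken node; non-nested patterns indicate
    breakpoint reuse and are assigned to the most recent breaking branch
    with confidence ``reuse_flagged``.
    """
    series = list(series)
    names = [n for n, _ in series]
    status = []
    probes = (0, 1_000, 10_000, 100_000)
    for name, k in series[:-1]:
        ok = None
        for p in probes:
            left = ebr.start - 1 - p
            if left < 0:
                break
            ok = _adjacency_intact(k, ebr.ref_chrom, left, ebr.end + p)
            if ok is not None:
                break
        if ok is None:
            # a flanking base falls in this genome's own alignment gap at
            # every probe distance: the EBR cannot be dated on this lineage
            return BranchAssignment(ebr_id, (None, None), "unassignable",
                                    "unassignable")
        status.append((name, ok))
    broken = [n for n, ok in status if not ok]
    if not broken:
        return BranchAssignment(ebr_id, (None, None), "clean", "not_a_break")
    nested = broken == names[:len(broken)]
    youngest = broken[-1]
    child = names[names.index(youngest) + 1]
    label = ("reference_specific" if child == names[-1]
             else f"{youngest}_specific")
    return BranchAssignment(ebr_id, (youngest, child),
                            "clean" if nested else "reuse_flagged", label)


def classify_ebr_type(ebr, events, slack: int = 0) -> str:
    """inversion_ebr vs interchromosomal_ebr from the matched events.

    An event matches when one of its induced reference breakpoints falls
    inside the EBR interval (boundaries inclusive, so zero-width EBRs at a
    shared coordinate still match).  ``slack`` widens the matching window
    on both sides — needed when alignment gaps jitter the recorded
    breakpoint coordinates between genomes.  Fusion/fission matches win
    over inversion; an EBR with no matching event is ``unassigned``.
    """
    matched = set()
    for ev in events:
        for chrom, pos in ev.breakpoints:
            if (chrom == ebr.ref_chrom
                    and ebr.start - slack <= pos <= ebr.end + slack):
                matched.add(ev.event_type)
                break
    if not matched:
        return "unassigned"
    if matched & {"fusion", "fission"}:
        return "interchromosomal_ebr"
    return "inversion_ebr"


# ---------------------------------------------------------------------------
# SF history and rates
# ---------------------------------------------------------------------------

def classify_sf_history(sfs, events, assembly: GenomeAssembly):
    """Label each reference SF by the set of event types that changed its
    chromosome context or orientation along the lineage.

    Returns (per-SF DataFrame, fraction of the assembly per label).
    """
    by_chrom: dict = {}
    for i, sf in enumerate(sfs):
        by_chrom.setdefault(sf.ref_chrom, []).append(
            (sf.ref_start, sf.ref_end, i))
    for v in by_chrom.values():
        v.sort()
    types_per_sf = [set() for _ in sfs]
    for ev in events:
        for chrom, s, e in ev.affected:
            for ss, ee, i in by_chrom.get(chrom, ()):
                if ss < e and s < ee:
                    types_per_sf[i].add(ev.event_type)
    rows = []
    fractions = {}
    for sf, types in zip(sfs, types_per_sf):
        label = label_from_types(types)
        rows.append((sf.sf_id, sf.ref_chrom, sf.ref_start, sf.ref_end,
                     sf.ref_length, label))
        fractions[label] = fractions.get(label, 0) + sf.ref_length
    total = assembly.total_size
    fractions = {k: v / total for k, v in sorted(fractions.items())}
    df = pd.DataFrame(rows, columns=["sf_id", "ref_chrom", "ref_start",
                                     "ref_end", "length", "label"])
    return df, fractions


def rearrangement_rates(counts_by_branch: dict, durations: dict) -> pd.DataFrame:
    """Events/My per branch; interchromosomal = fissions + fusions.

    ``durations`` maps (parent, child) to My.  Rates are reported to two
    decimals, as count / duration.
    """
    rows = []
    for branch, counts in counts_by_branch.items():
        dur = durations[branch]
        if dur <= 0:
            raise ValueError(f"branch {branch} has non-positive duration")
        inv = counts.get("inversion", 0)
        interchrom = counts.get("fission", 0) + counts.get("fusion", 0)
        cx = counts.get("complex", 0)
        total = inv + interchrom + cx
        rows.append({
            "parent": branch[0], "child": branch[1], "duration_my": dur,
            "inversions": inv, "fissions": counts.get("fission", 0),
            "fusions": counts.get("fusion", 0), "complex": cx,
            "interchromosomal": interchrom, "total": total,
            "inversion_rate": round(inv / dur, 2),
            "interchromosomal_rate": round(interchrom / dur, 2),
            "total_rate": round(total / dur, 2),
        })
    return pd.DataFrame(rows)
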