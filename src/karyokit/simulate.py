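"""Karyotype-evolution simulator with a ground-truth event log.

The simulator evolves a root karyotype along a dated lineage by inversions,
fissions and fusions, then emits reference-anchored synteny blocks for every
node, the true breakpoint regions, and (optionally) annotations and
expression matrices with the statistical structure the downstream analysis
assumes.

Coordinates: the root ancestor is its own reference; every descendant
karyotype is a list of signed root fragments.  ``emit_synteny`` re-expresses
all genomes in the frame of a chosen extant reference leaf.

Identifiability regime (``no_reuse=True``): event breakpoints stay at least
``resolution`` away from every prior breakpoint and from chromosome ends,
inversion intervals are pairwise disjoint with all prior event regions, and
each chromosome takes part in at most one fission or fusion per branch.
Under this regime (and zero jitter) the event log is exactly recoverable
from the emitted synteny maps.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import (EventLog, ExpressionMatrix, FeatureSet, GenomeAssembly,
                    Karyotype, RearrangementEvent, SignedFragment,
                    SyntenyBlock, label_from_types)

#: Default lineage: five nested ancestors above the reference leaf, ages in
#: My before present.
DEFAULT_LINEAGE = (
    ("RAK", 50.0), ("PAK", 34.0), ("BOCE", 30.0),
    ("BOMO", 27.0), ("BOVIN", 24.0), ("reference", 0.0),
)


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Root ancestor and elementary rearrangement operators
# ---------------------------------------------------------------------------

def simulate_ancestor(n_chrom: int, total_size: int, seed=None,
                      name: str = "root", alpha: float = 5.0) -> Karyotype:
    """Draw a root karyotype: Dirichlet-partitioned chromosome lengths.

    A minimum chromosome length of 1% of the mean is enforced; each
    chromosome starts as a single forward fragment of itself.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if total_size < n_chrom:
        raise ValueError("total_size must be >= n_chrom")
    rng = _rng(seed)
    min_len = max(1, int(0.01 * total_size / n_chrom))
    if min_len * n_chrom > total_size:
        raise ValueError("minimum chromosome length infeasible for total_size")
    w = rng.dirichlet(np.full(n_chrom, alpha))
    lengths = np.maximum((w * total_size).astype(np.int64), min_len)
    # repair the rounding/clipping drift on the largest chromosome
    lengths[int(np.argmax(lengths))] += total_size - int(lengths.sum())
    if lengths.min() < 1:
        raise ValueError("minimum chromosome length infeasible for total_size")
    chroms = {}
    for i, L in enumerate(lengths, start=1):
        cid = f"chr{i}"
        chroms[cid] = [SignedFragment(cid, 0, int(L), 1)]
    return Karyotype(name, chroms)


def apply_inversion(k: Karyotype, chrom: str, start: int, end: int,
                    mark_history: bool = False) -> Karyotype:
    """Reverse fragment order and flip signs inside [start, end)."""
    L = k.chrom_length(chrom)
    if not (0 <= start < end <= L):
        raise ValueError(f"inversion [{start}, {end}) outside {chrom} (len {L})")
    out = k.copy()
    out.split_at(chrom, start)
    out.split_at(chrom, end)
    frags = out.chromosomes[chrom]
    i0, off0 = out.locate(chrom, start)
    assert off0 == 0
    if end == L:
        i1 = len(frags)
    else:
        i1, off1 = out.locate(chrom, end)
        assert off1 == 0
    frags[i0:i1] = [f.flipped(mark=mark_history) for f in reversed(frags[i0:i1])]
    out.coalesce()
    return out


def apply_fission(k: Karyotype, chrom: str, pos: int, names=None,
                  mark_history: bool = False) -> Karyotype:
    """Split one chromosome into two at frame position pos (strictly inside)."""
    L = k.chrom_length(chrom)
    if not (0 < pos < L):
        raise ValueError("fission position must be strictly inside the chromosome")
    out = k.copy()
    out.split_at(chrom, pos)
    frags = out.chromosomes[chrom]
    i, off = out.locate(chrom, pos)
    assert off == 0
    left, right = frags[:i], frags[i:]
    if mark_history:
        left = [f.with_history("fission") for f in left]
        right = [f.with_history("fission") for f in right]
    na, nb = names if names else (f"{chrom}.1", f"{chrom}.2")
    rebuilt = {}
    for cid, fl in out.chromosomes.items():
        if cid == chrom:
            rebuilt[na] = left
            rebuilt[nb] = right
        else:
            rebuilt[cid] = fl
    out.chromosomes = rebuilt
    out.coalesce()
    return out


def apply_fusion(k: Karyotype, chrom_a: str, chrom_b: str,
                 flip_a: bool = False, flip_b: bool = False, name=None,
                 mark_history: bool = False) -> Karyotype:
    """Concatenate two chromosomes (optionally reversing an operand)."""
    if chrom_a == chrom_b:
        raise ValueError("fusion operands must be distinct chromosomes")
    out = k.copy()
    fa = out.chromosomes.pop(chrom_a)
    fb = out.chromosomes.pop(chrom_b)
    if flip_a:
        fa = [replace(f, sign=-f.sign) for f in reversed(fa)]
    if flip_b:
        fb = [replace(f, sign=-f.sign) for f in reversed(fb)]
    fused = fa + fb
    if mark_history:
        fused = [f.with_history("fusion") for f in fused]
    name = name or f"{chrom_a}+{chrom_b}"
    rebuilt = {}
    placed = False
    for cid, fl in k.chromosomes.items():
        if cid == chrom_a:
            rebuilt[name] = fused
            placed = True
        elif cid == chrom_b:
            continue
        else:
            rebuilt[cid] = out.chromosomes[cid]
    assert placed
    out.chromosomes = rebuilt
    out.coalesce()
    return out


# ---------------------------------------------------------------------------
# Lineage simulation
# ---------------------------------------------------------------------------

def draw_event_counts(rates: dict, duration: float, rng) -> dict:
    """Poisson counts per event type for one branch: n ~ Poisson(rate x My)."""
    if duration <= 0:
        raise ValueError("branch duration must be positive")
    return {t: int(rng.poisson(r * duration)) for t, r in rates.items()}


class _Forbidden:
    """Root-frame exclusion regions for breakpoint-reuse avoidance."""

    def __init__(self):
        self.by_chrom: dict = {}

    def add(self, chrom, start, end):
        self.by_chrom.setdefault(chrom, []).append((int(start), int(end)))

    def clashes(self, chrom, start, end) -> bool:
        for s, e in self.by_chrom.get(chrom, ()):
            if start < e and s < end:
                return True
        return False


def _span_root_intervals(k: Karyotype, chrom: str, start: int, end: int) -> list:
    """Root intervals covered by frame span [start, end) of one chromosome."""
    out = []
    off = 0
    for f in k.chromosomes[chrom]:
        lo = max(start, off)
        hi = min(end, off + len(f))
        if lo < hi:
            a, b = lo - off, hi - off
            if f.sign > 0:
                out.append((f.ref_chrom, f.ref_start + a, f.ref_start + b))
            else:
                out.append((f.ref_chrom, f.ref_end - b, f.ref_end - a))
        off += len(f)
        if off >= end:
            break
    return out


def _chrom_content(k: Karyotype, chrom: str) -> tuple:
    return tuple((f.ref_chrom, f.ref_start, f.ref_end) for f in k.chromosomes[chrom])


def _weighted_chrom(rng, k: Karyotype, exclude=frozenset(), min_len=0):
    ids = [c for c in k.chromosomes
           if c not in exclude and k.chrom_length(c) >= min_len]
    if not ids:
        return None
    w = np.array([k.chrom_length(c) for c in ids], dtype=float)
    return ids[int(rng.choice(len(ids), p=w / w.sum()))]


def simulate_lineage(root: Karyotype, nodes=DEFAULT_LINEAGE, spec=None,
                     rates=None, seed=None, no_reuse: bool = True,
                     resolution: int = 300_000,
                     inv_len_median: float = 10_000_000.0,
                     inv_len_sigma: float = 1.0,
                     inv_len_min: int = 1_000_000,
                     max_attempts: int = 1000):
    """Evolve ``root`` along a chain of dated nodes; return karyotypes + log.

    ``nodes`` is [(name, age_My), ...] oldest first; the root karyotype is
    assigned to nodes[0].  Event numbers come either from ``spec``
    ({child_name: {type: count}}) or from ``rates`` ({type: events/My},
    drawn as Poisson(rate x branch duration)).  Inversion lengths are
    log-normal (median ``inv_len_median``, sigma of the log ``inv_len_sigma``)
    truncated to [inv_len_min, chromosome length].
    """
    if spec is None and rates is None:
        raise ValueError("provide per-branch counts (spec) or per-My rates")
    nodes = [(str(n), float(a)) for n, a in nodes]
    rng = _rng(seed)
    forbidden = _Forbidden()
    log = EventLog()
    karyotypes = {nodes[0][0]: root}
    current = root

    for (pname, page), (cname, cage) in zip(nodes, nodes[1:]):
        branch = (pname, cname)
        if spec is not None:
            counts = {t: int(n) for t, n in spec.get(cname, {}).items()}
        else:
            counts = draw_event_counts(rates, page - cage, rng)
        order = ([("inversion")] * counts.get("inversion", 0)
                 + [("fission")] * counts.get("fission", 0)
                 + [("fusion")] * counts.get("fusion", 0))
        rng.shuffle(order)
        blocked = set()  # chromosomes already in an interchromosomal event this branch
        for etype in order:
            placed = False
            for _ in range(max_attempts):
                if etype == "inversion":
                    chrom = _weighted_chrom(rng, current,
                                            min_len=inv_len_min + 2 * resolution)
                    if chrom is None:
                        break
                    clen = current.chrom_length(chrom)
                    L = int(np.exp(rng.normal(math.log(inv_len_median),
                                              inv_len_sigma)))
                    L = min(max(L, inv_len_min), clen - 2 * resolution)
                    if L < inv_len_min:
                        continue
                    start = int(rng.integers(resolution, clen - resolution - L + 1))
                    end = start + L
                    spans = _span_root_intervals(current, chrom, start, end)
                    if no_reuse and any(
                            forbidden.clashes(c, s - resolution, e + resolution)
                            for c, s, e in spans):
                        continue
                    bp = (current.ref_point(chrom, start),
                          current.ref_point(chrom, end))
                    current = apply_inversion(current, chrom, start, end,
                                              mark_history=True)
                    for c, s, e in spans:
                        forbidden.add(c, s, e)
                    log.events.append(RearrangementEvent(
                        "inversion", branch=branch, chroms=(chrom,),
                        breakpoints=bp, affected=tuple(spans)))
                    placed = True
                    break
                elif etype == "fission":
                    chrom = _weighted_chrom(rng, current, exclude=blocked,
                                            min_len=2 * resolution + 2)
                    if chrom is None:
                        break
                    clen = current.chrom_length(chrom)
                    pos = int(rng.integers(resolution, clen - resolution + 1))
                    rc, rp = current.ref_point(chrom, pos)
                    if no_reuse and forbidden.clashes(rc, rp - resolution,
                                                      rp + resolution):
                        continue
                    content = _chrom_content(current, chrom)
                    names = (f"{chrom}.1", f"{chrom}.2")
                    current = apply_fission(current, chrom, pos, names=names,
                                            mark_history=True)
                    forbidden.add(rc, rp, rp)
                    blocked.update({chrom, *names})
                    log.events.append(RearrangementEvent(
                        "fission", branch=branch, chroms=(chrom,),
                        breakpoints=((rc, rp),), affected=content))
                    placed = True
                    break
                else:  # fusion
                    avail = [c for c in current.chromosomes if c not in blocked]
                    if len(avail) < 2:
                        break
                    a, b = (avail[i] for i in rng.choice(len(avail), size=2,
                                                         replace=False))
                    flip_a = bool(rng.integers(2))
                    flip_b = bool(rng.integers(2))
                    # junction root points: the two chromosome ends being joined
                    ja = current.ref_point(a, 0 if flip_a else current.chrom_length(a))
                    jb = current.ref_point(b, current.chrom_length(b) if flip_b else 0)
                    content = _chrom_content(current, a) + _chrom_content(current, b)
                    name = f"{a}+{b}"
                    current = apply_fusion(current, a, b, flip_a=flip_a,
                                           flip_b=flip_b, name=name,
                                           mark_history=True)
                    for rc, rp in (ja, jb):
                        forbidden.add(rc, rp, rp)
                    blocked.update({a, b, name})
                    log.events.append(RearrangementEvent(
                        "fusion", branch=branch, chroms=(a, b),
                        breakpoints=(ja, jb), affected=content))
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place a {etype} on branch {pname}->{cname} after "
                    f"{max_attempts} attempts; use a larger genome or fewer events")
        karyotypes[cname] = current
    return karyotypes, log


# ---------------------------------------------------------------------------
# Synteny emission
# ---------------------------------------------------------------------------

@dataclass
class SyntenyEmission:
    """Blocks in the reference frame per genome, plus simulation truth."""

    assembly: GenomeAssembly
    blocks: dict            # genome name -> list[SyntenyBlock]
    truth_ebrs: dict        # genome name -> list[(ref_chrom, start, end)]


def _frame_entries(k: Karyotype) -> dict:
    """Per root chromosome, sorted (root_start, root_end, sign, chrom, frame_start)."""
    per_root: dict = {}
    for chrom, frags in k.chromosomes.items():
        off = 0
        for f in frags:
            per_root.setdefault(f.ref_chrom, []).append(
                (f.ref_start, f.ref_end, f.sign, chrom, off))
            off += len(f)
    for entries in per_root.values():
        entries.sort()
    return per_root


def _image(entries, starts, a: int, b: int):
    """Image of root sub-interval [a, b) under a frame map: (chrom, s, e, sign)."""
    i = bisect_right(starts, a) - 1
    rs, re, sign, chrom, off = entries[i]
    if not (rs <= a and b <= re):
        raise AssertionError("karyotypes do not tile the root genome consistently")
    if sign > 0:
        return chrom, off + (a - rs), off + (b - rs), sign
    return chrom, off + (re - b), off + (re - a), sign


def reference_assembly(k: Karyotype, name=None) -> GenomeAssembly:
    return GenomeAssembly(name or k.name,
                          tuple((c, k.chrom_length(c)) for c in k.chromosomes))


def emit_synteny(karyotypes: dict, reference: str, jitter_bp: int = 0,
                 split_rate: float = 0.0, resolution: int = 300_000,
                 seed=None) -> SyntenyEmission:
    """Express every genome as synteny blocks on the reference leaf.

    Each true breakpoint (a broken target adjacency on the reference) is
    widened into a gap of total width ~ Uniform[0, 2*jitter_bp] by trimming
    the flanking blocks.  ``split_rate`` (expected cuts per Mb) breaks long
    blocks into collinear sub-blocks separated by sub-resolution gaps, to
    exercise downstream merging.
    """
    if reference not in karyotypes:
        raise ValueError(f"reference leaf {reference!r} not among karyotypes")
    rng = _rng(seed)
    if jitter_bp < 0:
        raise ValueError("jitter must be >= 0")
    ref_k = karyotypes[reference]
    ref_map = _frame_entries(ref_k)
    ref_starts = {c: [e[0] for e in v] for c, v in ref_map.items()}
    assembly = reference_assembly(ref_k)

    blocks_out, truth_out = {}, {}
    for gname, gk in karyotypes.items():
        g_map = _frame_entries(gk)
        g_starts = {c: [e[0] for e in v] for c, v in g_map.items()}
        raw = []
        for root_chrom, entries in ref_map.items():
            cuts = {e[0] for e in entries} | {e[1] for e in entries}
            cuts |= {e[0] for e in g_map.get(root_chrom, ())}
            cuts |= {e[1] for e in g_map.get(root_chrom, ())}
            cuts = sorted(cuts)
            for a, b in zip(cuts, cuts[1:]):
                rchrom, rs, re_, rsign = _image(entries, ref_starts[root_chrom], a, b)
                tchrom, ts, te, tsign = _image(g_map[root_chrom],
                                               g_starts[root_chrom], a, b)
                raw.append(SyntenyBlock(rchrom, rs, re_, gname, tchrom, ts, te,
                                        rsign * tsign))
        raw.sort(key=lambda blk: (blk.ref_chrom, blk.ref_start))

        # locate true breakpoints: broken target adjacency on the reference
        breakpoints = []  # indices i such that raw[i], raw[i+1] are broken
        for i in range(len(raw) - 1):
            cur, nxt = raw[i], raw[i + 1]
            if cur.ref_chrom != nxt.ref_chrom:
                continue
            intact = (cur.tgt_chrom == nxt.tgt_chrom
                      and cur.orientation == nxt.orientation
                      and ((cur.orientation > 0 and nxt.tgt_start == cur.tgt_end)
                           or (cur.orientation < 0 and nxt.tgt_end == cur.tgt_start)))
            if not intact:
                breakpoints.append(i)

        trims = {}  # block index -> [left_trim, right_trim]
        truth = []
        for i in breakpoints:
            p = raw[i].ref_end
            w = int(rng.integers(0, 2 * jitter_bp + 1)) if jitter_bp else 0
            lt = min(w // 2, raw[i].ref_length - 1)
            rt = min(w - w // 2, raw[i + 1].ref_length - 1)
            trims.setdefault(i, [0, 0])[1] = lt
            trims.setdefault(i + 1, [0, 0])[0] = rt
            truth.append((raw[i].ref_chrom, p - lt, p + rt))
        final = []
        for i, blk in enumerate(raw):
            lt, rt = trims.get(i, (0, 0))[0], trims.get(i, (0, 0))[1]
            if lt or rt:
                blk = _trim_block(blk, lt, rt)
            final.extend(_split_block(blk, split_rate, resolution, rng)
                         if split_rate > 0 else [blk])
        blocks_out[gname] = final
        truth_out[gname] = truth
    return SyntenyEmission(assembly, blocks_out, truth_out)


def _trim_block(blk: SyntenyBlock, left: int, right: int) -> SyntenyBlock:
    rs, re_ = blk.ref_start + left, blk.ref_end - right
    if blk.orientation > 0:
        ts, te = blk.tgt_start + left, blk.tgt_end - right
    else:
        ts, te = blk.tgt_start + right, blk.tgt_end - left
    return SyntenyBlock(blk.ref_chrom, rs, re_, blk.tgt_genome, blk.tgt_chrom,
                        ts, te, blk.orientation)


def _split_block(blk: SyntenyBlock, rate: float, resolution: int, rng) -> list:
    n_cuts = int(rng.poisson(rate * blk.ref_length / 1e6))
    if n_cuts == 0 or blk.ref_length < 4:
        return [blk]
    cuts = sorted(int(c) for c in rng.integers(1, blk.ref_length, size=n_cuts))
    pieces, prev = [], 0
    for c in cuts:
        gap = int(rng.integers(0, max(2, resolution // 2)))
        if c <= prev or c + gap >= blk.ref_length:
            continue
        pieces.append((prev, c))
        prev = c + gap
    pieces.append((prev, blk.ref_length))
    out = []
    for u, v in pieces:
        if v <= u:
            continue
        if blk.orientation > 0:
            ts, te = blk.tgt_start + u, blk.tgt_start + v
        else:
            ts, te = blk.tgt_end - v, blk.tgt_end - u
        out.append(SyntenyBlock(blk.ref_chrom, blk.ref_start + u,
                                blk.ref_start + v, blk.tgt_genome,
                                blk.tgt_chrom, ts, te, blk.orientation))
    return out


def truth_sf_labels(karyotypes: dict, reference: str) -> pd.DataFrame:
    """Reference-frame truth history labels, one row per leaf fragment."""
    ref_k = karyotypes[reference]
    rows = []
    for chrom, frags in ref_k.chromosomes.items():
        off = 0
        for f in frags:
            rows.append((chrom, off, off + len(f), label_from_types(f.history)))
            off += len(f)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


# ---------------------------------------------------------------------------
# Annotation and expression generators
# ---------------------------------------------------------------------------

def _place_intervals(rng, assembly: GenomeAssembly, n: int, mean_len: int,
                     len_sigma: float, fold: float, bias, non_overlap: bool,
                     max_attempts: int = 1000):
    """Place intervals with density multiplied by ``fold`` inside ``bias``."""
    from ._intervals import LinearGenome, MergedSet

    if fold < 0:
        raise ValueError("fold must be >= 0")
    lin = LinearGenome(assembly)
    bias_set = MergedSet(lin.linearize(bias)) if bias else None
    occupied: dict = {}
    accept_base = 1.0 / max(fold, 1.0)
    out = []
    for _ in range(n):
        ok = False
        for _try in range(max_attempts):
            length = max(1, int(np.exp(rng.normal(math.log(mean_len), len_sigma))))
            ci = int(rng.choice(len(lin.lengths), p=lin.lengths / lin.lengths.sum()))
            clen = int(lin.lengths[ci])
            if length >= clen:
                continue
            start = int(rng.integers(0, clen - length + 1))
            ls = int(lin.offsets[ci]) + start
            if bias_set is not None and len(bias_set):
                inside = bool(bias_set.any_overlap(np.array([ls]),
                                                   np.array([ls + length]))[0])
                p_accept = accept_base * fold if inside else accept_base
                if rng.random() >= p_accept:
                    continue
            chrom = lin.chrom_ids[ci]
            if non_overlap:
                clash = any(start < e and s < start + length
                            for s, e in occupied.get(chrom, ()))
                if clash:
                    continue
                occupied.setdefault(chrom, []).append((start, start + length))
            out.append((chrom, start, start + length))
            ok = True
            break
        if not ok:
            raise RuntimeError("could not place features without overlap; "
                               "reduce n or lengths")
    return out


def simulate_annotations(assembly: GenomeAssembly, n_genes: int = 0,
                         te_spec=None, gc_spec=None, bias_intervals=None,
                         gene_fold: float = 1.0, seed=None) -> dict:
    """Generate gene/TE feature sets and a per-window GC table.

    Genes: non-overlapping, log-normal lengths (median 30 kb).  TE families
    (``te_spec = {family: {"n": ..., "mean_len": ..., "fold": ...}}``) are
    placed with sampling density multiplied by their fold inside
    ``bias_intervals`` (fold 0 = exclusion, 1 = uniform).  GC per 10-kb
    window ~ Normal(0.42, 0.05) truncated to [0, 1], plus ``gc_spec["delta"]``
    inside the bias intervals.
    """
    rng = _rng(seed)
    bias = list(bias_intervals) if bias_intervals else []
    out = {}
    gene_rows = _place_intervals(rng, assembly, n_genes, mean_len=30_000,
                                 len_sigma=0.5, fold=gene_fold, bias=bias,
                                 non_overlap=True) if n_genes else []
    out["gene"] = FeatureSet("gene", [(c, s, e, f"gene{i+1}", "")
                                      for i, (c, s, e) in enumerate(gene_rows)])
    te_rows = []
    for family, fspec in (te_spec or {}).items():
        rows = _place_intervals(rng, assembly, int(fspec.get("n", 0)),
                                mean_len=int(fspec.get("mean_len", 3000)),
                                len_sigma=0.3, fold=float(fspec.get("fold", 1.0)),
                                bias=bias, non_overlap=False)
        te_rows.extend((c, s, e, f"{family}_{i+1}", family)
                       for i, (c, s, e) in enumerate(rows))
    out["TE"] = FeatureSet("TE", te_rows)

    gc_spec = dict(gc_spec or {})
    window = int(gc_spec.get("window", 10_000))
    mean, sd = float(gc_spec.get("mean", 0.42)), float(gc_spec.get("sd", 0.05))
    delta = float(gc_spec.get("delta", 0.0))
    from ._intervals import LinearGenome, MergedSet
    lin = LinearGenome(assembly)
    bias_set = MergedSet(lin.linearize(bias)) if bias else None
    rows = []
    for chrom, clen in assembly.chromosomes:
        for ws in range(0, clen - window + 1, window):
            gc = float(np.clip(rng.normal(mean, sd), 0.0, 1.0))
            if delta and bias_set is not None and len(bias_set):
                a, b = lin.to_linear(chrom, ws, ws + window)
                if bias_set.any_overlap(np.array([a]), np.array([b]))[0]:
                    gc = float(np.clip(gc + delta, 0.0, 1.0))
            rows.append((chrom, ws, ws + window, gc))
    out["gc_windows"] = pd.DataFrame(rows, columns=["chrom", "start", "end", "gc"])
    return out


def simulate_expression(n_genes: int, n_tissues: int = 9,
                        hk_fraction: float = 0.5,
                        species=("cattle", "sheep", "pig", "human"),
                        focal: str = "cattle",
                        species_specific_fraction: float = 0.0, seed=None):
    """Expression matrices with housekeeping structure, plus truth labels.

    Housekeeping genes: TPM ~ LogNormal(log 50, 0.2) in every tissue (low
    Gini).  Tissue-specific genes: LogNormal(log 100, 0.3) in one random
    tissue and LogNormal(log 1, 0.5) elsewhere (high Gini).  Ortholog ids
    map 1:1 across species; a configurable fraction of groups is
    housekeeping in the focal species only.

    Returns (matrices: {species: ExpressionMatrix}, truth: DataFrame,
    orthologs: DataFrame).
    """
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    if not (0.0 <= hk_fraction <= 1.0):
        raise ValueError("hk_fraction must be in [0, 1]")
    if hk_fraction + species_specific_fraction > 1.0:
        raise ValueError("hk_fraction + species_specific_fraction must be <= 1")
    rng = _rng(seed)
    species = list(species)
    if focal not in species:
        raise ValueError("focal species must be among species")
    tissues = [f"tissue{i+1}" for i in range(n_tissues)]
    u = rng.random(n_genes)
    category = np.where(u < hk_fraction, "all_hk",
                        np.where(u < hk_fraction + species_specific_fraction,
                                 "focal_hk", "non_hk"))
    matrices = {}
    for sp in species:
        vals = np.empty((n_genes, n_tissues))
        for gi in range(n_genes):
            is_hk = category[gi] == "all_hk" or (
                category[gi] == "focal_hk" and sp == focal)
            if is_hk:
                vals[gi] = np.exp(rng.normal(math.log(50.0), 0.2, size=n_tissues))
            else:
                row = np.exp(rng.normal(0.0, 0.5, size=n_tissues))
                row[int(rng.integers(n_tissues))] = float(
                    np.exp(rng.normal(math.log(100.0), 0.3)))
                vals[gi] = row
        df = pd.DataFrame(vals, index=[f"{sp}_g{i+1}" for i in range(n_genes)],
                          columns=tissues)
        matrices[sp] = ExpressionMatrix(sp, df)
    truth = pd.DataFrame({
        "group_id": [f"og{i+1}" for i in range(n_genes)],
        "category": category,
    })
    ortho = pd.DataFrame({"group_id": truth["group_id"]})
    for sp in species:
        ortho[sp] = [f"{sp}_g{i+1}" for i in range(n_genes)]
    return matrices, truth, ortho
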