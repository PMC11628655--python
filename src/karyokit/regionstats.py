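"""Permutation-based association between region sets and genomic features.

The null model re-places every region uniformly at random on the genome
(chromosome chosen with probability proportional to its length), preserving
each region's length and forbidding overlap among placed regions.  The
empirical p-value uses the add-one rule p = (b + 1) / (n_perm + 1), where b
counts permutations as or more extreme in the direction of the alternative,
so p is never zero.  No multiple-testing correction is applied across
families or chromosomes; raw p-values are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from ._intervals import LinearGenome, MergedSet
from .model import GenomeAssembly, PermutationResult

STATISTICS = ("region_overlap_count", "base_overlap")


def ebrs_as_intervals(ebrs, min_width: int = 1) -> list:
    """EBRs as (chrom, start, end) triples; zero-width EBRs (abutting SFs)
    are widened to ``min_width`` bp around their midpoint so they can carry
    overlap signal."""
    out = []
    for e in ebrs:
        if e.width >= min_width:
            out.append((e.ref_chrom, e.start, e.end))
        else:
            out.append((e.ref_chrom, e.start, e.start + min_width))
    return out


def _as_intervals(obj) -> list:
    if hasattr(obj, "intervals"):
        return obj.intervals()
    return [(c, int(s), int(e)) for c, s, e in obj]


def _random_starts(rng, lin: LinearGenome, lengths: np.ndarray,
                   n_perm: int, max_tries: int = 200) -> np.ndarray:
    """Linear start coordinates, (n_perm, k): uniform placement proportional
    to chromosome length, each region inside one chromosome, regions of one
    permutation mutually non-overlapping."""
    k = len(lengths)
    clens = lin.lengths
    if lengths.max() > clens.max():
        raise ValueError("a region is longer than the longest chromosome")
    w = clens / clens.sum()
    out = np.empty((n_perm, k), dtype=np.int64)
    for p in range(n_perm):
        for _ in range(max_tries):
            ci = rng.choice(len(clens), size=k, p=w)
            bad = clens[ci] < lengths
            tries = 0
            while bad.any():
                ci[bad] = rng.choice(len(clens), size=int(bad.sum()), p=w)
                bad = clens[ci] < lengths
                tries += 1
                if tries > max_tries:
                    raise ValueError("cannot fit all regions on the genome")
            starts = (rng.random(k) * (clens[ci] - lengths + 1)).astype(np.int64)
            ls = lin.offsets[ci] + starts
            le = ls + lengths
            order = np.argsort(ls, kind="stable")
            if not (ls[order][1:] < le[order][:-1]).any():
                out[p] = ls
                break
        else:
            # crowded genome: place one region at a time, resampling only
            # the colliding region
            placed: list = []
            for j in np.argsort(-lengths, kind="stable"):
                L = int(lengths[j])
                for _ in range(1000):
                    cj = int(rng.choice(len(clens), p=w))
                    if clens[cj] < L:
                        continue
                    s = int(lin.offsets[cj]
                            + rng.integers(0, clens[cj] - L + 1))
                    if not any(s < pe and ps < s + L for ps, pe in placed):
                        placed.append((s, s + L))
                        out[p, j] = s
                        break
                else:
                    raise ValueError("could not place non-overlapping "
                                     "regions; genome too crowded")
    return out


def _statistic(starts: np.ndarray, lengths: np.ndarray,
               feats: MergedSet, statistic: str) -> np.ndarray:
    """Statistic per permutation for a (n_perm, k) start matrix."""
    n_perm, k = starts.shape
    flat_s = starts.ravel()
    flat_e = flat_s + np.tile(lengths, n_perm)
    if statistic == "region_overlap_count":
        vals = feats.any_overlap(flat_s, flat_e).reshape(n_perm, k)
        return vals.sum(axis=1).astype(float)
    vals = feats.base_overlap(flat_s, flat_e).reshape(n_perm, k)
    return vals.sum(axis=1).astype(float)


def permutation_overlap_test(regions, features, assembly: GenomeAssembly,
                             n_perm: int = 1000, seed=None,
                             statistic: str = "region_overlap_count",
                             alternative: str = "auto") -> PermutationResult:
    """Randomization test of region/feature overlap.

    ``alternative="auto"`` tests in the direction of the observed deviation
    from the permutation mean (greater when observed > mean).  A degenerate
    permutation distribution (sd = 0) is flagged with p = 1 and undefined z.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    lin = LinearGenome(assembly)
    reg = lin.linearize(_as_intervals(regions))
    if len(reg) == 0:
        raise ValueError("empty region set")
    feats = MergedSet(lin.linearize(_as_intervals(features)))
    lengths = reg[:, 1] - reg[:, 0]
    obs = float(_statistic(reg[:, 0][None, :], lengths, feats, statistic)[0])
    starts = _random_starts(rng, lin, lengths, n_perm)
    perm = _statistic(starts, lengths, feats, statistic)
    mean, sd = float(perm.mean()), float(perm.std(ddof=1))
    if sd == 0.0:
        return PermutationResult(statistic, obs, n_perm, mean, sd,
                                 float("nan"), 1.0,
                                 "greater" if alternative == "auto" else alternative,
                                 degenerate=True)
    if alternative == "auto":
        alternative = "greater" if obs >= mean else "less"
    if alternative == "greater":
        b = int((perm >= obs).sum())
    elif alternative == "less":
        b = int((perm <= obs).sum())
    else:
        raise ValueError("alternative must be auto, greater or less")
    z = (obs - mean) / sd
    p = (b + 1) / (n_perm + 1)
    return PermutationResult(statistic, obs, n_perm, mean, sd, z, p, alternative)


def per_chromosome_density_test(ebrs, assembly: GenomeAssembly,
                                n_perm: int = 1000, seed=None):
    """EBR density per chromosome (EBRs/Mbp) against a uniform-scatter null.

    Permutations scatter the EBR midpoints across chromosomes with
    probability proportional to chromosome length; z and a direction-aware
    empirical p are reported per chromosome.  Returns (DataFrame,
    genome-mean density).
    """
    ebrs = list(ebrs)
    if not ebrs:
        raise ValueError("empty EBR set")
    rng = np.random.default_rng(seed)
    chrom_ids = [c for c, _ in assembly.chromosomes]
    clens = np.array([n for _, n in assembly.chromosomes], dtype=float)
    n = len(ebrs)
    counts = np.zeros(len(chrom_ids), dtype=int)
    index = {c: i for i, c in enumerate(chrom_ids)}
    for e in ebrs:
        counts[index[e.ref_chrom]] += 1
    mb = clens / 1e6
    obs_density = counts / mb
    genome_mean = round(n / (clens.sum() / 1e6), 3)
    perm_counts = rng.multinomial(n, clens / clens.sum(), size=n_perm)
    perm_density = perm_counts / mb[None, :]
    mean = perm_density.mean(axis=0)
    sd = perm_density.std(axis=0, ddof=1)
    rows = []
    for i, chrom in enumerate(chrom_ids):
        if sd[i] == 0:
            z, p = float("nan"), 1.0
        else:
            z = (obs_density[i] - mean[i]) / sd[i]
            if obs_density[i] >= mean[i]:
                b = int((perm_density[:, i] >= obs_density[i]).sum())
            else:
                b = int((perm_density[:, i] <= obs_density[i]).sum())
            p = (b + 1) / (n_perm + 1)
        rows.append({"chrom": chrom, "n_ebrs": int(counts[i]),
                     "length_mbp": round(mb[i], 3),
                     "density": round(obs_density[i], 3),
                     "z_score": z, "p_value": p})
    return pd.DataFrame(rows), genome_mean


# ---------------------------------------------------------------------------
# GC windows
# ---------------------------------------------------------------------------

def gc_windows(source, window: int = 10_000, high_gc_threshold: float = 0.60,
               threshold_mode: str = "fixed") -> pd.DataFrame:
    """Per-window GC fraction with a high-GC flag.

    ``source`` is a FASTA path or a precomputed DataFrame with columns
    chrom/start/end/gc.  Windows tile each chromosome; the trailing partial
    window is dropped.  N bases count in the denominator; windows with more
    than 50% N are flagged missing and excluded from the high-GC set.
    ``threshold_mode="ci"`` derives the cutoff as mean + 2 x the half-width
    of the 95% CI of the window mean instead of the fixed threshold.
    """
    if window < 1000:
        raise ValueError("window must be >= 1 kb")
    if not (0.0 < high_gc_threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        if "missing" not in df.columns:
            df["missing"] = False
    else:
        from Bio import SeqIO
        rows = []
        for rec in SeqIO.parse(str(source), "fasta"):
            seq = str(rec.seq).upper()
            for ws in range(0, len(seq) - window + 1, window):
                chunk = seq[ws:ws + window]
                gc = (chunk.count("G") + chunk.count("C")) / window
                n_frac = chunk.count("N") / window
                rows.append((rec.id, ws, ws + window, gc, n_frac > 0.5))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gc",
                                         "missing"])
    if threshold_mode == "ci":
        usable = df.loc[~df["missing"], "gc"]
        half = 1.96 * usable.std(ddof=1) / np.sqrt(len(usable))
        thr = float(usable.mean() + 2 * half)
    elif threshold_mode == "fixed":
        thr = high_gc_threshold
    else:
        raise ValueError("threshold_mode must be 'fixed' or 'ci'")
    df["high_gc"] = (~df["missing"]) & (df["gc"] >= thr)
    df.attrs["threshold"] = thr
    return df


# ---------------------------------------------------------------------------
# Composite profiles around anchor midpoints
# ---------------------------------------------------------------------------

@dataclass
class CompositeProfile:
    """Mean feature density in fixed windows around anchor midpoints."""

    offsets: np.ndarray          # window offsets, -flank..+flank
    mean_density: np.ndarray     # feature bases per window, mean over anchors
    ci_half_width: np.ndarray    # 95% t-interval half-width
    n_anchors: np.ndarray        # anchors contributing at each offset
    genome_mean: float           # expected bases per window genome-wide

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset": self.offsets, "mean_density": self.mean_density,
            "ci_low": self.mean_density - self.ci_half_width,
            "ci_high": self.mean_density + self.ci_half_width,
            "n_anchors": self.n_anchors,
            "genome_mean": self.genome_mean,
        })


def composite_profile(anchors, features, assembly: GenomeAssembly,
                      flank_windows: int = 30,
                      window: int = 10_000) -> CompositeProfile:
    """Feature density in ``2*flank_windows + 1`` windows centred on each
    anchor midpoint (offset 0 centred on the midpoint itself).

    Anchors whose flank extends past a chromosome end contribute only their
    fully in-bounds windows.
    """
    anchors = list(anchors)
    if not anchors:
        raise ValueError("no anchors")
    lin = LinearGenome(assembly)
    feats = MergedSet(lin.linearize(_as_intervals(features)))
    lengths = assembly.lengths
    n_off = 2 * flank_windows + 1
    sums = np.zeros(n_off)
    sumsq = np.zeros(n_off)
    counts = np.zeros(n_off, dtype=int)
    offsets = np.arange(-flank_windows, flank_windows + 1)
    for chrom, mid in anchors:
        clen = lengths[chrom]
        w_start = mid + offsets * window - window // 2
        w_end = w_start + window
        ok = (w_start >= 0) & (w_end <= clen)
        if not ok.any():
            continue
        ls = np.array([lin.to_linear(chrom, int(s)) for s in w_start[ok]])
        dens = feats.base_overlap(ls, ls + window).astype(float)
        sums[ok] += dens
        sumsq[ok] += dens ** 2
        counts[ok] += 1
    if counts.max() == 0:
        raise ValueError("no anchor window fits inside the assembly")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(counts > 1,
                       (sumsq - counts * mean ** 2) / np.maximum(counts - 1, 1),
                       np.nan)
        sem = np.sqrt(np.maximum(var, 0.0) / np.maximum(counts, 1))
        tcrit = sstats.t.ppf(0.975, np.maximum(counts - 1, 1))
        half = np.where(counts > 1, tcrit * sem, np.nan)
    genome_mean = feats.total_bases / assembly.total_size * window
    return CompositeProfile(offsets, mean, half, counts, genome_mean)


def anchor_midpoints(ebrs) -> list:
    return [(e.ref_chrom, e.midpoint) for e in ebrs]


# ---------------------------------------------------------------------------
# TE-family association
# ---------------------------------------------------------------------------

def te_family_association(ebrs, te_features, assembly: GenomeAssembly,
                          n_perm: int = 1000, seed=None) -> pd.DataFrame:
    """Per-family base-overlap permutation test between EBRs and TEs.

    Fold enrichment = observed / permutation mean (reported only when the
    permutation mean is positive).  Raw p-values, no multiple-testing
    correction.
    """
    regions = ebrs_as_intervals(ebrs) if ebrs and hasattr(
        next(iter(ebrs)), "size_class") else _as_intervals(ebrs)
    if not regions:
        raise ValueError("empty EBR set")
    families = te_features.by_subclass()
    if not families:
        raise ValueError("no TE families supplied")
    rng = np.random.default_rng(seed)
    rows = []
    for family in sorted(families):
        fs = families[family]
        if len(fs) == 0:
            warnings.warn(f"TE family {family} has no intervals; skipped")
            continue
        res = permutation_overlap_test(
            regions, fs, assembly, n_perm=n_perm,
            seed=int(rng.integers(2 ** 31)), statistic="base_overlap")
        fold = (res.observed / res.perm_mean) if res.perm_mean > 0 else np.nan
        rows.append({"family": family, "observed_bases": res.observed,
                     "perm_mean": res.perm_mean, "perm_sd": res.perm_sd,
                     "z_score": res.z_score, "p_value": res.p_value,
                     "alternative": res.alternative, "fold": fold,
                     "degenerate": res.degenerate})
    return pd.DataFrame(rows)
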