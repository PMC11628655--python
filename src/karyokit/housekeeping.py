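"""Housekeeping-gene calling from tissue expression, ortholog
cross-classification, and co-location with breakpoint regions.

A gene is *expressed* when its TPM exceeds 10 in strictly more than 90% of
the shared tissues, and *housekeeping* when it is expressed and its Gini
coefficient across tissues is at most 0.4.  The Gini coefficient is the
mean absolute pairwise difference scaled by twice the mean,
G = sum_ij |x_i - x_j| / (2 n^2 xbar), optionally with the small-sample
n/(n-1) correction (matching the default of common statistical packages).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model import ExpressionMatrix, GenomeAssembly

HK_CLASSES = ("mammalian_ancestral", "clade_ancestral", "species_specific",
              "shared_other", "non_hk")


def gini(values, unbiased: bool = True) -> float:
    """Gini coefficient of a non-negative vector, clipped to [0, 1].

    Raises on negative entries or an all-zero vector (undefined).  The
    unbiased mode multiplies by n/(n-1), making a one-hot vector score
    exactly 1.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("gini expects a non-empty 1-D vector")
    if (x < 0).any():
        raise ValueError("gini is undefined for negative values")
    total = x.sum()
    if total == 0:
        raise ValueError("gini is undefined for an all-zero vector")
    n = x.size
    if n == 1:
        return 0.0
    xs = np.sort(x)
    ranks = np.arange(1, n + 1)
    g = 2.0 * np.sum(ranks * xs) / (n * total) - (n + 1) / n
    if unbiased:
        g *= n / (n - 1)
    return float(min(max(g, 0.0), 1.0))


def expressed_flags(matrix: ExpressionMatrix, tpm_threshold: float = 10.0,
                    tissue_fraction: float = 0.9) -> pd.Series:
    """Expressed = TPM strictly above the threshold in strictly more than
    ``tissue_fraction`` of the tissues."""
    if matrix.values.empty:
        raise ValueError("empty expression matrix")
    n_tissues = matrix.values.shape[1]
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    frac = (matrix.values > tpm_threshold).sum(axis=1) / n_tissues
    return frac > tissue_fraction


def call_housekeeping(matrix: ExpressionMatrix, gini_max: float = 0.4,
                      tpm_threshold: float = 10.0,
                      tissue_fraction: float = 0.9,
                      unbiased: bool = True) -> pd.DataFrame:
    """Per-gene summary: expressed flag, Gini, housekeeping call.

    Housekeeping = expressed AND gini <= gini_max (inclusive).  Genes whose
    Gini is undefined (all-zero rows) are kept as non-housekeeping with a
    missing coefficient, with a warning.
    """
    expressed = expressed_flags(matrix, tpm_threshold, tissue_fraction)
    ginis, failed = [], 0
    for _, row in matrix.values.iterrows():
        try:
            ginis.append(gini(row.to_numpy(), unbiased=unbiased))
        except ValueError:
            ginis.append(np.nan)
            failed += 1
    if failed:
        warnings.warn(f"{failed} genes had undefined Gini (all-zero rows); "
                      "treated as non-housekeeping")
    g = pd.Series(ginis, index=matrix.genes)
    hk = expressed & (g <= gini_max)
    return pd.DataFrame({"expressed": expressed, "gini": g,
                         "housekeeping": hk.fillna(False)},
                        index=matrix.genes)


def classify_orthologs(hk_sets: dict, ortholog_table: pd.DataFrame,
                       clade_species, focal_species: str) -> pd.DataFrame:
    """Cross-species classification of ortholog groups by housekeeping status.

    ``hk_sets`` maps species to its set of housekeeping gene ids;
    ``ortholog_table`` has a group_id column plus one gene-id column per
    species (1:1 orthologs).  Labels: housekeeping in every species ->
    mammalian_ancestral; in exactly the clade set -> clade_ancestral; only
    in the focal species -> species_specific; any other non-empty
    combination -> shared_other; none -> non_hk.
    """
    species = [c for c in ortholog_table.columns if c != "group_id"]
    missing = [sp for sp in hk_sets if sp not in species]
    if missing:
        raise ValueError(f"species {missing} absent from the ortholog table")
    clade = frozenset(clade_species)
    if focal_species not in species:
        raise ValueError("focal species absent from ortholog table")
    rows = []
    for rec in ortholog_table.itertuples(index=False):
        rec = rec._asdict()
        flags = {sp: rec[sp] in hk_sets.get(sp, frozenset()) for sp in species}
        hk_in = frozenset(sp for sp, f in flags.items() if f)
        if not hk_in:
            label = "non_hk"
        elif hk_in == frozenset(species):
            label = "mammalian_ancestral"
        elif hk_in == clade:
            label = "clade_ancestral"
        elif hk_in == {focal_species}:
            label = "species_specific"
        else:
            label = "shared_other"
        rows.append({"group_id": rec["group_id"],
                     **{f"hk_{sp}": flags[sp] for sp in species},
                     "label": label})
    return pd.DataFrame(rows)


def hk_intersection_matrix(hk_sets: dict, ortholog_table: pd.DataFrame) -> pd.DataFrame:
    """Upset-style counts of ortholog groups per species-combination."""
    species = [c for c in ortholog_table.columns if c != "group_id"]
    combos: dict = {}
    for rec in ortholog_table.itertuples(index=False):
        rec = rec._asdict()
        key = tuple(sorted(sp for sp in species
                           if rec[sp] in hk_sets.get(sp, frozenset())))
        combos[key] = combos.get(key, 0) + 1
    rows = [{"species_set": "+".join(k) if k else "(none)", "n_groups": v}
            for k, v in sorted(combos.items(), key=lambda kv: (-len(kv[0]), kv[0]))]
    return pd.DataFrame(rows)


def hk_location_summary(genes: pd.DataFrame, ebrs, sf_history: pd.DataFrame,
                        assembly: GenomeAssembly, n_perm: int = 1000,
                        seed=None, run_permutations: bool = True):
    """Fraction of housekeeping genes per genomic compartment, per HK class.

    ``genes`` needs columns gene_id/chrom/start/end/hk_class.  Compartments
    are the well-defined and not-defined EBRs plus each SF-history label.
    A gene overlapping both an EBR and an SF (boundary-spanning) is counted
    in the EBR compartment, with a warning.  Association per compartment is
    assessed with the region-overlap permutation test.

    Returns (fractions DataFrame, {(hk_class, compartment): PermutationResult}).
    """
    from .regionstats import ebrs_as_intervals, permutation_overlap_test

    compartments = {
        "well_defined_ebr": ebrs_as_intervals(
            [e for e in ebrs if e.size_class == "well_defined"]),
        "not_defined_ebr": ebrs_as_intervals(
            [e for e in ebrs if e.size_class == "not_defined"]),
    }
    for label, grp in sf_history.groupby("label"):
        compartments[f"sf_{label}"] = list(
            zip(grp["ref_chrom"], grp["ref_start"], grp["ref_end"]))

    def overlaps(chrom, s, e, intervals):
        return any(c == chrom and s < ie and is_ < e for c, is_, ie in intervals)

    order = list(compartments)
    assign = []
    boundary_spanners = 0
    for rec in genes.itertuples(index=False):
        hits = [name for name in order
                if overlaps(rec.chrom, rec.start, rec.end, compartments[name])]
        ebr_hits = [h for h in hits if h.endswith("_ebr")]
        if ebr_hits and len(hits) > len(ebr_hits):
            boundary_spanners += 1
        chosen = ebr_hits[0] if ebr_hits else (hits[0] if hits else "unlocated")
        assign.append(chosen)
    if boundary_spanners:
        warnings.warn(f"{boundary_spanners} genes span an EBR/SF boundary; "
                      "counted in the EBR compartment")
    genes = genes.assign(compartment=assign)
    rows = []
    for hk_class, grp in genes.groupby("hk_class"):
        n = len(grp)
        for comp in order + ["unlocated"]:
            k = int((grp["compartment"] == comp).sum())
            rows.append({"hk_class": hk_class, "compartment": comp,
                         "n_genes": k, "fraction": k / n if n else np.nan})
    fractions = pd.DataFrame(rows)
    perms = {}
    if run_permutations:
        rng = np.random.default_rng(seed)
        for hk_class, grp in genes.groupby("hk_class"):
            regions = list(zip(grp["chrom"], grp["start"], grp["end"]))
            for comp in order:
                if not compartments[comp] or not regions:
                    continue
                perms[(hk_class, comp)] = permutation_overlap_test(
                    regions, compartments[comp], assembly, n_perm=n_perm,
                    seed=int(rng.integers(2 ** 31)))
    return fractions, perms
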