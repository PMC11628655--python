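"""Domain types shared across the pipeline.

Every interval in this package is 0-based, half-open ([start, end)), on the
reference assembly unless a field name says otherwise.  Orientation is stored
as +1/-1 internally and rendered as "+"/"-" in files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import pandas as pd

SIGN_TOKENS = {"+": 1, "-": -1, "−": -1, "1": 1, "-1": -1, "+1": 1}


def parse_sign(token) -> int:
    """Normalize an orientation token ("+", "-", "1", "-1", ints) to +1/-1."""
    if isinstance(token, (int, float)) and token in (1, -1):
        return int(token)
    tok = str(token).strip()
    if tok not in SIGN_TOKENS:
        raise ValueError(f"unrecognized orientation token {token!r}")
    return SIGN_TOKENS[tok]


def sign_str(sign: int) -> str:
    return "+" if sign > 0 else "-"


@dataclass(frozen=True)
class GenomeAssembly:
    """A named genome: ordered chromosomes with lengths in bp."""

    name: str
    chromosomes: tuple  # of (chrom_id, length)

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(
            (str(c), int(n)) for c, n in self.chromosomes))
        ids = [c for c, _ in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate chromosome ids in assembly")
        for c, n in self.chromosomes:
            if n <= 0:
                raise ValueError(f"chromosome {c} has non-positive length {n}")

    @property
    def lengths(self) -> dict:
        return dict(self.chromosomes)

    @property
    def total_size(self) -> int:
        return sum(n for _, n in self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass(frozen=True)
class SyntenyBlock:
    """One alignment block: reference interval mapped onto a target interval."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    tgt_genome: str
    tgt_chrom: str
    tgt_start: int
    tgt_end: int
    orientation: int  # +1 / -1

    def __post_init__(self):
        if not self.ref_start < self.ref_end:
            raise ValueError(
                f"ref interval empty: {self.ref_chrom}:{self.ref_start}-{self.ref_end}")
        if not self.tgt_start < self.tgt_end:
            raise ValueError(
                f"target interval empty: {self.tgt_chrom}:{self.tgt_start}-{self.tgt_end}")

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class SignedFragment:
    """An oriented reference interval; the atom karyotypes are built from.

    ``history`` accumulates the rearrangement types that have touched the
    fragment (used by the simulator for truth labels; analysis-side
    karyotypes leave it empty).
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    sign: int = 1
    history: frozenset = frozenset()

    def __post_init__(self):
        if not self.ref_start < self.ref_end:
            raise ValueError("fragment must have ref_start < ref_end")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")

    def __len__(self) -> int:
        return self.ref_end - self.ref_start

    def flipped(self, mark: bool = False) -> "SignedFragment":
        hist = self.history | {"inversion"} if mark else self.history
        return replace(self, sign=-self.sign, history=hist)

    def with_history(self, event_type: str) -> "SignedFragment":
        return replace(self, history=self.history | {event_type})


class Karyotype:
    """A genome as ordered chromosomes of signed reference fragments."""

    def __init__(self, name: str, chromosomes: dict | Iterable = ()):
        self.name = name
        if isinstance(chromosomes, dict):
            self.chromosomes = {k: list(v) for k, v in chromosomes.items()}
        else:
            self.chromosomes = {k: list(v) for k, v in chromosomes}

    def copy(self) -> "Karyotype":
        return Karyotype(self.name, {k: list(v) for k, v in self.chromosomes.items()})

    def chrom_length(self, chrom: str) -> int:
        return sum(len(f) for f in self.chromosomes[chrom])

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_length(c) for c in self.chromosomes)

    def fragments(self) -> Iterator[tuple]:
        for chrom, frags in self.chromosomes.items():
            for f in frags:
                yield chrom, f

    def locate(self, chrom: str, pos: int) -> tuple:
        """Return (fragment index, offset within fragment) for frame position pos."""
        if pos < 0 or pos >= self.chrom_length(chrom):
            raise ValueError(f"position {pos} outside {chrom}")
        off = 0
        for i, f in enumerate(self.chromosomes[chrom]):
            if pos < off + len(f):
                return i, pos - off
            off += len(f)
        raise AssertionError("unreachable")

    def ref_point(self, chrom: str, pos: int) -> tuple:
        """Map a frame cut position (between bases pos-1 and pos) to a
        reference-frame point (ref_chrom, ref_pos)."""
        length = self.chrom_length(chrom)
        if pos < 0 or pos > length:
            raise ValueError(f"cut position {pos} outside {chrom}")
        off = 0
        for f in self.chromosomes[chrom]:
            if pos <= off + len(f):
                d = pos - off
                if f.sign > 0:
                    return f.ref_chrom, f.ref_start + d
                return f.ref_chrom, f.ref_end - d
            off += len(f)
        raise AssertionError("unreachable")

    def coalesce(self) -> None:
        """Merge adjacent fragments that are contiguous on the reference with
        equal sign and history (in place); inverse operations then restore
        the original fragment representation exactly."""
        for chrom, frags in self.chromosomes.items():
            out: list = []
            for f in frags:
                if out:
                    g = out[-1]
                    if (g.ref_chrom == f.ref_chrom and g.sign == f.sign
                            and g.history == f.history
                            and ((f.sign > 0 and g.ref_end == f.ref_start)
                                 or (f.sign < 0 and g.ref_start == f.ref_end))):
                        lo = min(g.ref_start, f.ref_start)
                        hi = max(g.ref_end, f.ref_end)
                        out[-1] = replace(g, ref_start=lo, ref_end=hi)
                        continue
                out.append(f)
            self.chromosomes[chrom] = out

    def split_at(self, chrom: str, pos: int) -> None:
        """Introduce a fragment boundary at frame position pos (in place)."""
        length = self.chrom_length(chrom)
        if pos <= 0 or pos >= length:
            return
        frags = self.chromosomes[chrom]
        off = 0
        for i, f in enumerate(frags):
            if pos < off + len(f):
                d = pos - off
                if d == 0:
                    return
                if f.sign > 0:
                    left = replace(f, ref_end=f.ref_start + d)
                    right = replace(f, ref_start=f.ref_start + d)
                else:
                    left = replace(f, ref_start=f.ref_end - d)
                    right = replace(f, ref_end=f.ref_end - d)
                frags[i:i + 1] = [left, right]
                return
            off += len(f)


@dataclass
class RearrangementEvent:
    """One typed rearrangement with its reference-frame footprint."""

    event_type: str                      # inversion | fusion | fission | complex
    branch: tuple = (None, None)         # (parent node, child node)
    chroms: tuple = ()                   # participating chromosome ids
    breakpoints: tuple = ()              # ref-frame points: (ref_chrom, pos)
    affected: tuple = ()                 # ref intervals (chrom, start, end) the event acted on
    lower_bound: int = 1                 # minimum number of simple events (complex only)
    detail: str = ""

    def __post_init__(self):
        if self.event_type not in {"inversion", "fusion", "fission", "complex"}:
            raise ValueError(f"unknown event type {self.event_type}")


@dataclass
class EventLog:
    """Ground-truth record of simulated rearrangements."""

    events: list = field(default_factory=list)

    def counts(self) -> dict:
        """Per-branch counts by type: {branch: {type: n}}."""
        out: dict = {}
        for e in self.events:
            out.setdefault(e.branch, {}).setdefault(e.event_type, 0)
            out[e.branch][e.event_type] += 1
        return out

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class SynFragment:
    """A resolution-limited syntenic fragment (merged collinear blocks)."""

    sf_id: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    tgt_genome: str
    tgt_chrom: str
    tgt_start: int
    tgt_end: int
    orientation: int
    resolution: int
    n_blocks: int = 1

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start


# Size classes per the breakpoint-width thresholds (kb): <=50 well-defined,
# (50, 300] not defined, >300 treated as an assembly gap and discarded.
WELL_DEFINED_MAX = 50_000
NOT_DEFINED_MAX = 300_000


@dataclass(frozen=True)
class EBRInterval:
    """The gap between two reference-adjacent SFs whose target adjacency broke."""

    ref_chrom: str
    start: int
    end: int
    size_class: str
    left_sf: str
    right_sf: str
    breakage: str = ""   # what broke: chrom / orientation / order

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("EBR with negative width")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


#: Syntenic-fragment history labels: the set of rearrangement types that
#: touched a fragment along the lineage maps onto one label.
SF_LABELS = ("collinear", "inversion", "fission_collinear", "fission_fused",
             "fission_inverted", "complex")


def label_from_types(types) -> str:
    """Map a set of event types to a fragment-history label."""
    t = frozenset(types)
    if not t:
        return "collinear"
    if t == {"inversion"}:
        return "inversion"
    if t == {"fission"}:
        return "fission_collinear"
    if t == {"fission", "fusion"}:
        return "fission_fused"
    if t == {"fission", "inversion"}:
        return "fission_inverted"
    return "complex"


def classify_width(width: int) -> str:
    if width < 0:
        raise ValueError("negative EBR width")
    if width <= WELL_DEFINED_MAX:
        return "well_defined"
    if width <= NOT_DEFINED_MAX:
        return "not_defined"
    return "gap_discarded"


@dataclass
class PermutationResult:
    """Outcome of a randomization test for region/feature association."""

    statistic: str
    observed: float
    n_perm: int
    perm_mean: float
    perm_sd: float
    z_score: float
    p_value: float
    alternative: str           # greater | less
    degenerate: bool = False

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("empirical p must lie in (0, 1]")


class FeatureSet:
    """Genomic features of one class, as a tidy frame of half-open intervals."""

    COLUMNS = ["chrom", "start", "end", "name", "subclass"]

    def __init__(self, feature_class: str, intervals: pd.DataFrame | Iterable = ()):
        self.feature_class = feature_class
        if isinstance(intervals, pd.DataFrame):
            df = intervals.copy()
        else:
            rows = [tuple(r) for r in intervals]
            ncol = len(rows[0]) if rows else len(self.COLUMNS)
            df = pd.DataFrame(rows, columns=self.COLUMNS[:ncol])
        for col, default in (("name", ""), ("subclass", "")):
            if col not in df.columns:
                df[col] = default
        if df.empty:
            df = pd.DataFrame(columns=self.COLUMNS)
        df = df[self.COLUMNS].reset_index(drop=True)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["end"] <= df["start"]).any():
            raise ValueError("features must have start < end")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def validate_bounds(self, assembly: GenomeAssembly) -> None:
        lengths = assembly.lengths
        for row in self.df.itertuples():
            if row.chrom not in lengths:
                raise ValueError(f"feature chromosome {row.chrom} not in assembly")
            if row.start < 0 or row.end > lengths[row.chrom]:
                raise ValueError(
                    f"feature {row.chrom}:{row.start}-{row.end} outside assembly bounds")

    def by_subclass(self) -> dict:
        return {k: FeatureSet(self.feature_class, g.reset_index(drop=True))
                for k, g in self.df.groupby("subclass", sort=True)}

    def intervals(self) -> list:
        return list(zip(self.df["chrom"], self.df["start"], self.df["end"]))


class ExpressionMatrix:
    """TPM expression, genes x tissues, for one species."""

    def __init__(self, species: str, values: pd.DataFrame):
        if values.columns.empty:
            raise ValueError("tissue set must be non-empty")
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if (values.to_numpy() < 0).any():
            raise ValueError("negative TPM values")
        self.species = species
        self.values = values.astype(float)

    @property
    def genes(self):
        return self.values.index

    @property
    def tissues(self):
        return self.values.columns

    @property
    def shape(self):
        return self.values.shape

    def restrict_tissues(self, tissues) -> "ExpressionMatrix":
        keep = [t for t in self.values.columns if t in set(tissues)]
        if not keep:
            raise ValueError("no shared tissues left after restriction")
        return ExpressionMatrix(self.species, self.values[keep])
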