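"""Readers and writers for every external format the pipeline touches.

Conventions: BED and the block/fragment TSVs are 0-based half-open; GFF3 is
1-based closed and converted at the boundary.  All outputs are TSV with a
commented header stating units and conventions.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import dendropy
import pandas as pd

from .model import (ExpressionMatrix, FeatureSet, GenomeAssembly, SyntenyBlock,
                    parse_sign, sign_str)

BLOCK_COLUMNS = ["ref_chrom", "ref_start", "ref_end", "tgt_genome",
                 "tgt_chrom", "tgt_start", "tgt_end", "orientation"]


class ParseError(ValueError):
    pass


def _open_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_assembly(path) -> GenomeAssembly:
    """Two-column TSV: chrom_id, length (bp). Name taken from the file stem."""
    chroms = []
    for lineno, line in _open_lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        chroms.append((parts[0], int(parts[1])))
    return GenomeAssembly(Path(path).stem, tuple(chroms))


def write_assembly(assembly: GenomeAssembly, path) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tlength_bp\n")
        for c, n in assembly.chromosomes:
            fh.write(f"{c}\t{n}\n")


def read_synteny_blocks(path, assembly: GenomeAssembly | None = None) -> list:
    """Read the canonical tab-delimited block exchange format.

    Columns: ref_chrom ref_start ref_end tgt_genome tgt_chrom tgt_start
    tgt_end orientation.  Blocks come back sorted by (ref_chrom, ref_start)
    with orientation normalized to +1/-1.
    """
    blocks = []
    for lineno, line in _open_lines(path):
        parts = line.split("\t")
        if len(parts) < 8:
            raise ParseError(f"{path}:{lineno}: expected 8 columns, got {len(parts)}")
        try:
            b = SyntenyBlock(parts[0], int(parts[1]), int(parts[2]), parts[3],
                             parts[4], int(parts[5]), int(parts[6]),
                             parse_sign(parts[7]))
        except ValueError as err:
            raise ParseError(f"{path}:{lineno}: {err}") from err
        if assembly is not None:
            lengths = assembly.lengths
            if b.ref_chrom not in lengths:
                raise ParseError(f"{path}:{lineno}: unknown ref chromosome {b.ref_chrom}")
            if b.ref_start < 0 or b.ref_end > lengths[b.ref_chrom]:
                raise ParseError(
                    f"{path}:{lineno}: interval outside {b.ref_chrom} bounds")
        blocks.append(b)
    blocks.sort(key=lambda b: (b.ref_chrom, b.ref_start, b.ref_end))
    return blocks


def write_synteny_blocks(blocks, path) -> None:
    with open(path, "w") as fh:
        fh.write("# 0-based half-open reference and target intervals (bp)\n")
        fh.write("# " + "\t".join(BLOCK_COLUMNS) + "\n")
        for b in blocks:
            fh.write("\t".join(map(str, [
                b.ref_chrom, b.ref_start, b.ref_end, b.tgt_genome, b.tgt_chrom,
                b.tgt_start, b.tgt_end, sign_str(b.orientation)])) + "\n")


class PhyloTree:
    """A dated tree: newick topology plus node ages in My before present."""

    def __init__(self, tree: dendropy.Tree, root_age: float | None = None):
        self.tree = tree
        depths = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                bl = node.edge.length
                if bl is None:
                    raise ValueError("branch without a length in newick input")
                if bl <= 0:
                    raise ValueError(f"non-positive branch length {bl}")
                depths[node] = depths[node.parent_node] + bl
        height = max(depths.values()) if depths else 0.0
        if root_age is None:
            root_age = height
        self.ages = {}
        for node, d in depths.items():
            label = node.taxon.label if node.taxon else node.label
            if label:
                self.ages[label] = root_age - d
        self._nodes = {}
        for node in tree.preorder_node_iter():
            label = node.taxon.label if node.taxon else node.label
            if label:
                self._nodes[label] = node

    def age(self, name: str) -> float:
        if name not in self.ages:
            raise KeyError(f"no node named {name!r} in tree")
        return self.ages[name]

    def branch_duration(self, parent: str, child: str) -> float:
        dur = self.age(parent) - self.age(child)
        if dur <= 0:
            raise ValueError(f"branch {parent}->{child} has non-positive duration")
        return dur

    def lineage(self, leaf: str) -> list:
        """Named nodes from the root down to ``leaf`` (oldest first)."""
        node = self._nodes[leaf]
        path = []
        while node is not None:
            label = node.taxon.label if node.taxon else node.label
            if label:
                path.append(label)
            node = node.parent_node
        return list(reversed(path))

    @classmethod
    def from_chain(cls, names_ages) -> "PhyloTree":
        """Build a single-lineage dated tree from [(name, age), ...], oldest first."""
        names_ages = [(str(n), float(a)) for n, a in names_ages]
        if len(names_ages) < 2:
            raise ValueError("a lineage chain needs at least two nodes")
        tree = dendropy.Tree()
        node = tree.seed_node
        node.label = names_ages[0][0]
        prev_age = names_ages[0][1]
        for name, age in names_ages[1:]:
            if age >= prev_age:
                raise ValueError("chain ages must strictly decrease")
            child = dendropy.Node()
            child.label = name
            child.edge.length = prev_age - age
            node.add_child(child)
            node = child
            prev_age = age
        return cls(tree, root_age=names_ages[0][1])


def read_tree(path, root_age: float | None = None) -> PhyloTree:
    """Read a newick tree with branch lengths in My.

    Node ages are root_age minus root-to-node depth; by default the root age
    is the tree height, placing the deepest leaves at the present (age 0).
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             suppress_internal_node_taxa=True)
    return PhyloTree(tree, root_age=root_age)


def read_features(path, feature_class: str, fmt: str | None = None,
                  subclass_attribute: str | None = None) -> FeatureSet:
    """Read a BED (0-based half-open) or GFF3 (1-based closed) feature file.

    GFF coordinates are converted to the internal 0-based half-open
    convention on read; ``subclass_attribute`` names the GFF attribute (or
    BED column 4 is used) to populate the subclass field.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix in {".bed"}:
            fmt = "bed"
        elif suffix in {".gff", ".gff3"}:
            fmt = "gff"
        else:
            raise ParseError(f"cannot infer format of {path}; pass fmt=")
    rows = []
    if fmt == "bed":
        for lineno, line in _open_lines(path):
            if line.startswith(("track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >=3 columns")
            name = parts[3] if len(parts) > 3 else ""
            sub = parts[4] if len(parts) > 4 else name
            rows.append((parts[0], int(parts[1]), int(parts[2]), name, sub))
    elif fmt == "gff":
        for lineno, line in _open_lines(path):
            parts = line.split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{lineno}: GFF3 needs 9 columns")
            start1, end1 = int(parts[3]), int(parts[4])
            if start1 < 1 or end1 < start1:
                raise ParseError(f"{path}:{lineno}: bad GFF coordinates")
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            name = attrs.get("ID", attrs.get("Name", ""))
            sub = attrs.get(subclass_attribute, "") if subclass_attribute else parts[2]
            rows.append((parts[0], start1 - 1, end1, name, sub))
    else:
        raise ParseError(f"unknown feature format {fmt!r}")
    return FeatureSet(feature_class, rows)


def write_features(features: FeatureSet, path) -> None:
    """Write as BED with name in column 4 and subclass in column 5."""
    with open(path, "w") as fh:
        fh.write(f"# class={features.feature_class}; 0-based half-open; "
                 "col4=name col5=subclass\n")
        for row in features.df.itertuples():
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t{row.subclass}\n")


SF_COLUMNS = ["sf_id", "ref_chrom", "ref_start", "ref_end", "tgt_genome",
              "tgt_chrom", "tgt_start", "tgt_end", "orientation",
              "resolution", "n_blocks"]


def write_sfs(sfs, path) -> None:
    with open(path, "w") as fh:
        fh.write("# syntenic fragments; 0-based half-open; resolution in bp\n")
        fh.write("# " + "\t".join(SF_COLUMNS) + "\n")
        for sf in sfs:
            fh.write("\t".join(map(str, [
                sf.sf_id, sf.ref_chrom, sf.ref_start, sf.ref_end,
                sf.tgt_genome, sf.tgt_chrom, sf.tgt_start, sf.tgt_end,
                sign_str(sf.orientation), sf.resolution, sf.n_blocks])) + "\n")


def read_sfs(path) -> list:
    from .model import SynFragment
    out = []
    for lineno, line in _open_lines(path):
        p = line.split("\t")
        if len(p) < 11:
            raise ParseError(f"{path}:{lineno}: expected 11 columns")
        out.append(SynFragment(p[0], p[1], int(p[2]), int(p[3]), p[4], p[5],
                               int(p[6]), int(p[7]), parse_sign(p[8]),
                               int(p[9]), int(p[10])))
    return out


def write_ebrs(ebrs, path) -> None:
    """BED-like: chrom start end size_class with flank ids and breakage kind."""
    with open(path, "w") as fh:
        fh.write("# EBRs; BED 0-based half-open; col4=size_class col5=width "
                 "col6=left_sf col7=right_sf col8=breakage\n")
        for e in ebrs:
            fh.write(f"{e.ref_chrom}\t{e.start}\t{e.end}\t{e.size_class}\t"
                     f"{e.width}\t{e.left_sf}\t{e.right_sf}\t{e.breakage}\n")


def read_ebrs(path) -> list:
    from .model import EBRInterval
    out = []
    for lineno, line in _open_lines(path):
        p = line.split("\t")
        if len(p) < 4:
            raise ParseError(f"{path}:{lineno}: expected >=4 columns")
        out.append(EBRInterval(p[0], int(p[1]), int(p[2]), p[3],
                               p[5] if len(p) > 5 else "",
                               p[6] if len(p) > 6 else "",
                               p[7] if len(p) > 7 else ""))
    return out


def write_karyotype(k, path) -> None:
    """TSV of ordered signed fragments per chromosome."""
    with open(path, "w") as fh:
        fh.write("# chrom\tposition_in_chrom\tref_chrom\tref_start\tref_end\tsign\n")
        for chrom, frags in k.chromosomes.items():
            for i, f in enumerate(frags):
                fh.write(f"{chrom}\t{i}\t{f.ref_chrom}\t{f.ref_start}\t"
                         f"{f.ref_end}\t{sign_str(f.sign)}\n")


def read_karyotype(path, name: str | None = None):
    from .model import Karyotype, SignedFragment
    chroms: dict = {}
    for lineno, line in _open_lines(path):
        p = line.split("\t")
        if len(p) < 6:
            raise ParseError(f"{path}:{lineno}: expected 6 columns")
        chroms.setdefault(p[0], []).append(
            (int(p[1]), SignedFragment(p[2], int(p[3]), int(p[4]),
                                       parse_sign(p[5]))))
    return Karyotype(name or Path(path).stem,
                     {c: [f for _, f in sorted(v)] for c, v in chroms.items()})


def events_to_frame(events) -> pd.DataFrame:
    rows = []
    for i, ev in enumerate(events):
        rows.append({
            "event_id": f"ev{i+1}", "type": ev.event_type,
            "parent": ev.branch[0], "child": ev.branch[1],
            "chroms": ",".join(map(str, ev.chroms)),
            "breakpoints": ";".join(f"{c}:{p}" for c, p in ev.breakpoints),
            "affected": ";".join(f"{c}:{s}-{e}" for c, s, e in ev.affected),
            "lower_bound": ev.lower_bound,
        })
    return pd.DataFrame(rows)


def read_expression(path, species: str | None = None,
                    shared_tissues=None) -> ExpressionMatrix:
    """Read a genes x tissues TPM TSV (gene ids in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    species = species or Path(path).stem
    mat = ExpressionMatrix(species, df)
    if shared_tissues is not None:
        mat = mat.restrict_tissues(shared_tissues)
    return mat


def write_expression(matrix: ExpressionMatrix, path) -> None:
    buf = _io.StringIO()
    matrix.values.to_csv(buf, sep="\t", index_label="gene_id")
    with open(path, "w") as fh:
        fh.write(f"# species={matrix.species}; values are TPM\n")
        fh.write(buf.getvalue())


def write_tsv(df: pd.DataFrame, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
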