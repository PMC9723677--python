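"""Readers and writers for the formats the pipeline touches.

Conventions fixed here and relied on everywhere else:

* Sequences are uppercase DNA over ``{A, C, G, T, N}``. Anything else is
  replaced by ``N`` on input (with a warning carrying the substitution count).
* Feature coordinates are **0-based half-open** in memory. GFF3 is 1-based
  inclusive; the conversion happens only at read/write time.
* Taxonomy strings use the 7-rank prefix convention
  (``d__``, ``p__``, ``c__``, ``o__``, ``f__``, ``g__``, ``s__``), with
  components separated by ``;``.

Newick trees are represented as :class:`dendropy.Tree` objects; internal
node labels carry taxonomy strings.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Contig",
    "Feature",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_newick",
    "write_newick",
    "split_taxonomy_label",
    "read_taxonomy_tsv",
    "revcomp",
    "RANK_PREFIXES",
]

RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Raised for malformed input files."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Contig:
    """A single contig: an id and an uppercase ACGTN sequence."""

    id: str
    seq: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


@dataclass
class Feature:
    """A genomic feature on a contig.

    ``start``/``end`` are 0-based half-open. ``kind`` is typically one of
    ``CDS``, ``tRNA``, ``SECIS`` or ``marker`` but unknown GFF3 types are
    carried through verbatim.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    kind: str
    product: str = ""
    function_ids: set[str] = field(default_factory=set)
    attrs: dict[str, str] = field(default_factory=dict)
    id: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid feature interval [{self.start}, {self.end}) "
                f"on {self.contig_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def sequence(self, contigs: dict[str, Contig]) -> str:
        """Feature sequence in reading orientation (revcomp on '-')."""
        s = contigs[self.contig_id].seq[self.start : self.end]
        return revcomp(s) if self.strand == "-" else s


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a text FASTA file into a list of :class:`Contig`.

    Lowercase is uppercased; characters outside ACGTN become N (one warning
    with the total substitution count). Duplicate ids and empty files raise
    :class:`FormatError`.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    n_subst = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        cleaned = _NON_ACGTN.sub("N", seq)
        n_subst += sum(1 for a, b in zip(seq, cleaned) if a != b)
        if not cleaned:
            raise FormatError(f"empty sequence for {rec.id!r} in {path}")
        contigs.append(Contig(rec.id, cleaned))
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    if n_subst:
        warnings.warn(
            f"{n_subst} non-ACGTN character(s) replaced by N in {path}",
            stacklevel=2,
        )
    return contigs


def write_fasta(contigs: list[Contig], path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(c.seq), id=c.id, description="") for c in contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3


def _parse_attrs(col: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in col.strip().split(";"):
        part = part.strip()
        if not part or part == ".":
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF3 attribute {part!r}")
        key, val = part.split("=", 1)
        attrs[key] = val
    return attrs


def read_gff3(path: str | Path) -> list[Feature]:
    """Read GFF3 features.

    Coordinates are converted from 1-based inclusive to the internal 0-based
    half-open convention. ``product=`` and ``function_ids=`` (comma-separated)
    attributes are lifted onto the Feature; everything else stays in
    ``attrs``. Unknown feature types pass through with ``kind`` verbatim.
    """
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            contig_id, _source, kind, start_s, end_s, _score, strand, _phase, attr_col = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: strand must be + or -")
            attrs = _parse_attrs(attr_col)
            product = attrs.pop("product", "")
            fid_raw = attrs.pop("function_ids", "")
            function_ids = {f for f in fid_raw.split(",") if f}
            feat_id = attrs.pop("ID", None)
            features.append(
                Feature(
                    contig_id=contig_id,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    kind=kind,
                    product=product,
                    function_ids=function_ids,
                    attrs=attrs,
                    id=feat_id,
                )
            )
    return features


def _format_attrs(f: Feature) -> str:
    parts: list[str] = []
    if f.id is not None:
        parts.append(f"ID={f.id}")
    if f.product:
        parts.append(f"product={f.product}")
    if f.function_ids:
        parts.append("function_ids=" + ",".join(sorted(f.function_ids)))
    for k in sorted(f.attrs):
        parts.append(f"{k}={f.attrs[k]}")
    return ";".join(parts) if parts else "."


def write_gff3(features: list[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "magrecode",
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if f.kind == "CDS" else ".",
                        _format_attrs(f),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree, preserving branch lengths and internal labels."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise FormatError(f"could not parse Newick file {path}: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError(f"negative branch length {edge.length} in {path}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )


def split_taxonomy_label(label: str | None) -> list[tuple[str, str]]:
    """Split ``'p__X;c__Y'`` into ``[('p', 'p__X'), ('c', 'c__Y')]``.

    Components without a recognised rank prefix are ignored.
    """
    if not label:
        return []
    out: list[tuple[str, str]] = []
    for comp in label.split(";"):
        comp = comp.strip()
        if len(comp) >= 3 and comp[:3] in RANK_PREFIXES:
            out.append((comp[0], comp))
    return out


def read_taxonomy_tsv(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Read a genome_id → 7-rank taxonomy string table (TSV, header row)."""
    taxonomy: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise FormatError(f"empty taxonomy table {path}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            genome_id, tax = line.split("\t")[:2]
            taxonomy[genome_id] = split_taxonomy_label(tax)
    return taxonomy
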