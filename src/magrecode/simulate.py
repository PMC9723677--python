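"""Synthetic genomes and trees with known ground truth.

Every downstream stage of the pipeline is exercised against data generated
here: contigs at a target GC content; CDSs whose stop codons follow a
configurable UAA/UAG/UGA usage vector; planted readthrough genes (one long
ORF split at an internal in-frame UAG or UGA into two CDSs with matching
annotations, the way a gene caller fragments a recoded gene); a pylTSBCD
cluster with pylS placed ~6 kb from pylBCD; the Sec machinery gene set with
a tRNAsec; SECIS elements a known distance downstream of UGA-readthrough
genes; cloverleaf tRNAs with dot-bracket structures; and single-copy
markers emulating completeness/contamination estimates. The planted layout
is returned as a :class:`Truth` record so recovery can be scored exactly.

The mutation model is substitution-only, which keeps planted coordinates
valid and makes the expected nucleotide identity of a mutated copy simply
``1 - rate``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .io import Contig, Feature, revcomp

__all__ = [
    "SimConfig",
    "Truth",
    "FusedTruth",
    "simulate_genome",
    "simulate_tree",
    "mutate_genome",
    "emit_truth",
    "load_truth",
    "build_trna",
    "marker_qc_estimate",
]

TRUTH_SCHEMA_VERSION = 1

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOP_DNA = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Parameters of one simulated genome.

    Defaults reflect the study conditions emulated: ~21% UAG usage as in
    the Pyl-recoded lineage, GC near the middle of the observed 28.8-48.4%
    range, SECIS elements 30-500 nt downstream of selenoprotein CDSs, 100
    single-copy markers, and completeness/contamination near the
    high-quality type MAG (94% / 4%).
    """

    seed: int = 0
    n_contigs: int = 3
    contig_len: int = 150_000
    gc_target: float = 0.40
    n_cds: int = 500
    stop_usage: tuple[float, float, float] = (0.60, 0.21, 0.19)  # UAA, UAG, UGA
    n_readthrough_uag: int = 2
    n_readthrough_uga: int = 3
    plant_pyl_cluster: bool = True
    plant_sec_machinery: bool = True
    n_secis: int = 3
    secis_dist_range: tuple[int, int] = (30, 500)
    n_markers: int = 100
    completeness_target: float = 0.94
    contamination_target: float = 0.04
    mutation_rate: float = 0.01
    cds_len_range: tuple[int, int] = (300, 900)

    def validate(self) -> None:
        for name in ("gc_target", "completeness_target", "contamination_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.stop_usage) - 1.0) > 1e-9:
            raise ValueError("stop_usage must sum to 1")
        if any(f < 0 for f in self.stop_usage):
            raise ValueError("stop_usage fractions must be non-negative")
        d_min, d_max = self.secis_dist_range
        if d_min > d_max:
            raise ValueError("secis_dist_range must satisfy d_min <= d_max")
        if self.n_secis > self.n_readthrough_uga:
            raise ValueError(
                "n_secis exceeds n_readthrough_uga: every SECIS is planted "
                "downstream of a UGA-readthrough gene"
            )
        if not 0.0 <= self.mutation_rate <= 0.3:
            raise ValueError("mutation_rate outside [0, 0.3]")


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class FusedTruth:
    upstream_id: str
    downstream_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    codon: str  # UAG | UGA
    gap_nt: int


@dataclass
class Truth:
    """Planted layout of one simulated genome."""

    fused_genes: list[FusedTruth] = field(default_factory=list)
    pyl_genes: dict[str, str] = field(default_factory=dict)  # gene -> feature id
    sec_genes: dict[str, str] = field(default_factory=dict)
    trnas: list[dict] = field(default_factory=list)
    secis_partners: list[dict] = field(default_factory=list)
    completeness: float = 0.0
    contamination: float = 0.0
    n_markers_present: int = 0
    n_markers_duplicated: int = 0
    stop_usage: tuple[float, float, float] = (0.0, 0.0, 0.0)


def emit_truth(truth: Truth, path: str | Path) -> None:
    """Serialise a Truth record to versioned JSON (lossless roundtrip)."""
    payload = {"version": TRUTH_SCHEMA_VERSION, **asdict(truth)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_truth(path: str | Path) -> Truth:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.pop("version", None)
    if version != TRUTH_SCHEMA_VERSION:
        raise ValueError(f"unsupported truth schema version {version!r}")
    payload["fused_genes"] = [FusedTruth(**d) for d in payload["fused_genes"]]
    payload["stop_usage"] = tuple(payload["stop_usage"])
    return Truth(**payload)


# ---------------------------------------------------------------------------
# sequence building blocks


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _random_codons(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """GC-biased random codons with no stop codon among them."""
    arr = _random_bases(rng, 3 * n_codons, gc).reshape(n_codons, 3)
    # rewrite any TAA/TAG/TGA middle base to C: TAA->TCA etc.
    t = ord("T")
    a = ord("A")
    g = ord("G")
    is_stop = (arr[:, 0] == t) & (
        ((arr[:, 1] == a) & ((arr[:, 2] == a) | (arr[:, 2] == g)))
        | ((arr[:, 1] == g) & (arr[:, 2] == a))
    )
    arr[is_stop, 1] = ord("C")
    return arr.tobytes().decode("ascii")


def _cds_seq(rng: np.random.Generator, length: int, gc: float, stop: str) -> str:
    """A complete CDS of ``length`` nt (multiple of 3) ending in ``stop``."""
    assert length % 3 == 0 and length >= 9
    return "ATG" + _random_codons(rng, length // 3 - 2, gc) + stop


def build_trna(
    rng: np.random.Generator,
    anticodon: str = "UCA",
    tail: str = "CCA",
    d_stem_bp: int = 6,
    acceptor_bp: int = 7,
    anticodon_stem_bp: int = 5,
    t_stem_bp: int = 5,
    d_loop_len: int = 8,
    t_loop_len: int = 7,
) -> tuple[str, str]:
    """Build a synthetic cloverleaf tRNA (DNA sequence, dot-bracket).

    All stems use strict Watson-Crick pairs. The anticodon loop is 7 nt
    with the anticodon in the middle; the 3' tail is the unpaired overhang
    after the acceptor stem (``CCA`` canonically, ``GC`` for the unusual
    acceptor tail variant).
    """
    comp = str.maketrans("ACGT", "TGCA")

    def stem(n: int) -> tuple[str, str]:
        five = _random_bases(rng, n, 0.5).tobytes().decode("ascii")
        three = five.translate(comp)[::-1]
        return five, three

    def loop(n: int) -> str:
        # avoid accidental pairing concerns: loops are unpaired by structure
        return _random_bases(rng, n, 0.5).tobytes().decode("ascii")

    ac_dna = anticodon.upper().replace("U", "T")
    acc5, acc3 = stem(acceptor_bp)
    d5, d3 = stem(d_stem_bp)
    a5, a3 = stem(anticodon_stem_bp)
    t5, t3 = stem(t_stem_bp)
    ac_loop = loop(2) + ac_dna + loop(2)

    seq = (
        acc5
        + "A"
        + d5 + loop(d_loop_len) + d3
        + "A"
        + a5 + ac_loop + a3
        + "A"
        + t5 + loop(t_loop_len) + t3
        + "A"
        + acc3
        + tail.upper().replace("U", "T")
    )
    struct = (
        "(" * acceptor_bp
        + "."
        + "(" * d_stem_bp + "." * d_loop_len + ")" * d_stem_bp
        + "."
        + "(" * anticodon_stem_bp + "." * 7 + ")" * anticodon_stem_bp
        + "."
        + "(" * t_stem_bp + "." * t_loop_len + ")" * t_stem_bp
        + "."
        + ")" * acceptor_bp
        + "." * len(tail)
    )
    assert len(seq) == len(struct)
    return seq, struct


# ---------------------------------------------------------------------------
# genome assembly from blocks

# A block is (length, seq, [features relative to block start]) laid out on a
# contig behind a random intergenic gap. Relative features use reading
# coordinates when built and are mirrored here for '-' strand blocks.


@dataclass
class _Block:
    seq: str
    features: list[Feature]  # contig_id empty, coords relative to block


def _mirror_block(block: _Block) -> _Block:
    """Reverse-complement a block, flipping feature coordinates/strands."""
    n = len(block.seq)
    feats = []
    for f in block.features:
        feats.append(
            Feature(
                contig_id="",
                start=n - f.end,
                end=n - f.start,
                strand="-" if f.strand == "+" else "+",
                kind=f.kind,
                product=f.product,
                function_ids=set(f.function_ids),
                attrs=dict(f.attrs),
                id=f.id,
            )
        )
    feats.sort(key=lambda f: f.start)
    return _Block(revcomp(block.seq), feats)


def _cds_block(
    rng: np.random.Generator,
    cfg: SimConfig,
    length: int,
    stop: str,
    product: str,
    feat_id: str,
    function_ids: set[str] | None = None,
) -> _Block:
    seq = _cds_seq(rng, length, cfg.gc_target, stop)
    feat = Feature(
        contig_id="",
        start=0,
        end=length,
        strand="+",
        kind="CDS",
        product=product,
        function_ids=function_ids or set(),
        id=feat_id,
    )
    return _Block(seq, [feat])


def _readthrough_block(
    rng: np.random.Generator,
    cfg: SimConfig,
    codon: str,  # "UAG" | "UGA"
    idx: int,
    with_secis: bool,
) -> tuple[_Block, str, str, int, int | None]:
    """One split readthrough gene, optionally with a SECIS downstream.

    Returns (block, upstream_id, downstream_id, gap, secis distance).
    """
    stop_dna = codon.replace("U", "T")
    l1 = 3 * int(rng.integers(100, 201))
    l2 = 3 * int(rng.integers(100, 201))
    gap = 3 * int(rng.integers(0, 11))  # 0-30 nt, frame-preserving
    base = f"rt_{codon.lower()}_{idx}"
    product = f"dimethylamine methyltransferase {base}"
    fam = {f"FAM_{base}"}

    up_seq = _cds_seq(rng, l1, cfg.gc_target, stop_dna)
    gap_seq = _random_bases(rng, gap, cfg.gc_target).tobytes().decode("ascii")
    down_seq = _random_codons(rng, l2 // 3 - 1, cfg.gc_target) + "TAA"
    seq = up_seq + gap_seq + down_seq
    feats = [
        Feature("", 0, l1, "+", "CDS", product, set(fam), id=f"{base}_a"),
        Feature(
            "", l1 + gap, l1 + gap + l2, "+", "CDS", product, set(fam),
            id=f"{base}_b",
        ),
    ]
    secis_d: int | None = None
    if with_secis:
        d_min, d_max = cfg.secis_dist_range
        secis_d = int(rng.integers(d_min, d_max + 1))
        spacer = _random_bases(rng, secis_d, cfg.gc_target).tobytes().decode("ascii")
        secis_seq = _random_bases(rng, 60, cfg.gc_target).tobytes().decode("ascii")
        start = len(seq) + secis_d
        feats.append(
            Feature("", start, start + 60, "+", "SECIS", id=f"secis_{base}")
        )
        seq = seq + spacer + secis_seq
    return _Block(seq, feats), f"{base}_a", f"{base}_b", gap, secis_d


def _pyl_cluster_block(rng: np.random.Generator, cfg: SimConfig, truth: Truth) -> _Block:
    """pylT + pylS, a ~6 kb spacer with filler genes, then pylBCD."""
    gc = cfg.gc_target
    parts: list[str] = []
    feats: list[Feature] = []
    pos = 0

    def put(seq: str, feat: Feature | None = None) -> None:
        nonlocal pos
        if feat is not None:
            feat.start += pos
            feat.end += pos
            feats.append(feat)
        parts.append(seq)
        pos += len(seq)

    trna_seq, trna_struct = build_trna(rng, anticodon="CUA", tail="GC", d_stem_bp=4)
    put(
        trna_seq,
        Feature(
            "", 0, len(trna_seq), "+", "tRNA",
            product="tRNA-Pyl",
            attrs={"isotype": "pyl", "anticodon": "CUA", "structure": trna_struct},
            id="pylT",
        ),
    )
    truth.trnas.append(
        {
            "id": "pylT",
            "isotype": "Pyl-amber",
            "anticodon": "CUA",
            "sequence": trna_seq,
            "structure": trna_struct,
            "acceptor_tail": "GC",
        }
    )
    put(_random_bases(rng, 80, gc).tobytes().decode("ascii"))

    pyls_len = 3 * int(rng.integers(330, 380))
    put(
        _cds_seq(rng, pyls_len, gc, "TAA"),
        Feature("", 0, pyls_len, "+", "CDS", "pyrrolysyl-tRNA synthetase",
                {"TIGR03912", "TIGR02367"}, id="pylS"),
    )
    truth.pyl_genes["PylS"] = "pylS"

    # ~6 kb between pylS and pylB, holding a NAD kinase and hypotheticals
    spacer_budget = 6000 + int(rng.integers(-300, 301))
    filler_products = ["NAD kinase", "hypothetical protein fp1",
                       "hypothetical protein fp2"]
    used = 0
    for i, prod in enumerate(filler_products):
        gap = int(rng.integers(100, 200))
        flen = 3 * int(rng.integers(100, 160))
        if used + gap + flen > spacer_budget - 100:
            break
        put(_random_bases(rng, gap, gc).tobytes().decode("ascii"))
        put(
            _cds_seq(rng, flen, gc, "TAA"),
            Feature("", 0, flen, "+", "CDS", prod, id=f"pyl_spacer_{i}"),
        )
        used += gap + flen
    put(_random_bases(rng, spacer_budget - used, gc).tobytes().decode("ascii"))

    for gene, tigr, length in (
        ("PylB", "TIGR03910", 3 * 320),
        ("PylC", "TIGR03909", 3 * 300),
        ("PylD", "TIGR03911", 3 * 240),
    ):
        put(
            _cds_seq(rng, length, gc, "TAA"),
            Feature("", 0, length, "+", "CDS",
                    f"pyrrolysine biosynthesis protein {gene}", {tigr},
                    id=gene.lower()),
        )
        truth.pyl_genes[gene] = gene.lower()
        put(_random_bases(rng, int(rng.integers(30, 90)), gc).tobytes().decode("ascii"))

    return _Block("".join(parts), feats)


def _sec_machinery_blocks(
    rng: np.random.Generator, cfg: SimConfig, truth: Truth
) -> list[_Block]:
    gc = cfg.gc_target
    blocks: list[_Block] = []
    for gene, product, length in (
        ("SerRS", "seryl-tRNA synthetase", 3 * 300),
        ("PSTK", "phosphoseryl-tRNA kinase", 3 * 180),
        ("SepSecS", "O-phosphoseryl-tRNA:selenocysteinyl-tRNA synthase", 3 * 300),
        ("SPS", "selenophosphate synthetase", 3 * 230),
        ("SelB", "selenocysteine-specific elongation factor", 3 * 400),
    ):
        blocks.append(
            _cds_block(rng, cfg, length, "TAA", product, gene.lower())
        )
        truth.sec_genes[gene] = gene.lower()
    trna_seq, trna_struct = build_trna(rng, anticodon="UCA", tail="CCA", d_stem_bp=6)
    blocks.append(
        _Block(
            trna_seq,
            [
                Feature(
                    "", 0, len(trna_seq), "+", "tRNA",
                    product="tRNA-Sec",
                    attrs={
                        "isotype": "sec",
                        "anticodon": "UCA",
                        "structure": trna_struct,
                    },
                    id="trna_sec",
                )
            ],
        )
    )
    truth.trnas.append(
        {
            "id": "trna_sec",
            "isotype": "Sec-opal",
            "anticodon": "UCA",
            "sequence": trna_seq,
            "structure": trna_struct,
            "acceptor_tail": "CCA",
        }
    )
    return blocks


# ---------------------------------------------------------------------------
# main generator


def simulate_genome(
    cfg: SimConfig,
) -> tuple[list[Contig], list[Feature], Truth]:
    """Generate one annotated genome plus its ground-truth record.

    Deterministic given ``cfg.seed``. Raises ``ValueError`` when the
    requested features cannot fit on ``n_contigs`` contigs of
    ``contig_len`` bp.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = Truth(stop_usage=tuple(cfg.stop_usage))

    blocks: list[tuple[_Block, str | None]] = []  # (block, planted strand)

    # ordinary CDSs
    lo, hi = cfg.cds_len_range
    stops = [_STOP_DNA[i] for i in rng.choice(3, size=cfg.n_cds, p=cfg.stop_usage)]
    for i in range(cfg.n_cds):
        length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        blocks.append(
            (
                _cds_block(
                    rng, cfg, length, stops[i],
                    product=f"hypothetical protein {i:05d}",
                    feat_id=f"cds_{i:05d}",
                ),
                None,
            )
        )

    # readthrough genes (SECIS attached to the first n_secis UGA ones)
    rt_meta: list[tuple[str, str, str, int, int | None]] = []
    for codon, count in (("UAG", cfg.n_readthrough_uag), ("UGA", cfg.n_readthrough_uga)):
        for i in range(count):
            with_secis = codon == "UGA" and i < cfg.n_secis
            block, up_id, down_id, gap, secis_d = _readthrough_block(
                rng, cfg, codon, i, with_secis
            )
            blocks.append((block, None))
            rt_meta.append((codon, up_id, down_id, gap, secis_d))

    if cfg.plant_pyl_cluster:
        blocks.append((_pyl_cluster_block(rng, cfg, truth), None))
    if cfg.plant_sec_machinery:
        for b in _sec_machinery_blocks(rng, cfg, truth):
            blocks.append((b, None))

    # single-copy markers: present set plus duplicated foreign copies
    n_present = round(cfg.n_markers * cfg.completeness_target)
    n_dup = round(cfg.n_markers * cfg.contamination_target)
    present = rng.choice(cfg.n_markers, size=n_present, replace=False)
    present.sort()
    dup = present[: n_dup] if n_dup <= n_present else present
    for copy_tag, marker_set in (("", present), ("dup", dup)):
        for m in marker_set:
            seq = _random_bases(rng, 120, cfg.gc_target).tobytes().decode("ascii")
            fid = f"marker_{m:03d}" + (f"_{copy_tag}" if copy_tag else "")
            feat = Feature(
                "", 0, 120, "+", "marker",
                function_ids={f"MARK{m:03d}"},
                attrs={"foreign": "1"} if copy_tag else {},
                id=fid,
            )
            blocks.append((_Block(seq, [feat]), None))
    truth.completeness = n_present / cfg.n_markers
    truth.contamination = len(dup) / cfg.n_markers
    truth.n_markers_present = int(n_present)
    truth.n_markers_duplicated = int(len(dup))

    # random strand per block, random placement order
    order = rng.permutation(len(blocks))
    strands = rng.choice(np.array(["+", "-"]), size=len(blocks))

    contig_ids = [f"c{i + 1}" for i in range(cfg.n_contigs)]
    cursors = [0] * cfg.n_contigs
    placements: list[tuple[int, int, _Block]] = []  # (contig idx, offset, block)
    features: list[Feature] = []
    contig_idx = 0
    for bi in order:
        block, _ = blocks[bi]
        if strands[bi] == "-":
            block = _mirror_block(block)
        gap = int(rng.integers(20, 121))
        while (
            contig_idx < cfg.n_contigs
            and cursors[contig_idx] + gap + len(block.seq) > cfg.contig_len
        ):
            contig_idx += 1
        if contig_idx >= cfg.n_contigs:
            raise ValueError(
                f"contigs too short for requested features: need more than "
                f"{cfg.n_contigs} x {cfg.contig_len} bp"
            )
        offset = cursors[contig_idx] + gap
        cursors[contig_idx] = offset + len(block.seq)
        placements.append((contig_idx, offset, block))
        for f in block.features:
            features.append(
                Feature(
                    contig_id=contig_ids[contig_idx],
                    start=f.start + offset,
                    end=f.end + offset,
                    strand=f.strand,
                    kind=f.kind,
                    product=f.product,
                    function_ids=set(f.function_ids),
                    attrs=dict(f.attrs),
                    id=f.id,
                )
            )

    # assemble contig sequences: background, then planted blocks on top
    arrays = [
        bytearray(_random_bases(rng, cfg.contig_len, cfg.gc_target).tobytes())
        for _ in range(cfg.n_contigs)
    ]
    for ci, offset, block in placements:
        arrays[ci][offset : offset + len(block.seq)] = block.seq.encode("ascii")
    contigs = [
        Contig(contig_ids[i], arrays[i].decode("ascii"))
        for i in range(cfg.n_contigs)
    ]

    # resolve truth records that need absolute coordinates
    by_id = {f.id: f for f in features if f.id}
    for codon, up_id, down_id, gap, secis_d in rt_meta:
        up, down = by_id[up_id], by_id[down_id]
        truth.fused_genes.append(
            FusedTruth(
                upstream_id=up_id,
                downstream_id=down_id,
                contig_id=up.contig_id,
                start=min(up.start, down.start),
                end=max(up.end, down.end),
                strand=up.strand,
                codon=codon,
                gap_nt=gap,
            )
        )
        if secis_d is not None:
            truth.secis_partners.append(
                {
                    "secis_id": f"secis_rt_{codon.lower()}_{up_id.split('_')[-2]}",
                    "cds_id": up_id,
                    "distance_nt": secis_d,
                }
            )
    return contigs, features, truth


def marker_qc_estimate(
    features: list[Feature], n_markers: int
) -> tuple[float, float]:
    """Marker-based completeness/contamination fractions of a genome.

    Completeness = distinct markers found / marker-set size; contamination
    = markers found more than once / marker-set size.
    """
    counts: dict[str, int] = {}
    for f in features:
        if f.kind != "marker":
            continue
        for fid in f.function_ids:
            counts[fid] = counts.get(fid, 0) + 1
    distinct = len(counts)
    duplicated = sum(1 for v in counts.values() if v > 1)
    return distinct / n_markers, duplicated / n_markers


# ---------------------------------------------------------------------------
# mutation


def mutate_genome(
    contigs: list[Contig], mutation_rate: float, seed: int
) -> list[Contig]:
    """Apply i.i.d. substitutions at a per-site rate (uniform over the 3
    alternative bases); N positions are left untouched."""
    if not 0.0 <= mutation_rate <= 0.3:
        raise ValueError("mutation_rate outside [0, 0.3]")
    rng = np.random.default_rng(seed)
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        lut[b] = i
    out: list[Contig] = []
    for contig in contigs:
        arr = np.frombuffer(contig.seq.encode("ascii"), dtype=np.uint8).copy()
        idx = lut[arr]
        mutable = idx != 255
        hit = mutable & (rng.random(arr.size) < mutation_rate)
        shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
        idx_hit = (idx[hit] + shift) % 4
        arr[hit] = _BASES[idx_hit]
        out.append(Contig(contig.id, arr.tobytes().decode("ascii")))
    return out


# ---------------------------------------------------------------------------
# trees


def simulate_tree(
    n_taxa: int,
    n_phyla: int,
    classes_per_phylum: int,
    seed: int,
) -> tuple[dendropy.Tree, dict[str, list[tuple[str, str]]]]:
    """Random bifurcating tree with monophyletic phyla and classes.

    Leaves are genome ids; internal nodes carry ``p__``/``c__`` labels at
    the phylum/class roots. Returns the tree and the matching leaf taxonomy
    table (genome id -> rank components). Deterministic given ``seed``.
    """
    if n_taxa < 4 or n_phyla < 2:
        raise ValueError("need n_taxa >= 4 and n_phyla >= 2")
    if n_phyla * classes_per_phylum > n_taxa:
        raise ValueError(
            f"infeasible partition: {n_phyla} phyla x {classes_per_phylum} "
            f"classes need more than {n_taxa} taxa"
        )
    rng = np.random.default_rng(seed)

    def split_even(total: int, parts: int) -> list[int]:
        base = total // parts
        rem = total % parts
        return [base + (1 if i < rem else 0) for i in range(parts)]

    def join(subtrees: list[str]) -> str:
        trees = list(subtrees)
        while len(trees) > 1:
            i, j = sorted(rng.choice(len(trees), size=2, replace=False))
            right = trees.pop(j)
            left = trees.pop(i)
            bl1 = rng.uniform(0.05, 1.0)
            bl2 = rng.uniform(0.05, 1.0)
            trees.append(f"({left}:{bl1:.6f},{right}:{bl2:.6f})")
        return trees[0]

    taxonomy: dict[str, list[tuple[str, str]]] = {}
    phylum_newicks: list[str] = []
    for p, phylum_size in enumerate(split_even(n_taxa, n_phyla), start=1):
        phylum = f"p__P{p}"
        class_newicks: list[str] = []
        for c, class_size in enumerate(
            split_even(phylum_size, classes_per_phylum), start=1
        ):
            cls = f"c__P{p}C{c}"
            leaves = [f"g{p}_{c}_{k}" for k in range(1, class_size + 1)]
            for leaf in leaves:
                taxonomy[leaf] = [("p", phylum), ("c", cls)]
            sub = join(leaves)
            # a single-class phylum's class node coincides with the phylum
            # node; the phylum label wins there (taxonomy table still
            # carries the class)
            if class_size > 1 and classes_per_phylum > 1:
                sub = f"{sub}{cls}"
            class_newicks.append(sub)
        phylum_tree = join(class_newicks)
        if phylum_size > 1:
            phylum_tree = f"{phylum_tree}{phylum}"
        phylum_newicks.append(phylum_tree)
    newick = join(phylum_newicks) + "d__Root;"
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    return tree, taxonomy
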