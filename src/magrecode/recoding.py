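"""Detection and classification of Sec and Pyl stop-codon recoding.

Selenocysteine (Sec, the 21st amino acid) is inserted at recoded UGA (opal)
stop codons: a dedicated tRNAsec is first mischarged with serine, then
converted via PSTK and SepSecS, with selenophosphate supplied by SPS and
insertion mediated by the Sec-specific elongation factor SelB reading a
SECIS stem-loop in the 3' UTR. Pyrrolysine (Pyl, the 22nd amino acid) is
inserted at recoded UAG (amber) stops and requires the biosynthesis genes
pylB, pylC, pylD plus the pyrrolysyl-tRNA synthetase pylS charging
tRNApyl (pylT).

Because a standard gene caller terminates an ORF at the recoded stop, a
recoded gene appears as two consecutive CDSs with matching annotations;
fusing such pairs in silico recovers the candidate recoded gene. This
module implements those classification rules on top of annotated features:
stop-codon usage, machinery completeness (complete / partial / tRNA-only /
absent), readthrough fusion, selenoprotein–SECIS pairing and tRNA
cloverleaf feature extraction.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .io import Contig, Feature

__all__ = [
    "StopUsage",
    "MachineryStatus",
    "FusedCandidate",
    "SecisPair",
    "TrnaFeatures",
    "stop_codon_usage",
    "detect_sec_machinery",
    "detect_pyl_machinery",
    "fuse_stop_readthrough",
    "pair_selenoprotein_secis",
    "parse_cloverleaf",
    "recoding_report",
    "SEC_REQUIRED",
    "PYL_REQUIRED",
]

STOP_DNA_TO_RNA = {"TAA": "UAA", "TAG": "UAG", "TGA": "UGA"}
RNA_TO_DNA_STOP = {v: k for k, v in STOP_DNA_TO_RNA.items()}

# accepted identifiers (lower-cased products or function ids) per gene
SEC_GENE_VOCAB: dict[str, set[str]] = {
    "SerRS": {"serrs", "sers", "seryl-trna synthetase"},
    "PSTK": {"pstk", "phosphoseryl-trna kinase", "l-seryl-trna(sec) kinase"},
    "SepSecS": {
        "sepsecs",
        "o-phosphoseryl-trna:selenocysteinyl-trna synthase",
        "sep-trna:sec-trna synthase",
    },
    "SPS": {"sps", "seld", "selenophosphate synthetase"},
    "SelB": {"selb", "selenocysteine-specific elongation factor"},
}
SEC_REQUIRED = frozenset({"PSTK", "SepSecS", "SPS", "SelB"})

PYL_GENE_VOCAB: dict[str, set[str]] = {
    "PylS": {"pyls", "pyrrolysyl-trna synthetase"},
    "PylSn": {"pylsn", "tigr03912"},
    "PylSc": {"pylsc", "tigr02367"},
    "PylB": {"pylb", "tigr03910", "pyrrolysine biosynthesis radical sam protein"},
    "PylC": {"pylc", "tigr03909", "pyrrolysine biosynthesis protein pylc"},
    "PylD": {"pyld", "tigr03911", "pyrrolysine biosynthesis protein pyld"},
}
PYL_REQUIRED = frozenset({"PylS", "PylB", "PylC", "PylD"})

_WS = re.compile(r"\s+")


def _norm_product(product: str) -> str:
    return _WS.sub(" ", product.strip().lower())


def _gene_hits(feature: Feature, vocab: dict[str, set[str]]) -> set[str]:
    """Canonical gene names a feature's annotation matches."""
    tokens = {_norm_product(feature.product)} | {
        fid.lower() for fid in feature.function_ids
    }
    tokens.discard("")
    return {gene for gene, accepted in vocab.items() if tokens & accepted}


def _is_trna(feature: Feature, isotype: str) -> bool:
    """Does a tRNA feature carry the given isotype (``sec`` or ``pyl``)?"""
    if feature.kind != "tRNA":
        return False
    product = _norm_product(feature.product)
    if f"trna-{isotype}" in product or f"trna{isotype}" in product:
        return True
    if feature.attrs.get("isotype", "").lower() == isotype:
        return True
    anticodon = feature.attrs.get("anticodon", "").upper().replace("T", "U")
    return anticodon == {"sec": "UCA", "pyl": "CUA"}[isotype]


# ---------------------------------------------------------------------------
# stop codon usage


@dataclass
class StopUsage:
    genome_id: str
    n_complete_cds: int
    f_UAA: float
    f_UAG: float
    f_UGA: float
    n_excluded_partial: int


def _stop_codon(feature: Feature, contigs: dict[str, Contig]) -> str:
    """Last 3 nt of a CDS in reading orientation (revcomped on '-')."""
    seq = feature.sequence(contigs)
    return seq[-3:]


def stop_codon_usage(
    contigs: list[Contig],
    cds_features: list[Feature],
    genome_id: str = "",
) -> StopUsage:
    """Fractions of complete CDSs terminating in UAA / UAG / UGA.

    CDSs flagged partial, shorter than 6 nt, or not ending in a canonical
    stop are excluded from the denominator and counted separately: unclosed
    contig-edge fragments would otherwise bias the frequencies.
    """
    by_id = {c.id: c for c in contigs}
    counts = {"UAA": 0, "UAG": 0, "UGA": 0}
    excluded = 0
    for f in cds_features:
        if f.kind != "CDS":
            continue
        if f.attrs.get("partial", "").lower() in ("1", "true", "yes"):
            excluded += 1
            continue
        if len(f) < 6:
            warnings.warn(
                f"CDS {f.id or f.contig_id} shorter than 6 nt excluded",
                stacklevel=2,
            )
            excluded += 1
            continue
        stop = STOP_DNA_TO_RNA.get(_stop_codon(f, by_id))
        if stop is None:
            excluded += 1
            continue
        counts[stop] += 1
    n = sum(counts.values())
    if n == 0:
        return StopUsage(genome_id, 0, 0.0, 0.0, 0.0, excluded)
    return StopUsage(
        genome_id,
        n,
        counts["UAA"] / n,
        counts["UAG"] / n,
        counts["UGA"] / n,
        excluded,
    )


# ---------------------------------------------------------------------------
# machinery detection


@dataclass
class MachineryStatus:
    """Presence/absence classification of a recoding system.

    ``status`` follows the four-way scheme: *complete* (all required genes
    and the tRNA), *partial* (at least one required gene but not the full
    complement), *trna_only* (the tRNA with no required gene), *absent*.
    """

    trait: str
    detected_genes: set[str]
    has_trna: bool
    status: str
    included: bool = False
    notes: dict[str, object] = field(default_factory=dict)


def _classify(required: frozenset[str], detected: set[str], has_trna: bool) -> str:
    if detected >= required and has_trna:
        return "complete"
    if detected:
        return "partial"
    if has_trna:
        return "trna_only"
    return "absent"


def detect_sec_machinery(features: list[Feature]) -> MachineryStatus:
    """Classify the Sec biosynthesis/insertion system of one genome.

    Required genes: PSTK, SepSecS, SPS and SelB, plus tRNAsec. SerRS
    performs the initial mischarging but is housekeeping, so it is reported
    (``notes['serrs_present']``) without counting toward completeness.
    """
    detected: set[str] = set()
    serrs = False
    has_trna = False
    for f in features:
        hits = _gene_hits(f, SEC_GENE_VOCAB)
        serrs = serrs or "SerRS" in hits
        detected |= hits & SEC_REQUIRED
        has_trna = has_trna or _is_trna(f, "sec")
    status = _classify(SEC_REQUIRED, detected, has_trna)
    return MachineryStatus(
        "Sec", detected, has_trna, status, notes={"serrs_present": serrs}
    )


def detect_pyl_machinery(features: list[Feature]) -> MachineryStatus:
    """Classify the Pyl system and decide downstream inclusion.

    The biosynthesis genes pylB/C/D act in one pathway and sit in close
    proximity in genuine Pyl clusters, so hits that are not co-located on a
    single contig are discarded before counting: the contig carrying the
    most distinct pylB/C/D genes wins (ties broken lexicographically), and
    if no contig carries at least two, all pylB/C/D hits are dropped as
    likely spurious. PylSn + PylSc fragments jointly count as PylS. A
    genome is *included* for downstream analysis when at least two of the
    four required genes (50%) survive.
    """
    protein_hits: list[tuple[str, str]] = []  # (gene, contig)
    has_trna = False
    for f in features:
        for gene in _gene_hits(f, PYL_GENE_VOCAB):
            protein_hits.append((gene, f.contig_id))
        has_trna = has_trna or _is_trna(f, "pyl")

    bcd_by_contig: dict[str, set[str]] = {}
    others: set[str] = set()
    for gene, contig in protein_hits:
        if gene in ("PylB", "PylC", "PylD"):
            bcd_by_contig.setdefault(contig, set()).add(gene)
        else:
            others.add(gene)

    kept_bcd: set[str] = set()
    discarded_bcd: set[str] = set()
    if bcd_by_contig:
        best = max(sorted(bcd_by_contig), key=lambda c: len(bcd_by_contig[c]))
        if len(bcd_by_contig[best]) >= 2:
            kept_bcd = bcd_by_contig[best]
        all_bcd = set().union(*bcd_by_contig.values())
        discarded_bcd = all_bcd - kept_bcd

    detected = set(kept_bcd)
    if "PylS" in others or ("PylSn" in others and "PylSc" in others):
        detected.add("PylS")

    status = _classify(PYL_REQUIRED, detected, has_trna)
    included = len(detected & PYL_REQUIRED) >= 2
    return MachineryStatus(
        "Pyl",
        detected,
        has_trna,
        status,
        included=included,
        notes={"discarded_bcd": discarded_bcd},
    )


# ---------------------------------------------------------------------------
# readthrough fusion


@dataclass
class FusedCandidate:
    """Two consecutive CDSs fused across an in-frame recoded stop codon."""

    upstream_id: str
    downstream_id: str
    contig_id: str
    fused_start: int  # genomic, 0-based half-open
    fused_end: int
    strand: str
    recoded_codon: str  # UAG or UGA
    gap_nt: int
    in_frame: bool
    match_basis: str  # product | function_id


def _annotation_match(up: Feature, down: Feature) -> str | None:
    p_up, p_down = _norm_product(up.product), _norm_product(down.product)
    if p_up and p_up == p_down:
        return "product"
    if up.function_ids & down.function_ids:
        return "function_id"
    return None


def fuse_stop_readthrough(
    contigs: list[Contig],
    cds_features: list[Feature],
    codon: str,
    max_gap: int = 300,
) -> list[FusedCandidate]:
    """Find CDS pairs that look like a single gene split at a recoded stop.

    For every complete CDS terminating with the target codon (``UAG`` or
    ``UGA``), the next CDS downstream in translation direction on the same
    contig and strand is examined. The pair is a candidate iff the
    annotations match (normalised product equality or a shared function
    id), the reading frames are consistent (genomic offset divisible by 3,
    so the recoded stop stays in frame in the fusion) and the intervening
    gap is within ``max_gap`` nt. Non-matching pairs are skipped silently.
    """
    if codon not in RNA_TO_DNA_STOP:
        raise ValueError(f"codon must be UAG or UGA/UAA, got {codon!r}")
    by_id = {c.id: c for c in contigs}
    candidates: list[FusedCandidate] = []

    groups: dict[tuple[str, str], list[Feature]] = {}
    for f in cds_features:
        if f.kind == "CDS":
            groups.setdefault((f.contig_id, f.strand), []).append(f)

    for (contig_id, strand), feats in sorted(groups.items()):
        feats.sort(key=lambda f: f.start)
        order = feats if strand == "+" else feats[::-1]  # translation order
        for up, down in zip(order, order[1:]):
            if len(up) < 6 or len(up) % 3 != 0:
                continue
            if STOP_DNA_TO_RNA.get(_stop_codon(up, by_id)) != codon:
                continue
            basis = _annotation_match(up, down)
            if basis is None:
                continue
            if strand == "+":
                gap = down.start - up.end
                in_frame = (down.start - up.end) % 3 == 0
            else:
                gap = up.start - down.end
                in_frame = (up.start - down.end) % 3 == 0
            if not in_frame or gap < 0 or gap > max_gap:
                continue
            candidates.append(
                FusedCandidate(
                    upstream_id=up.id or f"{contig_id}:{up.start}",
                    downstream_id=down.id or f"{contig_id}:{down.start}",
                    contig_id=contig_id,
                    fused_start=min(up.start, down.start),
                    fused_end=max(up.end, down.end),
                    strand=strand,
                    recoded_codon=codon,
                    gap_nt=gap,
                    in_frame=True,
                    match_basis=basis,
                )
            )
    return candidates


# ---------------------------------------------------------------------------
# selenoprotein–SECIS pairing


@dataclass
class SecisPair:
    cds_id: str
    secis_id: str
    distance_nt: int
    strand: str


def pair_selenoprotein_secis(
    fused_uga_candidates: list[FusedCandidate],
    secis_features: list[Feature],
    d_min: int = 30,
    d_max: int = 500,
) -> list[SecisPair]:
    """Pair UGA-readthrough candidates with downstream SECIS elements.

    Archaeal SECIS elements sit in the 3' UTR, so the distance is measured
    in the gene's translation direction from the fused CDS 3' end to the
    SECIS 5' start and must fall in ``[d_min, d_max]`` nt on the same
    contig and strand. Each SECIS is assigned to at most one CDS (the
    nearest in range); a candidate with at least one pair is a confirmed
    selenoprotein.
    """
    best_for_secis: dict[str, tuple[int, FusedCandidate, Feature]] = {}
    for secis in secis_features:
        if secis.kind != "SECIS":
            continue
        sid = secis.id or f"{secis.contig_id}:{secis.start}"
        for cand in fused_uga_candidates:
            if cand.contig_id != secis.contig_id or cand.strand != secis.strand:
                continue
            if cand.strand == "+":
                d = secis.start - cand.fused_end
            else:
                d = cand.fused_start - secis.end
            if d_min <= d <= d_max:
                prev = best_for_secis.get(sid)
                if prev is None or d < prev[0]:
                    best_for_secis[sid] = (d, cand, secis)
    pairs = [
        SecisPair(cand.upstream_id, sid, d, cand.strand)
        for sid, (d, cand, _secis) in sorted(best_for_secis.items())
    ]
    return pairs


# ---------------------------------------------------------------------------
# tRNA cloverleaf parsing


@dataclass
class TrnaFeatures:
    sequence: str
    structure: str
    anticodon: str  # RNA alphabet
    isotype: str  # Sec-opal | Pyl-amber | other
    d_stem_bp: int
    acceptor_tail: str
    arms: dict[str, tuple[int, int]]  # name -> 0-based half-open span


_VALID_PAIRS = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"),
}


def _pair_table(structure: str) -> dict[int, int]:
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced structure: unmatched ')'")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced structure: unmatched '('")
    return pairs


def parse_cloverleaf(sequence: str, structure: str) -> TrnaFeatures:
    """Segment a tRNA cloverleaf from its dot-bracket structure.

    The outermost helix is the acceptor stem; the hairpins inside its
    multiloop are, 5' to 3', the D arm, the anticodon arm, an optional
    variable arm, and the T arm (at least three are required). Reported
    features: base pairs in the D stem, the anticodon (middle 3 nt of the
    anticodon loop, RNA alphabet), the unpaired 3' overhang after the
    acceptor stem (e.g. the canonical CCA tail), and the isotype implied by
    the anticodon (UCA → Sec-opal, CUA → Pyl-amber).
    """
    if len(sequence) != len(structure):
        raise ValueError("sequence and structure lengths differ")
    rna = sequence.upper().replace("T", "U")
    pairs = _pair_table(structure)
    if not pairs:
        raise ValueError("not cloverleaf: no base pairs")
    for i, j in pairs.items():
        if i < j and (rna[i], rna[j]) not in _VALID_PAIRS:
            raise ValueError(
                f"invalid base pair {rna[i]}-{rna[j]} at positions {i},{j}"
            )

    # acceptor stem: run of nested pairs starting at the first paired base
    i = min(pairs)
    j = pairs[i]
    acc_start = i
    while (
        i + 1 in pairs
        and pairs[i + 1] == j - 1
        and structure[i + 1] == "("
    ):
        i, j = i + 1, j - 1
    acc_inner_i, acc_inner_j = i, j
    acceptor_span = (acc_start, pairs[acc_start] + 1)

    # top-level hairpin arms inside the acceptor stem's multiloop
    arms_spans: list[tuple[int, int]] = []
    k = acc_inner_i + 1
    while k < acc_inner_j:
        if structure[k] == "(":
            arms_spans.append((k, pairs[k] + 1))
            k = pairs[k] + 1
        else:
            k += 1
    if len(arms_spans) < 3:
        raise ValueError("not cloverleaf: fewer than 3 hairpin arms")

    names = (
        ["D", "anticodon", "T"]
        if len(arms_spans) == 3
        else ["D", "anticodon", "variable", "T"][: len(arms_spans) - 1] + ["T"]
    )
    if len(arms_spans) > 4:
        raise ValueError("not cloverleaf: more than 4 hairpin arms")
    arms = {"acceptor": acceptor_span}
    for name, span in zip(names, arms_spans):
        arms[name] = span

    d_span = arms["D"]
    d_stem_bp = sum(
        1 for p in range(*d_span) if structure[p] == "("
    )

    ac_span = arms["anticodon"]
    # innermost pair of the anticodon hairpin encloses the loop
    inner = max(
        (p for p in range(*ac_span) if structure[p] == "("),
        key=lambda p: p,
    )
    loop = rna[inner + 1 : pairs[inner]]
    if len(loop) < 3:
        raise ValueError("anticodon loop shorter than 3 nt")
    mid = (len(loop) - 3) // 2
    anticodon = loop[mid : mid + 3]

    tail = rna[pairs[acc_start] + 1 :]
    isotype = {"UCA": "Sec-opal", "CUA": "Pyl-amber"}.get(anticodon, "other")
    return TrnaFeatures(
        sequence=sequence,
        structure=structure,
        anticodon=anticodon,
        isotype=isotype,
        d_stem_bp=d_stem_bp,
        acceptor_tail=tail,
        arms=arms,
    )


# ---------------------------------------------------------------------------
# per-genome report


def recoding_report(
    genomes: list[tuple[str, list[Contig], list[Feature]]],
    max_gap: int = 300,
    d_min: int = 30,
    d_max: int = 500,
) -> pd.DataFrame:
    """One summary row per genome: stop usage, machinery statuses, fused
    readthrough candidate counts, confirmed selenoproteins and tRNA
    isotypes found."""
    rows = []
    for genome_id, contigs, features in genomes:
        cds = [f for f in features if f.kind == "CDS"]
        secis = [f for f in features if f.kind == "SECIS"]
        usage = stop_codon_usage(contigs, cds, genome_id)
        sec = detect_sec_machinery(features)
        pyl = detect_pyl_machinery(features)
        fused_uag = fuse_stop_readthrough(contigs, cds, "UAG", max_gap=max_gap)
        fused_uga = fuse_stop_readthrough(contigs, cds, "UGA", max_gap=max_gap)
        secis_pairs = pair_selenoprotein_secis(
            fused_uga, secis, d_min=d_min, d_max=d_max
        )
        n_selenoproteins = len({p.cds_id for p in secis_pairs})
        isotypes = sorted(
            {
                iso
                for f in features
                for iso in ("sec", "pyl")
                if _is_trna(f, iso)
            }
        )
        rows.append(
            {
                "genome_id": genome_id,
                "n_complete_cds": usage.n_complete_cds,
                "f_UAA": usage.f_UAA,
                "f_UAG": usage.f_UAG,
                "f_UGA": usage.f_UGA,
                "n_excluded_partial": usage.n_excluded_partial,
                "sec_status": sec.status,
                "sec_has_trna": sec.has_trna,
                "pyl_status": pyl.status,
                "pyl_has_trna": pyl.has_trna,
                "pyl_included": pyl.included,
                "n_fused_uag": len(fused_uag),
                "n_fused_uga": len(fused_uga),
                "n_selenoproteins": n_selenoproteins,
                "trna_isotypes": ",".join(isotypes),
            }
        )
    return pd.DataFrame(rows)
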