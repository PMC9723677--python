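"""Reproducible evaluation experiments on synthetic data.

These drive the package's own validation: rank recovery from RED bins on
simulated trees, and recovery of planted readthrough genes and
selenoprotein-SECIS pairs from simulated genomes. They are used by the
test suite and by the results-reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .recoding import (
    fuse_stop_readthrough,
    pair_selenoprotein_secis,
    stop_codon_usage,
)
from .red import assign_rank, phylum_midpoint_rootings, rank_intervals
from .simulate import SimConfig, simulate_genome, simulate_tree

__all__ = [
    "rank_recovery_rate",
    "PlantedRecovery",
    "planted_recovery",
]

#: RED bin centres used when labelling simulated nodes with ranks; the
#: separation (0.25) exceeds twice the default interval half-width (0.1),
#: the regime in which rank assignment is expected to be reliable.
_BIN_CENTRES = {"p": 0.25, "c": 0.50, "o": 0.75}
_BIN_HALF_WIDTH = 0.05


def rank_recovery_rate(
    n_trees: int = 20,
    base_seed: int = 0,
    n_taxa: int = 24,
    h: float = 0.1,
) -> float:
    """Fraction (%) of rank labels recovered by interval-based assignment.

    For each simulated tree, internal-node RED values are computed over all
    phylum-midpoint rootings; nodes whose value falls within
    ``_BIN_HALF_WIDTH`` of a bin centre are labelled with that bin's rank.
    Rank intervals are then rebuilt from the labelled values alone and every
    labelled value is re-assigned; a recovery is an assignment matching the
    label.
    """
    n_ok = n_total = 0
    for t in range(n_trees):
        tree, taxonomy = simulate_tree(n_taxa, 3, 2, seed=base_seed + t)
        rootings = phylum_midpoint_rootings(tree, taxonomy)
        values: list[float] = []
        for rooting in rootings:
            for node, red_value in rooting.node_red.items():
                if node.is_leaf() or node.parent_node is None:
                    continue
                values.append(red_value)
        labelled: dict[str, float] = {}
        for i, v in enumerate(values):
            for rank, centre in _BIN_CENTRES.items():
                if abs(v - centre) <= _BIN_HALF_WIDTH:
                    labelled[f"{rank}__node{i}"] = v
                    break
        ranks_present = {name[0] for name in labelled}
        if len(ranks_present) < 2:
            continue
        intervals = rank_intervals(labelled, h=h)
        for name, v in labelled.items():
            n_total += 1
            if assign_rank(v, intervals).rank == name[0]:
                n_ok += 1
    if n_total == 0:
        raise RuntimeError("no labelled nodes produced; enlarge the trees")
    return 100.0 * n_ok / n_total


@dataclass
class PlantedRecovery:
    """Aggregate recovery of planted recoding features over many genomes."""

    n_genomes: int
    fusion_tp: int
    fusion_fp: int
    fusion_fn: int
    secis_tp: int
    secis_fp: int
    secis_fn: int
    max_usage_dev: float  # max |empirical - planted| over UAA/UAG/UGA
    mean_f_uag: float

    @property
    def fusion_precision(self) -> float:
        return self.fusion_tp / (self.fusion_tp + self.fusion_fp)

    @property
    def fusion_recall(self) -> float:
        return self.fusion_tp / (self.fusion_tp + self.fusion_fn)

    @property
    def secis_precision(self) -> float:
        return self.secis_tp / (self.secis_tp + self.secis_fp)

    @property
    def secis_recall(self) -> float:
        return self.secis_tp / (self.secis_tp + self.secis_fn)


def planted_recovery(
    seeds: range | list[int],
    base_config: SimConfig | None = None,
) -> PlantedRecovery:
    """Score readthrough-fusion and SECIS-pairing recovery on simulated
    genomes with known planted truth.

    A fusion is matched on (upstream id, downstream id, recoded codon); a
    SECIS pair on (CDS id, SECIS id). Stop-codon usage deviations are
    measured against the planting vector.
    """
    cfg0 = base_config or SimConfig()
    f_tp = f_fp = f_fn = s_tp = s_fp = s_fn = 0
    max_dev = 0.0
    f_uag_sum = 0.0
    n = 0
    for seed in seeds:
        cfg = replace(cfg0, seed=seed)
        contigs, features, truth = simulate_genome(cfg)
        cds = [f for f in features if f.kind == "CDS"]
        secis = [f for f in features if f.kind == "SECIS"]

        found = set()
        for codon in ("UAG", "UGA"):
            for cand in fuse_stop_readthrough(contigs, cds, codon):
                found.add((cand.upstream_id, cand.downstream_id, codon))
        expected = {
            (t.upstream_id, t.downstream_id, t.codon) for t in truth.fused_genes
        }
        f_tp += len(found & expected)
        f_fp += len(found - expected)
        f_fn += len(expected - found)

        fused_uga = fuse_stop_readthrough(contigs, cds, "UGA")
        pairs = pair_selenoprotein_secis(fused_uga, secis)
        found_pairs = {(p.cds_id, p.secis_id) for p in pairs}
        expected_pairs = {
            (t["cds_id"], t["secis_id"]) for t in truth.secis_partners
        }
        s_tp += len(found_pairs & expected_pairs)
        s_fp += len(found_pairs - expected_pairs)
        s_fn += len(expected_pairs - found_pairs)

        usage = stop_codon_usage(contigs, cds)
        for emp, planted in zip(
            (usage.f_UAA, usage.f_UAG, usage.f_UGA), cfg.stop_usage
        ):
            max_dev = max(max_dev, abs(emp - planted))
        f_uag_sum += usage.f_UAG
        n += 1
    return PlantedRecovery(
        n, f_tp, f_fp, f_fn, s_tp, s_fp, s_fn, max_dev, f_uag_sum / n
    )
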