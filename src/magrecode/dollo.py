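"""Gain/loss history of recoding traits under Dollo parsimony.

A complex trait such as a stop-codon recoding system is assumed to arise
once and be lost any number of times (Dollo parsimony): the single gain is
placed at the MRCA of the tips carrying the trait (or forced to the root
when external evidence argues for an ancestral origin), and the minimal set
of loss branches explaining the absent tips is reconstructed. The two trait
components — the machinery genes and the tRNA — are reconstructed
independently as binary characters; "partial loss" (machinery lost while
the tRNA is retained, leaving a remnant of the ancient trait) is a derived
label, not a third parsimony state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .treeutil import mrca as _mrca

__all__ = [
    "TraitMatrix",
    "TraitHistory",
    "Event",
    "derive_trait_states",
    "trait_label",
    "dollo_reconstruct",
    "event_summary",
]


def trait_label(machinery: bool, trna: bool) -> str:
    """complete / partial_loss (tRNA-only remnant) / full_loss."""
    if machinery and trna:
        return "complete"
    if trna:
        return "partial_loss"
    return "full_loss"


@dataclass
class TraitMatrix:
    """Per-taxon binary states for one trait's components."""

    trait: str
    machinery: dict[str, bool]
    trna: dict[str, bool]

    def label(self, taxon: str) -> str:
        return trait_label(self.machinery[taxon], self.trna[taxon])


def derive_trait_states(reports: pd.DataFrame) -> dict[str, TraitMatrix]:
    """Binary component states per genome from a recoding report table.

    Machinery counts as present when the detector status is ``complete`` or
    ``partial``; the tRNA component follows the has-tRNA flag (a
    ``trna_only`` status therefore maps to machinery-absent,
    tRNA-present, the partial-loss configuration).
    """
    out: dict[str, TraitMatrix] = {}
    for trait, status_col, trna_col in (
        ("Sec", "sec_status", "sec_has_trna"),
        ("Pyl", "pyl_status", "pyl_has_trna"),
    ):
        machinery: dict[str, bool] = {}
        trna: dict[str, bool] = {}
        for _, row in reports.iterrows():
            machinery[row["genome_id"]] = row[status_col] in ("complete", "partial")
            trna[row["genome_id"]] = bool(row[trna_col])
        out[trait] = TraitMatrix(trait, machinery, trna)
    return out


@dataclass
class Event:
    branch: str  # label/leaf of the child node of the branch
    component: str
    kind: str  # gain | loss


@dataclass
class TraitHistory:
    component: str
    node_state: dict[dendropy.Node, bool]
    events: list[Event] = field(default_factory=list)
    root_constrained: bool = False

    @property
    def loss_count(self) -> int:
        return sum(1 for e in self.events if e.kind == "loss")


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
    return f"mrca({','.join(leaves[:2])}{'...' if len(leaves) > 2 else ''})"


def dollo_reconstruct(
    cladogram: dendropy.Tree,
    tip_states: dict[str, bool],
    component: str,
    force_root_present: bool = False,
) -> TraitHistory:
    """Single-gain / irreversible-loss reconstruction of a binary trait.

    The gain is placed on the branch to the MRCA of the present tips
    (or the root when ``force_root_present``). Below the gain node, a node
    is present iff it has at least one present descendant tip; each
    maximal all-absent subtree costs exactly one loss on its stem, which is
    the minimum achievable under a single gain. With no present tips and an
    unconstrained root, the history is trivially all-absent.

    Raises ``KeyError`` naming the tip if a state is missing.
    """
    leaves = [lf for lf in cladogram.leaf_node_iter()]
    for lf in leaves:
        if lf.taxon.label not in tip_states:
            raise KeyError(f"missing tip state for {lf.taxon.label!r}")
    present_labels = {l for l, s in tip_states.items() if s}

    state: dict[dendropy.Node, bool] = {}
    history = TraitHistory(component, state, root_constrained=force_root_present)

    if not present_labels and not force_root_present:
        for node in cladogram.preorder_node_iter():
            state[node] = False
        return history

    root = cladogram.seed_node
    if force_root_present or not present_labels:
        gain_node = root
    else:
        gain_node = _mrca(cladogram, present_labels)

    # has-present-descendant flag, bottom-up
    has_present: dict[dendropy.Node, bool] = {}
    for node in cladogram.postorder_node_iter():
        if node.is_leaf():
            has_present[node] = node.taxon.label in present_labels
        else:
            has_present[node] = any(has_present[c] for c in node.child_nodes())

    in_gain_clade: dict[dendropy.Node, bool] = {}
    for node in cladogram.preorder_node_iter():
        parent = node.parent_node
        in_gain_clade[node] = node is gain_node or (
            parent is not None and in_gain_clade[parent]
        )
        if not in_gain_clade[node]:
            state[node] = False
        elif node is gain_node:
            state[node] = True
        else:
            state[node] = state[parent] and has_present[node]

    history.events.append(Event(_node_name(gain_node), component, "gain"))
    for node in cladogram.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        if state[parent] and not state[node] and in_gain_clade[node]:
            history.events.append(Event(_node_name(node), component, "loss"))
    return history


def event_summary(histories: dict[str, dict[str, TraitHistory]]) -> pd.DataFrame:
    """Flat event table over traits and components.

    ``histories`` maps trait -> component -> TraitHistory (components are
    typically ``machinery`` and ``trna``). A machinery loss on a branch
    where the tRNA component is still present is flagged as a partial loss
    (the tRNA-retaining remnant configuration).
    """
    rows = []
    for trait, comps in histories.items():
        trna_hist = comps.get("trna")
        trna_state_by_name = (
            {_node_name(n): s for n, s in trna_hist.node_state.items()}
            if trna_hist is not None
            else {}
        )
        for component, hist in comps.items():
            for ev in hist.events:
                partial = (
                    component == "machinery"
                    and ev.kind == "loss"
                    and trna_state_by_name.get(ev.branch, False)
                )
                rows.append(
                    {
                        "trait": trait,
                        "component": component,
                        "branch": ev.branch,
                        "event": ev.kind,
                        "partial_loss": bool(partial),
                    }
                )
    df = pd.DataFrame(
        rows, columns=["trait", "component", "branch", "event", "partial_loss"]
    )
    return df
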