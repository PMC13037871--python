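"""Diagnostic-SNP extraction and placement of incomplete mtDNA sequences.

Given a reference alignment and a fixed rooted tree with a designated
outgroup, Fitch parsimony assigns each variable column's substitution(s) to
branches. Columns with a single inferred origin become diagnostic SNPs of
the branch's child node: their derived allele marks exactly that node's
descendants. An incomplete (N-rich) query is then placed by walking from
the root toward the tips, descending while the query's derived-allele
support outweighs the evidence against, optionally omitting C/T and G/A
sites whose state could be an artifact of cytosine deamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .reference import BASES, BASE_TO_INT
from .simulate import label_nodes

_FULL = 0b1111
_LOWBIT_INDEX = np.array([-1] + [int(np.log2(m & -m)) for m in range(1, 16)], dtype=np.int8)


@dataclass
class PlacementResult:
    assigned_node: str
    path_support: list[dict] = field(default_factory=list)
    sites_omitted_damage: int = 0
    confidence_note: str = "tentative"


def _check_rooted(tree: dendropy.Tree) -> None:
    if not tree.is_rooted or len(tree.seed_node.child_nodes()) != 2:
        raise ValueError("a rooted (bifurcating-root) tree is required")


def _encode_alignment(alignment: dict[str, str], ids: list[str]) -> np.ndarray:
    mats = []
    for sid in ids:
        codes = np.frombuffer(alignment[sid].upper().encode(), dtype=np.uint8)
        col = np.full(len(codes), -1, dtype=np.int8)
        for b, i in BASE_TO_INT.items():
            col[codes == ord(b)] = i
        mats.append(col)
    return np.vstack(mats)


def node_defining_snps(
    alignment: dict[str, str], tree: dendropy.Tree, outgroup: str
) -> pd.DataFrame:
    """Per-column Fitch parsimony on the fixed tree, polarised by the outgroup.

    Returns one row per inferred substitution origin: position (1-based),
    ancestral, derived, node_id (child node of the origin branch),
    damage_susceptible (C<->T or G<->A), homoplasic (column needs >= 2
    origins on this topology).
    """
    _check_rooted(tree)
    label_nodes(tree)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in alignment]
    if missing:
        raise ValueError(f"tips missing from alignment: {missing}")
    if outgroup not in tips:
        raise ValueError(f"outgroup {outgroup!r} is not a tree tip")
    lengths = {len(alignment[t]) for t in tips}
    if len(lengths) != 1:
        raise ValueError("alignment must be rectangular")
    L = lengths.pop()

    states = _encode_alignment(alignment, tips)
    tip_row = {t: i for i, t in enumerate(tips)}

    # bottom-up Fitch state sets as bitmasks, vectorised over columns
    masks: dict[str, np.ndarray] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            s = states[tip_row[nd.taxon.label]]
            m = np.where(s >= 0, (1 << np.maximum(s, 0)).astype(np.uint8), _FULL)
            masks[nd.label] = m.astype(np.uint8)
        else:
            children = nd.child_nodes()
            m = masks[children[0].label]
            for ch in children[1:]:
                inter = m & masks[ch.label]
                union = m | masks[ch.label]
                m = np.where(inter > 0, inter, union).astype(np.uint8)
            masks[nd.label] = m

    # top-down assignment; root state pinned to the outgroup where possible
    out_state = states[tip_row[outgroup]]
    out_bit = np.where(out_state >= 0, (1 << np.maximum(out_state, 0)).astype(np.uint8), 0)
    root_mask = masks[tree.seed_node.label]
    use_out = (root_mask & out_bit) > 0
    assigned: dict[str, np.ndarray] = {}
    assigned[tree.seed_node.label] = np.where(
        use_out, out_state, _LOWBIT_INDEX[root_mask]
    ).astype(np.int8)

    change_edges: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        parent_state = assigned[nd.parent_node.label]
        m = masks[nd.label]
        keep = (m >> np.maximum(parent_state, 0)) & 1 > 0
        state = np.where(keep, parent_state, _LOWBIT_INDEX[m]).astype(np.int8)
        assigned[nd.label] = state
        changed = state != parent_state
        if changed.any():
            change_edges.append((nd.label, changed, parent_state, state))

    n_origins = np.zeros(L, dtype=np.int32)
    for _, changed, _, _ in change_edges:
        n_origins += changed

    rows = []
    for node_id, changed, anc, der in change_edges:
        for col in np.flatnonzero(changed):
            a, d = BASES[anc[col]], BASES[der[col]]
            rows.append(
                {
                    "position": int(col) + 1,
                    "ancestral": a,
                    "derived": d,
                    "node_id": node_id,
                    "damage_susceptible": {a, d} in ({"C", "T"}, {"G", "A"}),
                    "homoplasic": bool(n_origins[col] > 1),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["position", "ancestral", "derived", "node_id", "damage_susceptible", "homoplasic"],
    )
    return df.sort_values(["position", "node_id"], kind="stable").reset_index(drop=True)


def place_sequence(
    query: str,
    table: pd.DataFrame,
    tree: dendropy.Tree,
    omit_damage: bool = True,
    ref_length: int | None = None,
) -> PlacementResult:
    """Walk the query from the root toward the tips over diagnostic SNPs.

    At each step the query is tallied over every child's diagnostic SNPs
    (homoplasic sites excluded). With ``omit_damage``, a site is omitted iff
    the query's own call could be a deamination product there: a T call at a
    C<->T site (possibly a deaminated C) or an A call at a G<->A site
    (possibly a deaminated G). C and G calls cannot arise from deamination
    and therefore remain informative even at damage-susceptible sites. The
    walk descends into the child with the most derived matches, provided
    derived matches strictly exceed ancestral plus conflicting matches; it
    stops otherwise. A query informative at no first-step site is
    "unresolved".
    """
    _check_rooted(tree)
    label_nodes(tree)
    if ref_length is not None and len(query) != ref_length:
        raise ValueError(f"query length {len(query)} != reference length {ref_length}")
    if len(table) and table["position"].max() > len(query):
        raise ValueError("query shorter than diagnostic SNP coordinates")

    usable = table[~table["homoplasic"]]
    by_node: dict[str, list[tuple[int, str, str]]] = {}
    for row in usable.itertuples(index=False):
        by_node.setdefault(row.node_id, []).append(
            (row.position - 1, row.ancestral, row.derived)
        )

    q = query.upper()
    omitted = 0

    def call_could_be_damage(b: str, anc: str, der: str) -> bool:
        pair = {anc, der}
        return (b == "T" and pair == {"C", "T"}) or (b == "A" and pair == {"G", "A"})

    def tally(node_id: str) -> dict:
        nonlocal omitted
        derived = ancestral = miss = conflict = 0
        for pos0, anc, der in by_node.get(node_id, ()):
            b = q[pos0]
            if omit_damage and call_could_be_damage(b, anc, der):
                omitted += 1
                continue
            if b == der:
                derived += 1
            elif b == anc:
                ancestral += 1
            elif b in "ACGT":
                conflict += 1
            else:
                miss += 1
        return {
            "node_id": node_id,
            "derived": derived,
            "ancestral": ancestral,
            "missing": miss,
            "conflicting": conflict,
        }

    def candidate_children(node):
        """Children to evaluate, looking through branches that carry no
        diagnostic SNP: such a node is undefined by the data and cannot be
        distinguished from its parent, so its own children are evaluated in
        its stead."""
        for child in node.child_nodes():
            if by_node.get(child.label) or child.is_leaf():
                yield child
            else:
                yield from candidate_children(child)

    current = tree.seed_node
    path: list[dict] = []
    while True:
        best = None
        for child in candidate_children(current):
            t = tally(child.label)
            informative = t["derived"] + t["ancestral"] + t["conflicting"]
            net = t["derived"] - t["ancestral"] - t["conflicting"]
            if informative >= 1 and net > 0:
                key = (t["derived"], net, t["node_id"])
                if best is None or key > best[0]:
                    best = (key, child, t)
        if best is None:
            break
        _, child, t = best
        path.append(t)
        current = child

    if not path:
        return PlacementResult(
            assigned_node="unresolved", sites_omitted_damage=omitted
        )
    clean = all(t["conflicting"] == 0 and t["derived"] >= 2 for t in path)
    return PlacementResult(
        assigned_node=current.label,
        path_support=path,
        sites_omitted_damage=omitted,
        confidence_note="full" if clean else "tentative",
    )


def annotated_newick(tree: dendropy.Tree, result: PlacementResult, query_id: str) -> str:
    """Newick string with a comment tag on the assignment node."""
    label_nodes(tree)
    clone = tree.clone(depth=1)
    label_nodes(clone)
    for nd in clone.preorder_node_iter():
        if nd.label == result.assigned_node:
            nd.label = f"{nd.label}[&placement={query_id}]"
    return clone.as_string(schema="newick", suppress_rooting=False)
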