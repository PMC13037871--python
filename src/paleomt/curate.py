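"""Dataset-construction rules for mtDNA consensus sequences.

Completeness filtering (maximum unresolved positions), within-site duplicate
pruning under pairwise-resolved sequence equality, control-region (D-loop)
trimming, and alignment site-deletion (complete / partial-p) as used before
phylogenetic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import DLOOP_BOUNDS, MT_LENGTH

_RESOLVED = set("ACGT")


@dataclass
class CurationPolicy:
    max_n: int = 2_600
    min_completeness: float = 0.85
    dloop_bounds: tuple[tuple[int, int], ...] = DLOOP_BOUNDS

    def __post_init__(self) -> None:
        # the two thresholds state the same rule on the 16,569-bp reference
        implied = (1.0 - self.min_completeness) * MT_LENGTH
        if abs(self.max_n - implied) > 0.02 * MT_LENGTH:
            raise ValueError("max_n and min_completeness are inconsistent")


def _n_count(seq: str) -> int:
    return sum(1 for b in seq if b.upper() not in _RESOLVED)


def completeness_filter(
    sequences: dict[str, str], policy: CurationPolicy | None = None
) -> tuple[dict[str, str], pd.DataFrame]:
    """Retain sequences with at most ``max_n`` unresolved positions.

    The boundary is inclusive: a sequence with exactly ``max_n`` Ns is kept
    ("more than max_n" excludes). Returns the retained set and an exclusion
    log (id, reason, n_count).
    """
    policy = policy or CurationPolicy()
    retained: dict[str, str] = {}
    log = []
    for sid, seq in sequences.items():
        nc = _n_count(seq)
        if nc <= policy.max_n:
            retained[sid] = seq
        else:
            log.append({"id": sid, "reason": "incomplete", "n_count": nc})
    return retained, pd.DataFrame(log, columns=["id", "reason", "n_count"])


def _pairwise_identical(a: str, b: str) -> bool:
    """True iff the sequences agree at every position resolved in both."""
    aa = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    bb = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    if len(aa) != len(bb):
        raise ValueError("sequences must share the coordinate system")
    res = np.isin(aa, np.frombuffer(b"ACGT", dtype=np.uint8))
    res &= np.isin(bb, np.frombuffer(b"ACGT", dtype=np.uint8))
    return bool((aa[res] == bb[res]).all())


def prune_duplicates(site: str, sequences: dict[str, str]) -> dict[str, str]:
    """Collapse within-site duplicates to one representative each.

    Two sequences are duplicates iff they show no variable site where both
    are resolved; duplicate classes are the transitive closure of that
    relation. The representative is the sequence with the fewest Ns (ties
    broken by lexicographically first id).
    """
    ids = sorted(sequences)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if _pairwise_identical(sequences[a], sequences[b]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    classes: dict[str, list[str]] = {}
    for sid in ids:
        classes.setdefault(find(sid), []).append(sid)
    out = {}
    for members in classes.values():
        rep = min(members, key=lambda s: (_n_count(sequences[s]), s))
        out[rep] = sequences[rep]
    return out


def _dloop_columns(bounds: tuple[tuple[int, int], ...], length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for lo, hi in bounds:
        mask[lo - 1 : hi] = True
    return mask


def extract_region(
    alignment: dict[str, str],
    region: str = "whole",
    dloop_bounds: tuple[tuple[int, int], ...] = DLOOP_BOUNDS,
) -> tuple[dict[str, str], np.ndarray]:
    """Whole alignment or the coding region (reference minus the D-loop).

    Returns the sub-alignment and the retained 1-based column positions,
    order preserved.
    """
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ValueError("alignment must be rectangular")
    length = lengths.pop() if lengths else 0
    if region == "whole":
        return dict(alignment), np.arange(1, length + 1)
    if region != "coding":
        raise ValueError(f"unknown region: {region!r}")
    drop = _dloop_columns(dloop_bounds, length)
    keep = np.flatnonzero(~drop)
    sub = {sid: "".join(seq[i] for i in keep) for sid, seq in alignment.items()}
    return sub, keep + 1


def site_deletion(
    alignment: dict[str, str], mode: str = "complete", p: float = 0.90
) -> tuple[dict[str, str], np.ndarray]:
    """Column filtering before tree building.

    ``complete``: keep only columns resolved (A/C/G/T) in every row.
    ``partial``: keep columns where the resolved-row fraction is >= ``p``
    (inclusive threshold, MEGA convention).
    Returns the filtered alignment and the kept 1-based column indices.
    """
    if mode not in ("complete", "partial"):
        raise ValueError(f"unknown deletion mode: {mode!r}")
    if mode == "partial" and not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if not alignment:
        return {}, np.array([], dtype=int)
    ids = list(alignment)
    mat = np.vstack(
        [np.frombuffer(alignment[i].upper().encode(), dtype=np.uint8) for i in ids]
    )
    resolved = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    frac = resolved.mean(axis=0)
    if mode == "complete":
        keep = np.flatnonzero(frac >= 1.0)
    else:
        keep = np.flatnonzero(frac >= p - 1e-12)
    out = {i: mat[r, keep].tobytes().decode() for r, i in enumerate(ids)}
    return out, keep + 1
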