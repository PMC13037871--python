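"""Damage-aware read processing and rule-based mtDNA consensus calling.

Ancient-DNA fragments carry cytosine-deamination damage that reads as C→T
mismatches near the 5' end (and, with single-stranded library chemistry,
G→A near the 3' end). This module implements the standard authentication
workflow for a contaminated ancient sample:

1. classify fragments as deaminated (damage within a terminal window);
2. gate the fragment set on a present-day contamination estimate — above
   the threshold only deaminated (authentically ancient) fragments are kept;
3. mask putatively deaminated positions (quality set to 0, excluding them
   from evidence) and trim low-quality fragment termini;
4. call a per-position consensus under a depth/agreement rule: a base is
   emitted only where at least ``min_depth`` independent (deduplicated)
   fragments cover the position and at least ``min_agreement`` of them agree.

Positions failing the rule are reported as N. All coordinates are 1-based
on a circular reference (default 16,569 bp).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import BASES, BASE_TO_INT, MT_LENGTH

_DAMAGE_PAIRS = {("C", "T"), ("G", "A")}


class UnprocessableSampleError(ValueError):
    """No fragments survive filtering; the sample cannot be processed."""


@dataclass
class AlignedFragment:
    """A sequenced fragment aligned to the circular reference.

    ``bases`` are stored in reference orientation (as in SAM); ``strand``
    records the sequencing orientation. ``mismatches`` holds
    (reference position, reference base, read base) triples.
    """

    read_id: str
    start: int  # 1-based reference position of the first base
    strand: str  # '+' or '-'
    bases: str
    quals: np.ndarray
    mismatches: list[tuple[int, str, str]] = field(default_factory=list)
    ref_length: int = MT_LENGTH

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int32)
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals must have equal length")
        if self.start < 1:
            raise ValueError("start must be a 1-based position")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.bases)

    def positions(self) -> np.ndarray:
        """1-based reference positions covered, wrapping the circle."""
        return (self.start - 1 + np.arange(len(self.bases))) % self.ref_length + 1

    def read_index(self, ref_pos: int) -> int:
        """Index within the fragment of a covered reference position."""
        off = (ref_pos - self.start) % self.ref_length
        if off >= len(self.bases):
            raise IndexError(f"position {ref_pos} not covered by {self.read_id}")
        return int(off)


@dataclass
class ConsensusPolicy:
    """Depth/agreement consensus rule with damage masking and end trimming."""

    min_depth: int = 3
    min_agreement: float = 0.65
    damage_window: int = 3
    trim_quality: int = 20
    trim_max: int = 3

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0 < self.min_agreement <= 1:
            raise ValueError("min_agreement must be in (0, 1]")


@dataclass
class ContaminationEstimate:
    """Externally estimated present-day contamination fraction."""

    point: float
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.lower is None:
            self.lower = self.point
        if self.upper is None:
            self.upper = self.point
        if not 0 <= self.lower <= self.point <= self.upper <= 1:
            raise ValueError("require 0 <= lower <= point <= upper <= 1")


@dataclass
class ConsensusSequence:
    """Per-position consensus calls over the full reference."""

    calls: str
    depth: np.ndarray

    @property
    def n_count(self) -> int:
        return self.calls.count("N")

    @property
    def completeness(self) -> float:
        return 1.0 - self.n_count / len(self.calls)

    def __len__(self) -> int:
        return len(self.calls)


def _damage_mismatch_indices(fragment: AlignedFragment) -> list[int]:
    """Read indices of C→T / G→A mismatches (strand-agnostic)."""
    out = []
    for pos, ref, read in fragment.mismatches:
        if (ref, read) in _DAMAGE_PAIRS:
            out.append(fragment.read_index(pos))
    return out


def classify_deaminated(fragment: AlignedFragment, window: int = 3) -> bool:
    """True iff a deamination-type mismatch lies within ``window`` positions
    of either fragment end.

    C→T and its strand complement G→A both count, at both termini, since
    single-stranded libraries present damage at both fragment ends.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(fragment)
    for idx in _damage_mismatch_indices(fragment):
        if idx < window or idx >= n - window:
            return True
    return False


def mask_and_trim(fragment: AlignedFragment, policy: ConsensusPolicy | None = None) -> AlignedFragment:
    """Set quality 0 at deamination-type mismatch positions, then trim up to
    ``trim_max`` consecutive sub-threshold-quality bases from each end.

    Quality-0 bases are excluded from consensus evidence downstream; trimming
    removes at most ``trim_max`` positions per end even if more are low
    quality.
    """
    policy = policy or ConsensusPolicy()
    quals = fragment.quals.copy()
    for idx in _damage_mismatch_indices(fragment):
        quals[idx] = 0

    n = len(fragment)
    left = 0
    while left < min(policy.trim_max, n) and quals[left] < policy.trim_quality:
        left += 1
    right = 0
    while right < min(policy.trim_max, n - left) and quals[n - 1 - right] < policy.trim_quality:
        right += 1

    new_start = (fragment.start - 1 + left) % fragment.ref_length + 1
    bases = fragment.bases[left : n - right]
    quals = quals[left : n - right]
    kept = []
    for pos, ref, read in fragment.mismatches:
        off = (pos - new_start) % fragment.ref_length
        if off < len(bases):
            kept.append((pos, ref, read))
    return dataclasses.replace(
        fragment, start=new_start, bases=bases, quals=quals, mismatches=kept
    )


def contamination_gate(
    estimate: ContaminationEstimate,
    fragments: list[AlignedFragment],
    threshold: float = 0.10,
    window: int = 3,
) -> tuple[str, list[AlignedFragment]]:
    """Decide the processing path from a contamination estimate.

    At or below ``threshold`` all fragments pass ("all_reads"); strictly
    above it only fragments classified as deaminated are retained
    ("deaminated_only"). An empty post-gate set raises
    :class:`UnprocessableSampleError`.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if estimate.point <= threshold:
        return "all_reads", list(fragments)
    kept = [f for f in fragments if classify_deaminated(f, window)]
    if not kept:
        raise UnprocessableSampleError(
            "no deaminated fragments remain after contamination gating"
        )
    return "deaminated_only", kept


def dedup_fragments(fragments: list[AlignedFragment]) -> list[AlignedFragment]:
    """Keep one fragment per (start, length, strand) class (PCR duplicates)."""
    seen: set[tuple[int, int, str]] = set()
    out = []
    for f in fragments:
        key = (f.start, len(f), f.strand)
        if key not in seen:
            seen.add(key)
            out.append(f)
    return out


def call_consensus(
    fragments: list[AlignedFragment],
    policy: ConsensusPolicy | None = None,
    ref_length: int = MT_LENGTH,
    deduplicate: bool = True,
) -> ConsensusSequence:
    """Tally deduplicated fragment evidence and emit the consensus.

    At each reference position the modal base is called iff coverage by
    fragments with non-zero quality reaches ``min_depth``, the modal
    fraction reaches ``min_agreement``, and the mode is unique; otherwise N.
    """
    policy = policy or ConsensusPolicy()
    if deduplicate:
        fragments = dedup_fragments(fragments)

    counts = np.zeros((4, ref_length), dtype=np.int64)
    if fragments:
        pos_chunks, base_chunks = [], []
        for f in fragments:
            codes = np.frombuffer(f.bases.encode(), dtype=np.uint8)
            base_idx = np.full(len(codes), -1, dtype=np.int8)
            for b, i in BASE_TO_INT.items():
                base_idx[codes == ord(b)] = i
            ok = (base_idx >= 0) & (f.quals > 0)
            if ok.any():
                pos_chunks.append(f.positions()[ok] - 1)
                base_chunks.append(base_idx[ok])
        if pos_chunks:
            pos = np.concatenate(pos_chunks)
            idx = np.concatenate(base_chunks).astype(np.int64)
            np.add.at(counts, (idx, pos), 1)

    depth = counts.sum(axis=0)
    top = counts.max(axis=0)
    unique_mode = (counts == top).sum(axis=0) == 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, top / np.maximum(depth, 1), 0.0)
    called = (depth >= policy.min_depth) & (frac >= policy.min_agreement - 1e-12) & unique_mode

    calls = np.full(ref_length, "N", dtype="<U1")
    modal = np.asarray(list(BASES))[counts.argmax(axis=0)]
    calls[called] = modal[called]
    return ConsensusSequence(calls="".join(calls), depth=depth)


def process_sample(
    fragments: list[AlignedFragment],
    estimate: ContaminationEstimate,
    policy: ConsensusPolicy | None = None,
    threshold: float = 0.10,
    ref_length: int = MT_LENGTH,
) -> tuple[ConsensusSequence, dict]:
    """Full per-sample workflow: gate → mask/trim → consensus, with a QC dict."""
    policy = policy or ConsensusPolicy()
    n_deam = sum(classify_deaminated(f, policy.damage_window) for f in fragments)
    decision, kept = contamination_gate(estimate, fragments, threshold, policy.damage_window)
    processed = [mask_and_trim(f, policy) for f in kept]
    processed = [f for f in processed if len(f) > 0]
    cons = call_consensus(processed, policy, ref_length=ref_length)
    qc = {
        "n_fragments_in": len(fragments),
        "deaminated_fraction": n_deam / len(fragments) if fragments else 0.0,
        "contamination_point": estimate.point,
        "gate_decision": decision,
        "n_fragments_used": len(processed),
        "n_count": cons.n_count,
        "completeness": cons.completeness,
        "mean_depth": float(cons.depth.mean()),
    }
    return cons, qc


def read_sam(path: str, reference: str) -> list[AlignedFragment]:
    """Thin reader for pre-aligned single-end SAM records.

    Mismatches are recomputed against ``reference`` over aligned (non-indel)
    pairs. Unmapped and secondary records are skipped.
    """
    import pysam

    frags = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.query_sequence
            quals = rec.query_qualities
            if seq is None or quals is None:
                continue
            mism = []
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                rb = reference[rpos].upper()
                qb = seq[qpos].upper()
                if rb != qb:
                    mism.append((rpos + 1, rb, qb))
            frags.append(
                AlignedFragment(
                    read_id=rec.query_name,
                    start=rec.reference_start + 1,
                    strand="-" if rec.is_reverse else "+",
                    bases=seq.upper(),
                    quals=np.asarray(quals, dtype=np.int32),
                    mismatches=mism,
                    ref_length=len(reference),
                )
            )
    return frags


def depth_table(consensus: ConsensusSequence) -> pd.DataFrame:
    """Per-position depth table (1-based positions)."""
    return pd.DataFrame(
        {
            "position": np.arange(1, len(consensus) + 1),
            "depth": consensus.depth,
            "call": list(consensus.calls),
        }
    )
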