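"""Synthetic data with the statistical structure the pipeline assumes.

Generators for (i) serially sampled coalescent time trees, (ii) sequence
evolution under JC69 or TN93 with a fraction of invariant sites and a strict
molecular clock, (iii) short ancient-DNA fragments with terminal
cytosine-deamination damage and present-day contaminant reads, and (iv)
dated archaeological locality tables with controllable longitudinal spread.

Every generator is a pure function of its parameters and a seed: identical
inputs give identical outputs, so downstream stages are testable against
recorded truth without any external data.

Conventions
-----------
* ``ClockModel.rate`` is the substitution rate (subs/bp/year) at *variable*
  sites; a fraction ``invariant_fraction`` of sites never substitutes, so the
  realized genome-wide rate is ``rate * (1 - invariant_fraction)``.
* Tip ages are calendar years before present (positive into the past);
  branch lengths of simulated time trees are in years.
* Fragment damage follows single-stranded library chemistry: C→T miscoding
  decaying geometrically from the 5' end and the mirrored G→A from the 3'
  end. In reference orientation both strands therefore show C→T decaying
  from the left fragment end and G→A decaying from the right end.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg

from .consensus import AlignedFragment
from .reference import BASES, COMPLEMENT

_BASE_ARR = np.frombuffer("ACGT".encode(), dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ClockModel:
    """Strict-clock substitution model (JC69 or TN93 + invariant sites).

    ``kappa1`` is the A<->G and ``kappa2`` the C<->T transition/transversion
    rate ratio; both are ignored under JC69.
    """

    rate: float = 1.57e-8
    model: str = "TN93"
    invariant_fraction: float = 0.0
    kappa1: float = 4.0
    kappa2: float = 8.0
    base_freqs: tuple[float, float, float, float] = (0.31, 0.31, 0.13, 0.25)

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if not 0 <= self.invariant_fraction < 1:
            raise ValueError("invariant_fraction must be in [0, 1)")
        if self.model not in ("JC69", "TN93"):
            raise ValueError("model must be JC69 or TN93")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")

    def freqs(self) -> np.ndarray:
        if self.model == "JC69":
            return np.full(4, 0.25)
        return np.asarray(self.base_freqs, dtype=float)

    def rate_matrix(self) -> np.ndarray:
        """Instantaneous rate matrix normalized to 1 substitution/site/unit."""
        pi = self.freqs()
        k1 = k2 = 1.0
        if self.model == "TN93":
            k1, k2 = self.kappa1, self.kappa2
        q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                k = 1.0
                if {i, j} == {_A, _G}:
                    k = k1
                elif {i, j} == {_C, _T}:
                    k = k2
                q[i, j] = k * pi[j]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def transition_matrix(self, subs_per_site: float) -> np.ndarray:
        p = scipy.linalg.expm(self.rate_matrix() * subs_per_site)
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)


@dataclass
class DamageProfile:
    """Fragmentation, deamination, contamination and coverage parameters."""

    p_ct_5p: float = 0.30  # terminal 5' C->T probability (observed range 0.10-0.58)
    decay: float = 0.5  # geometric decay of damage probability into the read
    frag_len_mean: float = 60.0
    frag_len_sd: float = 15.0
    contamination_frac: float = 0.0
    coverage: float = 20.0
    quality_base: int = 40
    quality_damaged: int = 40

    def __post_init__(self) -> None:
        if not 0 <= self.p_ct_5p <= 1:
            raise ValueError("p_ct_5p must be in [0, 1]")
        if not 0 < self.decay <= 1:
            raise ValueError("decay must be in (0, 1]")
        if not 0 <= self.contamination_frac <= 1:
            raise ValueError("contamination_frac must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


@dataclass
class SliceSpec:
    """Locality counts and longitude distribution for one time slice."""

    start_ka: float
    end_ka: float
    n: int
    lon_center: float = 10.0
    lon_width: float = 40.0
    n_clusters: int = 0  # 0/1 -> uniform on the interval
    cluster_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("counts must be >= 0")
        if self.lon_width <= 0:
            raise ValueError("widths must be > 0")
        if self.start_ka <= self.end_ka:
            raise ValueError("start_ka must exceed end_ka")


@dataclass
class SpreadScenario:
    """A stack of time slices with a latitude band and date-range widths."""

    slices: list[SliceSpec]
    lat_band: tuple[float, float] = (36.0, 52.0)
    date_width_max_ky: float = 6.0

    def __post_init__(self) -> None:
        if self.date_width_max_ky <= 0:
            raise ValueError("widths must be > 0")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def simulate_tree(
    n_tips: int,
    tip_age_range: tuple[float, float],
    seed: int,
    pop_size: float = 50_000.0,
) -> dendropy.Tree:
    """Serial-sample coalescent tree with constant population-size parameter.

    Tip ages (years BP) are uniform on ``tip_age_range``; lineages enter the
    coalescent at their sampling age and pairs merge at rate k(k-1)/(2N)
    with N = ``pop_size`` in years. Branch lengths are years; every node
    carries an ``age`` attribute and tips are labelled ``t1..tn``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    lo, hi = tip_age_range
    if lo < 0 or hi < lo:
        raise ValueError("invalid tip_age_range")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(lo, hi, n_tips)

    tns = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_tips)])
    nodes = []
    for i in range(n_tips):
        nd = dendropy.Node(taxon=tns.get_taxon(f"t{i + 1}"))
        nd.age = float(ages[i])
        nodes.append(nd)

    pending = sorted(nodes, key=lambda nd: nd.age)
    active: list[dendropy.Node] = []
    t = pending[0].age
    while pending or len(active) > 1:
        if len(active) < 2:
            nxt = pending.pop(0)
            t = max(t, nxt.age)
            active.append(nxt)
            continue
        k = len(active)
        wait = rng.exponential(2.0 * pop_size / (k * (k - 1)))
        if pending and t + wait > pending[0].age:
            nxt = pending.pop(0)
            t = nxt.age
            active.append(nxt)
            continue
        t = t + wait
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        parent.age = t
        parent.add_child(active[i])
        parent.add_child(active[j])
        active = [nd for idx, nd in enumerate(active) if idx not in (i, j)]
        active.append(parent)

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = active[0]
    tree.is_rooted = True
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = nd.parent_node.age - nd.age
    label_nodes(tree)
    return tree


def add_outgroup(
    tree: dendropy.Tree, name: str = "outgroup", stem_fraction: float = 1.0
) -> dendropy.Tree:
    """Re-root the tree with an external outgroup tip.

    A new root is placed above the old one at ``(1 + stem_fraction) *
    root_age``; the outgroup branches from it down to age 0. This mirrors the
    usual practice of rooting an ingroup phylogeny with a distant reference
    sequence, and gives diagnostic-SNP polarisation a tip that is ancestral
    to the whole ingroup.
    """
    old_root = tree.seed_node
    new_age = old_root.age * (1.0 + stem_fraction)
    taxon = tree.taxon_namespace.new_taxon(name)
    out_tip = dendropy.Node(taxon=taxon)
    out_tip.age = 0.0
    new_root = dendropy.Node()
    new_root.age = new_age
    new_root.add_child(old_root)
    new_root.add_child(out_tip)
    tree.seed_node = new_root
    old_root.edge.length = new_age - old_root.age
    out_tip.edge.length = new_age
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf():
            nd.label = None
    label_nodes(tree)
    return tree


def label_nodes(tree: dendropy.Tree) -> None:
    """Give every node a stable label: taxon label for tips, node{i} preorder
    for unlabelled internal nodes."""
    i = 0
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            nd.label = nd.taxon.label if nd.taxon else nd.label
        elif not nd.label:
            nd.label = f"node{i}"
            i += 1


def tip_ages(tree: dendropy.Tree) -> dict[str, float]:
    return {leaf.taxon.label: float(leaf.age) for leaf in tree.leaf_node_iter()}


def write_newick(tree: dendropy.Tree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree))


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=False, real_value_format_specifier=".6f"
    )


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSequences:
    """Alignment plus full simulation bookkeeping (truth for the oracles)."""

    alignment: dict[str, str]  # tip label -> sequence
    node_sequences: dict[str, str]  # every node label -> sequence
    subs_per_branch: dict[str, int]  # child node label -> realized changes
    invariant_mask: np.ndarray
    length: int

    @property
    def total_substitutions(self) -> int:
        return int(sum(self.subs_per_branch.values()))


def evolve_sequences(
    tree: dendropy.Tree,
    clock: ClockModel,
    length: int,
    seed: int,
) -> SimulatedSequences:
    """Evolve sequences down a time tree under the clock model.

    Substitutions occur only at non-invariant sites; per-branch expected
    divergence at those sites is ``clock.rate * branch_length_years``.
    Returns tip sequences and the per-node / per-branch truth used by
    placement- and clock-recovery oracles.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    label_nodes(tree)
    rng = np.random.default_rng(seed)
    pi = clock.freqs()
    root_seq = rng.choice(4, size=length, p=pi).astype(np.int8)
    invariant = rng.random(length) < clock.invariant_fraction
    var_idx = np.flatnonzero(~invariant)

    # eigendecomposition once; P(t) = U diag(exp(lam t)) U^-1
    q = clock.rate_matrix()
    lam, u = np.linalg.eig(q)
    uinv = np.linalg.inv(u)

    def pmat(d: float) -> np.ndarray:
        p = (u * np.exp(lam * d)) @ uinv
        p = np.clip(p.real, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)

    node_seqs: dict[str, np.ndarray] = {}
    subs: dict[str, int] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            node_seqs[nd.label] = root_seq
            continue
        parent = node_seqs[nd.parent_node.label]
        child = parent.copy()
        bl = nd.edge.length or 0.0
        d = clock.rate * bl
        if d > 0 and len(var_idx):
            p = pmat(d)
            cum = np.cumsum(p, axis=1)
            cum[:, -1] = 1.0
            pv = parent[var_idx]
            drawn = np.empty(len(var_idx), dtype=np.int8)
            uu = rng.random(len(var_idx))
            for b in range(4):
                sel = pv == b
                if sel.any():
                    drawn[sel] = np.searchsorted(cum[b], uu[sel], side="right")
            child[var_idx] = np.clip(drawn, 0, 3)
        subs[nd.label] = int((child != parent).sum())
        node_seqs[nd.label] = child

    def decode(arr: np.ndarray) -> str:
        return _BASE_ARR[arr].tobytes().decode()

    alignment = {
        leaf.taxon.label: decode(node_seqs[leaf.label]) for leaf in tree.leaf_node_iter()
    }
    return SimulatedSequences(
        alignment=alignment,
        node_sequences={k: decode(v) for k, v in node_seqs.items()},
        subs_per_branch=subs,
        invariant_mask=invariant,
        length=length,
    )


def realized_substitution_tree(
    tree: dendropy.Tree, sim: SimulatedSequences
) -> dendropy.Tree:
    """Clone of the time tree with branch lengths in realized subs/bp."""
    clone = tree.clone(depth=1)
    label_nodes(clone)
    for nd in clone.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = sim.subs_per_branch[nd.label] / sim.length
    return clone


# ---------------------------------------------------------------------------
# fragments and damage
# ---------------------------------------------------------------------------


@dataclass
class FragmentSimulation:
    fragments: list[AlignedFragment]
    truth: pd.DataFrame  # read_id, origin, n_damage, start, length, strand


def fragment_and_damage(
    genome: str,
    profile: DamageProfile,
    contaminant: str | None = None,
    seed: int = 0,
) -> FragmentSimulation:
    """Shear a genome into aligned fragments with terminal deamination.

    Endogenous fragments get C→T miscoding with probability
    ``p_ct_5p * decay**i`` at distance *i* from the left end and the mirrored
    G→A from the right end; contaminant fragments (drawn with probability
    ``contamination_frac``) are faithful substrings of ``contaminant`` and
    carry no damage. Mismatch annotations are relative to ``genome``.
    """
    if not genome:
        raise ValueError("genome must be non-empty")
    L = len(genome)
    if L <= profile.frag_len_mean:
        raise ValueError("genome length must exceed frag_len_mean")
    if profile.contamination_frac > 0 and contaminant is None:
        raise ValueError("contaminant genome required when contamination_frac > 0")

    rng = np.random.default_rng(seed)
    g = np.frombuffer(genome.upper().encode(), dtype=np.uint8)
    genome_codes = np.searchsorted(np.sort(_BASE_ARR), g)  # ACGT are sorted already
    contam_codes = None
    if contaminant is not None:
        if len(contaminant) != L:
            raise ValueError("contaminant must be aligned to the same coordinates")
        c = np.frombuffer(contaminant.upper().encode(), dtype=np.uint8)
        contam_codes = np.searchsorted(np.sort(_BASE_ARR), c)

    n_frags = max(1, round(profile.coverage * L / profile.frag_len_mean))
    sigma2 = np.log1p(profile.frag_len_sd**2 / profile.frag_len_mean**2)
    mu = np.log(profile.frag_len_mean) - sigma2 / 2
    lengths = np.exp(rng.normal(mu, np.sqrt(sigma2), n_frags))
    lengths = np.clip(np.round(lengths).astype(int), 5, L)
    starts = rng.integers(0, L, n_frags)
    contam = (
        rng.random(n_frags) < profile.contamination_frac
        if contaminant is not None
        else np.zeros(n_frags, dtype=bool)
    )
    strands = np.where(rng.random(n_frags) < 0.5, "+", "-")

    fragments = []
    rows = []
    for i in range(n_frags):
        ln = int(lengths[i])
        idx = (int(starts[i]) + np.arange(ln)) % L
        src = contam_codes if contam[i] else genome_codes
        bases = src[idx].copy()
        n_damage = 0
        quals = np.full(ln, profile.quality_base, dtype=np.int32)
        if not contam[i] and profile.p_ct_5p > 0:
            p_left = profile.p_ct_5p * profile.decay ** np.arange(ln)
            ct = (bases == _C) & (rng.random(ln) < p_left)
            ga = (bases == _G) & (rng.random(ln) < p_left[::-1])
            bases[ct] = _T
            bases[ga] = _A
            damaged = ct | ga
            n_damage = int(damaged.sum())
            quals[damaged] = profile.quality_damaged
        ref_slice = genome_codes[idx]
        mm_at = np.flatnonzero(bases != ref_slice)
        mismatches = [
            (int(idx[k]) + 1, BASES[ref_slice[k]], BASES[bases[k]]) for k in mm_at
        ]
        read_id = f"frag{i:06d}"
        fragments.append(
            AlignedFragment(
                read_id=read_id,
                start=int(starts[i]) + 1,
                strand=str(strands[i]),
                bases=_BASE_ARR[bases].tobytes().decode(),
                quals=quals,
                mismatches=mismatches,
                ref_length=L,
            )
        )
        rows.append(
            {
                "read_id": read_id,
                "origin": "contaminant" if contam[i] else "endogenous",
                "n_damage": n_damage,
                "start": int(starts[i]) + 1,
                "length": ln,
                "strand": str(strands[i]),
            }
        )
    return FragmentSimulation(fragments=fragments, truth=pd.DataFrame(rows))


def random_genome(length: int, seed: int, freqs: tuple[float, ...] = (0.25,) * 4) -> str:
    rng = np.random.default_rng(seed)
    return _BASE_ARR[rng.choice(4, size=length, p=freqs)].tobytes().decode()


def mutated_copy(genome: str, n_subs: int, seed: int) -> str:
    """Copy of ``genome`` with ``n_subs`` random substitutions (distinct sites)."""
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.encode(), dtype=np.uint8).copy()
    sites = rng.choice(len(genome), size=n_subs, replace=False)
    for s in sites:
        cur = chr(arr[s])
        alts = [b for b in BASES if b != cur]
        arr[s] = ord(alts[rng.integers(3)])
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# localities
# ---------------------------------------------------------------------------


def simulate_localities(scenario: SpreadScenario, seed: int) -> pd.DataFrame:
    """Dated locality table (site_id, longitude, latitude, date_min_ka,
    date_max_ka) realizing the scenario's per-slice counts and spreads.

    Date ranges are drawn strictly inside their slice window so slice
    membership under the overlap rule reproduces the scenario exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for si, sl in enumerate(scenario.slices):
        half = sl.lon_width / 2.0
        lo, hi = sl.lon_center - half, sl.lon_center + half
        if sl.n_clusters and sl.n_clusters > 1:
            centers = rng.uniform(lo, hi, sl.n_clusters)
            which = rng.integers(0, sl.n_clusters, sl.n)
            lons = rng.normal(centers[which], sl.cluster_sd)
            lons = np.clip(lons, lo, hi)
        else:
            lons = rng.uniform(lo, hi, sl.n)
        lats = rng.uniform(scenario.lat_band[0], scenario.lat_band[1], sl.n)
        width = sl.start_ka - sl.end_ka
        w = rng.uniform(0, min(scenario.date_width_max_ky, 0.99 * width), sl.n)
        mid = rng.uniform(sl.end_ka + w / 2 + 0.005 * width, sl.start_ka - w / 2 - 0.005 * width)
        for i in range(sl.n):
            rows.append(
                {
                    "site_id": f"s{si}_{i:04d}",
                    "longitude": float(lons[i]),
                    "latitude": float(lats[i]),
                    "date_min_ka": float(mid[i] - w[i] / 2),
                    "date_max_ka": float(mid[i] + w[i] / 2),
                }
            )
    return pd.DataFrame(rows, columns=["site_id", "longitude", "latitude", "date_min_ka", "date_max_ka"])


# ---------------------------------------------------------------------------
# plain-text writers / readers
# ---------------------------------------------------------------------------


def write_alignment_fasta(seqs: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_alignment_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fragments_tsv(fragments: list[AlignedFragment], path: str) -> None:
    """Tab-separated pileup-ready fragments: read_id, start (1-based), strand,
    sequence (reference orientation), phred+33 quality string."""
    with open(path, "w") as fh:
        fh.write("read_id\tstart\tstrand\tsequence\tquality\n")
        for f in fragments:
            q = "".join(chr(int(x) + 33) for x in f.quals)
            fh.write(f"{f.read_id}\t{f.start}\t{f.strand}\t{f.bases}\t{q}\n")


def read_fragments_tsv(path: str, reference: str) -> list[AlignedFragment]:
    """Load fragments and recompute mismatch annotations vs ``reference``."""
    L = len(reference)
    frags = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError("missing fragment TSV header")
        for line in fh:
            read_id, start, strand, seq, q = line.rstrip("\n").split("\t")
            start = int(start)
            quals = np.frombuffer(q.encode(), dtype=np.uint8).astype(np.int32) - 33
            mism = []
            for k, b in enumerate(seq):
                pos = (start - 1 + k) % L
                rb = reference[pos].upper()
                if b != rb:
                    mism.append((pos + 1, rb, b))
            frags.append(
                AlignedFragment(
                    read_id=read_id,
                    start=start,
                    strand=strand,
                    bases=seq,
                    quals=quals,
                    mismatches=mism,
                    ref_length=L,
                )
            )
    return frags


def write_fastq(fragments: list[AlignedFragment], path: str) -> None:
    """Unaligned FASTQ; minus-strand fragments are reverse-complemented back
    to sequencing orientation."""
    with open(path, "w") as fh:
        for f in fragments:
            seq, quals = f.bases, f.quals
            if f.strand == "-":
                seq = seq.translate(COMPLEMENT)[::-1]
                quals = quals[::-1]
            q = "".join(chr(int(x) + 33) for x in quals)
            fh.write(f"@{f.read_id}\n{seq}\n+\n{q}\n")
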