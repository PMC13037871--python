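import numpy as np
import pytest

from paleomt.placement import node_defining_snps
from paleomt.simulate import (
    ClockModel,
    add_outgroup,
    evolve_sequences,
    simulate_tree,
)


@pytest.fixture(scope="session")
def reference_panel():
    """A 12-tip serial-coalescent reference set with an external outgroup,
    evolved deeply enough that every internal node carries a useful number
    of diagnostic SNPs, plus its node-defining SNP table."""
    tree = simulate_tree(12, (0, 40_000), seed=21, pop_size=60_000)
    add_outgroup(tree)
    clock = ClockModel(
        rate=2e-7, model="TN93", kappa1=2.0, kappa2=2.0, base_freqs=(0.25,) * 4
    )
    sim = evolve_sequences(tree, clock, 16_000, seed=22)
    table = node_defining_snps(sim.alignment, tree, outgroup="outgroup")
    return tree, sim, table


@pytest.fixture(scope="session")
def parent_map(reference_panel):
    tree, _, _ = reference_panel
    parents = {}
    for nd in tree.preorder_node_iter():
        for ch in nd.child_nodes():
            parents[ch.label] = nd.label
    return parents


def lineal_ancestors(label: str, parents: dict[str, str]) -> list[str]:
    out = []
    while label in parents:
        label = parents[label]
        out.append(label)
    return out


def random_pileup(rng, ref_length=80, max_fragments=50):
    """Random small fragment pileup for consensus-oracle checks."""
    from paleomt.consensus import AlignedFragment

    n = int(rng.integers(1, max_fragments + 1))
    frags = []
    for i in range(n):
        ln = int(rng.integers(5, min(40, ref_length)))
        start = int(rng.integers(1, ref_length + 1))
        bases = "".join(rng.choice(list("ACGT"), ln))
        quals = rng.choice([0, 10, 40], size=ln, p=[0.1, 0.2, 0.7])
        frags.append(
            AlignedFragment(
                read_id=f"r{i}",
                start=start,
                strand="+" if rng.random() < 0.5 else "-",
                bases=bases,
                quals=quals.astype(np.int32),
                ref_length=ref_length,
            )
        )
    return frags
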