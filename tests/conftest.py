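"""Shared fixtures: small synthetic genomes and a planted hotspot sister pair."""

import numpy as np
import pytest

from sisterscan.genomeio import Feature, GenomeRecord
from sisterscan.simulate import MutationSpec, derive_sisters, simulate_ancestor


@pytest.fixture(scope="session")
def ancestor():
    return simulate_ancestor(n_genes=60, seed=1)


def hotspot_spec(anc, seed=7, **overrides):
    """Mutation spec mirroring the selection-hotspot observation: one dense
    region at 70 SNPs / 67 non-synonymous around the anchor gene, one
    background region at 25 SNPs / 7 non-synonymous."""
    rdhA = anc.get("rdhA1")
    hot = (max(0, rdhA.start - 6000), min(len(anc), rdhA.end + 6000))
    bg = (0, 30_000) if hot[0] > 35_000 else (len(anc) - 30_000, len(anc))
    kwargs = dict(
        regions={"hotspot": hot, "background": bg},
        n_snps_by_region={"hotspot": (70, 67 / 70), "background": (25, 7 / 25)},
        seed=seed,
    )
    kwargs.update(overrides)
    return MutationSpec(**kwargs)


@pytest.fixture(scope="session")
def hotspot_pair(ancestor):
    spec = hotspot_spec(ancestor)
    A, B, truth = derive_sisters(ancestor, spec)
    return A, B, truth, spec


@pytest.fixture()
def toy_cds_genome():
    """Single-CDS genome for hand-checkable codon arithmetic.

    Forward CDS at [10, 31): ATG AAA TGG CCC GAA TAA; padding is all-T so
    any SNP outside the CDS is intergenic.
    """
    cds = "ATGAAATGGCCCGAATAA"
    seq = "T" * 10 + cds + "T" * 10
    feat = Feature("cds1", "CDS", 10, 10 + len(cds), "+", "toy protein")
    return GenomeRecord("toy", seq, "linear", [feat])


def random_dna(rng, n, p=None):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)]) if p is None else \
        "".join(rng.choice(np.array(list("ACGT")), n, p=p))
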