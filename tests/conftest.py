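import numpy as np
import pytest

from otscan.assign import GuideRNA
from otscan.io import AlignedRead
from otscan.sim import PlantSpec, SimConfig, simulate_genome_with_targets, \
    simulate_ots_reads


@pytest.fixture(scope="session")
def guides():
    return [
        GuideRNA(name="gA", spacer="ACGTACGTACGTACGTACGT"),
        GuideRNA(name="gB", spacer="TTGACCTGAATCGGATCCAA"),
        GuideRNA(name="gC", spacer="GGCATTAACCGGTTAACGTC"),
    ]


@pytest.fixture(scope="session")
def sim_bundle(guides):
    """One deterministic enrichment run with four planted sites of mixed
    mismatch make-up, shared across tests."""
    specs = [
        PlantSpec(guide="gA", position=50_000, cleavage_efficiency=0.9),
        PlantSpec(guide="gB", position=120_000, n_subs=5,
                  cleavage_efficiency=0.8),
        PlantSpec(guide="gA", position=200_000, n_subs=2, strand="-",
                  cleavage_efficiency=0.8),
        PlantSpec(guide="gC", position=250_000, n_subs=1, n_ins=1,
                  cleavage_efficiency=0.7),
    ]
    config = SimConfig()
    ref, planted = simulate_genome_with_targets(config, guides, specs, seed=101)
    reads, truth = simulate_ots_reads(ref, planted, config, seed=102)
    return {"config": config, "ref": ref, "planted": planted,
            "reads": reads, "truth": truth, "guides": guides}


def make_read(start, end, read_id=None, contig="c1", indels=(), **kw):
    return AlignedRead(read_id=read_id or f"r{start}_{end}", contig=contig,
                       ref_start=start, ref_end=end,
                       cigar_indels=tuple(indels), **kw)
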