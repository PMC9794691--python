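"""Shared fixtures: small synthetic studies generated at test time."""

import pytest

from persisterlab import growth_sim, omics_sim
from persisterlab.differential import ModeratedLinearModel


@pytest.fixture(scope="session")
def default_screen():
    """The default simulated combination screen: 20 compounds (5 strong
    persister killers), 3 cell lines, 3 replicates."""
    panel = growth_sim.default_panel(20, 5, seed=0)
    traces, truth = growth_sim.simulate_screen(
        panel, ["L1", "L2", "L3"], replicates=3, seed=1)
    return panel, traces, truth


@pytest.fixture(scope="session")
def small_genome():
    return omics_sim.make_genome(n_chrom=2, n_genes=200, n_elements=300, seed=1)


@pytest.fixture(scope="session")
def study(small_genome):
    """A full small multi-omics study: RNA counts, peak calls and counts,
    with planted effects and truth."""
    design = omics_sim.DesignMatrixSpec(cell_lines=("A", "B", "C"), replicates=3)
    effects = omics_sim.make_effects(small_genome, n_diff=100, seed=2)
    counts, samples = omics_sim.simulate_counts(small_genome, design, effects, seed=3)
    peak_effects = omics_sim.make_peak_effects(small_genome, effects,
                                               n_peaks=500, seed=4)
    calls, peak_counts, peak_samples = omics_sim.simulate_peaks(
        small_genome, design, peak_effects, seed=5)
    return {
        "genome": small_genome,
        "design": design,
        "effects": effects,
        "counts": counts,
        "samples": samples,
        "peak_effects": peak_effects,
        "calls": calls,
        "peak_counts": peak_counts,
        "peak_samples": peak_samples,
    }


@pytest.fixture(scope="session")
def rna_fit(study):
    model = ModeratedLinearModel.from_counts(study["counts"], study["samples"])
    return model.fit({"DTP_vs_DMSO": "DTP - DMSO",
                      "acute_vs_DMSO": "acute - DMSO"})
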