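"""Shared fixtures: one session-scoped synthetic MA experiment."""
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from mamut import calling, synth


@dataclass
class Experiment:
    genome: synth.SyntheticGenome
    truth: synth.TruthSet
    probes: list
    callset: object
    mask: calling.CallableMask
    result: calling.CallResult
    snms: list          # accepted SNMs excluding spike-in probes
    probe_keys: set


@pytest.fixture(scope="session")
def genome():
    return synth.generate_genome(2, [200_000, 100_000], 0.66,
                                 repeat_density=0.2, seed=5)


@pytest.fixture(scope="session")
def experiment(genome):
    """Noiseless 26-line experiment with default spectrum/context boosts."""
    truth = synth.simulate_ma_experiment(
        genome, n_lines=26, t=788.0, base_mu=4.2e-7, seed=6)
    probes = synth.spike_in_probes(genome)
    callset = synth.emit_call_records(genome, truth, seed=7, probes=probes)
    mask = calling.build_callable_mask(callset)
    result = calling.call_candidate_mutations(callset, mask)
    probe_keys = {(p.contig, p.pos) for p in probes}
    snms = [m for m in result.accepted
            if m.kind == "SNM" and (m.contig, m.pos) not in probe_keys]
    return Experiment(genome=genome, truth=truth, probes=probes,
                      callset=callset, mask=mask, result=result,
                      snms=snms, probe_keys=probe_keys)


@pytest.fixture(scope="session")
def mutation_features(experiment):
    """Context features for accepted SNM sites plus random callable sites."""
    from mamut import seqcontext
    from mamut.pipeline import _random_callable_sites

    exp = experiment
    mut_sites = pd.DataFrame({"contig": [m.contig for m in exp.snms],
                              "pos": [m.pos for m in exp.snms]})
    rng = np.random.default_rng(11)
    rand_sites = _random_callable_sites(
        rng, exp.mask, 3000, set(zip(mut_sites["contig"],
                                     mut_sites["pos"])))
    sites = pd.concat([mut_sites, rand_sites], ignore_index=True)
    feats = seqcontext.context_features(exp.genome, sites)
    labels = np.r_[np.ones(len(mut_sites)), np.zeros(len(rand_sites))]
    return feats, labels
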