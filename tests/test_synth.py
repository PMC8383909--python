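"""Synthetic-data generator: genome, MA simulation, call emission, probes."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mamut import calling, synth
from mamut.spectrum import FOLDED_TYPES, spectrum_counts
from mamut.types import Mutation


class TestGenerateGenome:
    def test_gc_within_band(self):
        g = synth.generate_genome(1, [100_000], 0.66, 0.0, seed=1)
        assert 0.64 <= g.gc() <= 0.68
        assert set(g.sequence("contig_1")) <= set("ACGT")

    def test_gc_zero_limit_gives_at_only(self):
        g = synth.generate_genome(1, [1000], 0.0, 0.0, seed=1)
        assert set(g.sequence("contig_1")) <= set("AT")

    def test_deterministic_for_fixed_seed(self):
        a = synth.generate_genome(2, [5000, 3000], 0.6, 0.1, seed=9)
        b = synth.generate_genome(2, [5000, 3000], 0.6, 0.1, seed=9)
        assert [c.seq for c in a.contigs] == [c.seq for c in b.contigs]
        assert a.annotation.equals(b.annotation)
        c = synth.generate_genome(2, [5000, 3000], 0.6, 0.1, seed=10)
        assert [x.seq for x in a.contigs] != [x.seq for x in c.contigs]

    def test_repeat_density_realized(self):
        g = synth.generate_genome(2, [50_000, 50_000], 0.66, 0.3, seed=7)
        # independent interval sum over merged repeat blocks
        covered = 0
        for contig, grp in g.repeats.groupby("contig"):
            iv = sorted(zip(grp["start"], grp["end"]))
            last_end = -1
            for s, e in iv:
                covered += max(0, e - max(s, last_end))
                last_end = max(last_end, e)
        assert covered / g.total_length >= 0.25

    def test_annotation_within_bounds(self):
        g = synth.generate_genome(1, [30_000], 0.5, 0.1, seed=3)
        ann = g.annotation
        assert (ann["start"] >= 0).all()
        assert (ann["end"] <= 30_000).all()
        assert set(ann["feature"]) <= {"CDS", "UTR5", "UTR3", "intron"}

    @pytest.mark.parametrize("kwargs", [
        dict(n_contigs=1, lengths=[0], gc=0.5),
        dict(n_contigs=1, lengths=[-5], gc=0.5),
        dict(n_contigs=1, lengths=[100], gc=1.5),
        dict(n_contigs=2, lengths=[100], gc=0.5),
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            synth.generate_genome(seed=0, repeat_density=0.0, **kwargs)


class TestSimulateMA:
    def test_zero_rate_gives_empty_truth(self, genome):
        t = synth.simulate_ma_experiment(genome, n_lines=5, base_mu=0.0,
                                         seed=1)
        assert t.mutations == []

    def test_spectrum_probs_must_sum_to_one(self, genome):
        bad = {t: 0.2 for t in FOLDED_TYPES}
        with pytest.raises(ValueError, match="sum to 1"):
            synth.simulate_ma_experiment(genome, spectrum_probs=bad, seed=1)

    def test_mean_events_per_line(self):
        # lam = mu * L * t chosen to match the emulated experiment (~76.5)
        g = synth.generate_genome(1, [100_000], 0.66, 0.0, seed=2)
        lam = 9.7165e-7 * 100_000 * 788
        counts = []
        for seed in range(20):
            t = synth.simulate_ma_experiment(g, n_lines=26, t=788.0,
                                             base_mu=9.7165e-7, seed=seed)
            counts.extend(t.per_line_counts().to_numpy())
        counts = np.array(counts, dtype=float)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - lam) < 3 * se

    def test_lognormal_heterogeneity_overdisperses_counts(self):
        g = synth.generate_genome(1, [100_000], 0.66, 0.0, seed=2)
        hits = 0
        for seed in range(30):
            t = synth.simulate_ma_experiment(g, n_lines=26, t=788.0,
                                             base_mu=9.7e-7, seed=100 + seed)
            c = t.per_line_counts().to_numpy(dtype=float)
            if c.mean() > 0 and c.var(ddof=1) / c.mean() > 5:
                hits += 1
        assert hits >= 28  # sdlog=1.15 inflates variance far beyond Poisson

    def test_realized_spectrum_converges_to_probs(self):
        g = synth.generate_genome(1, [400_000], 0.66, 0.0, seed=1)
        pvals = []
        for seed in range(5):
            t = synth.simulate_ma_experiment(
                g, n_lines=26, t=788.0, base_mu=1.7e-6, context_boosts={},
                indel_fraction=0.0, seed=seed)
            counts = spectrum_counts(t.mutations)
            total = sum(counts.values())
            obs = np.array([counts[k] for k in FOLDED_TYPES])
            exp = np.array([t.spectrum_probs[k] for k in FOLDED_TYPES])
            pvals.append(stats.chisquare(obs, exp * total).pvalue)
        assert np.median(pvals) > 0.01

    def test_snm_indel_counts_correlated(self):
        g = synth.generate_genome(1, [200_000], 0.66, 0.0, seed=4)
        t = synth.simulate_ma_experiment(g, n_lines=26, t=788.0,
                                         base_mu=8e-7, seed=3)
        snm = t.per_line_counts("SNM")
        indel = t.per_line_counts("DEL") + t.per_line_counts("INS")
        assert np.corrcoef(snm, indel)[0, 1] > 0.7

    def test_positions_within_contigs(self, experiment):
        lengths = experiment.genome.lengths
        for m in experiment.truth.mutations:
            assert 0 <= m.pos < lengths[m.contig]

    def test_deterministic(self, genome):
        a = synth.simulate_ma_experiment(genome, n_lines=4, base_mu=1e-7,
                                         seed=5)
        b = synth.simulate_ma_experiment(genome, n_lines=4, base_mu=1e-7,
                                         seed=5)
        assert a.mutations == b.mutations
        assert a.line_rates == b.line_rates


class TestSpikeInProbes:
    def _flat_genome(self, *lengths):
        contigs = [synth.Contig(f"c{i}", "ACGT" * (n // 4 + 1))
                   for i, n in enumerate(lengths)]
        for c, n in zip(contigs, lengths):
            c.seq = c.seq[:n]
        return synth.SyntheticGenome(contigs=contigs, target_gc=0.5)

    @pytest.mark.parametrize("lengths,expected", [
        ((270_000,), 10),
        ((10_000,), 0),          # shorter than the spacing
        ((54_000, 27_000), 3),
    ])
    def test_probe_counts(self, lengths, expected):
        g = self._flat_genome(*lengths)
        assert len(synth.spike_in_probes(g, spacing=27_000)) == expected

    def test_probes_deterministic_and_valid(self):
        g = self._flat_genome(100_000)
        p1 = synth.spike_in_probes(g, spacing=10_000)
        p2 = synth.spike_in_probes(g, spacing=10_000)
        assert p1 == p2
        for p in p1:
            assert p.ref != p.alt and p.kind == "SNM"

    def test_invalid_spacing(self):
        g = self._flat_genome(1000)
        with pytest.raises(ValueError):
            synth.spike_in_probes(g, spacing=0)


class TestEmitCallRecords:
    def test_noiseless_recall_and_precision(self, experiment):
        exp = experiment
        truth_keys = {(m.contig, m.pos, m.line_id)
                      for m in exp.truth.mutations if m.kind == "SNM"
                      and exp.mask.contains(m.contig, m.pos)}
        accepted_keys = {(m.contig, m.pos, m.line_id) for m in exp.snms}
        assert truth_keys <= accepted_keys          # recall = 1
        assert accepted_keys <= {(m.contig, m.pos, m.line_id)
                                 for m in exp.truth.mutations}  # precision = 1

    def test_low_mq_sites_absent_from_mask(self, genome):
        truth = synth.simulate_ma_experiment(genome, n_lines=26,
                                             base_mu=0.0, seed=1)
        noise = synth.NoiseModel(low_mq_frac=0.05)
        cs = synth.emit_call_records(genome, truth, noise=noise, seed=2)
        mask = calling.build_callable_mask(cs)
        for contig, st in cs.site_stats.items():
            low = np.flatnonzero(st.mq < 50)
            flags = np.zeros(len(st.mq), dtype=bool)
            for a, b in mask.intervals[contig]:
                flags[a:b] = True
            assert not flags[low].any()

    def test_shared_alt_noise_rejects_nearby_candidate(self, genome):
        truth = synth.simulate_ma_experiment(genome, n_lines=26,
                                             base_mu=0.0, seed=1)
        cs = synth.emit_call_records(genome, truth, seed=3)
        seq = genome.sequence("contig_1")
        pos = 5_000
        alt = "A" if seq[pos] != "A" else "G"
        row = dict(contig="contig_1", pos=pos, ref=seq[pos], alt=alt,
                   qual=1500.0, mq=60.0, site_dp=546.0,
                   focal_line="line_1", n_alt_lines=1, focal_gq=99,
                   focal_dp=20, focal_ref_reads=0, focal_alt_reads=20,
                   n_lines_highalt=1, n_alts=1, alt_lines=("line_1",),
                   origin="truth")
        artifact = dict(row, pos=pos + 8, focal_line=None, n_alt_lines=0,
                        focal_gq=-1, focal_dp=0, focal_alt_reads=0,
                        n_lines_highalt=15, alt_lines=(), origin="artifact")
        cs.variants = pd.DataFrame([row, artifact])
        mask = calling.build_callable_mask(cs)
        result = calling.call_candidate_mutations(cs, mask)
        assert result.accepted == []
        assert (result.rejections["failed_rule"]
                == "shared_alt_neighborhood").any()

    def test_probes_emitted_as_singletons(self, experiment):
        probes_in = experiment.probe_keys
        recovered = {(m.contig, m.pos) for m in experiment.result.accepted
                     if (m.contig, m.pos) in probes_in}
        in_mask = {(c, p) for c, p in probes_in
                   if experiment.mask.contains(c, p)}
        assert recovered == in_mask


def test_mutation_type_validation():
    with pytest.raises(ValueError):
        Mutation("l", "c", 0, "A", "A", "SNM")
    with pytest.raises(ValueError):
        Mutation("l", "c", 0, "AC", "A", "SNM")
    with pytest.raises(ValueError):
        Mutation("l", "c", 0, "A", "AG", "INS", length=0)
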