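"""Callable-site thresholds, the candidate filter cascade, spike-ins and
the contamination screen."""
import numpy as np
import pandas as pd
import pytest

from mamut import calling, synth
from mamut.callset import CallSet
from mamut.calling import CallingThresholds
from mamut.types import SiteCall


def _site(contig, pos, line, mq, qual, dp, gq, klass="nuclear", **kw):
    return SiteCall(contig=contig, pos=pos, line_id=line, ref="A",
                    alts=kw.get("alts", ()), qual=qual, mq=mq, dp=dp,
                    gq=gq, n_ref_reads=kw.get("n_ref", 0),
                    n_alt_reads=kw.get("n_alt", 0),
                    is_alt=kw.get("is_alt", False))


def _three_line_site(mq=50, qual=100, dp_each=56, gq=99, contig="c1",
                     pos=10, dp_last=55):
    recs = []
    for i, line in enumerate(("l1", "l2", "l3")):
        dp = dp_last if i == 2 else dp_each
        recs.append(_site(contig, pos, line, mq, qual, dp, gq))
    return recs


class TestCallableMask:
    def test_boundary_thresholds_callable(self):
        # MQ 50, QUAL 100, combined DP 167, 3 haploid lines at GQ 99
        cs = CallSet.from_site_calls(_three_line_site(),
                                     contig_lengths={"c1": 100})
        mask = calling.build_callable_mask(
            cs, CallingThresholds(min_combined_dp=167))
        assert mask.contains("c1", 9)
        assert mask.total() == 1

    def test_mq_boundary_excludes(self):
        cs = CallSet.from_site_calls(_three_line_site(mq=49),
                                     contig_lengths={"c1": 100})
        mask = calling.build_callable_mask(
            cs, CallingThresholds(min_combined_dp=167))
        assert mask.total() == 0

    def test_organelle_lower_qual_threshold(self):
        cs = CallSet.from_site_calls(
            _three_line_site(qual=70),
            contig_lengths={"c1": 100},
            contig_classes={"c1": "plastid"})
        mask = calling.build_callable_mask(
            cs, CallingThresholds(min_combined_dp=167))
        assert mask.contains("c1", 9)
        # same QUAL on a nuclear contig fails the 100 threshold
        cs_nuc = CallSet.from_site_calls(_three_line_site(qual=70),
                                         contig_lengths={"c1": 100})
        assert calling.build_callable_mask(
            cs_nuc, CallingThresholds(min_combined_dp=167)).total() == 0

    def test_too_few_gq99_lines(self):
        recs = _three_line_site()
        recs[2] = _site("c1", 10, "l3", 50, 100, 55, gq=98)
        cs = CallSet.from_site_calls(recs, contig_lengths={"c1": 100})
        assert calling.build_callable_mask(
            cs, CallingThresholds(min_combined_dp=167)).total() == 0

    def test_dp_rule_mean_minus_sd(self, experiment):
        # with the rule unset the threshold is recomputed from the data
        thr = experiment.mask.dp_thresholds["nuclear"]
        dps = np.concatenate([st.dp for st in
                              experiment.callset.site_stats.values()])
        assert thr == pytest.approx(dps.mean() - dps.std())

    def test_empty_input(self):
        mask = calling.build_callable_mask(
            CallSet(lines=[], contig_lengths={}, contig_classes={},
                    site_stats={}))
        assert mask.total() == 0


def _candidate_row(**kw):
    base = dict(contig="c1", pos=10, ref="A", alt="G", qual=1500.0,
                mq=60.0, site_dp=500.0, focal_line="l1", n_alt_lines=1,
                focal_gq=99, focal_dp=8, focal_ref_reads=0,
                focal_alt_reads=8, n_lines_highalt=1, n_alts=1,
                alt_lines=("l1",), origin="truth")
    base.update(kw)
    return base


def _callset_with(rows, n=100):
    from mamut.callset import SiteStats
    cs = CallSet(
        lines=[f"l{i}" for i in range(1, 21)],
        contig_lengths={"c1": n}, contig_classes={"c1": "nuclear"},
        site_stats={"c1": SiteStats(mq=np.full(n, 60.0),
                                    qual=np.full(n, 1500.0),
                                    dp=np.full(n, 500.0),
                                    n_gq99=np.full(n, 20, dtype=np.int16))},
        variants=pd.DataFrame(rows))
    return cs


class TestCandidateFilters:
    def _run(self, rows, **thr):
        cs = _callset_with(rows)
        thresholds = CallingThresholds(min_combined_dp=100, **thr)
        mask = calling.build_callable_mask(cs, thresholds)
        return calling.call_candidate_mutations(cs, mask, thresholds)

    def test_clean_candidate_accepted(self):
        res = self._run([_candidate_row()])
        assert len(res.accepted) == 1
        assert res.accepted[0].kind == "SNM"

    @pytest.mark.parametrize("row,rule", [
        (_candidate_row(n_alt_lines=2, alt_lines=("l1", "l2")),
         "multi_line_alt"),
        (_candidate_row(focal_gq=98), "gq"),
        (_candidate_row(n_alts=2), "not_biallelic"),
        (_candidate_row(focal_dp=5, focal_alt_reads=5), "depth"),
        # 2 of 6 reads reference: 2/6 > 1/6
        (_candidate_row(focal_dp=6, focal_ref_reads=2, focal_alt_reads=4),
         "ref_read_fraction"),
    ])
    def test_single_rule_rejection(self, row, rule):
        res = self._run([row])
        assert res.accepted == []
        assert res.rejections["failed_rule"].iloc[0] == rule

    def test_boundary_ref_fraction_accepted(self):
        # exactly one in six reads reference is allowed
        res = self._run([_candidate_row(focal_dp=6, focal_ref_reads=1,
                                        focal_alt_reads=5)])
        assert len(res.accepted) == 1

    def test_indels_accepted_and_reviewed(self):
        rows = [_candidate_row(pos=30, ref="ACG", alt="A"),
                _candidate_row(pos=60, ref="A", alt="ATT")]
        res = self._run(rows)
        kinds = sorted(m.kind for m in res.accepted)
        assert kinds == ["DEL", "INS"]
        assert len(res.review_list) == 2
        assert {m.length for m in res.accepted} == {2}

    def test_accepted_always_inside_mask(self, experiment):
        for m in experiment.result.accepted:
            assert experiment.mask.contains(m.contig, m.pos)

    def test_tightening_thresholds_is_monotone(self, experiment):
        base_keys = {(m.contig, m.pos, m.line_id)
                     for m in experiment.result.accepted}
        for tighter in (CallingThresholds(min_mq=55),
                        CallingThresholds(min_candidate_depth=10),
                        CallingThresholds(min_gq99_lines=30)):
            mask = calling.build_callable_mask(experiment.callset, tighter)
            res = calling.call_candidate_mutations(experiment.callset,
                                                   mask, tighter)
            keys = {(m.contig, m.pos, m.line_id) for m in res.accepted}
            assert keys <= base_keys


class TestSpikeInCallability:
    def test_simple_ratios(self, experiment):
        probes = experiment.probes
        rec = [m for m in experiment.result.accepted
               if (m.contig, m.pos) in experiment.probe_keys]
        df = calling.spike_in_callability(probes, rec)
        overall = df.loc[df["line_id"] == "__all__", "rate"].iloc[0]
        in_mask = sum(1 for p in probes
                      if experiment.mask.contains(p.contig, p.pos))
        assert overall == pytest.approx(in_mask / len(probes))

    def test_fraction_arithmetic(self):
        probes = [synth.Mutation("", "c1", i * 10, "A", "G")
                  for i in range(10)]
        rec = [synth.Mutation("l1", "c1", i * 10, "A", "G")
               for i in range(9)]
        df = calling.spike_in_callability(probes, rec)
        assert df["rate"].iloc[0] == pytest.approx(0.9)
        df_all = calling.spike_in_callability(probes, probes)
        assert df_all["rate"].iloc[0] == 1.0

    def test_zero_probes_error(self):
        with pytest.raises(ValueError):
            calling.spike_in_callability([], [])


class TestContaminationScreen:
    def _callset_sharing(self, sets):
        rows = []
        for pos, lines in enumerate(sets):
            rows.append(_candidate_row(
                pos=pos, n_alt_lines=len(lines), alt_lines=tuple(lines),
                focal_line=lines[0] if len(lines) == 1 else None))
        cs = _callset_with(rows, n=len(sets) + 1)
        cs.lines = sorted({l for s in sets for l in s})
        return cs

    def test_identical_sets_flagged(self):
        cs = self._callset_sharing([("a", "b"), ("a", "b"), ("a", "b")])
        df = calling.contamination_screen(cs)
        assert (df["share"] == 1.0).all()
        assert df["flagged"].all()

    def test_disjoint_sets_unflagged(self):
        sets = [("a",), ("b",), ("a",), ("b",)]
        df = calling.contamination_screen(self._callset_sharing(sets))
        assert (df["share"] == 0.0).all()
        assert not df["flagged"].any()

    def test_75_percent_overlap_pair_flagged(self):
        rng = np.random.default_rng(0)
        lines = [f"L{i}" for i in range(10)]
        sets = []
        # background: each line has 100 private alleles; lines L0/L1 share 75
        for pos in range(75):
            sets.append(("L0", "L1"))
        for line in lines:
            for _ in range(25 if line in ("L0", "L1") else 100):
                sets.append((line,))
        df = calling.contamination_screen(self._callset_sharing(sets))
        flagged = df[df["flagged"]]
        assert set(map(tuple, flagged[["line_a", "line_b"]].values)) \
            == {("L0", "L1"), ("L1", "L0")}

    def test_zero_allele_line_missing(self):
        cs = self._callset_sharing([("a",), ("b",)])
        cs.lines = ["a", "b", "c"]
        df = calling.contamination_screen(cs)
        c_rows = df[df["line_a"] == "c"]
        assert c_rows["share"].isna().all()

    def test_requires_two_lines(self):
        cs = self._callset_sharing([("a",)])
        cs.lines = ["a"]
        with pytest.raises(ValueError):
            calling.contamination_screen(cs)
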