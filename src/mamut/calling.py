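"""Callable-site determination and the de novo mutation filter cascade.

A site is callable iff it passes mapping-quality, site-quality, combined
read-depth and genotype-quality thresholds; a candidate mutation is
accepted iff its site is callable, the alternate allele is a biallelic
singleton (present in exactly one line) called at maximum genotype quality
with sufficient depth, at most one in six reads carry the reference
allele, and no multi-line shared-alt artifact lies within 10 bp.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .callset import CallSet
from .types import Mutation, SiteCall


@dataclass(frozen=True)
class CallingThresholds:
    """Filter-cascade thresholds.

    ``min_combined_dp`` of ``None`` applies the rule used to pick the
    original defaults: one standard deviation below the mean combined DP,
    recomputed per dataset and contig class. The documented defaults for
    the study this package emulates were 167 (nuclear), 26,000 (plastid)
    and 20,000 (mitochondrial).
    """

    min_mq: float = 50.0
    min_qual_nuclear: float = 100.0
    min_qual_organelle: float = 70.0
    min_combined_dp: float | None = None
    min_gq99_lines: int = 3
    candidate_gq: int = 99
    min_candidate_depth: int = 6
    max_ref_read_fraction: float = 1 / 6
    neighborhood_bp: int = 10          # inclusive distance
    shared_alt_lines: int = 14
    shared_alt_fraction: float = 1 / 6


@dataclass
class CallableMask:
    """Sorted, non-overlapping callable intervals per contig (0-based, half-open)."""

    intervals: dict[str, np.ndarray]       # (n, 2) arrays
    contig_classes: dict[str, str] = field(default_factory=dict)
    dp_thresholds: dict[str, float] = field(default_factory=dict)

    def contains(self, contig: str, pos: int) -> bool:
        iv = self.intervals.get(contig)
        if iv is None or len(iv) == 0:
            return False
        i = int(np.searchsorted(iv[:, 0], pos, side="right")) - 1
        return i >= 0 and pos < iv[i, 1]

    def positions(self, contig: str) -> np.ndarray:
        iv = self.intervals.get(contig)
        if iv is None or len(iv) == 0:
            return np.array([], dtype=np.int64)
        return np.concatenate([np.arange(a, b) for a, b in iv])

    def total(self, contig: str | None = None) -> int:
        if contig is not None:
            iv = self.intervals.get(contig)
            return int((iv[:, 1] - iv[:, 0]).sum()) if iv is not None and len(iv) else 0
        return sum(self.total(c) for c in self.intervals)

    def total_by_class(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for contig in self.intervals:
            k = self.contig_classes.get(contig, "nuclear")
            out[k] = out.get(k, 0) + self.total(contig)
        return out

    @staticmethod
    def from_bool(flags: dict[str, np.ndarray], **kw) -> "CallableMask":
        intervals = {}
        for contig, f in flags.items():
            edges = np.flatnonzero(np.diff(np.r_[0, f.astype(np.int8), 0]))
            intervals[contig] = edges.reshape(-1, 2)
        return CallableMask(intervals=intervals, **kw)


def _as_callset(calls) -> CallSet:
    if isinstance(calls, CallSet):
        return calls
    records = list(calls)
    if records and isinstance(records[0], SiteCall):
        return CallSet.from_site_calls(records)
    raise TypeError("calls must be a CallSet or an iterable of SiteCall")


def build_callable_mask(calls, thresholds: CallingThresholds | None = None
                        ) -> CallableMask:
    """Determine callable sites from per-site multi-line summary fields.

    A site is callable iff MQ >= min_mq, QUAL >= the class-specific
    minimum (nuclear vs organelle), combined DP >= the class threshold
    (fixed, or mean - 1 SD recomputed from the data when unset), and at
    least ``min_gq99_lines`` haploid lines have GQ at its maximum of 99.
    Sites with missing fields are non-callable.
    """
    cs = _as_callset(calls)
    th = thresholds or CallingThresholds()
    if not cs.site_stats:
        return CallableMask(intervals={})
    # per-class DP thresholds
    dp_thr: dict[str, float] = {}
    classes = {cs.contig_class(c) for c in cs.site_stats}
    for k in classes:
        if th.min_combined_dp is not None:
            dp_thr[k] = th.min_combined_dp
        else:
            dps = np.concatenate([cs.site_stats[c].dp for c in cs.site_stats
                                  if cs.contig_class(c) == k])
            dps = dps[~np.isnan(dps)]
            dp_thr[k] = float(dps.mean() - dps.std()) if len(dps) else np.inf
    flags = {}
    for contig, st in cs.site_stats.items():
        k = cs.contig_class(contig)
        min_qual = (th.min_qual_nuclear if k == "nuclear"
                    else th.min_qual_organelle)
        with np.errstate(invalid="ignore"):
            ok = ((st.mq >= th.min_mq) & (st.qual >= min_qual)
                  & (st.dp >= dp_thr[k]) & (st.n_gq99 >= th.min_gq99_lines))
        ok &= ~(np.isnan(st.mq) | np.isnan(st.qual))
        flags[contig] = ok
    return CallableMask.from_bool(flags, contig_classes=dict(cs.contig_classes),
                                  dp_thresholds=dp_thr)


@dataclass
class CallResult:
    accepted: list[Mutation]
    rejections: pd.DataFrame     # variant rows with the first failing rule
    review_list: pd.DataFrame    # accepted INDEL/INV calls flagged for review

    @property
    def accepted_df(self) -> pd.DataFrame:
        return pd.DataFrame([m.__dict__ for m in self.accepted])


def _variant_kind(ref: str, alt: str) -> str:
    if alt == "<INV>":
        return "INV"
    if len(ref) == 1 and len(alt) == 1:
        return "SNM"
    return "INS" if len(alt) > len(ref) else "DEL"


def call_candidate_mutations(calls, mask: CallableMask,
                             thresholds: CallingThresholds | None = None
                             ) -> CallResult:
    """Accept/reject candidate de novo mutations by the filter cascade.

    Rules (order-independent): site callable; alternate allele in exactly
    one line; focal-line GQ == 99; biallelic; focal depth >= 6; ref-read
    fraction <= 1/6; no site within 10 bp (inclusive) where >= 14 lines
    have >1/6 alt reads. Rejections are logged with the failing rule.
    """
    cs = _as_callset(calls)
    th = thresholds or CallingThresholds()
    variants = cs.variants
    # shared-alt artifact positions per contig, from the variant table
    shared = {
        contig: np.sort(g.loc[g["n_lines_highalt"] >= th.shared_alt_lines,
                              "pos"].to_numpy())
        for contig, g in variants.groupby("contig")
    }
    accepted: list[Mutation] = []
    rej_rows = []
    review = []
    for row in variants.itertuples(index=False):
        if row.origin == "artifact" or (row.n_alt_lines == 0
                                        and row.n_lines_highalt >= th.shared_alt_lines):
            continue  # artifact records are not candidates themselves
        rule = _first_failing_rule(row, cs, mask, th, shared)
        if rule is None:
            kind = _variant_kind(row.ref, row.alt)
            length = 1 if kind == "SNM" else max(
                abs(len(row.alt) - len(row.ref)), 1)
            mut = Mutation(row.focal_line, row.contig, int(row.pos),
                           row.ref, row.alt, kind, length)
            accepted.append(mut)
            if kind in ("INS", "DEL", "INV"):
                review.append({**row._asdict(), "kind": kind})
        else:
            rej_rows.append({**row._asdict(), "failed_rule": rule})
    rejections = pd.DataFrame(rej_rows)
    review_df = pd.DataFrame(review)
    return CallResult(accepted=accepted, rejections=rejections,
                      review_list=review_df)


def _first_failing_rule(row, cs: CallSet, mask: CallableMask,
                        th: CallingThresholds, shared) -> str | None:
    if not mask.contains(row.contig, int(row.pos)):
        return "not_callable"
    if row.n_alt_lines != 1 or row.focal_line is None:
        return "multi_line_alt" if row.n_alt_lines > 1 else "no_alt_genotype"
    if row.focal_gq != th.candidate_gq:
        return "gq"
    if row.n_alts > 1:
        return "not_biallelic"
    depth = row.focal_ref_reads + row.focal_alt_reads
    if depth <= 0:
        depth = row.focal_dp
    if depth < th.min_candidate_depth:
        return "depth"
    if depth > 0 and row.focal_ref_reads / depth > th.max_ref_read_fraction:
        return "ref_read_fraction"
    arts = shared.get(row.contig)
    if arts is not None and len(arts):
        i = int(np.searchsorted(arts, row.pos))
        for j in (i - 1, i):
            if 0 <= j < len(arts) \
                    and abs(int(arts[j]) - int(row.pos)) <= th.neighborhood_bp:
                return "shared_alt_neighborhood"
    return None


def spike_in_callability(probes: list[Mutation],
                         recovered: list[Mutation],
                         probe_lines: dict[tuple[str, int], str] | None = None
                         ) -> pd.DataFrame:
    """Line-specific callable rate from spike-in probe recovery.

    ``probe_lines`` maps (contig, pos) to the line each probe was emitted
    in; when omitted, the round-robin assignment used by
    :func:`mamut.synth.emit_call_records` over the recovered lines cannot
    be reconstructed, so only the overall rate row is returned.
    Rate = recovered probes / total probes, per line, in [0, 1].
    """
    if not probes:
        raise ValueError("no probes supplied")
    probe_keys = {(p.contig, p.pos) for p in probes}
    rec_keys = {(m.contig, m.pos) for m in recovered} & probe_keys
    rows = [{"line_id": "__all__", "n_probes": len(probe_keys),
             "n_recovered": len(rec_keys),
             "rate": len(rec_keys) / len(probe_keys)}]
    if probe_lines:
        per_line: dict[str, list[int]] = {}
        for key, line in probe_lines.items():
            per_line.setdefault(line, []).append(key in rec_keys)
        for line in sorted(per_line):
            hits = per_line[line]
            rows.append({"line_id": line, "n_probes": len(hits),
                         "n_recovered": int(sum(hits)),
                         "rate": sum(hits) / len(hits)})
    return pd.DataFrame(rows)


def contamination_screen(calls, k: float = 5.0) -> pd.DataFrame:
    """Pairwise alternate-allele sharing between lines, with outlier flags.

    share(i, j) = |alt alleles of line i also seen in line j| / |alt
    alleles of line i|. Pairs whose share exceeds mean + k*SD of the
    off-diagonal entries are flagged (cross-contaminated lines share a
    large fraction of their alternate alleles). Lines with zero alternate
    alleles get a missing (NaN) row.
    """
    cs = _as_callset(calls)
    if len(cs.lines) < 2:
        raise ValueError("contamination screen needs >= 2 lines")
    allele_sets: dict[str, set] = {line: set() for line in cs.lines}
    for row in cs.variants.itertuples(index=False):
        for line in row.alt_lines:
            if line in allele_sets:
                allele_sets[line].add((row.contig, row.pos, row.alt))
    lines = cs.lines
    n = len(lines)
    share = np.full((n, n), np.nan)
    for i, li in enumerate(lines):
        a = allele_sets[li]
        if not a:
            continue
        for j, lj in enumerate(lines):
            if i == j:
                continue
            share[i, j] = len(a & allele_sets[lj]) / len(a)
    off = share[~np.isnan(share)]
    if len(off):
        thr = off.mean() + k * off.std()
    else:
        thr = np.inf
    rows = []
    for i, li in enumerate(lines):
        for j, lj in enumerate(lines):
            if i == j:
                continue
            s = share[i, j]
            flagged = (not np.isnan(s)) and (s > thr or s >= 1.0)
            rows.append({"line_a": li, "line_b": lj, "share": s,
                         "flagged": bool(flagged)})
    return pd.DataFrame(rows)


def tighten(th: CallingThresholds, **kw) -> CallingThresholds:
    """Return thresholds with the given fields replaced (convenience)."""
    return replace(th, **kw)
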