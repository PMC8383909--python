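"""Synthetic mutation-accumulation experiments.

Generates complete synthetic MA studies — a GC-rich multi-contig genome
with gene/repeat annotation, per-line de novo mutations with lognormal
between-line rate heterogeneity and a context-biased single-nucleotide
mutation (SNM) spectrum, and the multi-line call records the filter
cascade consumes — so every downstream stage is testable without any
sequencing data.

The generator emulates the structure of a *Chlamydomonas*-like MA study:
a ~66% GC nuclear genome, 26–27 clonal lines bottlenecked for ~788
generations, a C→T-dominated folded spectrum with hypermutable CTC/CAC
trinucleotide contexts, short INDELs whose per-line counts share the line
rate multiplier with SNMs, and synthetic spike-in probe mutations placed
every 27 kb to estimate line-specific callability.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dna import decode, encode, revcomp
from .callset import CallSet, SiteStats, empty_variants, VARIANT_COLUMNS
from .types import Mutation

#: folded SNM types (reference base collapsed to A or C)
FOLDED_TYPES = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")

#: default folded spectrum: C→T-dominated, transitions > transversions
DEFAULT_SPECTRUM = {
    "A>C": 0.04, "A>G": 0.13, "A>T": 0.04,
    "C>A": 0.14, "C>G": 0.13, "C>T": 0.52,
}

#: default trinucleotide rate multipliers (canonical surrounding context,
#: centre base A or C).  CTC and CAC are strongly hypermutable.
DEFAULT_CONTEXT_BOOSTS = {"CTC": 10.0, "CAC": 6.0}

#: fraction of events that are INDELs (618 of 2,609 in the emulated study)
DEFAULT_INDEL_FRACTION = 618 / 2609

#: per-site per-generation event rate (SNM + INDEL) of the emulated study
DEFAULT_BASE_MU = 15.1e-10

DEFAULT_LINE_DIST = (-3.01, 1.15)  # (meanlog, sdlog)

_TRANSITION = {"A": "G", "C": "T", "G": "A", "T": "C"}


@dataclass
class Contig:
    name: str
    seq: str
    klass: str = "nuclear"  # nuclear / plastid / mitochondrial

    def __len__(self):
        return len(self.seq)


@dataclass
class SyntheticGenome:
    """A synthetic reference genome with feature and repeat annotation.

    ``annotation`` holds gene-feature intervals (CDS, UTR5, UTR3, intron;
    0-based half-open); ``repeats`` holds repeat intervals with a
    ``repeat_class`` column (low_complexity, microsatellite, TE).
    """

    contigs: list[Contig]
    target_gc: float
    annotation: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["contig", "start", "end", "feature"]))
    repeats: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["contig", "start", "end", "repeat_class"]))

    def contig(self, name: str) -> Contig:
        for c in self.contigs:
            if c.name == name:
                return c
        raise KeyError(name)

    def sequence(self, name: str) -> str:
        return self.contig(name).seq

    @property
    def lengths(self) -> dict[str, int]:
        return {c.name: len(c.seq) for c in self.contigs}

    @property
    def classes(self) -> dict[str, str]:
        return {c.name: c.klass for c in self.contigs}

    @property
    def total_length(self) -> int:
        return sum(len(c.seq) for c in self.contigs)

    def gc(self) -> float:
        codes = np.concatenate([encode(c.seq) for c in self.contigs])
        valid = codes >= 0
        return float(((codes == 1) | (codes == 2)).sum() / valid.sum())


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _annotate_genes(rng: np.random.Generator, length: int, contig: str) -> list[dict]:
    """Tile a contig with gene models separated by intergenic gaps.

    Block sizes are drawn so that genome-wide proportions land near the
    emulated study's annotation (~30% CDS, ~3% UTR, ~18% intron, the rest
    intergenic).
    """
    rows = []
    cursor = int(rng.integers(200, 2000))
    while cursor < length - 3000:
        utr5 = int(rng.integers(40, 80))
        utr3 = int(rng.integers(60, 120))
        n_exons = int(rng.integers(4, 7))
        pieces = [("UTR5", utr5)]
        for i in range(n_exons):
            pieces.append(("CDS", int(rng.integers(200, 320))))
            if i < n_exons - 1:
                pieces.append(("intron", int(rng.integers(150, 300))))
        pieces.append(("UTR3", utr3))
        for feature, size in pieces:
            end = min(cursor + size, length)
            if end > cursor:
                rows.append({"contig": contig, "start": cursor, "end": end,
                             "feature": feature})
            cursor = end
            if cursor >= length:
                break
        cursor += int(rng.integers(800, 3200))  # intergenic gap
    return rows


def _repeat_blocks(rng: np.random.Generator, length: int, density: float,
                   probs: np.ndarray) -> list[tuple[int, str, str]]:
    """Plan non-overlapping repeat blocks covering exactly round(density*length) bp.

    Returns (start, repeat_class, sequence) triples. Unit length 1 ->
    low-complexity, 2-6 -> microsatellite, long shuffled template -> TE.
    """
    total = int(round(density * length))
    if total <= 0:
        return []
    sizes = []
    while sum(sizes) < total:
        sizes.append(int(rng.integers(100, 600)))
    sizes[-1] -= sum(sizes) - total
    if sizes[-1] < 10 and len(sizes) > 1:
        sizes[-2] += sizes[-1]
        sizes.pop()
    free = length - total
    gaps = rng.multinomial(free, np.ones(len(sizes) + 1) / (len(sizes) + 1))
    blocks, cursor = [], 0
    for size, gap in zip(sizes, gaps[:-1]):
        cursor += int(gap)
        kind = rng.choice(["low_complexity", "microsatellite", "TE"],
                          p=[0.3, 0.4, 0.3])
        if kind == "low_complexity":
            unit = decode(rng.choice(4, size=1, p=probs))
        elif kind == "microsatellite":
            u = int(rng.integers(2, 7))
            unit = decode(rng.choice(4, size=u, p=probs))
        else:
            unit = decode(rng.choice(4, size=500, p=probs))
        seq = (unit * (size // len(unit) + 1))[:size]
        blocks.append((cursor, kind, seq))
        cursor += size
    return blocks


def generate_genome(n_contigs: int, lengths: list[int], gc: float,
                    repeat_density: float = 0.0, seed: int = 0,
                    contig_classes: list[str] | None = None) -> SyntheticGenome:
    """Generate a synthetic multi-contig genome.

    Bases are drawn i.i.d. with P(G)=P(C)=gc/2; ``repeat_density`` of each
    contig is then overwritten with tandem low-complexity/microsatellite/TE
    template blocks whose composition preserves the target GC in
    expectation. Gene features (CDS/UTR/intron) are tiled over the contig;
    everything else is intergenic. Deterministic for a fixed seed.
    """
    if n_contigs < 1 or len(lengths) != n_contigs:
        raise ValueError("lengths must list one positive size per contig")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be a fraction in [0, 1]")
    if not 0.0 <= repeat_density < 1.0:
        raise ValueError("repeat_density must be in [0, 1)")
    rng = np.random.default_rng(seed)
    probs = _base_probs(gc)
    classes = contig_classes or ["nuclear"] * n_contigs
    contigs, ann_rows, rep_rows = [], [], []
    for i, (length, klass) in enumerate(zip(lengths, classes)):
        name = f"contig_{i + 1}"
        codes = rng.choice(4, size=length, p=probs).astype(np.int8)
        seq = decode(codes)
        if repeat_density > 0:
            chars = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            for start, kind, block in _repeat_blocks(rng, length,
                                                     repeat_density, probs):
                chars[start:start + len(block)] = np.frombuffer(
                    block.encode(), dtype=np.uint8)
                rep_rows.append({"contig": name, "start": start,
                                 "end": start + len(block),
                                 "repeat_class": kind})
            seq = chars.tobytes().decode()
        ann_rows.extend(_annotate_genes(rng, length, name))
        contigs.append(Contig(name, seq, klass))
    annotation = pd.DataFrame(
        ann_rows, columns=["contig", "start", "end", "feature"])
    repeats = pd.DataFrame(
        rep_rows, columns=["contig", "start", "end", "repeat_class"])
    return SyntheticGenome(contigs=contigs, target_gc=gc,
                           annotation=annotation, repeats=repeats)


@dataclass
class TruthSet:
    """Ground-truth mutations of a simulated MA experiment."""

    mutations: list[Mutation]
    line_rates: dict[str, float]        # per-line rate multipliers (mean ~1)
    spectrum_probs: dict[str, float]
    context_boosts: dict[str, float]
    indel_fraction: float
    generations: float = 0.0

    def per_line_counts(self, kind: str | None = None) -> pd.Series:
        counts = {line: 0 for line in self.line_rates}
        for m in self.mutations:
            if kind is None or m.kind == kind:
                counts[m.line_id] += 1
        return pd.Series(counts)


def _canonical_weights(codes: np.ndarray, boosts: dict[str, float]) -> np.ndarray:
    """Per-site sampling weights from canonical upstream-context boosts.

    Boost keys are canonical upstream triplets — the two bases upstream of
    the focal site plus the focal base itself, strand-collapsed so the
    focal base is A or C (e.g. CTC = a C preceded by CT). A focal site on
    the other strand matches through the reverse complement of its
    downstream triplet.
    """
    n = len(codes)
    w = np.ones(n)
    if not boosts or n < 3:
        return w
    up_boost = np.ones(64)     # keyed by s[i-2..i] codes, focal base A/C
    down_boost = np.ones(64)   # keyed by s[i..i+2] codes, focal base G/T
    for tri, b in boosts.items():
        t = encode(tri)
        if (t < 0).any() or len(t) != 3 or tri[2] not in "AC":
            raise ValueError(
                f"context boost {tri!r} must be a canonical upstream "
                "triplet (focal base A or C last)")
        up_boost[t[0] * 16 + t[1] * 4 + t[2]] = b
        rc = encode(revcomp(tri))
        down_boost[rc[0] * 16 + rc[1] * 4 + rc[2]] = b
    is_ac = (codes == 0) | (codes == 1)
    safe = np.where(codes < 0, 0, codes).astype(np.int64)
    valid3 = (codes[:-2] >= 0) & (codes[1:-1] >= 0) & (codes[2:] >= 0)
    tri_codes = safe[:-2] * 16 + safe[1:-1] * 4 + safe[2:]
    # upstream triplet ends at i: positions i >= 2
    up_w = np.where(valid3, up_boost[tri_codes], 1.0)
    sel_up = is_ac[2:]
    w[2:][sel_up] = up_w[sel_up]
    # downstream triplet starts at i: positions i <= n-3
    down_w = np.where(valid3, down_boost[tri_codes], 1.0)
    sel_down = ~is_ac[:-2] & (codes[:-2] >= 0)
    w[:-2][sel_down] = down_w[sel_down]
    return w


def simulate_ma_experiment(genome: SyntheticGenome, n_lines: int = 26,
                           t: float = 788.0, base_mu: float = DEFAULT_BASE_MU,
                           line_dist: tuple[float, float] = DEFAULT_LINE_DIST,
                           spectrum_probs: dict[str, float] | None = None,
                           context_boosts: dict[str, float] | None = None,
                           indel_fraction: float = DEFAULT_INDEL_FRACTION,
                           seed: int = 0) -> TruthSet:
    """Simulate mutation accumulation under a haploid neutral model.

    Per line, the event count is Poisson(multiplier × base_mu × genome
    length × t), where the multiplier is lognormal(meanlog, sdlog)
    normalized to unit mean so that ``base_mu`` is the across-line mean
    rate and ``sdlog`` controls between-line heterogeneity. SNM positions
    are sampled with weights given by the canonical trinucleotide context
    boosts; alternate alleles follow ``spectrum_probs`` conditional on the
    reference base. SNMs and INDELs share the line multiplier, which
    induces the strong cross-correlation of their per-line counts.
    """
    if base_mu < 0:
        raise ValueError("base_mu must be >= 0")
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    spectrum = dict(spectrum_probs or DEFAULT_SPECTRUM)
    if set(spectrum) != set(FOLDED_TYPES):
        raise ValueError("spectrum_probs must cover the six folded SNM types")
    total_p = sum(spectrum.values())
    if abs(total_p - 1.0) > 1e-9:
        raise ValueError(f"spectrum_probs must sum to 1 (got {total_p})")
    boosts = DEFAULT_CONTEXT_BOOSTS if context_boosts is None else context_boosts
    meanlog, sdlog = line_dist
    rng = np.random.default_rng(seed)
    lines = [f"line_{i + 1}" for i in range(n_lines)]
    raw = rng.lognormal(meanlog, sdlog, size=n_lines)
    mult = raw / np.exp(meanlog + sdlog ** 2 / 2)  # normalize to mean 1
    line_rates = dict(zip(lines, mult))

    # per-contig sequence codes and context-boosted sampling weights;
    # folded types are drawn from spectrum_probs first, then a site of
    # the matching source-base class is picked, so the realized folded
    # spectrum converges to spectrum_probs irrespective of GC content
    seqs = {c.name: c.seq for c in genome.contigs}
    codes = {name: encode(s) for name, s in seqs.items()}
    weights = np.concatenate([_canonical_weights(codes[c.name], boosts)
                              for c in genome.contigs])
    flat_codes = np.concatenate([codes[c.name] for c in genome.contigs])
    offsets, names = [], []
    off = 0
    for c in genome.contigs:
        offsets.append(off)
        names.append(c.name)
        off += len(c.seq)
    bounds = np.array(offsets + [off])
    class_pos = {  # flat positions per folded source-base class
        "A": np.flatnonzero((flat_codes == 0) | (flat_codes == 3)),
        "C": np.flatnonzero((flat_codes == 1) | (flat_codes == 2)),
    }
    class_logw = {k: np.log(weights[v]) for k, v in class_pos.items()}
    probs6 = np.array([spectrum[ty] for ty in FOLDED_TYPES])
    #               folded target ->  alt at A  alt at T   alt at C  alt at G
    alt_lookup = {"A>C": ("C", "G"), "A>G": ("G", "C"), "A>T": ("T", "A"),
                  "C>A": ("A", "T"), "C>G": ("G", "C"), "C>T": ("T", "A")}

    L = genome.total_length
    mutations: list[Mutation] = []
    for line, m in zip(lines, mult):
        n_events = rng.poisson(m * base_mu * L * t)
        if n_events == 0:
            continue
        is_indel = rng.random(n_events) < indel_fraction
        n_snm = int((~is_indel).sum())
        if n_snm:
            types = rng.choice(6, size=n_snm, p=probs6)
            for src in ("A", "C"):
                t_idx = np.flatnonzero(np.array(
                    [FOLDED_TYPES[ty][0] for ty in types]) == src)
                k = len(t_idx)
                if k == 0 or len(class_pos[src]) == 0:
                    continue
                k = min(k, len(class_pos[src]))
                # Gumbel top-k = weighted sampling without replacement
                keys = class_logw[src] + rng.gumbel(
                    size=len(class_logw[src]))
                flat = class_pos[src][np.argpartition(-keys, k - 1)[:k]]
                for fp, ti in zip(flat, types[t_idx[:k]]):
                    ci = int(np.searchsorted(bounds, fp, side="right") - 1)
                    contig, pos = names[ci], int(fp - bounds[ci])
                    ref = seqs[contig][pos]
                    folded = FOLDED_TYPES[ti]
                    alt = alt_lookup[folded][0] if ref in "AC" \
                        else alt_lookup[folded][1]
                    mutations.append(
                        Mutation(line, contig, pos, ref, alt, "SNM", 1))
        # INDELs: uniform positions; geometric lengths (del mean 3, ins mean 2)
        n_indel = int(is_indel.sum())
        if n_indel:
            flat = rng.integers(0, L, size=n_indel)
            dels = rng.random(n_indel) < 350 / 618
            for fp, is_del in zip(np.sort(flat), dels):
                ci = int(np.searchsorted(bounds, fp, side="right") - 1)
                contig, pos = names[ci], int(fp - bounds[ci])
                seq = seqs[contig]
                if is_del:
                    g = int(rng.geometric(1 / 3))
                    if pos + g + 1 > len(seq):
                        g = max(1, len(seq) - pos - 1)
                    ref, alt = seq[pos:pos + g + 1], seq[pos]
                    kind = "DEL"
                else:
                    g = int(rng.geometric(1 / 2))
                    ins = decode(rng.choice(4, size=g,
                                            p=_base_probs(genome.target_gc)))
                    ref, alt = seq[pos], seq[pos] + ins
                    kind = "INS"
                if len(ref) == len(alt):
                    continue
                mutations.append(Mutation(line, contig, pos, ref, alt, kind, g))
    return TruthSet(mutations=mutations, line_rates=line_rates,
                    spectrum_probs=spectrum, context_boosts=dict(boosts),
                    indel_fraction=indel_fraction, generations=t)


def spike_in_probes(genome: SyntheticGenome, spacing: int = 27000) -> list[Mutation]:
    """Plant synthetic known-site probe mutations every ``spacing`` bp.

    One probe per full spacing interval per contig, at the interval
    midpoint; positions are deterministic. Probes carry a transition
    alternate allele and an empty line id (line assignment happens when the
    call records are emitted).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    probes = []
    for c in genome.contigs:
        for i in range(len(c.seq) // spacing):
            pos = i * spacing + spacing // 2
            ref = c.seq[pos]
            if ref not in "ACGT":
                continue
            probes.append(Mutation("", c.name, pos, ref, _TRANSITION[ref],
                                   "SNM", 1))
    return probes


@dataclass
class NoiseModel:
    """Parametric per-site call-quality noise.

    All fractions default to zero (noiseless closure: every truth SNM in
    callable territory is recovered). ``realistic()`` returns settings that
    emulate the ~72% callable rate of the study this generator mirrors.
    """

    low_mq_frac: float = 0.0        # fraction of genome in low-MQ regions
    low_mq_region_len: int = 500
    low_qual_frac: float = 0.0      # fraction of sites with QUAL below threshold
    low_gq_frac: float = 0.0        # fraction of sites with <3 lines at GQ 99
    dp_mean: float = 546.0          # combined depth (26 lines at ~21X)
    dp_sd: float = 0.0
    line_dp_mean: float = 21.0
    shared_artifact_rate: float = 0.0   # per-bp rate of >=14-line alt artifacts
    fp_singleton_rate: float = 0.0      # per-bp rate of rejectable singletons

    @classmethod
    def realistic(cls) -> "NoiseModel":
        return cls(low_mq_frac=0.08, low_qual_frac=0.04, low_gq_frac=0.03,
                   dp_sd=120.0, shared_artifact_rate=2e-5,
                   fp_singleton_rate=2e-5)


def emit_call_records(genome: SyntheticGenome, truth: TruthSet,
                      noise: NoiseModel | None = None, seed: int = 0,
                      probes: list[Mutation] | None = None) -> CallSet:
    """Emit the multi-line call records implied by a truth set.

    Produces per-site summary stats (MQ/QUAL/combined DP/GQ-99 line count)
    for every genomic site plus a variant-record table holding the truth
    mutations, optional spike-in probes (assigned round-robin to lines),
    false-positive singletons that the candidate filters must reject, and
    shared-alt alignment artifacts that trigger the neighborhood filter.
    Use :func:`mamut.io.write_vcf` to serialize as multi-sample VCF v4.2.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    lines = sorted(truth.line_rates) or ["line_1"]
    stats: dict[str, SiteStats] = {}
    artifact_positions: dict[str, list[int]] = {}
    var_rows: list[dict] = []
    for c in genome.contigs:
        n = len(c.seq)
        mq = np.full(n, 60.0)
        if noise.low_mq_frac > 0:
            n_regions = max(1, int(noise.low_mq_frac * n
                                   / noise.low_mq_region_len))
            starts = rng.integers(0, max(1, n - noise.low_mq_region_len),
                                  size=n_regions)
            for s in starts:
                mq[s:s + noise.low_mq_region_len] = rng.uniform(10, 49.9)
        qual = np.full(n, 1500.0)
        if noise.low_qual_frac > 0:
            idx = rng.random(n) < noise.low_qual_frac
            qual[idx] = rng.uniform(0, 69.9, size=int(idx.sum()))
        if noise.dp_sd > 0:
            dp = np.clip(rng.normal(noise.dp_mean, noise.dp_sd, size=n),
                         0, None).round()
        else:
            dp = np.full(n, noise.dp_mean)
        ngq = np.full(n, len(lines), dtype=np.int16)
        if noise.low_gq_frac > 0:
            idx = rng.random(n) < noise.low_gq_frac
            ngq[idx] = rng.integers(0, 3, size=int(idx.sum()))
        stats[c.name] = SiteStats(mq, qual, dp, ngq)
        # shared-alt artifact sites (>=14 lines with >1/6 alt reads)
        arts = []
        if noise.shared_artifact_rate > 0:
            k = rng.poisson(noise.shared_artifact_rate * n)
            arts = sorted(int(p) for p in rng.integers(0, n, size=k))
        artifact_positions[c.name] = arts
        for pos in arts:
            ref = c.seq[pos]
            if ref not in "ACGT":
                continue
            var_rows.append(_variant_row(
                c.name, pos, ref, _TRANSITION[ref], qual[pos], mq[pos],
                dp[pos], focal_line=None, n_alt_lines=0, focal_gq=-1,
                focal_dp=0, n_ref=0, n_alt=0,
                n_highalt=int(14 + rng.poisson(3)), origin="artifact"))
        # rejectable false-positive singletons (low GQ or ref-read excess)
        if noise.fp_singleton_rate > 0:
            k = rng.poisson(noise.fp_singleton_rate * n)
            for pos in rng.integers(0, n, size=k):
                ref = c.seq[pos]
                if ref not in "ACGT":
                    continue
                line = lines[int(rng.integers(len(lines)))]
                if rng.random() < 0.5:  # low genotype quality
                    gq, fdp, nref = int(rng.integers(20, 99)), 12, 0
                else:                    # too many reference reads
                    gq, fdp, nref = 99, 12, int(rng.integers(3, 7))
                var_rows.append(_variant_row(
                    c.name, int(pos), ref, _TRANSITION[ref], qual[pos],
                    mq[pos], dp[pos], focal_line=line, n_alt_lines=1,
                    focal_gq=gq, focal_dp=fdp, n_ref=nref, n_alt=fdp - nref,
                    n_highalt=1, origin="fp"))

    def _truth_row(m: Mutation, line: str, origin: str):
        st = stats[m.contig]
        fdp = max(6, int(rng.poisson(noise.line_dp_mean)))
        var_rows.append(_variant_row(
            m.contig, m.pos, m.ref, m.alt, st.qual[m.pos], st.mq[m.pos],
            st.dp[m.pos], focal_line=line, n_alt_lines=1, focal_gq=99,
            focal_dp=fdp, n_ref=0, n_alt=fdp, n_highalt=1, origin=origin))

    for m in truth.mutations:
        _truth_row(m, m.line_id, "truth")
    for i, p in enumerate(probes or []):
        _truth_row(p, lines[i % len(lines)], "probe")

    variants = pd.DataFrame(var_rows, columns=VARIANT_COLUMNS) \
        if var_rows else empty_variants()
    variants = variants.sort_values(["contig", "pos"], kind="stable") \
        .reset_index(drop=True)
    return CallSet(lines=lines, contig_lengths=genome.lengths,
                   contig_classes=genome.classes, site_stats=stats,
                   variants=variants)


def _variant_row(contig, pos, ref, alt, qual, mq, site_dp, focal_line,
                 n_alt_lines, focal_gq, focal_dp, n_ref, n_alt, n_highalt,
                 origin) -> dict:
    return {
        "contig": contig, "pos": int(pos), "ref": ref, "alt": alt,
        "qual": float(qual), "mq": float(mq), "site_dp": float(site_dp),
        "focal_line": focal_line, "n_alt_lines": int(n_alt_lines),
        "focal_gq": int(focal_gq), "focal_dp": int(focal_dp),
        "focal_ref_reads": int(n_ref), "focal_alt_reads": int(n_alt),
        "n_lines_highalt": int(n_highalt), "n_alts": 1,
        "alt_lines": (focal_line,) if focal_line else (),
        "origin": origin,
    }
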