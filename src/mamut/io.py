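"""Format readers and writers: FASTA, multi-sample VCF, BED, TSV, config.

Internal coordinates are 0-based half-open everywhere; VCF positions are
1-based and BED intervals 0-based half-open, per their standards.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from .callset import CallSet, SiteStats, empty_variants, VARIANT_COLUMNS
from .calling import CallableMask
from .synth import Contig, SyntheticGenome
from .types import Mutation


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(genome: SyntheticGenome, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for c in genome.contigs:
            fh.write(f">{c.name} class={c.klass}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i:i + width] + "\n")


def read_genome(path, organelles: dict[str, str] | None = None
                ) -> SyntheticGenome:
    """Read a FASTA reference into a SyntheticGenome-compatible structure.

    Soft-masked (lowercase) bases are uppercased; a ``class=`` tag on the
    header line, or the ``organelles`` mapping (name -> plastid/
    mitochondrial), assigns non-nuclear contigs.
    """
    organelles = organelles or {}
    contigs = []
    try:
        fa = Fasta(str(path), read_long_names=True)
    except Exception as exc:
        raise ValueError(f"could not read FASTA {path}: {exc}") from exc
    for long_name in fa.keys():
        name = long_name.split()[0]
        klass = "nuclear"
        for tok in long_name.split()[1:]:
            if tok.startswith("class="):
                klass = tok.split("=", 1)[1]
        klass = organelles.get(name, klass)
        seq = str(fa[long_name][:]).upper()
        contigs.append(Contig(name, seq, klass))
    gc_vals = [c.seq for c in contigs]
    genome = SyntheticGenome(contigs=contigs, target_gc=0.0)
    genome.target_gc = genome.gc() if gc_vals else 0.0
    return genome


# ---------------------------------------------------------------------------
# BED

def write_bed(intervals: pd.DataFrame, path, name_col: str | None = None
              ) -> None:
    cols = ["contig", "start", "end"] + ([name_col] if name_col else [])
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def write_mask_bed(mask: CallableMask, path) -> None:
    rows = []
    for contig, iv in mask.intervals.items():
        for a, b in iv:
            rows.append((contig, int(a), int(b)))
    pd.DataFrame(rows, columns=["contig", "start", "end"]).to_csv(
        path, sep="\t", header=False, index=False)


def read_mask_bed(path, contig_classes: dict[str, str] | None = None
                  ) -> CallableMask:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["contig", "start", "end"])
    intervals = {
        c: g[["start", "end"]].to_numpy(dtype=np.int64)
        for c, g in df.groupby("contig")}
    return CallableMask(intervals=intervals,
                        contig_classes=contig_classes or {})


# ---------------------------------------------------------------------------
# VCF

def write_vcf(cs: CallSet, path, all_sites: bool = False,
              genome: SyntheticGenome | None = None) -> None:
    """Serialize a CallSet as multi-sample VCF v4.2 (haploid genotypes).

    With ``all_sites`` every genomic position is written (REF from
    ``genome`` when supplied), so the per-site summary stats round-trip
    through :func:`read_calls`; otherwise only variant records appear.
    """
    lines = cs.lines
    var_by_site: dict[tuple[str, int], list] = {}
    for row in cs.variants.itertuples(index=False):
        var_by_site.setdefault((row.contig, row.pos), []).append(row)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mamut\n")
        for contig, length in cs.contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,'
                 'Description="RMS mapping quality">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,'
                 'Description="Combined depth across samples">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                 'Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                 'Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(lines) + "\n")
        for contig, length in cs.contig_lengths.items():
            st = cs.site_stats.get(contig)
            positions = (range(length) if all_sites else
                         sorted({p for (c, p) in var_by_site if c == contig}))
            seq = genome.sequence(contig) if genome is not None else None
            for pos in positions:
                rows = var_by_site.get((contig, pos))
                if rows:
                    for row in rows:
                        fh.write(_vcf_variant_line(row, lines, st))
                elif all_sites and st is not None:
                    fh.write(_vcf_invariant_line(contig, pos, seq, lines, st))


def _fmt_qual(q) -> str:
    return "." if q is None or (isinstance(q, float) and np.isnan(q)) \
        else f"{q:g}"


def _vcf_variant_line(row, lines, st) -> str:
    n = len(lines)
    per_line_dp = max(1, int(round(row.site_dp / max(n, 1))))
    alt_lines = set(row.alt_lines)
    n_high_extra = max(0, row.n_lines_highalt - len(alt_lines))
    samples = []
    high_budget = n_high_extra
    for line in lines:
        if line in alt_lines:
            dp = row.focal_dp or per_line_dp
            nref, nalt = row.focal_ref_reads, row.focal_alt_reads or dp
            gq = row.focal_gq if row.focal_gq >= 0 else 99
            samples.append(f"1:{dp}:{nref},{nalt}:{gq}")
        elif high_budget > 0:
            nalt = max(1, int(per_line_dp * 0.3))
            samples.append(f"0:{per_line_dp}:{per_line_dp - nalt},{nalt}:99")
            high_budget -= 1
        else:
            samples.append(f"0:{per_line_dp}:{per_line_dp},0:99")
    return (f"{row.contig}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t"
            f"{_fmt_qual(row.qual)}\t.\t"
            f"MQ={row.mq:g};DP={int(round(row.site_dp))}\tGT:DP:AD:GQ\t"
            + "\t".join(samples) + "\n")


def _vcf_invariant_line(contig, pos, seq, lines, st) -> str:
    ref = seq[pos] if seq is not None else "N"
    n = len(lines)
    per_line_dp = max(0, int(round(st.dp[pos] / max(n, 1))))
    ngq = int(st.n_gq99[pos])
    samples = []
    for i in range(n):
        gq = 99 if i < ngq else 50
        samples.append(f"0:{per_line_dp}:{per_line_dp},0:{gq}")
    mq = st.mq[pos]
    dp_info = f"DP={int(round(st.dp[pos]))}"
    info = f"MQ={mq:g};{dp_info}" if not np.isnan(mq) else dp_info
    return (f"{contig}\t{pos + 1}\t.\t{ref}\t.\t{_fmt_qual(st.qual[pos])}\t"
            f".\t{info}\tGT:DP:AD:GQ\t" + "\t".join(samples) + "\n")


def read_calls(path, contig_classes: dict[str, str] | None = None,
               highalt_fraction: float = 1 / 6) -> CallSet:
    """Read a multi-sample VCF into a CallSet.

    Sites absent from the file (or with missing required fields) keep NaN
    summary stats and are treated as non-callable. Multiallelic records
    are retained with ``n_alts`` set so the biallelic filter can reject
    them.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    stats = {
        c: SiteStats(mq=np.full(n, np.nan), qual=np.full(n, np.nan),
                     dp=np.zeros(n), n_gq99=np.zeros(n, dtype=np.int16))
        for c, n in lengths.items()}
    var_rows = []
    for v in vcf:
        contig, pos = v.CHROM, v.POS - 1
        st = stats[contig]
        mq = v.INFO.get("MQ")
        st.mq[pos] = np.nan if mq is None else float(mq)
        st.qual[pos] = np.nan if v.QUAL is None else float(v.QUAL)
        def _fmt(tag):
            try:
                return v.format(tag)
            except KeyError:     # tag absent from the header
                return None

        dps = _fmt("DP")
        gqs = _fmt("GQ")
        ads = _fmt("AD")
        dp_arr = (np.clip(dps.astype(float), 0, None).ravel()
                  if dps is not None else np.zeros(len(lines)))
        site_dp = v.INFO.get("DP")
        st.dp[pos] = (float(site_dp) if site_dp is not None
                      else float(np.nansum(dp_arr)))
        genotypes = v.genotypes
        haploid = [len(g) == 2 for g in genotypes]  # [allele, phased]
        alleles = np.array([g[0] for g in genotypes])
        if gqs is not None:
            gq_arr = gqs.astype(float).ravel()
            st.n_gq99[pos] = int(sum(
                1 for i in range(len(lines))
                if haploid[i] and gq_arr[i] == 99))
        else:
            gq_arr = np.full(len(lines), np.nan)
        if not v.ALT:
            continue
        alt_idx = np.flatnonzero(alleles > 0)
        n_high = 0
        if ads is not None:
            ad = np.clip(ads.astype(float), 0, None)
            reads = ad.sum(axis=1)
            alt_reads = reads - ad[:, 0]
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(reads > 0, alt_reads / reads, 0.0)
            n_high = int((frac > highalt_fraction).sum())
        focal = lines[alt_idx[0]] if len(alt_idx) == 1 else None
        f_dp = f_gq = -1
        f_ref = f_alt = 0
        if focal is not None:
            i = alt_idx[0]
            f_dp = int(dp_arr[i]) if not np.isnan(dp_arr[i]) else 0
            f_gq = int(gq_arr[i]) if not np.isnan(gq_arr[i]) else -1
            if ads is not None:
                f_ref = int(ad[i, 0])
                f_alt = int(ad[i, 1:].sum())
        var_rows.append({
            "contig": contig, "pos": pos, "ref": v.REF, "alt": v.ALT[0],
            "qual": st.qual[pos], "mq": st.mq[pos], "site_dp": st.dp[pos],
            "focal_line": focal, "n_alt_lines": int(len(alt_idx)),
            "focal_gq": f_gq, "focal_dp": max(f_dp, 0),
            "focal_ref_reads": f_ref, "focal_alt_reads": f_alt,
            "n_lines_highalt": n_high, "n_alts": len(v.ALT),
            "alt_lines": tuple(lines[i] for i in alt_idx),
            "origin": "input"})
    variants = pd.DataFrame(var_rows, columns=VARIANT_COLUMNS) \
        if var_rows else empty_variants()
    classes = contig_classes or {}
    return CallSet(lines=lines, contig_lengths=lengths,
                   contig_classes={c: classes.get(c, "nuclear")
                                   for c in lengths},
                   site_stats=stats, variants=variants)


# ---------------------------------------------------------------------------
# mutation tables

def mutations_to_frame(muts: list[Mutation]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in muts],
                        columns=["line_id", "contig", "pos", "ref", "alt",
                                 "kind", "length"])


def frame_to_mutations(df: pd.DataFrame) -> list[Mutation]:
    return [Mutation(r.line_id, r.contig, int(r.pos), r.ref, r.alt, r.kind,
                     int(r.length)) for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# config and provenance

def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def write_table(df: pd.DataFrame, path, cfg_hash: str = "", seed=None,
                float_format: str = "%.6g") -> None:
    """TSV with a provenance header comment (config hash + seed)."""
    with open(path, "w") as fh:
        fh.write(f"# mamut config={cfg_hash or 'n/a'} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
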