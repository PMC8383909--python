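"""In-memory representation of a multi-line call set.

A :class:`CallSet` stores, per contig, the per-site summary fields the
filter cascade consumes (site MQ, QUAL, combined DP across lines, number of
haploid lines at maximum genotype quality) as dense numpy arrays, plus a
table of variant records. It can be built by the synthetic-data generator,
or reconstructed from an all-sites multi-sample VCF via
:func:`mamut.io.read_calls`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import SiteCall

GQ_MAX = 99

#: columns of the variant-record table
VARIANT_COLUMNS = [
    "contig",      # contig name
    "pos",         # 0-based position
    "ref",
    "alt",
    "qual",        # site QUAL
    "mq",          # site MQ
    "site_dp",     # combined depth over lines
    "focal_line",  # line carrying the alternate genotype (None if 0 or >1)
    "n_alt_lines",     # number of lines with an alternate genotype
    "focal_gq",
    "focal_dp",        # focal-line read depth
    "focal_ref_reads",
    "focal_alt_reads",
    "n_lines_highalt",  # lines with >1/6 alt-read fraction (any genotype)
    "n_alts",          # number of ALT alleles at the site
    "alt_lines",       # tuple of line ids with an alternate genotype
    "origin",          # synthetic provenance tag (truth/probe/fp/artifact)
]


@dataclass
class SiteStats:
    """Per-contig dense arrays of site-level summary fields."""

    mq: np.ndarray
    qual: np.ndarray
    dp: np.ndarray       # combined DP over all lines
    n_gq99: np.ndarray   # haploid lines with GQ == 99

    def __len__(self):
        return len(self.mq)


@dataclass
class CallSet:
    lines: list[str]
    contig_lengths: dict[str, int]
    contig_classes: dict[str, str]  # nuclear / plastid / mitochondrial
    site_stats: dict[str, SiteStats]
    variants: pd.DataFrame = field(default_factory=lambda: empty_variants())

    @property
    def contigs(self) -> list[str]:
        return list(self.contig_lengths)

    def contig_class(self, contig: str) -> str:
        return self.contig_classes.get(contig, "nuclear")

    @classmethod
    def from_site_calls(cls, records: list[SiteCall],
                        contig_lengths: dict[str, int] | None = None,
                        contig_classes: dict[str, str] | None = None,
                        highalt_fraction: float = 1 / 6) -> "CallSet":
        """Aggregate per-line :class:`SiteCall` records into a CallSet.

        Intended for small hand-built fixtures and for streaming VCF input.
        Sites not present in ``records`` are treated as non-callable
        (missing fields), per the filter contract.
        """
        if not records:
            raise ValueError("no records supplied")
        lines = sorted({r.line_id for r in records})
        df = pd.DataFrame([{
            "contig": r.contig, "pos": r.pos - 1, "line_id": r.line_id,
            "ref": r.ref, "alts": r.alts, "qual": r.qual, "mq": r.mq,
            "dp": r.dp, "gq": r.gq, "n_ref": r.n_ref_reads,
            "n_alt": r.n_alt_reads, "haploid": r.haploid, "is_alt": r.is_alt,
        } for r in records])
        if contig_lengths is None:
            contig_lengths = {
                c: int(g["pos"].max()) + 1 for c, g in df.groupby("contig")
            }
        stats: dict[str, SiteStats] = {}
        var_rows = []
        for contig, cg in df.groupby("contig"):
            n = contig_lengths[contig]
            mq = np.full(n, np.nan)
            qual = np.full(n, np.nan)
            dp = np.zeros(n)
            ngq = np.zeros(n, dtype=np.int16)
            for pos, sg in cg.groupby("pos"):
                mq[pos] = sg["mq"].iloc[0]
                qual[pos] = sg["qual"].iloc[0]
                dp[pos] = sg["dp"].sum()
                ngq[pos] = int(((sg["gq"] == GQ_MAX) & sg["haploid"]).sum())
                alt_rows = sg[sg["is_alt"]]
                reads = sg["n_ref"] + sg["n_alt"]
                highalt = int((sg["n_alt"] > highalt_fraction
                               * reads.where(reads > 0, sg["dp"])).sum())
                if len(alt_rows) or highalt:
                    focal = alt_rows.iloc[0] if len(alt_rows) == 1 else None
                    alts = sg["alts"].iloc[0]
                    var_rows.append({
                        "contig": contig, "pos": int(pos),
                        "ref": sg["ref"].iloc[0],
                        "alt": alts[0] if alts else ".",
                        "qual": sg["qual"].iloc[0], "mq": sg["mq"].iloc[0],
                        "site_dp": float(sg["dp"].sum()),
                        "focal_line": focal["line_id"] if focal is not None else None,
                        "n_alt_lines": int(len(alt_rows)),
                        "focal_gq": int(focal["gq"]) if focal is not None else -1,
                        "focal_dp": int(focal["dp"]) if focal is not None else 0,
                        "focal_ref_reads": int(focal["n_ref"]) if focal is not None else 0,
                        "focal_alt_reads": int(focal["n_alt"]) if focal is not None else 0,
                        "n_lines_highalt": highalt,
                        "n_alts": len(alts),
                        "alt_lines": tuple(alt_rows["line_id"]),
                        "origin": "input",
                    })
            stats[contig] = SiteStats(mq, qual, dp, ngq)
        variants = pd.DataFrame(var_rows, columns=VARIANT_COLUMNS) \
            if var_rows else empty_variants()
        classes = contig_classes or {}
        return cls(lines=lines, contig_lengths=dict(contig_lengths),
                   contig_classes={c: classes.get(c, "nuclear")
                                   for c in contig_lengths},
                   site_stats=stats, variants=variants)


def empty_variants() -> pd.DataFrame:
    return pd.DataFrame(columns=VARIANT_COLUMNS)
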