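"""Domain types shared by the simulation, calling and downstream modules."""
from __future__ import annotations

from dataclasses import dataclass, field

VARIANT_CLASSES = ("SNM", "INS", "DEL", "INV")


@dataclass(frozen=True)
class Mutation:
    """An accepted de novo variant in one MA line.

    Positions are 0-based contig coordinates (VCF emission converts to
    1-based). ``length`` is 1 for SNMs and the number of inserted/deleted
    bases for INDELs.
    """

    line_id: str
    contig: str
    pos: int
    ref: str
    alt: str
    kind: str = "SNM"
    length: int = 1

    def __post_init__(self):
        if self.kind not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.kind!r}")
        if self.kind == "SNM":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("SNM ref and alt must be single bases")
            if self.ref == self.alt:
                raise ValueError("SNM ref and alt must differ")
        elif self.kind in ("INS", "DEL") and self.length < 1:
            raise ValueError("INDEL length must be >= 1")


@dataclass(frozen=True)
class SiteCall:
    """One genomic site in one line, as read from a multi-sample VCF.

    ``pos`` is 1-based here because this type mirrors the VCF record; it is
    converted to 0-based coordinates when aggregated into a
    :class:`~mamut.callset.CallSet`. ``dp`` is the per-line read depth;
    ``DP >= n_ref_reads + n_alt_reads`` is caller-dependent and not required.
    """

    contig: str
    pos: int
    line_id: str
    ref: str
    alts: tuple[str, ...]
    qual: float
    mq: float
    dp: int
    gq: int
    n_ref_reads: int = 0
    n_alt_reads: int = 0
    haploid: bool = True
    is_alt: bool = False


@dataclass
class LineMeta:
    """Per-line metadata: transfer count and colony-count growth assays.

    ``assays`` holds (N0, Nt) colony counts, one pair per assayed transfer
    period. Generations are derived via
    :func:`mamut.rates.generations_from_colonies`.
    """

    line_id: str
    n_transfers: int = 0
    assays: list[tuple[float, float]] = field(default_factory=list)
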