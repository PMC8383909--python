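"""Folded SNM spectrum, GC-corrected deviations and Ka/Ks.

Single-nucleotide mutations are folded into six strand-collapsed types
(reference base A or C). Under equal per-type rates, the expected share
of each C-source type in a genome with GC fraction g is g/3, and of each
A-source type (1−g)/3; the deviation of a type is its observed share
divided by that expectation. In a 66% GC genome an observed C→T share of
52% therefore corresponds to a 2.36-fold deviation.

Ka/Ks on concatenated mutated coding sequence uses equal-weight pathway
counting (NG86-style): per-codon synonymous/nonsynonymous site fractions
summed over the sequence, observed substitutions classified by codon
effect, ratio = (N_obs/N_sites) / (S_obs/S_sites).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._dna import complement_base

FOLDED_TYPES = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")

CODON_TABLE = {}
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, _a in enumerate(_BASES):
    for _j, _b in enumerate(_BASES):
        for _k, _c in enumerate(_BASES):
            CODON_TABLE[_a + _b + _c] = _AA[16 * _i + 4 * _j + _k]


def fold_snm(ref: str, alt: str) -> str:
    """Collapse an SNM onto the strand where the reference base is A or C."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        raise ValueError(f"not a valid SNM: {ref}>{alt}")
    if ref in "GT":
        ref, alt = complement_base(ref), complement_base(alt)
    return f"{ref}>{alt}"


def spectrum_counts(mutations) -> dict[str, int]:
    """Folded-type counts from an iterable of SNM Mutation objects."""
    counts = {t: 0 for t in FOLDED_TYPES}
    for m in mutations:
        if m.kind == "SNM":
            counts[fold_snm(m.ref, m.alt)] += 1
    return counts


@dataclass
class SpectrumTable:
    counts: dict[str, int]
    gc: float
    observed_share: dict[str, float]
    expected_share: dict[str, float]
    deviation: dict[str, float]
    chi2: float
    p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "type": list(FOLDED_TYPES),
            "count": [self.counts[t] for t in FOLDED_TYPES],
            "observed_share": [self.observed_share[t] for t in FOLDED_TYPES],
            "expected_share": [self.expected_share[t] for t in FOLDED_TYPES],
            "deviation": [self.deviation[t] for t in FOLDED_TYPES],
        })


def gc_corrected_spectrum(counts, gc: float) -> SpectrumTable:
    """Observed/expected deviation of each folded type after GC correction.

    ``counts`` maps folded types to counts (or is a 6-sequence in
    FOLDED_TYPES order). Expected shares under equal per-type rates are
    gc/3 for C-source and (1−gc)/3 for A-source types; a χ² goodness-of-
    fit test against those shares is attached.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    if not isinstance(counts, dict):
        counts = dict(zip(FOLDED_TYPES, counts))
    if set(counts) != set(FOLDED_TYPES):
        raise ValueError("counts must cover the six folded SNM types")
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total count must be positive")
    expected = {t: (gc / 3 if t.startswith("C") else (1 - gc) / 3)
                for t in FOLDED_TYPES}
    observed = {t: counts[t] / total for t in FOLDED_TYPES}
    deviation = {t: observed[t] / expected[t] for t in FOLDED_TYPES}
    obs = np.array([counts[t] for t in FOLDED_TYPES], dtype=float)
    exp = np.array([expected[t] * total for t in FOLDED_TYPES])
    chi2, p = stats.chisquare(obs, exp)
    return SpectrumTable(counts=dict(counts), gc=gc,
                         observed_share=observed, expected_share=expected,
                         deviation=deviation, chi2=float(chi2), p=float(p))


def spectrum_ratio(table_a: SpectrumTable, table_b: SpectrumTable
                   ) -> dict[str, float]:
    """Per-type deviation ratio A/B (cross-dataset spectrum comparison)."""
    out = {}
    for t in FOLDED_TYPES:
        if table_b.deviation[t] == 0:
            raise ValueError(f"zero deviation for {t} in reference table")
        out[t] = table_a.deviation[t] / table_b.deviation[t]
    return out


# ---------------------------------------------------------------------------
# Ka/Ks

def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon (sum = 3)."""
    aa = CODON_TABLE[codon]
    syn = 0.0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt_codon = codon[:i] + b + codon[i + 1:]
            if CODON_TABLE[alt_codon] == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: float
    syn_sites: float
    nonsyn_sites: float
    syn_obs: int
    nonsyn_obs: int
    fisher_p: float


def ka_ks(cds_concat: str, mutations_in_cds: list[tuple[int, str]]
          ) -> KaKsResult:
    """Ka/Ks from substitutions on a concatenated coding sequence.

    ``mutations_in_cds`` holds (0-based position in the concatenated
    sequence, alternate base) pairs. Site fractions are counted per codon
    with equal pathway weights; substitutions are classified by their
    codon effect (changes creating or destroying stop codons count as
    nonsynonymous). A Fisher exact test compares observed substitution
    counts against the site counts.
    """
    cds = cds_concat.upper()
    if len(cds) % 3 != 0:
        raise ValueError("concatenated CDS length must be divisible by 3")
    syn_sites = nonsyn_sites = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        if any(b not in "ACGT" for b in codon):
            continue
        s, n = _codon_site_fractions(codon)
        syn_sites += s
        nonsyn_sites += n
    syn_obs = nonsyn_obs = 0
    for pos, alt in mutations_in_cds:
        if not 0 <= pos < len(cds):
            raise ValueError(f"position {pos} outside the CDS")
        ci = (pos // 3) * 3
        codon = cds[ci:ci + 3]
        off = pos - ci
        if codon[off] == alt:
            raise ValueError(f"alt equals reference at {pos}")
        alt_codon = codon[:off] + alt + codon[off + 1:]
        if CODON_TABLE[alt_codon] == CODON_TABLE[codon]:
            syn_obs += 1
        else:
            nonsyn_obs += 1
    ka = nonsyn_obs / nonsyn_sites if nonsyn_sites > 0 else np.nan
    ks = syn_obs / syn_sites if syn_sites > 0 else np.nan
    ratio = ka / ks if ks and ks > 0 else (0.0 if ka == 0 else np.inf)
    table = [[nonsyn_obs, syn_obs],
             [int(round(nonsyn_sites)), int(round(syn_sites))]]
    fisher_p = float(stats.fisher_exact(table).pvalue)
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, syn_sites=syn_sites,
                      nonsyn_sites=nonsyn_sites, syn_obs=syn_obs,
                      nonsyn_obs=nonsyn_obs, fisher_p=fisher_p)


def plot_deviation(table: SpectrumTable, path=None, ax=None):
    """Bar plot of per-type GC-corrected deviations (Fig.-style summary)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 3))
    types = list(FOLDED_TYPES)
    heights = [table.deviation[t] for t in types]
    colors = ["#9ecae1" if t.startswith("A") else "#3182bd" for t in types]
    ax.bar(types, heights, color=colors)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("observed / expected")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
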