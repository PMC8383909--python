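"""Alternate-DNA-conformation motif detection and enrichment.

Scans short windows for sequence motifs associated with non-B DNA:
palindromes (inverted repeats; hairpin/cruciform-forming), mirrors
(mirror repeats; H-DNA-related), G-quadruplex tracts and triplex motifs
(homopurine/homopyrimidine mirror repeats). All thresholds are
configurable because the published scanners these mirror do not document
their settings; cross-tool numeric identity is not claimed.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._dna import revcomp

PURINES = set("AG")
PYRIMIDINES = set("CT")


@dataclass(frozen=True)
class MotifParams:
    palindrome_arm: int = 5
    palindrome_loop: tuple[int, int] = (0, 5)
    mirror_arm: int = 5
    mirror_loop: tuple[int, int] = (0, 5)
    g_run: int = 3
    g_loop: tuple[int, int] = (1, 7)
    g_tracts: int = 4
    triplex_arm: int = 6
    triplex_loop_max: int = 8


@dataclass
class MotifHits:
    palindrome: int
    mirror: int
    g_quadruplex: int
    triplex: int
    window_length: int

    def as_dict(self) -> dict[str, int]:
        return {"palindrome": self.palindrome, "mirror": self.mirror,
                "g_quadruplex": self.g_quadruplex, "triplex": self.triplex}


def _count_arm_loop(seq: str, arm: int, loop: tuple[int, int],
                    match) -> int:
    """Count arm–loop–arm occurrences where ``match(left, right)`` holds."""
    n = len(seq)
    hits = 0
    for a in range(arm, n // 2 + 1):
        for g in range(loop[0], loop[1] + 1):
            span = 2 * a + g
            if span > n:
                break
            for i in range(n - span + 1):
                left = seq[i:i + a]
                right = seq[i + a + g: i + span]
                if match(left, right, seq[i:i + span]):
                    hits += 1
    return hits


def detect_motifs(seq: str, params: MotifParams | None = None) -> MotifHits:
    """Count palindrome, mirror, G-quadruplex and triplex motifs in ``seq``.

    Palindrome: arm ≥ 5 bp equal to the reverse complement of the
    opposite arm, loop 0–5. Mirror: arm equal to the reverse of the
    opposite arm. G4: four runs of ≥ 3 G separated by 1–7 nt loops
    (either strand). Triplex: homopurine or homopyrimidine mirror repeat,
    arm ≥ 6, loop ≤ 8.
    """
    p = params or MotifParams()
    seq = seq.upper()
    pal = _count_arm_loop(
        seq, p.palindrome_arm, p.palindrome_loop,
        lambda l, r, _s: r == revcomp(l))
    mir = _count_arm_loop(
        seq, p.mirror_arm, p.mirror_loop,
        lambda l, r, _s: r == l[::-1])
    g4_re = re.compile(
        "G{%d,}" % p.g_run
        + ("(?:[ACGT]{%d,%d}G{%d,})" % (p.g_loop[0], p.g_loop[1], p.g_run))
        * (p.g_tracts - 1))
    g4 = len(g4_re.findall(seq)) + len(g4_re.findall(revcomp(seq)))

    def _triplex(l, r, s):
        return (r == l[::-1]
                and (set(s) <= PURINES or set(s) <= PYRIMIDINES))

    tri = _count_arm_loop(seq, p.triplex_arm, (0, p.triplex_loop_max),
                          _triplex)
    return MotifHits(palindrome=pal, mirror=mir, g_quadruplex=g4,
                     triplex=tri, window_length=len(seq))


def _window(seq: str, pos: int, radius: int) -> str | None:
    if pos - radius < 0 or pos + radius + 1 > len(seq):
        return None
    return seq[pos - radius: pos + radius + 1]


def motif_enrichment(genome, mutation_sites: pd.DataFrame,
                     random_sites: pd.DataFrame, radius: int = 10,
                     n_boot: int = 1000, seed: int = 0,
                     params: MotifParams | None = None) -> pd.DataFrame:
    """Per-motif enrichment of windows around mutated vs random sites.

    For each motif class: the proportion of site-centred windows
    (site ± radius) containing ≥ 1 motif in each group, the fold ratio,
    a Kruskal–Wallis rank test on the binary indicators, and bootstrap
    95% CIs of the proportions (``n_boot`` resamples).
    """
    if mutation_sites.empty or random_sites.empty:
        raise ValueError("both site groups must be non-empty")
    rng = np.random.default_rng(seed)

    def indicators(sites):
        flags = {k: [] for k in ("palindrome", "mirror", "g_quadruplex",
                                 "triplex")}
        for row in sites.itertuples(index=False):
            win = _window(genome.sequence(row.contig), int(row.pos), radius)
            if win is None:
                continue
            hits = detect_motifs(win, params).as_dict()
            for k in flags:
                flags[k].append(1 if hits[k] > 0 else 0)
        return {k: np.array(v) for k, v in flags.items()}

    mut = indicators(mutation_sites)
    ran = indicators(random_sites)
    rows = []
    for motif in ("palindrome", "mirror", "g_quadruplex", "triplex"):
        a, b = mut[motif], ran[motif]
        if len(a) == 0 or len(b) == 0:
            raise ValueError("no windows survived edge filtering")
        pa, pb = a.mean(), b.mean()
        if a.std() == 0 and b.std() == 0 and pa == pb:
            p_value = 1.0
        else:
            p_value = float(stats.kruskal(a, b).pvalue)
        boots_a = rng.choice(a, size=(n_boot, len(a))).mean(axis=1)
        boots_b = rng.choice(b, size=(n_boot, len(b))).mean(axis=1)
        rows.append({
            "motif": motif, "prop_mutated": pa, "prop_random": pb,
            "fold": pa / pb if pb > 0 else np.inf,
            "p": p_value,
            "ci_low_mutated": float(np.percentile(boots_a, 2.5)),
            "ci_high_mutated": float(np.percentile(boots_a, 97.5)),
            "ci_low_random": float(np.percentile(boots_b, 2.5)),
            "ci_high_random": float(np.percentile(boots_b, 97.5)),
            "n_mutated": len(a), "n_random": len(b),
        })
    return pd.DataFrame(rows)
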