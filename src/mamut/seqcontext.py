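"""Per-site genomic-context features.

For a focal site the package computes, at four scales w ∈ {2, 10, 100,
1000} (window = site ± w, i.e. lengths 5, 21, 201, 2001):

* GC — window GC fraction;
* E — Shannon entropy of base composition, normalized to [0, 1]
  (0 for homopolymers, 1 for uniform composition);
* L — linguistic complexity, the ratio of distinct substrings present to
  the maximum possible number;

plus the Δ-statistics ΔGC/ΔE/ΔL: the standard deviation of the window
statistic across all fixed-length windows overlapping the site. Canonical
trinucleotide contexts (upstream/surrounding/downstream, centre base
collapsed to A or C via reverse complement), gene-feature class with
CDS > UTR > intron precedence, repeat class, and distances to the nearest
feature of each class complete the feature vector. Sites whose windows
leave the contig or contain ambiguity codes get missing values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._dna import encode, revcomp

DEFAULT_RADII = (2, 10, 100, 1000)

FEATURE_PRECEDENCE = ("CDS", "UTR5", "UTR3", "intron")


# ---------------------------------------------------------------------------
# scalar statistics

def shannon_entropy(seq: str) -> float:
    """Normalized Shannon entropy of base composition: −Σ p·log2 p / 2.

    1 when all four bases are equally frequent, 0 for a homopolymer.
    Ambiguity codes make the value undefined (NaN).
    """
    if not seq:
        raise ValueError("empty sequence")
    codes = encode(seq)
    if (codes < 0).any():
        return float("nan")
    counts = np.bincount(codes, minlength=4)
    p = counts[counts > 0] / len(codes)
    return float(-(p * np.log2(p)).sum() / 2.0)


def _lc_denominator(n: int, max_k: int) -> int:
    total = 0
    for k in range(1, max_k + 1):
        total += min(4 ** k if k < 32 else n, n - k + 1)
    return total


def linguistic_complexity(seq: str, max_k: int | None = None) -> float:
    """Distinct-substring ratio L ∈ (0, 1].

    L = (number of distinct substrings of length 1..K) / Σ_k min(4^k,
    |seq|−k+1), with K = |seq| by default. ``max_k`` caps the substring
    length; the windowed feature pipeline uses a cap because contributions
    of long substrings saturate (see ContextConfig.lc_max_k).
    """
    if not seq:
        raise ValueError("empty sequence")
    codes = encode(seq)
    if (codes < 0).any():
        return float("nan")
    n = len(seq)
    kmax = n if max_k is None else min(max_k, n)
    distinct = 0
    data = seq.encode()
    for k in range(1, kmax + 1):
        distinct += len({data[i:i + k] for i in range(n - k + 1)})
    return distinct / _lc_denominator(n, kmax)


def windowed_stats(genome, contig: str, pos: int, w: int,
                   lc_max_k: int | None = None) -> tuple[float, float, float]:
    """(GC, E, L) in the window site ± w (length 2w+1, site included).

    Near-edge sites (window not fully inside the contig) return NaNs and
    are excluded downstream.
    """
    seq = genome.sequence(contig)
    if pos - w < 0 or pos + w + 1 > len(seq):
        return (float("nan"),) * 3
    window = seq[pos - w: pos + w + 1]
    codes = encode(window)
    if (codes < 0).any():
        return (float("nan"),) * 3
    gc = float(((codes == 1) | (codes == 2)).mean())
    return gc, shannon_entropy(window), linguistic_complexity(window, lc_max_k)


def delta_stats(genome, contig: str, pos: int, W: int,
                lc_max_k: int | None = None, ddof: int = 0
                ) -> tuple[float, float, float]:
    """(ΔGC, ΔE, ΔL): SD of each statistic over the W windows of length W
    that contain the site. All windows must lie inside the contig."""
    seq = genome.sequence(contig)
    if pos - W + 1 < 0 or pos + W > len(seq):
        return (float("nan"),) * 3
    gcs, es, ls = [], [], []
    for start in range(pos - W + 1, pos + 1):
        window = seq[start:start + W]
        codes = encode(window)
        if (codes < 0).any():
            return (float("nan"),) * 3
        gcs.append(float(((codes == 1) | (codes == 2)).mean()))
        es.append(shannon_entropy(window))
        ls.append(linguistic_complexity(window, lc_max_k))
    return (float(np.std(gcs, ddof=ddof)), float(np.std(es, ddof=ddof)),
            float(np.std(ls, ddof=ddof)))


# ---------------------------------------------------------------------------
# canonical trinucleotide contexts

def canonicalize_contexts(up: str, mid: str, down: str
                          ) -> tuple[str, str, str]:
    """Collapse strand so the focal (centre) base is A or C.

    If the centre base is G or T, all three triplets are reverse
    complemented and upstream/downstream swap. Already-canonical contexts
    are returned unchanged.
    """
    centre = mid[1]
    if centre in "AC":
        return up, mid, down
    return revcomp(down), revcomp(mid), revcomp(up)


def trinucleotide_contexts(genome, contig: str, pos: int
                           ) -> tuple[str, str, str]:
    """Canonical (upstream, surrounding, downstream) triplets at a site.

    Upstream = [pos−2, pos], surrounding = [pos−1, pos+1], downstream =
    [pos, pos+2], then strand-collapsed so the focal base is A or C.
    Sites within 2 bp of a contig end (or with ambiguity codes in range)
    are missing.
    """
    seq = genome.sequence(contig)
    if pos < 2 or pos + 3 > len(seq):
        return ("", "", "")
    region = seq[pos - 2: pos + 3].upper()
    if any(b not in "ACGT" for b in region):
        return ("", "", "")
    return canonicalize_contexts(region[0:3], region[1:4], region[2:5])


def canonical_triplets(slot: str = "mid") -> list[str]:
    """The 32 canonical triplets for a context slot.

    After strand collapse the focal-site base (A or C) sits at position 3
    of the upstream triplet, 2 of the surrounding triplet and 1 of the
    downstream triplet, so each slot has its own 32-triplet space.
    """
    focal = {"up": 2, "mid": 1, "down": 0}[slot]
    out = []
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                tri = a + b + c
                if tri[focal] in "AC":
                    out.append(tri)
    return out


# ---------------------------------------------------------------------------
# feature classes and distances

def _class_intervals(annotation: pd.DataFrame, contig: str, klass: str
                     ) -> np.ndarray:
    sel = annotation[(annotation["contig"] == contig)
                     & (annotation["feature"] == klass)]
    if sel.empty:
        return np.empty((0, 2), dtype=np.int64)
    iv = sel[["start", "end"]].to_numpy(dtype=np.int64)
    return iv[np.argsort(iv[:, 0])]


def assign_feature_class(pos: int, annotation: pd.DataFrame,
                         contig: str) -> str:
    """Feature class at a site with precedence CDS > UTR5/UTR3 > intron;
    sites in no annotated feature are intergenic."""
    for klass in FEATURE_PRECEDENCE:
        iv = _class_intervals(annotation, contig, klass)
        if len(iv):
            i = int(np.searchsorted(iv[:, 0], pos, side="right")) - 1
            if i >= 0 and pos < iv[i, 1]:
                return klass
    return "intergenic"


def distance_to_feature(pos: int, annotation: pd.DataFrame, contig: str,
                        klass: str) -> float:
    """bp distance from a site to the nearest feature of a class
    (0 inside; NaN when the contig has no such feature)."""
    iv = _class_intervals(annotation, contig, klass)
    if not len(iv):
        return float("nan")
    i = int(np.searchsorted(iv[:, 0], pos, side="right")) - 1
    if i >= 0 and pos < iv[i, 1]:
        return 0.0
    cands = []
    if i >= 0:
        cands.append(pos - (iv[i, 1] - 1))
    if i + 1 < len(iv):
        cands.append(iv[i + 1, 0] - pos)
    return float(min(cands))


# ---------------------------------------------------------------------------
# vectorized per-contig machinery

def _cum(x: np.ndarray) -> np.ndarray:
    return np.concatenate([[0], np.cumsum(x)])


def _sliding_composition(codes: np.ndarray, W: int):
    """(gc, entropy, n_invalid) over all windows of length W (starts 0..L−W)."""
    L = len(codes)
    m = L - W + 1
    counts = np.empty((4, m))
    for b in range(4):
        c = _cum(codes == b)
        counts[b] = c[W:] - c[:-W]
    inv = _cum(codes < 0)
    n_invalid = inv[W:] - inv[:-W]
    gc = (counts[1] + counts[2]) / W
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / W
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1)), 0.0)
    entropy = -terms.sum(axis=0) / 2.0
    return gc, entropy, n_invalid


def _kmer_prev(codes: np.ndarray, k: int) -> np.ndarray:
    """Previous-occurrence index of each k-mer (−1 if first occurrence)."""
    L = len(codes)
    m = L - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    safe = np.where(codes < 0, 0, codes).astype(np.int64)
    kcodes = safe[:m].copy()
    for j in range(1, k):
        kcodes = kcodes * 4 + safe[j:j + m]
    order = np.argsort(kcodes, kind="stable")
    prev = np.full(m, -1, dtype=np.int64)
    same = kcodes[order[1:]] == kcodes[order[:-1]]
    prev[order[1:][same]] = order[:-1][same]
    return prev


def _sliding_distinct(prev: np.ndarray, m: int, span: int, n_windows: int
                      ) -> np.ndarray:
    """Distinct k-mer count per window, via the previous-occurrence trick.

    ``prev`` is the previous-occurrence array over ``m`` k-mer positions,
    ``span`` the number of k-mer start positions per window (W−k+1) and
    ``n_windows`` the number of window starts (L−W+1). Position j counts
    as distinct in window s iff s ≤ j < s+span and prev[j] < s.
    """
    j = np.arange(m)
    lo = np.maximum(np.maximum(j - span + 1, prev + 1), 0)
    hi = np.minimum(j, n_windows - 1)
    valid = lo <= hi
    diff = (np.bincount(lo[valid], minlength=n_windows + 1)
            - np.bincount(hi[valid] + 1, minlength=n_windows + 2)[:-1])
    return np.cumsum(diff)[:n_windows]


def _sliding_lc(codes: np.ndarray, W: int, max_k: int,
                prev_cache: dict[int, np.ndarray]) -> np.ndarray:
    """Linguistic complexity over all windows of length W on a contig."""
    L = len(codes)
    n_windows = L - W + 1
    kmax = min(max_k, W)
    numerator = np.zeros(n_windows, dtype=np.int64)
    for k in range(1, kmax + 1):
        if k not in prev_cache:
            prev_cache[k] = _kmer_prev(codes, k)
        prev = prev_cache[k]
        m = L - k + 1
        numerator += _sliding_distinct(prev, m, W - k + 1, n_windows)
    return numerator / _lc_denominator(W, kmax)


def _sliding_std(x: np.ndarray, W: int, bad: np.ndarray) -> np.ndarray:
    """SD (ddof=0) over length-W windows of x; windows touching ``bad``
    positions are NaN."""
    # centring before the cumulative sums limits cancellation error
    good = ~bad
    centre = float(x[good].mean()) if good.any() else 0.0
    xs = np.where(bad, 0.0, x - centre)
    c1 = _cum(xs)
    c2 = _cum(xs ** 2)
    nb = _cum(bad)
    s1 = c1[W:] - c1[:-W]
    s2 = c2[W:] - c2[:-W]
    nbad = nb[W:] - nb[:-W]
    var = np.clip(s2 / W - (s1 / W) ** 2, 0.0, None)
    out = np.sqrt(var)
    # cancellation noise floor: the smallest genuine nonzero SD of any of
    # the windowed statistics is ~1e-5 at these window sizes
    out[out < 1e-6] = 0.0
    out[nbad > 0] = np.nan
    return out


@dataclass
class ContextConfig:
    """Feature-extraction settings.

    ``lc_max_k`` caps the substring length in windowed linguistic
    complexity; 16 keeps the 5 and 21 bp windows exact (cap ≥ window
    length there is irrelevant since k ≤ window anyway — at those scales
    the full-range definition is recovered) while making the 201/2001 bp
    scales linear-time.
    """

    radii: tuple[int, ...] = DEFAULT_RADII
    lc_max_k: int = 16
    sd_ddof: int = 0
    distance_classes: tuple[str, ...] = FEATURE_PRECEDENCE


def contig_window_stats(seq: str, W: int, lc_max_k: int = 16,
                        prev_cache: dict | None = None):
    """(gc, E, L, valid) arrays over every length-W window of a contig."""
    codes = encode(seq)
    gc, entropy, n_invalid = _sliding_composition(codes, W)
    lc = _sliding_lc(codes, W, lc_max_k,
                     prev_cache if prev_cache is not None else {})
    valid = n_invalid == 0
    gc = np.where(valid, gc, np.nan)
    entropy = np.where(valid, entropy, np.nan)
    lc = np.where(valid, lc, np.nan)
    return gc, entropy, lc, valid


def context_features(genome, sites: pd.DataFrame,
                     annotation: pd.DataFrame | None = None,
                     repeats: pd.DataFrame | None = None,
                     config: ContextConfig | None = None) -> pd.DataFrame:
    """Feature matrix for a table of sites (columns ``contig``, ``pos``).

    Columns: GC_w/E_w/L_w and dGC_w/dE_w/dL_w per radius w, canonical
    up/mid/down trinucleotide contexts, ``feature_class``,
    ``repeat_class`` and per-class feature distances. Row order follows
    the input. Missing values mark near-edge or ambiguous windows.
    """
    cfg = config or ContextConfig()
    if annotation is None:
        annotation = getattr(genome, "annotation", None)
    if repeats is None:
        repeats = getattr(genome, "repeats", None)
    sites = sites.reset_index(drop=True)
    out = sites[["contig", "pos"]].copy()
    for w in cfg.radii:
        for name in ("GC", "E", "L", "dGC", "dE", "dL"):
            out[f"{name}_{w}"] = np.nan
    out["up_ctx"] = ""
    out["mid_ctx"] = ""
    out["down_ctx"] = ""
    out["feature_class"] = "intergenic"
    out["repeat_class"] = "none"
    for klass in cfg.distance_classes:
        out[f"dist_{klass}"] = np.nan

    for contig, group in sites.groupby("contig"):
        seq = genome.sequence(contig)
        L = len(seq)
        idx = group.index.to_numpy()
        pos = group["pos"].to_numpy(dtype=np.int64)
        prev_cache: dict[int, np.ndarray] = {}
        for w in cfg.radii:
            W = 2 * w + 1
            if L < 2 * W - 1:   # too short for the Δ windows at this scale
                continue
            gc, entropy, lc, valid = contig_window_stats(
                seq, W, cfg.lc_max_k, prev_cache)
            bad = ~valid
            std_gc = _sliding_std(gc, W, bad)
            std_e = _sliding_std(entropy, W, bad)
            std_l = _sliding_std(lc, W, bad)
            centre = pos - w
            ok_c = (centre >= 0) & (centre < len(gc))
            for name, arr in (("GC", gc), ("E", entropy), ("L", lc)):
                vals = np.full(len(pos), np.nan)
                vals[ok_c] = arr[centre[ok_c]]
                out.loc[idx, f"{name}_{w}"] = vals
            first = pos - W + 1  # start of the first overlapping window
            ok_d = (first >= 0) & (first < len(std_gc))
            for name, arr in (("dGC", std_gc), ("dE", std_e), ("dL", std_l)):
                vals = np.full(len(pos), np.nan)
                vals[ok_d] = arr[first[ok_d]]
                out.loc[idx, f"{name}_{w}"] = vals
        ups, mids, downs = [], [], []
        for p in pos:
            u, m, d = trinucleotide_contexts(genome, contig, int(p))
            ups.append(u)
            mids.append(m)
            downs.append(d)
        out.loc[idx, "up_ctx"] = ups
        out.loc[idx, "mid_ctx"] = mids
        out.loc[idx, "down_ctx"] = downs
        if annotation is not None and len(annotation):
            classes = np.full(len(pos), "intergenic", dtype=object)
            for klass in reversed(FEATURE_PRECEDENCE):
                iv = _class_intervals(annotation, contig, klass)
                if not len(iv):
                    continue
                i = np.searchsorted(iv[:, 0], pos, side="right") - 1
                inside = (i >= 0) & (pos < iv[np.clip(i, 0, None), 1])
                classes[inside] = klass
            out.loc[idx, "feature_class"] = classes
            for klass in cfg.distance_classes:
                out.loc[idx, f"dist_{klass}"] = [
                    distance_to_feature(int(p), annotation, contig, klass)
                    for p in pos]
        if repeats is not None and len(repeats):
            rep = repeats[repeats["contig"] == contig]
            if len(rep):
                iv = rep[["start", "end"]].to_numpy(dtype=np.int64)
                order = np.argsort(iv[:, 0])
                iv = iv[order]
                kinds = rep["repeat_class"].to_numpy()[order]
                i = np.searchsorted(iv[:, 0], pos, side="right") - 1
                inside = (i >= 0) & (pos < iv[np.clip(i, 0, None), 1])
                vals = np.full(len(pos), "none", dtype=object)
                vals[inside] = kinds[i[inside]]
                out.loc[idx, "repeat_class"] = vals
    return out
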