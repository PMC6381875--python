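"""Phospho-motif extraction and motif-class comparisons.

Each confidently localized phosphosite contributes a fixed-width sequence
window (default 6 residues each side, 13-mer) read from the parent protein,
with 'X' padding where the protein ends.  Over-represented motifs are
extracted by the iterative greedy binomial procedure popularized by
Motif-X: repeatedly fix the (offset, residue) position with the smallest
exact binomial tail probability, provided it occurs in at least
``min_occurrences`` foreground windows and its p-value is at or below the
significance threshold; restrict foreground and background to matching
windows and recurse; emit the accumulated pattern as a motif, remove its
windows from the foreground, and restart until no further motif forms.

The proline-directed class (proline at position +1, the recognition
signature of CDKs, MAPKs and GSK-3) gets a dedicated classifier and a
paired per-sample abundance comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .models import (
    PhosphopeptideObservation,
    ProteinDatabase,
    SampleDescriptor,
    PHOSPHO_RESIDUES,
)

PAD = "X"
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SiteWindow:
    """A 13-mer (for width 6) centered on a phosphosite."""

    sequence: str
    accession: str
    position: int  # 1-based global position of the central residue
    key: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        width = (len(self.sequence) - 1) // 2
        if len(self.sequence) != 2 * width + 1:
            raise ValueError("window length must be odd")
        if self.sequence[width] not in PHOSPHO_RESIDUES:
            raise ValueError(f"central residue {self.sequence[width]!r} is not S/T/Y")

    @property
    def center(self) -> str:
        return self.sequence[(len(self.sequence) - 1) // 2]


def window_at(protein: str, position: int, width: int = 6) -> str:
    """Fixed-width window around 1-based ``position``, 'X'-padded at termini."""
    i = position - 1
    left = protein[max(0, i - width) : i]
    right = protein[i + 1 : i + 1 + width]
    return (
        PAD * (width - len(left)) + left + protein[i] + right + PAD * (width - len(right))
    )


def extract_windows(
    observations: list[PhosphopeptideObservation],
    db: ProteinDatabase,
    confidence_min: float = 0.95,
    width: int = 6,
) -> list[SiteWindow]:
    """One window per confidently localized phosphosite.

    Flanking residues are read from the protein sequence (extending beyond
    peptide boundaries).  Sites whose protein residue is not S/T/Y are
    excluded (coordinate mismatch).
    """
    windows: list[SiteWindow] = []
    for o in observations:
        if o.site_confidence < confidence_min or not o.phospho_offsets:
            continue
        if o.protein_accession not in db:
            continue
        protein = db[o.protein_accession]
        for off in o.phospho_offsets:
            pos = o.preceding_position + off  # 1-based global position
            if pos > len(protein) or protein[pos - 1] not in PHOSPHO_RESIDUES:
                continue
            windows.append(
                SiteWindow(
                    sequence=window_at(protein, pos, width),
                    accession=o.protein_accession,
                    position=pos,
                    key=str(o.key(confidence_min)),
                    sample_id=o.sample_id,
                )
            )
    return windows


def proteome_windows(db: ProteinDatabase, residue: str, width: int = 6) -> list[str]:
    """All windows centered on ``residue`` across the database — the default
    motif-extraction background."""
    out = []
    for _, seq in db.items():
        start = 0
        while True:
            i = seq.find(residue, start)
            if i < 0:
                break
            out.append(window_at(seq, i + 1, width))
            start = i + 1
    return out


def binomial_tail(k: int, n: int, q: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, q).

    Computed by summation in log space (stable up to n ~ 1e5).
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 <= q <= 1.0:
        raise ValueError("require 0 <= q <= 1")
    if k == 0:
        return 1.0
    if q == 0.0:
        return 0.0
    if q == 1.0:
        return 1.0
    i = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * math.log(q)
        + (n - i) * math.log1p(-q)
    )
    return float(min(1.0, math.exp(logsumexp(log_terms))))


@dataclass(frozen=True)
class MotifPattern:
    """Fixed (offset, residue) constraints around a central phospho-residue."""

    center: str
    constraints: frozenset[tuple[int, str]]

    def __post_init__(self) -> None:
        offsets = [o for o, _ in self.constraints]
        if len(offsets) != len(set(offsets)):
            raise ValueError("at most one residue per offset")
        if 0 in offsets:
            raise ValueError("offset 0 is the central residue")

    def matches(self, window: str) -> bool:
        width = (len(window) - 1) // 2
        if window[width] != self.center:
            return False
        return all(window[width + off] == res for off, res in self.constraints)

    def __str__(self) -> str:
        """Bracket notation, e.g. ``[Sxxx(pS)P]`` for {-4: S, +1: P}."""
        if not self.constraints:
            return f"[(p{self.center})]"
        offsets = dict(self.constraints)
        lo = min(min(offsets), 0)
        hi = max(max(offsets), 0)
        parts = []
        for off in range(lo, hi + 1):
            if off == 0:
                parts.append(f"(p{self.center})")
            elif off in offsets:
                parts.append(offsets[off])
            else:
                parts.append("x")
        return "[" + "".join(parts) + "]"


@dataclass
class MotifResult:
    pattern: MotifPattern
    foreground_matches: int
    foreground_size: int
    background_matches: int
    background_size: int
    p_final: float  # binomial tail of the last fixed position
    fold_enrichment: float
    order: int


def motif_fold_enrichment(
    foreground: list[str], background: list[str], pattern: MotifPattern
) -> float:
    """(fg match fraction) / (bg match fraction)."""
    fg = sum(pattern.matches(w) for w in foreground) / len(foreground)
    bg = sum(pattern.matches(w) for w in background) / len(background)
    if fg == 0.0:
        return 0.0
    return fg / bg


def classify_proline_directed(item) -> bool:
    """True iff the residue at offset +1 is proline.

    Accepts a window string, a :class:`SiteWindow`, or a
    :class:`MotifPattern`.
    """
    if isinstance(item, MotifPattern):
        return (1, "P") in item.constraints
    seq = item.sequence if isinstance(item, SiteWindow) else item
    width = (len(seq) - 1) // 2
    return seq[width + 1] == "P"


def _encode(windows: list[str], width: int) -> np.ndarray:
    codes = np.full((len(windows), 2 * width + 1), -1, dtype=np.int8)
    lookup = {c: i for i, c in enumerate(ALPHABET)}
    for r, w in enumerate(windows):
        for c, ch in enumerate(w):
            codes[r, c] = lookup.get(ch, -1)  # padding 'X' -> -1
    return codes


def motifx_extract(
    foreground: list[str],
    background: list[str],
    width: int = 6,
    min_occurrences: int = 5,
    significance: float = 4e-6,
) -> list[MotifResult]:
    """Iterative greedy binomial motif extraction.

    ``foreground`` and ``background`` are pre-aligned (2*width+1)-mers with
    identical central residue.  Padding 'X' is excluded from both numerator
    and denominator counts at its offset.  Ties on minimal p are broken by
    larger fold enrichment, then smaller |offset|, then alphabetical
    residue.  Windows matched by distinct motifs are disjoint.
    """
    if not background:
        raise ValueError("background must be non-empty")
    wlen = 2 * width + 1
    for w in foreground + background:
        if len(w) != wlen:
            raise ValueError(f"window {w!r} is not a {wlen}-mer")
    centers = {w[width] for w in foreground} | {w[width] for w in background}
    if len(centers) > 1:
        raise ValueError(f"mixed central residues {sorted(centers)}")
    center = centers.pop() if foreground else background[0][width]

    fg_codes = _encode(foreground, width)
    bg_codes = _encode(background, width)
    n_aa = len(ALPHABET)
    offsets = [off for off in range(-width, width + 1) if off != 0]

    remaining = np.ones(len(foreground), dtype=bool)
    results: list[MotifResult] = []

    while True:
        fg_idx = np.flatnonzero(remaining)
        if fg_idx.size < min_occurrences:
            break
        cur_fg = fg_codes[fg_idx]
        cur_bg = bg_codes
        fixed: list[tuple[int, str, float]] = []  # (offset, residue, p)
        while True:
            best = None  # (p, -fold, |offset|, residue, offset, col, code, k)
            for off in offsets:
                if any(off == f[0] for f in fixed):
                    continue
                col = width + off
                fg_col = cur_fg[:, col]
                bg_col = cur_bg[:, col]
                n_fg = int((fg_col >= 0).sum())
                n_bg = int((bg_col >= 0).sum())
                if n_fg == 0 or n_bg == 0:
                    continue
                fg_counts = np.bincount(fg_col[fg_col >= 0], minlength=n_aa)
                bg_counts = np.bincount(bg_col[bg_col >= 0], minlength=n_aa)
                for code in np.flatnonzero(fg_counts >= min_occurrences):
                    if bg_counts[code] == 0:
                        continue  # no finite binomial model
                    q = bg_counts[code] / n_bg
                    k = int(fg_counts[code])
                    p = binomial_tail(k, n_fg, q)
                    if p > significance:
                        continue
                    fold = (k / n_fg) / q
                    cand = (p, -fold, abs(off), ALPHABET[code], off, col, code, k)
                    if best is None or cand < best:
                        best = cand
            if best is None:
                break
            p, _, _, residue, off, col, code, _k = best
            fixed.append((off, residue, p))
            keep_fg = cur_fg[:, col] == code
            cur_fg = cur_fg[keep_fg]
            fg_idx = fg_idx[keep_fg]
            cur_bg = cur_bg[cur_bg[:, col] == code]
        if not fixed:
            break
        pattern = MotifPattern(
            center=center, constraints=frozenset((o, r) for o, r, _ in fixed)
        )
        fg_size = int(remaining.sum())
        fg_matches = int(fg_idx.size)
        bg_matches = int(cur_bg.shape[0])
        bg_size = len(background)
        fold = (fg_matches / fg_size) / (bg_matches / bg_size) if bg_matches else 0.0
        results.append(
            MotifResult(
                pattern=pattern,
                foreground_matches=fg_matches,
                foreground_size=fg_size,
                background_matches=bg_matches,
                background_size=bg_size,
                p_final=fixed[-1][2],
                fold_enrichment=fold,
                order=len(results),
            )
        )
        remaining[fg_idx] = False
    return results


def write_windows(windows, path) -> None:
    """Write pre-aligned site windows one per line (the plain-text exchange
    format motif tools accept).  Accepts strings or :class:`SiteWindow`."""
    with open(path, "w", encoding="utf-8") as fh:
        for w in windows:
            fh.write((w.sequence if isinstance(w, SiteWindow) else w) + "\n")


def read_windows(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip().upper() for line in fh if line.strip()]


def motif_class_abundance(
    windows_by_sample: dict[str, list],
    design: list[SampleDescriptor],
    classifier=classify_proline_directed,
) -> dict:
    """Per-sample proportion of windows in a motif class, with a two-tailed
    paired t-test across matched KO/WT pairs (matched via ``pair_id``).

    ``windows_by_sample`` maps sample id to that sample's site windows
    (strings or :class:`SiteWindow`).
    """
    proportions: dict[str, float] = {}
    for sid, windows in windows_by_sample.items():
        if windows:
            proportions[sid] = sum(bool(classifier(w)) for w in windows) / len(windows)
        else:
            proportions[sid] = math.nan
    pairs: dict[str, dict[str, str]] = {}
    for s in design:
        if s.pair_id is not None:
            pairs.setdefault(s.pair_id, {})[s.genotype] = s.sample_id
    wt_vals, ko_vals, pair_ids = [], [], []
    for pid in sorted(pairs):
        members = pairs[pid]
        if "WT" in members and "KO" in members:
            wt = proportions.get(members["WT"], math.nan)
            ko = proportions.get(members["KO"], math.nan)
            if not (math.isnan(wt) or math.isnan(ko)):
                wt_vals.append(wt)
                ko_vals.append(ko)
                pair_ids.append(pid)
    if len(pair_ids) < 2:
        raise ValueError("paired comparison needs at least 2 complete pairs")
    diffs = np.array(wt_vals) - np.array(ko_vals)
    if np.ptp(diffs) == 0:
        t_stat, p = (0.0, 1.0) if diffs[0] == 0 else (math.inf * np.sign(diffs[0]), 0.0)
    else:
        t_stat, p = map(float, stats.ttest_rel(wt_vals, ko_vals))
    return {
        "per_sample_proportion": proportions,
        "pairs": pair_ids,
        "mean_wt": float(np.mean(wt_vals)),
        "mean_ko": float(np.mean(ko_vals)),
        "t": t_stat,
        "p_two_sided": p,
        "n_pairs": len(pair_ids),
    }
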