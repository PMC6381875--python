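"""Presence/absence differential-detection analysis.

MS data-dependent acquisition samples abundant precursors more often, so
whether a phosphopeptide is detected at all in a replicate carries
quantitative information.  A peptide detected in at least ``min_detect`` of
one group's replicates and in none of the other group's is called
differentially detected, with significance from the pooled two-proportion
z statistic

    z = (p1 - p2) / sqrt( p (1 - p) (1/n1 + 1/n2) ),   p = (x1 + x2)/(n1 + n2)

referred to the upper tail of the standard normal.  With groups of 8 this
reproduces the classic cut-off: 3/8 vs 0/8 gives z = 1.92, one-sided
p = 0.027 < 0.05, while 2/8 vs 0/8 gives p = 0.066 and is not called.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    Contrast,
    PeptideKey,
    PhosphopeptideObservation,
    SampleDescriptor,
    ValidationError,
    check_design,
)


class DegenerateProportionsError(ValueError):
    """Pooled variance is zero (no detections, or detected everywhere)."""


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> float:
    """Pooled two-proportion z statistic for counts x1/n1 vs x2/n2.

    Raises :class:`DegenerateProportionsError` when the pooled proportion is
    0 or 1, where the statistic is undefined.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    total = x1 + x2
    if total == 0 or total == n1 + n2:
        raise DegenerateProportionsError(
            f"pooled proportion is {'0' if total == 0 else '1'}: z undefined"
        )
    p1, p2 = x1 / n1, x2 / n2
    pooled = total / (n1 + n2)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    return (p1 - p2) / se


def one_sided_p(z: float) -> float:
    """Upper-tail standard-normal probability P(N(0,1) > z).

    Closed form via the complementary error function; no continuity
    correction is applied.
    """
    return 0.5 * math.erfc(z / math.sqrt(2.0))


@dataclass
class DetectionMatrix:
    """Boolean peptide-key x sample detection table.

    A key is detected in a sample iff at least one observation of that key
    exists in any gel fraction of that sample.  ``accessions`` maps each key
    string to the protein accessions it was observed on (shared tryptic
    sequences may map to several homologous proteins).
    """

    detected: pd.DataFrame  # bool, index = key strings, columns = sample ids
    design: list[SampleDescriptor]
    keys: dict[str, PeptideKey]
    accessions: dict[str, frozenset[str]]

    def group_samples(self, contrast: Contrast) -> tuple[list[str], list[str]]:
        return contrast.split(self.design)


def build_detection_matrix(
    observations: list[PhosphopeptideObservation],
    design: list[SampleDescriptor],
    confidence_min: float = 0.95,
) -> DetectionMatrix:
    """Collapse observations over gel fractions and Met-ox states into a
    detection matrix.  Idempotent: duplicate observations change nothing."""
    check_design(design)
    sample_ids = [s.sample_id for s in design]
    legal = set(sample_ids)
    keys: dict[str, PeptideKey] = {}
    accessions: dict[str, set[str]] = {}
    cells: set[tuple[str, str]] = set()
    for o in observations:
        if o.sample_id not in legal:
            raise ValidationError(f"observation references unknown sample {o.sample_id!r}")
        key = o.key(confidence_min)
        ks = str(key)
        keys.setdefault(ks, key)
        accessions.setdefault(ks, set()).add(o.protein_accession)
        cells.add((ks, o.sample_id))
    index = sorted(keys)
    detected = pd.DataFrame(False, index=index, columns=sample_ids, dtype=bool)
    for ks, sid in cells:
        detected.at[ks, sid] = True
    return DetectionMatrix(
        detected=detected,
        design=list(design),
        keys=keys,
        accessions={k: frozenset(v) for k, v in accessions.items()},
    )


@dataclass
class DetectionContrastResult:
    key: PeptideKey
    x1: int
    n1: int
    x2: int
    n2: int
    z: float
    p_one_sided: float
    direction: str  # level_a, level_b, or "none"
    significant: bool


def exclusive_peptides(
    matrix: DetectionMatrix,
    contrast: Contrast,
    min_detect: int = 3,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> list[DetectionContrastResult]:
    """Peptides detected in >= ``min_detect`` replicates of one group and in
    none of the other, annotated with the pooled z and one-sided p
    (doubled when ``two_sided`` is set).

    Sorted by p then key for reproducible reports.
    """
    group_a, group_b = matrix.group_samples(contrast)
    xa = matrix.detected[group_a].sum(axis=1)
    xb = matrix.detected[group_b].sum(axis=1)
    na, nb = len(group_a), len(group_b)
    results: list[DetectionContrastResult] = []
    for ks in matrix.detected.index:
        x1, x2 = int(xa[ks]), int(xb[ks])
        a_excl = x1 >= min_detect and x2 == 0
        b_excl = x2 >= min_detect and x1 == 0
        if not (a_excl or b_excl):
            continue
        z = two_proportion_z(x1, na, x2, nb)
        p = one_sided_p(abs(z))
        if two_sided:
            p = min(1.0, 2.0 * p)
        direction = contrast.level_a if z > 0 else contrast.level_b
        if p < alpha:
            results.append(
                DetectionContrastResult(
                    key=matrix.keys[ks],
                    x1=x1,
                    n1=na,
                    x2=x2,
                    n2=nb,
                    z=z,
                    p_one_sided=p,
                    direction=direction,
                    significant=True,
                )
            )
    results.sort(key=lambda r: (r.p_one_sided, str(r.key)))
    return results


def detection_contrast_table(results: list[DetectionContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "key": str(r.key),
                "x1": r.x1,
                "n1": r.n1,
                "x2": r.x2,
                "n2": r.n2,
                "z": r.z,
                "p": r.p_one_sided,
                "direction": r.direction,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=["key", "x1", "n1", "x2", "n2", "z", "p", "direction", "significant"],
    )


def detection_frequency_summary(
    matrix: DetectionMatrix, group: list[str]
) -> dict[int, float]:
    """Fraction of keys (detected at least once in the group) that are
    detected in >= k of the group's samples, for k = 1 .. group size."""
    counts = matrix.detected[group].sum(axis=1)
    counts = counts[counts >= 1]
    total = len(counts)
    summary = {}
    for k in range(1, len(group) + 1):
        summary[k] = float((counts >= k).sum()) / total if total else 0.0
    return summary


def pairwise_repeatability(
    matrix: DetectionMatrix,
    group: list[str],
    level: str = "peptide",
    denominator: str = "min",
) -> list[float]:
    """Per-pair detection overlap percentages within a replicate group.

    For each unordered pair of samples, overlap = |A ∩ B| / min(|A|, |B|)
    x 100 by default (``denominator="union"`` gives the Jaccard form).
    ``level="protein"`` collapses peptide keys to protein accessions first.
    """
    if level not in ("peptide", "protein"):
        raise ValueError("level must be 'peptide' or 'protein'")
    if denominator not in ("min", "union"):
        raise ValueError("denominator must be 'min' or 'union'")
    sets: list[set] = []
    for sid in group:
        detected_keys = set(matrix.detected.index[matrix.detected[sid]])
        if level == "protein":
            detected = set()
            for ks in detected_keys:
                detected.update(matrix.accessions[ks])
        else:
            detected = detected_keys
        sets.append(detected)
    overlaps = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            a, b = sets[i], sets[j]
            inter = len(a & b)
            denom = min(len(a), len(b)) if denominator == "min" else len(a | b)
            overlaps.append(100.0 * inter / denom if denom else 0.0)
    return overlaps
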