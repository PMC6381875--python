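"""Label-free MS1 peak-area quantification.

Aggregation rules for peak areas follow the standard gel-fractionated
label-free workflow: areas of an identical phosphopeptide from different
gel fractions of one sample are summed, Met-oxidation variants of one
peptide are pooled, mono- and multi-phosphorylated forms of one sequence
stay separate analytes, and a peptide sequence shared by homologous
proteins counts once at the peptide level but is attributed to every
matching protein in protein-level rollups.  Aggregated areas are normalized
to each sample's lysate protein concentration.

Group comparisons are run on natural-log-transformed normalized areas
(two-tailed Student's t, pooled variance by default, Welch by flag), and
per-key heat-map bias scores follow the signed ln-ratio convention
ln(group mean / grand mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    Contrast,
    PeptideKey,
    PhosphopeptideObservation,
    SampleDescriptor,
    ValidationError,
    check_design,
)


@dataclass
class QuantMatrix:
    """Peptide-key x sample table of normalized MS1 peak areas.

    Missing cells (NaN) mean the key was not detected in that sample.
    Present values are strictly positive; a detected key whose total area is
    zero cannot be quantified on the ln scale and is stored missing.
    """

    areas: pd.DataFrame  # float, NaN = missing; index key strings
    design: list[SampleDescriptor]
    keys: dict[str, PeptideKey]
    accessions: dict[str, frozenset[str]]
    genes: dict[str, frozenset[str]]

    def group_samples(self, contrast: Contrast) -> tuple[list[str], list[str]]:
        return contrast.split(self.design)


def aggregate_observations(
    observations: list[PhosphopeptideObservation],
    design: list[SampleDescriptor],
    confidence_min: float = 0.95,
) -> QuantMatrix:
    """Sum areas over gel fractions and Met-ox variants per (key, sample),
    then normalize by the sample's lysate protein concentration."""
    check_design(design)
    concentration = {s.sample_id: s.lysate_protein_concentration for s in design}
    sample_ids = [s.sample_id for s in design]
    sums: dict[tuple[str, str], float] = {}
    keys: dict[str, PeptideKey] = {}
    accessions: dict[str, set[str]] = {}
    genes: dict[str, set[str]] = {}
    for o in observations:
        if o.sample_id not in concentration:
            raise ValidationError(f"observation references unknown sample {o.sample_id!r}")
        key = o.key(confidence_min)
        ks = str(key)
        keys.setdefault(ks, key)
        accessions.setdefault(ks, set()).add(o.protein_accession)
        genes.setdefault(ks, set()).add(o.gene_symbol)
        sums[ks, o.sample_id] = sums.get((ks, o.sample_id), 0.0) + o.ms1_peak_area
    index = sorted(keys)
    areas = pd.DataFrame(np.nan, index=index, columns=sample_ids, dtype=float)
    for (ks, sid), total in sums.items():
        if total > 0:
            areas.at[ks, sid] = total / concentration[sid]
    return QuantMatrix(
        areas=areas,
        design=list(design),
        keys=keys,
        accessions={k: frozenset(v) for k, v in accessions.items()},
        genes={k: frozenset(v) for k, v in genes.items()},
    )


def bias_scores(matrix: QuantMatrix, contrast: Contrast) -> pd.DataFrame:
    """Signed ln-ratio heat-map scores per key.

    score_a = ln(mean of group-A present cells / mean of all present cells)
    and likewise score_b; the grand mean runs over every sample's present
    cells.  Keys lacking a present cell in either group are omitted.
    Identity: score_a - score_b = ln(mean_a) - ln(mean_b).
    """
    group_a, group_b = matrix.group_samples(contrast)
    mean_a = matrix.areas[group_a].mean(axis=1)
    mean_b = matrix.areas[group_b].mean(axis=1)
    grand = matrix.areas.mean(axis=1)
    present = mean_a.notna() & mean_b.notna()
    out = pd.DataFrame(
        {
            "score_a": np.log(mean_a[present] / grand[present]),
            "score_b": np.log(mean_b[present] / grand[present]),
        }
    )
    out.index.name = "key"
    return out


@dataclass
class QuantContrastResult:
    key: PeptideKey
    mean_ln_a: float
    mean_ln_b: float
    bias_score_a: float
    bias_score_b: float
    t: float
    p_two_sided: float
    direction: str
    n_a: int
    n_b: int
    significant: bool
    degenerate: bool = False


def quant_contrast(
    matrix: QuantMatrix,
    contrast: Contrast,
    min_per_group: int = 3,
    alpha: float = 0.05,
    welch: bool = False,
    log_transform: bool = True,
) -> list[QuantContrastResult]:
    """Two-tailed unpaired t-test per key on ln normalized areas.

    Only keys with >= ``min_per_group`` present cells on each side are
    tested (sparser keys belong to the presence/absence analysis).  A zero
    pooled variance with unequal means is reported as p = 0 with the
    ``degenerate`` flag set.
    """
    group_a, group_b = matrix.group_samples(contrast)
    scores = bias_scores(matrix, contrast)
    arr_a = matrix.areas[group_a].to_numpy()
    arr_b = matrix.areas[group_b].to_numpy()
    results: list[QuantContrastResult] = []
    for i, ks in enumerate(matrix.areas.index):
        a = arr_a[i][~np.isnan(arr_a[i])]
        b = arr_b[i][~np.isnan(arr_b[i])]
        if len(a) < min_per_group or len(b) < min_per_group:
            continue
        if log_transform:
            a, b = np.log(a), np.log(b)
        degenerate = False
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            if a.mean() == b.mean():
                t_stat, p = 0.0, 1.0
            else:
                t_stat = math.inf if a.mean() > b.mean() else -math.inf
                p = 0.0
            degenerate = True
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=not welch)
            t_stat, p = float(t_stat), float(p)
        direction = contrast.level_a if a.mean() > b.mean() else contrast.level_b
        results.append(
            QuantContrastResult(
                key=matrix.keys[ks],
                mean_ln_a=float(np.mean(a) if log_transform else np.log(a).mean()),
                mean_ln_b=float(np.mean(b) if log_transform else np.log(b).mean()),
                bias_score_a=float(scores.at[ks, "score_a"]),
                bias_score_b=float(scores.at[ks, "score_b"]),
                t=t_stat,
                p_two_sided=p,
                direction=direction,
                n_a=len(a),
                n_b=len(b),
                significant=p < alpha,
                degenerate=degenerate,
            )
        )
    results.sort(key=lambda r: (r.p_two_sided, str(r.key)))
    return results


def quant_contrast_table(results: list[QuantContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "key": str(r.key),
                "mean_ln_a": r.mean_ln_a,
                "mean_ln_b": r.mean_ln_b,
                "bias_score_a": r.bias_score_a,
                "neg_bias_score_b": -r.bias_score_b,
                "t": r.t,
                "p": r.p_two_sided,
                "direction": r.direction,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "significant": r.significant,
                "degenerate": r.degenerate,
            }
            for r in results
        ],
        columns=[
            "key",
            "mean_ln_a",
            "mean_ln_b",
            "bias_score_a",
            "neg_bias_score_b",
            "t",
            "p",
            "direction",
            "n_a",
            "n_b",
            "significant",
            "degenerate",
        ],
    )


def group_sum_comparison(
    matrix: QuantMatrix, contrast: Contrast, key_subset: list[str]
) -> dict:
    """Per-sample sums of normalized areas over a key subset, compared
    between the contrast's groups by a two-tailed unpaired t-test."""
    if not key_subset:
        raise ValueError("key_subset must be non-empty")
    missing = [k for k in key_subset if k not in matrix.areas.index]
    if missing:
        raise ValidationError(f"keys not in matrix: {missing[:5]}")
    group_a, group_b = matrix.group_samples(contrast)
    sums = matrix.areas.loc[key_subset].sum(axis=0, skipna=True)
    a = sums[group_a].to_numpy()
    b = sums[group_b].to_numpy()
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        t_stat, p = (0.0, 1.0) if a.mean() == b.mean() else (math.nan, 0.0)
    else:
        t_stat, p = map(float, stats.ttest_ind(a, b))
    return {
        "per_sample_sums": sums.to_dict(),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "t": t_stat,
        "p_two_sided": p,
    }


def fold_change_scatter(
    matrix: QuantMatrix,
    genotype_contrast: Contrast,
    sex_contrast: Contrast,
    cutoff: float = 1.0,
) -> pd.DataFrame:
    """Per-key scatter coordinates x = ln(KO mean / WT mean), y = ln(F mean /
    M mean) with flags at |coordinate| >= cutoff (cutoff 1 means an e-fold,
    about 2.7-fold, change).  Keys missing any group mean are omitted."""
    ko, wt = matrix.group_samples(genotype_contrast)
    f, m = matrix.group_samples(sex_contrast)
    means = {
        name: matrix.areas[grp].mean(axis=1)
        for name, grp in (("ko", ko), ("wt", wt), ("f", f), ("m", m))
    }
    present = pd.concat(means, axis=1).notna().all(axis=1)
    x = np.log(means["ko"][present] / means["wt"][present])
    y = np.log(means["f"][present] / means["m"][present])
    return pd.DataFrame(
        {
            "key": x.index,
            "ln_ratio_genotype": x.to_numpy(),
            "ln_ratio_sex": y.to_numpy(),
            "flag_genotype": np.abs(x.to_numpy()) >= cutoff,
            "flag_sex": np.abs(y.to_numpy()) >= cutoff,
        }
    )
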