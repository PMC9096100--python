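"""Pathogenic-allele spectrum and nonparametric biomarker comparisons.

For a cohort of patients with a recessive disease, every patient carries two
pathogenic alleles, so a cohort of n patients defines a spectrum over 2n
chromosomes.  This module tabulates that spectrum, splits it into
previously-described vs novel alleles, and provides the two rank tests used
to relate genotype classes to a quantitative biomarker: Mann-Whitney U for
independent groups (e.g. homozygous loss-of-function vs homozygous missense
patients) and the Wilcoxon signed-rank test for paired pre/post-therapy
measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "VariantAnnot",
    "SpectrumRow",
    "allelic_spectrum",
    "novelty_split",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "screening_yield",
]

# group sizes up to this total get the exact (enumeration) null distribution
EXACT_LIMIT = 12


@dataclass(frozen=True)
class VariantAnnot:
    """Annotation of one pathogenic variant (input, not computed)."""

    label: str
    consequence_class: str  # LoF | missense | splice_VUS | synonymous_splice
    novel: bool


@dataclass(frozen=True)
class SpectrumRow:
    """One variant's chromosome count and allelic frequency (percent)."""

    variant: str
    count: int
    frequency_pct: float


def _genotype_pairs(cohort) -> list[tuple[str, str]]:
    pairs = []
    for item in cohort:
        pair = item.disease_genotype if hasattr(item, "disease_genotype") else tuple(item)
        labels = [v for v in pair if v]
        if len(labels) != 2:
            raise ValueError(
                f"patient {getattr(item, 'sample_id', pair)!r} must carry exactly "
                f"two variant labels, got {len(labels)}"
            )
        pairs.append((labels[0], labels[1]))
    return pairs


def allelic_spectrum(cohort) -> list[SpectrumRow]:
    """Tabulate variant chromosome counts and percent frequencies.

    ``cohort`` is a sequence of GenotypeRecords or bare label pairs; every
    patient contributes two chromosomes.  Rows are sorted by descending
    count, then label, and the frequencies sum to 100%.
    """
    pairs = _genotype_pairs(cohort)
    total = 2 * len(pairs)
    counts: dict[str, int] = {}
    for a, b in pairs:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    rows = [
        SpectrumRow(v, c, 100.0 * c / total)
        for v, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return rows


def novelty_split(
    spectrum: Sequence[SpectrumRow], annotations: Mapping[str, VariantAnnot]
) -> dict[str, dict[str, float]]:
    """Split the spectrum into known vs novel variants.

    Returns ``{"known": {...}, "novel": {...}}`` with per-class variant
    count, chromosome count and percent of all chromosomes (the two
    percentages sum to 100).
    """
    missing = [row.variant for row in spectrum if row.variant not in annotations]
    if missing:
        raise ValueError(f"unannotated variant label(s): {missing}")
    total = sum(row.count for row in spectrum)
    out = {
        "known": {"n_variants": 0, "n_chromosomes": 0, "pct": 0.0},
        "novel": {"n_variants": 0, "n_chromosomes": 0, "pct": 0.0},
    }
    for row in spectrum:
        key = "novel" if annotations[row.variant].novel else "known"
        out[key]["n_variants"] += 1
        out[key]["n_chromosomes"] += row.count
    for key in out:
        out[key]["pct"] = 100.0 * out[key]["n_chromosomes"] / total
    return out


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Returns ``(U, p)`` with U the statistic of ``group_a``.  The exact null
    distribution (enumeration over rank splits) is used when the combined
    sample size is at most 12 and there are no ties; otherwise the normal
    approximation with mid-ranks and tie correction.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= EXACT_LIMIT and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_signed_rank(before: Sequence[float], after: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired measurements, two-sided.

    Zero differences are dropped.  Exact p for at most 12 non-zero pairs,
    else the normal approximation.  If every difference is zero the test is
    degenerate: returns ``(0.0, 1.0)`` with a warning.
    """
    x = np.asarray(list(before), dtype=float)
    y = np.asarray(list(after), dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("before/after must be equal-length, non-empty")
    diffs = x - y
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p-value is 1", stacklevel=2)
        return 0.0, 1.0
    method = "exact" if nonzero.size <= EXACT_LIMIT else "asymptotic"
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def screening_yield(n_positive: int, n_screened: int) -> float:
    """Percentage of screened individuals above the biomarker cutoff (1 d.p.)."""
    if n_screened <= 0:
        raise ValueError("n_screened must be positive")
    if not (0 <= n_positive <= n_screened):
        raise ValueError("n_positive must be between 0 and n_screened")
    return round(100.0 * n_positive / n_screened, 1)
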