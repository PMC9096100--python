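"""Disease–marker linkage disequilibrium and founder-haplotype inference.

The central statistic is the LD measure

    delta = (P_D - P_N) / (1 - P_N)

where ``P_D`` is the frequency of the associated marker allele on disease
(mutation-bearing) chromosomes and ``P_N`` its frequency on normal
chromosomes.  delta is 1 under complete association (every mutant chromosome
carries the allele and the excess over background is total) and 0 when case
and control frequencies coincide; it may be negative when the allele is
rarer on mutant chromosomes.  Under a single-founder model with
recombination fraction theta between marker and disease locus, the expected
delta at generation g is (1 - theta)^g, which is what makes the statistic a
decay profile of the founder haplotype.

Association at each marker is assessed on the 2x2 table
(associated allele vs all other alleles) x (mutant vs control chromosomes)
with a Pearson chi-square (no continuity correction) and a two-sided Fisher
exact test.  Confidence intervals for delta are percentile bootstrap over
chromosomes; the literature the delta formula descends from does not fix a
CI formula, so the bootstrap is the documented choice here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort_io import Chromosome, MarkerPanel

__all__ = [
    "AlleleCounts",
    "DeltaResult",
    "FounderCall",
    "allele_counts",
    "compute_delta",
    "delta_result",
    "select_associated_allele",
    "delta_ci",
    "association_test",
    "infer_founder_haplotype",
    "decay_profile",
]


@dataclass
class AlleleCounts:
    """Allele counts at one marker over a set of chromosomes.

    ``total`` is the number of chromosomes with a non-missing call; missing
    chromosomes never enter numerator or denominator of any frequency.
    """

    marker: str
    counts: dict[int, int]
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError(f"{self.marker}: total chromosomes must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"{self.marker}: negative allele count")
        if sum(self.counts.values()) > self.total:
            raise ValueError(f"{self.marker}: counts exceed total chromosomes")

    def frequency(self, allele: int) -> float:
        return self.counts.get(allele, 0) / self.total


@dataclass
class DeltaResult:
    """Per-marker LD summary for the associated allele."""

    marker: str
    allele: int
    pd: float
    pn: float
    delta: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    chi2_stat: Optional[float] = None
    chi2_p: Optional[float] = None
    fisher_p: Optional[float] = None
    n_mutant: int = 0
    n_control: int = 0


@dataclass
class FounderCall:
    """Modal (presumed founder) haplotype with per-marker support.

    ``support[m]`` = modal-allele count / counted mutant chromosomes at
    marker ``m``.  Markers where two or more alleles tie for the mode are
    listed in ``ambiguous`` with every tied allele's support in ``ties``.
    """

    markers: list[str]
    alleles: dict[str, int]
    support: dict[str, float]
    ambiguous: set[str] = field(default_factory=set)
    ties: dict[str, dict[int, float]] = field(default_factory=dict)

    @property
    def haplotype(self) -> str:
        return "-".join(str(self.alleles[m]) for m in self.markers)


def allele_counts(chromosomes: Sequence[Chromosome], marker: str, panel: MarkerPanel) -> AlleleCounts:
    """Count non-missing alleles at ``marker`` across chromosomes."""
    if not chromosomes:
        raise ValueError("no chromosomes supplied")
    idx = panel.index(marker)
    counts: dict[int, int] = {}
    for chrom in chromosomes:
        a = chrom.alleles[idx]
        if a is not None:
            counts[a] = counts.get(a, 0) + 1
    if not counts:
        raise ValueError(f"all chromosomes missing at marker {marker}")
    return AlleleCounts(marker, counts, sum(counts.values()))


def compute_delta(pd: float, pn: float) -> float:
    """delta = (PD - PN) / (1 - PN); undefined when the allele is fixed in controls."""
    if not (0.0 <= pd <= 1.0):
        raise ValueError(f"PD must be in [0, 1], got {pd}")
    if not (0.0 <= pn <= 1.0):
        raise ValueError(f"PN must be in [0, 1], got {pn}")
    if pn == 1.0:
        raise ZeroDivisionError("delta undefined: allele fixed on control chromosomes (PN = 1)")
    return (pd - pn) / (1.0 - pn)


def association_test(a: int, b: int, c: int, d: int):
    """chi-square and Fisher exact tests on the 2x2 table [[a, b], [c, d]].

    Layout: rows = (mutant, control) chromosomes, columns = (associated
    allele, all other alleles).  Returns ``(chi2_stat, chi2_p, fisher_p)``.
    The chi-square is Pearson without continuity correction; the Fisher p
    is two-sided by the point-probability rule (sum of all tables with the
    observed margins whose probability does not exceed the observed
    table's).  With a zero margin the chi-square is undefined (``None``
    returned) and the exact p is 1.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("2x2 counts must be nonnegative integers")
    if a + b + c + d == 0:
        raise ValueError("empty 2x2 table")
    table = np.array([[a, b], [c, d]], dtype=int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return None, None, 1.0
    chi2, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)
    fisher_p = stats.fisher_exact(table, alternative="two-sided")[1]
    return float(chi2), float(chi2_p), float(fisher_p)


def delta_result(
    case_counts: AlleleCounts,
    control_counts: AlleleCounts,
    allele: int,
) -> DeltaResult:
    """Build a :class:`DeltaResult` for one allele (no CI attached)."""
    pd = case_counts.frequency(allele)
    pn = control_counts.frequency(allele)
    delta = compute_delta(pd, pn)
    a = case_counts.counts.get(allele, 0)
    b = case_counts.total - a
    c = control_counts.counts.get(allele, 0)
    d = control_counts.total - c
    chi2, chi2_p, fisher_p = association_test(a, b, c, d)
    return DeltaResult(
        marker=case_counts.marker,
        allele=allele,
        pd=pd,
        pn=pn,
        delta=delta,
        chi2_stat=chi2,
        chi2_p=chi2_p,
        fisher_p=fisher_p,
        n_mutant=case_counts.total,
        n_control=control_counts.total,
    )


def select_associated_allele(
    case_counts: AlleleCounts, control_counts: AlleleCounts
) -> DeltaResult:
    """Pick the allele maximising delta at a marker.

    The scan covers every allele seen in either group (alleles fixed in
    controls are skipped, delta being undefined there).  Ties are broken by
    higher PD, then by smaller allele label, so runs are reproducible.
    """
    if case_counts.marker != control_counts.marker:
        raise ValueError(
            f"marker mismatch: {case_counts.marker} vs {control_counts.marker}"
        )
    candidates = sorted(set(case_counts.counts) | set(control_counts.counts))
    if not candidates:
        raise ValueError("no alleles observed")
    # exact rational comparison so near-ties are resolved by the documented
    # rule (higher PD, then smaller label), not by float rounding
    best: Optional[tuple[tuple[Fraction, Fraction, int], int]] = None
    for allele in candidates:
        cn = control_counts.counts.get(allele, 0)
        if cn == control_counts.total:
            continue  # fixed in controls: delta undefined
        pd = Fraction(case_counts.counts.get(allele, 0), case_counts.total)
        pn = Fraction(cn, control_counts.total)
        key = ((pd - pn) / (1 - pn), pd, -allele)
        if best is None or key > best[0]:
            best = (key, allele)
    if best is None:
        raise ValueError("delta undefined for every allele (controls monomorphic)")
    return delta_result(case_counts, control_counts, best[1])


def delta_ci(
    case_counts: AlleleCounts,
    control_counts: AlleleCounts,
    allele: int,
    alpha: float = 0.05,
    n_boot: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval for delta.

    Chromosomes are resampled with replacement within each group (for a
    single allele this reduces to binomial resampling of the allele count),
    delta recomputed per replicate, and the alpha/2 and 1-alpha/2 empirical
    quantiles returned.  Replicates in which the allele fixes among
    resampled controls (PN = 1, delta undefined) are redrawn.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if case_counts.total < 2 or control_counts.total < 2:
        raise ValueError("bootstrap needs at least 2 chromosomes per group")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_d, n_n = case_counts.total, control_counts.total
    pd_hat = case_counts.frequency(allele)
    pn_hat = control_counts.frequency(allele)
    if pn_hat == 1.0:
        raise ZeroDivisionError("delta undefined: PN = 1")

    pd_star = rng.binomial(n_d, pd_hat, size=n_boot) / n_d
    pn_star = rng.binomial(n_n, pn_hat, size=n_boot) / n_n
    bad = pn_star == 1.0
    while bad.any():
        pn_star[bad] = rng.binomial(n_n, pn_hat, size=int(bad.sum())) / n_n
        bad = pn_star == 1.0
    deltas = (pd_star - pn_star) / (1.0 - pn_star)
    low, high = np.quantile(deltas, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(low), float(high)


def infer_founder_haplotype(
    mutant: Sequence[Chromosome], panel: MarkerPanel
) -> FounderCall:
    """Modal allele per marker over mutant chromosomes = presumed founder.

    Support is the modal count over counted (non-missing) chromosomes.
    Exact ties are reported for each tied allele and the position flagged
    ambiguous; the haplotype string then shows the smallest tied label.
    """
    if len(mutant) < 2:
        raise ValueError("founder inference needs at least 2 mutant chromosomes")
    call = FounderCall(panel.names, {}, {})
    for name in panel.names:
        ac = allele_counts(mutant, name, panel)
        top = max(ac.counts.values())
        tied = sorted(a for a, c in ac.counts.items() if c == top)
        call.alleles[name] = tied[0]
        call.support[name] = top / ac.total
        if len(tied) > 1:
            call.ambiguous.add(name)
            call.ties[name] = {a: top / ac.total for a in tied}
    return call


def decay_profile(
    founder: FounderCall,
    mutant: Sequence[Chromosome],
    panel: MarkerPanel,
    distances: Optional[Sequence[float]] = None,
):
    """Founder-allele retention per marker, ordered by distance from the locus.

    retention(m) = fraction of counted mutant chromosomes carrying the
    founder allele at marker m.  Ordering needs a genetic map: either the
    panel is in cM or an explicit per-marker distance vector is supplied.
    Returns a pandas DataFrame with columns marker, distance, retention,
    n_counted, sorted by distance (ties keep panel order).
    """
    import pandas as pd

    if distances is None:
        if panel.unit != "genetic_cM":
            raise ValueError(
                "decay ordering needs genetic-map distances: supply a cM panel "
                "or an explicit `distances` vector (physical coordinates are "
                "not converted automatically)"
            )
        dist = panel.distances()
    else:
        dist = np.asarray(list(distances), dtype=float)
        if dist.shape != (len(panel),):
            raise ValueError("distances must have one entry per marker")
    rows = []
    for name, d in zip(panel.names, dist):
        ac = allele_counts(mutant, name, panel)
        retention = ac.frequency(founder.alleles[name])
        rows.append((name, float(d), retention, ac.total))
    frame = pd.DataFrame(rows, columns=["marker", "distance", "retention", "n_counted"])
    return frame.sort_values("distance", kind="stable").reset_index(drop=True)
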