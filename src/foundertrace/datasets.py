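"""Packaged reference datasets.

Transcriptions of the published cystinosis founder-analysis tables: the
phased microsatellite haplotypes of the c.1015G>A (Karachay) and c.518A>G
(Chechen) mutation carriers, the marker panels in physical (kb) and
Marshfield genetic (cM) coordinates, reconstructed control allele counts,
and the CTNS pathogenic-allele spectrum of the 40-patient cohort with
consequence/novelty annotations.

The control-count tables deserve a caveat: the study reports control allele
*frequencies* only in supplementary material, so the integer counts shipped
here were reconstructed by inverting the published delta values over the
stated control chromosome totals (38 Karachay, 34 Chechen) and verifying
that each integer count reproduces the printed delta to three decimals.
Only alleles for which that inversion is exact are included.
"""

from __future__ import annotations

from importlib import resources

from .cohort_io import GenotypeRecord, MarkerPanel, read_cohort, read_panel
from .founder_ld import AlleleCounts
from .spectrum_stats import VariantAnnot

__all__ = [
    "load_panel",
    "load_cohort",
    "load_control_counts",
    "load_spectrum_counts",
    "load_spectrum_cohort",
    "load_annotations",
    "default_sim_config",
]

_COHORT_FILES = {"karachay": "karachay_table3.tsv", "chechen": "chechen_table5.tsv"}
_CONTROL_FILES = {
    "karachay": "karachay_control_counts.tsv",
    "chechen": "chechen_control_counts.tsv",
}
VARIANT_LABELS = {"karachay": "c.1015G>A", "chechen": "c.518A>G"}


def _data_path(name: str):
    return resources.files("foundertrace.data").joinpath(name)


def load_panel(kind: str = "genetic") -> MarkerPanel:
    """The five-marker CTNS-flanking panel, ``"genetic"`` (cM) or ``"physical"`` (kb)."""
    fname = {"genetic": "panel_genetic_cm.yaml", "physical": "panel_physical_kb.yaml"}[kind]
    with resources.as_file(_data_path(fname)) as p:
        return read_panel(p)


def load_cohort(group: str, panel: MarkerPanel | None = None) -> list[GenotypeRecord]:
    """Published mutation-carrier haplotypes: ``"karachay"`` or ``"chechen"``."""
    if panel is None:
        panel = load_panel("physical")
    with resources.as_file(_data_path(_COHORT_FILES[group])) as p:
        return read_cohort(p, panel)


def load_control_counts(group: str) -> dict[str, AlleleCounts]:
    """Reconstructed control allele counts per marker (partial: target alleles only)."""
    counts: dict[str, AlleleCounts] = {}
    text = _data_path(_CONTROL_FILES[group]).read_text()
    for line in text.strip().splitlines()[1:]:
        marker, allele, count, total = line.split("\t")
        if marker in counts:
            counts[marker].counts[int(allele)] = int(count)
        else:
            counts[marker] = AlleleCounts(marker, {int(allele): int(count)}, int(total))
    return counts


def load_spectrum_counts() -> list[tuple[str, int]]:
    """Per-variant chromosome counts of the 40-patient spectrum (80 chromosomes)."""
    rows = []
    for line in _data_path("ctns_spectrum.tsv").read_text().strip().splitlines()[1:]:
        variant, count = line.rsplit("\t", 1)
        rows.append((variant, int(count)))
    return rows


def load_spectrum_cohort() -> list[tuple[str, str]]:
    """Synthetic 40-patient genotype pairing consistent with the spectrum counts.

    The publication prints per-variant chromosome counts, not all 40
    genotypes, so this loader expands the counts into 80 allele labels and
    pairs them deterministically.  Any statistic that depends only on
    allele counts (the spectrum itself, the novelty split) is exact; the
    individual pairings are synthetic.
    """
    alleles: list[str] = []
    for variant, count in load_spectrum_counts():
        alleles.extend([variant] * count)
    half = len(alleles) // 2
    return list(zip(alleles[:half], alleles[half:]))


def load_annotations() -> dict[str, VariantAnnot]:
    """Consequence class and novelty flag for every spectrum variant."""
    out: dict[str, VariantAnnot] = {}
    for line in _data_path("ctns_annotations.tsv").read_text().strip().splitlines()[1:]:
        variant, klass, novel = line.split("\t")
        out[variant] = VariantAnnot(variant, klass, bool(int(novel)))
    return out


def default_sim_config(seed: int = 0, **overrides):
    """A study-shaped simulation: 5-marker cM map, 4 cases, 19 controls.

    The genetic map mirrors the published panel's geometry (two markers
    ~3.4 cM proximal of the locus, one intragenic, one at the locus
    coordinate, one ~0.7 cM distal); the founder haplotype is the modal
    published one and control allele frequencies are a moderately
    polymorphic 4-allele distribution per marker.  ``g`` defaults to 15
    generations (a few centuries for a human population) and mu to 1e-3
    per meiosis, a typical dinucleotide microsatellite rate.
    """
    from .synth_cohort import SimConfig

    panel = load_panel("genetic")
    control_freqs = {
        name: {1: 0.4, 2: 0.3, 3: 0.2, 9: 0.1} for name in panel.names
    }
    cfg = dict(
        panel=panel,
        founder_haplotype=(1, 1, 3, 3, 9),
        control_freqs=control_freqs,
        g=15,
        mu=0.001,
        n_cases=4,
        n_controls=19,
        n_sites=200,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)
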