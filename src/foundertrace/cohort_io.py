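"""Cohort data model and I/O.

Genotype tables for a recessive-disease cohort: each sample carries a
disease-gene genotype (two pathogenic-variant labels, or none) plus unordered
or phased allele pairs at an ordered panel of microsatellite markers flanking
the disease locus.  The module also provides a minimal VCF/dosage reader for
the phylogeny stage and the extraction of phased mutant/control chromosomes
from mutation homozygotes.

Genotype-TSV dialect
--------------------
Tab-separated, UTF-8.  Header row::

    sample_id  population  variant1  variant2  <marker1>  <marker2> ...

Marker cells hold two integer allele labels joined by ``/`` (unordered) or
``|`` (phased: first allele belongs to the sample's first chromosome).
``.`` denotes a missing marker genotype; an empty variant column denotes no
pathogenic variant on that chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

MISSING = "."

__all__ = [
    "MarkerDef",
    "MarkerPanel",
    "GenotypeRecord",
    "Chromosome",
    "ChromosomeSet",
    "VariantMatrix",
    "read_panel",
    "write_panel",
    "read_cohort",
    "write_cohort",
    "read_variant_matrix",
    "extract_chromosomes",
]


@dataclass(frozen=True)
class MarkerDef:
    """A single microsatellite marker on the map.

    Parameters
    ----------
    name
        Marker label, e.g. ``"D17S831"``.
    position
        Map coordinate; the unit (physical or genetic) is declared on the
        enclosing :class:`MarkerPanel`, never assumed.
    intragenic
        True for a marker located inside the disease gene itself (such
        markers cannot recombine away from the causal variant).
    """

    name: str
    position: float
    intragenic: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("marker name must be non-empty")
        if not np.isfinite(self.position):
            raise ValueError(f"marker {self.name}: position must be finite")


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered set of flanking markers plus the disease-locus coordinate.

    Positions must be non-decreasing (genetic maps may assign tied
    coordinates to physically distinct markers) and marker names unique.
    ``unit`` is either ``"physical"`` (kb) or ``"genetic_cM"``.
    """

    markers: tuple[MarkerDef, ...]
    locus_position: float
    unit: str = "genetic_cM"

    def __post_init__(self) -> None:
        if self.unit not in ("physical", "genetic_cM"):
            raise ValueError(f"unknown panel unit {self.unit!r}")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names in panel")
        pos = [m.position for m in self.markers]
        if any(b < a for a, b in zip(pos, pos[1:])):
            raise ValueError("marker positions must be non-decreasing")
        if not np.isfinite(self.locus_position):
            raise ValueError("locus_position must be finite")

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    def __len__(self) -> int:
        return len(self.markers)

    def index(self, marker: str) -> int:
        try:
            return self.names.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in panel") from None

    def distances(self) -> np.ndarray:
        """Absolute map distance of each marker from the disease locus."""
        return np.abs(
            np.array([m.position for m in self.markers]) - self.locus_position
        )


def read_panel(path: str | Path) -> MarkerPanel:
    """Load a marker panel from a small YAML config.

    Expected keys: ``unit``, ``locus_position`` and a ``markers`` list of
    ``{name, position, intragenic}`` mappings (``intragenic`` optional).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    markers = tuple(
        MarkerDef(m["name"], float(m["position"]), bool(m.get("intragenic", False)))
        for m in doc["markers"]
    )
    return MarkerPanel(markers, float(doc["locus_position"]), doc.get("unit", "genetic_cM"))


def write_panel(panel: MarkerPanel, path: str | Path) -> None:
    doc = {
        "unit": panel.unit,
        "locus_position": panel.locus_position,
        "markers": [
            {"name": m.name, "position": m.position, "intragenic": m.intragenic}
            for m in panel.markers
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class GenotypeRecord:
    """One cohort sample: disease-gene genotype plus marker genotypes.

    ``disease_genotype`` holds two variant labels (empty string = no variant
    on that chromosome).  ``marker_genotypes`` maps marker name to an allele
    pair or ``None`` (missing); ``phased`` flags pairs whose order is
    chromosome order rather than arbitrary.
    """

    sample_id: str
    population: str
    disease_genotype: tuple[str, str]
    marker_genotypes: dict[str, Optional[tuple[int, int]]]
    phased: dict[str, bool] = field(default_factory=dict)

    def variant_dose(self, variant_label: str) -> int:
        return sum(1 for v in self.disease_genotype if v == variant_label)


@dataclass
class Chromosome:
    """A single (possibly phase-ambiguous) haplotype over the panel."""

    sample_id: str
    carries_mutation: bool
    alleles: tuple[Optional[int], ...]
    phase_source: str = "reported"  # homozygote | reported | simulated
    phase_ambiguous: bool = False


@dataclass
class ChromosomeSet:
    """Mutant (disease) and control (normal) chromosomes plus exclusions."""

    panel: MarkerPanel
    mutant: list[Chromosome]
    control: list[Chromosome]
    excluded: list[str] = field(default_factory=list)


@dataclass
class VariantMatrix:
    """Diploid alternate-allele dosage matrix (samples x sites).

    Dosages are 0/1/2 floats with ``nan`` for missing calls.
    """

    sample_ids: list[str]
    site_ids: list[str]
    dosages: np.ndarray  # float array, nan = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.site_ids)):
            raise ValueError("dosage matrix shape does not match ids")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")


# ---------------------------------------------------------------------------
# genotype-TSV reading/writing

_FIXED_COLS = ["sample_id", "population", "variant1", "variant2"]


def _parse_pair(cell: str, row: str, col: str) -> tuple[Optional[tuple[int, int]], bool]:
    cell = cell.strip()
    if cell == MISSING or cell == "":
        return None, False
    phased = "|" in cell
    sep = "|" if phased else "/"
    parts = cell.split(sep)
    if len(parts) != 2:
        raise ValueError(f"malformed allele pair {cell!r} at row {row!r}, column {col!r}")
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError:
        raise ValueError(
            f"malformed allele pair {cell!r} at row {row!r}, column {col!r}"
        ) from None
    if a <= 0 or b <= 0:
        raise ValueError(f"allele labels must be positive at row {row!r}, column {col!r}")
    return (a, b), phased


def read_cohort(path: str | Path, panel: MarkerPanel) -> list[GenotypeRecord]:
    """Read a genotype-TSV cohort table against a marker panel.

    Raises
    ------
    ValueError
        If the header names a marker absent from the panel, or a cell holds
        a malformed allele pair.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file, expected a header row")
    header = lines[0].split("\t")
    if header[: len(_FIXED_COLS)] != _FIXED_COLS:
        raise ValueError(
            f"{path}: header must start with {_FIXED_COLS}, got {header[:4]}"
        )
    marker_cols = header[len(_FIXED_COLS) :]
    unknown = [m for m in marker_cols if m not in panel.names]
    if unknown:
        raise ValueError(f"{path}: unknown marker column(s) {unknown}")

    records: list[GenotypeRecord] = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise ValueError(
                f"{path}: row {cells[0]!r} has {len(cells)} cells, expected {len(header)}"
            )
        sample_id, population, v1, v2 = (c.strip() for c in cells[:4])
        v1 = "" if v1 == MISSING else v1
        v2 = "" if v2 == MISSING else v2
        genos: dict[str, Optional[tuple[int, int]]] = {}
        phased: dict[str, bool] = {}
        for col, cell in zip(marker_cols, cells[4:]):
            pair, ph = _parse_pair(cell, sample_id, col)
            genos[col] = pair
            phased[col] = ph
        # markers absent from the file are missing for every sample
        for name in panel.names:
            genos.setdefault(name, None)
            phased.setdefault(name, False)
        records.append(GenotypeRecord(sample_id, population, (v1, v2), genos, phased))
    return records


def write_cohort(records: Sequence[GenotypeRecord], panel: MarkerPanel, path: str | Path) -> None:
    """Write records in the canonical genotype-TSV dialect (round-trip safe)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_FIXED_COLS + panel.names) + "\n")
        for rec in records:
            v1, v2 = rec.disease_genotype
            cells = [rec.sample_id, rec.population, v1 or MISSING, v2 or MISSING]
            for name in panel.names:
                pair = rec.marker_genotypes.get(name)
                if pair is None:
                    cells.append(MISSING)
                else:
                    sep = "|" if rec.phased.get(name, False) else "/"
                    cells.append(f"{pair[0]}{sep}{pair[1]}")
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# minimal VCF / dosage matrix

def read_variant_matrix(path: str | Path) -> VariantMatrix:
    """Read a multi-sample VCF into an alternate-allele dosage matrix.

    Only biallelic SNV records are used; others are skipped with a logged
    count.  Half-calls and ``./.`` genotypes become missing.  Any phasing in
    GT separators is ignored (dosage is phase-free).
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF contains no samples")
        site_ids: list[str] = []
        rows: list[list[float]] = []
        n_skipped = 0
        for rec in vf:
            if (
                rec.alts is None
                or len(rec.alts) != 1
                or len(rec.ref) != 1
                or len(rec.alts[0]) != 1
            ):
                n_skipped += 1
                continue
            site_ids.append(f"{rec.chrom}:{rec.pos}:{rec.ref}>{rec.alts[0]}")
            col: list[float] = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt) or len(gt) != 2:
                    col.append(np.nan)
                else:
                    col.append(float(sum(gt)))
            rows.append(col)
    if n_skipped:
        logger.info("read_variant_matrix: skipped %d non-biallelic-SNV records", n_skipped)
    dosages = (
        np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    )
    return VariantMatrix(samples, site_ids, dosages)


# ---------------------------------------------------------------------------
# chromosome extraction

def extract_chromosomes(
    records: Sequence[GenotypeRecord], variant_label: str, panel: MarkerPanel
) -> ChromosomeSet:
    """Split a cohort into mutant and control chromosomes for one variant.

    Each sample homozygous for ``variant_label`` contributes two mutant
    chromosomes.  Where such a sample is marker-heterozygous, phased pairs
    are split in reported order; unphased pairs keep both alleles as
    unordered contributions (each chromosome takes one allele arbitrarily
    and is flagged phase-ambiguous — per-marker allele *counts*, the
    quantity every downstream frequency uses, are unaffected).  Samples
    without the variant contribute two control chromosomes; compound
    heterozygotes carrying one copy are excluded from frequency counting.
    """
    if not any(variant_label in r.disease_genotype for r in records):
        raise ValueError(f"variant {variant_label!r} not present in cohort")

    out = ChromosomeSet(panel, [], [], [])
    for rec in records:
        dose = rec.variant_dose(variant_label)
        if dose == 1:
            out.excluded.append(rec.sample_id)
            continue
        carries = dose == 2
        hap_a: list[Optional[int]] = []
        hap_b: list[Optional[int]] = []
        ambiguous = False
        all_phased = True
        for name in panel.names:
            pair = rec.marker_genotypes.get(name)
            if pair is None:
                hap_a.append(None)
                hap_b.append(None)
                all_phased = False
                continue
            a, b = pair
            if a != b and not rec.phased.get(name, False):
                ambiguous = True
            if not rec.phased.get(name, False):
                all_phased = False
            hap_a.append(a)
            hap_b.append(b)
        source = "reported" if all_phased else "homozygote"
        dest = out.mutant if carries else out.control
        for hap in (hap_a, hap_b):
            dest.append(
                Chromosome(rec.sample_id, carries, tuple(hap), source, ambiguous)
            )
    return out
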