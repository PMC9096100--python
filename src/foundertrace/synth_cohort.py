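"""Synthetic founder-cohort simulator.

Generates cohorts with the statistical structure the founder-effect
analysis assumes: a single founder chromosome carrying the pathogenic
variant was introduced ``g`` generations ago; flanking microsatellites
recombine away from the disease locus per a genetic map (Haldane map
function, no interference) and mutate under a symmetric single-step
stepwise model; sampled patients are mutation homozygotes formed from two
independent founder-descended chromosomes (a consanguinity approximation —
no explicit pedigree), and controls are draws from population allele
frequencies.  A matched variant dosage matrix is emitted for the phylogeny
stage, in which cases share rare founder background variants to a degree
set by founder recency.

Ground truth (founder haplotype, per-marker recombination fraction theta,
expected retention ``(1 - theta)^g``) is returned alongside every cohort so
recovery of the decay parameters can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort_io import Chromosome, ChromosomeSet, GenotypeRecord, MarkerPanel, VariantMatrix, read_panel
from .founder_ld import allele_counts, compute_delta

__all__ = [
    "SimConfig",
    "SimTruth",
    "haldane_theta",
    "expected_retention",
    "transmit_mutant_chromosome",
    "simulate_case_alleles",
    "simulate_cohort",
    "recover_parameters",
    "load_sim_config",
]


def haldane_theta(distance_cm: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: recombination fraction from distance in cM.

    theta = (1 - exp(-2 d)) / 2 with d in Morgans; approaches 0.5 for
    unlinked loci and is ~d for tight linkage.
    """
    d = np.asarray(distance_cm, dtype=float)
    if (d < 0).any():
        raise ValueError("map distance must be nonnegative")
    theta = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(theta) if np.isscalar(distance_cm) else theta


def expected_retention(theta: float | np.ndarray, g: int) -> float | np.ndarray:
    """Probability the founder allele survives g meioses: (1 - theta)^g."""
    return (1.0 - np.asarray(theta, dtype=float)) ** g


@dataclass
class SimConfig:
    """Parameters of one synthetic founder cohort.

    Defaults mirror the study conditions of the motivating analysis: a
    five-marker genetic map around the disease locus, four mutation
    homozygotes against ~19 controls, and a founding event some tens of
    generations back with a per-marker stepwise mutation rate typical of
    dinucleotide microsatellites (~1e-3 per meiosis).
    """

    panel: MarkerPanel
    founder_haplotype: tuple[int, ...]
    control_freqs: dict[str, dict[int, float]]
    g: int = 15
    mu: float = 0.001
    n_cases: int = 4
    n_controls: int = 19
    n_sites: int = 200
    variant_label: str = "c.100A>G"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.founder_haplotype) != len(self.panel):
            raise ValueError("founder haplotype length must match panel")
        if self.g < 0:
            raise ValueError("g must be nonnegative")
        if not (0.0 <= self.mu <= 0.01):
            raise ValueError("mu must be in [0, 0.01]")
        if self.n_cases < 1:
            raise ValueError("need at least one case")
        for name in self.panel.names:
            freqs = self.control_freqs.get(name)
            if not freqs:
                raise ValueError(f"no control frequencies for marker {name}")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"control frequencies at {name} must sum to 1")

    def thetas(self) -> np.ndarray:
        """Per-marker recombination fraction from the genetic map.

        Intragenic markers are held at theta = 0 regardless of their map
        coordinate (they cannot recombine away from the causal variant).
        """
        if self.panel.unit != "genetic_cM":
            raise ValueError("simulation requires a genetic-map (cM) panel")
        theta = haldane_theta(self.panel.distances())
        intragenic = np.array([m.intragenic for m in self.panel.markers])
        return np.where(intragenic, 0.0, theta)


@dataclass
class SimTruth:
    """Simulator ground truth for parameter-recovery tests."""

    founder_haplotype: tuple[int, ...]
    g: int
    theta: np.ndarray
    expected_retention: np.ndarray
    realized_retention: np.ndarray = field(default=None)  # IBD fraction per marker


def _marker_samplers(config: SimConfig):
    """Per-marker (alleles, freqs) arrays for control draws."""
    out = []
    for name in config.panel.names:
        freqs = config.control_freqs[name]
        alleles = np.array(sorted(freqs), dtype=int)
        probs = np.array([freqs[a] for a in alleles], dtype=float)
        out.append((alleles, probs / probs.sum()))
    return out


def simulate_case_alleles(
    config: SimConfig, n_chromosomes: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw founder-descended chromosomes (vectorised).

    Returns ``(alleles, retained)``: an (n, markers) integer allele matrix
    and the boolean identity-by-descent indicator (True where the founder
    allele survived recombination, before mutation).  Per marker the
    founder allele is retained with probability ``(1 - theta)^g``; lost
    positions are redrawn from the control frequencies; finally a stepwise
    +/-1 mutation hits each allele with probability ``1 - (1 - mu)^g``
    (reflected at the minimum label 1).
    """
    k = len(config.panel)
    ret_p = expected_retention(config.thetas(), config.g)
    retained = rng.random((n_chromosomes, k)) < ret_p[None, :]
    alleles = np.empty((n_chromosomes, k), dtype=int)
    samplers = _marker_samplers(config)
    founder = np.asarray(config.founder_haplotype, dtype=int)
    for j, (pool, probs) in enumerate(samplers):
        repl = rng.choice(pool, size=n_chromosomes, p=probs)
        alleles[:, j] = np.where(retained[:, j], founder[j], repl)
    p_mut = 1.0 - (1.0 - config.mu) ** config.g
    if p_mut > 0:
        hits = rng.random((n_chromosomes, k)) < p_mut
        steps = rng.choice([-1, 1], size=(n_chromosomes, k))
        stepped = alleles + np.where(hits, steps, 0)
        stepped[stepped < 1] = 2  # reflect a 1 -> 0 step back up
        retained = retained & ~hits
        alleles = stepped
    return alleles, retained


def transmit_mutant_chromosome(config: SimConfig, rng: np.random.Generator) -> Chromosome:
    """One founder-descended, mutation-carrying chromosome."""
    alleles, _ = simulate_case_alleles(config, 1, rng)
    return Chromosome("sim", True, tuple(int(a) for a in alleles[0]), "simulated")


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[GenotypeRecord], SimTruth, VariantMatrix]:
    """Simulate a full cohort: case/control genotype records, truth, dosages.

    Cases are mutation homozygotes built from two independent
    founder-descended chromosomes each; controls draw both chromosomes from
    the population frequencies.  Marker pairs are emitted phased (the
    simulator knows the chromosomes).  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    k = len(config.panel)
    theta = config.thetas()

    case_alleles, case_ibd = simulate_case_alleles(config, 2 * config.n_cases, rng)
    samplers = _marker_samplers(config)
    ctrl_alleles = np.empty((2 * config.n_controls, k), dtype=int)
    for j, (pool, probs) in enumerate(samplers):
        ctrl_alleles[:, j] = rng.choice(pool, size=2 * config.n_controls, p=probs)

    records: list[GenotypeRecord] = []
    for i in range(config.n_cases):
        h1, h2 = case_alleles[2 * i], case_alleles[2 * i + 1]
        records.append(
            GenotypeRecord(
                sample_id=f"CASE{i + 1:03d}",
                population="simulated",
                disease_genotype=(config.variant_label, config.variant_label),
                marker_genotypes={
                    name: (int(h1[j]), int(h2[j])) for j, name in enumerate(config.panel.names)
                },
                phased={name: True for name in config.panel.names},
            )
        )
    for i in range(config.n_controls):
        h1, h2 = ctrl_alleles[2 * i], ctrl_alleles[2 * i + 1]
        records.append(
            GenotypeRecord(
                sample_id=f"CTRL{i + 1:03d}",
                population="simulated",
                disease_genotype=("", ""),
                marker_genotypes={
                    name: (int(h1[j]), int(h2[j])) for j, name in enumerate(config.panel.names)
                },
                phased={name: True for name in config.panel.names},
            )
        )

    truth = SimTruth(
        founder_haplotype=tuple(config.founder_haplotype),
        g=config.g,
        theta=theta,
        expected_retention=expected_retention(theta, config.g),
        realized_retention=case_ibd.mean(axis=0),
    )

    # --- background variant sites for the phylogeny stage -----------------
    # Each site has a population alt frequency; the founder chromosome's
    # genotype at linked sites is inherited by case chromosomes with the
    # same (1-theta_site)^g retention law, so recent founders leave a
    # shared rare-variant signature.
    s = config.n_sites
    site_freq = rng.uniform(0.02, 0.30, size=s)
    # the founder is a population member: its background haplotype is drawn
    # from the same site frequencies, so descendants are recognisable by
    # *which* alleles they share, not by an inflated allele load
    founder_bg = rng.random(s) < site_freq
    theta_site = rng.uniform(0.0, 0.05, size=s)
    ret_site = expected_retention(theta_site, config.g)

    def _case_bg(n_chrom: int) -> np.ndarray:
        keep = rng.random((n_chrom, s)) < ret_site[None, :]
        fresh = rng.random((n_chrom, s)) < site_freq[None, :]
        return np.where(keep, founder_bg[None, :], fresh)

    case_h = _case_bg(2 * config.n_cases)
    ctrl_h = rng.random((2 * config.n_controls, s)) < site_freq[None, :]
    haps = np.vstack([case_h, ctrl_h]).astype(float)
    dosages = haps[0::2] + haps[1::2]
    matrix = VariantMatrix(
        [r.sample_id for r in records],
        [f"site{j + 1}" for j in range(s)],
        dosages,
    )
    return records, truth, matrix


def recover_parameters(
    chromosomes: ChromosomeSet,
    founder_haplotype: Sequence[int],
    control_freqs: Optional[dict[str, dict[int, float]]] = None,
    g_true: Optional[int] = None,
) -> pd.DataFrame:
    """Estimate per-marker founder retention and generations since founding.

    Retention is estimated as the delta statistic of the founder allele
    (case frequency against control frequency): under the transmission
    model the case frequency is ``r + (1 - r) p`` with ``p`` the population
    frequency, so ``delta = (PD - PN)/(1 - PN)`` recovers ``r`` free of
    background allele sharing.  Then ``g_hat = log r / log(1 - theta)``,
    undefined (NaN) where theta is 0 or the retention estimate is <= 0;
    retention estimates >= 1 give g_hat = 0.

    ``control_freqs`` may supply known population frequencies (e.g. from
    simulator truth); otherwise they are estimated from the control
    chromosomes.
    """
    panel = chromosomes.panel
    theta = haldane_theta(panel.distances())
    theta = np.where([m.intragenic for m in panel.markers], 0.0, theta)
    rows = []
    for j, name in enumerate(panel.names):
        fa = int(founder_haplotype[j])
        case = allele_counts(chromosomes.mutant, name, panel)
        pd_hat = case.frequency(fa)
        if control_freqs is not None:
            pn_hat = control_freqs[name].get(fa, 0.0)
        else:
            ctrl = allele_counts(chromosomes.control, name, panel)
            pn_hat = ctrl.frequency(fa)
        retention = np.nan if pn_hat == 1.0 else compute_delta(pd_hat, pn_hat)
        th = theta[j]
        if not np.isfinite(retention) or retention <= 0.0 or th <= 0.0:
            g_hat = np.nan
        elif retention >= 1.0:
            g_hat = 0.0
        else:
            g_hat = np.log(retention) / np.log(1.0 - th)
        rows.append((name, th, retention, g_hat))
    frame = pd.DataFrame(rows, columns=["marker", "theta", "retention_hat", "g_hat"])
    if g_true is not None:
        frame["g_true"] = g_true
    return frame


def load_sim_config(path: str | Path, panel: Optional[MarkerPanel] = None) -> SimConfig:
    """Load a SimConfig from a flat YAML file.

    The file holds scalar keys of :class:`SimConfig` plus either an inline
    ``panel`` mapping or a ``panel_path``; ``founder_haplotype`` is a list
    and ``control_freqs`` a mapping marker -> {allele: freq}.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if panel is None:
        if "panel_path" in doc:
            panel = read_panel(Path(path).parent / doc["panel_path"])
        else:
            from .cohort_io import MarkerDef

            pdoc = doc["panel"]
            panel = MarkerPanel(
                tuple(
                    MarkerDef(m["name"], float(m["position"]), bool(m.get("intragenic", False)))
                    for m in pdoc["markers"]
                ),
                float(pdoc["locus_position"]),
                pdoc.get("unit", "genetic_cM"),
            )
    control_freqs = {
        str(mk): {int(a): float(f) for a, f in freqs.items()}
        for mk, freqs in doc["control_freqs"].items()
    }
    kwargs = {
        k: doc[k]
        for k in ("g", "mu", "n_cases", "n_controls", "n_sites", "variant_label", "seed")
        if k in doc
    }
    return SimConfig(
        panel=panel,
        founder_haplotype=tuple(int(a) for a in doc["founder_haplotype"]),
        control_freqs=control_freqs,
        **kwargs,
    )
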