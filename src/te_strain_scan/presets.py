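"""Preset synthetic study datasets.

These bundle the generator parameters used throughout the test-bed:

* ``strain_contrast_dataset`` — the full two-strain scenario: one family
  ("POLY") with a recently amplified, near-identical clade private to
  the inducer strain plus shared ancient degraded fragments, and one
  control family ("UBIQ") equally active in both strains.
* ``copy_ratio_dataset`` — a minimal one-family design with a planted
  copy-number ratio k between strains, for fold-recovery checks.

No per-strain copy numbers for the real element are published, so the
presets are illustrative study conditions, not calibrated estimates: an
inducer-specific burst of 20 copies against a handful of heavily
degraded (13-22% diverged, truncated) relics, sequenced at modest
single-end coverage with 0.5% base error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import simulate as sim
from .enrichment import RepeatLibrary


@dataclass
class StrainDataset:
    library: RepeatLibrary
    families: dict[str, sim.FamilyCopies]
    genomes: dict[str, sim.SyntheticGenome]
    readsets: dict[str, sim.SimReadSet]
    denominators: dict[str, int]  # reads wholly from the genomic background
    seed: int


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def strain_contrast_dataset(
    seed: int = 0,
    background_length: int = 200_000,
    coverage: float = 8.0,
    read_length: int = 100,
    error_rate: float = 0.005,
    n_active_inducer: int = 20,
) -> StrainDataset:
    """Inducer ("160") vs non-inducer ("9") strains: POLY active only in
    the inducer, UBIQ active in both, degraded POLY relics shared."""
    s = _subseeds(seed, 8)
    poly = sim.TEFamilySpec(
        "POLY", consensus_length=1708, tir_length=235,
        n_active_copies_per_strain={"160": n_active_inducer, "9": 0},
        active_divergence=0.01, n_degraded_copies=8,
        degraded_divergence_range=(0.14, 0.24),
        truncation_fraction_range=(0.4, 0.9), seed=s[0])
    ubiq = sim.TEFamilySpec(
        "UBIQ", consensus_length=1200, tir_length=50,
        n_active_copies_per_strain={"160": 6, "9": 6},
        active_divergence=0.01, n_degraded_copies=0, seed=s[1])
    fams = {f.family_id: sim.simulate_family(f) for f in (poly, ubiq)}
    genomes = sim.build_genomes(list(fams.values()), background_length,
                                seed=s[2])
    readsets, denominators = {}, {}
    for i, (strain, genome) in enumerate(sorted(genomes.items())):
        rs = sim.simulate_reads(genome, coverage, read_length, error_rate,
                                seed=s[3 + i])
        readsets[strain] = rs
        denominators[strain] = sim.background_read_count(rs, genome)
    library = RepeatLibrary({fid: fam.consensus for fid, fam in fams.items()})
    return StrainDataset(library, fams, genomes, readsets, denominators, seed)


def copy_ratio_dataset(
    k: int,
    seed: int = 0,
    copies_low: int = 3,
    background_length: int = 200_000,
    coverage: float = 6.0,
    read_length: int = 100,
    error_rate: float = 0.005,
) -> StrainDataset:
    """One family with k-fold more active copies in strain A than B."""
    s = _subseeds(seed + 7919 * k, 6)
    spec = sim.TEFamilySpec(
        "FAM", consensus_length=1000, tir_length=50,
        n_active_copies_per_strain={"A": k * copies_low, "B": copies_low},
        active_divergence=0.005, n_degraded_copies=0, seed=s[0])
    fam = sim.simulate_family(spec)
    genomes = sim.build_genomes([fam], background_length, seed=s[1])
    readsets, denominators = {}, {}
    for i, (strain, genome) in enumerate(sorted(genomes.items())):
        rs = sim.simulate_reads(genome, coverage, read_length, error_rate,
                                seed=s[2 + i])
        readsets[strain] = rs
        denominators[strain] = sim.background_read_count(rs, genome)
    library = RepeatLibrary({"FAM": fam.consensus})
    return StrainDataset(library, {"FAM": fam}, genomes, readsets,
                         denominators, seed)
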