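"""Synthetic data: TE family histories, host genomes, short reads and
factorial expression tables.

The generator emulates the contrast the downstream screen is built to
detect: two host strains share a background of ancient, degraded TE
fragments (high divergence, truncated), but only the *inducer* strain
carries copies of a recently amplified, near-identical clade of the same
family.  Reads are 100-bp single-end with substitution errors; the
expression generator produces the 16-observation factorial layout
(treatment x age x barcoded library x lane) the ANOVA module fits.

Every operation is a pure function of its seed and arguments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import encode, mutate, random_dna, revcomp
from .io import FastqRead


@dataclass
class TEFamilySpec:
    """Parameters of one simulated TE family's history.

    active_divergence is the within-clade per-site substitution
    probability of the recent burst (near 0 for a just-amplified
    lineage); degraded copies draw a divergence uniformly from
    degraded_divergence_range and keep a uniform fraction of their
    length from truncation_fraction_range, truncated from a random end.
    """

    family_id: str
    consensus_length: int
    tir_length: int
    n_active_copies_per_strain: dict[str, int]
    active_divergence: float = 0.01
    n_degraded_copies: int = 0
    degraded_divergence_range: tuple[float, float] = (0.10, 0.20)
    truncation_fraction_range: tuple[float, float] = (0.2, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.consensus_length <= 0 or self.tir_length < 0:
            raise ValueError("lengths must be positive")
        if 2 * self.tir_length >= self.consensus_length:
            raise ValueError("tir_length*2 must be < consensus_length")
        divs = (self.active_divergence, *self.degraded_divergence_range)
        if any(not 0.0 <= d <= 0.75 for d in divs):
            raise ValueError("divergences must lie in [0, 0.75]")
        if self.n_degraded_copies < 0 or any(
            n < 0 for n in self.n_active_copies_per_strain.values()
        ):
            raise ValueError("copy counts must be >= 0")


@dataclass
class TECopy:
    family_id: str
    copy_id: str
    sequence: str
    is_active_clade: bool
    divergence: float
    kept_fraction: float = 1.0


@dataclass
class FamilyCopies:
    spec: TEFamilySpec
    consensus: str
    active_by_strain: dict[str, list[TECopy]]
    degraded: list[TECopy]  # shared between strains


@dataclass
class Insertion:
    family_id: str
    copy_id: str
    start: int
    end: int
    strand: str
    is_active_clade: bool
    copy_sequence: str  # plus-strand sequence as inserted source


@dataclass
class SyntheticGenome:
    sequence: str
    insertions: list[Insertion]
    strain_label: str


@dataclass
class SimRead:
    id: str
    sequence: str
    qualities: list[int]
    origin: tuple[int, int, str]  # 0-based half-open interval + strand on genome


@dataclass
class SimReadSet:
    reads: list[SimRead]
    read_length: int
    strain_label: str
    seed: int

    def to_fastq(self) -> list[FastqRead]:
        return [FastqRead(r.id, r.sequence, r.qualities) for r in self.reads]


def make_consensus(length: int, tir_length: int, rng: np.random.Generator) -> str:
    """Random ancestral consensus whose last tir_length bases are the
    reverse complement of the first tir_length bases."""
    seq = random_dna(length, rng)
    if tir_length:
        seq = seq[: length - tir_length] + revcomp(seq[:tir_length])
    return seq


def simulate_family(spec: TEFamilySpec) -> FamilyCopies:
    rng = np.random.default_rng(spec.seed)
    consensus = make_consensus(spec.consensus_length, spec.tir_length, rng)
    active: dict[str, list[TECopy]] = {}
    for strain in sorted(spec.n_active_copies_per_strain):
        n = spec.n_active_copies_per_strain[strain]
        active[strain] = [
            TECopy(spec.family_id, f"{spec.family_id}.{strain}.act{i}",
                   mutate(consensus, spec.active_divergence, rng),
                   True, spec.active_divergence)
            for i in range(n)
        ]
    lo, hi = spec.degraded_divergence_range
    flo, fhi = spec.truncation_fraction_range
    degraded = []
    for i in range(spec.n_degraded_copies):
        div = float(rng.uniform(lo, hi))
        frac = float(rng.uniform(flo, fhi))
        seq = mutate(consensus, div, rng)
        keep = max(1, int(round(frac * len(seq))))
        if rng.random() < 0.5:  # truncate from a uniformly chosen end
            seq = seq[:keep]
        else:
            seq = seq[len(seq) - keep:]
        degraded.append(
            TECopy(spec.family_id, f"{spec.family_id}.deg{i}", seq, False,
                   div, keep / spec.consensus_length)
        )
    return FamilyCopies(spec, consensus, active, degraded)


def build_genomes(
    families: list[TEFamilySpec] | list[FamilyCopies],
    background_length: int,
    seed: int,
) -> dict[str, SyntheticGenome]:
    """Assemble one genome per strain: a shared random background with
    degraded copies at shared positions and strain-specific active copies.

    Insertions are placed at distinct offsets of the background (copies
    displace, rather than overwrite, background sequence) so they can
    never overlap; the returned truth table records the realized 0-based
    half-open intervals on each strain's final coordinates.
    """
    rng = np.random.default_rng(seed)
    fams = [simulate_family(f) if isinstance(f, TEFamilySpec) else f
            for f in families]
    strains = sorted({s for f in fams for s in f.spec.n_active_copies_per_strain})
    if not strains:
        raise ValueError("no strains declared in family specs")
    total_inserted = sum(
        sum(len(c.sequence) for c in f.degraded)
        + max(
            (sum(len(c.sequence) for c in f.active_by_strain.get(s, []))
             for s in strains),
            default=0,
        )
        for f in fams
    )
    if background_length <= total_inserted:
        raise ValueError(
            f"background_length {background_length} must exceed total "
            f"inserted length {total_inserted}"
        )
    background = random_dna(background_length, rng)

    # shared (degraded) placements: one offset/strand per copy, reused in
    # every strain; active placements drawn per strain
    shared: list[tuple[int, str, TECopy]] = []
    used_offsets: set[int] = set()

    def draw_offset() -> int:
        while True:
            o = int(rng.integers(0, background_length + 1))
            if o not in used_offsets:
                used_offsets.add(o)
                return o

    for fam in fams:
        for copy in fam.degraded:
            strand = "+" if rng.random() < 0.5 else "-"
            shared.append((draw_offset(), strand, copy))

    genomes: dict[str, SyntheticGenome] = {}
    for strain in strains:
        placements = list(shared)
        strain_used = set(used_offsets)
        for fam in fams:
            for copy in fam.active_by_strain.get(strain, []):
                while True:
                    o = int(rng.integers(0, background_length + 1))
                    if o not in strain_used:
                        strain_used.add(o)
                        break
                strand = "+" if rng.random() < 0.5 else "-"
                placements.append((o, strand, copy))
        placements.sort(key=lambda t: t[0])
        parts: list[str] = []
        insertions: list[Insertion] = []
        cursor = 0
        shift = 0
        for offset, strand, copy in placements:
            parts.append(background[cursor:offset])
            start = offset + shift
            seq = copy.sequence if strand == "+" else revcomp(copy.sequence)
            parts.append(seq)
            insertions.append(
                Insertion(copy.family_id, copy.copy_id, start,
                          start + len(seq), strand, copy.is_active_clade,
                          copy.sequence)
            )
            shift += len(seq)
            cursor = offset
        parts.append(background[cursor:])
        genomes[strain] = SyntheticGenome("".join(parts), insertions, strain)
    return genomes


def simulate_reads(
    genome: SyntheticGenome,
    mean_coverage: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    base_quality: int = 35,
    low_quality_tail: tuple[int, int] | None = None,
) -> SimReadSet:
    """Uniform single-end reads at round(coverage * G / L) depth.

    low_quality_tail=(n, q) gives every read an n-base 3' tail at Phred
    quality q, for exercising the QC trimmer.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be > 0")
    glen = len(genome.sequence)
    if read_length > glen:
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(seed)
    n_reads = int(round(mean_coverage * glen / read_length))
    starts = rng.integers(0, glen - read_length + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    quals = [base_quality] * read_length
    if low_quality_tail:
        ntail, qtail = low_quality_tail
        quals = quals[: read_length - ntail] + [qtail] * ntail
    reads = []
    for i in range(n_reads):
        s = int(starts[i])
        frag = genome.sequence[s: s + read_length]
        strand = "-" if strands[i] else "+"
        if strand == "-":
            frag = revcomp(frag)
        if error_rate > 0:
            frag = mutate(frag, error_rate, rng)
        reads.append(
            SimRead(f"{genome.strain_label}.r{i}", frag, list(quals),
                    (s, s + read_length, strand))
        )
    return SimReadSet(reads, read_length, genome.strain_label, seed)


def background_read_count(readset: SimReadSet, genome: SyntheticGenome) -> int:
    """Reads whose true origin lies wholly outside every TE insertion —
    the truth-table stand-in for 'reads mapped to the reference genome'
    used as the normalization denominator in simulations."""
    bounds = sorted((ins.start, ins.end) for ins in genome.insertions)
    starts = np.array([b[0] for b in bounds])
    ends = np.array([b[1] for b in bounds])
    n = 0
    for r in readset.reads:
        s, e, _ = r.origin
        i = np.searchsorted(ends, s, side="right")
        if i >= len(starts) or starts[i] >= e:
            n += 1
    return n


# ---------------------------------------------------------------------------
# expression design

TREATMENTS = ("dysgenic", "non-dysgenic")
AGE_CLASSES = ("12-16d", "19-21d")


@dataclass
class ExpressionDesign:
    """Reciprocal-cross germline expression design: RNA from embryos of F1
    females of the dysgenic and non-dysgenic cross, at two maternal ages,
    each sample split into two barcoded libraries, each library run on two
    lanes — 16 RPM observations.

    cell_means maps (treatment, age_class) -> mean RPM.  barcode_levels
    defaults to 3 so the fitted barcode factor carries 2 df, matching the
    published table structure (1, 1, 2, 1, 10); set 2 for a fully
    balanced crossed design.
    """

    cell_means: dict[tuple[str, str], float]
    noise_sd: float = 1.0
    barcode_levels: int = 3
    seed: int = 0
    barcode_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.barcode_levels < 2:
            raise ValueError("need >= 2 barcode levels")
        for key in itertools.product(TREATMENTS, AGE_CLASSES):
            if key not in self.cell_means:
                raise ValueError(f"missing cell mean for {key}")


def simulate_expression(design: ExpressionDesign) -> pd.DataFrame:
    """16 RPM observations: cell mean + barcode effect + Gaussian noise."""
    rng = np.random.default_rng(design.seed)
    rows = []
    lib = 0
    for treat, age in itertools.product(TREATMENTS, AGE_CLASSES):
        for index in range(2):
            barcode = f"B{lib % design.barcode_levels}"
            for lane in range(2):
                mean = design.cell_means[(treat, age)]
                mean += design.barcode_effects.get(barcode, 0.0)
                rpm = mean + rng.normal(0.0, design.noise_sd)
                rows.append(
                    {"library": f"L{lib}", "treatment": treat,
                     "age_class": age, "barcode": barcode,
                     "lane": f"lane{lane}", "rpm": float(rpm)}
                )
            lib += 1
    return pd.DataFrame(rows)
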