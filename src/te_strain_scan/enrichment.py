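"""Repeat-family read abundance screen.

Reads from each strain are assigned to a consensus repeat library by a
k-mer seed + gapless diagonal extension assigner (best-identity family
wins), counts are normalized to reads-per-million-mapped against a
per-strain denominator, and per-family inducer:non-inducer fold ratios
are tested with a Pearson chi-squared on the 2x2 family-vs-rest table.

The assigner is a desk-scale stand-in for an external short-read mapper;
a SAM import path (`assignments_from_sam`) lets externally mapped reads
enter the same count table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from ._seq import encode, revcomp
from .io import read_fasta

DEFAULT_K = 15
DEFAULT_MIN_IDENTITY = 0.85
DEFAULT_MIN_ALIGNED_FRACTION = 0.5


@dataclass
class RepeatLibrary:
    """Named consensus sequences reads are assigned to."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for fid, seq in self.entries.items():
            if not set(seq) <= set("ACGTN"):
                raise ValueError(f"{fid}: sequence not over ACGTN")

    @classmethod
    def from_fasta(cls, path) -> "RepeatLibrary":
        return cls(read_fasta(path))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ReadAssignment:
    read_id: str
    family_id: str | None
    start: int  # 0-based on consensus
    strand: str
    identity: float
    aligned_length: int
    aligned_sequence: str = ""  # consensus-oriented read segment

    @property
    def assigned(self) -> bool:
        return self.family_id is not None


UNASSIGNED = ("", None, 0, ".", 0.0, 0, "")


class KmerIndex:
    """Exact k-mer index over both strands of every library consensus.

    Lookup returns (family_id, position, strand) where position is on
    the consensus for '+' entries and on the reverse-complemented
    consensus for '-' entries.
    """

    def __init__(self, library: RepeatLibrary, k: int = DEFAULT_K):
        if k < 8:
            raise ValueError("k must be >= 8")
        shortest = min(len(s) for s in library.entries.values())
        if k > shortest:
            raise ValueError(f"k={k} exceeds shortest consensus ({shortest} bp)")
        self.k = k
        self.library = library
        self.codes = {fid: encode(seq) for fid, seq in library.entries.items()}
        self.lengths = {fid: len(seq) for fid, seq in library.entries.items()}
        self._map: dict[str, list[tuple[str, int, str]]] = {}
        for fid, seq in library.entries.items():
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                for i in range(len(s) - k + 1):
                    self._map.setdefault(s[i: i + k], []).append((fid, i, strand))

    def lookup(self, kmer: str) -> Sequence[tuple[str, int, str]]:
        return self._map.get(kmer, ())

    def __len__(self) -> int:
        return sum(len(v) for v in self._map.values())


def build_index(library: RepeatLibrary, k: int = DEFAULT_K) -> KmerIndex:
    return KmerIndex(library, k)


def assign_read(
    read: str,
    index: KmerIndex,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aligned_fraction: float = DEFAULT_MIN_ALIGNED_FRACTION,
    read_id: str = "",
    n_seeds: int = 9,
) -> ReadAssignment:
    """Assign one read to its best-identity family, or leave unassigned.

    Seeds (k-mers sampled along the read) nominate (family, strand,
    diagonal) candidates; each candidate is scored by gapless comparison
    of the strand-oriented read against the consensus along that
    diagonal, clipped at consensus ends.  Ties break by higher aligned
    length, then lexicographically smallest family id.
    """
    k = index.k
    n = len(read)
    if n < k:
        return ReadAssignment(read_id, *UNASSIGNED[1:])
    stride = max(1, (n - k) // max(1, n_seeds - 1)) if n > k else 1
    positions = list(range(0, n - k + 1, stride))
    if positions[-1] != n - k:
        positions.append(n - k)
    candidates: set[tuple[str, str, int]] = set()
    for r in positions:
        for fid, p, strand in index.lookup(read[r: r + k]):
            L = index.lengths[fid]
            if strand == "+":
                offset = p - r  # consensus position of oriented-read base 0
            else:
                # read kmer matches revcomp(consensus) at p; the oriented
                # read (revcomp) base (n-r-k) sits at consensus (L-p-k)
                offset = L - p - n + r
            candidates.add((fid, strand, offset))
    if not candidates:
        return ReadAssignment(read_id, *UNASSIGNED[1:])

    fwd = encode(read)
    rev = None
    best = None  # (identity, aligned_len, -ord, record)
    for fid, strand, offset in sorted(candidates):
        cons = index.codes[fid]
        L = cons.shape[0]
        if strand == "+":
            oriented_codes, oriented_str = fwd, read
        else:
            if rev is None:
                rev_str = revcomp(read)
                rev = (encode(rev_str), rev_str)
            oriented_codes, oriented_str = rev
        ostart = max(0, -offset)
        cstart = max(0, offset)
        length = min(n - ostart, L - cstart)
        if length < min_aligned_fraction * n:
            continue
        seg = oriented_codes[ostart: ostart + length]
        matches = int(np.count_nonzero(seg == cons[cstart: cstart + length]))
        identity = matches / length
        key = (identity, length)
        if best is None or key > best[0] or (key == best[0] and fid < best[1]):
            best = (key, fid,
                    ReadAssignment(read_id, fid, cstart, strand, identity,
                                   length,
                                   oriented_str[ostart: ostart + length]))
    if best is None:
        return ReadAssignment(read_id, *UNASSIGNED[1:])
    (identity, length), _, rec = best
    if identity < min_identity or length < min_aligned_fraction * n:
        return ReadAssignment(read_id, *UNASSIGNED[1:])
    return rec


def assign_reads(
    reads: Iterable[tuple[str, str]] | Iterable,
    index: KmerIndex,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aligned_fraction: float = DEFAULT_MIN_ALIGNED_FRACTION,
) -> list[ReadAssignment]:
    """Vector form of assign_read over (id, sequence) pairs or objects
    with .id/.sequence attributes."""
    out = []
    for item in reads:
        if isinstance(item, tuple):
            rid, seq = item
        else:
            rid, seq = item.id, item.sequence
        out.append(assign_read(seq, index, min_identity,
                               min_aligned_fraction, read_id=rid))
    return out


def assignments_from_sam(path, library: RepeatLibrary) -> list[ReadAssignment]:
    """Import assignments from a SAM file mapped against the library."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.reference_name not in library.entries:
                continue
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            alen = aln.query_alignment_length
            identity = 1.0 - nm / max(1, alen)
            out.append(
                ReadAssignment(aln.query_name, aln.reference_name,
                               aln.reference_start,
                               "-" if aln.is_reverse else "+",
                               identity, alen,
                               aln.query_alignment_sequence or "")
            )
    return out


# ---------------------------------------------------------------------------
# counting and the enrichment statistics


@dataclass
class ReadAssignmentTable:
    counts: pd.DataFrame  # index strain, columns family_id
    denominators: dict[str, int]  # per-strain mapped-read denominator
    denominator_source: str = "genome-mapped"

    def __post_init__(self) -> None:
        for strain in self.counts.index:
            if strain not in self.denominators:
                raise ValueError(f"missing denominator for strain {strain}")
            strain_max = (int(self.counts.loc[strain].max())
                          if len(self.counts.columns) else 0)
            if strain_max > self.denominators[strain]:
                raise ValueError(
                    f"count exceeds denominator for strain {strain}")


def count_table(
    assignments_by_strain: Mapping[str, Iterable[ReadAssignment]],
    denominators: Mapping[str, int],
    families: Sequence[str] | None = None,
    denominator_source: str = "genome-mapped",
) -> ReadAssignmentTable:
    strains = sorted(assignments_by_strain)
    rows = {}
    for strain in strains:
        tally: dict[str, int] = {}
        for a in assignments_by_strain[strain]:
            if a.assigned:
                tally[a.family_id] = tally.get(a.family_id, 0) + 1
        rows[strain] = tally
    cols = sorted(families if families is not None
                  else {f for t in rows.values() for f in t})
    counts = pd.DataFrame(
        [[rows[s].get(f, 0) for f in cols] for s in strains],
        index=pd.Index(strains, name="strain"), columns=cols, dtype=int,
    )
    return ReadAssignmentTable(counts, dict(denominators), denominator_source)


def normalize(table: ReadAssignmentTable) -> pd.DataFrame:
    """Reads per million mapped: n = 1e6 * count / denominator."""
    denom = pd.Series(table.denominators, dtype=float)
    if (denom[table.counts.index] <= 0).any():
        raise ValueError("all denominators must be > 0")
    return table.counts.div(denom[table.counts.index], axis=0) * 1e6


def fold_enrichment(
    table: ReadAssignmentTable,
    family: str,
    strain_pair: tuple[str, str],
    pseudocount: float = 0.0,
) -> float:
    """Ratio of normalized counts n_1/n_2 (NaN if undefined)."""
    norm = normalize(table)
    s1, s2 = strain_pair
    n1 = norm.at[s1, family] + pseudocount
    n2 = norm.at[s2, family] + pseudocount
    if n1 == 0 and n2 == 0:
        return float("nan")
    if n2 == 0:
        return float("inf")
    return n1 / n2


def chisq_enrichment(r1: int, m1: int, r2: int, m2: int) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on the 2x2
    table [[r1, M1-r1], [r2, M2-r2]].  Returns (statistic, p)."""
    if r1 > m1 or r2 > m2:
        raise ValueError("family count exceeds its denominator")
    obs = np.array([[r1, m1 - r1], [r2, m2 - r2]], dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        return float("nan"), float("nan")
    if r1 * m2 == r2 * m1:  # identical proportions
        return 0.0, 1.0
    stat, p, _, _ = chi2_contingency(obs, correction=False)
    return float(stat), float(p)


def enrichment_report(
    table: ReadAssignmentTable, strain_pair: tuple[str, str],
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-family normalized counts, fold ratio and chi-squared test."""
    s1, s2 = strain_pair
    norm = normalize(table)
    rows = []
    for fam in table.counts.columns:
        stat, p = chisq_enrichment(
            int(table.counts.at[s1, fam]), table.denominators[s1],
            int(table.counts.at[s2, fam]), table.denominators[s2],
        )
        rows.append({
            "family_id": fam,
            f"rpm_{s1}": norm.at[s1, fam],
            f"rpm_{s2}": norm.at[s2, fam],
            "fold_ratio": fold_enrichment(table, fam, strain_pair, pseudocount),
            "chi2": stat,
            "p_value": p,
        })
    out = pd.DataFrame(rows)
    out.attrs["strain_pair"] = strain_pair
    out.attrs["denominator_source"] = table.denominator_source
    out.attrs["test"] = "Pearson chi-squared, 2x2 family-vs-rest by strain, 1 df"
    return out


def coverage_estimate(
    read_pairs: float, read_length: int, ends_per_pair: int, genome_size: float
) -> float:
    """Fold coverage C = pairs * ends_per_pair * read_length / genome_size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    if min(read_pairs, read_length, ends_per_pair) <= 0:
        raise ValueError("all inputs must be positive")
    return read_pairs * ends_per_pair * read_length / genome_size
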