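"""Per-site coverage and sequence-heterogeneity profiles.

For one consensus and the reads assigned to it, the pileup counts each
aligned read base at its consensus position (minus-strand reads enter
already reverse-complemented by the assigner).  From the pileup:

  depth d_i      — reads covering position i
  c_i = 1e6 d_i / M   — coverage per million mapped reads
  h_i = max base count / total base count at i — major-variant frequency

h near 1 along the element means the mapped read population is
homogeneous (a recently amplified single lineage); depressed, ragged h
indicates reads drawn from a diverged set of degraded copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._seq import encode
from .enrichment import ReadAssignment

DEFAULT_MIN_DEPTH = 4
DEFAULT_H_THRESHOLD = 0.95


@dataclass
class SiteProfile:
    family_id: str
    base_counts: np.ndarray  # (length, 4) int, A/C/G/T
    mapped_denominator: int | None = None
    min_depth: int = DEFAULT_MIN_DEPTH

    @property
    def length(self) -> int:
        return self.base_counts.shape[0]

    @property
    def depth(self) -> np.ndarray:
        return self.base_counts.sum(axis=1)

    def coverage_per_million(self) -> np.ndarray:
        if not self.mapped_denominator or self.mapped_denominator <= 0:
            raise ValueError("mapped_denominator must be set and > 0")
        return coverage_profile(self, self.mapped_denominator)

    def major_fraction(self) -> np.ndarray:
        return heterogeneity_profile(self, self.min_depth)

    def to_frame(self) -> pd.DataFrame:
        d = self.depth
        frame = pd.DataFrame({
            "pos": np.arange(self.length),
            "depth": d,
            "A": self.base_counts[:, 0], "C": self.base_counts[:, 1],
            "G": self.base_counts[:, 2], "T": self.base_counts[:, 3],
            "major_fraction": self.major_fraction(),
        })
        if self.mapped_denominator:
            frame["coverage_per_million"] = self.coverage_per_million()
        return frame


def pileup(
    assignments: Iterable[ReadAssignment],
    consensus_length: int,
    family_id: str = "",
    mapped_denominator: int | None = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> SiteProfile:
    """Tally aligned read bases per consensus position.

    N bases (and anything non-ACGT) are excluded from the counts;
    alignments are substitution-only so each aligned base occupies
    exactly one consensus position.
    """
    counts = np.zeros((consensus_length, 4), dtype=np.int64)
    for a in assignments:
        if not a.assigned or (family_id and a.family_id != family_id):
            continue
        seg = encode(a.aligned_sequence)
        if a.start < 0 or a.start + seg.shape[0] > consensus_length:
            raise ValueError(
                f"assignment {a.read_id} interval "
                f"[{a.start}, {a.start + seg.shape[0]}) outside consensus")
        valid = seg < 4
        pos = np.arange(a.start, a.start + seg.shape[0])[valid]
        np.add.at(counts, (pos, seg[valid].astype(np.intp)), 1)
    return SiteProfile(family_id, counts, mapped_denominator, min_depth)


def heterogeneity_profile(
    profile: SiteProfile | np.ndarray, min_depth: int = DEFAULT_MIN_DEPTH
) -> np.ndarray:
    """h_i = max base count / total; NaN where depth < min_depth."""
    counts = profile.base_counts if isinstance(profile, SiteProfile) else profile
    total = counts.sum(axis=1).astype(float)
    h = np.full(counts.shape[0], np.nan)
    ok = total >= max(1, min_depth)
    h[ok] = counts[ok].max(axis=1) / total[ok]
    return h


def coverage_profile(
    profile: SiteProfile | np.ndarray, mapped_denominator: int
) -> np.ndarray:
    """c_i = 1e6 * depth_i / M."""
    if mapped_denominator <= 0:
        raise ValueError("mapped_denominator must be > 0")
    counts = profile.base_counts if isinstance(profile, SiteProfile) else profile
    depth = counts.sum(axis=1) if counts.ndim == 2 else counts
    return 1e6 * depth.astype(float) / mapped_denominator


def activity_summary(
    profiles_by_strain: Mapping[str, SiteProfile],
    h_threshold: float = DEFAULT_H_THRESHOLD,
) -> pd.DataFrame:
    """Side-by-side per-strain summary: mean defined h, median coverage,
    and an active-like / degraded-like / unclassified call.

    active-like iff the mean of defined h values is >= h_threshold —
    i.e. the mapped read population is nearly homogeneous.
    """
    rows = []
    for strain in sorted(profiles_by_strain):
        prof = profiles_by_strain[strain]
        h = prof.major_fraction()
        defined = h[~np.isnan(h)]
        mean_h = float(defined.mean()) if defined.size else float("nan")
        if prof.mapped_denominator:
            cov = prof.coverage_per_million()
            median_c = float(np.median(cov))
        else:
            median_c = float(np.median(prof.depth))
        if not defined.size:
            call = "unclassified"
        elif mean_h >= h_threshold:
            call = "active-like"
        else:
            call = "degraded-like"
        rows.append({"strain": strain, "family_id": prof.family_id,
                     "mean_major_fraction": mean_h, "median_coverage": median_c,
                     "n_defined_sites": int(defined.size),
                     "classification": call})
    return pd.DataFrame(rows)
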