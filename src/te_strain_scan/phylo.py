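"""Fragment collection, distance trees and insertion-age estimation.

Genomic fragments of a TE consensus are located by exact k-mer seeding
chained along diagonals with X-drop extension (substitution-only
alignments), anchored onto consensus coordinates, and used directly as a
multiple alignment.  Pairwise distances (p or Jukes-Cantor corrected)
over shared ungapped columns feed a neighbor-joining tree; each leaf's
pendant (terminal) branch length L in substitutions/bp converts to an
age in years via a molecular clock,

    age = L / (mu * g)

with mu the per-nucleotide substitution rate per generation and g the
number of generations per year.  A recently amplified clade shows near-
zero terminal branches; ancient degraded fragments center at the
divergence accumulated since their last activity.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from ._seq import encode, revcomp

GAP = 255  # sentinel for "no base at this consensus column"


@dataclass
class Hit:
    genome_start: int
    genome_end: int
    cons_start: int
    cons_end: int
    strand: str
    identity: float


def _chain_plus(genome: str, query: str, k: int, max_gap: int,
                xdrop: float) -> list[tuple[int, int, int, int, float]]:
    """Plus-strand seed chains of `query` within `genome`: returns
    (gstart, gend, cstart, cend, identity) after X-drop extension."""
    qmap: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        qmap.setdefault(query[i: i + k], []).append(i)
    by_diag: dict[int, list[int]] = {}
    for g in range(len(genome) - k + 1):
        for q in qmap.get(genome[g: g + k], ()):
            by_diag.setdefault(g - q, []).append(g)
    gcodes, qcodes = encode(genome), encode(query)
    glen, qlen = len(genome), len(query)
    out = []
    for diag, gs in by_diag.items():
        gs.sort()
        cluster_start = prev = gs[0]
        clusters = []
        for g in gs[1:]:
            if g - prev > max_gap:
                clusters.append((cluster_start, prev + k))
                cluster_start = g
            prev = g
        clusters.append((cluster_start, prev + k))
        for g0, g1 in clusters:
            # X-drop extension along the diagonal
            lo = g0
            score, best, best_lo = 0.0, 0.0, g0
            i = g0 - 1
            while i >= 0 and i - diag >= 0:
                score += 1.0 if gcodes[i] == qcodes[i - diag] else -2.0
                if score > best:
                    best, best_lo = score, i
                if score < best - xdrop:
                    break
                i -= 1
            lo = best_lo
            score, best, best_hi = 0.0, 0.0, g1
            i = g1
            while i < glen and i - diag < qlen:
                score += 1.0 if gcodes[i] == qcodes[i - diag] else -2.0
                if score > best:
                    best, best_hi = score, i + 1
                if score < best - xdrop:
                    break
                i += 1
            hi = best_hi
            seg_g = gcodes[lo:hi]
            seg_q = qcodes[lo - diag: hi - diag]
            ident = float(np.count_nonzero(seg_g == seg_q)) / max(1, hi - lo)
            out.append((lo, hi, lo - diag, hi - diag, ident))
    return out


def find_hits(
    genome: str,
    query: str,
    k: int = 13,
    min_length: int = 100,
    min_identity: float = 0.0,
    max_gap: int = 150,
    xdrop: float = 10.0,
) -> list[Hit]:
    """Locate copies/fragments of `query` in `genome` on both strands.

    Overlapping hits on the genome are deduplicated, keeping the longer
    (then higher-identity) one.
    """
    hits: list[Hit] = []
    for gstart, gend, cs, ce, ident in _chain_plus(genome, query, k,
                                                   max_gap, xdrop):
        hits.append(Hit(gstart, gend, cs, ce, "+", ident))
    rcg = revcomp(genome)
    glen = len(genome)
    for gstart, gend, cs, ce, ident in _chain_plus(rcg, query, k,
                                                   max_gap, xdrop):
        hits.append(Hit(glen - gend, glen - gstart, cs, ce, "-", ident))
    hits = [h for h in hits
            if h.cons_end - h.cons_start >= min_length
            and h.identity >= min_identity]
    hits.sort(key=lambda h: (-(h.genome_end - h.genome_start), -h.identity))
    kept: list[Hit] = []
    for h in hits:
        if all(min(h.genome_end, o.genome_end) - max(h.genome_start, o.genome_start)
               <= 0.5 * (h.genome_end - h.genome_start)
               for o in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.genome_start)
    return kept


@dataclass
class FragmentSet:
    ids: list[str]
    hits: list[Hit]
    anchored: np.ndarray  # (n_fragments, consensus_length) uint8, GAP=absent
    consensus_length: int
    min_length: int

    def __len__(self) -> int:
        return len(self.ids)


def collect_fragments(
    genome: dict[str, str] | str,
    consensus: str,
    k: int = 13,
    min_length: int = 100,
    min_identity: float = 0.0,
    exclude_tir: tuple[int, int] | None = None,
) -> FragmentSet:
    """Collect consensus fragments from a genome as an anchored alignment.

    exclude_tir=(left_end, right_start) drops hits lying (essentially)
    inside either terminal inverted repeat — which would otherwise
    cross-match between the two ends of the element; a hit must overlap
    the TIR-free interior by at least 20 bp to be kept, since chance
    matches let extension run a few bases past the repeat boundary.
    """
    contigs = {"seq": genome} if isinstance(genome, str) else genome
    L = len(consensus)
    ids, hits, rows = [], [], []
    for cname, cseq in contigs.items():
        for h in find_hits(cseq, consensus, k=k, min_length=min_length,
                           min_identity=min_identity):
            if exclude_tir is not None:
                left_end, right_start = exclude_tir
                interior = (min(h.cons_end, right_start)
                            - max(h.cons_start, left_end))
                if interior < 20:
                    continue
            seq = cseq[h.genome_start: h.genome_end]
            if h.strand == "-":
                seq = revcomp(seq)
            row = np.full(L, GAP, dtype=np.uint8)
            row[h.cons_start: h.cons_end] = encode(seq)
            ids.append(f"{cname}_{h.genome_start}_{h.genome_end}_{h.strand}")
            hits.append(h)
            rows.append(row)
    anchored = (np.vstack(rows) if rows
                else np.empty((0, L), dtype=np.uint8))
    return FragmentSet(ids, hits, anchored, L, min_length)


def pairwise_distance(
    fragments: FragmentSet | np.ndarray,
    correction: str = "jc",
    ids: list[str] | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Distances over shared ungapped columns.

    Returns (ids, distance matrix, saturated mask).  p-distance is the
    mismatch fraction over columns where both fragments have a base;
    with correction="jc", d = -(3/4) ln(1 - 4p/3).  Pairs with p >= 0.75
    are flagged saturated (distance set to NaN).  Pairs with no shared
    columns get NaN.
    """
    if isinstance(fragments, FragmentSet):
        mat, ids = fragments.anchored, fragments.ids
    else:
        mat = fragments
        ids = ids or [f"f{i}" for i in range(mat.shape[0])]
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need >= 2 fragments")
    dist = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    present = mat != GAP
    for i in range(n):
        for j in range(i + 1, n):
            shared = present[i] & present[j]
            ns = int(shared.sum())
            if ns == 0:
                dist[i, j] = dist[j, i] = np.nan
                continue
            p = float(np.count_nonzero(mat[i, shared] != mat[j, shared])) / ns
            if p >= 0.75:
                saturated[i, j] = saturated[j, i] = True
                dist[i, j] = dist[j, i] = np.nan
                continue
            if correction == "jc":
                d = -0.75 * np.log1p(-4.0 * p / 3.0)
            elif correction == "none":
                d = p
            else:
                raise ValueError(f"unknown correction {correction!r}")
            dist[i, j] = dist[j, i] = d
    return list(ids), dist, saturated


def nj_tree(ids: list[str], dist: np.ndarray) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths clamped to zero."""
    if np.isnan(dist).any():
        raise ValueError("distance matrix incomplete (NaN entries); "
                         "remove saturated/disjoint fragments first")
    if len(ids) < 3:
        raise ValueError("need >= 3 taxa")
    return nj(DistanceMatrix(dist, ids))


def terminal_branch_lengths(tree: TreeNode | str) -> list[tuple[str, float]]:
    """(leaf id, pendant edge length) per leaf of a tree or newick string."""
    if isinstance(tree, str):
        tree = TreeNode.read(_io.StringIO(tree))
    out = []
    for tip in tree.tips():
        if tip.length is None:
            raise ValueError(f"leaf {tip.name} has no branch length")
        out.append((str(tip.name), float(tip.length)))
    return out


@dataclass
class AgeModel:
    """Molecular clock: substitutions/bp/generation and generations/year."""

    substitution_rate: float = 1.45e-9
    generations_per_year: float = 10.0

    def __post_init__(self) -> None:
        if self.substitution_rate <= 0 or self.generations_per_year <= 0:
            raise ValueError("rate and generations/year must be > 0")


def branch_length_to_age(L: float, model: AgeModel | None = None) -> float:
    """Age in years: L / (mu * g)."""
    if L < 0:
        raise ValueError("branch length must be >= 0")
    model = model or AgeModel()
    return L / (model.substitution_rate * model.generations_per_year)


@dataclass
class FragmentAgeResult:
    tree: TreeNode
    terminal: pd.DataFrame  # leaf, branch_length, age_years
    model: AgeModel

    @property
    def newick(self) -> str:
        buf = _io.StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()

    @property
    def ages_years(self) -> np.ndarray:
        return self.terminal["age_years"].to_numpy()


def date_fragments(
    fragments: FragmentSet,
    model: AgeModel | None = None,
    correction: str = "jc",
) -> FragmentAgeResult:
    """Distance tree + terminal branch ages for a fragment set."""
    model = model or AgeModel()
    ids, dist, saturated = pairwise_distance(fragments, correction)
    # NaN entries (disjoint or saturated pairs) cannot enter NJ; greedily
    # drop the fragment involved in the most undefined pairs until the
    # matrix is complete — removes the minimum practical number of rows.
    while np.isnan(dist).any():
        worst = int(np.nanargmax(np.isnan(dist).sum(axis=1)))
        keep = [i for i in range(len(ids)) if i != worst]
        ids = [ids[i] for i in keep]
        dist = dist[np.ix_(keep, keep)]
    tree = nj_tree(ids, dist)
    rows = [{"leaf": name, "branch_length": L,
             "age_years": branch_length_to_age(L, model)}
            for name, L in terminal_branch_lengths(tree)]
    return FragmentAgeResult(tree, pd.DataFrame(rows), model)


def age_distribution(
    ages: np.ndarray | list[float], bins: int | np.ndarray = 20
) -> dict:
    """Histogram summary: counts, edges, mode bin and quartiles."""
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("no ages to summarize")
    counts, edges = np.histogram(ages, bins=bins)
    mode = int(np.argmax(counts))
    q1, q2, q3 = np.percentile(ages, [25, 50, 75])
    return {
        "counts": counts, "bin_edges": edges,
        "mode_bin": (float(edges[mode]), float(edges[mode + 1])),
        "quartiles": (float(q1), float(q2), float(q3)),
        "n": int(ages.size),
    }
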