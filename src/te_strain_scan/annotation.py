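"""Element annotation: copy extraction, core-consensus building, terminal
inverted repeat (TIR) detection, ORF finding and protein identity.

The workflow mirrors how a cut-and-paste DNA transposon is characterized
from a draft assembly: pull near-identical genomic copies of a candidate
consensus with flanking sequence, reduce them to the high-identity core
they share, then look for the hallmarks of a Tc1-like element — long
terminal inverted repeats and a transposase ORF (possibly with in-frame
alternate start codons upstream of the annotated start).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._seq import encode, revcomp
from .phylo import find_hits


@dataclass
class TirRecord:
    length: int
    identity: float
    left: tuple[int, int]   # 0-based half-open
    right: tuple[int, int]


@dataclass
class OrfRecord:
    strand: str
    frame: int
    start: int  # forward-strand 0-based half-open, stop codon included
    end: int
    n_codons: int
    protein: str
    alternate_starts: list[int] = field(default_factory=list)


@dataclass
class ElementAnnotation:
    core_sequence: str
    tir: TirRecord | None
    orfs: list[OrfRecord]
    source_copy_ids: list[str] = field(default_factory=list)

    @property
    def core_length(self) -> int:
        return len(self.core_sequence)


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner


def extract_copies_with_flanks(
    genome: dict[str, str] | str,
    query: str,
    flank: int = 1000,
    min_identity: float = 0.85,
    min_length: int = 100,
    k: int = 13,
) -> list[tuple[str, str]]:
    """Find genomic copies of `query` and extract them with up to `flank`
    bp of flanking sequence each side (clipped at contig ends).

    Returns (hit id, extracted sequence); minus-strand hits are
    reverse-complemented so every extraction carries the copy in query
    orientation.
    """
    if not query:
        raise ValueError("query must be non-empty")
    contigs = {"seq": genome} if isinstance(genome, str) else genome
    out = []
    for cname, cseq in contigs.items():
        for i, hit in enumerate(find_hits(cseq, query, k=k,
                                          min_length=min_length,
                                          min_identity=min_identity)):
            gs = max(0, hit.genome_start - flank)
            ge = min(len(cseq), hit.genome_end + flank)
            seq = cseq[gs:ge]
            if hit.strand == "-":
                seq = revcomp(seq)
            out.append((f"{cname}.hit{i}", seq))
    return out


def core_consensus(
    flanked_copies: list[str] | list[tuple[str, str]],
    min_identity: float = 0.85,
    min_length: int = 50,
) -> str:
    """Core shared by all copies: the longest interval of copy 1 covered
    by a high-identity local alignment against every other copy, with a
    per-position majority consensus (ties resolved to copy 1's base).

    Returns "" when the copies share no high-identity interval of at
    least min_length bp (unrelated sequences still share short perfect
    local matches by chance).
    """
    seqs = [c[1] if isinstance(c, tuple) else c for c in flanked_copies]
    if len(seqs) < 2:
        raise ValueError("need >= 2 copies")
    ref = seqs[0]
    n = len(ref)
    aligner = _local_aligner()
    covered = np.ones(n, dtype=bool)
    # aligned_base[j, i]: base code of copy j at ref position i (4 = none)
    aligned = np.full((len(seqs) - 1, n), 4, dtype=np.uint8)
    for j, other in enumerate(seqs[1:]):
        best = None
        for cand in (other, revcomp(other)):
            aln = aligner.align(ref, cand)[0]
            if best is None or aln.score > best[0].score:
                best = (aln, cand)
        aln, cand = best
        blocks_ref, blocks_other = aln.aligned
        matches = total = 0
        ref_codes, oth_codes = encode(ref), encode(cand)
        for (rs, re), (os_, oe) in zip(blocks_ref, blocks_other):
            matches += int(np.count_nonzero(ref_codes[rs:re] == oth_codes[os_:oe]))
            total += re - rs
        if total == 0 or matches / total < min_identity:
            covered[:] = False
            break
        mask = np.zeros(n, dtype=bool)
        for (rs, re), (os_, oe) in zip(blocks_ref, blocks_other):
            mask[rs:re] = True
            aligned[j, rs:re] = oth_codes[os_:oe]
        covered &= mask
    if not covered.any():
        return ""
    # longest run of positions covered in every pairwise alignment
    runs = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
    starts, ends = runs[::2], runs[1::2]
    best_run = int(np.argmax(ends - starts))
    lo, hi = int(starts[best_run]), int(ends[best_run])
    if hi - lo < min_length:
        return ""
    ref_codes = encode(ref)
    out = []
    for i in range(lo, hi):
        col = [ref_codes[i]] + [aligned[j, i] for j in range(len(seqs) - 1)
                                if aligned[j, i] < 4]
        vals, cnts = np.unique(col, return_counts=True)
        top = cnts.max()
        winners = set(vals[cnts == top].tolist())
        out.append(int(ref_codes[i]) if ref_codes[i] in winners
                   else int(vals[np.argmax(cnts)]))
    return "".join("ACGT"[c] for c in out)


def detect_tir(
    sequence: str,
    min_len: int = 20,
    min_identity: float = 0.80,
    max_offset: int = 10,
    max_len: int | None = None,
    mismatch_penalty: float = 3.0,
) -> TirRecord | None:
    """Detect a terminal inverted repeat by anchored comparison of the 5'
    terminus against the reverse complement of the 3' terminus.

    Small terminal offsets (up to max_offset on each end) are allowed.
    For each offset pair the TIR length maximizing
    matches - mismatch_penalty * mismatches is taken (a plain longest
    prefix at >= min_identity overshoots, since unrelated sequence still
    matches ~25% of the time); the best-scoring record passing min_len
    and min_identity is returned, None otherwise.
    """
    n = len(sequence)
    if n < 2 * min_len:
        return None
    cap = max_len if max_len is not None else min(n // 2, 1000)
    fwd = encode(sequence)
    rc = encode(revcomp(sequence))
    best = None  # (score, record)
    for off5 in range(max_offset + 1):
        for off3 in range(max_offset + 1):
            m = min(cap, (n - off5 - off3) // 2)
            if m < min_len:
                continue
            a = fwd[off5: off5 + m]
            b = rc[off3: off3 + m]
            match = (a == b) & (a < 4)
            cmatch = np.cumsum(match)
            lens = np.arange(1, m + 1)
            scores = cmatch - mismatch_penalty * (lens - cmatch)
            i = int(np.argmax(scores))
            length = i + 1
            if length < min_len:
                continue
            identity = cmatch[i] / length
            if identity < min_identity:
                continue
            score = float(scores[i])
            if best is None or score > best[0] or (
                score == best[0] and length > best[1].length
            ):
                best = (score, TirRecord(
                    length, float(identity),
                    (off5, off5 + length),
                    (n - off3 - length, n - off3)))
    return best[1] if best else None


_STOPS = {"TAA", "TAG", "TGA"}


def find_orfs(sequence: str, min_codons: int = 50) -> list[OrfRecord]:
    """Six-frame ORF scan: maximal ATG..stop spans with >= min_codons
    codons (stop excluded from the codon count, included in the span).

    The ORF starts at the first in-frame ATG after the previous stop;
    further in-frame ATGs before the stop are reported as alternate
    starts (forward-strand coordinates).
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    n = len(sequence)
    out = []
    for strand, seq in (("+", sequence.upper()), ("-", revcomp(sequence.upper()))):
        for frame in range(3):
            starts: list[int] = []
            for i in range(frame, n - 2, 3):
                codon = seq[i: i + 3]
                if codon == "ATG":
                    starts.append(i)
                elif codon in _STOPS:
                    if starts:
                        first = starts[0]
                        n_codons = (i - first) // 3
                        if n_codons >= min_codons:
                            protein = str(Seq(seq[first:i]).translate())
                            s, e = first, i + 3
                            if strand == "-":
                                alt = [n - a - 3 for a in starts[1:]]
                                s, e = n - e, n - first
                            else:
                                alt = list(starts[1:])
                            out.append(OrfRecord(strand, frame, s, e,
                                                 n_codons, protein, alt))
                    starts = []
    out.sort(key=lambda o: (-o.n_codons, o.start))
    return out


def protein_identity(query: str, subject: str) -> float:
    """Percent identity over an end-to-end global alignment (BLOSUM62,
    affine gaps); identity = matches / alignment columns."""
    if not query or not subject:
        raise ValueError("proteins must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(query, subject)[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return 100.0 * matches / len(a)


def to_gff3(annotation: "ElementAnnotation", seqid: str = "core") -> str:
    """GFF3 for the TIRs, ORFs and alternate starts of an annotation.

    Internal coordinates are 0-based half-open; GFF3 output is 1-based
    inclusive (stated in the header).
    """
    lines = ["##gff-version 3",
             "# coordinates converted from 0-based half-open to "
             "1-based inclusive"]
    src = "te-strain-scan"
    if annotation.tir is not None:
        t = annotation.tir
        for tag, (s, e) in (("left", t.left), ("right", t.right)):
            lines.append(
                f"{seqid}\t{src}\tterminal_inverted_repeat\t{s + 1}\t{e}\t"
                f"{t.identity:.3f}\t{'+' if tag == 'left' else '-'}\t.\t"
                f"ID=tir_{tag};length={t.length}")
    for i, orf in enumerate(annotation.orfs):
        lines.append(
            f"{seqid}\t{src}\tCDS\t{orf.start + 1}\t{orf.end}\t.\t"
            f"{orf.strand}\t0\tID=orf{i};codons={orf.n_codons}")
        for a in orf.alternate_starts:
            lines.append(
                f"{seqid}\t{src}\tstart_codon\t{a + 1}\t{a + 3}\t.\t"
                f"{orf.strand}\t0\tParent=orf{i};note=alternate_start")
    return "\n".join(lines) + "\n"


def annotate_element(
    core: str,
    tir_min_len: int = 20,
    tir_min_identity: float = 0.80,
    orf_min_codons: int = 50,
    source_copy_ids: list[str] | None = None,
) -> ElementAnnotation:
    """Bundle TIR detection and ORF finding on a core consensus."""
    return ElementAnnotation(
        core_sequence=core,
        tir=detect_tir(core, tir_min_len, tir_min_identity),
        orfs=find_orfs(core, orf_min_codons),
        source_copy_ids=source_copy_ids or [],
    )
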