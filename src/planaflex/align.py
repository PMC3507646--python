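"""Six-frame translation and translated local alignment.

A desk-scale stand-in for translated similarity search (TBLASTX-like):
each nucleotide sequence is translated in all six frames, peptides are
split at stop codons, and every segment pair is aligned with an affine-gap
Smith-Waterman under BLOSUM62.  The best high-scoring segment pair over all
36 frame combinations is reported with Karlin-Altschul E-value.  No k-mer
seeding or composition statistics: the dynamic programme is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from numba import njit

#: residue order used for integer encoding (matches the NCBI BLOSUM62 file)
ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
_X = _INDEX["X"]
GAP = "-"

#: the 20 standard residues
STANDARD_AA = set(ALPHABET[:20])


@lru_cache(maxsize=1)
def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as an int16 array over :data:`ALPHABET` (NCBI integers)."""
    bl = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    mat = np.zeros((n, n), dtype=np.int16)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            mat[i, j] = int(bl[a][b])
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and E-value constants.

    Gap penalties follow the common protein-search default (11/1, a gap of
    length k costing 11 + k).  lambda/K are the usual gapped-BLOSUM62
    Karlin-Altschul constants; ``search_space`` optionally overrides the
    m*n product in the E-value formula.
    """

    matrix: np.ndarray = field(default_factory=blosum62_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    search_space: float | None = None

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if not np.array_equal(self.matrix[:20, :20], self.matrix[:20, :20].T):
            raise ValueError("substitution matrix must be symmetric")

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[_INDEX.get(a, _X), _INDEX.get(b, _X)])


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class LocalAlignment:
    """One locally aligned high-scoring segment pair.

    Nucleotide spans are 1-based inclusive on the original strand of each
    sequence; for peptide-level alignments (no frames) they are absent.
    """

    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    raw_score: int
    query_frame: int = 0
    subject_frame: int = 0
    evalue: float | None = None
    query_span_nt: tuple[int, int] | None = None
    subject_span_nt: tuple[int, int] | None = None
    # 0-based half-open residue spans on the frame peptides
    query_span_pep: tuple[int, int] = (0, 0)
    subject_span_pep: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("aligned strings must have equal length")
        if self.raw_score < 0:
            raise ValueError("raw_score must be >= 0")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)


def encode_peptide(pep: str) -> np.ndarray:
    return np.fromiter((_INDEX.get(a, _X) for a in pep), dtype=np.int8,
                       count=len(pep))


@njit(cache=True)
def _sw_fill(q, s, mat, gap_open, gap_extend):  # pragma: no cover - numba
    """Affine-gap Smith-Waterman fill.

    Returns best score, its end cell (first maximal cell in row-major
    order) and the three pointer matrices for traceback.  State M ends in a
    residue pair; Ix consumes a query residue (gap in subject, "up"); Iy
    consumes a subject residue (gap in query, "left").  A gap of length k
    costs gap_open + k * gap_extend.
    """
    m, n = len(q), len(s)
    NEG = -10_000_000
    M = np.zeros((m + 1, n + 1), dtype=np.int32)
    Ix = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    Iy = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    # pointer codes: 0 restart/none, 1 from M, 2 from Ix, 3 from Iy
    pm = np.zeros((m + 1, n + 1), dtype=np.int8)
    px = np.zeros((m + 1, n + 1), dtype=np.int8)
    py = np.zeros((m + 1, n + 1), dtype=np.int8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            # gap states; on ties prefer opening from M
            open_x = M[i - 1, j] - gap_open - gap_extend
            ext_x = Ix[i - 1, j] - gap_extend
            if open_x >= ext_x:
                Ix[i, j] = open_x
                px[i, j] = 1
            else:
                Ix[i, j] = ext_x
                px[i, j] = 2
            open_y = M[i, j - 1] - gap_open - gap_extend
            ext_y = Iy[i, j - 1] - gap_extend
            if open_y >= ext_y:
                Iy[i, j] = open_y
                py[i, j] = 1
            else:
                Iy[i, j] = ext_y
                py[i, j] = 3
            # match state: prefer diagonal (M), then up (Ix), then left (Iy)
            sc = mat[q[i - 1], s[j - 1]]
            prev = M[i - 1, j - 1]
            ptr = 1
            if Ix[i - 1, j - 1] > prev:
                prev = Ix[i - 1, j - 1]
                ptr = 2
            if Iy[i - 1, j - 1] > prev:
                prev = Iy[i - 1, j - 1]
                ptr = 3
            val = prev + sc
            if val <= 0:
                M[i, j] = 0
                pm[i, j] = 0
            else:
                M[i, j] = val
                pm[i, j] = ptr
            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    return best, bi, bj, M, pm, px, py


def local_align(pep_a: str, pep_b: str, scheme: ScoringScheme = DEFAULT_SCHEME,
                query_id: str = "", subject_id: str = "") -> LocalAlignment:
    """Optimal affine-gap local alignment of two peptides.

    Deterministic traceback: ties prefer the diagonal move, then the gap in
    the subject ("up"), then the gap in the query ("left").  If no residue
    pair scores positively the empty alignment (score 0) is returned.
    """
    if not pep_a or not pep_b:
        raise ValueError("peptides must be non-empty")
    q = encode_peptide(pep_a)
    s = encode_peptide(pep_b)
    best, bi, bj, M, pm, px, py = _sw_fill(
        q, s, blosum_as_int16(scheme), np.int16(scheme.gap_open),
        np.int16(scheme.gap_extend))
    if best <= 0:
        return LocalAlignment(query_id, subject_id, "", "", 0)
    cols_q: list[str] = []
    cols_s: list[str] = []
    i, j, state = bi, bj, 1
    while True:
        if state == 1:
            if M[i, j] <= 0:
                break
            cols_q.append(pep_a[i - 1])
            cols_s.append(pep_b[j - 1])
            state = pm[i, j]
            i -= 1
            j -= 1
        elif state == 2:
            cols_q.append(pep_a[i - 1])
            cols_s.append(GAP)
            state = px[i, j]
            i -= 1
        else:
            cols_q.append(GAP)
            cols_s.append(pep_b[j - 1])
            state = py[i, j]
            j -= 1
    return LocalAlignment(
        query_id, subject_id,
        "".join(reversed(cols_q)), "".join(reversed(cols_s)),
        int(best),
        query_span_pep=(i, bi), subject_span_pep=(j, bj),
    )


def blosum_as_int16(scheme: ScoringScheme) -> np.ndarray:
    mat = np.asarray(scheme.matrix, dtype=np.int16)
    if mat.shape != (len(ALPHABET), len(ALPHABET)):
        raise ValueError("matrix must cover the full residue alphabet")
    return mat


# ----------------------------------------------------------- translation

FRAMES = (1, 2, 3, -1, -2, -3)


def six_frame_translate(seq: str) -> dict[int, str]:
    """Translate a nucleotide sequence in all six frames.

    Standard genetic code; trailing partial codons are dropped; codons with
    ambiguity codes translate to X unless every resolution agrees; stop
    codons are rendered '*'.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than 3 nt cannot be translated")
    out: dict[int, str] = {}
    fwd = seq.upper().replace("U", "T")
    rev = str(Seq(fwd).reverse_complement())
    for frame in FRAMES:
        src = fwd if frame > 0 else rev
        off = abs(frame) - 1
        trimmed = src[off: off + 3 * ((len(src) - off) // 3)]
        out[frame] = str(Seq(trimmed).translate()) if trimmed else ""
    return out


def split_at_stops(pep: str) -> list[tuple[int, str]]:
    """Split a frame peptide at stop codons into (offset, segment) pieces."""
    segments = []
    start = 0
    for i, aa in enumerate(pep + "*"):
        if aa == "*":
            if i > start:
                segments.append((start, pep[start:i]))
            start = i + 1
    return segments


def _pep_to_nt_span(frame: int, pep_span: tuple[int, int], seq_len: int
                    ) -> tuple[int, int]:
    """Map a 0-based half-open residue span on a frame peptide to a 1-based
    inclusive nucleotide span on the original strand."""
    p0, p1 = pep_span
    off = abs(frame) - 1
    if frame > 0:
        return (off + 3 * p0 + 1, off + 3 * p1)
    return (seq_len - off - 3 * p1 + 1, seq_len - off - 3 * p0)


def evalue_from_score(raw_score: float, scheme: ScoringScheme,
                      query_len: int, db_len: int) -> float:
    """Karlin-Altschul E-value, E = K * m * n * exp(-lambda * S)."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    space = scheme.search_space if scheme.search_space else query_len * db_len
    return scheme.karlin_k * space * math.exp(-scheme.karlin_lambda * raw_score)


def best_translated_hit(query, subject, scheme: ScoringScheme = DEFAULT_SCHEME,
                        max_evalue: float | None = None) -> LocalAlignment | None:
    """Best local alignment over all 36 translation-frame pairs.

    Frame peptides are split at stop codons and every segment pair is a
    candidate, so no alignment ever crosses a stop.  Ties in raw score keep
    the first candidate in fixed frame/segment order, making the result
    deterministic.  Returns None when nothing scores positively or the best
    E-value exceeds ``max_evalue``.
    """
    q_frames = six_frame_translate(query.seq)
    s_frames = six_frame_translate(subject.seq)
    best: LocalAlignment | None = None
    for fq in FRAMES:
        q_segs = split_at_stops(q_frames[fq])
        if not q_segs:
            continue
        for fs in FRAMES:
            s_segs = split_at_stops(s_frames[fs])
            for q_off, q_seg in q_segs:
                for s_off, s_seg in s_segs:
                    aln = local_align(q_seg, s_seg, scheme,
                                      query_id=query.id, subject_id=subject.id)
                    if aln.raw_score <= 0:
                        continue
                    if best is None or aln.raw_score > best.raw_score:
                        qs = (q_off + aln.query_span_pep[0],
                              q_off + aln.query_span_pep[1])
                        ss = (s_off + aln.subject_span_pep[0],
                              s_off + aln.subject_span_pep[1])
                        aln.query_frame = fq
                        aln.subject_frame = fs
                        aln.query_span_pep = qs
                        aln.subject_span_pep = ss
                        aln.query_span_nt = _pep_to_nt_span(fq, qs, len(query.seq))
                        aln.subject_span_nt = _pep_to_nt_span(fs, ss, len(subject.seq))
                        best = aln
    if best is None:
        return None
    best.evalue = evalue_from_score(best.raw_score, scheme,
                                    len(query.seq), len(subject.seq))
    if max_evalue is not None and best.evalue > max_evalue:
        return None
    return best
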