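"""Waterman-Eggert local alignment with EDNAFULL scoring and affine gaps.

Implements the Smith-Waterman optimum plus Waterman-Eggert sub-optimal
alignments (successive best local alignments sharing no aligned residue
pair with any earlier one), under the scoring used by EMBOSS Matcher for
DNA: the EDNAFULL (NUC.4.4) substitution table, gap open 16, gap extend 4,
where a gap of length L costs ``open + (L - 1) * extend``.

The dynamic programming kernels are JIT-compiled with numba; declumping is
done by re-running the DP with previously used residue pairs forbidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numba import njit
from scipy.optimize import brentq

__all__ = [
    "ScoringScheme",
    "LocalAlignment",
    "EDNAFULL",
    "waterman_eggert",
    "percent_identity",
    "alignment_evalue",
    "karlin_lambda",
    "AlphabetError",
    "CalibrationError",
]

#: Symbol order of the EDNAFULL (NUC.4.4) substitution table.
EDNAFULL_ALPHABET = "ATGCSWRYKMBVHDN"

#: Standard EDNAFULL / NUC.4.4 nucleotide substitution scores.
EDNAFULL = np.array(
    [
        #  A   T   G   C   S   W   R   Y   K   M   B   V   H   D   N
        [  5, -4, -4, -4, -4,  1,  1, -4, -4,  1, -4, -1, -1, -1, -2],  # A
        [ -4,  5, -4, -4, -4,  1, -4,  1,  1, -4, -1, -4, -1, -1, -2],  # T
        [ -4, -4,  5, -4,  1, -4,  1, -4,  1, -4, -1, -1, -4, -1, -2],  # G
        [ -4, -4, -4,  5,  1, -4, -4,  1, -4,  1, -1, -1, -1, -4, -2],  # C
        [ -4, -4,  1,  1, -1, -4, -2, -2, -2, -2, -1, -1, -3, -3, -1],  # S
        [  1,  1, -4, -4, -4, -1, -2, -2, -2, -2, -3, -3, -1, -1, -1],  # W
        [  1, -4,  1, -4, -2, -2, -1, -4, -2, -2, -3, -1, -3, -1, -1],  # R
        [ -4,  1, -4,  1, -2, -2, -4, -1, -2, -2, -1, -3, -1, -3, -1],  # Y
        [ -4,  1,  1, -4, -2, -2, -2, -2, -1, -4, -1, -3, -3, -1, -1],  # K
        [  1, -4, -4,  1, -2, -2, -2, -2, -4, -1, -3, -1, -1, -3, -1],  # M
        [ -4, -1, -1, -1, -1, -3, -3, -1, -1, -3, -1, -2, -2, -2, -1],  # B
        [ -1, -4, -1, -1, -1, -3, -1, -3, -3, -1, -2, -1, -2, -2, -1],  # V
        [ -1, -1, -4, -1, -3, -1, -3, -1, -3, -1, -2, -2, -1, -2, -1],  # H
        [ -1, -1, -1, -4, -3, -1, -1, -3, -1, -3, -2, -2, -2, -1, -1],  # D
        [ -2, -2, -2, -2, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1],  # N
    ],
    dtype=np.int32,
)

_ENCODE = {c: i for i, c in enumerate(EDNAFULL_ALPHABET)}
_ENCODE["U"] = _ENCODE["T"]

_NEG = np.int32(-(10**7))


class AlphabetError(ValueError):
    """Sequence contains a character outside the IUPAC nucleotide alphabet."""


class CalibrationError(ValueError):
    """Karlin-Altschul lambda cannot be solved for the scoring scheme."""


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution table plus affine gap penalties (Matcher convention)."""

    substitution_table: np.ndarray = field(default_factory=lambda: EDNAFULL.copy())
    gap_open: int = 16
    gap_extend: int = 4

    def __post_init__(self) -> None:
        t = np.asarray(self.substitution_table, dtype=np.int32)
        if t.shape != (15, 15):
            raise ValueError("substitution table must be 15x15 over " + EDNAFULL_ALPHABET)
        if not np.array_equal(t, t.T):
            raise ValueError("substitution table must be symmetric")
        if not (t[:4].diagonal() > 0).all():
            raise ValueError("A/C/G/T diagonal must be strictly positive")
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("need gap_open >= gap_extend > 0")
        object.__setattr__(self, "substitution_table", t)

    @property
    def match(self) -> int:
        return int(self.substitution_table[0, 0])

    @property
    def mismatch(self) -> int:
        return int(self.substitution_table[0, 1])


@dataclass(frozen=True)
class LocalAlignment:
    """One gapped local alignment between a query and a template.

    ``columns`` pairs 0-based residue indices; ``None`` marks a gap.  The
    first and last columns are always gapless and the alignment score is
    strictly positive, as required of a local alignment.
    """

    query_interval: tuple[int, int]
    template_interval: tuple[int, int]
    columns: tuple[tuple[int | None, int | None], ...]
    score: int
    n_identical: int

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.n_identical / self.n_columns

    def cigar(self) -> str:
        """CIGAR-like operation string (M/I/D run-length encoded)."""
        ops = []
        for q, t in self.columns:
            ops.append("M" if q is not None and t is not None else ("D" if q is None else "I"))
        out, run, prev = [], 0, ""
        for op in ops + [""]:
            if op == prev:
                run += 1
            else:
                if prev:
                    out.append(f"{run}{prev}")
                prev, run = op, 1
        return "".join(out)


def encode(sequence: str) -> np.ndarray:
    """Encode a nucleotide string as EDNAFULL row indices."""
    try:
        return np.fromiter(
            (_ENCODE[c] for c in sequence.upper()), dtype=np.int8, count=len(sequence)
        )
    except KeyError as exc:
        raise AlphabetError(f"non-nucleotide character {exc.args[0]!r}") from None


@njit(cache=True)
def _fill(q, t, sub, gap_open, gap_extend, forbidden):  # pragma: no cover - jit
    m, n = q.size, t.size
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), _NEG, np.int32)
    F = np.full((m + 1, n + 1), _NEG, np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - gap_open
            if E[i, j - 1] - gap_extend > e:
                e = E[i, j - 1] - gap_extend
            f = H[i - 1, j] - gap_open
            if F[i - 1, j] - gap_extend > f:
                f = F[i - 1, j] - gap_extend
            E[i, j] = e
            F[i, j] = f
            if forbidden[i - 1, j - 1]:
                d = _NEG
            else:
                d = H[i - 1, j - 1] + sub[q[i - 1], t[j - 1]]
            h = d
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def _traceback(H, E, F, q, t, sub, gap_open, gap_extend, forbidden, bi, bj):  # pragma: no cover
    maxlen = q.size + t.size
    cq = np.empty(maxlen, np.int32)
    ct = np.empty(maxlen, np.int32)
    nc = 0
    i, j = bi, bj
    state = 0  # 0=H, 1=E (gap in query), 2=F (gap in template)
    while True:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            if forbidden[i - 1, j - 1]:
                d = _NEG
            else:
                d = H[i - 1, j - 1] + sub[q[i - 1], t[j - 1]]
            if h == d:
                cq[nc] = i - 1
                ct[nc] = j - 1
                nc += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            cq[nc] = -1
            ct[nc] = j - 1
            nc += 1
            if E[i, j] == H[i, j - 1] - gap_open:
                state = 0
            j -= 1
        else:
            cq[nc] = i - 1
            ct[nc] = -1
            nc += 1
            if F[i, j] == H[i - 1, j] - gap_open:
                state = 0
            i -= 1
    return cq[:nc][::-1], ct[:nc][::-1]


def _identical(qi: np.ndarray, ti: np.ndarray, cq: np.ndarray, ct: np.ndarray) -> int:
    n = 0
    for a, b in zip(cq, ct):
        if a >= 0 and b >= 0 and qi[a] == ti[b] and qi[a] < 4:
            n += 1
    return n


def waterman_eggert(
    query: str,
    template: str,
    scheme: ScoringScheme | None = None,
    k: int = 1,
) -> list[LocalAlignment]:
    """Top ``k`` non-intersecting local alignments, best first.

    The first alignment is the Smith-Waterman optimum; each subsequent one
    is the best alignment sharing no aligned residue pair with any earlier
    one (Waterman-Eggert declumping).  Alignments with non-positive score
    are never returned, so fewer than ``k`` results are possible.
    """
    if scheme is None:
        scheme = ScoringScheme()
    if k < 1:
        raise ValueError("k must be >= 1")
    if not query or not template:
        raise ValueError("sequences must be non-empty")
    qi, ti = encode(query), encode(template)
    sub = scheme.substitution_table
    forbidden = np.zeros((qi.size, ti.size), np.bool_)
    results: list[LocalAlignment] = []
    for _ in range(k):
        H, E, F, best, bi, bj = _fill(
            qi, ti, sub, np.int32(scheme.gap_open), np.int32(scheme.gap_extend), forbidden
        )
        if best <= 0:
            break
        cq, ct = _traceback(
            H, E, F, qi, ti, sub,
            np.int32(scheme.gap_open), np.int32(scheme.gap_extend), forbidden, bi, bj,
        )
        columns = tuple(
            (int(a) if a >= 0 else None, int(b) if b >= 0 else None)
            for a, b in zip(cq, ct)
        )
        qpos = [a for a in cq if a >= 0]
        tpos = [b for b in ct if b >= 0]
        results.append(
            LocalAlignment(
                query_interval=(int(qpos[0]), int(qpos[-1]) + 1),
                template_interval=(int(tpos[0]), int(tpos[-1]) + 1),
                columns=columns,
                score=int(best),
                n_identical=_identical(qi, ti, cq, ct),
            )
        )
        for a, b in zip(cq, ct):
            if a >= 0 and b >= 0:
                forbidden[a, b] = True
    return results


def percent_identity(alignment: LocalAlignment) -> float:
    """Identity over alignment columns, in percent; gap columns count against."""
    return alignment.pct_identity


@lru_cache(maxsize=32)
def _lambda_cached(table_bytes: bytes, gc: float) -> float:
    sub = np.frombuffer(table_bytes, dtype=np.int32).reshape(15, 15)[:4, :4]
    p = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])  # A T G C

    def f(lam: float) -> float:
        return float(np.sum(np.outer(p, p) * np.exp(lam * sub)) - 1.0)

    expected = float(np.sum(np.outer(p, p) * sub))
    if expected >= 0:
        raise CalibrationError(
            f"expected pair score {expected:.3f} >= 0; lambda undefined"
        )
    hi = 0.5
    while f(hi) < 0:
        hi *= 2.0
        if hi > 64:
            raise CalibrationError("failed to bracket lambda")
    return float(brentq(f, 1e-9, hi, xtol=1e-12))


def karlin_lambda(scheme: ScoringScheme, gc_fraction: float = 0.4) -> float:
    """Karlin-Altschul lambda for the ungapped scheme at a GC composition."""
    return _lambda_cached(scheme.substitution_table.tobytes(), gc_fraction)


def alignment_evalue(
    alignment: LocalAlignment,
    query_len: int,
    template_len: int,
    scheme: ScoringScheme | None = None,
    gc_fraction: float = 0.4,
    K: float = 0.1,
) -> float:
    """Approximate Karlin-Altschul expect value for a local alignment score.

    ``E = K * m * n * exp(-lambda * score)`` with lambda solved exactly from
    the ungapped scheme at the given background composition, and K a
    configurable order-of-magnitude constant.  This is an approximation (the
    gapped K and lambda are not estimated); it is monotone decreasing in the
    score and linear in the search space, which is what the optional
    E-value filter relies on.
    """
    if scheme is None:
        scheme = ScoringScheme()
    lam = karlin_lambda(scheme, gc_fraction)
    return K * query_len * template_len * math.exp(-lam * alignment.score)


def format_alignment(query: str, template: str, aln: LocalAlignment, width: int = 60) -> str:
    """Render an alignment as a Matcher-style three-row text block."""
    qrow, mrow, trow = [], [], []
    for a, b in aln.columns:
        qc = query[a] if a is not None else "-"
        tc = template[b] if b is not None else "-"
        qrow.append(qc)
        trow.append(tc)
        mrow.append("|" if a is not None and b is not None and qc == tc and qc in "ACGT" else " ")
    lines = [
        f"# score: {aln.score}  length: {aln.n_columns}  "
        f"identity: {aln.n_identical}/{aln.n_columns} ({aln.pct_identity:.1f}%)"
    ]
    for i in range(0, len(qrow), width):
        lines.append("".join(qrow[i : i + width]))
        lines.append("".join(mrow[i : i + width]))
        lines.append("".join(trow[i : i + width]))
    return "\n".join(lines)
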