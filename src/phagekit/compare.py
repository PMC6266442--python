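"""Pairwise proteome comparison with the smallest-protein identity statistic.

The statistic divides the number of identical aligned residues by the
length of the *smaller* of the two unaligned proteins (not the alignment
length), rounded half-up to an integer percentage — the convention used in
phage comparative tables. Shared-protein sets are then counted at identity
cutoffs (e.g. "more than 90%").

Alignment is global Needleman–Wunsch with affine gaps (Gotoh), BLOSUM62,
gap open 10 / extend 1 (a gap of length k costs 10 + k). Among equal-score
alignments the one with the most identical columns is chosen, which makes
the identical-residue count deterministic; the dynamic program tracks
(score, identities) lexicographically via a scaled integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from ._round import round_half_up

__all__ = [
    "AlignParams",
    "HomologyHit",
    "SharedSetReport",
    "percent_identity",
    "align_and_count",
    "best_hits",
    "shared_proteins_at_cutoff",
    "genome_map_table",
]

_NEG = np.int64(-(2**55))
_SCALE = np.int64(4096)  # identities ride in the low bits of the DP score


@dataclass(frozen=True)
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: int = 10  # opening surcharge; a length-k gap costs open + k*extend
    gap_extend: int = 1


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    identical_residues: int
    query_len: int
    subject_len: int
    aligned: bool = True
    # Published hit tables sometimes print an identity computed with a
    # different denominator (e.g. BLAST's alignment length); when transcribed
    # it is carried here and takes precedence over the recomputed value.
    reported_identity: int | None = None

    def __post_init__(self):
        if self.identical_residues > min(self.query_len, self.subject_len):
            raise ValueError("identical residues exceed the smallest protein")

    @property
    def percent_identity(self) -> int:
        if self.reported_identity is not None:
            return self.reported_identity
        return percent_identity(
            self.identical_residues, self.query_len, self.subject_len
        )


@dataclass(frozen=True)
class SharedSetReport:
    cutoff: float
    strict: bool
    pairs: frozenset

    @property
    def count(self) -> int:
        return len(self.pairs)


def percent_identity(identical: int, len_a: int, len_b: int) -> int:
    """Identical residues over the smallest protein length, half-up percent."""
    if len_a <= 0 or len_b <= 0:
        raise ValueError("protein lengths must be positive")
    smallest = min(len_a, len_b)
    if identical < 0 or identical > smallest:
        raise ValueError(
            f"identical residues ({identical}) outside [0, {smallest}]"
        )
    return int(round_half_up(100.0 * identical / smallest))


def _matrix_tables(params: AlignParams):
    mat = substitution_matrices.load(params.matrix)
    letters = mat.alphabet
    index = {c: i for i, c in enumerate(letters)}
    arr = np.asarray(mat, dtype=np.int64)
    return index, arr


_TABLE_CACHE: dict[str, tuple] = {}


def _encode(seq: str, index: dict) -> np.ndarray:
    try:
        return np.fromiter((index[c] for c in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} not in substitution matrix") from exc


def _gotoh(a: str, b: str, params: AlignParams) -> tuple[int, int]:
    """Optimal global score and (tie-broken max) identical count."""
    if params.matrix not in _TABLE_CACHE:
        _TABLE_CACHE[params.matrix] = _matrix_tables(params)
    index, smat = _TABLE_CACHE[params.matrix]
    m, n = len(a), len(b)
    if min(m, n) >= int(_SCALE):
        raise ValueError("sequences too long for the scaled-identity DP")
    ea, eb = _encode(a, index), _encode(b, index)
    openext = np.int64((params.gap_open + params.gap_extend)) * _SCALE
    ext = np.int64(params.gap_extend) * _SCALE
    # substitution in combined units: score*SCALE + (1 if identical)
    sub = smat[np.ix_(ea, eb)] * _SCALE + (ea[:, None] == eb[None, :])

    j_ext = ext * np.arange(n + 1, dtype=np.int64)
    M = np.full(n + 1, _NEG)
    X = np.full(n + 1, _NEG)
    Y = np.full(n + 1, _NEG)
    M[0] = 0
    if n:
        Y[1:] = -params.gap_open * _SCALE - j_ext[1:]
    for i in range(1, m + 1):
        newM = np.full(n + 1, _NEG)
        newM[1:] = np.maximum(np.maximum(M[:-1], X[:-1]), Y[:-1]) + sub[i - 1]
        newX = np.maximum(np.maximum(M, Y) - openext, X - ext)
        H = np.maximum(newM, newX) + j_ext
        prefix = np.maximum.accumulate(H)
        newY = np.full(n + 1, _NEG)
        if n:
            newY[1:] = prefix[:-1] - openext - j_ext[1:] + ext
        M, X, Y = newM, newX, newY
    best = max(int(M[n]), int(X[n]), int(Y[n]))
    return best // int(_SCALE), best % int(_SCALE)


def align_and_count(
    a, b, params: AlignParams = AlignParams(), ids: tuple[str, str] = ("a", "b")
) -> HomologyHit:
    """Globally align two proteins and count identical columns.

    Accepts raw strings or :class:`phagekit.proteins.ProteinRecord`s.
    """
    id_a, id_b = ids
    seq_a = getattr(a, "sequence", a)
    seq_b = getattr(b, "sequence", b)
    id_a = getattr(a, "id", id_a)
    id_b = getattr(b, "id", id_b)
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty protein")
    _, identical = _gotoh(seq_a, seq_b, params)
    return HomologyHit(id_a, id_b, identical, len(seq_a), len(seq_b))


def align_score(a: str, b: str, params: AlignParams = AlignParams()) -> int:
    """Optimal global alignment score (exposed for cross-checks)."""
    return _gotoh(a, b, params)[0]


def best_hits(
    proteome_a: Sequence,
    proteome_b: Sequence,
    min_identity: float = 0.0,
    params: AlignParams = AlignParams(),
    reciprocal: bool = False,
) -> list[HomologyHit]:
    """Best subject per query by percent identity (tie: lowest subject index).

    Hits below ``min_identity`` are dropped; ``reciprocal`` additionally
    requires the query to be its subject's best hit (ortholog-style).
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")

    def _best(qs, ss):
        out = []
        for qi, q in enumerate(qs):
            hits = [
                align_and_count(q, s, params, ids=(f"q{qi}", f"s{si}"))
                for si, s in enumerate(ss)
            ]
            best = max(range(len(hits)), key=lambda i: (hits[i].percent_identity, -i))
            out.append(hits[best])
        return out

    forward = [h for h in _best(proteome_a, proteome_b) if h.percent_identity >= min_identity]
    if not reciprocal:
        return forward
    # reciprocal mode needs id-bearing records so the two directions meet
    back = {h.query_id: h.subject_id for h in _best(proteome_b, proteome_a)}
    return [h for h in forward if back.get(h.subject_id) == h.query_id]


def shared_proteins_at_cutoff(
    hits: Iterable[HomologyHit], cutoff: float, strict: bool = False
) -> SharedSetReport:
    """Pairs at/above an identity cutoff (``strict`` = strictly above)."""
    if strict:
        pairs = {(h.query_id, h.subject_id) for h in hits if h.percent_identity > cutoff}
    else:
        pairs = {(h.query_id, h.subject_id) for h in hits if h.percent_identity >= cutoff}
    return SharedSetReport(cutoff=cutoff, strict=strict, pairs=frozenset(pairs))


def genome_map_table(
    tables: Sequence,
    hits: Mapping[tuple[str, str], Iterable[HomologyHit]],
    shade_cutoffs: Sequence[float] = (90.0, 80.0, 70.0),
) -> pd.DataFrame:
    """Tabular genome-map layout: ordered ORF rows with cross-genome link bands.

    Each ORF row lists its best link into the partner genome and the band
    label ``>c`` for the highest cutoff ``c`` it strictly exceeds (blank
    below every cutoff) — the information a synteny/identity map encodes
    with arrow colours and shading.
    """
    cutoffs = sorted(shade_cutoffs, reverse=True)
    known = {
        t.genome_id: {getattr(r, "id", "") for r in t.rows} for t in tables
    }
    links: dict[tuple[str, str], tuple[str, int]] = {}
    for (ga, gb), hs in hits.items():
        if ga not in known or gb not in known:
            raise ValueError(f"hit set references unknown genome pair ({ga}, {gb})")
        for h in hs:
            if h.query_id not in known[ga] or h.subject_id not in known[gb]:
                raise ValueError(
                    f"hit {h.query_id}->{h.subject_id} references unknown ORF ids"
                )
            cur = links.get((ga, h.query_id))
            if cur is None or h.percent_identity > cur[1]:
                links[(ga, h.query_id)] = (h.subject_id, h.percent_identity)

    rows = []
    for t in tables:
        for r in t.rows:
            link = links.get((t.genome_id, getattr(r, "id", "")))
            band = ""
            if link is not None:
                for c in cutoffs:
                    if link[1] > c:
                        band = f">{c:g}"
                        break
            rows.append(
                {
                    "genome_id": t.genome_id,
                    "orf_id": getattr(r, "id", ""),
                    "start": r.start,
                    "end": r.end,
                    "strand": r.strand,
                    "link_to": link[0] if link else "",
                    "link_identity": link[1] if link else pd.NA,
                    "band": band,
                }
            )
    return pd.DataFrame(rows)
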