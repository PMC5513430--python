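"""Pairwise nucleotide comparison: dotplots, fragment ANI, similarity segments.

Three complementary views of how two phage genomes relate at the
nucleotide level:

* :func:`dotplot` — all exact shared words of length ``w`` in both
  orientations, the classic dot-matrix view.
* :func:`fragment_ani` — average nucleotide identity in the fragment-based
  style: the query genome is cut into fixed-length fragments, each fragment
  is aligned to its best location in the subject, and fragments passing a
  30%-identity / 70%-coverage retention rule contribute to the mean.
  Fragments with no shared seed word anywhere in the subject are treated as
  unaligned, mirroring how BLAST-based ANI simply finds no hit for
  unrelated fragments.
* :func:`similarity_segments` — seeded-and-extended local alignments above
  a minimum length and identity, non-overlapping on the first genome, for
  genome-map colouring.

ANI is reported on the 0-1 scale.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import edlib
from Bio.Seq import Seq

from .genome_io import Genome

__all__ = [
    "DotplotMatrix",
    "AniParams",
    "AniResult",
    "SegmentParams",
    "SimilaritySegment",
    "dotplot",
    "fragment_ani",
    "similarity_segments",
    "revcomp",
]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _seq(g: Genome | str) -> str:
    return g.sequence if isinstance(g, Genome) else g.upper()


def _gid(g: Genome | str, default: str) -> str:
    return g.id if isinstance(g, Genome) else default


# ---------------------------------------------------------------------------
# Dotplot
# ---------------------------------------------------------------------------


@dataclass
class DotplotMatrix:
    """Exact word matches between two genomes.

    ``matches`` holds (x_pos, y_pos, orientation) triples; positions are the
    0-based starts of the shared word on genome x and genome y. For
    ``revcomp`` matches, y_pos is the start (forward coordinates on y) of
    the word whose reverse complement occurs at x_pos on x.
    """

    x_id: str
    y_id: str
    word: int
    matches: list[tuple[int, int, str]]
    warning: str = ""

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matches, columns=["x_pos", "y_pos", "orientation"])


def _word_index(seq: str, w: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - w + 1):
        word = seq[i : i + w]
        if "N" not in word:
            index[word].append(i)
    return index


def dotplot(a: Genome | str, b: Genome | str, w: int = 10) -> DotplotMatrix:
    """All exact shared ``w``-mers between two genomes, both orientations."""
    if w < 4:
        raise ValueError("dotplot word length must be >= 4")
    sa, sb = _seq(a), _seq(b)
    xa, yb = _gid(a, "x"), _gid(b, "y")
    if w > len(sa) or w > len(sb):
        return DotplotMatrix(xa, yb, w, [], warning="word length exceeds a sequence; empty matrix")
    fwd = _word_index(sb, w)
    rc = _word_index(revcomp(sb), w)
    L = len(sb)
    matches: list[tuple[int, int, str]] = []
    for x in range(len(sa) - w + 1):
        word = sa[x : x + w]
        if "N" in word:
            continue
        for y in fwd.get(word, ()):
            matches.append((x, y, "forward"))
        for y_rc in rc.get(word, ()):
            # convert revcomp-strand start back to forward coordinates on b
            matches.append((x, L - w - y_rc, "revcomp"))
    return DotplotMatrix(xa, yb, w, matches)


# ---------------------------------------------------------------------------
# Fragment-based ANI
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AniParams:
    fragment_size: int = 1020
    min_last_fraction: float = 0.5  # keep trailing fragment if >= this * fragment_size
    retain_identity: float = 0.30  # fragment kept if identity >= this ...
    retain_coverage: float = 0.70  # ... over >= this fraction of its length
    seed_word: int = 13  # alignment seeding word length
    min_seed_words: int = 3  # distinct shared words needed to call a hit at all


@dataclass
class AniResult:
    a_id: str
    b_id: str
    ani: float  # mean identity of retained fragments, 0-1
    aligned_fraction: float  # retained fragments / total fragments
    direction: str  # "a->b", "b->a" or "symmetric"


def _fragments(seq: str, params: AniParams) -> list[str]:
    F = params.fragment_size
    frags = [seq[i : i + F] for i in range(0, len(seq), F)]
    if len(frags) > 1 and len(frags[-1]) < params.min_last_fraction * F:
        frags.pop()
    return frags


_MATCH, _MISMATCH, _GAP_OPEN, _GAP_EXTEND = 1.0, -1.0, -2.0, -0.5


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _best_local_stats(cigar: str, query_len: int) -> tuple[float, float]:
    """Identity and query coverage of the best-scoring local stretch.

    The edlib alignment covers the whole query; rescoring its columns
    (match +1, mismatch -1, gap open -2 / extend -0.5) and taking the
    maximum-scoring contiguous stretch recovers the local high-scoring
    segment a local aligner would report, so a fragment that is only
    partially homologous shows the low query coverage it deserves.
    """
    scores: list[float] = []
    is_match: list[bool] = []
    on_query: list[bool] = []
    for n, op in _parse_cigar(cigar):
        if op == "=":
            scores.extend([_MATCH] * n)
            is_match.extend([True] * n)
            on_query.extend([True] * n)
        elif op == "X":
            scores.extend([_MISMATCH] * n)
            is_match.extend([False] * n)
            on_query.extend([True] * n)
        else:  # I or D
            scores.append(_GAP_OPEN)
            scores.extend([_GAP_EXTEND] * (n - 1))
            is_match.extend([False] * n)
            on_query.extend([op == "I"] * n)
    best = run = 0.0
    start = 0
    best_span = (0, 0)
    for i, s in enumerate(scores):
        if run <= 0:
            run = s
            start = i
        else:
            run += s
        if run > best:
            best = run
            best_span = (start, i + 1)
    lo, hi = best_span
    if hi <= lo:
        return 0.0, 0.0
    columns = hi - lo
    matches = sum(is_match[lo:hi])
    qbases = sum(on_query[lo:hi])
    return matches / columns, qbases / query_len if query_len else 0.0


class _AniCache:
    """Per-genome precomputation shared across pair comparisons."""

    def __init__(self, seq: str, params: AniParams):
        w = params.seed_word
        self.seq = seq
        self.rc = revcomp(seq)
        self.fragments = [
            (frag, frozenset(frag[i : i + w] for i in range(len(frag) - w + 1)))
            for frag in _fragments(seq, params)
        ]
        self.index_f = _word_index(seq, w)
        self.index_r = _word_index(self.rc, w)
        self.words_f = frozenset(self.index_f)
        self.words_r = frozenset(self.index_r)


def _align_windowed(frag: str, target: str, hits: list[int]) -> tuple[float, float]:
    """Identity/coverage of the fragment aligned near its seed hits.

    The densest cluster of seed positions (within one fragment length)
    picks the window; restricting the subject to that neighbourhood only
    discards placements without seed support, which the retention rule
    would reject anyway.
    """
    hits = sorted(hits)
    width = len(frag)
    best_lo = best_n = 0
    j = 0
    for i, h in enumerate(hits):
        while hits[j] < h - width:
            j += 1
        if i - j + 1 > best_n:
            best_n = i - j + 1
            best_lo = hits[j]
    lo = max(0, best_lo - width)
    hi = min(len(target), best_lo + 3 * width)
    res = edlib.align(frag, target[lo:hi], mode="HW", task="path")
    if res["editDistance"] < 0:
        return 0.0, 0.0
    return _best_local_stats(res["cigar"], len(frag))


def _best_fragment_identity(frag: str, words: frozenset[str], subject: "_AniCache",
                            min_seed_words: int) -> tuple[float, float] | None:
    """(identity, coverage) of the best alignment, or None if unaligned.

    A strand counts as hit only with >= ``min_seed_words`` distinct shared
    seed words; isolated chance word matches between unrelated sequences do
    not constitute an alignment, mirroring BLAST-based ANI where unrelated
    fragments simply return no hit.
    """
    shared_f = words & subject.words_f
    shared_r = words & subject.words_r
    if len(shared_f) < min_seed_words:
        shared_f = frozenset()
    if len(shared_r) < min_seed_words:
        shared_r = frozenset()
    if not shared_f and not shared_r:
        return None
    best = None
    for shared, index, tgt in (
        (shared_f, subject.index_f, subject.seq),
        (shared_r, subject.index_r, subject.rc),
    ):
        if not shared:
            continue
        hits = [pos for word in shared for pos in index[word]]
        identity, coverage = _align_windowed(frag, tgt, hits)
        if best is None or identity * coverage > best[0] * best[1]:
            best = (identity, coverage)
    return best


def _directional_ani(query: "_AniCache", subject: "_AniCache", params: AniParams) -> tuple[float, float]:
    retained: list[float] = []
    for frag, words in query.fragments:
        stats = _best_fragment_identity(frag, words, subject, params.min_seed_words)
        if stats is None:
            continue
        identity, coverage = stats
        if identity >= params.retain_identity and coverage >= params.retain_coverage:
            retained.append(identity)
    if not retained:
        return 0.0, 0.0
    return sum(retained) / len(retained), len(retained) / len(query.fragments)


def fragment_ani(a: Genome | str, b: Genome | str, params: AniParams = AniParams(),
                 direction: str = "symmetric",
                 _caches: tuple["_AniCache", "_AniCache"] | None = None) -> AniResult:
    """Fragment-based average nucleotide identity between two genomes.

    The symmetrized result is the mean of the two directional values; a
    genome against itself gives ANI 1.0 with aligned fraction 1.0.
    """
    sa, sb = _seq(a), _seq(b)
    if not sa or not sb:
        raise ValueError("fragment_ani requires non-empty genomes")
    aid, bid = _gid(a, "a"), _gid(b, "b")
    ca, cb = _caches if _caches is not None else (_AniCache(sa, params), _AniCache(sb, params))
    if direction == "a->b":
        ani, af = _directional_ani(ca, cb, params)
        return AniResult(aid, bid, ani, af, "a->b")
    if direction == "b->a":
        ani, af = _directional_ani(cb, ca, params)
        return AniResult(aid, bid, ani, af, "b->a")
    ani_ab, af_ab = _directional_ani(ca, cb, params)
    ani_ba, af_ba = _directional_ani(cb, ca, params)
    return AniResult(aid, bid, (ani_ab + ani_ba) / 2.0, (af_ab + af_ba) / 2.0, "symmetric")


def ani_matrix(genomes: Sequence[Genome], params: AniParams = AniParams()):
    """Square symmetrized-ANI DataFrame over a genome collection."""
    import pandas as pd

    ids = [g.id for g in genomes]
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    caches = [_AniCache(g.sequence, params) for g in genomes]
    results = {}
    for i, ga in enumerate(genomes):
        mat.loc[ga.id, ga.id] = 1.0
        for j in range(i + 1, len(genomes)):
            gb = genomes[j]
            res = fragment_ani(ga, gb, params, _caches=(caches[i], caches[j]))
            mat.loc[ga.id, gb.id] = mat.loc[gb.id, ga.id] = res.ani
            results[(ga.id, gb.id)] = res
    return mat, results


# ---------------------------------------------------------------------------
# Similarity segments (genome-map colouring)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentParams:
    seed_word: int = 13
    min_length: int = 200  # minimum segment span on genome A, bp
    min_identity: float = 60.0  # percent
    diagonal_band: int = 200  # seeds within this diagonal offset are chained
    max_seed_gap: int = 1500  # seeds further apart than this start a new chain


@dataclass(frozen=True)
class SimilaritySegment:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orientation: str  # forward / revcomp
    percent_identity: float


def _chain_seeds(hits: list[tuple[int, int]], w: int, params: SegmentParams) -> list[tuple[int, int, int, int]]:
    """Greedy diagonal chaining of (x, y) seed starts into candidate blocks."""
    chains: list[tuple[int, int, int, int]] = []
    by_diag: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for x, y in hits:
        by_diag[(x - y) // max(1, params.diagonal_band)].append((x, y))
    for bucket in by_diag.values():
        bucket.sort()
        cur = [bucket[0]]
        for x, y in bucket[1:]:
            if x - cur[-1][0] <= params.max_seed_gap:
                cur.append((x, y))
            else:
                chains.append((cur[0][0], cur[-1][0] + w, cur[0][1], cur[-1][1] + w))
                cur = [(x, y)]
        chains.append((cur[0][0], cur[-1][0] + w, cur[0][1], cur[-1][1] + w))
    return chains


def _segment_identity(sub_a: str, sub_b: str) -> float:
    res = edlib.align(sub_a, sub_b, mode="NW", task="path")
    matches = columns = 0
    for n, op in _parse_cigar(res["cigar"]):
        columns += n
        if op == "=":
            matches += n
    return 100.0 * matches / columns if columns else 0.0


def similarity_segments(a: Genome | str, b: Genome | str,
                        params: SegmentParams = SegmentParams()) -> list[SimilaritySegment]:
    """Local similarity blocks between two genomes.

    Shared seed words are chained along diagonals, each chain's spanned
    region is realigned for an identity estimate, and surviving segments are
    selected greedily best-score-first with overlap suppression on genome A
    only (overlaps on B are allowed, so duplications are representable).
    """
    sa, sb = _seq(a), _seq(b)
    if not sa or not sb:
        raise ValueError("similarity_segments requires non-empty genomes")
    w = params.seed_word
    candidates: list[tuple[float, SimilaritySegment]] = []
    for orientation in ("forward", "revcomp"):
        tgt = sb if orientation == "forward" else revcomp(sb)
        index = _word_index(tgt, w)
        hits = [
            (x, y)
            for x in range(len(sa) - w + 1)
            if "N" not in sa[x : x + w]
            for y in index.get(sa[x : x + w], ())
        ]
        if not hits:
            continue
        for a0, a1, b0, b1 in _chain_seeds(hits, w, params):
            if a1 - a0 < params.min_length:
                continue
            identity = _segment_identity(sa[a0:a1], tgt[b0:b1])
            if identity < params.min_identity:
                continue
            if orientation == "revcomp":
                b0, b1 = len(sb) - b1, len(sb) - b0
            seg = SimilaritySegment(a0, a1, b0, b1, orientation, round(identity, 2))
            candidates.append((identity / 100.0 * (a1 - a0), seg))
    candidates.sort(key=lambda t: (-t[0], t[1].a_start))
    chosen: list[SimilaritySegment] = []
    for _, seg in candidates:
        if all(seg.a_end <= s.a_start or seg.a_start >= s.a_end for s in chosen):
            chosen.append(seg)
    return sorted(chosen, key=lambda s: s.a_start)
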