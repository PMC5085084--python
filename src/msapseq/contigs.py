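"""Pooled amplicon-sequencing analysis: demultiplexing, trimming,
read clustering, local alignment, and differential-contig extraction.

The read pools are MID-barcoded mixtures of MSAP amplicons from two
independent cultivar/somaclone pairs.  Reads are demultiplexed by exact
(or budgeted-mismatch) barcode prefix, adaptor-trimmed and
quality-filtered, and clustered per pool into contigs by greedy centroid
clustering at a global-identity threshold; single-read contigs are
discarded.  Contigs of each pool are then searched against the paired
pool by Smith-Waterman local alignment with a Karlin-Altschul e-value:
a contig with no acceptable hit in the paired pool is *differential*.
Differential contigs of pair 1 that match (at the same e-value
threshold) a differential contig of pair 2 form the *consensual* set —
amplicons repeatedly polymorphic across both pairs, the candidates for
methylation changes that recur under in vitro cultivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
from Bio import Align
from scipy.optimize import brentq

from .digest import revcomp

__all__ = [
    "SequencedRead",
    "Contig",
    "AlignmentHit",
    "DifferentialReport",
    "AlignScoring",
    "DEFAULT_MID_TABLE",
    "demultiplex",
    "trim_adaptors",
    "cluster_contigs",
    "local_align",
    "differential_set",
    "repeated_polymorphic",
]

UNASSIGNED = "UNASSIGNED"

#: Default MID/barcode table for the four pooled samples: mixtures of
#: LX987 standards (1), AS208 somaclones (2), YM66 standards (3), AS34
#: somaclones (4); Roche rapid-library MIDs RL8-RL11.
DEFAULT_MID_TABLE: dict[str, str] = {
    "1": "ACGTACTGTGT",
    "2": "ACGTAGATCGT",
    "3": "ACTACGTCTCT",
    "4": "ACTATACGAGT",
}


@dataclass(frozen=True)
class SequencedRead:
    id: str
    bases: str
    qualities: tuple[int, ...]
    assigned_pool: str = UNASSIGNED

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases and qualities must have the same length")

    def mean_quality(self) -> float:
        return float(np.mean(self.qualities)) if self.qualities else 0.0


@dataclass(frozen=True)
class Contig:
    """Consensus of one read cluster."""

    id: str
    consensus: str
    read_count: int
    pool: str
    read_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    score: float
    e_value: float
    identity: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    strand: str = "+"


@dataclass(frozen=True)
class DifferentialReport:
    """Directional difference sets for two cultivar/somaclone pairs plus
    the consensual (repeatedly polymorphic) set."""

    pair1_standard_only: tuple[Contig, ...]
    pair1_somaclone_only: tuple[Contig, ...]
    pair2_standard_only: tuple[Contig, ...]
    pair2_somaclone_only: tuple[Contig, ...]
    consensual: tuple[tuple[Contig, AlignmentHit, str, str], ...] = ()
    # consensual entries: (contig, best partner hit, direction in own
    # pair "gain"/"loss", partner's direction)


# ---------------------------------------------------------------------------
# demultiplexing and trimming


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[SequencedRead],
    mid_table: Mapping[str, str] = DEFAULT_MID_TABLE,
    max_mismatch: int = 0,
) -> tuple[dict[str, list[SequencedRead]], list[SequencedRead]]:
    """Assign reads to sample pools by MID barcode prefix.

    A read goes to the unique sample whose barcode matches its prefix
    within `max_mismatch` substitutions; the barcode is removed from the
    assigned read.  Ambiguous or non-matching reads are returned
    unassigned.  Barcodes must be unique and of equal length.
    """
    barcodes = list(mid_table.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate MID barcodes")
    if len({len(b) for b in barcodes}) > 1:
        raise ValueError("MID barcodes must have equal length")
    blen = len(barcodes[0])
    pools: dict[str, list[SequencedRead]] = {s: [] for s in mid_table}
    unassigned: list[SequencedRead] = []
    for read in reads:
        prefix = read.bases[:blen]
        matches = [
            s
            for s, bc in mid_table.items()
            if len(prefix) == blen and _hamming(prefix, bc) <= max_mismatch
        ]
        if len(matches) == 1:
            s = matches[0]
            pools[s].append(
                SequencedRead(
                    id=read.id,
                    bases=read.bases[blen:],
                    qualities=read.qualities[blen:],
                    assigned_pool=s,
                )
            )
        else:
            unassigned.append(read)
    return pools, unassigned


def _strip_end(bases: str, adaptors: Sequence[str], prefix: bool, max_mismatch: int) -> int:
    """Length of the longest adaptor matching the read prefix/suffix
    within `max_mismatch` substitutions (0 if none)."""
    best = 0
    for ad in adaptors:
        if len(ad) > len(bases):
            continue
        seg = bases[: len(ad)] if prefix else bases[-len(ad) :]
        if _hamming(seg, ad) <= max_mismatch:
            best = max(best, len(ad))
    return best


def trim_adaptors(
    read: SequencedRead,
    adaptors: Sequence[str],
    *,
    min_length: int = 40,
    min_mean_quality: float = 20.0,
    max_mismatch: int = 1,
) -> Optional[SequencedRead]:
    """Trim adaptor prefixes/suffixes and apply length/quality filters.

    The longest adaptor matching the read start (and, independently, the
    read end) exactly or within `max_mismatch` substitutions is removed.
    Returns None when the trimmed read is shorter than `min_length` or
    its mean Phred quality falls below `min_mean_quality`.
    """
    if not adaptors:
        raise ValueError("adaptor list must be non-empty")
    adaptors = [a.upper() for a in adaptors]
    lead = _strip_end(read.bases, adaptors, prefix=True, max_mismatch=max_mismatch)
    bases = read.bases[lead:]
    quals = read.qualities[lead:]
    tail = _strip_end(bases, adaptors, prefix=False, max_mismatch=max_mismatch)
    if tail:
        bases = bases[:-tail]
        quals = quals[:-tail]
    trimmed = replace(read, bases=bases, qualities=quals)
    if len(bases) < min_length or trimmed.mean_quality() < min_mean_quality:
        return None
    return trimmed


# ---------------------------------------------------------------------------
# greedy centroid clustering


def _global_identity(a: str, b: str) -> float:
    """Global (Needleman-Wunsch) identity 1 - edits/max(len)."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _oriented(seq: str, centroid: str) -> tuple[str, float]:
    """Orient `seq` (forward or reverse complement) to best match the
    centroid; returns (oriented sequence, identity)."""
    fwd = _global_identity(seq, centroid)
    rc = revcomp(seq)
    rev = _global_identity(rc, centroid)
    return (seq, fwd) if fwd >= rev else (rc, rev)


def _column_majority(seqs: Sequence[str]) -> str:
    """Per-column majority consensus over the most common length class;
    ties broken alphabetically."""
    from collections import Counter

    length = Counter(len(s) for s in seqs).most_common(1)[0][0]
    cols = [s for s in seqs if len(s) == length]
    out = []
    for i in range(length):
        counts = Counter(s[i] for s in cols)
        top = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0][0])))
        out.append(top[0])
    return "".join(out)


def cluster_contigs(
    reads: Iterable[SequencedRead],
    min_identity: float = 0.97,
    min_reads: int = 2,
    *,
    pool: str = "",
) -> list[Contig]:
    """Greedy centroid clustering of one pool's reads into contigs.

    Reads are processed in order of descending length, then lexicographic
    id; each read joins the first centroid it matches at
    >= `min_identity` global identity (forward or reverse complement),
    otherwise it founds a new centroid.  The contig consensus is the
    per-column majority over the cluster's (orientation-normalised)
    members; clusters supported by fewer than `min_reads` reads are
    excluded.
    """
    if not 0.5 < min_identity <= 1.0:
        raise ValueError("min_identity must lie in (0.5, 1]")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    ordered = sorted(reads, key=lambda r: (-len(r.bases), r.id))
    centroids: list[str] = []
    members: list[list[SequencedRead]] = []
    oriented_members: list[list[str]] = []
    for read in ordered:
        placed = False
        for k, cen in enumerate(centroids):
            oriented, ident = _oriented(read.bases, cen)
            if ident >= min_identity:
                members[k].append(read)
                oriented_members[k].append(oriented)
                placed = True
                break
        if not placed:
            centroids.append(read.bases)
            members.append([read])
            oriented_members.append([read.bases])
    contigs: list[Contig] = []
    n = 0
    for k in range(len(centroids)):
        if len(members[k]) < min_reads:
            continue
        n += 1
        contigs.append(
            Contig(
                id=f"{pool + '_' if pool else ''}contig{n}",
                consensus=_column_majority(oriented_members[k]),
                read_count=len(members[k]),
                pool=pool,
                read_ids=tuple(r.id for r in members[k]),
            )
        )
    return contigs


# ---------------------------------------------------------------------------
# local alignment with Karlin-Altschul e-values


@dataclass(frozen=True)
class AlignScoring:
    """Local-alignment scoring scheme and e-value parameters.

    Gap convention: the first gapped column scores `gap_open`, each
    additional column `gap_extend`.  `lambda_` is the Karlin-Altschul
    decay computed for the ungapped match/mismatch scheme at uniform
    base composition; `K` is the search-space scale (default 0.3,
    configurable — the e-value threshold is insensitive to K over
    orders of magnitude at these score scales).
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    K: float = 0.3

    @property
    def lambda_(self) -> float:
        return _karlin_lambda(self.match, self.mismatch)


def _karlin_lambda(match: float, mismatch: float) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for lambda > 0 at
    uniform base composition (match probability 1/4)."""
    if match <= 0 or mismatch >= 0:
        raise ValueError("need match > 0 and mismatch < 0")
    expected = 0.25 * match + 0.75 * mismatch
    if expected >= 0:
        raise ValueError("expected score must be negative for the e-value theory")

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, 1e-9, hi))


def _aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    return al


def e_value(score: float, m: int, n: int, scoring: AlignScoring) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * score)."""
    return scoring.K * m * n * math.exp(-scoring.lambda_ * score)


def local_align(
    query: str,
    subject: str,
    scoring: AlignScoring = AlignScoring(),
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    db_length: Optional[int] = None,
) -> AlignmentHit:
    """Best Smith-Waterman local alignment of query vs subject, both
    strands, with a Karlin-Altschul e-value.

    `db_length` is the total subject-pool length for database-style
    search statistics (defaults to len(subject)).
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    al = _aligner(scoring)
    best = None
    for strand, subj in (("+", subject), ("-", revcomp(subject))):
        score = al.score(query, subj)
        if best is None or score > best[0]:
            best = (score, strand, subj)
    score, strand, subj = best
    n = db_length if db_length is not None else len(subject)
    ev = e_value(score, len(query), n, scoring)
    if score <= 0:
        return AlignmentHit(query_id, subject_id, 0.0, ev, 0.0, (0, 0), (0, 0), strand)
    aln = next(iter(al.align(query, subj)))
    qa, sa = aln[0], aln[1]
    matches = sum(x == y and x != "-" for x, y in zip(qa, sa))
    cols = len(qa)
    qspan = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
    sspan = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        score=float(score),
        e_value=ev,
        identity=matches / cols if cols else 0.0,
        query_span=qspan,
        subject_span=sspan,
        strand=strand,
    )


def best_hit(
    query: Contig,
    subjects: Sequence[Contig],
    scoring: AlignScoring = AlignScoring(),
) -> Optional[AlignmentHit]:
    """Lowest-e-value hit of `query` against the subject pool (database
    search semantics: m*n uses the summed subject length)."""
    if not subjects:
        return None
    db_len = sum(len(s.consensus) for s in subjects)
    al = _aligner(scoring)
    # score-only pass; the full alignment is computed for the winner only
    best_subj, best_score = None, -math.inf
    for s in sorted(subjects, key=lambda s: s.id):
        score = max(
            al.score(query.consensus, s.consensus),
            al.score(query.consensus, revcomp(s.consensus)),
        )
        if score > best_score:
            best_subj, best_score = s, score
    return local_align(
        query.consensus,
        best_subj.consensus,
        scoring,
        query_id=query.id,
        subject_id=best_subj.id,
        db_length=db_len,
    )


def differential_set(
    contigs_a: Sequence[Contig],
    contigs_b: Sequence[Contig],
    e_threshold: float = 1e-5,
    scoring: AlignScoring = AlignScoring(),
) -> list[Contig]:
    """Contigs of pool A with no alignment hit in pool B at
    e <= `e_threshold` (pool A's side of a reciprocal comparison)."""
    if e_threshold <= 0:
        raise ValueError("e_threshold must be positive")
    out = []
    for c in contigs_a:
        hit = best_hit(c, contigs_b, scoring)
        if hit is None or hit.e_value > e_threshold:
            out.append(c)
    return out


def repeated_polymorphic(
    diff_pair1: Mapping[str, Sequence[Contig]] | Sequence[Contig],
    diff_pair2: Mapping[str, Sequence[Contig]] | Sequence[Contig],
    e_threshold: float = 1e-5,
    scoring: AlignScoring = AlignScoring(),
) -> list[tuple[Contig, AlignmentHit, str, str]]:
    """Consensual contigs: differential contigs of pair 1 that match a
    differential contig of pair 2 at e <= `e_threshold`.

    Inputs may be plain contig sequences or mappings direction ->
    contigs (directions "gain"/"loss"); any-hit semantics, direction
    agreement is reported in the result tuples, not required.
    """

    def _flatten(d):
        if isinstance(d, Mapping):
            return [(c, direction) for direction, cs in d.items() for c in cs]
        return [(c, "?") for c in d]

    p1 = _flatten(diff_pair1)
    p2 = _flatten(diff_pair2)
    if not p1 or not p2:
        return []
    p2_dir = {c.id: direction for c, direction in p2}
    p2_contigs = [c for c, _d in p2]
    out = []
    for contig, direction in p1:
        hit = best_hit(contig, p2_contigs, scoring)
        if hit is not None and hit.e_value <= e_threshold:
            out.append((contig, hit, direction, p2_dir.get(hit.subject_id, "?")))
    return out
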