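"""Internal exact-k-mer seed-and-extend matcher.

Produces pairwise local-alignment records in the same shape as the standard
12-column tabular output, so the rest of the pipeline is agnostic to whether
hits came from an external aligner or from here. Seeds are exact k-mer
matches found with vectorized 2-bit k-mer codes; seeds on nearby diagonals
are chained into candidate segments, each segment is verified with a global
alignment (edlib) to get an identity, and an e-value proxy is computed from
a blastn-like bit score so that downstream e-value thresholds behave as
expected. Both strands are searched; minus-strand hits are reported with
forward-normalized subject coordinates and a strand flag.

The reference external invocation this replaces for large inputs is
``blastn -evalue 1e-5 -outfmt 6 -max_target_seqs 10000``.
"""

from __future__ import annotations

import numpy as np
import edlib

from .io_formats import AlignmentHit, ElementRecord

__all__ = ["kmer_codes", "SeqIndex", "match_pair", "self_align", "search_sequence"]

_ENC = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i

_RC = str.maketrans("ACGTN", "TGCAN")

# ungapped blastn-like scoring for the e-value proxy (match +2 / mismatch -3)
_MATCH, _MISMATCH = 2.0, 3.0


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit packed codes of all k-mers; windows containing N get code -1."""
    enc = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = enc[j : j + n].astype(np.int64)
        bad |= window < 0
        codes = codes * 4 + np.where(window < 0, 0, window)
    codes[bad] = -1
    return codes


class SeqIndex:
    """Cached k-mer view of one sequence (forward strand)."""

    def __init__(self, seq: str, k: int):
        self.seq = seq
        self.k = k
        codes = kmer_codes(seq, k)
        valid = codes >= 0
        self.pos = np.flatnonzero(valid)
        self.codes = codes[valid]
        order = np.argsort(self.codes, kind="stable")
        self.sorted_codes = self.codes[order]
        self.sorted_pos = self.pos[order]
        self._rc: "SeqIndex | None" = None

    @property
    def rc(self) -> "SeqIndex":
        if self._rc is None:
            self._rc = SeqIndex(_revcomp(self.seq), self.k)
        return self._rc


def _shared_kmer_positions(query: SeqIndex, subject: SeqIndex) -> tuple[np.ndarray, np.ndarray]:
    """All (qpos, spos) pairs with identical k-mer codes.

    One binary-search pass finds the first subject occurrence of each query
    code; duplicate subject occurrences (e.g. the two long terminal repeats)
    are collected by cheap vectorized forward scans, which are rare.
    """
    sc, sp = subject.sorted_codes, subject.sorted_pos
    left = np.searchsorted(sc, query.codes, side="left")
    n_s = sc.size
    safe = np.minimum(left, n_s - 1) if n_s else left
    match = (left < n_s) & (sc[safe] == query.codes) if n_s else np.zeros(0, bool)
    out_q = [query.pos[match]]
    out_s = [sp[left[match]]]
    cur = left[match] + 1
    codes = query.codes[match]
    pos = query.pos[match]
    while cur.size:
        ok = (cur < n_s) & (sc[np.minimum(cur, n_s - 1)] == codes)
        if not ok.any():
            break
        cur, codes, pos = cur[ok], codes[ok], pos[ok]
        out_q.append(pos)
        out_s.append(sp[cur])
        cur = cur + 1
    if not out_q:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(out_q), np.concatenate(out_s)


def _chain_segments(
    qpos: np.ndarray,
    spos: np.ndarray,
    k: int,
    max_gap: int = 200,
    max_drift: int = 60,
    band_width: int = 400,
) -> list[tuple[int, int, int, int, int]]:
    """Chain seeds into candidate segments (vectorized).

    Seeds are grouped into coarse diagonal bands (repeats of the same region
    land on distant diagonals and must not interleave), ordered by query
    position within a band, and split wherever the query gap exceeds
    ``max_gap`` or the diagonal jumps by more than ``max_drift`` between
    consecutive seeds — indels shift the diagonal gradually, so long
    alignments survive while structural breakpoints split chains. Returns
    (qstart, qend, sstart, send, n_seeds) per segment.
    """
    if qpos.size == 0:
        return []
    diag = qpos - spos
    band = diag // band_width
    order = np.lexsort((qpos, band))
    q, s, b, d = qpos[order], spos[order], band[order], diag[order]
    new_chain = np.ones(q.size, dtype=bool)
    if q.size > 1:
        new_chain[1:] = (
            (b[1:] != b[:-1])
            | (q[1:] - q[:-1] > max_gap)
            | (np.abs(d[1:] - d[:-1]) > max_drift)
        )
    starts = np.flatnonzero(new_chain)
    q_min = np.minimum.reduceat(q, starts)
    q_max = np.maximum.reduceat(q, starts) + k
    s_min = np.minimum.reduceat(s, starts)
    s_max = np.maximum.reduceat(s, starts) + k
    counts = np.diff(np.append(starts, q.size))
    return list(
        zip(q_min.tolist(), q_max.tolist(), s_min.tolist(), s_max.tolist(), counts.tolist())
    )


def _segment_hits(
    query: SeqIndex,
    subject: SeqIndex,
    min_len: int,
    min_identity: float,
    self_pair: bool,
    minus: bool,
    s_true_len: int,
) -> list[tuple[int, int, int, int, float, float]]:
    k = query.k
    qpos, spos = _shared_kmer_positions(query, subject)
    if self_pair and not minus:
        keep = qpos + 50 <= spos  # skip the trivial diagonal; one orientation only
        qpos, spos = qpos[keep], spos[keep]
    out = []
    for qs, qe, ss, se, n_seeds in _chain_segments(qpos, spos, k):
        if min(qe - qs, se - ss) < min_len:
            continue
        span = max(qe - qs, se - ss)
        # dense exact seeds certify high identity without alignment: a
        # divergence d leaves a fraction ~(1-d)^k of positions seeded
        density = n_seeds / max(span - k + 1, 1)
        if density >= 0.30:  # (1-d)^k >= 0.30 at k=12 -> identity >= 0.90
            identity = min(density ** (1.0 / k), 1.0)
        else:
            max_d = int((1.0 - min_identity) * span) + 1
            d = edlib.align(
                query.seq[qs:qe], subject.seq[ss:se], mode="NW", task="distance", k=max_d
            )["editDistance"]
            if d < 0:  # more than max_d edits: below the identity floor
                continue
            identity = 1.0 - d / span
        if identity < min_identity:
            continue
        score = span * identity * _MATCH - span * (1.0 - identity) * _MISMATCH
        evalue = float(len(query.seq)) * float(s_true_len) * 2.0 ** (-score)
        if minus:  # map back to forward subject coordinates
            ss, se = len(subject.seq) - se, len(subject.seq) - ss
        out.append((qs, qe, ss, se, identity, max(evalue, 1e-300)))
    return out


def _pair_hits(
    qid: str,
    sid: str,
    query: SeqIndex,
    subject: SeqIndex,
    min_len: int,
    min_identity: float,
    both_strands: bool,
) -> list[AlignmentHit]:
    self_pair = qid == sid and query.seq == subject.seq
    hits: list[AlignmentHit] = []
    strands = [(False, subject)]
    if both_strands:
        strands.append((True, subject.rc))
    for minus, s_oriented in strands:
        for qs, qe, ss, se, ident, ev in _segment_hits(
            query, s_oriented, min_len, min_identity, self_pair, minus, len(subject.seq)
        ):
            if self_pair and minus and qs == ss and qe == se:
                continue  # palindromic self-artifact
            score = (qe - qs) * ident * _MATCH
            hits.append(
                AlignmentHit(
                    qid=qid,
                    sid=sid,
                    qstart=qs,
                    qend=qe,
                    sstart=ss,
                    send=se,
                    identity=round(ident, 4),
                    evalue=ev,
                    bitscore=round(score, 1),
                    sminus=minus,
                )
            )
    return hits


def match_pair(
    qid: str,
    qseq: str,
    sid: str,
    sseq: str,
    k: int = 12,
    min_len: int = 30,
    min_identity: float = 0.65,
    both_strands: bool = True,
) -> list[AlignmentHit]:
    """Local alignments between one query and one subject sequence."""
    return _pair_hits(
        qid, sid, SeqIndex(qseq, k), SeqIndex(sseq, k), min_len, min_identity, both_strands
    )


class _GlobalIndex:
    """One sorted k-mer table over many sequences, for batched lookups."""

    def __init__(self, indexes: list[SeqIndex]):
        codes = np.concatenate([ix.codes for ix in indexes])
        pos = np.concatenate([ix.pos for ix in indexes])
        el = np.concatenate(
            [np.full(ix.codes.size, i, dtype=np.int32) for i, ix in enumerate(indexes)]
        )
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order]
        self.el = el[order]


def _batched_hits(
    elements: list[ElementRecord],
    indexes: list[SeqIndex],
    k: int,
    min_len: int,
    min_identity: float,
) -> list[AlignmentHit]:
    """All-vs-all hits via one global k-mer table per strand.

    Every query element is looked up once against the table of all elements
    (instead of once per partner); seed pairs are then chained per
    (partner, diagonal band) exactly as in the pairwise path. Only ordered
    pairs j >= i are emitted.
    """
    glob_f = _GlobalIndex(indexes)
    glob_r = _GlobalIndex([ix.rc for ix in indexes])
    lens = np.array([len(e.seq) for e in elements])
    hits: list[AlignmentHit] = []
    for i, query in enumerate(indexes):
        for minus, glob in ((False, glob_f), (True, glob_r)):
            left = np.searchsorted(glob.codes, query.codes, side="left")
            right = np.searchsorted(glob.codes, query.codes, side="right")
            counts = right - left
            total = int(counts.sum())
            if total == 0:
                continue
            qpos = np.repeat(query.pos, counts)
            gidx = np.repeat(left, counts) + (
                np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
            )
            j_el = glob.el[gidx].astype(np.int64)
            spos = glob.pos[gidx]
            if minus:
                keep = j_el >= i
            else:
                keep = (j_el > i) | ((j_el == i) & (qpos + 50 <= spos))
            qpos, spos, j_el = qpos[keep], spos[keep], j_el[keep]
            if qpos.size == 0:
                continue
            # chain within (partner, diagonal band), query-ordered
            diag = qpos - spos
            band = diag // 400
            order = np.lexsort((qpos, band, j_el))
            q, s, b, d, j = qpos[order], spos[order], band[order], diag[order], j_el[order]
            new_chain = np.ones(q.size, dtype=bool)
            if q.size > 1:
                new_chain[1:] = (
                    (j[1:] != j[:-1])
                    | (b[1:] != b[:-1])
                    | (q[1:] - q[:-1] > 200)
                    | (np.abs(d[1:] - d[:-1]) > 60)
                )
            starts = np.flatnonzero(new_chain)
            q_min = np.minimum.reduceat(q, starts)
            q_max = np.maximum.reduceat(q, starts) + k
            s_min = np.minimum.reduceat(s, starts)
            s_max = np.maximum.reduceat(s, starts) + k
            n_seeds = np.diff(np.append(starts, q.size))
            seg_j = j[starts]
            for qs, qe, ss, se, ns, jj in zip(
                q_min.tolist(), q_max.tolist(), s_min.tolist(), s_max.tolist(),
                n_seeds.tolist(), seg_j.tolist(),
            ):
                if min(qe - qs, se - ss) < min_len:
                    continue
                span = max(qe - qs, se - ss)
                density = ns / max(span - k + 1, 1)
                if density >= 0.30:
                    identity = min(density ** (1.0 / k), 1.0)
                else:
                    max_d = int((1.0 - min_identity) * span) + 1
                    s_seq = indexes[jj].rc.seq if minus else indexes[jj].seq
                    d_edit = edlib.align(
                        query.seq[qs:qe], s_seq[ss:se], mode="NW", task="distance", k=max_d
                    )["editDistance"]
                    if d_edit < 0:
                        continue
                    identity = 1.0 - d_edit / span
                    if identity < min_identity:
                        continue
                score = span * identity * _MATCH - span * (1.0 - identity) * _MISMATCH
                evalue = float(lens[i]) * float(lens[jj]) * 2.0 ** (-score)
                fs, fe = (int(lens[jj]) - se, int(lens[jj]) - ss) if minus else (ss, se)
                if jj == i and minus and qs == fs and qe == fe:
                    continue  # palindromic self-artifact
                hits.append(
                    AlignmentHit(
                        qid=elements[i].element_id,
                        sid=elements[jj].element_id,
                        qstart=qs,
                        qend=qe,
                        sstart=fs,
                        send=fe,
                        identity=round(identity, 4),
                        evalue=max(evalue, 1e-300),
                        bitscore=round((qe - qs) * identity * _MATCH, 1),
                        sminus=minus,
                    )
                )
    return hits


def self_align(
    elements: list[ElementRecord],
    k: int = 12,
    min_len: int = 30,
    min_identity: float = 0.65,
    pairs_per_element: int = 150,
    seed: int = 0,
) -> list[AlignmentHit]:
    """All-vs-all (or sparsely sampled) self-comparison of a dataset.

    For small datasets every pair is aligned, using one batched k-mer table
    per strand; for larger ones each element is compared against
    ``pairs_per_element`` deterministically sampled partners, which mirrors
    capping the number of alignment records per element and keeps the
    homology graph connected through transitivity.
    """
    n = len(elements)
    indexes = [SeqIndex(e.seq, k) for e in elements]
    if n * (n - 1) // 2 <= n * pairs_per_element:
        return _batched_hits(elements, indexes, k, min_len, min_identity)
    pair_set: set[tuple[int, int]] = {(i, i) for i in range(n)}
    rng = np.random.default_rng(seed)
    for i in range(n):
        partners = rng.choice(n - 1, size=pairs_per_element, replace=False)
        for p in partners:
            j = int(p) + (p >= i)
            pair_set.add((min(i, j), max(i, j)))
    hits: list[AlignmentHit] = []
    for i, j in sorted(pair_set):
        hits.extend(
            _pair_hits(
                elements[i].element_id,
                elements[j].element_id,
                indexes[i],
                indexes[j],
                min_len,
                min_identity,
                both_strands=True,
            )
        )
    return hits


def search_sequence(
    seed_id: str,
    seed_seq: str,
    chromosomes: dict[str, str],
    k: int = 12,
    min_len: int = 30,
    min_identity: float = 0.65,
    _chrom_indexes: dict[str, "SeqIndex"] | None = None,
) -> list[AlignmentHit]:
    """Search one seed sequence against a genome; subject ids are chromosome
    names, subject coordinates genomic. Pass ``_chrom_indexes`` to reuse
    genome k-mer indexes across many seeds."""
    query = SeqIndex(seed_seq, k)
    hits: list[AlignmentHit] = []
    for chrom in sorted(chromosomes):
        if _chrom_indexes is not None:
            idx = _chrom_indexes.setdefault(chrom, SeqIndex(chromosomes[chrom], k))
        else:
            idx = SeqIndex(chromosomes[chrom], k)
        hits.extend(
            _pair_hits(seed_id, chrom, query, idx, min_len, min_identity, both_strands=True)
        )
    return hits
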