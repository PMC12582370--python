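"""Genome-wide identification and quantification of module copies.

Sublineage-discriminative modules (high diffScore) are searched across a
genome using randomly drawn member sections as seeds; hits shorter than half
the seed length are discarded, overlapping hits from different seeds are
merged (merged start/end = median of member starts/ends), merged copies are
labeled intact or truncated by overlap with intact-element intervals, and
redundant modules (median overlap with a longer module's copies > 0.2) are
removed. Copy coordinates export to GTF; expression is quantified from a
per-module count table with the FPKM formula
count / (median_length x total_count) x 1e9.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import search_sequence
from .homology_graph import ModuleDef
from .io_formats import ElementRecord

__all__ = [
    "GenomeHit",
    "diff_score",
    "scan_genome",
    "merge_hits",
    "deduplicate_modules",
    "elimination_rate",
    "fpkm",
    "write_gtf",
    "read_gtf",
]


@dataclass
class GenomeHit:
    """One merged genomic copy of a module (0-based half-open interval)."""

    module_id: str
    chrom: str
    start: int
    end: int
    source: str = "truncated"  # {"intact", "truncated"}
    seed_support: int = 1

    def __len__(self) -> int:
        return self.end - self.start


def diff_score(module_percent_by_cluster: Mapping[str, float]) -> float:
    """Range (max - min) of a module's per-cluster occurrence fractions.

    High values mark modules that discriminate sublineages; the usual
    selection threshold is 0.8.
    """
    if len(module_percent_by_cluster) < 2:
        raise ValueError("diffScore needs at least 2 clusters")
    vals = list(module_percent_by_cluster.values())
    if any(not (0.0 <= v <= 1.0) for v in vals):
        raise ValueError("module percentages must be fractions in [0,1]")
    return max(vals) - min(vals)


def merge_hits(intervals: Sequence[tuple[int, int]]) -> tuple[int, int]:
    """Median-merge rule for overlapping raw hits: the merged interval takes
    the median of member starts and the median of member ends.

    For an even member count the integer part of the midpoint average is
    used. Worked example: starts {100,110,105}, ends {200,190,210} ->
    [105, 200).
    """
    starts = [s for s, _ in intervals]
    ends = [e for _, e in intervals]
    return int(statistics.median(starts)), int(statistics.median(ends))


def _chain_overlapping(intervals: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Single-linkage chaining of positionally overlapping intervals."""
    groups: list[list[tuple[int, int]]] = []
    cur: list[tuple[int, int]] = []
    cur_end = -1
    for iv in sorted(intervals):
        if cur and iv[0] < cur_end:
            cur.append(iv)
            cur_end = max(cur_end, iv[1])
        else:
            if cur:
                groups.append(cur)
            cur = [iv]
            cur_end = iv[1]
    if cur:
        groups.append(cur)
    return groups


def scan_genome(
    module: ModuleDef,
    elements: Sequence[ElementRecord],
    genome: Mapping[str, str],
    intact_intervals: Sequence[tuple[str, int, int, str]] = (),
    n_seeds: int = 10,
    evalue_max: float = 1e-5,
    min_len_frac: float = 0.5,
    seed: int = 42,
    k: int = 12,
) -> list[GenomeHit]:
    """Find genomic copies of one module.

    ``n_seeds`` member sections are drawn with a fixed RNG seed and searched
    against the genome; hits shorter than ``min_len_frac`` of their seed are
    dropped; overlapping hits from different seeds are merged with the
    median rule; each merged copy is labeled intact when it overlaps any
    interval of the intact-element annotation, truncated otherwise.
    """
    seq_of = {e.element_id: e.seq for e in elements}
    usable = [s for s in module.members if s.element_id in seq_of]
    if not usable:
        raise ValueError(f"module {module.module_id}: no member with an extractable sequence")
    rng = np.random.default_rng(seed)
    if len(usable) > n_seeds:
        idx = rng.choice(len(usable), size=n_seeds, replace=False)
        seeds = [usable[i] for i in sorted(idx)]
    else:
        seeds = usable

    raw: dict[str, list[tuple[int, int]]] = {}
    for sec in seeds:
        seed_seq = seq_of[sec.element_id][sec.start : sec.end]
        for h in search_sequence(
            f"{module.module_id}:{sec.element_id}", seed_seq, dict(genome), k=k
        ):
            if h.evalue >= evalue_max:
                continue
            if (h.send - h.sstart) < min_len_frac * len(seed_seq):
                continue
            if h.sid not in genome:
                raise ValueError(f"hit on unknown chromosome {h.sid}")
            raw.setdefault(h.sid, []).append((h.sstart, h.send))

    intact_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, _name in intact_intervals:
        intact_by_chrom.setdefault(chrom, []).append((start, end))

    out: list[GenomeHit] = []
    for chrom in sorted(raw):
        for group in _chain_overlapping(raw[chrom]):
            start, end = merge_hits(group)
            if end <= start:
                continue
            intact = any(
                min(end, ie) > max(start, istart)
                for istart, ie in intact_by_chrom.get(chrom, [])
            )
            out.append(
                GenomeHit(
                    module_id=module.module_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    source="intact" if intact else "truncated",
                    seed_support=len(group),
                )
            )
    return out


def _best_overlap_frac(hit: GenomeHit, others: Sequence[GenomeHit]) -> float:
    best = 0.0
    for o in others:
        if o.chrom != hit.chrom:
            continue
        ov = min(hit.end, o.end) - max(hit.start, o.start)
        if ov > 0:
            best = max(best, ov / len(hit))
    return best


def deduplicate_modules(
    hit_sets: Mapping[str, Sequence[GenomeHit]],
    rep_lengths: Mapping[str, float],
    max_median_overlap: float = 0.2,
) -> list[str]:
    """Drop redundant modules: processed in descending representative length,
    a module is removed when the median (over its copies) of per-copy overlap
    fraction with any already-retained longer module's copies exceeds
    ``max_median_overlap`` (strictly greater than)."""
    order = sorted(hit_sets, key=lambda m: (-rep_lengths[m], m))
    retained: list[str] = []
    for mod in order:
        hits = list(hit_sets[mod])
        redundant = False
        for kept in retained:
            if not hits:
                break
            fracs = [_best_overlap_frac(h, hit_sets[kept]) for h in hits]
            if statistics.median(fracs) > max_median_overlap:
                redundant = True
                break
        if not redundant:
            retained.append(mod)
    return retained


def elimination_rate(hits: Sequence[GenomeHit]) -> float | None:
    """Fraction of a module's genomic copies lying outside intact elements
    (truncated fragments); None when there are no copies."""
    if not hits:
        return None
    truncated = sum(1 for h in hits if h.source == "truncated")
    return truncated / len(hits)


def fpkm(
    counts: Mapping[str, int],
    median_lengths: Mapping[str, float],
    total_count: int,
) -> dict[str, float]:
    """FPKM_m = count_m / (median_length_m x total_count) x 1e9."""
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    out = {}
    for mod, count in counts.items():
        ml = median_lengths[mod]
        if ml <= 0:
            raise ValueError(f"non-positive median length for module {mod}")
        out[mod] = count / (ml * total_count) * 1e9
    return out


def write_gtf(hits: Iterable[GenomeHit], path) -> None:
    """GTF export: 1-based inclusive coordinates, one feature per merged copy."""
    with open(path, "w") as fh:
        for h in hits:
            attrs = (
                f'module_id "{h.module_id}"; source_class "{h.source}"; '
                f'seed_support "{h.seed_support}";'
            )
            fh.write(
                f"{h.chrom}\tltrtrace\tmodule_copy\t{h.start + 1}\t{h.end}\t.\t.\t.\t{attrs}\n"
            )


def read_gtf(path) -> list[GenomeHit]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = {}
            for part in f[8].split(";"):
                part = part.strip()
                if part:
                    key, val = part.split(" ", 1)
                    attrs[key] = val.strip('"')
            out.append(
                GenomeHit(
                    module_id=attrs["module_id"],
                    chrom=f[0],
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    source=attrs.get("source_class", "truncated"),
                    seed_support=int(attrs.get("seed_support", 1)),
                )
            )
    return out
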