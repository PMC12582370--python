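"""Readers and writers for every on-disk artifact the pipeline touches.

All coordinate conventions are normalized at this boundary: internally every
interval is 0-based half-open; writers convert back to each format's native
convention (BLAST tabular and GTF are 1-based inclusive, BED stays 0-based
half-open).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "ElementRecord",
    "AlignmentHit",
    "read_fasta",
    "write_fasta",
    "read_alignment_table",
    "write_alignment_table",
    "write_cluster_tsv",
    "read_cluster_tsv",
    "read_bed",
    "write_bed",
    "read_config_file",
    "write_config_file",
]

_VALID_NT = set("ACGTN")


@dataclass(frozen=True)
class ElementRecord:
    """One intact LTR-RT: identifier, nucleotide sequence, optional group tag."""

    element_id: str
    seq: str
    tag: str | None = None

    def __post_init__(self) -> None:
        if not self.element_id or any(c.isspace() for c in self.element_id):
            raise ValueError(f"invalid element id: {self.element_id!r}")
        if not self.seq:
            raise ValueError(f"empty sequence for element {self.element_id}")
        bad = set(self.seq) - _VALID_NT
        if bad:
            raise ValueError(
                f"element {self.element_id}: non-nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise local alignment, coordinates 0-based half-open, forward.

    ``sminus`` records that the subject interval was reverse-orientation in the
    source record; the interval itself is always stored forward
    (``sstart < send``).
    """

    qid: str
    sid: str
    qstart: int
    qend: int
    sstart: int
    send: int
    identity: float
    evalue: float
    bitscore: float = 0.0
    sminus: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend):
            raise ValueError(f"bad query interval [{self.qstart},{self.qend})")
        if not (0 <= self.sstart < self.send):
            raise ValueError(f"bad subject interval [{self.sstart},{self.send})")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0,1]")
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")


def read_fasta(path: str | os.PathLike) -> list[ElementRecord]:
    """Read a multi-FASTA of elements; uppercase sequences, reject duplicate ids."""
    records: list[ElementRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate element id in {path}: {rec.id}")
        seen.add(rec.id)
        records.append(ElementRecord(element_id=rec.id, seq=str(rec.seq).upper()))
    if not records:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.strip():
                    raise ValueError(
                        f"{path}:{lineno}: not FASTA (no '>' header before content)"
                    )
    return records


def write_fasta(records: Iterable[ElementRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.element_id}\n")
            for i in range(0, len(rec.seq), 80):
                fh.write(rec.seq[i : i + 80] + "\n")


def read_alignment_table(
    path: str | os.PathLike, max_hits_per_query: int = 10_000
) -> list[AlignmentHit]:
    """Read 12-column tabular alignments (qid sid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore; 1-based inclusive coordinates).

    Per-query hit lists are truncated to ``max_hits_per_query``, keeping the
    lowest e-values (ties broken by higher bitscore, then input order).
    Full-span identical self-hits (an element aligned to its own entire length
    on both sides) are dropped.
    """
    if max_hits_per_query < 1:
        raise ValueError("max_hits_per_query must be positive")
    raw: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            qid, sid = fields[0], fields[1]
            try:
                pident = float(fields[2])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if qend < qstart:
                raise ValueError(f"{path}:{lineno}: qend < qstart")
            sminus = send < sstart
            if sminus:
                sstart, send = send, sstart
            hit = AlignmentHit(
                qid=qid,
                sid=sid,
                qstart=qstart - 1,
                qend=qend,
                sstart=sstart - 1,
                send=send,
                identity=pident / 100.0,
                evalue=evalue,
                bitscore=bitscore,
                sminus=sminus,
            )
            if (
                hit.qid == hit.sid
                and hit.qstart == hit.sstart
                and hit.qend == hit.send
                and not hit.sminus
            ):
                continue  # trivial full/self-span alignment carries no signal
            raw.append(hit)
    return truncate_hits(raw, max_hits_per_query)


def truncate_hits(hits: Sequence[AlignmentHit], max_hits_per_query: int) -> list[AlignmentHit]:
    """Keep at most ``max_hits_per_query`` hits per query, lowest e-value first
    (ties: higher bitscore, then original order), preserving input order among
    the survivors."""
    by_query: dict[str, list[tuple[float, float, int]]] = {}
    for idx, h in enumerate(hits):
        by_query.setdefault(h.qid, []).append((h.evalue, -h.bitscore, idx))
    keep: set[int] = set()
    for rows in by_query.values():
        rows.sort()
        keep.update(idx for _, _, idx in rows[:max_hits_per_query])
    return [h for i, h in enumerate(hits) if i in keep]


def write_alignment_table(hits: Iterable[AlignmentHit], path: str | os.PathLike) -> None:
    """Write hits back to the 12-column tabular dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        for h in hits:
            sstart, send = h.sstart + 1, h.send
            if h.sminus:
                sstart, send = send, sstart
            span = h.qend - h.qstart
            fh.write(
                "\t".join(
                    [
                        h.qid,
                        h.sid,
                        f"{h.identity * 100:.2f}",
                        str(span),
                        str(round(span * (1 - h.identity))),
                        "0",
                        str(h.qstart + 1),
                        str(h.qend),
                        str(sstart),
                        str(send),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


_CLUSTER_HEADER = ["element_id", "sublineage", "x", "y", "z", "confidence"]


def write_cluster_tsv(assignments, coords, path: str | os.PathLike) -> None:
    """Write final sublineage assignments with 3D view coordinates.

    ``assignments`` is an iterable of ClusterAssignment-like objects
    (element_id, label, confidence); ``coords`` maps element_id to a
    3-sequence of floats. An assigned element without coordinates is a
    consistency error; unassigned elements may omit coordinates.
    """
    rows = sorted(assignments, key=lambda a: a.element_id)
    with open(path, "w") as fh:
        fh.write("\t".join(_CLUSTER_HEADER) + "\n")
        for a in rows:
            xyz = coords.get(a.element_id)
            if xyz is None:
                if a.label != "unassigned":
                    raise ValueError(f"missing coordinates for assigned element {a.element_id}")
                xyz = (float("nan"),) * 3
            fh.write(
                f"{a.element_id}\t{a.label}\t"
                f"{xyz[0]:.6g}\t{xyz[1]:.6g}\t{xyz[2]:.6g}\t{a.confidence}\n"
            )


def read_cluster_tsv(path: str | os.PathLike):
    """Inverse of :func:`write_cluster_tsv`; returns (assignments, coords)."""
    from .clustering import ClusterAssignment  # local import: avoid cycle

    assignments: list[ClusterAssignment] = []
    coords: dict[str, tuple[float, float, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CLUSTER_HEADER:
            raise ValueError(f"unexpected cluster-TSV header: {header}")
        for line in fh:
            eid, label, x, y, z, conf = line.rstrip("\n").split("\t")
            assignments.append(ClusterAssignment(element_id=eid, label=label, confidence=conf))
            coords[eid] = (float(x), float(y), float(z))
    return assignments, coords


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str]]:
    """Read BED3/BED4 intervals (chrom, start, end[, name]); 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            start, end = int(f[1]), int(f[2])
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            out.append((f[0], start, end, f[3] if len(f) > 3 else f"{f[0]}:{start}-{end}"))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_config_file(path: str | os.PathLike) -> dict[str, str]:
    """Plain ``key=value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, val = line.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def write_config_file(values: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for key in sorted(values):
            fh.write(f"{key}={values[key]}\n")
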