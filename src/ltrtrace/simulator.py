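"""Labeled simulator of LTR-RT evolution along independent paths.

Each path starts from a founder derived from an ancestral sequence by a
divergence dose of substitutions and structural mutations. The population
then evolves in discrete generations: every active copy spawns children
(burst), each child receives per-site substitutions, small host-style
indels and at most one structural mutation (insertion of random sequence,
deletion, or inversion), and every copy is then eliminated with a fixed
probability. Surviving copies are emitted as FASTA together with a truth
table carrying path labels and the full per-copy mutation log, so every
emitted sequence can be reproduced exactly by replaying its log.

Defaults aim at desk-scale datasets in which evolutionary paths are
recoverable yet carry realistic within-path structural noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .io_formats import ElementRecord

__all__ = ["SimConfig", "TruthRow", "SimTruth", "simulate", "make_benchmark", "replay"]

_NT = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# event tuples: ("sub", pos, base) | ("ins", pos, seq) | ("del", pos, len) | ("inv", pos, len)
Event = tuple


@dataclass(frozen=True)
class SimConfig:
    ancestors: tuple[str, ...] | None = None  # None: random ancestors are drawn
    ancestor_len: int = 8000
    n_paths: int = 3
    n_generations: int = 4
    burst_copies_per_gen: int = 2
    p_sub: float = 0.02  # substitutions / site / generation
    p_indel_te: float = 0.002  # small indels / site / generation
    indel_len_p: float = 0.5  # geometric length parameter for small indels
    p_sv: float = 0.3  # per-copy chance of one structural mutation per generation
    sv_len_range: tuple[int, int] = (100, 2000)  # uniform structural-event length
    p_elim: float = 0.1  # per-copy per-generation elimination probability
    founder_subs: int = 200  # path-divergence dose applied to each founder
    founder_svs: int = 6
    min_seq_len: int = 100  # deletions never shrink a copy below this
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_indel_te", "p_sv", "p_elim", "indel_len_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.n_paths < 2:
            raise ValueError("n_paths must be >= 2")
        if self.n_generations < 0 or self.burst_copies_per_gen < 0:
            raise ValueError("negative generation/burst settings")

    def write(self, path) -> None:
        """Dump as a plain key=value config file (ancestors by length only)."""
        from .io_formats import write_config_file

        values = {k: v for k, v in self.__dict__.items() if k != "ancestors"}
        values["sv_len_range"] = f"{self.sv_len_range[0]},{self.sv_len_range[1]}"
        write_config_file(values, path)

    @classmethod
    def from_file(cls, path, **overrides) -> "SimConfig":
        from .io_formats import read_config_file

        raw = read_config_file(path)
        kwargs: dict = {}
        defaults = cls()
        for key, val in raw.items():
            if key == "sv_len_range":
                lo, hi = val.split(",")
                kwargs[key] = (int(lo), int(hi))
                continue
            if not hasattr(defaults, key):
                raise ValueError(f"unknown simulator config key: {key}")
            cur = getattr(defaults, key)
            kwargs[key] = type(cur)(val) if cur is not None else val
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class TruthRow:
    element_id: str
    path_id: str
    generation: int
    alive: bool
    parent_id: str  # another element id, or an ancestor id for founders
    events: list[Event] = field(default_factory=list)


@dataclass
class SimTruth:
    rows: dict[str, TruthRow]
    ancestors: dict[str, str]  # ancestor id -> sequence

    def alive_ids(self) -> list[str]:
        return [eid for eid, r in self.rows.items() if r.alive]

    def path_of(self, element_id: str) -> str:
        return self.rows[element_id].path_id

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("element_id\tpath_id\tgeneration\talive\tparent_id\n")
            for eid in sorted(self.rows):
                r = self.rows[eid]
                fh.write(
                    f"{r.element_id}\t{r.path_id}\t{r.generation}\t"
                    f"{int(r.alive)}\t{r.parent_id}\n"
                )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


def apply_event(seq: str, ev: Event) -> str:
    """Apply one mutation event; positions refer to the sequence as it is at
    application time, so replaying an ordered log is exact."""
    kind = ev[0]
    if kind == "sub":
        _, pos, base = ev
        return seq[:pos] + base + seq[pos + 1 :]
    if kind == "ins":
        _, pos, ins = ev
        return seq[:pos] + ins + seq[pos:]
    if kind == "del":
        _, pos, ln = ev
        return seq[:pos] + seq[pos + ln :]
    if kind == "inv":
        _, pos, ln = ev
        segment = seq[pos : pos + ln]
        return seq[:pos] + segment.translate(_COMPLEMENT)[::-1] + seq[pos + ln :]
    raise ValueError(f"unknown event kind {kind!r}")


def apply_events(seq: str, events: Iterable[Event]) -> str:
    for ev in events:
        seq = apply_event(seq, ev)
    return seq


def _draw_substitutions(seq: str, n_or_rate, rng: np.random.Generator) -> list[Event]:
    length = len(seq)
    if isinstance(n_or_rate, int):
        n = min(n_or_rate, length)
        positions = rng.choice(length, size=n, replace=False)
    else:
        mask = rng.random(length) < n_or_rate
        positions = np.flatnonzero(mask)
    events: list[Event] = []
    for pos in sorted(int(p) for p in positions):
        old = seq[pos]
        choices = [b for b in "ACGT" if b != old]
        events.append(("sub", pos, choices[rng.integers(0, len(choices))]))
    return events


def _draw_small_indels(length: int, cfg: SimConfig, rng: np.random.Generator) -> list[Event]:
    n = rng.binomial(length, cfg.p_indel_te)
    events: list[Event] = []
    for _ in range(n):
        ln = int(rng.geometric(cfg.indel_len_p))
        pos = int(rng.integers(0, max(length, 1)))
        if rng.random() < 0.5:
            events.append(("ins", pos, _random_seq(rng, ln)))
        else:
            events.append(("del", pos, ln))
    return events


def _draw_sv(length: int, cfg: SimConfig, rng: np.random.Generator) -> Event | None:
    lo, hi = cfg.sv_len_range
    ln = int(rng.integers(lo, hi + 1))
    kind = ("ins", "del", "inv")[rng.integers(0, 3)]
    if kind == "ins":
        pos = int(rng.integers(0, length + 1))
        return ("ins", pos, _random_seq(rng, ln))
    # deletions and inversions must fit inside the sequence
    ln = min(ln, max(length - cfg.min_seq_len, 0) if kind == "del" else length)
    if ln < 1:
        return None
    pos = int(rng.integers(0, length - ln + 1))
    return (kind, pos, ln)


def _sanitize_events(seq_len: int, events: list[Event], cfg: SimConfig) -> list[Event]:
    """Clip event positions/lengths so the ordered log is always applicable."""
    out: list[Event] = []
    cur = seq_len
    for ev in events:
        kind = ev[0]
        if kind == "sub":
            if ev[1] < cur:
                out.append(ev)
        elif kind == "ins":
            pos = min(ev[1], cur)
            out.append(("ins", pos, ev[2]))
            cur += len(ev[2])
        elif kind in ("del", "inv"):
            ln = min(ev[2], cur - cfg.min_seq_len if kind == "del" else cur)
            pos = min(ev[1], max(cur - ln, 0))
            if ln >= 1:
                out.append((kind, pos, ln))
                if kind == "del":
                    cur -= ln
    return out


def _mutate(seq: str, cfg: SimConfig, rng: np.random.Generator, with_sv: bool) -> tuple[str, list[Event]]:
    events: list[Event] = []
    events += _draw_substitutions(seq, cfg.p_sub, rng)
    events += _draw_small_indels(len(seq), cfg, rng)
    if with_sv and rng.random() < cfg.p_sv:
        sv = _draw_sv(len(seq), cfg, rng)
        if sv is not None:
            events.append(sv)
    events = _sanitize_events(len(seq), events, cfg)
    return apply_events(seq, events), events


def _make_founder(
    ancestor: str, cfg: SimConfig, rng: np.random.Generator
) -> tuple[str, list[Event]]:
    events: list[Event] = list(_draw_substitutions(ancestor, int(cfg.founder_subs), rng))
    seq = apply_events(ancestor, events)
    for _ in range(cfg.founder_svs):
        sv = _draw_sv(len(seq), cfg, rng)
        if sv is not None:
            events.append(sv)
            seq = apply_event(seq, sv)
    return seq, events


def simulate(config: SimConfig) -> tuple[list[ElementRecord], SimTruth]:
    """Run the burst/mutation/elimination process; return surviving elements
    and the full truth table (eliminated copies appear with alive=False)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if config.ancestors is not None:
        ancestors = [a.upper() for a in config.ancestors]
        if len(ancestors) < 1:
            raise ValueError("ancestors must be non-empty when given")
    else:
        ancestors = [_random_seq(rng, config.ancestor_len)]
    anc_map = {f"anc{i}": seq for i, seq in enumerate(ancestors)}

    rows: dict[str, TruthRow] = {}
    sequences: dict[str, str] = {}

    for p in range(config.n_paths):
        path_id = f"P{p + 1}"
        anc_id = f"anc{p % len(ancestors)}"
        founder_seq, founder_events = _make_founder(anc_map[anc_id], config, rng)
        founder_id = f"{path_id}_g0_c0"
        rows[founder_id] = TruthRow(founder_id, path_id, 0, True, anc_id, founder_events)
        sequences[founder_id] = founder_seq

        active = [founder_id]
        for gen in range(1, config.n_generations + 1):
            children: list[str] = []
            counter = 0
            for parent in active:
                for _ in range(config.burst_copies_per_gen):
                    child_id = f"{path_id}_g{gen}_c{counter}"
                    counter += 1
                    seq, events = _mutate(sequences[parent], config, rng, with_sv=True)
                    rows[child_id] = TruthRow(child_id, path_id, gen, True, parent, events)
                    sequences[child_id] = seq
                    children.append(child_id)
            survivors = []
            for eid in active + children:
                if rng.random() < config.p_elim:
                    rows[eid].alive = False
                else:
                    survivors.append(eid)
            active = survivors
        # copies eliminated mid-run are dropped from the emitted set
        for eid in list(sequences):
            if eid.startswith(path_id + "_") and not rows[eid].alive:
                del sequences[eid]

    elements = [
        ElementRecord(element_id=eid, seq=sequences[eid], tag=rows[eid].path_id)
        for eid in sorted(sequences)
    ]
    return elements, SimTruth(rows=rows, ancestors=anc_map)


def replay(truth: SimTruth, element_id: str, _memo: dict[str, str] | None = None) -> str:
    """Reconstruct an element's sequence by replaying mutation logs from its
    path ancestor down the genealogy; must equal the emitted sequence."""
    memo = _memo if _memo is not None else {}
    if element_id in memo:
        return memo[element_id]
    row = truth.rows[element_id]
    if row.parent_id in truth.ancestors:
        base = truth.ancestors[row.parent_id]
    else:
        base = replay(truth, row.parent_id, memo)
    seq = apply_events(base, row.events)
    memo[element_id] = seq
    return seq


def make_benchmark(
    base_config: SimConfig | None = None,
    n_ancestors: int = 3,
    path_counts: Sequence[int] = (2, 3, 4),
    master_seed: int = 0,
) -> list[tuple[list[ElementRecord], SimTruth, SimConfig]]:
    """Benchmark grid: {ancestor} x {path count}, default 3 x 3 = 9 labeled
    datasets; per-dataset seeds derive deterministically from the master seed."""
    base = base_config or SimConfig()
    ss = np.random.SeedSequence(master_seed)
    anc_rng = np.random.default_rng(ss.spawn(1)[0])
    datasets = []
    k = 0
    for a in range(n_ancestors):
        ancestor = _random_seq(anc_rng, base.ancestor_len)
        for n_paths in path_counts:
            child_seed = int(np.random.SeedSequence(master_seed, spawn_key=(1, k)).generate_state(1)[0] % (2**31))
            cfg = replace(base, ancestors=(ancestor,), n_paths=n_paths, seed=child_seed)
            elements, truth = simulate(cfg)
            datasets.append((elements, truth, cfg))
            k += 1
    return datasets
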