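"""Module-sequence encoding: each element becomes an ordered list of module ids.

When there are many modules, only the most widely distributed ones (present
in the largest number of distinct elements) are kept; the ``top_mod_num``
knob controls how many. A coverage curve over module-sequence lengths is the
tuning diagnostic for that choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .homology_graph import ModuleDef
from .io_formats import ElementRecord

__all__ = [
    "ModuleSequence",
    "module_spread",
    "select_top_modules",
    "encode",
    "coverage_curve",
    "write_modseq_tsv",
    "write_coverage_tsv",
]


@dataclass
class ModuleSequence:
    """Ordered module ids along one element (order = section start positions)."""

    element_id: str
    mods: list[str] = field(default_factory=list)
    starts: list[int] = field(default_factory=list)
    flagged_empty: bool = False

    def __len__(self) -> int:
        return len(self.mods)


def module_spread(modules: Iterable[ModuleDef]) -> dict[str, int]:
    """Spread of a module = number of distinct elements that contain it."""
    return {
        m.module_id: len({s.element_id for s in m.members}) for m in modules
    }


def _id_rank(module_id: str) -> int:
    return int(module_id.lstrip("b"))


def select_top_modules(modules: Sequence[ModuleDef], top_mod_num: int) -> list[ModuleDef]:
    """The ``top_mod_num`` most widespread modules; ties broken by id rank."""
    if top_mod_num < 1:
        raise ValueError("top_mod_num must be >= 1")
    spread = module_spread(modules)
    ranked = sorted(modules, key=lambda m: (-spread[m.module_id], _id_rank(m.module_id)))
    return ranked[:top_mod_num]


def encode(
    modules: Sequence[ModuleDef],
    elements: Sequence[ElementRecord],
    top_mod_num: int = 30,
) -> list[ModuleSequence]:
    """Encode every element as its ordered sequence of retained module ids.

    Elements containing none of the retained modules get an empty sequence
    with ``flagged_empty`` set; they stay in the output so downstream stages
    can report them as unassigned.
    """
    retained = select_top_modules(modules, top_mod_num)
    per_element: dict[str, list[tuple[int, int, str]]] = {e.element_id: [] for e in elements}
    for mod in retained:
        for s in mod.members:
            if s.element_id in per_element:
                per_element[s.element_id].append((s.start, s.end, mod.module_id))
    out = []
    for e in elements:
        sections = sorted(per_element[e.element_id])
        out.append(
            ModuleSequence(
                element_id=e.element_id,
                mods=[mid for _, _, mid in sections],
                starts=[start for start, _, _ in sections],
                flagged_empty=not sections,
            )
        )
    return out


def coverage_curve(
    sequences: Sequence[ModuleSequence], lengths: Sequence[int]
) -> list[tuple[int, float]]:
    """Fraction of elements whose module sequence has at least L modules, for
    each L in ``lengths``. Non-increasing in L by construction."""
    if not lengths:
        raise ValueError("lengths must be non-empty")
    n = len(sequences)
    out = []
    for L in lengths:
        frac = sum(1 for s in sequences if len(s) >= L) / n if n else 0.0
        out.append((L, frac))
    return out


def write_modseq_tsv(sequences: Iterable[ModuleSequence], path) -> None:
    with open(path, "w") as fh:
        fh.write("element_id\tmodule_sequence\n")
        for s in sequences:
            fh.write(f"{s.element_id}\t{','.join(s.mods)}\n")


def write_coverage_tsv(curve: Iterable[tuple[int, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("length\tcoverage\n")
        for L, frac in curve:
            fh.write(f"{L}\t{frac:.6g}\n")
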