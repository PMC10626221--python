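"""ISCN karyotype parsing and interphase-FISH tally arithmetic.

The ISCN parser covers the constructs that occur in clinical myeloid/plasma
cell karyotypes of this kind: modal counts and ranges (``55-57``), sex
designations, whole-chromosome gains/losses (``+8``, ``-7``), interstitial
deletions (``del(20)(q11.2)``), ``?``-qualified aberrations, ``xN``
multipliers, stemline references (``idem``, ``sl``, ``sdl``) including
doubling (``slx2``), bracketed cell counts (``[7]``) and composite clones
(``[cp3]``).  Unparseable tokens are kept verbatim in an ``unparsed`` list
with a warning — never silently dropped.

FISH tallies follow clinical reporting conventions: percentages and
non-PC:PC ratios are rounded half-up to one decimal, and positivity is
decided against probe-specific cutoffs that depend on the number of scored
cells (100/200/300 brackets).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources

__all__ = [
    "Aberration", "Clone", "Karyotype", "FishTally", "CutoffTable",
    "parse_iscn", "tally_fish", "ratio_nonpc_pc", "apply_cutoff",
    "load_default_cutoffs",
]

log = logging.getLogger(__name__)

_EN_DASH = "–"


@dataclass(frozen=True)
class Aberration:
    kind: str                 # gain | loss | del
    chrom: str
    bands: str | None = None  # e.g. "q11.2" for deletions
    multiplicity: int = 1
    uncertain: bool = False

    def render(self) -> str:
        core = {
            "gain": f"+{self.chrom}",
            "loss": f"-{self.chrom}",
            "del": f"del({self.chrom})({self.bands})",
        }[self.kind]
        if self.uncertain:
            core = "?" + core
        if self.multiplicity > 1:
            core += f"x{self.multiplicity}"
        return core

    def expand(self) -> tuple["Aberration", ...]:
        """Multiplicity-1 copies, for multiset comparisons."""
        one = Aberration(self.kind, self.chrom, self.bands, 1, self.uncertain)
        return (one,) * self.multiplicity


@dataclass
class Clone:
    modal_count: int | tuple[int, int]
    sex: str | None
    aberrations: list[Aberration]     # the clone's own listed aberrations
    cell_count: int
    composite: bool = False
    stemline_ref: tuple[str, int] | None = None  # ("idem"|"sl"|"sdl", multiplier)

    @property
    def modal_low(self) -> int:
        return self.modal_count[0] if isinstance(self.modal_count, tuple) else self.modal_count


@dataclass
class Karyotype:
    clones: list[Clone]
    unparsed: list[str] = field(default_factory=list)

    def resolved_aberrations(self, i: int) -> list[Aberration]:
        """Clone *i*'s full aberration list with stemline references expanded."""
        clone = self.clones[i]
        out: list[Aberration] = []
        if clone.stemline_ref is not None:
            ref, mult = clone.stemline_ref
            base_idx = 1 if ref == "sdl" else 0  # sideline refers to the 2nd clone
            if base_idx >= len(self.clones) or base_idx == i:
                raise ValueError(f"{ref} reference cannot be resolved for clone {i}")
            base = self.resolved_aberrations(base_idx)
            for ab in base:
                out.append(Aberration(ab.kind, ab.chrom, ab.bands,
                                      ab.multiplicity * mult, ab.uncertain))
        out.extend(clone.aberrations)
        return out

    def resolved_multiset(self, i: int) -> tuple[Aberration, ...]:
        expanded: list[Aberration] = []
        for ab in self.resolved_aberrations(i):
            expanded.extend(ab.expand())
        return tuple(sorted(expanded, key=lambda a: (a.kind, a.chrom, a.bands or "")))

    def to_iscn(self) -> str:
        """Render with stemline references expanded to explicit aberrations."""
        first_sex = next((c.sex for c in self.clones if c.sex), None)
        parts = []
        for i, clone in enumerate(self.clones):
            if isinstance(clone.modal_count, tuple):
                modal = f"{clone.modal_count[0]}-{clone.modal_count[1]}"
            else:
                modal = str(clone.modal_count)
            tokens = [modal]
            tokens.append(clone.sex or first_sex or "XX")
            tokens.extend(ab.render() for ab in self.resolved_aberrations(i))
            count = f"[cp{clone.cell_count}]" if clone.composite else f"[{clone.cell_count}]"
            parts.append(",".join(tokens) + count)
        return "/".join(parts)


_COUNT_RE = re.compile(r"\[(cp)?(\d+)\]\s*$")
_MODAL_RE = re.compile(rf"^(\d+)(?:[-{_EN_DASH}](\d+))?$")
_SEX_RE = re.compile(r"^[XY?]{1,4}$")
_CHROM = r"(\d{1,2}|[XY])"
_GAIN_RE = re.compile(rf"^(\?)?\+{_CHROM}(?:x(\d+))?$")
_LOSS_RE = re.compile(rf"^(\?)?[-−]{_CHROM}(?:x(\d+))?$")
_DEL_RE = re.compile(r"^(\?)?del\((\w+)\)\(([^)]+)\)(?:x(\d+))?$")
_REF_RE = re.compile(r"^(idem|sl|sdl)(?:x(\d+))?$")


def _parse_clone(text: str, unparsed: list[str]) -> Clone:
    text = text.strip()
    m = _COUNT_RE.search(text)
    if not m:
        raise ValueError(f"clone {text!r} lacks a [n] cell count")
    composite = m.group(1) == "cp"
    cell_count = int(m.group(2))
    body = text[:m.start()].strip()
    tokens = [t.strip() for t in body.split(",") if t.strip()]
    if not tokens:
        raise ValueError(f"clone {text!r} has no modal count")

    mm = _MODAL_RE.match(tokens[0])
    if not mm:
        raise ValueError(f"clone {text!r}: cannot parse modal count {tokens[0]!r}")
    modal: int | tuple[int, int]
    modal = (int(mm.group(1)), int(mm.group(2))) if mm.group(2) else int(mm.group(1))

    rest = tokens[1:]
    sex = None
    if rest and _SEX_RE.match(rest[0]):
        sex = rest[0]
        rest = rest[1:]

    aberrations: list[Aberration] = []
    stemline_ref: tuple[str, int] | None = None
    for tok in rest:
        rm = _REF_RE.match(tok)
        if rm:
            stemline_ref = (rm.group(1), int(rm.group(2) or 1))
            continue
        dm = _DEL_RE.match(tok)
        if dm:
            aberrations.append(Aberration("del", dm.group(2), dm.group(3),
                                          int(dm.group(4) or 1), bool(dm.group(1))))
            continue
        gm = _GAIN_RE.match(tok)
        if gm:
            aberrations.append(Aberration("gain", gm.group(2), None,
                                          int(gm.group(3) or 1), bool(gm.group(1))))
            continue
        lm = _LOSS_RE.match(tok)
        if lm:
            aberrations.append(Aberration("loss", lm.group(2), None,
                                          int(lm.group(3) or 1), bool(lm.group(1))))
            continue
        log.warning("unparseable ISCN token %r kept verbatim", tok)
        unparsed.append(tok)

    return Clone(modal_count=modal, sex=sex, aberrations=aberrations,
                 cell_count=cell_count, composite=composite, stemline_ref=stemline_ref)


def parse_iscn(karyotype: str) -> Karyotype:
    """Parse an ISCN karyotype string into structured clones."""
    if not karyotype or not karyotype.strip():
        raise ValueError("empty karyotype string")
    unparsed: list[str] = []
    clones = [_parse_clone(part, unparsed) for part in karyotype.strip().split("/")]
    return Karyotype(clones=clones, unparsed=unparsed)


# --------------------------------------------------------------------------
# FISH tallies


def _round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def tally_fish(positive: int, scored: int, cell_class: str = "TNC") -> float:
    """Percentage of positive cells, rounded half-up to one decimal."""
    if scored <= 0:
        raise ValueError("scored cell count must be > 0")
    if not 0 <= positive <= scored:
        raise ValueError("positive count must be in [0, scored]")
    return _round_half_up(100.0 * positive / scored)


def ratio_nonpc_pc(non_pc_positive: int, pc_positive: int) -> float | None:
    """Direct non-PC:PC quotient, half-up to one decimal; None when PC = 0."""
    if pc_positive == 0:
        return None
    return _round_half_up(non_pc_positive / pc_positive)


def format_ratio(ratio: float | None) -> str:
    return "—" if ratio is None else f"{ratio:.1f}"


@dataclass(frozen=True)
class FishTally:
    """One probe-pattern count in one scoring class, with derived values."""

    probe: str
    pattern: str
    cell_class: str  # TNC | PC | non-PC
    positive: int
    scored: int

    def __post_init__(self) -> None:
        if not 0 <= self.positive <= self.scored:
            raise ValueError("positive must be in [0, scored]")

    @property
    def percent(self) -> float:
        return tally_fish(self.positive, self.scored, self.cell_class)


class CutoffTable:
    """Probe-pattern FISH cutoffs per scored-cell bracket (100/200/300)."""

    def __init__(self, cutoffs: dict[str, dict[int, float]]):
        self.cutoffs = {
            probe: {int(k): float(v) for k, v in brackets.items()}
            for probe, brackets in cutoffs.items()
        }

    def cutoff_for(self, probe_pattern: str, scored: int) -> float:
        if probe_pattern not in self.cutoffs:
            raise KeyError(f"no cutoffs for probe pattern {probe_pattern!r}")
        brackets = self.cutoffs[probe_pattern]
        if scored not in brackets:
            nearest = min(brackets, key=lambda b: (abs(b - scored), b))
            log.info("scored=%d not a cutoff bracket; using nearest bracket %d",
                     scored, nearest)
            return brackets[nearest]
        return brackets[scored]

    @classmethod
    def from_json(cls, path) -> "CutoffTable":
        with open(path) as fh:
            return cls(json.load(fh))


def load_default_cutoffs() -> CutoffTable:
    """Cutoff table shipped with the package (clinical probe panel)."""
    text = resources.files("hemaseq.data").joinpath("fish_cutoffs.json").read_text()
    return CutoffTable(json.loads(text))


def apply_cutoff(percent: float, probe_pattern: str, scored: int,
                 cutoffs: CutoffTable) -> str:
    """``"positive"`` iff percent >= the probe's cutoff at this bracket."""
    cut = cutoffs.cutoff_for(probe_pattern, scored)
    return "positive" if percent >= cut else "below_cutoff"
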