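"""Packaged worked-example case: a marrow with concurrent AML and myeloma.

These fixtures encode the published clinical laboratory values of a single
case followed over four serial bone-marrow specimens — karyotype strings,
FISH cell tallies with their printed percentages, the bulk targeted-
sequencing VAF table, and the aberration-group character matrix of the
sorted cell populations — so that every reporting stage of the package can
run end-to-end on real printed numbers without external downloads.

Sequencing depths for the VAF table and genomic coordinates of the variants
are NOT published; the ones here are synthetic stand-ins constructed to be
consistent with the printed VAF percentages (see ``case_variants``).

A few printed cells are internally inconsistent with their own counts
(direct computation gives a different rounded value); those carry
``divergent=True`` and the printed value is kept for reference only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cytogenetics import FishTally
from .lineage import CharacterMatrix
from .variants import SpecimenObservation, VariantRecord

__all__ = [
    "SPECIMEN_DAYS", "KARYOTYPES", "case_fish_tallies", "case_variants",
    "case_character_matrix", "CHARACTER_MEMBERS",
]

#: days after initial diagnosis, per specimen
SPECIMEN_DAYS = {"specimen1": 0, "specimen2": 42, "specimen3": 142, "specimen4": 364}

#: diagnostic ISCN karyotype strings of the four serial specimens
KARYOTYPES = {
    "specimen1": "47,XX,+8,del(20)(q11.2)[7]/48,idem,+19[8]/46,XX[9]",
    "specimen2": ("47,XX,+8,del(20)(q11.2)[1]/48,idem,+19[9]/"
                  "55–57,XX,+3,+5,+6,+7,+9,+9,+11,?del(11)(q14q23)x2,"
                  "+15,+18,+19,+21 [cp3]/46,XX[7]"),
    "specimen3": "47,XX,+8,del(20)(q11.2)[1]/48,idem,+19[3]/46,XX[17]",
    "specimen4": "47,XX,+8,del(20)(q11.2)[1]/48,sl,+19[6]/94,slx2[1]/46,XX[12]",
}


@dataclass(frozen=True)
class PrintedCell:
    """A reported FISH cell: counts, the value as printed, consistency flag."""

    tally: FishTally
    printed_percent: float
    below_cutoff_printed: bool = False
    divergent: bool = False  # printed value disagrees with direct computation


@dataclass(frozen=True)
class PrintedRatio:
    non_pc_positive: int
    pc_positive: int
    printed_ratio: float
    divergent: bool = False


def _cell(probe, pattern, cls, pos, scored, printed, below=False, divergent=False):
    return PrintedCell(FishTally(probe, pattern, cls, pos, scored), printed,
                       below, divergent)


def case_fish_tallies() -> dict[str, dict[str, dict]]:
    """Per specimen, per probe: the reported FISH tallies and ratios.

    Specimen 2 was not tested by FISH and is absent.  Keys under each probe:
    ``"TNC"``, ``"PC"`` (PrintedCell) and optionally ``"ratio"``
    (PrintedRatio, non-PC:PC among TNC positives).
    """
    t = {
        "specimen1": {
            "TCF3 3 copies": {
                "TNC": _cell("TCF3", "3 copies", "TNC", 44, 200, 22.0),
                "PC": _cell("TCF3", "3 copies", "PC", 19, 20, 95.0),
                "ratio": PrintedRatio(21, 23, 0.9),
            },
            "CDKN2A tetrasomy": {
                "TNC": _cell("CDKN2A", "tetrasomy", "TNC", 25, 200, 12.5),
                "PC": _cell("CDKN2A", "tetrasomy", "PC", 20, 20, 100.0),
            },
            "RUNX1 3 copies": {
                "TNC": _cell("RUNX1", "3 copies", "TNC", 23, 200, 11.5),
                "PC": _cell("RUNX1", "3 copies", "PC", 41, 50, 82.0),
            },
            "MLL 3 copies": {
                "TNC": _cell("MLL", "3 copies", "TNC", 16, 200, 8.0),
                "PC": _cell("MLL", "3 copies", "PC", 18, 20, 90.0),
            },
            "PML 3 copies": {
                "TNC": _cell("PML", "3 copies", "TNC", 18, 200, 9.0),
                "PC": _cell("PML", "3 copies", "PC", 20, 20, 100.0),
            },
            "CEP8 3 copies": {
                "TNC": _cell("CEP8", "3 copies", "TNC", 40, 200, 20.0),
                "PC": _cell("CEP8", "3 copies", "PC", 0, 20, 0.0),
            },
            "20q deletion": {
                "TNC": _cell("20q", "deletion", "TNC", 41, 200, 20.5),
                "PC": _cell("20q", "deletion", "PC", 0, 20, 0.0),
            },
        },
        "specimen3": {
            "TCF3 3 copies": {
                "TNC": _cell("TCF3", "3 copies", "TNC", 23, 200, 11.5),
                "PC": _cell("TCF3", "3 copies", "PC", 3, 10, 30.0),
                "ratio": PrintedRatio(20, 3, 7.0, divergent=True),  # direct: 6.7
            },
            "CDKN2A tetrasomy": {
                "TNC": _cell("CDKN2A", "tetrasomy", "TNC", 2, 300, 0.7, below=True),
                "PC": _cell("CDKN2A", "tetrasomy", "PC", 7, 20, 35.0),
            },
            "RUNX1 3 copies": {
                "TNC": _cell("RUNX1", "3 copies", "TNC", 1, 300, 0.3),
                "PC": _cell("RUNX1", "3 copies", "PC", 2, 10, 20.0),
            },
            "MLL 3 copies": {
                "TNC": _cell("MLL", "3 copies", "TNC", 3, 200, 1.5),
                "PC": _cell("MLL", "3 copies", "PC", 3, 10, 30.0),
            },
            "PML 3 copies": {
                "TNC": _cell("PML", "3 copies", "TNC", 2, 300, 0.7),
                "PC": _cell("PML", "3 copies", "PC", 2, 10, 20.0),
            },
            "CEP8 3 copies": {
                "TNC": _cell("CEP8", "3 copies", "TNC", 24, 200, 12.0),
                "PC": _cell("CEP8", "3 copies", "PC", 0, 20, 0.0),
            },
            "20q deletion": {
                "TNC": _cell("20q", "deletion", "TNC", 30, 200, 15.0),
                "PC": _cell("20q", "deletion", "PC", 0, 20, 0.0),
            },
        },
        "specimen4": {
            "TCF3 3 copies": {
                "TNC": _cell("TCF3", "3 copies", "TNC", 40, 200, 20.0),
                "PC": _cell("TCF3", "3 copies", "PC", 3, 10, 30.0),
                "ratio": PrintedRatio(37, 3, 12.0, divergent=True),  # direct: 12.3
            },
            "CDKN2A tetrasomy": {
                "TNC": _cell("CDKN2A", "tetrasomy", "TNC", 2, 300, 0.7, below=True),
                "PC": _cell("CDKN2A", "tetrasomy", "PC", 0, 20, 0.0),
            },
            "RUNX1 3 copies": {
                "TNC": _cell("RUNX1", "3 copies", "TNC", 2, 300, 0.7),
                "PC": _cell("RUNX1", "3 copies", "PC", 1, 5, 20.0),
            },
            "MLL 3 copies": {
                "TNC": _cell("MLL", "3 copies", "TNC", 2, 300, 0.7),
                "PC": _cell("MLL", "3 copies", "PC", 2, 10, 20.0),
            },
            "PML 3 copies": {
                "TNC": _cell("PML", "3 copies", "TNC", 1, 300, 0.3),
                "PC": _cell("PML", "3 copies", "PC", 2, 7, 28.5, divergent=True),  # direct: 28.6
            },
            "CEP8 3 copies": {
                "TNC": _cell("CEP8", "3 copies", "TNC", 49, 200, 24.5),
                "PC": _cell("CEP8", "3 copies", "PC", 0, 8, 0.0),
            },
            "20q deletion": {
                "TNC": _cell("20q", "deletion", "TNC", 61, 200, 30.5),
                "PC": _cell("20q", "deletion", "PC", 0, 20, 0.0),
            },
        },
    }
    return t


#: published serial VAF percentages per variant (None = not detected)
_VAF_TABLE = [
    ("DDX41", "c.679A>G", (3.6, 4.4, 9.5, 12.4)),
    ("BAX", "c.280C>T", (8.4, 9.5, 8.0, 16.8)),
    ("ATM", "c.1262C>A", (4.7, 2.6, 2.5, None)),
    ("ZNF676", "c.1564G>T", (4.2, None, None, None)),
    ("PRPF3", "c.11C>A", (1.2, None, None, None)),
    ("GPC3", "c.352G>T", (2.2, None, None, 1.7)),
    ("GPC3", "c.355G>T", (1.9, None, None, None)),
    ("KMT2C", "c.2576G>T", (13.2, None, None, None)),
    ("KDR", "c.409T>G", (2.2, None, None, None)),
]


def case_variants(total_depth: int = 1000) -> list[VariantRecord]:
    """The serial-specimen somatic variant table.

    Only the VAF percentages are published; ``total_depth`` (default 1000x,
    a typical on-target panel depth at which every printed one-decimal VAF
    is exactly representable) and the genomic coordinates are
    synthetic stand-ins, with alt depths derived from the printed VAFs.
    Undetected timepoints carry no observation.
    """
    specimens = list(SPECIMEN_DAYS)
    out = []
    for i, (gene, cdna, vafs) in enumerate(_VAF_TABLE):
        observations = {}
        for spec, vaf in zip(specimens, vafs):
            if vaf is None:
                continue
            alt = round(vaf / 100 * total_depth)
            observations[spec] = SpecimenObservation(total_depth, alt, alt / total_depth)
        out.append(VariantRecord(
            gene=gene, cdna=cdna,
            chrom="chr1", pos=1_000_000 + 1000 * i,  # synthetic placeholder loci
            ref="A", alt="G",
            consequence="missense", maf=0.0,
            observations=observations,
        ))
    return out


#: aberration-group membership of the copy-number (A-I) and SNV (1-3) characters
CHARACTER_MEMBERS = {
    "A": ["polysomy 3", "polysomy 15", "polysomy 19"],
    "B": ["polysomy 5", "polysomy 6", "polysomy 7", "polysomy 9", "polysomy 11",
          "polysomy 18", "polysomy 21", "11q loss", "TP53 loss"],
    "C": ["loss of 2"],
    "D": ["4q loss", "X loss"],
    "E": ["polysomy 8", "20q loss"],
    "F": ["polysomy 6"],
    "G": ["polysomy 16", "loss of 10"],
    "H": ["polysomy 21"],
    "I": ["polysomy 11", "polysomy 15", "polysomy 19", "loss of 4"],
    "1": ["ZNF676 c.1564G>T", "PRPF3 c.11C>A"],
    "2": ["GPC3 c.352G>T", "GPC3 c.355G>T", "KMT2C c.2576G>T", "KDR c.409T>G"],
    "3": ["ATM c.1262C>A"],
}


def case_character_matrix() -> CharacterMatrix:
    """Aberration groups by sorted population for the worked-example case.

    Two neoplastic plasma-cell and two myeloblast subpopulations plus the
    mature lineages; granulocyte rows do not carry character A (whether they
    do is not resolved by the source data — flipping those entries to 1
    keeps the matrix laminar and moves G rootward).
    """
    rows = {
        "nPC_ABC1": ["A", "B", "C", "1"],
        "nPC_ABD2": ["A", "B", "D", "2"],
        "MB_AEF3": ["A", "E", "F", "3"],
        "MB_AE": ["A", "E"],
        "neutrophil": ["G", "H"],
        "eosinophil": ["G"],
        "erythrocyte": ["I"],
        "megakaryocyte": [],
    }
    cell_types = {
        "nPC_ABC1": "PC", "nPC_ABD2": "PC",
        "MB_AEF3": "MB", "MB_AE": "MB",
        "neutrophil": "neutrophil", "eosinophil": "eosinophil",
        "erythrocyte": "erythrocyte", "megakaryocyte": "megakaryocyte",
    }
    chars = list(CHARACTER_MEMBERS)
    df = pd.DataFrame(
        [[1 if c in carried else 0 for c in chars] for carried in rows.values()],
        index=list(rows), columns=chars,
    )
    return CharacterMatrix(matrix=df, cell_types=cell_types,
                           members={k: list(v) for k, v in CHARACTER_MEMBERS.items()})
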