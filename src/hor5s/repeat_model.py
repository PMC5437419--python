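"""Domain model of the 5S rDNA repeat unit and its reference sequences.

A 5S unit is a conserved 120-bp genic region (carrying the internal RNA
polymerase III promoter: Box-A, IE, Box-C) followed by a variable intergenic
spacer (IGS/NTS). Spacers fall into three length classes — short (95–116 bp),
long (321–340 bp) and ultralong (1153–1209 bp) — and carry a tetranucleotide
multi-nucleotide polymorphism (MNP) whose two prominent states are the "T"
(TCCT) and "A" (AGGA) variants.

The reference sequences bundled here are *synthetic*: deterministic stand-ins
with the documented structural properties (one CCGG site per monomer, the MNP
core at unit position 152–155, unique 10-nt motif queries), built for
simulation and testing rather than copied from any sequencing archive.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import edlib

from .errors import EmptyInput, InvalidArgument, NoGenicRegion

GENIC_LEN = 120

# ---------------------------------------------------------------------------
# Frozen synthetic reference sequences (see module docstring).
# ---------------------------------------------------------------------------

DEFAULT_GENIC = (
    "AGTACCGTGAGCGAACAGGTCGGTGGCTAGATTGCGTCGCATCCATGGTCACCCCAGCCG"
    "CCGGTAAATCTAAAATAGCAATATCAGCCGATAAGGAATCCCAATACTGAAGCTCAAGTG"
)

# Neutral short spacer; positions 32..36 are replaced by the variant core.
_SPACER_S_NEUTRAL = (
    "TCTTGGATGAGCTCTATTAAGGCCCGCGTACGTGCCCACCAGGGCCCATGATTTTTCCGT"
    "ACAACGTATGCGGGGCTGAATAAAAGAAGGCTCCCCGCAG"
)

_FILLER_L = (
    "AGAGTTCCGTCGGTACTTCCTTTGCAATGTAAAATACGTACCTGAGGACAAAGACCTAGA"
    "CTCGTGAGTGACGTAGCATATCCAGGACAGCTCCTCGCGCGACCGACGGTCGTTGCATCA"
    "GGGTAGCTAGCTCCAGCTAAAAACAGGCACTAATTCGTTTCTCGAAGTGAGTCTGCGGTT"
    "TCGTTAAGTAACGAATCCCCTTTTATGGGGCGCGTAATTCAATCTAGTAG"
)

_FILLER_UL = (
    "ATGGGCTGCTTGTTTACTTGAATCCGATGATACAATTTCCCAGTGCTGGGACCACAGCAG"
    "TCTACATTAGATGTCAAAGTAAGTCGGGCAAATAGACAGCGACGCGAGTTGTAGAATGCG"
    "GTCGTCTTTCTCTACTTCCGCTTGACGCCGTACGGCACCTAGAGGTAATCTAAAACCCAC"
    "GACAGGGGATGCTGTGGTGATAAATCAAATAGTAGGAGCCCGTGGTAGTCACAGTTCTGA"
    "TAGTTATAAACAGAAGCTGTCAAGTTCGAATTCACAAACGTTTACCCAATCTGAGGCGAT"
    "CTTAAACTGCGCGCACGTATTCGTTCCCAGACTAACGCTGACGCAACCGCACACATAACG"
    "GAATTATAGCCCTTTCTTCTTTCGCCTGCTAGCGAGGGACTCCATCGCAGTACAGCTCCG"
    "CTCAGTCCTGATGATTGGCGGCATGAACATACTAGAAGGTGAGGCAAACGTAATTAGCTA"
    "TGGTGAATGTTGAATGTCAGGGGGTATCCACTCCCAACTGGAGTCCTATTTTACAGCGAA"
    "CGTATGCTGCATCCTTCATGAATCCGTTGGACGTCGCGTCACTTTCTTGAAATGAGCACA"
    "GAACGACCGAAGGCAGAGGACTATACCACTGTCAGTAGTGACACACGGCGAGAAATGCAA"
    "CCAGAGTAGTAGTCGCCAACGCTTTCATTCTCTCAAGTATGTAGGTAATATCAGAATTGG"
    "GGCTAGTGAATGAATCGTAAAGGAAAGGCGAGCTGCTCCTCTCTCCGATGTATTCGGGTC"
    "AGCAAGACCAATCCCCTGCATGCTAATTGGCGACGTCAGTTAGGGTCTAGTCCTGAGCAA"
    "AGTAGTTAGAACCTCCTTAAAGGAATAGGAGTGTCAGCGAGCAGCGAGCATATGTGTGCA"
    "ACGCATCCAGGCAATGACCCTACTCCGACTGCAGGATGCGAACTTAAGCTTCCAGCACAA"
    "GGGCCCTATGCCGCGGGATTCATCGTACAATGGTCCAATCACCACTTAAGTTCGAACCTT"
    "AGAGTCGGCATGTATACCCTTAAGAAACCGACCAACAGAGTGTGACGCTAAAAGTTAACC"
)

MNP_OFFSET = 32           # offset of the 4-nt core within the spacer
MNP_CORE = {"T": "TCCT", "A": "AGGA"}
QUERY_FLANK = 3           # the 10-nt motif query is core +/- 3 nt
RDNA18S_FRAGMENT_LEN = 1581

# Canonical tripartite Pol III internal promoter layout (0-based, half-open,
# within the genic region).
DEFAULT_PROMOTER_BOXES = {"Box-A": (50, 64), "IE": (67, 72), "Box-C": (80, 97)}


class MotifVariant(str, Enum):
    T = "T"
    A = "A"
    OTHER = "other"


class SpacerClass(str, Enum):
    S = "S"
    L = "L"
    UL = "UL"
    OTHER = "other"


@dataclass(frozen=True)
class SpacerClassRanges:
    """Closed length intervals for the three IGS length classes."""

    short: tuple[int, int] = (95, 116)
    long: tuple[int, int] = (321, 340)
    ultralong: tuple[int, int] = (1153, 1209)

    def __post_init__(self):
        ivs = [self.short, self.long, self.ultralong]
        for lo, hi in ivs:
            if lo > hi:
                raise InvalidArgument(f"degenerate interval [{lo},{hi}]")
        if not (self.short[1] < self.long[0] and self.long[1] < self.ultralong[0]):
            raise InvalidArgument("spacer class intervals must be disjoint and ordered")

    def classify(self, length: int) -> SpacerClass:
        if length < 0:
            raise InvalidArgument("spacer length must be non-negative")
        if self.short[0] <= length <= self.short[1]:
            return SpacerClass.S
        if self.long[0] <= length <= self.long[1]:
            return SpacerClass.L
        if self.ultralong[0] <= length <= self.ultralong[1]:
            return SpacerClass.UL
        return SpacerClass.OTHER


def motif_variant_of(spacer: str, mnp_offset: int = MNP_OFFSET) -> MotifVariant:
    core = spacer[mnp_offset:mnp_offset + 4]
    if core == MNP_CORE["T"]:
        return MotifVariant.T
    if core == MNP_CORE["A"]:
        return MotifVariant.A
    return MotifVariant.OTHER


@dataclass(frozen=True)
class UnitTemplate:
    """One 5S repeat unit: 120-nt genic region plus an intergenic spacer."""

    genic: str
    spacer: str
    motif_variant: MotifVariant
    spacer_class: SpacerClass
    mnp_offset: int = MNP_OFFSET

    def __post_init__(self):
        if len(self.genic) != GENIC_LEN:
            raise InvalidArgument(f"genic region must be {GENIC_LEN} nt, got {len(self.genic)}")
        if motif_variant_of(self.spacer, self.mnp_offset) != self.motif_variant:
            raise InvalidArgument("motif_variant inconsistent with spacer core")

    @classmethod
    def from_parts(
        cls,
        genic: str,
        spacer: str,
        mnp_offset: int = MNP_OFFSET,
        ranges: SpacerClassRanges | None = None,
    ) -> "UnitTemplate":
        ranges = ranges or SpacerClassRanges()
        return cls(
            genic=genic,
            spacer=spacer,
            motif_variant=motif_variant_of(spacer, mnp_offset),
            spacer_class=ranges.classify(len(spacer)),
            mnp_offset=mnp_offset,
        )

    @property
    def sequence(self) -> str:
        return self.genic + self.spacer

    def __len__(self) -> int:
        return len(self.genic) + len(self.spacer)


def default_spacer(variant: str = "T", spacer_class: str = "S") -> str:
    """Synthetic spacer of the requested variant ('T'/'A') and class (S/L/UL)."""
    core = MNP_CORE[variant]
    sp = _SPACER_S_NEUTRAL[:MNP_OFFSET] + core + _SPACER_S_NEUTRAL[MNP_OFFSET + 4:]
    if spacer_class == "S":
        return sp
    if spacer_class == "L":
        return sp[:60] + _FILLER_L + sp[60:]
    if spacer_class == "UL":
        return sp[:60] + _FILLER_UL + sp[60:]
    raise InvalidArgument(f"unknown spacer class {spacer_class!r}")


def default_unit_library() -> dict[str, UnitTemplate]:
    """Template library covering both MNP variants and all length classes."""
    lib = {}
    for variant in ("T", "A"):
        for klass in ("S", "L", "UL"):
            lib[f"{klass}_{variant}"] = UnitTemplate.from_parts(
                DEFAULT_GENIC, default_spacer(variant, klass)
            )
    return lib


@dataclass(frozen=True)
class RegionAnnotation:
    """Genic/spacer partition of a monomer plus promoter box coordinates."""

    genic_interval: tuple[int, int]
    spacer_interval: tuple[int, int]
    promoter_boxes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PROMOTER_BOXES)
    )

    def region_of(self, position: int, monomer_len: int) -> str:
        """'genic' or 'spacer' for a 0-based monomer position."""
        g0, g1 = self.genic_interval
        p = position % monomer_len
        if g0 <= g1:
            return "genic" if g0 <= p < g1 else "spacer"
        return "genic" if (p >= g0 or p < g1) else "spacer"


@dataclass(frozen=True)
class ReferenceSet:
    """The reference bundle every pipeline stage shares."""

    genic_consensus: str
    monomer: str
    motif_queries: dict[str, str]
    mnp_offset: int = MNP_OFFSET
    spacer_ranges: SpacerClassRanges = field(default_factory=SpacerClassRanges)
    rdna18s_fragment_len: int = RDNA18S_FRAGMENT_LEN
    annotation: RegionAnnotation | None = None

    def __post_init__(self):
        for name, q in self.motif_queries.items():
            if len(q) != 10:
                raise InvalidArgument(f"motif query {name!r} must be 10 nt, got {len(q)}")

    @property
    def monomer_len(self) -> int:
        return len(self.monomer)

    # -- serialization: FASTA (sequences) + JSON (everything scalar) --------

    def write(self, fasta_path: str | Path, config_path: str | Path) -> None:
        fasta_path, config_path = Path(fasta_path), Path(config_path)
        with open(fasta_path, "w") as fh:
            fh.write(f">genic_consensus\n{self.genic_consensus}\n")
            fh.write(f">monomer\n{self.monomer}\n")
        cfg = {
            "motif_queries": self.motif_queries,
            "mnp_offset": self.mnp_offset,
            "spacer_ranges": {
                "short": list(self.spacer_ranges.short),
                "long": list(self.spacer_ranges.long),
                "ultralong": list(self.spacer_ranges.ultralong),
            },
            "rdna18s_fragment_len": self.rdna18s_fragment_len,
            "annotation": None
            if self.annotation is None
            else {
                "genic_interval": list(self.annotation.genic_interval),
                "spacer_interval": list(self.annotation.spacer_interval),
                "promoter_boxes": {k: list(v) for k, v in self.annotation.promoter_boxes.items()},
            },
        }
        config_path.write_text(json.dumps(cfg, indent=1))

    @classmethod
    def read(cls, fasta_path: str | Path, config_path: str | Path) -> "ReferenceSet":
        from Bio import SeqIO

        records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
        cfg = json.loads(Path(config_path).read_text())
        ann = None
        if cfg.get("annotation"):
            a = cfg["annotation"]
            ann = RegionAnnotation(
                genic_interval=tuple(a["genic_interval"]),
                spacer_interval=tuple(a["spacer_interval"]),
                promoter_boxes={k: tuple(v) for k, v in a["promoter_boxes"].items()},
            )
        sr = cfg["spacer_ranges"]
        return cls(
            genic_consensus=records["genic_consensus"],
            monomer=records["monomer"],
            motif_queries=dict(cfg["motif_queries"]),
            mnp_offset=int(cfg["mnp_offset"]),
            spacer_ranges=SpacerClassRanges(
                tuple(sr["short"]), tuple(sr["long"]), tuple(sr["ultralong"])
            ),
            rdna18s_fragment_len=int(cfg["rdna18s_fragment_len"]),
            annotation=ann,
        )


def default_reference() -> ReferenceSet:
    """The bundled synthetic reference: genic consensus + short-T monomer."""
    spacer = default_spacer("T", "S")
    queries = {
        v: default_spacer(v, "S")[MNP_OFFSET - QUERY_FLANK:MNP_OFFSET + 4 + QUERY_FLANK]
        for v in ("T", "A")
    }
    return ReferenceSet(
        genic_consensus=DEFAULT_GENIC,
        monomer=DEFAULT_GENIC + spacer,
        motif_queries=queries,
        annotation=RegionAnnotation(
            genic_interval=(0, GENIC_LEN),
            spacer_interval=(GENIC_LEN, GENIC_LEN + len(spacer)),
        ),
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def build_consensus(columns) -> str:
    """Majority-rule consensus from a per-position base-count table.

    ``columns`` is a sequence of mappings base -> count. Ties are broken by
    fixed alphabetical order (A < C < G < T), so the call is deterministic.
    """
    cols = list(columns)
    if not cols:
        raise EmptyInput("consensus of an empty column table")
    out = []
    for i, col in enumerate(cols):
        if not col or sum(col.values()) < 1:
            raise EmptyInput(f"column {i} has no counts")
        best = max(sorted(col), key=lambda b: col[b])
        out.append(best)
    return "".join(out)


def annotate_unit(
    monomer: str,
    genic_consensus: str,
    min_identity: float = 0.8,
    promoter_boxes: dict[str, tuple[int, int]] | None = None,
) -> RegionAnnotation:
    """Locate the genic region inside a (possibly rotated) monomer.

    The monomer is treated as circular: the consensus is aligned against the
    doubled sequence and the winning interval is reported modulo its length,
    so the genic interval may wrap.
    """
    L = len(monomer)
    if L < len(genic_consensus):
        raise InvalidArgument("monomer shorter than the genic consensus")
    doubled = monomer + monomer
    res = edlib.align(genic_consensus, doubled, mode="HW", task="locations")
    dist = res["editDistance"]
    if dist < 0 or 1.0 - dist / len(genic_consensus) < min_identity:
        raise NoGenicRegion(
            f"best genic placement identity below {min_identity:.2f}"
        )
    # leftmost best location; edlib end positions are inclusive
    start, end = min(res["locations"])
    span = end + 1 - start
    g0 = start % L
    g1 = (start + span) % L
    if g1 == 0:
        g1 = L
    genic_iv = (g0, g1)  # g1 < g0 marks a wrapped (circular) interval
    spacer_iv = (g1 % L, g0)
    return RegionAnnotation(
        genic_interval=genic_iv,
        spacer_interval=spacer_iv,
        promoter_boxes=dict(promoter_boxes or DEFAULT_PROMOTER_BOXES),
    )


def extract_interval(seq: str, interval: tuple[int, int]) -> str:
    """Extract a possibly wrapping (circular) interval from ``seq``."""
    a, b = interval
    if a <= b:
        return seq[a:b]
    return seq[a:] + seq[:b]
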