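"""Synthetic inputs for every pipeline stage.

Emulates the study conditions without any sequencing archive: unit libraries
with two spacer-motif variants (TCCT "T" / AGGA "A") and three spacer length
classes; long reads (10–30 kb) assembled from the four higher-order
architectural groups (pure tandem, tandem + unique DNA, inverted blocks,
dispersed copies); short-read sets drawn from a genome with a planted rDNA
genome proportion; single-pass long-read noise (~13 %/base, indel-dominated);
and methylation-aware in-silico CCGG digestion.

Truth tables carry exact unit coordinates *on the emitted read*: when an error
model is applied, truth intervals are remapped through the edit log, so they
stay exact coordinates of the corrupted unit copies.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _seq
from .errors import EmptyInput, InvalidArgument
from .fastx import FastqRecord
from .repeat_model import (
    MotifVariant,
    SpacerClass,
    UnitTemplate,
    default_unit_library,
)

GROUPS = ("I", "II", "III", "IV")

# Default architectural mixture: Table-2-style read proportions.
DEFAULT_GROUP_WEIGHTS = {"I": 95 / 286, "II": 72 / 286, "III": 11 / 286, "IV": 108 / 286}

# Spacer-class and motif-variant frequencies used when drawing homogeneous
# blocks (short 94 %, long 5 %, ultralong 1 %; "T" 83 %, "A" 17 %).
DEFAULT_CLASS_WEIGHTS = {"S": 0.94, "L": 0.05, "UL": 0.01}
DEFAULT_VARIANT_WEIGHTS = {"T": 0.83, "A": 0.17}

DEFAULT_READ_QUALITY = 11  # nominal single-pass Phred


# ---------------------------------------------------------------------------
# Error model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErrorModel:
    """Per-base i.i.d. substitution/insertion/deletion noise.

    The default split realises the ~13 % single-pass error rate as
    1 % substitutions, 8 % insertions and 4 % deletions (indel-dominated,
    long-read-like).
    """

    substitution_rate: float = 0.01
    insertion_rate: float = 0.08
    deletion_rate: float = 0.04
    seed: int = 0

    def __post_init__(self):
        rates = (self.substitution_rate, self.insertion_rate, self.deletion_rate)
        if any(r < 0 or r >= 1 for r in rates):
            raise InvalidArgument("error rates must lie in [0, 1)")
        if sum(rates) >= 1:
            raise InvalidArgument("summed error rates must be < 1")

    @property
    def total_rate(self) -> float:
        return self.substitution_rate + self.insertion_rate + self.deletion_rate


ERROR_FREE = ErrorModel(0.0, 0.0, 0.0)


def corrupt(seq: str, model: ErrorModel, rng: np.random.Generator | None = None):
    """Apply the error model; returns (noisy sequence, edit log).

    Edit-log entries, in clean-sequence order:
      ("sub", i, new_base) — base at clean position i replaced
      ("del", i)           — base at clean position i deleted
      ("ins", i, base)     — base inserted after clean position i
    Replaying the log with :func:`apply_edits` reconstructs the noisy
    sequence byte-for-byte.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    n = len(seq)
    if n == 0 or model.total_rate == 0.0:
        return seq, []
    codes = _seq.encode(seq).astype(np.int8)
    u = rng.random(n)
    dele = u < model.deletion_rate
    sub = (~dele) & (u < model.deletion_rate + model.substitution_rate)
    ins = rng.random(n) < model.insertion_rate
    new_codes = ((codes + rng.integers(1, 4, size=n)) % 4).astype(np.int8)
    ins_codes = rng.integers(0, 4, size=n).astype(np.int8)

    out_codes = np.where(sub, new_codes, codes)
    keep = ~dele
    lengths = keep.astype(np.int64) + ins.astype(np.int64)
    starts = np.concatenate(([0], np.cumsum(lengths)))
    total = int(starts[-1])
    out = np.empty(total, dtype=np.int8)
    out[starts[:-1][keep]] = out_codes[keep]
    out[(starts[:-1] + keep.astype(np.int64))[ins]] = ins_codes[ins]

    log: list[tuple] = []
    bases = "ACGT"
    events = np.nonzero(dele | sub | ins)[0]
    for i in events:
        if dele[i]:
            log.append(("del", int(i)))
        elif sub[i]:
            log.append(("sub", int(i), bases[new_codes[i]]))
        if ins[i]:
            log.append(("ins", int(i), bases[ins_codes[i]]))
    return _seq.decode(out), log


def apply_edits(clean: str, log: list[tuple]) -> str:
    """Replay a corrupt() edit log against the clean sequence."""
    sub: dict[int, str] = {}
    dele: set[int] = set()
    ins: dict[int, str] = {}
    for entry in log:
        op, i = entry[0], entry[1]
        if op == "sub":
            sub[i] = entry[2]
        elif op == "del":
            dele.add(i)
        elif op == "ins":
            ins[i] = ins.get(i, "") + entry[2]
        else:
            raise InvalidArgument(f"unknown edit op {op!r}")
    out = []
    for i, b in enumerate(clean):
        if i not in dele:
            out.append(sub.get(i, b))
        if i in ins:
            out.append(ins[i])
    return "".join(out)


def coordinate_map(clean_len: int, log: list[tuple]) -> np.ndarray:
    """Map clean positions -> noisy positions (length clean_len + 1).

    ``cmap[i]`` is the noisy-coordinate offset at which clean position i
    lands; ``cmap[clean_len]`` is the noisy length, so a clean interval
    (a, b) maps to (cmap[a], cmap[b]).
    """
    lengths = np.ones(clean_len, dtype=np.int64)
    for entry in log:
        op, i = entry[0], entry[1]
        if op == "del":
            lengths[i] -= 1
        elif op == "ins":
            lengths[i] += len(entry[2])
    return np.concatenate(([0], np.cumsum(lengths)))


# ---------------------------------------------------------------------------
# Array construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockSpec:
    """One building block of a long read."""

    kind: str  # "tandem" | "unique" | "dispersed_copy"
    n_units: int = 1
    orientation: str = "+"
    unit_mixture: dict[str, float] | None = None  # template-id -> weight
    linker_len: int = 0  # unique blocks only

    def __post_init__(self):
        if self.kind not in ("tandem", "unique", "dispersed_copy"):
            raise InvalidArgument(f"unknown block kind {self.kind!r}")
        if self.kind != "unique" and self.n_units < 1:
            raise InvalidArgument("tandem blocks need n_units >= 1")
        if self.orientation not in "+-":
            raise InvalidArgument("orientation must be '+' or '-'")
        if self.unit_mixture is not None:
            tot = sum(self.unit_mixture.values())
            if abs(tot - 1.0) > 1e-9:
                raise InvalidArgument("unit_mixture weights must sum to 1")


@dataclass(frozen=True)
class ArraySpec:
    blocks: tuple[BlockSpec, ...]
    read_quality: int = DEFAULT_READ_QUALITY

    def __post_init__(self):
        if not self.blocks:
            raise EmptyInput("ArraySpec needs at least one block")


@dataclass(frozen=True)
class UnitRecord:
    start: int
    end: int
    strand: str
    template_id: str
    motif_variant: MotifVariant
    spacer_class: SpacerClass


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    group_label: str
    unit_records: tuple[UnitRecord, ...]


def _pick(rng: np.random.Generator, weights: dict[str, float]) -> str:
    keys = sorted(weights)
    probs = np.array([weights[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def build_array(
    spec: ArraySpec,
    library: dict[str, UnitTemplate] | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[str, ReadTruth]:
    """Realize an ArraySpec into a clean sequence plus exact unit truth."""
    library = library if library is not None else default_unit_library()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for b in spec.blocks:
        if b.kind != "unique" and b.unit_mixture:
            missing = set(b.unit_mixture) - set(library)
            if missing:
                raise InvalidArgument(f"unknown template ids {sorted(missing)}")
    parts: list[str] = []
    units: list[UnitRecord] = []
    offset = 0
    for b in spec.blocks:
        if b.kind == "unique":
            parts.append(_seq.random_dna(rng, b.linker_len))
            offset += b.linker_len
            continue
        mixture = b.unit_mixture or {sorted(library)[0]: 1.0}
        chunk_parts: list[str] = []
        local: list[tuple[int, int, str]] = []  # (start, end, template_id) fwd coords
        pos = 0
        for _ in range(b.n_units):
            tid = _pick(rng, mixture)
            useq = library[tid].sequence
            chunk_parts.append(useq)
            local.append((pos, pos + len(useq), tid))
            pos += len(useq)
        chunk = "".join(chunk_parts)
        if b.orientation == "-":
            chunk = _seq.revcomp(chunk)
            local = [(pos - e, pos - s, tid) for (s, e, tid) in reversed(local)]
        for s, e, tid in local:
            t = library[tid]
            units.append(
                UnitRecord(
                    start=offset + s,
                    end=offset + e,
                    strand=b.orientation,
                    template_id=tid,
                    motif_variant=t.motif_variant,
                    spacer_class=t.spacer_class,
                )
            )
        parts.append(chunk)
        offset += pos
    seq = "".join(parts)
    truth = ReadTruth(
        read_id="",
        group_label=derive_group_label(spec, library),
        unit_records=tuple(sorted(units, key=lambda u: u.start)),
    )
    return seq, truth


def derive_group_label(
    spec: ArraySpec,
    library: dict[str, UnitTemplate] | None = None,
    long_min_units: int = 5,
    unique_min: int = 500,
    cover_min: float = 0.9,
) -> str:
    """Structural group implied by an ArraySpec, mirroring classify_read.

    Group III: >= 2 long (>= 5-unit) blocks of opposite orientation;
    Group I:   long blocks cover >= cover_min of the read and no unique
               stretch reaches unique_min;
    Group II:  at least one long block otherwise;
    Group IV:  no long block at all.
    """
    library = library if library is not None else default_unit_library()

    def block_len(b: BlockSpec) -> int:
        if b.kind == "unique":
            return b.linker_len
        mixture = b.unit_mixture or {sorted(library)[0]: 1.0}
        mean_unit = sum(w * len(library[t]) for t, w in mixture.items())
        return int(round(b.n_units * mean_unit))

    total = sum(block_len(b) for b in spec.blocks)
    long_blocks = [b for b in spec.blocks if b.kind != "unique" and b.n_units >= long_min_units]
    orientations = {b.orientation for b in long_blocks}
    if len(long_blocks) >= 2 and orientations == {"+", "-"}:
        return "III"
    if not long_blocks:
        return "IV"
    unique_runs = [b.linker_len for b in spec.blocks if b.kind == "unique"]
    covered = sum(block_len(b) for b in long_blocks)
    if all(r < unique_min for r in unique_runs) and total > 0 and covered / total >= cover_min:
        return "I"
    return "II"


# ---------------------------------------------------------------------------
# Random ArraySpecs per architectural group
# ---------------------------------------------------------------------------


def _draw_template(rng: np.random.Generator,
                   class_weights=None, variant_weights=None) -> str:
    klass = _pick(rng, class_weights or DEFAULT_CLASS_WEIGHTS)
    variant = _pick(rng, variant_weights or DEFAULT_VARIANT_WEIGHTS)
    return f"{klass}_{variant}"


def random_array_spec(
    group: str,
    target_len: int,
    rng: np.random.Generator,
    library: dict[str, UnitTemplate] | None = None,
    class_weights: dict[str, float] | None = None,
    variant_weights: dict[str, float] | None = None,
) -> ArraySpec:
    """Draw an ArraySpec of the requested group with ~target_len total bases."""
    library = library if library is not None else default_unit_library()
    if group not in GROUPS:
        raise InvalidArgument(f"unknown group {group!r}")

    def tandem(n_units: int, orientation: str = "+") -> BlockSpec:
        tid = _draw_template(rng, class_weights, variant_weights)
        return BlockSpec("tandem", n_units=max(1, n_units), orientation=orientation,
                         unit_mixture={tid: 1.0})

    def unit_len_of(b: BlockSpec) -> int:
        tid = next(iter(b.unit_mixture))
        return len(library[tid])

    if group == "I":
        b = tandem(1)
        n = max(5, int(round(target_len / unit_len_of(b))))
        return ArraySpec((replace(b, n_units=n),))

    if group == "II":
        linker = int(rng.integers(2000, 4001))
        rest = max(0, target_len - linker)
        b1, b2 = tandem(1), tandem(1)
        n1 = max(5, int(round(rest / 2 / unit_len_of(b1))))
        n2 = max(5, int(round(rest / 2 / unit_len_of(b2))))
        return ArraySpec((
            replace(b1, n_units=n1),
            BlockSpec("unique", linker_len=linker),
            replace(b2, n_units=n2),
        ))

    if group == "III":
        linker = 0 if rng.random() < 0.5 else int(rng.integers(200, 1800))
        rest = max(0, target_len - linker)
        b1, b2 = tandem(1, "+"), tandem(1, "-")
        n1 = max(5, int(round(rest / 2 / unit_len_of(b1))))
        n2 = max(5, int(round(rest / 2 / unit_len_of(b2))))
        blocks = [replace(b1, n_units=n1)]
        if linker:
            blocks.append(BlockSpec("unique", linker_len=linker))
        blocks.append(replace(b2, n_units=n2))
        return ArraySpec(tuple(blocks))

    # Group IV: dispersed single copies or <5-unit tandems in unique DNA.
    blocks: list[BlockSpec] = []
    length = 0
    blocks.append(BlockSpec("unique", linker_len=int(rng.integers(1500, 4000))))
    length += blocks[-1].linker_len
    while length < target_len:
        n = int(rng.integers(1, 5))  # < 5 units by construction
        tid = _draw_template(rng, class_weights, variant_weights)
        orientation = "+" if rng.random() < 0.5 else "-"
        b = BlockSpec("dispersed_copy", n_units=n, orientation=orientation,
                      unit_mixture={tid: 1.0})
        blocks.append(b)
        length += n * len(library[tid])
        linker = int(rng.integers(2000, 5000))
        blocks.append(BlockSpec("unique", linker_len=linker))
        length += linker
    return ArraySpec(tuple(blocks))


# ---------------------------------------------------------------------------
# Read-set simulators
# ---------------------------------------------------------------------------


def largest_remainder(weights: dict[str, float], n: int) -> dict[str, int]:
    """Apportion n items to keys by largest-remainder rounding."""
    keys = sorted(weights)
    total_w = sum(weights[k] for k in keys)
    quotas = {k: n * weights[k] / total_w for k in keys}
    counts = {k: int(np.floor(quotas[k])) for k in keys}
    short = n - sum(counts.values())
    by_rem = sorted(keys, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def simulate_long_read_set(
    group_weights: dict[str, float] | None = None,
    n_reads: int = 286,
    length_range: tuple[int, int] = (10_000, 30_000),
    model: ErrorModel | None = None,
    seed: int = 0,
    deterministic_counts: bool = False,
    library: dict[str, UnitTemplate] | None = None,
    class_weights: dict[str, float] | None = None,
    variant_weights: dict[str, float] | None = None,
    read_quality: int = DEFAULT_READ_QUALITY,
) -> tuple[list[FastqRecord], list[ReadTruth]]:
    """Simulate a long-read set with per-read architectural ground truth.

    Truth unit intervals are expressed in emitted-read coordinates (exact even
    under the error model, via edit-log remapping).
    """
    if n_reads < 0:
        raise InvalidArgument("n_reads must be non-negative")
    group_weights = group_weights or dict(DEFAULT_GROUP_WEIGHTS)
    if abs(sum(group_weights.values()) - 1.0) > 1e-6:
        raise InvalidArgument("group weights must sum to 1")
    if length_range[0] < 1:
        raise InvalidArgument("length_range lower bound must be >= 1")
    library = library if library is not None else default_unit_library()
    model = model or ERROR_FREE
    rng = np.random.default_rng(seed)

    if deterministic_counts:
        counts = largest_remainder(group_weights, n_reads)
        labels = [g for g in GROUPS for _ in range(counts.get(g, 0))]
    else:
        keys = sorted(group_weights)
        probs = np.array([group_weights[k] for k in keys])
        labels = [keys[i] for i in rng.choice(len(keys), size=n_reads, p=probs / probs.sum())]

    lo, hi = length_range
    # expected length change under the error model (insertions grow, deletions shrink)
    growth = 1.0 + model.insertion_rate - model.deletion_rate
    t_lo = int(lo / growth * 1.03) + 300
    t_hi = max(t_lo + 300, int(hi / growth * 0.97))
    records: list[FastqRecord] = []
    truths: list[ReadTruth] = []
    for ridx, group in enumerate(labels):
        read_id = f"lr{ridx:05d}|{group}"
        target = int(rng.uniform(t_lo, t_hi))
        for _attempt in range(20):
            spec = random_array_spec(group, target, rng, library,
                                     class_weights, variant_weights)
            clean, truth = build_array(spec, library, rng)
            if model.total_rate == 0.0:
                noisy, units = clean, truth.unit_records
            else:
                noisy, log = corrupt(clean, model, rng)
                cmap = coordinate_map(len(clean), log)
                units = tuple(
                    replace(u, start=int(cmap[u.start]), end=int(cmap[u.end]))
                    for u in truth.unit_records
                )
            if lo <= len(noisy) <= hi:
                break
            target = int(target * (1.08 if len(noisy) < lo else 0.92))
        records.append(FastqRecord(read_id, noisy, _seq.phred_to_qual(read_quality, len(noisy))))
        truths.append(ReadTruth(read_id=read_id, group_label=truth.group_label, unit_records=units))
    return records, truths


def simulate_genome_and_short_reads(
    rdna_copies: int,
    unit: UnitTemplate | None = None,
    background_len: int = 1_000_000,
    read_len: int = 100,
    n_reads: int = 10_000,
    seed: int = 0,
    read_quality: int = 40,
) -> tuple[list[FastqRecord], float]:
    """Uniform short reads from background + a planted tandem rDNA compartment.

    Returns (records, planted_GP) where planted_GP = rDNA bases / genome
    bases x 100. Each read id carries its true origin (``|rdna`` when the
    majority of the read lies in the rDNA compartment, else ``|bg``).
    """
    if rdna_copies < 0:
        raise InvalidArgument("rdna_copies must be non-negative")
    if read_len < 90:
        raise InvalidArgument("read_len must be >= 90")
    if background_len < read_len:
        raise InvalidArgument("background must be at least one read long")
    if n_reads < 0:
        raise InvalidArgument("n_reads must be non-negative")
    unit = unit or default_unit_library()["S_T"]
    rng = np.random.default_rng(seed)
    rdna = unit.sequence * rdna_copies
    half = background_len // 2
    genome = (
        _seq.random_dna(rng, half) + rdna + _seq.random_dna(rng, background_len - half)
    )
    G = len(genome)
    planted_gp = 100.0 * len(rdna) / G
    rd_start, rd_end = half, half + len(rdna)

    starts = rng.integers(0, G - read_len + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    qual = _seq.phred_to_qual(read_quality, read_len)
    records = []
    for i in range(n_reads):
        s = int(starts[i])
        frag = genome[s:s + read_len]
        if strands[i]:
            frag = _seq.revcomp(frag)
        overlap = max(0, min(s + read_len, rd_end) - max(s, rd_start))
        origin = "rdna" if overlap * 2 >= read_len else "bg"
        records.append(FastqRecord(f"sr{i:06d}|{origin}", frag, qual))
    return records, planted_gp


# ---------------------------------------------------------------------------
# Methylation-aware in-silico digestion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MethylationMask:
    """Methylated CG positions (index of the C of each CG dinucleotide)."""

    positions: frozenset[int] = frozenset()

    def validate(self, seq: str) -> None:
        for p in self.positions:
            if not (0 <= p < len(seq) - 1) or seq[p:p + 2] != "CG":
                raise InvalidArgument(f"mask position {p} is not a CG site")

    @classmethod
    def fully_methylated(cls, seq: str) -> "MethylationMask":
        return cls(frozenset(i for i in range(len(seq) - 1) if seq[i:i + 2] == "CG"))

    @classmethod
    def unmethylated(cls) -> "MethylationMask":
        return cls(frozenset())


def digest_in_silico(
    seq: str,
    enzyme: str,
    mask: MethylationMask | None = None,
) -> list[int]:
    """Fragment lengths from CCGG digestion (cut C^CGG).

    MspI ignores the mask; HpaII skips sites whose internal CG (second
    position of CCGG) is marked methylated. Fragment lengths always sum to
    the sequence length.
    """
    if enzyme not in ("MspI", "HpaII"):
        raise InvalidArgument(f"unknown enzyme {enzyme!r}")
    mask = mask or MethylationMask.unmethylated()
    mask.validate(seq)
    cuts = []
    pos = seq.find("CCGG")
    while pos != -1:
        internal_cg = pos + 1  # the CG inside CCGG
        if enzyme == "MspI" or internal_cg not in mask.positions:
            cuts.append(pos + 1)  # C^CGG
        pos = seq.find("CCGG", pos + 1)
    bounds = [0] + cuts + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
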