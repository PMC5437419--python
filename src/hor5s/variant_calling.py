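"""Pileup construction, thresholded variant calling, diversity and phasing.

Variant filters follow the high-frequency-SNP convention: minimum coverage
300, minimum supporting count 50, minimum allele frequency 5 %. Adjacent SNVs
whose alternative alleles travel together on reads are merged into a single
multi-nucleotide polymorphism (MNP) — the mechanism behind the TCCT/AGGA
spacer variants. Nucleotide diversity (Pi) is the mean pairwise per-site
difference with pairwise deletion of gap/N columns and no multiple-hit
correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _seq
from .errors import EmptyInput, InvalidArgument, InsufficientData, InvalidPlacement
from .read_mapping import ReadPlacement, _cigar_spans
from .repeat_model import RegionAnnotation


@dataclass(frozen=True)
class VariantThresholds:
    min_coverage: int = 300
    min_count: int = 50
    min_frequency: float = 0.05
    mnp_cooccurrence: float = 0.9

    def __post_init__(self):
        if self.min_count > self.min_coverage:
            raise InvalidArgument("min_count cannot exceed min_coverage")
        if not (0 < self.min_frequency <= 1):
            raise InvalidArgument("min_frequency must lie in (0, 1]")


@dataclass(frozen=True)
class VariantCall:
    position: int          # 0-based on the monomer
    ref_allele: str
    alt_allele: str
    kind: str              # SNV | MNP | insertion | deletion
    count: int
    coverage: int
    frequency: float
    region_label: str = ""


@dataclass(frozen=True)
class DiversityResult:
    region_label: str
    n_sequences: int
    n_sites: int
    pi: float
    snp_density: float | None = None


@dataclass(frozen=True)
class MotifHit:
    position: int
    strand: str
    matches: int


@dataclass(frozen=True)
class UnitVariantComposition:
    read_id: str
    n_complete_units: int
    counts: dict  # {"T": int, "A": int, "other": int}


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------


class PileupTable:
    """Per-position base/indel counts on the monomer, plus per-read bases.

    Positions on the doubled reference are folded modulo the monomer length.
    Insertions are attributed to the left flanking reference position.
    """

    def __init__(self, ref: str):
        self.ref = ref
        L = len(ref)
        self.base_counts = np.zeros((L, 4), dtype=np.int64)
        self.del_counts = np.zeros(L, dtype=np.int64)
        self.ins_counts = np.zeros(L, dtype=np.int64)
        self.coverage = np.zeros(L, dtype=np.int64)
        # per-read substitution/match bases, for MNP phasing and windows
        self.read_bases: list[dict[int, str]] = []
        self.read_spans: list[tuple[int, int]] = []  # folded, may wrap

    def __len__(self) -> int:
        return len(self.ref)

    def to_columns(self) -> list[dict[str, int]]:
        cols = []
        for i in range(len(self.ref)):
            col = {b: int(self.base_counts[i, k]) for k, b in enumerate("ACGT")
                   if self.base_counts[i, k] > 0}
            cols.append(col)
        return cols

    def window_alignment(self, interval: tuple[int, int]) -> list[str]:
        """Rows for reads fully covering [a, b); deletions become '-'. """
        a, b = interval
        rows = []
        for bases, (s, e) in zip(self.read_bases, self.read_spans):
            if s <= a and e >= b:
                row = "".join(bases.get(p, "-") for p in range(a, b))
                rows.append(row)
        return rows


def pileup_columns(
    placements: Iterable[ReadPlacement],
    ref: str,
) -> PileupTable:
    """Build a pileup over the monomer from doubled-reference placements."""
    L = len(ref)
    table = PileupTable(ref)
    for p in placements:
        ops = _cigar_spans(p.cigar)
        rpos = 0  # position in read_seq (aligned orientation)
        gpos = p.ref_interval[0]
        ref_len = sum(n for n, op in ops if op in "=XD")
        if p.ref_interval[0] < 0 or p.ref_interval[0] + ref_len > 2 * L:
            raise InvalidPlacement(
                f"{p.read_id}: interval outside the doubled reference"
            )
        bases: dict[int, str] = {}
        start_fold = gpos % L
        for n, op in ops:
            if op == "S":
                rpos += n
            elif op in "=X":
                for t in range(n):
                    pos = (gpos + t) % L
                    base = p.read_seq[rpos + t]
                    k = "ACGT".find(base)
                    if k >= 0:
                        table.base_counts[pos, k] += 1
                    table.coverage[pos] += 1
                    bases[pos] = base
                gpos += n
                rpos += n
            elif op == "D":
                for t in range(n):
                    pos = (gpos + t) % L
                    table.del_counts[pos] += 1
                    table.coverage[pos] += 1
                gpos += n
            elif op == "I":
                table.ins_counts[(gpos - 1) % L] += 1
                rpos += n
            else:
                raise InvalidPlacement(f"unknown cigar op {op!r}")
        if start_fold + ref_len <= L:
            table.read_bases.append(bases)
            table.read_spans.append((start_fold, start_fold + ref_len))
        else:
            # junction-spanning read: split into two folded segments so each
            # position is attributed exactly once
            wrap = (start_fold + ref_len) % L
            table.read_bases.append({k: v for k, v in bases.items() if k >= start_fold})
            table.read_spans.append((start_fold, L))
            table.read_bases.append({k: v for k, v in bases.items() if k < wrap})
            table.read_spans.append((0, wrap))
    return table


# ---------------------------------------------------------------------------
# Variant calling
# ---------------------------------------------------------------------------


def call_variants(
    pileup: PileupTable,
    thresholds: VariantThresholds | None = None,
    annotation: RegionAnnotation | None = None,
) -> list[VariantCall]:
    """Emit every non-reference allele passing all three thresholds.

    Adjacent SNVs are merged into one MNP when, among jointly covering reads
    carrying at least one of the two alternative alleles, the fraction
    carrying both reaches the co-occurrence threshold.
    """
    th = thresholds or VariantThresholds()
    L = len(pileup.ref)
    region = (lambda p: annotation.region_of(p, L)) if annotation else (lambda p: "")

    snvs: list[VariantCall] = []
    others: list[VariantCall] = []
    for pos in range(L):
        cov = int(pileup.coverage[pos])
        if cov < th.min_coverage:
            continue
        ref_base = pileup.ref[pos]
        for k, base in enumerate("ACGT"):
            if base == ref_base:
                continue
            cnt = int(pileup.base_counts[pos, k])
            freq = cnt / cov
            if cnt >= th.min_count and freq >= th.min_frequency:
                snvs.append(VariantCall(pos, ref_base, base, "SNV", cnt, cov, freq,
                                        region(pos)))
        dcnt = int(pileup.del_counts[pos])
        if dcnt >= th.min_count and dcnt / cov >= th.min_frequency:
            others.append(VariantCall(pos, ref_base, "-", "deletion", dcnt, cov,
                                      dcnt / cov, region(pos)))
        icnt = int(pileup.ins_counts[pos])
        if icnt >= th.min_count and icnt / cov >= th.min_frequency:
            others.append(VariantCall(pos, ref_base, ref_base + "+", "insertion",
                                      icnt, cov, icnt / cov, region(pos)))

    merged = _merge_mnps(snvs, pileup, th, region)
    return sorted(merged + others, key=lambda c: (c.position, c.alt_allele))


def _merge_mnps(snvs, pileup: PileupTable, th: VariantThresholds, region):
    """Chain adjacent phased SNVs into MNPs."""
    by_pos: dict[int, list[VariantCall]] = {}
    for c in snvs:
        by_pos.setdefault(c.position, []).append(c)

    def phased(a: VariantCall, b: VariantCall) -> bool:
        joint = either = both = 0
        for bases in pileup.read_bases:
            ba, bb = bases.get(a.position), bases.get(b.position)
            if ba is None or bb is None:
                continue
            joint += 1
            has_a, has_b = ba == a.alt_allele, bb == b.alt_allele
            if has_a or has_b:
                either += 1
                if has_a and has_b:
                    both += 1
        return joint > 0 and either > 0 and both / either >= th.mnp_cooccurrence

    used: set[int] = set()
    out: list[VariantCall] = []
    for c in sorted(snvs, key=lambda c: (c.position, c.alt_allele)):
        if id(c) in used:
            continue
        chain = [c]
        used.add(id(c))
        while True:
            nxt = None
            for cand in by_pos.get(chain[-1].position + 1, []):
                if id(cand) not in used and phased(chain[-1], cand):
                    nxt = cand
                    break
            if nxt is None:
                break
            chain.append(nxt)
            used.add(id(nxt))
        if len(chain) == 1:
            out.append(c)
        else:
            count = min(x.count for x in chain)
            cov = min(x.coverage for x in chain)
            out.append(VariantCall(
                position=chain[0].position,
                ref_allele="".join(x.ref_allele for x in chain),
                alt_allele="".join(x.alt_allele for x in chain),
                kind="MNP",
                count=count,
                coverage=cov,
                frequency=count / cov if cov else 0.0,
                region_label=chain[0].region_label,
            ))
    return out


def snp_density(calls: Sequence[VariantCall], region_interval: tuple[int, int]) -> float:
    """SNPs per 100 bp inside a half-open region interval."""
    a, b = region_interval
    if b <= a:
        raise ZeroDivisionError("region must have positive length")
    n = sum(1 for c in calls if a <= c.position < b)
    return 100.0 * n / (b - a)


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------


def nucleotide_diversity(
    aligned_reads: Sequence[str],
    region_label: str = "",
) -> DiversityResult:
    """Pi = mean over unordered pairs of (differing sites / compared sites).

    Columns where either sequence has a gap or ambiguity are excluded per
    pair (pairwise deletion). Pairs with no comparable site contribute 0.
    """
    seqs = list(aligned_reads)
    if len(seqs) < 2:
        raise InsufficientData("need at least two sequences")
    m = len(seqs[0])
    if any(len(s) != m for s in seqs):
        raise InvalidArgument("sequences must have identical lengths")
    X = np.stack([_seq.encode(s.replace("-", "N")) for s in seqs])
    valid = X < 4
    n = len(seqs)
    # matches[i,j] = number of sites where both valid and equal
    matches = np.zeros((n, n), dtype=np.int64)
    for b in range(4):
        M = ((X == b) & valid).astype(np.int64)
        matches += M @ M.T
    comp = valid.astype(np.int64) @ valid.astype(np.int64).T
    iu = np.triu_indices(n, k=1)
    diffs = comp[iu] - matches[iu]
    with np.errstate(invalid="ignore", divide="ignore"):
        per_pair = np.where(comp[iu] > 0, diffs / np.maximum(comp[iu], 1), 0.0)
    return DiversityResult(
        region_label=region_label,
        n_sequences=n,
        n_sites=m,
        pi=float(per_pair.mean()),
    )


# ---------------------------------------------------------------------------
# Motif search and spacer-variant phasing
# ---------------------------------------------------------------------------


def find_motif(read: str, query: str, min_matches: int = 9) -> list[MotifHit]:
    """Ungapped placements of a 10-nt query on either strand.

    A hit needs >= min_matches identities over the 10 columns (default 9,
    tolerating the single error a 10-mer is likely to carry in noisy long
    reads). Overlapping hits are all reported.
    """
    if len(query) != 10:
        raise InvalidArgument("query must be exactly 10 nt")
    hits: list[MotifHit] = []
    rc = _seq.revcomp(query)
    codes = _seq.encode(read)
    n = len(read) - 10 + 1
    if n <= 0:
        return hits
    for strand, q in (("+", query), ("-", rc)):
        qc = _seq.encode(q)
        counts = np.zeros(n, dtype=np.int16)
        for j in range(10):
            counts += (codes[j:j + n] == qc[j]) & (qc[j] < 4)
        for pos in np.nonzero(counts >= min_matches)[0]:
            hits.append(MotifHit(int(pos), strand, int(counts[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def phase_units(
    read: str,
    gene_hits: Sequence,
    motif_queries: Mapping[str, str],
    min_matches: int = 9,
    gap_max: int = 1500,
    margin: int = 10,
) -> UnitVariantComposition:
    """Assign a spacer variant to every complete unit along one read.

    A complete unit is the stretch between two consecutive same-strand gene
    hits (gene + its spacer). The spacer region between the hits is searched
    with each variant query: exactly one matching query labels the unit with
    that variant; none or both yield "other".
    """
    hits = sorted(gene_hits, key=lambda h: h.interval[0])
    if not hits:
        raise EmptyInput("no gene hits on this read")
    read_id = getattr(hits[0], "read_id", "")
    counts = {"T": 0, "A": 0, "other": 0}
    n_units = 0
    for h1, h2 in zip(hits, hits[1:]):
        if h1.strand != h2.strand:
            continue
        gap = h2.interval[0] - h1.interval[1]
        if gap < 0 or gap > gap_max:
            continue
        n_units += 1
        a = max(0, h1.interval[1] - margin)
        b = min(len(read), h2.interval[0] + margin)
        spacer = read[a:b]
        matched = [name for name, q in sorted(motif_queries.items())
                   if find_motif(spacer, q, min_matches)]
        if len(matched) == 1:
            counts[matched[0]] = counts.get(matched[0], 0) + 1
        else:
            counts["other"] += 1
    return UnitVariantComposition(read_id=read_id, n_complete_units=n_units, counts=counts)


# ---------------------------------------------------------------------------
# VCF output (minimal)
# ---------------------------------------------------------------------------


def write_vcf(calls: Sequence[VariantCall], ref_id: str, path) -> int:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Coverage">\n')
        fh.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt count">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alt frequency">\n')
        fh.write('##INFO=<ID=KIND,Number=1,Type=String,Description="Variant kind">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            fh.write(
                f"{ref_id}\t{c.position + 1}\t.\t{c.ref_allele}\t{c.alt_allele}\t.\tPASS\t"
                f"DP={c.coverage};AD={c.count};AF={c.frequency:.4f};KIND={c.kind}\n"
            )
    return len(calls)
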