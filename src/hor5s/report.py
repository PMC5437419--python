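"""Pipeline configuration, the end-to-end driver, and report emission.

`run_pipeline` composes the stages in order: simulate (short + long read
sets) -> filter -> map -> copy-number chain -> pileup/variants/diversity ->
length filter -> gene hits -> blocks -> group classification -> spacer
phasing -> summaries. Identical config + seed yields byte-identical outputs
(no timestamps enter any artifact).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError
from .fastx import write_fastq
from .hor_analysis import (
    DEFAULT_COVER_MIN,
    DEFAULT_GAP_MAX,
    DEFAULT_MIN_READ_LEN,
    DEFAULT_UNIQUE_MIN,
    DotplotScoring,
    _ConsensusIndex,
    classify_read,
    find_gene_copies,
    gene_count_histogram,
    length_filter,
    segment_blocks,
    self_dotplot,
    summarize_groups,
    write_gff3,
)
from .read_mapping import (
    FilterPolicy,
    MappingParams,
    copy_number_chain,
    filter_reads,
    map_reads,
    write_placements,
)
from .repeat_model import default_reference, default_unit_library
from .synthetic_data import (
    DEFAULT_GROUP_WEIGHTS,
    ErrorModel,
    simulate_genome_and_short_reads,
    simulate_long_read_set,
)
from .variant_calling import (
    VariantThresholds,
    call_variants,
    nucleotide_diversity,
    phase_units,
    pileup_columns,
    snp_density,
    write_vcf,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the end-to-end run, with study-condition defaults."""

    seed: int = 0
    genome_size_mb: float = 1100.0
    unit_len_bp: int = 220
    # short-read simulation (planted genome proportion)
    short_rdna_copies: int = 200
    short_background_len: int = 2_000_000
    short_read_len: int = 100
    short_n_reads: int = 20_000
    # long-read simulation
    long_n_reads: int = 40
    long_length_min: int = 10_000
    long_length_max: int = 30_000
    long_group_weights: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_WEIGHTS))
    substitution_rate: float = 0.01
    insertion_rate: float = 0.08
    deletion_rate: float = 0.04
    # stage parameters
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    mapping: MappingParams = field(default_factory=MappingParams)
    variants: VariantThresholds = field(default_factory=VariantThresholds)
    dotplot: DotplotScoring = field(default_factory=DotplotScoring)
    min_read_len: int = DEFAULT_MIN_READ_LEN
    gap_max: int = DEFAULT_GAP_MAX
    unique_min: int = DEFAULT_UNIQUE_MIN
    cover_min: float = DEFAULT_COVER_MIN
    dotplot_reads: int = 1  # self-dotplots emitted per structural group

    def validate(self) -> None:
        if self.seed < 0:
            raise ConfigError("seed", "must be non-negative")
        if self.genome_size_mb <= 0:
            raise ConfigError("genome_size_mb", "must be positive")
        if self.unit_len_bp <= 0:
            raise ConfigError("unit_len_bp", "must be positive")
        if self.short_read_len < 90:
            raise ConfigError("short_read_len", "must be >= 90")
        if self.long_length_min < 1 or self.long_length_max < self.long_length_min:
            raise ConfigError("long_length_min", "invalid length range")
        if abs(sum(self.long_group_weights.values()) - 1.0) > 1e-6:
            raise ConfigError("long_group_weights", "must sum to 1")
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigError(name, "must lie in [0, 1)")
        if not (0 < self.variants.min_frequency <= 1):
            raise ConfigError("variants.min_frequency", "must lie in (0, 1]")
        if self.cover_min <= 0 or self.cover_min > 1:
            raise ConfigError("cover_min", "must lie in (0, 1]")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("filter_policy", FilterPolicy),
            ("mapping", MappingParams),
            ("variants", VariantThresholds),
            ("dotplot", DotplotScoring),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration field")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_order: list
    stage_counts: dict
    input_checksums: dict

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


def _stage_seed(base: int, k: int) -> int:
    return (base * 7919 + k) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Execute the full synthetic-data pipeline; all artifacts land in outdir."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    order: list[str] = []

    def stage(name: str, n: int):
        order.append(name)
        counts[name] = n

    # reference
    ref = default_reference()
    library = default_unit_library()
    ref.write(outdir / "reference.fasta", outdir / "reference.json")
    stage("reference", 2)

    # short-read simulation
    short_reads, planted_gp = simulate_genome_and_short_reads(
        rdna_copies=config.short_rdna_copies,
        unit=library["S_T"],
        background_len=config.short_background_len,
        read_len=config.short_read_len,
        n_reads=config.short_n_reads,
        seed=_stage_seed(config.seed, 1),
    )
    write_fastq(short_reads, outdir / "short_reads.fastq")
    stage("simulate_short", len(short_reads))

    # filter + map
    kept, tally = filter_reads(short_reads, config.filter_policy)
    stage("filter", len(kept))
    placements = map_reads(kept, ref, config.mapping)
    write_placements(placements, outdir / "placements.tsv")
    stage("map", len(placements))

    # copy-number chain
    est = copy_number_chain(
        n_mapped=len(placements),
        n_total=len(kept),
        genome_size_mb=config.genome_size_mb,
        unit_len_bp=config.unit_len_bp,
    )
    copy_report = {
        "platform": "synthetic-short",
        **est.as_dict(),
        "planted_gp_percent": round(planted_gp, 4),
        "filter_tally": tally,
    }
    (outdir / "copy_number.json").write_text(json.dumps(copy_report, indent=1, sort_keys=True))
    stage("copy_number", 1)

    # variants + diversity
    pileup = pileup_columns(placements, ref.monomer)
    calls = call_variants(pileup, config.variants, ref.annotation)
    write_vcf(calls, "monomer", outdir / "variants.vcf")
    stage("variants", len(calls))
    g0, g1 = ref.annotation.genic_interval
    s0, s1 = ref.annotation.spacer_interval
    div_rows = []
    for label, (a, b) in (("genic", (g0 + 25, g0 + 95)), ("spacer", (s0 + 10, s0 + 80))):
        rows = pileup.window_alignment((a, b))
        if len(rows) >= 2:
            div = nucleotide_diversity(rows, label)
            dens = snp_density(calls, (a, b))
            div_rows.append((label, a, b, div.n_sequences, div.pi, dens))
    with open(outdir / "diversity.tsv", "w") as fh:
        fh.write("# hor5s " + __version__ + "\n")
        fh.write("region\tstart\tend\tn_sequences\tpi\tsnp_per_100bp\n")
        for r in div_rows:
            fh.write(f"{r[0]}\t{r[1]}\t{r[2]}\t{r[3]}\t{r[4]:.6f}\t{r[5]:.4f}\n")
    stage("diversity", len(div_rows))

    # long-read simulation
    model = ErrorModel(config.substitution_rate, config.insertion_rate,
                       config.deletion_rate)
    long_reads, truths = simulate_long_read_set(
        group_weights=config.long_group_weights,
        n_reads=config.long_n_reads,
        length_range=(config.long_length_min, config.long_length_max),
        model=model,
        seed=_stage_seed(config.seed, 2),
    )
    write_fastq(long_reads, outdir / "long_reads.fastq")
    _write_truth(truths, outdir / "long_truth.tsv")
    stage("simulate_long", len(long_reads))

    kept_long = length_filter(long_reads, config.min_read_len)
    stage("length_filter", len(kept_long))

    # gene hits, blocks, classification, phasing
    index = _ConsensusIndex(ref.genic_consensus, 9)
    classifications = []
    compositions = []
    hits_per_read = {}
    for rec in kept_long:
        hits = find_gene_copies(rec, ref.genic_consensus, index=index)
        hits_per_read[rec.id] = hits
        blocks = segment_blocks(hits, len(rec.seq), config.gap_max, ref.spacer_ranges)
        c = classify_read(blocks, len(rec.seq), config.unique_min,
                          config.cover_min, read_id=rec.id)
        classifications.append(c)
        if hits:
            compositions.append(
                phase_units(rec.seq, hits, ref.motif_queries, gap_max=config.gap_max)
            )
    write_gff3(classifications, outdir / "hits.gff3")
    stage("gene_hits", sum(len(h) for h in hits_per_read.values()))

    with open(outdir / "classifications.tsv", "w") as fh:
        fh.write("# hor5s " + __version__ + "\n")
        fh.write("read_id\tgroup\tn_blocks\tn_genes\tevidence\n")
        for c in classifications:
            fh.write(
                f"{c.read_id}\t{c.group}\t{len(c.blocks)}\t"
                f"{sum(b.n_units for b in c.blocks)}\t{';'.join(c.evidence)}\n"
            )
    stage("classify", len(classifications))

    summary = summarize_groups(classifications)
    histogram = gene_count_histogram(kept_long, hits_per_read)
    write_report(copy_report, summary, compositions, histogram, outdir)
    stage("report", 1)

    # dot-plots: first read of each group
    seen: set[str] = set()
    n_dot = 0
    for c in classifications:
        if c.group in seen or len(seen) >= 4:
            continue
        if n_dot >= 4 * config.dotplot_reads:
            break
        seen.add(c.group)
        rec = next(r for r in kept_long if r.id == c.read_id)
        segs = self_dotplot(rec.seq[:8000], config.dotplot)
        safe = rec.id.replace("|", "_")
        with open(outdir / f"dotplot_{safe}.tsv", "w") as fh:
            fh.write("# hor5s " + __version__ + "\n")
            fh.write("x_start\tx_end\ty_start\ty_end\torientation\tscore\n")
            for s in segs:
                fh.write(f"{s.x_interval[0]}\t{s.x_interval[1]}\t{s.y_interval[0]}"
                         f"\t{s.y_interval[1]}\t{s.orientation}\t{s.score}\n")
        n_dot += 1
    stage("dotplot", n_dot)

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        stage_order=order,
        stage_counts=counts,
        input_checksums={
            p.name: _sha256(p)
            for p in sorted(outdir.glob("*.fastq")) + sorted(outdir.glob("*.fasta"))
        },
    )
    manifest.write(outdir / "manifest.json")
    return manifest


def _write_truth(truths, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tgroup\tunit_index\tstart\tend\tstrand\ttemplate_id"
                 "\tmotif_variant\tspacer_class\n")
        for t in truths:
            for i, u in enumerate(t.unit_records):
                fh.write(f"{t.read_id}\t{t.group_label}\t{i}\t{u.start}\t{u.end}\t"
                         f"{u.strand}\t{u.template_id}\t{u.motif_variant.value}\t"
                         f"{u.spacer_class.value}\n")


def write_report(copy_report: dict, summary, compositions, histogram, outdir: str | Path) -> None:
    """Table-1-style, Table-2-style and per-read composition reports."""
    outdir = Path(outdir)
    (outdir / "copy_number.json").write_text(
        json.dumps(copy_report, indent=1, sort_keys=True)
    )
    table2 = {
        "groups": {
            g: {
                "reads": summary.read_counts[g],
                "reads_pct": summary.read_pct[g],
                "genes": summary.gene_counts[g],
                "genes_pct": summary.gene_pct[g],
            }
            for g in ("I", "II", "III", "IV")
        },
        "total_reads": summary.total_reads,
        "total_genes": summary.total_genes,
    }
    (outdir / "group_summary.json").write_text(json.dumps(table2, indent=1, sort_keys=True))
    with open(outdir / "group_summary.tsv", "w") as fh:
        fh.write("# hor5s " + __version__ + "\n")
        fh.write("group\treads\treads_pct\tgenes\tgenes_pct\n")
        for g in ("I", "II", "III", "IV"):
            fh.write(f"{g}\t{summary.read_counts[g]}\t{summary.read_pct[g]}\t"
                     f"{summary.gene_counts[g]}\t{summary.gene_pct[g]}\n")
        fh.write(f"total\t{summary.total_reads}\t100\t{summary.total_genes}\t100\n")
    with open(outdir / "compositions.tsv", "w") as fh:
        fh.write("# hor5s " + __version__ + "\n")
        fh.write("read_id\tn_units\tT\tA\tother\n")
        for comp in compositions:
            fh.write(f"{comp.read_id}\t{comp.n_complete_units}\t"
                     f"{comp.counts.get('T', 0)}\t{comp.counts.get('A', 0)}\t"
                     f"{comp.counts.get('other', 0)}\n")
    with open(outdir / "gene_counts.tsv", "w") as fh:
        fh.write("# hor5s " + __version__ + "\n")
        fh.write("read_id\tlength\tn_genes\n")
        for read_id, length, n in histogram:
            fh.write(f"{read_id}\t{length}\t{n}\n")
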