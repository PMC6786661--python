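"""Synthetic mutation catalogs with ground truth.

The generator emulates a burst of double-strand breaks (DSBs) repaired by
homologous recombination in a cell expressing an ssDNA-specific cytidine
deaminase with no uracil glycosylase: every deamination of an exposed C
fixes as C->T on the exposed strand. Three repair geometries expose
hypermutable ssDNA around a break:

* ``bidirectional_resection`` — 5'->3' resection on both sides leaves the
  top strand single-stranded left of the break and the bottom strand right
  of it, so the top-strand reading is C mutations 5' of the break and G
  mutations 3' of it (a 5'C-3'G single switch);
* ``unidirectional_resection`` — one side resects far enough to be
  hypermutable; a fair coin picks the side, giving an all-C or all-G
  (top-strand) coordinated tract;
* ``bir`` — break-induced replication leaves a long one-strand ssDNA tail
  behind the migrating bubble (resected flank plus synthesis track), also
  fully coordinated.

Deamination prefers a signature motif (default ytCa) on the exposed strand;
off-motif cytosines mutate at 1/``motif_preference`` of the motif rate.
Scattered background SNVs with a uniform substitution spectrum are added
genome-wide. Diploids are simulated as independent haploid copies whose
catalogs merge without phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .enrichment import Motif
from .io import GenomeModel, MutationRecord

#: S. cerevisiae chromosome length profile (bp); scaled when a different
#: total genome length is requested.
YEAST_CHROM_LENGTHS = {
    "chrI": 230_218, "chrII": 813_184, "chrIII": 316_620, "chrIV": 1_531_933,
    "chrV": 576_874, "chrVI": 270_161, "chrVII": 1_090_940, "chrVIII": 562_643,
    "chrIX": 439_888, "chrX": 745_751, "chrXI": 666_816, "chrXII": 1_078_177,
    "chrXIII": 924_431, "chrXIV": 784_333, "chrXV": 1_091_291, "chrXVI": 948_066,
}

MECHANISMS = ("bidirectional_resection", "unidirectional_resection", "bir")


def random_genome(
    length: int = 12_070_000,
    gc_content: float = 0.38,
    ploidy: int = 1,
    seed: int | np.random.Generator = 0,
) -> GenomeModel:
    """A random genome with a yeast-like 16-chromosome length profile."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = sum(YEAST_CHROM_LENGTHS.values())
    lengths = {name: max(1000, int(round(l * length / total))) for name, l in YEAST_CHROM_LENGTHS.items()}
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {
        name: rng.choice(alphabet, size=n, p=p).tobytes().decode("ascii")
        for name, n in lengths.items()
    }
    return GenomeModel.from_dict(seqs, ploidy=ploidy)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated isolate.

    ``n_dsb`` counts the *abnormally repaired* breaks — the small fraction
    of a gamma burst whose delayed repair exposes hypermutable ssDNA — per
    haploid genome copy. Rates are per candidate base; ``deamination_rate``
    applies to motif-matching cytosines of the exposed strand and is scaled
    down ``motif_preference``-fold elsewhere.
    """

    n_dsb: int = 3
    mechanism_mix: dict[str, float] = field(
        default_factory=lambda: {m: 1 / 3 for m in MECHANISMS}
    )
    tract_median_bp: float = 5_000.0
    tract_sigma: float = 0.5
    deamination_rate: float = 0.06
    motif: str = "ytCa"
    motif_preference: float = 20.0
    background_rate: float = 2.5e-6
    ploidy: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mechanism_mix.values()) - 1.0) > 1e-9:
            raise ValueError("mechanism_mix must sum to 1")
        for m in self.mechanism_mix:
            if m not in MECHANISMS:
                raise ValueError(f"unknown mechanism {m!r}")
        for rate in (self.deamination_rate, self.background_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if self.tract_median_bp < 0:
            raise ValueError("tract lengths must be >= 0")


@dataclass(frozen=True)
class SimSegment:
    """One exposed ssDNA segment (closed 1-based interval on one strand)."""

    start: int
    end: int
    exposed_strand: str  # "top" | "bottom"
    mutation_positions: tuple[int, ...] = ()


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated DSB-repair event."""

    sample_id: str
    copy: int
    chrom: str
    break_pos: int
    mechanism: str
    segments: tuple[SimSegment, ...]
    truncated: bool = False


def _draw_chrom(genome: GenomeModel, rng: np.random.Generator) -> str:
    lengths = np.array([genome.chrom_lengths[c] for c in genome.chrom_names], dtype=float)
    return genome.chrom_names[rng.choice(len(lengths), p=lengths / lengths.sum())]


def _tract_length(config: SimConfig, rng: np.random.Generator) -> int:
    return max(1, int(round(rng.lognormal(np.log(config.tract_median_bp), config.tract_sigma))))


def _deaminate_segment(
    genome: GenomeModel,
    chrom: str,
    seg_start: int,
    seg_end: int,
    exposed: str,
    config: SimConfig,
    motif_fwd: Motif,
    motif_rev: Motif,
    rng: np.random.Generator,
    sample_id: str,
) -> tuple[list[MutationRecord], tuple[int, ...]]:
    """Deaminate exposed-strand cytosines of one segment.

    Top exposure mutates reference C's (C->T); bottom exposure mutates the
    bottom-strand C's, read as reference G's (G->A). Motif preference is
    evaluated on the exposed strand, i.e. with the reverse-complement motif
    for bottom exposure.
    """
    margin = len(config.motif)
    fetch_start = max(1, seg_start - margin)
    fetch_end = min(genome.chrom_lengths[chrom], seg_end + margin)
    seq = genome.sequence(chrom, fetch_start, fetch_end)
    target_base, alt_base, motif = ("C", "T", motif_fwd) if exposed == "top" else ("G", "A", motif_rev)
    base_rate = config.deamination_rate
    off_rate = base_rate / config.motif_preference
    records: list[MutationRecord] = []
    positions: list[int] = []
    lo, hi = seg_start - fetch_start, seg_end - fetch_start
    for i in range(lo, hi + 1):
        if seq[i] != target_base:
            continue
        rate = base_rate if motif.matches_at(seq, i) else off_rate
        if rng.random() < rate:
            pos = fetch_start + i
            records.append(MutationRecord(sample_id, chrom, pos, target_base, alt_base))
            positions.append(pos)
    return records, tuple(positions)


def _background(
    genome: GenomeModel, config: SimConfig, rng: np.random.Generator, sample_id: str
) -> list[MutationRecord]:
    haploid_len = sum(genome.chrom_lengths.values())
    n = rng.poisson(config.background_rate * haploid_len)
    return _uniform_snvs(genome, int(n), rng, sample_id)


def _uniform_snvs(
    genome: GenomeModel, n: int, rng: np.random.Generator, sample_id: str
) -> list[MutationRecord]:
    names = genome.chrom_names
    lengths = np.array([genome.chrom_lengths[c] for c in names])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])
    records: list[MutationRecord] = []
    used: set[int] = set()
    while len(records) < n:
        flat = int(rng.integers(0, total))
        if flat in used:
            continue
        used.add(flat)
        ci = int(np.searchsorted(offsets, flat, side="right") - 1)
        pos = flat - int(offsets[ci]) + 1
        ref = genome.sequence(names[ci], pos, pos)
        if ref not in "ACGT":
            continue
        alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
        records.append(MutationRecord(sample_id, names[ci], pos, ref, alt))
    return records


def simulate_catalog(
    config: SimConfig,
    genome: GenomeModel | None = None,
    sample_id: str = "sim_1",
    rng: np.random.Generator | None = None,
) -> tuple[list[MutationRecord], list[SimTruth]]:
    """Simulate one isolate's mutation catalog plus per-event ground truth.

    Reproducible for a fixed ``config.seed`` (or caller-supplied ``rng``).
    Segments extending past a chromosome end are truncated and flagged in
    the truth record. Duplicate sites arising from homolog merging are
    dropped (unphased calls collapse).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if genome is None:
        genome = random_genome(ploidy=config.ploidy, seed=rng)
    motif_fwd = Motif(config.motif)
    motif_rev = motif_fwd.reverse_complement()
    mech_names = list(config.mechanism_mix)
    mech_probs = np.array([config.mechanism_mix[m] for m in mech_names])

    records: list[MutationRecord] = []
    truths: list[SimTruth] = []
    for copy in range(config.ploidy):
        for _ in range(config.n_dsb):
            chrom = _draw_chrom(genome, rng)
            chrom_len = genome.chrom_lengths[chrom]
            break_pos = int(rng.integers(1, chrom_len + 1))
            mechanism = mech_names[int(rng.choice(len(mech_names), p=mech_probs))]
            raw_segments: list[tuple[int, int, str]] = []
            if mechanism == "bidirectional_resection":
                left = _tract_length(config, rng)
                right = _tract_length(config, rng)
                raw_segments.append((break_pos - left, break_pos - 1, "top"))
                raw_segments.append((break_pos, break_pos + right - 1, "bottom"))
            else:  # unidirectional resection or BIR: one tract, one strand
                tract = _tract_length(config, rng)
                if rng.random() < 0.5:  # repair initiates from the left end
                    raw_segments.append((break_pos - tract, break_pos - 1, "top"))
                else:
                    raw_segments.append((break_pos, break_pos + tract - 1, "bottom"))
            truncated = False
            segments: list[SimSegment] = []
            for start, end, strand in raw_segments:
                cstart, cend = max(1, start), min(chrom_len, end)
                if (cstart, cend) != (start, end):
                    truncated = True
                if cstart > cend:
                    continue
                muts, positions = _deaminate_segment(
                    genome, chrom, cstart, cend, strand, config, motif_fwd, motif_rev, rng, sample_id
                )
                records.extend(muts)
                segments.append(SimSegment(cstart, cend, strand, positions))
            truths.append(
                SimTruth(sample_id, copy, chrom, break_pos, mechanism, tuple(segments), truncated)
            )
        records.extend(_background(genome, config, rng, sample_id))

    # merge homolog copies without phase: duplicate sites collapse
    seen: set[tuple[str, int]] = set()
    unique: list[MutationRecord] = []
    for rec in sorted(records, key=lambda r: (genome.chrom_rank(r.chrom), r.pos)):
        site = (rec.chrom, rec.pos)
        if site in seen:
            continue
        seen.add(site)
        unique.append(rec)
    return unique, truths


def simulate_null(
    genome: GenomeModel,
    n_mutations: int,
    seed: int | np.random.Generator = 0,
    sample_id: str = "null_1",
) -> list[MutationRecord]:
    """Uniformly scattered SNVs (positions without replacement, uniform alt)."""
    haploid_len = sum(genome.chrom_lengths.values())
    if n_mutations > haploid_len:
        raise ValueError("more mutations than genome positions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = _uniform_snvs(genome, n_mutations, rng, sample_id)
    return sorted(records, key=lambda r: (genome.chrom_rank(r.chrom), r.pos))


def truth_to_bed(truths: Sequence[SimTruth], path) -> None:
    """Write truth segments as BED; name carries mechanism and strand."""
    with open(path, "w") as fh:
        for i, t in enumerate(truths):
            for seg in t.segments:
                name = f"{t.sample_id}:event{i}:{t.mechanism}:{seg.exposed_strand}"
                fh.write(f"{t.chrom}\t{seg.start - 1}\t{seg.end}\t{name}\t{len(seg.mutation_positions)}\t.\n")


def haploid_cohort(
    n_isolates: int,
    config: SimConfig | None = None,
    genome: GenomeModel | None = None,
    seed: int = 0,
    prefix: str = "iso",
) -> tuple[GenomeModel, dict[str, list[MutationRecord]], dict[str, list[SimTruth]]]:
    """Simulate a cohort of isolates sharing one reference genome."""
    rng = np.random.default_rng(seed)
    if config is None:
        config = SimConfig()
    if genome is None:
        genome = random_genome(ploidy=config.ploidy, seed=rng)
    catalogs: dict[str, list[MutationRecord]] = {}
    truths: dict[str, list[SimTruth]] = {}
    for i in range(n_isolates):
        sid = f"{prefix}_{i + 1}"
        n_dsb = int(rng.poisson(config.n_dsb))
        cfg = replace(config, n_dsb=n_dsb)
        catalogs[sid], truths[sid] = simulate_catalog(cfg, genome, sid, rng)
    return genome, catalogs, truths
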