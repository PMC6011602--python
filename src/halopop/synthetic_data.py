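"""Synthetic genomes, strain pairs, coverage tracks and metagenome
assemblies with planted truth.

The generator emulates the structure of Antarctic haloarchaeal data: a large
high-GC primary replicon (~67% GC) that is highly conserved between strains,
smaller lower-GC secondary replicons (~57% GC) that are largely
strain-unique, a provirus present in exactly one strain, intergenera
high-identity regions (HIRs) copied nearly verbatim between genomes,
replicon copy-number differences, and population-level coverage depressions
(genomic islands) created by mixing: inside an island only a fraction of the
population carries the reference sequence, so expected depth is scaled by
that fraction.

Base composition is i.i.d. per position with a GC parameter (no
dinucleotide structure); islands are modelled as population-fraction mixing,
not read-mapping artefacts. Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genomics_io import DepthTrack, Interval, SequenceRecord

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "HirSpec",
    "IslandSpec",
    "random_sequence",
    "mutate_sequence",
    "simulate_strain_pair",
    "simulate_coverage",
    "simulate_metagenome_assembly",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class HirSpec:
    """A segment to copy from genome A into a partner genome at a given
    identity (substitutions only)."""

    length: int
    identity: float = 1.0
    partner: str = "B"


@dataclass(frozen=True)
class IslandSpec:
    """A planted island: [start, start+length) carried by only
    `population_fraction` of the population."""

    start: int
    length: int
    population_fraction: float


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic haloarchaeal community.

    Desk-scale defaults: 200-kb primary replicon with 40/20-kb secondaries;
    `full_scale()` mirrors the published replicon inventory (2735/525/431 kb).
    GC defaults follow the observed primary/secondary contrast (67% vs 57%);
    the provirus is 29 kb; the strain pair's primary replicons differ at a
    low background rate (>99% identity) plus designated variable loci
    (<99%, cell-surface-like); base depth is 50x.
    """

    seed: int = 0
    primary_len: int = 200_000
    secondary_lens: tuple[int, ...] = (40_000, 20_000)
    gc_primary: float = 0.67
    gc_secondary: float = 0.57
    background_snp_rate: float = 0.0005
    snp_rate_variable_loci: float = 0.03
    n_variable_loci: int = 5
    variable_locus_len: int = 3000
    provirus_len: int = 29_000
    hir_specs: tuple[HirSpec, ...] = ()
    secondary_core_fraction: float = 0.30
    copy_numbers: dict = field(default_factory=dict)  # seq_id -> multiplier
    abundances: dict = field(default_factory=dict)  # species -> fraction
    base_depth: float = 50.0
    island_specs: dict = field(default_factory=dict)  # seq_id -> [IslandSpec]
    overdispersion: float | None = None  # Gamma shape; None = pure Poisson
    read_length: int = 150
    n_fractions: int = 3
    fraction_dispersion: float = 0.15
    contig_len_log_mean: float = np.log(8000.0)
    contig_len_log_sd: float = 0.5
    min_contig_len: int = 1000

    def __post_init__(self) -> None:
        for frac in (self.gc_primary, self.gc_secondary, self.secondary_core_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.abundances and abs(sum(self.abundances.values()) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")

    @classmethod
    def full_scale(cls, **kwargs) -> "SimulationConfig":
        """Published-inventory sizes: 2735-kb primary, 525/431-kb secondaries."""
        return cls(primary_len=2_735_000, secondary_lens=(525_000, 431_000), **kwargs)


@dataclass
class TruthSet:
    """Planted ground truth for pipeline validation."""

    islands: list[tuple[Interval, float]] = field(default_factory=list)
    hirs: list[dict] = field(default_factory=list)
    alleles: dict = field(default_factory=dict)  # locus -> {sample: bool}
    abundances: dict = field(default_factory=dict)  # species -> %
    variable_loci: list[Interval] = field(default_factory=list)
    provirus: Interval | None = None


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """i.i.d. sequence with P(G)=P(C)=gc/2."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def mutate_sequence(
    seq: str,
    rng: np.random.Generator,
    rate: float | None = None,
    n_subs: int | None = None,
    margin: int = 0,
) -> tuple[str, np.ndarray]:
    """Substitute bases at `rate` per bp (or exactly `n_subs` positions),
    keeping the first/last `margin` bp untouched. Substitutions always change
    the base. Returns (mutated sequence, positions)."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    lo, hi = margin, len(seq) - margin
    if hi <= lo:
        return seq, np.array([], dtype=int)
    if n_subs is not None:
        pos = rng.choice(np.arange(lo, hi), size=min(n_subs, hi - lo), replace=False)
    else:
        pos = np.flatnonzero(rng.random(hi - lo) < (rate or 0.0)) + lo
    for i in pos:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[rng.integers(3)]])
    return arr.tobytes().decode(), np.sort(pos)


def simulate_strain_pair(
    cfg: SimulationConfig,
) -> tuple[list[SequenceRecord], list[SequenceRecord], TruthSet]:
    """Generate two strains of one species.

    Primary replicons are >99% identical apart from designated variable loci
    (mutated at `snp_rate_variable_loci`, cell-surface-like) and a provirus
    present in strain A only. Secondary replicons share
    `secondary_core_fraction` of strain A's sequence, the rest being unique
    per strain. HIR specs are copied from A's secondary replicons into the
    designated partner genome; planted substitutions sit >= 50 bp interior
    to each segment and the partner flank mismatches at the insertion
    boundaries, so the planted extent is exactly recoverable.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = TruthSet()

    ancestor = random_sequence(rng, cfg.primary_len, cfg.gc_primary)

    # non-overlapping variable loci, away from the provirus insertion point
    provirus_pos = cfg.primary_len // 2
    loci: list[Interval] = []
    attempts = 0
    while len(loci) < cfg.n_variable_loci and attempts < 1000:
        attempts += 1
        s = int(rng.integers(0, cfg.primary_len - cfg.variable_locus_len))
        iv = Interval("primary", s, s + cfg.variable_locus_len)
        if any(iv.overlaps(o) for o in loci):
            continue
        if iv.start <= provirus_pos <= iv.end:
            raise ValueError("variable locus overlaps the provirus insertion point")
        loci.append(iv)
    truth.variable_loci = sorted(loci)

    # strain B primary: background SNPs + diverged variable loci
    b_primary, _ = mutate_sequence(ancestor, rng, rate=cfg.background_snp_rate)
    b_arr = list(b_primary)
    for iv in loci:
        div, _ = mutate_sequence(ancestor[iv.start : iv.end], rng, rate=cfg.snp_rate_variable_loci)
        b_arr[iv.start : iv.end] = div
    b_primary = "".join(b_arr)

    # provirus inserted into A only
    provirus = random_sequence(rng, cfg.provirus_len, cfg.gc_secondary)
    a_primary = ancestor[:provirus_pos] + provirus + ancestor[provirus_pos:]
    truth.provirus = Interval("A_primary", provirus_pos, provirus_pos + cfg.provirus_len)

    genome_a = [SequenceRecord("A_primary", a_primary, "primary")]
    genome_b = [SequenceRecord("B_primary", b_primary, "primary")]

    # secondary replicons: shared core prefix + unique remainder
    a_secondaries: list[str] = []
    for i, length in enumerate(cfg.secondary_lens):
        a_sec = random_sequence(rng, length, cfg.gc_secondary)
        core_len = int(length * cfg.secondary_core_fraction)
        b_sec = a_sec[:core_len] + random_sequence(rng, length - core_len, cfg.gc_secondary)
        a_secondaries.append(a_sec)
        genome_a.append(SequenceRecord(f"A_sec{i + 1}", a_sec, "secondary"))
        genome_b.append(SequenceRecord(f"B_sec{i + 1}", b_sec, "secondary"))

    # plant HIRs: source in A's unique secondary sequence, copy into partner
    partner_extra: dict[str, str] = {}
    for j, spec in enumerate(cfg.hir_specs):
        sec_idx = j % len(a_secondaries)
        sec = a_secondaries[sec_idx]
        core_len = int(len(sec) * cfg.secondary_core_fraction)
        max_start = len(sec) - spec.length
        if max_start <= core_len:
            raise ValueError(f"HIR spec {j} does not fit in the unique secondary region")
        src_start = int(rng.integers(core_len, max_start))
        segment = sec[src_start : src_start + spec.length]
        n_subs = int(round((1.0 - spec.identity) * spec.length))
        planted, _ = mutate_sequence(segment, rng, n_subs=n_subs, margin=50)
        # boundary-defining mismatched flank bases on each side
        left = _mismatching_base(rng, sec[src_start - 1] if src_start > 0 else "A")
        right = _mismatching_base(
            rng, sec[src_start + spec.length] if src_start + spec.length < len(sec) else "A"
        )
        extra = partner_extra.get(spec.partner, "")
        spacer = random_sequence(rng, 500, cfg.gc_secondary)
        partner_extra[spec.partner] = extra + spacer + left + planted + right
        truth.hirs.append(
            {
                "source": Interval(f"A_sec{sec_idx + 1}", src_start, src_start + spec.length),
                "partner": spec.partner,
                "length": spec.length,
                "identity": spec.identity,
                "n_subs": n_subs,
            }
        )
    for partner, extra in partner_extra.items():
        rec_id = f"{partner}_hir_carrier"
        rec = SequenceRecord(rec_id, extra + random_sequence(rng, 500, cfg.gc_secondary), "secondary")
        if partner == "B":
            genome_b.append(rec)
        else:
            genome_a.append(rec)
    return genome_a, genome_b, truth


def _mismatching_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(3))]


def simulate_coverage(
    genome: Sequence[SequenceRecord],
    cfg: SimulationConfig,
    species: str = "A",
    seed: int | None = None,
) -> tuple[list[DepthTrack], TruthSet]:
    """Simulate per-base depth tracks for a genome.

    Expected depth per position is ``base_depth * abundance * copy_number``,
    multiplied inside planted islands by their population fraction. Depth is
    Poisson (or Gamma-mixed Poisson when `overdispersion` is set). Seeded and
    reproducible.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    abundance = cfg.abundances.get(species, 1.0)
    truth = TruthSet()
    tracks: list[DepthTrack] = []
    for rec in genome:
        n = len(rec.seq)
        lam = np.full(n, cfg.base_depth * abundance * cfg.copy_numbers.get(rec.id, 1.0))
        for spec in cfg.island_specs.get(rec.id, ()):
            if spec.start + spec.length > n:
                raise ValueError(f"island outside {rec.id}")
            lam[spec.start : spec.start + spec.length] *= spec.population_fraction
            truth.islands.append(
                (Interval(rec.id, spec.start, spec.start + spec.length), spec.population_fraction)
            )
        if not np.all(np.isfinite(lam)):
            raise ValueError("expected depth overflow")
        if cfg.overdispersion is not None:
            g = rng.gamma(cfg.overdispersion, 1.0 / cfg.overdispersion, size=n)
            lam = lam * g
        depth = rng.poisson(lam).astype(float)
        tracks.append(DepthTrack(rec.id, depth))
    return tracks, truth


def simulate_metagenome_assembly(
    genomes: Mapping[str, Sequence[SequenceRecord]],
    cfg: SimulationConfig,
    seed: int | None = None,
    overlap: bool = False,
) -> tuple[list[SequenceRecord], "pd.DataFrame"]:
    """Fragment community genomes into contigs with coverage/taxon/fraction
    tables.

    Contig lengths are lognormal (min `min_contig_len`); with
    ``overlap=False`` contigs tile each replicon exactly. Per-contig
    coverage follows the same expected-depth model, with lognormal
    between-fraction dispersion. Returns (contigs, table) where the table
    has one row per (contig, fraction): columns contig_id, taxon, fraction,
    length, coverage, reads.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    abundances = cfg.abundances or {sp: 1.0 / len(genomes) for sp in genomes}
    contigs: list[SequenceRecord] = []
    rows = []
    for species, records in genomes.items():
        ab = abundances.get(species, 0.0)
        for rec in records:
            pos = 0
            i = 0
            while pos < len(rec.seq):
                length = int(np.exp(rng.normal(cfg.contig_len_log_mean, cfg.contig_len_log_sd)))
                length = max(cfg.min_contig_len, length)
                end = min(pos + length, len(rec.seq))
                if len(rec.seq) - end < cfg.min_contig_len:
                    end = len(rec.seq)  # absorb a short terminal remainder
                cid = f"{rec.id}_c{i}"
                contigs.append(SequenceRecord(cid, rec.seq[pos:end], "contig"))
                lam = cfg.base_depth * ab * cfg.copy_numbers.get(rec.id, 1.0)
                for frac in range(cfg.n_fractions):
                    noise = rng.lognormal(
                        -0.5 * cfg.fraction_dispersion**2, cfg.fraction_dispersion
                    )
                    cov = lam * noise
                    reads = rng.poisson(cov * (end - pos) / cfg.read_length)
                    rows.append(
                        {
                            "contig_id": cid,
                            "taxon": species,
                            "fraction": f"f{frac}",
                            "length": end - pos,
                            "coverage": cov,
                            "reads": int(reads),
                        }
                    )
                pos = end
                i += 1
    return contigs, pd.DataFrame(rows)
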