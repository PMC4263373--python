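"""Synthetic toy genome, sRNA-seq libraries, and PARE tags with ground truth.

The generator emulates the statistical structure the pipeline assumes,
at desk scale: a two-genotype (wild-type vs ta-siRNA-pathway mutant),
three-replicate sRNA-seq design over a toy genome carrying

* two-hit TAS3-like loci: two miR390-complementary sites separated by an
  integer number of 21-nt phase cycles (8-13), phased 21-nt reads on
  both strands with exact DCL4 duplex geometry (minus-strand partner
  offset -2 nt), strongly down in the mutant;
* discrete miRNA loci (21 nt, genotype-neutral);
* hairpin/antisense 22-nt loci (up in the mutant);
* LTR-repeat-like multicopy loci emitting multimapped 21/22-nt reads
  (up in the mutant);
* 24-nt heterochromatic loci (down in the mutant);
* null background loci: unphased 21-nt reads at unchanged abundance.

Per-locus, per-library counts are negative-binomial around
class-mean x genotype-fold x size-factor expectations. ARF3-like
transcripts carry two tasiR-ARF-complementary sites ~200 nt apart, and
PARE tags pile up at every truly cleaved position (the 3' miR390 site of
each TAS locus and both tasiR-ARF sites of each ARF transcript) over a
uniform low background; annotated decoy positions receive background
only.

Library size defaults to 1e6 so RPM equals raw counts, keeping hand
checks trivial. All outputs are deterministic given the seed.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .srio import AlignmentRecord, Library, write_bed
from .targetscore import reverse_complement_dna

# canonical trigger and effector sequences of the two-hit pathway
MIR390 = "AAGCUCAGGAGGGAUAGCGCC"  # 21-nt trigger miRNA
TASIARF = "UUCUUGACCUUGUAAGACCCC"  # 21-nt TAS3-derived ARF-targeting ta-siRNA

PHASE_LEN = 21
OVERHANG = 2


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic dataset."""

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 150_000
    # locus counts per class
    n_tas: int = 8
    n_mirna: int = 5
    n_hairpin22: int = 5
    n_repeat_families: int = 3
    repeat_copies: int = 3
    n_het24: int = 6
    n_null: int = 60
    n_arf: int = 3
    # per-strand phase cycles between the two miR390 sites of a TAS locus
    tas_cycles_min: int = 8
    tas_cycles_max: int = 13
    tasiarf_d_index: int = 7  # D position carrying the planted tasiR-ARF
    # class mean abundances (RPM; with lib_size 1e6, also expected counts)
    tas_mean: float = 300.0
    mirna_mean: float = 200.0
    hairpin_mean: float = 100.0
    repeat_mean: float = 100.0
    het_mean: float = 100.0
    null_mean: float = 60.0
    # genotype fold changes (mutant / wild-type)
    tas_fold: float = 0.02  # ~50x down, within the observed TAS range
    mirna_fold: float = 1.0
    hairpin_fold: float = 4.0
    repeat_fold: float = 4.0
    het_fold: float = 0.25
    null_fold: float = 1.0
    dispersion: float = 0.1  # NB dispersion of replicate counts
    noise_frac: float = 0.10  # out-of-phase fraction at TAS loci
    offsize_frac: float = 0.10  # non-21-nt fraction at 21-nt loci
    lib_size: float = 1e6  # genome-matched reads per library
    n_replicates: int = 3
    # PARE
    pare_depth: float = 20.0  # mean tags at a truly cleaved position
    pare_background: float = 0.02  # mean background tags per nt
    arf_len: int = 600
    arf_site_spacing: int = 200  # distance between the two tasiR-ARF sites

    def validate(self) -> None:
        rates = [
            self.tas_mean, self.mirna_mean, self.hairpin_mean, self.repeat_mean,
            self.het_mean, self.null_mean, self.pare_depth, self.pare_background,
            self.dispersion,
        ]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be >= 0")
        folds = [self.tas_fold, self.mirna_fold, self.hairpin_fold,
                 self.repeat_fold, self.het_fold, self.null_fold]
        if any(f <= 0 for f in folds):
            raise ValueError("fold changes must be > 0")
        for f in (self.noise_frac, self.offsize_frac):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class LocusTruth:
    """Ground truth for one planted locus."""

    locus_id: str
    locus_class: str  # tas | mirna | hairpin22 | repeat | het24 | null
    chrom: str
    start: int
    end: int
    mean_rpm: float
    fold: float  # mutant / wild-type
    size_class: int
    # TAS-specific
    n_cycles: int = 0
    site5: tuple[int, int] | None = None
    site3: tuple[int, int] | None = None
    cleavage: int | None = None  # genomic phase-setting cut position
    register: int | None = None
    tasiarf_d_index: int | None = None
    # repeat-specific: (chrom, start) of each family copy
    copy_positions: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class ArfTruth:
    """Ground truth for one ARF3-like target transcript."""

    transcript_id: str
    sequence: str
    site_intervals: list[tuple[int, int]]
    cleavage_positions: list[int]  # truly cleaved
    decoy_positions: list[int]  # never cleaved


@dataclass
class GroundTruth:
    config: GeneratorConfig
    chrom_lengths: dict[str, int]
    loci: list[LocusTruth]
    arfs: list[ArfTruth]
    tas_transcripts: dict[str, tuple[str, int]]  # locus -> (chrom, offset)
    size_factors: dict[str, float]

    def loci_of(self, locus_class: str) -> list[LocusTruth]:
        return [l for l in self.loci if l.locus_class == locus_class]


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _mutate(seq: str, idx: int, rng: np.random.Generator) -> str:
    """Substitute position idx with a different base."""
    options = [b for b in "ACGT" if b != seq[idx]]
    return seq[:idx] + options[rng.integers(0, len(options))] + seq[idx + 1 :]


def _place(
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    chroms: Sequence[str],
    chrom_len: int,
    width: int,
    margin: int = 1200,
    max_tries: int = 2000,
) -> tuple[str, int]:
    """Uniformly place an interval avoiding existing loci, with retries.

    The margin keeps distinct loci more than two analysis windows apart,
    mirroring the genomic sparsity of real sRNA loci, so windowed stages
    cannot merge two planted loci into one feature.
    """
    for _ in range(max_tries):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(margin, chrom_len - width - margin))
        if all(
            start >= e + margin or start + width + margin <= s
            for s, e in occupied[chrom]
        ):
            occupied[chrom].append((start, start + width))
            return chrom, start
    raise RuntimeError("could not place locus without overlap; genome too small")


def make_genome(config: GeneratorConfig) -> tuple[dict[str, str], GroundTruth]:
    """Build the toy genome and its ground truth.

    Returns ({chrom: sequence}, GroundTruth). Sequences are mutable via
    planting: TAS loci overwrite the background with their two miR390
    sites (the 5' site carries one seed-distal mismatch, the 3' site is
    perfectly complementary and cleavable) and, where configured, a
    tasiR-ARF at one D position.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i+1}" for i in range(config.n_chroms)]
    genome = {c: list(_random_seq(rng, config.chrom_len)) for c in chroms}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    loci: list[LocusTruth] = []
    tas_transcripts: dict[str, tuple[str, int]] = {}

    mir390_dna = MIR390.replace("U", "T")
    site_seq = reverse_complement_dna(mir390_dna)  # perfect miR390 site
    tasiarf_dna = TASIARF.replace("U", "T")

    # --- TAS3-like two-hit loci -------------------------------------------
    for j in range(config.n_tas):
        m = int(rng.integers(config.tas_cycles_min, config.tas_cycles_max + 1))
        width = 21 + 21 * m + 10  # site5 + phased span + 3' half of site3
        chrom, s5 = _place(rng, occupied, chroms, config.chrom_len, width)
        e5 = s5 + 21
        c = e5 + 21 * m  # phase-setting cleavage position
        s3 = c - 11  # 3' site [c-11, c+10): cut opposite trigger pos 10
        seq = genome[chrom]
        # 5' site: one mismatch at trigger position 16 (outside the core)
        site5_seq = _mutate(site_seq, 21 - 16, rng)
        seq[s5:e5] = list(site5_seq)
        seq[s3 : s3 + 21] = list(site_seq)
        d_idx = None
        if j % 4 != 3 and config.tasiarf_d_index <= m:
            d_idx = config.tasiarf_d_index
            ds = c - 21 * d_idx
            seq[ds : ds + 21] = list(tasiarf_dna)
        locus_id = f"tas_{j+1:02d}"
        loci.append(
            LocusTruth(
                locus_id, "tas", chrom, s5, c + 10,
                mean_rpm=config.tas_mean, fold=config.tas_fold, size_class=21,
                n_cycles=m, site5=(s5, e5), site3=(s3, s3 + 21),
                cleavage=c, register=c % PHASE_LEN, tasiarf_d_index=d_idx,
            )
        )
        tas_transcripts[locus_id] = (chrom, max(0, s5 - 30))

    # --- simple single-position and diffuse loci --------------------------
    def plain(cls, n, width, mean, fold, size):
        for j in range(n):
            chrom, s = _place(rng, occupied, chroms, config.chrom_len, width)
            loci.append(
                LocusTruth(
                    f"{cls}_{j+1:02d}", cls, chrom, s, s + width,
                    mean_rpm=mean, fold=fold, size_class=size,
                )
            )

    plain("mirna", config.n_mirna, 21, config.mirna_mean, config.mirna_fold, 21)
    plain("hairpin22", config.n_hairpin22, 120, config.hairpin_mean, config.hairpin_fold, 22)
    plain("het24", config.n_het24, 500, config.het_mean, config.het_fold, 24)
    plain("null", config.n_null, 500, config.null_mean, config.null_fold, 21)

    # --- multicopy repeat families ----------------------------------------
    rep_width = 300
    for j in range(config.n_repeat_families):
        fam_seq = _random_seq(rng, rep_width)
        positions = []
        chrom0 = None
        for _ in range(config.repeat_copies):
            chrom, s = _place(rng, occupied, chroms, config.chrom_len, rep_width)
            if chrom0 is None:
                chrom0 = chrom
            genome[chrom][s : s + rep_width] = list(fam_seq)
            positions.append((chrom, s))
        loci.append(
            LocusTruth(
                f"repeat_{j+1:02d}", "repeat", positions[0][0], positions[0][1],
                positions[0][1] + rep_width,
                mean_rpm=config.repeat_mean, fold=config.repeat_fold, size_class=22,
                copy_positions=positions,
            )
        )

    # --- ARF3-like transcripts --------------------------------------------
    arf_site = reverse_complement_dna(tasiarf_dna)
    # one mismatch outside the core: planted-site duplex score 1.0
    arfs: list[ArfTruth] = []
    for j in range(config.n_arf):
        tx = list(_random_seq(rng, config.arf_len))
        first = 120
        second = first + 21 + config.arf_site_spacing
        site_intervals, cleavages = [], []
        for s in (first, second):
            planted = _mutate(arf_site, 21 - 16, rng)
            tx[s : s + 21] = list(planted)
            site_intervals.append((s, s + 21))
            cleavages.append(s + 21 - 10)
        decoys = [config.arf_len - 80]
        arfs.append(
            ArfTruth(f"arf3_{chr(ord('a')+j)}", "".join(tx), site_intervals, cleavages, decoys)
        )

    lib_names = [
        f"{g}_{r+1}" for g in ("wildtype", "mutant") for r in range(config.n_replicates)
    ]
    truth = GroundTruth(
        config=config,
        chrom_lengths={c: config.chrom_len for c in chroms},
        loci=loci,
        arfs=arfs,
        tas_transcripts=tas_transcripts,
        size_factors={n: 1.0 for n in lib_names},
    )
    return {c: "".join(seq) for c, seq in genome.items()}, truth


def make_libraries(config: GeneratorConfig) -> dict[str, Library]:
    libs = {}
    for g in ("wildtype", "mutant"):
        for r in range(config.n_replicates):
            name = f"{g}_{r+1}"
            libs[name] = Library(name, g, r + 1, config.lib_size)
    return libs


def _nb_draw(rng: np.random.Generator, mean: float, phi: float) -> int:
    if mean <= 0:
        return 0
    if phi <= 1e-9:
        return int(rng.poisson(mean))
    r = 1.0 / phi
    return int(rng.negative_binomial(r, r / (r + mean)))


def _offsize(rng: np.random.Generator, base: int) -> int:
    choices = [k for k in (19, 20, 22, 23, 24) if k != base]
    return int(np.asarray(choices)[rng.integers(0, len(choices))])


def simulate_reads(
    truth: GroundTruth, config: GeneratorConfig | None = None, seed: int | None = None
) -> dict[str, list[AlignmentRecord]]:
    """Simulate per-library alignment records for every planted locus.

    Per library and locus the total read count is NB(mean x fold x size
    factor, dispersion). TAS reads land on D-position duplexes (minus
    strand at plus start - 2) with probability 1 - noise_frac, otherwise
    uniformly off register; a configured fraction of reads at 21/22-nt
    loci takes an off-size length. Repeat-family reads are reported at
    every genomic copy with n_hits = copy number.
    """
    cfg = config or truth.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    libs = make_libraries(cfg)
    out: dict[str, list[AlignmentRecord]] = {}
    for name, lib in libs.items():
        agg: Counter = Counter()
        mut = lib.genotype == "mutant"
        sf = truth.size_factors[name]
        for locus in truth.loci:
            mu = locus.mean_rpm * (locus.fold if mut else 1.0) * sf * cfg.lib_size / 1e6
            n_reads = _nb_draw(rng, mu, cfg.dispersion)
            if n_reads == 0:
                continue
            emit = getattr(_Emitters, locus.locus_class)
            emit(agg, locus, n_reads, cfg, rng)
        out[name] = [
            AlignmentRecord(chrom, start, length, strand, copies, n_hits)
            for (chrom, start, length, strand, n_hits), copies in sorted(agg.items())
        ]
    return out


class _Emitters:
    """Per-class read placement; each adds (chrom,start,len,strand,n_hits)->copies."""

    @staticmethod
    def tas(agg, locus, n, cfg, rng):
        c = locus.cleavage
        m = locus.n_cycles
        for _ in range(n):
            if rng.random() < cfg.offsize_frac:
                length = _offsize(rng, 21)
                start = int(rng.integers(locus.start, locus.end - length))
                agg[(locus.chrom, start, length, "+", 1)] += 1
                continue
            if rng.random() < cfg.noise_frac:
                # off-register: uniform start not congruent with the register
                while True:
                    start = int(rng.integers(locus.start, locus.end - 21))
                    if start % PHASE_LEN != locus.register:
                        break
                agg[(locus.chrom, start, 21, "+", 1)] += 1
            else:
                i = int(rng.integers(1, m + 1))
                plus_start = c - PHASE_LEN * i
                if rng.random() < 0.5:
                    agg[(locus.chrom, plus_start, 21, "+", 1)] += 1
                else:
                    agg[(locus.chrom, plus_start - OVERHANG, 21, "-", 1)] += 1

    @staticmethod
    def mirna(agg, locus, n, cfg, rng):
        for _ in range(n):
            length = 21 if rng.random() >= cfg.offsize_frac else _offsize(rng, 21)
            agg[(locus.chrom, locus.start, length, "+", 1)] += 1

    @staticmethod
    def hairpin22(agg, locus, n, cfg, rng):
        arms = (locus.start, locus.end - 22)
        for _ in range(n):
            a = int(rng.integers(0, 2))
            agg[(locus.chrom, arms[a], 22, "+-"[a], 1)] += 1

    @staticmethod
    def het24(agg, locus, n, cfg, rng):
        for _ in range(n):
            start = int(rng.integers(locus.start, locus.end - 24))
            strand = "+-"[rng.integers(0, 2)]
            agg[(locus.chrom, start, 24, strand, 1)] += 1

    @staticmethod
    def repeat(agg, locus, n, cfg, rng):
        copies = locus.copy_positions  # (chrom, start) of each family copy
        width = locus.end - locus.start
        n_hits = len(copies)
        for _ in range(n):
            off = int(rng.integers(0, width - 22))
            for chrom, cstart in copies:
                agg[(chrom, cstart + off, 22, "+", n_hits)] += 1

    @staticmethod
    def null(agg, locus, n, cfg, rng):
        for _ in range(n):
            start = int(rng.integers(locus.start, locus.end - 21))
            strand = "+-"[rng.integers(0, 2)]
            agg[(locus.chrom, start, 21, strand, 1)] += 1


def simulate_pare(
    truth: GroundTruth, config: GeneratorConfig | None = None, seed: int | None = None
) -> dict[str, dict[int, float]]:
    """Simulate pooled PARE tag maps for ARF3-like and TAS transcripts.

    Truly cleaved positions (both tasiR-ARF sites of each ARF transcript,
    the 3' miR390 cut of each TAS transcript) receive Poisson(depth)
    tags; every position receives Poisson(background) tags; decoys get
    background only.
    """
    cfg = config or truth.config
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    tags: dict[str, dict[int, float]] = {}

    def background(tx_id: str, length: int):
        tmap = tags.setdefault(tx_id, {})
        if cfg.pare_background > 0:
            counts = rng.poisson(cfg.pare_background, length)
            for pos in np.nonzero(counts)[0]:
                tmap[int(pos)] = tmap.get(int(pos), 0.0) + float(counts[pos])
        return tmap

    for arf in truth.arfs:
        tmap = background(arf.transcript_id, len(arf.sequence))
        for pos in arf.cleavage_positions:
            tmap[pos] = tmap.get(pos, 0.0) + float(rng.poisson(cfg.pare_depth))

    for locus in truth.loci_of("tas"):
        chrom, offset = truth.tas_transcripts[locus.locus_id]
        length = locus.end - offset + 40
        tmap = background(locus.locus_id, length)
        pos = locus.cleavage - offset
        tmap[pos] = tmap.get(pos, 0.0) + float(rng.poisson(cfg.pare_depth))
    return tags


# ---------------------------------------------------------------------------
# file emission


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_truth_gff(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for l in truth.loci:
            attrs = f"ID={l.locus_id};class={l.locus_class};fold={l.fold}"
            if l.locus_class == "tas":
                attrs += f";cycles={l.n_cycles};register={l.register};cleavage={l.cleavage}"
            fh.write(
                f"{l.chrom}\tphasitrack_sim\tsRNA_locus\t{l.start+1}\t{l.end}\t.\t+\t.\t{attrs}\n"
            )


def write_pare_tsv(tags: Mapping[str, Mapping[int, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript\tposition\tcount\n")
        for tx in sorted(tags):
            for pos in sorted(tags[tx]):
                fh.write(f"{tx}\t{pos}\t{tags[tx][pos]:g}\n")


def write_dataset(config: GeneratorConfig, outdir: str | Path) -> GroundTruth:
    """Emit a full dataset (FASTA, per-library BED, PARE TSV, truth GFF/JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = make_genome(config)
    write_fasta(genome, outdir / "genome.fa")
    reads = simulate_reads(truth, config)
    for name, records in reads.items():
        write_bed(records, outdir / f"{name}.bed")
    write_pare_tsv(simulate_pare(truth, config), outdir / "pare_tags.tsv")
    write_truth_gff(truth, outdir / "truth.gff3")
    sidecar = {
        "config": asdict(config),
        "chrom_lengths": truth.chrom_lengths,
        "size_factors": truth.size_factors,
        "loci": [
            {k: v for k, v in asdict(l).items()} for l in truth.loci
        ],
        "arf_transcripts": {a.transcript_id: a.sequence for a in truth.arfs},
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=1, default=list))
    return truth
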