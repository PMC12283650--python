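"""Self-contained synthetic cfDNA cohort with planted repeat-element effects.

The generator builds a small toy genome (i.i.d. uniform A/C/G/T background so
complexity contrasts are controlled), lays out non-overlapping repeat regions
for several families (Alu-like, L1-like, STR motifs over 1-6 bp units,
low-complexity, plus unclassified / blacklisted / sex-chromosome / dormant
regions that exercise the catalog filters), and simulates per-sample fragment
sets with the following planted differences between cancer and healthy
samples:

* per-region fragment counts are Poisson with a family-level enrichment
  multiplier in cancer (Alu and STR);
* fragment lengths come from a two-component discretised normal (short mode
  145 bp, long mode 167 bp, sd 10, truncated to [50, 400] bp) with a larger
  short-component probability in cancer;
* reads over an STR locus carry ``n2 + k`` motif units (k >= 1) with a
  label-dependent expansion probability, realised by inserting extra motif
  copies mid-locus into the read sequence;
* a fraction of cancer Alu reads is replaced by a low-complexity variant of
  the same length;
* regions designated as regulatory for a sample's cancer type receive an
  extra coverage boost, which is what the tissue-of-origin stage recovers.

Default effect sizes are deliberately comfortable for a 30-vs-30 cohort and
are recorded here as the shipped configuration.  Identical config + seed
yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalog import RepeatRegion, StrLocus, make_region, write_rmsk
from .fragments import Fragment, write_fragments_bed, write_fasta_sidecar

__all__ = [
    "SimulationConfig",
    "SyntheticGenome",
    "SampleRecord",
    "Cohort",
    "generate_catalog",
    "simulate_sample",
    "simulate_peaks",
    "simulate_cohort",
    "write_cohort",
    "HISTONE_MARKS",
]

HISTONE_MARKS = ("H3K27ac", "H3K4me1", "H3K4me3")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort (defaults = shipped config)."""

    seed: int = 0
    n_healthy: int = 30
    n_cancer: int = 30
    cancer_types: tuple[str, ...] = ("colorectal", "lung", "liver")
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 400_000),
        ("chr2", 250_000),
        ("chrX", 60_000),
    )
    # region layout
    n_alu: int = 40
    n_l1: int = 25
    n_low_complexity: int = 12
    n_rare: int = 4          # tiny family, removed by the family-frequency rule
    n_unclassified: int = 6
    n_blacklisted: int = 6   # regions whose span is added to the exclusion BED
    n_sex_chrom: int = 4     # Alu regions placed on chrX
    n_dormant: int = 4       # L1 regions that never receive fragments
    str_loci_per_unit: int = 10   # STR loci per unit length 1..6
    str_n2_min: int = 8
    str_max_span: int = 96   # cap n1*n2 so typical reads span the locus
    # coverage model
    coverage_lambda: float = 8.0
    enrichment_multiplier: tuple[tuple[str, float], ...] = (
        ("Alu", 1.6),
        ("Simple_repeat", 1.6),
    )
    background_fragments: float = 400.0
    # fragment length model
    short_fraction_healthy: float = 0.20
    short_fraction_cancer: float = 0.45
    length_modes: tuple[int, int, float] = (145, 167, 10.0)  # short, long, sd
    length_bounds: tuple[int, int] = (50, 400)
    # STR expansion model
    expansion_rate_healthy: float = 0.01
    expansion_rate_cancer: float = 0.08
    extra_unit_mean: float = 1.0  # expanded reads carry 1 + Poisson(mean) extra units
    # read complexity model
    complexity_decay_cancer: float = 0.25
    # tissue-of-origin model: designated regulatory regions keep normal
    # coverage in healthy plasma, are boosted in the matched cancer type and
    # strongly attenuated in other cancer types (tumor-specific chromatin)
    too_boost: float = 3.0
    too_attenuation: float = 0.05
    too_regions_per_type: int = 12
    n_chip_samples: int = 5
    # mapping metadata
    low_mapq_fraction: float = 0.02
    # catalog-filter scale matched to the toy genome
    min_family_instances: int = 10

    def validate(self) -> None:
        probs = [
            self.short_fraction_healthy,
            self.short_fraction_cancer,
            self.expansion_rate_healthy,
            self.expansion_rate_cancer,
            self.complexity_decay_cancer,
            self.low_mapq_fraction,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        counts = [self.n_healthy, self.n_cancer, self.n_alu, self.str_loci_per_unit,
                  self.n_chip_samples, self.too_regions_per_type]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.coverage_lambda <= 0 or self.too_boost <= 0:
            raise ValueError("coverage parameters must be positive")

    def enrichment(self) -> dict[str, float]:
        return dict(self.enrichment_multiplier)


@dataclass
class SyntheticGenome:
    """Toy reference, repeat catalog and planted structure."""

    config: SimulationConfig
    sequences: dict[str, str]
    regions: list[RepeatRegion]
    blacklist: list[tuple[str, int, int]]
    dormant: frozenset[int]
    too_regions: dict[str, tuple[int, ...]]  # cancer type -> region indices

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass
class SampleRecord:
    sample_id: str
    label: str  # "healthy" | "cancer"
    cancer_type: str | None
    split: str  # "train" | "test"
    fragments: list[Fragment]


@dataclass
class Cohort:
    config: SimulationConfig
    genome: SyntheticGenome
    samples: list[SampleRecord]
    reference: SampleRecord
    peaks: dict[tuple[str, str, str], list[tuple[str, int, int]]] = field(
        default_factory=dict
    )


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _random_motif(rng: np.random.Generator, n1: int) -> str:
    units = "ACGT"
    motif = "".join(units[rng.integers(0, 4)] for _ in range(n1))
    # avoid motifs that reduce to a shorter unit (e.g. "AA" -> "A")
    while n1 > 1 and len(set(motif)) == 1:
        motif = "".join(units[rng.integers(0, 4)] for _ in range(n1))
    return motif


def generate_catalog(config: SimulationConfig) -> SyntheticGenome:
    """Build the toy reference, rmsk-style catalog and exclusion regions."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    chrom_arrays = {name: _random_seq(rng, size) for name, size in config.genome}
    chrom_sizes = dict(config.genome)
    autosomes = [n for n in chrom_sizes if n not in {"chrX", "chrY"}]
    if not autosomes:
        raise ValueError("genome needs at least one autosome")

    plan: list[dict] = []
    for i in range(config.n_alu):
        plan.append(dict(name=f"AluY{i}", cls="SINE", fam="Alu", length=280))
    for i in range(config.n_l1):
        plan.append(dict(name=f"L1M{i}", cls="LINE", fam="L1", length=600,
                         dormant=i < config.n_dormant))
    for n1 in range(1, 7):
        for _ in range(config.str_loci_per_unit):
            motif = _random_motif(rng, n1)
            n2_max = max(config.str_n2_min + 1, config.str_max_span // n1)
            n2 = int(rng.integers(config.str_n2_min, n2_max + 1))
            plan.append(dict(name=f"({motif}){n2}", cls="Simple_repeat",
                             fam="Simple_repeat", length=n1 * n2, motif=motif,
                             n2=n2))
    for i in range(config.n_low_complexity):
        plan.append(dict(name=f"A-rich{i}", cls="Low_complexity",
                         fam="Low_complexity", length=100, lowc=True))
    for i in range(config.n_rare):
        plan.append(dict(name=f"MERr{i}", cls="DNA", fam="MER-rare", length=200))
    for i in range(config.n_unclassified):
        plan.append(dict(name=f"Un{i}", cls="Unknown", fam="Unknown", length=200))
    for i in range(config.n_blacklisted):
        plan.append(dict(name=f"AluBl{i}", cls="SINE", fam="Alu", length=280,
                         blacklisted=True))
    for i in range(config.n_sex_chrom):
        plan.append(dict(name=f"AluX{i}", cls="SINE", fam="Alu", length=280,
                         chrom="chrX"))

    # deterministic shuffled placement along autosome cursors
    order = rng.permutation(len(plan))
    cursors = {name: 1000 for name in chrom_sizes}
    chrom_cycle = 0
    placements: list[tuple[int, str, int]] = []  # (plan index, chrom, start)
    for pi in order:
        spec = plan[pi]
        if "chrom" in spec:
            chrom = spec["chrom"]
        else:
            chrom = autosomes[chrom_cycle % len(autosomes)]
            chrom_cycle += 1
        gap = int(rng.integers(150, 500))
        start = cursors[chrom] + gap
        end = start + spec["length"]
        if end + 1000 > chrom_sizes[chrom]:
            raise ValueError(
                f"genome too small: {chrom} cannot accommodate region {spec['name']}"
            )
        cursors[chrom] = end
        placements.append((pi, chrom, start))

    regions: list[RepeatRegion] = []
    blacklist: list[tuple[str, int, int]] = []
    dormant: set[int] = set()
    for pi, chrom, start in sorted(placements, key=lambda p: (p[1], p[2])):
        spec = plan[pi]
        end = start + spec["length"]
        arr = chrom_arrays[chrom]
        if "motif" in spec:  # STR locus: motif repeated exactly n2 times
            motif = spec["motif"]
            unit = np.frombuffer(motif.encode(), dtype=np.uint8)
            arr[start:end] = np.tile(unit, spec["n2"])
            # guard bases so the tandem run cannot extend into the flanks:
            # the reference then witnesses exactly n2 units
            left_guard = next(b for b in "ACGT" if b != motif[-1])
            right_guard = next(b for b in "ACGT" if b != motif[0])
            arr[start - 1] = ord(left_guard)
            arr[end] = ord(right_guard)
        elif spec.get("lowc"):  # AAAAC-tiled low-complexity stretch
            unit = np.frombuffer(b"AAAAC", dtype=np.uint8)
            arr[start:end] = np.tile(unit, spec["length"] // 5 + 1)[: spec["length"]]
        idx = len(regions)
        regions.append(
            make_region(chrom, start, end, "+", spec["name"], spec["cls"], spec["fam"])
        )
        if spec.get("blacklisted"):
            blacklist.append((chrom, start - 50, end + 50))
        if spec.get("dormant"):
            dormant.add(idx)

    # designate disjoint regulatory region sets per cancer type (Alu + STR,
    # autosomal, not blacklisted/dormant)
    eligible = [
        i
        for i, r in enumerate(regions)
        if r.family_key in {"Alu", "Simple_repeat"}
        and r.chrom not in {"chrX", "chrY"}
        and not any(r.chrom == c and r.start < e and r.end > s
                    for c, s, e in blacklist)
        and i not in dormant
    ]
    need = config.too_regions_per_type * len(config.cancer_types)
    if len(eligible) < need:
        raise ValueError("not enough eligible regions for the requested TOO sets")
    chosen = rng.choice(len(eligible), size=need, replace=False)
    too_regions: dict[str, tuple[int, ...]] = {}
    for t, ctype in enumerate(config.cancer_types):
        sel = chosen[t * config.too_regions_per_type : (t + 1) * config.too_regions_per_type]
        too_regions[ctype] = tuple(sorted(eligible[j] for j in sel))

    sequences = {name: arr.tobytes().decode() for name, arr in chrom_arrays.items()}
    return SyntheticGenome(config, sequences, regions, blacklist,
                           frozenset(dormant), too_regions)


def _draw_length(rng: np.random.Generator, config: SimulationConfig,
                 short_fraction: float) -> int:
    short_mode, long_mode, sd = config.length_modes
    mode = short_mode if rng.random() < short_fraction else long_mode
    lo, hi = config.length_bounds
    return int(np.clip(round(rng.normal(mode, sd)), lo, hi))


def simulate_sample(
    config: SimulationConfig,
    genome: SyntheticGenome,
    sample_id: str,
    label: str,
    cancer_type: str | None = None,
    depth_scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[Fragment]:
    """Simulate one sample's fragment set (sequences attached).

    Low-mapq decoy fragments are included so the QC stage has work to do;
    downstream feature extraction should consume the QC-filtered stream.
    """
    if label not in {"healthy", "cancer"}:
        raise ValueError(f"unknown label {label!r}")
    if (cancer_type is None) != (label == "healthy"):
        raise ValueError("cancer_type must be set iff label='cancer'")
    if cancer_type is not None and cancer_type not in config.cancer_types:
        raise ValueError(f"unknown cancer type {cancer_type!r}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    cancer = label == "cancer"
    short_fraction = (
        config.short_fraction_cancer if cancer else config.short_fraction_healthy
    )
    expansion_rate = (
        config.expansion_rate_cancer if cancer else config.expansion_rate_healthy
    )
    enrichment = config.enrichment()
    boosted = set(genome.too_regions.get(cancer_type, ())) if cancer else set()
    designated = (
        {i for ids in genome.too_regions.values() for i in ids} if cancer else set()
    )
    chrom_sizes = {name: len(seq) for name, seq in genome.sequences.items()}

    fragments: list[Fragment] = []
    serial = 0

    def emit(chrom: str, start: int, length: int, seq: str | None = None) -> None:
        nonlocal serial
        end = start + length
        ref = genome.sequences[chrom]
        mapq = 10 if rng.random() < config.low_mapq_fraction else 60
        fragments.append(
            Fragment(
                chrom,
                start,
                end,
                name=f"{sample_id}:f{serial}",
                mapq=mapq,
                strand="+" if rng.random() < 0.5 else "-",
                sequence=seq if seq is not None else ref[start:end],
            )
        )
        serial += 1

    for idx, region in enumerate(genome.regions):
        if idx in genome.dormant:
            continue
        lam = config.coverage_lambda * depth_scale
        if cancer:
            lam *= enrichment.get(region.family_key, 1.0)
            if idx in boosted:
                lam *= config.too_boost
            elif idx in designated:
                lam *= config.too_attenuation
        for _ in range(rng.poisson(lam)):
            length = _draw_length(rng, config, short_fraction)
            size = chrom_sizes[region.chrom]
            if isinstance(region, StrLocus):
                # center near the locus so reads usually span it
                center = (region.start + region.end) // 2 + int(rng.integers(-15, 16))
                start = center - length // 2
            else:
                start = int(rng.integers(region.start - length + 1, region.end))
            start = max(0, min(start, size - length))
            seq = None
            if isinstance(region, StrLocus):
                covers = start <= region.start and start + length >= region.end
                if covers and rng.random() < expansion_rate:
                    k = 1 + int(rng.poisson(config.extra_unit_mean))
                    ref = genome.sequences[region.chrom]
                    seq = (
                        ref[start : region.start]
                        + region.motif * (region.n2 + k)
                        + ref[region.end : start + length]
                    )
            elif (
                cancer
                and region.family_key == "Alu"
                and rng.random() < config.complexity_decay_cancer
            ):
                di = ("AT", "AC", "AG", "CT")[rng.integers(0, 4)]
                seq = (di * (length // 2 + 1))[:length]
            emit(region.chrom, start, length, seq)

    # background fragments spread uniformly over the genome
    chroms = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    dormant_spans = [
        (genome.regions[i].chrom, genome.regions[i].start, genome.regions[i].end)
        for i in genome.dormant
    ]
    for _ in range(rng.poisson(config.background_fragments * depth_scale)):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        length = _draw_length(rng, config, short_fraction)
        # keep dormant regions truly uncovered so the zero-coverage filter
        # has something to remove
        for _attempt in range(20):
            start = int(rng.integers(0, chrom_sizes[chrom] - length))
            end = start + length
            if not any(c == chrom and start < e and end > s
                       for c, s, e in dormant_spans):
                break
        emit(chrom, start, length)

    return fragments


def simulate_peaks(
    config: SimulationConfig,
    genome: SyntheticGenome,
    rng: np.random.Generator | None = None,
) -> dict[tuple[str, str, str], list[tuple[str, int, int]]]:
    """Per (cancer type, histone mark, ChIP sample) peak interval sets.

    Each type's designated regulatory regions are supported by 2 or 3 marks
    in strictly more than half of that mark's ChIP samples; all other Alu/STR
    regions only ever appear in a minority of samples.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    n = config.n_chip_samples
    if n < 3:
        raise ValueError("need >=3 ChIP samples per mark")
    majority = n // 2 + 1
    candidates = [
        i for i, r in enumerate(genome.regions)
        if r.family_key in {"Alu", "Simple_repeat"}
    ]
    peaks: dict[tuple[str, str, str], list[tuple[str, int, int]]] = {
        (ctype, mark, f"chip{s}"): []
        for ctype in config.cancer_types
        for mark in HISTONE_MARKS
        for s in range(n)
    }
    for ctype in config.cancer_types:
        designated = set(genome.too_regions[ctype])
        for idx in candidates:
            region = genome.regions[idx]
            interval = (region.chrom, max(0, region.start - 25), region.end + 25)
            if idx in designated:
                n_marks = 2 + int(rng.integers(0, 2))  # 2 or 3 supporting marks
                marks = rng.choice(len(HISTONE_MARKS), size=n_marks, replace=False)
                supporting = {HISTONE_MARKS[m] for m in marks}
            else:
                supporting = set()
            for mark in HISTONE_MARKS:
                if mark in supporting:
                    k = int(rng.integers(majority, n + 1))
                else:
                    k = int(rng.integers(0, majority))  # minority only
                for s in rng.choice(n, size=k, replace=False):
                    peaks[(ctype, mark, f"chip{s}")].append(interval)
    for key in peaks:
        peaks[key].sort()
    return peaks


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full synthetic cohort: catalog, samples, reference, peaks."""
    genome = generate_catalog(config)
    samples: list[SampleRecord] = []
    specs: list[tuple[str, str, str | None]] = []
    for i in range(config.n_healthy):
        specs.append((f"H{i:03d}", "healthy", None))
    for i in range(config.n_cancer):
        ctype = config.cancer_types[i % len(config.cancer_types)]
        specs.append((f"C{i:03d}", "cancer", ctype))
    n_train = round(len(specs) * 0.68)
    for si, (sid, label, ctype) in enumerate(specs):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1000 + si]))
        frags = simulate_sample(config, genome, sid, label, ctype, rng=rng)
        split = "train" if si % len(specs) < n_train else "test"
        samples.append(SampleRecord(sid, label, ctype, split, frags))
    # interleave train/test deterministically across labels
    for si, rec in enumerate(samples):
        rec.split = "train" if (si * 17) % 25 < 17 else "test"
    ref_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 999]))
    reference = SampleRecord(
        "REF", "healthy", None, "reference",
        simulate_sample(config, genome, "REF", "healthy", depth_scale=2.0,
                        rng=ref_rng),
    )
    peaks = simulate_peaks(
        config, genome, np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    )
    return Cohort(config, genome, samples, reference, peaks)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Persist a cohort as text files (BED/FASTA/TSV); returns the directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = cohort.genome

    with open(out / "genome.fa", "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_rmsk(genome.regions, out / "rmsk.tsv")
    with open(out / "exclusion.bed", "w") as fh:
        for chrom, start, end in sorted(genome.blacklist):
            fh.write(f"{chrom}\t{start}\t{end}\n")

    frag_dir = out / "fragments"
    frag_dir.mkdir(exist_ok=True)
    rows = []
    for rec in [*cohort.samples, cohort.reference]:
        bed = frag_dir / f"{rec.sample_id}.bed.gz"
        fasta = frag_dir / f"{rec.sample_id}.fa.gz"
        write_fragments_bed(rec.fragments, bed)
        write_fasta_sidecar(rec.fragments, fasta)
        rows.append(
            (rec.sample_id, str(bed.relative_to(out)), str(fasta.relative_to(out)),
             rec.label, rec.cancer_type or "NA", rec.split)
        )
    with open(out / "samples.tsv", "w") as fh:
        fh.write("sample_id\tpath\tseqs_path\tlabel\tcancer_type\tcohort_split\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")

    peak_dir = out / "peaks"
    peak_dir.mkdir(exist_ok=True)
    with open(out / "peaks_manifest.tsv", "w") as mh:
        mh.write("cancer_type\tmark\tchip_sample\tpath\n")
        for (ctype, mark, chip), intervals in sorted(cohort.peaks.items()):
            path = peak_dir / f"{ctype}_{mark}_{chip}.bed"
            with open(path, "w") as fh:
                for chrom, start, end in intervals:
                    fh.write(f"{chrom}\t{start}\t{end}\n")
            mh.write(f"{ctype}\t{mark}\t{chip}\t{path.relative_to(out)}\n")
    return out
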