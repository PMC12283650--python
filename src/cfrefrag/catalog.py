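"""Repeat-element catalog: rmsk parsing, cfRE filtering, STR sub-groups.

The catalog starts from a RepeatMasker-style annotation (UCSC rmsk table or
the 7-column dialect genoName/genoStart/genoEnd/strand/repName/repClass/
repFamily).  Simple_repeat rows whose repName encodes the motif as
``(MOTIF)n`` become :class:`StrLocus` records carrying the unit length ``n1``
and the reference unit count ``n2 = round(span / n1)``.

Regions covered by plasma cfDNA ("cfREs") are obtained by a five-step
filter applied in a fixed order:

i)   drop regions that cannot be classified (Unknown/Unspecified or a
     "?"-suffixed class/family);
ii)  drop regions on sex chromosomes or inside exclusion (blacklist) regions;
iii) drop regions with zero fragment coverage in more than 80% of the
     discovery-cohort samples;
iv)  drop regions with zero coverage in a designated reference-plasma sample;
v)   drop whole families whose genome-wide instance count (taken from the
     unfiltered annotation) is below a minimum.

An audit records how many regions each step removed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .fragments import Fragment

__all__ = [
    "RepeatRegion",
    "StrLocus",
    "CfreCatalog",
    "parse_rmsk",
    "write_rmsk",
    "region_fragment_counts",
    "filter_cfre",
    "build_str_subgroups",
    "subset_by_annotation",
    "DEFAULT_SPAN_EDGES",
]

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})
_UNCLASSIFIED = frozenset({"Unknown", "Unspecified", ""})
_STR_NAME = re.compile(r"^\(([ACGTNacgtn]+)\)(\d*)n?$")

#: default STR span bin edges (bp): [0,20), [20,30), ... [190,200), [200,inf)
DEFAULT_SPAN_EDGES: tuple[int, ...] = tuple(range(20, 201, 10))


@dataclass(slots=True)
class RepeatRegion:
    chrom: str
    start: int
    end: int
    strand: str
    rep_name: str
    rep_class: str
    rep_family: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.rep_name}: start >= end")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def family_key(self) -> str:
        return self.rep_family if self.rep_family not in _UNCLASSIFIED else self.rep_class


@dataclass(slots=True)
class StrLocus(RepeatRegion):
    """A short-tandem-repeat locus: ``motif`` repeated ~``n2`` times."""

    motif: str = ""
    n2: int = 0

    @property
    def n1(self) -> int:
        return len(self.motif)

    @property
    def family_key(self) -> str:  # STRs are grouped as one Simple_repeat family
        return "Simple_repeat"


def _is_unclassified(region: RepeatRegion) -> bool:
    for label in (region.rep_class, region.rep_family):
        if label in _UNCLASSIFIED or label.endswith("?"):
            return True
    return False


def parse_rmsk(path: str | Path) -> list[RepeatRegion]:
    """Parse an rmsk table into repeat regions / STR loci.

    Accepts either the 7-column dialect or the full UCSC table (>=15 cols,
    detected by column count).  Simple_repeat rows with a ``(MOTIF)n``
    repName become :class:`StrLocus` with ``n2`` inferred from the span.
    """
    regions: list[RepeatRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if len(parts) >= 15:  # full UCSC rmsk table
                    chrom, start, end = parts[5], int(parts[6]), int(parts[7])
                    strand, name = parts[9], parts[10]
                    rclass, rfamily = parts[11], parts[12]
                else:
                    chrom, start, end, strand, name, rclass, rfamily = parts[:7]
                    start, end = int(start), int(end)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed rmsk row") from exc
            regions.append(make_region(chrom, start, end, strand, name, rclass, rfamily))
    return regions


def make_region(
    chrom: str,
    start: int,
    end: int,
    strand: str,
    rep_name: str,
    rep_class: str,
    rep_family: str,
) -> RepeatRegion:
    """Build a RepeatRegion, promoting STR-encoded names to StrLocus."""
    m = _STR_NAME.match(rep_name) if rep_class == "Simple_repeat" else None
    if m:
        motif = m.group(1).upper()
        n2 = max(1, round((end - start) / len(motif)))
        return StrLocus(chrom, start, end, strand, rep_name, rep_class, rep_family,
                        motif=motif, n2=n2)
    return RepeatRegion(chrom, start, end, strand, rep_name, rep_class, rep_family)


def write_rmsk(regions: Iterable[RepeatRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\n")
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t"
                f"{r.rep_name}\t{r.rep_class}\t{r.rep_family}\n"
            )


def _interval_trees(regions: Sequence[RepeatRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, r in enumerate(regions):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, idx)
    return trees


def region_fragment_counts(
    regions: Sequence[RepeatRegion], fragments: Iterable[Fragment]
) -> np.ndarray:
    """Fragments overlapping (>=1 bp, half-open) each region."""
    trees = _interval_trees(regions)
    counts = np.zeros(len(regions), dtype=np.int64)
    for frag in fragments:
        tree = trees.get(frag.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(frag.start, frag.end):
            counts[iv.data] += 1
    return counts


@dataclass
class CfreCatalog:
    """Filtered region set grouped by family, with an STR sub-group index."""

    regions: list[RepeatRegion]
    family_counts: dict[str, int] = field(default_factory=dict)
    audit: dict[str, int] = field(default_factory=dict)
    subgroups: dict[tuple[int, str], list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._trees: dict[str, IntervalTree] | None = None

    @property
    def families(self) -> dict[str, list[int]]:
        fams: dict[str, list[int]] = {}
        for idx, r in enumerate(self.regions):
            fams.setdefault(r.family_key, []).append(idx)
        return fams

    @property
    def str_loci(self) -> list[int]:
        return [i for i, r in enumerate(self.regions) if isinstance(r, StrLocus)]

    def interval_trees(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            self._trees = _interval_trees(self.regions)
        return self._trees


def filter_cfre(
    regions: Sequence[RepeatRegion],
    coverage: Mapping[str, np.ndarray],
    *,
    reference_sample: str | None = None,
    exclusion: Sequence[tuple[str, int, int]] = (),
    sex_chroms: frozenset[str] = SEX_CHROMS,
    zero_cov_sample_frac: float = 0.8,
    min_family_instances: int = 500,
    require_reference: bool = True,
) -> CfreCatalog:
    """Apply the five cfRE filtering steps and return the surviving catalog.

    Parameters
    ----------
    coverage
        Per-sample fragment counts aligned to ``regions`` (discovery cohort;
        the reference sample may be included under its own id).
    reference_sample
        Sample id whose zero-coverage regions are removed at step iv.  Set
        ``require_reference=False`` to disable that step.
    """
    if require_reference:
        if reference_sample is None or reference_sample not in coverage:
            raise ValueError(
                "reference sample coverage required for step iv "
                "(pass require_reference=False to disable)"
            )
    discovery = {k: np.asarray(v) for k, v in coverage.items() if k != reference_sample}
    if not discovery:
        raise ValueError("at least one discovery-cohort sample is required")

    # family instance counts from the UNFILTERED annotation (genome-wide)
    family_counts: dict[str, int] = {}
    for r in regions:
        family_counts[r.family_key] = family_counts.get(r.family_key, 0) + 1

    excl_trees: dict[str, IntervalTree] = {}
    for chrom, start, end in exclusion:
        excl_trees.setdefault(chrom, IntervalTree()).addi(start, end)

    n_samples = len(discovery)
    zero_frac = np.zeros(len(regions))
    for counts in discovery.values():
        zero_frac += np.asarray(counts) == 0
    zero_frac /= n_samples
    ref_counts = (
        np.asarray(coverage[reference_sample])
        if require_reference and reference_sample is not None
        else None
    )

    audit = {"i_unclassified": 0, "ii_excluded": 0, "iii_zero_coverage": 0,
             "iv_reference_zero": 0, "v_rare_family": 0}
    survivors: list[RepeatRegion] = []
    for idx, region in enumerate(regions):
        if _is_unclassified(region):
            audit["i_unclassified"] += 1
            continue
        in_excl = region.chrom in sex_chroms
        if not in_excl:
            tree = excl_trees.get(region.chrom)
            in_excl = bool(tree and tree.overlap(region.start, region.end))
        if in_excl:
            audit["ii_excluded"] += 1
            continue
        if zero_frac[idx] > zero_cov_sample_frac:  # strictly "more than"
            audit["iii_zero_coverage"] += 1
            continue
        if ref_counts is not None and ref_counts[idx] == 0:
            audit["iv_reference_zero"] += 1
            continue
        if family_counts[region.family_key] < min_family_instances:
            audit["v_rare_family"] += 1
            continue
        survivors.append(region)

    return CfreCatalog(survivors, family_counts=family_counts, audit=audit)


def span_bin_label(span: int, edges: Sequence[int] = DEFAULT_SPAN_EDGES) -> str:
    """Bin label for an STR span, e.g. '20-29' or '200+'."""
    prev = 0
    for edge in edges:
        if span < edge:
            return f"{prev}-{edge - 1}"
        prev = edge
    return f"{edges[-1]}+"


def build_str_subgroups(
    catalog: CfreCatalog, edges: Sequence[int] = DEFAULT_SPAN_EDGES
) -> dict[tuple[int, str], list[int]]:
    """Partition STR loci into (unit length, span bin) sub-groups.

    Sub-groups are keyed by ``(n1, span_label)``; empty sub-groups are
    omitted, and every STR locus lands in exactly one sub-group.
    """
    groups: dict[tuple[int, str], list[int]] = {}
    for idx in catalog.str_loci:
        locus = catalog.regions[idx]
        key = (locus.n1, span_bin_label(locus.span, edges))
        groups.setdefault(key, []).append(idx)
    catalog.subgroups = dict(sorted(groups.items()))
    return catalog.subgroups


def subset_by_annotation(
    catalog: CfreCatalog, annotation: Sequence[tuple[str, int, int]]
) -> CfreCatalog:
    """Restrict the catalog to regions sharing >=1 bp with the annotation."""
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in annotation:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    keep = [
        r
        for r in catalog.regions
        if (tree := trees.get(r.chrom)) and tree.overlap(r.start, r.end)
    ]
    sub = CfreCatalog(keep, family_counts=dict(catalog.family_counts),
                      audit=dict(catalog.audit))
    if catalog.subgroups:
        build_str_subgroups(sub)
    return sub
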