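"""Per-sample fragmentomic features over repeat families.

Four scores are computed per repeat family for each sample:

* **FR** — fraction of qualified fragments overlapping the family's regions
  relative to all qualified fragments of the sample; a fragment overlapping
  several families counts once in each family's numerator.
* **FL** — ratio of short (<150 bp) to long (>=150 bp) fragments among the
  family's fragments; missing when no long fragment is present.  A length of
  exactly 150 bp counts as long, so the dichotomy is a complete partition.
* **FD** — fraction of the family's regions covered by at least one fragment.
* **FC** — median linguistic complexity of the read sequences mapped to the
  family (even counts average the central pair).

All four are produced in a single pass over the fragments using the
catalog's interval index; STR-locus expansion observations are collected in
the same pass when sub-groups are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

from .catalog import CfreCatalog, StrLocus
from .complexity import linguistic_complexity
from .expansion import ExpansionObservation, count_units
from .fragments import Fragment

__all__ = [
    "FamilyScores",
    "SampleFeatures",
    "fr_score",
    "fl_score",
    "fd_score",
    "fc_score",
    "compute_sample_features",
    "SHORT_LENGTH_BP",
]

#: fragments strictly shorter than this are "short"; >= counts as long
SHORT_LENGTH_BP = 150


def fr_score(n_family_fragments: int, n_total: int) -> float:
    """Fraction of qualified fragments mapped to the family's regions."""
    if n_total <= 0:
        raise ValueError("FR is undefined for a sample with no qualified fragments")
    return n_family_fragments / n_total


def fl_score(lengths: Iterable[int]) -> float | None:
    """Short/long fragment-count ratio; None when no long fragment exists."""
    short = long = 0
    for length in lengths:
        if length < SHORT_LENGTH_BP:
            short += 1
        else:
            long += 1
    return short / long if long else None


def fd_score(n_covered: int, n_regions: int) -> float:
    """Fraction of the family's regions with non-zero fragment coverage."""
    if n_regions <= 0:
        raise ValueError("FD is undefined for an empty family")
    return n_covered / n_regions


def fc_score(sequences: Sequence[str]) -> float | None:
    """Median linguistic complexity of the mapped read sequences."""
    if not sequences:
        return None
    return float(median(linguistic_complexity(s) for s in sequences))


@dataclass
class FamilyScores:
    fr: float = 0.0
    fl: float | None = None
    fd: float = 0.0
    fc: float | None = None
    n_fragments: int = 0


@dataclass
class SampleFeatures:
    """Per-family score table for one sample plus STR expansion tallies."""

    sample_id: str
    total_fragments: int
    families: dict[str, FamilyScores] = field(default_factory=dict)
    observations: dict[int, ExpansionObservation] = field(default_factory=dict)


def compute_sample_features(
    fragments: Sequence[Fragment],
    catalog: CfreCatalog,
    *,
    sample_id: str = "",
    collect_observations: bool = True,
    fc_max_reads: int | None = None,
) -> SampleFeatures:
    """Compute FR/FL/FD/FC per family (and STR tallies) for one sample.

    ``fc_max_reads`` caps the number of read sequences entering the FC
    median per family; the cap selects reads by sorted fragment name so the
    result does not depend on input order.
    """
    if not fragments:
        raise ValueError(f"sample {sample_id!r} has no qualified fragments")
    trees = catalog.interval_trees()
    families = catalog.families
    counts: dict[str, int] = {key: 0 for key in families}
    lengths: dict[str, list[int]] = {key: [] for key in families}
    covered: dict[str, set[int]] = {key: set() for key in families}
    seqs: dict[str, list[tuple[str, str]]] = {key: [] for key in families}
    observations: dict[int, ExpansionObservation] = {}

    for frag in fragments:
        tree = trees.get(frag.chrom)
        if tree is None:
            continue
        hit_families: set[str] = set()
        for iv in tree.overlap(frag.start, frag.end):
            idx = iv.data
            region = catalog.regions[idx]
            key = region.family_key
            covered[key].add(idx)
            hit_families.add(key)
            if collect_observations and isinstance(region, StrLocus):
                units = count_units(frag, region)
                if units:
                    obs = observations.setdefault(idx, ExpansionObservation(idx))
                    obs.N += 1
                    if units > region.n2:
                        obs.N_ETR += 1
                    elif (units < region.n2 and frag.start <= region.start
                          and frag.end >= region.end):
                        obs.N_contracted += 1
        for key in hit_families:
            counts[key] += 1
            lengths[key].append(frag.length)
            if frag.sequence:
                seqs[key].append((frag.name, frag.sequence))

    result = SampleFeatures(sample_id, len(fragments), observations=observations)
    for key, idxs in families.items():
        family_seqs = sorted(seqs[key])
        if fc_max_reads is not None:
            family_seqs = family_seqs[:fc_max_reads]
        result.families[key] = FamilyScores(
            fr=fr_score(counts[key], len(fragments)),
            fl=fl_score(lengths[key]),
            fd=fd_score(len(covered[key]), len(idxs)),
            fc=fc_score([s for _, s in family_seqs]),
            n_fragments=counts[key],
        )
    return result
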