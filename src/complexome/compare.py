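"""Comparison of complex datasets at protein, complex and pair level.

Two datasets are compared three ways: shared proteins; complexes matched by
Jaccard index over unique protein members at a chosen stringency (1.0 =
identical composition, lower thresholds admit partial matches, in which case
one complex may match several partners and match totals can exceed dataset
sizes); and the fraction of one dataset's co-complex pairs contained in the
other. Per-dataset size statistics (mean/median over complexes of size >= 3,
homomer and dimer counts, size histogram) round out the picture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean, median

from .io import ComplexDataset
from .pairs import cocomplex_pairs

__all__ = [
    "ComplexMatch",
    "SizeStats",
    "jaccard_index",
    "match_complexes",
    "protein_overlap",
    "pair_overlap_matrix",
    "size_statistics",
    "proteins_per_complex_distribution",
]


@dataclass(frozen=True)
class ComplexMatch:
    id_a: str
    id_b: str
    jaccard: float


@dataclass
class SizeStats:
    """Per-dataset size summary.

    ``mean_size``/``median_size`` are computed only over complexes with at
    least three unique protein members, so datasets that cannot contain
    dimers by construction remain comparable with curated ones.
    """

    n_complexes: int
    n_proteins: int
    max_size: int
    max_size_excluding: int
    mean_size: float
    median_size: float
    n_homomers: int
    n_dimers: int
    size_histogram: dict[int, int] = field(default_factory=dict)


def jaccard_index(set_a: frozenset[str] | set[str], set_b: frozenset[str] | set[str]) -> float:
    """|A n B| / |A u B| over unique protein members; symmetric, in [0, 1]."""
    if not set_a or not set_b:
        raise ValueError("jaccard_index requires nonempty sets")
    sa, sb = set(set_a), set(set_b)
    return len(sa & sb) / len(sa | sb)


def match_complexes(
    ds_a: ComplexDataset,
    ds_b: ComplexDataset,
    threshold: float = 1.0,
    min_size: int = 3,
) -> tuple[list[ComplexMatch], float, float]:
    """All cross-dataset complex pairs with Jaccard index >= threshold.

    Only complexes with >= ``min_size`` unique proteins enter on either side
    (numerator and denominator alike). Returns the matches plus the matched
    fraction per dataset: the share of its eligible complexes with at least
    one partner. No one-to-one assignment is attempted, so at thresholds
    below 1 the number of matches may exceed either dataset's size.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    sets_a = ds_a.protein_sets(min_size=min_size)
    sets_b = ds_b.protein_sets(min_size=min_size)
    matches: list[ComplexMatch] = []
    hit_a: set[str] = set()
    hit_b: set[str] = set()
    for ida, sa in sets_a.items():
        for idb, sb in sets_b.items():
            ji = jaccard_index(sa, sb)
            if ji >= threshold:
                matches.append(ComplexMatch(ida, idb, ji))
                hit_a.add(ida)
                hit_b.add(idb)
    frac_a = len(hit_a) / len(sets_a) if sets_a else 0.0
    frac_b = len(hit_b) / len(sets_b) if sets_b else 0.0
    return matches, frac_a, frac_b


def protein_overlap(ds_a: ComplexDataset, ds_b: ComplexDataset) -> dict:
    """Shared and unique protein counts plus per-dataset shared fractions."""
    pa, pb = ds_a.proteins(), ds_b.proteins()
    shared = pa & pb
    return {
        "shared": len(shared),
        "unique_a": len(pa - pb),
        "unique_b": len(pb - pa),
        "fraction_a": len(shared) / len(pa) if pa else 0.0,
        "fraction_b": len(shared) / len(pb) if pb else 0.0,
    }


def pair_overlap_matrix(datasets: list[ComplexDataset]) -> dict[str, dict[str, float]]:
    """Fraction of dataset i's co-complex pairs found among dataset j's.

    Asymmetric; the diagonal is exactly 1. Row dataset supplies the
    denominator, column dataset the containing pair set.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    pair_sets = {ds.dataset_name: cocomplex_pairs(ds).pairs for ds in datasets}
    out: dict[str, dict[str, float]] = {}
    for ds_i in datasets:
        row: dict[str, float] = {}
        pi = pair_sets[ds_i.dataset_name]
        for ds_j in datasets:
            pj = pair_sets[ds_j.dataset_name]
            row[ds_j.dataset_name] = len(pi & pj) / len(pi) if pi else 0.0
        out[ds_i.dataset_name] = row
    return out


def size_statistics(
    ds: ComplexDataset, exclude_ids: set[str] | None = None
) -> SizeStats:
    """Size summary of a dataset; ``exclude_ids`` (e.g. the paralog-inflated
    ribosomal subunits) are left out of the secondary maximum only."""
    if not ds.records:
        raise ValueError("empty dataset")
    sizes = [rec.size for rec in ds.records]
    sizes_excl = [rec.size for rec in ds.records if not exclude_ids or rec.complex_id not in exclude_ids]
    big = [s for s in sizes if s >= 3]
    hist: dict[int, int] = {}
    for s in sizes:
        hist[s] = hist.get(s, 0) + 1
    return SizeStats(
        n_complexes=len(ds.records),
        n_proteins=len(ds.proteins()),
        max_size=max(sizes),
        max_size_excluding=max(sizes_excl) if sizes_excl else 0,
        mean_size=mean(big) if big else float("nan"),
        median_size=float(median(big)) if big else float("nan"),
        n_homomers=sum(1 for s in sizes if s == 1),
        n_dimers=sum(1 for s in sizes if s == 2),
        size_histogram=dict(sorted(hist.items())),
    )


def proteins_per_complex_distribution(ds: ComplexDataset) -> tuple[dict[int, int], float]:
    """Histogram of how many complexes each protein occurs in.

    Returns ``{occurrence count: number of proteins}`` and the fraction of
    proteins found in exactly one complex (the multifunctionality summary:
    in real complexomes well over 70% of proteins sit in a single complex,
    with a short right tail of multi-complex proteins).
    """
    counts: dict[str, int] = {}
    for rec in ds.records:
        for p in rec.protein_members:
            counts[p] = counts.get(p, 0) + 1
    hist: dict[int, int] = {}
    for c in counts.values():
        hist[c] = hist.get(c, 0) + 1
    frac_one = hist.get(1, 0) / len(counts) if counts else float("nan")
    return dict(sorted(hist.items())), frac_one
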